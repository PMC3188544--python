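"""File formats: summary-statistic TSV, phased VCF, hap/legend, cohorts, YAML.

Coordinates are 1-based inclusive bp throughout (VCF convention) and
alleles are reported on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import AssocResult
from .errors import SchemaError
from .panels import HaplotypePanel
from .simulate import Cohort, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SUMMARY_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize_alleles",
    "write_vcf",
    "read_vcf",
    "write_hap_legend",
    "read_hap_legend",
    "write_cohort",
    "read_cohort",
    "load_sim_config",
    "save_sim_config",
]

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# frequency zone in which a strand-ambiguous (A/T or C/G) SNP cannot be
# oriented by allele frequency
AMBIGUOUS_FREQ_ZONE = (0.42, 0.58)


def _is_ambiguous_pair(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


# -- summary statistics ------------------------------------------------------


def write_summary_stats(table: pd.DataFrame, path) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"summary table missing columns: {missing}")
    # %.17g keeps doubles bit-exact across a write/read round trip
    table[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False,
                                  float_format="%.17g")


def read_summary_stats(path) -> pd.DataFrame:
    """Typed per-SNP association records from a tab-separated file.

    Requires the header columns SNP, CHR, POS, EA, OA, EAF, BETA, SE, P,
    N.  Alleles are upper-cased; rows with non-positive SE are rejected
    with line-numbered log records; duplicated CHR:POS entries whose
    allele pairs are strand complements are flagged as warnings.  The
    rejected line numbers are available as ``df.attrs["rejected_lines"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str},
                     float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df["EA"] = df["EA"].str.upper()
    df["OA"] = df["OA"].str.upper()
    bad = ~(df["SE"] > 0)
    rejected = []
    if bad.any():
        for i in np.flatnonzero(bad.to_numpy()):
            rejected.append(int(i) + 2)  # 1-based line number incl. header
            logger.error("%s line %d: SE <= 0, row rejected", path, int(i) + 2)
        df = df[~bad].reset_index(drop=True)
    dup_warnings = []
    for (_, _), grp in df.groupby(["CHR", "POS"]):
        if len(grp) < 2:
            continue
        pairs = grp[["EA", "OA"]].to_numpy()
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                flipped = {_COMPLEMENT[pairs[j][0]], _COMPLEMENT[pairs[j][1]]}
                if {pairs[i][0], pairs[i][1]} == flipped:
                    msg = (
                        f"duplicate position {grp['CHR'].iat[0]}:{grp['POS'].iat[0]}"
                        " with strand-complementary allele pairs"
                    )
                    logger.warning("%s: %s", path, msg)
                    dup_warnings.append(msg)
    df.attrs["rejected_lines"] = rejected
    df.attrs["duplicate_position_warnings"] = dup_warnings
    return df


def write_proxy_sets(proxy_sets, path) -> None:
    """Proxy sets as TSV: INDEX, INDEX_ALLELE, PROXY, R2, PREDICTED_ALLELE."""
    rows = []
    for ps in proxy_sets:
        if not ps.resolvable:
            continue
        for m in ps.members:
            rows.append(
                {"INDEX": ps.index, "INDEX_ALLELE": ps.index_allele,
                 "PROXY": m.snp, "R2": m.r2,
                 "PREDICTED_ALLELE": m.predicted_allele}
            )
    pd.DataFrame(
        rows, columns=["INDEX", "INDEX_ALLELE", "PROXY", "R2",
                       "PREDICTED_ALLELE"]
    ).to_csv(path, sep="\t", index=False)


def write_qq_table(qq, path) -> None:
    """QQ data (expected, observed, band) as TSV; no plotting required."""
    pd.DataFrame(
        {"EXPECTED": qq.expected, "OBSERVED": qq.observed,
         "LOWER": qq.lower, "UPPER": qq.upper}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def summary_records(table: pd.DataFrame) -> list:
    """Rows of a summary table as typed :class:`AssocResult` records."""
    return [
        AssocResult(
            snp=r.SNP, effect_allele=r.EA, other_allele=r.OA, eaf=float(r.EAF),
            beta=float(r.BETA), se=float(r.SE), p=float(r.P), n=int(r.N),
        )
        for r in table.itertuples(index=False)
    ]


def harmonize_alleles(record: AssocResult, panel_variant) -> AssocResult | None:
    """Align a summary record's effect allele to a panel variant's alt allele.

    ``panel_variant`` is a mapping with ``ref``, ``alt`` and (for
    ambiguous pairs) ``alt_freq``.  Swapping effect and other allele
    negates beta and complements the frequency; strand flips are
    resolved by complementing for non-ambiguous pairs.  A/T and C/G SNPs
    are oriented by comparing frequencies, and dropped (None) when the
    effect-allele frequency falls in the ambiguous zone
    (0.42, 0.58).
    """
    ref, alt = panel_variant["ref"].upper(), panel_variant["alt"].upper()
    ea, oa = record.effect_allele.upper(), record.other_allele.upper()

    def swapped(r: AssocResult) -> AssocResult:
        return replace(
            r, effect_allele=r.other_allele, other_allele=r.effect_allele,
            beta=-r.beta, eaf=1.0 - r.eaf,
        )

    if _is_ambiguous_pair(ea, oa):
        if {ea, oa} != {ref, alt}:
            logger.warning("%s: ambiguous pair does not match panel; dropped",
                           record.snp)
            return None
        lo, hi = AMBIGUOUS_FREQ_ZONE
        if lo < record.eaf < hi:
            logger.warning(
                "%s: strand-ambiguous SNP with EAF %.2f in (%.2f, %.2f); dropped",
                record.snp, record.eaf, lo, hi,
            )
            return None
        alt_freq = panel_variant["alt_freq"]
        # orient so the effect allele's frequency matches the panel alt freq
        direct_err = abs(record.eaf - alt_freq)
        swap_err = abs((1.0 - record.eaf) - alt_freq)
        rec = record if direct_err <= swap_err else swapped(record)
        return replace(rec, effect_allele=alt, other_allele=ref)

    if (ea, oa) == (alt, ref):
        return record
    if (ea, oa) == (ref, alt):
        return swapped(record)
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (alt, ref):
        return replace(record, effect_allele=alt, other_allele=ref)
    if (cea, coa) == (ref, alt):
        return replace(swapped(record), effect_allele=alt, other_allele=ref)
    logger.warning("%s: alleles %s/%s do not match panel %s/%s; dropped",
                   record.snp, ea, oa, ref, alt)
    return None


# -- phased VCF --------------------------------------------------------------


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a phased VCF (GT fields like ``0|1``)."""
    n_ind = panel.n_haplotypes // 2
    samples = [f"{panel.population or 'SAMPLE'}{i + 1}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=transheight\n##population={panel.population}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for i, row in panel.variants.iterrows():
            gts = "\t".join(
                f"{H[i, 2 * k]}|{H[i, 2 * k + 1]}" for k in range(n_ind)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, population: str = "") -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel` (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows = []
    haps = []
    for v in vcf:
        rows.append(
            {"chrom": v.CHROM, "pos": v.POS, "id": v.ID,
             "ref": v.REF, "alt": v.ALT[0]}
        )
        gt = np.asarray(v.genotypes)[:, :2]  # (n_ind, 2 alleles)
        haps.append(gt.reshape(-1))
    vcf.close()
    return HaplotypePanel(
        variants=pd.DataFrame(rows),
        haplotypes=np.asarray(haps, dtype=np.uint8),
        population=population,
    )


# -- IMPUTE-style hap/legend -------------------------------------------------


def write_hap_legend(panel: HaplotypePanel, prefix) -> None:
    """Write ``<prefix>.hap`` (space-separated 0/1) and ``<prefix>.legend``."""
    prefix = str(prefix)
    np.savetxt(prefix + ".hap", panel.haplotypes, fmt="%d")
    leg = panel.variants[["id", "pos", "ref", "alt"]].rename(
        columns={"id": "id", "pos": "position", "ref": "a0", "alt": "a1"}
    )
    leg.to_csv(prefix + ".legend", sep=" ", index=False)


def read_hap_legend(prefix, chrom: str = "1", population: str = "") -> HaplotypePanel:
    prefix = str(prefix)
    H = np.loadtxt(prefix + ".hap", dtype=np.uint8, ndmin=2)
    leg = pd.read_csv(prefix + ".legend", sep=r"\s+")
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": leg["position"], "id": leg["id"],
         "ref": leg["a0"], "alt": leg["a1"]}
    )
    return HaplotypePanel(variants=variants, haplotypes=H, population=population)


# -- cohorts -----------------------------------------------------------------


def write_cohort(cohort: Cohort, directory) -> None:
    """Cohort as individuals TSV + genotype/ancestry matrix text files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ind = cohort.individuals.copy()
    if cohort.height is not None:
        ind["height"] = cohort.height
    ind.to_csv(d / "individuals.tsv", sep="\t", index=False)
    cohort.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
    np.savetxt(d / "genotypes.txt", cohort.genotypes, fmt="%d")
    np.savetxt(d / "local_ancestry.txt", cohort.local_ancestry, fmt="%d")


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    ind = pd.read_csv(d / "individuals.tsv", sep="\t")
    height = ind.pop("height").to_numpy() if "height" in ind.columns else None
    return Cohort(
        variants=pd.read_csv(d / "variants.tsv", sep="\t"),
        genotypes=np.loadtxt(d / "genotypes.txt", dtype=np.int8, ndmin=2),
        individuals=ind,
        local_ancestry=np.loadtxt(d / "local_ancestry.txt", dtype=np.uint8, ndmin=2),
        height=height,
    )


# -- configuration -----------------------------------------------------------


def save_sim_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_sim_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
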