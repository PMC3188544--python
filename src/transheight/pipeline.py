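"""End-to-end synthetic experiment: simulate -> associate -> meta ->
replicate/fine-map -> eQTL enrichment.

Every stage draws from seeded substreams recorded in the run log, so a
run directory is reproducible bit-for-bit from its configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, io, meta
from .errors import InvalidConfigError, TransheightError
from .ld import LDCache
from .replication import (
    ReplicationEngine,
    fine_map_best,
    generate_matched_sets,
    run_replication,
)
from .eqtl import enrichment_test
from .simulate import (
    SimulationConfig,
    simulate_admixed_cohort,
    simulate_panels,
    simulate_phenotype,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and sizes of the full synthetic pipeline.

    The LD and significance thresholds default to the study's stated
    values: proxies at r^2 >= 0.8, bins at r^2 >= 0.3, null-set
    independence at r^2 < 0.2, nominal alpha 0.05, genome-wide
    significance 5e-8, follow-up threshold 1e-5, eQTL threshold 0.01.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    r2_proxy: float = 0.8
    r2_bin: float = 0.3
    r2_indep: float = 0.2
    alpha: float = 0.05
    genomewide_p: float = 5e-8
    followup_p: float = 1e-5
    eqtl_p: float = 0.01
    maf_tol: float = 0.02
    n_loci: int = 100
    n_causal: int = 40
    effect_range: tuple = (0.05, 0.10)
    n_sets: int = 200
    n_sims: int = 100
    eqtl_enrichment: float = 0.5   # P(planted eQTL) for causal-locus proxies
    seed: int = 0

    def __post_init__(self):
        for name in ("r2_proxy", "r2_bin", "r2_indep", "alpha", "eqtl_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidConfigError(f"{name} must be in (0, 1], got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["effect_range"] = list(self.effect_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        if "effect_range" in d:
            d["effect_range"] = tuple(d["effect_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _study_association(cohort, labels, study, covar_cols=("sex", "age", "disease")):
    """One study's scan: Z-scored height on genotype + global ancestry.

    The mean European dosage per individual serves as the global-ancestry
    covariate, standing in for the principal-component admixture
    correction (local-ancestry truth consumed as a generic covariate).
    """
    mask = labels == study
    ind = cohort.individuals[mask]
    z = association.zscore_transform(
        pd.DataFrame({"height": cohort.height[mask]}).join(
            ind[list(covar_cols)].reset_index(drop=True)
        ),
        covariates=covar_cols,
    )
    G = cohort.genotypes[mask].astype(float)
    if (G < 0).any():
        G[G < 0] = np.nan
        G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    global_anc = cohort.local_ancestry[mask].mean(axis=1)
    return association.scan(z, G, covariates=global_anc, variants=cohort.variants)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage into ``outdir``; returns the JSON-able summary.

    Writes per-study summary TSVs, the meta-analysis TSV, the
    replication report, fine-mapping table, eQTL enrichment result, a
    ``summary.json`` and a ``run.log`` that records each stage's seed
    and thresholds.  Identical config + seed reproduce identical
    outputs; any stage failure aborts with a stage-named error.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("transheight")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ["simulate", "phenotype", "replication", "eqtl", "causal"],
            ss.spawn(5),
        )
    }
    logger.info("stage seeds: %s", stage_seeds)
    logger.info(
        "thresholds: r2_proxy=%g r2_bin=%g r2_indep=%g alpha=%g "
        "genomewide=%g followup=%g eqtl=%g",
        config.r2_proxy, config.r2_bin, config.r2_indep, config.alpha,
        config.genomewide_p, config.followup_p, config.eqtl_p,
    )

    try:
        stage = "simulate"
        sim = config.sim
        source, target = simulate_panels(sim, seed=stage_seeds["simulate"])
        cohort = simulate_admixed_cohort(
            (source, target), sim, seed=stage_seeds["simulate"]
        )
        io.write_vcf(source, out / "panel_source.vcf")
        io.write_vcf(target, out / "panel_target.vcf")

        stage = "phenotype"
        rng = np.random.default_rng(stage_seeds["causal"])
        causal = list(sim.causal_effects)
        if not causal and config.n_causal > 0:
            maf = target.maf()
            common = np.flatnonzero(maf >= 0.05)
            picks = rng.choice(common, size=min(config.n_causal, common.size),
                               replace=False)
            lo, hi = config.effect_range
            betas = rng.uniform(lo, hi, picks.size) * rng.choice([-1, 1], picks.size)
            ids = target.variants["id"].to_numpy()
            causal = [(ids[k], float(b)) for k, b in zip(picks, betas)]
        sim_eff = SimulationConfig.from_dict(
            {**sim.to_dict(), "causal_effects": [list(c) for c in causal]}
        )
        cohort = simulate_phenotype(cohort, sim_eff, seed=stage_seeds["phenotype"])
        logger.info("phenotype: %d causal variants", len(causal))

        stage = "association"
        labels = cohort.study_labels()
        studies = []
        lambdas = {}
        for j, study in enumerate(sorted(set(labels))):
            tab = _study_association(cohort, labels, study)
            ok = tab["P"].notna()
            lam = meta.genomic_control_lambda(tab.loc[ok, "P"])
            lambdas[study] = lam.lambda_gc
            tab = meta.gc_correct_table(tab, lam)
            io.write_summary_stats(tab[ok], out / f"assoc_{study}.tsv")
            studies.append(tab[ok])
        summary["lambda_per_study"] = {k: round(v, 4) for k, v in lambdas.items()}

        stage = "meta"
        meta_tab = meta.meta_analyze(studies)
        lam_meta = meta.genomic_control_lambda(meta_tab["P"])
        meta_tab = meta.gc_correct_table(meta_tab, lam_meta)
        meta_tab.to_csv(out / "meta.tsv", sep="\t", index=False)
        io.write_qq_table(
            meta.qq_with_bands(meta_tab["P"].dropna(), n_permutations=100,
                               seed=stage_seeds["simulate"]),
            out / "qq.tsv",
        )
        summary["lambda_meta"] = round(lam_meta.lambda_gc, 4)
        summary["n_genomewide"] = int((meta_tab["P"] < config.genomewide_p).sum())
        summary["n_followup"] = int((meta_tab["P"] < config.followup_p).sum())

        stage = "replication"
        src_ld = LDCache(source)
        tgt_ld = LDCache(target)
        engine = ReplicationEngine(
            src_ld, tgt_ld, r2_proxy=config.r2_proxy, r2_bin=config.r2_bin
        )
        maf = source.maf()
        ids = source.variants["id"].to_numpy()
        alt = dict(zip(ids, source.variants["alt"]))
        ref = dict(zip(ids, source.variants["ref"]))
        causal_ids = {s for s, _ in causal}
        causal_sign = {s: b for s, b in causal}
        rng_rep = np.random.default_rng(stage_seeds["replication"])
        common = [s for s, m in zip(ids, maf) if m >= 0.05]
        # index list: the truly causal loci plus independent null fillers,
        # emulating a known-locus list from a source-population discovery
        index = [s for s in common if s in causal_ids]
        blocked = set(index)
        for s in index:
            blocked.update(
                ids[r] for r in src_ld.neighbors(src_ld.index_of(s), config.r2_indep)
            )
        fillers = [s for s in common if s not in blocked]
        rng_rep.shuffle(fillers)
        picked = []
        for s in fillers:
            if len(index) + len(picked) >= config.n_loci:
                break
            if s in blocked:
                continue
            picked.append(s)
            blocked.add(s)
            blocked.update(
                ids[r] for r in src_ld.neighbors(src_ld.index_of(s), config.r2_indep)
            )
        index += picked
        pairs = []
        for s in index:
            if s in causal_sign:
                inc = alt[s] if causal_sign[s] > 0 else ref[s]
            else:
                inc = alt[s] if rng_rep.integers(2) else ref[s]
            pairs.append((s, inc))
        beta_lookup = dict(zip(meta_tab["SNP"], meta_tab["BETA"]))
        p_lookup = dict(zip(meta_tab["SNP"], meta_tab["P"]))
        if config.n_sets > 0:
            report = run_replication(
                pairs, src_ld, tgt_ld, meta_tab, n_sets=config.n_sets,
                seed=stage_seeds["replication"], r2_proxy=config.r2_proxy,
                r2_bin=config.r2_bin, r2_indep=config.r2_indep,
                maf_tol=config.maf_tol, alpha=config.alpha, engine=engine,
            )
            summary["replication"] = report.summary()
            pd.DataFrame(
                [
                    {"INDEX": d.index, "N_PROXIES": d.n_proxies,
                     "N_BINS": d.n_bins, "N_SIGNIFICANT": d.n_significant,
                     "BEST_ONE_TAILED_P": d.best_one_tailed_p}
                    for d in report.per_locus
                ]
            ).to_csv(out / "replication.tsv", sep="\t", index=False)
        else:
            logger.info("replication skipped: n_sets = 0")
            summary["replication"] = "skipped (n_sets=0)"

        stage = "finemap"
        fine_rows = []
        best_by_locus = {}
        for s, inc in pairs:
            loc = engine.locus_proxies(s)
            if loc is None:
                continue
            flip = 1.0 if inc == alt[s] else -1.0
            p1 = {}
            for snp_id, sgn in zip(loc["ids"], loc["signs"] * flip):
                b, p2 = beta_lookup.get(snp_id), p_lookup.get(snp_id)
                if b is None or p2 is None or not np.isfinite(p2):
                    continue
                obs = np.sign(b) * sgn
                p1[snp_id] = 0.5 if obs == 0 else (
                    p2 / 2.0 if obs > 0 else 1.0 - p2 / 2.0
                )
            res = fine_map_best(
                loc["ids"], tgt_ld, p1, r2_bin=config.r2_bin,
                bonferroni_m=len(pairs),
            )
            if res is None:
                continue
            best_by_locus[s] = res
            fine_rows.append(
                {"INDEX": s, "BEST": res.best_snp, "BEST_ONE_TAILED_P": res.best_p,
                 "BONFERRONI": res.passes_bonferroni}
            )
        pd.DataFrame(fine_rows).to_csv(out / "finemap.tsv", sep="\t", index=False)
        summary["n_finemapped"] = len(fine_rows)
        summary["n_best_differs"] = int(
            sum(1 for s, r in best_by_locus.items() if r.best_snp != s)
        )

        stage = "eqtl"
        rng_e = np.random.default_rng(stage_seeds["eqtl"])
        all_ids = target.variants["id"].to_numpy()
        eqtl_p = dict(zip(all_ids, rng_e.uniform(0, 1, all_ids.size)))
        for s in causal_ids:  # plant cis-eQTLs on causal loci and their proxies
            loc = engine.locus_proxies(s)
            members = loc["ids"] if loc else [s]
            for m in members:
                if rng_e.random() < config.eqtl_enrichment:
                    eqtl_p[m] = rng_e.uniform(0, config.eqtl_p)
        pd.DataFrame(
            {"SNP": list(eqtl_p), "P": [eqtl_p[s] for s in eqtl_p]}
        ).to_csv(out / "eqtl_table.tsv", sep="\t", index=False)
        list_a = [s for s, _ in pairs]
        list_b = [best_by_locus[s].best_snp if s in best_by_locus else s
                  for s in list_a]
        maf_map = dict(zip(ids, maf))
        pool = pd.DataFrame({"snp": common, "maf": [maf_map[s] for s in common]})

        def null_gen(n_sims, rng):
            mafs = [maf_map.get(s, 0.2) for s in list_b]
            return generate_matched_sets(
                mafs, pool, src_ld, n_sets=n_sims, maf_tol=config.maf_tol,
                r2_indep=config.r2_indep, rng=rng,
            ).sets

        enr = enrichment_test(
            list_a, list_b, p_lookup, eqtl_p, null_gen, n_sims=config.n_sims,
            seed=stage_seeds["eqtl"], p_height=config.alpha, p_eqtl=config.eqtl_p,
        )
        summary["eqtl"] = {
            "fraction_index": round(enr.fraction_a, 4),
            "fraction_finemapped": round(enr.fraction_b, 4),
            "empirical_p": enr.empirical_p.p,
            "empirical_p_display": str(enr.empirical_p),
        }
    except TransheightError as exc:
        root.removeHandler(handler)
        raise TransheightError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        if handler in root.handlers:
            root.removeHandler(handler)
        handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
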