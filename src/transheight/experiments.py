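"""Replicate-level simulation experiments for the replication framework.

These drive the full pipeline (phenotype -> per-study scan -> genomic
control -> meta-analysis -> proxy expansion -> binning -> one-tailed
conversion -> matched-null empirical P) across many replicates over a
fixed pair of panels, sharing the LD caches so that large replicate
counts stay tractable.  They quantify:

* calibration -- under a global null (no shared effects) the empirical
  replication P must be uniform, so P <= 0.05 should occur for ~5% of
  replicates;
* power -- with a fraction of loci truly sharing effects between the
  populations, the empirical P should be small in nearly all replicates.

Problem sizes default to 100 index loci, 200 matched null sets and
panels of 4,000 variants x 400 haplotypes with a 2 x 1,000-individual
admixed cohort; larger target sample sizes are emulated by scaling the
planted effects by sqrt(n_effective / n_actual), which preserves the
per-SNP non-centrality and the LD propagation of signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association, meta
from .ld import LDCache
from .replication import ReplicationEngine, generate_matched_sets, run_replication
from .simulate import SimulationConfig, simulate_admixed_cohort, simulate_panels

__all__ = [
    "ExperimentBench",
    "replication_null_calibration",
    "replication_power",
]

# Ancestry tracts are kept short relative to the simulated chromosome
# (0.4 Mb on 4-6 Mb) so that local ancestry decorrelates along the
# chromosome the way 10-Mb tracts do on a full genome; with tracts as
# long as the chromosome, every frequency-divergent SNP would share the
# causal loci's ancestry axis and the scan would be confounded beyond
# what the global-ancestry covariate (or genomic control) can absorb.
_BENCH_CONFIG = dict(
    n_variants=4_000,
    n_haplotypes=400,
    n_studies=2,
    per_study_n=1_000,
    divergence_F=0.15,
    admixture_alpha=0.8,
    tract_length_mean=400_000.0,
)


@dataclass
class ExperimentBench:
    """Fixed panels, cohort and caches shared across replicates."""

    config: SimulationConfig
    source: object
    target: object
    cohort: object
    engine: ReplicationEngine
    pool: pd.DataFrame
    maf_map: dict
    alt_map: dict
    ref_map: dict

    @classmethod
    def build(cls, seed: int = 0, **overrides) -> "ExperimentBench":
        cfg = SimulationConfig(**{**_BENCH_CONFIG, **overrides, "seed": seed})
        source, target = simulate_panels(cfg)
        cohort = simulate_admixed_cohort((source, target), cfg)
        src_ld, tgt_ld = LDCache(source), LDCache(target)
        engine = ReplicationEngine(src_ld, tgt_ld)
        ids = source.variants["id"].to_numpy()
        maf = source.maf()
        common = maf >= 0.05
        pool = pd.DataFrame({"snp": ids[common], "maf": maf[common]})
        return cls(
            config=cfg, source=source, target=target, cohort=cohort,
            engine=engine, pool=pool, maf_map=dict(zip(ids, maf)),
            alt_map=dict(zip(ids, source.variants["alt"])),
            ref_map=dict(zip(ids, source.variants["ref"])),
        )

    # -- pieces ----------------------------------------------------------
    def draw_index_list(self, n_loci: int, rng: np.random.Generator) -> list:
        """A quasi-independent index list drawn by the matched-set sampler.

        Target MAFs are sampled from the pool itself, so the list has the
        same distribution as the null sets matched to it (exchangeability
        under the global null holds by construction).
        """
        mafs = rng.choice(self.pool["maf"].to_numpy(), size=n_loci, replace=False)
        sets = generate_matched_sets(
            mafs, self.pool, self.engine.src, n_sets=1, rng=rng
        )
        return sets.sets[0]

    def scan_meta(self, effects: dict | None, rng: np.random.Generator) -> pd.DataFrame:
        """Phenotype draw + per-study scan + GC + IVW meta + GC.

        ``effects`` maps SNP id -> beta (Z units, already scaled); None
        or empty means the global null.
        """
        cohort, cfg = self.cohort, self.config
        n = cohort.n_individuals
        genetic = np.zeros(n)
        for snp_id, beta in (effects or {}).items():
            genetic += beta * cohort.genotypes[:, cohort.index_of(snp_id)]
        ind = cohort.individuals
        height = (
            170.0 + cfg.height_scale * (genetic + rng.standard_normal(n))
            + cfg.sex_effect * ind["sex"].to_numpy()
            + cfg.age_effect * (ind["age"].to_numpy() - 45.0)
        )
        labels = cohort.study_labels()
        # global-ancestry covariate (mean European dosage), the stand-in
        # for the principal-component admixture correction
        global_anc = cohort.local_ancestry.mean(axis=1)
        tables = []
        for study in sorted(set(labels)):
            mask = labels == study
            z = association.zscore_transform(
                height[mask],
                covariates=np.column_stack(
                    [ind["sex"].to_numpy()[mask], ind["age"].to_numpy()[mask]]
                ),
            )
            tab = association.scan(
                z, cohort.genotypes[mask].astype(float),
                covariates=global_anc[mask], variants=cohort.variants,
            )
            ok = tab["P"].notna()
            tab = tab[ok]
            lam = meta.genomic_control_lambda(tab["P"])
            tables.append(meta.gc_correct_table(tab, lam))
        combined = meta.meta_analyze(tables)
        lam_meta = meta.genomic_control_lambda(combined["P"])
        return meta.gc_correct_table(combined, lam_meta)

    def replicate_once(
        self,
        seed: int,
        n_loci: int,
        n_sets: int,
        shared: int = 0,
        effect_range: tuple = (0.05, 0.10),
        effective_n: float = 20_000.0,
    ) -> float:
        """One full replicate; returns the empirical replication P."""
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        index_list = self.draw_index_list(n_loci, rng)
        effects: dict = {}
        pairs = []
        if shared > 0:
            scale = float(np.sqrt(effective_n / self.cohort.n_individuals))
            chosen = rng.choice(len(index_list), size=shared, replace=False)
            lo, hi = effect_range
            for k in chosen:
                beta = rng.uniform(lo, hi) * (1 if rng.integers(2) else -1)
                effects[index_list[k]] = beta * scale
        for s in index_list:
            if s in effects:
                inc = self.alt_map[s] if effects[s] > 0 else self.ref_map[s]
            else:
                inc = self.alt_map[s] if rng.integers(2) else self.ref_map[s]
            pairs.append((s, inc))
        meta_tab = self.scan_meta(effects, rng)
        report = run_replication(
            pairs, self.engine.src, self.engine.tgt, meta_tab, pool=self.pool,
            n_sets=n_sets, seed=int(ss.generate_state(2)[1] % 2**31),
            engine=self.engine,
        )
        return report.empirical_p.p


def replication_null_calibration(
    n_replicates: int = 200,
    n_loci: int = 100,
    n_sets: int = 200,
    seed: int = 0,
    bench: ExperimentBench | None = None,
) -> np.ndarray:
    """Empirical replication P over replicates with no shared effects."""
    if bench is None:
        bench = ExperimentBench.build(seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    return np.array(
        [
            bench.replicate_once(
                int(c.generate_state(1)[0] % 2**31), n_loci, n_sets
            )
            for c in children
        ]
    )


def replication_power(
    n_replicates: int = 50,
    n_loci: int = 100,
    n_shared: int = 40,
    n_sets: int = 200,
    effect_range: tuple = (0.05, 0.10),
    effective_n: float = 20_000.0,
    seed: int = 0,
    bench: ExperimentBench | None = None,
) -> np.ndarray:
    """Empirical replication P over replicates with truly shared loci."""
    if bench is None:
        bench = ExperimentBench.build(seed=seed)
    children = np.random.SeedSequence(seed + 1).spawn(n_replicates)
    return np.array(
        [
            bench.replicate_once(
                int(c.generate_state(1)[0] % 2**31), n_loci, n_sets,
                shared=n_shared, effect_range=effect_range,
                effective_n=effective_n,
            )
            for c in children
        ]
    )
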