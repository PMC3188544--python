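"""Trans-ethnic replication of known GWAS loci and fine-mapping.

The framework tests whether loci discovered in a source population
replicate, as a group, in a target population with different LD:

1. each index SNP is expanded to its source-population proxies
   (r^2 >= 0.8), each proxy carrying the trait-increasing allele
   predicted from phase;
2. proxies are clustered into bins with target-population LD
   (r^2 >= 0.3), in randomized order to avoid bias toward significance;
3. each bin is represented by its index SNP's one-tailed P (two-tailed
   P halved when the observed direction matches the prediction, else
   1 - P/2) and called significant at P <= alpha;
4. the genome-wide replication metric (total significant bins) is
   referred to an empirical null of frequency-matched, mutually
   quasi-independent SNP sets passed through the same machinery.

Fine-mapping reuses the binning but processes SNPs in ascending P order,
so the first bin's index SNP is the locus's best supported variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MatchingError
from .ld import DEFAULT_WINDOW_BP, LDCache

logger = logging.getLogger(__name__)

__all__ = [
    "Bin",
    "MatchedNullSets",
    "EmpiricalP",
    "FineMapResult",
    "LocusReplication",
    "ReplicationReport",
    "ReplicationEngine",
    "one_tailed",
    "build_bins",
    "count_significant_bins",
    "generate_matched_sets",
    "empirical_p",
    "fine_map_best",
    "run_replication",
]


@dataclass
class Bin:
    """An index SNP plus the SNPs clustered with it (index included)."""

    index: str
    members: list

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MatchedNullSets:
    """K frequency-matched, mutually quasi-independent null SNP sets."""

    sets: list                 # each a list of M SNP ids
    maf_tol_used: dict         # locus position in list -> tolerance used
    r2_indep: float
    n_sets: int


@dataclass(frozen=True)
class EmpiricalP:
    """Permutation P-value k/N with below-resolution reporting."""

    p: float
    n_null: int
    below_resolution: bool = False

    def __str__(self) -> str:
        if self.below_resolution:
            return f"< {1.0 / self.n_null:g}"
        return f"{self.p:g}"


@dataclass
class FineMapResult:
    best_snp: str
    best_p: float
    bins: list
    passes_bonferroni: bool | None = None


@dataclass
class LocusReplication:
    index: str
    n_proxies: int
    n_bins: int
    n_significant: int
    best_one_tailed_p: float
    dropped_no_direction: int = 0
    dropped_missing_p: int = 0
    resolvable: bool = True


@dataclass
class ReplicationReport:
    observed_total: int
    per_locus: list
    null_counts: np.ndarray
    empirical_p: EmpiricalP | None
    n_loci: int = 0

    def summary(self) -> dict:
        nulls = np.asarray(self.null_counts)
        return {
            "n_loci": self.n_loci,
            "observed_significant_bins": int(self.observed_total),
            "n_null_sets": int(nulls.size),
            "null_median": float(np.median(nulls)) if nulls.size else None,
            "null_range": [int(nulls.min()), int(nulls.max())] if nulls.size else None,
            "empirical_p": None if self.empirical_p is None else self.empirical_p.p,
            "empirical_p_display": None if self.empirical_p is None
            else str(self.empirical_p),
        }


def _sign(x) -> int:
    if isinstance(x, str):
        return {"+": 1, "-": -1}[x]
    return int(np.sign(x))


def one_tailed(p_two: float, observed_effect_sign, predicted_sign) -> float:
    """Directional one-tailed P from a two-tailed P.

    P/2 when the observed effect direction matches the predicted
    direction, else 1 - P/2; an effect of exactly zero gives 0.5.
    """
    if not 0.0 < p_two <= 1.0:
        raise DegenerateInputError(f"two-tailed P must be in (0, 1], got {p_two}")
    obs = _sign(observed_effect_sign)
    pred = _sign(predicted_sign)
    if pred == 0:
        raise DegenerateInputError("predicted sign must be non-zero")
    if obs == 0:
        return 0.5
    return p_two / 2.0 if obs == pred else 1.0 - p_two / 2.0


def _pairwise_r2(ld, snp_ids: Sequence[str]) -> np.ndarray:
    if hasattr(ld, "r2_matrix"):
        return ld.r2_matrix(snp_ids)
    m = len(snp_ids)
    R = np.zeros((m, m))
    for i in range(m):
        R[i, i] = 1.0
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = ld.r2_ids(snp_ids[i], snp_ids[j])
    return R


def _greedy_bins(order: Sequence[str], r2m: np.ndarray, r2_bin: float) -> list:
    """Greedy clustering of SNPs in the given order; r2m follows that order."""
    m = len(order)
    remaining = np.ones(m, dtype=bool)
    bins = []
    with np.errstate(invalid="ignore"):
        link = np.nan_to_num(r2m, nan=-1.0) >= r2_bin
    for i in range(m):
        if not remaining[i]:
            continue
        remaining[i] = False
        absorb = np.flatnonzero(remaining & link[i])
        remaining[absorb] = False
        bins.append(Bin(index=order[i], members=[order[i]] + [order[j] for j in absorb]))
    return bins


def build_bins(
    snp_ids: Sequence[str], ld, r2_bin: float = 0.3, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list:
    """Randomized-order greedy LD binning of one locus's proxy SNPs.

    The member order is shuffled under the seed; the first unbinned SNP
    becomes a bin index and absorbs every remaining SNP with
    r^2 >= ``r2_bin`` to it, until all SNPs are binned.  The resulting
    bins partition the input list.  Deterministic given the seed.
    """
    ids = list(snp_ids)
    if not ids:
        return []
    if rng is None:
        rng = np.random.default_rng(seed)
    order = [ids[k] for k in rng.permutation(len(ids))]
    return _greedy_bins(order, _pairwise_r2(ld, order), r2_bin)


def count_significant_bins(
    bins_by_locus: Mapping[str, Sequence[Bin]],
    p_lookup: Mapping[str, float],
    alpha: float = 0.05,
) -> tuple[dict, int]:
    """Count bins whose index SNP's one-tailed P is <= alpha, per locus.

    A bin whose index SNP has no P-value is excluded with a warning.
    Returns (per-locus counts, total across loci).
    """
    per_locus = {}
    total = 0
    for locus, bins in bins_by_locus.items():
        c = 0
        for b in bins:
            p = p_lookup.get(b.index)
            if p is None:
                logger.warning(
                    "bin index %s at locus %s has no P; bin excluded",
                    b.index, locus,
                )
                continue
            if p <= alpha:
                c += 1
        per_locus[locus] = c
        total += c
    return per_locus, total


def empirical_p(observed_count: float, null_counts) -> EmpiricalP:
    """Fraction of null counts >= the observed count (k/N convention).

    When no null count reaches the observation the value is stored as 0
    and flagged, to be reported as "< 1/N".
    """
    nulls = np.asarray(null_counts)
    if nulls.size == 0:
        raise DegenerateInputError("need at least one null count")
    k = int((nulls >= observed_count).sum())
    return EmpiricalP(
        p=k / nulls.size, n_null=int(nulls.size), below_resolution=(k == 0)
    )


def generate_matched_sets(
    index_mafs: Sequence[float],
    pool: pd.DataFrame,
    ld,
    n_sets: int = 5_819,
    maf_tol: float = 0.02,
    r2_indep: float = 0.2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_tol: float = 0.05,
    max_attempts: int = 20,
) -> MatchedNullSets:
    """K sets of pool SNPs frequency-matched to the index loci.

    For each set, one pool SNP per locus is sampled without replacement
    with |MAF - locus MAF| <= tolerance, rejecting candidates in LD
    (r^2 >= ``r2_indep`` within +/- ``window_bp``) with any SNP already
    in the set.  Loci with fewer than n_sets/10 eligible matches widen
    their tolerance stepwise (+0.01, logged) up to ``max_tol``; failure
    after widening raises :class:`MatchingError` naming the loci.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = pool.reset_index(drop=True)
    pool_ids = pool["snp"].to_numpy()
    pool_maf = pool["maf"].to_numpy(dtype=float)
    min_eligible = max(1, math.ceil(n_sets / 10))

    eligible = []
    tol_used = {}
    unmatched = []
    for li, m in enumerate(index_mafs):
        tol = maf_tol
        while True:
            rows = np.flatnonzero(np.abs(pool_maf - m) <= tol)
            if rows.size >= min_eligible or tol >= max_tol:
                break
            tol = min(round(tol + 0.01, 10), max_tol)
            logger.info("locus %d: widened MAF tolerance to %.3f", li, tol)
        if rows.size == 0:
            unmatched.append(li)
        eligible.append(rows)
        tol_used[li] = tol
    if unmatched:
        raise MatchingError(
            f"no MAF-matched pool SNPs for loci {unmatched} at tolerance {max_tol}"
        )

    # neighbor sets for the independence screen, built lazily per pool SNP
    nbr_cache: dict = {}
    id_set = set(pool_ids)

    def neighbors_of(snp: str) -> frozenset:
        hit = nbr_cache.get(snp)
        if hit is not None:
            return hit
        if hasattr(ld, "neighbors"):
            rows = ld.neighbors(ld.index_of(snp), r2_indep, window_bp)
            ids = frozenset(
                s for s in ld.panel.variants["id"].to_numpy()[rows] if s in id_set
            )
        else:  # generic pairwise fallback for small pools
            ids = frozenset(
                other for other in pool_ids
                if other != snp and ld.r2_ids(snp, other) >= r2_indep
            )
        nbr_cache[snp] = ids
        return ids

    sets = []
    for _ in range(n_sets):
        for _attempt in range(max_attempts):
            chosen: list = []
            blocked: set = set()
            ok = True
            for li in range(len(eligible)):
                rows = eligible[li]
                pick = None
                for _try in range(30):  # cheap rejection sampling first
                    cand = pool_ids[rows[rng.integers(rows.size)]]
                    if cand not in blocked:
                        pick = cand
                        break
                if pick is None:  # exhaustive scan in random order
                    for k in rng.permutation(rows.size):
                        cand = pool_ids[rows[k]]
                        if cand not in blocked:
                            pick = cand
                            break
                if pick is None:
                    ok = False
                    break
                chosen.append(pick)
                blocked.add(pick)
                blocked |= neighbors_of(pick)
            if ok:
                sets.append(chosen)
                break
        else:
            raise MatchingError(
                f"could not assemble a matched set after {max_attempts} attempts"
            )
    return MatchedNullSets(
        sets=sets, maf_tol_used=tol_used, r2_indep=r2_indep, n_sets=n_sets
    )


def fine_map_best(
    snp_ids: Sequence[str],
    ld,
    p_lookup: Mapping[str, float],
    r2_bin: float = 0.3,
    positions: Mapping[str, int] | None = None,
    bonferroni_m: int | None = None,
) -> FineMapResult | None:
    """Best-supported SNP of one locus by P-sorted greedy binning.

    SNPs are processed in ascending P (ties broken by genomic position,
    then id); the first bin's index is the locus's best SNP.  When
    ``bonferroni_m`` is given, flags whether the best P clears the
    0.05/m Bonferroni threshold.  Returns None for an empty locus.
    """
    ids = [s for s in snp_ids if s in p_lookup]
    n_missing = len(list(snp_ids)) - len(ids)
    if n_missing:
        logger.warning("fine-mapping: %d SNPs lack a P-value; dropped", n_missing)
    if not ids:
        return None
    if positions is None and hasattr(ld, "panel"):
        var = ld.panel.variants
        positions = dict(zip(var["id"], var["pos"]))
    pos = positions or {}
    order = sorted(ids, key=lambda s: (p_lookup[s], pos.get(s, 0), s))
    bins = _greedy_bins(order, _pairwise_r2(ld, order), r2_bin)
    best = bins[0].index
    best_p = float(p_lookup[best])
    flag = None if bonferroni_m is None else best_p < 0.05 / bonferroni_m
    return FineMapResult(best_snp=best, best_p=best_p, bins=bins,
                         passes_bonferroni=flag)


# ---------------------------------------------------------------------------
# orchestration


class ReplicationEngine:
    """Caches the LD work shared by the observed list and every null set.

    Holds the two panel LD caches and memoizes, per candidate index SNP,
    its source-population proxy list with phase-predicted allele signs
    and the target-population r^2 sub-matrix used for binning.  Intended
    to be reused across permutation sets and replicate experiments over
    the same panels.
    """

    def __init__(
        self,
        source_panel,
        target_panel,
        r2_proxy: float = 0.8,
        r2_bin: float = 0.3,
        window_bp: int = DEFAULT_WINDOW_BP,
        proxy_maf_min: float = 0.05,
    ):
        self.src = source_panel if isinstance(source_panel, LDCache) else LDCache(source_panel)
        self.tgt = target_panel if isinstance(target_panel, LDCache) else LDCache(target_panel)
        self.r2_proxy = r2_proxy
        self.r2_bin = r2_bin
        self.window_bp = window_bp
        # proxy sets are restricted to common SNPs: near-singleton
        # variants sharing a carrier haplotype form spurious perfect-LD
        # chains spanning unrelated loci
        self.proxy_maf_min = proxy_maf_min
        self._locus_cache: dict = {}
        f = self.src.panel.alt_frequency()
        self._src_common = np.minimum(f, 1 - f) >= proxy_maf_min

    def locus_proxies(self, index_id: str):
        """(proxy ids, alt-relative predicted signs, target link matrix) or None.

        ``signs[j] = +1`` means: when the index's increasing allele is its
        alt allele, proxy j's alt allele is predicted trait-increasing.
        None when the index is monomorphic in the source panel
        (unresolvable locus) or absent from the target panel.
        """
        hit = self._locus_cache.get(index_id, "miss")
        if hit != "miss":
            return hit
        out = self._compute_locus(index_id)
        self._locus_cache[index_id] = out
        return out

    def _compute_locus(self, index_id: str):
        src = self.src
        if index_id not in src.panel or not src.is_polymorphic(index_id):
            return None
        i = src.index_of(index_id)
        rows, d, r2 = src.window_ld(i, self.window_bp)
        with np.errstate(invalid="ignore"):
            keep = (
                (r2 >= self.r2_proxy) & (rows != i) & (d != 0.0)
                & self._src_common[rows]
            )
        ids = [index_id] + list(src.panel.variants["id"].to_numpy()[rows[keep]])
        signs = np.concatenate([[1.0], np.sign(d[keep])])
        dropped_no_dir = int(((r2 >= self.r2_proxy) & (rows != i) & (d == 0.0)).sum())
        in_tgt = np.array([s in self.tgt.panel for s in ids])
        dropped_tgt = int((~in_tgt).sum())
        ids = [s for s, k in zip(ids, in_tgt) if k]
        signs = signs[in_tgt]
        if not ids or index_id not in self.tgt.panel:
            return None
        with np.errstate(invalid="ignore"):
            link = np.nan_to_num(self.tgt.r2_matrix(ids), nan=-1.0) >= self.r2_bin
        return {
            "ids": ids,
            "signs": signs,
            "link": link,
            "dropped_no_direction": dropped_no_dir,
            "dropped_target": dropped_tgt,
        }

    def _locus_eval(
        self, index_id: str, beta_lookup, p_lookup, alpha: float,
        cache: dict | None,
    ):
        """Per-run evaluation arrays for one locus (memoized in ``cache``).

        Returns None for unresolvable loci, else a dict with the usable
        proxy one-tailed P for both allele orientations, significance
        masks, and the usable-row link matrix.
        """
        if cache is not None and index_id in cache:
            return cache[index_id]
        loc = self.locus_proxies(index_id)
        if loc is None:
            out = None
        else:
            ids, signs = loc["ids"], loc["signs"]
            beta = np.array([beta_lookup.get(s, np.nan) for s in ids])
            p_two = np.array([p_lookup.get(s, np.nan) for s in ids])
            usable = np.isfinite(beta) & np.isfinite(p_two)
            obs_alt = np.sign(beta) * signs  # orientation: index allele = alt
            with np.errstate(invalid="ignore"):
                p1_plus = np.where(obs_alt > 0, p_two / 2.0,
                                   np.where(obs_alt < 0, 1.0 - p_two / 2.0, 0.5))
                p1_minus = np.where(obs_alt < 0, p_two / 2.0,
                                    np.where(obs_alt > 0, 1.0 - p_two / 2.0, 0.5))
            rows = np.flatnonzero(usable)
            out = {
                "ids": [ids[r] for r in rows],
                "n_proxies": len(ids),
                "n_missing": int((~usable).sum()),
                "dropped_no_direction": loc["dropped_no_direction"],
                "p1_plus": p1_plus[rows],
                "p1_minus": p1_minus[rows],
                "sig_plus": p1_plus[rows] <= alpha,
                "sig_minus": p1_minus[rows] <= alpha,
                "link": loc["link"][np.ix_(rows, rows)],
            }
        if cache is not None:
            cache[index_id] = out
        return out

    @staticmethod
    def _greedy_count(link: np.ndarray, sig: np.ndarray, order: np.ndarray):
        """(n_bins, n_significant) of randomized greedy binning."""
        m = order.size
        remaining = np.ones(m, dtype=bool)
        n_bins = 0
        n_sig = 0
        for i in order:
            if not remaining[i]:
                continue
            remaining[i] = False
            remaining &= ~link[i]
            n_bins += 1
            if sig[i]:
                n_sig += 1
        return n_bins, n_sig

    def count_locus(
        self, index_id: str, increasing_is_alt: bool, beta_lookup, p_lookup,
        rng: np.random.Generator, alpha: float = 0.05,
        cache: dict | None = None,
    ) -> int:
        """Significant-bin count for one locus (fast path, no detail)."""
        ev = self._locus_eval(index_id, beta_lookup, p_lookup, alpha, cache)
        if ev is None or not ev["ids"]:
            return 0
        sig = ev["sig_plus"] if increasing_is_alt else ev["sig_minus"]
        _, n_sig = self._greedy_count(ev["link"], sig,
                                      rng.permutation(len(ev["ids"])))
        return n_sig

    def evaluate_locus(
        self,
        index_id: str,
        increasing_is_alt: bool,
        beta_lookup: Mapping[str, float],
        p_lookup: Mapping[str, float],
        rng: np.random.Generator,
        alpha: float = 0.05,
        cache: dict | None = None,
    ) -> LocusReplication:
        """Randomized binning + one-tailed significance for one locus."""
        ev = self._locus_eval(index_id, beta_lookup, p_lookup, alpha, cache)
        if ev is None:
            return LocusReplication(
                index=index_id, n_proxies=0, n_bins=0, n_significant=0,
                best_one_tailed_p=np.nan, resolvable=False,
            )
        if not ev["ids"]:
            return LocusReplication(
                index=index_id, n_proxies=ev["n_proxies"], n_bins=0,
                n_significant=0, best_one_tailed_p=np.nan,
                dropped_no_direction=ev["dropped_no_direction"],
                dropped_missing_p=ev["n_missing"],
            )
        p1 = ev["p1_plus"] if increasing_is_alt else ev["p1_minus"]
        sig = ev["sig_plus"] if increasing_is_alt else ev["sig_minus"]
        n_bins, n_sig = self._greedy_count(
            ev["link"], sig, rng.permutation(len(ev["ids"]))
        )
        return LocusReplication(
            index=index_id, n_proxies=ev["n_proxies"], n_bins=n_bins,
            n_significant=n_sig, best_one_tailed_p=float(np.min(p1)),
            dropped_no_direction=ev["dropped_no_direction"],
            dropped_missing_p=ev["n_missing"],
        )

    def evaluate_list(
        self, loci, beta_lookup, p_lookup, rng, alpha: float = 0.05,
        cache: dict | None = None,
    ) -> tuple[list, int]:
        """Evaluate a list of (index id, increasing_is_alt); return details+total."""
        details = [
            self.evaluate_locus(s, inc, beta_lookup, p_lookup, rng, alpha, cache)
            for s, inc in loci
        ]
        return details, sum(d.n_significant for d in details)

    def count_list(
        self, loci, beta_lookup, p_lookup, rng, alpha: float = 0.05,
        cache: dict | None = None,
    ) -> int:
        """Total significant-bin count of a list (fast path)."""
        return sum(
            self.count_locus(s, inc, beta_lookup, p_lookup, rng, alpha, cache)
            for s, inc in loci
        )


def run_replication(
    index_snps,
    source_panel,
    target_panel,
    meta_results: pd.DataFrame,
    pool: pd.DataFrame | None = None,
    n_sets: int = 5_819,
    seed: int = 0,
    r2_proxy: float = 0.8,
    r2_bin: float = 0.3,
    r2_indep: float = 0.2,
    maf_tol: float = 0.02,
    alpha: float = 0.05,
    window_bp: int = DEFAULT_WINDOW_BP,
    engine: ReplicationEngine | None = None,
) -> ReplicationReport:
    """End-to-end replication of a list of known loci in the target data.

    ``index_snps``: DataFrame with columns ``snp`` and
    ``increasing_allele``, or a list of (snp, allele) pairs.
    ``meta_results``: per-SNP meta-analysis summary with SNP, BETA, P,
    the effect allele being the panel alternate allele.  ``pool``: the
    candidate pool (columns ``snp, maf``) for the matched null sets;
    defaults to all common polymorphic source-panel SNPs outside the
    index list.  Null-set index SNPs receive a random increasing allele
    (direction carries no information under the null).
    """
    if isinstance(index_snps, pd.DataFrame):
        pairs = list(zip(index_snps["snp"], index_snps["increasing_allele"]))
    else:
        pairs = list(index_snps)
    if engine is None:
        engine = ReplicationEngine(
            source_panel, target_panel, r2_proxy=r2_proxy, r2_bin=r2_bin,
            window_bp=window_bp,
        )
    if not pairs:
        return ReplicationReport(
            observed_total=0, per_locus=[], null_counts=np.array([]),
            empirical_p=None, n_loci=0,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    beta_lookup = dict(zip(meta_results["SNP"], meta_results["BETA"]))
    p_lookup = dict(zip(meta_results["SNP"], meta_results["P"]))

    src_var = engine.src.panel.variants
    alt_map = dict(zip(src_var["id"], src_var["alt"]))
    loci = [(s, allele == alt_map.get(s)) for s, allele in pairs]
    eval_cache: dict = {}
    details, observed = engine.evaluate_list(
        loci, beta_lookup, p_lookup, rng, alpha, cache=eval_cache
    )

    null_counts = np.array([])
    emp = None
    if n_sets > 0:
        maf = engine.src.panel.maf()
        id_arr = src_var["id"].to_numpy()
        maf_map = dict(zip(id_arr, maf))
        if pool is None:
            index_ids = {s for s, _ in pairs}
            keep = (maf >= 0.05) & ~np.isin(id_arr, list(index_ids))
            pool = pd.DataFrame({"snp": id_arr[keep], "maf": maf[keep]})
        index_mafs = [maf_map[s] for s, _ in pairs if s in maf_map]
        matched = generate_matched_sets(
            index_mafs, pool, engine.src, n_sets=n_sets, maf_tol=maf_tol,
            r2_indep=r2_indep, rng=rng, window_bp=window_bp,
        )
        counts = np.empty(n_sets, dtype=int)
        for k, null_set in enumerate(matched.sets):
            null_loci = [(s, bool(rng.integers(2))) for s in null_set]
            counts[k] = engine.count_list(
                null_loci, beta_lookup, p_lookup, rng, alpha, cache=eval_cache
            )
        null_counts = counts
        emp = empirical_p(observed, null_counts)

    return ReplicationReport(
        observed_total=observed, per_locus=details, null_counts=null_counts,
        empirical_p=emp, n_loci=len(pairs),
    )
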