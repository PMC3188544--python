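"""Genomic control, inverse-variance meta-analysis and QQ diagnostics.

The fixed-effect inverse-variance combination weights each study
estimate by w_i = 1/SE_i^2; heterogeneity is summarized by Cochran's
Q = sum w_i (beta_i - beta)^2 on k-1 df and I^2 = max(0, (Q-(k-1))/Q).
Genomic control divides the association chi-square by the median-based
inflation factor lambda = median(chi2) / median(chi2_1df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .association import AssocResult, two_tailed_p
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "GCFactor",
    "MetaResult",
    "QQBands",
    "genomic_control_lambda",
    "gc_correct",
    "gc_correct_table",
    "inverse_variance_meta",
    "meta_analyze",
    "qq_with_bands",
]

# median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(chi2_dist.ppf(0.5, 1))


@dataclass(frozen=True)
class GCFactor:
    """Median-based genomic-control inflation factor."""

    lambda_gc: float

    def __post_init__(self):
        if not self.lambda_gc > 0:
            raise DegenerateInputError("lambda_gc must be > 0")


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect combination of k study estimates."""

    beta: float
    se: float
    p: float
    k: int
    q: float
    p_het: float
    i2: float  # percent


@dataclass(frozen=True)
class QQBands:
    expected: np.ndarray   # -log10 expected uniform order-statistic quantiles
    observed: np.ndarray   # sorted observed -log10 P (ascending in expected)
    lower: np.ndarray
    upper: np.ndarray


def genomic_control_lambda(p_values) -> GCFactor:
    """Inflation factor from two-tailed P-values.

    Each P is converted to its 1-df chi-square quantile and lambda is the
    ratio of the median statistic to the chi-square median (~0.4549).
    P = 0 is clipped to the smallest positive normal float and logged.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise DegenerateInputError("no P-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise DegenerateInputError("P-values must lie in [0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("clipping %d zero P-values for lambda", n_zero)
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = chi2_dist.isf(p, 1)
    return GCFactor(lambda_gc=float(np.median(chi2) / CHI2_1DF_MEDIAN))


def gc_correct(assoc: AssocResult, gc: GCFactor) -> AssocResult:
    """Scale one association result by genomic control.

    The chi-square statistic is divided by lambda, equivalently the SE is
    multiplied by sqrt(lambda), and P is recomputed; beta is unchanged.
    lambda < 1 is never used to deflate (correction applies only when
    lambda > 1, the conservative convention).
    """
    lam = max(1.0, gc.lambda_gc)
    se = assoc.se * float(np.sqrt(lam))
    return replace(assoc, se=se, p=two_tailed_p(assoc.beta, se))


def gc_correct_table(table: pd.DataFrame, gc: GCFactor) -> pd.DataFrame:
    """Vectorized :func:`gc_correct` over a summary-statistic DataFrame."""
    lam = max(1.0, gc.lambda_gc)
    out = table.copy()
    out["SE"] = table["SE"] * np.sqrt(lam)
    ok = out["SE"].to_numpy() > 0
    p = np.full(len(out), np.nan)
    p[ok] = two_tailed_p(out["BETA"].to_numpy()[ok], out["SE"].to_numpy()[ok])
    out["P"] = p
    return out


def inverse_variance_meta(estimates: Sequence[tuple]) -> MetaResult:
    """Fixed-effect IVW combination of (beta, SE) pairs.

    Returns the combined beta, SE = (sum w)^(-1/2), two-tailed P,
    Cochran's Q with its chi-square P on k-1 df, and I^2 floored at 0
    (0 when k = 1).
    """
    if len(estimates) == 0:
        raise DegenerateInputError("need at least one estimate")
    beta = np.asarray([e[0] for e in estimates], dtype=float)
    se = np.asarray([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise DegenerateInputError("all SE must be > 0")
    w = 1.0 / se**2
    b = float(np.sum(w * beta) / np.sum(w))
    s = float(1.0 / np.sqrt(np.sum(w)))
    k = len(estimates)
    q = float(np.sum(w * (beta - b) ** 2))
    if k == 1:
        p_het, i2 = 1.0, 0.0
    else:
        p_het = float(chi2_dist.sf(q, k - 1))
        i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(beta=b, se=s, p=two_tailed_p(b, s), k=k, q=q,
                      p_het=p_het, i2=i2)


def meta_analyze(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Vectorized per-SNP IVW meta-analysis across study summary tables.

    Tables must carry SNP, BETA, SE (and optionally N); SNPs are combined
    over whichever studies report them with SE > 0.  Output columns:
    SNP, BETA, SE, P, Q, P_HET, I2, K, N_TOTAL (plus CHR/POS/EA/OA from
    the first table reporting each SNP).
    """
    if len(tables) == 0:
        raise DegenerateInputError("no study tables supplied")
    frames = []
    for j, tab in enumerate(tables):
        t = tab[["SNP", "BETA", "SE"]].copy()
        t["N"] = tab["N"] if "N" in tab else np.nan
        t["study"] = j
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    long = long[(long["SE"] > 0) & np.isfinite(long["BETA"])]
    long["w"] = 1.0 / long["SE"] ** 2
    long["wb"] = long["w"] * long["BETA"]
    grp = long.groupby("SNP", sort=False)
    agg = grp.agg(
        sw=("w", "sum"), swb=("wb", "sum"), k=("w", "size"), n_total=("N", "sum")
    )
    agg["BETA"] = agg["swb"] / agg["sw"]
    agg["SE"] = 1.0 / np.sqrt(agg["sw"])
    agg["P"] = two_tailed_p(agg["BETA"].to_numpy(), agg["SE"].to_numpy())
    # Cochran Q needs a second pass against the combined beta
    long = long.merge(agg[["BETA"]], left_on="SNP", right_index=True,
                      suffixes=("", "_meta"))
    long["qterm"] = long["w"] * (long["BETA"] - long["BETA_meta"]) ** 2
    q = long.groupby("SNP", sort=False)["qterm"].sum()
    agg["Q"] = q
    k = agg["k"].to_numpy()
    agg["P_HET"] = np.where(
        k > 1, chi2_dist.sf(agg["Q"].to_numpy(), np.maximum(k - 1, 1)), 1.0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(
            (k > 1) & (agg["Q"].to_numpy() > 0),
            np.maximum(0.0, (agg["Q"].to_numpy() - (k - 1)) / agg["Q"].to_numpy())
            * 100.0,
            0.0,
        )
    agg["I2"] = i2
    out = agg.reset_index()[
        ["SNP", "BETA", "SE", "P", "Q", "P_HET", "I2", "k", "n_total"]
    ].rename(columns={"k": "K", "n_total": "N_TOTAL"})
    first = pd.concat(tables, ignore_index=True).drop_duplicates("SNP")
    keep = [c for c in ("CHR", "POS", "EA", "OA", "EAF") if c in first.columns]
    if keep:
        out = out.merge(first[["SNP"] + keep], on="SNP", how="left")
        out = out[["SNP"] + keep + ["BETA", "SE", "P", "Q", "P_HET", "I2",
                                    "K", "N_TOTAL"]]
    return out


def qq_with_bands(
    p_values, n_permutations: int = 200, band: float = 0.90,
    seed: int | None = None,
) -> QQBands:
    """QQ data with an empirical confidence band from uniform permutations.

    Expected quantiles are -log10 of the uniform order-statistic means
    i/(n+1); the band's lower/upper envelope is the (1-band)/2 and
    (1+band)/2 percentile of each order statistic across
    ``n_permutations`` simulated uniform samples of the same size.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    if n < 10:
        raise DegenerateInputError("need at least 10 P-values for a QQ plot")
    if n_permutations < 20:
        raise DegenerateInputError("n_permutations < 20 gives unreliable bands")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n + 1)
    expected = -np.log10(ranks / (n + 1.0))
    observed = -np.log10(np.maximum(p, np.finfo(float).tiny))
    sims = np.sort(rng.random((n_permutations, n)), axis=1)
    lo_q, hi_q = (1.0 - band) / 2.0, (1.0 + band) / 2.0
    lower = -np.log10(np.quantile(sims, hi_q, axis=0))
    upper = -np.log10(np.quantile(sims, lo_q, axis=0))
    return QQBands(expected=expected, observed=observed, lower=lower, upper=upper)
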