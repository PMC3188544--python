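"""Per-study association models.

Phenotypes are residualized on sex, age, disease status and any further
covariates, standardized to Z-scores (mean 0, sample SD 1), and each SNP
is tested with additive ordinary least squares, optionally jointly with
or stratified by the local-ancestry dosage at the locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeRecord",
    "AssocResult",
    "TermResult",
    "StratifiedResult",
    "zscore_transform",
    "snp_regression",
    "two_tailed_p",
    "conditional_model",
    "stratified_by_ancestry",
    "scan",
]

# Sample size above which the normal reference replaces the t reference
# for the genotype term; the studies modelled here have n >= 386 where
# the two are indistinguishable.
NORMAL_APPROX_N = 200


@dataclass(frozen=True)
class PhenotypeRecord:
    """One individual's raw phenotype and covariates."""

    individual: str
    height: float
    sex: int = 0
    age: float = 0.0
    disease: int = 0
    study: str = ""
    covariates: tuple = ()


@dataclass(frozen=True)
class AssocResult:
    """One SNP's association result in one study (Z-score units)."""

    snp: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self):
        if self.se <= 0:
            raise DegenerateInputError(f"SE must be > 0, got {self.se}")


@dataclass(frozen=True)
class TermResult:
    beta: float
    se: float
    p: float
    estimable: bool = True


@dataclass
class StratifiedResult:
    strata: dict            # European-dosage stratum -> AssocResult | None
    combined: "object"      # meta.MetaResult
    skipped: list           # (stratum, reason)


def _design(n: int, covariates) -> np.ndarray:
    """Intercept + covariate columns as an (n, 1+c) design matrix."""
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise DegenerateInputError("covariate rows do not match n")
        cols.append(C)
    return np.column_stack(cols)


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {
            "individual": r.individual, "height": r.height, "sex": r.sex,
            "age": r.age, "disease": r.disease, "study": r.study,
        }
        for k, v in enumerate(r.covariates):
            d[f"cov{k + 1}"] = v
        rows.append(d)
    return pd.DataFrame(rows)


def zscore_transform(heights, covariates=None) -> np.ndarray:
    """Residualize height on covariates, then standardize to Z-scores.

    ``heights`` may be a 1-D array or a DataFrame with a ``height``
    column (in which case ``covariates`` may name its columns).  The
    residuals of the least-squares fit on intercept + covariates are
    centered and scaled to sample SD 1 (n-1 denominator).
    """
    if isinstance(heights, pd.DataFrame):
        frame = heights
        y = frame["height"].to_numpy(dtype=float)
        if covariates is not None:
            covariates = frame[list(covariates)].to_numpy(dtype=float)
    else:
        y = np.asarray(heights, dtype=float)
    n = y.size
    if n < 2:
        raise DegenerateInputError("need at least two individuals")
    if not np.isfinite(y).all():
        raise DegenerateInputError("heights must be finite")
    X = _design(n, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("collinear covariate matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=1)
    if sd == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("height is constant after residualization")
    resid -= resid.mean()
    return resid / resid.std(ddof=1)


def two_tailed_p(beta, se):
    """Two-tailed normal P-value, 2*Phi(-|beta/se|).  Vectorized."""
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0):
        raise DegenerateInputError("SE must be > 0")
    p = 2.0 * norm.sf(np.abs(np.asarray(beta, dtype=float) / se_arr))
    return float(p) if p.ndim == 0 else p


def _p_from_t(tstat: float, df: int, n: int) -> float:
    if n > NORMAL_APPROX_N:
        return 2.0 * norm.sf(abs(tstat))
    return 2.0 * t_dist.sf(abs(tstat), df)


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS fit; returns (coef, se, df) or raises on deficient rank."""
    n, p = X.shape
    if n <= p:
        raise DegenerateInputError(f"n={n} <= parameters={p}")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < p:
        return None  # collinear; caller decides
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    return coef, se, df


def snp_regression(
    z, genotype, covariates=None, snp: str = "snp",
    effect_allele: str = "alt", other_allele: str = "ref",
) -> AssocResult | None:
    """Additive OLS of Z-scores on one SNP's allele counts plus covariates.

    Missing genotypes (NaN) are dropped per SNP; N records the complete
    cases.  A monomorphic SNP is logged and omitted (returns None); too
    few observations raise :class:`DegenerateInputError`.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(genotype, dtype=float)
    keep = ~np.isnan(g) & ~np.isnan(z)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= ~np.isnan(C).any(axis=1)
        C = C[keep]
    else:
        C = None
    z, g = z[keep], g[keep]
    n = z.size
    if n == 0 or np.var(g) == 0.0:
        logger.warning("SNP %s monomorphic after missing-data removal", snp)
        return None
    X = np.column_stack([_design(n, C), g])
    fit = _ols(z, X)
    if fit is None:
        raise DegenerateInputError("design matrix is rank deficient")
    coef, se, df = fit
    beta, se_b = float(coef[-1]), float(se[-1])
    if se_b == 0.0:
        p = 0.0  # perfect fit
    else:
        p = _p_from_t(beta / se_b, df, n)
    return AssocResult(
        snp=snp, effect_allele=effect_allele, other_allele=other_allele,
        eaf=float(np.mean(g) / 2.0), beta=beta,
        se=se_b if se_b > 0 else np.finfo(float).tiny, p=max(p, 0.0), n=n,
    )


def conditional_model(
    z, genotype, local_ancestry_dosage, covariates=None
) -> dict:
    """Joint OLS with both the SNP genotype and the ancestry dosage.

    Returns ``{"genotype": TermResult, "ancestry": TermResult}`` so the
    caller can report each term conditional on the other.  Perfectly
    collinear genotype/ancestry yields not-estimable terms rather than an
    exception.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(genotype, dtype=float)
    a = np.asarray(local_ancestry_dosage, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(z) | np.isnan(a))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= ~np.isnan(C).any(axis=1)
        C = C[keep]
    else:
        C = None
    z, g, a = z[keep], g[keep], a[keep]
    X = np.column_stack([_design(z.size, C), g, a])
    fit = _ols(z, X)
    if fit is None:
        nan_term = TermResult(np.nan, np.nan, np.nan, estimable=False)
        return {"genotype": nan_term, "ancestry": nan_term}
    coef, se, df = fit
    out = {}
    for name, k in (("genotype", -2), ("ancestry", -1)):
        b, s = float(coef[k]), float(se[k])
        p = _p_from_t(b / s, df, z.size) if s > 0 else 0.0
        out[name] = TermResult(beta=b, se=s, p=p)
    return out


def stratified_by_ancestry(
    z, genotype, local_ancestry_dosage, covariates=None,
    min_n: int = 50, snp: str = "snp",
) -> StratifiedResult:
    """Per-stratum association by European-chromosome count, IVW-combined.

    Strata {0, 1, 2} with fewer than ``min_n`` individuals, or with no
    genotype variance, are skipped with a log record; the remaining
    stratum estimates are combined by fixed-effect inverse-variance
    meta-analysis.  All strata skipped raises DegenerateInputError.
    """
    from .meta import inverse_variance_meta  # local import: avoids cycle

    z = np.asarray(z, dtype=float)
    g = np.asarray(genotype, dtype=float)
    a = np.asarray(local_ancestry_dosage)
    strata: dict = {}
    skipped: list = []
    estimates = []
    for level in (0, 1, 2):
        mask = a == level
        n_level = int(mask.sum())
        if n_level < min_n:
            skipped.append((level, f"n={n_level} < {min_n}"))
            logger.info("stratum %d skipped: n=%d < %d", level, n_level, min_n)
            strata[level] = None
            continue
        C = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            C = C[mask]
            C = C[:, C.std(axis=0) > 0]  # drop constants within stratum
            if C.shape[1] == 0:
                C = None
        res = snp_regression(z[mask], g[mask], C, snp=snp)
        if res is None:
            skipped.append((level, "monomorphic"))
            strata[level] = None
            continue
        strata[level] = res
        estimates.append((res.beta, res.se))
    if not estimates:
        raise DegenerateInputError("all ancestry strata were skipped")
    combined = inverse_variance_meta(estimates)
    return StratifiedResult(strata=strata, combined=combined, skipped=skipped)


def scan(
    z, genotypes, covariates=None, variants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Vectorized additive OLS of Z-scores on every SNP column.

    ``genotypes`` is (n_individuals, n_variants) without missing values
    (use :func:`snp_regression` per SNP otherwise).  Covariates are
    projected out of both phenotype and genotypes (Frisch-Waugh), with
    degrees of freedom adjusted accordingly.  Returns a DataFrame with
    BETA, SE, P, N, EAF (NaN rows for monomorphic SNPs).
    """
    z = np.asarray(z, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    X = _design(n, covariates)
    p_cov = X.shape[1]
    if n <= p_cov + 1:
        raise DegenerateInputError("too few individuals for the design")
    Q, _ = np.linalg.qr(X)
    z_r = z - Q @ (Q.T @ z)
    G_r = G - Q @ (Q.T @ G)
    ss_g = np.einsum("ij,ij->j", G_r, G_r)
    poly = ss_g > 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    gy = G_r.T @ z_r
    beta[poly] = gy[poly] / ss_g[poly]
    df = n - p_cov - 1
    ss_tot = float(z_r @ z_r)
    rss = np.maximum(ss_tot - beta[poly] ** 2 * ss_g[poly], 0.0)
    se[poly] = np.sqrt(rss / df / ss_g[poly])
    pvals = np.full(m, np.nan)
    ok = poly & (se > 0)
    with np.errstate(invalid="ignore"):
        tstat = beta / se
    if n > NORMAL_APPROX_N:
        pvals[ok] = 2.0 * norm.sf(np.abs(tstat[ok]))
    else:
        pvals[ok] = 2.0 * t_dist.sf(np.abs(tstat[ok]), df)
    out = pd.DataFrame(
        {
            "BETA": beta, "SE": se, "P": pvals,
            "N": n, "EAF": G.mean(axis=0) / 2.0,
        }
    )
    if variants is not None:
        out.insert(0, "SNP", variants["id"].to_numpy())
        out.insert(1, "CHR", variants["chrom"].to_numpy())
        out.insert(2, "POS", variants["pos"].to_numpy())
        out.insert(3, "EA", variants["alt"].to_numpy())
        out.insert(4, "OA", variants["ref"].to_numpy())
    return out
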