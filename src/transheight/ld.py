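"""Haplotype-based linkage disequilibrium and population differentiation.

All LD quantities are computed from phased haplotype counts: for two
variants with alternate-allele frequencies p_a, p_b and joint alt-alt
haplotype frequency p_ab, the coupling disequilibrium is
D = p_ab - p_a*p_b and r^2 = D^2 / (p_a(1-p_a) p_b(1-p_b)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NoPredictionError, UndefinedLDError
from .panels import HaplotypePanel

__all__ = [
    "LDPair",
    "ProxyMember",
    "ProxySet",
    "LDCache",
    "r2_from_haplotypes",
    "predict_direction",
    "expand_proxies",
    "ld_interval",
    "fst_two_pop",
]

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class LDPair:
    """Pairwise LD between the alternate alleles of two variants."""

    snp_a: str
    snp_b: str
    D: float
    r2: float


@dataclass(frozen=True)
class ProxyMember:
    snp: str
    r2: float
    D: float
    predicted_allele: str  # allele predicted to increase the trait


@dataclass
class ProxySet:
    """An index SNP with all panel SNPs tagging it at ``r2 >= threshold``.

    The index itself is always a member (r^2 = 1).  ``resolvable`` is
    False when the index is monomorphic in the panel, mirroring loci
    dropped for lack of usable LD data; ``dropped`` lists proxies whose
    allele direction could not be predicted (D == 0).
    """

    index: str
    index_allele: str
    members: list = field(default_factory=list)
    resolvable: bool = True
    dropped: list = field(default_factory=list)

    @property
    def member_ids(self) -> list:
        return [m.snp for m in self.members]


class LDCache:
    """Memoizing LD oracle over one haplotype panel.

    Exposes pairwise D/r^2 by variant id, windowed neighbour queries and
    small r^2 sub-matrices; repeated queries (as arise when thousands of
    matched null sets reuse the same pool SNPs) hit caches.
    """

    def __init__(self, panel: HaplotypePanel):
        self.panel = panel
        self._H = np.ascontiguousarray(panel.haplotypes, dtype=np.float64)
        self._n = panel.n_haplotypes
        self._freq = self._H.mean(axis=1)
        self._var = self._freq * (1.0 - self._freq)
        self._pos = panel.variants["pos"].to_numpy()
        self._chrom = panel.variants["chrom"].to_numpy()
        self._window_cache: dict = {}
        self._nbr_cache: dict = {}

    # -- index helpers ---------------------------------------------------
    def index_of(self, snp_id: str) -> int:
        return self.panel.index_of(snp_id)

    def alt_freq(self, snp_id: str) -> float:
        return float(self._freq[self.index_of(snp_id)])

    def is_polymorphic(self, snp_id: str) -> bool:
        return self._var[self.index_of(snp_id)] > 0.0

    # -- pairwise --------------------------------------------------------
    def d_r2(self, i: int, j: int) -> tuple[float, float]:
        """(D, r^2) between the alt alleles of variants at rows i and j."""
        if self._var[i] == 0.0 or self._var[j] == 0.0:
            raise UndefinedLDError(
                f"LD undefined for monomorphic variant "
                f"{self.panel.variants['id'].iat[i if self._var[i] == 0 else j]}"
            )
        p_ab = float(self._H[i] @ self._H[j]) / self._n
        d = p_ab - self._freq[i] * self._freq[j]
        return d, d * d / (self._var[i] * self._var[j])

    def r2_ids(self, a: str, b: str) -> float:
        return self.d_r2(self.index_of(a), self.index_of(b))[1]

    # -- windowed --------------------------------------------------------
    def window_rows(self, i: int, window_bp: int = DEFAULT_WINDOW_BP) -> np.ndarray:
        """Row indices within +/- window of variant i on its chromosome."""
        same = np.flatnonzero(self._chrom == self._chrom[i])
        pos = self._pos[same]
        lo = np.searchsorted(pos, self._pos[i] - window_bp, side="left")
        hi = np.searchsorted(pos, self._pos[i] + window_bp, side="right")
        return same[lo:hi]

    def window_ld(
        self, i: int, window_bp: int = DEFAULT_WINDOW_BP
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, D, r^2) of variant i against every variant in its window.

        Monomorphic window variants get r^2 = NaN.  Cached per (i, window).
        """
        key = (i, window_bp)
        hit = self._window_cache.get(key)
        if hit is not None:
            return hit
        if self._var[i] == 0.0:
            raise UndefinedLDError(
                f"LD undefined for monomorphic variant "
                f"{self.panel.variants['id'].iat[i]}"
            )
        rows = self.window_rows(i, window_bp)
        p_ab = (self._H[rows] @ self._H[i]) / self._n
        d = p_ab - self._freq[rows] * self._freq[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(
                self._var[rows] > 0.0,
                d * d / (self._var[rows] * self._var[i]),
                np.nan,
            )
        out = (rows, d, r2)
        self._window_cache[key] = out
        return out

    def neighbors(
        self, i: int, r2_min: float, window_bp: int = DEFAULT_WINDOW_BP
    ) -> np.ndarray:
        """Rows of variants (excluding i) with r^2 >= r2_min to variant i."""
        key = (i, r2_min, window_bp)
        hit = self._nbr_cache.get(key)
        if hit is not None:
            return hit
        rows, _, r2 = self.window_ld(i, window_bp)
        with np.errstate(invalid="ignore"):
            mask = (r2 >= r2_min) & (rows != i)  # NaN compares False
        out = rows[mask]
        self._nbr_cache[key] = out
        return out

    def r2_matrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Pairwise r^2 matrix over a (small) list of variant ids."""
        rows = [self.index_of(s) for s in snp_ids]
        X = self._H[rows]
        f = self._freq[rows]
        v = self._var[rows]
        C = (X @ X.T) / self._n - np.outer(f, f)
        with np.errstate(divide="ignore", invalid="ignore"):
            R2 = C * C / np.outer(v, v)
        R2[np.outer(v == 0, np.ones(len(v), bool))] = np.nan
        R2[np.outer(np.ones(len(v), bool), v == 0)] = np.nan
        return R2


def _as_cache(panel_or_cache) -> LDCache:
    if isinstance(panel_or_cache, LDCache):
        return panel_or_cache
    return LDCache(panel_or_cache)


def r2_from_haplotypes(panel, snp_a: str, snp_b: str) -> LDPair:
    """Haplotype-count D and r^2 between the alt alleles of two variants."""
    ld = _as_cache(panel)
    d, r2 = ld.d_r2(ld.index_of(snp_a), ld.index_of(snp_b))
    return LDPair(snp_a, snp_b, D=d, r2=r2)


def _effective_d(ld: LDCache, index: str, index_allele: str, proxy: str) -> float:
    """D between the stated index allele and the proxy's alt allele."""
    var = ld.panel.variants
    i = ld.index_of(index)
    alt = var["alt"].iat[i]
    ref = var["ref"].iat[i]
    if index_allele not in (ref, alt):
        raise NoPredictionError(
            f"allele {index_allele} is neither ref nor alt of {index}"
        )
    d, _ = ld.d_r2(i, ld.index_of(proxy))
    return d if index_allele == alt else -d


def predict_direction(
    panel, index: str, index_allele: str, proxy: str
) -> str:
    """Proxy allele predicted to move the trait in the index allele's direction.

    The prediction is the proxy allele positively coupled (D > 0) with
    the stated index allele on phased haplotypes.  D == 0 admits no
    prediction and raises :class:`NoPredictionError`.
    """
    ld = _as_cache(panel)
    d = _effective_d(ld, index, index_allele, proxy)
    if d == 0.0:
        raise NoPredictionError(f"D = 0 between {index} and {proxy}")
    j = ld.index_of(proxy)
    var = ld.panel.variants
    return var["alt"].iat[j] if d > 0 else var["ref"].iat[j]


def expand_proxies(
    index_snps: Sequence[tuple[str, str]],
    panel,
    r2_min: float = 0.8,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ProxySet]:
    """Proxy sets (r^2 >= ``r2_min`` within +/- ``window_bp``) per index SNP.

    ``index_snps`` is a list of ``(snp_id, trait-increasing allele)``.
    Indices monomorphic in the panel yield an unresolvable ProxySet;
    proxies whose direction cannot be predicted (D == 0) are dropped and
    tallied.
    """
    ld = _as_cache(panel)
    var = ld.panel.variants
    out = []
    for snp_id, allele in index_snps:
        i = ld.index_of(snp_id)
        if not ld.is_polymorphic(snp_id):
            out.append(
                ProxySet(index=snp_id, index_allele=allele, resolvable=False)
            )
            continue
        pset = ProxySet(index=snp_id, index_allele=allele)
        pset.members.append(
            ProxyMember(snp=snp_id, r2=1.0, D=float("nan"), predicted_allele=allele)
        )
        rows, d, r2 = ld.window_ld(i, window_bp)
        alt_is_increasing = allele == var["alt"].iat[i]
        for row, d_j, r2_j in zip(rows, d, r2):
            if row == i or not (r2_j >= r2_min):
                continue
            d_eff = d_j if alt_is_increasing else -d_j
            proxy_id = var["id"].iat[row]
            if d_eff == 0.0:
                pset.dropped.append(proxy_id)
                continue
            pred = var["alt"].iat[row] if d_eff > 0 else var["ref"].iat[row]
            pset.members.append(
                ProxyMember(
                    snp=proxy_id, r2=float(r2_j), D=float(d_eff),
                    predicted_allele=pred,
                )
            )
        out.append(pset)
    return out


def ld_interval(
    snp_id: str,
    panel,
    r2_min: float = 0.8,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> tuple[int, int, int]:
    """(leftmost bp, rightmost bp, width bp) spanned by SNPs tagging ``snp_id``.

    The interval is flanked by the leftmost and rightmost variants with
    r^2 >= ``r2_min`` to the SNP (the SNP itself included), limited to
    the proxy window.
    """
    ld = _as_cache(panel)
    i = ld.index_of(snp_id)
    if not ld.is_polymorphic(snp_id):
        raise UndefinedLDError(f"{snp_id} is monomorphic in panel")
    rows, _, r2 = ld.window_ld(i, window_bp)
    qual = rows[(np.nan_to_num(r2, nan=-1.0) >= r2_min) | (rows == i)]
    pos = ld.panel.variants["pos"].to_numpy()[qual]
    return int(pos.min()), int(pos.max()), int(pos.max() - pos.min())


def fst_two_pop(p1, p2):
    """Wright's fixation index between two populations with equal weights.

    With p_bar = (p1 + p2)/2, H_T = 2 p_bar (1 - p_bar) and H_S the mean
    of the within-population heterozygosities 2 p_i (1 - p_i), returns
    (H_T - H_S)/H_T, and 0 where H_T = 0.  Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2.0
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0.0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    if fst.ndim == 0:
        return float(fst)
    return fst
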