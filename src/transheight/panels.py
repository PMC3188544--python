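"""Phased haplotype panels.

A :class:`HaplotypePanel` holds a binary allele matrix (variants x haplotypes,
0 = reference allele, 1 = alternate allele) for one reference population,
together with the variant coordinates and alleles.  Panels stand in for
phased reference data such as the HapMap CEU and YRI releases: two panels
over the same variant list with divergent allele frequencies and block-wise
linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix over variants x haplotypes for one population.

    Parameters
    ----------
    variants:
        One row per variant with columns ``chrom, pos, id, ref, alt``;
        positions are 1-based bp, strictly increasing within a chromosome.
    haplotypes:
        ``(n_variants, n_haplotypes)`` array with entries in {0, 1}.  The
        number of haplotypes must be even (panels represent diploid
        reference individuals).
    population:
        Free-text population label (e.g. ``"EUR"`` or ``"AFR"``).
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray
    population: str = ""
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise InvalidConfigError(f"variant table missing columns: {missing}")
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.ndim != 2:
            raise InvalidConfigError("haplotype matrix must be 2-D")
        if len(self.variants) != self.haplotypes.shape[0]:
            raise InvalidConfigError(
                "variant table and haplotype matrix disagree on n_variants"
            )
        if self.haplotypes.shape[1] == 0 or self.haplotypes.shape[1] % 2:
            raise InvalidConfigError("n_haplotypes must be even and positive")
        vals = np.unique(self.haplotypes)
        if not np.isin(vals, [0, 1]).all():
            raise InvalidConfigError("haplotype entries must be 0/1")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise InvalidConfigError(
                    "positions must be strictly increasing within a chromosome"
                )
        if self.variants["id"].duplicated().any():
            raise InvalidConfigError("variant ids must be unique")
        self.variants = self.variants.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.variants["id"])}

    # -- basic accessors -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def index_of(self, snp_id: str) -> int:
        """Row index of ``snp_id``; raises ``KeyError`` if absent."""
        return self._index[snp_id]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def alt_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per variant."""
        return self.haplotypes.mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def is_polymorphic(self) -> np.ndarray:
        f = self.alt_frequency()
        return (f > 0.0) & (f < 1.0)

    def subset(self, snp_ids) -> "HaplotypePanel":
        """New panel restricted to ``snp_ids`` (panel order preserved)."""
        rows = sorted(self.index_of(s) for s in snp_ids)
        return HaplotypePanel(
            variants=self.variants.iloc[rows].reset_index(drop=True),
            haplotypes=self.haplotypes[rows],
            population=self.population,
        )

    def same_variants(self, other: "HaplotypePanel") -> bool:
        cols = list(VARIANT_COLUMNS)
        return self.variants[cols].equals(other.variants[cols])
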