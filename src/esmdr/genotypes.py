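"""Genotype matrix container with additive {0,1,2} coding."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive minor-allele dosage matrix.

    Entries are in {0, 1, 2} with :data:`MISSING` (-1) for absent calls.
    Minor-allele frequencies are computed from non-missing entries; columns
    whose computed allele frequency exceeds 0.5 are flipped (0 <-> 2) so the
    coding always counts the minor allele.
    """

    geno: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    orient_minor: bool = True

    def __post_init__(self) -> None:
        g = np.asarray(self.geno)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(g[bad])}")
        self.geno = g.astype(np.int8)
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.geno.shape[1])]
        if len(self.snp_ids) != self.geno.shape[1]:
            raise ValueError("snp_ids length mismatch")
        if self.orient_minor:
            freq = self._allele_freq()
            flip = freq > 0.5
            if flip.any():
                cols = self.geno[:, flip]
                miss = cols == MISSING
                cols = 2 - cols
                cols[miss] = MISSING
                self.geno[:, flip] = cols

    def _allele_freq(self) -> np.ndarray:
        g = self.geno
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(0) > 0, (g * obs).sum(0) / (2.0 * obs.sum(0)), 0.0)

    @property
    def n(self) -> int:
        return self.geno.shape[0]

    @property
    def m(self) -> int:
        return self.geno.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, in [0, 0.5] after orientation."""
        return self._allele_freq()

    def subset_subjects(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.geno[idx], list(self.snp_ids), orient_minor=False)

    def subset_snps(self, cols) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            self.geno[:, cols], [self.snp_ids[j] for j in cols], orient_minor=False
        )
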