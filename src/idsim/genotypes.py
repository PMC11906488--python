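"""Genotype-matrix container shared by the simulator and the estimators.

The matrix holds minor-allele dosages (0/1/2) for one population sample at
segregating biallelic SNPs, together with the per-SNP minor-allele frequency
``p`` computed from that same sample and the physical position of each SNP.
Minor-allele orientation is fixed once, at construction: columns whose
mutant-allele frequency exceeds 0.5 are folded (dosage x -> 2 - x) and
flagged, and frequency ties at 0.5 keep the mutant allele as "minor".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix.

    Parameters
    ----------
    counts : ndarray, shape (n, S), integer
        Minor-allele dosages in {0, 1, 2}.
    p : ndarray, shape (S,)
        Minor-allele frequency of each SNP in the current sample,
        ``p = mean(dosage) / 2``, in (0, 0.5].
    pos : ndarray, shape (S,)
        Physical positions (bp), ascending.
    region_length : int
        Physical length L of the region (bp); denominator of F_ROH.
    flipped : ndarray of bool, shape (S,)
        True where the minor allele is the wild-type allele (the column was
        folded from mutant dosages).
    mut_id : ndarray or None
        Optional originating mutation identifiers.
    """

    counts: np.ndarray
    p: np.ndarray
    pos: np.ndarray
    region_length: int
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]
    mut_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.ascontiguousarray(self.counts, dtype=np.int8)
        self.p = np.asarray(self.p, dtype=np.float64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.flipped is None:
            self.flipped = np.zeros(self.n_snps, dtype=bool)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (individuals x SNPs)")
        if not (len(self.p) == len(self.pos) == self.counts.shape[1]):
            raise ValueError("p, pos and counts disagree on SNP number")
        if np.any(np.diff(self.pos) < 0):
            raise ValueError("SNP positions must be ascending")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_mutant_dosages(
        cls,
        dosages: np.ndarray,
        pos: np.ndarray,
        region_length: int,
        mut_id: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Build from mutant-allele dosages, folding to the minor allele.

        Columns with mutant frequency > 0.5 are folded; ties keep the mutant
        allele. Frequencies are the sample frequencies of the given matrix.
        """
        dosages = np.asarray(dosages)
        q = dosages.mean(axis=0) / 2.0
        flip = q > 0.5
        counts = np.where(flip[None, :], 2 - dosages, dosages).astype(np.int8)
        p = np.where(flip, 1.0 - q, q)
        return cls(
            counts=counts,
            p=p,
            pos=np.asarray(pos, dtype=np.int64),
            region_length=int(region_length),
            flipped=flip,
            mut_id=None if mut_id is None else np.asarray(mut_id),
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset of SNP columns (keeps frequencies as-is, per-sample)."""
        return GenotypeMatrix(
            counts=self.counts[:, index],
            p=self.p[index],
            pos=self.pos[index],
            region_length=self.region_length,
            flipped=self.flipped[index],
            mut_id=None if self.mut_id is None else self.mut_id[index],
        )

    def recompute_p(self) -> np.ndarray:
        """Minor-allele frequencies recomputed from the dosages."""
        return self.counts.mean(axis=0) / 2.0
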