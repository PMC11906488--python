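"""SNP-by-SNP genomic inbreeding coefficients.

Seven per-individual estimators of the inbreeding coefficient F computed
from a minor-allele dosage matrix, using the sample allele frequencies of
the current population:

* ``f_vr1`` / ``f_vr2`` -- drift-based, from the variance of additive
  genetic values: (x - 2p)^2 scaled by 2p(1-p), as a ratio of sums
  (subscript 1) or a mean of per-SNP ratios (subscript 2), minus 1.
* ``f_lh1`` / ``f_lh2`` -- homozygosity-based: deviation of observed from
  Hardy-Weinberg-expected heterozygosity, again ratio-of-sums vs
  mean-of-ratios.
* ``f_nj`` -- the raw proportion of homozygous SNPs, in [0, 1]; affinely
  related to f_lh1, so their Pearson correlation is exactly 1.
* ``f_ya1`` / ``f_ya2`` -- correlation between uniting gametes, with the
  per-SNP term x^2 - (1+2p)x + 2p^2; homozygotes are weighted by the
  inverse of their allele frequency, which makes f_ya2 sensitive to rare
  alleles.

The printed form "x^2 - x" of the homozygosity estimators is implemented as
the heterozygote indicator 1{x=1} (equivalently x(2-x)), which is what
"proportion of homozygous SNPs" requires for 0/1/2 dosages; the literal
x^2 - x reading (0, 0, 2) is available behind ``literal_het=True`` for
audit.

All estimators assume every column is polymorphic in the sample
(0 < p <= 0.5), which the export guarantees.
"""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "maf_prune",
    "f_vr1",
    "f_vr2",
    "f_lh1",
    "f_lh2",
    "f_nj",
    "f_ya1",
    "f_ya2",
    "all_estimators",
    "delta_form_check",
    "SNP_ESTIMATORS",
]


def maf_prune(m: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency below ``threshold``.

    SNPs at exactly the threshold are retained. Frequencies are not
    recomputed: they already describe the current sample.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    keep = m.p >= threshold
    if not keep.any():
        raise ValueError("MAF pruning removed every SNP")
    if keep.all():
        return m
    return m.take_snps(np.flatnonzero(keep))


def _checked(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = m.counts.astype(np.float64)
    p = m.p
    if x.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    two_pq = 2.0 * p * (1.0 - p)
    if np.any(two_pq <= 0.0):
        raise ZeroDivisionError("monomorphic SNP (p(1-p) = 0) in matrix")
    return x, p, two_pq


def _het(x: np.ndarray, literal_het: bool) -> np.ndarray:
    # "x^2 - x" read as the heterozygote indicator; literal form for audit
    return x * x - x if literal_het else (x == 1.0).astype(np.float64)


def f_vr1(m: GenotypeMatrix) -> np.ndarray:
    x, p, two_pq = _checked(m)
    num = ((x - 2.0 * p) ** 2).sum(axis=1)
    return num / two_pq.sum() - 1.0


def f_vr2(m: GenotypeMatrix) -> np.ndarray:
    x, p, two_pq = _checked(m)
    return ((x - 2.0 * p) ** 2 / two_pq).mean(axis=1) - 1.0


def f_lh1(m: GenotypeMatrix, literal_het: bool = False) -> np.ndarray:
    x, p, two_pq = _checked(m)
    return 1.0 - _het(x, literal_het).sum(axis=1) / two_pq.sum()


def f_lh2(m: GenotypeMatrix, literal_het: bool = False) -> np.ndarray:
    x, p, two_pq = _checked(m)
    return 1.0 - (_het(x, literal_het) / two_pq).mean(axis=1)


def f_nj(m: GenotypeMatrix, literal_het: bool = False) -> np.ndarray:
    x = m.counts.astype(np.float64)
    if x.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    return 1.0 - _het(x, literal_het).mean(axis=1)


def _ya_terms(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    x, p, two_pq = _checked(m)
    term = x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    return term, two_pq


def f_ya1(m: GenotypeMatrix) -> np.ndarray:
    term, two_pq = _ya_terms(m)
    return term.sum(axis=1) / two_pq.sum()


def f_ya2(m: GenotypeMatrix) -> np.ndarray:
    term, two_pq = _ya_terms(m)
    return (term / two_pq).mean(axis=1)


SNP_ESTIMATORS = {
    "F_VR1": f_vr1,
    "F_VR2": f_vr2,
    "F_LH1": f_lh1,
    "F_LH2": f_lh2,
    "F_NJ": f_nj,
    "F_YA1": f_ya1,
    "F_YA2": f_ya2,
}


def all_estimators(m: GenotypeMatrix) -> dict[str, np.ndarray]:
    """All seven SNP-by-SNP F estimates, keyed by their usual names."""
    return {name: fn(m) for name, fn in SNP_ESTIMATORS.items()}


def delta_form_check(m: GenotypeMatrix, atol: float = 1e-10) -> bool:
    """Verify the delta identity for f_ya2.

    f_ya2 equals sum(delta_k)/S - 1 where delta is 1/p for minor-allele
    homozygotes, 1/(1-p) for major-allele homozygotes and 0 for
    heterozygotes. Returns True when both forms agree to ``atol`` for every
    individual.
    """
    x = m.counts
    p = m.p
    delta = np.zeros(x.shape, dtype=np.float64)
    delta[x == 2] = (1.0 / p)[np.nonzero(x == 2)[1]]
    delta[x == 0] = (1.0 / (1.0 - p))[np.nonzero(x == 0)[1]]
    alt = delta.mean(axis=1) - 1.0
    return bool(np.allclose(alt, f_ya2(m), rtol=0.0, atol=atol))
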