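"""Deterministic toy datasets used by the test suite and examples."""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["make_fixture"]


def _distinct_sorted_positions(rng, n, length):
    pos = rng.choice(length, size=n, replace=False)
    return np.sort(pos).astype(np.int64)


def _hwe_matrix(rng, n, S, region_length, p_range=(0.1, 0.5)):
    p = rng.uniform(*p_range, size=S)
    dosages = rng.binomial(2, p, size=(n, S)).astype(np.int8)
    # redraw monomorphic columns so every column segregates in the sample
    for _ in range(100):
        mono = (dosages.min(axis=0) == dosages.max(axis=0))
        if not mono.any():
            break
        dosages[:, mono] = rng.binomial(2, p[mono], size=(n, int(mono.sum())))
    return GenotypeMatrix.from_mutant_dosages(
        dosages, _distinct_sorted_positions(rng, S, region_length), region_length
    )


def _inbred_lines(rng, n, S, region_length, f=0.5):
    """Individuals with excess homozygosity: realized inbreeding f."""
    p = rng.uniform(0.1, 0.5, size=S)
    ibd = rng.random(size=(n, S)) < f
    one = rng.binomial(1, p, size=(n, S))
    dosages = np.where(ibd, 2 * one, one + rng.binomial(1, p, size=(n, S)))
    return GenotypeMatrix.from_mutant_dosages(
        dosages.astype(np.int8),
        _distinct_sorted_positions(rng, S, region_length),
        region_length,
    )


def _roh_toy(rng, region_length=10_000_000, spacing=4_000, n=5):
    """n individuals; individual 0 carries one embedded 2-Mb homozygous tract.

    Outside the tract every individual is heterozygous often enough that no
    window is called homozygous; inside [4 Mb, 6 Mb) individual 0 is
    homozygous at every SNP.
    """
    pos = np.arange(spacing, region_length, spacing, dtype=np.int64)
    S = len(pos)
    dosages = rng.binomial(2, np.full(S, 0.5), size=(n, S)).astype(np.int8)
    # guarantee heterozygosity density outside the tract: every 3rd SNP het
    dosages[:, ::3] = 1
    tract = (pos >= 4_000_000) & (pos < 6_000_000)
    dosages[0, tract] = 2 * rng.binomial(1, 0.5, size=int(tract.sum())).astype(np.int8)
    return GenotypeMatrix.from_mutant_dosages(dosages, pos, region_length)


def make_fixture(kind: str, seed: int = 0, **kwargs) -> GenotypeMatrix:
    """Deterministic toy genotype matrices.

    Kinds: ``hwe-20x50`` (20 individuals, 50 HWE SNPs), ``hwe`` (sizes via
    ``n``/``S``), ``inbred-lines`` (excess homozygosity, realized f via
    ``f``), ``roh-toy`` (one embedded 2-Mb homozygous tract on individual 0).
    Identical (kind, seed, kwargs) give identical fixtures.
    """
    rng = np.random.default_rng(seed)
    if kind == "hwe-20x50":
        return _hwe_matrix(rng, 20, 50, region_length=1_000_000)
    if kind == "hwe":
        return _hwe_matrix(
            rng,
            kwargs.pop("n", 100),
            kwargs.pop("S", 200),
            kwargs.pop("region_length", 10_000_000),
            **kwargs,
        )
    if kind == "inbred-lines":
        return _inbred_lines(
            rng,
            kwargs.pop("n", 20),
            kwargs.pop("S", 100),
            kwargs.pop("region_length", 1_000_000),
            **kwargs,
        )
    if kind == "roh-toy":
        return _roh_toy(rng, **kwargs)
    raise KeyError(f"unknown fixture kind {kind!r}")
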