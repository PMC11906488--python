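"""Runs of homozygosity: LD pruning, detection, and ROH-based inbreeding.

Detection follows the sliding-window procedure popularised by the PLINK
``--homozyg`` defaults: a 50-SNP window slides along the chromosome, a
window is called homozygous when it contains at most one heterozygous call,
each SNP's hit rate is the fraction of windows overlapping it that are
homozygous, and SNPs whose hit rate exceeds 5% are ROH-eligible. Maximal
runs of eligible SNPs become segments, which are then split at inter-SNP
gaps above 1 Mb and filtered on SNP count, SNP density and physical span.

The inbreeding coefficient F_ROH is the summed span of an individual's
segments (at or above a length threshold: 0.1, 1 or 5 Mb for the variants
F_R01, F_R1, F_R5) divided by the region length L.

When simulations compress the physical region (keeping N, the per-region
mutation rates and the total map length), all physical ROH parameters are
rescaled by the compression factor so that ROH statistics stay comparable;
:func:`scaled_params` applies the rescaling and logs it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import ceil

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "ROHParams",
    "LDPruneParams",
    "ld_prune",
    "detect_roh",
    "f_roh",
    "roh_inbreeding",
    "scaled_params",
    "REFERENCE_REGION_BP",
    "ROH_THRESHOLDS_BP",
]

logger = logging.getLogger(__name__)

#: physical length of the full-scale genomic regions the defaults refer to
REFERENCE_REGION_BP = 90_000_000

#: length thresholds (bp) defining the F_R01 / F_R1 / F_R5 variants
ROH_THRESHOLDS_BP = {"F_R01": 100_000, "F_R1": 1_000_000, "F_R5": 5_000_000}


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH detection parameters (PLINK-style defaults)."""

    window_snps: int = 50
    window_max_het: int = 1
    hit_fraction: float = 0.05
    min_snps: int = 100
    min_density_bp_per_snp: float = 50_000.0
    max_gap_bp: float = 1_000_000.0
    min_length_bp: float = 100_000.0

    def __post_init__(self) -> None:
        for name in (
            "window_snps",
            "min_snps",
            "min_density_bp_per_snp",
            "max_gap_bp",
            "min_length_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LDPruneParams:
    """Greedy windowed LD pruning (the ``--indep-pairwise 50 5 0.9`` rule)."""

    window_snps: int = 50
    step_snps: int = 5
    r2_threshold: float = 0.9


def scaled_params(
    params: ROHParams = ROHParams(),
    region_length: int = REFERENCE_REGION_BP,
    reference_length: int = REFERENCE_REGION_BP,
) -> tuple[ROHParams, dict[str, float]]:
    """Rescale physical ROH parameters for a compressed region.

    Returns the rescaled detection parameters together with the rescaled
    F_R01/F_R1/F_R5 length thresholds. SNP-count windowing (window size,
    heterozygote allowance, hit fraction) is untouched; ``min_snps`` scales
    with length so that the SNP-count and length filters stay consistent.
    """
    factor = reference_length / region_length
    if factor == 1.0:
        return params, dict(ROH_THRESHOLDS_BP)
    scaled = replace(
        params,
        min_snps=max(2, ceil(params.min_snps / factor)),
        min_density_bp_per_snp=params.min_density_bp_per_snp / factor,
        max_gap_bp=params.max_gap_bp / factor,
        min_length_bp=params.min_length_bp / factor,
    )
    thresholds = {k: v / factor for k, v in ROH_THRESHOLDS_BP.items()}
    logger.info(
        "ROH parameters rescaled by compression factor %.3g: %s", factor, scaled
    )
    return scaled, thresholds


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(m: GenotypeMatrix, params: LDPruneParams = LDPruneParams()) -> GenotypeMatrix:
    """Remove highly linked SNPs by greedy windowed pruning.

    Within each window of ``window_snps`` retained-or-not columns, while any
    retained pair has squared dosage correlation above the threshold, the
    later-positioned member of the first offending pair is removed; the
    window then advances by ``step_snps``.
    """
    S = m.n_snps
    removed = np.zeros(S, dtype=bool)
    x = m.counts.astype(np.float64)
    start = 0
    while start < S - 1:
        idx = np.flatnonzero(~removed[start : start + params.window_snps]) + start
        if len(idx) > 1:
            sub = x[:, idx]
            with np.errstate(invalid="ignore"):
                r2 = np.corrcoef(sub, rowvar=False) ** 2
            np.fill_diagonal(r2, 0.0)
            alive = np.ones(len(idx), dtype=bool)
            # remove the later member of each offending pair, earliest first
            for j in range(1, len(idx)):
                if np.any(r2[:j, j][alive[:j]] > params.r2_threshold):
                    alive[j] = False
            removed[idx[~alive]] = True
        start += params.step_snps
    return m.take_snps(np.flatnonzero(~removed))


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------


def _eligible_snps(het: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean ROH-eligibility of each SNP from the sliding-window scan."""
    S = len(het)
    w = params.window_snps
    het_cum = np.concatenate([[0], np.cumsum(het)])
    win_het = het_cum[w:] - het_cum[:-w]  # heterozygotes per window start
    hom = win_het <= params.window_max_het
    hom_cum = np.concatenate([[0], np.cumsum(hom)])
    i = np.arange(S)
    lo = np.maximum(i - w + 1, 0)
    hi = np.minimum(i, S - w)
    n_windows = hi - lo + 1
    n_hom = hom_cum[hi + 1] - hom_cum[lo]
    return n_hom / n_windows > params.hit_fraction


def _segments_of(eligible: np.ndarray, pos: np.ndarray, params: ROHParams):
    """Maximal eligible runs, gap-split and filtered; yields (start, end, n)."""
    padded = np.concatenate([[False], eligible, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    for a, b in zip(starts, ends):
        # split the run at inter-SNP gaps larger than max_gap_bp
        gaps = np.flatnonzero(np.diff(pos[a:b]) > params.max_gap_bp) + a + 1
        bounds = np.concatenate([[a], gaps, [b]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n = hi - lo
            span = pos[hi - 1] - pos[lo] + 1
            if (
                n >= params.min_snps
                and span / n <= params.min_density_bp_per_snp
                and span >= params.min_length_bp
            ):
                yield int(pos[lo]), int(pos[hi - 1]), int(n)


def detect_roh(m: GenotypeMatrix, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """Detect ROH segments for every individual of a genotype matrix.

    Returns a table with columns individual, start_bp, end_bp, n_snps,
    span_bp. With fewer SNPs than the window size, no calls are made (a
    warning is logged).
    """
    cols = ["individual", "start_bp", "end_bp", "n_snps", "span_bp"]
    if m.n_snps < params.window_snps:
        logger.warning(
            "only %d SNPs (< window of %d): no ROH calls",
            m.n_snps,
            params.window_snps,
        )
        return pd.DataFrame(columns=cols).astype(int)
    rows = []
    for i in range(m.n_individuals):
        het = (m.counts[i] == 1).astype(np.int64)
        eligible = _eligible_snps(het, params)
        for start, end, n in _segments_of(eligible, m.pos, params):
            rows.append((i, start, end, n, end - start + 1))
    return pd.DataFrame(rows, columns=cols).astype(int)


def f_roh(
    segments: pd.DataFrame,
    n_individuals: int,
    region_length: int,
    min_length_bp: float,
) -> np.ndarray:
    """F_ROH per individual: summed span of segments >= min_length_bp over L."""
    f = np.zeros(n_individuals)
    if len(segments):
        kept = segments[segments["span_bp"] >= min_length_bp]
        sums = kept.groupby("individual")["span_bp"].sum()
        f[sums.index.to_numpy()] = sums.to_numpy() / region_length
    return f


def roh_inbreeding(
    m: GenotypeMatrix,
    params: ROHParams | None = None,
    ld: LDPruneParams | None = LDPruneParams(),
    thresholds: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """The three ROH-based F variants on an (optionally LD-pruned) matrix.

    Detection parameters and thresholds default to the values appropriate
    for the matrix's region length (rescaled when compressed).
    """
    if params is None or thresholds is None:
        auto_params, auto_thresholds = scaled_params(
            ROHParams(), region_length=m.region_length
        )
        params = params or auto_params
        thresholds = thresholds or auto_thresholds
    pruned = ld_prune(m, ld) if ld is not None else m
    segments = detect_roh(pruned, params)
    return {
        name: f_roh(segments, m.n_individuals, m.region_length, thr)
        for name, thr in thresholds.items()
    }
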