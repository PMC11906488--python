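"""Forward-time Wright-Fisher simulator with selection and recombination.

Implements an individual-based diploid monoecious population of constant
size N evolving under mutation, recombination, multiplicative fecundity
selection and drift. Mutations fall into four classes:

* neutral (s = 0) -- the SNPs later used to estimate inbreeding,
* deleterious (s < 0, partially recessive) with s drawn from a gamma
  distribution of fitness effects (shape ``beta``, mean ``mean_s``, clamped
  at -1) and dominance h ~ Uniform(0, e^{k s}), k calibrated so that the
  mean dominance coefficient hits a target (default 0.283),
* sterile -- deleterious mutations with s below a threshold (default -0.9),
  tracked separately when partitioning the inbreeding load,
* overdominant (s > 0, h > 1) with fixed coefficients, giving genotypic
  fitnesses 1, 1+sh, 1+s and heterozygote advantage.

Fitness is multiplicative across loci and acts on fecundity: each of the N
offspring draws two parents independently with probability proportional to
fitness (selfing possible at rate ~1/N), each parent contributing one
recombinant, mutated gamete.

Internally the population is a pair of dense haplotype matrices (2N rows by
one column per segregating mutation, selected and neutral kept apart) with
numba inner loops; the module also exposes single-gamete operations
(``meiosis``, ``mutate_gamete``, ``individual_fitness``) on sparse
mutation-id lists, which serve as the reference implementation in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._kernels import fitness_kernel, gather_kernel

__all__ = [
    "NEUTRAL",
    "DELETERIOUS",
    "STERILE",
    "OVERDOMINANT",
    "CLASS_NAMES",
    "GeneticMap",
    "RegionSpec",
    "DFEConfig",
    "ScenarioConfig",
    "Mutation",
    "MutationRegistry",
    "Population",
    "SimulationResult",
    "ExtinctionError",
    "calibrate_k",
    "sample_mutation_effect",
    "locus_fitness_factor",
    "individual_fitness",
    "meiosis",
    "mutate_gamete",
    "next_generation",
    "run_simulation",
    "od_equilibrium_frequency",
    "export_neutral_genotypes",
]

logger = logging.getLogger(__name__)

NEUTRAL, DELETERIOUS, STERILE, OVERDOMINANT = 0, 1, 2, 3
CLASS_NAMES = {
    NEUTRAL: "neutral",
    DELETERIOUS: "deleterious",
    STERILE: "sterile",
    OVERDOMINANT: "overdominant",
}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}


class ExtinctionError(RuntimeError):
    """All individuals have fitness zero; no parent can be drawn."""


_DEFER = object()  # sentinel: delay fitness evaluation until after compaction


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear map from physical position (bp) to genetic position.

    ``breakpoints`` are ascending physical positions and ``cum_cM`` the
    nondecreasing cumulative genetic positions at those points. Crossover
    placement inverts the map at genetic positions drawn uniformly on the
    total genetic length (no interference).
    """

    breakpoints: np.ndarray
    cum_cM: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.float64)
        self.cum_cM = np.asarray(self.cum_cM, dtype=np.float64)
        if self.breakpoints.ndim != 1 or len(self.breakpoints) < 2:
            raise ValueError("map needs at least two points")
        if len(self.breakpoints) != len(self.cum_cM):
            raise ValueError("breakpoints and cum_cM differ in length")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(np.diff(self.cum_cM) < 0):
            raise ValueError("cumulative genetic positions must be nondecreasing")

    @property
    def total_cM(self) -> float:
        return float(self.cum_cM[-1] - self.cum_cM[0])

    @property
    def total_morgans(self) -> float:
        return self.total_cM / 100.0

    def bp_of_cM(self, u):
        """Invert the map: physical position of genetic position(s) ``u``."""
        return np.interp(u, self.cum_cM - self.cum_cM[0], self.breakpoints)

    def cM_of_bp(self, x):
        return np.interp(x, self.breakpoints, self.cum_cM - self.cum_cM[0])

    @classmethod
    def uniform(cls, length_bp: int, total_cM: float) -> "GeneticMap":
        """Uniform-rate map over [0, length_bp] with the given total length."""
        return cls(
            breakpoints=np.array([0.0, float(length_bp)]),
            cum_cM=np.array([0.0, float(total_cM)]),
        )


@dataclass
class RegionSpec:
    """Physical region (length L in bp) with its genetic map."""

    length_bp: int
    map: GeneticMap

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.map.breakpoints[0] > 0 or self.map.breakpoints[-1] < self.length_bp:
            raise ValueError("genetic map must cover [0, length_bp]")

    @classmethod
    def uniform(cls, length_bp: int, total_cM: float) -> "RegionSpec":
        return cls(length_bp=length_bp, map=GeneticMap.uniform(length_bp, total_cM))


@dataclass
class DFEConfig:
    """Distribution of fitness effects of deleterious mutations.

    s = -G with G ~ Gamma(shape ``beta``, mean ``|mean_s|``), clamped at
    ``clamp_s``; h ~ Uniform(0, e^{k s}) with the clamped s. ``k`` is
    calibrated so that E[h] = ``mean_h_target`` (see :func:`calibrate_k`);
    leave it as None to have it solved on first use. Mutations with
    s < ``sterile_threshold`` are classed sterile.
    """

    beta: float = 0.33
    mean_s: float = -0.2
    mean_h_target: float = 0.283
    k: float | None = None
    sterile_threshold: float = -0.9
    clamp_s: float = -1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.mean_s >= 0:
            raise ValueError("mean_s must be negative")
        if not 0 < self.mean_h_target < 1:
            raise ValueError("mean_h_target must be in (0, 1)")
        if not self.clamp_s <= self.sterile_threshold < 0:
            raise ValueError("need clamp_s <= sterile_threshold < 0")

    def ensure_k(self) -> float:
        if self.k is None:
            self.k = calibrate_k(self)
        return self.k


@dataclass
class ScenarioConfig:
    """One simulation scenario: population, rates and region.

    U_* are per-haploid-region mutation rates: the expected number of new
    mutations of that class per gamete per generation.
    """

    N: int
    generations: int
    U_neutral: float
    U_deleterious: float
    U_overdominant: float = 0.0
    od_s: float = 0.02
    od_h: float = 1.5
    seed: int | None = None
    region: RegionSpec = field(
        default_factory=lambda: RegionSpec.uniform(10_000_000, 100.0)
    )
    name: str = ""

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        for u in (self.U_neutral, self.U_deleterious, self.U_overdominant):
            if u < 0:
                raise ValueError("mutation rates must be nonnegative")
        if self.U_overdominant > 0 and not (self.od_s > 0 and self.od_h > 1):
            raise ValueError("overdominance requires od_s > 0 and od_h > 1")


@dataclass
class Mutation:
    """A single variant record."""

    id: int
    pos: int
    s: float
    h: float
    cls: str
    origin_gen: int = 0


# ---------------------------------------------------------------------------
# mutation effects
# ---------------------------------------------------------------------------


def calibrate_k(dfe: DFEConfig, include_clamp: bool = True) -> float:
    """Solve for the dominance-scaling constant k.

    With s = -min(G, |clamp|), G ~ Gamma(beta, theta) and h ~ U(0, e^{ks}),
    E[h] = E[e^{ks}]/2. The expectation has a closed form through the gamma
    moment-generating function; with the clamp it splits into a truncated
    MGF plus the atom at the clamp, both expressible with regularised
    incomplete gamma functions. k is the unique positive root of
    E[h] = mean_h_target (E[h] decreases from 1/2 at k = 0, so targets
    >= 0.5 are unreachable).
    """
    if dfe.mean_h_target >= 0.5:
        raise ValueError("mean_h_target >= 0.5 is unreachable (e^{ks} <= 1)")
    beta = dfe.beta
    theta = abs(dfe.mean_s) / beta
    c = abs(dfe.clamp_s)

    if include_clamp:
        def expected_h(k: float) -> float:
            scale_ratio = 1.0 + k * theta
            trunc = scale_ratio ** (-beta) * special.gammainc(
                beta, c * scale_ratio / theta
            )
            atom = np.exp(-k * c) * special.gammaincc(beta, c / theta)
            return 0.5 * (trunc + atom)
    else:
        def expected_h(k: float) -> float:
            return 0.5 * (1.0 + k * theta) ** (-beta)

    return float(
        optimize.brentq(
            lambda k: expected_h(k) - dfe.mean_h_target, 1e-12, 1e6, xtol=1e-12
        )
    )


def sample_mutation_effect(dfe: DFEConfig, rng: np.random.Generator, size=None):
    """Draw (s, h) for new deleterious mutations.

    s = -G, G ~ Gamma(beta, mean |mean_s|), clamped at clamp_s; h drawn
    uniformly on (0, e^{k s}) using the clamped s.
    """
    k = dfe.ensure_k()
    g = rng.gamma(dfe.beta, abs(dfe.mean_s) / dfe.beta, size=size)
    s = np.maximum(-g, dfe.clamp_s)
    h = rng.uniform(0.0, np.exp(k * s))
    if size is None:
        return float(s), float(h)
    return s, h


def locus_fitness_factor(s: float, h: float, copies: int) -> float:
    """Genotypic fitness factor 1, 1+sh or 1+s for 0, 1 or 2 mutant copies."""
    if copies == 0:
        return 1.0
    if copies == 1:
        return 1.0 + s * h
    if copies == 2:
        return 1.0 + s
    raise ValueError("copies must be 0, 1 or 2")


def individual_fitness(
    hapA: Sequence[int],
    hapB: Sequence[int],
    registry: "MutationRegistry",
) -> float:
    """Multiplicative fitness of an individual from its two haplotypes.

    Reference (sparse) implementation: product of locus factors over every
    non-neutral mutation carried. Used directly for small populations and as
    the brute-force oracle for the matrix engine.
    """
    from collections import Counter

    copies = Counter(hapA)
    copies.update(hapB)
    w = 1.0
    for mid, c in copies.items():
        if registry.cls_of(mid) == NEUTRAL:
            continue
        w *= locus_fitness_factor(registry.s_of(mid), registry.h_of(mid), c)
    return max(w, 0.0)


def od_equilibrium_frequency(s: float, h: float, method: str = "closed") -> float:
    """Stable internal equilibrium of one overdominant locus.

    Genotypic fitnesses are 1, 1+sh, 1+s for 0/1/2 mutant copies. With
    heterozygote advantage (s > 0, h > 1) the mutant-allele equilibrium is
    t1/(t1+t2) with t1 = sh/(1+sh), t2 = (sh-s)/(1+sh), which simplifies to
    h/(2h-1). ``method='recursion'`` iterates the deterministic
    single-locus recursion from q0 = 0.5 to |dq| < 1e-12 instead.
    """
    w11, w12, w22 = 1.0, 1.0 + s * h, 1.0 + s
    if not (w12 > w11 and w12 > w22):
        raise ValueError("not in the overdominant regime (heterozygote not superior)")
    if method == "closed":
        return h / (2.0 * h - 1.0)
    if method == "recursion":
        q = 0.5
        for _ in range(10_000_000):
            p = 1.0 - q
            wbar = p * p * w11 + 2 * p * q * w12 + q * q * w22
            q_new = (q * q * w22 + p * q * w12) / wbar
            if abs(q_new - q) < 1e-12:
                return q_new
            q = q_new
        raise RuntimeError("recursion failed to converge")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# mutation registry
# ---------------------------------------------------------------------------


class MutationRegistry:
    """Append-only table of every mutation that ever arose.

    Records are stored in columnar chunks; ids are consecutive integers in
    order of appearance. Final status (segregating / fixed / lost) and
    frequencies are attached by :meth:`to_dataframe` at the end of a run.
    """

    def __init__(self) -> None:
        self._chunks: list[tuple] = []
        self.n = 0
        self._cache: dict | None = None

    def record_batch(self, pos, s, h, cls, origin_gen: int) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        m = len(pos)
        ids = np.arange(self.n, self.n + m, dtype=np.int64)
        self._chunks.append(
            (
                pos,
                np.asarray(s, dtype=np.float64),
                np.asarray(h, dtype=np.float64),
                np.asarray(cls, dtype=np.int8),
                np.full(m, origin_gen, dtype=np.int64),
            )
        )
        self.n += m
        self._cache = None
        return ids

    def record(self, pos: int, s: float, h: float, cls: int, origin_gen: int = 0) -> int:
        return int(
            self.record_batch([pos], [s], [h], [cls], origin_gen)[0]
        )

    def _arrays(self) -> dict:
        if self._cache is None:
            if self._chunks:
                cols = list(zip(*self._chunks))
                self._cache = {
                    "pos": np.concatenate(cols[0]),
                    "s": np.concatenate(cols[1]),
                    "h": np.concatenate(cols[2]),
                    "cls": np.concatenate(cols[3]),
                    "origin_gen": np.concatenate(cols[4]),
                }
            else:
                self._cache = {
                    "pos": np.empty(0, dtype=np.int64),
                    "s": np.empty(0),
                    "h": np.empty(0),
                    "cls": np.empty(0, dtype=np.int8),
                    "origin_gen": np.empty(0, dtype=np.int64),
                }
        return self._cache

    def pos_of(self, mid: int) -> int:
        return int(self._arrays()["pos"][mid])

    def s_of(self, mid: int) -> float:
        return float(self._arrays()["s"][mid])

    def h_of(self, mid: int) -> float:
        return float(self._arrays()["h"][mid])

    def cls_of(self, mid: int) -> int:
        return int(self._arrays()["cls"][mid])

    def to_dataframe(self, pop: "Population | None" = None) -> pd.DataFrame:
        """Full mutation table; with ``pop`` given, adds count/freq/status."""
        arr = self._arrays()
        df = pd.DataFrame(
            {
                "id": np.arange(self.n, dtype=np.int64),
                "pos": arr["pos"],
                "s": arr["s"],
                "h": arr["h"],
                "cls": pd.Categorical.from_codes(
                    arr["cls"], categories=[CLASS_NAMES[i] for i in range(4)]
                ),
                "origin_gen": arr["origin_gen"],
            }
        )
        if pop is not None:
            count = np.zeros(self.n, dtype=np.int64)
            status = np.full(self.n, "lost", dtype=object)
            for ids, counts in (
                (pop.sel_ids, pop.H_sel.sum(axis=0, dtype=np.int64)),
                (pop.neu_ids, pop.H_neu.sum(axis=0, dtype=np.int64)),
            ):
                count[ids] = counts
                status[ids[(counts > 0) & (counts < 2 * pop.N)]] = "segregating"
                status[ids[counts == 2 * pop.N]] = "fixed"
            if pop.fixed_ids:
                fixed = np.asarray(pop.fixed_ids, dtype=np.int64)
                count[fixed] = 2 * pop.N
                status[fixed] = "fixed"
            df["count"] = count
            df["freq"] = count / (2.0 * pop.N)
            df["status"] = status
        return df


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Population state: dense haplotype matrices over segregating mutations.

    Rows 2i and 2i+1 of each matrix are the two haplotypes of individual i.
    Selected (non-neutral) and neutral mutations are stored separately so
    that fitness evaluation touches only the selected columns. Mutations
    lost or fixed are purged every generation; fixed non-neutral mutations
    multiply every individual's fitness by the same constant and are
    therefore dropped from fitness computation (fitness is relative).
    """

    N: int
    generation: int = 0
    registry: MutationRegistry = field(default_factory=MutationRegistry)
    H_sel: np.ndarray = None  # type: ignore[assignment]
    sel_ids: np.ndarray = None  # type: ignore[assignment]
    sel_pos: np.ndarray = None  # type: ignore[assignment]
    sel_s: np.ndarray = None  # type: ignore[assignment]
    sel_h: np.ndarray = None  # type: ignore[assignment]
    sel_cls: np.ndarray = None  # type: ignore[assignment]
    H_neu: np.ndarray = None  # type: ignore[assignment]
    neu_ids: np.ndarray = None  # type: ignore[assignment]
    neu_pos: np.ndarray = None  # type: ignore[assignment]
    fitness: np.ndarray | None = None
    fixed_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n2 = 2 * self.N
        if self.H_sel is None:
            self.H_sel = np.zeros((n2, 0), dtype=np.uint8)
            self.sel_ids = np.empty(0, dtype=np.int64)
            self.sel_pos = np.empty(0, dtype=np.int64)
            self.sel_s = np.empty(0)
            self.sel_h = np.empty(0)
            self.sel_cls = np.empty(0, dtype=np.int8)
        if self.H_neu is None:
            self.H_neu = np.zeros((n2, 0), dtype=np.uint8)
            self.neu_ids = np.empty(0, dtype=np.int64)
            self.neu_pos = np.empty(0, dtype=np.int64)
        if self.fitness is None:
            self.fitness = self.compute_fitness()
        elif self.fitness is _DEFER:
            self.fitness = None

    def log_factors(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore"):
            lhet = np.log1p(self.sel_s * self.sel_h)
            lhom = np.log1p(self.sel_s)
        return lhet, lhom

    def compute_fitness(self) -> np.ndarray:
        lhet, lhom = self.log_factors()
        return fitness_kernel(self.H_sel, lhet, lhom)

    def compact(self) -> None:
        """Drop lost columns and archive fixed ones (in place).

        Lost (count 0) and fixed (count 2N) mutations no longer vary among
        individuals: a fixed non-neutral mutation multiplies every fitness
        by the same constant, which cancels in fecundity-proportional
        sampling, so both can be removed from the segregating bookkeeping.
        """
        n2 = 2 * self.N
        c = self.H_sel.sum(axis=0, dtype=np.int64)
        keep = (c > 0) & (c < n2)
        if not keep.all():
            self.fixed_ids.extend(self.sel_ids[c == n2].tolist())
            self.H_sel = self.H_sel[:, keep]
            self.sel_ids = self.sel_ids[keep]
            self.sel_pos = self.sel_pos[keep]
            self.sel_s = self.sel_s[keep]
            self.sel_h = self.sel_h[keep]
            self.sel_cls = self.sel_cls[keep]
        c = self.H_neu.sum(axis=0, dtype=np.int64)
        keep = (c > 0) & (c < n2)
        if not keep.all():
            self.fixed_ids.extend(self.neu_ids[c == n2].tolist())
            self.H_neu = self.H_neu[:, keep]
            self.neu_ids = self.neu_ids[keep]
            self.neu_pos = self.neu_pos[keep]

    def haplotype_ids(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """The two haplotypes of individual i as arrays of mutation ids."""
        out = []
        for r in (2 * i, 2 * i + 1):
            ids = np.concatenate(
                [self.sel_ids[self.H_sel[r] > 0], self.neu_ids[self.H_neu[r] > 0]]
            )
            out.append(np.sort(ids))
        return out[0], out[1]

    def allele_counts(self) -> dict[int, int]:
        """Mutant-allele counts of all segregating mutations, from haplotypes."""
        counts = {}
        for ids, H in ((self.sel_ids, self.H_sel), (self.neu_ids, self.H_neu)):
            c = H.sum(axis=0, dtype=np.int64)
            counts.update(zip(ids.tolist(), c.tolist()))
        return counts


# ---------------------------------------------------------------------------
# single-gamete reference operations
# ---------------------------------------------------------------------------


def meiosis(
    hapA: np.ndarray,
    hapB: np.ndarray,
    positions: Mapping[int, int],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a parent's two haplotypes (sparse reference form).

    Draw order: starting haplotype (probability 1/2 each), crossover count
    ~ Poisson(total map length in Morgans), crossover physical positions by
    inverting the map at uniform genetic positions. The gamete takes
    alternating parental haplotypes between crossovers; no interference.
    """
    hapA = np.asarray(hapA, dtype=np.int64)
    hapB = np.asarray(hapB, dtype=np.int64)
    start = int(rng.integers(0, 2))
    k = int(rng.poisson(gmap.total_morgans))
    first, second = (hapA, hapB) if start == 0 else (hapB, hapA)
    if k == 0:
        return np.sort(first.copy())
    cross_bp = np.sort(gmap.bp_of_cM(rng.uniform(0.0, gmap.total_cM, size=k)))

    def seg(hap):
        pos = np.array([positions[m] for m in hap], dtype=np.float64)
        return np.searchsorted(cross_bp, pos, side="right")

    keep_first = first[seg(first) % 2 == 0]
    keep_second = second[seg(second) % 2 == 1]
    return np.sort(np.concatenate([keep_first, keep_second]))


def mutate_gamete(
    gamete: np.ndarray,
    cfg: ScenarioConfig,
    dfe: DFEConfig,
    rng: np.random.Generator,
    registry: MutationRegistry,
    generation: int = 0,
) -> np.ndarray:
    """Add new mutations to one gamete (sparse reference form).

    Per-class counts are Poisson with the per-gamete rates U_*; positions
    are uniform on [0, length_bp); deleterious effects come from the DFE
    (classed sterile below the threshold), overdominant effects are fixed,
    neutral mutations have s = 0. New records are appended to the registry.
    """
    L = cfg.region.length_bp
    new_ids = []
    n = rng.poisson(cfg.U_neutral)
    if n:
        ids = registry.record_batch(
            rng.integers(0, L, size=n),
            np.zeros(n),
            np.full(n, 0.5),
            np.full(n, NEUTRAL),
            generation,
        )
        new_ids.append(ids)
    n = rng.poisson(cfg.U_deleterious)
    if n:
        s, h = sample_mutation_effect(dfe, rng, size=n)
        cls = np.where(s < dfe.sterile_threshold, STERILE, DELETERIOUS)
        ids = registry.record_batch(
            rng.integers(0, L, size=n), s, h, cls, generation
        )
        new_ids.append(ids)
    n = rng.poisson(cfg.U_overdominant)
    if n:
        ids = registry.record_batch(
            rng.integers(0, L, size=n),
            np.full(n, cfg.od_s),
            np.full(n, cfg.od_h),
            np.full(n, OVERDOMINANT),
            generation,
        )
        new_ids.append(ids)
    if not new_ids:
        return np.asarray(gamete, dtype=np.int64)
    return np.concatenate([np.asarray(gamete, dtype=np.int64)] + new_ids)


# ---------------------------------------------------------------------------
# generation step (matrix engine)
# ---------------------------------------------------------------------------


def _sorted_crossovers(rng, gmap, n_gametes):
    """Per-gamete sorted crossover positions in CSR layout."""
    k = rng.poisson(gmap.total_morgans, size=n_gametes)
    total = int(k.sum())
    offsets = np.zeros(n_gametes + 1, dtype=np.int64)
    np.cumsum(k, out=offsets[1:])
    if total == 0:
        return np.empty(0), offsets
    u = rng.uniform(0.0, gmap.total_cM, size=total)
    bp = gmap.bp_of_cM(u)
    gamete_idx = np.repeat(np.arange(n_gametes), k)
    order = np.lexsort((bp, gamete_idx))
    return bp[order], offsets


def _new_mutation_columns(rng, cfg, dfe, registry, generation):
    """Draw this generation's new mutations for all 2N gametes.

    Returns (gamete_row, pos, s, h, cls, ids) concatenated over classes in
    the documented order: neutral, deleterious, overdominant.
    """
    n2 = 2 * cfg.N
    L = cfg.region.length_bp
    rows, poss, ss, hs, clss = [], [], [], [], []

    counts = rng.poisson(cfg.U_neutral, size=n2)
    m = int(counts.sum())
    if m:
        rows.append(np.repeat(np.arange(n2), counts))
        poss.append(rng.integers(0, L, size=m))
        ss.append(np.zeros(m))
        hs.append(np.full(m, 0.5))
        clss.append(np.full(m, NEUTRAL, dtype=np.int8))

    counts = rng.poisson(cfg.U_deleterious, size=n2)
    m = int(counts.sum())
    if m:
        s, h = sample_mutation_effect(dfe, rng, size=m)
        rows.append(np.repeat(np.arange(n2), counts))
        poss.append(rng.integers(0, L, size=m))
        ss.append(s)
        hs.append(h)
        clss.append(
            np.where(s < dfe.sterile_threshold, STERILE, DELETERIOUS).astype(np.int8)
        )

    counts = rng.poisson(cfg.U_overdominant, size=n2)
    m = int(counts.sum())
    if m:
        rows.append(np.repeat(np.arange(n2), counts))
        poss.append(rng.integers(0, L, size=m))
        ss.append(np.full(m, cfg.od_s))
        hs.append(np.full(m, cfg.od_h))
        clss.append(np.full(m, OVERDOMINANT, dtype=np.int8))

    if not rows:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0), np.empty(0), np.empty(0, np.int8), empty
    row = np.concatenate(rows)
    pos = np.concatenate(poss).astype(np.int64)
    s = np.concatenate(ss)
    h = np.concatenate(hs)
    cls = np.concatenate(clss)
    ids = registry.record_batch(pos, s, h, cls, generation)
    return row, pos, s, h, cls, ids


def next_generation(
    pop: Population,
    cfg: ScenarioConfig,
    dfe: DFEConfig,
    rng: np.random.Generator,
) -> Population:
    """Advance the population by one generation of fecundity selection.

    Each of the 2N gametes draws its parent independently with probability
    proportional to fitness (monoecious, with replacement, so selfing
    happens with probability ~1/N), recombines, and mutates. Lost and fixed
    mutations are purged afterwards.
    """
    N = pop.N
    n2 = 2 * N
    w = pop.fitness
    wsum = w.sum()
    if wsum <= 0:
        raise ExtinctionError("all individuals have fitness zero")

    # documented draw order: parents, start haplotypes, crossovers, mutations
    parents = rng.choice(N, size=n2, p=w / wsum)
    starts = rng.integers(0, 2, size=n2).astype(np.int64)
    cross_bp, offsets = _sorted_crossovers(rng, cfg.region.map, n2)

    gen = pop.generation + 1
    row, mpos, ms, mh, mcls, mids = _new_mutation_columns(
        rng, cfg, dfe, pop.registry, gen
    )
    neu_new = mcls == NEUTRAL
    sel_new = ~neu_new

    def reproduce(H, pos, new_mask):
        """Gamete matrix with this generation's new columns merge-inserted.

        Columns stay position-sorted: old column l goes to slot
        l + #{new pos < pos[l]}, new column j (new columns sorted by
        position, ties after old columns) to #{old pos <= pos} + j.
        Returns the matrix, merge slots for old/new columns, and the
        new-column order.
        """
        L = H.shape[1]
        new_order = np.argsort(mpos[new_mask], kind="stable")
        npos = mpos[new_mask][new_order]
        m = len(npos)
        idx_old = np.arange(L) + np.searchsorted(npos, pos, side="left")
        idx_new = np.searchsorted(pos, npos, side="right") + np.arange(m)
        G = np.zeros((n2, L + m), dtype=np.uint8)
        gather_kernel(
            H, parents, starts, cross_bp, offsets,
            pos.astype(np.float64), idx_old, G,
        )
        if m:
            G[row[new_mask][new_order], idx_new] = 1
        return G, idx_old, idx_new, new_order

    def merge(idx_old, idx_new, old, new_vals, new_order):
        out = np.empty(len(idx_old) + len(idx_new), dtype=old.dtype)
        out[idx_old] = old
        out[idx_new] = new_vals[new_order]
        return out

    G_sel, io_s, in_s, ord_s = reproduce(pop.H_sel, pop.sel_pos, sel_new)
    G_neu, io_n, in_n, ord_n = reproduce(pop.H_neu, pop.neu_pos, neu_new)

    new = Population(
        N=N,
        generation=gen,
        registry=pop.registry,
        H_sel=G_sel,
        sel_ids=merge(io_s, in_s, pop.sel_ids, mids[sel_new], ord_s),
        sel_pos=merge(io_s, in_s, pop.sel_pos, mpos[sel_new], ord_s),
        sel_s=merge(io_s, in_s, pop.sel_s, ms[sel_new], ord_s),
        sel_h=merge(io_s, in_s, pop.sel_h, mh[sel_new], ord_s),
        sel_cls=merge(io_s, in_s, pop.sel_cls, mcls[sel_new], ord_s),
        H_neu=G_neu,
        neu_ids=merge(io_n, in_n, pop.neu_ids, mids[neu_new], ord_n),
        neu_pos=merge(io_n, in_n, pop.neu_pos, mpos[neu_new], ord_n),
        fixed_ids=list(pop.fixed_ids),
        fitness=_DEFER,
    )
    # lost/fixed columns are inert for fitness; sweep them out periodically
    if gen % 8 == 0:
        new.compact()
    new.fitness = new.compute_fitness()
    return new


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Final population with the mutation registry and per-class summaries."""

    population: Population
    registry: pd.DataFrame
    summary: pd.DataFrame
    cfg: ScenarioConfig
    dfe: DFEConfig

    def export_neutral_genotypes(self):
        return export_neutral_genotypes(self.population, self.cfg)


def class_summary(registry: pd.DataFrame) -> pd.DataFrame:
    """Per-class segregating counts and mean mutant-allele frequency."""
    seg = registry[registry["status"] == "segregating"]
    rows = []
    for name in [CLASS_NAMES[i] for i in range(4)]:
        sub = seg[seg["cls"] == name]
        rows.append(
            {
                "cls": name,
                "n_segregating": len(sub),
                "mean_freq": float(sub["freq"].mean()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cls")


def _run_sparse(cfg: ScenarioConfig, dfe: DFEConfig, rng) -> Population:
    """Sparse-engine generation loop; draw order matches the dense path."""
    from ._sparse import SparseGroup, sparse_fitness

    N = cfg.N
    n2 = 2 * N
    registry = MutationRegistry()
    sel = SparseGroup(n2)
    sel.meta = {
        "ids": np.empty(0, dtype=np.int64),
        "s": np.empty(0),
        "h": np.empty(0),
        "cls": np.empty(0, dtype=np.int8),
    }
    neu = SparseGroup(n2)
    neu.meta = {"ids": np.empty(0, dtype=np.int64)}
    fixed_ids: list[int] = []
    w = np.ones(N)
    for gen in range(1, cfg.generations + 1):
        wsum = w.sum()
        if wsum <= 0:
            raise ExtinctionError("all individuals have fitness zero")
        parents = rng.choice(N, size=n2, p=w / wsum)
        starts = rng.integers(0, 2, size=n2).astype(np.int64)
        cross_bp, offsets = _sorted_crossovers(rng, cfg.region.map, n2)
        row, mpos, ms, mh, mcls, mids = _new_mutation_columns(
            rng, cfg, dfe, registry, gen
        )
        neu_new = mcls == NEUTRAL
        sel_new = ~neu_new
        sel.reproduce(
            parents, starts, cross_bp, offsets,
            row[sel_new], mpos[sel_new],
            {
                "ids": mids[sel_new],
                "s": ms[sel_new],
                "h": mh[sel_new],
                "cls": mcls[sel_new],
            },
        )
        neu.reproduce(
            parents, starts, cross_bp, offsets,
            row[neu_new], mpos[neu_new], {"ids": mids[neu_new]},
        )
        if gen % 8 == 0 or gen == cfg.generations:
            fixed_ids.extend(sel.compact(n2).tolist())
            fixed_ids.extend(neu.compact(n2).tolist())
        with np.errstate(divide="ignore"):
            lhet = np.log1p(sel.meta["s"] * sel.meta["h"])
            lhom = np.log1p(sel.meta["s"])
        w = sparse_fitness(sel.indptr, sel.indices, lhet, lhom, N)
    return Population(
        N=N,
        generation=cfg.generations,
        registry=registry,
        H_sel=sel.to_dense(n2),
        sel_ids=sel.meta["ids"],
        sel_pos=sel.pos,
        sel_s=sel.meta["s"],
        sel_h=sel.meta["h"],
        sel_cls=sel.meta["cls"],
        H_neu=neu.to_dense(n2),
        neu_ids=neu.meta["ids"],
        neu_pos=neu.pos,
        fixed_ids=fixed_ids,
    )


def run_simulation(
    cfg: ScenarioConfig,
    dfe: DFEConfig | None = None,
    rng: np.random.Generator | None = None,
    engine: str = "sparse",
) -> SimulationResult:
    """Run cfg.generations of the scenario and summarise the final state.

    Deterministic given (cfg, dfe, seed): identical inputs give
    bit-identical registries and genotype exports, with either engine
    (``sparse`` is the fast production engine; ``dense`` the reference
    implementation built on :func:`next_generation`).
    """
    if dfe is None:
        dfe = DFEConfig()
    dfe.ensure_k()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if engine == "sparse":
        pop = _run_sparse(cfg, dfe, rng)
    elif engine == "dense":
        pop = Population(N=cfg.N)
        for _ in range(cfg.generations):
            pop = next_generation(pop, cfg, dfe, rng)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    pop.compact()
    registry = pop.registry.to_dataframe(pop)
    return SimulationResult(
        population=pop,
        registry=registry,
        summary=class_summary(registry),
        cfg=cfg,
        dfe=dfe,
    )


def export_neutral_genotypes(pop: Population, cfg: ScenarioConfig):
    """Genotype matrix of segregating neutral SNPs, minor-allele coded.

    Columns are position-sorted; neutral mutations landing on an occupied
    position are dropped (keeping the first-arisen), with the dropped count
    logged. Fixed and lost mutations are never present (purged each
    generation).
    """
    from .genotypes import GenotypeMatrix

    c = pop.H_neu.sum(axis=0, dtype=np.int64)
    if np.any((c == 0) | (c == 2 * pop.N)):
        pop.compact()
    order = np.lexsort((pop.neu_ids, pop.neu_pos))
    pos = pop.neu_pos[order]
    ids = pop.neu_ids[order]
    dup = np.zeros(len(pos), dtype=bool)
    dup[1:] = pos[1:] == pos[:-1]
    if dup.any():
        logger.info("dropping %d duplicate-position neutral SNPs", int(dup.sum()))
    keep = order[~dup]
    if keep.size == 0:
        logger.warning("no neutral SNP segregates; empty genotype matrix")
    H = pop.H_neu[:, keep]
    dosages = (H[0::2].astype(np.int16) + H[1::2]).astype(np.int8)
    return GenotypeMatrix.from_mutant_dosages(
        dosages, pop.neu_pos[keep], cfg.region.length_bp, mut_id=pop.neu_ids[keep]
    )
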