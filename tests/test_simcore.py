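"""Simulator core: DFE sampling, fitness, meiosis, generation step, runs."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from idsim import (
    DFEConfig,
    GeneticMap,
    MutationRegistry,
    Population,
    RegionSpec,
    ScenarioConfig,
    calibrate_k,
    individual_fitness,
    locus_fitness_factor,
    meiosis,
    mutate_gamete,
    next_generation,
    od_equilibrium_frequency,
    run_simulation,
    sample_mutation_effect,
)
from idsim.simcore import (
    DELETERIOUS,
    NEUTRAL,
    STERILE,
    ExtinctionError,
    _sorted_crossovers,
)


# ---------------------------------------------------------------------------
# DFE and dominance calibration
# ---------------------------------------------------------------------------


def _bisect_pure_mgf_k(beta, mean_s, target):
    """Independent oracle: bisection on (1 + k|s|/beta)^(-beta) = 2*target."""
    theta = abs(mean_s) / beta
    lo, hi = 0.0, 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if 0.5 * (1 + mid * theta) ** (-beta) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_calibrate_k_matches_bisection_oracle():
    dfe = DFEConfig()
    k_oracle = _bisect_pure_mgf_k(0.33, -0.2, 0.283)
    assert calibrate_k(dfe, include_clamp=False) == pytest.approx(k_oracle, abs=1e-8)
    # the clamp correction is a small positive shift of k
    k = calibrate_k(dfe)
    assert 0 < k - k_oracle < 0.01


def test_calibrate_k_limits_and_errors():
    # target -> 1/2 corresponds to h ~ U(0,1), i.e. k -> 0
    assert calibrate_k(DFEConfig(mean_h_target=0.49999)) < 1e-3
    with pytest.raises(ValueError):
        calibrate_k(DFEConfig(mean_h_target=0.5))


def test_sampled_mean_h_hits_calibration_target(rng):
    dfe = DFEConfig()
    s, h = sample_mutation_effect(dfe, rng, size=2_000_000)
    assert np.mean(h) == pytest.approx(0.283, abs=0.002)


def test_sampled_s_clamped_gamma(rng):
    dfe = DFEConfig()
    s, h = sample_mutation_effect(dfe, rng, size=1_000_000)
    assert s.max() <= 0 and s.min() == -1.0
    assert np.any(s == -1.0)  # the clamp atom is real at these parameters
    # closed-form mean of min(G, 1), G ~ Gamma(0.33, mean 0.2)
    beta, theta = dfe.beta, abs(dfe.mean_s) / dfe.beta
    m = abs(dfe.mean_s) * special.gammainc(beta + 1, 1 / theta) + special.gammaincc(
        beta, 1 / theta
    )
    assert np.mean(s) == pytest.approx(-m, abs=3 * np.std(s) / 1000)
    # the *unclamped* gamma has mean 0.2 by construction; the clamp bites
    assert -m > dfe.mean_s
    # h is bounded by its per-draw envelope e^{ks}
    assert np.all(h <= np.exp(dfe.k * s))


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s,h,copies,expected",
    [
        (0.02, 1.5, 1, 1.03),
        (-0.2, 0.5, 2, 0.8),
        (-0.2, 0.1, 0, 1.0),
        (-1.0, 0.0, 2, 0.0),
    ],
)
def test_locus_fitness_factor(s, h, copies, expected):
    assert locus_fitness_factor(s, h, copies) == pytest.approx(expected)


def test_individual_fitness_reference_cases():
    reg = MutationRegistry()
    od1 = reg.record(100, 0.02, 1.5, 3)
    od2 = reg.record(200, 0.02, 1.5, 3)
    lethal = reg.record(300, -1.0, 0.0, STERILE)
    neut = reg.record(400, 0.0, 0.5, NEUTRAL)
    assert individual_fitness([], [], reg) == 1.0
    assert individual_fitness([od1, od2, neut], [neut], reg) == pytest.approx(1.03**2)
    assert individual_fitness([lethal], [lethal], reg) == 0.0


def test_population_fitness_matches_bruteforce(small_run):
    """Matrix-engine fitness equals a per-locus recomputation from scratch."""
    pop = small_run.population
    reg = pop.registry
    for i in range(0, pop.N, 17):
        hapA, hapB = pop.haplotype_ids(i)
        assert pop.fitness[i] == pytest.approx(
            individual_fitness(hapA.tolist(), hapB.tolist(), reg), rel=1e-9
        )


# ---------------------------------------------------------------------------
# meiosis and mutation
# ---------------------------------------------------------------------------


def test_meiosis_zero_map_copies_one_haplotype(rng):
    gmap = GeneticMap(breakpoints=[0.0, 1e6], cum_cM=[0.0, 0.0])
    positions = {1: 100, 2: 200, 3: 300}
    for _ in range(10):
        g = meiosis([1, 3], [2], positions, gmap, rng)
        assert g.tolist() in ([1, 3], [2])


def test_meiosis_homozygous_parent_invariant(rng):
    gmap = GeneticMap.uniform(1_000_000, 200.0)  # 2 Morgans: many crossovers
    positions = {i: i * 1000 for i in range(1, 100)}
    hap = list(range(1, 100))
    for _ in range(20):
        assert meiosis(hap, hap, positions, gmap, rng).tolist() == hap


def test_crossover_count_is_poisson_with_map_length(rng):
    gmap = GeneticMap.uniform(10_000_000, 100.0)  # 1 Morgan
    bp, offsets = _sorted_crossovers(rng, gmap, 100_000)
    counts = np.diff(offsets)
    assert counts.mean() == pytest.approx(1.0, abs=0.01)
    assert np.var(counts) == pytest.approx(1.0, abs=0.03)  # Poisson dispersion
    assert bp.min() >= 0 and bp.max() <= 10_000_000


def test_mutate_gamete_rates(rng):
    region = RegionSpec.uniform(1_000_000, 100.0)
    cfg0 = ScenarioConfig(
        N=10, generations=1, U_neutral=0, U_deleterious=0, region=region
    )
    dfe = DFEConfig()
    reg = MutationRegistry()
    assert mutate_gamete([5], cfg0, dfe, rng, reg).tolist() == [5]
    cfg = ScenarioConfig(
        N=10, generations=1, U_neutral=0.0, U_deleterious=0.07, region=region
    )
    n = 100_000
    total = sum(len(mutate_gamete([], cfg, dfe, rng, reg)) for _ in range(n))
    se = np.sqrt(0.07 / n)
    assert total / n == pytest.approx(0.07, abs=3 * se)
    df = reg.to_dataframe()
    assert set(df["cls"].unique()) <= {"deleterious", "sterile"}
    assert (df.loc[df["cls"] == "sterile", "s"] < -0.9).all()


# ---------------------------------------------------------------------------
# generation step
# ---------------------------------------------------------------------------


def _population_with_private_markers(N, lethal_for=()):
    """Each individual homozygous for a private neutral marker; optionally
    homozygous for a private s = -1 allele."""
    reg = MutationRegistry()
    n2 = 2 * N
    H_neu = np.zeros((n2, N), dtype=np.uint8)
    ids = []
    for i in range(N):
        ids.append(reg.record(1000 * (i + 1), 0.0, 0.5, NEUTRAL))
        H_neu[2 * i, i] = H_neu[2 * i + 1, i] = 1
    sel_cols = []
    H_sel = np.zeros((n2, len(lethal_for)), dtype=np.uint8)
    for j, i in enumerate(lethal_for):
        sel_cols.append(reg.record(500 + j, -1.0, 0.0, STERILE))
        H_sel[2 * i, j] = H_sel[2 * i + 1, j] = 1
    return Population(
        N=N,
        registry=reg,
        H_neu=H_neu,
        neu_ids=np.array(ids, dtype=np.int64),
        neu_pos=np.arange(1000, 1000 * (N + 1), 1000, dtype=np.int64),
        H_sel=H_sel,
        sel_ids=np.array(sel_cols, dtype=np.int64),
        sel_pos=np.arange(500, 500 + len(lethal_for), dtype=np.int64),
        sel_s=np.full(len(lethal_for), -1.0),
        sel_h=np.zeros(len(lethal_for)),
        sel_cls=np.full(len(lethal_for), STERILE, dtype=np.int8),
    )


def _neutral_cfg(N, generations=1, total_cM=100.0):
    return ScenarioConfig(
        N=N,
        generations=generations,
        U_neutral=0.0,
        U_deleterious=0.0,
        region=RegionSpec.uniform(1_000_000, total_cM),
    )


def test_equal_fitness_gives_uniform_parent_choice(rng):
    """Private-marker counts across repeated single generations are uniform."""
    N = 40
    base = _population_with_private_markers(N)
    cfg = _neutral_cfg(N)
    dfe = DFEConfig()
    counts = np.zeros(N)
    reps = 120
    for _ in range(reps):
        off = next_generation(base, cfg, dfe, rng)
        # dosage sum of marker i counts gametes contributed by parent i
        idx = np.searchsorted(off.neu_ids, base.neu_ids[np.isin(base.neu_ids, off.neu_ids)])
        c = np.zeros(N)
        present = np.isin(base.neu_ids, off.neu_ids)
        c[present] = off.H_neu.sum(axis=0)[idx]
        counts += c
    total = counts.sum()
    chi2 = ((counts - total / N) ** 2 / (total / N)).sum()
    assert stats.chi2.sf(chi2, N - 1) > 0.01


def test_zero_fitness_parent_never_sampled(rng):
    N = 30
    base = _population_with_private_markers(N, lethal_for=(0,))
    assert base.fitness[0] == 0.0
    cfg = _neutral_cfg(N)
    for _ in range(30):
        off = next_generation(base, cfg, DFEConfig(), rng)
        off.compact()
        assert base.neu_ids[0] not in off.neu_ids  # marker of individual 0 gone
        assert off.H_neu.shape[0] == 2 * N  # constant population size


def test_extinction_raises(rng):
    base = _population_with_private_markers(5, lethal_for=(0, 1, 2, 3, 4))
    with pytest.raises(ExtinctionError):
        next_generation(base, _neutral_cfg(5), DFEConfig(), rng)


def test_neutral_frequency_is_martingale(rng):
    """Mean final frequency of a p0 = 0.3 neutral locus stays 0.3 (drift only)."""
    N = 50
    reps, gens = 300, 30
    finals = []
    cfg = _neutral_cfg(N)
    dfe = DFEConfig()
    for _ in range(reps):
        reg = MutationRegistry()
        mid = reg.record(500_000, 0.0, 0.5, NEUTRAL)
        H = np.zeros((2 * N, 1), dtype=np.uint8)
        carriers = rng.choice(2 * N, size=30, replace=False)  # p0 = 0.3
        H[carriers, 0] = 1
        pop = Population(
            N=N,
            registry=reg,
            H_neu=H,
            neu_ids=np.array([mid]),
            neu_pos=np.array([500_000]),
        )
        for _ in range(gens):
            pop = next_generation(pop, cfg, dfe, rng)
        c = pop.H_neu.sum() if pop.H_neu.shape[1] else (
            2 * N if mid in pop.fixed_ids else 0
        )
        finals.append(c / (2 * N))
    se = np.std(finals, ddof=1) / np.sqrt(reps)
    assert np.mean(finals) == pytest.approx(0.3, abs=3 * se)


def test_registry_counts_match_haplotypes(small_run):
    pop = small_run.population
    from_hap = pop.allele_counts()
    seg = small_run.registry[small_run.registry["status"] == "segregating"]
    assert dict(zip(seg["id"], seg["count"])) == from_hap


# ---------------------------------------------------------------------------
# whole runs
# ---------------------------------------------------------------------------


def test_seed_determinism_and_engine_equivalence():
    cfg = ScenarioConfig(
        N=50,
        generations=100,
        U_neutral=1.37,
        U_deleterious=0.07,
        U_overdominant=0.002,
        seed=3,
        region=RegionSpec.uniform(10_000_000, 100.0),
    )
    a = run_simulation(cfg, engine="sparse")
    b = run_simulation(cfg, engine="sparse")
    c = run_simulation(cfg, engine="dense")
    pd.testing.assert_frame_equal(a.registry, b.registry)
    pd.testing.assert_frame_equal(a.registry, c.registry)
    ma, mc = a.export_neutral_genotypes(), c.export_neutral_genotypes()
    assert np.array_equal(ma.counts, mc.counts)
    assert np.array_equal(ma.pos, mc.pos)
    assert np.allclose(a.population.fitness, c.population.fitness)
    d = run_simulation(
        ScenarioConfig(**{**cfg.__dict__, "seed": 4}), engine="sparse"
    )
    assert not d.registry.equals(a.registry)


def test_neutral_run_matches_watterson_expectation():
    """Segregating-site count under pure drift vs the coalescent prediction."""
    N, U = 100, 2.0
    cfg = ScenarioConfig(
        N=N,
        generations=8 * N,
        U_neutral=U,
        U_deleterious=0.0,
        seed=5,
        region=RegionSpec.uniform(10_000_000, 100.0),
    )
    res = run_simulation(cfg)
    theta = 4 * N * U
    expected = theta * np.sum(1.0 / np.arange(1, 2 * N))
    observed = res.summary.loc["neutral", "n_segregating"]
    assert abs(observed - expected) / expected < 0.15


def test_overdominant_frequency_approaches_equilibrium():
    """Mean frequency of standing OD loci nears h/(2h-1) as N*s grows.

    Forty unlinked overdominant loci start at frequency 0.5 with no further
    mutation; after 400 generations the surviving loci's mean frequency
    should approach the deterministic equilibrium as N increases.
    """
    from idsim.simcore import OVERDOMINANT

    def final_mean_freq(N, seed):
        rng = np.random.default_rng(seed)
        n_loci = 40
        reg = MutationRegistry()
        pos = np.sort(rng.choice(10_000_000, n_loci, replace=False))
        ids = reg.record_batch(
            pos, np.full(n_loci, 0.02), np.full(n_loci, 1.5),
            np.full(n_loci, OVERDOMINANT), 0,
        )
        pop = Population(
            N=N,
            registry=reg,
            H_sel=(rng.random((2 * N, n_loci)) < 0.5).astype(np.uint8),
            sel_ids=ids,
            sel_pos=pos,
            sel_s=np.full(n_loci, 0.02),
            sel_h=np.full(n_loci, 1.5),
            sel_cls=np.full(n_loci, OVERDOMINANT, dtype=np.int8),
        )
        cfg = ScenarioConfig(
            N=N, generations=1, U_neutral=0, U_deleterious=0,
            region=RegionSpec.uniform(10_000_000, 100.0),
        )
        dfe = DFEConfig()
        for _ in range(400):
            pop = next_generation(pop, cfg, dfe, rng)
        pop.compact()
        c = pop.H_sel.sum(axis=0)
        return c.sum() / (2 * N) / len(c)

    eq = od_equilibrium_frequency(0.02, 1.5)
    means = [final_mean_freq(N, seed) for N, seed in ((30, 1), (120, 2), (480, 3))]
    assert means[1] < means[2]
    assert abs(means[1] - eq) < abs(means[0] - eq)
    assert abs(means[2] - eq) < 0.05


# ---------------------------------------------------------------------------
# overdominance equilibrium
# ---------------------------------------------------------------------------


def test_od_equilibrium_reference_values():
    assert od_equilibrium_frequency(0.02, 1.5) == 0.75
    assert od_equilibrium_frequency(0.02, 1.5, "recursion") == pytest.approx(
        0.75, abs=1e-9
    )
    assert od_equilibrium_frequency(0.02, 1e9) == pytest.approx(0.5, rel=1e-6)
    with pytest.raises(ValueError):
        od_equilibrium_frequency(0.02, 0.5)  # heterozygote not superior


def test_od_equilibrium_closed_form_equals_recursion(rng):
    for _ in range(100):
        s = rng.uniform(0.001, 0.5)
        h = rng.uniform(1.05, 5.0)
        closed = od_equilibrium_frequency(s, h)
        iterated = od_equilibrium_frequency(s, h, "recursion")
        assert closed == pytest.approx(iterated, abs=1e-9)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def test_export_neutral_genotypes(small_run):
    m = small_run.export_neutral_genotypes()
    assert np.all(np.diff(m.pos) > 0)  # sorted, duplicates dropped
    assert np.all((m.p > 0) & (m.p <= 0.5))
    assert np.allclose(m.recompute_p(), m.p)
    seg_neutral = small_run.registry.query(
        "cls == 'neutral' and status == 'segregating'"
    )
    assert m.n_snps <= len(seg_neutral)
    assert m.n_snps >= len(seg_neutral) - len(seg_neutral["pos"]) + len(
        seg_neutral["pos"].unique()
    )


def test_genetic_map_inversion_roundtrip():
    gmap = GeneticMap(breakpoints=[0, 2e6, 10e6], cum_cM=[0.0, 30.0, 100.0])
    u = np.linspace(0, 100, 33)
    assert np.allclose(gmap.cM_of_bp(gmap.bp_of_cM(u)), u)
    assert gmap.total_morgans == pytest.approx(1.0)
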