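# Methods

## Generative model

`idsim.simcore` implements an individual-based Wright–Fisher model:
diploid, monoecious, constant size N, discrete generations, random mating
with selfing allowed at its incidental rate (~1/N, because both parents of
an offspring are drawn independently with replacement). Selection is on
fecundity: every offspring survives, and the probability that an
individual is drawn as a parent is proportional to its fitness, which is
the product over its non-neutral loci of the genotypic factors 1, 1+sh,
1+s for 0/1/2 mutant copies. Because parent sampling uses relative
fitness, mutations that fix multiply every individual's fitness by the
same constant and are dropped from the fitness computation; lost and
fixed mutations are swept from the segregating bookkeeping every eight
generations (an implementation schedule with no effect on the dynamics)
and always before any analysis or export.

Recombination uses a piecewise-linear genetic map: the crossover count per
meiosis is Poisson with mean the map length in Morgans, and crossover
physical positions are obtained by inverting the map at uniform genetic
positions (no interference). Mutations arise per gamete as Poisson counts
with per-haploid-region rates U_neutral, U_deleterious, U_overdominant and
land uniformly on the region; positions may collide (duplicate-position
neutral SNPs are dropped at export, with a logged count).

### Distribution of fitness effects

Deleterious selection coefficients are s = −G, G ~ Gamma(shape β = 0.33,
mean 0.2); draws below −1 are clamped to −1, and mutations with s < −0.9
are classed *sterile* (a label used when partitioning the inbreeding
load; they obey the same genotypic-fitness formula). Dominance is
h ~ Uniform(0, e^{ks}), drawn with the *clamped* s (the order is a
modelling choice; at these parameters it shifts E[h] by ~3·10⁻⁴ and is
configurable in principle through the DFE parameters). The constant k
solves E[h] = 0.283 exactly:

E[h] = ½·E[e^{k·max(−G,−1)}]
     = ½[(1+kθ)^{−β}·P(β, (1+kθ)/θ) + e^{−k}·Q(β, 1/θ)],

with θ the gamma scale and P/Q the regularised incomplete gamma
functions; the root (k ≈ 7.609) is found by Brent's method. Note that the
*clamped* mean selection coefficient is E[min(G,1)] ≈ 0.18, not 0.20: the
nominal mean −0.2 describes the gamma distribution before clamping.

Overdominant mutations have fixed s = 0.02, h = 1.5, so the heterozygote
(1.03) beats both homozygotes (1, 1.02). The deterministic one-locus
equilibrium frequency of the mutant allele is h/(2h−1) = 0.75
(`od_equilibrium_frequency`, closed form or iterated recursion).

### Engines

Two interchangeable engines exist. The dense reference engine
(`next_generation`) stores haplotypes as 2N×L 0/1 matrices over
segregating mutations and is the implementation the unit tests exercise
directly. The production engine (`run_simulation`'s default) stores each
haplotype as a sorted array of column indices (CSR) and performs meiosis
by binary-searching crossover cut points — selected loci are sparse
(tens of mutations per haplotype), which makes this ~5× faster at full
scale. Both draw from one seeded numpy Generator in the same documented
order (parents, start haplotypes, crossovers, new mutations per class),
so identical (scenario, DFE, seed) give bit-identical mutation registries
and genotype exports; the suite asserts this equivalence.

## Scenario presets and scaling choices

The shipped presets (`no-od`/`low-od`/`high-od` at N = 1000 and 10,000)
carry the benchmark's reference rates: at N = 1000, U_neutral = 1.37, U_deleterious =
0.07 (chosen so the load is about one sterile equivalent), U_overdominant
= 1.5·10⁻⁴ (low) or 7.5·10⁻⁴ (high), for 10,000 generations on a 90-Mb
region. The presets use a uniform 100-cM map — a stand-in for empirical
human maps of ~90-Mb regions (~1.1 cM/Mb); map heterogeneity is the one
feature of the original setting this package deliberately does not
emulate.

Two scaled-down run shapes keep the test suite and the acceptance script
within desk runtimes; both are the package's own choices and are stated
here once:

* **Compressed region** (used everywhere): physical length shrunk to
  10 Mb with N, all per-region U and the 100-cM map length kept. The
  quantities of interest — B, segregating selected counts, overdominant
  frequencies — are driven by N, U and the DFE, not physical length;
  only SNP density changes, so all physical ROH parameters (min length,
  density, gap, minimum SNP count) are rescaled by the 9× compression
  (`idsim.roh.scaled_params`).
* **Desk evaluation scenario** (`desk_scenario`): N = 200 run for 2,000
  generations (10N, enough for mutation–selection–drift
  quasi-equilibrium), U_neutral and U_deleterious kept (the deleterious
  load is rate-driven, not N-driven), and the low-OD rate raised to
  2·10⁻³ so that the overdominant share of the load over the shorter run
  is comparable to the full-scale Low-OD share (~30%). At this N the
  absolute load is smaller (B ≈ 0.4–0.8, weakly selected mutations drift
  out faster), which is why the desk scenario is used only for
  *qualitative* estimator-ranking checks, never for calibrating B.

Load-calibration and standing-variation runs omit neutral mutations
(U_neutral = 0): neutral sites never touch fitness, so selected-locus
dynamics and B are distribution-identical, at ~10× less work.

## Inbreeding estimators

All SNP-by-SNP estimators use minor-allele dosages and the sample
frequencies of the analysed population (no base-population frequencies).
Monomorphic columns never occur (the export keeps only segregating
SNPs). The printed "x²−x" numerator of the homozygosity-based estimators
is implemented as the heterozygote indicator 1{x=1} — required for F_NJ
to be the proportion of homozygous SNPs when dosages are 0/1/2 — with the
literal x²−x form available behind `literal_het=True` for audit. MAF
pruning drops SNPs with p < threshold (boundary retained) and does not
recompute frequencies.

ROH detection follows the familiar sliding-window defaults: 50-SNP
windows, at most one heterozygote per "homozygous" window, SNPs whose
fraction of homozygous overlapping windows exceeds 0.05 are eligible,
maximal eligible runs are split at inter-SNP gaps > 1 Mb and filtered on
≥100 SNPs, ≥1 SNP/50 kb and a minimum span; the three F_R variants
(0.1/1/5 Mb) are obtained by post-filtering the same segment set rather
than re-running detection. The window heterozygote allowance and the 5%
hit fraction are the detection tool's documented defaults. Segment span
is last−first SNP position + 1. LD pruning is the greedy windowed rule
(window 50, step 5, r² > 0.9 removes the later-positioned SNP of the
first offending pair, repeatedly). No missing genotypes exist, so no
missing-call allowances are implemented.

## Load and regression

B = Σ 2dpq over segregating non-neutral loci, d = s(h−½) for
deleterious/sterile and s(h−½)/(1+sh) for overdominant alleles, with q
the mutant frequency. The estimated rate of inbreeding depression for a
measure F is minus the OLS slope of ln(fitness) on F over the final
generation's individuals (all N, no binning), so the estimate is directly
comparable to B. Individuals with zero fitness (homozygotes for s = −1,
which essentially never appear at N ≥ 1000 but occasionally do in the
small desk scenario) are excluded from the regression with a logged
warning, since their log-fitness is undefined. Figure-style correlations
use raw fitness by default (`log=True` available). Replicate aggregation
pools deviations and reports the standard error of means over replicates;
RMSE is computed against each replicate's own B.

## Numerical choices and degenerate inputs

* k-calibration: Brent on [10⁻¹², 10⁶], xtol 10⁻¹²; targets ≥ 0.5 raise
  (e^{ks} ≤ 1 makes them unreachable).
* Equilibrium recursion: iterate from q₀ = 0.5 until |Δq| < 10⁻¹²;
  non-overdominant regimes raise.
* Fitness uses log-space accumulation; log1p(−1) = −inf propagates to
  fitness 0 without special-casing.
* Minor-allele folding: ties at frequency 0.5 keep the mutant allele as
  minor; orientation is recorded and survives VCF round trips via a flag.
* All-zero-fitness populations raise an extinction error; an empty
  neutral export warns; MAF pruning that removes every SNP raises.
* Coordinates are 0-based half-open internally and 1-based in VCF.

## What passing tests do and do not show

The suite verifies the machinery (estimators, ROH, LD pruning and both
engines against brute-force oracles; analytic equilibria; calibrations)
and reproduces the full-scale calibration targets (B near one sterile
equivalent, ~1250 segregating deleterious sites, ~114 overdominant sites
near frequency 0.75 under Low OD) plus the qualitative estimator ranking
at desk scale. It does not simulate empirical recombination-map
heterogeneity, real population history, genotyping error or missing
data — conclusions about real data inherit those caveats. The mean
overdominant-allele frequency under Low OD comes out near 0.74 on the
uniform map, slightly above the ~0.71 seen with heterogeneous maps, which
is consistent with reduced interference when recombination has no cold
spots.

## Known limitations

* One region per run; no separate sexes; no non-constant N; no
  tree-sequence recording.
* Dominance models beyond those stated (uniform-exponential for
  deleterious, fixed for overdominant) are not supported.
* The ID regression assumes strictly positive fitness; threshold/logistic
  alternatives for mortality-type traits are out of scope.
* Pedigree inbreeding and detection of balancing selection are out of
  scope.
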