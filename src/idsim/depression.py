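"""Inbreeding load, depression regression, and estimator evaluation.

The true (expected) rate of inbreeding depression is the inbreeding load

    B = sum over segregating fitness-affecting loci of 2 d p q,

with q the mutant and p = 1 - q the wild-type frequency and the dominance
deviation d = s(h - 1/2) for deleterious and sterile alleles or
d = s(h - 1/2)/(1 + sh) for overdominant ones. B is in log-fitness units
("sterile equivalents") and is partitioned by mutation class.

The *estimated* rate for a given inbreeding measure F is minus the slope of
the ordinary least-squares regression of log individual fitness on F, which
is the standard estimator under multiplicative fitness with strictly
positive fitness values. Estimates are compared with B through proportional
deviations (est - B)/B, their central 95% interval over replicates, the
root-mean-square error, and the Pearson correlation of F with fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import estimators as est_mod
from . import roh as roh_mod
from .simcore import (
    DFEConfig,
    ScenarioConfig,
    SimulationResult,
    run_simulation,
)

__all__ = [
    "InbreedingLoad",
    "RegressionResult",
    "EvaluationSummary",
    "compute_d",
    "compute_B",
    "estimate_id",
    "proportional_deviation",
    "rmse",
    "correlate_f_fitness",
    "evaluate_replicate",
    "evaluate_scenario",
]

logger = logging.getLogger(__name__)

_DEL_CLASSES = ("deleterious", "sterile")


def compute_d(s: float, h: float, cls: str) -> float:
    """Dominance deviation d of one mutation.

    d = s(h - 1/2) for deleterious and sterile alleles and
    d = s(h - 1/2)/(1 + sh) for overdominant ones; neutral mutations have
    no d (error).
    """
    if cls in _DEL_CLASSES:
        return s * (h - 0.5)
    if cls == "overdominant":
        return s * (h - 0.5) / (1.0 + s * h)
    raise ValueError(f"no dominance deviation for class {cls!r}")


@dataclass(frozen=True)
class InbreedingLoad:
    """B partitioned by mutation class (log-fitness units)."""

    b_del: float
    b_ste: float
    b_od: float

    @property
    def total(self) -> float:
        return self.b_del + self.b_ste + self.b_od


def compute_B(registry: pd.DataFrame) -> InbreedingLoad:
    """Inbreeding load from a mutation registry table.

    Sums 2 d q (1-q) over rows with status 'segregating' and a non-neutral
    class; ``freq`` must hold current mutant-allele frequencies.
    """
    seg = registry
    if "status" in registry.columns:
        seg = registry[registry["status"] == "segregating"]
    parts = {}
    for cls in ("deleterious", "sterile", "overdominant"):
        sub = seg[seg["cls"] == cls]
        if len(sub) == 0:
            parts[cls] = 0.0
            continue
        s = sub["s"].to_numpy()
        h = sub["h"].to_numpy()
        q = sub["freq"].to_numpy()
        d = s * (h - 0.5)
        if cls == "overdominant":
            d = d / (1.0 + s * h)
        parts[cls] = float(np.sum(2.0 * d * q * (1.0 - q)))
    return InbreedingLoad(
        b_del=parts["deleterious"], b_ste=parts["sterile"], b_od=parts["overdominant"]
    )


@dataclass
class RegressionResult:
    """OLS fit of log fitness on an inbreeding measure."""

    slope: float
    intercept: float
    se_slope: float
    n: int
    sm_results: object = field(repr=False, default=None)

    @property
    def id_estimate(self) -> float:
        """Estimated rate of inbreeding depression, -slope (estimand B)."""
        return -self.slope


def estimate_id(fitness: np.ndarray, f_values: np.ndarray) -> RegressionResult:
    """Regress log fitness on an F measure; the ID estimate is -slope."""
    fitness = np.asarray(fitness, dtype=np.float64)
    f_values = np.asarray(f_values, dtype=np.float64)
    if np.any(fitness <= 0):
        raise ValueError("fitness must be strictly positive for the log regression")
    if np.ptp(f_values) == 0:
        raise ValueError("F has zero variance; slope undefined")
    X = sm.add_constant(f_values)
    res = sm.OLS(np.log(fitness), X).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        se_slope=float(res.bse[1]),
        n=len(fitness),
        sm_results=res,
    )


def proportional_deviation(id_estimate: float, B: float) -> float:
    """(estimate - B)/B: +1 is a 100% overestimate, -1 a 100% underestimate."""
    if B <= 0:
        raise ValueError("B must be positive")
    return (id_estimate - B) / B


def rmse(id_estimates: np.ndarray, B) -> float:
    """Root mean squared error of replicate estimates around the true B."""
    id_estimates = np.asarray(id_estimates, dtype=np.float64)
    return float(np.sqrt(np.mean((id_estimates - np.asarray(B)) ** 2)))


def correlate_f_fitness(
    f_values: np.ndarray, fitness: np.ndarray, log: bool = False
) -> float:
    """Pearson correlation of an F measure with (raw, or log) fitness."""
    y = np.log(fitness) if log else np.asarray(fitness, dtype=np.float64)
    return float(np.corrcoef(np.asarray(f_values, dtype=np.float64), y)[0, 1])


# ---------------------------------------------------------------------------
# scenario evaluation
# ---------------------------------------------------------------------------


def _all_measures(result: SimulationResult, maf: float | None) -> dict[str, np.ndarray]:
    """All F measures for one finished replicate.

    SNP-by-SNP estimators on the (optionally MAF-pruned) neutral-SNP matrix;
    ROH variants on its LD-pruned version, with detection parameters
    rescaled to the region's compression.
    """
    m = result.export_neutral_genotypes()
    if maf:
        m = est_mod.maf_prune(m, maf)
    measures = est_mod.all_estimators(m)
    measures.update(roh_mod.roh_inbreeding(m))
    return measures


def evaluate_replicate(
    result: SimulationResult, maf: float | None = None
) -> pd.DataFrame:
    """Per-measure ID estimate, deviation and fitness correlation for one run."""
    load = compute_B(result.registry)
    fitness = result.population.fitness
    ok = fitness > 0
    if not ok.all():
        logger.warning(
            "excluding %d zero-fitness individuals from the log regression",
            int((~ok).sum()),
        )
    rows = []
    for name, f_values in _all_measures(result, maf).items():
        if np.ptp(f_values[ok]) == 0:
            reg_id, corr = np.nan, np.nan
        else:
            reg_id = estimate_id(fitness[ok], f_values[ok]).id_estimate
            corr = correlate_f_fitness(f_values[ok], fitness[ok])
        rows.append(
            {
                "measure": name,
                "id_estimate": reg_id,
                "deviation": proportional_deviation(reg_id, load.total)
                if load.total > 0
                else np.nan,
                "corr_fitness": corr,
                "B_total": load.total,
                "B_del": load.b_del,
                "B_ste": load.b_ste,
                "B_od": load.b_od,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationSummary:
    """Replicate-aggregated estimator evaluation for one scenario.

    ``table`` is indexed by measure with the mean proportional deviation,
    its standard error over replicates, the 2.5%/97.5% deviation quantiles,
    the RMSE against the per-replicate true B, and the mean and SE of the
    F-fitness correlation. ``replicates`` keeps the per-replicate values.
    """

    scenario: str
    maf: float | None
    n_replicates: int
    table: pd.DataFrame
    replicates: pd.DataFrame

    @property
    def mean_B(self) -> float:
        per_rep = self.replicates.groupby("replicate")["B_total"].first()
        return float(per_rep.mean())


def summarize_replicates(
    reps: pd.DataFrame, scenario: str = "", maf: float | None = None
) -> EvaluationSummary:
    """Aggregate per-replicate measure tables into an EvaluationSummary."""
    n_rep = reps["replicate"].nunique()
    rows = []
    for name, g in reps.groupby("measure", sort=False):
        dev = g["deviation"].to_numpy()
        corr = g["corr_fitness"].to_numpy()
        errs = g["id_estimate"].to_numpy() - g["B_total"].to_numpy()
        rows.append(
            {
                "measure": name,
                "mean_deviation": np.nanmean(dev),
                "se_deviation": np.nanstd(dev, ddof=1) / np.sqrt(len(dev)),
                "dev_q2.5": np.nanquantile(dev, 0.025),
                "dev_q97.5": np.nanquantile(dev, 0.975),
                "rmse": float(np.sqrt(np.nanmean(errs**2))),
                "mean_corr_fitness": np.nanmean(corr),
                "se_corr_fitness": np.nanstd(corr, ddof=1) / np.sqrt(len(corr)),
            }
        )
    table = pd.DataFrame(rows).set_index("measure")
    return EvaluationSummary(
        scenario=scenario,
        maf=maf,
        n_replicates=n_rep,
        table=table,
        replicates=reps,
    )


def evaluate_scenario(
    cfg: ScenarioConfig,
    dfe: DFEConfig | None = None,
    n_replicates: int = 20,
    maf: float | None = None,
    base_seed: int | None = None,
) -> EvaluationSummary:
    """Full pipeline over independent replicates of one scenario.

    Each replicate runs the simulation (seeded base_seed + r), exports the
    neutral SNPs, computes every F measure, the true load B, and the ID
    regression for each measure; deviations, RMSE and correlations are then
    aggregated over replicates with standard errors of means.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if dfe is None:
        dfe = DFEConfig()
    if base_seed is None:
        base_seed = cfg.seed if cfg.seed is not None else 0
    all_reps = []
    for r in range(n_replicates):
        cfg_r = ScenarioConfig(
            **{**cfg.__dict__, "seed": base_seed + r, "name": cfg.name}
        )
        result = run_simulation(cfg_r, dfe)
        rep = evaluate_replicate(result, maf)
        rep.insert(0, "replicate", r)
        all_reps.append(rep)
        logger.info("replicate %d/%d done", r + 1, n_replicates)
    reps = pd.concat(all_reps, ignore_index=True)
    return summarize_replicates(reps, scenario=cfg.name or "scenario", maf=maf)


def plot_deviations(summary: EvaluationSummary, ax=None):
    """Bar chart of mean proportional deviations with 95% replicate bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = summary.table
    x = np.arange(len(t))
    ax.bar(x, t["mean_deviation"], color="#4878a8")
    ax.vlines(x, t["dev_q2.5"], t["dev_q97.5"], color="black", lw=1)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks(x, t.index, rotation=45, ha="right")
    ax.set_ylabel("proportional deviation of ID")
    ax.set_title(f"{summary.scenario} (MAF {summary.maf or 'none'})")
    return ax
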