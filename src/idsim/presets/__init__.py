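"""Scenario presets and desk-scale variants.

The shipped YAML presets encode the benchmark's reference conditions (mutation rates per
haploid region per generation, selection and dominance coefficients, DFE
shape) for the three overdominance levels at N = 1000 and N = 10,000 on a
90-Mb region with a 100-cM uniform map. :func:`load_preset` reads them;
:func:`compressed` shrinks the physical region while keeping N, the
per-region rates and the total map length (SNP density changes, so ROH
parameters must be rescaled -- see :mod:`idsim.roh`).

:func:`desk_scenario` returns the package's scaled-down evaluation
conditions: N = 200 run for 2,000 generations (10N, enough to reach
mutation-selection-drift quasi-equilibrium) on a compressed 10-Mb/100-cM
region, keeping U_neutral and U_deleterious (the load from partially
recessive mutations is driven by U, not N), with the overdominant rate
raised so that the cumulative flux of established overdominant alleles over
the shorter run yields an overdominant share of the load comparable to the
full-scale low/high scenarios.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import replace

import yaml

from ..simcore import DFEConfig, RegionSpec, ScenarioConfig

__all__ = ["available_presets", "load_preset", "compressed", "desk_scenario",
           "config_from_dict"]

_DESK_U_OD = {"no-od": 0.0, "low-od": 0.002, "high-od": 0.01}


def _preset_dir():
    return importlib.resources.files("idsim.presets")


def available_presets() -> list[str]:
    return sorted(
        p.name.removesuffix(".yaml")
        for p in _preset_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def config_from_dict(doc: dict, seed: int | None = None):
    """(ScenarioConfig, DFEConfig) from a parsed preset/config mapping."""
    sc = dict(doc["scenario"])
    reg = sc.pop("region")
    region = RegionSpec.uniform(int(reg["length_bp"]), float(reg["total_cM"]))
    cfg = ScenarioConfig(
        region=region, seed=seed, name=doc.get("name", ""), **sc
    )
    dfe = DFEConfig(**doc.get("dfe", {}))
    return cfg, dfe


def load_preset(name: str, seed: int | None = None):
    """Load a shipped preset by name (e.g. ``no-od-n1000``)."""
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    return config_from_dict(yaml.safe_load(text), seed=seed)


def compressed(
    cfg: ScenarioConfig, length_bp: int = 10_000_000
) -> ScenarioConfig:
    """Same scenario on a physically compressed region.

    Keeps N, all per-region mutation rates and the total genetic length;
    only the physical length (hence SNP density and physical ROH scales)
    shrinks.
    """
    region = RegionSpec.uniform(length_bp, cfg.region.map.total_cM)
    return replace(cfg, region=region)


def desk_scenario(kind: str, seed: int | None = None,
                  generations: int = 2000, N: int = 200):
    """Scaled-down evaluation scenario ('no-od', 'low-od' or 'high-od')."""
    if kind not in _DESK_U_OD:
        raise KeyError(f"kind must be one of {sorted(_DESK_U_OD)}")
    cfg = ScenarioConfig(
        N=N,
        generations=generations,
        U_neutral=1.37,
        U_deleterious=0.07,
        U_overdominant=_DESK_U_OD[kind],
        od_s=0.02,
        od_h=1.5,
        seed=seed,
        region=RegionSpec.uniform(10_000_000, 100.0),
        name=f"desk-{kind}",
    )
    return cfg, DFEConfig()
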