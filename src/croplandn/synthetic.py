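"""Synthetic input tables with known ground truth.

Every downstream stage of the pipeline (meta-analysis, budgeting,
mitigation, cost-benefit, scenarios) is exercised against tables drawn
here, whose generating parameters are known exactly, so estimator bias,
interval coverage and end-to-end parameter recovery are all testable
without any external data.

The generator emulates five table families:

* field observations — control/treatment mean pairs per measure ×
  outcome cell.  Control means are lognormal (field fluxes are positive
  and right-skewed); treatment means multiply the control by
  exp(true effect + Gaussian log-scale noise), which keeps every mean
  positive and makes the log response ratio the natural estimand;
* regional cropland N budgets — five inputs, harvest and six loss
  fluxes, constructed to close exactly (inputs = outputs, soil stock
  change zero by convention), with NUE spanning a configurable range;
* measure specifications — abatement efficacies derived from the
  configured true effects, plus per-region implementation rates;
* economic parameter tables — unit abatement costs, US-reference
  ecosystem damage costs with WTP/PGDP transfer terms, health and
  (signed) climate unit costs, crop and fertilizer prices.  One region
  ("USA") is always present as the willingness-to-pay reference;
* targets, region attributes and scenario demand trajectories.

Default magnitudes are set to the conditions the study design reports:
eleven measures cutting total N losses by 30-70% while raising yield by
10-30% and NUE by 10-80% (the enhanced-efficiency-fertilizer cell is
anchored at −47% total loss, +25% yield, +18% NUE), 17 observations per
cell (≈1,500 in the full grid), and log-scale observation noise of 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .budget import RegionBudget, TargetSpec
from .econ import EconParams
from .meta import FieldObservation
from .mitigation import MeasureSpec
from .vocab import LOSS_PATHWAYS, MEASURES, OUTCOMES, TIER_OF_MEASURE

__all__ = [
    "SyntheticConfig",
    "ConfigError",
    "DEFAULT_TRUE_EFFECTS",
    "generate_observations",
    "generate_budgets",
    "generate_measures",
    "generate_econ_params",
    "generate_targets",
    "generate_attributes",
    "generate_demand",
    "measures_from_true_effects",
    "SyntheticWorld",
    "generate_world",
]


class ConfigError(ValueError):
    pass


def _pct(p: float) -> float:
    """ln response ratio for a percentage change."""
    return math.log(1.0 + p / 100.0)


# Per-measure true percentage changes (loss pathways negative = reduction).
# EEF anchors: total loss −47%, yield +25%, NUE +18%; the rest span the
# reported 30-70% loss-reduction, 10-30% yield and 10-80% NUE ranges.
_MEASURE_PROFILES: dict[str, dict[str, float]] = {
    "EEF": {"NH3": -45, "NOx": -40, "N2O": -50, "leaching": -40, "runoff": -35,
            "total N loss": -47, "yield": 25, "NUE": 18},
    "organic amendment": {"NH3": -25, "NOx": -20, "N2O": -30, "leaching": -40,
                          "runoff": -45, "total N loss": -35, "yield": 12, "NUE": 15},
    "legume rotation": {"NH3": -30, "NOx": -25, "N2O": -35, "leaching": -45,
                        "runoff": -40, "total N loss": -40, "yield": 15, "NUE": 30},
    "buffer zone": {"NH3": -5, "NOx": -5, "N2O": -10, "leaching": -55,
                    "runoff": -60, "total N loss": -45, "yield": 5, "NUE": 10},
    "fertilizer rate": {"NH3": -35, "NOx": -30, "N2O": -40, "leaching": -45,
                        "runoff": -40, "total N loss": -40, "yield": 10, "NUE": 35},
    "fertilizer type": {"NH3": -40, "NOx": -20, "N2O": -25, "leaching": -20,
                        "runoff": -20, "total N loss": -30, "yield": 10, "NUE": 12},
    "fertilizer timing": {"NH3": -30, "NOx": -25, "N2O": -30, "leaching": -35,
                          "runoff": -30, "total N loss": -35, "yield": 12, "NUE": 20},
    "fertilizer placement": {"NH3": -55, "NOx": -30, "N2O": -35, "leaching": -30,
                             "runoff": -30, "total N loss": -50, "yield": 15, "NUE": 25},
    "new cultivar": {"NH3": -20, "NOx": -15, "N2O": -20, "leaching": -30,
                     "runoff": -25, "total N loss": -30, "yield": 20, "NUE": 40},
    "tillage": {"NH3": -10, "NOx": -15, "N2O": -20, "leaching": -30,
                "runoff": -50, "total N loss": -30, "yield": 10, "NUE": 12},
    "irrigation": {"NH3": -25, "NOx": -20, "N2O": -40, "leaching": -55,
                   "runoff": -50, "total N loss": -45, "yield": 15, "NUE": 35},
}

#: (measure, outcome) -> true mean log response ratio for the full grid.
DEFAULT_TRUE_EFFECTS: dict[tuple[str, str], float] = {
    (m, o): _pct(p)
    for m, profile in _MEASURE_PROFILES.items()
    for o, p in profile.items()
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic world; the seed fixes every table."""

    seed: int = 0
    n_studies: int = 300
    n_obs_per_cell: int = 17
    true_effect: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS)
    )
    obs_noise_sd: float = 0.25
    n_regions: int = 8
    budget_scale: float = 1000.0  # total N input per region, kt N/yr
    price_scale: float = 1.0  # multiplies all USD/kg unit costs
    nue_range: tuple[float, float] = (0.2, 0.8)
    control_median: float = 50.0  # median control-group flux/yield level
    control_log_sd: float = 0.6
    adoption_range: tuple[float, float] = (0.3, 0.9)
    nue_target_uplift: float = 0.13  # added to baseline NUE, capped
    harvest_growth: float = 1.2  # target harvest / baseline harvest

    def validate(self) -> "SyntheticConfig":
        if self.n_obs_per_cell < 1:
            raise ConfigError("n_obs_per_cell must be >= 1")
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        if self.obs_noise_sd < 0:
            raise ConfigError("obs_noise_sd must be >= 0")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.budget_scale <= 0 or self.price_scale <= 0:
            raise ConfigError("scale parameters must be positive")
        if self.control_median <= 0 or self.control_log_sd < 0:
            raise ConfigError("control-mean parameters must be positive")
        lo, hi = self.nue_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("nue_range must satisfy 0 < lo <= hi <= 1")
        lo, hi = self.adoption_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("adoption_range must lie in [0, 1]")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_effect"] = {f"{m}|{o}": v for (m, o), v in self.true_effect.items()}
        return d


_STREAMS = ("observations", "budgets", "measures", "econ", "targets",
            "attributes", "demand")


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    """Named substream so each table family draws independently."""
    idx = _STREAMS.index(stream)
    child = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[idx]
    return np.random.default_rng(child)


def region_names(config: SyntheticConfig) -> list[str]:
    """Region vocabulary; "USA" is always first (the WTP/PGDP reference)."""
    return ["USA"] + [f"R{i:02d}" for i in range(1, config.n_regions)]


# -- observations -----------------------------------------------------------

def generate_observations(config: SyntheticConfig) -> list[FieldObservation]:
    """Field observations for every configured measure × outcome cell.

    Control means are lognormal around ``control_median``; the treatment
    mean is the control times exp(true effect + N(0, obs_noise_sd)).
    """
    config.validate()
    rng = _rng(config, "observations")
    regions = region_names(config)
    obs: list[FieldObservation] = []
    study_counter = 0
    cells = sorted(
        config.true_effect,
        key=lambda c: (MEASURES.index(c[0]), OUTCOMES.index(c[1])),
    )
    for (measure, outcome) in cells:
        effect = config.true_effect[(measure, outcome)]
        controls = config.control_median * np.exp(
            rng.normal(0.0, config.control_log_sd, size=config.n_obs_per_cell)
        )
        noise = (
            rng.normal(0.0, config.obs_noise_sd, size=config.n_obs_per_cell)
            if config.obs_noise_sd > 0
            else np.zeros(config.n_obs_per_cell)
        )
        treatments = controls * np.exp(effect + noise)
        cell_regions = rng.choice(regions, size=config.n_obs_per_cell)
        for i in range(config.n_obs_per_cell):
            obs.append(
                FieldObservation(
                    study_id=f"S{study_counter % config.n_studies:04d}",
                    measure=measure,
                    outcome=outcome,
                    mean_treatment=float(treatments[i]),
                    mean_control=float(controls[i]),
                    sub_treatment="",
                    region=str(cell_regions[i]),
                )
            )
            study_counter += 1
    return obs


# -- budgets ----------------------------------------------------------------

# Dirichlet concentration for splitting inputs among
# (fertilizer, manure, fixation, deposition, irrigation) and losses among
# (NH3, N2O, NOx, N2, leaching, runoff); shaped to typical global shares.
_INPUT_ALPHA = np.array([12.0, 4.0, 2.5, 2.0, 0.5])
_LOSS_ALPHA = np.array([5.0, 0.6, 0.8, 4.0, 4.5, 2.5])


def generate_budgets(config: SyntheticConfig) -> list[RegionBudget]:
    """Closed regional budgets: input = harvest + gaseous + leach + runoff."""
    config.validate()
    rng = _rng(config, "budgets")
    budgets = []
    lo, hi = config.nue_range
    for region in region_names(config):
        n_input = config.budget_scale
        nue = float(rng.uniform(lo, hi))
        harvest = nue * n_input
        losses = n_input - harvest
        in_shares = rng.dirichlet(_INPUT_ALPHA)
        loss_shares = rng.dirichlet(_LOSS_ALPHA)
        e_nh3, e_n2o, e_nox, e_n2, n_leach, n_runoff = losses * loss_shares
        n_fer, n_man, n_fix, n_dep, n_irr = n_input * in_shares
        intensity = float(rng.uniform(0.05, 0.2))  # kt N per kha
        budgets.append(
            RegionBudget(
                region=region,
                n_fer=float(n_fer), n_man=float(n_man), n_fix=float(n_fix),
                n_dep=float(n_dep), n_irr=float(n_irr),
                n_harvest=float(harvest),
                e_nh3=float(e_nh3), e_n2o=float(e_n2o), e_nox=float(e_nox),
                e_n2=float(e_n2),
                n_leach=float(n_leach), n_runoff=float(n_runoff),
                area=n_input / intensity,
            ).validate()
        )
    return budgets


# -- measures ---------------------------------------------------------------

def measures_from_true_effects(
    config: SyntheticConfig,
    implementation: Mapping[str, Mapping[str, float]] | None = None,
) -> list[MeasureSpec]:
    """The ground-truth measure specs implied by the configured effects.

    Efficacy η is the negated fractional loss change, clipped to [0, 1];
    yield/NUE changes become multipliers.  ``implementation`` maps
    measure -> region -> X; defaults to the generated adoption table.
    """
    if implementation is None:
        implementation = generate_adoption(config)
    specs = []
    for m in MEASURES:
        eta = {}
        y_mult = nue_mult = 1.0
        for j in LOSS_PATHWAYS:
            eff = config.true_effect.get((m, j))
            pct = (math.exp(eff) - 1.0) * 100.0 if eff is not None else 0.0
            eta[j] = min(max(-pct / 100.0, 0.0), 1.0)
        y_eff = config.true_effect.get((m, "yield"))
        if y_eff is not None:
            y_mult = math.exp(y_eff)
        n_eff = config.true_effect.get((m, "NUE"))
        if n_eff is not None:
            nue_mult = math.exp(n_eff)
        specs.append(
            MeasureSpec(
                measure_id=m,
                tier=TIER_OF_MEASURE[m],
                eta=eta,
                yield_multiplier=y_mult,
                nue_multiplier=nue_mult,
                implementation_rate=dict(implementation.get(m, {})),
            )
        )
    return specs


def generate_adoption(config: SyntheticConfig) -> dict[str, dict[str, float]]:
    """Per-measure, per-region implementation rates X in adoption_range."""
    config.validate()
    rng = _rng(config, "measures")
    lo, hi = config.adoption_range
    return {
        m: {r: float(rng.uniform(lo, hi)) for r in region_names(config)}
        for m in MEASURES
    }


generate_measures = measures_from_true_effects


# -- economic parameters ----------------------------------------------------

# US-reference unit damage costs per loss form, USD per kg N; the climate
# costs are signed (NH3 and NOx abatement forgoes aerosol cooling).
_ECO_UNIT_COST_US = {"NH3": 12.0, "NOx": 10.0, "N2O": 4.0,
                     "leaching": 16.0, "runoff": 14.0}
_HCOST_US = {"NH3": 20.0, "NOx": 15.0, "N2O": 1.0, "leaching": 2.0, "runoff": 1.0}
_CCOST = {"NH3": -3.0, "NOx": -2.0, "N2O": 9.0, "leaching": 0.0, "runoff": 0.0}
_PGDP_US = 60_000.0
_WTP_US = 100.0


def generate_econ_params(config: SyntheticConfig) -> dict[str, EconParams]:
    """Per-region economic parameters; "USA" is the WTP/PGDP reference.

    Health costs scale with per-capita GDP (mortality valuation);
    willingness to pay scales as the square root of relative income.
    """
    config.validate()
    rng = _rng(config, "econ")
    params = {}
    for region in region_names(config):
        if region == "USA":
            pgdp = _PGDP_US
        else:
            pgdp = float(rng.uniform(2_000.0, 50_000.0))
        wtp = _WTP_US * math.sqrt(pgdp / _PGDP_US)
        rel = pgdp / _PGDP_US
        params[region] = EconParams(
            region=region,
            uc=float(rng.uniform(1.0, 5.0)) * config.price_scale,
            eco_unit_cost={j: v * config.price_scale
                           for j, v in _ECO_UNIT_COST_US.items()},
            wtp=wtp,
            wtp_us=_WTP_US,
            pgdp=pgdp,
            pgdp_us=_PGDP_US,
            hcost={j: v * rel * config.price_scale for j, v in _HCOST_US.items()},
            ccost={j: v * config.price_scale for j, v in _CCOST.items()},
            crop_price=float(rng.uniform(5.0, 12.0)) * config.price_scale,
            fertilizer_price=float(rng.uniform(0.7, 1.2)) * config.price_scale,
        )
    return params


# -- targets, attributes, demand -------------------------------------------

def generate_targets(
    config: SyntheticConfig, budgets: list[RegionBudget]
) -> dict[str, TargetSpec]:
    """NUE targets: baseline NUE plus an uplift, capped at 0.85; target
    harvest grows by ``harvest_growth`` over the baseline."""
    from .budget import total_input

    config.validate()
    targets = {}
    for b in budgets:
        base_nue = b.n_harvest / total_input(b)
        targets[b.region] = TargetSpec(
            region=b.region,
            nue_target=min(base_nue + config.nue_target_uplift, 0.85),
            target_harvest=b.n_harvest * config.harvest_growth,
        )
    return targets


def generate_attributes(config: SyntheticConfig) -> pd.DataFrame:
    """Region attribute table used by scenario tier filtering."""
    config.validate()
    rng = _rng(config, "attributes")
    rows = []
    for region in region_names(config):
        rows.append(
            {
                "region": region,
                "farm_size_class": str(rng.choice(["small", "large"])),
                "income_class": (
                    "high" if region == "USA"
                    else str(rng.choice(["low", "middle", "high"]))
                ),
                "land_scarce": bool(rng.random() < 0.3),
            }
        )
    return pd.DataFrame(rows)


def generate_demand(
    config: SyntheticConfig,
    budgets: list[RegionBudget],
    base_year: int = 2015,
    horizon_year: int = 2050,
) -> pd.DataFrame:
    """Linear harvest-N demand trajectories from base year to horizon.

    Demand grows to ``harvest_growth`` times the baseline harvest by the
    horizon, the same driver under every scenario.
    """
    config.validate()
    rows = []
    for b in budgets:
        for year in range(base_year, horizon_year + 1, 5):
            f = (year - base_year) / (horizon_year - base_year)
            rows.append(
                {
                    "region": b.region,
                    "year": year,
                    "harvest_n": b.n_harvest * (1.0 + (config.harvest_growth - 1.0) * f),
                }
            )
    return pd.DataFrame(rows)


# -- bundled world ----------------------------------------------------------

@dataclass
class SyntheticWorld:
    """All table families of one synthetic study, from a single seed."""

    config: SyntheticConfig
    observations: list[FieldObservation]
    budgets: list[RegionBudget]
    measures: list[MeasureSpec]
    econ: dict[str, EconParams]
    targets: dict[str, TargetSpec]
    attributes: pd.DataFrame
    demand: pd.DataFrame
    interactions: dict[tuple[str, str], dict[str, float]]


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    config.validate()
    budgets = generate_budgets(config)
    return SyntheticWorld(
        config=config,
        observations=generate_observations(config),
        budgets=budgets,
        measures=measures_from_true_effects(config),
        econ=generate_econ_params(config),
        targets=generate_targets(config, budgets),
        attributes=generate_attributes(config),
        demand=generate_demand(config, budgets),
        interactions={},
    )
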