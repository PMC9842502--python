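"""Projection of cropland N flows to 2050 under tiered measure adoption.

Four scenarios are compared: business-as-usual (BAU, no further
improvement of cropland N management) and three cumulative packages —
Tier 1, Tier 1+2, Tier 1+2+3 — each adding the next tier's measures.
Harvest-N demand (driven by exogenous population and income) is the same
under every scenario; adoption changes how much N input, fertilizer and
area are needed to supply it.

Per region and year the projection sets harvest to demand, moves NUE
linearly from its base-year value towards the NUE achieved by the
scenario's measure package at full adoption (capped by the regional NUE
target), derives total input as harvest / NUE, splits the surplus into
loss pathways by interpolated shares, and closes the fertilizer balance
with the deposition feedback and constant fixation/irrigation inputs.
Cropping area adjusts as harvest over yield, with yield improving along
the adoption path.  A demand point that would need NUE above one halts
with a diagnostic naming the region-year rather than being silently
capped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .budget import RegionBudget, TargetSpec, nue as budget_nue, total_input
from .mitigation import (
    CombinedReduction,
    MeasureSpec,
    apply_mitigation,
    combine_measures,
)
from .vocab import GASEOUS_PATHWAYS, LOSS_PATHWAYS

__all__ = [
    "ScenarioSpec",
    "ScenarioError",
    "InfeasibleScenarioError",
    "SCENARIO_TIER_MAX",
    "tier_filter",
    "project",
    "DEFAULT_ADOPTION_RULES",
]


class ScenarioError(ValueError):
    pass


class InfeasibleScenarioError(ScenarioError):
    """Demand would require NUE > 1 in some region-year."""


SCENARIO_TIER_MAX = {"BAU": 0, "Tier1": 1, "Tier1+2": 2, "Tier1+2+3": 3}


@dataclass(frozen=True)
class ScenarioSpec:
    """One projection scenario."""

    name: str
    base_year: int = 2015
    horizon_year: int = 2050

    def __post_init__(self):
        if self.name not in SCENARIO_TIER_MAX:
            raise ScenarioError(
                f"unknown scenario {self.name!r}; expected one of "
                f"{sorted(SCENARIO_TIER_MAX)}"
            )
        if self.horizon_year <= self.base_year:
            raise ScenarioError("horizon_year must follow base_year")

    @property
    def tier_max(self) -> int:
        return SCENARIO_TIER_MAX[self.name]


#: Declarative adoption caps: a rule matches a region when the attribute
#: column equals the value, and caps X for the named measure (or every
#: measure of the named tier).  Buffer zones occupy marginal cropland, so
#: land-scarce regions cap their adoption hard; knowledge-intensive
#: higher tiers are capped in low-income regions.
DEFAULT_ADOPTION_RULES: list[dict] = [
    {"attribute": "land_scarce", "value": True, "measure": "buffer zone",
     "max_x": 0.2},
    {"attribute": "income_class", "value": "low", "tier": 2, "max_x": 0.5},
    {"attribute": "income_class", "value": "low", "tier": 3, "max_x": 0.3},
]

_RULE_KEYS = {"attribute", "value", "measure", "tier", "max_x"}


def tier_filter(
    measures: Sequence[MeasureSpec],
    tier_max: int,
    region_attributes: pd.DataFrame,
    rules: Sequence[Mapping] | None = None,
) -> dict[str, list[MeasureSpec]]:
    """Adoptable measures per region with attribute-based X caps.

    Only measures with tier <= ``tier_max`` pass.  ``region_attributes``
    needs a ``region`` column plus the attribute columns the rules name.
    Returns measure lists whose implementation rates are already capped.
    """
    rules = list(DEFAULT_ADOPTION_RULES if rules is None else rules)
    for rule in rules:
        unknown = set(rule) - _RULE_KEYS
        if unknown:
            raise ScenarioError(f"unknown rule key(s) {sorted(unknown)} in {rule}")
        if rule["attribute"] not in region_attributes.columns:
            raise ScenarioError(
                f"rule references unknown attribute {rule['attribute']!r}"
            )
    out: dict[str, list[MeasureSpec]] = {}
    for _, row in region_attributes.iterrows():
        region = row["region"]
        caps: dict[str, float] = {}
        for rule in rules:
            if row[rule["attribute"]] != rule["value"]:
                continue
            for m in measures:
                hits = (
                    rule.get("measure") == m.measure_id
                    or rule.get("tier") == m.tier
                )
                if hits:
                    caps[m.measure_id] = min(
                        caps.get(m.measure_id, 1.0), float(rule["max_x"])
                    )
        kept = []
        for m in measures:
            if m.tier > tier_max:
                continue
            cap = caps.get(m.measure_id, 1.0)
            rate = {
                r: min(x, cap) for r, x in m.implementation_rate.items()
            }
            kept.append(
                MeasureSpec(
                    measure_id=m.measure_id,
                    tier=m.tier,
                    eta=m.eta,
                    yield_multiplier=m.yield_multiplier,
                    nue_multiplier=m.nue_multiplier,
                    implementation_rate=rate,
                )
            )
        out[region] = kept
    return out


def _demand_interp(demand: pd.DataFrame, region: str, year: int) -> float:
    d = demand[demand["region"] == region].sort_values("year")
    if d.empty:
        raise ScenarioError(f"no demand trajectory for region {region!r}")
    return float(np.interp(year, d["year"].to_numpy(), d["harvest_n"].to_numpy()))


@dataclass
class _RegionEndpoint:
    """Base-year state and full-adoption endpoint for one region."""

    budget: RegionBudget
    nue_base: float
    nue_reach: float
    yield_mult_full: float
    loss_shares_base: dict[str, float]
    loss_shares_full: dict[str, float]
    dep_per_gas: float


def _loss_shares(b: RegionBudget) -> dict[str, float]:
    fluxes = {
        "NH3": b.e_nh3, "NOx": b.e_nox, "N2O": b.e_n2o,
        "N2": b.e_n2, "leaching": b.n_leach, "runoff": b.n_runoff,
    }
    total = sum(fluxes.values())
    if total <= 0:
        return {j: 0.0 for j in fluxes}
    return {j: v / total for j, v in fluxes.items()}


def _endpoint(
    budget: RegionBudget,
    adoptable: Sequence[MeasureSpec],
    target: TargetSpec,
) -> _RegionEndpoint:
    nue_base = budget_nue(budget)
    gas_nr = budget.e_nh3 + budget.e_nox + budget.e_n2o
    dep_per_gas = budget.n_dep / gas_nr if gas_nr > 0 else 0.0
    if not adoptable:
        return _RegionEndpoint(
            budget=budget,
            nue_base=nue_base,
            nue_reach=nue_base,
            yield_mult_full=1.0,
            loss_shares_base=_loss_shares(budget),
            loss_shares_full=_loss_shares(budget),
            dep_per_gas=dep_per_gas,
        )
    combined = combine_measures(budget, adoptable, target)
    outcome = apply_mitigation(budget, combined)
    return _RegionEndpoint(
        budget=budget,
        nue_base=nue_base,
        nue_reach=max(min(combined.nue_post, target.nue_target), nue_base),
        yield_mult_full=combined.yield_multiplier,
        loss_shares_base=_loss_shares(budget),
        loss_shares_full=_loss_shares(outcome.budget_post),
        dep_per_gas=dep_per_gas,
    )


def project(
    base_budgets: Sequence[RegionBudget],
    spec: ScenarioSpec,
    measures: Sequence[MeasureSpec],
    targets: Mapping[str, TargetSpec],
    demand: pd.DataFrame,
    region_attributes: pd.DataFrame | None = None,
    rules: Sequence[Mapping] | None = None,
    step: int = 5,
) -> pd.DataFrame:
    """Project region trajectories from base year to horizon.

    Returns a frame with one row per region-year: ``n_input``, ``n_fer``,
    ``area``, ``yield_n`` (harvest N per kha), ``harvest_n``,
    ``n_surplus`` (= input − harvest exactly), ``nue`` (= harvest/input
    exactly) and per-pathway losses.
    """
    if region_attributes is None:
        # No attribute table: no attribute-based caps can apply.
        region_attributes = pd.DataFrame(
            {"region": [b.region for b in base_budgets]}
        )
        if rules is None:
            rules = []
    adoptable = tier_filter(measures, spec.tier_max, region_attributes, rules)
    years = list(range(spec.base_year, spec.horizon_year + 1, step))
    if years[-1] != spec.horizon_year:
        years.append(spec.horizon_year)
    rows = []
    for b in base_budgets:
        target = targets[b.region]
        ep = _endpoint(b, adoptable.get(b.region, []), target)
        area_base = b.area
        yield_base = b.n_harvest / area_base if area_base > 0 else np.nan
        for year in years:
            f = (year - spec.base_year) / (spec.horizon_year - spec.base_year)
            harvest = _demand_interp(demand, b.region, year)
            nue_t = ep.nue_base + (ep.nue_reach - ep.nue_base) * f
            if nue_t > 1.0:
                raise InfeasibleScenarioError(
                    f"scenario {spec.name!r}: region {b.region!r} in {year} "
                    f"would require NUE {nue_t:.3f} > 1"
                )
            n_input = harvest / nue_t
            surplus = n_input - harvest
            shares = {
                j: ep.loss_shares_base[j]
                + (ep.loss_shares_full[j] - ep.loss_shares_base[j]) * f
                for j in ep.loss_shares_base
            }
            losses = {j: surplus * s for j, s in shares.items()}
            gas_nr = sum(losses[j] for j in GASEOUS_PATHWAYS)
            n_dep = ep.dep_per_gas * gas_nr
            n_man, n_fix, n_irr = b.n_man, b.n_fix, b.n_irr
            n_fer = max(n_input - n_man - n_fix - n_dep - n_irr, 0.0)
            ymult_t = 1.0 + (ep.yield_mult_full - 1.0) * f
            yield_t = yield_base * ymult_t
            area_t = harvest / yield_t if yield_t and np.isfinite(yield_t) else np.nan
            row = {
                "scenario": spec.name,
                "region": b.region,
                "year": year,
                "harvest_n": harvest,
                "n_input": n_input,
                "n_fer": n_fer,
                "n_surplus": surplus,
                "nue": harvest / n_input,
                "area": area_t,
                "yield_n": yield_t,
            }
            row.update({f"loss_{j}": losses[j] for j in LOSS_PATHWAYS})
            row["loss_N2"] = losses["N2"]
            rows.append(row)
    return pd.DataFrame(rows)


def project_all(
    base_budgets: Sequence[RegionBudget],
    measures: Sequence[MeasureSpec],
    targets: Mapping[str, TargetSpec],
    demand: pd.DataFrame,
    region_attributes: pd.DataFrame | None = None,
    rules: Sequence[Mapping] | None = None,
    base_year: int = 2015,
    horizon_year: int = 2050,
    step: int = 5,
    scenarios: Sequence[str] = ("BAU", "Tier1", "Tier1+2", "Tier1+2+3"),
) -> pd.DataFrame:
    """The requested scenarios (default: all four) stacked in one frame."""
    frames = [
        project(
            base_budgets,
            ScenarioSpec(name, base_year=base_year, horizon_year=horizon_year),
            measures,
            targets,
            demand,
            region_attributes,
            rules,
            step=step,
        )
        for name in scenarios
    ]
    return pd.concat(frames, ignore_index=True)
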