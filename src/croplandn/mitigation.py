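"""Abatement of cropland nitrogen losses under measure adoption.

The reduction of one loss pathway j in region i by measure k is

    ΔE_{i,j,k} = A_{i,j,k} × EF_{i,j} × η_{i,j,k} × X_{i,j,k}

where A is the activity level, EF the uncontrolled emission factor
(baseline loss per unit activity), η the abatement efficacy estimated by
the meta-analysis, and X the implementation rate (zero at baseline).
When no explicit activity/EF table is supplied, the decomposition is
derived from the baseline budget itself (EF := baseline flux / activity
with total N input as the activity), which reproduces the baseline flux
exactly at η = X = 1.

Measures combine additively unless a pair appears in an interaction
table, in which case the pair's joint efficacy from combined-treatment
experiments replaces the sum for the co-adopted fraction of activity.
The per-region NUE target caps the package: measures are taken in a
deterministic priority order (ascending tier, then descending standalone
reduction) and the set is truncated once the target NUE is reached.

The fertilizer-saving chain closes the budget: the drop in total N input
equals the total loss reduction (including N2) minus the harvest gain,
and the avoided chemical fertilizer is

    ΔN_fer = ΔN_input + ΔN_man − ΔN_dep

(extra manure recycling displaces fertilizer; reduced volatilization
feeds back as reduced deposition).  Post-mitigation fertilizer cannot go
negative: by default ΔN_fer is capped at the baseline fertilizer use; a
strict mode instead zeroes any ΔN_fer exceeding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .budget import (
    RegionBudget,
    TargetSpec,
    BudgetError,
    nr_loss,
    nue,
    total_input,
)
from .vocab import GASEOUS_PATHWAYS, LOSS_PATHWAYS

__all__ = [
    "MeasureSpec",
    "ActivitySet",
    "CombinedReduction",
    "MitigationError",
    "emission_reduction",
    "activity_from_budget",
    "standalone_reductions",
    "combine_measures",
    "fertilizer_reduction",
    "deposition_feedback",
    "manure_recycling_adjustment",
    "apply_mitigation",
]


class MitigationError(ValueError):
    pass


@dataclass(frozen=True)
class MeasureSpec:
    """One mitigation measure: efficacies, tier and regional adoption."""

    measure_id: str
    tier: int
    eta: Mapping[str, float]  # pathway -> efficacy in [0, 1]
    yield_multiplier: float = 1.0
    nue_multiplier: float = 1.0
    implementation_rate: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.tier not in (1, 2, 3):
            raise MitigationError(f"{self.measure_id}: tier must be 1, 2 or 3")
        for j, v in self.eta.items():
            if j not in LOSS_PATHWAYS:
                raise MitigationError(f"{self.measure_id}: unknown pathway {j!r}")
            if not 0.0 <= v <= 1.0:
                raise MitigationError(f"{self.measure_id}: eta[{j}]={v} outside [0, 1]")
        for r, x in self.implementation_rate.items():
            if not 0.0 <= x <= 1.0:
                raise MitigationError(f"{self.measure_id}: X[{r}]={x} outside [0, 1]")
        if self.yield_multiplier <= 0 or self.nue_multiplier <= 0:
            raise MitigationError(f"{self.measure_id}: multipliers must be positive")

    def x_in(self, region: str) -> float:
        return float(self.implementation_rate.get(region, 0.0))


@dataclass(frozen=True)
class ActivitySet:
    """Activity level and uncontrolled emission factor for one pathway."""

    region: str
    pathway: str
    activity: float  # e.g. total N input
    emission_factor: float  # kt N emitted per activity unit
    activity_unit: str = "ktN_input"
    ef_unit: str = "ktN/ktN_input"

    def __post_init__(self):
        if self.activity < 0 or self.emission_factor < 0:
            raise MitigationError(
                f"{self.region}/{self.pathway}: A and EF must be non-negative"
            )
        if self.ef_unit != f"ktN/{self.activity_unit}":
            raise MitigationError(
                f"{self.region}/{self.pathway}: emission-factor unit "
                f"{self.ef_unit!r} does not match activity unit {self.activity_unit!r}"
            )

    @property
    def baseline_flux(self) -> float:
        return self.activity * self.emission_factor


def activity_from_budget(budget: RegionBudget, pathway: str) -> ActivitySet:
    """Baseline-consistent A × EF decomposition of one pathway flux.

    Uses total N input as the activity; EF = flux / input, so
    A × EF equals the baseline flux exactly.
    """
    a = total_input(budget)
    flux = budget.loss(pathway)
    ef = flux / a if a > 0 else 0.0
    return ActivitySet(region=budget.region, pathway=pathway, activity=a, emission_factor=ef)


def emission_reduction(activity: ActivitySet, measure: MeasureSpec) -> float:
    """ΔE = A × EF × η × X for one region, pathway and measure (kt N/yr)."""
    eta = float(measure.eta.get(activity.pathway, 0.0))
    x = measure.x_in(activity.region)
    return activity.activity * activity.emission_factor * eta * x


def standalone_reductions(
    budget: RegionBudget, measures: Sequence[MeasureSpec]
) -> pd.DataFrame:
    """Per-measure, per-pathway ΔE for one region, ignoring interactions."""
    rows = []
    for m in measures:
        for j in LOSS_PATHWAYS:
            act = activity_from_budget(budget, j)
            rows.append(
                {
                    "region": budget.region,
                    "measure_id": m.measure_id,
                    "pathway": j,
                    "delta_e": emission_reduction(act, m),
                }
            )
    return pd.DataFrame(rows)


# -- combination ------------------------------------------------------------

InteractionTable = Mapping[tuple[str, str], Mapping[str, float]]


def _normalize_interactions(
    interactions: InteractionTable | None, measures: Sequence[MeasureSpec]
) -> dict[tuple[str, str], dict[str, float]]:
    known = {m.measure_id for m in measures}
    table: dict[tuple[str, str], dict[str, float]] = {}
    for pair, joint in (interactions or {}).items():
        a, b = sorted(pair)
        if a not in known or b not in known:
            raise MitigationError(
                f"interaction table references unknown measure(s) in pair {pair}"
            )
        for j, v in joint.items():
            if j not in LOSS_PATHWAYS or not 0.0 <= v <= 1.0:
                raise MitigationError(f"interaction {pair}: bad joint eta {j}={v}")
        table[(a, b)] = dict(joint)
    return table


def _pathway_delta(
    budget: RegionBudget,
    selected: Sequence[MeasureSpec],
    interactions: dict[tuple[str, str], dict[str, float]],
) -> dict[str, float]:
    """Combined per-pathway ΔE for a measure set, with interaction pairs.

    For an interacting pair the co-adopted activity fraction
    min(X_a, X_b) abates at the joint efficacy; each measure's remaining
    adoption abates at its own efficacy.  The total is capped at the
    baseline flux.
    """
    region = budget.region
    delta: dict[str, float] = {}
    ids = {m.measure_id: m for m in selected}
    for j in LOSS_PATHWAYS:
        act = activity_from_budget(budget, j)
        remaining = {mid: m.x_in(region) for mid, m in ids.items()}
        eta_x = 0.0
        for (a, b) in sorted(interactions):
            if a in ids and b in ids:
                x_pair = min(remaining[a], remaining[b])
                eta_x += interactions[(a, b)].get(j, 0.0) * x_pair
                remaining[a] -= x_pair
                remaining[b] -= x_pair
        for mid, m in ids.items():
            eta_x += float(m.eta.get(j, 0.0)) * remaining[mid]
        d = act.activity * act.emission_factor * eta_x
        delta[j] = min(d, act.baseline_flux)
    return delta


def _combined_yield_multiplier(
    budget: RegionBudget, selected: Sequence[MeasureSpec]
) -> float:
    """Adoption-weighted yield multipliers compound multiplicatively."""
    mult = 1.0
    for m in selected:
        mult *= 1.0 + (m.yield_multiplier - 1.0) * m.x_in(budget.region)
    return mult


def _n2_reduction(budget: RegionBudget, delta: Mapping[str, float]) -> float:
    """N2 saving scaled by the fractional reduction of reactive-N losses.

    N2 losses (denitrification to dinitrogen) shrink alongside the Nr
    pathways when inputs are used more efficiently; the same fractional
    reduction achieved on total Nr losses is applied to the N2 flux.
    """
    base = nr_loss(budget)
    if base <= 0:
        return 0.0
    frac = sum(delta.values()) / base
    return budget.e_n2 * min(frac, 1.0)


@dataclass
class CombinedReduction:
    """Combined mitigation outcome for one region."""

    region: str
    selected: list[str]
    delta_e: dict[str, float]  # pathway -> kt N/yr
    delta_n2: float
    yield_multiplier: float
    harvest_post: float
    delta_harvest: float
    delta_input: float
    nue_post: float

    @property
    def delta_e_total(self) -> float:
        return sum(self.delta_e.values())

    @property
    def delta_gaseous_nr(self) -> float:
        return sum(self.delta_e[j] for j in GASEOUS_PATHWAYS)


def _evaluate_set(
    budget: RegionBudget,
    selected: Sequence[MeasureSpec],
    interactions: dict[tuple[str, str], dict[str, float]],
    target: TargetSpec,
) -> CombinedReduction:
    delta = _pathway_delta(budget, selected, interactions)
    d_n2 = _n2_reduction(budget, delta)
    ymult = _combined_yield_multiplier(budget, selected)
    harvest_post = min(budget.n_harvest * ymult, max(target.target_harvest, budget.n_harvest))
    d_harvest = harvest_post - budget.n_harvest
    # Mass balance: the input no longer needed is what is no longer lost,
    # net of the extra N exported in the larger harvest.
    d_input = sum(delta.values()) + d_n2 - d_harvest
    input_post = max(total_input(budget) - d_input, harvest_post)
    nue_post = harvest_post / input_post if input_post > 0 else 1.0
    return CombinedReduction(
        region=budget.region,
        selected=[m.measure_id for m in selected],
        delta_e=delta,
        delta_n2=d_n2,
        yield_multiplier=ymult,
        harvest_post=harvest_post,
        delta_harvest=d_harvest,
        delta_input=d_input,
        nue_post=nue_post,
    )


def measure_priority(
    budget: RegionBudget, measures: Sequence[MeasureSpec]
) -> list[MeasureSpec]:
    """Deterministic adoption order: ascending tier, then descending
    standalone total ΔE, then measure id."""
    def key(m: MeasureSpec):
        total = sum(
            emission_reduction(activity_from_budget(budget, j), m)
            for j in LOSS_PATHWAYS
        )
        return (m.tier, -total, m.measure_id)

    return sorted(measures, key=key)


def combine_measures(
    budget: RegionBudget,
    measures: Sequence[MeasureSpec],
    target: TargetSpec,
    interactions: InteractionTable | None = None,
) -> CombinedReduction:
    """Combine measures for one region under the NUE-target cap.

    Measures are added in priority order; once the region's
    post-mitigation NUE reaches its target, no further measure is
    adopted.  Non-interacting measures add; interacting pairs use the
    joint efficacy table.  Per-pathway reductions never exceed the
    baseline flux.
    """
    table = _normalize_interactions(interactions, measures)
    order = measure_priority(budget, measures)
    selected: list[MeasureSpec] = []
    result = _evaluate_set(budget, selected, table, target)
    for m in order:
        if result.nue_post >= target.nue_target:
            break
        selected.append(m)
        result = _evaluate_set(budget, selected, table, target)
    return result


# -- fertilizer chain -------------------------------------------------------

def fertilizer_reduction(
    budget: RegionBudget,
    delta_input: float,
    delta_man: float,
    delta_dep: float,
    strict: bool = False,
) -> float:
    """Avoided chemical fertilizer ΔN_fer = ΔN_input + ΔN_man − ΔN_dep.

    Fertilizer use cannot go negative.  Default mode caps ΔN_fer at the
    baseline fertilizer input (post-mitigation fertilizer floored at
    zero); ``strict`` mode zeroes any ΔN_fer exceeding the baseline.
    """
    raw = delta_input + delta_man - delta_dep
    if raw > budget.n_fer:
        return 0.0 if strict else budget.n_fer
    return raw


def deposition_feedback(
    total_nr_emission_reduction: float,
    redeposition_fraction: float,
) -> float:
    """Deposition decrease proportional to the gaseous Nr emission cut."""
    if not 0.0 <= redeposition_fraction <= 1.0:
        raise MitigationError(
            f"redeposition_fraction {redeposition_fraction} outside [0, 1]"
        )
    return total_nr_emission_reduction * redeposition_fraction


def default_redeposition_fraction(budget: RegionBudget) -> float:
    """Baseline cropland-deposition share of gaseous Nr emissions."""
    gas_nr = budget.e_nh3 + budget.e_nox + budget.e_n2o
    if gas_nr <= 0:
        return 0.0
    return min(budget.n_dep / gas_nr, 1.0)


def manure_recycling_adjustment(
    budget: RegionBudget,
    recycling_ratio_target: float,
    carrying_capacity: float,
    manure_production: float | None = None,
    baseline_recycling_ratio: float = 0.5,
    allow_negative: bool = False,
) -> float:
    """Extra manure N recycled to cropland (kt N/yr).

    The target recycling ratio is applied to the manure production
    potential; the implied input is capped at the cropland's maximum
    carrying capacity, and the change is floored at zero unless
    ``allow_negative``.  When production is not given it is inferred from
    the baseline input and the assumed baseline recycling ratio.
    """
    if not 0.0 <= recycling_ratio_target <= 1.0:
        raise MitigationError("recycling_ratio_target outside [0, 1]")
    if carrying_capacity < 0:
        raise MitigationError("carrying_capacity must be >= 0")
    if manure_production is None:
        if baseline_recycling_ratio <= 0:
            raise MitigationError("baseline_recycling_ratio must be > 0")
        manure_production = budget.n_man / baseline_recycling_ratio
    implied = min(recycling_ratio_target * manure_production, carrying_capacity)
    delta = implied - budget.n_man
    if delta < 0 and not allow_negative:
        return 0.0
    return delta


@dataclass
class MitigationOutcome:
    """Post-mitigation budget and the Eq-6 chain aggregates for a region."""

    budget_post: RegionBudget
    combined: CombinedReduction
    delta_dep: float
    delta_man: float
    delta_fer: float
    delta_fer_raw: float


def apply_mitigation(
    budget: RegionBudget,
    combined: CombinedReduction,
    redeposition_fraction: float | None = None,
    delta_man: float = 0.0,
    strict_fertilizer_clamp: bool = False,
) -> MitigationOutcome:
    """Apply a combined reduction to a budget and close the N balance.

    Pathway fluxes drop by ΔE, N2 by its tracked saving, harvest rises by
    the (capped) yield effect, deposition falls in proportion to the
    gaseous Nr cut, manure input rises by ``delta_man``, and fertilizer
    absorbs the remainder per ΔN_fer = ΔN_input + ΔN_man − ΔN_dep with
    the non-negativity clamp.  The returned budget satisfies all flux
    invariants.
    """
    if combined.region != budget.region:
        raise MitigationError(
            f"combined reduction is for {combined.region!r}, budget is "
            f"{budget.region!r}"
        )
    for j, d in combined.delta_e.items():
        if d > budget.loss(j) * (1 + 1e-12):
            raise MitigationError(
                f"{budget.region}/{j}: reduction {d} exceeds baseline flux "
                f"{budget.loss(j)}"
            )
    if redeposition_fraction is None:
        redeposition_fraction = default_redeposition_fraction(budget)
    d_dep = deposition_feedback(combined.delta_gaseous_nr, redeposition_fraction)
    d_dep = min(d_dep, budget.n_dep)
    d_fer_raw = combined.delta_input + delta_man - d_dep
    d_fer = fertilizer_reduction(
        budget, combined.delta_input, delta_man, d_dep,
        strict=strict_fertilizer_clamp,
    )
    post = budget.copy(
        n_fer=budget.n_fer - d_fer,
        n_man=budget.n_man + delta_man,
        n_dep=budget.n_dep - d_dep,
        n_harvest=combined.harvest_post,
        e_nh3=budget.e_nh3 - combined.delta_e["NH3"],
        e_nox=budget.e_nox - combined.delta_e["NOx"],
        e_n2o=budget.e_n2o - combined.delta_e["N2O"],
        e_n2=budget.e_n2 - combined.delta_n2,
        n_leach=budget.n_leach - combined.delta_e["leaching"],
        n_runoff=budget.n_runoff - combined.delta_e["runoff"],
    )
    # Guard against floating-point dust producing tiny negatives.
    for f in ("e_nh3", "e_nox", "e_n2o", "e_n2", "n_leach", "n_runoff"):
        v = getattr(post, f)
        if -1e-9 < v < 0:
            post = post.copy(**{f: 0.0})
    post.validate()
    return MitigationOutcome(
        budget_post=post,
        combined=combined,
        delta_dep=d_dep,
        delta_man=delta_man,
        delta_fer=d_fer,
        delta_fer_raw=d_fer_raw,
    )
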