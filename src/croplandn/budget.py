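"""Cropland nitrogen mass-balance budgets per region.

A region's cropland N budget has five inputs (chemical fertilizer,
manure, biological fixation, atmospheric deposition, irrigation water)
and, on the output side, harvested crop N, four gaseous emissions (NH3,
N2O, NOx, N2), leaching and runoff.  Nitrogen use efficiency (NUE) is
harvested N divided by total N input.  From a target NUE and a target
harvest the budget yields a target input, and the signed surplus of the
current input over that target: positive surplus marks regions that
over-apply nitrogen, negative surplus marks regions that should apply
more to sustain yields.

All fluxes are kept in kt N per year per region; per-hectare intensities
are derivable through the cropland ``area`` field (kha).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
import math

import pandas as pd

__all__ = [
    "RegionBudget",
    "TargetSpec",
    "BudgetError",
    "total_input",
    "total_output",
    "n_gas",
    "nr_loss",
    "nue",
    "target_input",
    "input_surplus",
    "is_closed",
    "summarize",
]


class BudgetError(ValueError):
    """A budget violates its invariants (e.g. a negative flux)."""


_FLUX_FIELDS = (
    "n_fer",
    "n_man",
    "n_fix",
    "n_dep",
    "n_irr",
    "n_harvest",
    "e_nh3",
    "e_n2o",
    "e_nox",
    "e_n2",
    "n_leach",
    "n_runoff",
)

INPUT_FIELDS = ("n_fer", "n_man", "n_fix", "n_dep", "n_irr")


@dataclass
class RegionBudget:
    """One region-year cropland N budget (all fluxes in kt N/yr)."""

    region: str
    n_fer: float
    n_man: float
    n_fix: float
    n_dep: float
    n_irr: float
    n_harvest: float
    e_nh3: float
    e_n2o: float
    e_nox: float
    e_n2: float
    n_leach: float
    n_runoff: float
    year: int = 2015
    area: float = field(default=math.nan)  # cropland area, kha

    def validate(self) -> "RegionBudget":
        for name in _FLUX_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise BudgetError(
                    f"region {self.region!r}: flux {name}={v} must be finite and >= 0"
                )
        return self

    def copy(self, **changes) -> "RegionBudget":
        return replace(self, **changes)

    def loss(self, pathway: str) -> float:
        """Baseline flux of one Nr loss pathway."""
        return getattr(self, _PATHWAY_ATTR[pathway])

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_PATHWAY_ATTR = {
    "NH3": "e_nh3",
    "NOx": "e_nox",
    "N2O": "e_n2o",
    "leaching": "n_leach",
    "runoff": "n_runoff",
}


@dataclass(frozen=True)
class TargetSpec:
    """Per-region NUE target and the harvest it should sustain."""

    region: str
    nue_target: float
    target_harvest: float

    def __post_init__(self):
        if not 0 < self.nue_target <= 1:
            raise BudgetError(
                f"region {self.region!r}: nue_target must lie in (0, 1], "
                f"got {self.nue_target}"
            )
        if self.target_harvest < 0:
            raise BudgetError(f"region {self.region!r}: target_harvest < 0")


def total_input(budget: RegionBudget) -> float:
    """Total N input: fertilizer + manure + fixation + deposition + irrigation."""
    budget.validate()
    return budget.n_fer + budget.n_man + budget.n_fix + budget.n_dep + budget.n_irr


def n_gas(budget: RegionBudget) -> float:
    """Total gaseous N emission (NH3 + N2O + NOx + N2)."""
    return budget.e_nh3 + budget.e_n2o + budget.e_nox + budget.e_n2


def nr_loss(budget: RegionBudget) -> float:
    """Total reactive-N loss (gaseous Nr + leaching + runoff); excludes N2."""
    return (
        budget.e_nh3
        + budget.e_n2o
        + budget.e_nox
        + budget.n_leach
        + budget.n_runoff
    )


def total_output(budget: RegionBudget) -> float:
    """Total N output: harvest + gaseous emissions + leaching + runoff."""
    budget.validate()
    return budget.n_harvest + n_gas(budget) + budget.n_leach + budget.n_runoff


def nue(budget: RegionBudget) -> float:
    """Nitrogen use efficiency: harvested N / total N input."""
    tin = total_input(budget)
    if tin <= 0:
        raise BudgetError(
            f"region {budget.region!r}: NUE undefined for non-positive total input"
        )
    return budget.n_harvest / tin


def target_input(t: TargetSpec) -> float:
    """Input consistent with the target harvest at the target NUE."""
    return t.target_harvest / t.nue_target


def input_surplus(budget: RegionBudget, t: TargetSpec) -> float:
    """Signed input surplus: current input minus target input.

    Negative values flag "too little" regions where N input should be
    increased to reach the target harvest.
    """
    return total_input(budget) - target_input(t)


def is_closed(budget: RegionBudget, rtol: float = 1e-9) -> bool:
    """Whether inputs balance outputs (soil stock change of zero)."""
    tin, tout = total_input(budget), total_output(budget)
    scale = max(abs(tin), abs(tout), 1.0)
    return abs(tin - tout) <= rtol * scale


def summarize(
    budgets: list[RegionBudget], targets: dict[str, TargetSpec] | None = None
) -> pd.DataFrame:
    """Per-region table of input, output, NUE, closure and surplus."""
    rows = []
    for b in budgets:
        tin = total_input(b)
        row = {
            "region": b.region,
            "year": b.year,
            "n_input": tin,
            "n_output": total_output(b),
            "n_harvest": b.n_harvest,
            "nr_loss": nr_loss(b),
            "nue": b.n_harvest / tin if tin > 0 else math.nan,
            "closed": is_closed(b),
        }
        if targets and b.region in targets:
            t = targets[b.region]
            row["target_input"] = target_input(t)
            row["surplus"] = input_surplus(b, t)
        rows.append(row)
    return pd.DataFrame(rows)
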