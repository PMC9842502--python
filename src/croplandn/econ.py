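"""Monetization of nitrogen mitigation: costs, benefits and uncertainty.

Implementation cost is the abated mass times an integrated unit
abatement cost, IC = ΔE × UC.  Societal benefit is the sum of four
components,

    SOC = EH + HH + YD + GHG,

where the ecosystem benefit transfers US unit damage costs to other
regions through willingness-to-pay and per-capita-GDP ratios,

    EH = Σ_j ΔE_j × ∂_US,j × (WTP_i / WTP_US) × (PGDP_i / PGDP_US),

the health benefit prices avoided PM2.5 mortality per kg of Nr emission,
HH = Σ_j ΔE_j × HCost_j, the yield benefit prices the extra harvested N,
YD = ΔHν × YP, and the climate term GHG = Σ_j ΔE_j × CCost_j is signed:
N2O abatement warms the ledger positively while NH3/NOx abatement can
carry a negative climate price (their aerosols cool, and reduced
deposition lowers carbon sequestration).

Fertilizer savings (ΔN_fer × fertilizer price) offset part of the gross
implementation cost; the net cost is IC minus that saving.  All
accounting is single-year in constant 2017 USD.  The headline "±"
spreads are produced by Monte-Carlo propagation (mean ± 1 SD).

Internal convention: masses in kt N, unit prices in USD per kg N,
monetary results in USD (1 kt = 10^6 kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .vocab import LOSS_PATHWAYS

__all__ = [
    "EconParams",
    "CostBenefitResult",
    "EconError",
    "implementation_cost",
    "ecosystem_benefit",
    "health_benefit",
    "yield_benefit",
    "climate_benefit",
    "societal_benefit",
    "fertilizer_saving",
    "cost_benefit",
    "propagate_uncertainty",
]

KG_PER_KT = 1.0e6


class EconError(ValueError):
    pass


@dataclass(frozen=True)
class EconParams:
    """Per-region economic parameters (constant 2017 USD, per kg N)."""

    region: str
    uc: float  # integrated unit abatement cost
    eco_unit_cost: Mapping[str, float]  # ∂_US per loss form (US reference)
    wtp: float
    wtp_us: float
    pgdp: float
    pgdp_us: float
    hcost: Mapping[str, float]  # health damage cost per loss form
    ccost: Mapping[str, float]  # climate cost per loss form (signed)
    crop_price: float  # USD per kg harvested N
    fertilizer_price: float

    def __post_init__(self):
        for name in ("uc", "wtp", "wtp_us", "pgdp", "pgdp_us", "crop_price",
                     "fertilizer_price"):
            if getattr(self, name) <= 0:
                raise EconError(f"{self.region}: {name} must be positive")
        for j, v in self.eco_unit_cost.items():
            if v < 0:
                raise EconError(f"{self.region}: eco_unit_cost[{j}] must be >= 0")

    @property
    def wtp_ratio(self) -> float:
        return self.wtp / self.wtp_us

    @property
    def pgdp_ratio(self) -> float:
        return self.pgdp / self.pgdp_us


def _mass_kg(delta_e: Mapping[str, float]) -> dict[str, float]:
    return {j: v * KG_PER_KT for j, v in delta_e.items()}


def implementation_cost(delta_e_total: float, params: EconParams) -> float:
    """IC = ΔE × UC, with ΔE in kt N; returns USD."""
    if delta_e_total < 0:
        raise EconError("abated mass must be non-negative")
    return delta_e_total * KG_PER_KT * params.uc


def ecosystem_benefit(delta_e: Mapping[str, float], params: EconParams) -> float:
    """US unit ecosystem damage costs transferred via WTP and PGDP ratios."""
    scale = params.wtp_ratio * params.pgdp_ratio
    return sum(
        kg * params.eco_unit_cost.get(j, 0.0) * scale
        for j, kg in _mass_kg(delta_e).items()
    )


def health_benefit(delta_e: Mapping[str, float], params: EconParams) -> float:
    """Avoided premature-mortality cost of Nr emission, per-form prices."""
    return sum(
        kg * params.hcost.get(j, 0.0) for j, kg in _mass_kg(delta_e).items()
    )


def yield_benefit(delta_harvest: float, params: EconParams) -> float:
    """Value of the change in harvested N; negative for yield losses."""
    return delta_harvest * KG_PER_KT * params.crop_price


def climate_benefit(delta_e: Mapping[str, float], params: EconParams) -> float:
    """Signed climate value of abatement; NH3/NOx prices may be negative."""
    return sum(
        kg * params.ccost.get(j, 0.0) for j, kg in _mass_kg(delta_e).items()
    )


def societal_benefit(eh: float, hh: float, yd: float, ghg: float) -> float:
    """SOC = EH + HH + YD + GHG (exact sum)."""
    return eh + hh + yd + ghg


def fertilizer_saving(delta_n_fer: float, params: EconParams) -> float:
    """Avoided fertilizer purchase, ΔN_fer × price; ΔN_fer in kt N."""
    if delta_n_fer < 0:
        raise EconError("delta_n_fer must be non-negative after clamping")
    return delta_n_fer * KG_PER_KT * params.fertilizer_price


@dataclass
class CostBenefitResult:
    """Monetized outcome for one region (or the global aggregate)."""

    region: str
    ic: float
    fertilizer_saving: float
    eh: float
    hh: float
    yd: float
    ghg: float
    soc: float
    net_cost: float
    bcr_net: float = float("nan")
    bcr_gross: float = float("nan")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def cost_benefit(
    delta_e: Mapping[str, float],
    delta_harvest: float,
    delta_n_fer: float,
    params: EconParams,
) -> CostBenefitResult:
    """Full single-region cost-benefit account.

    Benefit-to-cost ratios use the net cost (after fertilizer savings) as
    the headline denominator and are only reported when that denominator
    is positive; a gross-cost variant is carried alongside.
    """
    ic = implementation_cost(sum(delta_e.values()), params)
    sav = fertilizer_saving(delta_n_fer, params)
    eh = ecosystem_benefit(delta_e, params)
    hh = health_benefit(delta_e, params)
    yd = yield_benefit(delta_harvest, params)
    ghg = climate_benefit(delta_e, params)
    soc = societal_benefit(eh, hh, yd, ghg)
    net = ic - sav
    return CostBenefitResult(
        region=params.region,
        ic=ic,
        fertilizer_saving=sav,
        eh=eh,
        hh=hh,
        yd=yd,
        ghg=ghg,
        soc=soc,
        net_cost=net,
        bcr_net=soc / net if net > 0 else float("nan"),
        bcr_gross=soc / ic if ic > 0 else float("nan"),
    )


def aggregate_results(results: Sequence[CostBenefitResult],
                      region: str = "GLOBAL") -> CostBenefitResult:
    """Currency-conserving sum of regional accounts."""
    ic = sum(r.ic for r in results)
    sav = sum(r.fertilizer_saving for r in results)
    eh = sum(r.eh for r in results)
    hh = sum(r.hh for r in results)
    yd = sum(r.yd for r in results)
    ghg = sum(r.ghg for r in results)
    soc = societal_benefit(eh, hh, yd, ghg)
    net = ic - sav
    return CostBenefitResult(
        region=region, ic=ic, fertilizer_saving=sav, eh=eh, hh=hh, yd=yd,
        ghg=ghg, soc=soc, net_cost=net,
        bcr_net=soc / net if net > 0 else float("nan"),
        bcr_gross=soc / ic if ic > 0 else float("nan"),
    )


_NUMERIC_FIELDS = ("ic", "fertilizer_saving", "eh", "hh", "yd", "ghg", "soc",
                   "net_cost")


def propagate_uncertainty(
    sampler: Callable[[np.random.Generator], CostBenefitResult],
    n_draws: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo spread of a cost-benefit account.

    ``sampler`` evaluates the full account for one random draw of the
    uncertain inputs (efficacies, prices, ...).  Returns a frame indexed
    by field with columns ``mean`` and ``sd``; the component-sum identity
    SOC = EH + HH + YD + GHG holds in every draw by construction, hence
    also for the means.
    """
    if n_draws < 2:
        raise EconError("n_draws must be at least 2")
    rng = np.random.default_rng(seed)
    draws = {f: np.empty(n_draws) for f in _NUMERIC_FIELDS}
    for d in range(n_draws):
        res = sampler(rng)
        for f in _NUMERIC_FIELDS:
            draws[f][d] = getattr(res, f)
    return pd.DataFrame(
        {
            "mean": {f: float(v.mean()) for f, v in draws.items()},
            "sd": {f: float(v.std(ddof=1)) for f, v in draws.items()},
        }
    )
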