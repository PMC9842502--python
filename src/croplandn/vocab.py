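"""Closed vocabularies for measures, outcomes and loss pathways.

Eleven field-level management measures are tracked, grouped into three
adoption tiers of increasing technical threshold and cost:

* Tier 1 — nitrogen-addition approaches and landscape buffers that need
  little training: enhanced-efficiency fertilizers (EEF), organic
  amendments (manure, straw, biochar), legume rotation, buffer zones.
* Tier 2 — the 4R nutrient-stewardship practices (right rate, type,
  timing and placement of fertilizer).
* Tier 3 — measures needing advanced knowledge or capital: new
  cultivars, no-tillage, optimized (drip) irrigation.

Outcome variables cover the five reactive-N loss pathways, the directly
reported total N loss, plus crop yield and nitrogen use efficiency (NUE).
"""

from __future__ import annotations

MEASURES: tuple[str, ...] = (
    "EEF",
    "organic amendment",
    "legume rotation",
    "buffer zone",
    "fertilizer rate",
    "fertilizer type",
    "fertilizer timing",
    "fertilizer placement",
    "new cultivar",
    "tillage",
    "irrigation",
)

TIER_OF_MEASURE: dict[str, int] = {
    "EEF": 1,
    "organic amendment": 1,
    "legume rotation": 1,
    "buffer zone": 1,
    "fertilizer rate": 2,
    "fertilizer type": 2,
    "fertilizer timing": 2,
    "fertilizer placement": 2,
    "new cultivar": 3,
    "tillage": 3,
    "irrigation": 3,
}

#: Loss pathways of reactive nitrogen (Nr).  N2 is unreactive and is
#: tracked outside this set, as its reduction is a fertilizer saving but
#: not an environmental improvement.
LOSS_PATHWAYS: tuple[str, ...] = ("NH3", "NOx", "N2O", "leaching", "runoff")

GASEOUS_PATHWAYS: tuple[str, ...] = ("NH3", "NOx", "N2O")
WATER_PATHWAYS: tuple[str, ...] = ("leaching", "runoff")

OUTCOMES: tuple[str, ...] = LOSS_PATHWAYS + ("total N loss", "yield", "NUE")

#: Outcomes that are N losses (a negative percentage change is a benefit).
LOSS_OUTCOMES: tuple[str, ...] = LOSS_PATHWAYS + ("total N loss",)


def tier(measure: str) -> int:
    """Adoption tier (1, 2 or 3) of a measure."""
    try:
        return TIER_OF_MEASURE[measure]
    except KeyError:
        raise KeyError(f"unknown measure {measure!r}; expected one of {MEASURES}")
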