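"""CSV interchange, validation and run manifests.

All tables travel as headed CSV (diff-able, text-only).  Column layouts:

* ``observations.csv`` — study_id, measure, sub_treatment, outcome,
  mean_treatment, mean_control, region
* ``budgets.csv`` — region, year, n_fer, n_man, n_fix, n_dep, n_irr,
  n_harvest, e_nh3, e_n2o, e_nox, e_n2, n_leach, n_runoff, area
* ``targets.csv`` — region, nue_target, target_harvest
* ``measures.csv`` — measure_id, tier, eta_NH3, eta_NOx, eta_N2O,
  eta_leaching, eta_runoff, yield_multiplier, nue_multiplier
* ``adoption.csv`` — region, measure_id, x
* ``interactions.csv`` — measure_a, measure_b, eta_<pathway> columns
* ``econ.csv`` — region, is_reference, uc, wtp, pgdp, crop_price,
  fertilizer_price, eco_<pathway>, hcost_<pathway>, ccost_<pathway>
* ``effects.csv`` — the EffectEstimate fields
* ``demand.csv`` — region, year, harvest_n
* ``attributes.csv`` — region, farm_size_class, income_class, land_scarce

Validation distinguishes errors (schema violations, out-of-vocabulary
labels, non-positive means, negative fluxes) from warnings (a user
budget that does not close: closure is a synthetic-data convention, not
a requirement on real data).  Each run writes a JSON manifest capturing
the configuration, the root seed and SHA-256 hashes of every input, so
the manifest alone reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .budget import RegionBudget, TargetSpec, is_closed
from .econ import EconParams
from .meta import EffectEstimate, FieldObservation
from .mitigation import MeasureSpec
from .vocab import LOSS_PATHWAYS, MEASURES, OUTCOMES, TIER_OF_MEASURE

__all__ = [
    "SchemaError",
    "read_observations",
    "write_observations",
    "read_budgets",
    "write_budgets",
    "read_targets",
    "write_targets",
    "read_measures",
    "write_measures",
    "read_interactions",
    "write_interactions",
    "read_econ",
    "write_econ",
    "write_effects",
    "validate_tables",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table violates its documented schema."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


# -- observations -----------------------------------------------------------

OBS_COLUMNS = ["study_id", "measure", "sub_treatment", "outcome",
               "mean_treatment", "mean_control", "region"]


def observations_to_frame(obs: Iterable[FieldObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": o.study_id,
                "measure": o.measure,
                "sub_treatment": o.sub_treatment,
                "outcome": o.outcome,
                "mean_treatment": o.mean_treatment,
                "mean_control": o.mean_control,
                "region": o.region,
            }
            for o in obs
        ],
        columns=OBS_COLUMNS,
    )


def write_observations(obs: Iterable[FieldObservation], path: str | Path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


def read_observations(path: str | Path) -> list[FieldObservation]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, OBS_COLUMNS, str(path))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                FieldObservation(
                    study_id=str(row["study_id"]),
                    measure=str(row["measure"]),
                    sub_treatment=str(row["sub_treatment"]),
                    outcome=str(row["outcome"]),
                    mean_treatment=float(row["mean_treatment"]),
                    mean_control=float(row["mean_control"]),
                    region=str(row["region"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


# -- budgets ----------------------------------------------------------------

BUDGET_COLUMNS = ["region", "year", "n_fer", "n_man", "n_fix", "n_dep",
                  "n_irr", "n_harvest", "e_nh3", "e_n2o", "e_nox", "e_n2",
                  "n_leach", "n_runoff", "area"]


def budgets_to_frame(budgets: Iterable[RegionBudget]) -> pd.DataFrame:
    return pd.DataFrame([b.to_dict() for b in budgets])[BUDGET_COLUMNS]


def write_budgets(budgets: Iterable[RegionBudget], path: str | Path) -> None:
    budgets_to_frame(budgets).to_csv(path, index=False)


def read_budgets(path: str | Path) -> list[RegionBudget]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BUDGET_COLUMNS, str(path))
    out = []
    for i, row in df.iterrows():
        kwargs = {c: (str(row[c]) if c == "region" else
                      int(row[c]) if c == "year" else float(row[c]))
                  for c in BUDGET_COLUMNS}
        try:
            out.append(RegionBudget(**kwargs).validate())
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


# -- targets ----------------------------------------------------------------

TARGET_COLUMNS = ["region", "nue_target", "target_harvest"]


def write_targets(targets: Mapping[str, TargetSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"region": t.region, "nue_target": t.nue_target,
             "target_harvest": t.target_harvest}
            for t in targets.values()
        ],
        columns=TARGET_COLUMNS,
    ).to_csv(path, index=False)


def read_targets(path: str | Path) -> dict[str, TargetSpec]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TARGET_COLUMNS, str(path))
    out = {}
    for i, row in df.iterrows():
        try:
            t = TargetSpec(
                region=str(row["region"]),
                nue_target=float(row["nue_target"]),
                target_harvest=float(row["target_harvest"]),
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
        out[t.region] = t
    return out


# -- measures ---------------------------------------------------------------

MEASURE_COLUMNS = (
    ["measure_id", "tier"]
    + [f"eta_{j}" for j in LOSS_PATHWAYS]
    + ["yield_multiplier", "nue_multiplier"]
)
ADOPTION_COLUMNS = ["region", "measure_id", "x"]


def write_measures(measures: Iterable[MeasureSpec],
                   measures_path: str | Path,
                   adoption_path: str | Path | None = None) -> None:
    measures = list(measures)
    rows = []
    for m in measures:
        row = {"measure_id": m.measure_id, "tier": m.tier,
               "yield_multiplier": m.yield_multiplier,
               "nue_multiplier": m.nue_multiplier}
        row.update({f"eta_{j}": m.eta.get(j, 0.0) for j in LOSS_PATHWAYS})
        rows.append(row)
    pd.DataFrame(rows, columns=MEASURE_COLUMNS).to_csv(measures_path, index=False)
    if adoption_path is not None:
        arows = [
            {"region": r, "measure_id": m.measure_id, "x": x}
            for m in measures
            for r, x in sorted(m.implementation_rate.items())
        ]
        pd.DataFrame(arows, columns=ADOPTION_COLUMNS).to_csv(
            adoption_path, index=False
        )


def read_measures(measures_path: str | Path,
                  adoption_path: str | Path | None = None) -> list[MeasureSpec]:
    df = pd.read_csv(measures_path, float_precision="round_trip")
    _require_columns(df, MEASURE_COLUMNS, str(measures_path))
    adoption: dict[str, dict[str, float]] = {}
    if adoption_path is not None:
        adf = pd.read_csv(adoption_path, float_precision="round_trip")
        _require_columns(adf, ADOPTION_COLUMNS, str(adoption_path))
        for i, row in adf.iterrows():
            adoption.setdefault(str(row["measure_id"]), {})[str(row["region"])] = (
                float(row["x"])
            )
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                MeasureSpec(
                    measure_id=str(row["measure_id"]),
                    tier=int(row["tier"]),
                    eta={j: float(row[f"eta_{j}"]) for j in LOSS_PATHWAYS},
                    yield_multiplier=float(row["yield_multiplier"]),
                    nue_multiplier=float(row["nue_multiplier"]),
                    implementation_rate=adoption.get(str(row["measure_id"]), {}),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{measures_path}: row {i}: {exc}") from exc
    return out


INTERACTION_COLUMNS = ["measure_a", "measure_b"] + [f"eta_{j}" for j in LOSS_PATHWAYS]


def write_interactions(
    interactions: Mapping[tuple[str, str], Mapping[str, float]],
    path: str | Path,
) -> None:
    rows = [
        {"measure_a": a, "measure_b": b,
         **{f"eta_{j}": joint.get(j, 0.0) for j in LOSS_PATHWAYS}}
        for (a, b), joint in sorted(interactions.items())
    ]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, index=False)


def read_interactions(path: str | Path) -> dict[tuple[str, str], dict[str, float]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INTERACTION_COLUMNS, str(path))
    return {
        (str(r["measure_a"]), str(r["measure_b"])): {
            j: float(r[f"eta_{j}"]) for j in LOSS_PATHWAYS
        }
        for _, r in df.iterrows()
    }


# -- econ -------------------------------------------------------------------

ECON_COLUMNS = (
    ["region", "is_reference", "uc", "wtp", "pgdp", "crop_price",
     "fertilizer_price"]
    + [f"eco_{j}" for j in LOSS_PATHWAYS]
    + [f"hcost_{j}" for j in LOSS_PATHWAYS]
    + [f"ccost_{j}" for j in LOSS_PATHWAYS]
)


def write_econ(params: Mapping[str, EconParams], path: str | Path) -> None:
    rows = []
    for region in params:
        p = params[region]
        row = {
            "region": p.region,
            "is_reference": p.wtp == p.wtp_us and p.pgdp == p.pgdp_us,
            "uc": p.uc, "wtp": p.wtp, "pgdp": p.pgdp,
            "crop_price": p.crop_price, "fertilizer_price": p.fertilizer_price,
        }
        row.update({f"eco_{j}": p.eco_unit_cost.get(j, 0.0) for j in LOSS_PATHWAYS})
        row.update({f"hcost_{j}": p.hcost.get(j, 0.0) for j in LOSS_PATHWAYS})
        row.update({f"ccost_{j}": p.ccost.get(j, 0.0) for j in LOSS_PATHWAYS})
        rows.append(row)
    pd.DataFrame(rows, columns=ECON_COLUMNS).to_csv(path, index=False)


def read_econ(path: str | Path) -> dict[str, EconParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ECON_COLUMNS, str(path))
    refs = df[df["is_reference"].astype(bool)]
    if refs.empty:
        raise SchemaError(
            f"{path}: no reference region (is_reference=True) for the "
            f"willingness-to-pay transfer"
        )
    ref = refs.iloc[0]
    out = {}
    for i, row in df.iterrows():
        try:
            p = EconParams(
                region=str(row["region"]),
                uc=float(row["uc"]),
                eco_unit_cost={j: float(row[f"eco_{j}"]) for j in LOSS_PATHWAYS},
                wtp=float(row["wtp"]),
                wtp_us=float(ref["wtp"]),
                pgdp=float(row["pgdp"]),
                pgdp_us=float(ref["pgdp"]),
                hcost={j: float(row[f"hcost_{j}"]) for j in LOSS_PATHWAYS},
                ccost={j: float(row[f"ccost_{j}"]) for j in LOSS_PATHWAYS},
                crop_price=float(row["crop_price"]),
                fertilizer_price=float(row["fertilizer_price"]),
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
        out[p.region] = p
    return out


# -- effects ----------------------------------------------------------------

def write_effects(effects: Iterable[EffectEstimate], path: str | Path) -> None:
    pd.DataFrame([e.to_dict() for e in effects]).to_csv(path, index=False)


# -- validation -------------------------------------------------------------

def validate_tables(paths: Mapping[str, str | Path]) -> dict[str, list[str]]:
    """Validate a set of input tables; returns {"errors": [...], "warnings": [...]}.

    Recognized keys: observations, budgets, targets, measures, adoption,
    interactions, econ.  Schema violations and vocabulary errors go to
    ``errors``; non-closed budgets go to ``warnings``.
    """
    errors: list[str] = []
    warnings: list[str] = []
    readers = {
        "observations": lambda p: read_observations(p),
        "budgets": lambda p: read_budgets(p),
        "targets": lambda p: read_targets(p),
        "econ": lambda p: read_econ(p),
        "interactions": lambda p: read_interactions(p),
    }
    if "measures" in paths:
        readers["measures"] = lambda p: read_measures(
            p, paths.get("adoption")
        )
    loaded: dict[str, object] = {}
    for key, path in paths.items():
        if key == "adoption":
            continue  # read together with measures
        reader = readers.get(key)
        if reader is None:
            errors.append(f"unknown table key {key!r}")
            continue
        if not Path(path).exists():
            errors.append(f"{key}: file not found: {path}")
            continue
        try:
            loaded[key] = reader(path)
        except (SchemaError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
    budgets = loaded.get("budgets")
    if budgets:
        for b in budgets:
            if not is_closed(b, rtol=1e-6):
                warnings.append(
                    f"budgets: region {b.region!r} does not close "
                    f"(input != output); proceeding, closure is not required "
                    f"for user data"
                )
    return {"errors": errors, "warnings": warnings}


# -- manifest ---------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping,
    input_paths: Mapping[str, str | Path] | None = None,
) -> dict:
    """JSON manifest with config, seed and input-file hashes."""
    manifest = {
        "config": dict(config),
        "inputs": {
            k: {"path": str(p), "sha256": _sha256(p)}
            for k, p in (input_paths or {}).items()
            if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


# -- scenario config --------------------------------------------------------

def read_scenario_config(path: str | Path) -> dict:
    """YAML scenario configuration.

    Recognized keys (all optional): ``scenarios`` (list of names),
    ``base_year``, ``horizon_year``, ``step``, ``rules`` (list of
    adoption-cap rules).  Unknown keys raise :class:`SchemaError`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    allowed = {"scenarios", "base_year", "horizon_year", "step", "rules"}
    unknown = set(raw) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    out = {
        "scenarios": raw.get("scenarios",
                             ["BAU", "Tier1", "Tier1+2", "Tier1+2+3"]),
        "base_year": int(raw.get("base_year", 2015)),
        "horizon_year": int(raw.get("horizon_year", 2050)),
        "step": int(raw.get("step", 5)),
        "rules": raw.get("rules"),
    }
    return out


def write_scenario_config(path: str | Path, config: Mapping | None = None) -> None:
    import yaml

    payload = {
        "scenarios": ["BAU", "Tier1", "Tier1+2", "Tier1+2+3"],
        "base_year": 2015,
        "horizon_year": 2050,
        "step": 5,
    }
    payload.update(config or {})
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
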