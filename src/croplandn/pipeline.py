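"""End-to-end pipeline: synthetic tables → meta-analysis → budgets →
mitigation → cost-benefit → scenarios.

Two entry points:

* :func:`run_study` — in-memory chain on a :class:`SyntheticWorld` (or
  user-supplied pieces), returning every intermediate artifact.  This is
  what tests and the acceptance script drive.
* :func:`run_pipeline` — the disk-based driver behind the CLI: reads and
  writes the documented CSV tables stage by stage and records a JSON
  manifest (config, root seed, input hashes).

All randomness flows from a single root seed, split into named
per-stage substreams, so one integer reproduces a whole run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .budget import RegionBudget, TargetSpec, nue, summarize, total_input
from .econ import (
    CostBenefitResult,
    EconParams,
    aggregate_results,
    cost_benefit,
    propagate_uncertainty,
)
from .meta import (
    EffectEstimate,
    effect_table,
    effects_to_frame,
    efficacy_from_effects,
)
from .mitigation import (
    MeasureSpec,
    MitigationOutcome,
    apply_mitigation,
    combine_measures,
    manure_recycling_adjustment,
    standalone_reductions,
)
from .scenario import project_all
from .synthetic import SyntheticConfig, SyntheticWorld, generate_world
from .vocab import (
    GASEOUS_PATHWAYS,
    LOSS_PATHWAYS,
    TIER_OF_MEASURE,
    WATER_PATHWAYS,
)

__all__ = ["RunConfig", "StudyResult", "run_study", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_STREAMS = ("meta", "cba", "scenario")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the root seed."""
    idx = _STAGE_STREAMS.index(stage)
    child = np.random.SeedSequence(root_seed).spawn(len(_STAGE_STREAMS))[idx]
    return int(child.generate_state(1, dtype=np.uint32)[0])


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    n_boot: int = 4999
    n_draws: int = 200
    out_dir: str = "out"
    strict_fertilizer_clamp: bool = False
    log_level: str = "INFO"
    # synthetic-world knobs (used by the synth stage)
    n_regions: int = 8
    n_obs_per_cell: int = 17
    obs_noise_sd: float = 0.25
    # manure-recycling defaults for the mitigation stage
    recycling_ratio_target: float = 0.7
    baseline_recycling_ratio: float = 0.5
    carrying_capacity_factor: float = 1.5  # × baseline manure input
    # optional explicit input-table paths (default: files in out_dir)
    paths: dict = field(default_factory=dict)

    def path(self, name: str) -> Path:
        if name in self.paths:
            return Path(self.paths[name])
        return Path(self.out_dir) / name


def measures_from_estimates(
    effects: Sequence[EffectEstimate],
    implementation: Mapping[str, Mapping[str, float]],
) -> list[MeasureSpec]:
    """Measure specs whose efficacies come from the meta-analysis."""
    eta, mult, _ = efficacy_from_effects(effects)
    return [
        MeasureSpec(
            measure_id=m,
            tier=TIER_OF_MEASURE[m],
            eta=eta[m],
            yield_multiplier=max(mult[m]["yield"], 1e-9),
            nue_multiplier=max(mult[m]["nue"], 1e-9),
            implementation_rate=dict(implementation.get(m, {})),
        )
        for m in sorted(eta, key=lambda mm: list(TIER_OF_MEASURE).index(mm))
    ]


def _delta_man(budget: RegionBudget, config: RunConfig) -> float:
    return manure_recycling_adjustment(
        budget,
        recycling_ratio_target=config.recycling_ratio_target,
        carrying_capacity=config.carrying_capacity_factor * budget.n_man,
        baseline_recycling_ratio=config.baseline_recycling_ratio,
    )


def mitigate_world(
    budgets: Sequence[RegionBudget],
    measures: Sequence[MeasureSpec],
    targets: Mapping[str, TargetSpec],
    config: RunConfig,
    interactions=None,
) -> dict[str, MitigationOutcome]:
    """Combine and apply measures region by region."""
    out = {}
    for b in budgets:
        combined = combine_measures(b, measures, targets[b.region], interactions)
        out[b.region] = apply_mitigation(
            b,
            combined,
            delta_man=_delta_man(b, config),
            strict_fertilizer_clamp=config.strict_fertilizer_clamp,
        )
    return out


def cba_world(
    outcomes: Mapping[str, MitigationOutcome],
    econ: Mapping[str, EconParams],
) -> tuple[dict[str, CostBenefitResult], CostBenefitResult]:
    """Regional and global cost-benefit accounts of mitigation outcomes."""
    regional = {}
    for region, o in outcomes.items():
        regional[region] = cost_benefit(
            delta_e=o.combined.delta_e,
            delta_harvest=o.combined.delta_harvest,
            # "Too little" regions increase fertilizer (negative delta);
            # that is not a saving.
            delta_n_fer=max(o.delta_fer, 0.0),
            params=econ[region],
        )
    return regional, aggregate_results(list(regional.values()))


@dataclass
class StudyResult:
    """Every artifact of one in-memory end-to-end run."""

    world: SyntheticWorld
    effects: list[EffectEstimate]
    tradeoffs: pd.DataFrame
    measures_est: list[MeasureSpec]
    outcomes: dict[str, MitigationOutcome]
    cba_regional: dict[str, CostBenefitResult]
    cba_global: CostBenefitResult
    uncertainty: pd.DataFrame | None = None

    # -- physical aggregates ------------------------------------------------

    def total(self, fn) -> float:
        return sum(fn(o) for o in self.outcomes.values())

    @property
    def air_reduction(self) -> float:
        """Gaseous Nr abatement (NH3 + NOx + N2O), kt N/yr."""
        return self.total(
            lambda o: sum(o.combined.delta_e[j] for j in GASEOUS_PATHWAYS)
        )

    @property
    def water_reduction(self) -> float:
        """Leaching + runoff abatement, kt N/yr."""
        return self.total(
            lambda o: sum(o.combined.delta_e[j] for j in WATER_PATHWAYS)
        )

    @property
    def nr_reduction(self) -> float:
        return self.air_reduction + self.water_reduction

    @property
    def fertilizer_reduction(self) -> float:
        return self.total(lambda o: o.delta_fer)

    @property
    def harvest_gain(self) -> float:
        return self.total(lambda o: o.combined.delta_harvest)

    def global_nue(self, post: bool = False) -> float:
        budgets = (
            [o.budget_post for o in self.outcomes.values()]
            if post
            else self.world.budgets
        )
        tin = sum(total_input(b) for b in budgets)
        return sum(b.n_harvest for b in budgets) / tin


def _effect_se_ln(e: EffectEstimate) -> float:
    """Log-scale standard error implied by the 95% CI width."""
    if e.degenerate:
        return 0.0
    lo = math.log(1.0 + e.ci_low / 100.0)
    hi = math.log(1.0 + e.ci_high / 100.0)
    return max((hi - lo) / (2.0 * 1.959964), 0.0)


def _perturb_econ(p: EconParams, rng: np.random.Generator,
                  rel_sd: float) -> EconParams:
    """Price draw: normal, truncated at zero (signed climate costs keep
    their sign convention and are drawn untruncated)."""

    def pos(v: float) -> float:
        if v <= 0 or rel_sd <= 0:
            return v
        return max(rng.normal(v, rel_sd * v), 1e-12 * v)

    def signed(v: float) -> float:
        return rng.normal(v, rel_sd * abs(v)) if v != 0 and rel_sd > 0 else v

    return EconParams(
        region=p.region,
        uc=pos(p.uc),
        eco_unit_cost={j: pos(v) for j, v in p.eco_unit_cost.items()},
        wtp=p.wtp, wtp_us=p.wtp_us, pgdp=p.pgdp, pgdp_us=p.pgdp_us,
        hcost={j: pos(v) for j, v in p.hcost.items()},
        ccost={j: signed(v) for j, v in p.ccost.items()},
        crop_price=pos(p.crop_price),
        fertilizer_price=pos(p.fertilizer_price),
    )


def make_study_sampler(
    effects: Sequence[EffectEstimate],
    world: SyntheticWorld,
    config: RunConfig,
    price_rel_sd: float = 0.2,
):
    """Sampler re-running the mitigation + cost-benefit chain per draw.

    Efficacies are drawn on the log-response-ratio scale (normal around
    the cell estimate with the CI-implied SE); prices are normal
    truncated at zero.  Each draw rebuilds the measure set, re-runs the
    combination and budget chain, and returns the global account, so the
    component-sum identity holds draw-wise.
    """
    adoption = {
        m.measure_id: dict(m.implementation_rate) for m in world.measures
    }
    eff_stats = [
        (e, math.log(1.0 + e.mean_pct_change / 100.0), _effect_se_ln(e))
        for e in effects
    ]

    def sampler(rng: np.random.Generator) -> CostBenefitResult:
        drawn = [
            EffectEstimate(
                measure=e.measure, outcome=e.outcome, n_obs=e.n_obs,
                mean_pct_change=(math.exp(rng.normal(mu, se)) - 1.0) * 100.0,
                ci_low=e.ci_low, ci_high=e.ci_high, n_boot=e.n_boot,
                seed=e.seed, significant=e.significant, degenerate=e.degenerate,
            )
            for e, mu, se in eff_stats
        ]
        measures = measures_from_estimates(drawn, adoption)
        outcomes = mitigate_world(
            world.budgets, measures, world.targets, config, world.interactions
        )
        econ = {r: _perturb_econ(p, rng, price_rel_sd)
                for r, p in world.econ.items()}
        _, glob = cba_world(outcomes, econ)
        return glob

    return sampler


def run_study(
    config: RunConfig,
    world: SyntheticWorld | None = None,
    with_uncertainty: bool = True,
) -> StudyResult:
    """Full in-memory chain; ``world`` defaults to a synthetic one."""
    if world is None:
        world = generate_world(
            SyntheticConfig(
                seed=config.seed,
                n_regions=config.n_regions,
                n_obs_per_cell=config.n_obs_per_cell,
                obs_noise_sd=config.obs_noise_sd,
            )
        )
    effects = effect_table(
        world.observations, n_boot=config.n_boot,
        seed=stage_seed(config.seed, "meta"),
    )
    _, _, tradeoffs = efficacy_from_effects(effects)
    adoption = {m.measure_id: dict(m.implementation_rate) for m in world.measures}
    measures_est = measures_from_estimates(effects, adoption)
    outcomes = mitigate_world(
        world.budgets, measures_est, world.targets, config, world.interactions
    )
    regional, glob = cba_world(outcomes, world.econ)
    uncertainty = None
    if with_uncertainty and config.n_draws >= 2:
        sampler = make_study_sampler(effects, world, config)
        uncertainty = propagate_uncertainty(
            sampler, n_draws=config.n_draws, seed=stage_seed(config.seed, "cba")
        )
    return StudyResult(
        world=world,
        effects=effects,
        tradeoffs=tradeoffs,
        measures_est=measures_est,
        outcomes=outcomes,
        cba_regional=regional,
        cba_global=glob,
        uncertainty=uncertainty,
    )


# -- disk-based driver ------------------------------------------------------

STAGES = ("synth", "meta", "budget", "mitigate", "cba", "scenario")


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in dependency order, writing CSV artifacts.

    Returns a dict of artifact paths.  Identical config and inputs give
    byte-identical outputs.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; expected subset of {STAGES}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    scfg = SyntheticConfig(
        seed=config.seed,
        n_regions=config.n_regions,
        n_obs_per_cell=config.n_obs_per_cell,
        obs_noise_sd=config.obs_noise_sd,
    )

    if "synth" in stages:
        world = generate_world(scfg)
        cio.write_observations(world.observations, out / "observations.csv")
        cio.write_budgets(world.budgets, out / "budgets.csv")
        cio.write_targets(world.targets, out / "targets.csv")
        cio.write_measures(
            world.measures, out / "measures.csv", out / "adoption.csv"
        )
        cio.write_interactions(world.interactions, out / "interactions.csv")
        cio.write_econ(world.econ, out / "econ.csv")
        world.attributes.to_csv(out / "attributes.csv", index=False)
        world.demand.to_csv(out / "demand.csv", index=False)
        cio.write_scenario_config(out / "scenario.yaml")
        for n in ("observations", "budgets", "targets", "measures",
                  "adoption", "interactions", "econ", "attributes", "demand"):
            artifacts[n] = out / f"{n}.csv"
        artifacts["scenario_config"] = out / "scenario.yaml"

    def need(name: str) -> Path:
        p = config.path(f"{name}.csv")
        if not p.exists():
            raise FileNotFoundError(
                f"stage input {name}.csv not found at {p}; run the producing "
                f"stage first or point config.paths at it"
            )
        return p

    effects: list[EffectEstimate] | None = None
    if "meta" in stages:
        obs = cio.read_observations(need("observations"))
        effects = effect_table(
            obs, n_boot=config.n_boot, seed=stage_seed(config.seed, "meta")
        )
        cio.write_effects(effects, out / "effects.csv")
        _, _, tradeoffs = efficacy_from_effects(effects)
        tradeoffs.to_csv(out / "tradeoffs.csv", index=False)
        artifacts["effects"] = out / "effects.csv"
        artifacts["tradeoffs"] = out / "tradeoffs.csv"

    if "budget" in stages:
        budgets = cio.read_budgets(need("budgets"))
        targets = cio.read_targets(need("targets"))
        summarize(budgets, targets).to_csv(out / "budget_summary.csv", index=False)
        artifacts["budget_summary"] = out / "budget_summary.csv"

    outcomes: dict[str, MitigationOutcome] | None = None
    if "mitigate" in stages:
        budgets = cio.read_budgets(need("budgets"))
        targets = cio.read_targets(need("targets"))
        measures = cio.read_measures(need("measures"), need("adoption"))
        inter_path = config.path("interactions.csv")
        interactions = (
            cio.read_interactions(inter_path) if inter_path.exists() else None
        )
        outcomes = mitigate_world(budgets, measures, targets, config, interactions)
        red_rows = []
        for region, o in outcomes.items():
            for j, d in o.combined.delta_e.items():
                red_rows.append({"region": region, "pathway": j, "delta_e": d})
            red_rows.append(
                {"region": region, "pathway": "N2", "delta_e": o.combined.delta_n2}
            )
        pd.DataFrame(red_rows).to_csv(out / "reductions.csv", index=False)
        cio.write_budgets(
            [o.budget_post for o in outcomes.values()], out / "post_budgets.csv"
        )
        artifacts["reductions"] = out / "reductions.csv"
        artifacts["post_budgets"] = out / "post_budgets.csv"

    if "cba" in stages:
        if outcomes is None:
            raise ValueError("cba stage requires the mitigate stage in the same run")
        econ = cio.read_econ(need("econ"))
        regional, glob = cba_world(outcomes, econ)
        rows = [r.to_dict() for r in regional.values()] + [glob.to_dict()]
        pd.DataFrame(rows).to_csv(out / "cba.csv", index=False)
        artifacts["cba"] = out / "cba.csv"
        if config.n_draws >= 2 and effects is not None:
            world = generate_world(scfg)
            sampler = make_study_sampler(effects, world, config)
            unc = propagate_uncertainty(
                sampler, n_draws=config.n_draws,
                seed=stage_seed(config.seed, "cba"),
            )
            unc.to_csv(out / "cba_uncertainty.csv", index_label="field")
            artifacts["cba_uncertainty"] = out / "cba_uncertainty.csv"

    if "scenario" in stages:
        budgets = cio.read_budgets(need("budgets"))
        targets = cio.read_targets(need("targets"))
        measures = cio.read_measures(need("measures"), need("adoption"))
        demand = pd.read_csv(need("demand"))
        attr_path = config.path("attributes.csv")
        attributes = pd.read_csv(attr_path) if attr_path.exists() else None
        scn_path = config.path("scenario.yaml")
        if scn_path.exists():
            scn = cio.read_scenario_config(scn_path)
        else:
            scn = {"scenarios": ("BAU", "Tier1", "Tier1+2", "Tier1+2+3"),
                   "base_year": 2015, "horizon_year": 2050, "step": 5,
                   "rules": None}
        traj = project_all(
            budgets, measures, targets, demand, attributes,
            rules=scn["rules"], base_year=scn["base_year"],
            horizon_year=scn["horizon_year"], step=scn["step"],
            scenarios=scn["scenarios"],
        )
        traj.to_csv(out / "trajectories.csv", index=False)
        artifacts["trajectories"] = out / "trajectories.csv"

    cio.write_manifest(
        out / "manifest.json",
        config=asdict(config),
        input_paths={k: str(v) for k, v in artifacts.items()},
    )
    artifacts["manifest"] = out / "manifest.json"
    return {k: str(v) for k, v in artifacts.items()}
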