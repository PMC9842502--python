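import numpy as np
import pandas as pd
import pytest

from croplandn.budget import RegionBudget, TargetSpec, nue, total_input
from croplandn.mitigation import MeasureSpec
from croplandn.scenario import (
    InfeasibleScenarioError,
    ScenarioError,
    ScenarioSpec,
    project,
    project_all,
    tier_filter,
)
from croplandn.vocab import LOSS_PATHWAYS


def flat_demand(region, harvest, years):
    return pd.DataFrame(
        [{"region": region, "year": y, "harvest_n": h}
         for y, h in zip(years, harvest)]
    )


@pytest.fixture
def hand_measure():
    return MeasureSpec(
        measure_id="hand", tier=1,
        eta={j: 0.5 for j in LOSS_PATHWAYS},
        yield_multiplier=1.25,
        implementation_rate={"T": 1.0},
    )


class TestTierFilter:
    def _attrs(self, **kw):
        row = {"region": "T", "farm_size_class": "small",
               "income_class": "high", "land_scarce": False}
        row.update(kw)
        return pd.DataFrame([row])

    def test_tier_one_only(self, small_world):
        out = tier_filter(small_world.measures, 1, self._attrs())
        assert all(m.tier == 1 for m in out["T"])
        assert len(out["T"]) == 4

    def test_permissive_passes_all_eleven(self, small_world):
        out = tier_filter(small_world.measures, 3, self._attrs())
        assert len(out["T"]) == 11

    def test_land_scarce_caps_buffer_zone(self, small_world):
        out = tier_filter(small_world.measures, 1, self._attrs(land_scarce=True))
        buffer = next(m for m in out["T"] if m.measure_id == "buffer zone")
        assert all(x <= 0.2 for x in buffer.implementation_rate.values())

    def test_unknown_attribute_rejected(self, small_world):
        with pytest.raises(ScenarioError):
            tier_filter(
                small_world.measures, 1, self._attrs(),
                rules=[{"attribute": "altitude", "value": 1, "max_x": 0.5}],
            )


class TestProjection:
    def test_bau_is_exact_fixed_point(self, toy_budget):
        spec = ScenarioSpec("BAU", base_year=2015, horizon_year=2025)
        targets = {"T": TargetSpec("T", 0.5, 60.0)}
        demand = flat_demand("T", [40.0, 40.0], [2015, 2025])
        traj = project([toy_budget], spec, [], targets, demand, step=5)
        assert np.allclose(traj["n_input"], 100.0)
        assert np.allclose(traj["n_fer"], 50.0)
        assert np.allclose(traj["harvest_n"], 40.0)
        assert np.allclose(traj["nue"], 0.4)
        assert np.allclose(traj["area"], 100.0)

    def test_hand_worked_three_year_trajectory(self, toy_budget, hand_measure):
        """Midpoint of a 2015-2017 Tier1 path, checked against arithmetic
        done by hand: NUE 0.40 -> 0.50 linearly, demand 40 -> 44."""
        spec = ScenarioSpec("Tier1", base_year=2015, horizon_year=2017)
        targets = {"T": TargetSpec("T", 0.5, 60.0)}
        demand = flat_demand("T", [40.0, 44.0], [2015, 2017])
        traj = project(
            [toy_budget], spec, [hand_measure], targets, demand, step=1
        ).set_index("year")
        mid = traj.loc[2016]
        assert mid["nue"] == pytest.approx(0.45)
        assert mid["n_input"] == pytest.approx(42.0 / 0.45)
        assert mid["n_surplus"] == pytest.approx(42.0 / 0.45 - 42.0)
        assert mid["loss_NH3"] == pytest.approx(mid["n_surplus"] * 0.25)
        # fer = input - man - fix - dep - irr with dep = 0.5 x gaseous Nr
        gas_nr = mid["n_surplus"] / 3.0
        assert mid["n_fer"] == pytest.approx(
            mid["n_input"] - 20.0 - 10.0 - 0.5 * gas_nr - 10.0
        )
        assert mid["yield_n"] == pytest.approx(0.45)  # 0.4 x (1 + 0.25/2)
        assert mid["area"] == pytest.approx(42.0 / 0.45)
        end = traj.loc[2017]
        assert end["nue"] == pytest.approx(0.5)
        assert end["n_input"] == pytest.approx(44.0 / 0.5)

    def test_full_adoption_constant_demand_closed_form(self, toy_budget, hand_measure):
        spec = ScenarioSpec("Tier1+2+3", base_year=2015, horizon_year=2025)
        targets = {"T": TargetSpec("T", 0.5, 60.0)}
        demand = flat_demand("T", [40.0, 40.0], [2015, 2025])
        traj = project([toy_budget], spec, [hand_measure], targets, demand, step=5)
        final = traj[traj["year"] == 2025].iloc[0]
        assert final["n_input"] == pytest.approx(40.0 / 0.5)

    def test_identities_hold_at_every_point(self, small_world):
        traj = project_all(
            small_world.budgets, small_world.measures, small_world.targets,
            small_world.demand, small_world.attributes,
        )
        assert np.allclose(
            traj["n_surplus"], traj["n_input"] - traj["harvest_n"]
        )
        assert np.allclose(traj["nue"], traj["harvest_n"] / traj["n_input"])

    def test_cumulative_tiers_monotonically_cut_losses(self, small_world):
        traj = project_all(
            small_world.budgets, small_world.measures, small_world.targets,
            small_world.demand, small_world.attributes,
        )
        loss_cols = [f"loss_{j}" for j in LOSS_PATHWAYS]
        totals = (
            traj.assign(nr_loss=traj[loss_cols].sum(axis=1))
            .groupby(["scenario", "year"])["nr_loss"].sum()
            .unstack("scenario")
        )
        order = ["BAU", "Tier1", "Tier1+2", "Tier1+2+3"]
        for lower, higher in zip(order, order[1:]):
            assert (totals[higher] <= totals[lower] + 1e-9).all()

    def test_infeasible_nue_halts_with_region_year(self):
        bad = RegionBudget(
            region="B", n_fer=50.0, n_man=0, n_fix=0, n_dep=0, n_irr=0,
            n_harvest=60.0, e_nh3=1, e_n2o=1, e_nox=1, e_n2=1,
            n_leach=1, n_runoff=1,
        )
        spec = ScenarioSpec("BAU", base_year=2015, horizon_year=2020)
        demand = flat_demand("B", [60.0, 60.0], [2015, 2020])
        with pytest.raises(InfeasibleScenarioError, match="'B'.*2015"):
            project([bad], spec, [], {"B": TargetSpec("B", 0.9, 60.0)},
                    demand, step=5)

    def test_unknown_scenario_name_rejected(self):
        with pytest.raises(ScenarioError):
            ScenarioSpec("Tier4")
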