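import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from croplandn.budget import RegionBudget, TargetSpec, nue, total_input, total_output
from croplandn.mitigation import (
    ActivitySet,
    MeasureSpec,
    MitigationError,
    activity_from_budget,
    apply_mitigation,
    combine_measures,
    deposition_feedback,
    emission_reduction,
    fertilizer_reduction,
    manure_recycling_adjustment,
)
from croplandn.vocab import LOSS_PATHWAYS

from oracles import oracle_combine


def measure(mid="m1", tier=1, eta=None, ymult=1.0, x=1.0, region="T"):
    return MeasureSpec(
        measure_id=mid, tier=tier,
        eta=eta or {j: 0.0 for j in LOSS_PATHWAYS},
        yield_multiplier=ymult,
        implementation_rate={region: x},
    )


class TestEmissionReduction:
    def test_product_formula(self):
        act = ActivitySet("T", "NH3", activity=100.0, emission_factor=0.1)
        m = measure(eta={"NH3": 0.47}, x=0.5)
        assert emission_reduction(act, m) == pytest.approx(2.35)

    def test_zero_implementation_is_baseline(self):
        act = ActivitySet("T", "NH3", activity=100.0, emission_factor=0.1)
        assert emission_reduction(act, measure(eta={"NH3": 0.9}, x=0.0)) == 0.0

    def test_full_abatement_equals_baseline_flux(self, toy_budget):
        act = activity_from_budget(toy_budget, "leaching")
        m = measure(eta={"leaching": 1.0}, x=1.0)
        assert emission_reduction(act, m) == pytest.approx(toy_budget.n_leach)
        assert act.baseline_flux == pytest.approx(toy_budget.n_leach)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(MitigationError):
            ActivitySet("T", "NH3", activity=1.0, emission_factor=0.1,
                        activity_unit="kha", ef_unit="ktN/ktN_input")

    @given(
        a=st.floats(min_value=0, max_value=1e4),
        ef=st.floats(min_value=0, max_value=1.0),
        eta=st.floats(min_value=0, max_value=1.0),
        x=st.floats(min_value=0, max_value=1.0),
        c=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_joint_linearity(self, a, ef, eta, x, c):
        act = ActivitySet("T", "NH3", activity=a, emission_factor=ef)
        base = emission_reduction(act, measure(eta={"NH3": eta}, x=x))
        scaled_act = ActivitySet("T", "NH3", activity=a * c, emission_factor=ef)
        assert emission_reduction(
            scaled_act, measure(eta={"NH3": eta}, x=x)
        ) == pytest.approx(base * c, rel=1e-9, abs=1e-12)


class TestCombine:
    def test_disjoint_pathways_add_exactly(self, toy_budget, toy_target):
        m1 = measure("a", eta={"NH3": 0.4}, x=0.5)
        m2 = measure("b", eta={"leaching": 0.6}, x=0.5)
        combined = combine_measures(toy_budget, [m1, m2], toy_target)
        assert combined.delta_e["NH3"] == pytest.approx(15.0 * 0.4 * 0.5)
        assert combined.delta_e["leaching"] == pytest.approx(20.0 * 0.6 * 0.5)
        assert combined.delta_e["runoff"] == 0.0

    def test_single_measure_identity(self, toy_budget, toy_target):
        m = measure("solo", eta={"NH3": 0.3, "runoff": 0.2}, x=0.8)
        combined = combine_measures(toy_budget, [m], toy_target)
        assert combined.selected == ["solo"]
        assert combined.delta_e["NH3"] == pytest.approx(15.0 * 0.3 * 0.8)

    def test_unknown_measure_in_interactions_rejected(self, toy_budget, toy_target):
        m = measure("a", eta={"NH3": 0.3})
        with pytest.raises(MitigationError):
            combine_measures(
                toy_budget, [m], toy_target,
                interactions={("a", "ghost"): {"NH3": 0.4}},
            )

    def test_reduction_capped_at_baseline_flux(self, toy_budget, toy_target):
        ms = [measure(f"m{i}", eta={"NH3": 0.9}, x=1.0) for i in range(3)]
        combined = combine_measures(toy_budget, ms, toy_target)
        assert combined.delta_e["NH3"] <= toy_budget.e_nh3 + 1e-12

    def test_matches_brute_force_oracle_on_toy_instances(self, toy_budget):
        """Exhaustive cross-check on randomized <=4-measure instances."""
        rng = np.random.default_rng(123)
        pathways = ("NH3", "leaching", "runoff")  # <=3 active pathways
        for trial in range(40):
            n_m = int(rng.integers(1, 5))
            ms = []
            for i in range(n_m):
                eta = {j: float(rng.uniform(0, 0.8)) for j in pathways}
                ms.append(
                    measure(
                        f"m{i}", tier=int(rng.integers(1, 4)), eta=eta,
                        ymult=float(rng.uniform(1.0, 1.3)),
                        x=float(rng.uniform(0.0, 1.0)),
                    )
                )
            interactions = None
            if n_m >= 2 and rng.random() < 0.6:
                a, b = rng.choice(n_m, size=2, replace=False)
                interactions = {
                    (f"m{a}", f"m{b}"): {
                        j: float(rng.uniform(0, 0.9)) for j in pathways
                    }
                }
            target = TargetSpec(
                "T", nue_target=float(rng.uniform(0.4, 0.9)), target_harvest=60.0
            )
            got = combine_measures(toy_budget, ms, target, interactions)
            sel, delta, nue_post = oracle_combine(toy_budget, ms, target, interactions)
            assert got.selected == sel, f"trial {trial}"
            for j in LOSS_PATHWAYS:
                assert got.delta_e[j] == pytest.approx(
                    delta[j], rel=1e-9, abs=1e-12
                ), f"trial {trial}, pathway {j}"
            assert got.nue_post == pytest.approx(nue_post, rel=1e-9)


class TestFertilizerChain:
    def test_component_sum(self, toy_budget):
        assert fertilizer_reduction(toy_budget, 18.0, 11.0, 5.0) == pytest.approx(24.0)

    def test_clamp_modes(self):
        b = RegionBudget(
            region="T", n_fer=10.0, n_man=0, n_fix=0, n_dep=0, n_irr=0,
            n_harvest=1, e_nh3=0, e_n2o=0, e_nox=0, e_n2=0,
            n_leach=0, n_runoff=0,
        )
        assert fertilizer_reduction(b, 15.0, 0.0, 0.0) == pytest.approx(10.0)
        assert fertilizer_reduction(b, 15.0, 0.0, 0.0, strict=True) == 0.0

    def test_zero_deltas(self, toy_budget):
        assert fertilizer_reduction(toy_budget, 0.0, 0.0, 0.0) == 0.0

    def test_deposition_feedback(self):
        assert deposition_feedback(10.0, 0.5) == pytest.approx(5.0)
        assert deposition_feedback(10.0, 0.0) == 0.0
        with pytest.raises(MitigationError):
            deposition_feedback(1.0, 1.5)

    def test_manure_adjustment(self, toy_budget):
        # baseline ratio 0.5 implies production 40 for n_man=20
        assert manure_recycling_adjustment(
            toy_budget, 0.5, carrying_capacity=100.0
        ) == 0.0
        # unconstrained target above capacity caps at capacity - baseline
        assert manure_recycling_adjustment(
            toy_budget, 1.0, carrying_capacity=30.0
        ) == pytest.approx(10.0)
        with pytest.raises(MitigationError):
            manure_recycling_adjustment(toy_budget, 0.5, carrying_capacity=-1.0)


class TestApplyMitigation:
    def test_zero_adoption_is_identity(self, toy_budget, toy_target):
        ms = [measure("idle", eta={"NH3": 0.5}, x=0.0)]
        combined = combine_measures(toy_budget, ms, toy_target)
        out = apply_mitigation(toy_budget, combined)
        assert out.budget_post == toy_budget
        assert out.delta_fer == 0.0

    def test_full_abatement_zeroes_all_nr_losses(self, toy_budget, toy_target):
        ms = [measure("max", eta={j: 1.0 for j in LOSS_PATHWAYS}, x=1.0)]
        combined = combine_measures(toy_budget, ms, toy_target)
        out = apply_mitigation(toy_budget, combined)
        p = out.budget_post
        assert p.e_nh3 == p.e_nox == p.e_n2o == p.n_leach == p.n_runoff == 0.0

    def test_hand_computed_chain(self, toy_budget, toy_target):
        """Worked end-to-end example on round numbers.

        Budget: input 100 (fer 50, man 20, fix 10, dep 10, irr 10),
        harvest 40, losses NH3 15 / N2O 3 / NOx 2 / N2 10 / leach 20 /
        runoff 10.  One measure, eta 0.5 everywhere, X=1, yield x1.25.
        """
        m = measure("hand", eta={j: 0.5 for j in LOSS_PATHWAYS}, ymult=1.25, x=1.0)
        combined = combine_measures(toy_budget, [m], toy_target)
        assert combined.delta_e == pytest.approx(
            {"NH3": 7.5, "NOx": 1.0, "N2O": 1.5, "leaching": 10.0, "runoff": 5.0}
        )
        assert combined.delta_n2 == pytest.approx(5.0)  # 10 * (25/50)
        assert combined.harvest_post == pytest.approx(50.0)
        assert combined.delta_input == pytest.approx(20.0)  # 25 + 5 - 10

        out = apply_mitigation(toy_budget, combined, delta_man=4.0)
        # deposition feedback: dep/gaseous-Nr = 10/20, gaseous cut 10 -> 5
        assert out.delta_dep == pytest.approx(5.0)
        assert out.delta_fer == pytest.approx(19.0)  # 20 + 4 - 5
        p = out.budget_post
        assert p.n_fer == pytest.approx(31.0)
        assert p.n_man == pytest.approx(24.0)
        assert total_input(p) == pytest.approx(80.0)
        assert total_output(p) == pytest.approx(80.0)  # closure preserved
        assert nue(p) == pytest.approx(0.625)

    def test_invariants_on_synthetic_world(self, small_world):
        for b in small_world.budgets:
            t = small_world.targets[b.region]
            combined = combine_measures(b, small_world.measures, t)
            out = apply_mitigation(b, combined)
            p = out.budget_post
            p.validate()
            for j in LOSS_PATHWAYS:
                assert combined.delta_e[j] <= b.loss(j) + 1e-9
            assert p.n_fer >= 0.0
            assert nue(p) >= nue(b) - 1e-12
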