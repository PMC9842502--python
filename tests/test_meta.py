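import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from croplandn.meta import (
    EffectEstimate,
    FieldObservation,
    ValidationError,
    bootstrap_effect,
    effect_table,
    efficacy_from_effects,
    log_response_ratio,
    percent_change,
)

from oracles import oracle_bootstrap

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


def obs(ratio, measure="EEF", outcome="total N loss", control=10.0, i=0):
    return FieldObservation(
        study_id=f"S{i}", measure=measure, outcome=outcome,
        mean_treatment=control * ratio, mean_control=control,
    )


class TestLogResponseRatio:
    def test_identity(self):
        assert log_response_ratio(5.0, 5.0) == 0.0

    def test_closed_form(self):
        assert log_response_ratio(2.0, 1.0) == pytest.approx(math.log(2), abs=1e-12)

    def test_domain_violation(self):
        with pytest.raises(ValidationError):
            log_response_ratio(0.0, 1.0)
        with pytest.raises(ValidationError):
            log_response_ratio(1.0, -2.0)

    @given(a=positive, b=positive)
    def test_antisymmetry(self, a, b):
        assert log_response_ratio(a, b) == pytest.approx(
            -log_response_ratio(b, a), abs=1e-9
        )


class TestPercentChange:
    @pytest.mark.parametrize(
        "lnr,expected", [(0.0, 0.0), (math.log(1.25), 25.0), (math.log(0.53), -47.0)]
    )
    def test_values(self, lnr, expected):
        assert percent_change(lnr) == pytest.approx(expected)

    @given(lnr=st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_roundtrip_identity(self, lnr):
        pct = percent_change(lnr)
        assert pct > -100.0
        assert math.log(1.0 + pct / 100.0) == pytest.approx(lnr, abs=1e-9)


class TestBootstrapEffect:
    def test_zero_variance_cell(self):
        cell = [obs(1.10, i=i) for i in range(20)]
        e = bootstrap_effect(cell, n_boot=199, seed=4)
        assert e.mean_pct_change == pytest.approx(10.0)
        assert e.ci_low == pytest.approx(10.0)
        assert e.ci_high == pytest.approx(10.0)
        assert e.degenerate and e.significant

    def test_single_record_degenerate(self):
        e = bootstrap_effect([obs(0.8)], n_boot=99, seed=1)
        assert e.n_obs == 1 and e.degenerate
        assert e.mean_pct_change == pytest.approx(-20.0)
        assert e.ci_low == e.ci_high == pytest.approx(-20.0)

    def test_empty_and_mixed_cells_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_effect([])
        with pytest.raises(ValidationError):
            bootstrap_effect([obs(1.1), obs(1.1, outcome="yield")])

    @pytest.mark.parametrize("method", ["bc", "percentile"])
    def test_matches_independent_resampling_oracle(self, method):
        rng = np.random.default_rng(20)
        n = 200
        lnr = math.log(0.7) + rng.normal(0.0, 0.2, size=n)
        cell = [obs(math.exp(v), i=i) for i, v in enumerate(lnr)]
        e = bootstrap_effect(cell, n_boot=999, seed=77, method=method)
        se_pct = 100 * math.exp(math.log(0.7)) * 0.2 / math.sqrt(n)
        assert e.mean_pct_change == pytest.approx(-30.0, abs=3 * se_pct)
        point, lo, hi = oracle_bootstrap(lnr, n_boot=999, seed=77, method=method)
        assert e.mean_pct_change == pytest.approx(point, abs=1e-9)
        assert e.ci_low == pytest.approx(lo, abs=1e-9)
        assert e.ci_high == pytest.approx(hi, abs=1e-9)

    def test_significance_matches_interval(self):
        rng = np.random.default_rng(3)
        cell = [obs(math.exp(rng.normal(0, 0.3)), i=i) for i in range(40)]
        e = bootstrap_effect(cell, n_boot=999, seed=5)
        assert e.significant == (not e.ci_low <= 0.0 <= e.ci_high)
        assert e.ci_low <= e.mean_pct_change <= e.ci_high

    def test_units_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        ratios = np.exp(rng.normal(-0.2, 0.15, size=30))
        a = bootstrap_effect([obs(r, control=5.0, i=i) for i, r in enumerate(ratios)],
                             n_boot=499, seed=9)
        b = bootstrap_effect([obs(r, control=500.0, i=i) for i, r in enumerate(ratios)],
                             n_boot=499, seed=9)
        assert a.mean_pct_change == pytest.approx(b.mean_pct_change, abs=1e-9)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-9)
        assert a.ci_high == pytest.approx(b.ci_high, abs=1e-9)


class TestEffectTable:
    def _grid_obs(self, measures, outcomes, n=4):
        rng = np.random.default_rng(6)
        out = []
        for m in measures:
            for o in outcomes:
                for i in range(n):
                    out.append(obs(math.exp(rng.normal(0, 0.2)), measure=m,
                                   outcome=o, i=i))
        return out

    def test_cell_counting(self):
        rows = effect_table(
            self._grid_obs(["EEF", "tillage"], ["NH3", "yield", "NUE"]),
            n_boot=99, seed=0,
        )
        assert len(rows) == 6

    def test_full_grid_counting(self, small_world):
        rows = effect_table(small_world.observations, n_boot=99, seed=0)
        assert len(rows) == 88  # 11 measures x 8 outcomes

    def test_order_invariance_and_determinism(self):
        grid = self._grid_obs(["EEF", "irrigation"], ["NH3", "leaching"], n=8)
        a = effect_table(grid, n_boot=299, seed=42)
        shuffled = grid.copy()
        random.Random(1).shuffle(shuffled)
        b = effect_table(shuffled, n_boot=299, seed=42)
        c = effect_table(grid, n_boot=299, seed=42)
        assert [e.to_dict() for e in a] == [e.to_dict() for e in b]
        assert [e.to_dict() for e in a] == [e.to_dict() for e in c]


class TestEfficacy:
    def _est(self, measure, outcome, pct):
        return EffectEstimate(
            measure=measure, outcome=outcome, n_obs=10,
            mean_pct_change=pct, ci_low=pct - 5, ci_high=pct + 5,
            n_boot=99, seed=0, significant=True,
        )

    def test_loss_reduction_becomes_efficacy(self):
        eta, mult, trade = efficacy_from_effects(
            [self._est("EEF", "total N loss", -47.0),
             self._est("EEF", "leaching", -40.0)]
        )
        assert mult["EEF"]["total_loss"] == pytest.approx(0.47)
        assert eta["EEF"]["leaching"] == pytest.approx(0.40)
        assert trade.empty

    def test_pollution_increase_clipped_and_reported(self):
        eta, _, trade = efficacy_from_effects([self._est("tillage", "NH3", 10.0)])
        assert eta["tillage"]["NH3"] == 0.0
        assert list(trade["measure"]) == ["tillage"]
        assert list(trade["pathway"]) == ["NH3"]

    def test_yield_multiplier(self):
        _, mult, _ = efficacy_from_effects([self._est("EEF", "yield", 25.0)])
        assert mult["EEF"]["yield"] == pytest.approx(1.25)

    def test_missing_pathway_defaults_to_zero(self, caplog):
        eta, _, _ = efficacy_from_effects([self._est("EEF", "NH3", -45.0)])
        assert eta["EEF"]["runoff"] == 0.0
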