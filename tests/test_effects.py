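"""Effect measures: point estimates, intervals, cluster adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hipdd import effects, matching

from conftest import make_panel_slice

PRE = [2000, 2001, 2002, 2003]
POST = [2004, 2005, 2006, 2007]


def series(values, years):
    return pd.Series(list(values), index=list(years), dtype=float)


def _match_result(panel_slice, treated_ids, donor_ids):
    """Assemble a MatchResult directly from a chosen donor set."""
    spec = matching.MatchSpec(pre_years=tuple(PRE), validation_years=(PRE[-1],))
    wide = panel_slice.pivot_table(index="municipality_id", columns="year",
                                   values="rate")
    matched = wide.loc[list(donor_ids)].mean(axis=0)
    return matching.MatchResult(
        treated_ids=tuple(treated_ids),
        treated=matching.treated_series(panel_slice, treated_ids),
        ranking=pd.DataFrame({"municipality_id": list(donor_ids),
                              "distance": 0.0}),
        cv_error=pd.Series([0.0], index=[1]),
        n=len(donor_ids),
        donor_ids=tuple(donor_ids),
        matched=matched,
        spec=spec,
    )


class TestPointEstimates:
    def test_dd_hand_example(self):
        treated = series([100] * 4 + [90] * 4, PRE + POST)
        control = series([100] * 4 + [95] * 4, PRE + POST)
        assert effects.dd_estimate(treated, control, PRE, POST) == pytest.approx(-5.0)

    def test_dd_identical_series_zero(self):
        s = series(np.linspace(80, 120, 8), PRE + POST)
        assert effects.dd_estimate(s, s, PRE, POST) == 0.0

    def test_dynamic_constant_gap_all_zero(self):
        treated = series([110] * 8, PRE + POST)
        control = series([100] * 8, PRE + POST)
        d = effects.dynamic_effects(treated, control, PRE, POST)
        assert (d == 0.0).all()

    def test_dynamic_mean_equals_dd(self):
        rng = np.random.default_rng(1)
        treated = series(100 + rng.normal(0, 5, 8), PRE + POST)
        control = series(100 + rng.normal(0, 5, 8), PRE + POST)
        d = effects.dynamic_effects(treated, control, PRE, POST)
        assert d.mean() == pytest.approx(
            effects.dd_estimate(treated, control, PRE, POST)
        )

    def test_dynamic_step_effect_recovered(self):
        treated = series([100] * 4 + [100 - 30] * 4, PRE + POST)
        control = series([100] * 8, PRE + POST)
        d = effects.dynamic_effects(treated, control, PRE, POST)
        np.testing.assert_allclose(d.to_numpy(), -30.0)

    def test_cumulative_effect_linearity(self):
        # a -5/100k gap on 100,000 person-years for 8 post years = -40 cases
        years = list(range(2000, 2004)) + list(range(2004, 2012))
        pre, post = years[:4], years[4:]
        treated = series([100] * 4 + [95] * 8, years)
        control = series([100] * 12, years)
        pops = series([100_000] * 12, years)
        ce = effects.cumulative_effect(treated, control, pops, pre, post)
        assert ce == pytest.approx(-40.0)

    def test_cumulative_effect_null_zero(self):
        s = series(np.linspace(90, 110, 8), PRE + POST)
        pops = series([50_000] * 8, PRE + POST)
        assert effects.cumulative_effect(s, s, pops, PRE, POST) == 0.0

    def test_missing_population_year_errors(self):
        s = series([100] * 8, PRE + POST)
        pops = series([50_000] * 4, PRE)
        with pytest.raises(effects.EffectsError, match="missing year"):
            effects.cumulative_effect(s, s, pops, PRE, POST)

    def test_empty_period_errors(self):
        s = series([100] * 4, PRE)
        with pytest.raises(effects.EffectsError, match="non-empty"):
            effects.dd_estimate(s, s, PRE, [])


class TestScaleEquivariance:
    @given(c=st.floats(min_value=0.5, max_value=20.0))
    def test_population_scaling(self, c):
        """Scaling person-years leaves DD (a rate) unchanged and scales
        the cumulative case count linearly."""
        rng = np.random.default_rng(4)
        treated = series(100 + rng.normal(0, 5, 8), PRE + POST)
        control = series(100 + rng.normal(0, 5, 8), PRE + POST)
        pops = series(rng.integers(10_000, 50_000, 8).astype(float), PRE + POST)
        dd = effects.dd_estimate(treated, control, PRE, POST)
        ce = effects.cumulative_effect(treated, control, pops, PRE, POST)
        ce_scaled = effects.cumulative_effect(treated, control, pops * c, PRE, POST)
        assert ce_scaled == pytest.approx(c * ce, rel=1e-12)
        assert effects.dd_estimate(treated, control, PRE, POST) == dd


class TestPoissonCI:
    def test_rate_interval_hand_computation(self):
        # 100 cases on 10,000 person-years: 1,000 +/- 1.96*100 per 100k
        lo, hi = effects.poisson_ci(1000.0, 100, 10_000)
        assert lo == pytest.approx(804.0, abs=0.5)
        assert hi == pytest.approx(1196.0, abs=0.5)

    def test_higher_level_is_wider(self):
        ci95 = effects.poisson_ci(1000.0, 100, 10_000, level=0.95)
        ci999 = effects.poisson_ci(1000.0, 100, 10_000, level=0.999)
        assert ci999[0] < ci95[0] < ci95[1] < ci999[1]

    def test_design_effect_widens(self):
        plain = effects.poisson_ci(1000.0, 100, 10_000)
        inflated = effects.poisson_ci(1000.0, 100, 10_000, deff=4.0)
        assert (inflated[1] - inflated[0]) == pytest.approx(
            2 * (plain[1] - plain[0]), rel=1e-9
        )

    def test_all_zero_counts_warn(self):
        with pytest.warns(UserWarning, match="zero"):
            effects.poisson_ci(0.0, 0, 10_000)


class TestClusterAdjustment:
    def test_deff_formula_and_floor(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "municipality_id": np.repeat(np.arange(30), 16),
            "rate": rng.normal(1000, 50, 480),  # no cluster structure
        })
        adj = effects.cluster_adjust(df)
        assert adj.deff == pytest.approx(1 + (adj.m_bar - 1) * adj.icc)
        assert 0.0 <= adj.icc <= 1.0

    def test_icc_recovers_variance_ratio(self):
        """One-way ANOVA ICC approaches sigma_b^2/(sigma_b^2+sigma_w^2)."""
        rng = np.random.default_rng(15)
        k, m = 200, 30
        sigma_b, sigma_w = 40.0, 60.0
        cluster_means = rng.normal(1000, sigma_b, k)
        df = pd.DataFrame({
            "municipality_id": np.repeat(np.arange(k), m),
            "rate": np.repeat(cluster_means, m) + rng.normal(0, sigma_w, k * m),
        })
        adj = effects.cluster_adjust(df)
        rho = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        assert adj.icc == pytest.approx(rho, abs=0.05)

    def test_single_cluster_warns_deff_one(self):
        df = pd.DataFrame({"municipality_id": [1] * 5, "rate": [1.0, 2, 3, 4, 5]})
        with pytest.warns(UserWarning, match="clusters"):
            adj = effects.cluster_adjust(df)
        assert adj.deff == 1.0


class TestEstimateEffects:
    def _two_unit_panel(self, t_cases, c_cases, population=100_000):
        years = PRE + POST
        rates = {}
        rows = []
        for mid, case_list in ((1, t_cases), (2, c_cases)):
            for y, c in zip(years, case_list):
                rows.append({
                    "municipality_id": mid, "year": y, "age_group": "65+",
                    "sex": "both", "cases": c, "population": population,
                    "rate": c / population * 1e5, "treated": mid == 1,
                })
        return pd.DataFrame(rows)

    def test_irr_hand_example(self):
        # one pre and one post period cell per arm:
        # (100, 80, 100, 100) cases at equal person-years -> IRR 0.8
        panel = self._two_unit_panel([100] * 4 + [80] * 4, [100] * 8)
        res = _match_result(panel, [1], [2])
        est = effects.estimate_effects(panel, res, PRE, POST)
        assert est.irr == pytest.approx(0.8)
        hand_se = np.sqrt(1 / 400 + 1 / 320 + 1 / 400 + 1 / 400)
        assert est.log_irr_se / np.sqrt(est.deff) == pytest.approx(hand_se, rel=1e-6)

    def test_irr_halving_treated(self):
        panel = self._two_unit_panel([200] * 4 + [100] * 4, [150] * 8)
        res = _match_result(panel, [1], [2])
        est = effects.estimate_effects(panel, res, PRE, POST)
        assert est.irr == pytest.approx(0.5)

    def test_null_invariance_is_exact(self):
        panel = self._two_unit_panel([123] * 8, [123] * 8)
        res = _match_result(panel, [1], [2])
        est = effects.estimate_effects(panel, res, PRE, POST)
        assert est.dd == 0.0
        assert est.irr == 1.0
        assert est.ce == 0.0
        assert (est.dynamic["effect"] == 0.0).all()

    def test_zero_cell_continuity_correction_warns(self):
        panel = self._two_unit_panel([10] * 4 + [0] * 4, [10] * 8)
        res = _match_result(panel, [1], [2])
        with pytest.warns(UserWarning, match="zero cell"):
            est = effects.estimate_effects(panel, res, PRE, POST)
        assert 0 < est.irr < 1
        assert "zero cell" in est.notes[0]

    def test_adjusted_se_never_below_naive(self):
        rng = np.random.default_rng(21)
        panel = self._two_unit_panel(
            rng.poisson(100, 8).tolist(), rng.poisson(100, 8).tolist()
        )
        res = _match_result(panel, [1], [2])
        est = effects.estimate_effects(panel, res, PRE, POST)
        assert est.se_adjusted >= est.se_naive
        assert est.dd_ci[0] <= est.dd <= est.dd_ci[1]
        assert est.irr_ci[0] <= est.irr <= est.irr_ci[1]

    def test_gap_variance_propagated_is_wider(self):
        panel = self._two_unit_panel([110] * 4 + [90] * 4, [100] * 8)
        res = _match_result(panel, [1], [2])
        fixed = effects.estimate_effects(panel, res, PRE, POST)
        prop = effects.estimate_effects(panel, res, PRE, POST,
                                        gap_variance="propagated")
        assert prop.se_naive > fixed.se_naive
        assert fixed.dd == prop.dd

    def test_control_variance_conventions_ordered(self):
        """With n donors the donor-mean convention is ~n times the exact
        delta-method variance; pooled sits at the exact value for equal
        populations."""
        rng = np.random.default_rng(30)
        years = PRE + POST
        rows = []
        for mid in (1, 2, 3, 4, 5):
            for y in years:
                c = int(rng.poisson(100))
                rows.append({
                    "municipality_id": mid, "year": y, "age_group": "65+",
                    "sex": "both", "cases": c, "population": 100_000,
                    "rate": c / 1e5 * 1e5, "treated": mid == 1,
                })
        panel = pd.DataFrame(rows)
        res = _match_result(panel, [1], [2, 3, 4, 5])
        ses = {
            how: effects.estimate_effects(panel, res, PRE, POST,
                                          control_variance=how).se_naive
            for how in ("donor-wise", "pooled", "donor-mean")
        }
        assert ses["donor-wise"] <= ses["donor-mean"]
        assert ses["pooled"] == pytest.approx(ses["donor-wise"], rel=0.15)
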