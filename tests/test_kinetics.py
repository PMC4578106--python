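"""Estimator tests: index calculations, hinge and PLM fits, closed forms."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from cmzcycle import (
    CycleParams,
    ExperimentDesign,
    closed_form_li,
    closed_form_plm,
    expected_mitotic_index,
    fit_cumulative,
    fit_plm,
    labeling_index,
    mitotic_index,
    plm_curve,
    simulate_experiment,
)
from cmzcycle.kinetics import LabelingCurve, compare_groups
from cmzcycle.popsim import LabelingObservation


def _obs(time, rep, n, edu=0, ph3=0, double=0):
    return LabelingObservation(time=time, replicate=rep, n_scored=n,
                               n_edu_pos=edu, n_ph3_pos=ph3, n_double_pos=double)


def _curve(times, lis, replicate=0):
    return LabelingCurve(points=pd.DataFrame(
        {"time_h": times, "replicate": replicate, "li": lis}))


class TestIndices:
    def test_labeling_index_ratio_and_zero(self):
        curve = labeling_index([_obs(1, 0, 100, edu=30), _obs(2, 0, 50, edu=0)])
        assert list(curve.points["li"]) == [0.30, 0.0]

    def test_replicate_mean_and_sem(self):
        # two replicates 0.2 and 0.4: mean 0.3, SEM = sd/sqrt(2) = 0.1
        curve = labeling_index([_obs(5, 0, 100, edu=20), _obs(5, 1, 100, edu=40)])
        s = curve.summary()
        assert s["mean"].iloc[0] == pytest.approx(0.3)
        assert s["sem"].iloc[0] == pytest.approx(0.1)

    def test_zero_scored_rejected(self):
        df = pd.DataFrame({"time_h": [1.0], "replicate": [0], "n_scored": [0],
                           "n_edu_pos": [0], "n_ph3_pos": [0], "n_double_pos": [0]})
        with pytest.raises(ValueError, match="n_scored"):
            labeling_index(df)

    def test_mitotic_index_fraction(self):
        mi = mitotic_index([_obs(0, 0, 100, ph3=5)])
        assert mi["mean"].iloc[0] == pytest.approx(0.05)

    def test_mitotic_index_matches_occupancy_in_simulation(self):
        p = CycleParams(gf=1.0, t_g1=13, t_s=4, t_g2=2, t_m=1, n_cells=20_000)
        d = ExperimentDesign(mode="cumulative", observation_times=(2.0,),
                             n_replicates=1, cells_scored_per_replicate=20_000,
                             seed=9)
        mi = mitotic_index(simulate_experiment(p, d))
        expected = expected_mitotic_index(p)  # 0.05
        se = math.sqrt(expected * (1 - expected) / 20_000)
        assert abs(mi["mean"].iloc[0] - expected) < 3 * se

    def test_plm_curve_pools_mitoses(self):
        obs = [_obs(3, 0, 100, edu=50, ph3=4, double=2),
               _obs(3, 1, 100, edu=50, ph3=6, double=4)]
        c = plm_curve(obs)
        assert c["plm"].iloc[0] == pytest.approx(6 / 10)
        assert c["n_mitoses"].iloc[0] == 10


class TestFitCumulative:
    def test_noiseless_hinge_recovery(self):
        # LI(t) = min(0.2 + 0.05 t, 1.0): GF=1, LI0=0.2, Tp=16, TC=20, TS=4
        t = np.array([0, 4, 8, 12, 16, 20, 24], float)
        fit = fit_cumulative(_curve(t, np.minimum(0.2 + 0.05 * t, 1.0)))
        assert fit.plateau_reached
        assert fit.gf_hat == pytest.approx(1.0, abs=1e-6)
        assert fit.li0_hat == pytest.approx(0.2, abs=1e-6)
        assert fit.t_plateau_hat == pytest.approx(16.0, abs=1e-5)
        assert fit.t_c_hat == pytest.approx(20.0, abs=1e-5)
        assert fit.t_s_hat == pytest.approx(4.0, abs=1e-5)

    def test_closed_form_inversion(self):
        gf, tc, ts = 0.9, 22.0, 5.0
        t = np.linspace(0, 30, 9)
        fit = fit_cumulative(_curve(t, gf * np.minimum((ts + t) / tc, 1.0)))
        assert fit.gf_hat == pytest.approx(gf, rel=1e-6)
        assert fit.t_c_hat == pytest.approx(tc, rel=1e-6)
        assert fit.t_s_hat == pytest.approx(ts, rel=1e-6)

    def test_internal_identities(self):
        t = np.linspace(0, 30, 8)
        fit = fit_cumulative(_curve(t, 0.85 * np.minimum((3.5 + t) / 18.0, 1.0)))
        assert fit.t_plateau_hat == pytest.approx(fit.t_c_hat - fit.t_s_hat, abs=1e-9)
        assert fit.li0_hat == pytest.approx(
            fit.gf_hat * fit.t_s_hat / fit.t_c_hat, abs=1e-9)

    def test_constant_curve_is_no_rising_phase(self):
        with pytest.raises(ValueError, match="no rising phase"):
            fit_cumulative(_curve([0, 4, 8, 12], [0.6, 0.6, 0.6, 0.6]))

    def test_too_few_times(self):
        with pytest.raises(ValueError, match="3 distinct times"):
            fit_cumulative(_curve([0, 4], [0.1, 0.3]))

    def test_rising_only_curve_reports_no_plateau(self):
        t = np.array([0, 2, 4, 6, 8], float)
        fit = fit_cumulative(_curve(t, 0.1 + 0.05 * t))
        assert not fit.plateau_reached
        assert fit.gf_hat is None and fit.t_c_hat is None

    def test_plateau_constrained_to_max_gf(self):
        t = np.array([0, 3, 6, 9, 12, 15, 18], float)
        y = np.minimum(0.25 + 0.07 * t, 1.0) + np.array(
            [0.0, 0.01, -0.01, 0.012, 0.0, 0.01, 0.005])
        fit = fit_cumulative(_curve(t, np.clip(y, 0, 1)))
        assert fit.gf_hat <= 1.0 + 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(gf=st.floats(0.5, 1.0), tc=st.floats(10.0, 40.0), ts=st.floats(2.0, 10.0))
    def test_property_noiseless_inversion(self, gf, tc, ts):
        assume(ts <= 0.9 * tc)  # T_S -> T_C leaves no rising phase to fit
        tp = tc - ts
        # a designed grid samples both segments whatever T_plateau is
        t = np.concatenate([np.linspace(0, tp, 5, endpoint=False),
                            np.linspace(tp, 1.3 * tc, 5)])
        fit = fit_cumulative(_curve(t, gf * np.minimum((ts + t) / tc, 1.0)))
        assert fit.plateau_reached
        assert fit.gf_hat == pytest.approx(gf, rel=1e-6)
        assert fit.t_c_hat == pytest.approx(tc, rel=1e-6)
        assert fit.t_s_hat == pytest.approx(ts, rel=1e-6)


class TestFitPLM:
    def test_noiseless_ramp_half_max(self):
        # deterministic-cycle PLM for T_G2=2.5, T_M=1: half-max at 3.0
        t = np.array([0, 1, 2, 2.5, 3, 3.5, 4, 6], float)
        curve = pd.DataFrame({"time_h": t, "plm": np.clip(t - 2.5, 0, 1)})
        fit = fit_plm(curve, t_m=1.0)
        assert fit.t_g2_hat == pytest.approx(3.0, abs=0.05)
        assert fit.t_g2_corrected_hat == pytest.approx(2.5, abs=0.05)

    def test_all_zero_curve_not_bracketed(self):
        curve = pd.DataFrame({"time_h": [0, 1, 2, 3], "plm": [0.0] * 4})
        with pytest.raises(ValueError, match="not bracketed"):
            fit_plm(curve)

    def test_saturated_curve_boundary_with_warning(self):
        curve = pd.DataFrame({"time_h": [0, 1, 2, 3], "plm": [1.0] * 4})
        with pytest.warns(UserWarning, match="half-maximum"):
            fit = fit_plm(curve)
        assert fit.t_g2_hat == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 4 time points"):
            fit_plm(pd.DataFrame({"time_h": [0, 1, 2], "plm": [0, 0.5, 1]}))

    def test_half_max_within_time_range(self):
        rng = np.random.default_rng(0)
        t = np.array([0.5, 1.5, 2.5, 3.0, 3.5, 4.5, 6.0])
        y = np.clip(np.clip(t - 2.5, 0, 1) + rng.normal(0, 0.08, t.size), 0, 1)
        fit = fit_plm(pd.DataFrame({"time_h": t, "plm": y}))
        assert t[0] <= fit.t_g2_hat <= t[-1]


class TestClosedForms:
    def test_closed_form_li_values(self, control_params):
        p1 = CycleParams(gf=1.0, t_g1=13, t_s=4, t_g2=2, t_m=1)
        assert closed_form_li(p1, 0.0) == pytest.approx(0.2)
        assert closed_form_li(p1, 16.0) == pytest.approx(1.0)
        assert closed_form_li(control_params, 8.0) == pytest.approx(0.48)

    def test_closed_form_plm_values(self, control_params):
        assert closed_form_plm(control_params, 2.5) == pytest.approx(0.0)
        assert closed_form_plm(control_params, 3.0) == pytest.approx(0.5)
        assert closed_form_plm(control_params, 4.0) == pytest.approx(1.0)

    def test_negative_time_rejected(self, control_params):
        with pytest.raises(ValueError, match=">= 0"):
            closed_form_li(control_params, -1.0)
        with pytest.raises(ValueError, match=">= 0"):
            closed_form_plm(control_params, -0.5)

    def test_expected_mitotic_index(self):
        assert expected_mitotic_index(
            CycleParams(gf=1.0, t_g1=13, t_s=4, t_g2=2, t_m=1)) == pytest.approx(0.05)
        assert expected_mitotic_index(
            CycleParams(gf=0.5, t_g1=17, t_s=4, t_g2=3, t_m=1)) == pytest.approx(0.02)
        assert expected_mitotic_index(
            CycleParams(gf=0.0, t_g1=13, t_s=4, t_g2=2, t_m=1)) == 0.0

    def test_plm_monotone_in_t_g2(self):
        # longer G2 delays labeled mitoses at every fixed time
        base = dict(gf=0.8, t_g1=12.5, t_s=4.0, t_m=1.0)
        t = np.linspace(0, 8, 33)
        prev = closed_form_plm(CycleParams(t_g2=2.0, **base), t)
        for g2 in (3.0, 4.5, 6.0):
            cur = closed_form_plm(CycleParams(t_g2=g2, **base), t)
            assert np.all(cur <= prev + 1e-12)
            prev = cur


def test_compare_groups_detects_difference():
    res = compare_groups([0.1, 0.12, 0.11, 0.13], [0.2, 0.22, 0.21, 0.19])
    assert res["p_value"] < 0.01
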