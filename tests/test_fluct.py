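"""Band-pass, pooled response, fluctuation index, and its group tests."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluctica as fl
from conftest import simulate_condition_indices
from fluctica.design import IMAGERY, SUPPRESSION
from fluctica.fluct import (
    bandpass,
    compare_conditions,
    fluctuation_index,
    pooled_response,
    report_association,
)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, 2.0)
        mid = slice(100, 300)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        y = bandpass(x, 2.0)
        assert np.abs(y[100:300]).max() < 0.1

    def test_constant_series_maps_to_zero(self):
        y = bandpass(np.full(300, 5.0), 2.0)
        assert np.allclose(y, 0.0, atol=1e-7)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(np.zeros(20), 2.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(300), 2.0, low=0.1, high=0.5)


class TestPooledResponse:
    def test_identical_trials_return_the_trial(self):
        trial = np.sin(np.linspace(0, 3, 24))
        pooled, amp = pooled_response(np.tile(trial, (7, 1)))
        assert np.allclose(pooled, trial)
        assert amp == pytest.approx(trial.max() - trial.min())

    def test_antisymmetric_pair_cancels(self):
        s = np.sin(np.linspace(0, 3, 24))
        pooled, _ = pooled_response(np.stack([s, -s]))
        assert np.allclose(pooled, 0.0, atol=1e-15)

    def test_convergence_rate_one_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        s = np.sin(np.linspace(0, 3, 24))
        def rmse(n):
            trials = s + rng.standard_normal((n, 24))
            pooled, _ = pooled_response(trials)
            return np.sqrt(np.mean((pooled - s) ** 2))
        assert rmse(400) < rmse(4) / 5  # ~1/sqrt(100) = 10x expected

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="zero trials"):
            pooled_response(np.empty((0, 10)))


class TestFluctuationIndex:
    def test_zero_for_trials_equal_to_pooled(self):
        pooled = np.sin(np.linspace(0, 3, 24))
        trials = np.tile(pooled, (6, 1))
        assert fluctuation_index(trials, pooled, 1.0) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        trials = 1.0 + rng.standard_normal((8, 24)) * 0.3
        pooled, amp = pooled_response(trials)
        base = fluctuation_index(trials, pooled, amp)
        for c in (0.1, 3.0, 1e4):
            pooled_c, amp_c = pooled_response(c * trials)
            scaled = fluctuation_index(c * trials, pooled_c, amp_c)
            assert scaled == pytest.approx(base, rel=1e-10)

    def test_recovers_sigma_over_amplitude(self):
        """Monte-Carlo recovery: index converges to sigma/A at long blocks."""
        rng = np.random.default_rng(2)
        sigma, A = 0.4, 2.0
        base = np.sin(np.linspace(0, np.pi, 200))
        tmpl = base / (base.max() - base.min()) * A
        trials = tmpl + rng.normal(0, sigma, (500, 200))
        pooled, amp = pooled_response(trials)
        idx = fluctuation_index(trials, pooled, amp)
        assert idx == pytest.approx(sigma / A, rel=0.05)

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(3)
        trials = rng.standard_normal((5, 30))
        pooled, amp = pooled_response(trials)
        resid = [trials[i] - pooled for i in range(5)]
        flat = np.concatenate(resid)
        mean = sum(flat) / flat.size
        var = sum((v - mean) ** 2 for v in flat) / flat.size
        oracle = np.sqrt(var) / amp
        assert fluctuation_index(trials, pooled, amp) == pytest.approx(
            float(oracle), rel=1e-10
        )

    def test_zero_amplitude_gives_inf_sentinel(self):
        trials = np.random.default_rng(4).standard_normal((3, 10))
        with pytest.warns(UserWarning, match="amplitude"):
            assert fluctuation_index(trials, np.zeros(10), 0.0) == np.inf


class TestCompareConditions:
    def test_identical_indices_give_t_zero_p_one(self):
        index = np.ones((10, 3, 2)) * np.array([1.0, 2.0, 0.5])[None, :, None]
        res = compare_conditions(index)
        assert np.allclose(res.t, 0.0)
        assert np.allclose(res.p, 1.0)

    def test_zero_index_pairs_excluded_with_warning(self):
        index = np.ones((6, 1, 2))
        index[0, 0, 0] = 0.0
        with pytest.warns(UserWarning, match="zero index"):
            res = compare_conditions(index)
        assert res.n_excluded == 1

    def test_injected_ratio_two_recovered_on_cohort(
        self, cohort, cohort_truth_by_subject
    ):
        """The suppression and imagery networks carry a twofold fluctuation
        increase during suppression; the paired log-test recovers it."""
        tab = fl.fluctuation_table(cohort_truth_by_subject, cohort.design, trim_volumes=4)
        res = compare_conditions(tab)
        for name in ("suppression_fpn", "imagery_fpn"):
            k = cohort.component_names.index(name)
            assert res.p[k] < 0.05
            assert 1.8 <= res.geometric_ratio[k] <= 2.2, name

    def test_null_networks_not_inflated_on_cohort(
        self, cohort, cohort_truth_by_subject
    ):
        tab = fl.fluctuation_table(cohort_truth_by_subject, cohort.design, trim_volumes=4)
        res = compare_conditions(tab)
        for name in ("dorsal_attention", "primary_visual", "somatomotor"):
            k = cohort.component_names.index(name)
            assert 0.9 <= res.geometric_ratio[k] <= 1.1, name

    def test_type_one_error_coarse(self):
        index = simulate_condition_indices(300, ratio=1.0, jitter_sd=0.0, seed=5)
        res = compare_conditions(index)
        assert 0.02 <= (res.p < 0.05).mean() <= 0.10


class TestReportAssociation:
    def test_clear_group_difference(self):
        rng = np.random.default_rng(6)
        ratios = np.concatenate([np.full(3, 2.0), np.full(3, 1.0)])[:, None]
        ratios = ratios * np.exp(rng.normal(0, 0.01, (6, 1)))
        flags = np.array([1, 1, 1, 0, 0, 0])
        res = report_association(ratios, flags)
        assert res.p[0] < 0.01
        assert res.t[0] > 0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            report_association(np.ones((4, 1)), np.ones(4))

    def test_control_component_attains_minimum_p(self, cohort, cohort_truth_by_subject):
        """The self-report flag is a median split on the control network's
        injected fluctuation ratio, so that network should dominate the
        association scan."""
        tab = fl.fluctuation_table(cohort_truth_by_subject, cohort.design, trim_volumes=4)
        res = report_association(tab.task_ratio(), cohort.reports)
        k_ctrl = cohort.component_names.index(cohort.config.control_component)
        assert int(np.argmin(res.p)) == k_ctrl
        assert res.p[k_ctrl] < 0.05

    def test_null_association_is_flat(self):
        rng = np.random.default_rng(7)
        ratios = np.exp(rng.normal(0, 0.3, (20, 200)))
        flags = np.r_[np.ones(10), np.zeros(10)]
        res = report_association(ratios, flags)
        assert 0.01 <= (res.p < 0.05).mean() <= 0.12


@settings(deadline=None, max_examples=15, derandomize=True)
@given(c=st.floats(0.01, 1000.0), seed=st.integers(0, 500))
def test_index_scale_invariance_property(c, seed):
    """Multiplying all data by c > 0 leaves the index unchanged."""
    rng = np.random.default_rng(seed)
    trials = 1.0 + rng.standard_normal((6, 20)) * 0.4
    pooled, amp = pooled_response(trials)
    p2, a2 = pooled_response(c * trials)
    assert fluctuation_index(c * trials, p2, a2) == pytest.approx(
        fluctuation_index(trials, pooled, amp), rel=1e-9
    )
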