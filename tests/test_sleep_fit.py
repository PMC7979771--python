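"""Survival fitting: active-index MLE, KS changepoint scan, tail model
comparison and the assembled five-parameter signature."""

import numpy as np
import pytest
from scipy import stats

from flysleep import (
    LatencyScanError,
    TwoPhaseSpec,
    empirical_survival,
    find_sleep_latency,
    fit_active_index,
    fit_phases,
    sample_two_phase,
    sleep_parameters,
    switch_rate,
    tail_aic_compare,
)


def pareto_survival_sample(beta, xmin, n, rng):
    """Pure power law with survival exponent beta: X = xmin * U^(-1/beta)."""
    return xmin * rng.random(n) ** (-1.0 / beta)


class TestEmpiricalSurvival:
    def test_small_example(self):
        curve = empirical_survival([1.0, 2.0, 3.0])
        assert curve.p[curve.t == 2.0] == pytest.approx(1 / 3)
        assert np.all(np.diff(curve.p) <= 0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            empirical_survival([])


class TestActiveIndex:
    def test_recovers_pure_pareto_exponent(self, rng):
        x = pareto_survival_sample(0.8, 3.0, 100_000, rng)
        fit = fit_active_index(x, xmin=3.0)
        assert 0.78 <= fit.beta <= 0.82

    def test_bounded_mle_recovers_truncated_head(self, two_phase_spec, rng):
        x = sample_two_phase(two_phase_spec, rng)
        fit = fit_active_index(x, xmin=3.0, K=two_phase_spec.K)
        assert abs(fit.beta - two_phase_spec.beta) < 3 * fit.se

    def test_all_below_xmin_raises(self):
        with pytest.raises(ValueError, match="below xmin"):
            fit_active_index(np.full(100, 1.5), xmin=3.0)

    def test_too_few_head_samples_raises(self):
        with pytest.raises(ValueError, match="head"):
            fit_active_index(np.array([4.0, 5.0, 6.0]), xmin=3.0)

    def test_scale_invariance_of_exponent(self, two_phase_spec, rng):
        x = sample_two_phase(two_phase_spec, rng)
        a = fit_active_index(x, xmin=3.0, K=two_phase_spec.K)
        c = 7.3
        b = fit_active_index(c * x, xmin=3.0 * c, K=two_phase_spec.K * c)
        assert b.beta == pytest.approx(a.beta, abs=1e-6)


class TestLatencyScan:
    def test_shifted_exponential_accepts_first_candidate(self, rng):
        x = 50.0 + rng.exponential(300.0, 2000)
        # the conservative asymptotic test accepts the very first candidate
        fit = find_sleep_latency(x, scan_start=50.0, method="asymptotic")
        assert fit.K == pytest.approx(50.0)
        assert abs(fit.lam - 300.0) < 3 * 300.0 / np.sqrt(fit.n_tail)
        # the corrected test has proper size: it stops at the start or,
        # for the ~10% of samples it rejects there, one step later
        fit_lf = find_sleep_latency(x, scan_start=50.0, method="lilliefors", step=5.0)
        assert fit_lf.K <= 55.0

    def test_too_few_tail_samples_raises(self, rng):
        x = np.concatenate([rng.uniform(1, 10, 100), 50.0 + rng.exponential(100.0, 5)])
        with pytest.raises(ValueError, match="fewer"):
            find_sleep_latency(x, scan_start=50.0, min_tail=10)

    def test_exhausted_scan_is_flagged_failure(self, rng):
        # near-degenerate durations: excesses are never exponential at any K,
        # down to the smallest admissible tail
        x = rng.normal(1000.0, 0.01, 3000)
        with pytest.raises(LatencyScanError):
            find_sleep_latency(x, scan_start=50.0)

    def test_returns_smallest_accepted_candidate(self, rng):
        spec = TwoPhaseSpec(beta=0.8, K=150.0, lam=600.0, xmin=3.0, n_bouts=3000)
        x = sample_two_phase(spec, rng)
        fit = find_sleep_latency(x, scan_start=50.0, method="asymptotic", step=None)
        # exhaustive oracle: independently test every candidate below K-hat
        candidates = np.concatenate(([50.0], np.unique(x[x >= 50.0])))
        for K in candidates[candidates < fit.K]:
            exc = x[x > K] - K
            assert stats.kstest(exc, "expon", args=(0, exc.mean())).pvalue < 0.10
        exc = x[x > fit.K] - fit.K
        assert stats.kstest(exc, "expon", args=(0, exc.mean())).pvalue >= 0.10

    def test_stepped_grid_candidates_are_multiples_of_step(self, rng):
        spec = TwoPhaseSpec(beta=0.8, K=150.0, lam=600.0, xmin=3.0, n_bouts=3000)
        fit = find_sleep_latency(sample_two_phase(spec, rng), scan_start=50.0, step=5.0)
        assert (fit.K - 50.0) % 5.0 == pytest.approx(0.0, abs=1e-9)


class TestTailModelComparison:
    def test_exponential_tail_favoured_on_exponential_data(self, rng):
        x = 100.0 + rng.exponential(500.0, 1000)
        assert tail_aic_compare(x, K=100.0) > 0

    def test_gaussian_tail_favoured_on_half_gaussian_data(self, rng):
        x = 100.0 + np.abs(rng.normal(0.0, 500.0, 1000))
        assert tail_aic_compare(x, K=100.0) < 0

    def test_single_excess_raises(self):
        with pytest.raises(ValueError, match="excess"):
            tail_aic_compare(np.array([10.0, 150.0]), K=100.0)

    def test_sign_matches_generating_model_in_most_trials(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            exp_data = r.exponential(500.0, 1000)
            gauss_data = np.abs(r.normal(0.0, 500.0, 1000))
            hits += int(tail_aic_compare(exp_data, K=0.0) > 0)
            hits += int(tail_aic_compare(gauss_data, K=0.0) < 0)
        assert hits >= 36  # >= 18/20 per generating model


class TestSwitchRate:
    def test_piecewise_values(self):
        params = _params(beta=0.8, K=200.0, lam=500.0)
        assert switch_rate(100.0, params) == pytest.approx(0.008)
        assert switch_rate(300.0, params) == pytest.approx(0.002)

    def test_nonpositive_time_raises(self):
        with pytest.raises(ValueError):
            switch_rate(0.0, _params(beta=0.8, K=200.0, lam=500.0))


def _params(beta, K, lam, N=10):
    from flysleep import SleepParams

    return SleepParams(beta=beta, K=K, lam=lam, N=N, total=N * lam, xmin=3.0,
                       ks_p_at_K=0.5, n_head=100, n_tail=N,
                       delta_aic_gauss_minus_exp=1.0)


class TestSleepParameters:
    def test_total_is_N_times_lam(self, two_phase_spec, rng):
        p = sleep_parameters(sample_two_phase(two_phase_spec, rng))
        assert p.total == p.N * p.lam
        assert p.N == p.n_tail

    def test_no_bouts_beyond_fixed_K(self, rng):
        x = rng.uniform(3.0, 40.0, 200)
        p = sleep_parameters(x, fixed_K=100.0, min_tail=0)
        assert p.N == 0 and p.total == 0.0

    def test_recovery_on_two_phase_synthetic(self, two_phase_spec, rng):
        x = sample_two_phase(two_phase_spec, rng)
        p = sleep_parameters(x)
        assert abs(p.beta - two_phase_spec.beta) < 0.05
        assert abs(p.K - two_phase_spec.K) / two_phase_spec.K < 0.25
        assert abs(p.lam - two_phase_spec.lam) / two_phase_spec.lam < 0.15

    def test_parameter_recovery_over_random_specs(self):
        # 20 random generating configurations; median errors must be small
        spec_rng = np.random.default_rng(42)
        b_err, k_err, l_err = [], [], []
        for i in range(20):
            spec = TwoPhaseSpec(
                beta=spec_rng.uniform(0.7, 1.0), K=spec_rng.uniform(100, 400),
                lam=spec_rng.uniform(300, 2000), xmin=3.0, n_bouts=5000,
                seed=5000 + i,
            )
            x = sample_two_phase(spec)
            p = sleep_parameters(x)
            b_err.append(abs(p.beta - spec.beta))
            k_err.append(abs(p.K - spec.K) / spec.K)
            l_err.append(abs(p.lam - spec.lam) / spec.lam)
        assert np.median(b_err) <= 0.03
        assert np.median(k_err) <= 0.25
        assert np.median(l_err) <= 0.10

    def test_per_phase_failure_does_not_abort_other_phase(self, two_phase_spec):
        import pandas as pd

        good = sample_two_phase(two_phase_spec)
        df = pd.concat([
            pd.DataFrame({"duration_s": good, "phase": "day"}),
            pd.DataFrame({"duration_s": [4.0, 5.0, 6.0], "phase": "night"}),
        ])
        out = fit_phases(df)
        day = out[out.phase == "day"].iloc[0]
        night = out[out.phase == "night"].iloc[0]
        assert day.error == "" and np.isfinite(day.beta)
        assert night.error != "" and np.isnan(night.beta)

    def test_dequantized_fit_handles_frame_grid_ties(self, two_phase_spec):
        x = sample_two_phase(two_phase_spec)
        q = np.round(x * 25.0) / 25.0  # quantize to a 25 fps grid
        p = sleep_parameters(q, dequantize_fps=25.0, rng=np.random.default_rng(0))
        assert abs(p.beta - two_phase_spec.beta) < 0.06
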