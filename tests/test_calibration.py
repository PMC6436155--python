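import math

import numpy as np
import pytest

from gravitropism import (AvalancheTrace, ContractError, DoseResponseCurve,
                          ModelParameters, SyntheticCohortSpec, TipTrajectory,
                          detect_reaction_time, dose_response_curve,
                          fit_avalanche_tau, fit_dose_response,
                          recovery_report, simulate_transient, solve_avalanche,
                          synth_avalanche_dataset, synth_tip_dataset,
                          build_protocol)


def _exp_trace(tau, a_stem=45.0, t_end=10.0, dt=0.05, noise=None, rng=None):
    t = np.arange(0.0, t_end + 1e-9, dt)
    a = a_stem * (1.0 - np.exp(-t / tau))
    if noise:
        a = a + rng.normal(0.0, noise, size=t.size)
    return AvalancheTrace(t=t, A_stato=a, A_stem=a_stem)


class TestAvalancheFit:
    def test_self_consistent_recovery_to_four_figures(self):
        """Fitting the exponential to exponential data returns the
        generating time constant to 4 significant figures."""
        res = fit_avalanche_tau(_exp_trace(1.04))
        assert res.converged
        assert res.estimates["tau_aval"] == pytest.approx(1.04, abs=5e-4)

    def test_mismatch_against_sine_relaxation_bounded(self):
        """The exponential surrogate fitted to the sine-ODE trace is biased
        by the model mismatch, but stays within 15% of the generator."""
        t = np.arange(0.0, 10.0 + 1e-9, 0.05)
        trace = solve_avalanche(1.04, 45.0, 0.0, t)
        res = fit_avalanche_tau(trace)
        assert abs(res.estimates["tau_aval"] / 1.04 - 1.0) < 0.15

    def test_noisy_monte_carlo_recovery(self):
        """Mean estimate over 10 noisy replicates (sd 2 deg) within 5%."""
        rng = np.random.default_rng(5)
        taus = [fit_avalanche_tau(
            _exp_trace(1.04, noise=2.0, rng=rng)).estimates["tau_aval"]
            for _ in range(10)]
        assert abs(np.mean(taus) / 1.04 - 1.0) < 0.05

    def test_hypergravity_cohort_scaling_through_estimator(self):
        """tau estimated from the 3g cohort is one third of the 1g value."""
        spec = SyntheticCohortSpec(n_replicates=10, noise_sd=1.0,
                                   param_jitter_cv=0.0, seed=7,
                                   sampling_interval=0.05)
        taus = {}
        for g in (1.0, 3.0):
            cohort = synth_avalanche_dataset(1.04, 45.0, [g], spec,
                                             duration=8.0 / g)
            taus[g] = np.mean([fit_avalanche_tau(tr).estimates["tau_aval"]
                               for tr in cohort.traces])
        assert taus[3.0] / taus[1.0] == pytest.approx(1.0 / 3.0, rel=0.10)

    def test_flat_trace_does_not_converge(self):
        t = np.linspace(0.0, 10.0, 50)
        flat = AvalancheTrace(t=t, A_stato=np.full(50, 45.0), A_stem=45.0)
        res = fit_avalanche_tau(flat)
        assert not res.converged
        assert "summary" in dir(res) and "Converged: False" in res.summary()


class TestReactionTimeDetection:
    def test_noiseless_simulation_onset_exact(self, wheat):
        traj = simulate_transient(wheat, 20.0, 45.0)
        onset = detect_reaction_time(traj, threshold=1e-8)
        assert onset == pytest.approx(wheat.tau_reaction, abs=1e-6)

    def test_no_response_returns_sentinel(self, wheat):
        t = np.linspace(0.0, 100.0, 200)
        flat = TipTrajectory(t=t, theta_tip=np.zeros(200),
                             theta_base=np.zeros(200))
        assert detect_reaction_time(flat) is None

    def test_noisy_cohort_minimum_onset_bounds(self, wheat):
        """With a false-alarm-safe threshold, detections never precede the
        cohort's earliest (jittered) delay and the cohort minimum lags the
        13-min delay by no more than about one memory time — the intrinsic
        bias of threshold detection on a rate that rises over tau_memory."""
        proto = build_protocol(45.0, 20.0, observe_after=120.0)
        spec = SyntheticCohortSpec(n_replicates=12, noise_sd=2.0,
                                   param_jitter_cv=0.10, seed=3,
                                   sampling_interval=5.0)
        cohort = synth_tip_dataset(wheat, proto, spec)
        onsets = [detect_reaction_time(tr, threshold=0.3, min_consecutive=3,
                                       smooth_window=9)
                  for tr in cohort.trajectories]
        onsets = [o for o in onsets if o is not None]
        assert onsets, "no replicate produced a detectable onset"
        earliest_delay = min(p.tau_reaction for p in cohort.true_params)
        assert min(onsets) >= earliest_delay
        assert min(onsets) <= 13.0 + wheat.tau_memory


class TestDoseResponseFit:
    def test_noiseless_self_consistency(self, wheat):
        """Refitting (beta, tau_memory) to a curve the model itself
        generated recovers the generators within 2%."""
        curve = dose_response_curve(wheat, [3.0, 8.0, 20.0, 35.0],
                                    n_nodes=32, time_step=0.1)
        res = fit_dose_response(curve, wheat, n_nodes=32, time_step=0.1)
        assert res.converged
        assert res.estimates["beta"] == pytest.approx(0.8, rel=0.02)
        assert res.estimates["tau_memory"] == pytest.approx(13.0, rel=0.02)

    def test_noisy_cohort_curve_monte_carlo_recovery(self, wheat):
        """Seeded Monte-Carlo: cohort dose-response curves (12 plants per
        duration, per-plant scatter 10% of the plateau, points are cohort
        means) refit the generating gain and memory time within 15% on
        average over replicate experiments."""
        from gravitropism.calibration import DoseResponseModel

        n_plants = 12
        curve = dose_response_curve(wheat, [2.0, 3.0, 5.0, 8.0, 11.0,
                                            20.0, 35.0],
                                    n_nodes=32, time_step=0.2)
        betas, taus = [], []
        for seed in (17, 18, 19):
            rng = np.random.default_rng(seed)
            noisy = curve.points.copy()
            scatter = rng.normal(0.0, 0.10 * curve.beta_tilde.max(),
                                 size=(len(noisy), n_plants))
            noisy["beta_tilde"] = curve.beta_tilde + scatter.mean(axis=1)
            noisy_curve = DoseResponseCurve(points=noisy, theta_incl=45.0)
            res = DoseResponseModel(noisy_curve, wheat, n_nodes=32,
                                    n_starts=1, time_step=0.2).fit()
            assert res.converged
            betas.append(res.estimates["beta"])
            taus.append(res.estimates["tau_memory"])
        assert abs(np.mean(betas) / 0.8 - 1.0) < 0.15
        assert abs(np.mean(taus) / 13.0 - 1.0) < 0.15

    def test_plateau_only_curve_flags_memory_time(self, wheat):
        """Durations all far beyond the knee leave tau_memory unconstrained:
        the degeneracy is flagged, and the fitted gain absorbs the plateau
        level (the gain/memory pair is only a ridge on such data)."""
        curve = dose_response_curve(wheat, [1300.0, 2000.0, 3000.0],
                                    n_nodes=32, time_step=0.1)
        with pytest.warns(UserWarning, match="plateau"):
            res = fit_dose_response(curve, wheat, n_nodes=32, time_step=0.1)
        assert res.flags.get("tau_memory_identifiable") is False
        plateau = float(curve.beta_tilde.max())
        assert res.estimates["beta"] == pytest.approx(plateau, rel=0.10)
        assert res.residual_norm < 0.01 * plateau


class TestRecoveryReport:
    def test_noiseless_pairs_have_zero_bias(self, wheat):
        fits = [fit_avalanche_tau(_exp_trace(1.04)) for _ in range(3)]
        report = recovery_report(wheat.replace(tau_aval_ref=1.04), fits)
        row = report.set_index("parameter").loc["tau_aval"]
        assert abs(row["relative_bias"]) < 1e-4
        assert row["rmse"] < 1e-3

    def test_jittered_ensemble_bias_bounded(self):
        rng = np.random.default_rng(23)
        gens, fits = [], []
        for _ in range(20):
            tau_i = 1.04 * math.exp(rng.normal(0.0, 0.10))
            gens.append(ModelParameters(tau_aval_ref=tau_i))
            fits.append(fit_avalanche_tau(
                _exp_trace(tau_i, noise=2.0, rng=rng)))
        report = recovery_report(gens, fits)
        row = report.set_index("parameter").loc["tau_aval"]
        assert abs(row["relative_bias"]) < 0.10

    def test_contract_errors(self, wheat):
        with pytest.raises(ContractError):
            recovery_report(wheat, [])
        with pytest.raises(ContractError):
            recovery_report([wheat, wheat], [fit_avalanche_tau(_exp_trace(1.0))])
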