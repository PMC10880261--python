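"""Parameter recovery, identifiability fallback, and optimizer behavior."""

import numpy as np
import pytest

import flowbind as fb
from flowbind.core import Phase, replace
from flowbind.fitting import InsufficientDataError, assess_koff_identifiability


class TestNoiseFreeRecovery:
    def test_exact_data_recovers_truth(self, config, calib, truth):
        """On noise-free model output all three parameters come back to
        well under 0.1% relative."""
        curve = fb.expected_curve(config, calib, truth)
        res = fb.fit(curve, config, calib, fb.FitOptions(seed=1))
        assert res.converged
        assert res.k_on == pytest.approx(truth.k_on, rel=1e-3)
        assert res.k_off == pytest.approx(truth.k_off, rel=1e-3)
        assert res.n_ar == pytest.approx(truth.n_antigens_total, rel=1e-3)
        assert res.b_max_per_cell == pytest.approx(1.1e6, rel=1e-3)
        assert not res.koff_imputed

    def test_log_and_linear_parameterizations_agree(self, config, calib, truth):
        curve = fb.expected_curve(config, calib, truth)
        log_fit = fb.fit(curve, config, calib, fb.FitOptions(seed=1, n_starts=2))
        lin_fit = fb.fit(
            curve, config, calib, fb.FitOptions(seed=1, n_starts=2, param_space="linear")
        )
        assert log_fit.k_on == pytest.approx(lin_fit.k_on, rel=1e-3)
        assert log_fit.n_ar == pytest.approx(lin_fit.n_ar, rel=1e-3)

    def test_loss_modes_agree_on_exact_data(self, config, calib, truth):
        curve = fb.expected_curve(config, calib, truth)
        a = fb.fit(curve, config, calib, fb.FitOptions(seed=1, n_starts=2))
        b = fb.fit(
            curve, config, calib, fb.FitOptions(seed=1, n_starts=2, loss="unweighted")
        )
        assert a.k_on == pytest.approx(b.k_on, rel=1e-4)


class TestKoffIdentifiability:
    def test_truncated_uptake_triggers_fallback(self, config, calib, truth):
        """A 30 min acquisition without washout cannot constrain k_off;
        the fit freezes it at the fallback median and flags imputation."""
        curve = fb.generate_curve(config, calib, truth, seed=3).truncated(1800.0)
        res = fb.fit(curve, config, calib, fb.FitOptions(seed=1))
        assert res.koff_imputed
        assert res.k_off == 0.45e-5
        assert res.diagnostics["identifiability"]["criterion"] == "short_uptake_no_washout"

    def test_washout_run_estimates_koff(self, calib, truth):
        """3 h uptake + 4 h washout pins dissociation: no imputation, and
        the estimate lands within a factor of two."""
        config = fb.AssayConfig(
            phases=(Phase(3 * 3600.0, "radioligand"), Phase(4 * 3600.0, "blank"))
        )
        t = replace(truth, k_off=2e-5)
        curve = fb.generate_curve(config, calib, t, seed=4)
        res = fb.fit(curve, config, calib, fb.FitOptions(seed=1))
        assert not res.koff_imputed
        assert 0.5 < res.k_off / t.k_off < 2.0

    def test_zero_koff_with_washout_lands_at_bound(self, config, calib, truth):
        """Truly irreversible binding drives the estimate to the lower
        k_off bound, flagged rather than imputed (noise-free data)."""
        t = replace(truth, k_off=0.0)
        curve = fb.expected_curve(config, calib, t)
        res = fb.fit(curve, config, calib, fb.FitOptions(seed=1))
        assert not res.koff_imputed
        assert res.diagnostics["koff_at_bound"]
        assert res.k_off <= 1.25e-7

    def test_longer_washout_never_widens_koff_profile(self, calib, truth):
        """Widening the observation window adds dissociation information:
        the flat span of the k_off profile must not grow."""
        spans = []
        for washout_h in (1.0, 4.0):
            config = fb.AssayConfig(
                phases=(
                    Phase(3 * 3600.0, "radioligand"),
                    Phase(washout_h * 3600.0, "blank"),
                )
            )
            curve = fb.expected_curve(config, calib, truth)
            res = fb.fit(curve, config, calib, fb.FitOptions(seed=1, n_starts=2))
            ident = res.diagnostics["identifiability"]
            spans.append(ident.get("flat_span_decades", 0.0))
        assert spans[1] <= spans[0] + 1e-9

    def test_assessment_uses_curve_extent_not_schedule(self, config, calib, truth):
        """Identifiability must consider the acquired data: a schedule with
        washout whose curve stops before the washout is uptake-only."""
        curve = fb.expected_curve(config, calib, truth).truncated(3 * 3600.0)
        identifiable, diag = assess_koff_identifiability(
            curve, config, calib, truth, fb.FitOptions(seed=1)
        )
        assert not identifiable
        assert diag["washout_s"] == 0.0


class TestEstimatorQuality:
    def test_kon_estimator_bias_small(self, config, calib, truth):
        """Across replicate noisy assays at fixed truth, the k_on estimator
        mean stays within 5% of truth."""
        rng_seeds = np.random.SeedSequence(77).generate_state(50)
        opts = fb.FitOptions(seed=1, n_starts=2, check_identifiability=False)
        kons = []
        for s in rng_seeds:
            curve = fb.generate_curve(config, calib, truth, seed=int(s))
            kons.append(fb.fit(curve, config, calib, opts).k_on)
        assert abs(np.mean(kons) / truth.k_on - 1) < 0.05

    def test_objective_not_worse_than_center_start(self, config, calib, truth):
        """The accepted optimum must beat the deterministic central start."""
        curve = fb.generate_curve(config, calib, truth, seed=9)
        res = fb.fit(curve, config, calib, fb.FitOptions(seed=1, n_starts=2))
        center = fb.KineticParams(np.sqrt(1e3 * 1e7), np.sqrt(1e-7 * 1e-3), np.sqrt(1e10 * 1e13))
        sig = fb.predict_channel_signals(config, calib, center, n_channels=curve.n_channels)
        r0 = (curve.counts - sig.true_counts) / np.sqrt(np.maximum(sig.true_counts, 1e-2))
        assert res.ssr <= np.sum(r0**2)


class TestValidation:
    def test_too_short_curve_rejected(self, config, calib, truth):
        curve = fb.generate_curve(config, calib, truth, seed=1).truncated(300.0)
        with pytest.raises(InsufficientDataError):
            fb.fit(curve, config, calib, fb.FitOptions(seed=1))

    def test_channel_width_mismatch_rejected(self, config, calib, truth):
        curve = fb.generate_curve(config, calib, truth, seed=1)
        bad = fb.TimeActivityCurve(curve.channel_start_s * 2, curve.counts, 120.0)
        with pytest.raises(fb.core.InvalidParameterError):
            fb.fit(bad, config, calib, fb.FitOptions(seed=1))
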