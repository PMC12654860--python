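"""Power-law rheology: exact limits, grid recovery, regime comparison."""

import numpy as np
import pytest

from micropress import (
    CompressionRunSpec,
    RheologyFit,
    RheologySample,
    VirtualCellParams,
    apparent_modulus_at_checkpoint,
    build_curve,
    compare_regimes,
    fit_power_law,
    simulate_compression,
)

TIMES = (0.2, 0.5, 1.0, 2.0)


def _samples(E0, beta, times=TIMES, noise=None, rng=None):
    out = []
    for t in times:
        E = E0 * t ** (-beta)
        if noise is not None:
            E *= 1.0 + noise * rng.standard_normal()
        out.append(RheologySample(t=t, apparent_E=E))
    return out


class TestFitPowerLaw:
    def test_exact_log_log_line(self):
        fit = fit_power_law(_samples(5.0, 0.3))
        assert fit.E0 == pytest.approx(5.0, abs=1e-9)
        assert fit.beta == pytest.approx(0.3, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_elastic_solid_limit_beta_zero(self):
        fit = fit_power_law(_samples(4.0, 0.0))
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_newtonian_liquid_limit_beta_one(self):
        fit = fit_power_law(_samples(2.0, 1.0))
        assert fit.beta == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("E0", [1.0, 3.0, 5.0, 10.0])
    @pytest.mark.parametrize("beta", [0.0, 0.1, 0.3, 0.5, 1.0])
    def test_grid_recovery_noise_free(self, E0, beta):
        """Indentation times from the 2.5-15 µm/s speed sweep at a fixed
        checkpoint recover (E0, beta) to 1e-6 relative error."""
        # t = ε*·L0/speed for ε*=0.15, L0=15 µm over the speed sweep
        times = [0.15 * 15.0 / v for v in (2.5, 5.0, 10.0, 15.0)]
        fit = fit_power_law(_samples(E0, beta, times=times))
        assert fit.E0 == pytest.approx(E0, rel=1e-6)
        assert fit.beta == pytest.approx(beta, abs=1e-6)

    def test_beta_error_small_under_multiplicative_noise(self, rng):
        """5% multiplicative noise, 100 replicates: median |beta error| ≤ 0.05."""
        errs = []
        for _ in range(100):
            fit = fit_power_law(_samples(3.0, 0.3, noise=0.05, rng=rng))
            errs.append(abs(fit.beta - 0.3))
        assert np.median(errs) <= 0.05

    def test_tref_rescaling_identity(self):
        """Refit with tref' = 2 s: E0 scales by (tref'/tref)^(-beta), beta fixed."""
        samples = _samples(5.0, 0.4)
        f1 = fit_power_law(samples, tref=1.0)
        f2 = fit_power_law(samples, tref=2.0)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-9)
        assert f2.E0 == pytest.approx(f1.E0 * 2.0 ** (-f1.beta), rel=1e-9)

    def test_nls_cross_check_matches_ols_noise_free(self):
        samples = _samples(6.0, 0.25)
        ols = fit_power_law(samples, method="ols")
        nls = fit_power_law(samples, method="nls")
        assert nls.E0 == pytest.approx(ols.E0, rel=1e-6)
        assert nls.beta == pytest.approx(ols.beta, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_power_law(_samples(3.0, 0.3, times=(1.0, 1.0, 1.0)))
        with pytest.raises(ValueError):
            fit_power_law(_samples(3.0, 0.3, times=(0.5, 1.0)))
        with pytest.raises(ValueError):
            RheologySample(t=1.0, apparent_E=-1.0)


class TestApparentModulus:
    def test_elastic_cell_speed_invariant(self):
        cell = VirtualCellParams(E0_cyto=4.0, E0_nuc=4.0, beta_cyto=0, beta_nuc=0)
        for speed in (2.5, 15.0):
            run = CompressionRunSpec(
                speed=speed, max_strain=0.5, sample_rate=200,
                include_unloading=False, force_noise_sd=0.0,
            )
            rec = simulate_compression(cell, run, seed=0)
            s = apparent_modulus_at_checkpoint(build_curve(rec), rec, 0.3)
            assert s.apparent_E == pytest.approx(4.0, rel=1e-9)

    def test_checkpoint_time_from_speed(self):
        cell = VirtualCellParams(
            L0=10.0, E0_cyto=4.0, E0_nuc=4.0, beta_cyto=0, beta_nuc=0
        )
        run = CompressionRunSpec(
            speed=2.5, max_strain=0.4, sample_rate=100,
            include_unloading=False, force_noise_sd=0.0,
        )
        rec = simulate_compression(cell, run, seed=0)
        s = apparent_modulus_at_checkpoint(build_curve(rec), rec, 0.2)
        assert s.t == pytest.approx(0.2 * 10.0 / 2.5, rel=1e-12)  # 0.8 s

    def test_interpolated_checkpoint_matches_dense_grid(self):
        """Linear interpolation at a between-samples checkpoint agrees with a
        10x refined grid within 0.5%."""
        cell = VirtualCellParams(
            L0=15.0, nucleus_fraction=0.6,
            E0_cyto=3.0, E0_nuc=3.0, beta_cyto=0.4, beta_nuc=0.4,
        )
        vals = {}
        for rate in (40.0, 400.0):
            run = CompressionRunSpec(
                speed=7.0, max_strain=0.35, sample_rate=rate,
                include_unloading=False, force_noise_sd=0.0,
            )
            rec = simulate_compression(cell, run, seed=0)
            vals[rate] = apparent_modulus_at_checkpoint(
                build_curve(rec), rec, 0.17
            ).apparent_E
        assert vals[40.0] == pytest.approx(vals[400.0], rel=0.005)

    def test_unreached_checkpoint_rejected(self):
        cell = VirtualCellParams(E0_cyto=4.0, E0_nuc=4.0, beta_cyto=0, beta_nuc=0)
        run = CompressionRunSpec(speed=5, max_strain=0.2, include_unloading=False)
        rec = simulate_compression(cell, run, seed=0)
        with pytest.raises(ValueError, match="checkpoint"):
            apparent_modulus_at_checkpoint(build_curve(rec), rec, 0.4)

    def test_regime_tagging(self):
        cell = VirtualCellParams(E0_cyto=4.0, E0_nuc=4.0, beta_cyto=0, beta_nuc=0)
        run = CompressionRunSpec(speed=10, max_strain=0.5, include_unloading=False)
        rec = simulate_compression(cell, run, seed=0)
        curve = build_curve(rec)
        low = apparent_modulus_at_checkpoint(curve, rec, 0.15, nucleus_contact_strain=0.4)
        high = apparent_modulus_at_checkpoint(curve, rec, 0.45, nucleus_contact_strain=0.4)
        assert low.regime == "low_compression"
        assert high.regime == "high_compression"

    def test_speed_sweep_spans_sixfold_time_range(self):
        times = [0.15 * 15.0 / v for v in (2.5, 15.0)]
        assert times[0] / times[1] >= 6.0


class TestCompareRegimes:
    def test_expected_ordering_flagged(self):
        low = RheologyFit(E0=2.0, beta=0.35)
        high = RheologyFit(E0=6.0, beta=0.1)
        rep = compare_regimes(low, high)
        assert rep["stiffer_at_depth"] and rep["more_solid_at_depth"]
        assert rep["E0_ratio_high_over_low"] == pytest.approx(3.0)

    def test_identical_regimes_are_neutral(self):
        fit = RheologyFit(E0=3.0, beta=0.2)
        rep = compare_regimes(fit, fit)
        assert rep["E0_ratio_high_over_low"] == 1.0
        assert rep["beta_diff_low_minus_high"] == 0.0

    def test_swapped_parameters_invert_flags(self):
        low = RheologyFit(E0=6.0, beta=0.1)
        high = RheologyFit(E0=2.0, beta=0.35)
        rep = compare_regimes(low, high)
        assert not rep["stiffer_at_depth"] and not rep["more_solid_at_depth"]

    def test_missing_regime_rejected(self):
        with pytest.raises(ValueError):
            compare_regimes(None, RheologyFit(E0=1.0, beta=0.0))
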