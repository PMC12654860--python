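"""Virtual instrument: sweep geometry, compression physics, populations."""

import numpy as np
import pytest
from scipy import stats

from micropress import (
    CompressionRunSpec,
    PopulationPreset,
    SensorParams,
    VirtualCellParams,
    contact_diameter,
    get_preset,
    sample_population,
    simulate_calibration_sweep,
    simulate_compression,
)
from micropress.virtual_instrument import sample_moduli, simulate_max_force_scenario


class TestCalibrationSweepGeometry:
    def test_fifty_steps_give_7p2_degrees(self, sensor):
        sweep = simulate_calibration_sweep(sensor, 3.27e-5, n_steps=50, seed=0)
        steps = np.diff(sweep.angles)
        np.testing.assert_allclose(steps, 7.2)
        assert sweep.angles[0] == 0.0

    def test_adc_at_quadrature_equals_baseline(self):
        sensor = SensorParams(2.0, 0.0, 0.0, 0.0)
        sweep = simulate_calibration_sweep(sensor, 1.0, n_steps=4, seed=0)
        # angle 90°: cos = 0 -> pure baseline (here 0)
        assert sweep.adc_values[1] == pytest.approx(0.0, abs=1e-9)

    def test_invalid_arguments_rejected(self, sensor):
        with pytest.raises(ValueError):
            simulate_calibration_sweep(sensor, -1.0, 50)
        with pytest.raises(ValueError):
            simulate_calibration_sweep(sensor, 1.0, 3)

    def test_seed_reproducibility(self):
        noisy = SensorParams(2.0, 0.0, 0.0, 1.0)
        a = simulate_calibration_sweep(noisy, 1.0, 50, seed=9)
        b = simulate_calibration_sweep(noisy, 1.0, 50, seed=9)
        c = simulate_calibration_sweep(noisy, 1.0, 50, seed=10)
        np.testing.assert_array_equal(a.adc_values, b.adc_values)
        assert not np.array_equal(a.adc_values, c.adc_values)


class TestContactGeometry:
    def test_half_strain_closed_form(self):
        # ε=0.5, L0=10 -> Dt = 10·sqrt(0.75) = 8.660, Lt = 5
        assert contact_diameter(0.5, 10.0) == pytest.approx(8.660254, abs=1e-6)

    def test_chord_limits_and_monotonicity(self):
        eps = np.linspace(0.0, 0.999, 500)
        d = contact_diameter(eps, 12.0)
        assert d[0] == 0.0
        assert np.all(np.diff(d) > 0)
        assert np.all(d <= 12.0)


class TestSimulateCompression:
    def test_elastic_cell_has_constant_stress_strain_ratio(
        self, elastic_cell, quiet_run
    ):
        rec = simulate_compression(elastic_cell, quiet_run, seed=0)
        strain = (elastic_cell.L0 - rec.Lt) / elastic_cell.L0
        area = np.pi * rec.Dt**2 / 4
        loading = rec.branch == "loading"
        ratio = rec.force[loading] / (area[loading] * strain[loading])
        np.testing.assert_allclose(ratio, 5.0, rtol=1e-9)

    @pytest.mark.parametrize("speed", [2.5, 7.5, 15.0])
    @pytest.mark.parametrize("beta", [0.0, 0.3, 0.8])
    def test_loading_force_monotone_single_compartment(self, speed, beta):
        """On a dense grid, loading force increases monotonically for a
        single-compartment cell (checked by brute force)."""
        cell = VirtualCellParams(
            L0=15.0, nucleus_fraction=0.6, E0_cyto=3.0, E0_nuc=3.0,
            beta_cyto=beta, beta_nuc=beta,
        )
        run = CompressionRunSpec(
            speed=speed, max_strain=0.39, sample_rate=500.0,
            include_unloading=False, force_noise_sd=0.0,
        )
        rec = simulate_compression(cell, run, seed=0)
        assert np.all(np.diff(rec.force) > 0)

    def test_unloading_mirrors_loading_with_retention(self, quiet_run):
        cell = VirtualCellParams(
            L0=15.0, E0_cyto=4.0, E0_nuc=9.0, beta_cyto=0.3, beta_nuc=0.1,
            unload_retention=0.7,
        )
        rec = simulate_compression(cell, quiet_run, seed=0)
        strain = (cell.L0 - rec.Lt) / cell.L0
        area = np.pi * rec.Dt**2 / 4
        stress = rec.force / area
        load = rec.branch == "loading"
        unload = ~load
        # match unloading strains to loading strains and compare stresses
        for eps_u, sig_u in zip(strain[unload], stress[unload]):
            i = np.argmin(np.abs(strain[load] - eps_u))
            assert sig_u == pytest.approx(0.7 * stress[load][i], rel=1e-9)

    def test_geometry_series_consistent_with_strain(self, elastic_cell, quiet_run):
        rec = simulate_compression(elastic_cell, quiet_run, seed=0)
        strain = (elastic_cell.L0 - rec.Lt) / elastic_cell.L0
        np.testing.assert_allclose(
            rec.Dt, contact_diameter(strain, elastic_cell.L0), atol=1e-12
        )

    def test_max_strain_validated(self, elastic_cell):
        with pytest.raises(ValueError):
            CompressionRunSpec(speed=5, max_strain=1.0)

    def test_seed_reproducibility(self, elastic_cell):
        run = CompressionRunSpec(force_noise_sd=2.0)
        a = simulate_compression(elastic_cell, run, seed=3)
        b = simulate_compression(elastic_cell, run, seed=3)
        np.testing.assert_array_equal(a.force, b.force)


class TestPopulations:
    def test_large_sample_mean_approaches_preset_mean(self):
        preset = get_preset("HEK293A")
        x = sample_moduli(preset, 20000, seed=0)
        # truncation at 0.1 kPa barely shifts a 2.85 ± 1.15 distribution
        assert x.mean() == pytest.approx(2.85, abs=3 * 1.15 / np.sqrt(20000) + 0.01)
        assert np.all(x >= 0.1)

    def test_degenerate_sd_gives_constant_population(self):
        preset = PopulationPreset("const", ((1.0, 4.0, 0.0),))
        x = sample_moduli(preset, 50, seed=1)
        np.testing.assert_allclose(x, 4.0)

    def test_two_component_mixture_is_bimodal_by_kde(self):
        preset = PopulationPreset("mix", ((0.5, 3.0, 0.5), (0.5, 7.0, 0.5)))
        x = sample_moduli(preset, 500, seed=7)
        kde = stats.gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(0, 10, 2000)
        d = kde(grid)
        peaks = grid[
            1:-1][(d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]) & (d[1:-1] > 0.1 * d.max())
        ]
        assert len(peaks) == 2
        assert abs(peaks[0] - 3.0) < 0.5 and abs(peaks[1] - 7.0) < 0.5

    def test_cells_carry_matched_effective_modulus(self):
        preset = get_preset("C2C12")
        cells = sample_population(preset, 10, seed=2)
        for c in cells:
            assert c.E0_cyto == c.E0_nuc > 0
            assert c.beta_cyto == c.beta_nuc == 0.0

    def test_unknown_preset_name_raises(self):
        with pytest.raises(KeyError):
            get_preset("HEK293B")

    def test_sampling_deterministic_under_seed(self):
        preset = get_preset("Progerin_OX")
        np.testing.assert_array_equal(
            sample_moduli(preset, 100, seed=5), sample_moduli(preset, 100, seed=5)
        )


class TestEndEffectorScenario:
    def test_needle_max_force_spread_exceeds_plate(self):
        """At equal cell parameters the needle's unstable engagement widens
        the max-force distribution relative to the plate."""
        cell = VirtualCellParams(
            E0_cyto=2.85, E0_nuc=2.85, beta_cyto=0.0, beta_nuc=0.0
        )
        run = CompressionRunSpec(
            speed=10, max_strain=0.5, sample_rate=50,
            include_unloading=False, force_noise_sd=2.0,
        )
        cells = [cell] * 40
        plate = simulate_max_force_scenario(cells, run, "plate", seed=1)
        needle = simulate_max_force_scenario(cells, run, "needle", seed=2)
        assert np.var(needle, ddof=1) > np.var(plate, ddof=1)

    def test_unknown_effector_rejected(self, elastic_cell, quiet_run):
        with pytest.raises(ValueError):
            simulate_max_force_scenario([elastic_cell], quiet_run, "cone", seed=0)
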