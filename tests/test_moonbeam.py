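import dataclasses
import math

import numpy as np
import pytest

from pswarp import moonbeam
from pswarp.errors import ConfigurationError, DomainError, NumericalError
from pswarp.moonbeam import (DamageLaw, SimConfig, default_run_to_failure_config,
                             default_single_mode_config,
                             default_stationary_config, default_two_mode_config,
                             mechanical_energy, read_damage, read_timeseries,
                             simulate, well_frequency, write_timeseries)


def make_config(**overrides):
    base = dict(
        damping_ratio=0.1, forcing_amplitude=0.0, forcing_frequency=9.5,
        sample_rate=200.0, duration=5.0, noise_sd=0.0,
        damage_modes=(DamageLaw(rate_constant=0.0, label="ductile"),),
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestValidation:
    def test_nyquist(self):
        with pytest.raises(ConfigurationError, match="sample_rate"):
            make_config(sample_rate=15.0)

    def test_step_must_divide_sampling_interval(self):
        with pytest.raises(ConfigurationError, match="divide"):
            make_config(integrator_step=0.0007)

    def test_default_step_is_twentieth_of_interval(self):
        cfg = make_config()
        assert cfg.substeps == 20
        assert cfg.integrator_step == pytest.approx(1.0 / 200.0 / 20.0)

    def test_mode_count_bounds(self):
        law = DamageLaw(rate_constant=0.0, label="ductile")
        with pytest.raises(ConfigurationError):
            make_config(damage_modes=())
        with pytest.raises(ConfigurationError):
            make_config(damage_modes=(law, law, law))

    def test_rate_constant_scale_separation(self):
        with pytest.raises(ConfigurationError, match="rate_constant"):
            DamageLaw(rate_constant=0.05, label="ductile")

    def test_gate_side_tied_to_label(self):
        with pytest.raises(ConfigurationError):
            DamageLaw(rate_constant=1e-4, gate_side="above", label="ductile")
        with pytest.raises(ConfigurationError):
            DamageLaw(rate_constant=1e-4, gate_side="below", label="brittle")

    def test_negative_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            make_config(damping_ratio=-0.1)
        with pytest.raises(ConfigurationError):
            DamageLaw(rate_constant=1e-4, exponent=-1.0, label="ductile")


class TestSimulate:
    def test_unforced_damped_decays_to_well_bottom(self):
        # [TRIVIAL] A = 0, eps = 0, zeta > 0: x -> +-1, phi = 0 throughout
        cfg = make_config(duration=20.0, damping_ratio=0.2)
        out = simulate(cfg)
        assert abs(abs(out.fast_state[-1, 0]) - 1.0) < 1e-3
        assert abs(out.fast_state[-1, 1]) < 1e-3
        assert np.all(out.damage == 0.0)

    def test_constant_rate_damage_is_linear(self):
        # [DERIVED] gate accepting everything, p = 0: phi(t) = min(eps t, 1)
        eps = 5e-3
        law = DamageLaw(rate_constant=eps, amplitude_gate=1e9,
                        gate_side="below", exponent=0.0, label="ductile")
        cfg = make_config(duration=30.0, damage_modes=(law,),
                          forcing_amplitude=0.2)
        out = simulate(cfg)
        expected = np.minimum(eps * out.times, 1.0)
        np.testing.assert_allclose(out.damage[:, 0], expected, rtol=1e-9,
                                   atol=1e-12)

    def test_default_two_mode_mixes_regimes(self):
        # [DERIVED] canonical default: sign changes and partial occupancy of
        # the |x| > x_c region, mirroring mixed small/large-amplitude loading
        cfg = default_two_mode_config(seed=2)
        cfg = dataclasses.replace(cfg, duration=60.0, noise_sd=0.0)
        out = simulate(cfg)
        x = out.fast_state[:, 0]
        assert np.any(np.diff(np.sign(x)) != 0), "no cross-well excursions"
        x_c = cfg.damage_modes[0].amplitude_gate
        frac = np.mean(np.abs(x) > x_c)
        assert 0.0 < frac < 1.0

    def test_measurement_length_exclusive_endpoint(self):
        cfg = make_config(duration=1.0)
        out = simulate(cfg)
        assert len(out.measurement) == 200
        assert out.times[0] == 0.0
        assert out.times[-1] == pytest.approx(199 / 200)

    def test_damage_nondecreasing(self):
        out = simulate(default_two_mode_config(seed=1, accelerated=True))
        assert np.all(np.diff(out.damage, axis=0) >= -1e-15)

    def test_seed_determinism(self):
        cfg = default_single_mode_config(seed=11, accelerated=True)
        cfg = dataclasses.replace(cfg, duration=30.0)
        a = simulate(cfg)
        b = simulate(cfg)
        np.testing.assert_array_equal(a.measurement, b.measurement)
        np.testing.assert_array_equal(a.damage, b.damage)

    def test_different_seeds_differ(self):
        cfg1 = default_stationary_config(seed=1, duration=10.0)
        cfg2 = default_stationary_config(seed=2, duration=10.0)
        assert not np.array_equal(simulate(cfg1).measurement,
                                  simulate(cfg2).measurement)

    def test_failure_truncates_and_sets_failed_at(self):
        out = simulate(default_run_to_failure_config(seed=1))
        assert out.failed_at is not None
        assert len(out.measurement) < out.config.n_samples
        assert out.damage[-1].sum() < 1.0  # truncated at last completed sample

    def test_no_failure_leaves_failed_at_none(self):
        out = simulate(make_config(duration=2.0))
        assert out.failed_at is None

    def test_energy_nonincreasing_unforced(self):
        cfg = make_config(duration=10.0, damping_ratio=0.05)
        out = simulate(cfg)
        e = mechanical_energy(cfg, out.fast_state[:, 0], out.fast_state[:, 1])
        # tolerance: integrator error per step
        assert np.all(np.diff(e) <= 1e-6 * cfg.substeps)

    def test_quasi_stationarity(self):
        # over any window <= 0.01/eps, max |delta phi| <= 0.01
        cfg = default_single_mode_config(seed=4, accelerated=True)
        out = simulate(cfg)
        eps = cfg.damage_modes[0].rate_constant
        window = int(0.01 / eps * cfg.sample_rate)
        phi = out.damage[:, 0]
        deltas = phi[window:] - phi[:-window]
        assert deltas.max() <= 0.01

    def test_blowup_raises_numerical_error(self):
        cfg = make_config(forcing_amplitude=1e130, duration=2.0,
                          forcing_frequency=9.5)
        with pytest.raises(NumericalError, match="t ="):
            simulate(cfg)

    def test_scale_separation_canonical_defaults(self, stationary_run):
        # autocorrelation time of x << 1/eps (ratio >= 1e3) for the canonical
        # (non-accelerated) defaults
        x = stationary_run.fast_state[:, 0]
        x = x - x.mean()
        acf = np.correlate(x, x, mode="full")[x.size - 1:]
        acf /= acf[0]
        below = np.nonzero(acf < np.exp(-1))[0]
        t_ac = below[0] / stationary_run.config.sample_rate
        for cfg in (default_single_mode_config(), default_two_mode_config()):
            for law in cfg.damage_modes:
                assert 1.0 / law.rate_constant / t_ac >= 1e3


class TestWellFrequency:
    def test_undamaged_matches_time_scaling(self):
        assert well_frequency(make_config()) == pytest.approx(9.5)

    def test_degraded_stiffness_sqrt_law(self):
        # [DERIVED] k = 0.81 -> frequency = 0.9 x undamaged
        cfg = make_config()
        assert well_frequency(cfg, damage_total=0.19) == \
            pytest.approx(0.9 * 9.5)

    def test_vanishing_stiffness_limit(self):
        cfg = make_config()
        assert well_frequency(cfg, damage_total=1.0 - 1e-12) < 1e-4

    def test_fully_damaged_raises(self):
        with pytest.raises(DomainError):
            well_frequency(make_config(), damage_total=1.0)


class TestIO:
    def test_csv_row_count_and_header(self, tmp_path):
        cfg = make_config(duration=3 / 200.0)
        out = simulate(cfg)
        assert len(out.measurement) == 3
        path = write_timeseries(out, tmp_path / "ts.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time,measurement"
        assert len(lines) == 4

    def test_csv_roundtrip_full_precision(self, tmp_path):
        cfg = default_stationary_config(seed=5, duration=2.0)
        out = simulate(cfg)
        path = write_timeseries(out, tmp_path / "ts.csv")
        _, values, rate = read_timeseries(path)
        np.testing.assert_array_equal(values, out.measurement)
        assert rate == pytest.approx(cfg.sample_rate)

    def test_hdf_damage_roundtrip_bitwise(self, tmp_path):
        cfg = default_two_mode_config(seed=5, accelerated=True)
        cfg = dataclasses.replace(cfg, duration=5.0)
        out = simulate(cfg)
        path = write_timeseries(out, tmp_path / "ts.h5", fmt="hdf")
        _, damage, labels = read_damage(path)
        order = [labels.index(lbl) for lbl in out.damage_labels]
        np.testing.assert_array_equal(damage[:, order], out.damage)

    def test_damage_written_separately_from_measurement(self, tmp_path):
        cfg = make_config(duration=0.1)
        out = simulate(cfg)
        path = write_timeseries(out, tmp_path / "ts.csv")
        assert "damage" not in path.read_text()
        assert (tmp_path / "ts.damage.csv").exists()

    def test_unwritable_path_raises(self, tmp_path):
        out = simulate(make_config(duration=0.1))
        with pytest.raises(OSError):
            write_timeseries(out, tmp_path / "no" / "such" / "dir" / "f.csv")
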