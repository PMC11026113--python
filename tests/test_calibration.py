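"""Figure of merit, grid scan, per-pulse energy fit, schedule application."""

import warnings

import numpy as np
import pytest

from dodsfx import calibration as cal
from dodsfx import synthetic as syn
from dodsfx.cell_stats import PulseCellStats, pulse_stats
from dodsfx.exceptions import DodSfxError


def _stats(ir, sigma=0.0, kappa=0.0):
    params = ("a", "b", "c", "alpha", "beta", "gamma")
    return PulseCellStats(
        pulse_id=0, ir=ir,
        mu={p: 79.0 for p in params},
        sigma={p: sigma for p in params},
        kappa={p: kappa for p in params},
        sample_mu={p: 79.0 for p in params},
        sample_sigma={p: sigma for p in params},
        fit_ok={p: True for p in params},
    )


class TestComputeFom:
    def test_zero_skew_equals_ir(self):
        assert cal.compute_fom(_stats(1000, sigma=0.5, kappa=0.0)) == 1000

    def test_zero_ir(self):
        assert cal.compute_fom(_stats(0, sigma=1.0, kappa=1.0)) == 0.0

    def test_direct_formula(self):
        # six parameters contribute sigma*|kappa| each; arrange sum = 0.2
        st = _stats(500, sigma=0.1, kappa=1.0 / 3.0)
        assert cal.compute_fom(st) == pytest.approx(500 * (1 - 0.2))

    def test_negative_skew_penalises_with_absolute_value(self):
        st = _stats(500, sigma=0.1, kappa=-1.0 / 3.0)
        assert cal.compute_fom(st) == pytest.approx(400.0)
        assert cal.compute_fom(st, signed_kappa=True) == pytest.approx(600.0)

    def test_clamped_at_zero(self):
        assert cal.compute_fom(_stats(10, sigma=2.0, kappa=1.0)) == 0.0

    def test_absent_stats_error(self):
        with pytest.raises(DodSfxError):
            cal.compute_fom(None)


class TestNormalizeAndLocate:
    def test_single_corner_mass(self):
        grid = cal.CalibrationGrid([235.0, 236.0], [9290.0, 9291.0],
                                   [[1.0, 0.0], [0.0, 0.0]])
        d, e = cal.normalize_and_locate(grid, interp_factor=1)
        assert (d, e) == (235.0, 9290.0)

    def test_uniform_matrix_geometric_centre(self):
        grid = cal.CalibrationGrid([230.0, 232.0, 234.0], [9280.0, 9300.0],
                                   np.ones((3, 2)))
        d, e = cal.normalize_and_locate(grid, interp_factor=4)
        assert d == pytest.approx(232.0)
        assert e == pytest.approx(9290.0)

    def test_symmetric_peak_at_peak_coordinate(self):
        ds = np.linspace(234, 238, 9)
        es = np.linspace(9280, 9300, 9)
        dd, ee = np.meshgrid(ds, es, indexing="ij")
        fom = np.exp(-((dd - 236.0) ** 2 / 0.5 + (ee - 9290.0) ** 2 / 12.0))
        grid = cal.CalibrationGrid(ds, es, fom)
        d, e = cal.normalize_and_locate(grid, interp_factor=8)
        assert d == pytest.approx(236.0, abs=1e-6)
        assert e == pytest.approx(9290.0, abs=1e-6)

    def test_normalised_matrix_max_is_one(self):
        grid = cal.CalibrationGrid([1.0, 2.0], [1.0, 2.0], [[3.0, 1.0], [0.5, 2.0]])
        matrix, _, _ = cal.interpolate_normalize(grid, interp_factor=5)
        assert matrix.max() == pytest.approx(1.0)
        assert matrix.min() >= 0.0

    def test_all_zero_grid_rejected(self):
        grid = cal.CalibrationGrid([1.0, 2.0], [1.0], np.zeros((2, 1)))
        with pytest.raises(DodSfxError):
            cal.normalize_and_locate(grid)


class TestFitPulseEnergy:
    REF = {"a": 79.45, "b": 79.47, "c": 38.32}

    def test_identity(self):
        e = cal.fit_pulse_energy(dict(self.REF), dict(self.REF), 9290.0)
        assert e == pytest.approx(9290.0, rel=1e-9)

    def test_uniform_shrink_gives_scaled_energy(self):
        mu = {k: v * 0.999 for k, v in self.REF.items()}
        e = cal.fit_pulse_energy(mu, dict(self.REF), 9290.0)
        assert e == pytest.approx(0.999 * 9290.0, rel=1e-7)

    def test_partial_scaling_least_squares_average(self):
        mu = {"a": self.REF["a"] * 1.001, "b": self.REF["b"] * 1.001, "c": self.REF["c"]}
        e = cal.fit_pulse_energy(mu, dict(self.REF), 9290.0, scan_step=0.5)
        expected = 9290.0 * (1 + 0.001 * 2 / 3)
        assert abs(e - expected) < 0.5  # within one scan step of the closed form

    def test_boundary_minimum_warns(self):
        mu = {k: v * 1.01 for k, v in self.REF.items()}  # ~93 eV shift, far out of range
        with pytest.warns(UserWarning, match="boundary"):
            cal.fit_pulse_energy(mu, dict(self.REF), 9290.0, scan_halfwidth=25.0)


def _chirped_frames(e_slope, noise, n_trains=50, seed=0):
    return syn.simulate_frames(
        syn.TrainConfig(),
        syn.ChirpModel(e_start=9295.5, e_slope=e_slope),
        syn.SampleModel(cell_noise_rel=noise),
        syn.HitModel(base_rate=1.0, within_droplet_decay=1.0, droplet_decay=1.0),
        n_trains=n_trains, assumed_energy=9290.0, assumed_distance=236.0, seed=seed,
    )


class TestSchedule:
    def test_zero_chirp_schedule_constant_and_identity(self):
        frames = _chirped_frames(0.0, 0.0)
        stats = pulse_stats(frames)
        sched = cal.build_schedule(stats, optimum_energy=9295.5)
        assert all(e == pytest.approx(9295.5, abs=1e-6) for e in sched.energies.values())
        corrected = cal.apply_schedule(frames, sched)
        # constant schedule rescales all cells by the same factor: drift still flat
        np.testing.assert_allclose(corrected["a"], corrected["a"].iloc[0], rtol=1e-12)

    def test_linear_chirp_slope_recovered_exactly(self):
        s = -15.5 / 15.0
        frames = _chirped_frames(s, 0.0)
        stats = pulse_stats(frames)
        sched = cal.build_schedule(stats, optimum_energy=9295.5)
        energies = [sched.energies[p] for p in range(16)]
        slopes = np.diff(energies)
        np.testing.assert_allclose(slopes, s, rtol=1e-6)
        # noise-free recovery of the generator energies to <1e-6 relative
        truth = 9295.5 + s * np.arange(16)
        np.testing.assert_allclose(energies, truth, rtol=1e-6)

    def test_drift_is_last_minus_first(self):
        frames = _chirped_frames(-1.0, 0.0)
        sched = cal.build_schedule(pulse_stats(frames), optimum_energy=9295.5)
        assert sched.drift == pytest.approx(sched.energies[15] - sched.energies[0])
        assert sched.drift == pytest.approx(-15.0, abs=1e-4)

    def test_reference_pulse_has_highest_ir(self):
        frames = _chirped_frames(-1.0, 0.001, n_trains=60)
        frames = frames[~((frames.pulse_id == 0) & (frames.train_id >= 20))]
        sched = cal.build_schedule(pulse_stats(frames), optimum_energy=9290.0)
        assert sched.reference_pulse != 0  # pulse 0 was decimated
        assert sched.energies[sched.reference_pulse] == pytest.approx(9290.0)

    def test_pulse_without_stats_flagged_with_reference_energy(self):
        frames = _chirped_frames(-1.0, 0.0)
        frames = frames[frames.pulse_id != 7]
        stats = pulse_stats(frames, pulses_per_train=16)
        sched = cal.build_schedule(stats, optimum_energy=9295.5)
        assert 7 in sched.flagged
        assert sched.energies[7] == pytest.approx(9295.5)

    def test_apply_schedule_flattens_cell_drift(self):
        frames = _chirped_frames(-15.5 / 15.0, 0.001, n_trains=100, seed=5)
        stats = pulse_stats(frames)
        sched = cal.build_schedule(stats, optimum_energy=9295.5)
        corrected = cal.apply_schedule(frames, sched)
        before = frames.groupby("pulse_id")["a"].mean()
        after = corrected.groupby("pulse_id")["a"].mean()
        assert after.max() - after.min() < before.max() - before.min()

    def test_monotone_chirp_gives_monotone_schedule(self):
        frames = _chirped_frames(-1.0, 0.0005, n_trains=200, seed=9)
        sched = cal.build_schedule(pulse_stats(frames), optimum_energy=9295.5)
        energies = [sched.energies[p] for p in range(16)]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_schedule_json_round_trip(self, tmp_path):
        frames = _chirped_frames(-1.0, 0.0)
        sched = cal.build_schedule(pulse_stats(frames), optimum_energy=9295.5)
        path = tmp_path / "sched.json"
        sched.to_json(path)
        back = cal.EnergySchedule.from_json(path)
        assert back.reference_pulse == sched.reference_pulse
        assert back.energies == pytest.approx(sched.energies)


class TestScanGrid:
    def _evaluator(self, noise=0.0, n_trains=30, seed=1, **kw):
        return syn.MiscalibrationEvaluator(
            syn.TrainConfig(),
            syn.ChirpModel(e_start=9290.0, e_slope=0.0),
            syn.SampleModel(cell_noise_rel=noise),
            syn.HitModel(base_rate=1.0, within_droplet_decay=1.0, droplet_decay=1.0),
            n_trains=n_trains, true_distance=236.0, seed=seed, **kw)

    def test_single_point_at_truth_fom_equals_frame_count(self):
        ev = self._evaluator(noise=0.0, n_trains=10)
        grid = cal.scan_grid(ev, [236.0], [9290.0])
        assert grid.fom[0, 0] == 160  # noise-free: sigma=0, kappa=0 -> FOM = IR

    def test_argmax_at_true_calibration(self):
        ev = self._evaluator(noise=0.001, n_trains=60, seed=3)
        ds = 236.0 + 0.5 * np.arange(-3, 4)
        es = 9290.0 + 2.5 * np.arange(-3, 4)
        grid = cal.scan_grid(ev, ds, es)
        assert grid.argmax() == (236.0, 9290.0)

    def test_low_count_combinations_absent_not_zero(self):
        ev = self._evaluator(noise=0.001, n_trains=30)
        grid = cal.scan_grid(ev, [236.0, 260.0], [9290.0])
        assert np.isfinite(grid.fom[0, 0])
        # 24 mm off: survival ~0 -> zero indexed frames is a true zero
        assert grid.fom[1, 0] == 0.0 or np.isnan(grid.fom[1, 0])


class TestModelResults:
    def test_fit_without_evaluator_uses_assumed_optimum(self):
        frames = _chirped_frames(-1.0, 0.0)
        res = cal.ChirpCalibration(frames).fit()
        assert res.optimal_energy == pytest.approx(9290.0)
        assert res.optimal_distance == pytest.approx(236.0)
        assert res.schedule.reference_pulse == 0
        assert "chirp calibration" in res.summary()

    def test_results_apply_and_corrected_stats(self):
        frames = _chirped_frames(-1.0, 0.001, n_trains=200, seed=2)
        res = cal.ChirpCalibration(frames).fit()
        cstats = res.corrected_stats()
        mus = [cstats[p].mu["a"] for p in range(16) if cstats[p] is not None]
        assert max(mus) - min(mus) < 0.02

    def test_energy_standard_errors_reference_zero(self):
        frames = _chirped_frames(-1.0, 0.001, n_trains=80, seed=2)
        res = cal.ChirpCalibration(frames).fit()
        se = res.energy_standard_errors()
        assert se[res.schedule.reference_pulse] == 0.0
        assert all(se[p] > 0 for p in range(1, 16))

    def test_summary_reports_grid_when_scanned(self):
        ev = TestScanGrid()._evaluator(noise=0.001, n_trains=60, seed=3)
        frames = ev(236.0, 9290.0)
        res = cal.ChirpCalibration(frames).fit(
            evaluator=ev,
            distances=236.0 + 0.5 * np.arange(-2, 3),
            energies=9290.0 + 2.5 * np.arange(-2, 3))
        assert "Grid scan" in res.summary()
        assert abs(res.optimal_distance - 236.0) < 0.5
        assert abs(res.optimal_energy - 9290.0) < 2.5
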