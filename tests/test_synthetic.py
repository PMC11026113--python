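"""Generator contracts: scaling model, hit statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

from dodsfx import synthetic as syn
from dodsfx.cells import CELL_LENGTHS, CELL_PARAMS, UnitCell
from dodsfx.exceptions import ConfigurationError
from dodsfx.merging import rsplit


def test_identity_case_reproduces_true_cell(train_cfg, quiet_sample, flat_chirp, always_hit):
    """With no chirp, no noise and correct assumptions, every observed cell is exact."""
    frames = syn.simulate_frames(train_cfg, flat_chirp, quiet_sample, always_hit,
                                 n_trains=5, assumed_energy=9290.0,
                                 assumed_distance=236.0, seed=0)
    true = quiet_sample.true_cell
    for p in CELL_PARAMS:
        assert np.allclose(frames[p], getattr(true, p), rtol=0, atol=1e-12)


def test_certain_hits_give_full_frame_count(train_cfg, quiet_sample, flat_chirp, always_hit):
    frames = syn.simulate_frames(train_cfg, flat_chirp, quiet_sample, always_hit,
                                 n_trains=10, assumed_energy=9290.0,
                                 assumed_distance=236.0, seed=0)
    assert len(frames) == 160
    assert frames.groupby("pulse_id").size().eq(10).all()


def test_linear_chirp_scales_last_pulse_cell(train_cfg, quiet_sample, always_hit):
    """e_slope = -1 eV/pulse: pulse 15 sees e_start-15, so a scales accordingly."""
    e_start = 9290.0
    chirp = syn.ChirpModel(e_start=e_start, e_slope=-1.0, e_jitter_sd=0.0)
    frames = syn.simulate_frames(train_cfg, chirp, quiet_sample, always_hit,
                                 n_trains=3, assumed_energy=e_start,
                                 assumed_distance=236.0, seed=0)
    last = frames[frames.pulse_id == 15]
    expected = 79.45 * (e_start - 15.0) / e_start
    assert np.allclose(last["a"], expected, rtol=1e-12)


def test_distance_mismatch_scales_cells(train_cfg, quiet_sample, flat_chirp, always_hit):
    frames = syn.simulate_frames(train_cfg, flat_chirp, quiet_sample, always_hit,
                                 n_trains=2, assumed_energy=9290.0,
                                 assumed_distance=237.0, seed=0, true_distance=236.0)
    assert np.allclose(frames["a"], 79.45 * 237.0 / 236.0, rtol=1e-12)
    assert np.allclose(frames["alpha"], 90.0)  # angles unaffected by scaling


def test_fixed_seed_is_bit_identical(train_cfg, always_hit):
    sample = syn.SampleModel(cell_noise_rel=0.002)
    chirp = syn.ChirpModel(e_jitter_sd=0.5)
    kw = dict(n_trains=20, assumed_energy=9290.0, assumed_distance=236.0, seed=42)
    a = syn.simulate_frames(train_cfg, chirp, sample, always_hit, **kw)
    b = syn.simulate_frames(train_cfg, chirp, sample, always_hit, **kw)
    pd.testing.assert_frame_equal(a, b)


def test_expected_hit_count_matches_hit_model(train_cfg, quiet_sample, flat_chirp):
    """Mean frames/train over many trains within 3 SE of the slot-probability sum."""
    hit = syn.HitModel()  # defaults: mean rate ~0.29
    n_trains = 10_000
    frames = syn.simulate_frames(train_cfg, flat_chirp, quiet_sample, hit,
                                 n_trains=n_trains, assumed_energy=9290.0,
                                 assumed_distance=236.0, seed=3)
    p = hit.slot_probabilities(train_cfg)
    expected = p.sum()
    se = np.sqrt((p * (1 - p)).sum() / n_trains)
    assert abs(len(frames) / n_trains - expected) < 3 * se


def test_per_pulse_mean_slope_matches_scaling_model(train_cfg, always_hit):
    """Regression of mean observed a on pulse index recovers a_true*e_slope/E_assumed."""
    chirp = syn.ChirpModel(e_start=9290.0, e_slope=-1.0, e_jitter_sd=0.0)
    sample = syn.SampleModel(cell_noise_rel=0.001)
    frames = syn.simulate_frames(train_cfg, chirp, sample, always_hit,
                                 n_trains=2000, assumed_energy=9290.0,
                                 assumed_distance=236.0, seed=11)
    means = frames.groupby("pulse_id")["a"].mean()
    slope, _ = np.polyfit(means.index.to_numpy(float), means.to_numpy(), 1)
    expected = 79.45 * chirp.e_slope / 9290.0
    # fit error: sem of each pulse mean propagated through the regression
    sem = 0.001 * 79.45 / np.sqrt(2000)
    tol = 4 * sem / np.sqrt(np.sum((np.arange(16) - 7.5) ** 2))
    assert abs(slope - expected) < tol


@pytest.mark.parametrize("kwargs, fieldname", [
    (dict(n_trains=0), "n_trains"),
    (dict(assumed_energy=-1.0), "assumed_energy"),
    (dict(assumed_distance=0.0), "assumed_distance"),
])
def test_invalid_config_names_offending_field(train_cfg, quiet_sample, flat_chirp,
                                              always_hit, kwargs, fieldname):
    kw = dict(n_trains=1, assumed_energy=9290.0, assumed_distance=236.0, seed=0)
    kw.update(kwargs)
    with pytest.raises(ConfigurationError, match=fieldname):
        syn.simulate_frames(train_cfg, flat_chirp, quiet_sample, always_hit, **kw)


def test_train_config_invariant_enforced():
    with pytest.raises(ConfigurationError, match="pulses_per_train"):
        syn.TrainConfig(pulses_per_train=15)


def test_chirp_exceeding_bandwidth_rejected(train_cfg, quiet_sample, always_hit):
    chirp = syn.ChirpModel(e_slope=-2.0, bandwidth=25.0)  # 30 eV span over 16 pulses
    with pytest.raises(ConfigurationError, match="e_slope"):
        syn.simulate_frames(train_cfg, chirp, quiet_sample, always_hit,
                            n_trains=1, assumed_energy=9290.0,
                            assumed_distance=236.0, seed=0)


def test_sample_model_rejects_heavy_contamination():
    with pytest.raises(ConfigurationError, match="contamination_fraction"):
        syn.SampleModel(contamination_fraction=0.6)


# -- pixel statistics -------------------------------------------------------


def test_pixel_stats_no_hot_pixels_empty_mask():
    stats, truth = syn.simulate_pixel_stats(32, 32, n_hot=0, hot_magnitude=10, seed=0)
    assert truth == set()
    assert all(stats[k].shape == (32, 32) for k in stats)


def test_planted_pixels_are_top_k_by_robust_zscore():
    """The 10 planted pixels dominate the robust z-score of the offset feature."""
    stats, truth = syn.simulate_pixel_stats(64, 64, n_hot=10, hot_magnitude=10, seed=5)
    mean_map = stats["mean"]
    med = np.median(mean_map)
    mad = np.median(np.abs(mean_map - med))
    z = np.abs(mean_map - med) / (1.4826 * mad)
    flat_top = np.argsort(z.ravel())[-10:]
    top = {tuple(np.unravel_index(i, z.shape)) for i in flat_top}
    assert {(int(r), int(c)) for r, c in top} == truth


def test_pixel_stats_deterministic():
    a, ta = syn.simulate_pixel_stats(16, 16, 5, 8.0, seed=9)
    b, tb = syn.simulate_pixel_stats(16, 16, 5, 8.0, seed=9)
    assert ta == tb
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_too_many_hot_pixels_rejected():
    with pytest.raises(ConfigurationError, match="n_hot"):
        syn.simulate_pixel_stats(4, 4, n_hot=16, hot_magnitude=5, seed=0)


# -- half intensities -------------------------------------------------------


def test_zero_error_halves_identical():
    i1, i2, _ = syn.simulate_half_intensities(100, [0.0] * 16, error_scale=0.01,
                                              noise_rel=0.0, seed=0)
    np.testing.assert_allclose(i1, i2)
    assert rsplit(i1, i2) == 0.0


def test_energy_bias_inflates_rsplit():
    """Monte-Carlo: energy-proportional bias worsens half-dataset agreement."""
    errors = list(np.linspace(0, 15.5, 16))
    r = {}
    for scale in (0.0, 0.01):
        i1, i2, _ = syn.simulate_half_intensities(2000, errors, error_scale=scale,
                                                  noise_rel=0.02, seed=21)
        r[scale] = rsplit(i1, i2)
    assert r[0.0] < r[0.01]


def test_half_intensities_validation():
    with pytest.raises(ConfigurationError, match="noise_rel"):
        syn.simulate_half_intensities(10, [1.0], error_scale=0.0, noise_rel=-0.1, seed=0)
    with pytest.raises(ConfigurationError, match="n_reflections"):
        syn.simulate_half_intensities(1, [1.0], error_scale=0.0, noise_rel=0.0, seed=0)


# -- miscalibration evaluator ----------------------------------------------


def test_evaluator_peaks_at_true_calibration(train_cfg, always_hit, flat_chirp):
    """Indexed count is maximal at the true (D, E) and falls off away from it."""
    sample = syn.SampleModel(cell_noise_rel=0.002)
    ev = syn.MiscalibrationEvaluator(train_cfg, flat_chirp, sample, always_hit,
                                     n_trains=100, true_distance=236.0, seed=2)
    n_true = len(ev(236.0, 9290.0))
    assert n_true == 1600  # survival probability 1 at zero mismatch
    assert len(ev(236.0, 9295.0)) < n_true
    assert len(ev(238.0, 9290.0)) < n_true


def test_evaluator_miscalibration_induces_skew(train_cfg, always_hit, flat_chirp):
    """The contaminant subpopulation skews cell lengths away from the optimum."""
    from scipy.stats import skew

    sample = syn.SampleModel(cell_noise_rel=0.001, contamination_fraction=0.2,
                             contamination_offset=0.005)
    ev = syn.MiscalibrationEvaluator(train_cfg, flat_chirp, sample, always_hit,
                                     n_trains=400, true_distance=236.0, seed=8,
                                     index_width_ev=10.0, index_width_mm=2.0)
    at_truth = skew(ev(236.0, 9290.0)["a"])
    off = skew(ev(236.0, 9305.0)["a"])
    assert abs(off) > abs(at_truth) + 0.2
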