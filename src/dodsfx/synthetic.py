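"""Synthetic data emulating a kHz droplet-on-demand SFX experiment.

The generator reproduces the statistical structure of the experiment this
package analyses, without simulating diffraction images:

* a macro-pulse (train) of 16 X-ray pulses at 47 kHz, trains at 10 Hz,
  probing 4 droplets with 4 consecutive hits each;
* a linear intra-train photon-energy chirp of order 15 eV, inside a 25 eV
  SASE bandwidth, with optional shot-to-shot jitter;
* tetragonal lysozyme cells (a=79.45, b=79.47, c=38.32 Å, 90° angles) with
  multiplicative per-frame noise of ~0.1–0.3 % on the lengths;
* a hit probability that decays with hit number within a droplet and weakly
  from droplet to droplet, averaging ≈29 % over the 16-slot scheme;
* per-pixel detector statistic maps with planted hot pixels; and
* half-dataset reflection intensities whose disagreement grows with the
  photon-energy error of the pulses they were collected on.

Apparent-cell model: with spot positions (Bragg angles) fixed, the cell the
indexer reports scales as (E_true / E_assumed) x (D_assumed / D_true) on the
lengths; angles only pick up additive noise.  All randomness flows from a
single ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import FRAME_COLUMNS, UnitCell
from .exceptions import ConfigurationError

__all__ = [
    "TrainConfig",
    "ChirpModel",
    "SampleModel",
    "HitModel",
    "simulate_frames",
    "simulate_pixel_stats",
    "simulate_half_intensities",
    "MiscalibrationEvaluator",
    "PIXEL_STAT_DISTRIBUTIONS",
]


@dataclass(frozen=True)
class TrainConfig:
    """Macro-pulse structure: droplets per train and hits per droplet.

    The product droplets_per_train x hits_per_droplet must equal
    pulses_per_train: every pulse lands on a droplet, none falls between.
    """

    pulses_per_train: int = 16
    intra_train_rate_khz: float = 47.0
    train_rate_hz: float = 10.0
    droplets_per_train: int = 4
    hits_per_droplet: int = 4

    def __post_init__(self):
        for name in ("pulses_per_train", "droplets_per_train", "hits_per_droplet"):
            if getattr(self, name) < 1:
                raise ConfigurationError(name, "count must be >= 1")
        if self.intra_train_rate_khz <= 0:
            raise ConfigurationError("intra_train_rate_khz", "must be > 0")
        if self.train_rate_hz <= 0:
            raise ConfigurationError("train_rate_hz", "must be > 0")
        if self.pulses_per_train != self.droplets_per_train * self.hits_per_droplet:
            raise ConfigurationError(
                "pulses_per_train",
                "must equal droplets_per_train * hits_per_droplet "
                f"({self.droplets_per_train} * {self.hits_per_droplet})",
            )


@dataclass(frozen=True)
class ChirpModel:
    """Linear intra-train photon-energy drift with shot-to-shot jitter.

    e_start is the true energy of pulse 0 (eV); e_slope the drift per pulse
    (eV, may be 0); e_jitter_sd the shot-to-shot SASE jitter; bandwidth the
    SASE envelope the total drift must stay inside.

    The default slope -15.5/15 eV/pulse makes the last-minus-first drift over
    a 16-pulse train exactly -15.5 eV.
    """

    e_start: float = 9295.5
    e_slope: float = -15.5 / 15.0
    e_jitter_sd: float = 0.0
    bandwidth: float = 25.0

    def __post_init__(self):
        if self.e_start <= 0:
            raise ConfigurationError("e_start", "photon energy must be > 0")
        if self.e_jitter_sd < 0:
            raise ConfigurationError("e_jitter_sd", "must be >= 0")
        if self.bandwidth <= 0:
            raise ConfigurationError("bandwidth", "must be > 0")

    def validate_span(self, pulses_per_train: int) -> None:
        span = abs(self.e_slope * (pulses_per_train - 1))
        if span > self.bandwidth:
            raise ConfigurationError(
                "e_slope",
                f"total drift {span:.1f} eV exceeds the SASE bandwidth {self.bandwidth:.1f} eV",
            )

    def true_energy(self, pulse_id) -> np.ndarray:
        """Mean true energy of each pulse (eV), before jitter."""
        return self.e_start + self.e_slope * np.asarray(pulse_id, dtype=float)


@dataclass(frozen=True)
class SampleModel:
    """Crystal population: true cell, per-frame cell noise, contaminant subpopulation.

    cell_noise_rel is the relative standard deviation of the multiplicative
    per-frame noise on the cell lengths (angles get additive noise of
    cell_noise_rel x 90 deg).  The contaminant fraction/offset describe a
    subpopulation whose cells shift ∝ calibration mismatch, used by
    :class:`MiscalibrationEvaluator` to make σ and κ grow away from the true
    (distance, energy) — plain :func:`simulate_frames` never applies it.
    """

    true_cell: UnitCell = field(default_factory=lambda: UnitCell(79.45, 79.47, 38.32))
    cell_noise_rel: float = 0.002
    contamination_fraction: float = 0.15
    contamination_offset: float = 0.003

    def __post_init__(self):
        if self.cell_noise_rel < 0:
            raise ConfigurationError("cell_noise_rel", "must be >= 0")
        if not 0 <= self.contamination_fraction < 0.5:
            raise ConfigurationError("contamination_fraction", "must lie in [0, 0.5)")


@dataclass(frozen=True)
class HitModel:
    """Per-slot hit probability over the droplet/hit scheme.

    p(droplet d, hit h) = base_rate * within_droplet_decay**h * droplet_decay**d
    (both indices 0-based).  The decay within a droplet reflects growing
    instability after each explosion; the weak droplet-to-droplet decay the
    incompletely damped acoustic wave.  Defaults give a 16-slot mean of
    0.291, matching the ≈29 % average hit rate of the experiment.
    """

    base_rate: float = 0.40
    within_droplet_decay: float = 0.82
    droplet_decay: float = 0.97

    def __post_init__(self):
        for name in ("base_rate", "within_droplet_decay", "droplet_decay"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(name, "probability/decay must lie in [0, 1]")

    def slot_probabilities(self, cfg: TrainConfig) -> np.ndarray:
        """Hit probability for each pulse slot 0..pulses_per_train-1."""
        k = np.arange(cfg.pulses_per_train)
        droplet = k // cfg.hits_per_droplet
        hit = k % cfg.hits_per_droplet
        return (self.base_rate
                * self.within_droplet_decay ** hit
                * self.droplet_decay ** droplet)


def _cell_arrays(sample: SampleModel, scale: np.ndarray, rng: np.random.Generator):
    """Observed cell parameter columns for frames with given length scale factors."""
    n = scale.shape[0]
    true = sample.true_cell
    noise = rng.normal(0.0, sample.cell_noise_rel, size=(n, 3)) if sample.cell_noise_rel > 0 \
        else np.zeros((n, 3))
    angle_noise = (rng.normal(0.0, sample.cell_noise_rel * 90.0, size=(n, 3))
                   if sample.cell_noise_rel > 0 else np.zeros((n, 3)))
    lengths = np.array([true.a, true.b, true.c]) * scale[:, None] * (1.0 + noise)
    angles = np.array([true.alpha, true.beta, true.gamma]) + angle_noise
    return lengths, angles


def simulate_frames(
    train_cfg: TrainConfig,
    chirp: ChirpModel,
    sample: SampleModel,
    hit: HitModel,
    n_trains: int,
    assumed_energy: float,
    assumed_distance: float,
    seed: int,
    true_distance: float | None = None,
) -> pd.DataFrame:
    """Simulate indexed frames for ``n_trains`` macro-pulses.

    Each pulse slot hits (and indexes) with its HitModel probability; each
    indexed frame's observed cell is the true cell scaled by
    (E_true/assumed_energy) x (assumed_distance/true_distance) times
    multiplicative noise.  Returns the canonical frame DataFrame
    (:data:`dodsfx.cells.FRAME_COLUMNS`), deterministic for a fixed seed.
    """
    if n_trains < 1:
        raise ConfigurationError("n_trains", "must be >= 1")
    if assumed_energy <= 0:
        raise ConfigurationError("assumed_energy", "must be > 0")
    if assumed_distance <= 0:
        raise ConfigurationError("assumed_distance", "must be > 0")
    chirp.validate_span(train_cfg.pulses_per_train)
    if true_distance is None:
        true_distance = assumed_distance

    rng = np.random.default_rng(seed)
    p_slot = hit.slot_probabilities(train_cfg)

    hits = rng.random((n_trains, train_cfg.pulses_per_train)) < p_slot
    train_idx, pulse_idx = np.nonzero(hits)
    n = train_idx.size

    e_true = chirp.true_energy(pulse_idx)
    if chirp.e_jitter_sd > 0:
        e_true = e_true + rng.normal(0.0, chirp.e_jitter_sd, size=n)

    scale = (e_true / assumed_energy) * (assumed_distance / true_distance)
    lengths, angles = _cell_arrays(sample, scale, rng)

    return pd.DataFrame({
        "train_id": train_idx,
        "pulse_id": pulse_idx,
        "indexed": np.ones(n, dtype=bool),
        "a": lengths[:, 0], "b": lengths[:, 1], "c": lengths[:, 2],
        "alpha": angles[:, 0], "beta": angles[:, 1], "gamma": angles[:, 2],
        "photon_energy": np.full(n, float(assumed_energy)),
        "detector_distance": np.full(n, float(assumed_distance)),
    }, columns=list(FRAME_COLUMNS))


#: Background distributions (mean, sd) for the four per-pixel statistics.
PIXEL_STAT_DISTRIBUTIONS = {
    "mean": (100.0, 5.0),
    "std": (30.0, 3.0),
    "skewness": (0.0, 0.3),
    "kurtosis": (0.0, 0.5),
}

#: Features in which planted hot pixels are offset.
HOT_OFFSET_FEATURES = ("mean", "std")


def simulate_pixel_stats(
    n_rows: int,
    n_cols: int,
    n_hot: int,
    hot_magnitude: float,
    seed: int,
):
    """Per-pixel moment maps with planted hot pixels.

    Background pixels draw each statistic (mean, std, skewness, kurtosis)
    independently from the normal distributions in
    :data:`PIXEL_STAT_DISTRIBUTIONS`.  ``n_hot`` distinct pixels are offset
    by ``hot_magnitude`` background standard deviations in the mean and std
    features (a hot pixel fires high and erratically).  Returns
    ``(stats, true_mask)`` where ``stats`` maps statistic name -> (n_rows,
    n_cols) array and ``true_mask`` is the set of planted (row, col) pixels.
    """
    n_pixels = n_rows * n_cols
    if n_hot >= n_pixels:
        raise ConfigurationError("n_hot", "must be smaller than the pixel count")
    if n_hot < 0:
        raise ConfigurationError("n_hot", "must be >= 0")

    rng = np.random.default_rng(seed)
    stats = {
        name: rng.normal(mu, sd, size=(n_rows, n_cols))
        for name, (mu, sd) in PIXEL_STAT_DISTRIBUTIONS.items()
    }
    flat = rng.choice(n_pixels, size=n_hot, replace=False) if n_hot else np.array([], dtype=int)
    rows, cols = np.unravel_index(flat, (n_rows, n_cols))
    for name in HOT_OFFSET_FEATURES:
        _, sd = PIXEL_STAT_DISTRIBUTIONS[name]
        stats[name][rows, cols] += hot_magnitude * sd
    true_mask = {(int(r), int(c)) for r, c in zip(rows, cols)}
    return stats, true_mask


def simulate_half_intensities(
    n_reflections: int,
    energy_error_per_pulse,
    error_scale: float,
    noise_rel: float,
    seed: int,
    obs_per_half: int = 4,
    d_range: tuple[float, float] = (1.38, 10.0),
):
    """Half-dataset reflection intensities with energy-proportional bias.

    True intensities are exponential; each half-dataset accumulates
    ``obs_per_half`` observations per reflection, each taken on a random
    pulse whose photon-energy error inflates the observation's relative
    error: sd_eff = sqrt(noise_rel² + (error_scale·|ΔE|)²).  With all energy
    errors and noise zero the halves are identical.  Returns
    ``(I1, I2, inv_d)`` with inv_d the 1/d resolution label (Å⁻¹) of each
    reflection.
    """
    if n_reflections < 2:
        raise ConfigurationError("n_reflections", "must be >= 2")
    if noise_rel < 0:
        raise ConfigurationError("noise_rel", "must be >= 0")
    energy_error = np.abs(np.asarray(energy_error_per_pulse, dtype=float))
    if energy_error.size == 0:
        raise ConfigurationError("energy_error_per_pulse", "must be nonempty")

    rng = np.random.default_rng(seed)
    i_true = rng.exponential(1.0, size=n_reflections)
    inv_d = rng.uniform(1.0 / d_range[1], 1.0 / d_range[0], size=n_reflections)

    halves = []
    for _ in range(2):
        pulses = rng.integers(0, energy_error.size, size=(n_reflections, obs_per_half))
        z = rng.standard_normal((n_reflections, obs_per_half))
        sd_eff = np.sqrt(noise_rel ** 2 + (error_scale * energy_error[pulses]) ** 2)
        obs = i_true[:, None] * (1.0 + sd_eff * z)
        halves.append(obs.mean(axis=1))
    return halves[0], halves[1], inv_d


class MiscalibrationEvaluator:
    """Re-evaluate synthetic indexing under arbitrary assumed (distance, energy).

    Emulates what re-running the indexer at a different assumed detector
    distance D and photon energy E does to the per-frame outcome:

    * the apparent cell rescales by (E_true/E) x (D/D_true);
    * the probability that a frame still indexes falls off as
      exp(-m²/2) in the normalised mismatch
      m² = ((E-E_true)/index_width_ev)² + ((D-D_true)/index_width_mm)²,
      so the indexed-pattern count IR peaks at the true calibration;
    * a contaminant fraction of frames picks up a positive multiplicative
      cell shift of contamination_offset x m, so the cell distribution
      broadens and skews away from the optimum.

    All per-frame random draws are made once at construction; calling the
    evaluator at different (D, E) is deterministic and smooth, which is what
    a figure-of-merit grid scan needs.
    """

    def __init__(
        self,
        train_cfg: TrainConfig,
        chirp: ChirpModel,
        sample: SampleModel,
        hit: HitModel,
        n_trains: int,
        true_distance: float,
        seed: int,
        index_width_ev: float = 5.0,
        index_width_mm: float = 1.0,
    ):
        if n_trains < 1:
            raise ConfigurationError("n_trains", "must be >= 1")
        if true_distance <= 0:
            raise ConfigurationError("true_distance", "must be > 0")
        chirp.validate_span(train_cfg.pulses_per_train)

        self.train_cfg = train_cfg
        self.sample = sample
        self.true_distance = float(true_distance)
        self.index_width_ev = float(index_width_ev)
        self.index_width_mm = float(index_width_mm)

        rng = np.random.default_rng(seed)
        p_slot = hit.slot_probabilities(train_cfg)
        hits = rng.random((n_trains, train_cfg.pulses_per_train)) < p_slot
        self._train_idx, self._pulse_idx = np.nonzero(hits)
        n = self._train_idx.size
        self._e_true = chirp.true_energy(self._pulse_idx)
        if chirp.e_jitter_sd > 0:
            self._e_true = self._e_true + rng.normal(0.0, chirp.e_jitter_sd, size=n)
        # frozen per-frame draws: indexing survival, cell noise, contamination
        self._survival_u = rng.random(n)
        self._noise = (rng.normal(0.0, sample.cell_noise_rel, size=(n, 3))
                       if sample.cell_noise_rel > 0 else np.zeros((n, 3)))
        self._angle_noise = (rng.normal(0.0, sample.cell_noise_rel * 90.0, size=(n, 3))
                             if sample.cell_noise_rel > 0 else np.zeros((n, 3)))
        self._contaminant = rng.random(n) < sample.contamination_fraction

    def __call__(self, distance: float, energy: float) -> pd.DataFrame:
        """Frame table as if indexing had assumed (distance mm, energy eV)."""
        if distance <= 0:
            raise ConfigurationError("distance", "must be > 0")
        if energy <= 0:
            raise ConfigurationError("energy", "must be > 0")
        m2 = (((energy - self._e_true) / self.index_width_ev) ** 2
              + ((distance - self.true_distance) / self.index_width_mm) ** 2)
        keep = self._survival_u < np.exp(-0.5 * m2)

        e_true = self._e_true[keep]
        m = np.sqrt(m2[keep])
        scale = (e_true / energy) * (distance / self.true_distance)
        shift = 1.0 + self.sample.contamination_offset * m * self._contaminant[keep]
        true = self.sample.true_cell
        lengths = (np.array([true.a, true.b, true.c])
                   * (scale * shift)[:, None] * (1.0 + self._noise[keep]))
        angles = np.array([true.alpha, true.beta, true.gamma]) + self._angle_noise[keep]

        n = int(keep.sum())
        return pd.DataFrame({
            "train_id": self._train_idx[keep],
            "pulse_id": self._pulse_idx[keep],
            "indexed": np.ones(n, dtype=bool),
            "a": lengths[:, 0], "b": lengths[:, 1], "c": lengths[:, 2],
            "alpha": angles[:, 0], "beta": angles[:, 1], "gamma": angles[:, 2],
            "photon_energy": np.full(n, float(energy)),
            "detector_distance": np.full(n, float(distance)),
        }, columns=list(FRAME_COLUMNS))
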