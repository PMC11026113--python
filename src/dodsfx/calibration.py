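"""Joint photon-energy / detector-distance calibration and chirp correction.

The central problem: at a SASE XFEL the photon energy drifts systematically
across the pulses of a train (the *chirp*), and neither energy nor camera
length is known exactly per pulse.  Because indexed unit cells scale with
the assumed wavelength and camera length, a wrong assumption shows up as a
shifted, broadened and skewed cell distribution and a lower indexing rate.

Calibration proceeds in two stages:

1. **Grid scan.** An indexing figure of merit

       FOM = IR × (1 − Σ_i σ_i·|κ_i|),   i ∈ {a, b, c, α, β, γ}

   (IR = indexed-pattern count, σ/κ = Gaussian width and skewness of each
   cell-parameter distribution; clamped at 0) is evaluated over a grid of
   assumed (detector distance, photon energy).  The grid is bilinearly
   interpolated, normalised to max 1, and the FOM-weighted centre of mass
   gives the optimal (D, E) for the reference pulse.

2. **Per-pulse energy fit.** Holding D fixed, each pulse's photon energy is
   scanned so that its mean cell lengths match the reference pulse's; the
   resulting per-pulse energies form an :class:`EnergySchedule` whose
   last-minus-first difference is the chirp drift.  Applying the schedule
   rescales every frame's cell to what re-indexing at the corrected energy
   would give, flattening the intra-train cell drift.

The statsmodels-style entry point is :class:`ChirpCalibration` (model) /
:class:`ChirpCalibrationResults`; the stage functions are exposed for
direct use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator

from .cells import CELL_LENGTHS
from .cell_stats import (
    MIN_FRAMES_PER_PULSE,
    PulseCellStats,
    pooled_stats,
    pulse_stats,
    stats_table,
)
from .exceptions import DodSfxError, InsufficientDataError

__all__ = [
    "CalibrationGrid",
    "EnergySchedule",
    "compute_fom",
    "scan_grid",
    "normalize_and_locate",
    "interpolate_normalize",
    "fit_pulse_energy",
    "build_schedule",
    "apply_schedule",
    "ChirpCalibration",
    "ChirpCalibrationResults",
]


def compute_fom(stats: PulseCellStats, signed_kappa: bool = False,
                normalize_sigma: bool = False) -> float:
    """Indexing figure of merit: IR × (1 − Σ σ_i·|κ_i|), clamped at 0.

    ``signed_kappa`` uses κ instead of |κ| (off by default: a negative skew
    must penalise, not inflate, the FOM).  ``normalize_sigma`` divides each
    σ by the corresponding μ before the sum (off by default: σ enters in
    native units, Å or degrees).
    """
    if stats is None:
        raise DodSfxError("cannot compute FOM from absent pulse statistics")
    if stats.ir == 0:
        return 0.0
    penalty = 0.0
    for p in stats.mu:
        sigma = stats.sigma[p]
        if normalize_sigma and stats.mu[p] != 0:
            sigma = sigma / abs(stats.mu[p])
        k = stats.kappa[p] if signed_kappa else abs(stats.kappa[p])
        penalty += sigma * k
    return max(stats.ir * (1.0 - penalty), 0.0)


@dataclass
class CalibrationGrid:
    """FOM values over a (detector distance × photon energy) grid.

    ``fom[i, j]`` corresponds to ``distances[i]``, ``energies[j]``; failed
    or unevaluated combinations are NaN (absent), never 0.
    """

    distances: np.ndarray
    energies: np.ndarray
    fom: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.fom = np.asarray(self.fom, dtype=float)
        if self.fom.shape != (self.distances.size, self.energies.size):
            raise DodSfxError(
                f"FOM shape {self.fom.shape} does not match axes "
                f"({self.distances.size}, {self.energies.size})"
            )

    @property
    def evaluated_count(self) -> int:
        return int(np.isfinite(self.fom).sum())

    def argmax(self) -> tuple[float, float]:
        """(distance, energy) of the largest raw FOM (no interpolation)."""
        i, j = np.unravel_index(np.nanargmax(self.fom), self.fom.shape)
        return float(self.distances[i]), float(self.energies[j])


def scan_grid(evaluator, distances, energies,
              min_frames: int = MIN_FRAMES_PER_PULSE, **fom_kwargs) -> CalibrationGrid:
    """Evaluate the FOM for every (distance, energy) combination.

    ``evaluator(distance, energy)`` must return a frame DataFrame as if
    indexing had been run under that assumption — for synthetic data the
    :class:`~dodsfx.synthetic.MiscalibrationEvaluator`, for real data a
    callable that re-reads re-indexed streams.  Combinations whose indexed
    count falls below ``min_frames`` are recorded as absent (NaN).
    """
    distances = np.asarray(distances, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if distances.size == 0 or energies.size == 0:
        raise DodSfxError("scan axes must be nonempty")
    fom = np.full((distances.size, energies.size), np.nan)
    for i, d in enumerate(distances):
        for j, e in enumerate(energies):
            frames = evaluator(d, e)
            n = int(frames["indexed"].sum()) if len(frames) else 0
            if n == 0:
                fom[i, j] = 0.0
                continue
            if n < min_frames:
                continue  # absent, not zero
            fom[i, j] = compute_fom(pooled_stats(frames, min_frames=min_frames),
                                    **fom_kwargs)
    if not np.isfinite(fom).any():
        raise DodSfxError("every (distance, energy) combination failed to evaluate")
    return CalibrationGrid(distances, energies, fom)


def interpolate_normalize(grid: CalibrationGrid, interp_factor: int = 8):
    """Bilinear refinement of the FOM grid, normalised to max 1.

    Returns ``(matrix, d_axis, e_axis)``.  Absent (NaN) cells contribute
    zero mass.  Each coarse step is subdivided into ``interp_factor``
    intervals; ``interp_factor=1`` reproduces the raw grid.
    """
    if interp_factor < 1:
        raise DodSfxError("interp_factor must be >= 1")
    filled = np.nan_to_num(grid.fom, nan=0.0)
    d_axis = _refine_axis(grid.distances, interp_factor)
    e_axis = _refine_axis(grid.energies, interp_factor)
    if grid.distances.size == 1 and grid.energies.size == 1:
        matrix = filled.copy()
    else:
        interp = RegularGridInterpolator(
            (_safe_axis(grid.distances), _safe_axis(grid.energies)),
            filled, method="linear", bounds_error=False, fill_value=0.0,
        )
        dd, ee = np.meshgrid(d_axis, e_axis, indexing="ij")
        matrix = interp(np.stack([dd.ravel(), ee.ravel()], axis=1)).reshape(dd.shape)
    peak = matrix.max()
    if peak <= 0:
        raise DodSfxError("all-zero FOM grid: cannot normalise")
    return matrix / peak, d_axis, e_axis


def _refine_axis(axis: np.ndarray, factor: int) -> np.ndarray:
    if axis.size == 1:
        return axis.copy()
    return np.linspace(axis[0], axis[-1], (axis.size - 1) * factor + 1)


def _safe_axis(axis: np.ndarray) -> np.ndarray:
    # RegularGridInterpolator needs strictly increasing axes of length >= 1;
    # a singleton axis is padded conceptually by nearest behaviour.
    if axis.size == 1:
        return axis
    if not np.all(np.diff(axis) > 0):
        raise DodSfxError("scan axes must be strictly increasing")
    return axis


def normalize_and_locate(grid: CalibrationGrid, interp_factor: int = 8,
                         threshold: float | None = None) -> tuple[float, float]:
    """Optimal (distance, energy) as the centre of mass of the normalised FOM.

    The interpolated, max-normalised matrix is used in full (no threshold
    by default); ``threshold`` zeroes values below it before the weighted
    mean, if given.
    """
    matrix, d_axis, e_axis = interpolate_normalize(grid, interp_factor)
    if threshold is not None:
        matrix = np.where(matrix >= threshold, matrix, 0.0)
    total = matrix.sum()
    if total <= 0:
        raise DodSfxError("FOM matrix has no mass above the threshold")
    d_opt = float((matrix.sum(axis=1) * d_axis).sum() / total)
    e_opt = float((matrix.sum(axis=0) * e_axis).sum() / total)
    return d_opt, e_opt


def fit_pulse_energy(pulse_mu: dict, reference_mu: dict, e0: float,
                     scan_halfwidth: float = 25.0, scan_step: float = 0.5) -> float:
    """Photon energy that maps a pulse's mean cell onto the reference pulse's.

    Scans E over e0 ± scan_halfwidth (step ``scan_step``) minimising the
    mean squared relative deviation of the rescaled lengths {a, b, c} from
    the reference, then refines the discrete minimum by bounded search.
    Agrees with the closed form E = e0 · mean(pulse_mu/reference_mu) to
    within one scan step.  A minimum on the scan boundary triggers a
    warning (scan range too narrow).
    """
    ratios = np.array([pulse_mu[p] / reference_mu[p] for p in CELL_LENGTHS])

    def objective(e):
        return float(np.mean((ratios * (e0 / e) - 1.0) ** 2))

    n_steps = int(round(scan_halfwidth / scan_step))
    grid = e0 + scan_step * np.arange(-n_steps, n_steps + 1)
    grid = grid[grid > 0]
    values = [objective(e) for e in grid]
    k = int(np.argmin(values))
    if k in (0, len(grid) - 1):
        warnings.warn(
            f"pulse-energy scan minimum at boundary ({grid[k]:.1f} eV): "
            "scan range may be too narrow", stacklevel=2)
        return float(grid[k])
    # the objective is exactly quadratic in g = e0/E: its minimiser has the
    # closed form E = e0·Σr²/Σr; take it when it refines the bracketed scan
    # minimum, fall back to bounded search otherwise
    e_exact = e0 * float((ratios ** 2).sum() / ratios.sum())
    if grid[k - 1] <= e_exact <= grid[k + 1]:
        return e_exact
    res = optimize.minimize_scalar(
        objective, bounds=(grid[k - 1], grid[k + 1]), method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


@dataclass
class EnergySchedule:
    """Per-pulse corrected photon energies relative to a reference pulse.

    ``energies`` maps pulse_id → eV; pulses without usable statistics carry
    the reference energy and are listed in ``flagged``.  ``drift`` is the
    last-pulse energy minus the first-pulse energy.
    """

    reference_pulse: int
    energies: dict
    flagged: frozenset = field(default_factory=frozenset)

    @property
    def drift(self) -> float:
        pids = sorted(self.energies)
        return self.energies[pids[-1]] - self.energies[pids[0]]

    def to_json(self, path=None) -> str:
        payload = {
            "reference_pulse": self.reference_pulse,
            "energies_ev": {str(k): v for k, v in sorted(self.energies.items())},
            "drift_ev": self.drift,
            "flagged_pulses": sorted(self.flagged),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "EnergySchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            reference_pulse=int(payload["reference_pulse"]),
            energies={int(k): float(v) for k, v in payload["energies_ev"].items()},
            flagged=frozenset(payload.get("flagged_pulses", [])),
        )


def build_schedule(stats: dict, optimum_energy: float,
                   scan_halfwidth: float = 25.0, scan_step: float = 0.5,
                   reference_pulse: int | None = None) -> EnergySchedule:
    """Fit a per-pulse photon-energy schedule against the reference pulse.

    The reference is the pulse with the highest indexed-pattern count
    (ties go to the earliest pulse; in the experiment this was the first
    pulse of the train) and is pinned to ``optimum_energy``.  Pulses with
    absent statistics carry the reference energy and are flagged.
    """
    present = {pid: st for pid, st in stats.items() if st is not None}
    if not present:
        raise DodSfxError("no pulse has usable statistics")
    if reference_pulse is None:
        reference_pulse = min(present, key=lambda pid: (-present[pid].ir, pid))
    elif reference_pulse not in present:
        raise DodSfxError(f"reference pulse {reference_pulse} has no statistics")
    ref_mu = present[reference_pulse].mu

    energies, flagged = {}, set()
    for pid in sorted(stats):
        st = stats[pid]
        if st is None:
            energies[pid] = float(optimum_energy)
            flagged.add(pid)
        elif pid == reference_pulse:
            energies[pid] = float(optimum_energy)
        else:
            energies[pid] = fit_pulse_energy(st.mu, ref_mu, optimum_energy,
                                             scan_halfwidth, scan_step)
    return EnergySchedule(reference_pulse=reference_pulse, energies=energies,
                          flagged=frozenset(flagged))


def apply_schedule(frames: pd.DataFrame, schedule: EnergySchedule) -> pd.DataFrame:
    """Rescale frames to the corrected per-pulse photon energies.

    Re-indexing a frame at energy E' instead of the assumed E multiplies
    its apparent cell lengths by E/E' (fixed Bragg angles), so the
    corrected cell is observed_cell × assumed_energy / schedule_energy and
    the frame's photon energy is overwritten with the schedule value.
    Pulses absent from the schedule carry the reference-pulse energy.
    """
    corrected = frames.copy()
    ref_energy = schedule.energies[schedule.reference_pulse]
    sched = corrected["pulse_id"].map(schedule.energies).fillna(ref_energy)
    factor = corrected["photon_energy"] / sched
    for p in CELL_LENGTHS:
        corrected[p] = corrected[p] * factor
    corrected["photon_energy"] = sched.to_numpy()
    return corrected


# ---------------------------------------------------------------------------
# Model / Results


class ChirpCalibration:
    """Intra-train photon-energy chirp calibration model over indexed frames.

    Parameters
    ----------
    frames : DataFrame
        Canonical frame table (see :data:`dodsfx.cells.FRAME_COLUMNS`).
    min_frames_per_pulse : int
        Pulses with fewer indexed frames are excluded from the fit.
    pulses_per_train : int, optional
        Makes empty pulse positions explicit in the results.
    signed_kappa, normalize_sigma : bool
        FOM variants (see :func:`compute_fom`).

    ``fit()`` runs the grid scan (when an evaluator and axes are supplied),
    locates the optimum, and fits the per-pulse energy schedule; it returns
    a :class:`ChirpCalibrationResults`.
    """

    def __init__(self, frames: pd.DataFrame, *,
                 min_frames_per_pulse: int = MIN_FRAMES_PER_PULSE,
                 pulses_per_train: int | None = None,
                 signed_kappa: bool = False,
                 normalize_sigma: bool = False):
        if len(frames) == 0:
            raise InsufficientDataError("no frames supplied")
        self.frames = frames
        self.min_frames_per_pulse = min_frames_per_pulse
        self.pulses_per_train = pulses_per_train
        self.signed_kappa = signed_kappa
        self.normalize_sigma = normalize_sigma

    @classmethod
    def from_stream(cls, path, **kwargs) -> "ChirpCalibration":
        """Build the model from a CrystFEL-style stream file."""
        from .stream_io import read_stream_dataframe

        return cls(read_stream_dataframe(path), **kwargs)

    def fit(self, *, evaluator=None, distances=None, energies=None,
            interp_factor: int = 8, scan_halfwidth: float = 25.0,
            scan_step: float = 0.5,
            reference_pulse: int | None = None) -> "ChirpCalibrationResults":
        """Calibrate: optional (D, E) grid scan, then per-pulse energy fit.

        Without an evaluator the frames' own assumed distance and energy
        are taken as the optimum (schedule-only fit).
        """
        stats = pulse_stats(self.frames, min_frames=self.min_frames_per_pulse,
                            pulses_per_train=self.pulses_per_train)

        grid = None
        if evaluator is not None:
            if distances is None or energies is None:
                raise DodSfxError("grid scan needs both distances and energies axes")
            grid = scan_grid(evaluator, distances, energies,
                             min_frames=self.min_frames_per_pulse,
                             signed_kappa=self.signed_kappa,
                             normalize_sigma=self.normalize_sigma)
            opt_d, opt_e = normalize_and_locate(grid, interp_factor)
        else:
            opt_d = float(self.frames["detector_distance"].iloc[0])
            opt_e = float(self.frames["photon_energy"].iloc[0])

        schedule = build_schedule(stats, opt_e, scan_halfwidth, scan_step,
                                  reference_pulse=reference_pulse)
        return ChirpCalibrationResults(self, stats, grid, opt_d, opt_e, schedule)


class ChirpCalibrationResults:
    """Fitted calibration: optimum, per-pulse statistics, energy schedule."""

    def __init__(self, model: ChirpCalibration, stats: dict,
                 grid: CalibrationGrid | None,
                 optimal_distance: float, optimal_energy: float,
                 schedule: EnergySchedule):
        self.model = model
        self.pulse_stats = stats
        self.grid = grid
        self.optimal_distance = optimal_distance
        self.optimal_energy = optimal_energy
        self.schedule = schedule

    @property
    def drift(self) -> float:
        """Chirp drift: last-pulse minus first-pulse corrected energy (eV)."""
        return self.schedule.drift

    def energy_standard_errors(self) -> dict:
        """Approximate 1-sigma errors of the per-pulse energies (eV).

        Propagates the standard error of each fitted cell mean (σ_i/√IR,
        pulse and reference in quadrature) through the closed-form energy
        ratio; the reference pulse is pinned, so its error is 0.
        """
        ref = self.pulse_stats.get(self.schedule.reference_pulse)
        out = {}
        for pid, energy in self.schedule.energies.items():
            st = self.pulse_stats.get(pid)
            if st is None or ref is None:
                out[pid] = float("nan")
                continue
            if pid == self.schedule.reference_pulse:
                out[pid] = 0.0
                continue
            var = 0.0
            for p in CELL_LENGTHS:
                se_p = st.sigma[p] / np.sqrt(st.ir)
                se_r = ref.sigma[p] / np.sqrt(ref.ir)
                var += (se_p / ref.mu[p]) ** 2 + (se_r * st.mu[p] / ref.mu[p] ** 2) ** 2
            out[pid] = float(self.optimal_energy * np.sqrt(var) / len(CELL_LENGTHS))
        return out

    def apply(self, frames: pd.DataFrame | None = None) -> pd.DataFrame:
        """Corrected frame table (defaults to the model's own frames)."""
        return apply_schedule(self.model.frames if frames is None else frames,
                              self.schedule)

    def corrected_stats(self) -> dict:
        return pulse_stats(self.apply(), min_frames=self.model.min_frames_per_pulse,
                           pulses_per_train=self.model.pulses_per_train)

    def stats_table(self) -> pd.DataFrame:
        table = stats_table(self.pulse_stats)
        se = self.energy_standard_errors()
        table["energy_ev"] = table["pulse_id"].map(self.schedule.energies)
        table["energy_se_ev"] = table["pulse_id"].map(se)
        return table

    def summary(self) -> str:
        """Human-readable calibration report."""
        lines = []
        lines.append("Intra-train photon-energy chirp calibration")
        lines.append("=" * 60)
        if self.grid is not None:
            lines.append(f"Grid scan: {self.grid.evaluated_count} (distance, energy) "
                         "combinations evaluated")
        lines.append(f"Optimal detector distance : {self.optimal_distance:10.3f} mm")
        lines.append(f"Optimal photon energy     : {self.optimal_energy:10.2f} eV")
        lines.append(f"Reference pulse           : {self.schedule.reference_pulse:6d}")
        lines.append(f"Energy drift over train   : {self.drift:+10.2f} eV")
        lines.append("-" * 60)
        lines.append(f"{'pulse':>5} {'IR':>7} {'E (eV)':>10} {'±(eV)':>7} "
                     f"{'mu_a (Å)':>10} {'sigma_a':>8} {'kappa_a':>8}")
        se = self.energy_standard_errors()
        for pid in sorted(self.schedule.energies):
            st = self.pulse_stats.get(pid)
            e = self.schedule.energies[pid]
            if st is None:
                lines.append(f"{pid:>5} {'--':>7} {e:>10.2f} {'--':>7} "
                             f"{'(no stats)':>10}")
                continue
            lines.append(f"{pid:>5} {st.ir:>7d} {e:>10.2f} {se[pid]:>7.2f} "
                         f"{st.mu['a']:>10.4f} {st.sigma['a']:>8.4f} {st.kappa['a']:>8.3f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_grid(self, ax=None, interp_factor: int = 8):
        """Normalised FOM matrix over (distance, energy) with the optimum marked."""
        import matplotlib.pyplot as plt

        if self.grid is None:
            raise DodSfxError("no grid scan was performed")
        matrix, d_axis, e_axis = interpolate_normalize(self.grid, interp_factor)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(e_axis, d_axis, matrix, shading="auto")
        ax.plot(self.optimal_energy, self.optimal_distance, "r+", markersize=12)
        ax.set_xlabel("photon energy (eV)")
        ax.set_ylabel("detector distance (mm)")
        ax.figure.colorbar(im, ax=ax, label="normalised FOM")
        return ax

    def plot_schedule(self, ax=None):
        """Corrected photon energy per pulse with propagated errors."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pids = sorted(self.schedule.energies)
        es = [self.schedule.energies[p] for p in pids]
        errs = [self.energy_standard_errors()[p] for p in pids]
        ax.errorbar(pids, es, yerr=errs, fmt="o-")
        ax.set_xlabel("pulse in train")
        ax.set_ylabel("corrected photon energy (eV)")
        return ax

    def plot_cells(self, param: str = "a", ax=None):
        """Per-pulse mean cell parameter before (red) and after (blue) correction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for stats, color, label in ((self.pulse_stats, "tab:red", "uncorrected"),
                                    (self.corrected_stats(), "tab:blue", "corrected")):
            pids = [p for p in sorted(stats) if stats[p] is not None]
            mu = [stats[p].mu[param] for p in pids]
            sd = [stats[p].sigma[param] for p in pids]
            ax.errorbar(pids, mu, yerr=sd, fmt="o", color=color, label=label)
        ax.set_xlabel("pulse in train")
        unit = "Å" if param in CELL_LENGTHS else "deg"
        ax.set_ylabel(f"{param} ({unit})")
        ax.legend()
        return ax
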