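"""Per-pulse unit-cell distribution statistics.

Frames are grouped by pulse position within the train and each pulse's six
cell-parameter distributions are characterised by a Gaussian fit to the
histogram (centre μ, width σ) plus the adjusted Fisher–Pearson sample
skewness κ.  These are the ingredients of the indexing figure of merit:
a well-calibrated photon energy / detector distance gives many indexed
patterns with narrow, symmetric cell distributions, and any miscalibration
shows up as inflated σ·|κ|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .cells import CELL_PARAMS
from .exceptions import InsufficientDataError

__all__ = [
    "PulseCellStats",
    "group_by_pulse",
    "fit_gaussian",
    "skewness",
    "pulse_stats",
    "pooled_stats",
    "stats_table",
    "MIN_FRAMES_PER_PULSE",
]

#: Minimum frames per pulse for stable Gaussian fits.
MIN_FRAMES_PER_PULSE = 50


@dataclass(frozen=True)
class PulseCellStats:
    """Gaussian-fit summary of one pulse's cell distributions.

    ``mu``/``sigma``/``kappa`` map each cell parameter to the fitted mean,
    fitted standard deviation and sample skewness; ``sample_mu``/
    ``sample_sigma`` carry the plain moment estimates (the fit values are
    the default downstream, the moments are exposed for comparison).
    ``fit_ok`` is False for any parameter where the Gaussian fit fell back
    to sample moments.
    """

    pulse_id: int
    ir: int
    mu: dict
    sigma: dict
    kappa: dict
    sample_mu: dict
    sample_sigma: dict
    fit_ok: dict

    def skew_penalty(self, signed: bool = False) -> float:
        """Σ_i σ_i·κ_i over the six cell parameters (|κ| unless signed)."""
        total = 0.0
        for p in CELL_PARAMS:
            k = self.kappa[p] if signed else abs(self.kappa[p])
            total += self.sigma[p] * k
        return total


def group_by_pulse(frames: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Partition indexed frames by pulse position within the train."""
    if len(frames) == 0:
        return {}
    indexed = frames[frames["indexed"]] if "indexed" in frames else frames
    return {int(pid): grp for pid, grp in indexed.groupby("pulse_id", sort=True)}


def _degenerate(std: float, scale: float) -> bool:
    """Variance indistinguishable from 0 at float precision for this scale."""
    return std <= 1e-12 * max(1.0, abs(scale))


def _gaussian(x, amplitude, mu, sigma):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fd_bins(values: np.ndarray, min_bins: int = 20) -> int:
    """Freedman–Diaconis bin count, floored at ``min_bins``."""
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr <= 0:
        return min_bins
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    n = int(np.ceil((values.max() - values.min()) / width))
    return max(n, min_bins)


def fit_gaussian(values, min_samples: int = MIN_FRAMES_PER_PULSE):
    """Fit a Gaussian to the histogram of ``values``.

    Returns ``(mu, sigma, ok)``.  ``ok`` is False when the nonlinear fit
    failed or the sample is degenerate, in which case sample mean/std are
    returned instead.  Fewer than ``min_samples`` values raises
    :class:`InsufficientDataError` (a distinct condition from fit failure).
    """
    values = np.asarray(values, dtype=float)
    if values.size < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} values for a Gaussian fit, got {values.size}"
        )
    mean, std = float(values.mean()), float(values.std(ddof=1))
    if _degenerate(std, mean):
        return mean, 0.0, False

    counts, edges = np.histogram(values, bins=_fd_bins(values))
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gaussian, centers, counts,
                p0=(counts.max(), mean, std),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return mean, std, False
    _, mu, sigma = popt
    sigma = abs(float(sigma))
    # reject fits that wandered off the data
    if not (values.min() - 3 * std <= mu <= values.max() + 3 * std) or sigma > 10 * std:
        return mean, std, False
    return float(mu), sigma, True


def skewness(values) -> float:
    """Adjusted Fisher–Pearson sample skewness (bias-corrected).

    Zero-variance samples are defined to have skewness 0 (with a warning);
    fewer than 3 values is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("skewness needs >= 3 values")
    if _degenerate(float(values.std()), float(values.mean())):
        warnings.warn("zero-variance sample: skewness defined as 0", stacklevel=2)
        return 0.0
    kappa = float(sps.skew(values, bias=False))
    if not np.isfinite(kappa):
        warnings.warn("non-finite skewness (near-degenerate sample): defined as 0",
                      stacklevel=2)
        return 0.0
    return kappa


def pulse_stats(
    frames: pd.DataFrame,
    min_frames: int = MIN_FRAMES_PER_PULSE,
    pulses_per_train: int | None = None,
) -> dict[int, PulseCellStats | None]:
    """Per-pulse cell statistics for every pulse position.

    Pulses with fewer than ``min_frames`` indexed frames map to ``None``
    (stats absent; such pulses are excluded downstream).  When
    ``pulses_per_train`` is given, absent pulses appear explicitly.
    """
    groups = group_by_pulse(frames)
    pulse_ids = sorted(groups)
    if pulses_per_train is not None:
        pulse_ids = list(range(pulses_per_train))
    out: dict[int, PulseCellStats | None] = {}
    for pid in pulse_ids:
        grp = groups.get(pid)
        if grp is None or len(grp) < min_frames:
            out[pid] = None
            continue
        mu, sigma, kappa, smu, ssd, ok = {}, {}, {}, {}, {}, {}
        for p in CELL_PARAMS:
            vals = grp[p].to_numpy()
            m, s, flag = fit_gaussian(vals, min_samples=min_frames)
            mu[p], sigma[p], ok[p] = m, s, flag
            smu[p] = float(vals.mean())
            ssd[p] = float(vals.std(ddof=1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kappa[p] = skewness(vals)
        out[pid] = PulseCellStats(pulse_id=pid, ir=len(grp), mu=mu, sigma=sigma,
                                  kappa=kappa, sample_mu=smu, sample_sigma=ssd, fit_ok=ok)
    return out


def pooled_stats(frames: pd.DataFrame, min_frames: int = MIN_FRAMES_PER_PULSE) -> PulseCellStats:
    """Statistics over all indexed frames pooled into one group (pulse_id -1).

    Used by the calibration grid scan, where the figure of merit is
    evaluated on the whole (or reference-pulse) dataset at once.
    """
    indexed = frames[frames["indexed"]] if "indexed" in frames else frames
    if len(indexed) < min_frames:
        raise InsufficientDataError(
            f"need >= {min_frames} indexed frames, got {len(indexed)}"
        )
    pooled = indexed.copy()
    pooled["pulse_id"] = -1
    return pulse_stats(pooled, min_frames=min_frames)[-1]


def stats_table(stats: dict[int, PulseCellStats | None]) -> pd.DataFrame:
    """Plot-ready table: one row per pulse, columns mu_*/sigma_*/kappa_*/ir."""
    rows = []
    for pid in sorted(stats):
        st = stats[pid]
        if st is None:
            rows.append({"pulse_id": pid, "ir": 0})
            continue
        row = {"pulse_id": pid, "ir": st.ir}
        for p in CELL_PARAMS:
            row[f"mu_{p}"] = st.mu[p]
            row[f"sigma_{p}"] = st.sigma[p]
            row[f"kappa_{p}"] = st.kappa[p]
        rows.append(row)
    return pd.DataFrame(rows)
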