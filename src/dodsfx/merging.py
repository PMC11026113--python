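"""Half-dataset crystallographic merging statistics.

The quality of merged SFX intensities is judged by splitting the frames
into two halves, merging each independently, and comparing:

* Rsplit = 2^(-1/2) · Σ|I1 − I2| / (½ Σ(I1 + I2)) — the half-dataset
  disagreement (lower is better);
* CC1/2 — the Pearson correlation of half intensities; and
* CC* = sqrt(2·CC1/2 / (1 + CC1/2)) — its extrapolation to the full
  dataset (defined for CC1/2 > 0).

Statistics are reported per resolution shell (equal reflection counts by
1/d).  A systematic per-pulse photon-energy error inflates the spread of
the observations, so correcting the chirp lowers Rsplit and raises CC* —
the directional improvement this module is used to demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DodSfxError

__all__ = [
    "ShellStats",
    "split_halves",
    "rsplit",
    "cc_half",
    "cc_star",
    "shell_table",
]


@dataclass(frozen=True)
class ShellStats:
    """Merging statistics for one resolution shell (d_max .. d_min, Å)."""

    shell_id: int
    d_max: float
    d_min: float
    n_reflections: int
    rsplit: float
    cc_half: float
    cc_star: float  # NaN when cc_half <= 0


def split_halves(observations: pd.DataFrame):
    """Merge per-frame reflection observations into two half-datasets.

    ``observations`` needs columns ``refl_id``, ``frame_id``, ``intensity``
    (``refl_id`` is any hashable reflection key, e.g. packed hkl).  Frames
    are assigned alternately by even/odd frame index — deterministic and
    seedless — and each half's intensity is the mean over its observations.
    Reflections observed in only one half are dropped.

    Returns ``(i1, i2, dropped)``: two aligned Series indexed by refl_id,
    and the number of dropped reflections.
    """
    if len(observations) == 0:
        empty = pd.Series(dtype=float)
        return empty, empty.copy(), 0
    half = observations["frame_id"].astype(int) % 2
    merged = observations.groupby([half.rename("half"), observations["refl_id"]])[
        "intensity"].mean()
    i1 = merged.get(0, pd.Series(dtype=float))
    i2 = merged.get(1, pd.Series(dtype=float))
    common = i1.index.intersection(i2.index)
    dropped = (len(i1) - len(common)) + (len(i2) - len(common))
    return i1.loc[common], i2.loc[common], dropped


def rsplit(i1, i2) -> float:
    """Rsplit = 2^(-1/2) · Σ|I1−I2| / (½ Σ(I1+I2)).

    Scale-invariant under a common positive factor; 0 for identical halves.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.size == 0 or i1.shape != i2.shape:
        raise DodSfxError("Rsplit needs two equal-length nonempty intensity lists")
    denom = 0.5 * (i1 + i2).sum()
    if denom == 0:
        raise DodSfxError("Rsplit denominator is zero")
    return float(np.abs(i1 - i2).sum() / denom / np.sqrt(2.0))


def cc_half(i1, i2) -> float:
    """Pearson correlation of half-dataset intensities (CC1/2).

    Zero variance in either half is undefined and returns NaN.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.size < 2 or i1.shape != i2.shape:
        raise DodSfxError("CC1/2 needs two equal-length lists of >= 2 reflections")
    if i1.std() == 0 or i2.std() == 0:
        return float("nan")
    return float(np.corrcoef(i1, i2)[0, 1])


def cc_star(cchalf: float) -> float:
    """CC* = sqrt(2·CC1/2 / (1 + CC1/2)); NaN for CC1/2 <= 0.

    Monotone increasing on (0, 1] with fixed point CC*(1) = 1.
    """
    if not np.isfinite(cchalf) or cchalf <= 0:
        return float("nan")
    return float(np.sqrt(2.0 * cchalf / (1.0 + cchalf)))


def shell_table(i1, i2, inv_d, n_shells: int = 10) -> pd.DataFrame:
    """Per-shell merging statistics over equal-count resolution shells.

    ``i1``/``i2`` are aligned half intensities; ``inv_d`` the 1/d (Å⁻¹)
    of each reflection.  Shells are equal-reflection-count bins in 1/d,
    shell 0 the lowest resolution.  Returns a DataFrame with one row per
    shell (columns from :class:`ShellStats`).
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    inv_d = np.asarray(inv_d, dtype=float)
    n = i1.size
    if n != i2.size or n != inv_d.size:
        raise DodSfxError("half intensities and resolutions must be aligned")
    if n < n_shells:
        raise DodSfxError(f"{n} reflections cannot fill {n_shells} shells")
    order = np.argsort(inv_d, kind="stable")
    bounds = np.linspace(0, n, n_shells + 1).round().astype(int)
    rows = []
    for s in range(n_shells):
        idx = order[bounds[s]:bounds[s + 1]]
        sub_d = inv_d[idx]
        rows.append(ShellStats(
            shell_id=s,
            d_max=float(1.0 / sub_d.min()),
            d_min=float(1.0 / sub_d.max()),
            n_reflections=idx.size,
            rsplit=rsplit(i1[idx], i2[idx]),
            cc_half=cc_half(i1[idx], i2[idx]),
            cc_star=cc_star(cc_half(i1[idx], i2[idx])),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
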