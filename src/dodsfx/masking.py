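"""Statistical detector masking.

Burst-mode detectors like the LPD accumulate "hot" pixels whose response is
anomalous in one or more statistical moments.  Three complementary rules
identify them:

* **Isolation forest on moment features** — for each pixel the deviation of
  its mean, standard deviation, skewness and kurtosis from the respective
  median over unmasked pixels forms a 4-feature vector; an isolation forest
  (scikit-learn) flags the most easily isolated fraction.
* **Peak occurrence** — pixels where the peak finder fires far more often
  than average (mean + t·sd of per-pixel peak counts).
* **Peakogram hot areas** — bins of the (resolution, log-intensity)
  histogram that sit above the intensity cut yet are isolated from the
  continuous accumulation ridge point back to the offending pixels.

Rules combine by union into a :class:`~dodsfx.stream_io.MaskFile` that
records, per pixel, every rule that flagged it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .exceptions import DodSfxError, MaskShapeError
from .stream_io import MaskFile

__all__ = [
    "moment_features",
    "isolation_forest_mask",
    "peak_occurrence_mask",
    "build_peakogram",
    "Peakogram",
    "peakogram_hot_areas",
    "combine_masks",
]

STAT_NAMES = ("mean", "std", "skewness", "kurtosis")


def moment_features(stats: dict, pre_mask: set | None = None) -> pd.DataFrame:
    """Median-centred moment features, one row per unmasked pixel.

    ``feature_f(pixel) = stat_f(pixel) − median_f`` with the median taken
    over unmasked pixels only (pre-masked pixels — e.g. a dead panel — are
    excluded from both the medians and the output).  Columns: row, col and
    the four centred statistics.
    """
    shapes = {np.asarray(stats[n]).shape for n in STAT_NAMES}
    if len(shapes) != 1:
        raise MaskShapeError(f"statistic maps disagree in shape: {shapes}")
    shape = shapes.pop()
    keep = np.ones(shape, dtype=bool)
    for r, c in (pre_mask or ()):
        keep[r, c] = False
    if not keep.any():
        raise DodSfxError("no unmasked pixels left to featurise")
    rows, cols = np.nonzero(keep)
    table = {"row": rows, "col": cols}
    for name in STAT_NAMES:
        values = np.asarray(stats[name], dtype=float)[keep]
        table[name] = values - np.median(values)
    return pd.DataFrame(table)


def isolation_forest_mask(
    features: pd.DataFrame,
    contamination: float = 0.01,
    n_trees: int = 100,
    seed: int = 0,
    max_samples: int = 256,
):
    """Mask the most anomalous ``contamination`` fraction of pixels.

    Fits an isolation forest (random axis-parallel splits; anomaly score
    from average isolation path length) on the centred moment features and
    masks the pixels with the top ``contamination`` fraction of scores.
    Returns ``(masked_pixels, scores)`` with scores a Series indexed like
    ``features`` (higher = more anomalous).  Deterministic for fixed seed.
    """
    if not 0 < contamination <= 0.5:
        raise DodSfxError("contamination must lie in (0, 0.5]")
    if len(features) < 2:
        raise DodSfxError("need at least 2 unmasked pixels")
    x = features[list(STAT_NAMES)].to_numpy()
    if np.allclose(x, x[0]):
        warnings.warn("degenerate (all-identical) features: empty mask", stacklevel=2)
        return set(), pd.Series(np.zeros(len(features)), index=features.index)

    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(max_samples, len(features)),
        contamination=contamination,
        random_state=seed,
    )
    forest.fit(x)
    scores = pd.Series(-forest.score_samples(x), index=features.index)
    n_mask = int(round(contamination * len(features)))
    if n_mask == 0:
        return set(), scores
    top = scores.nlargest(n_mask).index
    masked = {(int(features.at[i, "row"]), int(features.at[i, "col"])) for i in top}
    return masked, scores


def peak_occurrence_mask(peaks: pd.DataFrame, threshold_sd: float = 5.0) -> set:
    """Mask pixels whose peak count is far above the average occurrence.

    The threshold is mean + threshold_sd × sd of per-pixel peak counts,
    computed over pixels that saw at least one peak.  An empty peak list
    gives an empty mask.
    """
    if len(peaks) == 0:
        return set()
    counts = peaks.groupby(["row", "col"]).size()
    mean, sd = counts.mean(), counts.std(ddof=0)
    cut = mean + threshold_sd * sd
    return {(int(r), int(c)) for (r, c), n in counts.items() if n > cut}


class Peakogram:
    """2-D histogram of found peaks over (1/d in Å⁻¹, log10 intensity).

    Tracks, per occupied bin, which pixels contributed how many peaks, so
    hot bins can be traced back to detector coordinates.
    """

    def __init__(self, peaks: pd.DataFrame, n_bins: int = 100):
        if len(peaks) == 0:
            raise DodSfxError("peakogram needs at least one peak")
        inv_d = peaks["inv_d"].to_numpy(dtype=float)
        log_i = np.log10(np.clip(peaks["intensity"].to_numpy(dtype=float), 1e-12, None))
        self.res_edges = np.linspace(inv_d.min(), inv_d.max() + 1e-12, n_bins + 1)
        self.int_edges = np.linspace(log_i.min(), log_i.max() + 1e-12, n_bins + 1)
        self.counts, _, _ = np.histogram2d(inv_d, log_i,
                                           bins=[self.res_edges, self.int_edges])
        ri = np.clip(np.digitize(inv_d, self.res_edges) - 1, 0, n_bins - 1)
        ii = np.clip(np.digitize(log_i, self.int_edges) - 1, 0, n_bins - 1)
        contrib = pd.DataFrame({
            "res_bin": ri, "int_bin": ii,
            "row": peaks["row"].to_numpy(), "col": peaks["col"].to_numpy(),
        })
        self.contributions = contrib.groupby(
            ["res_bin", "int_bin", "row", "col"]).size()
        self.log_intensity = log_i


def build_peakogram(peaks: pd.DataFrame, n_bins: int = 100) -> Peakogram:
    return Peakogram(peaks, n_bins=n_bins)


def peakogram_hot_areas(pg: Peakogram, intensity_percentile: float = 99.0,
                        min_count: int = 10) -> set:
    """Pixels feeding isolated high-intensity peakogram bins.

    A bin is *hot* when its log-intensity exceeds the given percentile of
    all peaks' intensities and it is isolated from the continuous
    accumulation ridge: neither neighbouring resolution bin (same intensity
    bin) is occupied.  Pixels contributing at least ``min_count`` peaks to
    hot bins are masked.
    """
    cut = np.percentile(pg.log_intensity, intensity_percentile)
    occupied = pg.counts > 0
    n_res = pg.counts.shape[0]
    int_centers = 0.5 * (pg.int_edges[:-1] + pg.int_edges[1:])

    hot_bins = set()
    for ri, ii in zip(*np.nonzero(occupied)):
        if int_centers[ii] < cut:
            continue
        left = occupied[ri - 1, ii] if ri > 0 else False
        right = occupied[ri + 1, ii] if ri < n_res - 1 else False
        if not left and not right:
            hot_bins.add((ri, ii))
    if not hot_bins:
        return set()

    per_pixel: dict[tuple[int, int], int] = {}
    for (ri, ii, r, c), n in pg.contributions.items():
        if (ri, ii) in hot_bins:
            per_pixel[(int(r), int(c))] = per_pixel.get((int(r), int(c)), 0) + int(n)
    return {pix for pix, n in per_pixel.items() if n >= min_count}


def combine_masks(shape: tuple[int, int], rules: dict,
                  pre_mask: set | None = None) -> MaskFile:
    """Union of per-rule pixel sets with provenance.

    ``rules`` maps rule name → pixel set.  A ``pre_mask`` (e.g. an excluded
    detector panel) is merged under the rule name ``"pre_mask"``.  The
    returned mask records every rule that flagged each pixel; masking is
    monotone — adding a rule can only grow the mask.
    """
    all_rules = dict(rules)
    if pre_mask:
        all_rules["pre_mask"] = set(pre_mask)
    masked: set = set()
    provenance: dict = {}
    for name, pixels in all_rules.items():
        for pix in pixels:
            pix = (int(pix[0]), int(pix[1]))
            masked.add(pix)
            provenance.setdefault(pix, []).append(name)
    return MaskFile(shape=shape, masked=masked, provenance=provenance)
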