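"""Population-level competition metrics.

Quantities reported per organoid or microtissue: class fractions,
expansion ratios (count at time t over count at the start of imaging),
doubling times from log-linear fits of nuclear counts, inter-nuclear
distance as the mean distance to the five nearest neighbours, simple
linear regressions of expansion against initial composition, expected
seeding fractions, per-population microtissue volumes and apoptosis
counts in randomly placed standard crops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "population_fractions",
    "expansion_ratio",
    "fit_doubling_time",
    "internuclear_distance",
    "RegressionResult",
    "simple_linear_regression",
    "expected_seeding_fraction",
    "microtissue_population_volume",
    "caspase_crop_counts",
    "organoid_summary",
]


def population_fractions(labels) -> dict:
    """Percentage of nuclei per class label for one organoid / frame."""
    labels = pd.Series(list(labels))
    if labels.empty:
        raise ValueError("empty organoid: no nuclei to count")
    counts = labels.value_counts()
    total = int(counts.sum())
    return {str(k): 100.0 * int(v) / total for k, v in counts.items()}


def expansion_ratio(count_t: float, count_0: float) -> float:
    """Fold change of a population count relative to the first frame.

    Undefined (NaN, with a warning) when the initial count is zero.
    """
    if count_0 == 0:
        warnings.warn("expansion ratio undefined for zero initial count")
        return float("nan")
    return float(count_t) / float(count_0)


def fit_doubling_time(counts, times_h) -> float:
    """Doubling time (h) from a least-squares fit of log2(count) vs time.

    For exactly two time points this reduces to the closed form
    ``dt / log2(count_1 / count_0)``.  A non-positive growth slope gives
    ``inf`` with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if counts.size != times.size or counts.size < 2:
        raise ValueError("need at least two (count, time) pairs")
    if np.any(counts <= 0):
        raise ValueError("all counts must be positive for a log fit")
    slope = np.polyfit(times, np.log2(counts), 1)[0]
    if slope <= 1e-12:
        warnings.warn("non-growing series: doubling time is infinite")
        return float("inf")
    return 1.0 / slope


def internuclear_distance(centroids_um, k: int = 5):
    """Mean distance to the k nearest neighbours, per nucleus.

    The proxy for inter-nuclear distance: for each nucleus the Euclidean
    distances (µm) to its ``k`` closest neighbours of the same
    population are averaged; the organoid value is the mean over nuclei.
    When fewer than ``k`` neighbours exist, ``k`` is reduced to ``n - 1``
    with a warning.

    Returns
    -------
    per_nucleus : numpy.ndarray
    organoid_mean : float
    """
    pts = np.asarray(centroids_um, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least two nuclei for neighbour distances")
    k_eff = min(k, n - 1)
    if k_eff < k:
        warnings.warn(f"only {n - 1} neighbours available; using k={k_eff}")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k_eff + 1)
    per_nucleus = dists[:, 1:].mean(axis=1)
    return per_nucleus, float(per_nucleus.mean())


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def simple_linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the slope's two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p_value=float(res.pvalue), n=int(x.size))


def expected_seeding_fraction(parts_a: float, parts_b: float) -> float:
    """Expected % contribution of population a under a parts_a:parts_b mix."""
    if parts_a < 0 or parts_b < 0:
        raise ValueError("mixing parts must be non-negative")
    total = parts_a + parts_b
    if total == 0:
        raise ValueError("at least one mixing part must be positive")
    return 100.0 * parts_a / total


def microtissue_population_volume(population_masks: dict,
                                  voxel_size) -> dict:
    """Total physical volume (µm³) per population mask."""
    voxel_vol = float(np.prod(np.asarray(voxel_size, dtype=float)))
    shapes = {name: np.asarray(m).shape for name, m in population_masks.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"population masks disagree in geometry: {shapes}")
    return {name: float(np.count_nonzero(m)) * voxel_vol
            for name, m in population_masks.items()}


def caspase_crop_counts(records: pd.DataFrame, extent_um,
                        crop_um=(50.0, 250.0, 250.0), n_crops: int = 3,
                        seed: int = 0, positive_col: str = "Casp3_positive",
                        population: str = "WT",
                        exclude_border: bool = True) -> list[int]:
    """Count apoptotic wild-type nuclei in randomly placed standard crops.

    Crops of 250 x 250 x 50 µm (X/Y/Z) are placed at seeded random
    positions inside the physical stack extent — a reproducible surrogate
    for blinded manual crop placement — and Cleaved-Caspase3-positive
    nuclei of the wild-type epithelium are counted in each, excluding
    border-flagged records (the surrogate for debris / extruded cells).
    """
    extent = np.asarray(extent_um, dtype=float)
    crop = np.asarray(crop_um, dtype=float)
    if np.any(extent < crop):
        raise ValueError(
            f"stack extent {tuple(extent)} µm smaller than crop "
            f"{tuple(crop)} µm in at least one axis")
    rng = np.random.default_rng(seed)
    sel = records
    if "population" in sel.columns:
        sel = sel[sel["population"] == population]
    if exclude_border and "border" in sel.columns:
        sel = sel[~sel["border"].astype(bool)]
    if positive_col in sel.columns:
        sel = sel[sel[positive_col].astype(bool)]
    pts = sel[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)

    counts = []
    for _ in range(n_crops):
        origin = rng.uniform(np.zeros(3), extent - crop)
        inside = np.all((pts >= origin) & (pts < origin + crop), axis=1)
        counts.append(int(inside.sum()))
    return counts


def organoid_summary(records: pd.DataFrame, organoid_id: str = "organoid",
                     experiment_id: str = "exp",
                     population_col: str = "population",
                     k_neighbors: int = 5) -> pd.DataFrame:
    """Per-frame summary of one organoid's composition and dynamics.

    Returns one row per frame with total and per-population counts,
    population fractions (%), expansion ratios relative to the first
    frame, and the mean inter-nuclear (k-NN) distance per population.
    """
    if records.empty:
        raise ValueError("empty organoid: nothing to summarize")
    frames = sorted(records["frame"].unique())
    populations = sorted(records[population_col].dropna().unique())
    first = {p: int((records[records["frame"] == frames[0]][population_col]
                     == p).sum()) for p in populations}
    rows = []
    for f in frames:
        sub = records[records["frame"] == f]
        row = {"organoid_id": organoid_id, "experiment_id": experiment_id,
               "frame": f, "n_total": len(sub)}
        if "time_h" in sub.columns and len(sub):
            row["time_h"] = float(sub["time_h"].iloc[0])
        fracs = population_fractions(sub[population_col])
        for p in populations:
            n_p = int((sub[population_col] == p).sum())
            row[f"n_{p}"] = n_p
            row[f"fraction_{p}_pct"] = fracs.get(p, 0.0)
            row[f"expansion_{p}"] = (expansion_ratio(n_p, first[p])
                                     if first[p] else np.nan)
            pop_pts = sub.loc[sub[population_col] == p,
                              ["z_um", "y_um", "x_um"]].to_numpy()
            if pop_pts.shape[0] >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, mean_d = internuclear_distance(pop_pts, k=k_neighbors)
                row[f"knn_dist_{p}_um"] = mean_d
            else:
                row[f"knn_dist_{p}_um"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
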