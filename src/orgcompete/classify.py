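"""Population and marker-class assignment for detected nuclei.

Positivity calls use the volume ratio alpha (marker volume over nuclear
volume): 0.1 for the membrane and pulse markers (mTmG, EdU, pH3) and
0.25 for the H2B nuclear label, compared inclusively so the printed
thresholds are themselves attainable.  SOX9 expression classes are
percentile-based on per-experiment max-normalised mean intensities;
FUCCI2 reporter intensities map to cell-cycle phases via a two-channel
truth table; EdU/pH3 positivity maps to S, S-to-M, M or negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassThresholds",
    "alpha_threshold_for",
    "assign_population",
    "assign_population_df",
    "classify_sox9",
    "classify_fucci",
    "fucci_phases",
    "default_fucci_cutoffs",
    "classify_cell_cycle_edu_ph3",
    "WT_MARKERS_MASK", "WT_MARKER_H2B",
]

#: Markers whose positivity uses the 0.1 alpha threshold.
WT_MARKERS_MASK = ("mTmG", "EdU", "pH3")
WT_MARKER_H2B = "H2B"


@dataclass
class ClassThresholds:
    """Classifier configuration.

    ``alpha_mask_markers`` applies to mTmG, EdU and pH3; ``alpha_h2b``
    to the H2B nuclear label.  SOX9 low/high classes cut the pooled
    normalised intensity distribution at the given percentiles.  FUCCI
    cutoffs are intensity units; ``None`` means derive them from the
    data (Otsu on the pooled per-nucleus means).
    """

    alpha_mask_markers: float = 0.1
    alpha_h2b: float = 0.25
    sox9_low_pct: float = 25.0
    sox9_high_pct: float = 75.0
    fucci_mcherry_cutoff: float | None = None
    fucci_mvenus_cutoff: float | None = None

    def __post_init__(self):
        for name in ("alpha_mask_markers", "alpha_h2b"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.sox9_low_pct < self.sox9_high_pct <= 100:
            raise ValueError("need 0 <= low percentile < high percentile <= 100")


def alpha_threshold_for(marker_name: str,
                        thresholds: ClassThresholds) -> float:
    if marker_name == WT_MARKER_H2B:
        return thresholds.alpha_h2b
    return thresholds.alpha_mask_markers


def _get_alpha(record, marker_name: str) -> float:
    if isinstance(record, (int, float, np.floating)):
        return float(record)
    key = f"{marker_name}_alpha"
    try:
        return float(record[key])
    except (KeyError, IndexError):
        raise KeyError(
            f"record carries no alpha for marker {marker_name!r} "
            f"(expected field {key!r})") from None


def assign_population(record, marker_name: str,
                      thresholds: ClassThresholds | None = None) -> str:
    """Call one nucleus positive/negative for a marker by its alpha.

    ``record`` may be a bare alpha value or a mapping/row with an
    ``<marker>_alpha`` field.  The comparison is inclusive: a nucleus
    exactly at the threshold is positive.
    """
    thresholds = thresholds or ClassThresholds()
    alpha = _get_alpha(record, marker_name)
    t = alpha_threshold_for(marker_name, thresholds)
    return "positive" if alpha >= t else "negative"


def assign_population_df(records: pd.DataFrame, marker_name: str,
                         thresholds: ClassThresholds | None = None
                         ) -> np.ndarray:
    """Vectorised positivity call; returns a boolean array."""
    thresholds = thresholds or ClassThresholds()
    t = alpha_threshold_for(marker_name, thresholds)
    return records[f"{marker_name}_alpha"].to_numpy() >= t


def classify_sox9(records: pd.DataFrame,
                  thresholds: ClassThresholds | None = None,
                  intensity_col: str = "SOX9_mean",
                  experiment_col: str = "experiment_id") -> pd.Series:
    """Classify nuclei as SOX9 low / mid / high by pooled percentiles.

    Each experiment's mean intensities are first normalised by that
    experiment's maximum (making the classes invariant to per-experiment
    multiplicative intensity scaling), then pooled; the 25th and 75th
    percentiles (linear interpolation) of the pooled values define the
    class boundaries with strict inequalities.  A degenerate pool in
    which all values coincide yields all-mid with a warning.
    """
    thresholds = thresholds or ClassThresholds()
    if experiment_col in records.columns:
        groups = records.groupby(experiment_col)[intensity_col]
        norm = records[intensity_col] / groups.transform("max")
    else:
        norm = records[intensity_col] / records[intensity_col].max()
    norm = norm.to_numpy(dtype=float)
    if np.unique(norm[~np.isnan(norm)]).size < 2:
        warnings.warn("degenerate SOX9 pool (all intensities equal); "
                      "classifying every nucleus as mid")
        return pd.Series(["mid"] * len(records), index=records.index,
                         name="sox9_class")
    p_low, p_high = np.percentile(
        norm, [thresholds.sox9_low_pct, thresholds.sox9_high_pct])
    cls = np.where(norm < p_low, "low", np.where(norm > p_high, "high", "mid"))
    return pd.Series(cls, index=records.index, name="sox9_class")


def default_fucci_cutoffs(records: pd.DataFrame,
                          mcherry_col: str = "mCherry_mean",
                          mvenus_col: str = "mVenus_mean"
                          ) -> tuple[float, float]:
    """Data-derived FUCCI cutoffs: Otsu on each pooled mean distribution.

    The Otsu threshold is refined by the intermeans iteration
    (t <- midpoint of the two class means, iterated to convergence) so
    the cutoff settles mid-way between the intensity groups instead of
    at the edge of a histogram bin.
    """
    from skimage.filters import threshold_otsu

    def one(values: np.ndarray) -> float:
        t = float(threshold_otsu(values))
        for _ in range(100):
            lo = values[values <= t]
            hi = values[values > t]
            if lo.size == 0 or hi.size == 0:
                break
            t_new = (lo.mean() + hi.mean()) / 2.0
            if abs(t_new - t) < 1e-6:
                break
            t = t_new
        return float(t)

    return (one(records[mcherry_col].to_numpy(dtype=float)),
            one(records[mvenus_col].to_numpy(dtype=float)))


def classify_fucci(mcherry_mean: float, mvenus_mean: float,
                   mcherry_cutoff: float, mvenus_cutoff: float) -> str:
    """Cell-cycle phase from the two FUCCI2 reporter intensities.

    mCherry+/mVenus- is G1, mCherry-/mVenus+ is S-G2-M and the double
    negative is the G0-like arrested state.  The double positive (G1/S
    transition) is reported as its own class rather than folded into
    S-G2-M.
    """
    cherry = mcherry_mean > mcherry_cutoff
    venus = mvenus_mean > mvenus_cutoff
    if cherry and venus:
        return "double-positive"
    if cherry:
        return "G1"
    if venus:
        return "S-G2-M"
    return "G0-like"


def fucci_phases(records: pd.DataFrame,
                 thresholds: ClassThresholds | None = None,
                 mcherry_col: str = "mCherry_mean",
                 mvenus_col: str = "mVenus_mean") -> pd.Series:
    """Vectorised FUCCI classification of a record table."""
    thresholds = thresholds or ClassThresholds()
    for col in (mcherry_col, mvenus_col):
        if col not in records.columns:
            raise KeyError(f"missing FUCCI channel column {col!r}")
    tc, tv = thresholds.fucci_mcherry_cutoff, thresholds.fucci_mvenus_cutoff
    if tc is None or tv is None:
        otc, otv = default_fucci_cutoffs(records, mcherry_col, mvenus_col)
        tc = otc if tc is None else tc
        tv = otv if tv is None else tv
    phases = [classify_fucci(c, v, tc, tv)
              for c, v in zip(records[mcherry_col], records[mvenus_col])]
    return pd.Series(phases, index=records.index, name="fucci_phase")


def classify_cell_cycle_edu_ph3(edu_positive: bool, ph3_positive: bool) -> str:
    """Cell-cycle state from EdU / pH3 positivity.

    EdU marks DNA replication (S phase), pH3 marks mitotic chromatin;
    double positives progressed from S into mitosis within the labelling
    window, and double negatives are arrest candidates.
    """
    if edu_positive and ph3_positive:
        return "S-to-M"
    if edu_positive:
        return "S"
    if ph3_positive:
        return "M"
    return "negative"
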