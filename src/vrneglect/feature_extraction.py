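"""The eight raw gameplay metrics computed from one session.

Orientation metrics (signed; positive = rightward orientation, the
pattern expected in left neglect):

* ``accuracy_subtract`` — accuracy(right targets) − accuracy(left
  targets), percentage points, pooled over set sizes 8/16/24;
* ``rt_subtract`` — mean RT(left) − mean RT(right) in seconds over
  correct, outlier-filtered trials (slower on the left is rightward);
* ``headset_mean`` / ``gaze_mean`` — per-set-size mean lateral raycast
  angle in degrees;
* ``headset_slope`` / ``gaze_slope`` — OLS slope of those means against
  set size, degrees/item.

Challenge metrics (search inefficiency):

* ``accuracy_slope`` — OLS slope of per-set-size accuracy, %/item;
* ``rt_slope`` — OLS slope of per-set-size mean correct RT, s/item.

RT outlier removal uses per-player Tukey fences (Q1 − 1.5·IQR,
Q3 + 1.5·IQR with linear-interpolation quartiles) on correct-trial RTs:
pooled across all analysis trials for the subtraction contrast, within
each set size for the per-set-size RT means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gameplay_data import ANALYSIS_SET_SIZES, CohortDataset, PlayerSession

__all__ = [
    "RawFeatureVector",
    "ORIENTATION_METRICS",
    "CHALLENGE_METRICS",
    "MEAN_METRICS",
    "filter_rt_outliers",
    "hemispace_contrast_accuracy",
    "hemispace_contrast_rt",
    "set_size_slope",
    "extract_features",
    "extract_features_cohort",
    "features_frame",
]

ORIENTATION_METRICS = (
    "accuracy_subtract",
    "rt_subtract",
    "headset_mean",
    "gaze_mean",
    "headset_slope",
    "gaze_slope",
)
CHALLENGE_METRICS = ("accuracy_slope", "rt_slope")
#: Metrics carried per set size (fenced per set size downstream).
MEAN_METRICS = ("headset_mean", "gaze_mean")


@dataclass
class RawFeatureVector:
    """The raw metric values of one player, before normative thresholding.

    Missing values (a hemispace or raycast source with no usable data)
    are ``nan``; downstream flagging treats them as typical.
    """

    player_id: str
    group: str
    accuracy_subtract: float = math.nan
    rt_subtract: float = math.nan
    headset_mean: dict[int, float] = field(default_factory=dict)
    gaze_mean: dict[int, float] = field(default_factory=dict)
    headset_slope: float = math.nan
    gaze_slope: float = math.nan
    accuracy_slope: float = math.nan
    rt_slope: float = math.nan
    #: per-set-size accuracy (%) and mean filtered correct RT (s)
    accuracy_by_set_size: dict[int, float] = field(default_factory=dict)
    rt_by_set_size: dict[int, float] = field(default_factory=dict)
    #: pooled per-hemispace accuracy (%), for severity
    accuracy_left: float = math.nan
    accuracy_right: float = math.nan

    def as_row(self) -> dict[str, float | str]:
        """Flatten to one CSV row (mean metrics expanded per set size)."""
        row: dict[str, float | str] = {
            "player_id": self.player_id,
            "group": self.group,
            "accuracy_subtract": self.accuracy_subtract,
            "rt_subtract": self.rt_subtract,
            "headset_slope": self.headset_slope,
            "gaze_slope": self.gaze_slope,
            "accuracy_slope": self.accuracy_slope,
            "rt_slope": self.rt_slope,
            "accuracy_left": self.accuracy_left,
            "accuracy_right": self.accuracy_right,
        }
        for metric in MEAN_METRICS:
            means = getattr(self, metric)
            for s in ANALYSIS_SET_SIZES:
                row[f"{metric}_{s}"] = means.get(s, math.nan)
        return row


def filter_rt_outliers(rts) -> np.ndarray:
    """Drop RTs strictly outside the player's own Tukey fences.

    Quartiles use linear interpolation between order statistics; values
    exactly on a fence are kept.  Fewer than 4 values: returned unchanged
    (with a warning) since quartiles are not meaningful.

    Raises
    ------
    ValueError
        If ``rts`` is empty.
    """
    arr = np.asarray(rts, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot filter an empty RT sequence")
    if arr.size < 4:
        warnings.warn(
            f"only {arr.size} RTs; outlier fences need >= 4 values, returning input",
            stacklevel=2,
        )
        return arr
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return arr[(arr >= lower) & (arr <= upper)]


def set_size_slope(set_sizes, values) -> float:
    """OLS slope of ``values`` against ``set_sizes`` (per-item change).

    With the three equally spaced set sizes 8/16/24 this equals
    ``(v24 - v8) / 16``.  Fewer than two finite points: ``nan``.
    """
    x = np.asarray(set_sizes, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return math.nan
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return math.nan
    return float(xc @ (y - y.mean()) / denom)


def _split_hemispaces(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    # Midline targets (lateral angle exactly 0) enter neither side.
    left = trials[trials["target_lateral_angle"] < 0]
    right = trials[trials["target_lateral_angle"] > 0]
    return left, right


def hemispace_contrast_accuracy(session: PlayerSession | pd.DataFrame) -> float:
    """Accuracy(right) − accuracy(left) in percentage points, pooled over
    analysis trials.  ``nan`` if either hemispace has no trials."""
    trials = session.analysis_trials() if isinstance(session, PlayerSession) else session
    left, right = _split_hemispaces(trials)
    if not len(left) or not len(right):
        return math.nan
    return 100.0 * (right["correct"].mean() - left["correct"].mean())


def hemispace_contrast_rt(session: PlayerSession | pd.DataFrame) -> float:
    """Mean RT(left) − mean RT(right) in seconds on correct trials after
    pooled outlier filtering.  ``nan`` if a hemispace has no survivors."""
    trials = session.analysis_trials() if isinstance(session, PlayerSession) else session
    correct = trials[trials["correct"]]
    if not len(correct):
        return math.nan
    kept = filter_rt_outliers(correct["rt_s"].to_numpy())
    keep_mask = _kept_mask(correct["rt_s"].to_numpy(), kept)
    correct = correct[keep_mask]
    left, right = _split_hemispaces(correct)
    if not len(left) or not len(right):
        return math.nan
    return float(left["rt_s"].mean() - right["rt_s"].mean())


def _kept_mask(values: np.ndarray, kept: np.ndarray) -> np.ndarray:
    if kept.size == values.size:
        return np.ones(values.size, dtype=bool)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)


def extract_features(session: PlayerSession) -> RawFeatureVector:
    """Compute all eight raw metrics for one session.

    Per-set-size RT means are computed after outlier filtering *within*
    each set size; the subtraction contrast filters pooled across all
    analysis trials.  Both repetitions of a set size are pooled.  Absent
    orientation summaries leave the raycast metrics ``nan``; gameplay
    metrics are still computed.
    """
    trials = session.analysis_trials()
    feats = RawFeatureVector(player_id=session.player_id, group=session.group)

    if len(trials):
        feats.accuracy_subtract = hemispace_contrast_accuracy(trials)
        feats.rt_subtract = hemispace_contrast_rt(trials)

        left, right = _split_hemispaces(trials)
        if len(left):
            feats.accuracy_left = 100.0 * left["correct"].mean()
        if len(right):
            feats.accuracy_right = 100.0 * right["correct"].mean()

        for s in ANALYSIS_SET_SIZES:
            sub = trials[trials["set_size"] == s]
            if not len(sub):
                continue
            feats.accuracy_by_set_size[s] = 100.0 * sub["correct"].mean()
            rts = sub.loc[sub["correct"], "rt_s"].to_numpy()
            if rts.size:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    feats.rt_by_set_size[s] = float(np.mean(filter_rt_outliers(rts)))
        feats.accuracy_slope = set_size_slope(
            list(feats.accuracy_by_set_size), list(feats.accuracy_by_set_size.values())
        )
        feats.rt_slope = set_size_slope(
            list(feats.rt_by_set_size), list(feats.rt_by_set_size.values())
        )

    for metric, source in (("headset_mean", "headset"), ("gaze_mean", "gaze")):
        means = {
            s: m
            for s, m in session.orientation_means(source).items()
            if s in ANALYSIS_SET_SIZES
        }
        setattr(feats, metric, means)
        slope = set_size_slope(list(means), list(means.values())) if means else math.nan
        setattr(feats, metric.replace("_mean", "_slope"), slope)
    return feats


def extract_features_cohort(dataset: CohortDataset) -> list[RawFeatureVector]:
    """Extract features for every session of a cohort, in cohort order."""
    return [extract_features(s) for s in dataset]


def features_frame(features: list[RawFeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors as one row per player (``features.csv``)."""
    return pd.DataFrame([f.as_row() for f in features])
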