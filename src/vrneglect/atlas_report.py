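"""Numeric report surfaces: heatmap tables, raycast histograms,
gameplay position maps and per-category summaries.

Every operation here is a pure function of its inputs, returning plain
DataFrames/arrays suitable for CSV export; rendering is left to the
caller.  Controller raycasts may be reported but never feed
classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import PlayerSummary, classification_frame
from .feature_extraction import (
    CHALLENGE_METRICS,
    ORIENTATION_METRICS,
    RawFeatureVector,
)

__all__ = [
    "HeatmapTable",
    "RaycastHistogram",
    "heatmap_table",
    "raycast_histogram",
    "position_maps",
    "category_summary",
]

#: Column order of the heatmap: outcome metadata then features.
SUMMARY_COLUMNS = ("atypicality", "orientation", "challenge", "severity")


@dataclass
class HeatmapTable:
    """Per-player normalized feature intensities plus atypicality mask.

    ``values`` holds each metric min–max normalized to [0, 1] over the
    cohort (constant columns sit at 0.5); ``mask`` is True where the
    corresponding feature flag is non-zero.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    labels: pd.Series

    @property
    def mask_density(self) -> float:
        """Fraction of masked feature cells = mean atypicality / 8."""
        feature_cols = [c for c in self.mask.columns]
        return float(self.mask[feature_cols].to_numpy().mean())


def _minmax(col: pd.Series) -> pd.Series:
    finite = col[np.isfinite(col)]
    if not len(finite):
        return pd.Series(0.5, index=col.index)
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        warnings.warn(f"constant column {col.name!r}: normalized to 0.5", stacklevel=2)
        return pd.Series(0.5, index=col.index)
    return (col - lo) / (hi - lo)


def heatmap_table(
    summaries: Sequence[PlayerSummary],
    raw_features: Sequence[RawFeatureVector],
) -> dict[str, HeatmapTable]:
    """Build the classifier heatmap tables, patients and controls separate.

    Mean metrics are summarized by the per-set-size mean with the largest
    absolute value (the level driving the flag).  Returns a dict with
    keys ``"patients"`` and ``"controls"`` (present when non-empty).
    """
    cls = classification_frame(summaries).set_index("player_id")
    raw_rows = {}
    for f in raw_features:
        row = {
            "accuracy_subtract": f.accuracy_subtract,
            "rt_subtract": f.rt_subtract,
            "headset_slope": f.headset_slope,
            "gaze_slope": f.gaze_slope,
            "accuracy_slope": f.accuracy_slope,
            "rt_slope": f.rt_slope,
        }
        for metric in ("headset_mean", "gaze_mean"):
            means = [v for v in getattr(f, metric).values() if math.isfinite(v)]
            row[metric] = max(means, key=abs) if means else math.nan
        raw_rows[f.player_id] = row
    raw_df = pd.DataFrame.from_dict(raw_rows, orient="index")

    out = {}
    for key, group in (("patients", "patient"), ("controls", "control")):
        ids = sorted(cls.index[cls["group"] == group])
        if not ids:
            continue
        feats = raw_df.loc[ids, list(ORIENTATION_METRICS + CHALLENGE_METRICS)]
        summ = cls.loc[ids, list(SUMMARY_COLUMNS)].astype(float)
        values = pd.concat([summ, feats], axis=1).apply(_minmax)
        mask = pd.DataFrame(
            {
                m: cls.loc[ids, f"flag_{m}"].ne(0)
                for m in ORIENTATION_METRICS + CHALLENGE_METRICS
            },
            index=ids,
        )
        out[key] = HeatmapTable(values=values, mask=mask, labels=cls.loc[ids, "label"])
    return out


@dataclass
class RaycastHistogram:
    """2D frame-count histogram over (lateral, vertical) with 1° bins."""

    source: str
    counts: np.ndarray
    lateral_edges: np.ndarray
    vertical_edges: np.ndarray

    @property
    def total_frames(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        """Long-format (lateral_bin, vertical_bin, count) with count > 0."""
        lat_idx, vert_idx = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "source": self.source,
                "lateral_deg": self.lateral_edges[lat_idx],
                "vertical_deg": self.vertical_edges[vert_idx],
                "count": self.counts[lat_idx, vert_idx].astype(int),
            }
        )


def raycast_histogram(
    frames: pd.DataFrame,
    source: str,
    set_size: int | None = 24,
) -> RaycastHistogram:
    """Histogram raw raycast frames of one source with 1° bin width.

    ``frames`` uses the frames.csv schema (player_id, source, set_size,
    x, y, z).  By default only the hardest (24-element) levels enter, as
    in the attention maps.  Bin edges sit at integer degrees covering the
    full sphere; counts conserve the number of input frames.
    """
    sub = frames[frames["source"] == source]
    if set_size is not None:
        sub = sub[sub["set_size"] == set_size]
    lat_edges = np.arange(-180.0, 181.0)
    vert_edges = np.arange(-90.0, 91.0)
    if not len(sub):
        counts = np.zeros((len(lat_edges) - 1, len(vert_edges) - 1))
        return RaycastHistogram(source, counts, lat_edges[:-1], vert_edges[:-1])
    x = sub["x"].to_numpy(float)
    y = sub["y"].to_numpy(float)
    z = sub["z"].to_numpy(float)
    norm = np.sqrt(x * x + y * y + z * z)
    if np.any(norm <= 0):
        raise ValueError("degenerate raycast frames (zero vector)")
    lat = np.degrees(np.arctan2(x, z))
    vert = np.degrees(np.arcsin(np.clip(y / norm, -1.0, 1.0)))
    counts, _, _ = np.histogram2d(lat, vert, bins=[lat_edges, vert_edges])
    return RaycastHistogram(source, counts, lat_edges[:-1], vert_edges[:-1])


def position_maps(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-target-position accuracy (%) and mean correct-trial RT (s).

    RT is computed on correct trials only, after per-player pooled
    outlier filtering; positions with no surviving correct trials carry
    ``NaN`` RT.  Input: analysis trials (trials.csv schema).
    """
    trials = trials.copy()
    keep = np.ones(len(trials), dtype=bool)
    for _, idx in trials.groupby("player_id").groups.items():
        sub = trials.loc[idx]
        corr = sub["correct"].to_numpy(bool)
        rts = sub.loc[sub["correct"], "rt_s"].to_numpy()
        if rts.size >= 4:
            q1, q3 = np.quantile(rts, [0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            bad = corr & ((sub["rt_s"] < lo) | (sub["rt_s"] > hi)).to_numpy()
            keep[trials.index.get_indexer(idx)] &= ~bad
    rt_ok = trials[keep & trials["correct"].to_numpy(bool)]

    pos_cols = ["target_lateral_angle", "target_vertical_angle"]
    acc = (
        trials.groupby(pos_cols)["correct"]
        .agg(accuracy_pct=lambda c: 100.0 * c.mean(), n_trials="size")
        .reset_index()
    )
    rt = (
        rt_ok.groupby(pos_cols)["rt_s"]
        .agg(mean_rt_s="mean", n_rt="size")
        .reset_index()
    )
    out = acc.merge(rt, on=pos_cols, how="left")
    out["n_rt"] = out["n_rt"].fillna(0).astype(int)
    return out


def category_summary(
    summaries: Sequence[PlayerSummary],
    reference_neglect: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-category table: n, %, mean ± SD of the four summary scores.

    Rows: one per occupied neglect category (patients), plus pooled
    ``non_neglect`` and ``minor_atypicality`` rows.  ``reference_neglect``
    optionally maps player_id -> binary reference-test outcome, filling
    the detected-on-reference percentage.  SD is ``NaN`` for singleton
    rows.
    """
    patients = [s for s in summaries if s.group == "patient"]
    rows = []

    def _row(name: str, members: list[PlayerSummary], n_total: int | None) -> dict:
        vals = {
            "atypicality": [s.atypicality for s in members],
            "orientation": [s.orientation for s in members],
            "challenge": [s.challenge for s in members],
            "severity": [s.severity for s in members],
        }
        row: dict[str, object] = {"category": name, "n": len(members)}
        row["pct"] = 100.0 * len(members) / n_total if n_total else math.nan
        if reference_neglect is not None and members:
            detected = [
                bool(reference_neglect.get(s.player_id, False)) for s in members
            ]
            row["detected_on_reference_pct"] = 100.0 * float(np.mean(detected))
        else:
            row["detected_on_reference_pct"] = math.nan
        for k, v in vals.items():
            row[f"{k}_mean"] = float(np.mean(v)) if v else math.nan
            row[f"{k}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
        return row

    neglect = [s for s in patients if s.label == "neglect"]
    n_neglect = len(neglect)
    codes = sorted({s.category_code for s in neglect if s.category_code})
    for code in codes:
        members = [s for s in neglect if s.category_code == code]
        rows.append(_row(f"neglect_{code}", members, n_neglect))
    rows.append(
        _row("non_neglect", [s for s in patients if s.label == "non_neglect"], None)
    )
    rows.append(
        _row(
            "minor_atypicality",
            [s for s in patients if s.label == "minor_atypicality"],
            None,
        )
    )
    return pd.DataFrame(rows)
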