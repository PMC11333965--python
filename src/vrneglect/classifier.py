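"""Rule-based three-class neglect classification and category coding.

Summary scores from the eight thresholded features:

* **atypicality** (0–8) — count of non-zero flags;
* **orientation** (−6..+6) — algebraic sum of the six orientation flags,
  opposite directions cancelling (positive = rightward bias = left
  neglect);
* **challenge** (0–2) — sum of the two challenge flags;
* **severity** (0–1) — proportion of detection errors in the worse
  hemispace, descriptive only.

Diagnostic rule: **neglect** when |orientation| > 1, or when both
|orientation| > 0 and challenge > 0; **minor atypicality** when some
flag is set but the neglect rule is not met; **non-neglect** when no
flag is set.  The rule operates on |orientation| so right-neglect
(negative orientation) players satisfy it symmetrically.

Neglect cases get a multidimensional category code: side letter
(L/R from the orientation sign) + 'O' when |orientation| is at or above
the neglect cohort's median + 'C' when challenge is at or above its
median (medians pooled over both sides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_extraction import (
    CHALLENGE_METRICS,
    ORIENTATION_METRICS,
    RawFeatureVector,
    extract_features_cohort,
)
from .gameplay_data import CohortDataset
from .normative_model import FeatureFlags, NormativeCutoffs, compute_cutoffs, flag_features

__all__ = [
    "PlayerSummary",
    "summarize",
    "classify",
    "assign_categories",
    "classify_cohort",
    "classification_frame",
]

LABELS = ("neglect", "minor_atypicality", "non_neglect")


@dataclass
class PlayerSummary:
    """One player's summary scores, label and (for neglect) category."""

    player_id: str
    group: str
    flags: FeatureFlags
    atypicality: int
    orientation: int
    challenge: int
    severity: float
    atypicality_band: str
    label: str = ""
    neglected_side: str = "none"
    category_code: str | None = None


def _band(atypicality: int) -> str:
    if atypicality == 0:
        return "none"
    if atypicality <= 2:
        return "minor"
    if atypicality <= 4:
        return "moderate"
    return "comprehensive"


def summarize(
    flags: FeatureFlags,
    accuracy_left: float,
    accuracy_right: float,
    group: str = "patient",
) -> PlayerSummary:
    """Aggregate thresholded flags into the four summary scores.

    ``accuracy_left``/``accuracy_right`` are the pooled per-hemispace
    accuracies in percent; severity is 1 − worst/100 (``nan`` accuracy in
    either hemispace yields severity from the other, or 0 if both absent).
    """
    orient = flags.orientation_flags()
    chall = flags.challenge_flags()
    atypicality = sum(1 for v in orient if v != 0) + sum(chall)
    orientation = sum(orient)
    challenge = sum(chall)
    worst = np.nanmin(
        [v for v in (accuracy_left, accuracy_right)]
    ) if not (math.isnan(accuracy_left) and math.isnan(accuracy_right)) else 100.0
    severity = 1.0 - float(worst) / 100.0
    return PlayerSummary(
        player_id=flags.player_id,
        group=group,
        flags=flags,
        atypicality=atypicality,
        orientation=orientation,
        challenge=challenge,
        severity=severity,
        atypicality_band=_band(atypicality),
    )


def classify(summary: PlayerSummary) -> PlayerSummary:
    """Apply the neglect rule; fills ``label`` and ``neglected_side``."""
    o, c = summary.orientation, summary.challenge
    if abs(o) > 1 or (abs(o) > 0 and c > 0):
        summary.label = "neglect"
    elif summary.atypicality > 0:
        summary.label = "minor_atypicality"
    else:
        summary.label = "non_neglect"
    if o > 0:
        summary.neglected_side = "left"
    elif o < 0:
        summary.neglected_side = "right"
    else:
        summary.neglected_side = "none"
    return summary


def assign_categories(
    neglect_summaries: Sequence[PlayerSummary],
    orientation_cutoff: float | None = None,
    challenge_cutoff: float | None = None,
) -> list[str]:
    """Assign L/R + O + C category codes to neglect-labelled players.

    Cut-offs default to the median |orientation| and median challenge over
    the given neglect cohort (both hemispaces pooled); 'O'/'C' are awarded
    at or above the cut-off.  Explicit cut-offs override the medians (e.g.
    to score new players against a frozen cohort).

    Raises
    ------
    ValueError
        If any summary is not labelled neglect, or the cohort is empty.
    """
    if not neglect_summaries:
        raise ValueError("assign_categories requires >= 1 neglect-labelled player")
    for s in neglect_summaries:
        if s.label != "neglect":
            raise ValueError(
                f"player {s.player_id} is labelled {s.label!r}, not neglect"
            )
    if orientation_cutoff is None:
        orientation_cutoff = float(
            np.median([abs(s.orientation) for s in neglect_summaries])
        )
    if challenge_cutoff is None:
        challenge_cutoff = float(np.median([s.challenge for s in neglect_summaries]))
    codes = []
    for s in neglect_summaries:
        code = "L" if s.orientation > 0 else "R"
        if abs(s.orientation) >= orientation_cutoff:
            code += "O"
        if s.challenge >= challenge_cutoff:
            code += "C"
        s.category_code = code
        codes.append(code)
    return codes


def classify_cohort(
    dataset: CohortDataset,
    cutoffs: NormativeCutoffs | None = None,
    features: Sequence[RawFeatureVector] | None = None,
) -> tuple[list[PlayerSummary], NormativeCutoffs]:
    """Run the full pipeline on a cohort: features → fences → flags →
    summary scores → labels → categories.

    When ``cutoffs`` is omitted the fences are derived from this cohort.
    Controls are scored and labelled like patients, but category codes are
    assigned among neglect-labelled *patients* only.
    """
    if features is None:
        features = extract_features_cohort(dataset)
    if cutoffs is None:
        cutoffs = compute_cutoffs(features)
    summaries = []
    for raw in features:
        flags = flag_features(raw, cutoffs)
        s = summarize(flags, raw.accuracy_left, raw.accuracy_right, group=raw.group)
        summaries.append(classify(s))
    neglect_patients = [
        s for s in summaries if s.group == "patient" and s.label == "neglect"
    ]
    if neglect_patients:
        assign_categories(neglect_patients)
    return summaries, cutoffs


def classification_frame(summaries: Sequence[PlayerSummary]) -> pd.DataFrame:
    """Tabulate summaries as ``classification.csv`` (one row per player)."""
    rows = []
    for s in summaries:
        row = {"player_id": s.player_id, "group": s.group}
        for m in ORIENTATION_METRICS + CHALLENGE_METRICS:
            row[f"flag_{m}"] = getattr(s.flags, m)
        row.update(
            atypicality=s.atypicality,
            orientation=s.orientation,
            challenge=s.challenge,
            severity=s.severity,
            band=s.atypicality_band,
            label=s.label,
            side=s.neglected_side,
            category_code=s.category_code,
        )
        rows.append(row)
    return pd.DataFrame(rows)
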