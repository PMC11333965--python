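"""Distribution-free normative model: Tukey fences over two cohorts.

A raw metric value is *atypical* only when it falls strictly outside the
Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) of **both** the control cohort
and the patient cohort — a conjunction that demands the behaviour be
unusual relative to healthy players *and* relative to the clinical
population, suppressing false positives that a single-cohort rule would
admit.  Quartiles use linear interpolation between order statistics.

Flag semantics (the classifier's inputs):

* the six orientation metrics flag ``sign(value)`` when atypical
  (−1 leftward, +1 rightward), else 0; the per-set-size mean metrics
  flag if atypical at ≥ 1 set size, with direction taken from the
  set size with the largest absolute fence exceedance;
* the two challenge metrics flag 1 only when atypical in the harmful
  direction — accuracy falling (below the lower fences) or RT rising
  (above the upper fences) with set size.

Missing metric values are flagged 0 with a warning: the model never
fabricates pathology from absent data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .feature_extraction import (
    CHALLENGE_METRICS,
    MEAN_METRICS,
    ORIENTATION_METRICS,
    RawFeatureVector,
)
from .gameplay_data import ANALYSIS_SET_SIZES

__all__ = [
    "TukeyFence",
    "NormativeCutoffs",
    "FeatureFlags",
    "InsufficientCohortError",
    "tukey_fence",
    "compute_cutoffs",
    "is_atypical",
    "flag_features",
]

#: Default minimum number of finite values required to fit a fence.
MIN_COHORT_SIZE = 4

CUTOFFS_SCHEMA_VERSION = 1

#: Scalar metrics (one fence pair each); mean metrics get one pair per set size.
SCALAR_METRICS = tuple(
    m for m in ORIENTATION_METRICS + CHALLENGE_METRICS if m not in MEAN_METRICS
)


class InsufficientCohortError(ValueError):
    """Too few values to compute quartile fences."""


@dataclass(frozen=True)
class TukeyFence:
    """Quartile fences of one metric within one cohort."""

    cohort: str
    metric_id: str
    q1: float
    q3: float
    set_size: int | None = None
    n: int = 0

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr

    def excludes(self, value: float) -> bool:
        """Strictly outside the fences (boundary values are typical)."""
        return value < self.lower or value > self.upper

    def exceedance(self, value: float) -> float:
        """How far beyond the nearer fence ``value`` lies (0 if inside)."""
        if value < self.lower:
            return self.lower - value
        if value > self.upper:
            return value - self.upper
        return 0.0


def tukey_fence(
    values: Sequence[float] | np.ndarray,
    cohort: str = "",
    metric_id: str = "",
    set_size: int | None = None,
    min_n: int = MIN_COHORT_SIZE,
) -> TukeyFence:
    """Fit Tukey fences to a sample.

    Raises
    ------
    InsufficientCohortError
        With fewer than ``min_n`` finite values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise InsufficientCohortError(
            f"metric {metric_id or '<unnamed>'}: {arr.size} finite values in "
            f"cohort {cohort or '<unnamed>'}, need >= {min_n}"
        )
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return TukeyFence(
        cohort=cohort, metric_id=metric_id, q1=float(q1), q3=float(q3),
        set_size=set_size, n=int(arr.size),
    )


FenceKey = tuple[str, int | None]  # (metric_id, set_size or None)


@dataclass
class NormativeCutoffs:
    """Control and patient fences for every metric the classifier needs."""

    fences: dict[FenceKey, dict[str, TukeyFence]] = field(default_factory=dict)
    min_cohort_size: int = MIN_COHORT_SIZE

    def pair(self, metric_id: str, set_size: int | None = None) -> dict[str, TukeyFence]:
        return self.fences[(metric_id, set_size)]

    def to_json(self, path: str | Path | None = None) -> str:
        entries = []
        for (metric, set_size), pair in sorted(
            self.fences.items(), key=lambda kv: (kv[0][0], kv[0][1] or 0)
        ):
            entry: dict[str, object] = {"metric_id": metric, "set_size": set_size}
            for cohort, f in pair.items():
                entry[cohort] = {
                    "q1": f.q1, "q3": f.q3, "iqr": f.iqr,
                    "lower": f.lower, "upper": f.upper, "n": f.n,
                }
            entries.append(entry)
        payload = {
            "schema_version": CUTOFFS_SCHEMA_VERSION,
            "min_cohort_size": self.min_cohort_size,
            "fences": entries,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NormativeCutoffs":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        if payload.get("schema_version") != CUTOFFS_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported cutoffs schema version {payload.get('schema_version')}"
            )
        cutoffs = cls(min_cohort_size=payload.get("min_cohort_size", MIN_COHORT_SIZE))
        for entry in payload["fences"]:
            metric = entry["metric_id"]
            set_size = entry["set_size"]
            pair = {}
            for cohort in ("controls", "patients"):
                f = entry[cohort]
                pair[cohort] = TukeyFence(
                    cohort=cohort, metric_id=metric, q1=f["q1"], q3=f["q3"],
                    set_size=set_size, n=f.get("n", 0),
                )
            cutoffs.fences[(metric, set_size)] = pair
        return cutoffs


@dataclass(frozen=True)
class FeatureFlags:
    """Thresholded feature values: −1/0/+1 orientation, 0/1 challenge."""

    player_id: str
    accuracy_subtract: int = 0
    rt_subtract: int = 0
    headset_mean: int = 0
    gaze_mean: int = 0
    headset_slope: int = 0
    gaze_slope: int = 0
    accuracy_slope: int = 0
    rt_slope: int = 0

    def __post_init__(self) -> None:
        for m in ORIENTATION_METRICS:
            if getattr(self, m) not in (-1, 0, 1):
                raise ValueError(f"{m} flag must be in {{-1, 0, +1}}")
        for m in CHALLENGE_METRICS:
            if getattr(self, m) not in (0, 1):
                raise ValueError(f"{m} flag must be in {{0, 1}}")

    def orientation_flags(self) -> tuple[int, ...]:
        return tuple(getattr(self, m) for m in ORIENTATION_METRICS)

    def challenge_flags(self) -> tuple[int, ...]:
        return tuple(getattr(self, m) for m in CHALLENGE_METRICS)


def _metric_values(
    features: Iterable[RawFeatureVector], metric: str, set_size: int | None
) -> list[float]:
    out = []
    for f in features:
        v = getattr(f, metric)
        if set_size is not None:
            v = v.get(set_size, math.nan)
        out.append(v)
    return out


def compute_cutoffs(
    cohort_features: Sequence[RawFeatureVector],
    min_cohort_size: int = MIN_COHORT_SIZE,
) -> NormativeCutoffs:
    """Fit control and patient fences for every metric.

    Per-set-size mean metrics get one fence pair per analysis set size.

    Raises
    ------
    InsufficientCohortError
        Listing every metric whose control or patient sample is too small.
    """
    controls = [f for f in cohort_features if f.group == "control"]
    patients = [f for f in cohort_features if f.group == "patient"]
    keys: list[FenceKey] = [(m, None) for m in SCALAR_METRICS]
    keys += [(m, s) for m in MEAN_METRICS for s in ANALYSIS_SET_SIZES]

    cutoffs = NormativeCutoffs(min_cohort_size=min_cohort_size)
    failures = []
    for metric, set_size in keys:
        pair = {}
        try:
            pair["controls"] = tukey_fence(
                _metric_values(controls, metric, set_size),
                "controls", metric, set_size, min_cohort_size,
            )
            pair["patients"] = tukey_fence(
                _metric_values(patients, metric, set_size),
                "patients", metric, set_size, min_cohort_size,
            )
        except InsufficientCohortError as err:
            failures.append(str(err))
            continue
        cutoffs.fences[(metric, set_size)] = pair
    if failures:
        raise InsufficientCohortError("; ".join(failures))
    return cutoffs


def is_atypical(
    value: float, control_fence: TukeyFence, patient_fence: TukeyFence
) -> bool:
    """True iff ``value`` is strictly outside *both* cohorts' fences.

    Missing (non-finite) values are typical by decision, with a warning.
    """
    if not math.isfinite(value):
        warnings.warn(
            f"missing value for {control_fence.metric_id or 'metric'}; treated as typical",
            stacklevel=2,
        )
        return False
    return control_fence.excludes(value) and patient_fence.excludes(value)


def _flag_scalar_orientation(value: float, pair: Mapping[str, TukeyFence]) -> int:
    if not math.isfinite(value):
        return 0
    if is_atypical(value, pair["controls"], pair["patients"]):
        return int(np.sign(value)) or 0
    return 0


def _flag_mean_metric(
    means: Mapping[int, float], metric: str, cutoffs: NormativeCutoffs
) -> int:
    """Atypical at >= 1 set size; direction from the largest exceedance."""
    best_exceed = 0.0
    best_sign = 0
    tie = False
    for s in ANALYSIS_SET_SIZES:
        if (metric, s) not in cutoffs.fences:
            continue
        pair = cutoffs.pair(metric, s)
        v = means.get(s, math.nan)
        if not math.isfinite(v):
            continue
        if not is_atypical(v, pair["controls"], pair["patients"]):
            continue
        exceed = min(
            pair["controls"].exceedance(v), pair["patients"].exceedance(v)
        )
        sign = int(np.sign(v)) or 0
        if exceed > best_exceed:
            best_exceed, best_sign, tie = exceed, sign, False
        elif exceed == best_exceed and best_exceed > 0 and sign != best_sign:
            tie = True
    if tie:
        warnings.warn(
            f"{metric}: atypical set sizes disagree in direction with equal "
            "exceedance; flag set to 0",
            stacklevel=2,
        )
        return 0
    return best_sign


def _flag_challenge(
    value: float, pair: Mapping[str, TukeyFence], harmful: str
) -> int:
    """One-sided challenge flag: only the harmful direction counts."""
    if not math.isfinite(value):
        return 0
    if not is_atypical(value, pair["controls"], pair["patients"]):
        return 0
    if harmful == "low":
        return int(value < pair["controls"].lower and value < pair["patients"].lower)
    return int(value > pair["controls"].upper and value > pair["patients"].upper)


def flag_features(raw: RawFeatureVector, cutoffs: NormativeCutoffs) -> FeatureFlags:
    """Threshold one player's raw metrics against the normative cut-offs."""
    missing = [
        m for m in ("accuracy_subtract", "rt_subtract", "headset_slope",
                    "gaze_slope", "accuracy_slope", "rt_slope")
        if not math.isfinite(getattr(raw, m))
    ]
    missing += [m for m in MEAN_METRICS if not getattr(raw, m)]
    if missing:
        warnings.warn(
            f"player {raw.player_id}: missing metrics {missing} flagged as typical",
            stacklevel=2,
        )
    flags = {
        "accuracy_subtract": _flag_scalar_orientation(
            raw.accuracy_subtract, cutoffs.pair("accuracy_subtract")
        ),
        "rt_subtract": _flag_scalar_orientation(
            raw.rt_subtract, cutoffs.pair("rt_subtract")
        ),
        "headset_slope": _flag_scalar_orientation(
            raw.headset_slope, cutoffs.pair("headset_slope")
        ),
        "gaze_slope": _flag_scalar_orientation(
            raw.gaze_slope, cutoffs.pair("gaze_slope")
        ),
        "headset_mean": _flag_mean_metric(raw.headset_mean, "headset_mean", cutoffs),
        "gaze_mean": _flag_mean_metric(raw.gaze_mean, "gaze_mean", cutoffs),
        "accuracy_slope": _flag_challenge(
            raw.accuracy_slope, cutoffs.pair("accuracy_slope"), harmful="low"
        ),
        "rt_slope": _flag_challenge(
            raw.rt_slope, cutoffs.pair("rt_slope"), harmful="high"
        ),
    }
    return FeatureFlags(player_id=raw.player_id, **flags)
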