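"""Data model and I/O for VR visual-search gameplay.

The game presents a single target among distractors on a sphere of radius
2 m centred on the calibrated head position.  Per trial we store the set
size, the target's angular location, correctness and reaction time; per
game level we store the mean lateral angle of the headset and gaze
raycasts.  The lateral-angle sign convention used throughout the package
is negative = left of the calibrated midline, positive = right.

Coordinate frame: x to the player's right, y up, z straight ahead
(the convention of most game engines).  ``lateral_angle`` is the azimuth
``atan2(x, z)`` and ``vertical_angle`` the elevation ``asin(y / r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SPHERE_RADIUS_M",
    "ANALYSIS_SET_SIZES",
    "TUTORIAL_SET_SIZE",
    "RaycastSample",
    "TrialRecord",
    "LevelOrientationSummary",
    "PlayerSession",
    "CohortDataset",
    "SchemaError",
    "InvalidGeometryError",
    "cartesian_to_spherical",
    "spherical_to_cartesian",
    "hemispace_of",
    "read_cohort",
    "write_cohort",
]

#: Radius of the stimulus sphere in metres (fixed by the game design).
SPHERE_RADIUS_M = 2.0

#: Set sizes entering analysis; the 2-element level is a tutorial.
ANALYSIS_SET_SIZES = (8, 16, 24)
TUTORIAL_SET_SIZE = 2
VALID_SET_SIZES = (2, 8, 16, 24)

#: Relative tolerance for on-sphere validation.
ON_SPHERE_RTOL = 1e-6

RAYCAST_SOURCES = ("headset", "gaze", "controller")
#: Sources that feed classification (controller raycasts never do).
CLASSIFIER_SOURCES = ("headset", "gaze")

TRIALS_COLUMNS = [
    "player_id", "group", "level_index", "half", "set_size",
    "target_lateral_angle", "target_vertical_angle", "correct", "rt_s",
]
ORIENTATION_COLUMNS = [
    "player_id", "source", "set_size", "mean_lateral_angle_deg", "n_frames",
]
FRAMES_COLUMNS = ["player_id", "source", "set_size", "x", "y", "z"]


class SchemaError(ValueError):
    """A CSV table violates the documented column schema."""


class InvalidGeometryError(ValueError):
    """A raycast point is off the sphere or degenerate."""


def cartesian_to_spherical(
    x: float, y: float, z: float, r: float = SPHERE_RADIUS_M
) -> tuple[float, float]:
    """Convert an on-sphere Cartesian point to signed angular coordinates.

    Returns ``(lateral_angle, vertical_angle)`` in degrees.  Lateral angle
    is in (-180, 180], negative to the player's left; vertical angle is in
    [-90, 90], negative below the horizon.

    Raises
    ------
    InvalidGeometryError
        If ``r <= 0`` or the point is off the sphere by more than
        ``ON_SPHERE_RTOL * r``.
    """
    if not (r > 0):
        raise InvalidGeometryError(f"sphere radius must be positive, got {r}")
    norm = math.sqrt(x * x + y * y + z * z)
    if abs(norm - r) > ON_SPHERE_RTOL * r:
        raise InvalidGeometryError(
            f"point ({x}, {y}, {z}) has norm {norm:.9g}, expected radius {r}"
        )
    lateral = math.degrees(math.atan2(x, z))
    vertical = math.degrees(math.asin(max(-1.0, min(1.0, y / norm))))
    return lateral, vertical


def spherical_to_cartesian(
    lateral_angle: float, vertical_angle: float, r: float = SPHERE_RADIUS_M
) -> tuple[float, float, float]:
    """Inverse of :func:`cartesian_to_spherical`."""
    if not (r > 0):
        raise InvalidGeometryError(f"sphere radius must be positive, got {r}")
    lat = math.radians(lateral_angle)
    vert = math.radians(vertical_angle)
    y = r * math.sin(vert)
    horiz = r * math.cos(vert)
    return horiz * math.sin(lat), y, horiz * math.cos(lat)


def hemispace_of(lateral_angle: float) -> str:
    """Hemispace of a signed lateral angle: ``left``, ``right`` or ``midline``."""
    if not math.isfinite(lateral_angle):
        raise ValueError(f"lateral angle must be finite, got {lateral_angle}")
    if lateral_angle < 0:
        return "left"
    if lateral_angle > 0:
        return "right"
    return "midline"


@dataclass(frozen=True)
class RaycastSample:
    """One frame's raycast intersection with the stimulus sphere."""

    source: str
    x: float
    y: float
    z: float
    r: float = SPHERE_RADIUS_M
    lateral_angle: float = field(init=False)
    vertical_angle: float = field(init=False)

    def __post_init__(self) -> None:
        if self.source not in RAYCAST_SOURCES:
            raise ValueError(f"unknown raycast source {self.source!r}")
        lat, vert = cartesian_to_spherical(self.x, self.y, self.z, self.r)
        object.__setattr__(self, "lateral_angle", lat)
        object.__setattr__(self, "vertical_angle", vert)


@dataclass(frozen=True)
class TrialRecord:
    """One search trial: where the target was and how the player did."""

    player_id: str
    level_index: int
    half: int
    set_size: int
    target_lateral_angle: float
    target_vertical_angle: float
    correct: bool
    rt: float

    def __post_init__(self) -> None:
        if self.set_size not in VALID_SET_SIZES:
            raise ValueError(f"set_size must be one of {VALID_SET_SIZES}")
        if not 1 <= self.level_index <= 8:
            raise ValueError("level_index must be 1-8")
        if self.half not in (1, 2):
            raise ValueError("half must be 1 or 2")
        if not (self.rt > 0):
            raise ValueError("rt must be positive")

    @property
    def target_hemispace(self) -> str:
        return hemispace_of(self.target_lateral_angle)

    @property
    def is_analysis_trial(self) -> bool:
        return self.set_size != TUTORIAL_SET_SIZE


@dataclass(frozen=True)
class LevelOrientationSummary:
    """Mean lateral raycast angle for one (player, source, set size)."""

    player_id: str
    source: str
    set_size: int
    mean_lateral_angle: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.source not in RAYCAST_SOURCES:
            raise ValueError(f"unknown raycast source {self.source!r}")
        if self.set_size not in ANALYSIS_SET_SIZES:
            raise ValueError(f"set_size must be one of {ANALYSIS_SET_SIZES}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


class PlayerSession:
    """All gameplay of one player, plus optional clinical covariates.

    Trials and orientation summaries are stored as DataFrames with the
    documented CSV column schemas; tutorial (set size 2) trials are kept
    in storage but excluded by :meth:`analysis_trials`.
    """

    def __init__(
        self,
        player_id: str,
        group: str,
        trials: pd.DataFrame,
        orientation_summaries: pd.DataFrame,
        covariates: Mapping[str, object] | None = None,
        frames: pd.DataFrame | None = None,
    ) -> None:
        if group not in ("control", "patient"):
            raise ValueError(f"group must be 'control' or 'patient', got {group!r}")
        self.player_id = str(player_id)
        self.group = group
        self.trials = trials.reset_index(drop=True)
        self.orientation_summaries = orientation_summaries.reset_index(drop=True)
        self.covariates = dict(covariates) if covariates else {}
        self.frames = frames
        self._validate()

    def _validate(self) -> None:
        for df, cols, name in (
            (self.trials, TRIALS_COLUMNS, "trials"),
            (self.orientation_summaries, ORIENTATION_COLUMNS, "orientation"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing columns {missing}")
        if len(self.trials):
            bad = ~self.trials["set_size"].isin(VALID_SET_SIZES)
            if bad.any():
                raise SchemaError(
                    f"trials with invalid set_size at rows {list(self.trials.index[bad])}"
                )
            if (self.trials["rt_s"] <= 0).any():
                raise SchemaError("trials with non-positive rt_s")
            if (self.trials["player_id"].astype(str) != self.player_id).any():
                raise SchemaError("trial rows carry a foreign player_id")
        if len(self.orientation_summaries):
            osum = self.orientation_summaries
            if (osum["player_id"].astype(str) != self.player_id).any():
                raise SchemaError("orientation rows carry a foreign player_id")
            bad = ~osum["source"].isin(RAYCAST_SOURCES)
            if bad.any():
                raise SchemaError(
                    f"unknown raycast source at rows {list(osum.index[bad])}"
                )
            dup = osum.duplicated(subset=["source", "set_size"])
            if dup.any():
                raise SchemaError(
                    "duplicate (source, set_size) orientation summaries at rows "
                    f"{list(osum.index[dup])}"
                )

    def analysis_trials(self) -> pd.DataFrame:
        """Trials entering analysis (tutorial set size 2 excluded)."""
        return self.trials[self.trials["set_size"] != TUTORIAL_SET_SIZE]

    def orientation_means(self, source: str) -> dict[int, float]:
        """Mapping set_size -> mean lateral angle for one raycast source."""
        sub = self.orientation_summaries
        sub = sub[sub["source"] == source]
        return dict(zip(sub["set_size"].astype(int), sub["mean_lateral_angle_deg"]))

    def mirrored(self) -> "PlayerSession":
        """Left/right mirror of this session (negated lateral angles)."""
        trials = self.trials.copy()
        trials["target_lateral_angle"] = -trials["target_lateral_angle"]
        osum = self.orientation_summaries.copy()
        osum["mean_lateral_angle_deg"] = -osum["mean_lateral_angle_deg"]
        frames = None
        if self.frames is not None:
            frames = self.frames.copy()
            frames["x"] = -frames["x"]
        return PlayerSession(
            self.player_id, self.group, trials, osum, self.covariates, frames
        )


class CohortDataset:
    """A cohort of player sessions; the unit all pipelines operate on."""

    def __init__(self, sessions: Sequence[PlayerSession]) -> None:
        ids = [s.player_id for s in sessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate player ids: {dupes}")
        self.sessions = list(sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def __getitem__(self, player_id: str) -> PlayerSession:
        for s in self.sessions:
            if s.player_id == player_id:
                return s
        raise KeyError(player_id)

    @property
    def controls(self) -> list[PlayerSession]:
        return [s for s in self.sessions if s.group == "control"]

    @property
    def patients(self) -> list[PlayerSession]:
        return [s for s in self.sessions if s.group == "patient"]

    def trials_frame(self) -> pd.DataFrame:
        frames = [s.trials for s in self.sessions]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRIALS_COLUMNS)

    def orientation_frame(self) -> pd.DataFrame:
        frames = [s.orientation_summaries for s in self.sessions]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=ORIENTATION_COLUMNS)

    def frames_frame(self) -> pd.DataFrame | None:
        frames = [s.frames for s in self.sessions if s.frames is not None]
        return pd.concat(frames, ignore_index=True) if frames else None

    def covariates_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            row = {"player_id": s.player_id, **s.covariates}
            rows.append(row)
        return pd.DataFrame(rows)

    def mirrored(self) -> "CohortDataset":
        return CohortDataset([s.mirrored() for s in self.sessions])


def _require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required columns {missing}")


def read_cohort(
    trials_table: str | Path | pd.DataFrame,
    orientation_table: str | Path | pd.DataFrame,
    covariates_table: str | Path | pd.DataFrame | None = None,
    frames_table: str | Path | pd.DataFrame | None = None,
) -> CohortDataset:
    """Assemble a validated :class:`CohortDataset` from CSV tables.

    Tables may be given as paths or as already-loaded DataFrames.  Schema
    violations (missing columns, invalid set sizes or groups, duplicate
    players) raise :class:`SchemaError` naming the offending rows.
    """
    trials = _as_frame(trials_table)
    orientation = _as_frame(orientation_table)
    covariates = _as_frame(covariates_table) if covariates_table is not None else None
    frames = _as_frame(frames_table) if frames_table is not None else None

    _require_columns(trials, TRIALS_COLUMNS, "trials table")
    _require_columns(orientation, ORIENTATION_COLUMNS, "orientation table")
    if frames is not None:
        _require_columns(frames, FRAMES_COLUMNS, "frames table")

    bad = ~trials["set_size"].isin(VALID_SET_SIZES)
    if bad.any():
        raise SchemaError(
            f"invalid set_size values {sorted(trials.loc[bad, 'set_size'].unique())} "
            f"at rows {list(trials.index[bad])}"
        )
    bad = ~trials["group"].isin(["control", "patient"])
    if bad.any():
        raise SchemaError(f"unknown group values at rows {list(trials.index[bad])}")
    groups = trials.groupby("player_id")["group"].nunique()
    if (groups > 1).any():
        raise SchemaError(
            f"players with conflicting group labels: {list(groups.index[groups > 1])}"
        )

    trials = trials.copy()
    trials["player_id"] = trials["player_id"].astype(str)
    trials["correct"] = trials["correct"].astype(int).astype(bool)
    orientation = orientation.copy()
    orientation["player_id"] = orientation["player_id"].astype(str)

    cov_by_player: dict[str, dict] = {}
    if covariates is not None:
        _require_columns(covariates, ["player_id"], "covariates table")
        covariates = covariates.copy()
        covariates["player_id"] = covariates["player_id"].astype(str)
        if covariates["player_id"].duplicated().any():
            raise SchemaError("duplicate player_id rows in covariates table")
        cov_by_player = {
            row["player_id"]: {k: v for k, v in row.items() if k != "player_id"}
            for row in covariates.to_dict("records")
        }

    sessions = []
    for pid, sub in trials.groupby("player_id", sort=True):
        osub = orientation[orientation["player_id"] == pid]
        fsub = None
        if frames is not None:
            fsub = frames[frames["player_id"].astype(str) == pid].reset_index(drop=True)
            if not len(fsub):
                fsub = None
        sessions.append(
            PlayerSession(
                player_id=pid,
                group=sub["group"].iloc[0],
                trials=sub,
                orientation_summaries=osub,
                covariates=cov_by_player.get(pid),
                frames=fsub,
            )
        )
    return CohortDataset(sessions)


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``trials.csv``, ``orientation.csv``, ``covariates.csv``
    (and ``frames.csv`` when frame samples are present); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "orientation": out / "orientation.csv",
        "covariates": out / "covariates.csv",
    }
    dataset.trials_frame().to_csv(paths["trials"], index=False)
    dataset.orientation_frame().to_csv(paths["orientation"], index=False)
    dataset.covariates_frame().to_csv(paths["covariates"], index=False)
    frames = dataset.frames_frame()
    if frames is not None:
        paths["frames"] = out / "frames.csv"
        frames.to_csv(paths["frames"], index=False)
    return paths


def _as_frame(table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(table)
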