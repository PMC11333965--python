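"""Seeded simulator of control-like and patient-like gameplay sessions.

The generator emulates the game design: eight levels (two repetitions of
set sizes 2, 8, 16, 24; set sizes ascending in the first half, descending
in the second), targets balanced between left and right hemispaces within
each level, and per-level headset/gaze orientation summaries.  The
tutorial level (set size 2) is generated and marked but excluded from
analysis downstream.

Generative model per trial:

* correctness ~ Bernoulli(p) with
  ``p = accuracy_base + accuracy_slope_per_item * set_size - deficit(hemispace)``,
  clipped to [0, 1], further corrupted by a lapse process that gives a
  wrong response with probability ``lapse_rate`` regardless of p;
* RT ~ LogNormal centred on
  ``rt_base + rt_slope_per_item * set_size + rt_penalty(hemispace)`` with
  log-scale SD ``rt_noise_log_sd`` (RTs are positive and right-skewed;
  the log-normal is fixed here for reproducibility).

Per (source, set size) the orientation summary mean is normal around
``lateral_bias_mean + lateral_bias_slope * set_size`` with SD
``angle_noise_sd``; when per-frame raycasts are requested the summary is
the empirical mean of the generated frames (scattered around a jittered
centre), so the two surfaces are mutually consistent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gameplay_data import (
    ANALYSIS_SET_SIZES,
    CLASSIFIER_SOURCES,
    SPHERE_RADIUS_M,
    CohortDataset,
    PlayerSession,
)

__all__ = [
    "SimulationProfile",
    "PROFILE_LIBRARY",
    "DEFAULT_PATIENT_MIX",
    "simulate_player",
    "simulate_cohort",
    "save_profiles",
    "load_profiles",
]

#: Level schedule: (level_index, half, set_size); ascending then descending.
LEVEL_SCHEDULE = tuple(
    [(i + 1, 1, s) for i, s in enumerate((2, 8, 16, 24))]
    + [(i + 5, 2, s) for i, s in enumerate((24, 16, 8, 2))]
)

#: Candidate target eccentricities (degrees); drawn per trial, sign by hemispace.
_TARGET_LATERAL_GRID = np.array([12.5, 25.0, 37.5, 50.0, 62.5])
_TARGET_VERTICAL_GRID = np.array([-15.0, 0.0, 15.0])

#: Spatial spread of raw raycast frames around the level mean (degrees).
_FRAME_SPREAD_LATERAL = 18.0
_FRAME_SPREAD_VERTICAL = 9.0


@dataclass(frozen=True)
class SimulationProfile:
    """Effect sizes and noise levels for one simulated player type.

    Probabilities are clipped to [0, 1] at sampling time.  Deficits and
    penalties are expressed per hemispace so a profile is self-contained:
    a left-neglect-like player has ``accuracy_deficit_left > 0`` and/or
    ``rt_penalty_left > 0`` and a rightward ``lateral_bias_mean``.
    """

    accuracy_base: float = 0.95
    accuracy_deficit_left: float = 0.0
    accuracy_deficit_right: float = 0.0
    accuracy_slope_per_item: float = -0.002
    rt_base: float = 1.0
    rt_slope_per_item: float = 0.04
    rt_penalty_left: float = 0.0
    rt_penalty_right: float = 0.0
    lateral_bias_mean: float = 0.0
    lateral_bias_slope: float = 0.0
    angle_noise_sd: float = 1.5
    rt_noise_log_sd: float = 0.22
    lapse_rate: float = 0.01
    trials_per_level: int = 40

    def __post_init__(self) -> None:
        if self.rt_base <= 0:
            raise ValueError("rt_base must be positive")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        for name in ("angle_noise_sd", "rt_noise_log_sd", "lapse_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "SimulationProfile":
        return dataclasses.replace(self, **kwargs)


#: Named presets.  ``control`` is a typical player; ``minor`` shows a single
#: atypical feature; the six remaining presets target the observed neglect
#: categories (side letter + O for strong orientation + C for challenge).
PROFILE_LIBRARY: dict[str, SimulationProfile] = {
    "control": SimulationProfile(),
    "minor": SimulationProfile(rt_penalty_left=0.6),
    "LOC": SimulationProfile(
        accuracy_deficit_left=0.40,
        rt_penalty_left=0.8,
        lateral_bias_mean=25.0,
        accuracy_slope_per_item=-0.012,
    ),
    "LO": SimulationProfile(lateral_bias_mean=25.0, lateral_bias_slope=0.5),
    "LC": SimulationProfile(rt_penalty_left=0.7, rt_slope_per_item=0.16),
    "L": SimulationProfile(lateral_bias_mean=25.0),
    "RO": SimulationProfile(lateral_bias_mean=-25.0, lateral_bias_slope=-0.5),
    "RC": SimulationProfile(
        accuracy_deficit_right=0.30,
        rt_penalty_right=0.7,
        rt_slope_per_item=0.16,
        accuracy_slope_per_item=-0.012,
    ),
}

#: Default patient mix, approximating the label prevalences observed in
#: rehab inpatients (a majority typical, some one-off minor atypicality,
#: just over a quarter neglect split across the six categories).  Each
#: metric's atypical fraction is kept below ~20% of patients so the
#: patient-cohort quartiles stay inside the typical cluster — beyond
#: that the two-cohort conjunction rule stops treating the effect as an
#: outlier, which is a property of the rule, not of the simulator.
DEFAULT_PATIENT_MIX: dict[str, float] = {
    "control": 32 / 51,
    "minor": 5 / 51,
    "LOC": 3 / 51,
    "LO": 2 / 51,
    "LC": 2 / 51,
    "L": 2 / 51,
    "RO": 2 / 51,
    "RC": 3 / 51,
}


def _player_seed(master_seed: int, index: int) -> np.random.Generator:
    # Deterministic per-player stream independent of iteration order.
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def simulate_player(
    profile: SimulationProfile,
    group: str,
    seed: int | np.random.Generator,
    player_id: str | None = None,
    include_frames: bool = False,
    frames_per_level: int = 200,
) -> PlayerSession:
    """Simulate one player's full game under ``profile``.

    All randomness comes from ``seed``; identical (profile, seed) pairs
    yield identical sessions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))
    pid = player_id if player_id is not None else f"sim-{group}"
    n = profile.trials_per_level
    if n < 1:
        raise ValueError("trials_per_level must be >= 1")

    rows = []
    for level_index, half, set_size in LEVEL_SCHEDULE:
        # Balanced hemispaces: half left, half right (odd trial to the
        # larger remainder alternately via rounding).
        n_left = n // 2
        n_right = n - n_left
        sides = np.array([-1.0] * n_left + [1.0] * n_right)
        rng.shuffle(sides)
        lat = sides * rng.choice(_TARGET_LATERAL_GRID, size=n)
        vert = rng.choice(_TARGET_VERTICAL_GRID, size=n)

        deficit = np.where(
            sides < 0, profile.accuracy_deficit_left, profile.accuracy_deficit_right
        )
        p = np.clip(
            profile.accuracy_base
            + profile.accuracy_slope_per_item * set_size
            - deficit,
            0.0,
            1.0,
        )
        correct = rng.random(n) < p
        if profile.lapse_rate > 0:
            lapse = rng.random(n) < profile.lapse_rate
            correct = correct & ~lapse

        penalty = np.where(
            sides < 0, profile.rt_penalty_left, profile.rt_penalty_right
        )
        rt_mean = profile.rt_base + profile.rt_slope_per_item * set_size + penalty
        if profile.rt_noise_log_sd > 0:
            rt = rt_mean * np.exp(
                rng.normal(0.0, profile.rt_noise_log_sd, size=n)
            )
        else:
            rt = rt_mean.copy() if isinstance(rt_mean, np.ndarray) else np.full(n, rt_mean)
        rows.append(
            pd.DataFrame(
                {
                    "player_id": pid,
                    "group": group,
                    "level_index": level_index,
                    "half": half,
                    "set_size": set_size,
                    "target_lateral_angle": lat,
                    "target_vertical_angle": vert,
                    "correct": correct,
                    "rt_s": rt,
                }
            )
        )
    trials = pd.concat(rows, ignore_index=True)

    osum_rows = []
    frame_rows = []
    for source in CLASSIFIER_SOURCES + ("controller",):
        for set_size in ANALYSIS_SET_SIZES:
            centre = (
                profile.lateral_bias_mean + profile.lateral_bias_slope * set_size
            )
            n_frames = 2 * frames_per_level  # two repetitions pooled
            if include_frames:
                # Frame scatter around a per-level centre jitter so the
                # empirical level mean stays ~N(centre, angle_noise_sd).
                jitter = (
                    rng.normal(0.0, profile.angle_noise_sd)
                    if profile.angle_noise_sd > 0
                    else 0.0
                )
                lat_frames = centre + jitter + (
                    rng.normal(0.0, _FRAME_SPREAD_LATERAL, size=n_frames)
                    if profile.angle_noise_sd > 0
                    else np.zeros(n_frames)
                )
                vert_frames = (
                    rng.normal(0.0, _FRAME_SPREAD_VERTICAL, size=n_frames)
                    if profile.angle_noise_sd > 0
                    else np.zeros(n_frames)
                )
                mean_lat = float(np.mean(lat_frames))
                lat_r = np.radians(lat_frames)
                vert_r = np.radians(vert_frames)
                frame_rows.append(
                    pd.DataFrame(
                        {
                            "player_id": pid,
                            "source": source,
                            "set_size": set_size,
                            "x": SPHERE_RADIUS_M * np.cos(vert_r) * np.sin(lat_r),
                            "y": SPHERE_RADIUS_M * np.sin(vert_r),
                            "z": SPHERE_RADIUS_M * np.cos(vert_r) * np.cos(lat_r),
                        }
                    )
                )
            else:
                # angle_noise_sd is the SD of the level *mean*, not of
                # individual frames.
                mean_lat = centre + (
                    rng.normal(0.0, profile.angle_noise_sd)
                    if profile.angle_noise_sd > 0
                    else 0.0
                )
            osum_rows.append(
                {
                    "player_id": pid,
                    "source": source,
                    "set_size": set_size,
                    "mean_lateral_angle_deg": mean_lat,
                    "n_frames": n_frames,
                }
            )
    orientation = pd.DataFrame(osum_rows)
    frames = pd.concat(frame_rows, ignore_index=True) if frame_rows else None
    return PlayerSession(pid, group, trials, orientation, frames=frames)


def simulate_cohort(
    n_controls: int,
    n_patients: int,
    patient_profile_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    control_profile: str | SimulationProfile = "control",
    include_frames: bool = False,
) -> CohortDataset:
    """Simulate a full cohort of controls plus patients.

    Patient profiles are drawn from ``patient_profile_mix`` (preset name
    -> weight; defaults to :data:`DEFAULT_PATIENT_MIX`).  Each player gets
    a seed derived deterministically from the master ``seed`` and their
    index, so cohorts are reproducible independent of iteration order.
    The generating preset name is recorded in each session's covariates
    under ``"preset"`` (and mirrored into ``pen_paper_neglect`` absent
    other covariates: neglect presets 1, others 0).
    """
    if n_controls < 1 or n_patients < 1:
        raise ValueError("need at least one control and one patient")
    mix = dict(patient_profile_mix) if patient_profile_mix is not None else dict(DEFAULT_PATIENT_MIX)
    if not mix:
        raise ValueError("patient_profile_mix must not be empty")
    names = sorted(mix)
    weights = np.array([float(mix[k]) for k in names])
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("mix weights must be >= 0 and sum > 0")
    weights = weights / weights.sum()
    for name in names:
        if name not in PROFILE_LIBRARY:
            raise KeyError(f"unknown profile preset {name!r}")

    if isinstance(control_profile, str):
        control_profile = PROFILE_LIBRARY[control_profile]

    sessions = []
    width = len(str(n_controls + n_patients))
    for i in range(n_controls):
        rng = _player_seed(seed, i)
        pid = f"C{i + 1:0{width}d}"
        s = simulate_player(
            control_profile, "control", rng, player_id=pid,
            include_frames=include_frames,
        )
        s.covariates["preset"] = "control"
        sessions.append(s)
    # Stratified preset allocation: largest-remainder counts matching the
    # mix exactly, in an order shuffled from a derived stream.  Keeping
    # the composition deterministic stops sampling noise from loading one
    # metric with so many atypical patients that the patient-cohort
    # quartiles leave the typical cluster.
    assign_rng = _player_seed(seed, n_controls + n_patients)
    exact = weights * n_patients
    counts = np.floor(exact).astype(int)
    remainder = n_patients - counts.sum()
    if remainder > 0:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:remainder]] += 1
    preset_list = [names[i] for i in range(len(names)) for _ in range(counts[i])]
    assigned = assign_rng.permutation(preset_list)
    neglect_presets = {"LOC", "LO", "LC", "L", "RO", "RC"}
    for j in range(n_patients):
        rng = _player_seed(seed, n_controls + j)
        preset = assigned[j]
        pid = f"P{j + 1:0{width}d}"
        s = simulate_player(
            PROFILE_LIBRARY[preset], "patient", rng, player_id=pid,
            include_frames=include_frames,
        )
        s.covariates["preset"] = preset
        s.covariates["pen_paper_neglect"] = int(preset in neglect_presets)
        sessions.append(s)
    return CohortDataset(sessions)


def save_profiles(path: str | Path, profiles: Mapping[str, SimulationProfile] | None = None) -> None:
    """Serialize profile presets to JSON."""
    profiles = profiles if profiles is not None else PROFILE_LIBRARY
    payload = {name: dataclasses.asdict(p) for name, p in profiles.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_profiles(path: str | Path) -> dict[str, SimulationProfile]:
    payload = json.loads(Path(path).read_text())
    return {name: SimulationProfile(**kw) for name, kw in payload.items()}
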