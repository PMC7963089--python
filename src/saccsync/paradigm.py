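"""Task geometry and trial scheduling for the six-landmark synchronization task.

The paradigm: six landmarks evenly spaced on a circle of 7 degrees of visual
angle around the screen centre.  After a random fixation period the target
steps to the adjacent landmark every SOA (400 or 600 ms) for 12 s, moving
clockwise or counterclockwise.  On most trials a task-irrelevant rectangular
contour (the "inducer") covers three adjacent landmarks.

Conventions fixed here (the task description leaves them open):

* landmark 0 sits at 90 deg (screen-up); indices increase counterclockwise;
* an inducer location is the index of the *middle* of the three covered
  landmarks;
* inducer presence follows deterministic repeating cycles that start with the
  no-inducer trial, so the published trial counts (6 of 7 for monkeys, 66 of
  100 for humans) are reproduced exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "LandmarkLayout",
    "TrialConfig",
    "build_layout",
    "n_target_steps",
    "reward_window",
    "make_schedule",
    "schedule_to_frame",
    "advance_landmark",
]

Direction = Literal["cw", "ccw"]

#: Default number of landmarks and circle radius (degrees of visual angle).
N_LANDMARKS = 6
RADIUS_DEG = 7.0

#: Half-extent of the display in degrees (73 x 46 deg full size).
SCREEN_HALF_EXTENT = (36.5, 23.0)

#: Fixation duration range in ms.
FIXATION_RANGE_MS = (1400.0, 2100.0)

#: Duration of one target sequence in seconds.
SEQUENCE_DURATION_S = 12.0

#: Inducer presence cycles.  The no-inducer trial leads each cycle so that
#: 7-trial and 100-trial blocks reproduce the 6/7 and 66/34 splits exactly.
_INDUCER_CYCLES = {
    "monkey_6_of_7": (False, True, True, True, True, True, True),
    "human_2_of_3": (False, True, True),
    "all": (True,),
    "none": (False,),
}


@dataclass(frozen=True)
class LandmarkLayout:
    """Positions of the landmarks on the display, screen-centred degrees."""

    n_landmarks: int
    radius: float
    positions: np.ndarray  # (n_landmarks, 2), ordered counterclockwise
    landmark_size: float = 1.0

    @property
    def adjacent_distance(self) -> float:
        """Euclidean distance between neighbouring landmarks (chord length)."""
        return float(2.0 * self.radius * math.sin(math.pi / self.n_landmarks))

    def position(self, index: int) -> np.ndarray:
        return self.positions[index % self.n_landmarks]

    def nearest(self, x: float, y: float) -> tuple[int, float]:
        """Nearest landmark index and its distance from (x, y)."""
        d = np.hypot(self.positions[:, 0] - x, self.positions[:, 1] - y)
        k = int(np.argmin(d))
        return k, float(d[k])


def build_layout(
    n_landmarks: int = N_LANDMARKS,
    radius: float = RADIUS_DEG,
    landmark_size: float = 1.0,
) -> LandmarkLayout:
    """Place ``n_landmarks`` evenly on a circle of ``radius`` degrees.

    Landmark 0 is at 90 deg (screen-up); indices increase counterclockwise.
    For six landmarks the chord between neighbours equals the radius
    (regular hexagon), i.e. landmarks 7 deg from the centre are also 7 deg
    apart from each other.
    """
    if n_landmarks < 3:
        raise InvalidParameterError(f"n_landmarks must be >= 3, got {n_landmarks}")
    if radius <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    angles = np.deg2rad(90.0) + 2.0 * np.pi * np.arange(n_landmarks) / n_landmarks
    positions = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return LandmarkLayout(n_landmarks, float(radius), positions, landmark_size)


def n_target_steps(sequence_duration_s: float = SEQUENCE_DURATION_S, soa_ms: float = 400.0) -> int:
    """Number of target steps in one sequence: floor(duration / SOA).

    12 s gives 30 steps at a 400-ms SOA and 20 steps at 600 ms.
    """
    if soa_ms <= 0:
        raise InvalidParameterError(f"soa_ms must be positive, got {soa_ms}")
    if sequence_duration_s < 0:
        raise InvalidParameterError("sequence duration must be non-negative")
    return int(math.floor(sequence_duration_s * 1000.0 / soa_ms))


def reward_window(soa_ms: float, fraction: float = 0.2) -> float:
    """Half-width (ms) of the reward window around target onset.

    Saccades within +/- ``fraction * soa`` of target onset are rewarded in
    the predictive condition: +/-80 ms at 400 ms SOA, +/-120 ms at 600 ms.
    """
    if soa_ms <= 0:
        raise InvalidParameterError(f"soa_ms must be positive, got {soa_ms}")
    if not 0.0 <= fraction < 1.0:
        raise InvalidParameterError(f"fraction must be in [0, 1), got {fraction}")
    return fraction * soa_ms


def advance_landmark(landmark: int, steps: int, direction: Direction, n_landmarks: int = N_LANDMARKS) -> int:
    """Landmark reached after ``steps`` target steps in ``direction``.

    Counterclockwise motion increases the index (layout ordering is CCW).
    ``steps`` may be negative to walk backwards along the motion direction.
    """
    if direction == "ccw":
        return (landmark + steps) % n_landmarks
    if direction == "cw":
        return (landmark - steps) % n_landmarks
    raise InvalidParameterError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class TrialConfig:
    """Schedule of a single trial."""

    trial_id: int
    soa_ms: float
    direction: Direction
    start_landmark: int
    inducer_location: Optional[int]  # middle of the three covered landmarks
    fixation_ms: float
    n_steps: int
    condition: Literal["predictive", "reactive"] = "predictive"
    n_landmarks: int = N_LANDMARKS

    def __post_init__(self) -> None:
        if not FIXATION_RANGE_MS[0] <= self.fixation_ms <= FIXATION_RANGE_MS[1]:
            raise InvalidParameterError(
                f"fixation_ms {self.fixation_ms} outside {FIXATION_RANGE_MS}"
            )
        if self.direction not in ("cw", "ccw"):
            raise InvalidParameterError(f"unknown direction {self.direction!r}")
        if self.condition not in ("predictive", "reactive"):
            raise InvalidParameterError(f"unknown condition {self.condition!r}")

    @property
    def has_inducer(self) -> bool:
        return self.inducer_location is not None

    @property
    def covered_landmarks(self) -> tuple[int, ...]:
        """The three adjacent landmarks covered by the inducer."""
        if self.inducer_location is None:
            return ()
        m = self.inducer_location
        n = self.n_landmarks
        return ((m - 1) % n, m % n, (m + 1) % n)

    def target_landmark(self, step: int) -> int:
        """Target landmark at 1-based ``step`` of the sequence."""
        return advance_landmark(self.start_landmark, step, self.direction, self.n_landmarks)

    def target_onset_ms(self, step: int) -> float:
        """Onset time of the 1-based ``step``-th target, from trial start."""
        return self.fixation_ms + (step - 1) * self.soa_ms


def make_schedule(
    n_trials: int,
    inducer_pattern: str,
    soa_ms: float,
    seed: int,
    *,
    condition: Literal["predictive", "reactive"] = "predictive",
    sequence_duration_s: float = SEQUENCE_DURATION_S,
    inducer_balance: Literal["across", "within"] = "across",
    n_landmarks: int = N_LANDMARKS,
) -> list[TrialConfig]:
    """Build a reproducible session schedule.

    Parameters
    ----------
    n_trials
        Number of trials in the session.
    inducer_pattern
        ``monkey_6_of_7`` (inducer on 6 of every 7 trials), ``human_2_of_3``
        (2 of every 3; 66 of 100 trials), ``all`` or ``none``.  Presence
        follows a deterministic cycle; see module notes.
    soa_ms
        Stimulus onset asynchrony (400 or 600 ms in the task).
    seed
        Seeds fixation durations, motion directions, start landmarks and
        (for ``inducer_balance='across'``) inducer locations.
    inducer_balance
        ``across``: inducer locations drawn uniformly at random per trial.
        ``within``: the six locations cycle deterministically over the
        inducer-present trials, balancing them exactly within the session.
    """
    if n_trials <= 0:
        raise InvalidParameterError(f"n_trials must be positive, got {n_trials}")
    try:
        cycle = _INDUCER_CYCLES[inducer_pattern]
    except KeyError:
        raise InvalidParameterError(
            f"unknown inducer_pattern {inducer_pattern!r}; "
            f"choose from {sorted(_INDUCER_CYCLES)}"
        ) from None
    n_steps = n_target_steps(sequence_duration_s, soa_ms)
    rng = np.random.default_rng(seed)
    balanced_locations = itertools.cycle(range(n_landmarks))

    schedule: list[TrialConfig] = []
    for i in range(n_trials):
        present = cycle[i % len(cycle)]
        if present:
            if inducer_balance == "within":
                loc: Optional[int] = next(balanced_locations)
            elif inducer_balance == "across":
                loc = int(rng.integers(n_landmarks))
            else:
                raise InvalidParameterError(
                    f"unknown inducer_balance {inducer_balance!r}"
                )
        else:
            loc = None
        schedule.append(
            TrialConfig(
                trial_id=i,
                soa_ms=float(soa_ms),
                direction="ccw" if rng.integers(2) else "cw",
                start_landmark=int(rng.integers(n_landmarks)),
                inducer_location=loc,
                fixation_ms=float(rng.uniform(*FIXATION_RANGE_MS)),
                n_steps=n_steps,
                condition=condition,
                n_landmarks=n_landmarks,
            )
        )
    return schedule


def schedule_to_frame(schedule: Sequence[TrialConfig]) -> pd.DataFrame:
    """Tabular view of a schedule (one row per trial)."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in schedule],
            "soa_ms": [t.soa_ms for t in schedule],
            "direction": [t.direction for t in schedule],
            "start_landmark": [t.start_landmark for t in schedule],
            "inducer_loc": [
                np.nan if t.inducer_location is None else t.inducer_location
                for t in schedule
            ],
            "fixation_ms": [t.fixation_ms for t in schedule],
            "n_steps": [t.n_steps for t in schedule],
            "condition": [t.condition for t in schedule],
        }
    )
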