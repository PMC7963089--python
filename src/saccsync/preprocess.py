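"""Saccade detection, timing, exclusion filters and relative-location sorting.

Offline event extraction follows the task's analysis rules:

* saccade initiation is the time angular eye velocity exceeds 50 deg/s;
* a landing is assigned to a landmark if it falls within a 3-degree capture
  radius of it;
* latency is saccade onset minus target onset (negative = predictive);
* the inter-saccadic interval (ISI) is the time between consecutive
  *retained* saccade onsets within a trial;
* predictive sessions drop saccades to the 4th or earlier target, saccades
  to the two-next target or in the opposite direction, and latencies above
  150 ms; reactive sessions drop steps <= 4, saccades landing more than
  3 degrees from the scheduled target, latencies below zero and latencies
  above the SOA (a latency exactly equal to the SOA is retained).

ISIs on inducer trials are additionally labelled by the target's location
relative to the inducer: In1-In3 count the targets from the first covered
landmark entered along the motion direction, Out1-Out3 continue outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .exceptions import (
    InvalidParameterError,
    InvalidTraceError,
    JoinError,
    NoLabelError,
)
from .paradigm import LandmarkLayout, TrialConfig, advance_landmark, build_layout

__all__ = [
    "REL_CATEGORIES",
    "CAPTURE_RADIUS_DEG",
    "VELOCITY_THRESHOLD",
    "compute_velocity",
    "detect_saccades",
    "assign_landmarks",
    "assign_and_time",
    "assign_session",
    "filter_predictive",
    "filter_reactive",
    "recompute_isi",
    "relative_sequence_index",
    "relative_location",
    "label_events",
    "labeled_isis",
    "aggregate",
    "SessionISITable",
]

#: Relative-location categories in cycle order along the motion direction.
REL_CATEGORIES = ("In1", "In2", "In3", "Out1", "Out2", "Out3")

#: Landing capture radius around a landmark (degrees).
CAPTURE_RADIUS_DEG = 3.0

#: Saccade-onset velocity criterion (deg/s).
VELOCITY_THRESHOLD = 50.0

#: Predictive saccades later than this (ms after target onset) are excluded.
PREDICTIVE_MAX_LATENCY_MS = 150.0

#: Saccades to the 4th or earlier target step are excluded everywhere.
MIN_RETAINED_STEP = 5


# ---------------------------------------------------------------------------
# velocity and detection
# ---------------------------------------------------------------------------

def compute_velocity(trace, smooth_samples: int = 5) -> np.ndarray:
    """Angular speed (deg/s) of a gaze trace.

    Central-difference derivative of x and y against time, combined as
    sqrt(vx^2 + vy^2) and boxcar-smoothed over ``smooth_samples`` samples
    (endpoint values replicated).  ``smooth_samples <= 1`` disables
    smoothing.
    """
    t = np.asarray(trace.t, dtype=float)
    if len(t) < 3:
        raise InvalidTraceError("need at least 3 samples to compute velocity")
    vx = np.gradient(np.asarray(trace.x, dtype=float), t) * 1000.0
    vy = np.gradient(np.asarray(trace.y, dtype=float), t) * 1000.0
    speed = np.hypot(vx, vy)
    if smooth_samples > 1:
        speed = uniform_filter1d(speed, size=int(smooth_samples), mode="nearest")
    return speed


def detect_saccades(
    trace,
    threshold: float = VELOCITY_THRESHOLD,
    refractory_ms: float = 50.0,
    smooth_samples: int = 5,
) -> pd.DataFrame:
    """Detect saccade onsets and landings from a gaze trace.

    An onset is recorded at every upward crossing of the velocity
    ``threshold`` separated from the previous onset by at least
    ``refractory_ms``; the onset time is linearly interpolated between the
    samples bracketing the crossing.  The landing is the eye position at the
    first sub-threshold sample after the crossing.
    """
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be positive, got {threshold}")
    v = compute_velocity(trace, smooth_samples=smooth_samples)
    t = np.asarray(trace.t, dtype=float)
    x = np.asarray(trace.x, dtype=float)
    y = np.asarray(trace.y, dtype=float)

    above = v > threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])

    onsets, landings = [], []
    last_onset = -np.inf
    for i in rising:
        if i == 0:
            t_on = t[0]
        else:
            # linear interpolation of the threshold crossing time
            dv = v[i] - v[i - 1]
            frac = (threshold - v[i - 1]) / dv if dv > 0 else 1.0
            t_on = t[i - 1] + frac * (t[i] - t[i - 1])
        if t_on - last_onset < refractory_ms:
            continue
        last_onset = t_on
        below = np.flatnonzero(~above[i:])
        j = i + below[0] if len(below) else len(t) - 1
        onsets.append(t_on)
        landings.append((x[j], y[j]))

    landings = np.asarray(landings, dtype=float).reshape(-1, 2)
    return pd.DataFrame(
        {
            "onset_ms": np.asarray(onsets, dtype=float),
            "landing_x_deg": landings[:, 0],
            "landing_y_deg": landings[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# landmark assignment and timing
# ---------------------------------------------------------------------------

def assign_landmarks(
    events: pd.DataFrame,
    layout: Optional[LandmarkLayout] = None,
    capture_radius: float = CAPTURE_RADIUS_DEG,
) -> pd.DataFrame:
    """Add an ``assigned_landmark`` column (NaN if no landmark is captured).

    A landing is assigned to the nearest landmark if and only if it lies
    within ``capture_radius`` degrees of it.
    """
    if layout is None:
        layout = build_layout()
    out = events.copy()
    xy = out[["landing_x_deg", "landing_y_deg"]].to_numpy(dtype=float)
    d = np.hypot(
        xy[:, 0:1] - layout.positions[:, 0], xy[:, 1:2] - layout.positions[:, 1]
    )
    nearest = d.argmin(axis=1).astype(float)
    nearest[d.min(axis=1) > capture_radius] = np.nan
    out["assigned_landmark"] = nearest
    return out


def assign_and_time(
    events: pd.DataFrame,
    trial: TrialConfig,
    layout: Optional[LandmarkLayout] = None,
    capture_radius: float = CAPTURE_RADIUS_DEG,
) -> pd.DataFrame:
    """Attach step, target, latency and ISI to detected events of one trial.

    Each onset is matched to the target step minimising the absolute
    latency, preferring (among the neighbouring steps) one whose scheduled
    landmark equals the assigned landing landmark.  Latency is the onset
    time minus that step's target onset; ISIs are differences of
    consecutive onsets.
    """
    ev = assign_landmarks(events, layout, capture_radius).sort_values("onset_ms")
    ev = ev.reset_index(drop=True)

    steps = np.empty(len(ev), dtype=int)
    latencies = np.empty(len(ev))
    for i, row in ev.iterrows():
        onset = row["onset_ms"]
        k0 = int(round((onset - trial.fixation_ms) / trial.soa_ms)) + 1
        candidates = [k for k in (k0 - 1, k0, k0 + 1) if 1 <= k <= trial.n_steps]
        if not candidates:
            candidates = [min(max(k0, 1), trial.n_steps)]
        lat = {k: onset - trial.target_onset_ms(k) for k in candidates}
        matching = [
            k
            for k in candidates
            if not np.isnan(row["assigned_landmark"])
            and trial.target_landmark(k) == int(row["assigned_landmark"])
        ]
        pool = matching if matching else candidates
        k_best = min(pool, key=lambda k: abs(lat[k]))
        steps[i] = k_best
        latencies[i] = lat[k_best]

    ev["trial_id"] = trial.trial_id
    ev["step"] = steps
    ev["target_landmark"] = [trial.target_landmark(int(k)) for k in steps]
    ev["direction"] = trial.direction
    ev["soa_ms"] = trial.soa_ms
    ev["inducer_loc"] = (
        np.nan if trial.inducer_location is None else float(trial.inducer_location)
    )
    ev["latency_ms"] = latencies
    onset = ev["onset_ms"].to_numpy()
    ev["isi_ms"] = np.concatenate([[np.nan], np.diff(onset)])
    return ev


def assign_session(
    events_by_trial: dict[int, pd.DataFrame],
    schedule: Sequence[TrialConfig],
    layout: Optional[LandmarkLayout] = None,
    capture_radius: float = CAPTURE_RADIUS_DEG,
) -> pd.DataFrame:
    """Apply :func:`assign_and_time` across a session keyed by trial id."""
    by_id = {t.trial_id: t for t in schedule}
    frames = []
    for trial_id, ev in events_by_trial.items():
        if trial_id not in by_id:
            raise JoinError(f"trial_id {trial_id} not present in the schedule")
        frames.append(assign_and_time(ev, by_id[trial_id], layout, capture_radius))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

def _require_columns(events: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise InvalidParameterError(f"event table lacks columns {missing}")


def filter_predictive(events: pd.DataFrame) -> pd.DataFrame:
    """Exclusion rules for predictive (synchronized) sessions.

    Removes saccades to the 4th or earlier target step, saccades directed
    to the two-next target or in the opposite direction (judged from the
    assigned landing landmark relative to the scheduled target), and
    saccades generated later than 150 ms after target onset.  Unassigned
    landings do not trigger the direction rules.  Idempotent.
    """
    if len(events) == 0:
        return events.copy()
    _require_columns(
        events, ["step", "latency_ms", "assigned_landmark", "target_landmark", "direction"]
    )
    n = events["target_landmark"].to_numpy(dtype=int)
    assigned = events["assigned_landmark"].to_numpy(dtype=float)
    direction = events["direction"].to_numpy()

    two_next = np.array(
        [advance_landmark(int(tgt), 1, d) for tgt, d in zip(n, direction)]
    )
    opposite = np.array(
        [advance_landmark(int(tgt), -2, d) for tgt, d in zip(n, direction)]
    )
    has_assign = ~np.isnan(assigned)
    bad_dir = has_assign & ((assigned == two_next) | (assigned == opposite))

    keep = (
        (events["step"].to_numpy() >= MIN_RETAINED_STEP)
        & (events["latency_ms"].to_numpy() <= PREDICTIVE_MAX_LATENCY_MS)
        & ~bad_dir
    )
    return events.loc[keep].copy()


def filter_reactive(events: pd.DataFrame, soa_ms: Optional[float] = None) -> pd.DataFrame:
    """Exclusion rules for reactive sessions.

    Removes saccades to the 4th or earlier step, saccades terminating more
    than 3 degrees from the scheduled target (i.e. not assigned to it),
    saccades generated before target onset, and latencies above the SOA
    (latency exactly equal to the SOA is retained).  Idempotent.
    """
    if len(events) == 0:
        return events.copy()
    _require_columns(events, ["step", "latency_ms", "assigned_landmark", "target_landmark"])
    if soa_ms is None:
        _require_columns(events, ["soa_ms"])
        soa = events["soa_ms"].to_numpy(dtype=float)
    else:
        soa = float(soa_ms)
    assigned = events["assigned_landmark"].to_numpy(dtype=float)
    on_target = ~np.isnan(assigned) & (
        assigned == events["target_landmark"].to_numpy(dtype=float)
    )
    lat = events["latency_ms"].to_numpy(dtype=float)
    keep = (
        (events["step"].to_numpy() >= MIN_RETAINED_STEP)
        & on_target
        & (lat >= 0.0)
        & (lat <= soa)
    )
    return events.loc[keep].copy()


def recompute_isi(events: pd.DataFrame) -> pd.DataFrame:
    """Recompute ISIs between consecutive retained onsets within each trial."""
    out = events.sort_values(["trial_id", "onset_ms"]).reset_index(drop=True)
    out["isi_ms"] = out.groupby("trial_id")["onset_ms"].diff()
    return out


# ---------------------------------------------------------------------------
# relative-location sorting
# ---------------------------------------------------------------------------

def relative_sequence_index(
    target: int, inducer_loc: int, direction: str, n_landmarks: int = 6
) -> int:
    """Index 0..5 of ``target`` in the relative cycle In1..In3, Out1..Out3.

    The inducer covers the three adjacent landmarks centred on
    ``inducer_loc``; In1 is the first covered landmark entered along the
    motion direction.  The mapping is equivariant under joint rotation of
    target and inducer, and direction reversal reflects the cycle.
    """
    if direction == "ccw":
        return (target - (inducer_loc - 1)) % n_landmarks
    if direction == "cw":
        return ((inducer_loc + 1) - target) % n_landmarks
    raise InvalidParameterError(f"unknown direction {direction!r}")


def relative_location(
    target: int, inducer_loc: Optional[int], direction: str, n_landmarks: int = 6
) -> str:
    """Relative-location label of ``target`` (raises on inducer-free trials)."""
    if inducer_loc is None:
        raise NoLabelError("trial has no inducer; relative location undefined")
    return REL_CATEGORIES[
        relative_sequence_index(target, int(inducer_loc), direction, n_landmarks)
    ]


def label_events(events: pd.DataFrame) -> pd.DataFrame:
    """Add a ``relative_label`` column (None on inducer-free trials)."""
    out = events.copy()
    labels: list[Optional[str]] = []
    for tgt, loc, d in zip(
        out["target_landmark"], out["inducer_loc"], out["direction"]
    ):
        if pd.isna(loc):
            labels.append(None)
        else:
            labels.append(relative_location(int(tgt), int(loc), d))
    out["relative_label"] = labels
    return out


def labeled_isis(events: pd.DataFrame, require_inducer: bool = True) -> pd.DataFrame:
    """Tidy table of labelled ISIs for the inducer statistics.

    Keeps rows with a defined ISI; when ``require_inducer`` drops rows from
    inducer-free trials.  Columns: isi_ms, abs_location, direction,
    relative_label, soa_ms.
    """
    ev = events if "relative_label" in events.columns else label_events(events)
    mask = ev["isi_ms"].notna()
    if require_inducer:
        mask &= ev["relative_label"].notna()
    ev = ev.loc[mask]
    return pd.DataFrame(
        {
            "isi_ms": ev["isi_ms"].to_numpy(dtype=float),
            "abs_location": ev["target_landmark"].to_numpy(dtype=int),
            "direction": ev["direction"].to_numpy(),
            "relative_label": ev["relative_label"].to_numpy(),
            "soa_ms": ev["soa_ms"].to_numpy(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionISITable:
    """Labelled ISIs of one session with per-category summaries.

    ``category_stats`` covers the six relative-location categories
    (count, mean, SD; zero-count categories carry NaN means and are refused
    by downstream statistics).  ``location_direction_stats`` summarises by
    absolute target location x motion direction over all rows.
    """

    rows: pd.DataFrame
    category_stats: pd.DataFrame
    location_direction_stats: pd.DataFrame

    @property
    def category_means(self) -> dict[str, float]:
        return dict(
            zip(self.category_stats["category"], self.category_stats["mean_ms"])
        )

    @property
    def counts(self) -> dict[str, int]:
        return dict(zip(self.category_stats["category"], self.category_stats["n"]))


def aggregate(labeled: pd.DataFrame) -> SessionISITable:
    """Summarise a labelled ISI table per relative category.

    Category counts always sum to the number of labelled rows; a category
    with no rows is kept with n = 0 and NaN mean/SD.
    """
    if len(labeled) == 0:
        raise InvalidParameterError("labelled ISI table is empty")
    rows = labeled.reset_index(drop=True)

    with_label = rows[rows["relative_label"].notna()]
    stats = []
    for cat in REL_CATEGORIES:
        vals = with_label.loc[with_label["relative_label"] == cat, "isi_ms"]
        stats.append(
            {
                "category": cat,
                "n": int(len(vals)),
                "mean_ms": float(vals.mean()) if len(vals) else np.nan,
                "sd_ms": float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
            }
        )
    category_stats = pd.DataFrame(stats)

    loc_dir = (
        rows.groupby(["abs_location", "direction"])["isi_ms"]
        .agg(n="count", mean_ms="mean", sd_ms="std")
        .reset_index()
    )
    return SessionISITable(rows, category_stats, loc_dir)
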