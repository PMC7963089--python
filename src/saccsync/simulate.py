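"""Synthetic sessions of the six-landmark synchronization task.

The generator produces saccade-event tables (and optionally continuous gaze
traces) with the statistical structure the downstream analysis assumes.  The
latency of the saccade to each target step is modelled as

    latency = base + abs_location_offset[target]
            + direction_offset (clockwise trials)
            + boundary / inside-outside terms (inducer trials)
            + phase noise (stationary, SD = latency_sd)

The inter-saccadic interval is the difference of consecutive onsets, so a
one-shot latency delay at relative location k lengthens the interval ending
at k by the delay and shortens the following interval by the same amount in
expectation.

The stochastic part models the slow wander of saccade phase around the
target stream: a boxcar moving average of i.i.d. Gaussian innovations over
``phase_drift_window`` steps.  The window (default 32, longer than any
trial) gives latencies a triangular autocovariance whose second difference
vanishes, so the within-trial ISIs are exactly i.i.d. Gaussian - the
exchangeability that the label-shuffling permutation null assumes.  Setting
``phase_drift_window = 1`` recovers fully resynchronizing i.i.d. latency
noise, under which ISIs are MA(1) with lag-1 autocorrelation -1/2 and the
shuffle test is no longer calibrated (see the methods notes).

Named phenotypes emulate the three qualitative patterns of temporal grouping
observed in the task:

``NULL``
    no inducer effect (calibration baseline);
``BOUNDARY_DELAY_3``
    saccades delayed just before the inducer boundary is crossed
    (relative location 3, inside and outside alike);
``MIDDLE_DELAY_2``
    delay at the middle relative location (2);
``INSIDE_SLOW``
    every interval inside the inducer longer, every interval outside
    shorter, realised as a periodic triangular latency profile over the
    relative-location cycle (peak ``io_offset`` at the last inside target).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidEventError, InvalidParameterError, InvalidTraceError
from .paradigm import (
    N_LANDMARKS,
    SCREEN_HALF_EXTENT,
    LandmarkLayout,
    TrialConfig,
    build_layout,
)
from .preprocess import REL_CATEGORIES, relative_sequence_index

__all__ = [
    "PhenotypeParams",
    "EyeTrace",
    "PHENOTYPES",
    "get_phenotype",
    "sample_session",
    "render_trace",
    "SACCADE_DURATION_MS",
    "MIN_INTER_ONSET_MS",
]

#: Duration of the rendered (raised-cosine) saccadic displacement.
SACCADE_DURATION_MS = 30.0

#: Events closer than this cannot be rendered as separate saccades.
MIN_INTER_ONSET_MS = 40.0

#: Latency multipliers over the relative-location cycle In1..In3, Out1..Out3
#: realising the inside-slow phenotype: intervals inside the inducer lengthen
#: by io_offset/3 each, intervals outside shorten by the same amount.
_IO_PROFILE = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 0.0]) / 3.0


@dataclass(frozen=True)
class PhenotypeParams:
    """Latency-generating model of one simulated subject.

    Parameters
    ----------
    base_latency_ms
        Mean latency relative to target onset; ~0 for predictive
        (synchronized) behaviour, > 100 for reactive behaviour.
    latency_sd_ms
        Stationary (marginal) SD of the Gaussian phase noise (> 0).
    phase_drift_window
        Number of steps over which the phase noise drifts (boxcar
        moving-average window, >= 1).  The default 32 exceeds the longest
        trial (30 steps), making within-trial ISIs exactly i.i.d.;
        1 gives independent per-step latencies instead.
    abs_location_offsets
        Per-landmark latency offsets (ms), modelling grouping by absolute
        target location on the screen.
    direction_offset_ms
        Added on clockwise trials, modelling direction-dependent timing.
    boundary_delay
        ``(k, delay_ms)`` with k in {1, 2, 3}: one-shot delay of the saccade
        at relative location k after the inducer boundary (both In_k and
        Out_k, as the boundary is crossed twice per lap).
    io_offset_ms
        Peak of the triangular inside-slow latency profile (ms); each
        interval inside the inducer lengthens by one third of this value.
    landing_scatter_deg
        Isotropic Gaussian scatter of saccade endpoints around the target
        landmark.
    seed
        Default seed used by :func:`sample_session` when none is passed.
    """

    base_latency_ms: float = 0.0
    latency_sd_ms: float = 30.0
    phase_drift_window: int = 32
    abs_location_offsets: tuple[float, ...] = (0.0,) * N_LANDMARKS
    direction_offset_ms: float = 0.0
    boundary_delay: Optional[tuple[int, float]] = None
    io_offset_ms: float = 0.0
    landing_scatter_deg: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.latency_sd_ms <= 0:
            raise InvalidParameterError(
                f"latency_sd_ms must be > 0, got {self.latency_sd_ms}"
            )
        if self.phase_drift_window < 1:
            raise InvalidParameterError(
                f"phase_drift_window must be >= 1, got {self.phase_drift_window}"
            )
        if self.boundary_delay is not None:
            k, _ = self.boundary_delay
            if k not in (1, 2, 3):
                raise InvalidParameterError(
                    f"boundary_delay index must be in {{1,2,3}}, got {k}"
                )
        if self.landing_scatter_deg < 0:
            raise InvalidParameterError("landing_scatter_deg must be >= 0")


PHENOTYPES: dict[str, PhenotypeParams] = {
    "NULL": PhenotypeParams(),
    "BOUNDARY_DELAY_3": PhenotypeParams(boundary_delay=(3, 50.0)),
    "MIDDLE_DELAY_2": PhenotypeParams(boundary_delay=(2, 50.0)),
    "INSIDE_SLOW": PhenotypeParams(io_offset_ms=50.0),
}


def get_phenotype(name: str, **overrides) -> PhenotypeParams:
    """Named phenotype preset, optionally with field overrides."""
    try:
        base = PHENOTYPES[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown phenotype {name!r}; choose from {sorted(PHENOTYPES)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class EyeTrace:
    """Uniformly sampled gaze trace (time in ms, position in degrees)."""

    sample_rate: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t, x, y = np.asarray(self.t), np.asarray(self.x), np.asarray(self.y)
        if not (len(t) == len(x) == len(y)):
            raise InvalidTraceError("t, x, y must have equal length")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.sample_rate, rtol=1e-6):
                raise InvalidTraceError(
                    "t must increase uniformly at 1000/sample_rate ms steps"
                )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidTraceError("positions must be finite")
        if np.any(np.abs(x) > SCREEN_HALF_EXTENT[0]) or np.any(np.abs(y) > SCREEN_HALF_EXTENT[1]):
            raise InvalidTraceError("positions exceed the screen extent")

    def __len__(self) -> int:
        return len(self.t)


def _step_latencies(
    trial: TrialConfig, phenotype: PhenotypeParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Target landmarks and latencies for every step of one trial."""
    steps = np.arange(1, trial.n_steps + 1)
    sign = 1 if trial.direction == "ccw" else -1
    targets = (trial.start_landmark + sign * steps) % trial.n_landmarks

    offsets = np.asarray(phenotype.abs_location_offsets, dtype=float)
    if len(offsets) != trial.n_landmarks:
        raise InvalidParameterError(
            "abs_location_offsets length must equal n_landmarks"
        )
    lat = phenotype.base_latency_ms + offsets[targets]
    if trial.direction == "cw":
        lat = lat + phenotype.direction_offset_ms
    if trial.inducer_location is not None:
        rel = np.array(
            [
                relative_sequence_index(
                    int(tgt), trial.inducer_location, trial.direction, trial.n_landmarks
                )
                for tgt in targets
            ]
        )
        if phenotype.boundary_delay is not None:
            k, delay = phenotype.boundary_delay
            lat = lat + np.where(rel % 3 == k - 1, delay, 0.0)
        if phenotype.io_offset_ms:
            lat = lat + phenotype.io_offset_ms * _IO_PROFILE[rel]
    window = int(phenotype.phase_drift_window)
    if window == 1:
        noise = rng.normal(0.0, phenotype.latency_sd_ms, size=trial.n_steps)
    else:
        # boxcar MA of innovations: stationary SD latency_sd, i.i.d. ISIs
        # within the window (triangular autocovariance).
        innovations = rng.normal(
            0.0,
            phenotype.latency_sd_ms / np.sqrt(window),
            size=trial.n_steps + window - 1,
        )
        noise = np.convolve(innovations, np.ones(window), mode="valid")
    return targets, lat + noise


def sample_session(
    schedule: Sequence[TrialConfig],
    phenotype: PhenotypeParams,
    *,
    layout: Optional[LandmarkLayout] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate the saccade-event table of a whole session.

    One row per target step; onsets are target onset plus the phenotype's
    latency, inter-saccadic intervals (``isi_ms``) are differences of
    consecutive onsets within a trial (NaN for the first step).  Identical
    seeds give identical tables.  Nothing is clamped: pathological
    parameters yield pathological but structurally valid tables.
    """
    if not schedule:
        raise InvalidParameterError("schedule must be non-empty")
    if layout is None:
        layout = build_layout(schedule[0].n_landmarks)
    if seed is None:
        seed = phenotype.seed
    rng = np.random.default_rng(seed)

    frames = []
    for trial in schedule:
        targets, lat = _step_latencies(trial, phenotype, rng)
        steps = np.arange(1, trial.n_steps + 1)
        onset = trial.fixation_ms + (steps - 1) * trial.soa_ms + lat
        isi = np.concatenate([[np.nan], np.diff(onset)])
        landing = layout.positions[targets]
        if phenotype.landing_scatter_deg > 0:
            landing = landing + rng.normal(
                0.0, phenotype.landing_scatter_deg, size=landing.shape
            )
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial.trial_id,
                    "step": steps,
                    "target_landmark": targets,
                    "direction": trial.direction,
                    "soa_ms": trial.soa_ms,
                    "inducer_loc": (
                        np.nan if trial.inducer_location is None else float(trial.inducer_location)
                    ),
                    "onset_ms": onset,
                    "landing_x_deg": landing[:, 0],
                    "landing_y_deg": landing[:, 1],
                    "latency_ms": lat,
                    "isi_ms": isi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_trace(
    trial: TrialConfig,
    events: pd.DataFrame,
    sample_rate: float = 1000.0,
    *,
    layout: Optional[LandmarkLayout] = None,
) -> EyeTrace:
    """Render a trial's events as a continuous gaze trace.

    The eye is stationary at each landmark and moves along a raised-cosine
    position ramp of 30 ms at each saccade onset.  The ramp's peak angular
    velocity for a 7-degree displacement is ~367 deg/s, comfortably above
    the 50 deg/s detection threshold.  No noise or blinks are added.
    """
    if sample_rate < 250:
        raise InvalidParameterError(f"sample_rate must be >= 250 Hz, got {sample_rate}")
    if layout is None:
        layout = build_layout(trial.n_landmarks)

    ev = events.sort_values("onset_ms") if len(events) else events
    onsets = ev["onset_ms"].to_numpy(dtype=float) if len(ev) else np.empty(0)
    if len(onsets) >= 2 and np.any(np.diff(onsets) < MIN_INTER_ONSET_MS):
        raise InvalidEventError(
            f"inter-onset interval below {MIN_INTER_ONSET_MS} ms cannot be rendered"
        )

    dt = 1000.0 / sample_rate
    t_end = trial.fixation_ms + trial.n_steps * trial.soa_ms + 300.0
    if len(onsets):
        t_end = max(t_end, onsets[-1] + SACCADE_DURATION_MS + 100.0)
    t = np.arange(0.0, t_end, dt)

    pos = np.empty((len(t), 2))
    current = layout.position(trial.start_landmark).astype(float)
    pos[:] = current
    for _, row in ev.iterrows():
        target = np.array([row["landing_x_deg"], row["landing_y_deg"]], dtype=float)
        i0 = int(np.searchsorted(t, row["onset_ms"]))
        i1 = int(np.searchsorted(t, row["onset_ms"] + SACCADE_DURATION_MS))
        ramp_t = t[i0:i1] - row["onset_ms"]
        frac = 0.5 * (1.0 - np.cos(np.pi * ramp_t / SACCADE_DURATION_MS))
        pos[i0:i1] = current + frac[:, None] * (target - current)
        pos[i1:] = target
        current = target
    return EyeTrace(sample_rate=float(sample_rate), t=t, x=pos[:, 0], y=pos[:, 1])
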