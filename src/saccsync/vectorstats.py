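"""Resultant-vector statistics for inducer effects, with permutation nulls.

Two bespoke statistics quantify how the inducer modulates inter-saccadic
intervals, operating on the six relative-location category means:

*sequence statistic* — the six mean-ISI vectors are arranged circularly at
equal intervals: In_k and Out_k share direction theta_k, with theta_1,
theta_2, theta_3 spaced 120 degrees apart (theta_1 = 90, theta_2 = 210,
theta_3 = 330 degrees).  Because the arrangement is balanced, a constant
added to every mean cancels; the resultant's length measures how strongly
ISI depends on the sequence position after the inducer boundary and its
angle points at the delayed position.

*inside-outside statistic* — the In means point at 0 degrees and the Out
means at 180 degrees; the signed sum (sum of In means minus sum of Out
means) is positive when saccades are slower inside the inducer.

Significance is assessed against a permutation null built by shuffling the
relative-location labels over individual ISIs (category means recomputed
per shuffle): the sequence statistic is significant above the 95th
percentile of null lengths (one-sided), the inside-outside statistic when
it falls outside the middle 95% of the signed null (two-sided).  Ties at a
threshold count as not significant.  p-values use the standard
bias-avoiding estimate (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidParameterError,
    MissingCategoryError,
    UndefinedOrientationError,
)
from .preprocess import REL_CATEGORIES

__all__ = [
    "SEQ_ANGLES_DEG",
    "VectorStatResult",
    "PermutationResult",
    "sequence_resultant",
    "io_resultant",
    "permutation_test",
    "classify_orientation",
]

#: Direction (math convention, degrees CCW from +x) shared by In_k and Out_k.
SEQ_ANGLES_DEG = {1: 90.0, 2: 210.0, 3: 330.0}

_SEQ_UNIT = np.exp(1j * np.deg2rad([SEQ_ANGLES_DEG[k] for k in (1, 2, 3)]))
#: Complex unit vector per category In1..In3, Out1..Out3.
_CAT_UNIT = np.concatenate([_SEQ_UNIT, _SEQ_UNIT])
#: Signs for the inside-outside alignment (In at 0 deg, Out at 180 deg).
_IO_SIGN = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])

#: Categories with fewer ISIs than this trigger a warning.
MIN_CATEGORY_N = 5


def _means_vector(category_means: Mapping[str, float]) -> np.ndarray:
    try:
        m = np.array([float(category_means[c]) for c in REL_CATEGORIES])
    except KeyError as err:
        raise MissingCategoryError(f"category mean missing: {err}") from None
    if np.any(~np.isfinite(m)):
        bad = [c for c, v in zip(REL_CATEGORIES, m) if not np.isfinite(v)]
        raise MissingCategoryError(f"undefined category means: {bad}")
    return m


@dataclass(frozen=True)
class VectorStatResult:
    """Resultant of the circular category-mean vector sum."""

    resultant_length: float
    resultant_angle_deg: float
    category_vectors: dict[str, tuple[float, float]]
    mode: str = "sequence"


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic with its label-shuffling null summary."""

    mode: str
    observed: Union[VectorStatResult, float]
    statistic: float
    null_stats: np.ndarray
    threshold: Union[float, tuple[float, float]]
    p_value: float
    significant: bool
    n_perm: int
    seed: Optional[int]

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "mode": self.mode,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": bool(self.significant),
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        if self.mode == "sequence":
            d["threshold_upper_95"] = self.threshold
            d["resultant_angle_deg"] = self.observed.resultant_angle_deg
        else:
            d["threshold_lower_2p5"], d["threshold_upper_97p5"] = self.threshold
        if include_null:
            d["null_stats"] = np.asarray(self.null_stats).tolist()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(**kwargs), sort_keys=True)


def sequence_resultant(category_means: Mapping[str, float]) -> VectorStatResult:
    """Vector sum of the six category means in the three sequence directions.

    Equal means cancel exactly (balanced arrangement); adding a constant to
    all six means leaves the resultant unchanged.
    """
    m = _means_vector(category_means)
    vecs = m * _CAT_UNIT
    z = vecs.sum()
    return VectorStatResult(
        resultant_length=float(abs(z)),
        resultant_angle_deg=float(np.rad2deg(np.angle(z)) % 360.0),
        category_vectors={
            c: (float(v.real), float(v.imag)) for c, v in zip(REL_CATEGORIES, vecs)
        },
        mode="sequence",
    )


def io_resultant(category_means: Mapping[str, float]) -> float:
    """Signed inside-outside statistic: sum(In means) - sum(Out means).

    Positive values mean longer intervals (slower saccades) inside the
    inducer; swapping the In/Out labels flips the sign.
    """
    m = _means_vector(category_means)
    return float((m * _IO_SIGN).sum())


def classify_orientation(result: VectorStatResult) -> int:
    """Sequence location (1-3) whose direction is nearest the resultant.

    Raises for a zero-length resultant; an exact tie resolves to the lower
    index with a warning.
    """
    if result.resultant_length == 0:
        raise UndefinedOrientationError("zero-length resultant has no orientation")
    ang = result.resultant_angle_deg
    dist = {
        k: abs((ang - th + 180.0) % 360.0 - 180.0) for k, th in SEQ_ANGLES_DEG.items()
    }
    best = min(dist.values())
    winners = [k for k in sorted(dist) if dist[k] == best]
    if len(winners) > 1:
        warnings.warn(
            f"resultant angle {ang:.2f} deg equidistant from locations {winners}; "
            "returning the lower index",
            stacklevel=2,
        )
    return winners[0]


def _category_codes(labels: Sequence[str]) -> np.ndarray:
    codes = pd.Categorical(labels, categories=REL_CATEGORIES).codes
    if np.any(codes < 0):
        bad = sorted(set(np.asarray(labels)[codes < 0]))
        raise InvalidParameterError(f"unknown relative labels: {bad}")
    return codes.astype(np.int64)


def _means_by_code(codes: np.ndarray, values: np.ndarray) -> np.ndarray:
    counts = np.bincount(codes, minlength=6)
    sums = np.bincount(codes, weights=values, minlength=6)
    return sums / counts


def _seq_stat(means: np.ndarray) -> float:
    return float(abs((means * _CAT_UNIT).sum()))


def _io_stat(means: np.ndarray) -> float:
    return float((means * _IO_SIGN).sum())


def permutation_test(
    labeled: pd.DataFrame,
    mode: str = "sequence",
    n_perm: int = 1000,
    seed: Optional[int] = None,
    stratify_by: Optional[Sequence[str]] = None,
) -> PermutationResult:
    """Label-shuffling permutation test of an inducer-effect statistic.

    Parameters
    ----------
    labeled
        Tidy ISI table with at least ``isi_ms`` and ``relative_label``
        columns; every one of the six categories must be represented.
    mode
        ``sequence`` (one-sided on the resultant length) or
        ``inside_outside`` (two-sided on the signed statistic).
    n_perm
        Number of shuffles (>= 100; the task's analysis used 1000).
    stratify_by
        Optional column names (e.g. ``["abs_location", "direction"]``):
        labels are then shuffled only within strata.  Pooled shuffling is
        the default.
    """
    if mode not in ("sequence", "inside_outside"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if n_perm < 100:
        raise InvalidParameterError(f"n_perm must be >= 100, got {n_perm}")
    values = labeled["isi_ms"].to_numpy(dtype=float)
    codes = _category_codes(labeled["relative_label"].to_numpy())
    counts = np.bincount(codes, minlength=6)
    if np.any(counts == 0):
        empty = [c for c, n in zip(REL_CATEGORIES, counts) if n == 0]
        raise MissingCategoryError(f"no ISIs in categories {empty}")
    if np.any(counts < MIN_CATEGORY_N):
        small = {c: int(n) for c, n in zip(REL_CATEGORIES, counts) if n < MIN_CATEGORY_N}
        warnings.warn(f"categories with fewer than {MIN_CATEGORY_N} ISIs: {small}", stacklevel=2)

    observed_means = _means_by_code(codes, values)
    stat = _seq_stat if mode == "sequence" else _io_stat
    observed_stat = stat(observed_means)

    rng = np.random.default_rng(seed)
    if stratify_by:
        strata_codes, _ = pd.factorize(
            pd.MultiIndex.from_frame(labeled[list(stratify_by)])
        )
        groups = [np.flatnonzero(strata_codes == g) for g in np.unique(strata_codes)]
    else:
        groups = None

    null = np.empty(n_perm)
    perm = codes.copy()
    for b in range(n_perm):
        if groups is None:
            perm = rng.permutation(codes)
        else:
            perm = codes.copy()
            for idx in groups:
                perm[idx] = codes[idx][rng.permutation(len(idx))]
        null[b] = stat(_means_by_code(perm, values))

    # conservative order-statistic percentiles keep the exact permutation
    # level at or below nominal (linear interpolation is anticonservative)
    if mode == "sequence":
        threshold: Union[float, tuple[float, float]] = float(
            np.percentile(null, 95.0, method="higher")
        )
        significant = observed_stat > threshold
        p = (1.0 + np.sum(null >= observed_stat)) / (n_perm + 1.0)
        observed: Union[VectorStatResult, float] = sequence_resultant(
            dict(zip(REL_CATEGORIES, observed_means))
        )
    else:
        lo, hi = (
            float(np.percentile(null, 2.5, method="lower")),
            float(np.percentile(null, 97.5, method="higher")),
        )
        threshold = (lo, hi)
        significant = (observed_stat < lo) or (observed_stat > hi)
        p = (1.0 + np.sum(np.abs(null) >= abs(observed_stat))) / (n_perm + 1.0)
        observed = observed_stat

    return PermutationResult(
        mode=mode,
        observed=observed,
        statistic=observed_stat,
        null_stats=null,
        threshold=threshold,
        p_value=float(p),
        significant=bool(significant),
        n_perm=int(n_perm),
        seed=seed,
    )
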