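"""Two-way mean-squares decomposition of inducer effects and ternary shares.

The labelled ISIs form a 3 x 2 factorial layout: relative sequence after the
inducer boundary (1, 2, 3) crossed with inside/outside of the inducer.  Two
complementary analyses live here:

1. A category-mean mean-squares decomposition used to compare response
   patterns across sessions and species.  On the six cell means X_ij (i =
   sequence, j = inside/outside), with marginal means X_i., X_.j and grand
   mean X.. all *unweighted* (the cell counts do not enter):

       MS_seq = (1/2) * sum_i (X_i. - X..)^2          (df = 2)
       MS_io  =         sum_j (X_.j - X..)^2          (df = 1)
       MS_int = (1/2) * [ sum_ij (X_ij - X..)^2 - SS_seq - SS_io ]   (df = 2)

   where SS_seq = 2 * sum_i (X_i. - X..)^2 and SS_io = 3 * sum_j (X_.j -
   X..)^2 are the usual level-count-weighted sums of squares, so the
   bracket is the classical interaction SS and vanishes exactly for
   additive cells.  The three MS are normalized to sum to one and plotted
   in a ternary (triangular) diagram whose vertices are the pure-sequence,
   pure-inside-outside and pure-interaction patterns.

2. A classical count-weighted two-way fixed-effects ANOVA on the
   individual ISIs (type-II sums of squares via statsmodels), providing
   the F and p values per session.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDecompositionError,
    InsufficientDataError,
    InvalidParameterError,
    MissingCellError,
)
from .preprocess import REL_CATEGORIES

__all__ = [
    "CellMeans",
    "MSDecomposition",
    "cell_means",
    "ms_decomposition",
    "normalize_ms",
    "ternary_coordinates",
    "two_way_anova",
]

#: Ternary-plot vertices: sequence, inside-outside, interaction.
TERNARY_VERTICES = {
    "sequence": (0.0, 0.0),
    "inside_outside": (1.0, 0.0),
    "interaction": (0.5, math.sqrt(3.0) / 2.0),
}

_COMPONENTS = ("sequence", "inside_outside", "interaction")


@dataclass(frozen=True)
class CellMeans:
    """Cell, marginal and grand means of the 3 x 2 (sequence x io) layout.

    ``grid[i, j]`` is the mean ISI for sequence position i+1 (1..3) and
    j = 0 inside / j = 1 outside.  Marginals and the grand mean are
    unweighted means of cell means.
    """

    grid: np.ndarray  # (3, 2)
    counts: np.ndarray  # (3, 2) ints

    @property
    def seq_means(self) -> np.ndarray:
        return self.grid.mean(axis=1)

    @property
    def io_means(self) -> np.ndarray:
        return self.grid.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.grid.mean())


def _seq_io_frame(labeled: pd.DataFrame) -> pd.DataFrame:
    """Split relative labels into sequence (1-3) and io (In/Out) factors."""
    lab = labeled["relative_label"].astype(str)
    out = labeled.copy()
    out["io"] = lab.str[:-1]
    out["seq"] = lab.str[-1].astype(int)
    bad = ~out["io"].isin(["In", "Out"]) | ~out["seq"].isin([1, 2, 3])
    if bad.any():
        raise InvalidParameterError(
            f"unrecognised relative labels: {sorted(set(lab[bad]))}"
        )
    return out


def cell_means(labeled: pd.DataFrame) -> CellMeans:
    """Cell means of labelled ISIs; every one of the six cells must be filled."""
    df = _seq_io_frame(labeled)
    grid = np.full((3, 2), np.nan)
    counts = np.zeros((3, 2), dtype=int)
    for i, s in enumerate((1, 2, 3)):
        for j, io in enumerate(("In", "Out")):
            vals = df.loc[(df["seq"] == s) & (df["io"] == io), "isi_ms"]
            counts[i, j] = len(vals)
            if len(vals):
                grid[i, j] = float(vals.mean())
    if (counts == 0).any():
        empty = [
            f"{io}{s}"
            for i, s in enumerate((1, 2, 3))
            for j, io in enumerate(("In", "Out"))
            if counts[i, j] == 0
        ]
        raise MissingCellError(f"empty cells: {empty}")
    return CellMeans(grid=grid, counts=counts)


@dataclass(frozen=True)
class MSDecomposition:
    """Raw (ms^2) and optionally normalized mean-squares triple."""

    ms_seq: float
    ms_io: float
    ms_int: float
    normalized: Optional[tuple[float, float, float]] = None
    ternary_xy: Optional[tuple[float, float]] = None

    @property
    def raw(self) -> tuple[float, float, float]:
        return (self.ms_seq, self.ms_io, self.ms_int)

    @property
    def dominant(self) -> str:
        shares = self.normalized if self.normalized is not None else self.raw
        return _COMPONENTS[int(np.argmax(shares))]

    def to_dict(self) -> dict:
        d = {"ms_seq": self.ms_seq, "ms_io": self.ms_io, "ms_int": self.ms_int}
        if self.normalized is not None:
            d.update(
                norm_seq=self.normalized[0],
                norm_io=self.normalized[1],
                norm_int=self.normalized[2],
                ternary_x=self.ternary_xy[0],
                ternary_y=self.ternary_xy[1],
                dominant=self.dominant,
            )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def ms_decomposition(cells: CellMeans) -> MSDecomposition:
    """Mean squares of the two main effects and interaction on cell means.

    Implements the category-mean formulas documented in the module
    docstring (df_seq = 2, df_io = 1, df_int = 2 give the 1/2 factors).
    A negative interaction bracket can only arise from floating-point
    cancellation and is clamped to zero, with a warning beyond 1e-9
    relative magnitude.
    """
    grid = cells.grid
    grand = cells.grand_mean
    seq_dev2 = float(((cells.seq_means - grand) ** 2).sum())
    io_dev2 = float(((cells.io_means - grand) ** 2).sum())
    total_dev2 = float(((grid - grand) ** 2).sum())

    ms_seq = 0.5 * seq_dev2
    ms_io = io_dev2
    # SS_seq = 2*seq_dev2 and SS_io = 3*io_dev2 (level-count weighting):
    # the bracket is then the classical interaction SS of the 3x2 layout.
    bracket = total_dev2 - 2.0 * seq_dev2 - 3.0 * io_dev2
    if bracket < 0:
        scale = max(total_dev2, 1.0)
        if -bracket > 1e-9 * scale:
            warnings.warn(
                f"negative interaction sum of squares ({bracket:.3e}) clamped to 0",
                stacklevel=2,
            )
        bracket = 0.0
    ms_int = 0.5 * bracket
    return MSDecomposition(ms_seq=ms_seq, ms_io=ms_io, ms_int=ms_int)


def ternary_coordinates(triple) -> tuple[float, float]:
    """Map a non-negative triple summing to one to ternary x, y coordinates."""
    p_seq, p_io, p_int = (float(v) for v in triple)
    x = p_io * 1.0 + p_int * 0.5
    y = p_int * math.sqrt(3.0) / 2.0
    return (x, y)


def normalize_ms(raw: MSDecomposition) -> MSDecomposition:
    """Normalize the triple to sum to one and attach ternary coordinates."""
    total = raw.ms_seq + raw.ms_io + raw.ms_int
    if total <= 0:
        raise DegenerateDecompositionError(
            "all mean-square components are zero; shares undefined"
        )
    norm = (raw.ms_seq / total, raw.ms_io / total, raw.ms_int / total)
    return MSDecomposition(
        ms_seq=raw.ms_seq,
        ms_io=raw.ms_io,
        ms_int=raw.ms_int,
        normalized=norm,
        ternary_xy=ternary_coordinates(norm),
    )


def two_way_anova(labeled: pd.DataFrame) -> pd.DataFrame:
    """Classical two-way fixed-effects ANOVA on individual ISIs.

    Factors: relative sequence (3 levels) x inside/outside (2 levels),
    count-weighted type-II sums of squares on the raw observations.
    Returns a frame indexed by effect (``sequence``, ``inside_outside``,
    ``interaction``, ``residual``) with sum_sq, df, F and p columns.
    Requires at least two observations in each of the six cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _seq_io_frame(labeled)
    counts = df.groupby(["seq", "io"]).size()
    if len(counts) < 6 or (counts < 2).any():
        raise InsufficientDataError(
            "two-way ANOVA needs >= 2 ISIs in each of the six cells"
        )
    fit = smf.ols("isi_ms ~ C(seq) * C(io)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    tab = tab.rename(
        index={
            "C(seq)": "sequence",
            "C(io)": "inside_outside",
            "C(seq):C(io)": "interaction",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p_value"},
    )
    return tab
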