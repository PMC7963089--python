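"""Session-level inducer-effect model in the statsmodels mould.

:class:`InducerEffectModel` is built from a labelled ISI table (or directly
from a raw saccade-event table via :meth:`InducerEffectModel.from_events`,
which applies the condition-appropriate exclusion filters, recomputes ISIs
between retained onsets and sorts them by relative location).  ``fit()``
runs the full inferential battery for one session and returns an
:class:`InducerEffectResults` carrying:

* the six relative-location category means and counts;
* the sequence resultant vector with its permutation null and p-value,
  plus the orientation classification (delayed location 1-3);
* the signed inside-outside statistic with its two-sided permutation null;
* the normalized mean-squares decomposition (ternary coordinates and the
  dominant component);
* the count-weighted two-way ANOVA table.

``summary()`` renders the lot as a one-page text report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import preprocess
from .decomposition import (
    MSDecomposition,
    cell_means,
    ms_decomposition,
    normalize_ms,
    two_way_anova,
)
from .exceptions import InsufficientDataError, InvalidParameterError
from .paradigm import LandmarkLayout
from .preprocess import REL_CATEGORIES, SessionISITable, aggregate, labeled_isis
from .vectorstats import (
    PermutationResult,
    classify_orientation,
    permutation_test,
)

__all__ = ["InducerEffectModel", "InducerEffectResults"]


class InducerEffectModel:
    """Inducer-effect analysis of one session's labelled ISIs.

    Parameters
    ----------
    labeled
        Tidy table with columns ``isi_ms``, ``relative_label`` and
        (optionally) ``abs_location``, ``direction``, ``soa_ms``.
    """

    def __init__(self, labeled: pd.DataFrame):
        required = {"isi_ms", "relative_label"}
        missing = required - set(labeled.columns)
        if missing:
            raise InvalidParameterError(f"labelled ISI table lacks columns {sorted(missing)}")
        data = labeled[labeled["relative_label"].notna() & labeled["isi_ms"].notna()]
        if len(data) == 0:
            raise InvalidParameterError("no labelled ISIs to analyse")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        condition: str = "predictive",
        *,
        layout: Optional[LandmarkLayout] = None,
        capture_radius: float = preprocess.CAPTURE_RADIUS_DEG,
    ) -> "InducerEffectModel":
        """Build the model from a raw saccade-event table.

        Assigns landing landmarks, applies the predictive or reactive
        exclusion rules, recomputes ISIs between consecutive retained
        onsets, and keeps labelled ISIs from inducer trials.
        """
        model, _ = cls.from_events_with_report(
            events, condition, layout=layout, capture_radius=capture_radius
        )
        return model

    @classmethod
    def from_events_with_report(
        cls,
        events: pd.DataFrame,
        condition: str = "predictive",
        *,
        layout: Optional[LandmarkLayout] = None,
        capture_radius: float = preprocess.CAPTURE_RADIUS_DEG,
    ) -> tuple["InducerEffectModel", dict]:
        """Like :meth:`from_events` but also return per-stage row counts."""
        if condition not in ("predictive", "reactive"):
            raise InvalidParameterError(f"unknown condition {condition!r}")
        ev = events
        if "assigned_landmark" not in ev.columns:
            ev = preprocess.assign_landmarks(ev, layout, capture_radius)
        report = {"input_rows": int(len(ev)), "condition": condition}
        if condition == "predictive":
            retained = preprocess.filter_predictive(ev)
        else:
            retained = preprocess.filter_reactive(ev)
        report["retained_rows"] = int(len(retained))
        report["excluded_rows"] = report["input_rows"] - report["retained_rows"]
        retained = preprocess.recompute_isi(retained)
        lab = labeled_isis(retained, require_inducer=True)
        report["labeled_isis"] = int(len(lab))
        return cls(lab), report

    @property
    def nobs(self) -> int:
        return len(self.data)

    @property
    def isi_table(self) -> SessionISITable:
        return aggregate(self.data)

    def fit(
        self,
        n_perm: int = 1000,
        seed: Optional[int] = None,
        stratify_by: Optional[Sequence[str]] = None,
        anova: bool = True,
    ) -> "InducerEffectResults":
        """Run permutation tests, MS decomposition and (optionally) ANOVA.

        Both permutation modes reuse ``seed`` through independent child
        streams, so a fixed seed reproduces the full result exactly.
        """
        ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
        seq_seed, io_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
        seq_test = permutation_test(
            self.data, mode="sequence", n_perm=n_perm, seed=seq_seed, stratify_by=stratify_by
        )
        io_test = permutation_test(
            self.data, mode="inside_outside", n_perm=n_perm, seed=io_seed, stratify_by=stratify_by
        )
        decomp = normalize_ms(ms_decomposition(cell_means(self.data)))
        anova_table = None
        if anova:
            try:
                anova_table = two_way_anova(self.data)
            except InsufficientDataError as err:
                warnings.warn(f"two-way ANOVA skipped: {err}", stacklevel=2)
        table = self.isi_table
        return InducerEffectResults(
            model=self,
            isi_table=table,
            seq_test=seq_test,
            io_test=io_test,
            decomposition=decomp,
            anova_table=anova_table,
            n_perm=n_perm,
            seed=seed,
        )


@dataclass
class InducerEffectResults:
    """Fitted inducer-effect statistics of one session."""

    model: InducerEffectModel
    isi_table: SessionISITable
    seq_test: PermutationResult
    io_test: PermutationResult
    decomposition: MSDecomposition
    anova_table: Optional[pd.DataFrame]
    n_perm: int
    seed: Optional[int]

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def category_means(self) -> pd.Series:
        stats = self.isi_table.category_stats
        return pd.Series(stats["mean_ms"].to_numpy(), index=stats["category"], name="mean_isi_ms")

    @property
    def orientation(self) -> int:
        """Delayed sequence location (1-3) indicated by the resultant."""
        return classify_orientation(self.seq_test.observed)

    @property
    def dominant_component(self) -> str:
        return self.decomposition.dominant

    def to_dict(self) -> dict:
        stats = self.isi_table.category_stats
        d = {
            "nobs": self.nobs,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "category_stats": stats.to_dict(orient="records"),
            "sequence": self.seq_test.to_dict(),
            "inside_outside": self.io_test.to_dict(),
            "decomposition": self.decomposition.to_dict(),
        }
        try:
            d["sequence"]["orientation"] = self.orientation
        except Exception:
            d["sequence"]["orientation"] = None
        if self.anova_table is not None:
            d["anova"] = {
                effect: {
                    "sum_sq": float(row["sum_sq"]),
                    "df": float(row["df"]),
                    "F": None if np.isnan(row["F"]) else float(row["F"]),
                    "p_value": None if np.isnan(row["p_value"]) else float(row["p_value"]),
                }
                for effect, row in self.anova_table.iterrows()
            }
        return d

    def to_json(self, indent: Optional[int] = None) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    def summary(self) -> str:
        """One-page text summary of the session."""
        lines = []
        lines.append("Inducer-effect session summary")
        lines.append("=" * 62)
        lines.append(f"labelled ISIs: {self.nobs}    permutations: {self.n_perm}    seed: {self.seed}")
        lines.append("")
        lines.append("Mean ISI by relative target location (ms)")
        stats = self.isi_table.category_stats
        lines.append(f"{'category':>10} {'n':>6} {'mean':>9} {'sd':>8}")
        for _, row in stats.iterrows():
            lines.append(
                f"{row['category']:>10} {row['n']:>6d} {row['mean_ms']:>9.1f} {row['sd_ms']:>8.1f}"
            )
        lines.append("")
        s = self.seq_test
        star = "*" if s.significant else " "
        try:
            orient = str(self.orientation)
        except Exception:
            orient = "-"
        lines.append(
            f"sequence resultant: length {s.statistic:8.2f} ms  angle "
            f"{s.observed.resultant_angle_deg:6.1f} deg  location {orient}  "
            f"p = {s.p_value:.4f}{star}"
        )
        i = self.io_test
        star = "*" if i.significant else " "
        side = "inside slower" if i.statistic > 0 else "outside slower"
        lines.append(
            f"inside-outside:     {i.statistic:+8.2f} ms ({side})  p = {i.p_value:.4f}{star}"
        )
        lines.append("")
        n = self.decomposition.normalized
        lines.append(
            "normalized mean squares: seq {:.3f}  io {:.3f}  int {:.3f}  -> dominant: {}".format(
                n[0], n[1], n[2], self.dominant_component
            )
        )
        if self.anova_table is not None:
            lines.append("")
            lines.append("two-way ANOVA (individual ISIs, type-II SS)")
            lines.append(f"{'effect':>16} {'df':>5} {'F':>9} {'p':>10}")
            for effect, row in self.anova_table.iterrows():
                if effect == "residual":
                    lines.append(f"{effect:>16} {row['df']:>5.0f} {'':>9} {'':>10}")
                else:
                    lines.append(
                        f"{effect:>16} {row['df']:>5.0f} {row['F']:>9.2f} {row['p_value']:>10.2e}"
                    )
        return "\n".join(lines)

    def plot_polar(self, ax=None):
        from .plotting import plot_category_polar

        return plot_category_polar(self.isi_table, ax=ax)

    def plot_ternary(self, ax=None):
        from .plotting import plot_ternary

        return plot_ternary([self.decomposition.normalized], ax=ax)
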