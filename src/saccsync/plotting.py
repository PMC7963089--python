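"""Polar and ternary figures for session results."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .preprocess import REL_CATEGORIES, SessionISITable
from .decomposition import TERNARY_VERTICES, ternary_coordinates

__all__ = ["plot_category_polar", "plot_ternary"]

#: Display angle (deg) of each relative-location corner on the polar plot,
#: walking the In1..Out3 cycle counterclockwise from the top.
_POLAR_ANGLES = {c: 90.0 - 60.0 * k for k, c in enumerate(REL_CATEGORIES)}


def plot_category_polar(
    table: SessionISITable,
    ax=None,
    reference: Optional[float] = None,
):
    """Hexagonal polar plot of mean ISI per relative target location.

    ``reference`` (e.g. the SOA or the inducer-free mean ISI) is drawn as a
    dashed circle.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    means = table.category_means
    theta = [math.radians(_POLAR_ANGLES[c]) for c in REL_CATEGORIES]
    r = [means[c] for c in REL_CATEGORIES]
    ax.plot(theta + theta[:1], r + r[:1], "o-", color="tab:red")
    if reference is not None:
        circle = np.linspace(0, 2 * np.pi, 120)
        ax.plot(circle, np.full_like(circle, reference), "--", color="grey", lw=1)
    ax.set_xticks(theta)
    ax.set_xticklabels(REL_CATEGORIES)
    ax.set_title("mean ISI by relative target location (ms)")
    return ax


def plot_ternary(points: Sequence[tuple[float, float, float]], ax=None, labels=None):
    """Scatter normalized (seq, io, int) triples in the ternary triangle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    verts = [
        TERNARY_VERTICES["sequence"],
        TERNARY_VERTICES["inside_outside"],
        TERNARY_VERTICES["interaction"],
        TERNARY_VERTICES["sequence"],
    ]
    vx, vy = zip(*verts)
    ax.plot(vx, vy, "k-", lw=1)
    for name, (x, y) in TERNARY_VERTICES.items():
        ax.annotate(name, (x, y), textcoords="offset points", xytext=(0, 6), ha="center")
    xy = [ternary_coordinates(p) for p in points]
    ax.scatter([p[0] for p in xy], [p[1] for p in xy], marker="^", color="tab:blue")
    if labels is not None:
        for (x, y), lab in zip(xy, labels):
            ax.annotate(str(lab), (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
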