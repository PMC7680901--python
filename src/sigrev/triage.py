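"""Bibliometric triage of screen hits and the bubble-plot visualization.

The triage statistic for molecule m with c clinical trials, p publications,
impact tier i in {1, 2, 3} and a fixed weight w (default 2) is

    score_m = log10(c * p * i * w)

Molecules with c*p = 0 -- never trialed or never published in the disease
context -- get a sentinel score of -inf and are flagged ``unstudied``: they
sort FIRST, because the screen deliberately prizes molecules scarcely
described in the disease literature. Only the ordering of scores is used
downstream, so the choice of logarithm base is immaterial; base 10 is fixed
here for reproducible printed values.

The bubble plot groups molecules into one horizontal band per cell line
(default palette blue HL60, yellow MCF7, orange PC3), places them at
y = |mean ES| with seeded horizontal jitter, and sizes each bubble
*inversely* to its bibliometric score via a bounded linear map, so the
least-studied strong reversers are the big bubbles near the top. A tidy
table of plotted coordinates accompanies the image so the plot is testable
without pixel comparison.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import DataError
from .util import substream

__all__ = [
    "SENTINEL_SCORE",
    "bibliometric_score",
    "score_table",
    "rank_candidates",
    "BubbleConfig",
    "render_bubble_plot",
]

SENTINEL_SCORE = -math.inf

DEFAULT_COLORS = {"HL60": "#2c6fbb", "MCF7": "#f3c13a", "PC3": "#e8833a"}
FALLBACK_PALETTE = ("#7f7f7f", "#9467bd", "#8c564b", "#17becf", "#bcbd22")


def bibliometric_score(c: int, p: int, i: int, w: float = 2.0) -> float:
    """log10(c*p*i*w), or the -inf sentinel when c*p = 0 (unstudied)."""
    if c < 0 or p < 0:
        raise DataError("counts c and p must be non-negative")
    if i not in (1, 2, 3):
        raise DataError(f"impact tier must be 1, 2 or 3, got {i}")
    if w <= 0:
        raise DataError("weight w must be positive")
    if c * p == 0:
        return SENTINEL_SCORE
    return math.log10(c * p * i * w)


def score_table(biblio: pd.DataFrame, w: float = 2.0) -> pd.DataFrame:
    """Add ``score`` and ``unstudied`` columns to a (molecule, c, p, i) table."""
    required = {"molecule", "c", "p", "i"}
    missing = required - set(biblio.columns)
    if missing:
        raise DataError(f"bibliometric table lacks columns {sorted(missing)}")
    out = biblio.copy()
    out["score"] = [
        bibliometric_score(int(r.c), int(r.p), int(r.i), w=w)
        for r in out.itertuples()
    ]
    out["unstudied"] = ~np.isfinite(out["score"])
    return out


def rank_candidates(
    hits: pd.DataFrame, biblio_scores: pd.DataFrame, top_k: int | None = None
) -> pd.DataFrame:
    """Order screen hits by ascending bibliometric score.

    Unstudied molecules (sentinel score) come first; ties are broken by
    |mean ES| descending, then molecule name. Hits with no bibliometric
    record at all are treated as unstudied.
    """
    scores = biblio_scores.set_index("molecule")["score"]
    df = hits.copy()
    df["biblio_score"] = [
        float(scores.get(m, SENTINEL_SCORE)) for m in df["perturbagen"]
    ]
    df["unstudied"] = ~np.isfinite(df["biblio_score"])
    df = df.sort_values(
        by=["biblio_score", "mean_es", "perturbagen"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "mean_es" else col,
        kind="stable",
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df


@dataclass(frozen=True)
class BubbleConfig:
    r_min: float = 6.0           # bubble radius bounds, points
    r_max: float = 18.0
    jitter_width: float = 0.35   # half-width of uniform jitter within a band
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    seed: int = 0


def _radii(scores: np.ndarray, cfg: BubbleConfig) -> np.ndarray:
    """Bounded inverse-linear map from bibliometric score to radius.

    Sentinel (-inf) scores are treated as the minimum finite score, i.e. they
    get the largest bubbles. With zero score range every radius is the
    midpoint (r_min + r_max)/2.
    """
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        return np.full(len(scores), (cfg.r_min + cfg.r_max) / 2)
    smin, smax = float(finite.min()), float(finite.max())
    s = np.where(np.isfinite(scores), scores, smin)
    if smax == smin:
        return np.full(len(scores), (cfg.r_min + cfg.r_max) / 2)
    return cfg.r_min + (cfg.r_max - cfg.r_min) * (smax - s) / (smax - smin)


def render_bubble_plot(
    table: pd.DataFrame,
    out_image: str | os.PathLike | None = None,
    config: BubbleConfig | None = None,
) -> pd.DataFrame:
    """Render the triage bubble plot; return the tidy table of coordinates.

    ``table`` needs columns ``perturbagen``, ``cell_line``, ``mean_es`` and
    ``biblio_score`` (e.g. the output of :func:`rank_candidates`). When
    ``out_image`` is given, both ``<stem>.svg`` and ``<stem>.png`` are
    written.
    """
    cfg = config or BubbleConfig()
    required = {"perturbagen", "cell_line", "mean_es", "biblio_score"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"plot table lacks columns {sorted(missing)}")
    if len(table) == 0:
        raise DataError("nothing to plot: empty summary table")

    lines = sorted(table["cell_line"].unique())
    band = {line: i for i, line in enumerate(lines)}
    palette = dict(cfg.colors)
    cycle = iter(FALLBACK_PALETTE)
    for line in lines:
        if line not in palette:
            palette[line] = next(cycle, FALLBACK_PALETTE[-1])

    rng = substream(cfg.seed, "plot_jitter")
    tidy = table.copy().reset_index(drop=True)
    jitter = rng.uniform(-cfg.jitter_width, cfg.jitter_width, len(tidy))
    tidy["x"] = tidy["cell_line"].map(band).to_numpy(float) + jitter
    tidy["y"] = tidy["mean_es"].abs()
    tidy["radius"] = _radii(tidy["biblio_score"].to_numpy(float), cfg)
    tidy["color"] = tidy["cell_line"].map(palette)
    tidy = tidy[
        ["perturbagen", "cell_line", "mean_es", "biblio_score",
         "x", "y", "radius", "color"]
    ]

    if out_image is not None:
        stem, _ = os.path.splitext(str(out_image))
        fig, ax = plt.subplots(figsize=(1.8 + 1.6 * len(lines), 4.5))
        ax.scatter(
            tidy["x"], tidy["y"],
            s=tidy["radius"] ** 2,  # marker area ~ radius^2
            c=tidy["color"], alpha=0.75, edgecolors="black", linewidths=0.4,
        )
        for molecule, row in tidy.nlargest(5, "radius").iterrows():
            ax.annotate(row["perturbagen"], (row["x"], row["y"]),
                        fontsize=7, xytext=(2, 2), textcoords="offset points")
        ax.set_xticks(range(len(lines)), lines)
        ax.set_ylabel("|mean enrichment score|")
        ax.set_xlabel("cell line")
        ax.set_title("Screen hits: bubble size inverse to bibliometric score")
        fig.tight_layout()
        fig.savefig(stem + ".svg")
        fig.savefig(stem + ".png", dpi=150)
        plt.close(fig)
    return tidy
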