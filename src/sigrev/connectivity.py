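"""Connectivity-map style in-silico screening.

Each reference *instance* is a total ordering of the reference genes by how
strongly the perturbagen up-regulates them (rank 1 = most up-regulated). The
query is a pair of disjoint tag sets (up- and down-regulated disease genes).
For one tag set of size t with ordered ranks V(1) < ... < V(t) in a list of
n genes, the rank-based Kolmogorov-Smirnov statistic is

    a = max_j [ j/t - V(j)/n ]
    b = max_j [ V(j)/n - (j-1)/t ]
    ks = a  if a > b  else  -b

(positive when the tags crowd the top of the list). The raw combined
connectivity of an instance is ``s = ks_up - ks_down`` when the two
statistics disagree in sign (or one is zero), and 0 otherwise: an instance
only counts as connected when it pushes the up-tags and down-tags apart.
Raw scores are then scaled per screen -- positives divided by the largest
positive, negatives by the magnitude of the most negative -- so the scaled
enrichment score (ES) lies in [-1, 1]. A *negative* ES marks a perturbagen
whose expression consequences oppose the disease signature: a candidate
signature reverser.

Per-perturbagen summaries average the scaled ES over instances within one
(perturbagen, cell line) group and attach a permutation p-value (fraction of
random same-size instance groups from the same screen with at least as
extreme a |mean ES|). The permutation p is an addition of this package; the
classical connectivity-map output carries only n and the mean ES.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservedSignature
from .errors import DataError
from .util import substream

__all__ = [
    "QuerySignature",
    "RankedInstance",
    "ks_statistic",
    "instance_connectivity",
    "scale_scores",
    "score_screen",
    "summarize_perturbagens",
    "filter_hits",
    "build_query",
]

DEFAULT_MAX_TAGS = 1000


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint up/down tag lists, most significant first."""

    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.up or not self.down:
            raise DataError("query needs non-empty up AND down tag sets")
        if set(self.up) & set(self.down):
            raise DataError("up and down tag sets must be disjoint")


@dataclass
class RankedInstance:
    """One reference profile: a permutation of the reference genes."""

    instance_id: str
    perturbagen: str
    cell_line: str
    genes: tuple[str, ...]  # rank order; genes[0] is the most up-regulated

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"instance {self.instance_id}: duplicate genes")
        self._rank = {g: i + 1 for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def ranks_of(self, tags) -> np.ndarray:
        """Sorted 1-based ranks of the tags present in this instance."""
        return np.sort([self._rank[t] for t in tags if t in self._rank])

    def reversed_copy(self) -> "RankedInstance":
        return RankedInstance(
            instance_id=self.instance_id + ":rev",
            perturbagen=self.perturbagen,
            cell_line=self.cell_line,
            genes=self.genes[::-1],
        )


def ks_statistic(tag_ranks: np.ndarray, n: int) -> float:
    """Signed KS statistic for sorted 1-based ``tag_ranks`` in a list of ``n``."""
    v = np.asarray(tag_ranks, dtype=float)
    t = len(v)
    if t == 0:
        raise DataError("ks_statistic needs at least one tag rank")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


@dataclass(frozen=True)
class InstanceScore:
    instance_id: str
    perturbagen: str
    cell_line: str
    ks_up: float
    ks_down: float
    raw: float
    n_up_used: int
    n_down_used: int


def instance_connectivity(
    query: QuerySignature, instance: RankedInstance
) -> InstanceScore:
    """Raw combined connectivity of one instance against the query.

    Tags absent from the instance's gene universe are dropped (the effective
    tag counts are reported); an entirely absent side is an error naming the
    instance.
    """
    up_ranks = instance.ranks_of(query.up)
    down_ranks = instance.ranks_of(query.down)
    for side, ranks in (("up", up_ranks), ("down", down_ranks)):
        if len(ranks) == 0:
            raise DataError(
                f"instance {instance.instance_id}: no {side}-tag present in its gene list"
            )
    n = len(instance)
    ks_up = ks_statistic(up_ranks, n)
    ks_down = ks_statistic(down_ranks, n)
    if ks_up * ks_down > 0:  # same sign: query not split apart
        raw = 0.0
    else:
        raw = ks_up - ks_down
    return InstanceScore(
        instance_id=instance.instance_id,
        perturbagen=instance.perturbagen,
        cell_line=instance.cell_line,
        ks_up=ks_up,
        ks_down=ks_down,
        raw=raw,
        n_up_used=len(up_ranks),
        n_down_used=len(down_ranks),
    )


def scale_scores(raw: np.ndarray) -> np.ndarray:
    """Scale raw scores of one screen into [-1, 1].

    Positive scores are divided by the screen's maximum positive score,
    negative ones by the magnitude of its most negative score; zeros stay 0.
    """
    raw = np.asarray(raw, dtype=float)
    scaled = np.zeros_like(raw)
    pos, neg = raw > 0, raw < 0
    if pos.any():
        scaled[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = raw[neg] / abs(raw[neg].min())
    if not (pos.any() or neg.any()):
        warnings.warn("all raw connectivity scores are zero", stacklevel=2)
    return scaled


def score_screen(
    query: QuerySignature, instances: list[RankedInstance]
) -> pd.DataFrame:
    """Score every instance and batch-scale; one row per instance."""
    if not instances:
        raise DataError("empty screen: no instances to score")
    rows = [instance_connectivity(query, inst) for inst in instances]
    df = pd.DataFrame(
        {
            "instance_id": [r.instance_id for r in rows],
            "perturbagen": [r.perturbagen for r in rows],
            "cell_line": [r.cell_line for r in rows],
            "ks_up": [r.ks_up for r in rows],
            "ks_down": [r.ks_down for r in rows],
            "raw": [r.raw for r in rows],
        }
    )
    df["es"] = scale_scores(df["raw"].to_numpy())
    return df


def summarize_perturbagens(
    scores: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean scaled ES per (perturbagen, cell line) with a permutation p-value.

    The null for a group of size n resamples n instances without replacement
    from the whole screen ``n_perm`` times; p = (1 + #{|mean*| >= |mean|}) /
    (1 + n_perm). Labeled ``perm_p`` because it is this package's addition to
    the classical per-batch output.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = substream(seed, "connectivity_perm")
    es = scores["es"].to_numpy(float)
    n_inst = len(es)
    groups = scores.groupby(["perturbagen", "cell_line"], sort=True)
    # one null distribution of group means per distinct group size
    null_means: dict[int, np.ndarray] = {}
    for size in sorted({len(g) for _, g in groups}):
        if size >= n_inst:
            null_means[size] = np.full(n_perm, np.abs(es.mean()))
            continue
        u = rng.random((n_perm, n_inst))
        picks = np.argpartition(u, size, axis=1)[:, :size]
        null_means[size] = np.abs(es[picks].mean(axis=1))
    rows = []
    for (pert, line), grp in groups:
        mean_es = float(grp["es"].mean())
        n = len(grp)
        p = float((1 + (null_means[n] >= abs(mean_es)).sum()) / (1 + n_perm))
        rows.append((pert, line, mean_es, n, p))
    return pd.DataFrame(
        rows, columns=["perturbagen", "cell_line", "mean_es", "n", "perm_p"]
    )


def filter_hits(
    summaries: pd.DataFrame,
    cell_line: str = "HL60",
    min_n: int = 3,
    direction: str = "negative",
) -> pd.DataFrame:
    """Apply the screening filter and rank hits by |mean ES| (descending).

    Defaults mirror the reversal screen: keep only the chosen cell line,
    groups backed by at least 3 instances, and negative mean ES (signature
    reversers). ``direction`` may be ``negative``, ``positive`` or ``both``;
    ``cell_line=None`` keeps every line.
    """
    if min_n < 1:
        raise DataError("min_n must be >= 1")
    if direction not in ("negative", "positive", "both"):
        raise DataError(f"direction must be negative/positive/both, got {direction!r}")
    df = summaries.copy()
    if cell_line is not None:
        available = sorted(df["cell_line"].unique())
        if cell_line not in available:
            raise DataError(
                f"unknown cell line {cell_line!r}; available: {available}"
            )
        df = df[df["cell_line"] == cell_line]
    df = df[df["n"] >= min_n]
    if direction == "negative":
        df = df[df["mean_es"] < 0]
    elif direction == "positive":
        df = df[df["mean_es"] > 0]
    df = df.reindex(
        df["mean_es"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def build_query(
    csig: ConservedSignature,
    human_table: pd.DataFrame,
    max_per_side: int = DEFAULT_MAX_TAGS,
) -> QuerySignature:
    """Turn the conserved signature into query tags.

    Each side is ordered by ascending human p-value (ties broken by symbol)
    and truncated to ``max_per_side``. Both sides must be non-empty.
    """
    if max_per_side < 1:
        raise DataError("max_per_side must be >= 1")
    pvals = human_table["p"]
    pvals = pvals[~pvals.index.duplicated()]
    pvals.index = pvals.index.astype(str).str.upper()

    def side(genes: frozenset[str], label: str) -> tuple[str, ...]:
        if not genes:
            raise DataError(f"conserved signature has no {label}-regulated genes")
        ordered = sorted(genes, key=lambda g: (float(pvals.get(g, np.inf)), g))
        return tuple(ordered[:max_per_side])

    return QuerySignature(up=side(csig.up, "up"), down=side(csig.down, "down"))
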