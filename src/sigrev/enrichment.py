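"""Preranked gene-set enrichment (weighted-KS ES/NES) and over-representation.

The enrichment score walks the ranking from top to bottom: meeting a set
member ("hit") advances the running sum by |r_i|^w / sum_hits |r|^w, meeting
a non-member advances it by -1/(N - t). The ES is the running-sum extremum
of largest magnitude, in [-1, 1]. Significance comes from gene-label
permutations (random same-size sets), the only option when just a ranked
statistic is available; NES divides the ES by the mean |permuted ES| of the
same sign, and

    p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #same-sign permutations).

Over-representation (ORA) reuses the one-sided hypergeometric tail from
:mod:`sigrev.conservation` -- a single shared implementation -- and corrects
across sets with Benjamini-Hochberg.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .conservation import overlap_significance
from .errors import DataError
from .util import substream

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "gsea_es",
    "gsea_nes",
    "gsea",
    "ora_test",
    "top_k_report",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    collection: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int       # members found in the ranking
    es: float
    nes: float
    p: float


def _order_ranking(ranked: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending by statistic, ties broken by gene symbol (deterministic)."""
    if ranked.index.has_duplicates:
        raise DataError("ranked scores contain duplicate genes")
    if not np.all(np.isfinite(ranked.to_numpy(float))):
        raise DataError("ranked scores must be finite")
    df = pd.DataFrame({"gene": ranked.index.astype(str), "r": ranked.to_numpy(float)})
    df = df.sort_values(["r", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].to_numpy(), df["r"].to_numpy()


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Vectorized ES for rows of sorted 1-based hit positions.

    ``pos`` and ``weights`` are (n_rows, t); each row is one (possibly
    permuted) placement of the t hits, with the hit weights |r|^w taken at
    those positions. Only values of the running sum adjacent to hits can be
    extremal, so the extrema are evaluated there.
    """
    n_rows, t = pos.shape
    miss = 1.0 / (n_total - t)
    wsum = weights.sum(axis=1, keepdims=True)
    flat = wsum[:, 0] == 0
    if flat.any():  # all member stats exactly 0: fall back to unweighted
        weights = weights.copy()
        weights[flat] = 1.0
        wsum = weights.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights, axis=1) / wsum
    j = np.arange(1, t + 1, dtype=float)
    after = cum - (pos - j) * miss                    # just after hit j
    before = cum - weights / wsum[:, 0, None] - (pos - j) * miss  # just before
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)  # ties resolve positive


def gsea_es(ranked: pd.Series, gene_set: GeneSet, weight: float = 1.0) -> float:
    """Weighted-KS enrichment score of one set against one ranking.

    A set covering the whole ranking has no misses; its ES is 1 by
    convention. A set with no member in the ranking is an error (batch
    callers report it as missing instead).
    """
    genes, stats_ = _order_ranking(ranked)
    hit = np.isin(genes, list(gene_set.genes))
    t = int(hit.sum())
    if t == 0:
        raise DataError(f"gene set {gene_set.name!r} has no member in the ranking")
    n = len(genes)
    if t == n:
        return 1.0
    pos = (np.flatnonzero(hit) + 1).astype(float)[None, :]
    w = (np.abs(stats_[hit]) ** weight)[None, :]
    return float(_es_from_positions(pos, w, n)[0])


def gsea_nes(
    ranked: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    _rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """ES, permutation-normalized NES and permutation p for one set."""
    if n_perm < 100:
        raise DataError("n_perm must be >= 100 for a usable permutation p")
    genes, stats_ = _order_ranking(ranked)
    hit = np.isin(genes, list(gene_set.genes))
    t = int(hit.sum())
    if t == 0:
        raise DataError(f"gene set {gene_set.name!r} has no member in the ranking")
    n = len(genes)
    if t == n:
        return EnrichmentResult(gene_set.name, t, 1.0, np.nan, 1.0)
    es = gsea_es(ranked, gene_set, weight=weight)
    rng = _rng if _rng is not None else substream(seed, "enrichment_perm")
    abs_stats = np.abs(stats_) ** weight
    perm_es = np.empty(n_perm)
    done = 0
    batch = max(1, min(n_perm, 2_000_000 // max(n, 1)))  # bound memory
    while done < n_perm:
        b = min(batch, n_perm - done)
        u = rng.random((b, n))
        picks = np.argpartition(u, t, axis=1)[:, :t]
        picks.sort(axis=1)
        perm_es[done:done + b] = _es_from_positions(
            picks + 1.0, abs_stats[picks], n
        )
        done += b
    same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.zeros(n_perm, bool)
    n_same = int(same_sign.sum())
    if es == 0 or n_same == 0:
        return EnrichmentResult(gene_set.name, t, es, np.nan, 1.0)
    nes = es / float(np.mean(np.abs(perm_es[same_sign])))
    p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(gene_set.name, t, es, float(nes), float(p))


def gsea(
    ranked: pd.Series,
    gene_sets: list[GeneSet],
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Batch :func:`gsea_nes`; sets with no member in the ranking get NaN rows."""
    rng = substream(seed, "enrichment_perm")
    rows = []
    present = set(ranked.index.astype(str))
    for gs in gene_sets:
        if not (gs.genes & present):
            rows.append((gs.name, 0, np.nan, np.nan, np.nan))
            continue
        r = gsea_nes(ranked, gs, n_perm=n_perm, weight=weight, _rng=rng)
        rows.append((r.name, r.size, r.es, r.nes, r.p))
    return pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"])


def ora_test(
    gene_list,
    gene_sets: list[GeneSet],
    universe_size: int,
    p_cutoff: float = 0.001,
    q_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Returns one row per set with raw ``p``, BH ``q`` and a ``significant``
    flag at the (p_cutoff, q_cutoff) pair; the caller filters on the flag.
    """
    genes = frozenset(str(g).upper() for g in gene_list)
    if universe_size < len(genes):
        raise DataError(
            f"universe ({universe_size}) smaller than the gene list ({len(genes)})"
        )
    rows = []
    for gs in gene_sets:
        members = frozenset(str(g).upper() for g in gs.genes)
        k = len(genes & members)
        res = overlap_significance(
            size_a=min(len(members), universe_size),
            size_b=len(genes),
            overlap=k,
            background=universe_size,
        )
        rows.append((gs.name, len(members), k, res.p_value))
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    df["significant"] = (df["p"] < p_cutoff) & (df["q"] < q_cutoff)
    return df


def top_k_report(
    results: pd.DataFrame, k: int = 10, per_direction: bool = False
) -> pd.DataFrame:
    """Top-k rows of an enrichment table.

    GSEA-style tables (with an ``nes`` column) rank by |NES| descending; ORA
    tables rank by ascending p. Ties are broken by set name for a stable,
    reproducible report. With ``per_direction`` a GSEA table returns up to k
    rows per NES sign.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    df = results.dropna(subset=["p"]).copy()
    if "nes" in df.columns:
        df["_key"] = -df["nes"].abs()
        df = df.sort_values(["_key", "set"], kind="stable").drop(columns="_key")
        if per_direction:
            pos = df[df["nes"] > 0].head(k)
            neg = df[df["nes"] < 0].head(k)
            return pd.concat([pos, neg]).reset_index(drop=True)
        return df.head(k).reset_index(drop=True)
    return (
        df.sort_values(["p", "set"], kind="stable").head(k).reset_index(drop=True)
    )
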