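"""Cross-species conserved differential-expression signatures.

Mouse DEGs are lifted into human symbol space through an ortholog map, the
two lists are intersected, and only genes moving in the same direction in
both species (up/up or down/down) are kept -- the conserved DEG set (cDEG).
The size of the raw intersection is tested for enrichment against a gene
universe of configurable size ``N`` with the one-sided hypergeometric tail,
which is equivalent to a one-sided Fisher exact test on the 2x2 table.

Symbol comparison is case-insensitive throughout: mouse symbols are
conventionally capitalized ("Myc") where human symbols are upper-case
("MYC"), and the same convention leaks into ortholog tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEGList
from .errors import DataError

__all__ = [
    "OrthologMap",
    "MappingReport",
    "ConservedSignature",
    "OverlapTestResult",
    "map_orthologs",
    "conserved_signature",
    "overlap_significance",
]

#: Default gene-universe size for the overlap test: approximate number of
#: human protein-coding genes. Always an explicit, logged parameter.
DEFAULT_BACKGROUND = 20_000


@dataclass
class OrthologMap:
    """Mouse -> human symbol pairs with case-normalized lookup."""

    pairs: pd.DataFrame  # columns mouse_symbol, human_symbol

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise DataError("ortholog map is empty")
        df = self.pairs[["mouse_symbol", "human_symbol"]].astype(str).copy()
        df["mouse_key"] = df["mouse_symbol"].str.upper()
        df["human_key"] = df["human_symbol"].str.upper()
        df = df.drop_duplicates(["mouse_key", "human_key"])
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class MappingReport:
    """Book-keeping from the ortholog lift-over, logged by the pipeline."""

    n_input: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous: int


def map_orthologs(
    deg_mouse: DEGList,
    omap: OrthologMap,
    ambiguous: str = "drop",
) -> tuple[DEGList, MappingReport]:
    """Rename mouse DEGs to human symbols.

    ``ambiguous`` controls one-to-many / many-to-one pairs:

    - ``"drop"`` (default): only strict one-to-one pairs are translated;
      everything else is discarded and counted.
    - ``"first"``: ambiguous pairs resolved to the alphabetically first
      partner (deterministic, but double-counting of the shared partner is
      possible on many-to-one maps; the first occurrence wins).
    """
    if ambiguous not in ("drop", "first"):
        raise DataError(f"unknown ambiguity policy {ambiguous!r}")
    pairs = omap.pairs
    if ambiguous == "drop":
        uniq = pairs[
            ~pairs["mouse_key"].duplicated(keep=False)
            & ~pairs["human_key"].duplicated(keep=False)
        ]
    else:
        uniq = pairs.sort_values(["mouse_key", "human_key"], kind="stable")
        uniq = uniq.drop_duplicates("mouse_key", keep="first")
        uniq = uniq.drop_duplicates("human_key", keep="first")
    lookup = dict(zip(uniq["mouse_key"], uniq["human_symbol"].str.upper()))
    in_map_at_all = set(pairs["mouse_key"])

    table = deg_mouse.table
    keys = table.index.astype(str).str.upper()
    mapped_rows, n_unmapped, n_ambiguous = [], 0, 0
    for gene, key in zip(table.index, keys):
        if key in lookup:
            mapped_rows.append((gene, lookup[key]))
        elif key in in_map_at_all:
            n_ambiguous += 1
        else:
            n_unmapped += 1
    out = table.loc[[g for g, _ in mapped_rows]].copy()
    out.index = pd.Index([h for _, h in mapped_rows], name=table.index.name)
    if out.index.has_duplicates:  # two mouse genes onto one human symbol
        dup = out.index.duplicated(keep="first")
        n_ambiguous += int(dup.sum())
        out = out[~dup]
    report = MappingReport(
        n_input=len(table),
        n_mapped=len(out),
        n_unmapped=n_unmapped,
        n_ambiguous=n_ambiguous,
    )
    return DEGList(table=out, alpha=deg_mouse.alpha), report


@dataclass
class ConservedSignature:
    """Genes DE in both species, split by concordance of direction."""

    overlap: frozenset[str]
    up: frozenset[str]       # up in both species
    down: frozenset[str]     # down in both species
    discordant: frozenset[str]
    table: pd.DataFrame      # index gene; human_logfc, mouse_logfc, human_p, direction

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise DataError("cDEG up and down sets intersect")
        if not (self.up | self.down | self.discordant) <= self.overlap:
            raise DataError("cDEG sets must be subsets of the overlap")

    @property
    def cdeg(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.cdeg)


def conserved_signature(
    deg_human: DEGList, deg_mouse_mapped: DEGList
) -> ConservedSignature:
    """Intersect the two lists (human symbol space) and keep concordant genes."""
    ht = deg_human.table.copy()
    mt = deg_mouse_mapped.table.copy()
    ht.index = ht.index.astype(str).str.upper()
    mt.index = mt.index.astype(str).str.upper()
    common = ht.index.intersection(mt.index)
    hsign = np.sign(ht.loc[common, "logfc"].to_numpy(float))
    msign = np.sign(mt.loc[common, "logfc"].to_numpy(float))
    concordant = hsign == msign
    direction = np.where(hsign > 0, "up", "down")
    table = pd.DataFrame(
        {
            "human_logfc": ht.loc[common, "logfc"].to_numpy(float),
            "mouse_logfc": mt.loc[common, "logfc"].to_numpy(float),
            "human_p": ht.loc[common, "p"].to_numpy(float)
            if "p" in ht.columns else np.nan,
            "direction": np.where(concordant, direction, "discordant"),
        },
        index=common,
    ).sort_index()
    return ConservedSignature(
        overlap=frozenset(common),
        up=frozenset(table.index[table["direction"] == "up"]),
        down=frozenset(table.index[table["direction"] == "down"]),
        discordant=frozenset(table.index[table["direction"] == "discordant"]),
        table=table,
    )


@dataclass(frozen=True)
class OverlapTestResult:
    background: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float
    odds_ratio: float

    def as_dict(self) -> dict:
        return {
            "background": self.background,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "overlap": self.overlap,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
        }


def overlap_significance(
    size_a: int, size_b: int, overlap: int, background: int = DEFAULT_BACKGROUND
) -> OverlapTestResult:
    """One-sided enrichment p for an overlap of ``overlap`` genes.

    P(X >= k) for X ~ Hypergeometric(N=background, K=size_a, n=size_b);
    symmetric in (size_a, size_b). The odds ratio is the sample odds ratio of
    the 2x2 table (inf when a margin cell is empty).
    """
    k, K, n, N = overlap, size_a, size_b, background
    if not (0 <= k <= min(K, n)):
        raise DataError(f"overlap {k} exceeds min(list sizes) ({min(K, n)})")
    if max(K, n) > N:
        raise DataError(f"list sizes ({K}, {n}) exceed background {N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    a, b, c, d = k, K - k, n - k, N - K - n + k
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return OverlapTestResult(
        background=N, size_a=K, size_b=n, overlap=k,
        p_value=p, odds_ratio=float(odds),
    )
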