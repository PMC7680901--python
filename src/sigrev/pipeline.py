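"""End-to-end orchestration: simulate -> DE -> conserve -> screen -> enrich ->
triage -> visualize.

Every stage reads its inputs from, and writes its products to, a fixed layout
under one output directory, so any stage can be re-run standalone from the
persisted intermediates of an earlier run and produce the same result as the
one-shot chain. A JSON run manifest records the full configuration, the
record count at every filter and the software version.

Directory layout::

    <outdir>/inputs/    expression, groups, ortholog, perturbagen RNK+manifest,
                        bibliometrics, gene sets, planted truth
    <outdir>/de/        per-species DEG tables
    <outdir>/conserve/  cDEG table, overlap-test report
    <outdir>/connect/   query, instance scores, summaries, hit table
    <outdir>/enrich/    ranked list, GSEA and ORA tables
    <outdir>/triage/    triaged hits, bubble plot (svg+png) and tidy table
    <outdir>/manifest.json, run.log
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import io
from .conservation import (DEFAULT_BACKGROUND, OrthologMap, conserved_signature,
                           map_orthologs, overlap_significance)
from .connectivity import (QuerySignature, RankedInstance, build_query,
                           filter_hits, score_screen, summarize_perturbagens)
from .diffexpr import DEGList, ExpressionStudy, call_degs, run_de
from .enrichment import GeneSet, gsea, ora_test, top_k_report
from .errors import ConfigError, DataError, SigrevError
from .simulate import (PlantedTruth, SimulationConfig, simulate_bibliometrics,
                       simulate_expression_pair, simulate_gene_sets,
                       simulate_perturbagen_db)
from .triage import BubbleConfig, rank_candidates, render_bubble_plot, score_table

__all__ = ["RunConfig", "RunManifest", "run_all", "STAGES"]

log = logging.getLogger("sigrev")

STAGES = ("simulate", "de", "conserve", "connect", "enrich", "bibscore", "viz")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05                 # raw-p DE threshold
    background: int = DEFAULT_BACKGROUND  # overlap-test gene universe
    ambiguous_policy: str = "drop"      # ortholog one-to-many handling
    max_per_side: int = 1000            # query tags per side
    cell_line: str = "HL60"             # hit filter
    min_n: int = 3
    hit_direction: str = "negative"
    connectivity_n_perm: int = 10_000
    enrichment_n_perm: int = 10_000
    enrichment_weight: float = 1.0
    top_k: int = 10
    biblio_w: float = 2.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            try:
                self.simulation = SimulationConfig(**self.simulation)
            except TypeError as exc:
                raise ConfigError(f"bad simulation config: {exc}") from exc
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.background < 1:
            raise ConfigError("background must be positive")
        if self.max_per_side < 1 or self.min_n < 1 or self.top_k < 1:
            raise ConfigError("max_per_side, min_n and top_k must be >= 1")
        if self.hit_direction not in ("negative", "positive", "both"):
            raise ConfigError(f"bad hit_direction {self.hit_direction!r}")
        if self.connectivity_n_perm < 1 or self.enrichment_n_perm < 100:
            raise ConfigError("permutation counts too small")
        # the root seed propagates into the simulation unless set explicitly there
        if self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    counts: dict
    seed: int
    version: str
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _dirs(outdir: str) -> dict[str, str]:
    paths = {
        name: os.path.join(outdir, name)
        for name in ("inputs", "de", "conserve", "connect", "enrich", "triage")
    }
    paths["inputs_db"] = os.path.join(paths["inputs"], "perturbagens")
    return paths


def _ensure(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path


# ------------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["inputs"]); _ensure(d["inputs_db"])
    study_h, study_m, omap, truth = simulate_expression_pair(cfg.simulation)
    db = simulate_perturbagen_db(cfg.simulation, truth)
    biblio = simulate_bibliometrics(
        sorted(db.manifest["perturbagen"].unique()), seed=cfg.seed
    )
    sets = simulate_gene_sets(truth, seed=cfg.seed)

    io.write_expression(study_h.values, os.path.join(d["inputs"], "human_expr.tsv"))
    io.write_groups(study_h.groups, os.path.join(d["inputs"], "human_groups.tsv"))
    io.write_expression(study_m.values, os.path.join(d["inputs"], "mouse_expr.tsv"))
    io.write_groups(study_m.groups, os.path.join(d["inputs"], "mouse_groups.tsv"))
    io.write_ortholog_map(omap.pairs, os.path.join(d["inputs"], "orthologs.tsv"))
    manifest = db.manifest.copy()
    for i, inst in enumerate(db.instances):
        rel = os.path.join("perturbagens", f"{inst.instance_id}.rnk")
        io.write_rnk(db.scores[inst.instance_id], os.path.join(d["inputs"], rel))
        manifest.loc[i, "path"] = rel
    io.write_manifest(manifest, os.path.join(d["inputs"], "db_manifest.tsv"))
    biblio.to_csv(os.path.join(d["inputs"], "biblio.tsv"), sep="\t", index=False)
    io.write_gmt(
        [(s.name, s.collection, sorted(s.genes)) for s in sets],
        os.path.join(d["inputs"], "gene_sets.gmt"),
    )
    with open(os.path.join(d["inputs"], "truth.json"), "w") as fh:
        json.dump(truth.as_dict(), fh, sort_keys=True, default=str)
        fh.write("\n")
    log.info("simulate: %d genes, %d instances", cfg.simulation.n_genes, len(db))
    return {"genes_in": cfg.simulation.n_genes, "instances": len(db)}


def _load_study(outdir: str, species: str) -> ExpressionStudy:
    d = _dirs(outdir)
    prefix = "human" if species == "human" else "mouse"
    return ExpressionStudy(
        values=io.read_expression(os.path.join(d["inputs"], f"{prefix}_expr.tsv")),
        groups=io.read_groups(os.path.join(d["inputs"], f"{prefix}_groups.tsv")),
        species=species,
    )


def stage_de(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["de"])
    counts = {}
    for species in ("human", "mouse"):
        study = _load_study(outdir, species)
        prior, table, degs = run_de(study, alpha=cfg.alpha)
        io.write_deg_table(table, os.path.join(d["de"], f"{species}_degs.tsv"))
        counts[f"degs_{species}"] = len(degs)
        log.info("de[%s]: %d/%d genes at p<%g (prior d0=%.3g, s0^2=%.3g)",
                 species, len(degs), len(table), cfg.alpha, prior.d0, prior.s0_sq)
    return counts


def stage_conserve(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["conserve"])
    human = call_degs(
        io.read_deg_table(os.path.join(d["de"], "human_degs.tsv")), cfg.alpha
    )
    mouse = call_degs(
        io.read_deg_table(os.path.join(d["de"], "mouse_degs.tsv")), cfg.alpha
    )
    omap = OrthologMap(io.read_ortholog_map(os.path.join(d["inputs"], "orthologs.tsv")))
    mouse_mapped, report = map_orthologs(mouse, omap, ambiguous=cfg.ambiguous_policy)
    log.info("conserve: mapped %d/%d mouse DEGs (%d unmapped, %d ambiguous)",
             report.n_mapped, report.n_input, report.n_unmapped, report.n_ambiguous)
    csig = conserved_signature(human, mouse_mapped)
    test = overlap_significance(
        size_a=len(human.table), size_b=len(mouse_mapped.table),
        overlap=len(csig.overlap), background=cfg.background,
    )
    io.write_deg_table(csig.table, os.path.join(d["conserve"], "cdeg.tsv"))
    with open(os.path.join(d["conserve"], "overlap_test.json"), "w") as fh:
        json.dump({**test.as_dict(), "mapping": asdict(report)}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    log.info("conserve: overlap %d, cDEG %d (up %d / down %d), p=%.3g",
             len(csig.overlap), len(csig), len(csig.up), len(csig.down),
             test.p_value)
    return {"overlap": len(csig.overlap), "cdeg": len(csig),
            "cdeg_up": len(csig.up), "cdeg_down": len(csig.down)}


def _load_csig_tables(outdir: str):
    d = _dirs(outdir)
    cdeg = io._read_table(os.path.join(d["conserve"], "cdeg.tsv"), index_col=0)
    human = io.read_deg_table(os.path.join(d["de"], "human_degs.tsv"))
    return cdeg, human


def _query_from_tables(cdeg: pd.DataFrame, max_per_side: int) -> QuerySignature:
    def side(direction: str) -> tuple[str, ...]:
        sub = cdeg[cdeg["direction"] == direction]
        if len(sub) == 0:
            raise DataError(f"conserved signature has no {direction}-regulated genes")
        ordered = sub.assign(_g=sub.index.astype(str)).sort_values(
            ["human_p", "_g"], kind="stable"
        )
        return tuple(ordered.index.astype(str)[:max_per_side])

    return QuerySignature(up=side("up"), down=side("down"))


def load_instances(outdir: str) -> list[RankedInstance]:
    d = _dirs(outdir)
    manifest = io.read_manifest(os.path.join(d["inputs"], "db_manifest.tsv"))
    instances = []
    for row in manifest.itertuples():
        scores = io.read_rnk(os.path.join(d["inputs"], row.path))
        order = scores.sort_values(ascending=False, kind="stable")
        instances.append(RankedInstance(
            instance_id=row.instance_id, perturbagen=row.perturbagen,
            cell_line=row.cell_line, genes=tuple(order.index),
        ))
    return instances


def stage_connect(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["connect"])
    cdeg, _ = _load_csig_tables(outdir)
    query = _query_from_tables(cdeg, cfg.max_per_side)
    io.write_query_grp(query.up, query.down,
                       os.path.join(d["connect"], "query.grp"))
    instances = load_instances(outdir)
    scores = score_screen(query, instances)
    summaries = summarize_perturbagens(
        scores, n_perm=cfg.connectivity_n_perm, seed=cfg.seed
    )
    hits = filter_hits(summaries, cell_line=cfg.cell_line, min_n=cfg.min_n,
                       direction=cfg.hit_direction)
    scores.to_csv(os.path.join(d["connect"], "instance_scores.tsv"),
                  sep="\t", index=False, float_format=io.FLOAT_FMT)
    summaries.to_csv(os.path.join(d["connect"], "summaries.tsv"),
                     sep="\t", index=False, float_format=io.FLOAT_FMT)
    hits.to_csv(os.path.join(d["connect"], "hits.tsv"),
                sep="\t", index=False, float_format=io.FLOAT_FMT)
    log.info("connect: %d instances scored, %d summaries, %d hits "
             "(%s, n>=%d, %s ES)", len(scores), len(summaries), len(hits),
             cfg.cell_line, cfg.min_n, cfg.hit_direction)
    return {"instances_scored": len(scores), "hits": len(hits),
            "query_up": len(query.up), "query_down": len(query.down)}


def stage_enrich(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["enrich"])
    human = io.read_deg_table(os.path.join(d["de"], "human_degs.tsv"))
    ranked = pd.Series(human["t"].to_numpy(float), index=human.index.astype(str))
    io.write_rnk(ranked, os.path.join(d["enrich"], "ranked.rnk"))
    raw_sets = io.read_gmt(os.path.join(d["inputs"], "gene_sets.gmt"))
    sets = [GeneSet(name, frozenset(members), collection=desc)
            for name, desc, members in raw_sets]
    gsea_table = gsea(ranked, sets, n_perm=cfg.enrichment_n_perm, seed=cfg.seed,
                      weight=cfg.enrichment_weight)
    cdeg, _ = _load_csig_tables(outdir)
    cdeg_genes = cdeg.index[cdeg["direction"].isin(["up", "down"])].astype(str)
    ora_table = ora_test(cdeg_genes, sets, universe_size=cfg.background)
    gsea_table.to_csv(os.path.join(d["enrich"], "gsea.tsv"), sep="\t",
                      index=False, float_format=io.FLOAT_FMT)
    ora_table.to_csv(os.path.join(d["enrich"], "ora.tsv"), sep="\t",
                     index=False, float_format=io.FLOAT_FMT)
    top = top_k_report(gsea_table, k=cfg.top_k, per_direction=True)
    top.to_csv(os.path.join(d["enrich"], "gsea_top.tsv"), sep="\t",
               index=False, float_format=io.FLOAT_FMT)
    log.info("enrich: %d sets (GSEA), %d significant (ORA)", len(gsea_table),
             int(ora_table["significant"].sum()))
    return {"gene_sets": len(sets),
            "ora_significant": int(ora_table["significant"].sum())}


def stage_bibscore(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["triage"])
    biblio = io._read_table(os.path.join(d["inputs"], "biblio.tsv"))
    scored = score_table(biblio, w=cfg.biblio_w)
    hits = io._read_table(os.path.join(d["connect"], "hits.tsv"))
    triaged = rank_candidates(hits, scored)
    scored.to_csv(os.path.join(d["triage"], "biblio_scores.tsv"), sep="\t",
                  index=False, float_format=io.FLOAT_FMT)
    triaged.to_csv(os.path.join(d["triage"], "triaged.tsv"), sep="\t",
                   index=False, float_format=io.FLOAT_FMT)
    log.info("bibscore: %d hits triaged, %d unstudied", len(triaged),
             int(triaged["unstudied"].sum()) if len(triaged) else 0)
    return {"triaged": len(triaged)}


def stage_viz(cfg: RunConfig, outdir: str) -> dict:
    d = _dirs(outdir)
    _ensure(d["triage"])
    summaries = io._read_table(os.path.join(d["connect"], "summaries.tsv"))
    scored = io._read_table(os.path.join(d["triage"], "biblio_scores.tsv"))
    plot_in = summaries[summaries["n"] >= cfg.min_n].copy()
    if len(plot_in) == 0:
        log.warning("viz: no summary reaches n >= %d; skipping plot", cfg.min_n)
        return {"plotted": 0}
    lookup = scored.set_index("molecule")["score"]
    plot_in["biblio_score"] = [
        float(lookup.get(m, -np.inf)) for m in plot_in["perturbagen"]
    ]
    tidy = render_bubble_plot(
        plot_in, out_image=os.path.join(d["triage"], "bubble.svg"),
        config=BubbleConfig(seed=cfg.seed),
    )
    tidy.to_csv(os.path.join(d["triage"], "bubble_table.tsv"), sep="\t",
                index=False, float_format=io.FLOAT_FMT)
    log.info("viz: %d bubbles over %d cell lines", len(tidy),
             tidy["cell_line"].nunique())
    return {"plotted": len(tidy)}


_STAGE_FN = {
    "simulate": stage_simulate,
    "de": stage_de,
    "conserve": stage_conserve,
    "connect": stage_connect,
    "enrich": stage_enrich,
    "bibscore": stage_bibscore,
    "viz": stage_viz,
}


def _setup_logging(outdir: str, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(os.path.join(outdir, "run.log"))
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def run_all(cfg: RunConfig, outdir: str,
            stages: tuple[str, ...] = STAGES) -> RunManifest:
    """Run the requested stages in order; halt (and record) on first failure."""
    from . import __version__

    _ensure(outdir)
    _setup_logging(outdir, cfg.log_level)
    manifest = RunManifest(
        config=cfg.as_dict(), counts={}, seed=cfg.seed, version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    try:
        for name in stages:
            if name not in _STAGE_FN:
                raise ConfigError(f"unknown stage {name!r}; known: {STAGES}")
            manifest.counts.update(_STAGE_FN[name](cfg, outdir))
    except SigrevError as exc:
        manifest.failed_stage = name
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.write(os.path.join(outdir, "manifest.json"))
        log.error("stage %s failed: %s", name, exc)
        raise
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest
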