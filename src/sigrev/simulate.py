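"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical shape of a two-species (human/mouse)
case-control transcriptomics comparison and of a ranked-list perturbagen
reference, with every planted fact recorded so downstream stages can be
scored against a known answer:

* paired expression studies on a log scale (Gaussian noise around group
  means), sharing a planted orthologous, direction-concordant DE core plus
  species-private and deliberately discordant DE genes;
* an explicit mouse->human symbol map (mouse symbols are case-variants of
  the human ones with a suffix, so nothing works by accidental string
  identity), with a configurable fraction of genes missing from the map;
* a perturbagen reference whose planted "reversers" have latent effect
  vectors anti-correlated with the disease signature, "mimickers"
  positively correlated, and neutral drugs pure noise. Instance rankings
  order genes by effect + orthogonal noise; the noise share is tied to the
  correlation (x = s*rho*u + sqrt(1-rho^2)*eps), so reversal_strength=1
  means a noise-free, perfectly anti-correlated profile;
* Poisson bibliometric counts and a small GMT collection containing modules
  built from the planted up/down core among random filler sets.

All randomness flows from one root seed through named substreams
(:mod:`sigrev.util`), so each product is reproducible in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conservation import OrthologMap
from .connectivity import RankedInstance
from .diffexpr import ExpressionStudy
from .enrichment import GeneSet
from .errors import ConfigError, DataError
from .util import substream

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "PerturbagenDB",
    "CELL_LINES",
    "simulate_expression_pair",
    "simulate_perturbagen_db",
    "simulate_bibliometrics",
    "simulate_gene_sets",
]

CELL_LINES = ("HL60", "MCF7", "PC3")

# planted per-gene statuses
SHARED = "shared"              # DE in both species, same sign
PRIVATE_HUMAN = "private_human"
PRIVATE_MOUSE = "private_mouse"
DISCORDANT = "discordant"      # DE in both, opposite signs
NULL = "null"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_genes: int = 2000
    n_case: int = 13        # cases per species (13 leukemic vs 17 control
    n_control: int = 17     # samples mirrors the human study design)
    frac_de_shared: float = 0.05
    frac_de_private: float = 0.15
    frac_discordant: float = 0.02
    effect_logfc: float = 2.0
    noise_sd: float = 1.0
    ortholog_missing_frac: float = 0.10
    n_perturbagens: int = 50
    instances_per_perturbagen: int = 3
    n_reversers: int = 3
    n_mimickers: int = 2
    reversal_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_case", "n_control", "n_perturbagens",
                     "instances_per_perturbagen"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("frac_de_shared", "frac_de_private", "frac_discordant",
                     "ortholog_missing_frac", "reversal_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        total = self.frac_de_shared + self.frac_de_private + self.frac_discordant
        if total > 1.0 + 1e-12:
            raise ConfigError(f"DE fractions sum to {total:.3f} > 1")
        if self.n_reversers < 0 or self.n_mimickers < 0:
            raise ConfigError("planted drug counts must be non-negative")
        if self.n_reversers + self.n_mimickers > self.n_perturbagens:
            raise ConfigError("n_reversers + n_mimickers exceeds n_perturbagens")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth covering every simulated gene and perturbagen."""

    genes: pd.DataFrame  # index human_symbol; mouse_symbol, status,
                         # true_lfc_human, true_lfc_mouse, in_ortholog_map
    drugs: pd.DataFrame | None = None  # perturbagen, label, cell_line

    @property
    def shared_concordant(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["status"] == SHARED])

    def shared_by_sign(self, positive: bool) -> frozenset[str]:
        sel = (self.genes["status"] == SHARED) & (
            (self.genes["true_lfc_human"] > 0) == positive
        )
        return frozenset(self.genes.index[sel])

    def drug_labels(self) -> pd.Series:
        if self.drugs is None:
            raise DataError("perturbagen truth not populated yet")
        return self.drugs.set_index("perturbagen")["label"]

    def as_dict(self) -> dict:
        d = {"genes": self.genes.reset_index().to_dict(orient="list")}
        if self.drugs is not None:
            d["drugs"] = self.drugs.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        genes = pd.DataFrame(d["genes"]).set_index("human_symbol")
        drugs = pd.DataFrame(d["drugs"]) if "drugs" in d else None
        return cls(genes=genes, drugs=drugs)


@dataclass
class PerturbagenDB:
    """The screening reference: ranked instances plus their manifest."""

    instances: list[RankedInstance]
    manifest: pd.DataFrame  # instance_id, perturbagen, cell_line, path
    scores: dict[str, pd.Series] = field(default_factory=dict)  # latent, for RNK

    def __len__(self) -> int:
        return len(self.instances)


def _gene_symbols(n: int) -> tuple[list[str], list[str]]:
    width = max(4, len(str(n)))
    human = [f"GENE{i:0{width}d}" for i in range(1, n + 1)]
    mouse = [h.capitalize() + "m" for h in human]  # case-variant + suffix
    return human, mouse


def simulate_expression_pair(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, OrthologMap, PlantedTruth]:
    """Two species-specific case/control studies with a planted shared core."""
    rng = substream(config.seed, "expression")
    n = config.n_genes
    human_sym, mouse_sym = _gene_symbols(n)

    n_shared = round(config.frac_de_shared * n)
    n_private = round(config.frac_de_private * n)
    n_disc = round(config.frac_discordant * n)
    status = np.array(
        [SHARED] * n_shared
        + [PRIVATE_HUMAN] * (n_private // 2)
        + [PRIVATE_MOUSE] * (n_private - n_private // 2)
        + [DISCORDANT] * n_disc
        + [NULL] * (n - n_shared - n_private - n_disc)
    )
    status = status[rng.permutation(n)]

    sign = rng.choice([-1.0, 1.0], size=n)
    lfc_h = np.zeros(n)
    lfc_m = np.zeros(n)
    eff = config.effect_logfc
    lfc_h[status == SHARED] = sign[status == SHARED] * eff
    lfc_m[status == SHARED] = sign[status == SHARED] * eff
    lfc_h[status == PRIVATE_HUMAN] = sign[status == PRIVATE_HUMAN] * eff
    lfc_m[status == PRIVATE_MOUSE] = sign[status == PRIVATE_MOUSE] * eff
    lfc_h[status == DISCORDANT] = sign[status == DISCORDANT] * eff
    lfc_m[status == DISCORDANT] = -sign[status == DISCORDANT] * eff

    def build_study(symbols, lfc, species, prefix):
        baseline = rng.normal(7.0, 1.0, size=n)
        nc, nk = config.n_control, config.n_case
        cols = [f"{prefix}_ctrl_{i+1:02d}" for i in range(nc)] + [
            f"{prefix}_case_{i+1:02d}" for i in range(nk)
        ]
        mean = baseline[:, None] + np.concatenate(
            [np.zeros((n, nc)), np.tile(lfc[:, None], (1, nk))], axis=1
        )
        values = mean + rng.normal(0.0, config.noise_sd, size=(n, nc + nk))
        groups = pd.Series(
            ["control"] * nc + ["case"] * nk, index=cols, name="group"
        )
        return ExpressionStudy(
            values=pd.DataFrame(values, index=pd.Index(symbols, name="gene"),
                                columns=cols),
            groups=groups,
            species=species,
        )

    study_h = build_study(human_sym, lfc_h, "human", "hs")
    study_m = build_study(mouse_sym, lfc_m, "mouse", "mm")

    n_missing = round(config.ortholog_missing_frac * n)
    missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist())
    pairs = pd.DataFrame(
        [(mouse_sym[i], human_sym[i]) for i in range(n) if i not in missing_idx],
        columns=["mouse_symbol", "human_symbol"],
    )
    omap = OrthologMap(pairs=pairs)

    truth = PlantedTruth(
        genes=pd.DataFrame(
            {
                "mouse_symbol": mouse_sym,
                "status": status,
                "true_lfc_human": lfc_h,
                "true_lfc_mouse": lfc_m,
                "in_ortholog_map": [i not in missing_idx for i in range(n)],
            },
            index=pd.Index(human_sym, name="human_symbol"),
        )
    )
    return study_h, study_m, omap, truth


def simulate_perturbagen_db(
    config: SimulationConfig, truth: PlantedTruth
) -> PerturbagenDB:
    """Ranked-list reference with planted reversers and mimickers.

    Each instance ranks the human gene universe by a latent profile
    x = s * rho * u + sqrt(1 - rho^2) * eps, where u is the standardized
    disease log-fold-change vector, rho the configured reversal strength,
    s = -1 for reversers / +1 for mimickers, and eps fresh standard-normal
    noise per instance (neutral drugs are pure eps). Planted drugs are pinned
    to the first cell line so the default screening filter can see them with
    their full instance count; neutral drugs round-robin across all lines so
    every band of the visualization is populated.
    """
    rng = substream(config.seed, "perturbagens")
    lfc = truth.genes["true_lfc_human"].to_numpy(float)
    genes = np.asarray(truth.genes.index)
    n = len(genes)
    n_planted = config.n_reversers + config.n_mimickers
    if n_planted > 0 and np.allclose(lfc, 0.0):
        raise DataError(
            "planted truth carries no disease signature (all true logFC zero); "
            "cannot plant reversers/mimickers"
        )
    sd = lfc.std()
    u = (lfc - lfc.mean()) / sd if sd > 0 else np.zeros(n)

    width = max(3, len(str(config.n_perturbagens)))
    names = [f"cmpd-{i:0{width}d}" for i in range(1, config.n_perturbagens + 1)]
    labels = np.array(
        ["reverser"] * config.n_reversers
        + ["mimicker"] * config.n_mimickers
        + ["neutral"] * (config.n_perturbagens - n_planted)
    )
    labels = labels[rng.permutation(config.n_perturbagens)]

    cell_lines = []
    rr = 0
    for lab in labels:
        if lab == "neutral":
            cell_lines.append(CELL_LINES[rr % len(CELL_LINES)])
            rr += 1
        else:
            cell_lines.append(CELL_LINES[0])

    rho = config.reversal_strength
    resid = np.sqrt(max(0.0, 1.0 - rho * rho))
    instances: list[RankedInstance] = []
    rows = []
    scores: dict[str, pd.Series] = {}
    for name, lab, line in zip(names, labels, cell_lines):
        s = {"reverser": -1.0, "mimicker": 1.0, "neutral": 0.0}[lab]
        for j in range(config.instances_per_perturbagen):
            eps = rng.standard_normal(n)
            x = eps if s == 0.0 else s * rho * u + resid * eps
            order = np.argsort(-x, kind="stable")  # ties: lowest gene index first
            iid = f"{name}_i{j+1:02d}"
            instances.append(
                RankedInstance(
                    instance_id=iid,
                    perturbagen=name,
                    cell_line=line,
                    genes=tuple(genes[order]),
                )
            )
            scores[iid] = pd.Series(x[order], index=genes[order])
            rows.append((iid, name, line, ""))
    manifest = pd.DataFrame(
        rows, columns=["instance_id", "perturbagen", "cell_line", "path"]
    )
    truth.drugs = pd.DataFrame(
        {"perturbagen": names, "label": labels, "cell_line": cell_lines}
    )
    return PerturbagenDB(instances=instances, manifest=manifest, scores=scores)


def simulate_bibliometrics(
    molecules: list[str],
    seed: int = 0,
    trial_rate: float = 2.0,
    pub_rate: float = 10.0,
) -> pd.DataFrame:
    """Poisson trial/publication counts and a uniform impact tier per molecule."""
    if not molecules:
        raise DataError("empty molecule list")
    if trial_rate < 0 or pub_rate < 0:
        raise ConfigError("Poisson rates must be non-negative")
    rng = substream(seed, "bibliometrics")
    m = len(molecules)
    return pd.DataFrame(
        {
            "molecule": list(molecules),
            "c": rng.poisson(trial_rate, m),
            "p": rng.poisson(pub_rate, m),
            "i": rng.integers(1, 4, m),
        }
    )


def simulate_gene_sets(
    truth: PlantedTruth,
    seed: int = 0,
    n_random: int = 15,
    set_size: int = 40,
) -> list[GeneSet]:
    """A small collection: planted up/down modules plus random filler sets."""
    rng = substream(seed, "gene_sets")
    universe = np.asarray(truth.genes.index)
    sets: list[GeneSet] = []
    up = sorted(truth.shared_by_sign(True))
    down = sorted(truth.shared_by_sign(False))
    if up:
        sets.append(GeneSet("PLANTED_UP_MODULE", frozenset(up[:set_size]),
                            collection="planted"))
    if down:
        sets.append(GeneSet("PLANTED_DOWN_MODULE", frozenset(down[:set_size]),
                            collection="planted"))
    for k in range(1, n_random + 1):
        members = rng.choice(universe, size=min(set_size, len(universe)),
                             replace=False)
        sets.append(GeneSet(f"RANDOM_SET_{k:02d}", frozenset(members.tolist()),
                            collection="random"))
    return sets
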