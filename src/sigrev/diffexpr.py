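"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the classical moderated t for normalized log-scale expression:
for gene g with pooled within-group variance s2_g on d_g residual degrees of
freedom, the gene variances are shrunk toward a common prior variance s0^2
with prior degrees of freedom d0,

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated statistic

    t_g = logFC_g / (s_tilde_g * sqrt(1/n_case + 1/n_control))

is referred to a t distribution on d0 + d_g degrees of freedom.

The hyperparameters (d0, s0^2) are estimated by moment matching on the log
scale: under the hierarchical model s2_g ~ s0^2 * F(d_g, d0), so

    E[log s2_g]   = log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2)
    Var[log s2_g] = psi'(d_g/2) + psi'(d0/2)

where psi is the digamma function. Solving the second equation for d0 (via
the trigamma inverse) and substituting into the first gives s0^2. When the
empirical variance of log s2_g does not exceed psi'(d_g/2) there is no
evidence of gene-to-gene variance heterogeneity and d0 is set to infinity
(complete shrinkage: every s2_tilde_g = s0^2, normal reference distribution).

By design p-values are raw (no multiplicity correction is applied before
thresholding); a Benjamini-Hochberg ``q`` column is emitted for reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "ExpressionStudy",
    "ModerationParams",
    "DEGList",
    "fit_two_groups",
    "ebayes_moderate",
    "call_degs",
    "run_de",
]

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionStudy:
    """Normalized genes x samples matrix with a two-group design."""

    values: pd.DataFrame
    groups: pd.Series  # sample id -> "case" | "control"
    species: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("gene symbols must be unique")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise DataError(f"samples without group label: {sorted(missing)[:5]}")
        labels = set(self.groups.loc[list(self.values.columns)])
        if labels != {CASE, CONTROL}:
            raise DataError(
                f"need exactly the two groups {{'case', 'control'}}, got {sorted(labels)}"
            )
        for grp in (CASE, CONTROL):
            if len(self.samples(grp)) < 2:
                raise DataError(f"group {grp!r} has fewer than 2 samples")

    def samples(self, group: str) -> list[str]:
        mask = self.groups.loc[list(self.values.columns)] == group
        return [s for s, m in mask.items() if m]


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: degrees of freedom d0 (may be inf), variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise DataError("moderation prior requires d0 > 0 and s0^2 > 0")


@dataclass
class DEGList:
    """Significant genes split by direction; the underlying rows are retained."""

    table: pd.DataFrame  # index gene; columns logfc, p, direction (at least)
    alpha: float = 0.05

    @property
    def up(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["direction"] == "down"])

    def __len__(self) -> int:
        return len(self.table)


def fit_two_groups(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene effect and pooled variance for a case/control design.

    Returns a frame indexed by gene with columns ``logfc`` (case minus
    control), ``s2`` (pooled within-group variance), ``df`` (residual degrees
    of freedom), ``n_case`` and ``n_control``.
    """
    case = study.values[study.samples(CASE)].to_numpy(float)
    ctrl = study.values[study.samples(CONTROL)].to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    dof = n1 + n2 - 2
    return pd.DataFrame(
        {"logfc": logfc, "s2": ss / dof, "df": float(dof),
         "n_case": n1, "n_control": n2},
        index=study.values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 (psi' is strictly decreasing)."""
    lo, hi = 1e-8, 1e8
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi)


def estimate_prior(fit: pd.DataFrame) -> ModerationParams:
    """Moment-match (d0, s0^2) from the log sample variances (see module docs)."""
    s2 = fit["s2"].to_numpy(float)
    dof = fit["df"].to_numpy(float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise DataError(
            "need at least 10 genes with positive variance to estimate the prior: "
            "add noise to the data or supply an explicit ModerationParams"
        )
    e = np.log(s2[ok]) - special.digamma(dof[ok] / 2) + np.log(dof[ok] / 2)
    excess = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, dof[ok] / 2)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = float(np.mean(e)) + special.digamma(d0 / 2) - np.log(d0 / 2)
    else:
        d0 = np.inf
        log_s0 = float(np.mean(e))
    return ModerationParams(d0=d0, s0_sq=float(np.exp(log_s0)))


def ebayes_moderate(
    fit: pd.DataFrame, prior: ModerationParams | None = None
) -> tuple[ModerationParams, pd.DataFrame]:
    """Moderated t, two-sided p and BH q for every gene of ``fit``.

    ``prior=None`` (the default) estimates (d0, s0^2) from the data; passing an
    explicit :class:`ModerationParams` overrides it, which the tests use to
    probe the d0 -> 0 (ordinary t) and d0 -> inf (full shrinkage) limits.
    """
    if prior is None:
        prior = estimate_prior(fit)
    s2 = fit["s2"].to_numpy(float)
    dof = fit["df"].to_numpy(float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + dof * s2) / (prior.d0 + dof)
        df_total = prior.d0 + dof
    sem = np.sqrt(
        s2_post * (1.0 / fit["n_case"].to_numpy(float)
                   + 1.0 / fit["n_control"].to_numpy(float))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit["logfc"].to_numpy(float) / sem
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no effect, no evidence
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "logfc": fit["logfc"],
            "s2": fit["s2"],
            "df": fit["df"],
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": multipletests(p, method="fdr_bh")[1],
            "direction": np.where(fit["logfc"].to_numpy(float) >= 0, "up", "down"),
            "zero_variance": s2 == 0.0,
        },
        index=fit.index,
    )
    return prior, table


def call_degs(table: pd.DataFrame, alpha: float = 0.05) -> DEGList:
    """Genes with raw p strictly below ``alpha``, split by logFC sign."""
    if not 0 < alpha <= 1:
        raise DataError(f"alpha must lie in (0, 1], got {alpha}")
    hit = table[table["p"] < alpha].copy()
    return DEGList(table=hit, alpha=alpha)


def run_de(study: ExpressionStudy, alpha: float = 0.05,
           prior: ModerationParams | None = None
           ) -> tuple[ModerationParams, pd.DataFrame, DEGList]:
    """Convenience chain: fit -> moderate -> threshold."""
    prior, table = ebayes_moderate(fit_two_groups(study), prior=prior)
    return prior, table, call_degs(table, alpha=alpha)
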