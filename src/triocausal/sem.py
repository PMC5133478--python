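"""Structural equation models over three-node causal DAGs, selected by AIC.

The node set is {SNP, GE, PHEN} with the SNP exogenous (no model in which the
SNP is caused by another variable is admissible) and at most one edge between
GE and PHEN (acyclicity). That leaves 12 DAGs. Five of them carry the letter
labels conventional for this problem:

    (a) SNP->GE, SNP->PHEN      independent pleiotropic effects
    (b) SNP->GE, GE->PHEN       expression mediates the SNP effect
    (c) SNP->PHEN, PHEN->GE     phenotype mediates the SNP effect
    (d) SNP->GE, PHEN->GE       expression is a collider of SNP and phenotype
    (f) SNP->GE                 expression-only association

The remaining seven get descriptive labels. Each DAG is fitted as a recursive
linear Gaussian system: every endogenous continuous node (GE, PHEN) is a
linear regression on its parents (intercept-only when parentless) with
ML residual variance (denominator n), so the joint likelihood factorises into
per-equation Gaussian likelihoods. The SNP marginal is excluded from the
likelihood: it is identical across models and would otherwise require a
binomial marginal term that cancels in every AIC difference.

Distinct DAGs sharing skeleton and v-structures (Markov-equivalent ones, e.g.
the two 3-edge DAGs) achieve identical maximised likelihood and parameter
count, hence identical AIC on any data; ties are therefore expected and are
surfaced in the result rather than silently broken.
"""
from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd

from ._regression import gaussian_ml_loglik, ols_rss

EDGE_SG = "SNP->GE"
EDGE_SP = "SNP->PHEN"
EDGE_GP = "GE->PHEN"
EDGE_PG = "PHEN->GE"
ALL_EDGES = (EDGE_SG, EDGE_SP, EDGE_GP, EDGE_PG)

AIC_TIE_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class CausalDAG:
    """A labeled DAG on {SNP, GE, PHEN} with the SNP exogenous."""

    label: str
    edges: frozenset

    def __post_init__(self) -> None:
        bad = set(self.edges) - set(ALL_EDGES)
        if bad:
            raise ValueError(f"unknown edges {sorted(bad)}")
        if EDGE_GP in self.edges and EDGE_PG in self.edges:
            raise ValueError("GE->PHEN and PHEN->GE cannot both be present (cycle)")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self, node: str) -> tuple[str, ...]:
        if node == "GE":
            out = []
            if EDGE_SG in self.edges:
                out.append("SNP")
            if EDGE_PG in self.edges:
                out.append("PHEN")
            return tuple(out)
        if node == "PHEN":
            out = []
            if EDGE_SP in self.edges:
                out.append("SNP")
            if EDGE_GP in self.edges:
                out.append("GE")
            return tuple(out)
        if node == "SNP":
            return ()
        raise ValueError(f"unknown node {node!r}")


def _build_registry() -> list[CausalDAG]:
    named = {
        frozenset(): "null",
        frozenset({EDGE_SG}): "(f)",
        frozenset({EDGE_SP}): "snp_to_phen_only",
        frozenset({EDGE_SG, EDGE_SP}): "(a)",
        frozenset({EDGE_GP}): "ge_to_phen_only",
        frozenset({EDGE_SG, EDGE_GP}): "(b)",
        frozenset({EDGE_SP, EDGE_GP}): "snp_and_ge_to_phen",
        frozenset({EDGE_SG, EDGE_SP, EDGE_GP}): "full_ge_to_phen",
        frozenset({EDGE_PG}): "phen_to_ge_only",
        frozenset({EDGE_SG, EDGE_PG}): "(d)",
        frozenset({EDGE_SP, EDGE_PG}): "(c)",
        frozenset({EDGE_SG, EDGE_SP, EDGE_PG}): "full_phen_to_ge",
    }
    dags = []
    for sg in (False, True):
        for sp in (False, True):
            for gp_dir in (None, EDGE_GP, EDGE_PG):
                edges = set()
                if sg:
                    edges.add(EDGE_SG)
                if sp:
                    edges.add(EDGE_SP)
                if gp_dir:
                    edges.add(gp_dir)
                fs = frozenset(edges)
                dags.append(CausalDAG(named[fs], fs))
    order = list(named.values())
    dags.sort(key=lambda d: order.index(d.label))
    return dags


_REGISTRY = _build_registry()
DAG_BY_LABEL = {d.label: d for d in _REGISTRY}


def enumerate_dags(preset: str = "all") -> list[CausalDAG]:
    """All 12 admissible DAGs, or ``"paper_sem"`` = all minus (f).

    The (f) topology (expression associated with the SNP, phenotype entirely
    unlinked) is the one classically absent from the SEM comparison menu.
    """
    if preset == "all":
        return list(_REGISTRY)
    if preset == "paper_sem":
        return [d for d in _REGISTRY if d.label != "(f)"]
    raise ValueError(f"unknown preset {preset!r} (expected 'all' or 'paper_sem')")


@dataclasses.dataclass
class SemFitResult:
    """Per-DAG fit table plus the AIC-selected label and its tie set."""

    table: pd.DataFrame  # label, log_likelihood, n_params, aic, n_edges
    selected: str
    tie_set: tuple[str, ...]

    @property
    def selected_dag(self) -> CausalDAG:
        return DAG_BY_LABEL[self.selected]


def fit_sem(trio, dag: CausalDAG) -> tuple[float, int]:
    """ML fit of one DAG on a trio; returns (log_likelihood, n_params).

    The likelihood is the product of the GE and PHEN regression equations
    (each an OLS fit with ML variance); the SNP marginal is omitted.
    """
    data = {
        "SNP": np.asarray(trio.dosage, dtype=float),
        "GE": np.asarray(trio.expression, dtype=float),
        "PHEN": np.asarray(trio.phenotype, dtype=float),
    }
    n = len(data["SNP"])
    if n < 5:
        raise ValueError("need at least 5 individuals to fit a trio SEM")
    if np.ptp(data["GE"]) > 0 and np.ptp(data["PHEN"]) > 0:
        if abs(np.corrcoef(data["GE"], data["PHEN"])[0, 1]) >= 1 - 1e-12:
            raise ValueError("degenerate regressor: GE and PHEN are collinear")
    loglik = 0.0
    n_params = 0
    for node in ("GE", "PHEN"):
        parents = dag.parents(node)
        if "SNP" in parents and np.ptp(data["SNP"]) == 0:
            raise ValueError("degenerate regressor: SNP monomorphic in sample")
        X = np.column_stack([np.ones(n)] + [data[p] for p in parents])
        _, rss, rank = ols_rss(data[node], X)
        if rank < X.shape[1]:
            raise ValueError(f"degenerate regressor in equation for {node}")
        loglik += gaussian_ml_loglik(rss, n)
        n_params += 2 + len(parents)  # intercept + slopes + variance
    return loglik, n_params


def select_sem(trio, model_set="all") -> SemFitResult:
    """Fit every DAG in the model set and select the lowest AIC.

    ``model_set`` is a preset name or an iterable of CausalDAGs. Ties within
    ``AIC_TIE_TOL`` of the minimum are reported; the selected label is the tie
    member with fewest edges (then lexicographic label) so that Markov
    equivalence never makes the choice data-order dependent.
    """
    dags = enumerate_dags(model_set) if isinstance(model_set, str) else list(model_set)
    if not dags:
        raise ValueError("empty model set")
    rows = []
    for dag in dags:
        try:
            ll, k = fit_sem(trio, dag)
            rows.append((dag.label, ll, k, 2.0 * k - 2.0 * ll, dag.n_edges, ""))
        except ValueError as exc:
            rows.append((dag.label, np.nan, np.nan, np.nan, dag.n_edges, str(exc)))
    table = pd.DataFrame(
        rows, columns=["label", "log_likelihood", "n_params", "aic", "n_edges", "error"]
    )
    fitted = table.dropna(subset=["aic"])
    if fitted.empty:
        raise ValueError("no DAG could be fitted on this trio")
    amin = fitted["aic"].min()
    ties = fitted[fitted["aic"] <= amin + AIC_TIE_TOL]
    tie_sorted = ties.sort_values(["n_edges", "label"], kind="mergesort")
    return SemFitResult(table=table, selected=tie_sorted["label"].iloc[0],
                        tie_set=tuple(tie_sorted["label"]))
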