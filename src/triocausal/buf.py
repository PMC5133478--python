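"""Bayesian partition selection for trio causal inference.

The non-SNP variables {GE, PHEN} are partitioned into gamma = (U, D, I):
Unassociated with the SNP, Directly associated, and Indirectly associated
(conditionally independent of the SNP given the D members). An indirect
member needs a direct conduit, so I nonempty requires D nonempty, which
leaves exactly 6 partitions of two variables. Each partition is scored by a
Bayes factor against the all-U null; the winning partition maps to a causal
model label:

    U = {GE, PHEN}            -> "null"
    D = {GE},  U = {PHEN}     -> "(f)"
    D = {PHEN}, U = {GE}      -> "snp_to_phen_only"
    D = {GE, PHEN}            -> "(a)"
    D = {GE},  I = {PHEN}     -> "(b)"   (expression mediates)
    D = {PHEN}, I = {GE}      -> "(c)"   (phenotype mediates)

Note the built-in blind spots relative to the SEM menu: the collider model
(d) has no partition, and conversely (f) is exactly the partition the SEM
comparison lacks, so on collider data the two methods disagree by design.

The Bayes factor for "y is directly associated with s given covariates W" is
computed in closed form for the conjugate model

    y = W a + s b + e,   e ~ N(0, sigma^2 I),   b | sigma^2 ~ N(0, sigma_a^2 sigma^2)

with improper flat priors on (a, log sigma^2) shared by numerator and
denominator (they cancel). The genotype is standardised internally so that
sigma_a is an effect size in residual-SD units per genotype SD; the final BF
averages over a small sigma_a grid on the BF scale.

Derivation sketch: with W projected out (residuals y~, s~ and q = ncol(W)),

    BF(sigma_a) = (sigma_a^2 A)^(-1/2) * (R1/R0)^(-(n-q)/2),
    A  = s~'s~ + sigma_a^(-2),   R0 = y~'y~,   R1 = R0 - (s~'y~)^2 / A.

As sigma_a -> 0 the prior collapses onto the null and BF -> 1.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._regression import residualize

DEFAULT_SIGMA_GRID = (0.1, 0.2, 0.4)
NEAR_TIE_LOG10 = 0.1

_GE = "GE"
_PHEN = "PHEN"


@dataclasses.dataclass(frozen=True)
class Partition:
    """A (U, D, I) assignment of {GE, PHEN} relative to the SNP."""

    U: frozenset
    D: frozenset
    I: frozenset

    def __post_init__(self) -> None:
        full = {_GE, _PHEN}
        if set(self.U) | set(self.D) | set(self.I) != full:
            raise ValueError("U, D, I must cover {GE, PHEN}")
        if (self.U & self.D) or (self.U & self.I) or (self.D & self.I):
            raise ValueError("U, D, I must be disjoint")
        if self.I and not self.D:
            raise ValueError("indirect association requires a direct conduit (I => D)")

    @property
    def name(self) -> str:
        def fmt(s):
            return ",".join(sorted(s)) if s else "-"

        return f"U={fmt(self.U)};D={fmt(self.D)};I={fmt(self.I)}"


def _part(U=(), D=(), I=()):
    return Partition(frozenset(U), frozenset(D), frozenset(I))


def enumerate_partitions() -> list[Partition]:
    """The 6 valid partitions, in a fixed order (used for tie-breaking)."""
    return [
        _part(U=(_GE, _PHEN)),
        _part(D=(_GE,), U=(_PHEN,)),
        _part(D=(_PHEN,), U=(_GE,)),
        _part(D=(_GE, _PHEN)),
        _part(D=(_GE,), I=(_PHEN,)),
        _part(D=(_PHEN,), I=(_GE,)),
    ]


PARTITION_MODEL_MAP = {
    _part(U=(_GE, _PHEN)): "null",
    _part(D=(_GE,), U=(_PHEN,)): "(f)",
    _part(D=(_PHEN,), U=(_GE,)): "snp_to_phen_only",
    _part(D=(_GE, _PHEN)): "(a)",
    _part(D=(_GE,), I=(_PHEN,)): "(b)",
    _part(D=(_PHEN,), I=(_GE,)): "(c)",
}


@dataclasses.dataclass
class BufResult:
    """Per-partition log10 Bayes factors and the selected, mapped model."""

    table: pd.DataFrame  # partition, log10_bf, model
    selected: Partition
    model: str
    margin: float
    near_tie: bool


def univariate_log10_bf(
    y: np.ndarray,
    s: np.ndarray,
    W: np.ndarray,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
) -> float:
    """Closed-form log10 Bayes factor for a single-response SNP regression.

    ``W`` must contain an intercept column; ``[W s]`` must be full rank.
    The result is the log10 of the arithmetic mean of the per-sigma_a BFs.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != len(y):
        W = W.T
    n, q = W.shape
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(s) == 0:
        raise ValueError("monomorphic genotype: Bayes factor undefined")
    if np.linalg.matrix_rank(np.column_stack([W, s])) < q + 1:
        raise ValueError("rank-deficient design [W s]")
    s_std = (s - s.mean()) / s.std()
    y_t = residualize(y, W)
    s_t = residualize(s_std, W)
    R0 = float(y_t @ y_t)
    sts = float(s_t @ s_t)
    sty = float(s_t @ y_t)
    if R0 <= 0 or sts <= 0:
        raise ValueError("degenerate data after projecting out covariates")
    log_bfs = []
    for sig in sigma_grid:
        A = sts + sig ** -2
        R1 = R0 - sty * sty / A
        log_bfs.append(-0.5 * np.log(sig * sig * A) - 0.5 * (n - q) * np.log(R1 / R0))
    return float((logsumexp(log_bfs) - np.log(len(log_bfs))) / np.log(10.0))


def partition_log10_bf(trio, part: Partition,
                       sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID) -> float:
    """Bayes factor of one partition against the all-U null.

    The joint law factorises as p(Y_U) p(Y_D | Y_U, s) p(Y_I | Y_D); only the
    D-regression depends on the hypothesis, so the BF is the univariate BF of
    the D members on s with the U members as covariates. I members contribute
    no factor. For D = both, the chain-rule factorisation is averaged over
    its two orderings on the log10-BF scale to symmetrise the (slight) order
    dependence of the independent per-regression priors.
    """
    s = np.asarray(trio.dosage, dtype=float)
    g = np.asarray(trio.expression, dtype=float)
    p = np.asarray(trio.phenotype, dtype=float)
    ones = np.ones((len(s), 1))
    vec = {_GE: g, _PHEN: p}

    if not part.D:
        return 0.0
    if len(part.D) == 2:
        o1 = univariate_log10_bf(g, s, ones, sigma_grid) + univariate_log10_bf(
            p, s, np.column_stack([ones, g]), sigma_grid
        )
        o2 = univariate_log10_bf(p, s, ones, sigma_grid) + univariate_log10_bf(
            g, s, np.column_stack([ones, p]), sigma_grid
        )
        return 0.5 * (o1 + o2)
    (d,) = part.D
    other = _PHEN if d == _GE else _GE
    if other in part.U:
        W = np.column_stack([ones, vec[other]])
    else:  # other is indirect: it enters no regression on s
        W = ones
    return univariate_log10_bf(vec[d], s, W, sigma_grid)


def select_buf(trio, sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID) -> BufResult:
    """Score all 6 partitions, select the max-BF one, map it to a model label."""
    parts = enumerate_partitions()
    bfs = [partition_log10_bf(trio, pt, sigma_grid) for pt in parts]
    table = pd.DataFrame(
        {
            "partition": [pt.name for pt in parts],
            "log10_bf": bfs,
            "model": [PARTITION_MODEL_MAP[pt] for pt in parts],
        }
    )
    top = max(bfs)
    # exact ties resolved by the fixed enumeration order
    best = next(i for i, b in enumerate(bfs) if b == top)
    runner = max((b for i, b in enumerate(bfs) if i != best), default=-np.inf)
    margin = float(top - runner)
    return BufResult(
        table=table,
        selected=parts[best],
        model=PARTITION_MODEL_MAP[parts[best]],
        margin=margin,
        near_tie=margin < NEAR_TIE_LOG10,
    )
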