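"""Lightweight weighted coexpression network analysis.

The alternative filtering front-end: build an unsigned soft-thresholded
correlation network (adjacency |r|^beta), convert it to topological-overlap
similarity, cluster probes by average-linkage on 1 - TOM with a static tree
cut, summarise each module by its eigengene (first principal component of
the standardised member probes, orientation-fixed), and test module-trait
correlations with Bonferroni correction.

Module labels follow the conventional colour ordering (largest module is
"turquoise"; "grey" is reserved for unassigned probes), so a colour has a
stable meaning across runs.

Deliberate simplifications relative to the full WGCNA toolchain: static cut
instead of the dynamic hybrid tree cut, unsigned networks only, Pearson
correlation only, and no block-wise computation for very large probe sets.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix
from .phenotype import AdjustedPhenotype

log = logging.getLogger(__name__)

#: Conventional module colour ordering; "grey" is reserved for unassigned.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)
GREY = "grey"

DEFAULT_CANDIDATE_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclasses.dataclass
class NetworkConfig:
    """Parameters of the unsigned coexpression network.

    ``soft_power`` is the soft-threshold exponent (unsigned default 6);
    ``cut_height`` is the static cut on the 1-TOM dendrogram. For a factor
    module with probe-factor loading L the within-module dissimilarity sits
    near 1 - L^(2*soft_power), so the default 0.95 keeps modules with
    loadings down to ~0.78 intact at power 6 while unclustered probes (merge
    heights ~1) stay grey.
    """

    soft_power: int = 6
    sign: str = "unsigned"
    min_module_size: int = 10
    cut_height: float = 0.95
    candidate_powers: Sequence[int] = DEFAULT_CANDIDATE_POWERS

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0.0 < self.cut_height < 1.0:
            raise ValueError("cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.sign != "unsigned":
            raise ValueError("only unsigned networks are supported")


@dataclasses.dataclass
class ModuleSet:
    """Probe-module assignment with eigengenes and module-trait statistics."""

    assignment: pd.Series  # probe_id -> colour label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # individuals x module labels
    var_explained: dict
    module_trait: pd.DataFrame | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.eigengenes.columns)

    def members(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])


def _corr(values: np.ndarray, probe_ids: Sequence[str]) -> np.ndarray:
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = np.asarray(probe_ids)[sd == 0]
        raise ValueError(f"zero-variance probe(s): {', '.join(map(str, bad[:5]))}")
    r = np.corrcoef(values, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def adjacency(
    e: Union[ExpressionMatrix, np.ndarray], cfg: Union[NetworkConfig, int, None] = None
) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |cor(probe_i, probe_j)|^power."""
    values = e.values if isinstance(e, ExpressionMatrix) else np.asarray(e, dtype=float)
    ids = e.probe_ids if isinstance(e, ExpressionMatrix) else list(range(values.shape[1]))
    if values.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    power = cfg.soft_power if isinstance(cfg, NetworkConfig) else int(cfg or 6)
    a = np.abs(_corr(values, ids)) ** power
    np.fill_diagonal(a, 1.0)
    return a


def _validate_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0, atol=1e-10):
        raise ValueError("adjacency must have unit diagonal")
    return np.clip((a + a.T) / 2.0, 0.0, 1.0)


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_u a_iu a_uj over u distinct from i and j, and k_i is the
    connectivity sum_u a_iu (u != i). Diagonal is 1.
    """
    a = _validate_adjacency(a)
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=0) - 1.0
    a2 = a @ a
    ell = a2 - 2.0 * a  # removes u = i and u = j terms (unit diagonal)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (ell + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 freq(k) on log10 mean(k) over connectivity bins."""
    if np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() and k[m].mean() > 0:
            xs.append(np.log10(k[m].mean()))
            ys.append(np.log10(m.sum() / len(k)))
    if len(xs) < 5:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def pick_soft_threshold(
    e: Union[ExpressionMatrix, np.ndarray],
    candidate_powers: Sequence[int] = DEFAULT_CANDIDATE_POWERS,
    r2_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by approximate scale-free topology fit.

    Returns the smallest candidate whose fit R^2 reaches ``r2_target``, else
    the candidate with the highest (defined) R^2. Degenerate candidates
    (all connectivities equal) are reported with NaN and excluded.
    """
    if len(candidate_powers) < 1:
        raise ValueError("need at least one candidate power")
    values = e.values if isinstance(e, ExpressionMatrix) else np.asarray(e, dtype=float)
    ids = e.probe_ids if isinstance(e, ExpressionMatrix) else list(range(values.shape[1]))
    absr = np.abs(_corr(values, ids))
    rows = []
    for power in candidate_powers:
        a = absr ** power
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=0) - 1.0
        rows.append((int(power), _scale_free_r2(k), float(k.mean()), float(k.max())))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "mean_k", "max_k"])
    defined = table.dropna(subset=["r_squared"])
    if defined.empty:
        if len(candidate_powers) == 1:
            return int(candidate_powers[0]), table
        raise ValueError("scale-free fit undefined for every candidate power")
    good = defined[defined["r_squared"] >= r2_target]
    chosen = int(good["power"].iloc[0]) if not good.empty else int(
        defined.loc[defined["r_squared"].idxmax(), "power"]
    )
    return chosen, table


def detect_modules(
    tom: np.ndarray,
    cfg: NetworkConfig,
    probe_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` are merged into "grey"; the
    rest are labelled by decreasing size (ties: lowest member index first)
    from the conventional colour list.
    """
    tom = np.asarray(tom, dtype=float)
    m = tom.shape[0]
    if m < 2:
        raise ValueError("need at least 2 probes to cluster")
    if probe_ids is None:
        probe_ids = [f"probe{j}" for j in range(m)]
    diss = 1.0 - (tom + tom.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=cfg.cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for j, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(j)
    kept = [idx for idx in clusters.values() if len(idx) >= cfg.min_module_size]
    kept.sort(key=lambda idx: (-len(idx), min(idx)))
    labels = np.full(m, GREY, dtype=object)
    for rank, idx in enumerate(kept):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels[idx] = color
    return pd.Series(labels, index=list(probe_ids), name="module")


def eigengene(
    e: Union[ExpressionMatrix, np.ndarray],
    assignment: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Module eigengenes and per-module variance explained.

    Member probes are standardised; the eigengene is the first principal
    component score, scaled to unit variance and sign-oriented so its mean
    correlation with the member probes is positive. Variance explained is
    the leading eigenvalue over the number of members.
    """
    if isinstance(e, ExpressionMatrix):
        values, ids = e.values, e.probe_ids
    else:
        values = np.asarray(e, dtype=float)
        ids = list(assignment.index)
    col = {pid: j for j, pid in enumerate(ids)}
    eig: dict[str, np.ndarray] = {}
    varexp: dict[str, float] = {}
    order = []
    for label in assignment.unique():
        if label == GREY:
            continue
        members = [col[p] for p in assignment.index[assignment == label]]
        if len(members) < 2:
            raise ValueError(f"module {label!r} has fewer than 2 probes")
        X = values[:, members]
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"module {label!r} contains a constant probe")
        Xs = (X - X.mean(axis=0)) / sd
        U, S, _ = np.linalg.svd(Xs, full_matrices=False)
        score = U[:, 0] * S[0]
        score = score / score.std(ddof=1)
        corrs = [np.corrcoef(score, Xs[:, j])[0, 1] for j in range(Xs.shape[1])]
        if np.mean(corrs) < 0:
            score = -score
        eig[label] = score
        varexp[label] = float(S[0] ** 2 / (S ** 2).sum())
        order.append(label)
    samples = e.sample_ids if isinstance(e, ExpressionMatrix) else range(values.shape[0])
    rank = {c: i for i, c in enumerate(MODULE_COLORS)}
    order.sort(key=lambda lab: (rank.get(lab, len(MODULE_COLORS)), lab))
    frame = pd.DataFrame({lab: eig[lab] for lab in order}, index=list(samples))
    return frame, varexp


def module_trait_association(
    eigengenes: pd.DataFrame,
    traits: Union[Mapping[str, Union[pd.Series, AdjustedPhenotype]], pd.Series, AdjustedPhenotype],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait.

    Bonferroni-adjusts over (n_modules x n_traits) tests; a pair is
    significant when the adjusted p is below ``alpha``.
    """
    if isinstance(traits, (pd.Series, AdjustedPhenotype)):
        name = traits.trait if isinstance(traits, AdjustedPhenotype) else (traits.name or "trait")
        traits = {name: traits}
    n_tests = len(eigengenes.columns) * len(traits)
    rows = []
    for trait_name, y in traits.items():
        yv = (
            y.aligned(eigengenes.index)
            if isinstance(y, AdjustedPhenotype)
            else pd.Series(y).loc[eigengenes.index].to_numpy(dtype=float)
        )
        for label in eigengenes.columns:
            r, p = stats.pearsonr(eigengenes[label].to_numpy(), yv)
            p_b = min(1.0, p * n_tests)
            rows.append((label, trait_name, float(r), float(p), float(p_b), p_b < alpha))
    return pd.DataFrame(
        rows, columns=["module", "trait", "r", "p", "p_bonferroni", "significant"]
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return str(leaf_names[i])
        a, b, h, _ = Z[i - n]
        la, lb = int(a), int(b)
        return (
            f"({node(la)}:{h - heights[la]:.6g},{node(lb)}:{h - heights[lb]:.6g})"
        )

    for i, row in enumerate(Z):
        heights[n + i] = float(row[2])
    return node(n + len(Z) - 1) + ";"


def build_modules(e: ExpressionMatrix, cfg: NetworkConfig | None = None) -> ModuleSet:
    """Convenience pipeline: adjacency -> TOM -> modules -> eigengenes."""
    cfg = cfg or NetworkConfig()
    a = adjacency(e, cfg)
    tom = topological_overlap(a)
    assignment = detect_modules(tom, cfg, probe_ids=e.probe_ids)
    if (assignment == GREY).all():
        log.warning("no module passed min_module_size; all probes grey")
        empty = pd.DataFrame(index=e.sample_ids)
        return ModuleSet(assignment=assignment, eigengenes=empty, var_explained={})
    frame, varexp = eigengene(e, assignment)
    return ModuleSet(assignment=assignment, eigengenes=frame, var_explained=varexp)
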