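"""Phase-wise group comparisons.

Four inference tools used across the memory phases:

* :func:`permutation_mean_test` — two-sided label-permutation test on a
  per-subject scalar (e.g. mean within-network connectivity);
* :func:`edgewise_glm_t` — per-edge OLS t for the group contrast with
  age/sex regressed out;
* :func:`nbs` — network-based-statistic style inference: suprathreshold
  edges, sign-segregated connected components, and family-wise component
  p-values from a group-label permutation null of the maximal component
  size (in edges);
* :func:`chi_square_counts` — Pearson chi-square (df=1, no continuity
  correction) comparing reduced-node proportions across phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components


@dataclass
class ComponentResult:
    """One connected component of suprathreshold edges."""

    edges: list  # list of (i, j) node-index pairs
    nodes: list  # node indices touched by the component
    sign: int  # +1: controls > AD (reduced in AD); -1: AD > controls
    p: float

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass
class EdgeGroupResult:
    """Edge-wise group comparison for one phase."""

    node_ids: list
    edge_index: np.ndarray  # (n_edges, 2) upper-triangle node indices
    t_map: np.ndarray  # (n_edges,) t for the controls-minus-AD contrast
    threshold_t: float
    supra_mask: np.ndarray  # (n_edges,) bool
    components: list  # list of ComponentResult
    alpha: float
    phase: str = ""
    n_perm: int = 0
    seed: int | None = None

    @property
    def significant_components(self) -> list:
        return [c for c in self.components if c.p <= self.alpha]

    @property
    def reduced_edges(self) -> list:
        """Edges of significant components with controls > AD."""
        return [
            e for c in self.significant_components if c.sign > 0 for e in c.edges
        ]

    @property
    def reduced_nodes(self) -> set:
        return {i for e in self.reduced_edges for i in e}

    def to_edge_table(self) -> pd.DataFrame:
        comp_id = np.zeros(len(self.t_map), dtype=int)
        sig = np.zeros(len(self.t_map), dtype=bool)
        lookup = {tuple(e): k for k, (i, j) in enumerate(self.edge_index) for e in [(i, j)]}
        for ci, comp in enumerate(self.components, start=1):
            for e in comp.edges:
                k = lookup[e]
                comp_id[k] = ci
                sig[k] = comp.p <= self.alpha
        return pd.DataFrame(
            {
                "node_i": [self.node_ids[i] for i, _ in self.edge_index],
                "node_j": [self.node_ids[j] for _, j in self.edge_index],
                "t": self.t_map,
                "significant": sig.astype(int),
                "component_id": comp_id,
            }
        )


@dataclass
class NodeReductionSummary:
    """Per-phase counts of nodes/edges with significant AD reductions."""

    phase: str
    n_reduced_nodes: int
    n_reduced_edges: int
    n_total_nodes: int

    def __post_init__(self) -> None:
        if self.n_reduced_nodes > self.n_total_nodes:
            raise ValueError("reduced nodes cannot exceed total nodes")


def permutation_mean_test(values_a, values_b, n_perm: int = 10000, seed=None):
    """Two-sided permutation test on the difference of group means.

    Returns ``(mean_a, mean_b, p)`` with
    p = (1 + #{|diff_perm| >= |diff_obs|}) / (1 + n_perm).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very small; p-values are coarse", stacklevel=2)
    # sort the pool so the Monte-Carlo null depends only on the value
    # multiset, making p exactly label-swap invariant for equal group sizes
    pooled = np.sort(np.concatenate([a, b]))
    obs = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    diff = perms[:, : a.size].mean(axis=1) - perms[:, a.size :].mean(axis=1)
    p = (1 + np.count_nonzero(np.abs(diff) >= abs(obs) - 1e-12)) / (1 + n_perm)
    return float(a.mean()), float(b.mean()), float(p)


def _design(is_ad, covariates):
    is_ad = np.asarray(is_ad, dtype=float)
    cols = [np.ones_like(is_ad), is_ad]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design (constant group vector or collinear covariates)")
    return x


def _batch_group_t(x_batch, y):
    """Group-contrast t for a batch of designs sharing the response matrix.

    x_batch : (B, n, p) with the group column at index 1
    y       : (n, E)
    Returns (B, E) t-values for the AD coefficient, negated so positive t
    means controls > AD.
    """
    n, p = x_batch.shape[1], x_batch.shape[2]
    xtx = np.einsum("bij,bik->bjk", x_batch, x_batch)
    xty = np.einsum("bij,ik->bjk", x_batch, y)
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty  # (B, p, E)
    yty = np.einsum("ik,ik->k", y, y)  # (E,)
    rss = yty[None, :] - np.einsum("bjk,bjk->bk", beta, xty)
    dof = n - p
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 * xtx_inv[:, 1, 1][:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1, :] / se
    return -t  # positive = controls > AD


def edgewise_glm_t(fc_stack, is_ad, covariates=None) -> np.ndarray:
    """Per-edge OLS t for the group effect, nuisance covariates partialled.

    Parameters
    ----------
    fc_stack : (n_subjects, n_edges)
        Vectorized upper-triangle Fisher-z values.
    is_ad : (n_subjects,) 0/1 indicator of the AD group.
    covariates : (n_subjects, k), optional
        E.g. age and sex.

    Returns
    -------
    (n_edges,) t-values; positive t means controls > AD.  With no
    covariates this equals the pooled-variance two-sample t.
    """
    y = np.atleast_2d(np.asarray(fc_stack, dtype=float))
    x = _design(is_ad, covariates)
    if y.shape[0] != x.shape[0]:
        raise ValueError("fc_stack and design have different subject counts")
    if y.shape[0] <= x.shape[1]:
        raise ValueError("need more subjects than design columns")
    return _batch_group_t(x[None], y)[0]


def _max_component_sizes(t, edge_index, n_nodes, threshold):
    """Largest component edge-count per sign for one t-map."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) >= threshold
        if not mask.any():
            out.append(0)
            continue
        e = edge_index[mask]
        adj = sparse.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n_nodes, n_nodes)
        )
        n_comp, labels = connected_components(adj, directed=False)
        edge_labels = labels[e[:, 0]]
        out.append(int(np.bincount(edge_labels).max()))
    return out


def nbs(
    fc_stack,
    is_ad,
    covariates=None,
    threshold_t: float | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed=None,
    node_ids=None,
    phase: str = "",
    chunk: int = 200,
) -> EdgeGroupResult:
    """Network-based-statistic inference on edge-wise group differences.

    Suprathreshold edges (|t| >= ``threshold_t``; ties included) are
    segregated by sign and decomposed into connected components on the
    node graph.  The family-wise null distribution of the maximal
    component size (edge count, both signs) is built by permuting group
    labels while covariates stay attached to their subjects, giving each
    observed component p = (1 + #{max null >= size}) / (1 + n_perm).

    ``threshold_t`` defaults to the |t| of two-sided p = 0.01 at the
    design's residual degrees of freedom.
    """
    y = np.asarray(fc_stack, dtype=float)
    is_ad = np.asarray(is_ad)
    n_sub, n_edges = y.shape
    x = _design(is_ad, covariates)
    dof = n_sub - x.shape[1]
    if threshold_t is None:
        threshold_t = float(stats.t.ppf(1 - 0.005, dof))
    if not threshold_t > 0:
        raise ValueError("threshold_t must be positive")

    # infer node count / edge index from the vectorized upper triangle
    n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_nodes * (n_nodes - 1) // 2 != n_edges:
        raise ValueError("fc_stack edge count is not a full upper triangle")
    iu = np.triu_indices(n_nodes, 1)
    edge_index = np.column_stack(iu)
    if node_ids is None:
        node_ids = list(range(n_nodes))

    t_obs = edgewise_glm_t(y, is_ad, covariates)
    supra = np.abs(t_obs) >= threshold_t

    # observed components per sign
    components = []
    for sign in (1, -1):
        mask = (sign * t_obs) >= threshold_t
        if not mask.any():
            continue
        e = edge_index[mask]
        adj = sparse.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n_nodes, n_nodes)
        )
        _, labels = connected_components(adj, directed=False)
        for comp_label in np.unique(labels[e[:, 0]]):
            in_comp = labels[e[:, 0]] == comp_label
            comp_edges = [tuple(map(int, pair)) for pair in e[in_comp]]
            comp_nodes = sorted({i for pair in comp_edges for i in pair})
            components.append(
                ComponentResult(edges=comp_edges, nodes=comp_nodes, sign=sign, p=1.0)
            )

    # permutation null of the maximal component size
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    pos = 0
    while pos < n_perm:
        b = min(chunk, n_perm - pos)
        x_batch = np.repeat(x[None], b, axis=0)
        for k in range(b):
            x_batch[k, :, 1] = x[rng.permutation(n_sub), 1]
        t_perm = _batch_group_t(x_batch, y)
        for k in range(b):
            null_max[pos + k] = max(
                _max_component_sizes(t_perm[k], edge_index, n_nodes, threshold_t)
            )
        pos += b

    for comp in components:
        comp.p = float((1 + np.count_nonzero(null_max >= comp.size)) / (1 + n_perm))

    return EdgeGroupResult(
        node_ids=list(node_ids),
        edge_index=edge_index,
        t_map=t_obs,
        threshold_t=float(threshold_t),
        supra_mask=supra,
        components=components,
        alpha=alpha,
        phase=phase,
        n_perm=n_perm,
        seed=seed,
    )


def count_reduced(result: EdgeGroupResult) -> NodeReductionSummary:
    """Nodes and edges touched by significant AD-reduced components."""
    return NodeReductionSummary(
        phase=result.phase,
        n_reduced_nodes=len(result.reduced_nodes),
        n_reduced_edges=len(result.reduced_edges),
        n_total_nodes=len(result.node_ids),
    )


def chi_square_counts(k1: int, n1: int, k2: int, n2: int):
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Compares proportions k1/n1 vs k2/n2 (e.g. reduced-node counts in two
    phases).  Returns ``(chi2, p)``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n or n <= 0:
            raise ValueError("need 0 <= k <= n and n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: empty row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
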