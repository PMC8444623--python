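"""Data-driven network detection: weighted Louvain with consensus clustering.

The empirical networks are communities of a nonnegative weighted graph
(the group-average control maintenance-phase FC matrix, negatives zeroed),
found by modularity maximization.  Louvain is greedy and stochastic, so a
consensus procedure is used: many runs are summarized in a node-pair
agreement matrix, weak agreements are thresholded away, and the agreement
matrix is re-clustered until all runs coincide.

Louvain itself is the multilevel algorithm of igraph; stochasticity across
runs comes from random node-order permutation of the input (the same
device the Brain Connectivity Toolbox uses), and a single ``louvain`` call
keeps the best-modularity result over ``n_restarts`` permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd


@dataclass
class CommunityPartition:
    """Node-to-community assignment with its modularity.

    Community ids are contiguous from 1 and ordered by descending
    community size ("Network 1" is the largest), ties broken by the
    smallest member index.
    """

    assignment: dict  # node_id -> community id (1-based)
    modularity_q: float
    gamma: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def node_ids(self) -> list:
        return list(self.assignment)

    def labels(self) -> np.ndarray:
        return np.array([self.assignment[n] for n in self.assignment])

    def members(self, community: int) -> list:
        return [n for n, c in self.assignment.items() if c == community]

    def sizes(self) -> dict:
        out: dict = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return dict(sorted(out.items()))

    def to_tsv(self, path, parcellation=None) -> None:
        df = pd.DataFrame(
            {"node_id": list(self.assignment), "community": list(self.assignment.values())}
        )
        if parcellation is not None:
            df["a_priori_network"] = df["node_id"].map(parcellation.network_of())
        df.to_csv(path, sep="\t", index=False)


def _as_labels(assignment, node_ids=None) -> np.ndarray:
    if isinstance(assignment, dict):
        order = node_ids if node_ids is not None else list(assignment)
        return np.array([assignment[n] for n in order])
    return np.asarray(assignment)


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative (zero negatives first)")
    if w.sum() == 0:
        raise ValueError("all-zero weight matrix")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def modularity(weights, assignment, gamma: float = 1.0, node_ids=None) -> float:
    """Newman-Girvan weighted modularity.

    Q = (1/2m) * sum_ij [w_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j)
    with 2m the total weight (diagonal excluded).
    """
    w = _check_weights(weights)
    labels = _as_labels(assignment, node_ids)
    if labels.shape[0] != w.shape[0]:
        raise ValueError("assignment length does not match weight matrix")
    k = w.sum(axis=1)
    two_m = w.sum()
    same = labels[:, None] == labels[None, :]
    # diagonal terms carry w_ii = 0 but keep their null-model share
    b = w - gamma * np.outer(k, k) / two_m
    return float(b[same].sum() / two_m)


def _canonical(labels: np.ndarray) -> tuple:
    """Relabel by order of first appearance (for partition comparison)."""
    mapping: dict = {}
    out = []
    for v in labels:
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return tuple(out)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Contiguous 1-based ids, largest community first."""
    ids, counts = np.unique(labels, return_counts=True)
    first_seen = {c: int(np.argmax(labels == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_seen[c]))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def _louvain_single(w: np.ndarray, rng: np.random.Generator, gamma: float) -> np.ndarray:
    """One stochastic Louvain run: permute node order, run igraph, map back."""
    import random as _random

    n = w.shape[0]
    perm = rng.permutation(n)
    # pin igraph's global RNG too, so runs are reproducible end to end
    igraph.set_random_number_generator(_random.Random(int(rng.integers(2**31))))
    wp = w[np.ix_(perm, perm)]
    iu = np.triu_indices(n, 1)
    vals = wp[iu]
    keep = vals > 0
    g = igraph.Graph(
        n=n, edges=list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    )
    g.es["weight"] = vals[keep].tolist()
    membership = np.array(
        g.community_multilevel(weights="weight", resolution=gamma).membership
    )
    labels = np.empty(n, dtype=int)
    labels[perm] = membership
    return labels


def louvain(weights, gamma: float = 1.0, seed=None, n_restarts: int = 10, node_ids=None) -> CommunityPartition:
    """Best-of-``n_restarts`` Louvain modularity maximization.

    Deterministic given ``seed``.  Isolated nodes (all-zero rows) end up
    as singleton communities.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    if node_ids is None:
        node_ids = list(range(n))
    rng = np.random.default_rng(seed)
    best_q, best = -np.inf, None
    for _ in range(max(1, n_restarts)):
        labels = _louvain_single(w, rng, gamma)
        q = modularity(w, labels, gamma)
        if q > best_q:
            best_q, best = q, labels
    final = _relabel_by_size(best)
    return CommunityPartition(
        assignment=dict(zip(node_ids, final.tolist())), modularity_q=best_q, gamma=gamma
    )


def agreement_matrix(label_runs) -> np.ndarray:
    """Node-pair co-assignment frequency over runs; diagonal is 1."""
    runs = [np.asarray(r) for r in label_runs]
    if not runs:
        raise ValueError("no runs")
    n = runs[0].shape[0]
    agree = np.zeros((n, n))
    for labels in runs:
        agree += labels[:, None] == labels[None, :]
    agree /= len(runs)
    np.fill_diagonal(agree, 1.0)
    return agree


def consensus_partition(
    weights,
    n_runs: int = 100,
    tau: float = 0.5,
    seed=None,
    gamma: float = 1.0,
    max_iters: int = 50,
    node_ids=None,
) -> CommunityPartition:
    """Consensus clustering over repeated stochastic Louvain runs.

    Each iteration runs Louvain ``n_runs`` times with distinct seeds,
    builds the agreement matrix, zeroes entries below ``tau`` and
    re-clusters the agreement matrix, until all runs return the same
    partition (up to relabeling).  The returned modularity is evaluated
    on the *original* weights.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    w = _check_weights(weights)
    n = w.shape[0]
    if node_ids is None:
        node_ids = list(range(n))
    rng = np.random.default_rng(seed)
    current = w
    for _ in range(max_iters):
        if current.sum() == 0:
            # nothing co-clusters above tau: all-singletons fixed point
            labels = np.arange(n)
            return CommunityPartition(
                assignment=dict(zip(node_ids, (labels + 1).tolist())),
                modularity_q=modularity(w, labels, gamma),
                gamma=gamma,
            )
        runs = [_louvain_single(current, rng, gamma) for _ in range(n_runs)]
        canon = {_canonical(r) for r in runs}
        if len(canon) == 1:
            final = _relabel_by_size(runs[0])
            return CommunityPartition(
                assignment=dict(zip(node_ids, final.tolist())),
                modularity_q=modularity(w, final, gamma),
                gamma=gamma,
            )
        agree = agreement_matrix(runs)
        agree[agree < tau] = 0.0
        np.fill_diagonal(agree, 0.0)
        current = agree
    raise RuntimeError(
        f"consensus clustering did not converge in {max_iters} iterations "
        f"(n_runs={n_runs}, tau={tau})"
    )


def restrict_and_cluster(
    control_fc,
    parcellation,
    n_runs: int = 100,
    tau: float = 0.5,
    gamma: float = 1.0,
    seed=None,
) -> CommunityPartition:
    """Empirical networks from control maintenance-phase connectivity.

    Averages the control subjects' Fisher-z matrices, restricts to the
    cognitive-network node subset, zeroes negative weights, and runs
    consensus Louvain.  Communities are labelled by descending size
    ("Network 1" is the largest).
    """
    from memnet.connectivity import group_mean_matrix, zero_negative

    control_fc = list(control_fc)
    if not control_fc:
        raise ValueError("empty control group")
    mean_fc = group_mean_matrix(control_fc)
    restricted_ids = parcellation.restricted_node_ids
    sub = mean_fc.restrict(restricted_ids)
    w = zero_negative(sub)
    return consensus_partition(
        w, n_runs=n_runs, tau=tau, seed=seed, gamma=gamma, node_ids=restricted_ids
    )
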