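"""Fisher-z functional connectivity matrices and network-level summaries.

Functional connectivity between two nodes is the Fisher z-transform
(atanh) of the Pearson correlation between their phase time courses.
Negative weights are zeroed only on the community-detection path
(:func:`zero_negative`); group comparisons and mean connectivity always
use signed z values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: correlations are clamped to +/- this value before atanh so z stays finite
R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z FC matrix for one subject and phase."""

    z: np.ndarray  # (n, n) symmetric, zero diagonal
    node_ids: list
    subject_id: str = ""
    phase: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if z.shape[0] != len(self.node_ids):
            raise ValueError("node_ids length must match matrix size")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("z must be symmetric")
        if not np.isfinite(z).all():
            raise ValueError("z must be finite (clamp r before atanh)")
        self.z = z

    def restrict(self, node_subset) -> "ConnectivityMatrix":
        idx = [self.node_ids.index(n) for n in node_subset]
        return ConnectivityMatrix(
            z=self.z[np.ix_(idx, idx)],
            node_ids=list(node_subset),
            subject_id=self.subject_id,
            phase=self.phase,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.z, index=self.node_ids, columns=self.node_ids).to_csv(
            path, sep="\t", index_label="node_id"
        )

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.node_ids), 1)
        return pd.DataFrame(
            {
                "node_i": [self.node_ids[i] for i in iu[0]],
                "node_j": [self.node_ids[j] for j in iu[1]],
                "z": self.z[iu],
            }
        )


def compute_fc(phase_bold) -> ConnectivityMatrix:
    """Fisher-z Pearson correlation matrix of a :class:`PhaseBold`.

    r is clamped to +/-(1 - 1e-7) before atanh; the diagonal is set to 0
    by convention.  A zero-variance node raises, naming the node.
    """
    data = np.asarray(phase_bold.data, dtype=float)
    if data.shape[1] < 4:
        raise ValueError("need >= 4 volumes to estimate connectivity")
    sd = data.std(axis=1)
    if (sd == 0).any():
        bad = phase_bold.node_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance time course at node {bad}")
    r = np.corrcoef(data)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z=z,
        node_ids=list(phase_bold.node_ids),
        subject_id=getattr(phase_bold, "subject_id", ""),
        phase=getattr(phase_bold, "phase", ""),
    )


def zero_negative(matrix):
    """Entrywise max(z, 0); used only before community detection."""
    if isinstance(matrix, ConnectivityMatrix):
        return np.maximum(matrix.z, 0.0)
    return np.maximum(np.asarray(matrix, dtype=float), 0.0)


def mean_connectivity(matrix: ConnectivityMatrix, set_a, set_b=None) -> float:
    """Mean z over node pairs.

    Within mode (``set_b`` is None or equals ``set_a``): mean over
    unordered pairs i<j inside ``set_a`` (diagonal excluded).  Between
    mode: mean over all cross pairs of two disjoint sets.
    """
    ids = matrix.node_ids
    idx_a = np.array([ids.index(n) for n in set_a])
    if set_b is None or list(set_b) == list(set_a):
        if len(idx_a) < 2:
            raise ValueError("within-set mean needs at least 2 nodes")
        sub = matrix.z[np.ix_(idx_a, idx_a)]
        iu = np.triu_indices(len(idx_a), 1)
        return float(sub[iu].mean())
    idx_b = np.array([ids.index(n) for n in set_b])
    if set(set_a) & set(set_b):
        raise ValueError("between-set mean requires disjoint node sets")
    return float(matrix.z[np.ix_(idx_a, idx_b)].mean())


def group_mean_matrix(matrices) -> ConnectivityMatrix:
    """Element-wise average of per-subject matrices (same node order)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    ids = matrices[0].node_ids
    for m in matrices[1:]:
        if m.node_ids != ids:
            raise ValueError("node order differs across matrices")
    return ConnectivityMatrix(
        z=np.mean([m.z for m in matrices], axis=0),
        node_ids=list(ids),
        subject_id="group-mean",
        phase=matrices[0].phase,
    )
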