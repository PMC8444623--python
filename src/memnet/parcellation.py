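"""Cortical parcellation table: node ids, a-priori networks, hemispheres.

The analysis assumes a 200-node cortical parcellation in which every node
carries one of the seven canonical resting-state network labels (visual,
somatomotor, dorsal attention, ventral attention, limbic, frontoparietal,
default mode).  Community detection is restricted to the 136 nodes of the
five "cognitive" networks (limbic, DMN, DAN, VAN, FPN); visual and
somatomotor nodes are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEVEN_NETWORKS = ("Vis", "SomMot", "DAN", "VAN", "Limbic", "FPN", "DMN")

#: networks entering the restricted (cognitive) node set
RESTRICTED_NETWORKS = frozenset({"Limbic", "DMN", "DAN", "VAN", "FPN"})

# Node counts per network for the default 200-node table.  The five
# restricted networks sum to 136; Vis + SomMot make up the remaining 64.
_DEFAULT_SIZES_200 = {
    "Vis": 30,
    "SomMot": 34,
    "DAN": 22,
    "VAN": 30,
    "Limbic": 26,
    "FPN": 28,
    "DMN": 30,
}


@dataclass(frozen=True)
class Parcellation:
    """Node table with a-priori network labels.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``node_id`` (str), ``network`` (one of the seven canonical
        labels), ``hemisphere`` ('L'/'R') and ``in_restricted_set`` (bool).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"node_id", "network", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        bad = set(self.table["network"]) - set(SEVEN_NETWORKS)
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")
        if self.table["node_id"].duplicated().any():
            raise ValueError("duplicate node ids in parcellation")
        if "in_restricted_set" not in self.table.columns:
            object.__setattr__(
                self,
                "table",
                self.table.assign(
                    in_restricted_set=self.table["network"].isin(RESTRICTED_NETWORKS)
                ),
            )

    @property
    def node_ids(self) -> list[str]:
        return self.table["node_id"].tolist()

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def restricted_node_ids(self) -> list[str]:
        return self.table.loc[self.table["in_restricted_set"], "node_id"].tolist()

    def restricted_indices(self) -> np.ndarray:
        """Positional indices of the restricted (cognitive-network) nodes."""
        return np.flatnonzero(self.table["in_restricted_set"].to_numpy())

    def network_of(self) -> dict[str, str]:
        return dict(zip(self.table["node_id"], self.table["network"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t", dtype={"node_id": str}))


def make_parcellation(n_nodes: int = 200) -> Parcellation:
    """Build the default parcellation table.

    For ``n_nodes == 200`` the canonical network sizes are used (136
    restricted nodes).  For other sizes the seven networks are allocated
    proportionally (largest-remainder rounding), which keeps small test
    parcellations structurally faithful.
    """
    if n_nodes < 7:
        raise ValueError("need at least 7 nodes to cover the seven networks")
    if n_nodes == 200:
        sizes = dict(_DEFAULT_SIZES_200)
    else:
        quotas = {k: v * n_nodes / 200.0 for k, v in _DEFAULT_SIZES_200.items()}
        sizes = {k: int(np.floor(q)) for k, q in quotas.items()}
        for k in sizes:
            sizes[k] = max(sizes[k], 1)
        remainders = sorted(
            quotas, key=lambda k: (quotas[k] - np.floor(quotas[k])), reverse=True
        )
        i = 0
        while sum(sizes.values()) < n_nodes:
            sizes[remainders[i % len(remainders)]] += 1
            i += 1
        while sum(sizes.values()) > n_nodes:
            k = max(sizes, key=sizes.get)
            sizes[k] -= 1
    rows = []
    idx = 1
    width = max(3, len(str(n_nodes)))
    for net in SEVEN_NETWORKS:
        for j in range(sizes[net]):
            rows.append(
                {
                    "node_id": f"n{idx:0{width}d}",
                    "network": net,
                    "hemisphere": "L" if j < sizes[net] / 2 else "R",
                }
            )
            idx += 1
    return Parcellation(pd.DataFrame(rows))
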