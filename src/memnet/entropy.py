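"""Sample entropy of node time courses and group comparison.

Sample entropy SampEn(m, r) = -ln(A/B), where B counts pairs of distinct
length-m templates within Chebyshev distance r and A the same for length
m+1.  Both counts use the first N-m templates and exclude self-matches
(Richman-Moorman convention), so A and B are integers and A <= B.  Lower
values mean more ordered, predictable signals.

The tolerance r defaults to ``r_factor`` times a standard deviation whose
scope is configurable: the SD pooled over all node time courses of the
subject's phase (default, matching tolerance on a common scale across
nodes) or the per-node SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from memnet.group_stats import permutation_mean_test


@dataclass
class EntropyConfig:
    m: int = 2  # embedding dimension
    r_factor: float = 0.2  # tolerance as a fraction of the SD
    sd_scope: str = "all_timecourses"  # or "per_node"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.sd_scope not in ("all_timecourses", "per_node"):
            raise ValueError(f"unknown sd_scope {self.sd_scope!r}")


def template_counts(x, m: int, r: float):
    """(A, B): matched template pairs of length m+1 and m.

    Both counts range over the first N-m templates and exclude
    self-matches, so A <= B and both are integers.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    n_templates = n - m
    if n_templates < 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    xm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    xm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    b = int(np.count_nonzero(pdist(xm, metric="chebyshev") <= r))
    a = int(np.count_nonzero(pdist(xm1, metric="chebyshev") <= r))
    return a, b


def sample_entropy(ts, config: EntropyConfig | None = None, r: float | None = None) -> float:
    """SampEn of one series.

    ``r`` overrides the config-derived tolerance (used when the SD scope
    pools over all of a subject's node time courses).  Returns ``inf``
    when no template pair matches at length m+1 (A = 0).
    """
    if config is None:
        config = EntropyConfig()
    x = np.asarray(ts, dtype=float).ravel()
    if x.size < config.m + 2:
        raise ValueError(f"need at least m+2={config.m + 2} samples, got {x.size}")
    if r is None:
        sd = x.std()
        if sd == 0:
            raise ValueError(
                "constant series has zero SD; use sd_scope='all_timecourses' "
                "via phase_entropy, or pass an explicit r"
            )
        r = config.r_factor * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    a, b = template_counts(x, config.m, r)
    if b == 0 or a == 0:
        return math.inf
    return -math.log(a / b)


def sampen_ceiling(n_samples: int, m: int) -> float:
    """Largest resolvable SampEn for a series of given length.

    When no (m+1)-template pair matches (A = 0) the statistic is infinite;
    for comparisons it is conventionally capped at -ln(2 / [(N-m-1)(N-m)]),
    the value A = 1 would give against the maximal pair count.
    """
    n_templates = n_samples - m
    return float(math.log(n_templates * (n_templates - 1) / 2.0))


def phase_entropy(
    phase_data: np.ndarray, config: EntropyConfig | None = None, cap_infinite: bool = False
) -> np.ndarray:
    """Per-node SampEn for one subject's phase (nodes x volumes).

    With ``sd_scope='all_timecourses'`` a single tolerance
    r = r_factor * SD(all node time courses) is shared by every node.
    ``cap_infinite`` replaces infinite values (no template matches) by the
    series-length resolution ceiling so group statistics stay finite.
    """
    if config is None:
        config = EntropyConfig()
    data = np.asarray(phase_data, dtype=float)
    if config.sd_scope == "all_timecourses":
        sd = data.std()
        if sd == 0:
            raise ValueError("all time courses are constant; tolerance undefined")
        r = config.r_factor * sd
        out = np.array([sample_entropy(row, config, r=r) for row in data])
    else:
        out = np.array([sample_entropy(row, config) for row in data])
    if cap_infinite:
        out = np.minimum(out, sampen_ceiling(data.shape[1], config.m))
    return out


def entropy_group_compare(
    subjects,
    node_ids,
    phase: str,
    config: EntropyConfig | None = None,
    n_perm: int = 10000,
    seed=None,
    reduced_nodes=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Node-wise AD-vs-control comparison of sample entropy.

    Computes per-subject SampEn for each node of ``node_ids`` in the given
    phase, then a two-sided permutation test per node.  ``reduced_nodes``
    (from the connectivity comparison) flags overlap in the output.

    Returns a table with columns ``node_id, phase, sampen_ad_mean,
    sampen_cn_mean, p, significant_reduction, overlaps_reduced_fc``.
    """
    if config is None:
        config = EntropyConfig()
    groups = {"AD": [], "CN": []}
    for s in subjects:
        idx = [s.node_ids.index(n) for n in node_ids]
        groups[s.group].append(phase_entropy(s.phases[phase][idx], config, cap_infinite=True))
    if not groups["AD"] or not groups["CN"]:
        raise ValueError("need subjects from both groups")
    ad = np.vstack(groups["AD"])
    cn = np.vstack(groups["CN"])
    rng = np.random.default_rng(seed)
    reduced = set(reduced_nodes or ())
    rows = []
    for j, node in enumerate(node_ids):
        mean_ad, mean_cn, p = permutation_mean_test(
            ad[:, j], cn[:, j], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "node_id": node,
                "phase": phase,
                "sampen_ad_mean": mean_ad,
                "sampen_cn_mean": mean_cn,
                "p": p,
                "significant_reduction": bool(p <= alpha and mean_ad < mean_cn),
                "overlaps_reduced_fc": node in reduced,
            }
        )
    return pd.DataFrame(rows)
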