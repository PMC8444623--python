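"""Seeded synthetic cohort with planted network structure and ground truth.

The generator emulates a two-group memory-task fMRI study: ``n_per_group``
amyloid-positive AD participants and amyloid-negative controls, each with
parcellated node time courses for three task phases (encoding, maintenance,
retrieval).  Planted structure:

* block-covariance communities — node signals are multivariate Gaussian
  with an equicorrelation block for each planted community (``within_r``
  inside a community, ``between_r`` across communities);
* a group deficit — AD subjects' community-1 within-correlation is reduced
  by ``ad_within_delta`` during maintenance and retrieval (not encoding);
* low-entropy nodes — a designated node subset is given AR(1) dynamics
  (phi near 1) in AD subjects, lowering sample entropy at unchanged
  marginal variance;
* a linear-Gaussian mediation path — each subject's community-1 retrieval
  connectivity depends on amyloid burden (SUVR) through path coefficient
  ``a``, and the memory score depends on that connectivity propensity
  (path ``b``) and directly on SUVR (path ``c_prime``), so the true average
  causal mediation effect is ``a * b`` on the standardized scale.

Ground truth (:class:`SyntheticTruth`) is emitted alongside the cohort and
must never be consumed by analysis code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from memnet.cohort import SubjectRecord
from memnet.parcellation import Parcellation, make_parcellation

PHASES = ("encoding", "maintenance", "retrieval")

_AR_BURN_IN = 50  # volumes discarded to reach AR(1) stationarity


@dataclass
class MediationCoeffs:
    """Standardized path coefficients of the planted mediation model."""

    a: float = -0.25  # SUVR -> connectivity propensity
    b: float = 0.30  # connectivity propensity -> memory
    c_prime: float = -0.25  # direct SUVR -> memory


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated study: 36 AD + 36 controls, 200 nodes,
    TR = 3 s, and phase lengths inferred from the task timing (a 2-minute
    maintenance delay is 40 volumes at TR 3 s; encoding and retrieval
    default to 100 and 120 volumes).
    """

    n_per_group: int = 36
    n_nodes: int = 200
    tr_seconds: float = 3.0
    phase_lengths: dict = field(
        default_factory=lambda: {"encoding": 100, "maintenance": 40, "retrieval": 120}
    )
    planted_partition: dict | None = None  # node_id -> community id; None = derive
    within_r: float = 0.45
    between_r: float = 0.05
    ad_within_delta: float = 0.2
    deficit_community: int = 1
    deficit_phases: tuple = ("maintenance", "retrieval")
    entropy_nodes: list | None = None  # None = first 5 community-1 nodes
    n_entropy_nodes: int = 5
    ar_phi: float = 0.9
    mediation: MediationCoeffs = field(default_factory=MediationCoeffs)
    fc_subject_sd: float = 0.12  # between-subject SD of community-1 retrieval r
    mediation_phase: str = "retrieval"
    suvr_cn: tuple = (1.1, 0.1)
    suvr_ad: tuple = (1.4, 0.15)
    age_dist: tuple = (69.0, 7.0, 50.0, 90.0)  # mean, sd, lo, hi (truncated)
    edu_dist: tuple = (12.0, 3.0, 6.0, 20.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        if set(self.phase_lengths) != set(PHASES):
            raise ValueError(f"phase_lengths must have keys {PHASES}")
        for ph, n in self.phase_lengths.items():
            if n < 4:
                raise ValueError(f"phase '{ph}' needs >= 4 volumes, got {n}")
        for name, r in (("within_r", self.within_r), ("between_r", self.between_r)):
            if not abs(r) < 1:
                raise ValueError(f"|{name}| must be < 1, got {r}")
        if not 0 < self.ar_phi < 1:
            raise ValueError("ar_phi must lie in (0, 1)")
        if self.mediation_phase not in PHASES:
            raise ValueError(f"unknown mediation phase {self.mediation_phase!r}")
        if abs(self.mediation.a) > 1:
            raise ValueError("|a| must be <= 1 (standardized path)")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to a generated cohort."""

    planted_partition: dict  # node_id -> community id
    expected_within_z: dict  # group -> phase -> nominal mean within-community-1 z
    expected_between_z: float
    true_acme: float
    entropy_nodes: list
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _community_labels(partition, node_ids) -> np.ndarray:
    if isinstance(partition, dict):
        return np.array([partition[n] for n in node_ids])
    labels = np.asarray(partition)
    if labels.shape != (len(node_ids),):
        raise ValueError("partition length does not match node count")
    return labels


def default_planted_partition(parcellation: Parcellation) -> dict:
    """Derive the planted communities from a-priori network labels.

    Community 1 = DMN + limbic, community 2 = FPN + DAN, community 3 = VAN
    (the three data-driven networks the restricted clustering should find);
    visual and somatomotor nodes form communities 4 and 5 and are excluded
    from the restricted analysis.
    """
    mapping = {"DMN": 1, "Limbic": 1, "FPN": 2, "DAN": 2, "VAN": 3, "Vis": 4, "SomMot": 5}
    return {
        row.node_id: mapping[row.network] for row in parcellation.table.itertuples()
    }


def build_block_covariance(partition, within_r, between_r, node_ids=None, max_shrink_steps=19):
    """Equicorrelation block covariance for a planted community structure.

    Parameters
    ----------
    partition : mapping node->community or array of community labels
    within_r : float or dict community->float
        Target correlation inside each community block.
    between_r : float
        Target correlation across communities.
    node_ids : sequence, optional
        Node order; required when ``partition`` is a mapping and defaults
        to its key order.

    Returns
    -------
    numpy.ndarray
        Symmetric unit-diagonal positive-semidefinite matrix.  If the raw
        block matrix is not PSD it is shrunk toward the identity in convex
        steps of 0.05 until PSD; failure after ``max_shrink_steps`` raises.
    """
    if isinstance(partition, dict) and node_ids is None:
        node_ids = list(partition)
    if node_ids is None:
        node_ids = list(range(len(partition)))
    labels = _community_labels(partition, node_ids)
    communities = sorted(set(labels.tolist()))
    if np.isscalar(within_r):
        within = {c: float(within_r) for c in communities}
    else:
        within = {c: float(within_r.get(c, 0.0)) for c in communities}
    between_r = float(between_r)
    for c, w in within.items():
        if not abs(w) < 1:
            raise ValueError(f"|within_r| must be < 1 for community {c}, got {w}")
    if not abs(between_r) < 1:
        raise ValueError(f"|between_r| must be < 1, got {between_r}")

    n = len(labels)
    cov = np.full((n, n), between_r)
    for c in communities:
        idx = labels == c
        cov[np.ix_(idx, idx)] = within[c]
    np.fill_diagonal(cov, 1.0)

    # Fast analytic PSD certificate: with 0 <= between <= within_c < 1 the
    # matrix is a nonnegative sum of PSD rank-one/diagonal pieces.
    if 0 <= between_r <= min(within.values()):
        return cov

    target = cov.copy()
    for step in range(max_shrink_steps + 1):
        if np.linalg.eigvalsh(cov)[0] >= -1e-10:
            return cov
        s = 0.05 * (step + 1)
        cov = (1 - s) * target + s * np.eye(n)
    # identify an offending block for the error message
    offender = "between-community structure"
    for c in communities:
        idx = labels == c
        block = target[np.ix_(idx, idx)]
        if np.linalg.eigvalsh(block)[0] < -1e-10:
            offender = f"community {c} block"
            break
    raise ValueError(
        f"covariance not PSD after {max_shrink_steps} shrinkage steps; "
        f"offending block: {offender}"
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _ar1_filter(x, phi):
    """AR(1) recolouring of a unit-variance signal, variance preserved."""
    from scipy.signal import lfilter

    return lfilter([math.sqrt(1 - phi**2)], [1.0, -phi], x, axis=-1)


def _draw_signals(rng, labels, communities, within, between_r, t_len, entropy_idx, ar_phi, node_ids):
    """Unit-variance node signals with the planted block correlations.

    When ``0 <= between_r <= min(within)`` the block structure is realized
    by an explicit factor construction,

        x_i = sqrt(b) * g + sqrt(w_c - b) * f_c + sqrt(1 - w_c) * e_i,

    with a global factor ``g``, one factor ``f_c`` per community and
    idiosyncratic noise ``e_i``.  Low-entropy nodes get AR(1)-recoloured
    *idiosyncratic* noise only, which lowers their sample entropy while
    leaving every planted cross-correlation untouched.  Other parameter
    regimes fall back to a Cholesky draw (where AR recolouring would also
    scale cross-correlations, so entropy nodes are recoloured after the
    fact and the attenuation is accepted).
    """
    n_nodes = labels.shape[0]
    total = t_len + _AR_BURN_IN
    factorizable = 0 <= between_r <= min(within.values())
    if factorizable:
        g = rng.standard_normal(total)
        factors = {c: rng.standard_normal(total) for c in communities}
        e = rng.standard_normal((n_nodes, total))
        if entropy_idx.size:
            e[entropy_idx] = _ar1_filter(e[entropy_idx], ar_phi)
        w = np.array([within[c] for c in labels])
        f = np.vstack([factors[c] for c in labels])
        sig = (
            math.sqrt(between_r) * g[None, :]
            + np.sqrt(w - between_r)[:, None] * f
            + np.sqrt(1.0 - w)[:, None] * e
        )
    else:
        cov = build_block_covariance(labels, within, between_r, node_ids)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_nodes))
        sig = chol @ rng.standard_normal((n_nodes, total))
        if entropy_idx.size:
            sig[entropy_idx] = _ar1_filter(sig[entropy_idx], ar_phi)
    return sig[:, _AR_BURN_IN:]


def generate_cohort(config: CohortConfig, parcellation: Parcellation | None = None):
    """Draw a seeded synthetic cohort.

    Returns
    -------
    (list of SubjectRecord, SyntheticTruth)
        AD subjects first, then controls; bit-identical for a given config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if parcellation is None:
        parcellation = make_parcellation(config.n_nodes)
    if parcellation.n_nodes != config.n_nodes:
        raise ValueError(
            f"parcellation has {parcellation.n_nodes} nodes, config says {config.n_nodes}"
        )
    node_ids = parcellation.node_ids
    partition = config.planted_partition or default_planted_partition(parcellation)
    labels = _community_labels(partition, node_ids)

    community1 = [n for n, c in zip(node_ids, labels) if c == config.deficit_community]
    if config.entropy_nodes is not None:
        entropy_nodes = list(config.entropy_nodes)
    else:
        entropy_nodes = community1[: config.n_entropy_nodes]
    unknown = set(entropy_nodes) - set(node_ids)
    if unknown:
        raise ValueError(f"entropy_nodes not in parcellation: {sorted(unknown)}")
    entropy_idx = np.array([node_ids.index(n) for n in entropy_nodes], dtype=int)

    n = 2 * config.n_per_group
    groups = np.array(["AD"] * config.n_per_group + ["CN"] * config.n_per_group)

    med = config.mediation
    if n > 0:
        suvr = np.where(
            groups == "AD",
            _truncated_normal(rng, *config.suvr_ad, 1e-6, np.inf, n),
            _truncated_normal(rng, *config.suvr_cn, 1e-6, np.inf, n),
        )
        z_suvr = (suvr - suvr.mean()) / suvr.std() if n > 1 else np.zeros(n)
        eta = rng.standard_normal(n)
        zeta = med.a * z_suvr + math.sqrt(max(0.0, 1 - med.a**2)) * eta
        var_signal = med.c_prime**2 + med.b**2 + 2 * med.a * med.b * med.c_prime
        sigma_y = math.sqrt(max(0.05, 1 - var_signal))
        memory_latent = med.c_prime * z_suvr + med.b * zeta + sigma_y * rng.standard_normal(n)
        memory = 20.0 + 4.0 * memory_latent
        accuracy = np.clip(0.8 + 0.05 * memory_latent + rng.normal(0, 0.05, n), 0, 1)
        age = _truncated_normal(rng, config.age_dist[0], config.age_dist[1],
                                config.age_dist[2], config.age_dist[3], n)
        education = _truncated_normal(rng, config.edu_dist[0], config.edu_dist[1],
                                      config.edu_dist[2], config.edu_dist[3], n)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
    else:
        suvr = memory = accuracy = age = education = np.empty(0)
        sex = np.empty(0, dtype=str)
        zeta = np.empty(0)

    r_lo = config.between_r + 0.02
    communities = sorted(set(labels.tolist()))
    subjects = []
    for i in range(n):
        is_ad = groups[i] == "AD"
        phases = {}
        for phase in PHASES:
            t_len = config.phase_lengths[phase]
            r1 = config.within_r
            if is_ad and phase in config.deficit_phases:
                r1 -= config.ad_within_delta
            if phase == config.mediation_phase:
                r1 += config.fc_subject_sd * zeta[i]
            r1 = float(np.clip(r1, r_lo, 0.97))
            within = {c: config.within_r for c in communities}
            within[config.deficit_community] = r1
            phases[phase] = _draw_signals(
                rng, labels, communities, within, config.between_r, t_len,
                entropy_idx if is_ad else np.empty(0, dtype=int), config.ar_phi,
                node_ids,
            )
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}",
                group=str(groups[i]),
                age=float(age[i]),
                sex=str(sex[i]),
                education=float(education[i]),
                suvr=float(suvr[i]),
                memory=float(memory[i]),
                accuracy=float(accuracy[i]),
                node_ids=list(node_ids),
                phases=phases,
                tr_seconds=config.tr_seconds,
            )
        )

    expected_within = {
        "CN": {ph: math.atanh(config.within_r) for ph in PHASES},
        "AD": {
            ph: math.atanh(
                config.within_r
                - (config.ad_within_delta if ph in config.deficit_phases else 0.0)
            )
            for ph in PHASES
        },
    }
    truth = SyntheticTruth(
        planted_partition={n_: int(c) for n_, c in zip(node_ids, labels)},
        expected_within_z=expected_within,
        expected_between_z=math.atanh(config.between_r),
        true_acme=med.a * med.b,
        entropy_nodes=entropy_nodes,
        seed=config.seed,
    )
    return subjects, truth
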