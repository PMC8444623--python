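"""End-to-end pipeline driver.

Orchestrates the full analysis in the study's order: (simulate or load a
cohort) -> per-subject phase connectivity -> data-driven networks from the
control maintenance matrices -> phase-wise group comparisons (network mean
FC, NBS edge inference, reduced-node counts and cross-phase chi-square) ->
node-wise sample entropy -> amyloid-connectivity associations -> mediation.

Every stochastic stage receives its own child seed derived from the master
seed, and every artifact embeds the config hash and master seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from memnet.cohort import load_cohort
from memnet.community import restrict_and_cluster
from memnet.connectivity import compute_fc, mean_connectivity
from memnet.entropy import EntropyConfig, entropy_group_compare
from memnet.group_stats import chi_square_counts, count_reduced, nbs, permutation_mean_test
from memnet.mediation import corr_perm, mediate
from memnet.parcellation import Parcellation, make_parcellation
from memnet.prep import PhaseBold
from memnet.synthetic import CohortConfig, generate_cohort

PHASES = ("encoding", "maintenance", "retrieval")


@dataclass
class PipelineConfig:
    """All pipeline settings; YAML round-trippable."""

    cohort_dir: str | None = None  # None -> simulate with `simulate` settings
    parcellation_path: str | None = None  # None -> default table
    out_dir: str | None = None
    simulate: CohortConfig = field(default_factory=CohortConfig)
    # clustering
    cluster_n_runs: int = 100
    cluster_tau: float = 0.5
    gamma: float = 1.0
    # group comparisons
    mean_test_n_perm: int = 10000
    nbs_threshold_t: float | None = None  # None -> |t| at two-sided p=0.01
    nbs_n_perm: int = 5000
    nbs_alpha: float = 0.05
    # entropy
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    entropy_sd_scope: str = "all_timecourses"
    # mediation
    mediation_n_boot: int = 10000
    mediation_ci: str = "bca"
    # master seed
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulate")
        if isinstance(sim, dict):
            sim = dict(sim)
            med = sim.get("mediation")
            if isinstance(med, dict):
                from memnet.synthetic import MediationCoeffs

                sim["mediation"] = MediationCoeffs(**med)
            for key in ("deficit_phases", "suvr_cn", "suvr_ad", "age_dist", "edu_dist"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["simulate"] = CohortConfig(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        # out_dir is where results land, not part of the analysis identity
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seeds(master: int, n: int = 12) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(master).generate_state(n)]


def compute_all_fc(subjects) -> dict:
    """phase -> list of per-subject ConnectivityMatrix (cohort order)."""
    out: dict = {ph: [] for ph in PHASES}
    for s in subjects:
        for ph in PHASES:
            pb = PhaseBold(
                node_ids=s.node_ids, data=s.phases[ph], phase=ph, tr_seconds=s.tr_seconds
            )
            fc = compute_fc(pb)
            fc.subject_id = s.subject_id
            out[ph].append(fc)
    return out


def _edge_stack(fc_list, members):
    """subjects x edges matrix of the members' upper-triangle z values."""
    stacks = []
    for fc in fc_list:
        sub = fc.restrict(members)
        iu = np.triu_indices(len(members), 1)
        stacks.append(sub.z[iu])
    return np.vstack(stacks)


def run_pipeline(config: PipelineConfig, cohort=None, truth=None) -> dict:
    """Run the full analysis; returns the machine-readable summary.

    ``cohort`` (a list of SubjectRecord) bypasses loading/simulation, so
    individual stages and the end-to-end run see identical inputs.
    """
    seeds = _stage_seeds(config.seed)

    # --- stage: cohort ---------------------------------------------------
    if config.parcellation_path:
        parcellation = Parcellation.from_tsv(config.parcellation_path)
    else:
        n_nodes = config.simulate.n_nodes if cohort is None else len(cohort[0].node_ids)
        parcellation = make_parcellation(n_nodes)
    if cohort is None:
        if config.cohort_dir:
            cohort = load_cohort(config.cohort_dir, parcellation)
        else:
            sim = dataclasses.replace(config.simulate, seed=seeds[0])
            cohort, truth = generate_cohort(sim, parcellation)
    if not cohort:
        raise ValueError("empty cohort")
    is_ad = np.array([s.group == "AD" for s in cohort])
    if not is_ad.any() or is_ad.all():
        raise ValueError("pipeline needs both AD and control subjects")

    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(cohort),
        "n_ad": int(is_ad.sum()),
        "n_cn": int((~is_ad).sum()),
    }

    # --- stage: connectivity ---------------------------------------------
    fc = compute_all_fc(cohort)

    # --- stage: data-driven networks (controls, maintenance) -------------
    control_maint = [m for m, ad in zip(fc["maintenance"], is_ad) if not ad]
    partition = restrict_and_cluster(
        control_maint,
        parcellation,
        n_runs=config.cluster_n_runs,
        tau=config.cluster_tau,
        gamma=config.gamma,
        seed=seeds[1],
    )
    summary["partition"] = {
        "n_communities": partition.n_communities,
        "sizes": {str(k): v for k, v in partition.sizes().items()},
        "modularity_q": partition.modularity_q,
    }
    networks = sorted(set(partition.assignment.values()))

    # --- stage: network mean connectivity comparisons ---------------------
    rng = np.random.default_rng(seeds[2])
    mean_fc_rows = []
    mean_fc_summary: dict = {}
    subject_network_fc: dict = {}
    for ph in PHASES:
        mean_fc_summary[ph] = {}
        for net in networks:
            members = partition.members(net)
            if len(members) < 2:
                continue
            vals = np.array([mean_connectivity(m, members) for m in fc[ph]])
            subject_network_fc[(ph, net)] = vals
            mean_ad, mean_cn, p = permutation_mean_test(
                vals[is_ad], vals[~is_ad], config.mean_test_n_perm,
                seed=int(rng.integers(2**31)),
            )
            mean_fc_summary[ph][f"network{net}"] = {
                "mean_ad": mean_ad, "mean_cn": mean_cn, "p": p,
            }
            mean_fc_rows.append(
                {"phase": ph, "networks": f"{net}-{net}", "mean_ad": mean_ad,
                 "mean_cn": mean_cn, "p": p}
            )
        for i, na in enumerate(networks):
            for nb in networks[i + 1:]:
                ma, mb = partition.members(na), partition.members(nb)
                vals = np.array([mean_connectivity(m, ma, mb) for m in fc[ph]])
                mean_ad, mean_cn, p = permutation_mean_test(
                    vals[is_ad], vals[~is_ad], config.mean_test_n_perm,
                    seed=int(rng.integers(2**31)),
                )
                mean_fc_summary[ph][f"network{na}-{nb}"] = {
                    "mean_ad": mean_ad, "mean_cn": mean_cn, "p": p,
                }
                mean_fc_rows.append(
                    {"phase": ph, "networks": f"{na}-{nb}", "mean_ad": mean_ad,
                     "mean_cn": mean_cn, "p": p}
                )
    summary["mean_fc"] = mean_fc_summary

    # --- stage: NBS within Network 1 --------------------------------------
    net1 = partition.members(1)
    covariates = np.column_stack(
        [[s.age for s in cohort], [1.0 if s.sex == "F" else 0.0 for s in cohort]]
    )
    nbs_results = {}
    reduction = {}
    for ph in PHASES:
        stack = _edge_stack(fc[ph], net1)
        res = nbs(
            stack,
            is_ad.astype(float),
            covariates=covariates,
            threshold_t=config.nbs_threshold_t,
            n_perm=config.nbs_n_perm,
            alpha=config.nbs_alpha,
            seed=int(rng.integers(2**31)),
            node_ids=net1,
            phase=ph,
        )
        nbs_results[ph] = res
        reduction[ph] = count_reduced(res)
    summary["nbs"] = {
        ph: {
            "threshold_t": nbs_results[ph].threshold_t,
            "n_reduced_nodes": reduction[ph].n_reduced_nodes,
            "n_reduced_edges": reduction[ph].n_reduced_edges,
            "n_total_nodes": reduction[ph].n_total_nodes,
            "component_p": [c.p for c in nbs_results[ph].components],
        }
        for ph in PHASES
    }

    chi = {}
    for ph_a, ph_b in (("retrieval", "maintenance"), ("retrieval", "encoding"),
                       ("maintenance", "encoding")):
        ra, rb = reduction[ph_a], reduction[ph_b]
        try:
            chi2, p = chi_square_counts(
                ra.n_reduced_nodes, ra.n_total_nodes, rb.n_reduced_nodes, rb.n_total_nodes
            )
            chi[f"{ph_a}_vs_{ph_b}"] = {"chi2": chi2, "p": p}
        except ValueError:
            chi[f"{ph_a}_vs_{ph_b}"] = {"chi2": None, "p": None}
    summary["chi_square"] = chi

    # --- stage: sample entropy in Network 1 --------------------------------
    entropy_cfg = EntropyConfig(
        m=config.entropy_m, r_factor=config.entropy_r_factor,
        sd_scope=config.entropy_sd_scope,
    )
    entropy_tables = []
    entropy_summary = {}
    for ph in PHASES:
        table = entropy_group_compare(
            cohort, net1, ph, entropy_cfg,
            n_perm=config.mean_test_n_perm,
            seed=int(rng.integers(2**31)),
            reduced_nodes={net1[i] for i in nbs_results[ph].reduced_nodes},
        )
        entropy_tables.append(table)
        sig = table[table["significant_reduction"]]
        entropy_summary[ph] = {
            "n_reduced_entropy_nodes": int(len(sig)),
            "nodes": sig["node_id"].tolist(),
            "n_overlapping_reduced_fc": int(sig["overlaps_reduced_fc"].sum()),
        }
    summary["entropy"] = entropy_summary

    # --- stage: amyloid associations and mediation -------------------------
    suvr = np.array([s.suvr for s in cohort])
    memory = np.array([s.memory for s in cohort])
    associations = {}
    for ph in PHASES:
        r, p = corr_perm(
            suvr, subject_network_fc[(ph, 1)], n_perm=config.mean_test_n_perm,
            seed=int(rng.integers(2**31)),
        )
        associations[ph] = {"r": r, "p": p}
    summary["suvr_network1_fc"] = associations

    med_cov = np.column_stack(
        [
            [s.age for s in cohort],
            [1.0 if s.sex == "F" else 0.0 for s in cohort],
            [s.education for s in cohort],
        ]
    )
    med = mediate(
        suvr,
        subject_network_fc[("retrieval", 1)],
        memory,
        covariates=med_cov,
        n_boot=config.mediation_n_boot,
        ci_method=config.mediation_ci,
        seed=int(rng.integers(2**31)),
    )
    summary["mediation"] = med.to_dict()

    # --- stage: artifacts --------------------------------------------------
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        partition.to_tsv(out / "partition.tsv", parcellation)
        pd.DataFrame(mean_fc_rows).to_csv(out / "mean_fc_tests.tsv", sep="\t", index=False)
        for ph in PHASES:
            nbs_results[ph].to_edge_table().to_csv(
                out / f"nbs_edges_{ph}.tsv", sep="\t", index=False
            )
        pd.concat(entropy_tables).to_csv(out / "entropy.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
    return summary
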