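"""Subject records and plain-text cohort I/O.

A cohort directory holds one TSV per subject and phase
(``sub-XXX_phase-{encoding,maintenance,retrieval}.tsv``; rows are nodes,
first column ``node_id``, remaining columns are volumes) plus a
``participants.tsv`` phenotype table.  Synthetic cohorts additionally
carry a ``truth.json`` with planted ground truth, which analysis code
never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PHASES = ("encoding", "maintenance", "retrieval")

PARTICIPANT_COLUMNS = [
    "subject",
    "group",
    "age",
    "sex",
    "education",
    "suvr",
    "memory",
    "accuracy",
]


@dataclass
class SubjectRecord:
    """One participant: phase time courses plus phenotype."""

    subject_id: str
    group: str  # 'AD' or 'CN'
    age: float
    sex: str  # 'F'/'M'
    education: float
    suvr: float
    memory: float
    accuracy: float
    node_ids: list = field(repr=False)
    phases: dict = field(repr=False)  # phase -> (n_nodes, n_volumes) array
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        if self.group not in ("AD", "CN"):
            raise ValueError(f"{self.subject_id}: group must be 'AD' or 'CN', got {self.group!r}")
        for phase, data in self.phases.items():
            if data.shape[0] != len(self.node_ids):
                raise ValueError(
                    f"{self.subject_id} phase {phase}: {data.shape[0]} rows "
                    f"but {len(self.node_ids)} node ids"
                )
            if np.isnan(data).any():
                raise ValueError(f"{self.subject_id} phase {phase}: NaN values in time courses")


def write_cohort(subjects, out_dir, truth=None) -> Path:
    """Write subjects (and optional ground truth) to a cohort directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
                "suvr": s.suvr,
                "memory": s.memory,
                "accuracy": s.accuracy,
            }
        )
        for phase, data in s.phases.items():
            df = pd.DataFrame(
                data,
                index=pd.Index(s.node_ids, name="node_id"),
                columns=[f"v{t:04d}" for t in range(data.shape[1])],
            )
            # %.17g keeps doubles exact, so write -> read round-trips bit-identically
            df.to_csv(out / f"{s.subject_id}_phase-{phase}.tsv", sep="\t", float_format="%.17g")
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS).to_csv(
        out / "participants.tsv", sep="\t", index=False
    )
    if truth is not None:
        payload = truth.to_dict() if hasattr(truth, "to_dict") else truth
        (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out


def load_cohort(cohort_dir, parcellation=None, tr_seconds: float = 3.0):
    """Load a cohort directory into typed :class:`SubjectRecord` objects.

    If a parcellation is given, every subject's node list is checked
    against it and mismatches raise with the offending file named.
    """
    cohort_dir = Path(cohort_dir)
    ptable = cohort_dir / "participants.tsv"
    if not ptable.exists():
        raise FileNotFoundError(f"missing {ptable}")
    participants = pd.read_csv(ptable, sep="\t")
    missing = set(PARTICIPANT_COLUMNS) - set(participants.columns)
    if missing:
        raise ValueError(f"{ptable}: missing columns {sorted(missing)}")

    expected_nodes = parcellation.node_ids if parcellation is not None else None
    subjects = []
    for row in participants.itertuples():
        phases = {}
        node_ids = None
        for phase in PHASES:
            fp = cohort_dir / f"{row.subject}_phase-{phase}.tsv"
            if not fp.exists():
                raise FileNotFoundError(f"missing phase file {fp}")
            df = pd.read_csv(fp, sep="\t", index_col="node_id", float_precision="round_trip")
            df.index = df.index.astype(str)
            if df.isna().any().any():
                bad = df.index[df.isna().any(axis=1)][0]
                raise ValueError(f"{fp}: NaN values (first at node {bad})")
            if node_ids is None:
                node_ids = df.index.tolist()
            elif df.index.tolist() != node_ids:
                raise ValueError(f"{fp}: node order differs across phases for {row.subject}")
            phases[phase] = df.to_numpy(dtype=float)
        if expected_nodes is not None and node_ids != expected_nodes:
            raise ValueError(
                f"subject {row.subject}: {len(node_ids)} nodes do not match the "
                f"{len(expected_nodes)}-node parcellation"
            )
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject),
                group=str(row.group),
                age=float(row.age),
                sex=str(row.sex),
                education=float(row.education),
                suvr=float(row.suvr),
                memory=float(row.memory),
                accuracy=float(row.accuracy),
                node_ids=node_ids,
                phases=phases,
                tr_seconds=tr_seconds,
            )
        )
    return subjects
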