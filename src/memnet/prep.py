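"""Denoising and phase segmentation of node time courses.

The preparation order matches the conventional full-run pipeline: confound
regression, then linear detrending and zero-phase band-pass filtering of
the whole run, and only then splitting into the memory phases.  Filtering
before splitting avoids re-introducing edge transients at phase
boundaries.

Time axis convention: run matrices are *volumes x nodes* (time-major, so
filters operate along axis 0); :class:`PhaseBold` stores *nodes x volumes*
to match the on-disk TSV layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

PHASES = ("encoding", "maintenance", "retrieval")


@dataclass
class PhaseBold:
    """Node time courses for one memory phase."""

    node_ids: list
    data: np.ndarray  # (n_nodes, n_volumes)
    phase: str
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.node_ids):
            raise ValueError("data must be (n_nodes, n_volumes) matching node_ids")
        if self.data.shape[1] < 4:
            raise ValueError(f"phase {self.phase}: need >= 4 volumes, got {self.data.shape[1]}")
        if np.isnan(self.data).any():
            raise ValueError(f"phase {self.phase}: NaN values after preparation")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConfoundSet:
    """Volume-by-regressor nuisance matrix with column labels.

    Typical columns: head-motion parameters and their derivatives, tissue
    component time courses, outlier-scan indicators, and pre-convolved
    task-condition regressors (built upstream; never constructed here).
    """

    columns: np.ndarray  # (n_volumes, k)
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.ndim != 2:
            raise ValueError("confounds must be a 2-D volume x regressor matrix")
        if not self.labels:
            self.labels = [f"confound_{i}" for i in range(self.columns.shape[1])]
        if len(self.labels) != self.columns.shape[1]:
            raise ValueError("label count does not match confound columns")


def regress_confounds(run: np.ndarray, confounds: ConfoundSet) -> np.ndarray:
    """Residualize a (volumes x nodes) run against nuisance regressors.

    An intercept is always appended, so the output is demeaned even for an
    empty confound set.  Raises on rank-deficient designs, naming the
    collinear columns.
    """
    run = np.asarray(run, dtype=float)
    if confounds.columns.shape[0] not in (0, run.shape[0]):
        raise ValueError(
            f"confounds have {confounds.columns.shape[0]} volumes, run has {run.shape[0]}"
        )
    n_vol = run.shape[0]
    if confounds.columns.size:
        design = np.column_stack([np.ones(n_vol), confounds.columns])
        labels = ["intercept"] + list(confounds.labels)
    else:
        design = np.ones((n_vol, 1))
        labels = ["intercept"]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # locate dependent columns via the QR diagonal
        _, rmat = np.linalg.qr(design)
        diag = np.abs(np.diag(rmat))
        bad = [labels[i] for i in range(len(labels)) if i < len(diag) and diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad or labels}")
    beta, *_ = np.linalg.lstsq(design, run, rcond=None)
    return run - design @ beta


def bandpass_detrend(
    run: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    order: int = 2,
) -> np.ndarray:
    """Linear detrend then zero-phase Butterworth band-pass (volumes x nodes).

    The filter is a 2nd-order Butterworth applied forward-backward
    (``sosfiltfilt``), so phase boundaries are not shifted.
    """
    run = np.asarray(run, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist {nyquist:.4f} Hz")
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    detrended = signal.detrend(run, axis=0, type="linear")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, detrended, axis=0)


def events_from_seconds(events_s: dict, tr_seconds: float) -> dict:
    """Convert ``phase -> (start_s, end_s)`` to half-open volume intervals.

    Convention: ``floor(start / TR)`` to ``ceil(end / TR)``, 0-based.
    """
    return {
        ph: (int(math.floor(s / tr_seconds)), int(math.ceil(e / tr_seconds)))
        for ph, (s, e) in events_s.items()
    }


def split_phases(run: np.ndarray, events: dict, node_ids=None, tr_seconds: float = 3.0) -> dict:
    """Cut a (volumes x nodes) run into per-phase blocks.

    ``events`` maps phase name to a half-open 0-based volume interval
    ``(start, end)``.  Intervals must lie inside the run and must not
    overlap.
    """
    run = np.asarray(run, dtype=float)
    n_vol = run.shape[0]
    if node_ids is None:
        node_ids = [f"n{i + 1:03d}" for i in range(run.shape[1])]
    spans = sorted(events.items(), key=lambda kv: kv[1][0])
    prev_end = None
    for ph, (start, end) in spans:
        if ph not in PHASES:
            raise ValueError(f"unknown phase {ph!r}")
        if not (0 <= start < end <= n_vol):
            raise ValueError(f"phase {ph}: interval [{start}, {end}) outside run of {n_vol} volumes")
        if prev_end is not None and start < prev_end:
            raise ValueError(f"phase {ph}: interval overlaps the previous phase")
        prev_end = end
    return {
        ph: PhaseBold(
            node_ids=list(node_ids),
            data=run[start:end].T.copy(),
            phase=ph,
            tr_seconds=tr_seconds,
        )
        for ph, (start, end) in events.items()
    }


def prepare_run(run, confounds, events, tr_seconds, node_ids=None, **filter_kwargs) -> dict:
    """Full preparation: regress -> detrend/band-pass -> split into phases."""
    resid = regress_confounds(run, confounds)
    filtered = bandpass_detrend(resid, tr_seconds, **filter_kwargs)
    return split_phases(filtered, events, node_ids=node_ids, tr_seconds=tr_seconds)
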