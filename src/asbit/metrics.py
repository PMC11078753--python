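"""Event-error-rate accounting and the scalability / noise / code-length sweeps.

The event error rate (EER) of a node counts a missing true event or a false
detection as one error within a 1 ms bin, normalized by the number of true
events: ``EER = (missed + false) / true``.  Network-level results average the
per-node EER over the evaluated target nodes (unweighted).  The same metric
applied to transmitted neural spikes is called the spike error rate (SER).

Sweeps run the full pipeline (population -> events -> superposition ->
demodulation -> error report) over experiment axes with per-cell replicate
seeds and emit a tidy table, one row per (cell, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np
import pandas as pd

from .network_sim import DEFAULT_BIN_S, EventTrain
from .demodulator import DetectionResult

__all__ = [
    "ErrorReport",
    "SweepResult",
    "compute_error_rate",
    "run_sweep",
    "snr_sweep",
    "max_throughput_under",
]


@dataclass(eq=False)
class ErrorReport:
    """Per-node missed/false counts and the target-averaged EER."""

    per_node: pd.DataFrame
    bin_size: float = DEFAULT_BIN_S

    @property
    def mean_eer(self) -> float:
        """Unweighted mean of per-node EER over evaluated targets."""
        return float(self.per_node["eer"].mean())

    @property
    def pooled_eer(self) -> float:
        """(total missed + total false) / total true events."""
        t = self.per_node
        true = t["true_events"].sum()
        return float((t["missed"].sum() + t["false"].sum()) / true) if true else np.nan

    @property
    def totals(self) -> tuple[int, int, int]:
        t = self.per_node
        return int(t["missed"].sum()), int(t["false"].sum()), int(t["true_events"].sum())


def compute_error_rate(truth, detected, targets=None,
                       n_bins: int | None = None,
                       bin_size: float = DEFAULT_BIN_S) -> ErrorReport:
    """Per-bin set comparison of detections against ground truth.

    ``truth`` maps node id -> :class:`EventTrain`; ``detected`` maps node id
    -> :class:`DetectionResult`.  ``n_bins`` restricts the comparison to bins
    inside the evaluation epoch (detections or events beyond it are ignored).
    A node with zero true events gets EER equal to its false count (each
    false detection counted as one error against an empty train).
    """
    if isinstance(truth, list):
        truth = {t.node_id: t for t in truth}
    if isinstance(detected, list):
        detected = {d.node_id: d for d in detected}
    if targets is None:
        targets = sorted(detected)
    rows = []
    for nid in targets:
        tr = truth.get(nid)
        if tr is not None and abs(tr.bin_size - bin_size) > 1e-12:
            raise ValueError(f"bin size mismatch for node {nid}")
        tb = set() if tr is None else set(tr.bins().tolist())
        det = detected.get(nid)
        db = set() if det is None else set(det.bins.tolist())
        if n_bins is not None:
            tb = {b for b in tb if 0 <= b < n_bins}
            db = {b for b in db if 0 <= b < n_bins}
        missed = len(tb - db)
        false = len(db - tb)
        true = len(tb)
        eer = (missed + false) / true if true else float(false)
        rows.append((nid, missed, false, true, eer))
    per_node = pd.DataFrame(rows, columns=["node_id", "missed", "false",
                                           "true_events", "eer"])
    return ErrorReport(per_node=per_node, bin_size=bin_size)


@dataclass(eq=False)
class SweepResult:
    """Tidy sweep table: one row per (cell, replicate), with seeds recorded."""

    table: pd.DataFrame
    sweep_id: str = "sweep"

    _CELL_KEYS = ["n_nodes", "rate_hz", "snr_db", "code_len"]

    def cell_means(self) -> pd.DataFrame:
        """Mean EER and standard error per cell, plus aggregate throughput."""
        keys = [k for k in self._CELL_KEYS
                if k in self.table.columns and self.table[k].notna().any()]
        ok = self.table[self.table["eer"].notna()]
        g = ok.groupby(keys, as_index=False, dropna=False).agg(
            mean_eer=("eer", "mean"),
            sem_eer=("eer", "sem"),
            n_rep=("eer", "size"),
        )
        if {"n_nodes", "rate_hz"} <= set(g.columns):
            g["events_per_s"] = g["n_nodes"] * g["rate_hz"]
        return g


def run_sweep(axes: dict, cell_fn, replicates: int = 5, master_seed: int = 0,
              sweep_id: str = "sweep", extra: dict | None = None) -> SweepResult:
    """Run ``cell_fn(cell_params, seed)`` over the cartesian product of axes.

    ``cell_fn`` returns an :class:`ErrorReport`; per-cell failures are
    recorded (``eer = NaN`` plus the error message) and the sweep continues.
    Each replicate draws a distinct child seed from ``master_seed``.
    """
    if not axes:
        raise ValueError("sweep axes must be non-empty")
    names = list(axes)
    rows = []
    for ci, values in enumerate(_iterproduct(*(axes[n] for n in names))):
        cell = dict(zip(names, values))
        if extra:
            cell = {**extra, **cell}
        for rep in range(replicates):
            seed = int(np.random.SeedSequence([master_seed, rep, ci])
                       .generate_state(1)[0] % 2**31)
            row = {k: cell.get(k) for k in ("n_nodes", "rate_hz", "snr_db", "code_len")}
            row.update(sweep_id=sweep_id, replicate=rep, seed=seed)
            try:
                report = cell_fn(cell, seed)
                missed, false, true = report.totals
                row.update(eer=report.mean_eer, missed=missed, false=false,
                           true_events=true, error="")
            except Exception as exc:  # noqa: BLE001 - sweep must survive cell failure
                row.update(eer=np.nan, missed=np.nan, false=np.nan,
                           true_events=np.nan, error=str(exc))
            rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), sweep_id=sweep_id)


def snr_sweep(base, population, noise_sigmas, demod_fn,
              targets=None, truth=None, n_bins=None) -> pd.DataFrame:
    """Re-noise one base aggregate stream across a noise grid and re-demodulate.

    ``base`` is a noise-free (or low-noise) :class:`AggregateSignal`;
    for each added-noise sigma the average packet SNR is recomputed as the
    ratio of per-packet RSSI to the noise level, the stream is re-demodulated
    via ``demod_fn(noisy_samples, sigma)`` (returning node id ->
    :class:`DetectionResult`), and the EER recorded.
    """
    from .signal_model import apply_noise, measure_snr_rssi

    rows = []
    for i, sigma in enumerate(noise_sigmas):
        noisy = apply_noise(base.samples, sigma, rng=np.random.default_rng(1000 + i)) \
            if sigma > 0 else base.samples
        snrs = []
        for node in population:
            if targets is not None and node.node_id not in targets:
                continue
            _, snr = measure_snr_rssi(np.array([node.a_prime]), sigma if sigma > 0 else 0.0)
            snrs.append(snr)
        mean_snr = float(np.mean(snrs)) if snrs else np.inf
        detections = demod_fn(noisy, sigma)
        report = compute_error_rate(truth, detections, targets=targets, n_bins=n_bins)
        missed, false, true = report.totals
        rows.append(dict(noise_sigma=sigma, snr_db=mean_snr, eer=report.mean_eer,
                         missed=missed, false=false, true_events=true))
    return pd.DataFrame(rows)


def max_throughput_under(cell_means: pd.DataFrame, eer_budget: float = 1e-3) -> float:
    """Largest aggregate event throughput (rate x nodes) among cells whose
    mean EER stays below the budget."""
    ok = cell_means[cell_means["mean_eer"] < eer_budget]
    if ok.empty:
        return 0.0
    return float(ok["events_per_s"].max())
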