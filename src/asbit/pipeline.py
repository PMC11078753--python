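"""End-to-end experiment cells: population -> events -> stream -> detections.

One "cell" is a complete network transmission experiment at fixed conditions:
build a heterogeneous population (target + background nodes, the latter
replicated with replacement when the requested network exceeds the base
population), draw sparse Poisson event trains, superpose all packets onto the
ADC grid with additive noise, then demodulate an evaluation subset of target
nodes and score their event error rate.  All randomness derives from a
single cell seed through named child streams, so identical configurations
reproduce bitwise-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import network_sim
from .demodulator import demodulate_node, recover_slot, build_filter_bank
from .metrics import ErrorReport, compute_error_rate
from .network_sim import build_population, generate_poisson_events, \
    generate_periodic_events, scale_background, superpose, DEFAULT_BIN_S
from .signal_model import ReceiverChain, sigma_for_snr

__all__ = ["CellConfig", "run_cell", "simulate_cell", "demodulate_targets"]

#: Background-population size of the bench experiments; larger networks are
#: built by resampling these nodes with replacement.
BASE_BACKGROUND = 38


@dataclass
class CellConfig:
    """Conditions of one network experiment cell.

    Defaults mirror the reference scalability experiment: 40 target nodes
    plus replicated background, 50 events/s per node, 6 s epoch, equal
    average packet SNR 1.7 dB (set ``near_far_spread_db`` for a near-far
    amplitude spread across nodes), 511-symbol truncated m=13 identifiers,
    free-running oscillator clocks within
    +/-1,000 ppm demodulated by 31-clock-point x 3-phase filter banks.
    ``n_eval`` limits how many target nodes are actually demodulated and
    scored (desk-scale economy; all targets still transmit).
    """

    n_nodes: int = 750
    rate_hz: float = 50.0
    epoch_s: float = 6.0
    snr_db: float = 1.7
    near_far_spread_db: float = 0.0
    clock_mode: str = "oscillator"
    drift_ppm: float = 1000.0
    n_clock_points: int = 31
    n_phases: int = 3
    code_len: int = 511
    native_codes: bool = False
    n_target: int = 40
    n_eval: int = 10
    k: float | None = None
    combine: str = "product"
    event_mode: str = "poisson"
    sample_rate: float = 30e6
    bin_size: float = DEFAULT_BIN_S
    slot_clip_s: float | None = None

    def receiver(self) -> ReceiverChain:
        return ReceiverChain(sample_rate=self.sample_rate,
                             noise_sigma=sigma_for_snr(1.0, self.snr_db))

    def code_policy(self) -> dict:
        if self.native_codes:
            return {"length": self.code_len}
        return {"m": 13, "truncation": self.code_len}

    def snr_policy(self) -> tuple:
        if self.near_far_spread_db > 0:
            return ("near_far", self.snr_db, self.near_far_spread_db)
        return ("fixed", self.snr_db)

    def clock_policy(self) -> tuple:
        if self.clock_mode == "divider":
            return ("divider",)
        return ("oscillator", self.drift_ppm)


def _child_rngs(seed: int, *names: str) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_cell(cfg: CellConfig, seed: int):
    """Build population and events and synthesize the aggregate stream.

    Returns ``(population, events, aggregate, n_bins)`` where ``n_bins`` is
    the number of 1 ms evaluation bins in the epoch.  The stream carries a
    short tail guard beyond the epoch so every event bin has full packet
    support.
    """
    rngs = _child_rngs(seed, "population", "scale", "events", "noise")
    n_target = min(cfg.n_target, cfg.n_nodes)
    n_bg_base = min(BASE_BACKGROUND, cfg.n_nodes - n_target)
    base = build_population(n_target, n_bg_base,
                            code_policy=cfg.code_policy(),
                            snr_policy=cfg.snr_policy(),
                            clock_policy=cfg.clock_policy(),
                            rng=rngs["population"],
                            f_clk_nominal=cfg.sample_rate,
                            bin_size=cfg.bin_size)
    population = scale_background(base, cfg.n_nodes, rng=rngs["scale"],
                                  bin_size=cfg.bin_size)
    gen = generate_periodic_events if cfg.event_mode == "periodic" \
        else generate_poisson_events
    events = gen(cfg.rate_hz, cfg.epoch_s, [n.node_id for n in population],
                 rng=rngs["events"], bin_size=cfg.bin_size)
    rx = cfg.receiver()
    packet_s = 3 * cfg.code_len / (cfg.sample_rate * (1 - cfg.drift_ppm * 1e-6))
    guard = cfg.bin_size + packet_s + 16 / rx.sample_rate
    aggregate = superpose(population, events, rx, duration=cfg.epoch_s + guard,
                          rng=rngs["noise"])
    n_bins = int(round(cfg.epoch_s / cfg.bin_size))
    return population, events, aggregate, n_bins


def demodulate_targets(cfg: CellConfig, population, samples) -> dict:
    """Demodulate the evaluation subset of target nodes from a sample stream."""
    from .demodulator import StreamCorrelator

    rx = cfg.receiver()
    targets = [n for n in population if n.role == "target"][: cfg.n_eval]
    detections = {}
    stream_or_corr = samples
    if cfg.clock_mode == "oscillator" and len(targets) * cfg.n_clock_points > 8:
        lmax = int(np.ceil(3 * cfg.code_len /
                           (1 - cfg.drift_ppm * 1e-6))) + 2
        stream_or_corr = StreamCorrelator(samples, lmax)
    for node in targets:
        slot = None
        if cfg.clock_mode == "divider":
            clip = cfg.slot_clip_s
            if clip is None:
                clip = min(cfg.epoch_s, max(0.2, 10.0 / max(cfg.rate_hz, 1e-9)))
            bank = build_filter_bank(node.code, rx, clock_mode="divider",
                                     center_f_clk=cfg.sample_rate,
                                     combine=cfg.combine)
            slot = recover_slot(samples, bank, clip_duration=clip,
                                bin_size=cfg.bin_size)
        detections[node.node_id] = demodulate_node(
            stream_or_corr if cfg.clock_mode == "oscillator" else samples,
            node.code, rx, clock_mode=cfg.clock_mode,
            center_f_clk=cfg.sample_rate,
            drift_ppm=cfg.drift_ppm, n_clock_points=cfg.n_clock_points,
            n_phases=cfg.n_phases, k=cfg.k, node_id=node.node_id,
            slot_offset=slot, combine=cfg.combine,
            expected_amplitude=node.a_prime, bin_size=cfg.bin_size)
    return detections


def run_cell(cfg: CellConfig | dict, seed: int) -> ErrorReport:
    """Full pipeline for one cell; returns the target-averaged error report."""
    if isinstance(cfg, dict):
        cfg = CellConfig(**cfg)
    population, events, aggregate, n_bins = simulate_cell(cfg, seed)
    detections = demodulate_targets(cfg, population, aggregate.samples)
    return compute_error_rate(events, detections, targets=sorted(detections),
                              n_bins=n_bins, bin_size=cfg.bin_size)
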