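"""Node populations, sparse asynchronous events, and aggregate stream synthesis.

The received network signal is modelled as a superposition of per-event
packets, ``Y(t) = sum_i y_i(t - tau_i) + noise``: every time node ``i``
detects an event (1 ms bins), it backscatters its code packet starting at the
bin edge plus its fixed sub-bin offset ``tau_i``.  Nodes are heterogeneous in
backscatter amplitude (fixed-SNR or near-far policies), clock realization
(static per-node drift for free-running oscillators, zero drift for
carrier-divided clocks) and carrier phase.

A population is split into *target* nodes, whose communication fidelity is
scored, and *background* nodes, which only contribute interference.  Large
networks are built the way the bench experiments were extrapolated: a base
population's background nodes are resampled with replacement, replicas
keeping their source's code but receiving fresh delays, clock realizations
and event trains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .goldcode import (CodeIdentifier, GoldFamily, assign_identifier,
                       family_for_length, preferred_pair_specs)
from .signal_model import ClockModel, ReceiverChain, apply_noise, sigma_for_snr, synthesize_packet

__all__ = [
    "NodeModel",
    "EventTrain",
    "AggregateSignal",
    "generate_poisson_events",
    "generate_periodic_events",
    "build_population",
    "scale_background",
    "superpose",
    "DEFAULT_BIN_S",
]

DEFAULT_BIN_S = 1e-3


@dataclass(frozen=True, eq=False)
class NodeModel:
    """One sensor node: identity, code, clock, amplitude and start delay."""

    node_id: int
    code: CodeIdentifier
    clock: ClockModel
    a_prime: float
    snr_db: float
    tau: float
    phi_prime: float = 0.0
    role: str = "background"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("start delay tau must be >= 0")
        if self.role not in ("target", "background"):
            raise ValueError(f"unknown node role {self.role!r}")


@dataclass(frozen=True, eq=False)
class EventTrain:
    """Sorted event times of one node, at most one event per 1 ms bin."""

    node_id: int
    times: np.ndarray
    bin_size: float = DEFAULT_BIN_S

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if len(t) > 1:
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if np.any(np.diff(np.floor(t / self.bin_size + 1e-9)) < 1):
                raise ValueError("at most one event per bin is allowed")

    def __len__(self) -> int:
        return len(self.times)

    def bins(self) -> np.ndarray:
        """Integer 1 ms bin indices of the events."""
        return np.floor(self.times / self.bin_size + 1e-9).astype(np.int64)


@dataclass(eq=False)
class AggregateSignal:
    """Superposed complex baseband stream plus its ground-truth manifest."""

    samples: np.ndarray
    sample_rate: float
    duration: float
    manifest: pd.DataFrame
    noise_sigma: float = 0.0
    rx: ReceiverChain | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def generate_poisson_events(rate_hz: float, duration_s: float,
                            node_ids, rng=None,
                            bin_size: float = DEFAULT_BIN_S) -> list[EventTrain]:
    """Independent homogeneous Poisson event trains, collapsed to 1 ms bins.

    Collapsing a Poisson process to at most one event per bin is equivalent
    to Bernoulli bins with success probability ``1 - exp(-rate * bin)``;
    events are stamped at bin start times.  ``rate * bin > 1`` would saturate
    the binary-per-bin representation and is rejected.
    """
    if rate_hz < 0:
        raise ValueError("event rate must be >= 0")
    if rate_hz * bin_size > 1.0:
        raise ValueError(
            f"rate {rate_hz} Hz saturates the {bin_size * 1e3:.0f} ms event bins"
        )
    if np.isscalar(node_ids):
        node_ids = range(int(node_ids))
    rng = np.random.default_rng(rng)
    n_bins = int(round(duration_s / bin_size))
    p = 1.0 - np.exp(-rate_hz * bin_size)
    trains = []
    for nid in node_ids:
        if p == 0.0:
            trains.append(EventTrain(node_id=nid, times=np.empty(0), bin_size=bin_size))
            continue
        count = rng.binomial(n_bins, p)
        bins = np.sort(rng.choice(n_bins, size=count, replace=False))
        trains.append(EventTrain(node_id=nid, times=bins * bin_size, bin_size=bin_size))
    return trains


def generate_periodic_events(rate_hz: float, duration_s: float, node_ids,
                             rng=None, bin_size: float = DEFAULT_BIN_S) -> list[EventTrain]:
    """Deterministic transmit-every-1/rate trains (the bench configuration),
    each node starting at a random bin within its first period."""
    if rate_hz <= 0:
        raise ValueError("periodic mode needs a positive rate")
    period_bins = max(1, int(round(1.0 / (rate_hz * bin_size))))
    if np.isscalar(node_ids):
        node_ids = range(int(node_ids))
    rng = np.random.default_rng(rng)
    n_bins = int(round(duration_s / bin_size))
    trains = []
    for nid in node_ids:
        start = int(rng.integers(period_bins))
        bins = np.arange(start, n_bins, period_bins)
        trains.append(EventTrain(node_id=nid, times=bins * bin_size, bin_size=bin_size))
    return trains


def build_population(n_target: int, n_background: int,
                     code_policy: dict | None = None,
                     snr_policy: tuple = ("fixed", 1.7),
                     clock_policy: tuple = ("oscillator", 1000.0),
                     rng=None,
                     f_clk_nominal: float = 30e6,
                     bin_size: float = DEFAULT_BIN_S) -> list[NodeModel]:
    """Draw a heterogeneous node population with distinct codes.

    ``code_policy``: ``{"m": 13, "truncation": 511}`` (default; PUF-seeded
    truncated identifiers) or ``{"length": L}`` for a native Gold length.
    ``snr_policy``: ``("fixed", snr_db)`` or ``("near_far", mean_db, spread_db)``
    -- per-node SNR uniform within ``mean +/- spread/2`` (the bench chips
    spanned up to a 20 dB spread).  ``clock_policy``: ``("oscillator",
    drift_ppm)`` with static per-node offsets drawn within the bound, or
    ``("divider",)``.

    Amplitudes are expressed relative to a unit-amplitude reference node:
    the noise level that realizes the policy's mean SNR for a unit-amplitude
    packet is ``sigma_for_snr(1.0, mean_db)``, and node ``i`` gets
    ``A'_i = 10**((snr_i - mean_db) / 20)``.
    """
    n_total = n_target + n_background
    if n_total < 1:
        raise ValueError("population must contain at least one node")
    rng = np.random.default_rng(rng)
    code_policy = dict(code_policy or {"m": 13, "truncation": 511})

    if "length" in code_policy:
        family = family_for_length(code_policy["length"])
        if n_total > len(family):
            raise ValueError(
                f"{n_total} nodes exceed the {len(family)} codes of length "
                f"{code_policy['length']}; replicate a base population instead"
            )
        picks = rng.choice(len(family), size=n_total, replace=False)
        trunc = code_policy.get("truncation")
        codes = [family.identifier(int(k), trunc) for k in picks]
    else:
        m = code_policy.get("m", 13)
        if m != 13:
            family = GoldFamily(*preferred_pair_specs(m), validate=False)
            if n_total > len(family):
                raise ValueError(f"{n_total} nodes exceed the m={m} family size {len(family)}")
            picks = rng.choice(len(family), size=n_total, replace=False)
            codes = [family.identifier(int(k), code_policy.get("truncation")) for k in picks]
        else:
            seeds = rng.choice(2**13, size=n_total, replace=False)
            trunc = code_policy.get("truncation", 511)
            codes = [assign_identifier(int(s), trunc) for s in seeds]

    kind = snr_policy[0]
    if kind == "fixed":
        snrs = np.full(n_total, float(snr_policy[1]))
        mean_db = float(snr_policy[1])
    elif kind == "near_far":
        mean_db = float(snr_policy[1])
        spread = float(snr_policy[2]) if len(snr_policy) > 2 else 20.0
        snrs = mean_db + rng.uniform(-spread / 2, spread / 2, size=n_total)
    else:
        raise ValueError(f"unknown snr policy {kind!r}")

    nodes = []
    for i in range(n_total):
        if clock_policy[0] == "oscillator":
            drift = float(clock_policy[1]) if len(clock_policy) > 1 else 1000.0
            clock = ClockModel(f_nominal=f_clk_nominal, drift_ppm=drift,
                               mode="oscillator",
                               offset_ppm=float(rng.uniform(-drift, drift)))
        elif clock_policy[0] == "divider":
            clock = ClockModel(f_nominal=f_clk_nominal, drift_ppm=0.0,
                               mode="divider",
                               phase=float(rng.uniform(0, 2 * np.pi)))
        else:
            raise ValueError(f"unknown clock policy {clock_policy[0]!r}")
        nodes.append(NodeModel(
            node_id=i,
            code=codes[i],
            clock=clock,
            a_prime=float(10 ** ((snrs[i] - mean_db) / 20.0)),
            snr_db=float(snrs[i]),
            tau=float(rng.uniform(0, bin_size)),
            phi_prime=float(rng.uniform(0, 2 * np.pi)),
            role="target" if i < n_target else "background",
        ))
    return nodes


def scale_background(base: list[NodeModel], target_total: int,
                     rng=None, bin_size: float = DEFAULT_BIN_S) -> list[NodeModel]:
    """Expand a population by resampling background nodes with replacement.

    Replicas keep their source node's code (as in the bench extrapolation,
    where recorded chip packets were re-added in random sequence) but draw
    fresh delays, phases and clock realizations; their event trains are
    generated independently downstream.  Target nodes are never replicated.
    """
    if target_total < len(base):
        raise ValueError("target_total smaller than the base population")
    background = [n for n in base if n.role == "background"]
    if target_total > len(base) and not background:
        raise ValueError("cannot scale a population with no background nodes")
    rng = np.random.default_rng(rng)
    out = list(base)
    next_id = max(n.node_id for n in base) + 1
    for _ in range(target_total - len(base)):
        src = background[int(rng.integers(len(background)))]
        clock = src.clock
        if clock.mode == "oscillator":
            clock = replace(clock, offset_ppm=float(
                rng.uniform(-clock.drift_ppm, clock.drift_ppm)))
        else:
            clock = replace(clock, phase=float(rng.uniform(0, 2 * np.pi)))
        out.append(replace(src, node_id=next_id, clock=clock,
                           tau=float(rng.uniform(0, bin_size)),
                           phi_prime=float(rng.uniform(0, 2 * np.pi))))
        next_id += 1
    return out


def superpose(population: list[NodeModel], events: dict[int, EventTrain] | list[EventTrain],
              rx: ReceiverChain, duration: float,
              noise_sigma: float | None = None, rng=None,
              dtype=np.complex64) -> AggregateSignal:
    """Place every (node, event) packet on the global sample grid and add noise.

    Each packet starts at ``event_bin_start + tau_i`` rounded to the ADC grid.
    Packets extending past the epoch are truncated with a warning.  The
    ground-truth manifest records ``(node_id, event_time_s, start_sample)``.
    """
    if isinstance(events, list):
        events = {tr.node_id: tr for tr in events}
    fs = rx.sample_rate
    n_samples = int(round(duration * fs))
    Y = np.zeros(n_samples, dtype=dtype)
    rows = []
    truncated = 0
    for node in population:
        train = events.get(node.node_id)
        if train is None or len(train) == 0:
            continue
        pkt = synthesize_packet(node.code, node.clock, rx,
                                a_prime=node.a_prime, phi_prime=node.phi_prime,
                                dtype=dtype).samples
        L = len(pkt)
        starts = np.round((train.times + node.tau) * fs).astype(np.int64)
        for t, s0 in zip(train.times, starts):
            if s0 >= n_samples:
                truncated += 1
                continue
            s1 = min(s0 + L, n_samples)
            if s1 - s0 < L:
                truncated += 1
            Y[s0:s1] += pkt[: s1 - s0]
            rows.append((node.node_id, t, int(s0)))
    if truncated:
        warnings.warn(f"{truncated} packet(s) truncated at the epoch boundary",
                      stacklevel=2)
    manifest = pd.DataFrame(rows, columns=["node_id", "event_time_s", "start_sample"])
    sigma = rx.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        Y = apply_noise(Y, sigma, rng)
    return AggregateSignal(samples=Y, sample_rate=fs, duration=duration,
                           manifest=manifest, noise_sigma=sigma, rx=rx)
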