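"""Complex-baseband synthesis of one node's backscattered BPSK packet.

A transceiver hub emits a continuous carrier ``x_c(t) = Re[A_Tx e^{j2pi f_Tx t}]``.
A node announces an event by modulating its antenna impedance with its
spreading code: each coded symbol ``S_n`` spans three chips of the system
clock (``f_clk = 3 / T_s``), giving the chip sequence
``s_BPSK-bck(t) = S_n(t) * S_clk(t)``.  The reflected wave
``A_bck * s_BPSK-bck(t) * e^{j(2pi f_Tx t + phi)}`` (``phi = 2 pi D / lambda``
the round-trip phase) is amplified, downconverted and sampled, leaving the
complex baseband sequence

    y(v) = A' * s_BPSK-bck(v) * [cos(theta_v + phi') - j sin(theta_v + phi')] + w(v)

with ``A' = alpha' * G * A_bck``, ``phi' = phi + phi_ADC`` and ``w`` zero-mean
complex AWGN.  The receiver in this simulator downconverts to a low
intermediate frequency ``f_if`` (default a quarter of the sample rate) rather
than exactly to DC: ``theta_v = 2 pi f_if v / fs``.  At exactly-zero IF the
residual carrier aliases to a constant and the I/Q branches collapse onto a
single line in the complex plane, which would make the receiver's
phase-diverse I*Q matched-filter combination degenerate; a quarter-rate IF
keeps full quadrature diversity on the sample grid while preserving the
equation structure above.

Free-running node clocks drift (default bound +/-1,000 ppm), which stretches
or compresses the chip waveform relative to the fixed ADC grid; the grid is
never resampled -- the continuous-time chip waveform is simply evaluated at
the ADC instants, so drifted packets exhibit the chip-slip patterns a real
receiver sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CarrierParams",
    "ClockModel",
    "BackscatterParams",
    "ReceiverChain",
    "PacketWaveform",
    "CHIP_PATTERN",
    "bpsk_encode",
    "chip_waveform_samples",
    "synthesize_packet",
    "apply_noise",
    "measure_snr_rssi",
    "sigma_for_snr",
]

SPEED_OF_LIGHT = 299_792_458.0

#: Clock chip pattern spanning one coded symbol (f_clk = 3 / T_s).
CHIP_PATTERN = np.array([1, -1, 1], dtype=np.int8)


@dataclass(frozen=True)
class CarrierParams:
    """Continuous carrier emitted by the transceiver hub."""

    a_tx: float = 1.0
    f_tx: float = 915e6

    def __post_init__(self) -> None:
        if self.a_tx <= 0 or self.f_tx <= 0:
            raise ValueError("carrier amplitude and frequency must be positive")

    @property
    def wavelength(self) -> float:
        return SPEED_OF_LIGHT / self.f_tx


@dataclass(frozen=True)
class ClockModel:
    """A node's chip clock: nominal frequency, drift bound and realization.

    ``mode='oscillator'`` models a free-running relaxation oscillator whose
    actual frequency is offset from nominal by ``offset_ppm`` (a static
    per-node realization drawn within ``+/-drift_ppm``).  ``mode='divider'``
    models a clock derived by integer division of the downlink carrier:
    zero drift by construction, but an arbitrary start phase.
    """

    f_nominal: float = 30e6
    drift_ppm: float = 1000.0
    mode: str = "oscillator"
    offset_ppm: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("oscillator", "divider"):
            raise ValueError(f"unknown clock mode {self.mode!r}")
        if self.mode == "divider" and self.offset_ppm != 0.0:
            raise ValueError("divider-mode clocks have zero drift by construction")
        if abs(self.offset_ppm) > self.drift_ppm + 1e-12:
            raise ValueError(
                f"realized offset {self.offset_ppm} ppm exceeds drift bound "
                f"{self.drift_ppm} ppm"
            )

    @property
    def f_actual(self) -> float:
        return self.f_nominal * (1.0 + self.offset_ppm * 1e-6)


@dataclass(frozen=True)
class BackscatterParams:
    """Backscatter amplitude and geometric phase delay of one node."""

    a_bck: float = 1.0
    distance: float = 0.009
    wavelength: float = SPEED_OF_LIGHT / 915e6

    def __post_init__(self) -> None:
        if self.a_bck < 0:
            raise ValueError("backscattered amplitude must be >= 0")

    @property
    def phi(self) -> float:
        """Phase delay 2 pi D / lambda, wrapped to [0, 2 pi)."""
        return float((2 * np.pi * self.distance / self.wavelength) % (2 * np.pi))


@dataclass(frozen=True)
class ReceiverChain:
    """Amplifier, downconverter and ADC of the receiving hub.

    ``f_mix`` is the nominal chip-rate offset at which downconversion is
    performed (the node's sidebands sit at ``f_Tx +/- f_clk``); ``f_if`` is
    the residual intermediate frequency left on the sampled baseband.
    ``n_sc`` ADC samples per coded symbol (3 at 30 MSa/s for a 10 Msym/s
    packet, i.e. one sample per chip).
    """

    gain: float = 1.0
    alpha_prime: float = 1.0
    f_mix: float = 30e6
    sample_rate: float = 30e6
    n_sc: int = 3
    phi_adc: float = 0.0
    noise_sigma: float = 0.0
    f_if: float | None = None
    dbm_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sc < 1:
            raise ValueError("need at least one ADC sample per coded symbol")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.f_if is None:
            object.__setattr__(self, "f_if", self.sample_rate / 4.0)

    def composite_amplitude(self, a_bck: float) -> float:
        return self.alpha_prime * self.gain * a_bck


@dataclass(frozen=True, eq=False)
class PacketWaveform:
    """Complex I/Q samples of one packet on the ADC grid, with provenance."""

    samples: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("packet samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def bpsk_encode(symbols: np.ndarray, clock: ClockModel | None = None) -> np.ndarray:
    """Expand coded symbols into the chip-level +/-1 sequence.

    Each symbol spans 3 chips of the system clock; the chip pattern within a
    symbol is ``S_n * [+1, -1, +1]``, so the chips of a ``+1`` symbol are the
    negation of a ``-1`` symbol's chips.
    """
    symbols = np.asarray(getattr(symbols, "symbols", symbols), dtype=np.int8)
    if not np.all(np.abs(symbols) == 1):
        raise ValueError("symbols must be +1/-1")
    return np.kron(symbols, CHIP_PATTERN).astype(np.int8)


def chip_waveform_samples(chips: np.ndarray, clock: ClockModel,
                          rx: ReceiverChain) -> np.ndarray:
    """Sample the continuous-time chip waveform on the ADC grid.

    The node's chips tick at its *actual* (possibly drifted) clock; the ADC
    grid is fixed at ``rx.sample_rate``.  Under drift the packet occupies
    ``n_chips / (1 + drift)`` grid samples and chip edges slide relative to
    the grid, occasionally repeating or skipping a chip sample.
    """
    chips = np.asarray(chips, dtype=np.int8)
    n_chips = len(chips)
    f_chip = clock.f_actual
    fs = rx.sample_rate
    samples_per_chip = fs / f_chip
    if samples_per_chip < 0.9:
        raise ValueError(
            f"clock offset leaves {samples_per_chip:.3f} samples per chip; "
            "the ADC grid undersamples the chip stream"
        )
    n_samples = int(np.ceil(n_chips * samples_per_chip))
    v = np.arange(n_samples)
    chip_idx = np.floor(v * (f_chip / fs)).astype(np.intp)
    chip_idx = np.minimum(chip_idx, n_chips - 1)
    return chips[chip_idx]


def synthesize_packet(code, clock: ClockModel, rx: ReceiverChain,
                      a_prime: float = 1.0, phi_prime: float = 0.0,
                      dtype=np.complex128, meta: dict | None = None) -> PacketWaveform:
    """Noise-free complex baseband packet of one node on the ADC grid.

    ``samples[v] = A' * s(v) * [cos(theta_v + phi') - j sin(theta_v + phi')]``
    where ``s`` is the drift-warped chip waveform and
    ``theta_v = 2 pi f_if v / fs``.  Noise is added separately
    (:func:`apply_noise`), so the same routine synthesizes both transmitted
    packets and matched-filter templates.
    """
    symbols = getattr(code, "symbols", code)
    chips = bpsk_encode(symbols)
    s = chip_waveform_samples(chips, clock, rx).astype(np.float64)
    v = np.arange(len(s))
    theta = 2 * np.pi * rx.f_if * v / rx.sample_rate + phi_prime
    wave = (a_prime * s * (np.cos(theta) - 1j * np.sin(theta))).astype(dtype)
    info = {"f_clk": clock.f_actual, "a_prime": a_prime, "phi_prime": phi_prime}
    if meta:
        info.update(meta)
    return PacketWaveform(samples=wave, sample_rate=rx.sample_rate, meta=info)


def apply_noise(samples: np.ndarray, noise_sigma: float,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Add zero-mean complex AWGN of total std ``noise_sigma`` (sigma/sqrt(2) per
    I and Q component); seeded and reproducible."""
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    x = np.asarray(samples)
    if noise_sigma == 0:
        return x.copy()
    rng = np.random.default_rng(rng)
    scale = noise_sigma / np.sqrt(2.0)
    noise = rng.standard_normal(2 * x.size, dtype=np.float32).view(np.complex64)
    return (x + noise.reshape(x.shape) * scale).astype(x.dtype)


def sigma_for_snr(a_prime: float, snr_db: float) -> float:
    """Complex-noise std giving the requested per-sample packet SNR.

    Packet samples have constant modulus ``A'`` (antipodal chips times a
    unit-modulus carrier), so SNR = A'^2 / sigma^2.
    """
    return float(a_prime * 10 ** (-snr_db / 20.0))


def measure_snr_rssi(packet_samples: np.ndarray, noise_sigma: float,
                     dbm_scale: float = 1.0) -> tuple[float, float]:
    """RSSI (dBm, simulation units scaled by ``dbm_scale`` mW) and SNR (dB).

    RSSI is the mean packet power referenced to the configured dBm scale;
    SNR is the ratio of mean packet power to the complex noise power.  Zero
    noise yields ``+inf`` SNR.
    """
    x = np.asarray(packet_samples)
    if x.size == 0:
        raise ValueError("packet is empty")
    power = float(np.mean(np.abs(x) ** 2))
    rssi_dbm = 10 * np.log10(power * dbm_scale) if power > 0 else -np.inf
    if noise_sigma == 0:
        return rssi_dbm, np.inf
    snr_db = 10 * np.log10(power / noise_sigma**2)
    return rssi_dbm, float(snr_db)
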