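"""Maximum-length and Gold sequence generation, identifier assignment, correlation.

Every sensor node in an ASBIT network announces an event by backscattering its
unique spreading-code identifier.  The identifiers are Gold codes: for a
register length ``m``, a *preferred pair* of maximum-length sequences (MLS) is
combined by chip-wise XOR at every relative shift, yielding a family of
``2**m + 1`` quasi-orthogonal codes of period ``2**m - 1`` whose periodic
cross-correlations are three-valued and bounded by ``2**((m+1)//2) + 1`` for
odd ``m``.  The bounded cross-correlation is what lets a matched-filter
receiver separate colliding packets from different nodes.

Codes are represented as ``numpy`` arrays of ``+1``/``-1`` symbols (antipodal
alphabet), so XOR of bit sequences becomes element-wise multiplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LfsrSpec",
    "CodeIdentifier",
    "GoldFamily",
    "PREFERRED_PAIRS",
    "NonPrimitiveTapsError",
    "generate_mls",
    "gold_code_set",
    "assign_identifier",
    "periodic_correlation",
    "periodic_correlation_all_lags",
    "preferred_pair_specs",
    "write_codes",
    "read_codes",
]

#: Published primitive feedback polynomials forming preferred (or, for m = 8,
#: best-effort) MLS pairs.  Taps are polynomial exponents: ``[5, 2]`` means
#: x^5 + x^2 + 1.  Each pair was validated exhaustively: both members are
#: primitive (full period) and their periodic cross-correlation is
#: three-valued at the Gold bound -- except m = 8, where no preferred pair
#: exists (m divisible by 4) and the shipped pair is the best-effort choice
#: with measured max |cross-correlation| 63.
PREFERRED_PAIRS: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    5: ((5, 2), (5, 4, 3, 2)),
    6: ((6, 1), (6, 5, 2, 1)),
    7: ((7, 3), (7, 3, 2, 1)),
    8: ((8, 4, 3, 2), (8, 6, 5, 3)),
    9: ((9, 4), (9, 6, 4, 3)),
    10: ((10, 3), (10, 8, 3, 2)),
    11: ((11, 2), (11, 8, 5, 2)),
    13: ((13, 4, 3, 1), (13, 10, 9, 7, 5, 4)),
}

#: Native Gold-code lengths used in the code-length trade-off sweep.
NATIVE_SWEEP_LENGTHS = (127, 255, 511, 1023, 2047)


class NonPrimitiveTapsError(ValueError):
    """Raised when LFSR taps do not realize a full-period (primitive) register."""


@dataclass(frozen=True)
class LfsrSpec:
    """A linear-feedback shift register: ``m`` stages, feedback taps, seed.

    ``taps`` are the exponents of the feedback polynomial (the register
    length ``m`` itself need not be listed; it is implied).  ``seed`` is the
    nonzero initial register state, bit ``i`` of the integer filling stage
    ``i``.
    """

    m: int
    taps: tuple[int, ...]
    seed: int = 1

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"register length m must be >= 2, got {self.m}")
        if not 0 < self.seed < 2**self.m:
            raise ValueError(f"seed must be a nonzero {self.m}-bit integer, got {self.seed}")
        taps = tuple(sorted(set(self.taps) | {self.m}, reverse=True))
        if min(taps) < 1 or max(taps) > self.m:
            raise ValueError(f"tap positions must lie in [1, {self.m}], got {self.taps}")
        object.__setattr__(self, "taps", taps)

    @property
    def period(self) -> int:
        return 2**self.m - 1


@dataclass(frozen=True, eq=False)
class CodeIdentifier:
    """A node's +/-1 spreading-code identifier plus generator provenance."""

    symbols: np.ndarray
    m: int
    taps_pair: tuple[tuple[int, ...], tuple[int, ...]]
    shift: int | None
    truncation: int

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype=np.int8)
        if not np.all(np.abs(sym) == 1):
            raise ValueError("code symbols must be +1 or -1")
        if len(sym) != self.truncation:
            raise ValueError(
                f"symbol count {len(sym)} does not match truncation {self.truncation}"
            )
        object.__setattr__(self, "symbols", sym)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_symbols(self) -> int:
        return len(self.symbols)


def generate_mls(spec: LfsrSpec) -> np.ndarray:
    """Run the LFSR for one full period and return the +/-1 output sequence.

    The output has period exactly ``2**m - 1`` when the taps form a primitive
    polynomial; otherwise the register revisits its initial state early and a
    :class:`NonPrimitiveTapsError` reports the observed period.
    """
    m, N = spec.m, spec.period
    state = np.array([(spec.seed >> i) & 1 for i in range(m)], dtype=np.uint8)
    tap_idx = np.array([t - 1 for t in spec.taps], dtype=np.intp)
    out = np.empty(N, dtype=np.uint8)
    init = state.copy()
    for i in range(N):
        out[i] = state[m - 1]
        fb = np.bitwise_xor.reduce(state[tap_idx])
        state[1:] = state[:-1]
        state[0] = fb
        if i < N - 1 and np.array_equal(state, init):
            raise NonPrimitiveTapsError(
                f"taps {spec.taps} are not primitive for m={m}: observed period {i + 1} "
                f"< {N}"
            )
    if not np.array_equal(state, init):
        raise NonPrimitiveTapsError(
            f"taps {spec.taps} do not return the register to its seed after {N} steps"
        )
    return (1 - 2 * out.astype(np.int8)).astype(np.int8)


def periodic_correlation(a: np.ndarray, b: np.ndarray, lag: int = 0) -> int:
    """Integer-exact periodic correlation ``sum_k a[k] * b[(k + lag) % N]``."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.dot(a.astype(np.int64), np.roll(b, -lag).astype(np.int64)))


def periodic_correlation_all_lags(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Periodic correlation at every lag, via FFT, rounded back to exact integers."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    cc = np.fft.ifft(np.conj(np.fft.fft(a)) * np.fft.fft(b)).real
    return np.round(cc).astype(np.int64)


def _gold_bound(m: int) -> int:
    k = (m + 1) // 2 if m % 2 else (m + 2) // 2
    return 2**k + 1


class GoldFamily:
    """Lazy Gold-code family from a preferred pair of m-sequences.

    Member ``k`` for ``k in [0, 2**m - 1)`` is ``u * roll(v, -k)`` (the XOR
    product at relative shift ``k``); members ``2**m - 1`` and ``2**m`` are
    the parents ``u`` and ``v``.  Codes are materialized on demand so that
    the m = 13 family (8,193 codes of length 8,191) never needs to exist as
    a dense matrix.
    """

    def __init__(self, spec_u: LfsrSpec, spec_v: LfsrSpec, validate: bool = True):
        if spec_u.m != spec_v.m:
            raise ValueError(f"mismatched register lengths: {spec_u.m} vs {spec_v.m}")
        self.m = spec_u.m
        self.specs = (spec_u, spec_v)
        self.u = generate_mls(spec_u)
        self.v = generate_mls(spec_v)
        self.period = spec_u.period
        if validate:
            cc = periodic_correlation_all_lags(self.u, self.v)
            self.max_cross = int(np.max(np.abs(cc)))
            if self.max_cross > _gold_bound(self.m):
                warnings.warn(
                    f"m={self.m}: pair is not preferred "
                    f"(max |cross-correlation| {self.max_cross} exceeds bound "
                    f"{_gold_bound(self.m)}); family correlations are unbounded",
                    stacklevel=3,
                )
        else:
            self.max_cross = None

    def __len__(self) -> int:
        return 2**self.m + 1

    def code(self, k: int) -> np.ndarray:
        """Return family member ``k`` as a +/-1 array of length ``2**m - 1``."""
        N = self.period
        if not 0 <= k < len(self):
            raise IndexError(f"code index {k} outside family of size {len(self)}")
        if k == N:
            return self.u.copy()
        if k == N + 1:
            return self.v.copy()
        return (self.u * np.roll(self.v, -k)).astype(np.int8)

    def identifier(self, k: int, truncation: int | None = None) -> CodeIdentifier:
        """Member ``k`` truncated to its first ``truncation`` symbols."""
        N = self.period
        trunc = N if truncation is None else int(truncation)
        if trunc > N:
            raise ValueError(f"truncation {trunc} exceeds code period {N}")
        if trunc < 1:
            raise ValueError("truncation must be >= 1")
        sym = self.code(k)[:trunc]
        taps = (self.specs[0].taps, self.specs[1].taps)
        return CodeIdentifier(symbols=sym, m=self.m, taps_pair=taps,
                              shift=k if k < N else None, truncation=trunc)


def preferred_pair_specs(m: int, seed: int = 1) -> tuple[LfsrSpec, LfsrSpec]:
    """Table lookup of a published preferred pair for register length ``m``."""
    if m not in PREFERRED_PAIRS:
        raise ValueError(
            f"no preferred pair tabulated for m={m}; available: {sorted(PREFERRED_PAIRS)}"
        )
    t1, t2 = PREFERRED_PAIRS[m]
    return LfsrSpec(m, t1, seed), LfsrSpec(m, t2, seed)


def gold_code_set(spec_u: LfsrSpec, spec_v: LfsrSpec) -> GoldFamily:
    """Build the full Gold family ``{u, v, u*shift(v,k)}`` from a pair of LFSRs.

    The pair is validated by measuring the max periodic cross-correlation of
    the parents; a non-preferred pair produces a warning carrying the
    measured value (the family still works, with weaker guarantees).
    """
    return GoldFamily(spec_u, spec_v, validate=True)


def family_for_length(length: int, validate: bool = False) -> GoldFamily:
    """Gold family whose native period is ``length`` (must be ``2**m - 1``)."""
    m = int(round(np.log2(length + 1)))
    if 2**m - 1 != length:
        raise ValueError(f"{length} is not a native Gold length (2**m - 1)")
    return GoldFamily(*preferred_pair_specs(m), validate=validate)


_PUF_BITS = 13


def assign_identifier(puf_seed: int, truncation: int = 511,
                      family: GoldFamily | None = None) -> CodeIdentifier:
    """Map a 13-bit PUF seed to a truncated m=13 Gold-code identifier.

    The seed selects the relative shift between the two parent m-sequences
    (``shift = seed``); the all-ones seed ``2**13 - 1`` is reserved for the
    first parent sequence itself, making the seed -> code map injective over
    the full 13-bit range.  The identifier keeps the first ``truncation``
    symbols of the selected period-8191 code (default 511, the length the
    hardware transmits).
    """
    if not 0 <= puf_seed < 2**_PUF_BITS:
        raise ValueError(f"puf_seed must be a 13-bit integer, got {puf_seed}")
    if family is None:
        family = _default_m13_family()
    if family.m != _PUF_BITS:
        raise ValueError(f"identifier family must have m=13, got m={family.m}")
    N = family.period
    k = N if puf_seed == N else puf_seed
    return family.identifier(k, truncation)


_M13_CACHE: list[GoldFamily] = []


def _default_m13_family() -> GoldFamily:
    if not _M13_CACHE:
        _M13_CACHE.append(GoldFamily(*preferred_pair_specs(13), validate=False))
    return _M13_CACHE[0]


def write_codes(path, identifiers: list[CodeIdentifier]) -> None:
    """Export codes as plain text, one per line, with generator header lines."""
    with open(path, "w") as fh:
        for ident in identifiers:
            fh.write(f"#m={ident.m}\n")
            fh.write(f"#taps={ident.taps_pair[0]}|{ident.taps_pair[1]}\n")
            fh.write(f"#shift={ident.shift}\n")
            fh.write(",".join("+1" if s > 0 else "-1" for s in ident.symbols) + "\n")


def read_codes(path) -> list[CodeIdentifier]:
    """Read back codes written by :func:`write_codes`."""
    out: list[CodeIdentifier] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            sym = np.array([int(tok) for tok in line.split(",")], dtype=np.int8)

            def _parse_taps(s: str) -> tuple[int, ...]:
                return tuple(int(x) for x in s.strip("() ").split(",") if x.strip())

            taps_a, _, taps_b = meta.get("taps", "()|()").partition("|")
            taps_pair = (_parse_taps(taps_a), _parse_taps(taps_b))
            shift_s = meta.get("shift", "None")
            shift = None if shift_s == "None" else int(shift_s)
            out.append(CodeIdentifier(symbols=sym, m=int(meta.get("m", 0)) or len(sym).bit_length(),
                                      taps_pair=taps_pair, shift=shift, truncation=len(sym)))
            meta = {}
    return out
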