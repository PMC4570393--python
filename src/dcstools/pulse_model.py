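"""Data model and file I/O for photon-counting pulse acquisitions.

A photon-counting detector (an avalanche photodiode in Geiger mode)
emits one TTL pulse per detected photon packet.  A level-sampling
acquisition loop reads the digital line at a fixed period, producing a
binary pulse train; counting rising edges per time bin then yields the
intensity series ``I_j`` that the correlators consume.  For a
tick-counting acquisition loop the sampling period is simply
``ticks_per_read / clock_hz`` — exact division, no rounding.

Conventions (all deliberate, all documented):

* Sample instants are ``k * sampling_period`` for ``k = 0, 1, ...``; a
  pulse occupying ``[t, t + pulse_width)`` registers at sample ``k`` iff
  ``t <= k*dt < t + pulse_width`` (closed on the left).  Pulses narrower
  than the sampling period can fall between sample instants and be
  missed entirely; that loss is intrinsic to level sampling and is
  intended behaviour here.
* A rising edge is recorded at the index of the low sample immediately
  preceding a 0→1 transition; a train that starts high records one edge
  at index 0 (an acquisition starting mid-pulse counts the pulse once).
* When binning edges into counts, a trailing partial bin is dropped
  rather than padded, to avoid a biased final count.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArrivalTimes",
    "PulseTrain",
    "IntensitySeries",
    "FormatError",
    "ValidationError",
    "sampling_period_from_ticks",
    "sample_arrivals",
    "count_edges",
    "read_pulse_file",
    "write_pulse_file",
    "read_arrivals",
    "write_arrivals",
    "read_intensity",
    "write_intensity",
]

PULSE_MAGIC = b"DCSP"
PULSE_VERSION = 1


class FormatError(ValueError):
    """An on-disk payload violates one of the documented file formats."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrivalTimes:
    """Photon arrival (TTL pulse onset) times in seconds.

    ``times`` must be strictly increasing, non-negative and less than
    ``duration`` (the total acquisition time in seconds).
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValidationError("arrival times must be a 1-d sequence")
        duration = float(self.duration)
        if not duration >= 0:
            raise ValidationError("duration must be non-negative")
        if t.size:
            if t[0] < 0:
                raise ValidationError("arrival times must be non-negative")
            if np.any(np.diff(t) <= 0):
                raise ValidationError("arrival times must be strictly increasing")
            if t[-1] >= duration:
                raise ValidationError("all arrival times must be < duration")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "duration", duration)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PulseTrain:
    """Binary level samples of the TTL line at a fixed sampling period."""

    levels: np.ndarray
    sampling_period: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 1:
            raise ValidationError("levels must be a 1-d sequence")
        if lv.size and not np.isin(lv, (0, 1)).all():
            raise ValidationError("every level must be 0 or 1")
        if not float(self.sampling_period) > 0:
            raise ValidationError("sampling_period must be positive")
        object.__setattr__(self, "levels", lv.astype(np.uint8))
        object.__setattr__(self, "sampling_period", float(self.sampling_period))

    @property
    def n_samples(self) -> int:
        return int(self.levels.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_period

    def __len__(self) -> int:
        return self.n_samples


@dataclass(frozen=True)
class IntensitySeries:
    """Photon counts per time bin: the ``I_j`` the correlator consumes."""

    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValidationError("counts must be a 1-d sequence")
        if c.size and (not np.issubdtype(c.dtype, np.integer) or c.min() < 0):
            if np.issubdtype(c.dtype, np.floating) and np.all(c == np.floor(c)) and c.min() >= 0:
                c = c.astype(np.int64)
            else:
                raise ValidationError("counts must be non-negative integers")
        if not float(self.bin_width) > 0:
            raise ValidationError("bin_width must be positive")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "bin_width", float(self.bin_width))

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width

    def __len__(self) -> int:
        return int(self.counts.size)


# ---------------------------------------------------------------------------
# Acquisition model
# ---------------------------------------------------------------------------


def sampling_period_from_ticks(ticks_per_read: int, clock_hz: float) -> float:
    """Sampling period (s) of a loop taking ``ticks_per_read`` clock ticks.

    Exact division ``ticks_per_read / clock_hz``; e.g. a 137-tick read
    loop on a 700 MHz clock gives 1.9571...e-7 s (~5.11 MHz).
    """
    if int(ticks_per_read) != ticks_per_read or ticks_per_read < 1:
        raise ValueError("ticks_per_read must be a positive integer")
    if not clock_hz > 0:
        raise ValueError("clock_hz must be positive")
    return ticks_per_read / clock_hz


def _snap(x: np.ndarray | float, tol: float = 1e-9) -> np.ndarray | float:
    """Snap values that are within floating noise of an integer onto it."""
    r = np.rint(x)
    return np.where(np.abs(x - r) <= tol * np.maximum(1.0, np.abs(x)), r, x)


def sample_arrivals(
    arrivals: ArrivalTimes,
    sampling_period: float,
    pulse_width: float | None = None,
) -> PulseTrain:
    """Level-sample a pulse stream at a fixed period.

    Each arrival at ``t`` holds the line high over ``[t, t + pulse_width)``;
    sample ``k`` reads 1 iff some pulse covers ``k * sampling_period``.
    ``pulse_width`` defaults to one sampling period, which guarantees
    that isolated pulses are detected.
    """
    if not sampling_period > 0:
        raise ValueError("sampling_period must be positive")
    if pulse_width is None:
        pulse_width = sampling_period
    if not pulse_width > 0:
        raise ValueError("pulse_width must be positive")
    n = int(np.ceil(_snap(arrivals.duration / sampling_period)))
    if n == 0:
        return PulseTrain(np.zeros(0, np.uint8), sampling_period)
    levels = np.zeros(n, dtype=np.uint8)
    if len(arrivals):
        start = np.ceil(_snap(arrivals.times / sampling_period)).astype(np.int64)
        stop = np.ceil(_snap((arrivals.times + pulse_width) / sampling_period)).astype(np.int64)
        start = np.clip(start, 0, n)
        stop = np.clip(stop, 0, n)
        delta = np.zeros(n + 1, dtype=np.int64)
        np.add.at(delta, start, 1)
        np.add.at(delta, stop, -1)
        levels = (np.cumsum(delta[:-1]) > 0).astype(np.uint8)
    return PulseTrain(levels, sampling_period)


def rising_edges(train: PulseTrain) -> np.ndarray:
    """Per-sample rising-edge indicator (see module conventions)."""
    lv = train.levels
    edges = np.zeros(lv.size, dtype=np.int64)
    if lv.size == 0:
        return edges
    edges[:-1] = (lv[:-1] == 0) & (lv[1:] == 1)
    if lv[0] == 1:
        edges[0] += 1
    return edges


def count_edges(train: PulseTrain, bin_factor: int) -> IntensitySeries:
    """Count rising edges per bin of ``bin_factor`` samples.

    A trailing partial bin is dropped.  ``bin_width`` of the result is
    ``bin_factor * sampling_period``.
    """
    if int(bin_factor) != bin_factor or bin_factor < 1:
        raise ValueError("bin_factor must be a positive integer")
    bin_factor = int(bin_factor)
    edges = rising_edges(train)
    n_bins = edges.size // bin_factor
    counts = edges[: n_bins * bin_factor].reshape(n_bins, bin_factor).sum(axis=1)
    return IntensitySeries(counts, bin_factor * train.sampling_period)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# Pulse binary: magic "DCSP", 1-byte version, 8-byte little-endian IEEE-754
# sampling_period (s), 8-byte little-endian unsigned n_samples, then the
# levels bit-packed LSB-first.
#
# Arrival text: header line "# duration_s=<float>", one decimal time per line.
#
# Intensity CSV: comment "# bin_width_s=<float>", header "bin_index,count",
# then integer rows.


def write_pulse_file(train: PulseTrain, path) -> None:
    packed = np.packbits(train.levels, bitorder="little")
    with open(path, "wb") as fh:
        fh.write(PULSE_MAGIC)
        fh.write(bytes([PULSE_VERSION]))
        fh.write(struct.pack("<d", train.sampling_period))
        fh.write(struct.pack("<Q", train.n_samples))
        fh.write(packed.tobytes())


def read_pulse_file(path) -> PulseTrain:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 21:
        raise FormatError(f"pulse file shorter than 21-byte header ({len(raw)} bytes)")
    if raw[:4] != PULSE_MAGIC:
        raise FormatError(f"bad magic {raw[:4]!r} at offset 0 (expected {PULSE_MAGIC!r})")
    version = raw[4]
    if version != PULSE_VERSION:
        raise FormatError(f"unsupported pulse file version {version} at offset 4")
    (sampling_period,) = struct.unpack_from("<d", raw, 5)
    (n_samples,) = struct.unpack_from("<Q", raw, 13)
    expected = (n_samples + 7) // 8
    payload = raw[21:]
    if len(payload) < expected:
        raise FormatError(
            f"truncated payload at offset 21: expected {expected} level bytes, found {len(payload)}"
        )
    levels = np.unpackbits(
        np.frombuffer(payload[:expected], dtype=np.uint8),
        count=int(n_samples),
        bitorder="little",
    )
    return PulseTrain(levels, sampling_period)


def write_arrivals(arrivals: ArrivalTimes, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_s={arrivals.duration!r}\n")
        for t in arrivals.times:
            fh.write(f"{float(t)!r}\n")


def read_arrivals(path) -> ArrivalTimes:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# duration_s="):
        raise FormatError("line 1: expected header '# duration_s=<float>'")
    try:
        duration = float(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise FormatError(f"line 1: unparseable duration ({exc})") from None
    times = []
    prev = -np.inf
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            t = float(line)
        except ValueError:
            raise FormatError(f"line {lineno}: not a decimal time: {line!r}") from None
        if t <= prev:
            raise FormatError(f"line {lineno}: arrival time {t!r} not strictly increasing")
        prev = t
        times.append(t)
    return ArrivalTimes(np.asarray(times, dtype=float), duration)


def write_intensity(series: IntensitySeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width_s={series.bin_width!r}\n")
        fh.write("bin_index,count\n")
        for i, c in enumerate(series.counts):
            fh.write(f"{i},{int(c)}\n")


def read_intensity(path) -> IntensitySeries:
    with open(path) as fh:
        lines = fh.read().splitlines()
    bin_width = None
    counts = []
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# bin_width_s="):
                try:
                    bin_width = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: unparseable bin width ({exc})") from None
            continue
        if line.strip() == "bin_index,count":
            seen_header = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'bin_index,count' row, got {line!r}")
        try:
            idx, c = int(parts[0]), int(parts[1])
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer row {line!r}") from None
        if idx != len(counts):
            raise FormatError(f"line {lineno}: bin_index {idx} out of order (expected {len(counts)})")
        counts.append(c)
    if bin_width is None:
        raise FormatError("missing '# bin_width_s=' header comment")
    if not seen_header:
        raise FormatError("missing 'bin_index,count' column header")
    return IntensitySeries(np.asarray(counts, dtype=np.int64), bin_width)
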