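"""Normalized intensity autocorrelation estimators.

Three routes to the same quantity, the normalized intensity
autocorrelation

    g2(k·Δt) = [ (1/(N-k)) Σ_{j=0}^{N-1-k} I_j I_{j+k} ] / <I>²,

with ``<I>`` the full-series mean (unbiased per-lag averaging, so a
constant series gives exactly 1 at every lag):

* :func:`direct_g2` — the overlap-add method: explicit shifted-product
  sums, cost O(N·max_lag).
* :func:`fft_g2` — the Wiener–Khinchin route: the lagged-product sums
  are read off the inverse transform of the power spectrum of the
  zero-padded series (padding to >= 2N makes the circular correlation
  linear), cost O(N log N).  Agrees with the direct route to floating
  precision.
* :func:`multitau_g2` — the hardware-correlator style scheme: lags 1..m
  at the native resolution, then repeated pairwise rebinning with lags
  (m/2+1)..m at each coarser resolution, giving quasi-logarithmic delay
  coverage.  Each channel uses symmetric normalization (the product of
  the two lag-shifted means) for drift robustness.

The zero-lag channel is computed implicitly but excluded from every
returned curve: photon shot noise inflates g2(0) and hardware
correlators likewise omit it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "CorrelationCurve",
    "MultiTauConfig",
    "NormalizationError",
    "direct_g2",
    "fft_g2",
    "multitau_g2",
    "max_feasible_stages",
    "read_curve",
    "write_curve",
]


class NormalizationError(ValueError):
    """The series mean is not positive, so g2 cannot be normalized."""


@dataclass(frozen=True)
class CorrelationCurve:
    """Paired delays τ (s, strictly increasing, > 0) and g2 values."""

    delays: np.ndarray
    g2: np.ndarray
    estimator: str
    n_samples: int
    mean_intensity: float

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        g = np.asarray(self.g2, dtype=float)
        if d.shape != g.shape or d.ndim != 1:
            raise ValueError("delays and g2 must be 1-d arrays of equal length")
        if d.size:
            if d[0] <= 0 or np.any(np.diff(d) <= 0):
                raise ValueError("delays must be strictly increasing and positive")
            if not np.all(np.isfinite(g)):
                raise ValueError("g2 values must be finite")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "g2", g)

    def __len__(self) -> int:
        return int(self.delays.size)


@dataclass(frozen=True)
class MultiTauConfig:
    """Channel layout of the multi-tau ladder.

    Stage 0 covers lags 1..m at the native Δt; stage s >= 1 covers lags
    (m/2+1)..m of the 2^s-fold rebinned series, i.e. physical delays
    (m/2+1)·2^s·Δt .. m·2^s·Δt.  With the default m = 16 and 3 stages
    the ladder is 16 + 8 + 8 channels, strictly increasing in delay.
    """

    channels_per_stage: int = 16
    n_stages: int = 4

    def __post_init__(self) -> None:
        m = self.channels_per_stage
        if int(m) != m or m < 4 or m % 2:
            raise ValueError("channels_per_stage must be an even integer >= 4")
        if int(self.n_stages) != self.n_stages or self.n_stages < 1:
            raise ValueError("n_stages must be an integer >= 1")


def _series(intensity) -> tuple[np.ndarray, float]:
    """Accept IntensitySeries (counts) or SpeckleIntensity (values)."""
    values = getattr(intensity, "values", None)
    if values is None:
        values = intensity.counts
    return np.asarray(values), float(intensity.bin_width)


def _check_args(x: np.ndarray, max_lag: int | None) -> tuple[int, float]:
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if max_lag is None:
        max_lag = n // 2
    if int(max_lag) != max_lag or not 1 <= max_lag <= n // 2:
        raise ValueError(f"max_lag must be an integer in [1, {n // 2}]")
    mean = float(x.mean(dtype=np.float64))
    if mean <= 0:
        raise NormalizationError("series mean must be positive to normalize g2")
    return int(max_lag), mean


def direct_g2(intensity, max_lag: int | None = None) -> CorrelationCurve:
    """Overlap-add estimator: explicit lagged-product sums.

    Integer counts are accumulated exactly in 64-bit integers before the
    floating normalization.  ``max_lag`` defaults to N//2, which caps
    the variance blow-up of large-lag unbiased estimates.
    """
    x, dt = _series(intensity)
    max_lag, mean = _check_args(x, max_lag)
    n = x.size
    acc = x.astype(np.int64) if np.issubdtype(x.dtype, np.integer) else x.astype(np.float64)
    g2 = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        s = np.dot(acc[: n - k], acc[k:])
        g2[k - 1] = (s / (n - k)) / mean**2
    delays = np.arange(1, max_lag + 1) * dt
    return CorrelationCurve(delays, g2, "direct", n, mean)


def fft_g2(intensity, max_lag: int | None = None) -> CorrelationCurve:
    """Wiener–Khinchin estimator: lagged-product sums via the FFT."""
    x, dt = _series(intensity)
    max_lag, mean = _check_args(x, max_lag)
    n = x.size
    nfft = next_fast_len(2 * n)
    spectrum = rfft(x.astype(np.float64), nfft)
    acf = irfft(np.abs(spectrum) ** 2, nfft)[: max_lag + 1]
    lags = np.arange(1, max_lag + 1)
    g2 = acf[1:] / (n - lags) / mean**2
    return CorrelationCurve(lags * dt, g2, "fft", n, mean)


def max_feasible_stages(n_samples: int, channels_per_stage: int = 16) -> int:
    """Largest stage count whose coarsest series still has >= 2m samples."""
    stages = 0
    n = int(n_samples)
    while n >= 2 * channels_per_stage:
        stages += 1
        n //= 2
    return stages


def multitau_g2(intensity, config: MultiTauConfig | None = None) -> CorrelationCurve:
    """Multi-tau estimator on the documented ladder (see MultiTauConfig).

    Each channel uses symmetric normalization,

        g2 = [(1/(N_s-k)) Σ I_j I_{j+k}] / (mean(I[:N_s-k]) · mean(I[k:])),

    computed on the stage's rebinned series; the scheme is exact for a
    constant series and suppresses the drift bias of a global-mean
    normalization.  Rebinned stages smear fine lags over a triangular
    window of width ±(2^s - 1) native bins, a negligible bias while the
    coarse bin stays well below the decorrelation time.
    """
    if config is None:
        config = MultiTauConfig()
    x, dt = _series(intensity)
    x = x.astype(np.float64)
    n0 = x.size
    m = config.channels_per_stage
    feasible = max_feasible_stages(n0, m)
    if config.n_stages > feasible:
        raise ValueError(
            f"{config.n_stages} stages infeasible for {n0} samples with "
            f"m={m}; at most {feasible} stage(s) possible"
        )
    delays: list[float] = []
    g2: list[float] = []
    cur = x
    cur_dt = dt
    for stage in range(config.n_stages):
        ns = cur.size
        lags = range(1, m + 1) if stage == 0 else range(m // 2 + 1, m + 1)
        for k in lags:
            a = cur[: ns - k]
            b = cur[k:]
            den = a.mean() * b.mean()
            if den <= 0:
                raise NormalizationError("stage means must be positive to normalize g2")
            delays.append(k * cur_dt)
            g2.append((np.dot(a, b) / (ns - k)) / den)
        cur = cur[: (cur.size // 2) * 2].reshape(-1, 2).sum(axis=1)
        cur_dt *= 2
    label = f"multitau(m={m},stages={config.n_stages})"
    return CorrelationCurve(
        np.asarray(delays), np.asarray(g2), label, n0, float(x.mean())
    )


# ---------------------------------------------------------------------------
# Correlation CSV: "# estimator=", "# n_samples=", "# mean_intensity="
# comments, a "tau_s,g2" header, then full-precision rows.
# ---------------------------------------------------------------------------


def write_curve(curve: CorrelationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# estimator={curve.estimator}\n")
        fh.write(f"# n_samples={curve.n_samples}\n")
        fh.write(f"# mean_intensity={curve.mean_intensity!r}\n")
        fh.write("tau_s,g2\n")
        for tau, g in zip(curve.delays, curve.g2):
            fh.write(f"{float(tau)!r},{float(g)!r}\n")


def read_curve(path) -> CorrelationCurve:
    from .pulse_model import FormatError

    estimator = "unknown"
    n_samples = 0
    mean_intensity = float("nan")
    delays: list[float] = []
    g2: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("estimator="):
                estimator = body.split("=", 1)[1]
            elif body.startswith("n_samples="):
                n_samples = int(body.split("=", 1)[1])
            elif body.startswith("mean_intensity="):
                mean_intensity = float(body.split("=", 1)[1])
            continue
        if line.strip() == "tau_s,g2":
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'tau_s,g2' row, got {line!r}")
        try:
            delays.append(float(parts[0]))
            g2.append(float(parts[1]))
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric row {line!r}") from None
    return CorrelationCurve(np.asarray(delays), np.asarray(g2), estimator, n_samples, mean_intensity)
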