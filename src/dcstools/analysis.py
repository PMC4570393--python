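"""Logarithmic downsampling and empirical flow quantification of g2 curves.

Hardware correlators report g2 on a quasi-logarithmic delay grid; an
FFT-based software correlator reports it on a dense linear grid.
:func:`downsample_log` bridges the two by averaging the linear values
assigned (nearest neighbour in log delay) to each point of a
logarithmically even grid.

Curves are quantified empirically, without fitting a photon-diffusion
model (which would require the medium's optical properties):

* amplitude  A = max(g2) - min(g2);
* τ½ — the smallest delay at which g2 has decayed to min(g2) + A/2,
  linearly interpolated between the bracketing samples;
* flow parameter 1/τ½, a relative flow index (faster dynamics decay
  sooner, so higher flow gives larger 1/τ½);
* coherence factor β — the zero-delay intercept of g2 - 1, estimated as
  the mean of the first few points and clipped to [0, 1];
* Siegert inversion g1 = sqrt((g2 - 1)/β).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .correlator import CorrelationCurve

__all__ = [
    "LogGrid",
    "FlowSummary",
    "ReplicateSummary",
    "QuantificationError",
    "FlatCurveError",
    "NoCrossingError",
    "EmptyOverlapError",
    "DEFAULT_GRID",
    "downsample_log",
    "amplitude",
    "tau_half",
    "estimate_beta",
    "g1_from_g2",
    "summarize_curve",
    "compare_flow",
    "replicate_summary",
    "write_flow_summary",
    "write_replicate_csv",
]


class QuantificationError(RuntimeError):
    """A curve cannot be quantified."""


class FlatCurveError(QuantificationError):
    """Zero amplitude: τ½ is undefined."""


class NoCrossingError(QuantificationError):
    """The curve never decays to half amplitude after its maximum."""


class EmptyOverlapError(ValueError):
    """The curve's delay range does not overlap the grid."""


@dataclass(frozen=True)
class LogGrid:
    """Logarithmically even delay grid with a fixed point density."""

    min_delay: float
    max_delay: float
    points_per_decade: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.min_delay < self.max_delay:
            raise ValueError("need 0 < min_delay < max_delay")
        if int(self.points_per_decade) != self.points_per_decade or self.points_per_decade < 1:
            raise ValueError("points_per_decade must be an integer >= 1")

    def delays(self) -> np.ndarray:
        n_dec = np.log10(self.max_delay / self.min_delay)
        k = np.arange(int(np.floor(n_dec * self.points_per_decade + 1e-9)) + 1)
        return self.min_delay * 10.0 ** (k / self.points_per_decade)


#: Default grid: 1 µs to 0.1 s at 8 points per decade, spanning the delay
#: range a hardware correlator typically reports.
DEFAULT_GRID = LogGrid(1e-6, 0.1, 8)


def downsample_log(curve: CorrelationCurve, grid: LogGrid = DEFAULT_GRID) -> CorrelationCurve:
    """Average linear-delay g2 values onto a logarithmic grid.

    Each input delay is assigned to the grid point nearest in log
    distance; each surviving output value is the arithmetic mean of its
    assigned inputs, and grid points with no assignment are dropped.
    """
    if len(curve) == 0:
        raise ValueError("cannot downsample an empty curve")
    gd = grid.delays()
    d = curve.delays
    if d[-1] < grid.min_delay or d[0] > grid.max_delay:
        raise EmptyOverlapError("curve delays do not overlap the grid range")
    log_g = np.log(gd)
    mid = (log_g[:-1] + log_g[1:]) / 2.0
    idx = np.searchsorted(mid, np.log(d))
    sums = np.bincount(idx, weights=curve.g2, minlength=gd.size)
    counts = np.bincount(idx, minlength=gd.size)
    keep = counts > 0
    values = sums[keep] / counts[keep]
    return CorrelationCurve(gd[keep], values, curve.estimator, curve.n_samples, curve.mean_intensity)


def amplitude(curve: CorrelationCurve) -> float:
    """Full amplitude A: difference between highest and lowest g2."""
    if len(curve) == 0:
        raise ValueError("empty curve has no amplitude")
    return float(curve.g2.max() - curve.g2.min())


def tau_half(curve: CorrelationCurve, interpolate: bool = True) -> float:
    """Smallest delay at which g2 has decayed to half its amplitude.

    The half level is ``min(g2) + A/2`` (the empirical baseline is the
    curve minimum, not an asymptote).  The crossing is sought from the
    curve maximum onward and, by default, linearly interpolated between
    the bracketing samples; ``interpolate=False`` returns the first
    sampled delay at or below the level instead.
    """
    a = amplitude(curve)
    if a <= 0:
        raise FlatCurveError("curve has zero amplitude; tau_half is undefined")
    g = curve.g2
    level = float(g.min()) + a / 2.0
    start = int(np.argmax(g))
    below = np.nonzero(g[start:] <= level)[0]
    if below.size == 0:
        raise NoCrossingError("g2 never decays to half amplitude after its maximum")
    i = start + int(below[0])
    if not interpolate or i == 0:
        return float(curve.delays[i])
    d0, d1 = curve.delays[i - 1], curve.delays[i]
    y0, y1 = g[i - 1], g[i]
    return float(d0 + (y0 - level) * (d1 - d0) / (y0 - y1))


def estimate_beta(curve: CorrelationCurve, k: int = 3) -> float:
    """Coherence factor: mean of the first k values of g2 - 1, in [0, 1].

    Valid while the first delays sit well inside the decorrelation time;
    noise-driven negative estimates are clipped to 0 with a warning.
    """
    if len(curve) == 0:
        raise ValueError("cannot estimate beta from an empty curve")
    if int(k) != k or k < 1:
        raise ValueError("k must be an integer >= 1")
    raw = float(np.mean(curve.g2[: int(k)]) - 1.0)
    if raw < 0:
        warnings.warn("negative beta estimate clipped to 0", RuntimeWarning, stacklevel=2)
    return float(np.clip(raw, 0.0, 1.0))


def g1_from_g2(curve: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Siegert inversion: g1 = sqrt(max(g2 - 1, 0) / β)."""
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    g1 = np.sqrt(np.clip(curve.g2 - 1.0, 0.0, None) / beta)
    return CorrelationCurve(
        curve.delays, g1, curve.estimator + ":g1", curve.n_samples, curve.mean_intensity
    )


@dataclass(frozen=True)
class FlowSummary:
    """Empirical quantification of one g2 curve."""

    amplitude: float
    tau_half: float
    flow_parameter: float  # 1 / tau_half, s^-1
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.flow_parameter != 1.0 / self.tau_half:
            raise ValueError("flow_parameter must equal 1/tau_half exactly")

    def as_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "tau_half_s": self.tau_half,
            "flow_parameter_per_s": self.flow_parameter,
            "beta": self.beta,
        }


def summarize_curve(
    curve: CorrelationCurve, beta_points: int | None = 3
) -> FlowSummary:
    """Amplitude, τ½, 1/τ½ and (optionally) β for one curve."""
    a = amplitude(curve)
    th = tau_half(curve)
    beta = estimate_beta(curve, beta_points) if beta_points else None
    return FlowSummary(a, th, 1.0 / th, beta)


def compare_flow(curve_a: CorrelationCurve, curve_b: CorrelationCurve) -> float:
    """Symmetric percent difference of the two flow parameters.

    100·|f_a - f_b| / ((f_a + f_b)/2), with f = 1/τ½.
    """
    fa = 1.0 / tau_half(curve_a)
    fb = 1.0 / tau_half(curve_b)
    return 100.0 * abs(fa - fb) / ((fa + fb) / 2.0)


@dataclass(frozen=True)
class ReplicateSummary:
    """Sample mean and SD (n-1 denominator) of 1/τ½ over replicates."""

    mean_flow: float
    sd_flow: float
    n: int


def replicate_summary(curves) -> ReplicateSummary:
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 replicate curves")
    flows = np.array([1.0 / tau_half(c) for c in curves])
    return ReplicateSummary(float(flows.mean()), float(flows.std(ddof=1)), len(curves))


def write_flow_summary(summary: FlowSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")


def write_replicate_csv(rows, path) -> None:
    """Rows of (label, ReplicateSummary) to a summary CSV."""
    with open(path, "w") as fh:
        fh.write("label,mean_flow,sd_flow,n\n")
        for label, summ in rows:
            sd = "" if summ.sd_flow is None else repr(summ.sd_flow)
            fh.write(f"{label},{summ.mean_flow!r},{sd},{summ.n}\n")
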