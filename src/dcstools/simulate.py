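"""Synthetic speckle and photon-stream generator with known ground truth.

The generator produces a stationary complex circular Gaussian field
``E(t)`` whose normalized autocorrelation equals a prescribed ``g1(τ)``
exactly, using circulant embedding of the target covariance (the real
and imaginary parts are independent real Gaussian processes, each
carrying half the variance).  The speckle intensity is ``I_s = |E|^2``
and the emitted series mixes in a static background,

    I = f * I_s + (1 - f) * <I_s>,

so that in the long-series limit the intensity autocorrelation obeys the
Siegert relation ``g2(τ) = 1 + f^2 * g1(τ)^2`` with coherence factor
``β = f^2``.  Photon detection is inhomogeneous Poisson sampling of the
instantaneous intensity at a stated mean count rate, with event times
placed uniformly within each bin (sub-bin timing carries no information
at the correlator's native resolution).

Every estimator in :mod:`dcstools.correlator` can therefore be checked
against an analytic reference, which is the whole point of this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .pulse_model import ArrivalTimes, IntensitySeries

__all__ = [
    "FieldModel",
    "SimulationConfig",
    "SpeckleIntensity",
    "CovarianceError",
    "ConfigError",
    "field_g1",
    "simulate_field",
    "simulate_intensity",
    "simulate_counts",
    "simulate_arrivals",
    "run_manifest",
    "load_config",
    "dump_config",
]

FIELD_KINDS = ("exponential", "stretched_exponential", "tabulated")


class CovarianceError(RuntimeError):
    """The embedded covariance is not positive semidefinite."""


class ConfigError(ValueError):
    """A JSON configuration violates the strict schema."""


@dataclass(frozen=True)
class FieldModel:
    """Parametric normalized field autocorrelation g1(τ).

    ``exponential``: exp(-τ/tau_c) — single-exponential decorrelation,
    the usual idealization for flow-dominated speckle.
    ``stretched_exponential``: exp(-(τ/tau_c)^stretch_p), 0 < p <= 2.
    ``tabulated``: linear interpolation of a (τ, g1) table, clamped to
    [0, 1].
    """

    kind: str = "exponential"
    tau_c: float = 1e-4
    stretch_p: float = 1.0
    table: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"kind must be one of {FIELD_KINDS}, got {self.kind!r}")
        if not self.tau_c > 0:
            raise ValueError("tau_c must be positive")
        if not 0 < self.stretch_p <= 2:
            raise ValueError("stretch_p must be in (0, 2]")
        if self.kind == "tabulated":
            if self.table is None:
                raise ValueError("tabulated field model requires a (tau, g1) table")
            tau, g1 = (np.asarray(a, dtype=float) for a in self.table)
            if tau.size != g1.size or tau.size < 2:
                raise ValueError("table must hold >= 2 paired (tau, g1) values")
            if np.any(np.diff(tau) <= 0):
                raise ValueError("table delays must be strictly increasing")
            object.__setattr__(self, "table", (tau, g1))


def field_g1(model: FieldModel, delays) -> np.ndarray:
    """Evaluate g1 at non-negative delays (seconds)."""
    tau = np.asarray(delays, dtype=float)
    if np.any(tau < 0):
        raise ValueError("delays must be non-negative")
    if model.kind == "exponential":
        return np.exp(-tau / model.tau_c)
    if model.kind == "stretched_exponential":
        return np.exp(-((tau / model.tau_c) ** model.stretch_p))
    ttab, gtab = model.table
    return np.clip(np.interp(tau, ttab, gtab), 0.0, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic acquisition.

    Defaults mirror a desk-scale DCS acquisition: 1 s collection, 1 µs
    intensity bins (~the native period of a MHz-rate level sampler after
    light rebinning), a few 10^5 detected photons per second, and full
    coherence (β = 1) unless degraded via ``coherent_fraction``.
    """

    duration: float = 1.0
    bin_width: float = 1e-6
    count_rate: float = 2e5
    coherent_fraction: float = 1.0
    seed: int = 0
    field: FieldModel = field(default_factory=FieldModel)

    def __post_init__(self) -> None:
        if not self.bin_width > 0 or self.duration < self.bin_width:
            raise ValueError("need duration >= bin_width > 0")
        if not 0 <= self.coherent_fraction <= 1:
            raise ValueError("coherent_fraction must be in [0, 1]")
        if self.count_rate < 0:
            raise ValueError("count_rate must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))

    @property
    def true_beta(self) -> float:
        return self.coherent_fraction**2


@dataclass(frozen=True)
class SpeckleIntensity:
    """Real-valued simulated intensity per bin (mean ≈ 1), plus provenance."""

    values: np.ndarray
    bin_width: float
    config: SimulationConfig

    @property
    def true_beta(self) -> float:
        return self.config.true_beta

    def __len__(self) -> int:
        return int(self.values.size)


def _gaussian_field(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Complex circular Gaussian field with autocovariance g1(k·Δt).

    Circulant embedding: the length-(2n-2) symmetric extension of the
    covariance sequence is diagonalized by the DFT; sampling each
    Fourier mode with variance equal to its eigenvalue gives the target
    covariance exactly.  Eigenvalues in [-1e-10·max, 0) are clipped to
    zero (floating fuzz); anything more negative is a genuine embedding
    failure.
    """
    n = config.n_bins
    if n < 2:
        raise ValueError("need at least 2 bins (duration/bin_width >= 2)")
    r = field_g1(config.field, np.arange(n) * config.bin_width)
    c = np.concatenate([r, r[-2:0:-1]]) if n > 2 else r
    lam = np.fft.fft(c).real
    lmax = lam.max()
    if lam.min() < -1e-10 * lmax:
        raise CovarianceError(
            "embedded covariance is not positive semidefinite; "
            "use a longer series or a larger tau_c/bin_width ratio"
        )
    lam = np.clip(lam, 0.0, None)
    m = lam.size
    z = np.sqrt(lam / 2.0) * (rng.standard_normal(m) + 1j * rng.standard_normal(m))
    e = np.fft.ifft(z) * np.sqrt(m)
    return e[:n]


def simulate_field(config: SimulationConfig) -> np.ndarray:
    """Complex field samples E(k·Δt); Cov(E_j, E_{j+k}*) = g1(k·Δt)."""
    rng = np.random.default_rng(config.seed)
    return _gaussian_field(config, rng)


def _intensity_values(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    f = config.coherent_fraction
    if f == 0.0:
        # All fluctuation removed: a constant series at the mean level.
        return np.ones(config.n_bins)
    i_s = np.abs(_gaussian_field(config, rng)) ** 2
    return f * i_s + (1.0 - f)  # <I_s> = 1 by construction


def simulate_intensity(config: SimulationConfig) -> SpeckleIntensity:
    """Simulate the (pre-detection) intensity series; true β = f²."""
    rng = np.random.default_rng(config.seed)
    return SpeckleIntensity(_intensity_values(config, rng), config.bin_width, config)


def _photon_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    values = _intensity_values(config, rng)
    return rng.poisson(config.count_rate * config.bin_width * values)


def simulate_counts(config: SimulationConfig) -> IntensitySeries:
    """Poisson photon counts per bin (mean count_rate·I·Δt, <I> = 1)."""
    rng = np.random.default_rng(config.seed)
    return IntensitySeries(_photon_counts(config, rng), config.bin_width)


def simulate_arrivals(config: SimulationConfig) -> ArrivalTimes:
    """Photon arrival times: Poisson counts per bin, uniform within bins.

    Shares the RNG stream with :func:`simulate_counts`, so binning these
    arrivals at ``bin_width`` reproduces the counts for the same seed.
    """
    rng = np.random.default_rng(config.seed)
    counts = _photon_counts(config, rng)
    n = counts.size
    total = int(counts.sum())
    starts = np.repeat(np.arange(n) * config.bin_width, counts)
    times = starts + rng.random(total) * config.bin_width
    times.sort()
    return ArrivalTimes(times, n * config.bin_width)


# ---------------------------------------------------------------------------
# Configuration / manifest JSON (strict schema, unknown keys rejected)
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"duration", "bin_width", "count_rate", "coherent_fraction", "seed", "field"}
_FIELD_KEYS = {"kind", "tau_c", "stretch_p", "table"}


def _field_from_dict(obj: dict) -> FieldModel:
    unknown = set(obj) - _FIELD_KEYS
    if unknown:
        raise ConfigError(f"unknown field-model key(s): {sorted(unknown)}")
    kw = dict(obj)
    if kw.get("table") is not None:
        kw["table"] = tuple(np.asarray(col, dtype=float) for col in kw["table"])
    try:
        return FieldModel(**kw)
    except ValueError as exc:
        raise ConfigError(f"invalid field model: {exc}") from None


def load_config(source) -> SimulationConfig:
    """Build a SimulationConfig from a JSON file path or a parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            obj = json.load(fh)
    else:
        obj = dict(source)
    if not isinstance(obj, dict):
        raise ConfigError("config JSON must be an object")
    unknown = set(obj) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kw = dict(obj)
    if "field" in kw:
        kw["field"] = _field_from_dict(kw["field"])
    try:
        return SimulationConfig(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from None


def dump_config(config: SimulationConfig) -> dict:
    fm = config.field
    field_obj = {"kind": fm.kind, "tau_c": fm.tau_c, "stretch_p": fm.stretch_p}
    if fm.table is not None:
        field_obj["table"] = [list(map(float, col)) for col in fm.table]
    return {
        "duration": config.duration,
        "bin_width": config.bin_width,
        "count_rate": config.count_rate,
        "coherent_fraction": config.coherent_fraction,
        "seed": config.seed,
        "field": field_obj,
    }


def run_manifest(config: SimulationConfig) -> dict:
    """Provenance record written next to every simulated dataset."""
    return {
        "config": dump_config(config),
        "seed": config.seed,
        "true_beta": config.true_beta,
        "true_tau_c": config.field.tau_c,
        "n_bins": config.n_bins,
    }


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
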