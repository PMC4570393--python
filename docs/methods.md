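# Methods

## Signal model

A photon-counting detector reports each detected photon packet as a TTL
pulse. Level-sampling that line at a fixed period Δt (as a GPIO-polling
acquisition does) yields a binary train; rising edges binned into intervals
of width Δt_bin give the intensity series `I_j`. The sampling period of a
tick-counted polling loop is `ticks_per_read / clock_hz`, kept as exact
division (a 137-tick loop at 700 MHz is 0.19571 µs, i.e. 5.109 MHz).

Sampling conventions: sample instants are `k·Δt` from `k = 0`; a pulse
occupying `[t, t + w)` registers at sample `k` iff `t ≤ k·Δt < t + w`.
Pulses narrower than Δt can be missed — intrinsic to level sampling, not a
bug. The default pulse width is one sampling period (guarantees detection
of isolated pulses; real detector pulse widths vary by model and should be
passed explicitly when known). A rising edge is recorded at the low sample
immediately preceding the transition, with a train that starts high
recording one edge at index 0 — so an acquisition that begins mid-pulse
still counts the pulse exactly once. Trailing partial bins are dropped.

## Speckle simulator

The simulator exists so that every estimator can be checked against an
analytic reference. It draws a stationary complex circular Gaussian field
`E(kΔt)` with autocovariance equal to a prescribed `g1` (exponential
`exp(−τ/τc)`, stretched exponential `exp(−(τ/τc)^p)`, or tabulated) via
**circulant embedding**: the symmetric length-(2n−2) extension of the
covariance sequence is diagonalized by the DFT, each Fourier mode is drawn
with variance equal to its eigenvalue, and the first n samples are kept.
The covariance is exact, not approximated. Eigenvalues in
`[−1e−10·max, 0)` are clipped to zero (floating fuzz); anything more
negative raises an error advising a longer series or larger τc/Δt (the
usual cause is a tabulated `g1` that is not a valid covariance).

Speckle intensity is `I_s = |E|²` (unit mean by construction). Partial
coherence is modelled by static-background mixing,
`I = f·I_s + (1 − f)`, which gives the Siegert relation
`g2 = 1 + f²·g1²`, i.e. `β = f²`, exactly in expectation — the simplest
mechanism with a provable β. Photon detection is per-bin Poisson with mean
`count_rate · I · Δt_bin`, and arrival times are placed uniformly within
bins (sub-bin timing carries no information at the correlator's native
resolution). One RNG stream per simulation; the seed and ground truth are
recorded in a run manifest, and identical configs give bit-identical
output.

Default conditions: 1 s collection (a typical single DCS acquisition),
1 µs bins (~10⁶ samples), 2·10⁵ counts/s (a realistic single-speckle APD
rate), full coherence `f = 1`. What the generator does **not** emulate:
detector afterpulsing, dead time and dark counts, laser intensity drift,
multi-speckle averaging, and the diffusion-theory shape of `g1` in a
turbid medium (quantification here is deliberately empirical, since
absolute flow inversion requires the medium's optical properties). Passing
tests therefore demonstrate estimator correctness under ideal
Gaussian-speckle statistics, not robustness to those instrumental effects.

## Estimators

All three estimators target

    g2(kΔt) = [ (1/(N−k)) Σ_j I_j I_{j+k} ] / <I>²,

the unbiased per-lag average of lagged products over the squared
full-series mean, which is exactly 1 for a constant series and invariant
under positive scaling. The zero-lag channel is excluded from returned
curves (shot noise inflates it; hardware correlators omit it too), and
`max_lag` defaults to N/2 to cap the variance of large-lag estimates.

* **direct** — explicit shifted-product sums; integer counts accumulate in
  exact 64-bit arithmetic before the floating normalization.
* **fft** — by the Wiener–Khinchin theorem the lagged-product sums are the
  inverse transform of the power spectrum; the series is zero-padded to at
  least 2N so the circular correlation equals the linear one. Agrees with
  the direct route to ~1e−15 relative (asserted at 1e−9 in tests).
* **multi-tau** — stage 0 computes lags 1..m (default m = 16) at native
  Δt; each later stage halves resolution by summing adjacent pairs and
  computes lags m/2+1..m at the coarser Δt, so delays follow the standard
  doubling ladder `k·2^s·Δt` (for m = 16 and 3 stages: 16 + 8 + 8
  channels, strictly increasing). Channels use symmetric normalization —
  the product of the two lag-shifted means — which is standard for drift
  robustness and exact on constant input. Rebinning smears lags over a
  triangular window of ±(2^s − 1) native bins; the resulting bias is
  negligible while the coarse bin stays well under τc (measured ≤ 0.1 %
  against the direct estimator at τc ≥ 50 bins, tolerance 2 %).

## Downsampling and quantification

Linear-delay curves are averaged onto a logarithmically even grid
(default 1 µs–0.1 s at 8 points/decade, configurable): each input delay is
assigned to its nearest grid point in log distance, each surviving output
is the arithmetic mean of its assigned inputs, and empty grid points are
dropped. Outputs are means of subsets, so they stay within the input's
range.

Quantification is empirical, mirroring what one does when the medium's
optical properties are unknown:

* **amplitude** `A = max(g2) − min(g2)`;
* **τ½** — the smallest delay at which `g2` has decayed to
  `min(g2) + A/2`, sought from the curve maximum onward and linearly
  interpolated between the bracketing samples (interpolation removes the
  grid-resolution bias of snapping; a nearest-sample variant is
  available). A flat curve and a curve that never reaches the half level
  raise distinct errors. For the Siegert-exponential curve
  `g2 = 1 + β e^{−2τ/τc}`, `τ½ → (τc/2)·ln 2` under dense sampling.
* **flow parameter** `1/τ½` — a *relative* flow index (decay is faster for
  faster flow); comparisons use the symmetric percent difference
  `100·|f_a − f_b| / ((f_a + f_b)/2)` and replicate summaries report the
  sample mean and SD (n−1); a single repeat reports the SD as absent.
* **β** — mean of the first k (default 3) values of `g2 − 1`, clipped to
  [0, 1] with a warning on negative estimates. This intercept estimator is
  only unbiased when the first delays sit well inside τc: its expectation
  carries the decay factor `mean(e^{−2kΔt/τc})`, about −4 % at
  τc = 100 Δt and −0.3 % at τc = 1000 Δt. β-focused checks therefore use
  τc ≫ Δt.
* **Siegert inversion** `g1 = sqrt(max(g2 − 1, 0)/β)`.

## Known limitations and numerical choices

* The empirical amplitude uses `g2(Δt)`, not the τ→0 intercept `1 + β`,
  so recovered τ½ carries a deterministic offset of exactly +Δt for the
  exponential model (≈ +6 % at τc = 50 Δt, +1.4 % at 200 Δt), partly
  offset in practice by noise inflation of the curve maximum. This is a
  property of the half-amplitude definition itself, reported here rather
  than silently corrected.
* The intercept β estimator's decay bias (above) is likewise inherent to
  averaging the first few lags; at τc = 100 Δt it is several times larger
  than the seed-to-seed standard error of a 20-run ensemble.
* Simulation sizes in the tests (2¹⁷–2²⁰ bins, 6–20 seeds) were chosen as
  the smallest ensembles whose Monte-Carlo standard errors are well below
  the tolerances being asserted.
* Sample-instant arithmetic snaps ratios within 1e−9 relative of an
  integer onto it, so pulse boundaries that are exact multiples of Δt
  behave per the closed/open interval convention instead of at the mercy
  of floating rounding.
* The multi-tau channel layout (m = 16, doubling ladder) is a convention,
  recorded in each curve's estimator label; hardware boards differ in
  their exact layouts.
* No streaming correlator, no GPU path, no hardware-correlator file
  parsing, and no diffusion-model `G1` fitting for absolute blood-flow
  indices.
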