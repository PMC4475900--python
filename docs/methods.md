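# Methods

## The model

The package treats the movement-epoch activity of a motor-cortical
population as a linear dynamical system evolving from a condition-
dependent pre-movement (initial) state.  After preprocessing, the
population state is a vector `x(t)` in a reduced space of `d` principal
components (default `d = 6`), sampled at the bin width `Δ` and
organised as `C` condition blocks of `T` time points:
`X_red ∈ R^{d × CT}`.  Per-bin state changes `Ẋ_red` (forward
differences within each condition block, `d × C(T−1)`) are regressed
on the states under two models:

    Ẋ_red = M X_red          M unconstrained (ordinary least squares)
    Ẋ_red = M_skew X_red     M_skew = −M_skewᵀ (skew-symmetric)

A skew-symmetric transition matrix has purely imaginary eigenvalues
±iω, so it can only generate rotations — no expansion or contraction.
The *rotational variance fraction*

    R²_skew = 1 − ‖Ẋ − M_skew X‖²_F / ‖Ẋ‖²_F

measures how much of the state-change variance pure rotations explain;
it is bounded above by the unconstrained R².  The denominator is the
uncentered sum of squares (the variance of the state changes about
zero); a centered alternative is available via `centered=True`.

The skew fit is solved exactly by linear least squares over the
`d(d−1)/2`-dimensional basis of skew-symmetric matrices, so skew
symmetry holds by construction (≤1e−10).  The stationarity condition
is equivalent to the Sylvester equation
`M(XXᵀ) + (XXᵀ)M = ẊXᵀ − XẊᵀ`, which the test suite uses (via
`scipy.linalg.solve_sylvester`, and via a generic numerical minimiser)
as independent oracles.

### jPCA planes

Eigenvalues of `M_skew` come in pairs ±iω.  Each pair's eigenvector
`u = a + ib` spans a real 2-D invariant plane; `{a, b}` are
orthonormalised (QR; for distinct eigenvalues they are already
orthogonal, the QR guards repeated-eigenvalue degeneracy, and each
vector gets a deterministic sign: first non-negligible component
positive).  Planes are ordered by |ω| descending.  Zero eigenvalues
(e.g. `M_skew = 0`, or odd `d`) yield zero-frequency planes filled
deterministically from the orthogonal complement, with a warning.

Within a plane the basis is then oriented by two conventions: jPC₁ is
the leading eigenvector of the 2×2 covariance of the projected
pre-movement states (initial states maximally spread along jPC₁,
closed form); jPC₂'s sign is flipped if the summed cross product
`Σ(x₁ẋ₂ − x₂ẋ₁)` of the projected trajectories is negative, making
the net rotation counterclockwise.  An isotropic initial-state
covariance keeps the incoming basis and records the tie.

### Frequencies and discretisation

Because derivatives are per-bin differences, the fitted eigenvalue
magnitude is in radians per bin.  `angular_frequency` reports
`|λ|/Δ` (rad/s).  For a rotation at true angular frequency ω observed
through forward differences with isotropic in-plane covariance, the
fitted magnitude is `sin(ωΔ)`; `angular_frequency_corrected`
therefore reports `arcsin(min(|λ|, 1))/Δ`, which recovers ω exactly
in that regime and converges to the raw value as Δ → 0.  On noiseless
two-plane data (2.5 and 1 Hz, 10 ms bins) the corrected frequencies
are accurate to <0.1%; the raw per-bin rate converges monotonically as
the bin width shrinks (tested over 20, 10, 5, 1 ms).

### Plane variance fractions

`variance_captured_reduced` is the plane's share of `‖X_red‖²_F`; the
`⌊d/2⌋` planes partition the reduced space, so these fractions sum
to 1.  `variance_captured_full` divides the same plane sum of squares
by the total variance of the soft-normalised, mean-centered
electrode-space data (recorded at PCA time), expressing the plane's
share of the high-dimensional data variance — the quantity typically
quoted for the top plane.

## Preprocessing

1. **Trial averaging** — mean count per bin across a condition's
   trials ÷ bin width, in spikes/s.
2. **Smoothing** — unit-area Gaussian kernel, default SD 25 ms
   (the 25–30 ms range typical for this preparation), truncated at
   ±4 SD, reflective boundaries.  Constants pass unchanged; mass is
   conserved for interior-supported signals.
3. **Soft normalisation** — each electrode divided by (its rate range
   over the analysis window + constant), default constant 5 spikes/s.
   The range is computed over the analysis window only (recording
   start through epoch end), not the whole session.
4. **Mean-centering** — subtract the cross-condition mean at each
   (electrode, time); removes the condition-independent component.
5. **Epoch extraction** — half-open window `[start, start+250 ms)`.
   The epoch start is explicit configuration by default (or the trial
   markers' median); `detect_epoch_start` is an optional helper that
   finds the first bin where the population rate-of-change norm rises
   halfway from its baseline (25th percentile) to its maximum, with
   sub-bin interpolation.  A half-rise criterion is used rather than
   an argmax because constant-speed rotational dynamics produce a
   plateau, not a peak, in the rate-of-change score; for an isolated
   step change the two coincide.  On synthetic data it localises a
   planted onset within one bin of the first observably-changed bin.
6. **PCA** — on the E × (C·T) matrix of movement-epoch samples
   (sample mean removed, SVD); pre-movement samples are projected
   into the same basis, not included in the decomposition.  The
   pre-movement state per condition is the mean of the last 5
   pre-epoch bins (configurable) of the normalised, centered data.

The full chain is deterministic: a `TrialSet` plus a configuration
fixes every output bit-exactly.

## Synthetic data

The generator emulates the structure the analysis assumes, with known
ground truth: condition initial states drawn i.i.d. normal (spread
1 a.u.), latent dynamics `ẋ = Ax` with block-diagonal `A` (2×2
rotation blocks, scalar expansion terms), integrated exactly by the
per-step matrix exponential; a fixed random linear readout (rows unit
norm) maps latents to electrode rates
`max(0, baseline + gain · Wx(t))`, and counts are Poisson per bin.
The pre-movement period holds the initial-state rate constant.

Default study conditions: 8 conditions, 250 ms epoch at 10 ms bins,
300 ms pre-epoch, 40 electrodes, baseline 20 Hz, gain 10 Hz,
100 trials/condition, rotation planes at 2.5 and 1 Hz.  With unit
initial-state spread the per-electrode modulation SD is ≈ gain, so
rectification at 0 spikes/s is rare; the expansion control uses decay/
growth rates (−4, −2, 2, 4) s⁻¹, chosen to give temporal variation
comparable to the rotational fixture over 250 ms.

What the generator does *not* emulate: non-Poisson count dispersion,
electrode correlations beyond the shared latents, slow drifts across
trials, behavioural variability in epoch timing, and the
condition-independent translation component real populations show.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under its own model class, not that real recordings
contain rotations.

## Shuffle controls

All three controls operate on the smoothed, pre-normalisation
condition-averaged rates, and the full analysis (normalisation,
centering, PCA, skew fit) is re-run per shuffle trial; trials are
reproducible from (master seed, trial index) via counter-based child
seeds.

* **invert_half** — per channel, a random half of the conditions get
  `r′(t) = 2r(t₀) − r(t)` over the movement epoch (pivot `t₀` = first
  epoch bin, preserving continuity).  This destroys the cross-channel
  phase structure and collapses the rotational variance fraction on
  rotational data (typically 0.85–0.90 → 0.15–0.55 across seeds).
* **invert_all** — the same inversion for every channel and condition;
  deterministic.  Geometrically this reflects each condition's reduced
  trajectory through its initial state `x₀`: a circle about the origin
  maps to a circle about `2x₀`, so the shuffled dynamics are affine
  (`ẋ′ = Sx′ − 2Sx₀`) and a pure skew *linear* model fits them poorly
  when trajectories rotate about the origin through dispersed initial
  states, as this generator's model class does (R²_skew ≈ 0.99 → 0.3
  even noiselessly).  For short arcs (epoch ≪ rotation period) the
  inversion approaches a pure sign flip of the rotation and R² is
  preserved; the effect size is thus a property of the data geometry,
  not of the analysis.
* **reassign** — one random permutation (shared across channels) maps
  each condition's pre-movement activity to another condition's
  movement epoch; the reassigned epoch's first-bin rate is appended at
  the end of the pre-movement period (one inserted bin) to preserve
  continuity.  Because the movement-epoch ensemble is unchanged up to
  condition relabeling, and every downstream step is invariant to that
  relabeling, this control leaves R²_skew exactly equal to the
  original; what it disrupts is the pairing between initial states and
  rotation phase (visible in plane orientation, not in R²).

`run_shuffle_suite` aggregates `n_shuffles` (default 300) re-analyses
into mean ± SD against the unshuffled value.

## Numerical choices and degenerate inputs

* Rank-deficient state matrices: least-norm solutions with a warning,
  never silent.
* All-zero `Ẋ` (constant trajectories): variance fractions are
  undefined and raise.
* Eigen-order ties (equal |ω|): resolved by the deterministic
  eigendecomposition order with the lexicographic sign convention.
* Zero-norm states or derivatives in angle computation: skipped and
  counted (`n_skipped`).
* Soft-norm constant 0 with a silent electrode: raises rather than
  dividing by zero.
* Angle histograms: 36 bins over [0, π], unweighted pooling over
  conditions and time steps.

## Problem sizes

Tests and the acceptance script use the study-conditions geometry
throughout (8 × 40 × 25-bin epochs; 100 trials/condition); the shuffle
comparison uses 100 trials per master seed across 20 seeds in the test
suite and the full 300 trials in the acceptance script.  These sizes
were chosen to match the scale of the recordings the analysis targets
while keeping every run reproducible on a single CPU.

## Known limitations

* The emission model (rectified-linear Poisson) is a stand-in; the
  noise model of real threshold-crossing counts is unspecified.
* Forward differences bias in-plane angles by ωΔ/2 and the raw
  frequency by the `sin(ωΔ)/Δ` factor; both are documented and the
  latter corrected, but analyses at coarse bins should prefer the
  corrected frequency.
* Epoch-onset detection is a heuristic; explicit configuration is the
  recommended route, as the onset definition in real recordings is a
  scientific choice.
* The method measures *rotational structure under a linear model*; a
  high R²_skew does not by itself exclude non-linear or input-driven
  dynamics that mimic rotations over a 250 ms window.
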