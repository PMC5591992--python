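# Methods

## The model and what it stands in for

The physical device is a large-area transmission ionization chamber whose two
wedge-shaped electrode gaps make the local response grow along one axis (the
*gradient* axis, Y, mounted perpendicular to MLC leaf travel) and flatten into
a plateau near the thick end, where lateral electron equilibrium is lost. The
original study scored the chamber signal with full EGSnrc/BEAMnrc radiation
transport of an Elekta Synergy head with an Agility 160-leaf MLC. This package
replaces that engine with a parametric surrogate:

    w(y) = w0 + g·y            for y ≤ y_plateau
    w(y) = w0 + g·y_plateau    for y > y_plateau

    S(aperture) = ∫∫_aperture w(y) dx dy × N(1, σ_rel)

Fluence is uniform inside the aperture and zero outside (no penumbra, no
scatter, no energy dependence); the integral is evaluated exactly per leaf
pair because w is piecewise linear, and intervals wholly inside the plateau
are integrated with the constant plateau weight directly so that translation
invariance there holds bitwise. The multiplicative Gaussian factor emulates
Monte Carlo scoring uncertainty; its default σ_rel = 0.01 matches the original
study's stated < 1 % statistical uncertainty.

The surrogate reproduces every qualitative behaviour the sensitivity analysis
rests on — an area-dominated signal, a rising gradient profile whose trend
slope grows with field size, and a flat plateau — but none of the transport
physics. Consequences for interpreting results: absolute per-segment gradient
values are surrogate-dependent (they happen to land close to the published
Monte Carlo values because relative signals scale as 1/SA₀); quantities that
are *arithmetic* (protocol counts, aperture areas, power-law refits of
published numbers) are exact, and quantities that are *orderings* (small
segments more sensitive than large, profile slopes increasing with field
size) are robust to the surrogate choice. Passing tests therefore validate
the analysis machinery and the geometric model, not radiation transport.

### Default chamber parameters

| parameter | default | meaning |
|---|---|---|
| `span_cm` | 40 | active extent along Y (±20 cm at isocenter, the maximum monitorable field) |
| `w0` | 1.0 | relative weight at the beam axis (arbitrary units; normalization cancels in relative mode) |
| `gradient_per_cm` | 0.02 | ramp slope; must keep w > 0 over the span |
| `plateau_fraction` | 0.2 | fraction of the span, at the +Y end, with constant weight |

The defaults were chosen once so the ramp is clearly positive across the span
and the plateau occupies the top fifth — enough travel for the profile
experiment to show both the climb and the flat tail.

## Segment geometry

Segments are ordered lists of (left, right) leaf-edge positions in cm at the
isocenter plane, with 0.5 cm projected leaf width (the Agility geometry);
pairs not listed are closed. The six-segment library uses the study's areas:
9.00, 25.83, 70.82, 47.49, 1.00 and 19.99 cm². The two square segments are
constructed exactly. The four irregular segments' leaf positions were never
published — only their areas — so a deterministic seeded generator produces
smoothly varying openings (sinusoidal modulation plus small seeded wobble of
openings and centers) and rescales the openings analytically to hit each
target area to machine precision. Area, not shape, drives every statistic in
the analysis, which is why area is treated as the authoritative constraint.
The generated definitions are shipped verbatim in
`src/iqm_sense/data/library.seg` (synthetic reconstructions, not the original
apertures) and a test pins them to the generator.

## Perturbation protocol

Every edge of every open pair is shifted by an independent uniform draw in
[−δ, +δ], δ ∈ {1, 2, 3} mm, 10 trials per level. Draws are continuous, so an
exactly-zero shift has measure zero but is permitted (a zero draw simply
leaves that leaf unaltered); no discrete spike at zero is added. If a draw
would cross the leaves (left > right) or leave the ±20 cm field, that pair is
redrawn (bounded at 100 attempts, then an error) — redrawing preserves the
uniform-within-bounds intent without the bias clamping would introduce. For
the library segments the open gaps far exceed 2δ, so redraws never trigger
and the zero-mean symmetry of the draws is exact.

Randomness: each trial's stream is keyed on (run seed, segment label, level
in µm, trial index) through `numpy` `SeedSequence`, so any single trial can be
regenerated in isolation and the full study is reproducible from one seed.

## Normalization

Trial signals are reported relative to the segment's unaltered reference
signal by default (`normalization: relative`); raw chamber units are
available via config. Relative normalization is what makes the scatter-plot
gradient land near 1/SA₀ (slope 1.0 cm⁻² for the 1 cm² segment), consistent
with the magnitudes the original study printed; whether its plotted signals
were raw or normalized was never stated, so both modes exist. With noise
enabled, the reference is scored once (noisily) per segment and reused as the
denominator for that segment's 30 trials.

## Estimator choices

- **Scatter gradient**: OLS of S on SA over the 30 trials. The unaltered
  reference anchors the brute-force differences but is excluded from all
  regression/variance estimators, keeping the sample size at 30.
- **Brute force**: SIᵢ = (S₀ − Sᵢ)/(SA₀ − SAᵢ), sign fixed by this
  convention (summaries use magnitudes, so the opposite convention would be
  indistinguishable). Trials with |ΔSA| < ε (default 10⁻⁶ cm²) are flagged
  undefined and excluded from the global max-|SI| summary rather than
  producing infinities.
- **Variance-based**: the conditional expectation E[Y|X] from 30 samples
  requires an estimator the original study did not specify; equal-count
  binning (default 5 bins, population-variance convention in both numerator
  and denominator so the index is the between-bin variance fraction, bounded
  by 1) is the simplest choice consistent with the per-trial curves shown.
  The per-trial trace applies the same estimator cumulatively over the
  subset of trials with SA below each trial's SA (with the bin count capped
  at half the subset size; prefixes smaller than 4 are flagged undefined).
  This is an interpretation, not ground truth: the study's printed VAR maxima
  (0.556, 0.504) imply an estimator whose noise-free linear limit is far from
  1 and which is unrecoverable from the text, so those values are not
  reproduction targets; this estimator is instead validated against the
  closed form Var(X)/(Var(X)+σ²) for Y = X + ε.
- **SRC**: global value b·s_X/s_Y (sample standard deviations), equal to
  Pearson's r, so SRC² = r² is an exact identity used as a test. The
  per-observation values rearrange the normalized regression model into the
  standardized ratio z_Y(i)/z_X(i) — the only per-trial reading that yields
  30 values peaking near the unaltered area — flagged undefined where
  |z_X| < ε and reported normalized to the largest defined magnitude.

## Trend synthesis

Power laws y = a·SA^b are fitted by nonlinear least squares on the original
scale, initialized from the log–log OLS solution. Original-scale fitting is
the default because refitting the six published (SA, SP-gradient) pairs with
it reproduces the published coefficients (1.0493, −0.955) to better than 1 %,
whereas log–log OLS gives (1.037, −0.941) — a hand-checkable discrepancy that
identifies the scale the original fit used. On noiseless power data the two
scales agree exactly; on heteroscedastic data they differ (a regression test
documents this).

The derivative of a·SA^b is computed symbolically as (a·b)·SA^(b−1). For the
published variance-index law 0.555·SA^−0.024 this gives −0.01332·SA^−1.024.
The source printed the derivative as "0.013·SA^1.014" — a positive exponent
and a dropped sign that are inconsistent with elementary calculus and with
the same text's remark that the derivative is "approximately inversely
proportional" to SA; this package computes the analytically correct form, and
compares only the coefficient magnitude (0.013 after rounding) against the
printed value. Fits of the study's own VAR indices to that published law are
deliberately out of scope: the published per-segment VAR inputs for four of
the six segments were never printed.

## Pipeline and problem sizes

A full study (6 segments × 30 trials + 6 references, all four estimators,
trend fits) runs in well under a second, so the default test suite and the
acceptance script run the complete protocol rather than a scaled-down one.
Property tests that need large samples (area-envelope containment, zero-mean
symmetry, the variance-index closed form) use 10⁴ draws, chosen so sampling
error sits an order of magnitude below the asserted tolerances.

Noise-free runs are bitwise reproducible (two runs with the same config
produce identical CSVs); noisy runs are reproducible too because the noise
stream is seeded from the run seed, but they are only statistically
comparable across different seeds. The cross-segment monotone decrease of
the scatter gradient is asserted noise-free: it is a property of the chamber
surrogate, and at n = 30 with 1 % noise the gap between the two largest
segments' gradients is only ~1–2 standard errors, so strict ordering under
noise is not a statistically sound assertion. The headline claim — the
smallest segment's gradient exceeding the largest's by more than an order of
magnitude — is asserted with noise on, where it holds by a wide margin.

## Known limitations

- No radiation transport: no penumbra, interleaf leakage, tongue-and-groove,
  rounded leaf ends, beam spectra or energy dependence (beam energy is
  metadata only). Absolute signals are in arbitrary units.
- The irregular library shapes are synthetic reconstructions constrained
  only by area.
- The per-trial variance-index trace and the per-trial SRC definition are
  documented interpretations of under-specified estimators (see above), each
  isolated behind its own function/option.
- Static apertures only; dynamic (sliding-window) delivery is out of scope.
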