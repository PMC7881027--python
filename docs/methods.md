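# Methods

## The model

A single heartbeat, observed at times rescaled to phases
`t_1 < … < t_n` in `[0, 2π)`, is modelled as

```
X(t_i) = M + Σ_J W_J(t_i) + e(t_i),        J ∈ {P, Q, R, S, T}
W_J(t)  = A_J · cos( β_J + 2·arctan( ω_J · tan((t − α_J)/2) ) )
e(t_i) ~ i.i.d. N(0, σ²)
```

Each wave is a cosine whose phase is warped by a Möbius-type map.  The four
parameters per wave have direct morphological readings:

| parameter | meaning | range | reading |
|---|---|---|---|
| `A` | amplitude | `≥ 0` (signal units) | wave height; 0 = absent |
| `α` | location angle | `[0, 2π)` | where in the cycle the wave sits |
| `β` | shape / skewness angle | `[0, 2π)` | `β ≈ π`: symmetric crest; `β ≈ 0, 2π`: inverted wave; in between: asymmetric |
| `ω` | sharpness | `(0, 1]` | 1 = pure sinusoid, → 0 = spike |

The five location angles obey the circular order
`α_P ⪯ α_Q ⪯ α_R ⪯ α_S ⪯ α_T ⪯ α_P`, encoding the physiological
activation sequence (sinus node → atria → ventricles) and making the
letter assignment identifiable once R is anchored.

`ω = 0` is excluded although the limit is well defined pointwise: the wave
degenerates into a discontinuous spike, the fitter's grid therefore starts
at `ω = 0.01` (with a hard floor of `10⁻³` during refinement).

Closed forms give each wave's crest and trough phases,

```
t_U = α + 2·arctan((1/ω)·tan(−β/2)),   t_L = α + 2·arctan((1/ω)·tan((π−β)/2)),
```

evaluated through the two-argument arctangent so the tangent singularities
(`β = π` for `t_U`, `β = 0` for `t_L`) resolve by continuity.  A wave's
fiducial mark is `t_U` when the wave is a crest and `t_L` when it is a
trough.  The crest/trough decision itself is not published as an explicit
rule; this package classifies a wave as a crest iff `β ∈ (π/2, 3π/2)`,
which reproduces the symmetric limits (`β = π` crest, `β = 0` trough) and
matches the rendered shape away from the exactly-asymmetric boundary
(property-tested against a brute-force comparison of crest and trough
prominence).  Inter-wave separations use the chordal distance
`d(α_i, α_j) = 1 − cos(α_i − α_j)`; applied to Q and S it is a
QRS-duration feature.

## Estimation: the MI algorithm

The least-squares problem over all 21 parameters plus the order constraint
is attacked by alternating a Maximization step (fit `K = 7` unconstrained
oscillatory components by backfitting) and an Identification step (assign
letters to components by morphology rules), until the explained variance
gains fall below 0.01 % (`pv_tol = 10⁻⁴` as a fraction) or 10 iterations.

**Single-component fit.** For fixed `(α, ω)` the wave is linear in
`(M, A·cos β, −A·sin β)` through the regressors `{1, cos φ, sin φ}` with
`φ = phase_transform(t; α, ω)`, so the profile objective over `(α, ω)` is
evaluated exactly by OLS.  The fit is a grid search (48 locations ×
ω ∈ {0.01, 0.02, 0.05, 0.1, 0.15, 0.25, 0.5, 1}) followed by Nelder–Mead
refinement of `(α, ω)` with the linear part re-profiled at each probe.
Numerical safeguards that matter in practice:

- the response is centred and scaled internally, making the optimiser's
  stopping tolerances unit-free and the fit exactly shift/scale
  equivariant;
- ω is bounded by a quadratic penalty rather than a hard clamp — a clamp
  creates a flat plateau beyond `ω = 1` that captures the simplex when it
  overshoots a broad wave's optimum;
- when the best grid node is sinusoidal (`ω = 1`, where `α` is not
  identifiable), refinement also starts from the best sub-sinusoidal node,
  and the better result wins;
- grid ties resolve to the sharpest wave, making the fit deterministic.

**M step.** Backfitting is coordinate descent: each component is refit
against the residual of the others, so the model residual sum of squares
never increases within a pass.  The first M step introduces the seven
components one at a time with three backfitting turns after each
introduction; starting all slots from zero instead tends to merge the
small sharp Q and S waves flanking the dominant R into one compensating
component, a genuinely attracting local optimum (observed at `R² ≈ 0.999`
with badly wrong parameters).  Subsequent M steps start from the waves
currently lettered (other slots at zero) and run up to five turns,
stopping early when a turn gains less than `pv_tol`.

**Joint polish.** After each I step the lettered waves' `(α_J, ω_J)` are
refined *together* by Nelder–Mead (linear parameters re-profiled by OLS at
every probe).  Backfitting alone stalls where two overlapping sharp waves
trade energy — a valley that only a joint move can cross.  The true
parameter vector is an exact fixed point of the pipeline, and with the
polish the noiseless presets are recovered to machine precision.  Letters
can migrate between components during the polish, so identification runs
again afterwards; if it then fails, the pre-polish lettering is kept.

**I step.** Components are ranked by their leave-one-out (marginal)
explained-variance contribution — well defined even for narrow spikes,
whose *in-isolation* R² is dominated by their own baseline offset and can
be negative.  The ordered explained-variance increments
`PV_k = R²_{1..k} − R²_{1..k−1}` (intercept re-profiled at each
truncation) are also computed; they telescope to the full-model R² and are
what the fit reports per wave.

- **R** is the component, among the top five, whose crest lies within
  `0.2π` rad of the annotated QRS phase, with `β ∈ (π/2, 5π/3)` (a crest,
  not a trough) and `ω < 0.12` (sharp), maximising the fitted curve at its
  own crest.  No candidate ⇒ the fit is `incomplete`.
- **Noise flags.** A component is never lettered if its marginal
  contribution and sharpness are both tiny (`pv < 0.005` and `ω < 0.02`),
  or if its marginal contribution is below `pv_tol` regardless of shape.
- **Preassignment** solves a small order-preserving matching: the roles
  S, T, P, Q (the circular activation order after R) go to non-noise
  components so that polarities are respected (P/T crests, Q/S troughs),
  the circular order holds, and the total marginal contribution of the
  lettered components is maximal.  Components ranked beyond the top five
  may take a letter here — that is where the waves of atypical beats hide.
- **Revocation cascade** in the order Q, P, S, T: each letter keeps the
  morphology-passing candidate with the largest contribution (Q must also
  be sharper than P, `ω_Q < ω_P`); letters with no valid candidate stay
  unassigned and leave the fit `incomplete`.

The MI loop retains the best fully-lettered solution seen; an intermediate
iterate may dip in R² productively when a mislabelled wave is dropped and
regrown, so the reported trajectory (`r2_history`) is the best-so-far R²,
which is non-decreasing by construction.  `status = "OK"` requires all
five letters and the circular order; the reported `R²` and
`σ̂² = RSS/n` (maximum-likelihood form, no degrees-of-freedom correction)
refer to the full K-component fit, whose explained variance the per-wave
PV values telescope to.

Identification thresholds (`r_beta_interval`, `r_omega_max`,
`qrs_proximity = 0.2π`, `noise_pv_max = 0.005`, `noise_omega_max = 0.02`)
are tunable `MIConfig` fields.  The first two and the iteration limits are
standard for near-lead-II morphology; the others are this package's
defaults, not authoritative clinical constants.

## Segmentation

Beats are cut from a continuous record using externally supplied QRS
annotation sample indices (QRS detection is a solved, separate problem and
is never performed here).  An interior annotation with neighbouring
intervals `RR−`, `RR+` yields the half-open window
`[round(t − 0.4·RR−), round(t + 0.6·RR+))` (round-half-to-even), so
consecutive windows tile the record; first/last annotations have no window.
Samples map to equispaced phases `2π·i/len` — the endpoint `2π` is
excluded because the model is periodic — placing the annotation at phase
`0.8π` for equal RR intervals.  The mapping is exactly invertible, which is
how fiducial phases are exported in milliseconds.

Baseline drift is removed by subtracting the line through the means of the
first and last 5 % of samples, but only when those means differ by more
than 30 % of the window's standard deviation.  The trigger is deliberately
conservative: the edges of a clean beat legitimately differ a little (the
T-wave tail decays into the next P wave), and detrending an undrifted beat
distorts it.  Both knobs are arguments of `detrend`.

## Synthetic data

`simulate_beat` draws exactly from the model: the mean curve on an
equispaced phase grid plus i.i.d. Gaussian noise from a seeded generator.
Seven named morphology presets are provided — NORMAL, PACE, RBBB, APC,
PVC, LBBB_LIKE, NOISY.  **The preset parameter values are authored
fixtures of this package, not published clinical constants**: each is
specified by per-wave fiducial phases (inverted to `α` through the
closed-form mark equations), amplitudes relative to a unit R wave, shape
angles and sharpnesses chosen so that (a) every pattern refits with
`status = "OK"` and near-exact parameter recovery from noiseless data,
(b) the seven patterns are mutually discriminable by LDA at low noise, and
(c) the morphologies qualitatively echo their namesakes (RBBB: broadened
deep S; PACE/PVC/LBBB-like: wide QRS; APC: premature atypical P; NOISY:
typical shape at 10 % noise).  All presets use canonical polarities (P, R,
T crests; Q, S troughs) because the identification cascade by design
revokes, e.g., a trough-shaped T.  Default noise is 2 % of each preset's R
amplitude (10 % for NOISY).

Per-element seeds derive from the dataset seed through NumPy's
`SeedSequence` spawn keys `(pattern index, beat index)`, so any beat is
reproducible on its own.  `simulate_record` concatenates beats at a given
sampling rate with QRS annotations at the 40 % point of each beat window —
a valid end-to-end input for segmentation.

What the generator does *not* emulate: heart-rate variability (all RR
intervals equal), baseline wander, powerline or electrode artifacts,
beat-to-beat morphology variation, and multi-lead geometry.  Passing the
synthetic checks therefore demonstrates correctness of the estimator under
the model's own assumptions — identifiability, convergence, delineation
and discrimination — not robustness to everything real recordings contain.

## Evaluation

Goodness of fit is `R² = 1 − RSS/TSS`.  Fiducial-mark detection is scored
beat-wise: greedy one-to-one nearest matching within ±75 ms (ties by
smaller offset; each mark matches at most once), then
`Se = TP/(TP+FN)`, `PPV = TP/(TP+FP)`, `DER = (FP+FN)/(TP+FN)`,
`F1 = 2TP/(2TP+FP+FN)`, reported as percentages with half-up two-decimal
rounding where a printed-table convention applies.  Parameter-recovery
summaries use plain mean/SD for Euclidean parameters, circular mean and
resultant-length circular SD for angles, and relative errors for ω.

The discrimination harness is Fisher LDA (pooled within-class covariance,
ridge-stabilised when near-singular, empirical class priors) under
leave-one-out cross-validation, with missing features — waves an
incomplete fit failed to letter — imputed by the per-class median computed
without the held-out sample.  This mirrors the per-unit median-imputation
convention; it does use the held-out sample's class for imputation, which
is acceptable here because imputation happens per generating unit, not per
predicted class.  The LDA is validation tooling, not the contribution; an
independent implementation (scikit-learn) cross-checks it in the tests.

## Problem sizes and tolerances

Default synthetic studies use `n = 500` samples per beat (one nominal
second), 100 seeded beats for noisy fit-quality rates, 7 × 20 beats for
the discrimination study, and 250 Hz three-beat records for delineation —
sizes chosen so the full validation runs comfortably on a single CPU.
Noiseless recovery tolerances asserted in the tests: 2 % amplitude,
0.02 rad location, 0.05 rad shape, 10 % sharpness — comfortably met (the
pipeline recovers noiseless presets to ~10⁻⁶).  The fitter's accuracy
bottleneck is Nelder–Mead (`xatol 10⁻⁶`, 300 iterations for single waves;
up to 3000 for the joint polish), not the linear algebra.

## Known limitations

- Waves below roughly 10 % of the R amplitude that sit directly against a
  dominant neighbour can be absorbed by the other waves' fit; they then
  fall below any honest noise floor and the fit returns `incomplete`
  rather than inventing a letter.  This mirrors the method's own honesty
  criterion (a wave may genuinely be null).
- The identification rules assume near-lead-II polarity conventions;
  inverted-T morphologies are reported `incomplete` by design of the
  revocation cascade.
- At `ω = 1` the location and shape angles are only jointly identified
  (`β − α`); the fitter returns a valid representative.
- Atrial-flutter-like patterns outside the five-wave paradigm, multi-lead
  identification and real-database (Physionet) evaluation are out of
  scope.
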