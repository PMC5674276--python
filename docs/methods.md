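# Methods

## The model and its assumptions

The core object is a scalar-target AR-BEKK model.  For target $X$ and
driver $Y$ (both demeaned per-trial ROI series), the full model is

$$X_t = a X_{t-1} + d Y_{t-1} + r_t,\quad r_t = \sqrt{H_t} u_t,\quad
H_t = c^2 + (b_1 X_{t-1} + b_2 Y_{t-1})^2,$$

with $u_t$ i.i.d. standard normal; the restricted model removes $d$ and
$b_2$.  The variance recursion is the 2×1-B special case of a BEKK
volatility model: the conditional noise SD grows with a linear combination
of the lagged signals, which is the signal-dependent-noise (SDN) property
of BOLD data.  Orders are fixed at $p = q = 1$ (TR = 2 s; longer lags are
poorly identified at the segment lengths available).  Estimation is by
Gaussian quasi-maximum likelihood: the Gaussian objective is the standard
estimator for BEKK-type models and remains consistent for the conditional
mean/variance parameters under non-Gaussian innovations.  Each per-trial
segment conditions on its own first $p$ observations and segments'
likelihood terms are summed; cross-segment continuity is never assumed
(inter-trial scans are excluded and segments are demeaned independently).

The causality statistic is $F_{Y\to X} = \log(c_{xx}^2 / c_{xy}^2)$: the
drop in the *constant* noise component when the driver enters both the mean
and the variance.  It responds to mean-level influence ($d$) and to
variance-level influence ($b_2$); the latter is invisible to the classical
constant-variance Granger F-test, which is the method's point.

## Null calibration of F

The raw log ratio is non-negative by construction (the full model is
warm-started at the restricted optimum) and biased upward in small samples:
the extra parameters reallocate part of $c^2$ into the signal-dependent
term even for an uninformative driver.  The bias is dominated by the
variance-side coefficient $b_2$ — the likelihood surface has a
near-degenerate ridge trading $c^2$ against $b^2$ terms — and both the bias
and the statistic's sampling SD scale as $1/T$, so no sample size makes the
bias negligible; a subject-level one-sample t-test on raw F rejects the
null essentially always.  A fixed degrees-of-freedom adjustment removes
only the mean-side part (~$2/T$) and is insufficient.

The reported statistic therefore subtracts a surrogate: F is recomputed
with the driver's trial segments rotated across trials within classes of
equal segment length (a length class with a single member, including the
single-segment case, is time-reversed instead), and the mean over four
rotations is subtracted.  Under the no-coupling null, trial identity is
exchangeable, so the corrected statistic has mean zero by symmetry; under
coupling, cross-trial rotation destroys the driver-target relation and the
full signal survives the subtraction.  Simulations confirm nominal
behavior: the subject-level t-test rejects at ≈5% and power against planted
mean- or variance-level coupling is retained.  The raw ratio remains
available (`null_correction="none"`, and every result carries `f_raw` and
`f_surrogate`).

## Numerical choices

- Unconstrained reparameterization with the noise scale on a log axis
  (positivity of $c$), L-BFGS-B with analytic gradients (numba-compiled),
  coefficient bounds ±10 and $\log c \in [-12, 12]$, `ftol` 1e-8.
- Multi-start: least-squares AR initialization with variance coefficients
  near 0.05, plus jittered restarts (default 5).  Warm-started full-model
  fits use 2 jittered restarts: across cohort fits the warm start reaches
  the same optimum as the full multi-start to ~1e-7.
- Sign indeterminacy of $(b_1, b_2)$ (only the square enters $H$) is
  resolved by canonicalizing $b_1 \ge 0$.
- Nesting holds numerically: the warm start guarantees the full model's
  objective never exceeds the restricted one's beyond optimizer tolerance.
- Degenerate inputs: segments shorter than $p+2$ scans are flagged unusable
  and contribute no likelihood terms; a direction whose restricted, full or
  surrogate fit fails is reported as NaN with a convergence flag, and
  group statistics skip NaNs.
- The SDN test filters $(X^2_{t-1}, \hat u^2_t)$ pairs once, each
  coordinate marginally, at 3 SDs; the 6th-order Fourier residual model
  rescales the lagged signal to $[0, 2\pi]$.  The binned noise-vs-signal
  profile fits its line to within-bin mean signal strengths (bin centers
  are reported for plotting; fitting at centers cannot recover an exactly
  linear relation unless points are symmetric within bins).

## The synthetic cohort: what it emulates

Each buyer: 60 self-paced bargaining rounds.  Private values are uniform
integers 1–10; the suggested price is `round(intercept + slope·value +
noise)` clipped to 1–10 with the subject's slope drawn from the group's
(mean, SD).  Group parameters use the study population's reported fitted-IR
statistics — conservatives 0.13 ± 0.23, incrementalists 0.57 ± 0.18,
strategists −0.68 ± 0.21 — and suggestion-noise SDs (0.66 / 0.82 / 1.80)
set so the regression R² matches the reported group levels (0.24 / 0.80 /
0.54) given Var(value) = 8.25.  Decisions take 10–16 s early in the game
and 6–9 s (three to four scans at TR = 2 s) in the stable last half;
inter-trial intervals are uniform on [4, 6] s.  Early decision times are
unreported in the source experiment; they are set longer than late ones
(practice shortens deliberation) and long enough that the demeaned
segments retain usable lag-1 structure — with 2–3-scan segments,
per-segment demeaning both attenuates genuine coupling and creates
spurious reverse-direction causality (the demeaned own-lag underrepresents
the target's state, so a coupled driver's history helps in reverse).

The emitted series is `baseline (100 scanner units) + evoked + latent`.
The evoked component convolves the onset/choice/key-press impulse trains
with a canonical double-gamma HRF; the removal stage uses the
Hanning-tapered 4th-order Fourier basis, a deliberate kernel mismatch that
exercises the robustness of the removal (the basis captures ~94% of the
double-gamma's norm).  Choice-locked amplitudes differ by group following
the reported activation pattern (strategists ↑ rPFC/DLPFC/RSC, ↓ MPC;
incrementalists ↑ dACC/MPC) but the contrasts are kept ≤ 0.3 units on a
~2-unit response: the removal leftover is a common signal across regions,
and larger group-specific amplitudes would confound the connectivity
comparison — a caveat that applies equally to real task fMRI.

The latent component is a 5-region vector AR-BEKK: self-coefficients 0.5,
own-signal variance coupling 0.35 (every region exhibits SDN), base noise
1, a few weak mean edges shared by all groups (placed among regions whose
dynamics stay group-invariant), and, in strategists only, mean-level
couplings of +0.6 on RSC→rPFC, dACC→rPFC and DLPFC→rPFC.  The boost
magnitude was chosen by pilot simulation as the smallest value at which
the three planted directions reliably survive the Bonferroni ANOVA at the
study's group sizes (28/32/16); couplings this size correspond to clearly
super-threshold directed influence, i.e. the planted effect is strong by
design, matching the strong group differences the source study reports.

What the generator does **not** emulate: hemodynamic variability across
regions and subjects (one kernel for all), physiological noise spectra
(cardiac/respiratory), head motion, scanner drift beyond a linear trend,
value-dependent switching of strategy within subjects, and any seller-side
or interactive dynamics.  Passing tests therefore show that the estimator
and pipeline behave correctly under the modeled conditions, not that the
scientific conclusions transfer to arbitrary real data.

## Tunable parameters (defaults)

| parameter | default | units | rationale |
|---|---|---|---|
| TR | 2 | s | acquisition of the emulated study |
| HRF basis | order 4, 32 s window, Hanning | — | named basis; window is the basis software's default |
| min segment length | 3 | scans | p + 2, one conditional term plus presample |
| behavioral window | last 30 | trials | behavior stabilizes over the game |
| model orders p, q | 1, 1 | — | stated analysis choice |
| restarts | 5 (2 warm-started) | — | multimodal likelihood |
| surrogates per direction | 4 | — | variance of the correction vs cost |
| outlier exclusion | ±2.7 | SD | ≈99.3% normal coverage |
| alpha / directions | 0.05 / 20 | — | Bonferroni p < 0.0025 |
| SVM | linear, C = 10, LOO | — | stated classifier settings |

## Problem sizes in the test suite

The acceptance tests run: parameter recovery at T = 2000 over 100 seeds;
null calibration with 30 replicates × 50 subjects × T = 300; variance-
sensitivity with 50 replicates at T = 500 and coupling 0.25 (pilot-chosen so
the classical test stays within its null band — stronger couplings inflate
its size through heteroskedasticity); SDN detection over 10 pooled
5-region × T = 2000 replicates plus 200 null replicates; and the end-to-end
reproduction over 5 cohort seeds at the full study size (76 subjects),
asserting majorities.  These sizes keep the default suite at a few minutes
while leaving every assertion comfortably inside its Monte-Carlo error.

## Known limitations

- The causality statistic's c²-vs-b² ridge makes per-subject F noisy
  (SD ≈ 0.05–0.08 at ~300 usable scans); group inference needs tens of
  subjects, consistent with the emulated study's design.
- K-means recovery of the three behavioral groups at the reported group
  means and SDs plateaus at mean ARI ≈ 0.89: the conservative and
  incrementalist clouds genuinely overlap (a conservative with slope ≈ 0.4
  is indistinguishable from an incrementalist).  Strategists separate
  cleanly, which is what the downstream strategist-vs-rest analyses use.
- Pairwise (bivariate) analysis only: influences are not conditioned on
  the remaining three regions, so shared drivers can duplicate edges.
- The activation index (choice/onset scan ratio) carries a weak group
  signal by design; with small amplitude contrasts its LOO classifier
  performs near the base rate, and most classification signal comes from
  connectivity.
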