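# Methods

## The model

The Quality Index Method treats fish freshness as an ordinal sensory
measurement. A protocol lists attribute groups → parameters → descriptors;
each descriptor carries an integer demerit (0 up to 1 or 2). A complete
referee sheet scores every parameter, and the Quality Index is the sum of
demerits, so 0 ≤ QI ≤ M where M is the protocol maximum (21 for the bundled
whole-king-weakfish scheme: eight 0–2 parameters and five 0–1 parameters
across overall aspect, gills, eyes and anal area).

The central statistical assumption is that the *panel-mean* QI is linear in
storage days on ice:

    QI(d) = b1·d + b0 + ε ,   ε ~ N(0, σ²) .

Calibration is plain OLS (closed-form normal equations; R² = 1 − SSres/SStot,
residual SD with n−2 denominator). Inverse prediction — the practically
useful direction, "how long has this fish been on ice?" — is
d̂ = (QI − b0)/b1 with a first-order (delta-method) interval
d̂ ± z·σ̂/|b1|, clipped at 0. The delta method is adequate because QIM
slopes are many standard errors away from zero; a Fieller interval would
matter only for near-flat calibrations, which are already rejected as
uninformative. Integer QI predictions round half away from zero (a 0.5
demerit excess is evidence of the worse class) and clamp to [0, M].

Prediction-error conventions differ across chemometrics, so `sep()` reports
all three: bias = mean(pred−obs), RMSEP = √mean(e²), and the bias-corrected
SEP = √(Σ(e−ē)²/(n−1)); they satisfy RMSEP² = bias² + SEP²·(n−1)/n.

## Panel aggregation

How 4 referees × 3 fish collapse into one QI per day is a convention, not a
given: sheet QI = sum of its demerits; panel QI per day = arithmetic mean
over all sheets; dispersion = sample SD (0 for a single sheet). This keeps
the panel QI on the demerit scale and matches the per-attribute mean-demerit
view. Incomplete sheets are rejected rather than imputed — a QIM sum is
meaningless with missing parameters. Half-point demerits are disallowed.

## PLS1 and VIP

Sensory attributes are strongly collinear (one latent freshness factor), so
attribute importance uses PLS1 via the NIPALS recursion (w = X'y/‖X'y‖,
t = Xw, p = X't/t't, q = y't/t't, deflate), X mean-centered and by default
autoscaled to unit variance (sensible for mixed 0–1/0–2 ranges; a flag
disables it), y centered. Orientation is attributes → storage day. The
component count is chosen by leave-one-out RMSECV (ties to the smaller
model). VIP_j = √(p·Σ_a SSY_a w_ja² / Σ_a SSY_a) with SSY_a = q_a²(t_a't_a);
ΣVIP² = p identically, and VIP > 1 flags important attributes. PLS1 at full
rank reproduces OLS fitted values, which the tests exploit as an oracle
(together with an independent library implementation).

On simulated default panels the LOO criterion often picks 2–4 components
rather than 1: the sum-preserving discretization makes per-day attribute
means nearly deterministic functions of the latent total, so extra
components keep trimming LOO error at n = 6 days. The tests therefore assert
the defensible property (RMSECV at the chosen A never exceeds RMSECV at
A = 1; a strictly rank-1 design picks A = 1) rather than a fixed count.

## Indicator rules and the shelf-life decision

Each indicator series (strictly increasing days, finite values, named units)
can be tested against a limit rule (threshold + direction). Defaults:
plate counts at_or_above 7 log CFU/g (reaching the ceiling counts as
rejection), TVB-N at_or_above 30 mg N/100 g (the stricter of the two
customary limits 30/35), TBARS at_or_above 5 mg MDA/kg (low end of the 5–8
acceptance band), putrescine above 20 mg/kg. Putrescine boundaries are
strict ("below 10" fresh, "above 20" low quality), so exactly 10 or 20 mg/kg
falls in the intermediate band.

Crossing detection is reported twice: discrete (first observation day
satisfying the rule — observations, not fits, decide rejection) and
continuous ((threshold − intercept)/slope on a fitted line, 0 if already
violated at day 0, none if the trend moves away). Series are aligned for
correlation by exact inner join on day values; no interpolation, since
shelf-life designs share one sampling grid.

Shelf-life integrates findings: sensory rejection (rounded panel-mean QI
reaching M; an any-single-referee variant is available) plus every
*rejection-class* limit rule. The shelf-life is the greatest sampling day
strictly before the earliest rejection day; no rejection → "not reached
within study"; rejection at the first sampling day → "rejected at first
observation". The putrescine band is informational (rejection=False) by
default: amine accumulation marks quality loss days before the sensory and
microbial criteria reject, and folding it into the rejection set would let a
chemical quality grade override the panel; its crossings are still reported.
This is one defensible formalization of a decision that field studies make
narratively, and the report flags it as such.

## The simulator

`simulate_study` emulates a shelf-life assay: sampling days {1,4,8,11,14,18},
4 referees × 3 fish per day, latent freshness f(d) = 0.9281·d + 1.3378 plus
per-sheet Gaussian referee noise (default SD 0.5 latent demerit points — a
realistic trained-panel dispersion; no empirical noise magnitude is
available, so it was chosen once and kept). Each sheet's latent score is
rounded half-away-from-zero, clamped to [0, M], and apportioned over the 13
parameters proportionally to their maxima by the largest-remainder method
with per-parameter caps (ties by protocol order). Sum preservation is the
point: independent per-parameter rounding would not give sheets whose QI
equals the rounded line value in noiseless mode, which is the anchor the
generator is held to (noiseless day-18 sheets sum to exactly 18).

Indicator models: mesophilic log10 counts 0.1229·d + 3.4642 and
psychrotrophic 0.1593·d + 4.5679 (log CFU/g, additive noise SD 0.15),
TVB-N 0.9577·d + 8.0379 mg N/100 g (SD 1.0), TBARS 0.0034·d + 0.2253
mg MDA/kg (SD 0.01), putrescine exp(0.33649·d + 0.88397) mg/kg with
multiplicative log-normal noise (log-SD 0.3; the exponential coefficients
are a frozen log-linear OLS fit to a published ice-storage amine series —
no kinetic model is available). Noise SDs for the indicators are plausible
assay repeatabilities chosen once. Seeding: one root seed; per-stream child
generators are spawned from its SeedSequence in a fixed order (panel first,
then indicators sorted by name), so panel and indicator noise are
independent and every stream is reproducible bit-for-bit.

The microbial and TVB-N intercepts are used with positive sign. The source
equations print them negative, but the positive-intercept lines are the ones
that pass through the study's own reported endpoints (mesophilic 5.7 log
CFU/g at day 18, psychrotrophic ≈7 log at day 14, TVB-N below its 30 mg
limit across the grid); the generator is anchored to those endpoints.

What the simulator does *not* emulate — and hence what green tests do not
show about real data: referee-specific bias or drift (noise is exchangeable
across referees), fish-to-fish heterogeneity beyond sheet noise, seasonal
lot effects, nonlinear (lag/plateau) microbial kinetics such as
Baranyi/Gompertz growth, censoring at detection limits, and missing sheets.

## Numerical choices and degenerate inputs

- OLS requires n ≥ 2 and non-constant x; constant y yields R² = 1 (the flat
  line is exact). Residual SD is 0 for n = 2.
- NIPALS stops early with a logged warning when X deflates below 1e-12
  covariance with y; zero-variance columns get unit scale instead of
  dividing by ~0.
- Correlations require ≥ 3 aligned days and non-constant inputs.
- Rounding is half-away-from-zero everywhere a demerit scale is discretized
  (sheet totals, integer QI prediction, sensory rejection on panel means).
- Reports serialize with sorted keys and fixed separators, so identical
  inputs give bit-identical documents (hashable for reproducibility checks).

## Problem sizes

The test suite and the acceptance script run entirely on simulated or
printed-table inputs: panels of 72 sheets over 6 days, 500-replicate
Monte-Carlo checks for estimator bias, and a 200-seed correlation study —
desk-scale sizes at which the whole suite completes in seconds.

## Known limitations

- The delta-method inverse-prediction interval understates uncertainty for
  short calibrations with weak slopes.
- VIP importance inherits PLS's dependence on autoscaling; with scaling off,
  wide-range (0–2) parameters dominate.
- The shelf-life rule is grid-resolution-bounded: it cannot resolve a
  rejection between sampling days (the continuous crossing estimate is
  reported alongside as information only).
- With only 6 panel days, LOO component selection for PLS is noisy; fix the
  component count explicitly when comparing studies.
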