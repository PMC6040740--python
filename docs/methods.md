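# Methods

## Within-plate model

For each plate, log OCR of well `w` at time point `t` is modelled as

```
y[w, t] = θ[biosample(w), interval(t)] + β[w] + ε[w, t]
```

The log transform reflects the multiplicative error structure of the assay
(the between-replicate standard deviation of raw OCR grows proportionally with
its mean; on the log scale the dependence disappears).  The natural logarithm
is used throughout so that differences of θ exponentiate directly to the
ratio metrics.  Wells of all biosamples on a plate are fitted jointly by exact
least squares (one linear solve, no iterative optimizer or regularization).

**Identifiability.** Wells are nested within biosamples, so the design has one
aliasing direction per biosample: a constant can be moved between a
biosample's four interval effects and its wells' effects.  A single plate-wide
constraint is therefore not sufficient — the normal equations would be rank
deficient with B−1 free directions and a minimum-norm solve would leak
biosample levels into well effects.  We impose mean-zero well effects *within
each biosample* (which implies the plate-wide zero mean).  Under this
convention θ is the average log level of the biosample's own wells, the
deviation `d = y − θ̂ − mean(β̂)` reduces to `y − θ̂`, and all fitted values,
ratio metrics and cross-plate statistics are invariant to the convention
(verified against a reference-well-coded oracle).  Natural-scale measures do
depend on the convention; "average level of the biosample's wells" is the
interpretable choice.

A biosample with a single well is allowed; its well effect is pinned to zero
and noted in the fit log.  A biosample missing an entire interval is an
estimation error naming the empty cell.  Optional offsets — per-(plate,
interval) effects from the control anchor, or `log(cell_count)` for designs
with deliberately varying seeding density — are subtracted from `y` before
fitting.

## Outlier removal

Deviations deliberately retain the well effect (`d = y − θ̂`), so a
whole-well shift is visible to the well screen.  Per iteration and per
biological sample:

* **wells** — `s_w = mean_t d²[w, t]`; flag `s_w > median(s) + 5·mad(s)`;
* **points** — flag `d² > median(d²) + 7·mad(d²)` over all remaining points
  of the biosample.

`mad` uses the 1.4826 normal-consistency constant; both multipliers, the
constant and the grouping (biosample vs whole plate) are configurable.
Comparisons are strict, so constant vectors (mad = 0) flag nothing; a tiny
absolute guard (1e-12 on d²) prevents floating-point noise on effectively
noise-free data from being flagged.  Flagged units are dropped, the model
refit, and the screen repeated until a pass flags nothing — convergence is
guaranteed because the included set strictly shrinks.  Two safety floors keep
the design estimable: the well screen never reduces a biosample below 3 wells
(removal halts for that biosample, logged) and the point screen never empties
a (biosample, interval) cell.

Two behaviors of this screen are worth knowing.  First, with a realistic
well-effect spread (log-sd 0.1) the well screen flags roughly 7–8% of clean
wells: `s_w ≈ β_w² + noise` is χ²-like and its tail crosses a median+5·mad
threshold at a non-trivial rate.  This is intrinsic to screening on
deviations that include the well effect, and consistent with the large
flagged fractions reported for real plate collections; it costs little,
since discarding a few clean replicate wells barely moves θ̂.  Second, the
point screen trims a few percent of the noise tail over its iterations in
addition to gross points — again matching real-data behavior, where the
iterated screen settles after many passes.

## Ratio metrics and natural-scale measures

With `OCR_i = exp(θ_i)` (intervals 1..4 = initial, ATPase-independent,
maximal, ETC-independent):

| metric | definition | natural-scale analogue |
|---|---|---|
| E/I proportion | `1 − exp(θ_Ei − θ_I)` | basal = OCR1 − OCR4 |
| A/I proportion | `1 − exp(θ_Ai − θ_I)` | ATP-linked = OCR1 − OCR2 |
| E/Ai proportion | `1 − exp(θ_Ei − θ_Ai)` | proton leak = OCR2 − OCR4 |
| M/I fold change | `exp(θ_M − θ_I)` | spare = OCR3 − OCR1 |
| M/Ei fold change | `exp(θ_M − θ_Ei)` | maximal = OCR3 − OCR4 |
| — | — | non-mitochondrial = OCR4 |

Ratio metrics are invariant to any constant added to all four θ of a
biosample — this is why they, and not natural-scale differences, are the basis
for cross-plate testing.

Between-well variability is summarized per interval as the sd of log OCR over
all included (well, time point) observations per plate, median across plates,
converted to a natural-scale CV as `exp(σ) − 1` (close to the exact lognormal
CV for small σ; chosen because it is the conversion conventionally reported
with these assays).  CV percentages are rounded only at the reporting layer.

## Plate-interval correction

Control observations across plates are modelled as
`y = θ_control[interval] + β[interval, plate] + ε` and solved in closed form
(the model saturates the (interval, plate) cells): `β̂[i, p]` is the cell mean
minus its unweighted mean over plates, i.e. mean zero over plates per
interval.  Only contrasts between plates are identified; consequently an
additive shift on one (plate, interval) is absorbed only up to a constant
`shift/n_plates` shared by all plates — cross-plate contrasts and all ΔΔθ
statistics are exactly invariant, which is the property that matters.
Offsets are estimated after outlier removal on the control wells and are not
followed by a second outlier pass.

## Cross-plate testing

`ΔΔθ[b, p] = (θ_a,b − θ_a',b) − (θ_a,c − θ_a',c)` per ratio metric, defined
only where biosample and control share plate `p`.  The one-way model
`ΔΔθ[b, p] = μ_b + ε[b, p]` is fitted jointly over all biosamples; closed
form: `μ̂_b` is the plate mean and `σ̂² = RSS/(N − B)` pools the error
variance over the complete dataset, which is what makes biosamples on as few
as one plate testable.  t statistics use `N − B` degrees of freedom; 95% CIs
come from the same t distribution.  Raw two-sided p-values are the default
(one-sided and Benjamini–Hochberg adjustment available behind flags).  The
closed form is asserted against an OLS oracle to 1e-10 in the tests, and the
t-based test is exactly calibrated on Gaussian ΔΔθ (type-I ≈ 5%, CI coverage
≈ 95%, verified by simulation).

## Extreme Differences baseline

Per well on raw (QC-filtered, not outlier-cleaned) data: interval 1 takes the
last time point, intervals 2 and 4 the minimum, interval 3 the maximum; the
six measures are differences of these extremes, summarized per (plate,
biosample) as mean ± sd/sem.  Within-plate testing is a two-sided Wilcoxon
rank-sum on per-well measures vs the control wells; across-plate testing is a
paired Wilcoxon signed-rank on per-plate means (exact null distribution for
n ≤ 25, normal approximation with tie handling above).  The exact two-sided
floor `2/2^n` means fewer than five plates can never reach p < 0.05; results
with n < 5 are flagged underpowered.

## Power analysis

The minimal detectable relative difference at significance level α with `n`
plates is `exp(z_{1−α/2} · sd(ε)/√n) − 1`, with z fixed at 1.96 by default
(an `exact_t` option substitutes the t quantile).  The subsampling experiment
draws, per repetition, a without-replacement subset of each non-control
biosample's wells (4–16), re-runs outlier removal and the cross-plate test,
and records the pooled residual sd per metric.  Control wells are never
subsampled, since they anchor every plate contrast.

## Synthetic data generator

`log OCR = θ[biosample, interval] + β[well] + γ[plate, interval] +
η[biosample, plate, interval] + ε`, with Gaussian noise on the log scale
(= lognormal multiplicative noise), per-plate mean-centered well effects,
independent per-(plate, interval) batch effects, blank corner wells, the
control biosample on every plate, and one seeded generator fixing the output
bit-exactly.  Defaults: 3 plates, 5 biosamples × 12 wells, 4 intervals × 3
time points, interval levels (100, 40, 150, 20) pmol/min, σ_noise = 0.1,
σ_well = 0.1, σ_plate-interval = 0.15 — between-plate variability dominating
within-plate variability, as in real multi-plate collections.

The interaction term η (default sd 0) emulates growth-replicate variability —
the same line grown and assayed twice does not hit identical interval levels.
Without it, cross-plate residuals of ΔΔθ would shrink to zero as wells per
biosample grow; with it they plateau at `2·σ_η`, which is the floor the
subsampling power curve measures.  Injected artefacts are explicit rather than
heavy-tailed noise: whole-well outliers (all points shifted by ±0.5 log units
by default), single-point outliers (±1.0), and non-responder wells with a
flat profile at the mean level (exercising the QC ordering filter).  Corner
blanks carry small medium-only OCR values.

What the generator does *not* emulate: positional (edge) gradients, temporal
drift within intervals, correlated noise between neighboring wells, and
cell-count-driven well effects beyond a lognormal proxy.  Tests passing on
simulated plates therefore validate the estimation machinery under the
model's own assumptions plus the injected artefact types, not every failure
mode of real instruments.

## Numerical and design notes

* Exact least squares via `numpy.linalg.lstsq` on an explicit dummy/sum-coded
  design; plates are small (≤ ~100 wells × 12 points), so no sparse or
  incremental solver is warranted.
* The QC ordering filter uses strict inequalities on per-well interval
  medians of raw OCR; ties count as violations.  Manual (microscope-style)
  exclusions are a user-supplied list, applied before the ordering test so
  the report's categories partition the removed wells.  Note that a strong
  plate-interval batch draw can genuinely compress the interval ordering and
  cost a few responding wells — on such plates the filter is conservative by
  design.
* Well labels follow row letter + 1-based column ("C6"); corners are blank.
* CV benchmarking between estimation methods (Extreme Differences vs the
  log-linear fit with outlier removal) is informative only when contamination
  is substantial and several plates are available: extreme-picking biases the
  ED means upward, which deflates its CV, so with mild contamination the
  comparison is dominated by that artefact rather than by robustness.
* Determinism: outlier removal has no randomness; the simulator and the
  subsampling power curve take explicit seeds.

## Known limitations

* ECAR (the assay's second readout) is out of scope.
* Instrument-side background correction is assumed already applied; blank
  wells are carried but never used for correction.
* The plate-interval correction estimates fixed offsets from a single control
  line; no shrinkage across plates is attempted.
* The pooled-variance test assumes homoscedastic ΔΔθ residuals across
  biosamples; QQ diagnostics (`qq_residuals`) are provided to check this.
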