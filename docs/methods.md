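# Methods

This note documents the models and procedures implemented in `eaetools`,
the defaults and why they were chosen, the numerical decisions, and what a
green test on synthetic data does and does not establish.

## 1. Synthetic data: the stated world

The array generator emulates a pooled-RNA two-color hybridization: one
array per condition, reference channel = vehicle pool, sample channel =
treatment pool, three replicate probes per gene. Gene effects follow the
signature structure typical of an anti-inflammatory treatment in EAE: a
down-regulated set with log2 effects uniform in [−3, −1] (more than 2-fold
down), an up-regulated set in [+0.6, +2], and a null majority (defaults:
5% down, 5% up, `floor` rounding, remainder exactly zero).

Per spot, the reference log2 intensity is the gene's baseline (uniform in
[6, 16] log2, a typical two-color dynamic range) plus N(0, `noise_sd`)
jitter, and the sample log2 intensity adds the true effect plus another
N(0, `noise_sd`) term — so the per-spot log2 ratio carries noise of SD
`noise_sd` (default 0.15 log2), which is also the generative value of the
technical variability that preprocessing must recover. Corruptions, in
acquisition order:

1. **Dye bias**: the sample channel is distorted by
   `x → x + A·((hi − x)/(hi − lo))²` — a smooth monotone shift, largest
   (`A` log2 units) at the low end and vanishing at the top, producing the
   classic banana-shaped ratio-vs-intensity trend. Monotonicity requires
   `A <` half the baseline range; validated at construction.
2. **Background**: a constant linear offset added to both channels. No
   background subtraction is performed downstream, so ratios of
   low-intensity genes are attenuated toward zero — by the closed form
   `log2((x/2 + b)/(x + b)) > −1` a true 2-fold change can never reach
   2-fold near the detection limit. This is deliberate: it reproduces the
   documented trade-off of ratio estimation without background correction
   (robust selection, under-estimated magnitudes near the limit).
3. **Gross outliers**: with probability `outlier_rate` per experimental
   spot, the sample-channel value is shifted by ±`outlier_magnitude` log2
   (default 3), mimicking dust or array imperfections as rare, large,
   one-channel artifacts. Every injection is recorded in the truth ledger.

Control spots: `n_control_spots` spike-in spots (default 1000) in 20
replicated families spanning the intensity range with zero effect — these
calibrate the technical noise; and `n_negative_controls` spots (default
500) with both channels at background level (log2 ~ N(6, 0.3),
independent channels) — these calibrate the detection limit.

The qPCR generator produces `Cp = base_Cp − effect + sample_offset +
N(0, rep_sd)` triplicates; the per-sample offset (default SD 0.3 cycles)
models plate/loading variation that endogenous-control normalization must
cancel exactly. The score generator draws an onset day (~N(12, 1.5),
matching treatment-at-onset designs) and an animal plateau per group, rises
linearly at 0.5 score/day, snaps to the half-integer 0–6 grid, keeps zeros
before onset exactly, and truncates after a 6 (death absorbing). Defaults:
10 animals/group, day grid 0–51, vehicle plateau 3.5 vs treated 2.0.

**What the generator does not emulate**: spatial structure (print-tip
blocks, gradients), dye swaps, saturation, multi-array designs, probe
sequence effects, amplification-efficiency differences in qPCR, or relapse
dynamics in scores. A green test establishes correct recovery under the
stated noise model, not robustness to those artifacts.

## 2. Array preprocessing

**Q-spline normalization.** 100 evenly spaced quantile pairs of the two
channels' log2 intensities (experimental spots only; controls are
transformed but excluded from the fit) are interpolated by a cubic spline;
if the spline's derivative goes negative anywhere on the data range the fit
falls back to monotone PCHIP interpolation (logged on the curve object).
Order statistics (`inverted_cdf` quantiles) are used as knots, which makes
the transform exactly idempotent. Outside the 2nd/(n−1)th knots the curve
is extended linearly with the end-segment secant slopes — the module's
"modified" tail treatment, avoiding cubic extrapolation blow-up. The
target is the reference channel (not a synthetic intermediate): ratios are
Sample/Vehicle, so the vehicle channel is the natural anchor. Like any
quantile method, the fit assumes the two channels' marginals should agree —
a tail dominated by genuinely regulated genes is partially compressed,
which is why fold-change recovery is assessed on genes expressed above
background.

**Ratios.** `log2(sample) − log2(reference)` per spot, with mean log2
intensity `(log2 s + log2 r)/2`; no background subtraction anywhere.
Nonpositive intensities are floored at 1 linear unit and flagged.

**Detection limit** = mean + 2 SD of the negative controls' per-spot mean
log2 intensity (the conventional limit-of-detection rule);
**dynamic range** = 99th percentile of experimental intensity minus the
limit. A gene is `expressed` iff its surviving-replicate mean intensity
exceeds the limit; cross-treatment comparisons use only genes expressed in
both arrays.

**sigma_tech** is the pooled scaled MAD (×1.4826) of within-family
deviations of the spike-in log2 *ratios* (families need ≥ 10 spots). The
ratio scale is used — rather than single-channel signals — because the
statistic's sole downstream use is gating log2-ratio replicate outliers,
and calibration and use must share a scale. MAD-based, so one gross
artifact among a thousand controls moves it by well under 5%.

**Replicate outliers.** Within each gene's replicate set, a spot is
flagged iff its absolute deviation from the replicate median exceeds
`k·sigma_tech` (default k = 4). At most one replicate per gene is removed
(largest deviation; exact ties retain the lowest replicate index), which
guarantees ≥ 2 survivors at R = 3 and keeps the t-statistic defined.
k = 4 targets gross dust-scale artifacts while leaving ~4σ of headroom
over technical noise; with 1% injected 3-log2 artifacts over 0.1-log2
noise it recovers essentially all injections with a false-flag rate far
below 1%.

## 3. Regularized t

Baldi–Long / moderated-t form with point prior `σ₀` (default: the array's
sigma_tech) and weight `ν₀` (default 4 — strong stabilization at n = 3
without swamping the data):

    s̃² = (ν₀σ₀² + (n−1)s²) / (ν₀ + n − 1),  t = m/√(s̃²/n),  df = ν₀ + n − 1

`ν₀ = 0` reduces exactly to the ordinary one-sample t. The shrunken
variance always lies between `min(s², σ₀²)` and `max(s², σ₀²)`.

Calibration: the t(ν₀ + n − 1) reference is *exact* when true gene
variances are drawn from the conjugate scaled-inverse-χ² prior with ν₀ df
and scale σ₀ (Smyth 2004); the null-calibration tests sample from that
model and verify 5% type-I error and uniform p-values. When instead every
gene's true SD equals σ₀ exactly, the statistic's denominator is less
variable than the reference assumes and the test is *conservative*
(measured rejection ≈ 0.02 at α = 0.05 for ν₀ = 4, n = 3); this is asserted
as a one-sided property. σ₀ is global (no intensity-windowed empirical
Bayes) — a documented simplification.

Gene lists are gated by fold-change thresholds (the > 2-fold-down rule,
log2fc < −1, and the > 0.6-fold rule), restricted to expressed genes;
p-values are emitted but gate nothing by default. A Benjamini–Hochberg
column is provided as an optional extension (no correction is applied by
default).

## 4. Concordance

Pearson r over genes expressed in both arrays; `t = r·√(n−2)/√(1−r²)`,
two-tailed p from t at df = n − 2. At genome scale (n ≈ 19,000) even
moderate r yields t in the hundreds and p far below double precision;
p is floored at the smallest positive double rather than reported as 0.
The regression is OLS of profile B on profile A — slope < 1 reads as
"treatment A more potent" — and is deliberately asymmetric, while r, t, p
are symmetric. Classification at |log2fc| > 0.6 (strict) into
A-specific / B-specific / shared-same-direction / shared-opposite /
unregulated partitions the compared set.

## 5. qPCR

Triplicates are Grubbs-tested only when their sample SD (n−1 denominator)
exceeds 0.25 cycles; the test is two-sided, single-pass (at most one
removal, no iteration), α = 0.05, with the critical value computed from the
t-distribution closed form. At n = 3 the attainable G is capped at
(n−1)/√n = 1.1547 against a critical value of 1.1543, so removal occurs
only when two values nearly coincide — the implementation reproduces this
boundary exactly, and it means a single gross Cp outlier in a triplicate
usually survives filtering; the published-table values are frozen as test
oracles. −ΔΔCp follows the centering formula above; it is invariant to
per-sample constant Cp offsets, and `fold = 2^(−ΔΔCp)` is an exact
identity. Group comparisons: two-sided F ratio pretest at α = 0.05 decides
pooled vs Welch df; both-groups-zero-variance is a degenerate-input error.
No amplification-efficiency correction (Pfaffl) and no standard curves.

## 6. Clinical scores

Validation enforces the half-integer grid, unique days, and no
observations after a 6. CDI sums observed days up to the cut-off
(default 51); an optional carried-forward policy fills gaps with the last
observation (death carries 6 forward). Gaps are treated as data-entry
artifacts, so observed-days-only is the default. Severity bands are
configurable with defaults none = 0, mild ≤ 2, severe ≥ 3.5, moderate in
between — the anchors shared by typical EAE severity reporting; the
mild/moderate boundary varies between experiments in practice, hence
config. Dixon's Q uses the standard n-dependent ratio scheme (r10 for
n ≤ 7, r11 for 8–10, r21 for 11–13, r22 for 14–30) against the Rorabacher
(1991) two-sided 95% table, single pass, at most one removal; only
α = 0.05 is supported because only that table column is embedded and
verified.

## 7. Degenerate inputs and tie-breaks (summary)

- Nonpositive intensities: floored at 1 linear unit, flagged.
- Non-monotone normalization spline: monotone-interpolation fallback,
  recorded on the curve.
- sigma_tech = 0: outlier elimination skipped with a warning.
- Zero shrunken variance: p set to the smallest positive double, flagged.
- |r| = 1: t = ±inf, p = smallest positive double.
- Constant vector in Dixon: zero range, no test.
- Replicate-outlier ties: largest deviation flagged; exact ties retain the
  lowest replicate index.
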