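# Methods

This note documents the measurement definitions, the synthetic-data
models behind the tests, the numerical choices that were genuinely open,
and what the passing tests do and do not establish about real data.

## Bout measurement chain

Speed is the central-difference magnitude `√(ẋ² + ż²)` (one-sided at
epoch edges), with no smoothing by default (a boxcar width is
configurable). Bouts are maximal runs above 5 mm/s; sub-threshold dips
shorter than `merge_gap` (default 50 ms — the original criterion is
unstated; this prevents single-frame dips from splitting a bout) are
bridged. Each bout is aligned at its peak-speed frame and must carry a
full ±250 ms window; the acceleration-phase rotation exclusion uses the
window [t_peak − 250 ms, t_peak], where 30° over 250 ms equals the stated
120 °/s. Repeat matching down-samples the larger group without
replacement under a recorded seed; a random rule avoids temporal bias
since no matching rule is published.

Per-bout features follow the definitions in the README. Two readings
were open:

* **Expected depth change.** `|Δx|·tan(pitch(−100 ms))` — thrust along
  the body axis projected from horizontal travel. The alternative
  (total displacement × sin(pitch)) double-counts the depth component
  and was rejected.
* **Observed Δz for lift** uses the same −100→+100 ms window as Δx; a
  whole-bout window is the other possible reading and is configurable.

**Angular-velocity smoothing.** The peak of the pitch derivative is
found on a boxcar-smoothed series. At 160 Hz a 3-frame boxcar spans only
19 ms; against a rotation event lasting ~150 ms the argmax is then
dominated by frame noise (rotation measurement error sd ≈ 0.44° under
0.1° tracking jitter), which attenuates fin–body slopes by roughly 12%
through errors-in-variables. The default is therefore 7 frames (~44 ms
at 160 Hz, configurable), which halves the error variance while leaving
the pulse peak unbiased (the smoothing kernel is symmetric). On a
constant-angular-velocity plateau the argmax is ambiguous; the latest
maximum is taken so a monotone ramp contributes its full rotation.

**Qualifying bouts for coordination fits** must have positive upward
rotation, positive lift, and a climb-classified trajectory. The third
filter is implied rather than stated: coordination of trunk rotation
with fin lift is the climbing mechanism, and dive bouts whose measured
rotation is marginally positive carry only tracking noise. Without it,
such bouts form a near-origin cluster (lift ≈ 0) that inflates every
slope by ~+0.005 mm/° on synthetic data.

## Robust fits and bootstrap comparisons

`robust_linear_fit` is iteratively reweighted least squares with the
Tukey bisquare weight, tuning constant 4.685 × the scaled MAD
(1.4826 × median absolute deviation, median-centered) of the current
residuals, iterated to a 1e-8 relative coefficient change or 50
iterations. On outlier-free data it coincides with ordinary least
squares. R² is the squared weighted correlation between fitted and
observed values — one convention had to be fixed for a robust fit and
this one reduces to the usual R² at unit weights.

Fitted variables are bootstrapped by resampling bouts (not repeats; the
published description resamples "distributions … from the data from each
condition") 100 times with replacement. The group-difference p-value is
a formalization of the published intent: paired by draw index,
`p = 2·min(Pr(diff ≤ 0), Pr(diff ≥ 0))`, floored at 1/n_boot (0.01 at
100 draws). Bootstrap pairing uses independent seeds per group.

## Statistical layer

Wilcoxon rank-sum p-values are exact (full enumeration) when both
samples have n ≤ 10 without ties, otherwise the tie-corrected normal
approximation with continuity correction — immaterial at the bout counts
involved. The Šidák critical value `1 − (1−α)^(1/m)` takes the family
size m explicitly (8, 5, or 12 for the respective table families, which
reproduces every printed critical p). Significance requires both p below
the critical value and an **unrounded** |effect| ≥ 15% — the published
tables contain a row printing effect 15% with significance "no", which
pins down the unrounded convention. Fisher's exact test uses the
probability-mass two-sided rule, the only rule reproducing the printed
p = 0.0018 for the 0/44 vs 8/40 activation table.

The two-way IQR ANOVA is a fixed-effects decomposition with interaction
(Type I; the design is balanced so the decomposition is unique). On the
packaged activation-experiment IQR table the correct layout gives Group
F = 3.92 with df 3/4/12/340/359. The published reference table (Group
F = 0.225, measure SS 34.6) corresponds exactly to a layout in which,
within each group, the 18×5 replicate-by-measure block is transposed
relative to the factor labels; the acceptance test reconstructs that
label alignment explicitly and reproduces every published sum of squares
and F value, documenting it as the reference layout convention.

## Synthetic swim traces

The generator is an inverse model of the measurement chain, not a
hydrodynamic simulation. Bout peaks follow a renewal process
(exponential gap with mean `ibi_mean` = 1.5 s on top of a 0.3 s
refractory and 0.2 s bout duration, matching the printed inter-bout
interval and duration scales). Each bout superimposes three smooth
pulses:

* a raised-cosine speed pulse (200 ms, peak drawn uniformly within its
  speed bin; bin weights 0.126/0.426/0.448 follow the printed
  slow/medium/fast bout counts of the fin experiment);
* a raised-cosine angular-velocity pulse peaking 50 ms before peak
  speed; its symmetry makes the measured upward rotation exactly half
  the total pitch excursion, so a programmed rotation R is deposited as
  a 2R excursion. Rotation magnitudes are half-normal with scale 2°
  (printed per-bin rotation medians are 1.0–1.5°); dives rotate
  downward;
* a raised-cosine depth-rate pulse inside the ±100 ms lift window with
  integral L = 0.15 mm + slope(bin)·R + N(0, 0.05 mm) on climbs and pure
  noise on dives (dives rely on axial thrust alone). The intercept and
  noise give fit R² in the 0.3–0.75 range across bins, the order
  observed in the published fits.

Horizontal and vertical velocities are solved so the total speed matches
the programmed pulse while the depth change decomposes exactly into
`|Δx|·tan(pitch at −100 ms)` plus L. Pre-bout postures are
N(+14.7°, 10°) for climbs and N(−16.6°, 10°) for dives (printed climb
and dive medians); the climb fraction is 0.58. Re-orientation toward the
next posture happens in an 80 ms ramp midway through the inter-bout gap,
outside every ±250 ms analysis window; when a gap is too short for that
(< 0.6 s) the next bout inherits the carried-over pitch, as a fish that
has no time to re-orient would. Tracking noise is i.i.d. per frame:
0.1° on pitch, 2.5 µm on x and z — sub-degree and sub-pixel jitter at
the recording scale, small enough that rest frames never cross the 5
mm/s threshold.

In the noiseless limit the pipeline returns programmed posture,
rotation, and lift to ~1e-13 and peak times within one frame; the tests
assert this identity. Under default noise, recovered fin-body slopes
across seeded cohorts are within ~5–8% of programmed values (the
residual is errors-in-variables attenuation from rotation measurement
noise plus the positive-lift truncation), and a programmed +4.3°
climb-posture shift on a 14.7° mean is recovered as a ≈29% median
effect.

**What the generator does not emulate:** per-fish identity and
between-fish variance (bouts pool within a group), beat-and-glide
micro-structure inside a bout, roll/yaw coupling, depth- or
wall-dependent behavior, circadian modulation (the day filter is tested
on schedules, not emulated), and any dependence of inter-bout interval
on posture. Passing recovery tests therefore demonstrate that the
measurement chain is unbiased under the stated noise model — not that
the biological effect sizes would be recovered from real recordings with
their richer structure.

## Synthetic tilt responses

Per-trial scalars are Gaussian: r = gain(direction) + N(0, 1), with 21
trials per direction as in the imaging protocol. The published data do
not constrain the gains directly; the defaults (up 5.9, down 5.0) were
chosen so each cell's discriminability is d′ ≈ 0.9 — the value implied
by the printed 3-cell pseudo-population accuracy (~0.78) under ideal
pooling — while every cell stays far below the |DI| = 0.35 tuning
threshold (realized |DI| ≲ 0.1). Negative trial means are clipped at
zero before the DI (dF/F integrals can be negative; the convention keeps
DI within [−1, 1], and cells whose clipped responses sum to zero are
excluded).

## Decoding

Features are z-scored per cell inside each training fold (leakage-free,
via a scikit-learn pipeline) before a linear SVM with margin cost
C = 1.0 — no published hyperparameters exist, so one fixed value is
used. Folds are stratified and seeded; accuracy is 1 minus the mean
held-out misclassification loss; the null permutes trial labels (100
shuffles). A pseudo-population is a cell subset **plus** an
independently permuted within-direction trial pairing; when the
requested size equals the number of available cells the subset is fixed
but each draw still uses a fresh pairing, so medians at full size
aggregate over pseudo-populations rather than a single noisy number.
Accuracy is invariant to global affine rescaling of the responses
(z-scoring), which the tests assert.

## Degenerate inputs and tie rules

Zero-variance predictors and sub-3-point fits raise; speed bins are
half-open `[5, 7.5) / [7.5, 15) / [15, ∞)`; trajectory exactly 0° is
left unclassified; |DI| exactly at threshold is untuned; least-tuned
subsets break |DI| ties by cell id; MAD = 0 flags any point off the
median; all-zero Fisher margins return p = 1.

## Problem sizes

Recovery tests use 6000 s cohorts (~3000 bouts per group) over 10 seeds,
sizes at which the recovery bands (10% on slopes, ±5 percentage points
on the posture effect) test bias rather than sampling noise; the decoder
property pools 8 datasets × 8 draws per population size. These are the
package's chosen verification sizes; all parameters scale up unchanged.
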