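# Methods

This note documents the models, numerical choices and limitations of
`respdyn` in the package's own terms: what each stage computes, which
parameters matter, and what the synthetic-data validation does and does
not establish.

## Respiratory phase and breath events

Breath onset defines φ = 0 and offset φ = +π; expiration spans (−π, 0).
Phase is linear in time within each half of the breath. Internally the
expiration segment is interpolated on the unwrapped interval [π, 2π]
and wrapped to [−π, π): the offset sample is exactly +π, the midpoints
of inspiration and expiration are exactly ±π/2, and onset/offset times
are recovered exactly from the φ = 0 and φ = π crossings. The sample
immediately after an offset sits at −π + π·dt/T_exp, approaching −π in
the continuous-time limit; an alternative convention pins that sample
to −π exactly but then the expiratory midpoint is no longer exactly
−π/2, and the exact-midpoint property was preferred.

EMG integration follows the fixed order band-pass (300–5,000 Hz, 4th
order Butterworth, zero-phase), full-wave rectification, 50-ms median
filter, decimation to 1 kHz, division by the standard deviation. The
median filter is evaluated only at the retained 1-kHz instants, which
is arithmetically identical to filtering then decimating. Burst
detection uses local peaks (default height 0.5 s.d., minimum separation
100 ms — the field reports no standard values, so both are exposed in
configuration); onset and offset are the nearest crossings of a
configurable fraction (default 10%) of each peak's height.

The sigh rule flags breaths whose area exceeds the centered 51-breath
rolling median by more than 7× the rolling median absolute deviation.
A literal "area > 7×MAD" reading flags every breath as the MAD
approaches zero; the deviation form with a 10⁻⁹ MAD floor preserves the
intent (an outlier in MAD units) and is degenerate-safe. Gasping epochs
use the 7-breath median-filtered IBI with begin/end hysteresis at
1 s / 0.85 s; rolling windows truncate at the record edges.

## Coherence

Spike–diaphragm coherence is a segment-averaged multitaper estimate:
non-overlapping 10-s segments of the first 300 s, DPSS tapers with
time–bandwidth product 3 and 5 tapers, the spike train binned at the
trace rate and mean-centred per segment. Confidence bounds come from a
delete-one-segment jackknife on atanh(C) at error levels
[0.001, 0.999], transformed back and clipped to [0, 1]. The summary
values (C, C_lb, C_ub, phase lag) are read at the frequency of maximal
coherence inside 0.5–8 Hz — the physiological breathing band; the
segment length (10 s, hence 0.1-Hz resolution) is a package choice, as
is the variance-stabilizing transform. A unit is *phasic* when
C_lb > 0.1. The preferred phase used for inspiratory/expiratory
assignment defaults to the cross-spectral phase lag at the peak
frequency (which need not coincide with the tuning-curve maximum); the
tuning-curve argmax is available as an alternative.

## Clustering

Tuning curves are smoothed with a 3-sample Savitzky–Golay filter of
polynomial order 1 applied circularly (order 2 at window 3 is exact
interpolation, i.e. a no-op), max-normalized, and clustered as the raw
100-bin matrix, its leading 4 principal components (>95% of variance on
all tested families) and 20 NMF scores, by k-means (10 restarts,
seeded) and Ward linkage, for k = 2…15. Silhouettes are Euclidean in
the clustered space — including for the raw set. The optimal k
maximizes the silhouette (ties toward smaller k); the shuffle control
recomputes the silhouette under 5,000 random label permutations and
reports the 99th percentile. The threshold sweep repeats everything on
units with C_lb above each threshold; its confidence interval is taken
across the 6 technique combinations (3 feature sets × 2 clusterers).

## Manifold statistics

Rates are 5-ms spike counts smoothed with a σ = 10 ms Gaussian and
square-root transformed (variance stabilization). PCA is fitted on the
designated baseline epoch only; the fit-epoch mean centres the entire
recording so condition shifts remain visible. Components are reordered
by their multitaper coherence with the integrated diaphragm (same
taper settings as the unit calculation — the package reuses them for
the continuous–continuous case) and the leading reordered components
(those with coherence above 0.3, capped at 4) enter the trajectory
statistics.

Per-bin *speed* is the norm of the phase-binned mean first difference
of the projections at the native 5-ms step. Binning the norms of the
raw sample-wise differences instead folds the isotropic estimation
noise of the projections into a floor that tracks firing rate and is
several times the deterministic per-step motion at realistic rates;
the binned-mean displacement averages that noise out and estimates the
deterministic velocity profile. *Distance-to-mean* is computed per
breath: each breath's mean position per phase bin is compared with the
across-breath mean trajectory and the distances averaged per bin.

Principal angles between condition subspaces are the singular values of
AᵀB for orthonormal loading bases (defensively re-orthonormalized).
Pairwise structure is the zero-lag correlation of transformed rates per
unit pair; cross-condition similarity is the Pearson correlation of the
pair values with a Fisher-transform confidence interval.

## The switching dynamical system

The two-state, two-dimensional rSLDS is fitted to 10-ms spike counts by
coordinate ascent on the joint log posterior:

1. **Latent initialization.** PCA of σ = 2-bin-smoothed, square-rooted
   counts, standardized per dimension; discrete states initialized by
   k-means on (x, dx).
2. **Per-state dynamics** by least squares on regime interiors. Bins
   within ±3 steps of a marked state switch are excluded: the smoothed
   latent rounds the regime corners, marked switches can lag the true
   ones by a few bins, and the corner bins would otherwise blend the
   two regimes' dynamics (this blending, not measurement noise, was the
   dominant eigenvalue bias in development).
3. **Noise scale** estimated once from the interior residuals of the
   initial latent and then frozen. Re-estimating it from the refined
   path feeds back — the refined path shrinks residuals, the prior
   tightens, and the variance collapses toward zero (the classic joint
   MAP degeneracy).
4. **Recurrent weights** by multinomial logistic regression of z_t on
   x_{t−1}. The in-loop fit is unweighted (cleanest state labels); the
   final reported/simulated transition model is class-balanced so the
   majority regime (expiration) does not pull the switching surface
   toward itself.
5. **Discrete states** by exact per-bin argmax of dynamics likelihood
   plus transition log-probability.
6. **Emissions** by a vectorized damped-Newton Poisson GLM.
7. **Latent path** by banded-Newton MAP ascent (block-tridiagonal
   Hessian of the Poisson likelihood with the Gaussian dynamics prior,
   backtracking line search).

The objective is recorded per iteration and non-decreasing up to the
stated tolerance (the class-balance substitution can introduce
sub-tolerance wiggles; a warning is emitted if it exceeds them).

**Identifiability-guarded taxonomy.** A state-conditional regressor
direction whose variance sits within 3× the latent noise floor is not
identified by the regression: a fast-contracting direction that is
spent inside the excluded corner bins leaves nothing but smoothed
measurement noise in the interior, and a naive fit assigns it that
noise's autocorrelation (≈0.95–1.05), sometimes crossing the unit
circle and producing spurious saddles. The eigenvalue taxonomy
(`RSLDSResults.eigenvalues`, `state_categories`, `classify_dynamics`)
is therefore computed on matrices in which such directions are
annihilated — classified as contracting, which is what the regime
observably does to them. Simulation uses the raw regression dynamics:
the annihilation redirects states near the (curved) regime manifold and
measurably distorts simulated timing, whereas the raw on-manifold flow
carries the observed timing. Both matrices are stored (`A` and
`A_identified`).

Simulation is deterministic (noise set to zero; the state is the argmax
of the recurrent logits), started from the posterior latent at a
seed-chosen observed time, with an overflow guard. The diaphragm
decoder is an RBF support-vector regression from the 2-D latent to the
binned integrated diaphragm, trained on at most 4,000 subsampled
observed points. A simulation is *regenerative* when its decoded
diaphragm has a dominant spectral peak in 0.5–8 Hz at ≥5× the band's
median power and the burst amplitude of the last third is ≥50% of the
first third — an operationalization of a qualitative distinction that
is, in practice, sharply bimodal. Dropout analysis removes units in a
given order, refits model and decoder cold at each scheduled count, and
marks a step regenerative when its simulated frequency is 75–150% and
its inspiratory duration 75–125% of the full model's simulation; units
to failure is the greater of the logistic-regression decision boundary
(p = 0.5) and the last success before the first failure. Cross-recording
alignment solves the least-squares problem X W ≈ Z on 100-bin
phase-averaged latents (the pseudoinverse reading of a 100×2 system).

## The synthetic generator

The generator is the package's ground-truth instrument, not a fixture:
its defaults define the study conditions under which the analysis is
validated.

**Default (slow eupnea, "saddle" mode).** A 2-D latent steps at 10 ms:
inspiration is an unstable spiral (half a rotation from the onset
radius 1 to the offset radius 2 over 0.65 s; the per-step modulus is
derived so the mean onset radius reaches the offset radius in exactly
half a turn, keeping the offset aligned with the spiral's half
rotation), and expiration contracts onto the inspiratory-off target
along a near-dead-beat direction (eigenvalue 0.01) while a weakly
expanding direction (≈1.017) carries the state back to the onset
half-plane over 1.15 s. Switching is hysteretic: inspiration ends when
the spiral, armed after half a rotation, crosses the offset *radius* —
an amplitude lock that makes the off-target the tightest, slowest point
of the cycle — and expiration ends at the onset half-plane x₁ ≥ 1.
The breath period is 1.8 s (0.56 Hz), slower than rodent eupnea by
design: each of the 100 phase bins then spans ≥3 samples of the 5-ms
rate grid, so the sharp post-offset minima of speed and variability are
resolvable under the σ = 10 ms rate smoothing; at 2–4 Hz the smoothing
kernel alone spans >5 phase bins and the offset kinematics cannot be
localized by any analysis of the rates. Pure stable-node expiration
was rejected for the default because a node's deterministic speed and
variance decay monotonically toward the *end* of expiration, placing
both minima just before onset — the opposite of the off-target
phenomenology the analysis is designed to measure; the contracting/
expanding pair reproduces it.

**Spiral/node mode (`spiral_node_config`).** For dynamics-recovery and
regeneration studies: breathing at ≈2.9 Hz, inspiration an unstable
spiral with per-step modulus 1.06 (0.12 s half-rotation), expiration a
genuine stable node A = [[0.91, 0], [0.1, 0.5]] whose shear-coupled
slow manifold dips below the switching boundary at offset and
re-crosses it at the onset radius. Crucially the switching rule here is
a *memoryless half-plane* (inspiration ⇔ x₂ > 0): the generating
system lies inside the recurrent-softmax model class, so recovery and
regeneration measure estimation quality rather than model mismatch. A
conjugation experiment during development showed that hysteretic
switching rules are not representable by any recurrent-softmax
boundary — even the true dynamics then mis-time the simulated rhythm by
tens of percent — which also mirrors why fitted models of real
recordings are frequently non-regenerative.

**Emissions.** Each unit fires as an inhomogeneous Poisson process with
rate baseline·exp(c·(x − x₀)); coherent units draw |c| from the gain
range with a uniformly random preferred direction, tonic units have
c = 0. Counts are drawn per 10-ms bin (exactly equivalent to thinning
for piecewise-constant rates) and placed uniformly within the bin. All
randomness descends from one seed; per-unit streams use child seed
sequences so unit i is reproducible independently of the population
size. Rates are guarded at 1,000 spikes/s.

**Diaphragm.** A rectified affine readout max(0, w·x + 0.2), gated to
the inspiratory state, linearly upsampled to 1 kHz, plus Gaussian noise
(default 5% of the clean s.d.), normalized to unit variance. The
positive bias makes the gated trace step up at onset — diaphragm
recruitment is abrupt — so detected onsets coincide with the state
switch to within a sample.

**Perturbations.** Sigh mode scales the latent excursion (×2) and the
readout (×6, hence ≈12× diaphragm amplitude and area) on every 20th
breath; gasp mode parks the latent at a rest point with brief symmetric
ballistic excursions at 1.5–3-s intervals; opioid mode time-dilates the
latent update through a fractional accumulator (default 1.5×).

**What the generator does not emulate:** ECG contamination of the EMG,
electrode drift and unit instability, spike-sorting errors, anatomical
structure across units, history dependence within spike trains
(refractoriness, bursting), and state-dependent noise. Tests passing on
this generator establish that the estimators recover what they claim
under the stated statistical structure — not that real recordings
satisfy that structure.

## Validation: what is established, and known limits

The acceptance suite verifies, among others: exact phase round trips
and midpoints; coherence calibration (phase-locked unit C_lb > 0.9,
independent units below 0.1 in ≥95% of seeds); selectivity identities
(0, 1, and 0.5 ± 0.01 for 1 + cos φ against a numerical integral);
cluster-number selection of 3 at weak and 2 at strong coherence
thresholds with the real silhouette above the 5,000-shuffle 99th
percentile; eigenvalue-category recovery in ≥8/10 seeds with the
inspiratory modulus within 10% (median); the one-state control never
regenerating; simulated breathing rate within 10% of truth (median);
breath-aligned simulated-vs-observed R² above both shuffle controls;
strict dropout asymmetry; perfect sigh sensitivity/precision on
implanted events; exact gasp-epoch boundaries against a brute-force
rule evaluation; and latent-alignment recovery to 10⁻⁶.

Known limits: (i) the *exact* arg-minimum of the measured
distance-to-mean profile scatters over the first ~10 phase bins after
offset — the basin interior is flat to below the per-bin sampling
error because the residual Poisson noise floor tracks firing rate and
cancels the designed variance growth — so its localization test is
stricter than the measurement supports at 150 units × 300 s, and can
fail while the basin itself starts exactly at offset; (ii) rSLDS fits
at small populations (≲30 units) or few iterations may mislabel
boundary bins and blur the taxonomy; (iii) the fitted switching
boundary is linear, so generators with hysteretic switching are
systematically (and correctly) non-regenerative.
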