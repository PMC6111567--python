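# Methods

This note records the models, conventions and numerical choices behind
`tfemotion`, in the spirit of a package methods appendix: enough detail to
reimplement every stage and to understand what the tests do and do not show.

## Quadratic time-frequency representations

A windowed EEG segment `z[n]`, n = 0..M−1, is first made analytic with the
frequency-domain Hilbert transform; the real part of the result is forced
bitwise equal to the input. The discrete Wigner–Ville distribution (WVD) is
built from the instantaneous autocorrelation

    K[n, m] = a[n + m] · conj(a[n − m]),

kept where both indices lie inside the segment and zero elsewhere
(zero-padded edges). Because column m spans a physical lag of 2m samples, a
2M-point FFT over m yields N = 2M frequency bins spanning [0, fs/2): bin k
sits at k·(fs/2)/N Hz, and M = 512 gives the 512×1024 grid. Surfaces are
scaled by 1/N, which makes every time row sum exactly to |a[n]|² and the
whole surface sum to the analytic-signal energy — the scale-fixing
convention used by the energy tests; comparisons against other
implementations should use scale-invariant statistics (ratios, peak
positions), since no universal normalization exists for these transforms.

The Choi–Williams distribution (CWD) applies the exponential kernel in the
ambiguity (Doppler–lag) domain: K is DFT-transformed over time n, multiplied
by `Φ(ν, τ) = exp(−ν²τ²/β²)` with ν the normalized Doppler in cycles/sample
in [−½, ½) and τ = 2m the lag in samples, transformed back, then
FFT-transformed over lag. The kernel is exactly 1 on both axes, so
auto-terms (concentrated near ν = 0) survive while cross-terms — which
oscillate at the beat frequency of the interfering components and therefore
live at nonzero Doppler — are attenuated; β → ∞ recovers the WVD (verified
to 10⁻⁶ relative, with monotone convergence over β ∈ {0.5, 5, 50, 500}).
The default β = 0.5 suppresses the two-tone (8 + 24 Hz) midpoint cross-term
by roughly two orders of magnitude while leaving auto-term ridge positions
unchanged. The DFT over time is periodic, so Doppler smoothing wraps at
segment edges; interior rows (the regime all assertions use) are unaffected.
Both surfaces are real by the conjugate symmetry of K; the imaginary
residue of the finite-precision transform (observed below 10⁻⁸ of the real
part's magnitude) is discarded.

The kernel is deliberately applied in Doppler–lag coordinates even though
exponential-kernel formulas are sometimes written with time–frequency
variable names: multiplying the ambiguity function is what makes the kernel
a cross-term filter, and is the classic construction of this distribution.
A literal 2-D smoothing of the (t, f) surface is a different operator and is
not implemented.

## The 13 descriptors

All descriptors are computed over the full M×N surface ϱ of one channel
window. Conventions where the defining formulas leave freedom:

* **Moments** (mean, variance, skewness, kurtosis): population moments of
  the surface values; when the variance is zero the standardized third and
  fourth moments are defined as 0.
* **SLA** uses the natural log of |ϱ| floored at `log_floor = 1e-12`; the
  Rényi entropy uses log₂ (bits) as printed in its definition.
* **MAD** is the mean absolute deviation from the surface mean.
* **RMS** is √(mean of ϱ). The CWD sum approximates signal energy so the
  mean is nonnegative in practice; a negative mean (numerical artifact) is
  replaced by its absolute value with a logged warning.
* **IQR**: each frequency column's M time values are sorted ascending, and
  the feature is the mean over frequency of the difference between the
  values at 1-based positions round(3(M+1)/4) and round((M+1)/4)
  (round-half-up, clipped to [1, M]). Indexing quartile positions only
  yields an inter-quartile range on sorted values, hence the sort.
* **Flatness** is the geometric over arithmetic mean of |ϱ|, evaluated in
  the log domain so the MN-term product cannot underflow; an all-zero
  surface gives 1 (geometric = arithmetic mean).
* **Flux** sums forward differences over the (M−l)×(N−k) valid lattice with
  l = k = 1; no wraparound.
* **Spectral roll-off** has two modes. The default `index` mode reports the
  smallest frequency bin below which at least λ = 0.85 of the time-summed
  mass lies, normalized to (0, 1]. The `literal` mode reports λ times the
  total sum — a reading that carries no frequency information (it is
  collinear with the mean) but is retained for comparability; the
  non-degenerate roll-off-point reading is the default.
* **Rényi entropy** (order ν = 3): the surface is normalized by its total
  sum (equal to M·N·mean); the ν-th power sum is floored at `log_floor`
  before log₂ because negative CWD values can make it nonpositive, with a
  logged warning when the guard engages.
* **Energy concentration** is Σ|ϱ|².

Per-channel blocks are concatenated in a fixed canonical order (channels as
listed in the active configuration; descriptors in the order above), giving
26 columns for an electrode pair, 156 for the 12-channel frontal/temporal
group, 104 for the 8-channel parietal/occipital group and 286 for all 22
channels. Every descriptor is property-tested against a literal double-loop
reference implementation at 10⁻¹⁰ relative tolerance, plus scale-behaviour
checks (linear in a positive scale factor for mean/MAD/IQR, quadratic for
variance/EC, invariant for skewness/kurtosis/flatness).

## Labeling schemes

Ratings are continuous in [1, 9]. "High" on an axis means strictly greater
than 5; a rating of exactly 5 is low, following the greater-than-five /
otherwise phrasing of the two-class rule. The three-level schemes use
closed outer intervals [6.5, 9] and [1, 3.5] with an open neutral band
between. The five-class scheme is neutral iff *both* ratings lie in
(3.5, 6.5), otherwise the quadrant rule applies; restricted to ratings
outside the neutral box it coincides with the four-class scheme (property
tested on a dense grid including the boundary values 3.5, 5 and 6.5).

## Feature selection

mRMR with the mutual-information-difference criterion: greedily add the
column maximizing I(x; y) minus the mean mutual information with already
selected columns. Continuous features are discretized into three states at
mean ± one standard deviation — the canonical treatment of continuous
features for this selector; the exact discretization used in prior art is
typically unstated. Ties break toward the lower column index, making the
ranking deterministic and column-order invariant up to ties. Scenarios keep
ceil(fraction × n) columns for fractions 0.05/0.25/0.5/0.75, or all.

By default the selector is fitted inside each cross-validation fold on
training data only. A `pooled_selection` switch fits it once per subject on
all data — a common but leakage-prone protocol — retained for
comparability studies.

## Classification and evaluation

Subject-specific SVMs with the RBF kernel; multiclass problems use the
one-vs-one decomposition (k(k−1)/2 binary machines, majority voting with
decision-value tie-breaking, as implemented by the underlying library).
Features are z-scored with training-fold statistics. Hyperparameters come
from a two-dimensional powers-of-two grid (C ∈ 2^{−5..15}, γ ∈ 2^{−15..3},
step 2²) scored by stratified inner 5-fold CV on the training portion; the
grid is scanned in ascending (C, γ) order with strict improvement, so ties
resolve to the smallest C then smallest γ. The grid ranges and inner
protocol are this package's choices; no standard exists.

Outer evaluation is stratified 10-fold CV at the window level, every vector
tested exactly once. Accuracy is (tp + tn)/total; F1 is 2tp/(2tp + fp + fn)
with the "high" class positive for binary problems and the unweighted macro
average of one-vs-rest F1 beyond two classes (the imbalance-respecting
extension). A `groups` option folds at trial granularity instead, keeping
all windows of a trial together.

**Leakage note.** Overlapping windows of one trial are near-duplicates;
window-level folding places them on both sides of the split, which inflates
null-model accuracy toward the majority-class share. All end-to-end
recovery checks therefore use trial-grouped folds. A second artifact
matters at small trial counts: with one trial per fold, the held-out
trial's class is systematically underrepresented in training, biasing the
classifier *against* it (anti-learning, observed as zero-effect accuracy
far below chance). The shipped problem size — 20 trials, ten grouped folds
containing one trial of each class — avoids both artifacts.

## Synthetic data generator

Each channel is band-limited (4–45 Hz) 1/f background noise at unit
variance plus amplitude-modulated sinusoids in the theta (4.5–7.5 Hz),
alpha (9–12 Hz) and beta (15–28 Hz) bands, with random carrier frequencies
per trial/channel and slow (0.1–0.4 Hz) raised-sine envelopes that make
windows genuinely nonstationary. Base amplitudes (0.6/1.0/1.0) put each
rhythm's power on the order of the background power within its own band.
Rating effects are multiplicative log-amplitude gains: beta amplitude
scales by exp(0.2·(arousal − 5)) — about a 2.5× total beta-band power
ratio between arousal 8 and 2 — and alpha amplitude by
exp(±0.15·(valence − 5)) with opposite signs on the two hemispheres
(odd-numbered electrodes left, even right). Out-of-band power is below 1 %
by construction.

Ratings follow a class-balance schedule: the default cycles through the
archetypal regions of a requested labeling scheme (outer rating bands for
high/low, quadrant corners, the neutral box) and samples uniformly inside
each, guaranteeing populated, balanced classes; a `uniform` schedule over
the whole plane is available for realism studies. Randomness derives from
one integer seed with independent child streams per (subject, trial), so
any trial regenerates identically regardless of order.

What the generator does *not* emulate: volume conduction and realistic
scalp topographies, ocular/muscular artifacts, inter-subject variability in
band frequencies, non-Gaussian burst statistics, or any genuine
neurophysiology of emotion. Passing recovery tests therefore demonstrates
that the pipeline can extract band-power and asymmetry structure from
nonstationary signals — not that comparable accuracy is attainable on real
recordings.

## Problem sizes and determinism

Cross-validated end-to-end checks run one synthetic subject with 20 trials
of full 63 s length on one symmetric electrode pair, top-25 % selection, a
coarse 2×2 SVM grid and 3-fold inner CV; these sizes keep the quadratic
transform (the dominant cost, ~40 ms per 512-sample window) tractable while
preserving the full method. Typical seeded results: ~93–95 % accuracy with
default effects, ~50 % with zero effects or permuted labels (chance = 50 %).
All stochastic stages (generation, folding, permutation) are driven by
explicit seeds; reports embed the resolved configuration.

## Known limitations

* The spectral roll-off's literal mode duplicates information in the mean;
  it exists only for comparability.
* The discrete CWD is periodic in Doppler; very short segments (< ~32
  samples) see visible edge wrap.
* The grid search refits one SVM per grid point and inner fold with no
  warm starts; large grids on large tables are slow by design, not a bug.
* Multiclass recovery (3–5 classes) is exercised structurally but the
  shipped effect sizes are calibrated only to make the two-class arousal
  problem clearly decodable.
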