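# Methods

## Generative model and inference

The model neuron observes an image patch only through 18 oriented linear
filters: a quadrature pair (odd/even spatial phase) at the receptive-field
(RF) center and eight quadrature pairs whose Gaussian envelopes sit on a
ring around it, all sharing one orientation. Kernels are Gabor functions,
DC-removed and L2-normalized; within each pair the even kernel is projected
orthogonal to the odd one, because envelope truncation at the patch edge
otherwise leaves a small (~1e-4) overlap for surround positions. Image
coordinates are row-major with the origin at the patch center, the vertical
axis pointing up, and angles counterclockwise from horizontal; a filter's
orientation is the orientation of its preferred grating's bars.

The observation vector is generated as x = ν·g + η with Gaussian local
features g ~ N(0, C_g), a scalar Rayleigh mixer ν with mean 1 (scale
s = √(2/π)), and Gaussian observation noise η ~ N(0, C_noise). The mixer
is shared by all features, which is what couples the RF to its surround:
every filter's activation is evidence about ν.

Inference exploits the scalar mixer: p(ν | x) ∝ p(ν)·N(x; 0, ν²C_g + C_noise)
is a 1-D density, evaluated on a 2,000-point log-spaced grid spanning the
prior's [1e-4, 1−1e-8] quantiles. If more than 1e-6 of the posterior mass
sits at a grid edge the edge is doubled (up to 60 times) before failing, so
strong inputs whose posterior mixer lies far above the prior bulk are handled
automatically. Mixer draws come from the grid weights; each is completed by
one draw of g | ν, x from its conditional Gaussian. A single generalized
eigendecomposition of (C_noise, C_g) diagonalizes every per-ν operation, so
likelihood, moments and sampling are O(grid × d) per stimulus. The sampler
has no burn-in or autocorrelation; the tests check it against a brute-force
importance sampler over the joint (ν, g) prior, which shares no code with it.

### Asymptotics

In the noiseless limit, with λ = √(xᵀC_g⁻¹x),

    E[ν|x] ≈ √(sλ),  E[g₁₊|x] ≈ x₁₊/√(sλ),  FF[g₁₊|x] ≈ x₁₊·√s/(4λ^{3/2}),

with relative corrections of order 1/λ. The familiar forms x/√λ and
x/(4λ√λ) are the s = 1 special case; the scale factors are required for the
formulas to be exact asymptotics under the mean-1 mixer prior (verified
against the exact 1-D quadrature oracle: the relative error of the mean is
1.0%, 0.3%, 0.1% at λ = 10, 30, 100, and without the scale factor it
plateaus at ~11%). Summaries are reported with a warning below λ = 5
(configurable), where the 1/λ corrections are no longer negligible, and the
x₁₊ > 0 assumption is flagged when violated. The exact noiseless 1-D
posterior (change of variables ν = x/g) is exposed as
`noiseless_posterior_1d_exact` and serves as the oracle throughout.

### Training

C_g is moment-matched: the empirical covariance of filter outputs over the
training ensemble divided by E[ν²] = 2s² = 4/π. Training patches are treated
as noise-free (no C_noise subtraction). The result is symmetrized and
eigenvalue-floored at 1e-8 of the leading eigenvalue so real image ensembles
cannot produce an indefinite matrix. C_noise is the filter-output covariance
over 10,000 i.i.d. pixel-noise patches scaled by a heuristic 0.1; the noise
patches' pixel sd defaults to the training ensemble's typical RMS contrast
(0.2) so the heuristic keeps its meaning of "small relative to the trained
signal" independent of luminance units.

## Parameters that matter

- **Geometry** (`FilterBankSpec`): 80×80 px patch at 0.05°/px (4°×4°),
  envelope sd 0.3°, spatial frequency 1 cyc/°, ring radius 1.0°, 8 surround
  positions. This yields an RF of roughly 1° (≈4 envelope sd) and surround
  pooling that keeps growing out to ~2° eccentricity, so the normalization
  signal λ still increases between 2.4° and 3.8° stimuli — with a smaller
  ring (e.g. 0.5°) the surround pool saturates by ~2.2° and the largest two
  sizes of the standard series become indistinguishable.
- **Mixer prior**: Rayleigh with mean 1. Rescaling the prior is equivalent
  to rescaling C_g, so this is a units convention, not a free parameter.
- **Noise scale 0.1**: keeps weak-stimulus responses non-silent; with
  C_noise → 0 and λ large the sampled moments reproduce the noiseless
  asymptotics (tested).
- **Readout**: r = c·√(g₁₊² + g₁₋²) per posterior sample, c heuristic
  (2 for image scans, 15 for size tuning, 40 for surround tuning in the
  examples). r is kept continuous by default and treated as a count;
  rounding is available. A rectified expansive readout c·max(g₁₊,0)^p
  (default p = 2) is provided because the modulus readout mispredicts the
  contrast dependence of variance at fixed size; size and surround tuning
  are robust to the choice.
- **Samples per stimulus**: 400 (the "trial count" of the model neuron);
  experiment-level bootstrap CIs are 68% percentile intervals over those
  samples, 1,000 resamples.

## Stimuli and surrogate ensembles

Gratings are sine-phase (phase 0 aligns with the odd RF filter), presented
at 100% contrast in hard circular apertures on a gray background; compound
stimuli add an annular surround with independent orientation, separated
from the center disc by a gray gap. The default size series is 0.34, 0.55,
0.90, 2.4, 3.8°; the default annulus is 1.0–3.8° (the largest annulus the
4° patch holds).

When no natural images are on disk the package substitutes pink-texture
ensembles: random-phase 1/f-amplitude patches with a log-normal per-patch
RMS contrast (median 0.2 on the [-1, 1] luminance scale, log-sd 0.5). These
emulate two features of natural patches the model's predictions rest on —
a modest typical contrast (a unit-RMS patch would be as strong as a
full-contrast grating, pushing the trained model out of the large-λ regime)
and heavy-tailed contrast variation across patches. They lack oriented and
higher-order structure, so passing tests demonstrate the mechanism
(multiplicative-mixer inference), not quantitative agreement with responses
to real scenes; `load_image_patches` accepts a directory of real images,
with optional selection of patches whose RF energy x₁₊²+x₁₋² exceeds the
ensemble median.

## Spike-count analysis pipeline

Counts are taken in half-open windows [latency, latency + duration) so no
spike is double-counted; baseline is the fixed [-20, 30) ms window around
stimulus onset. Latency is the first post-onset crossing of the smoothed
PSTH (1-ms bins, trial-averaged rate in spikes/s) above baseline mean + 1
sd; smoothing is a cubic smoothing spline with roughness penalty 2e-6 on a
seconds time axis (the penalty is convention- and unit-dependent; this
convention recovers programmed step latencies within ~5 ms on synthetic
change-point fixtures and is pinned by those tests). The PSTH is taken at
the preferred (largest-response) condition for size-tuning data, or at the
smallest size otherwise.

Inclusion rules are configurable per experiment: responsivity above
baseline + 1 sd (which also defines the latency), average FF across
conditions ≤ 2, size-tuning peak not at the smallest (≤0.3°) or above the
largest (>4°) size as a centering proxy, RF-center offset ≤ 0.4° where RF
maps exist, per-stimulus drive at the ~1° size, minimum surround
suppression (15%) for image-level inclusion, and a minimum number of
significantly driven stimuli. Every firing rule is logged.

Per-condition statistics use the unbiased (n−1) variance; FF is flagged
undefined at zero mean. Across conditions, spike counts are averaged
arithmetically and FFs geometrically (zero/undefined FFs excluded with a
count). Size contrasts use the symmetric percent change
100·(FF_α − FF_β)/((FF_α+FF_β)/2), with sizes matched to ½·RF, RF and 2·RF
targets by smallest absolute log-ratio (the size series is multiplicative).
Mean matching bins cases by mean count (integer-width bins by default,
counts being integers), draws min(n_A, n_B) cases per bin from each group
without replacement — the matched histograms are identical by construction
and hard-asserted — and compares FFs with a one-sided paired t test of the
null that the difference has mean ≤ 0, pairing within bins. Two conditions
are called significantly different when their 68% bootstrap CIs are
disjoint; touching endpoints count as overlapping.

## Synthetic recordings

The generator emits gain-modulated Poisson trains: per trial a mean-1 gamma
gain with condition-specific CV multiplies the evoked rate, which replaces
the baseline rate from the programmed latency for the stimulus duration.
The evoked-window count then has FF = 1 + mean·CV² exactly (law of total
variance), giving every fixture an analytic ground truth;
`make_size_tuning_fixture` inverts this to hit target mean/FF series. The
family cannot express FF < 1; sub-Poisson fixtures would need a different
count model (not implemented). Neurons are independent; no oscillations,
adaptation or latency jitter are modeled, so pipeline tests validate the
estimators, not the realism of cortical dynamics.

## Numerical and design choices

- Problem sizes: experiments use 400 posterior samples per stimulus; model
  training uses 10,000 patches; recovery tests use 2,000 trials per
  condition, at which the FF estimator's sampling error (≈3% relative) sits
  comfortably inside the 5% recovery band on average — the worst of five
  conditions occasionally touches ~6%.
- Grid posterior: log-spacing matches the Rayleigh prior's dynamic range;
  trapezoid masses double as categorical sampling weights.
- PD repairs (eigenvalue floors), half-open windows, closed-interval CI
  overlap, and log-scale size matching are all pinned and tested explicitly,
  since each is a convention rather than a derived quantity.
- Known limitations: the surrogate ensembles carry no oriented structure;
  the quantitative magnitude of surround FF suppression in the model is much
  larger than in cortex (the model's only uncertainty sources are the mixer
  and the observation noise); and no fitting of GSM parameters to neural
  data is attempted.
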