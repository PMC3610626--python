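# Methods

`strflearn` studies how two population coding objectives — *sustained firing*
and *population sparsity* — shape ensembles of auditory spectro-temporal
receptive fields (STRFs) learned from natural-sound-like stimuli. This note
documents the model, the synthetic-data generators, the numerical choices,
and the limits of what the test suite demonstrates.

## Model

An STRF is a linear kernel `h(t, f)` mapping a spectro-temporal stimulus
patch to an instantaneous firing rate: stacking 250-ms patches of the
auditory spectrogram into vectors `x_t` (D = 50 frames x 60 channels = 3000)
and filters into a matrix `H`, the ensemble response is `y_t = H^T x_t`.

Two objectives are maximized over ensembles of K filters:

* **Sustained firing.** `Psi_s = sum_i sum_{n=1..N} w_n < y_i^2(t) y_i^2(t-n) >_t`
  rewards response energies that are correlated over a lag horizon N (the
  *correlation interval*, 10–2000 ms in the study grid). Lag weights decay
  linearly, `w_n = (N - n + 1)/N`: recent activity influences the present
  more than the distant past. The overall weight scale does not change the
  maximizer. Lag averages run over `t in [n+1, T]` for each lag.
* **Population sparsity.** `Psi_k = < mu4(t) / sigma^4(t) >_t`, the raw
  (non-excess) kurtosis of the instantaneous population response
  distribution, averaged over time. Raw rather than excess kurtosis: the −3
  shift is a constant and cannot move the argmax. Time points with
  numerically zero population variance (< 1e-12) are skipped with a warning.
  Note that for K = 3 neurons the sample kurtosis of a mean-centered
  population is identically 1.5, so the objective is uninformative below
  K = 4; it only becomes a reliable source-separation contrast for
  moderately large populations (we verified that at K = 8 a rotated basis
  can genuinely outscore the true sparse sources, while at K = 24 the
  sources win).

**Constraints.** Redundancy is controlled in one of two ways:

* *response* constraints: responses have unit variance and are mutually
  uncorrelated. Writing the patch covariance as `C = E L E^T`, this is
  equivalent to `B^T B = I` for `B = L^{1/2} E^T H` acting on whitened data
  `Z = L^{-1/2} E^T X`. Dimensionality is reduced to the M leading principal
  components capturing 95% of the variance (M is always data-driven, never
  hard-coded). The sample covariance uses 1/T normalization, matching the
  sample-average convention; at T ~ 10^4 the distinction from 1/(T−1) is
  immaterial.
* *shape* constraints: the filters themselves form an orthonormal basis in
  raw patch coordinates (`H^T H = I`); no whitening is involved.

**Optimization** is Rosen's gradient projection on the Stiefel manifold:
`B <- P(B + mu 2^{-k} grad Psi(B))` where `P(A) = A (A^T A)^{-1/2} = U V^T`
is the orthogonal Procrustes projection (nearest orthonormal-column matrix
in Frobenius norm, from the thin SVD). The halving counter k starts at 0
each outer iteration and increments while the candidate would decrease the
objective; iteration stops when the relative objective change falls below
`tol` (default 1e-4, exposed in config), after `max_iter` iterations
(default 30), or when halving is exhausted (k > 50). The initial ensemble
is seeded zero-mean unit-variance Gaussian noise, projected so iteration 0
is feasible. The halving counter resets each outer iteration (a design
choice; persisting it across iterations is an equally defensible variant).
Note that `P` is scale-invariant, so `mu` mainly matters when the gradient
is small relative to `B`; the default 1.0 is adequate. Analytic gradients
of both objectives (derived by the chain rule through `Y = B^T Z`; for the
kurtosis objective, the quotient rule over the per-time population moments)
are validated against central finite differences.

For recovery *experiments* (planted-subspace fixtures) we run the optimizer
to tighter tolerances (`max_iter` 300–500, `tol` 1e-7–1e-8): from a random
start, 30 iterations demonstrably under-converges, and the default budget
is only intended for the large-scale ensemble runs where each iteration is
expensive.

## Peripheral model

The front-end maps an 8 kHz mono waveform to an auditory spectrogram on a
six-octave tonotopic axis (62.5–4000 Hz, 10 channels/octave, f_c =
62.5·2^(c/10)). Stages: constant-Q 2nd-order Butterworth bandpass filters
with band edges at the half-channel spacing (adjacent filters cross near
−3 dB); half-wave rectification; lateral inhibition as a first difference
toward higher channels followed by rectification; 5-ms mean integration.
This is a deliberate simplification of full cochlear models: hair-cell
membrane nonlinearities and phase-locking dynamics are replaced by
rectification + short-term integration, because downstream analysis treats
the front-end purely as a fixed time-frequency representation with stated
axes and sampling. All stages are positively homogeneous, so input scaling
passes through linearly; an optional cube-root compression is off by
default (patches are later mean-removed and unit-normed, which largely
removes sensitivity to static compression). Filter Q and the inhibition
kernel are not dictated by the modeled physiology at this level of
abstraction; both are fixed by the defaults above and exposed in the
filterbank designer.

## Synthetic stimuli

The generators stand in for a natural corpus (speech + animal vocalizations
+ ambient noise) that is not redistributable. What matters for the learning
objectives is the *joint modulation spectrum* of the stimulus — natural
sound ensembles concentrate energy at slow temporal rates (< ~20 Hz) and
low spectral scales (< ~1 cyc/oct) — so the surrogates control modulation
content explicitly:

* **speech-like**: harmonic stacks with slowly drifting pitch (100–250 Hz),
  Gaussian formant resonances, and 3–8 Hz amplitude modulation (syllabic
  rate);
* **vocalization-like**: mixtures of 2–3 drifting ripples (rates 2–32 Hz,
  scales 0.25–2 cyc/oct, random direction), emulating oriented FM sweeps;
* **ambient-like**: narrowband carriers amplitude-modulated by a random
  spectrogram envelope low-pass filtered in 2D (rate cutoff 4–16 Hz, scale
  cutoff 0.5–2 cyc/oct).

Segments of 3 s are standardized to zero mean / unit variance, tapered with
a 50-ms raised cosine per edge (long enough to remove onset transients
without eating the segment interior), and concatenated in seeded random
order at fractions 0.5 / 0.25 / 0.25. All generators are deterministic
under a fixed seed. The generated ensembles satisfy the natural-statistics
property the objectives assume (>= 60% of modulation energy below 20 Hz and
1 cyc/oct), which the suite asserts.

What the surrogates do *not* emulate: phonetic structure, harmonicity
statistics of specific species, long-range temporal dependencies across
segments, or recording-channel effects. Passing tests therefore demonstrate
that the learning and characterization machinery behaves correctly on
stimuli with natural-sound-like modulation statistics — not that the exact
ensemble compositions reported for real corpora would be reproduced.

## Recovery fixtures

* **Slow subspace** (`gen_slow_latent_patches`): columns `x_t = A s_t` with
  orthonormal mixing. Slow sources are Rademacher carriers modulated by a
  smooth positive envelope (Gaussian-smoothed noise, sigma = 10 frames,
  giving lag-1 energy autocorrelation ~0.99 > the 0.9 contract); fast
  sources are white Gaussian. The default recovery experiment uses D = 20,
  4 slow + 16 fast sources, T = 30000 columns — the patch count of the
  full-scale study. At much smaller T, sampling flukes create genuine
  in-sample local maxima (an empirically "lucky" fast direction) that trap
  a filter; at the study-scale T the planted subspace is recovered to a few
  degrees across seeds.
* **Sparse sources** (`gen_sparse_latent_patches`): orthonormally mixed
  unit-variance Laplacian sources, D = K = 24, T = 15000. The population
  size follows from the population-kurtosis statistic itself (see above).

## STRF characterization

* **Separability index** `SPI = 1 − sigma_1^2 / sum sigma_k^2` from the
  patch SVD; 0 for time x frequency separable (rank-1) STRFs, large for
  noisy ones.
* **MTF**: magnitude of the 2D Fourier transform after zeroing entries
  within ±1 SD of zero (SD over the full patch including zeros — a
  convention, fixed here and exposed as a parameter). The plane is
  collapsed to scale >= 0 with signed rate; with 50 x 60 patches the axes
  step 4 Hz and 1/6 cyc/oct. Nyquist rows/columns (−100 Hz, 5 cyc/oct) are
  discarded: they have no conjugate partner inside the retained half-plane
  and would spuriously break the quadrant symmetry that makes the
  directionality of separable patches exactly zero.
* **Best rate / best scale**: the MTF magnitude peak, excluding the DC bin
  (a DC "peak" would make BR/BS meaningless); ties break toward slower
  modulations.
* **Profiles and 6-dB cutoffs**: the rate profile folds ±rate together and
  sums over scale; the scale profile sums over signed rate; both are
  peak-normalized. The upper 6-dB cutoff is the highest frequency above the
  peak where the profile crosses the −6 dB *amplitude* level
  (10^(−6/20) ≈ 0.501), linearly interpolated between bins; a power
  convention is exposed as an option.
* **Directionality** `DSI = (R1 − R2)/(R1 + R2)` over quadrant energies
  (squared magnitudes) with rate > 0, scale > 0 vs rate < 0, scale > 0.
  With patches oriented time-rightward / frequency-upward, positive DSI
  marks downward-moving preference. For separable patches DSI vanishes
  identically *on the patch's own MTF*; ±1 SD thresholding slightly breaks
  separability (residual DSI ~1e-3), which is why the exactness property is
  stated for the unthresholded transform.
* **Compactness**: a single 2D Gaussian envelope is least-squares fit to
  the magnitude of the thresholded patch (Levenberg–Marquardt, initialized
  from image moments, inverse covariance parameterized by its Cholesky
  factor to stay positive definite). The isoline 10 dB (amplitude) below
  the envelope maximum is an ellipse with semi-axes `rho·sqrt(lambda_i)`,
  `rho^2 = ln 10`; the isoperimetric quotient `q = 4 pi A / P^2` uses
  Ramanujan's perimeter approximation. q = 1 for circular regions; fit
  failures yield NaN with a warning.

## Ensemble analyses

Activation events are maximal runs with |y_i(t)| above one per-neuron
temporal SD (the two-sided reading of "±1 SD"; a one-sided mode is exposed).
Durations are multiples of the 5-ms frame; the "most persistent" subset is
the top ceil(0.1 K) neurons by median event duration. Population response
histograms use 101 uniform bins on [−6, 6] (fixed for comparability across
ensembles), values clipped into range so masses sum to one; comparison
ensembles (principal components, random filters) are rescaled to unit
temporal variance first. The stimulus modulation profile averages |FFT2|
over non-overlapping 250-ms spectrogram patches on the same axes as the
MTFs. Nearest-neighbor similarity distributions are compared with the
symmetric KL divergence in nats (additive smoothing 1e-6, 20 bins on
[0, 1]); when no explicit reference set is supplied, each ensemble is
scored against the other, which makes the comparison symmetric and
identically zero for identical ensembles.

## Clustering

STRF similarity is the maximum absolute normalized 2D cross-correlation
over all zero-padded shifts, with *global* unit-Frobenius pre-normalization
(the alternative — per-overlap normalization — can exceed 1 and rewards
large shifts; the global choice keeps s in [0, 1] and mildly penalizes
them, which suits grouping whole-pattern lookalikes). Spectral clustering
takes the eigenvectors of the normalized affinity `D^{-1/2} W D^{-1/2}`
for the k largest eigenvalues (equivalent, in ordering, to the smallest
eigenvalues of the normalized Laplacian), row-normalizes them, and runs
seeded k-means with 20 restarts. Merging: clusters ranked by mean SPI
descending are absorbed into one *noisy* class while the next cluster's own
mean exceeds 0.5 (its pooled mean then necessarily also exceeds the
threshold — this is the stopping rule that reproduces the canonical
12 → 2 merges → 9 classes outcome); among the remaining clusters the same
rule with mean compactness > 0.69 forms one *localized* class. The merge is
idempotent and a no-op when no cluster exceeds a threshold. Class diversity
is summarized by the Shannon entropy (bits) of the class distribution.

## Scale of the shipped experiments

The orchestrated reduced-scale study uses a 60-s training stimulus, a 30-s
held-out stimulus, K = 100 filters, the 95% whitening target, and 30
optimizer iterations for ensemble runs; this keeps a full pipeline run in
the minutes range on one core while preserving every qualitative contrast
of interest (structured vs noisy filters across objectives, activation
persistence across correlation intervals, leptokurtic population
histograms, and the response-vs-shape modulation coverage contrast).
Full-scale settings (3-minute stimulus, K = 400) are a config change.

Two caveats at this scale. First, the sustained-vs-sparse contrast in the
*fraction* of structured (low-SPI or high-compactness) filters is noisy
across stimulus/initialization seeds: kurtosis maximization also produces
highly localized (hence compact) filters when it converges, and at some
seeds the sparse ensemble's localized subset outnumbers the sustained
ensemble's structured subset. Second, reduced-scale ensembles are noisier
overall than full-scale ones (mean SPI ~0.6–0.8 rather than ~0.26), so the
noisy-cluster merge can absorb most or all clusters; the initial
(pre-merge) class entropy is reported alongside the merged one. The
response-vs-shape modulation comparison follows the full-scale procedure of
restricting to the STRFs that contribute 99% of the sustained objective —
in shape mode only a handful of filters (which coincide with the leading
principal components) carry the objective, and the remainder never leave
their random initialization.

## Known limitations

* The front-end is a deliberately minimal peripheral model; absolute
  channel gains and low-channel ringing differ from full cochlear models.
* Population kurtosis is uninformative for very small ensembles (see
  above); sparse-recovery claims hold for K >~ 20.
* The compactness fit assumes a single dominant excitatory blob; multi-lobe
  STRFs yield envelope fits that summarize only the overall extent.
* Clustering at desk scale (a few hundred STRFs) yields coarser classes
  than the full-scale study; entropy values are comparable only within a
  run.
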