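# Methods

This note documents the models, estimators and numerical choices behind
`songlearn`, and what the synthetic-data validation does and does not
establish about real recordings.

## The generative song model

A tutor **motif** is an ordered tuple of syllable templates. Each template
is parameterized by duration (ms), fundamental frequency (Hz), number of
harmonics, broadband-noise energy fraction (`noise_mix`, which controls
Wiener entropy), a linear frequency sweep (`fm_sweep_hz`; 0 marks a flat
harmonic stack eligible for constant-fundamental analysis), and amplitude.
`make_tutor_template` lays parameters out on permuted grids (duration
60–180 ms, fundamental 450–1050 Hz, noise mix 0–0.4, sweeps ±200 Hz on
odd positions) so types are mutually separated in feature space and
downstream clustering is well-posed; motif length defaults to a uniform
draw from 5–8, the species-typical range.

A **pupil model** perturbs renditions in two ways:

1. *Sequence noise*, applied in the fixed order omission → adjacent swap →
   immediate repetition → suffix truncation. Each stage is an independent
   Bernoulli event per syllable (or per rendition for truncation, with a
   uniformly drawn cut point). The order matters and is part of the model
   definition; it is threaded through a single per-bird RNG substream
   spawned from the global seed, so corpora are byte-identical across runs.
2. *Feature noise*, multiplicative Gaussian: realized value =
   template × (1 + ε), ε ~ N(0, CV<sub>eff</sub>), where CV<sub>eff</sub>
   multiplies the per-(feature, context) CV, the age-schedule multiplier,
   and — in the directed-song (DS) context — the `ds_variance_scale`.
   Multiplicative noise is used because vocal variability is conventionally
   reported as a coefficient of variation, and under this model the
   programmed CV *is* the expected measured CV. A scale of 0.5 makes DS
   noise half as large as undirected-song (UDS) noise, so the measured
   UDS/DS CV ratio converges to 1/scale = 2.

Waveforms are synthesized as sums of `n_harmonics` sinusoids with 1/k
amplitude roll-off (phase-integrated so sweeps are exact), mixed with unit
RMS Gaussian noise at the `noise_mix` energy fraction, windowed by 5 ms
raised-cosine ramps to avoid spectral splatter, and written as 16-bit PCM
mono WAV (default 44.1 kHz; tests and the acceptance study use 22.05 kHz,
which still leaves every harmonic below half the Nyquist margin). The
synthesizer makes no attempt at realistic vocal-tract acoustics; its only
job is controllable ground truth for the DSP stages.

Per-rendition timestamps are spread evenly over 06:00–14:00 and encoded in
ISO-8601 filenames so the amount-of-singing window (default 08:00–12:00,
half-open) has both included and excluded files.

## Frame features and segmentation

Frames are 9 ms with a 1.5 ms step and Hann window, FFT zero-padded to the
next power of two, DC excluded. Choices worth recording:

- **Wiener entropy** = ln(geometric mean / arithmetic mean) of the power
  spectrum, ≤ 0, exactly 0 for a flat spectrum. It is computed on the
  *band-averaged* spectrum (16 equal bands): single-frame periodogram bins
  are exponentially distributed, which would bias white noise to
  E[ln gm/am] = −γ ≈ −0.58; averaging 16 bins reduces the bias to
  ψ(16) − ln 16 ≈ −0.03, restoring the "noise ≈ 0" contract. The spectrum
  is sum-normalized first with a relative floor, so the statistic is
  exactly invariant to global amplitude scaling.
- **Pitch** is the parabolically interpolated peak of the frame
  autocorrelation (computed via FFT with sufficient padding to avoid
  circular wrap) in a 300–3,000 Hz search band; **goodness of pitch** is
  the normalized peak height, and frames with goodness < 0.25 are unvoiced
  and carry a missing pitch. The Hann window skews the autocorrelation
  peak slightly toward shorter lags, giving a small (~0.3 %) upward pitch
  bias — inside the 1 % accuracy the pipeline promises, but worth knowing.
- **Frequency modulation** is |Δ spectral centroid| per frame step (Hz/s).
- **Segmentation**: frames are active when amplitude exceeds the noise
  floor + 20 dB; the floor defaults to the 10th percentile of frame
  amplitudes (a median would land on song frames when a clip is mostly
  song). Gaps < 10 ms merge; runs < 10 ms drop. Because a frame is active
  whenever its 9 ms window overlaps any sound, boundaries are compensated
  for the frame span; on noiseless synthetic corpora detected boundaries
  match ground truth to within one frame step.

## Per-syllable summaries and cFF

Syllable features are arithmetic means of the frames inside the
annotation; pitch uses the median over voiced frames, which is robust to
the one or two edge frames whose window straddles a boundary. The
constant-fundamental-frequency (cFF) rule — maximal voiced windows with
pitch SD/mean ≤ 1 % lasting ≥ 30 ms, returning the qualifying segment with
the **lowest** mean fundamental — is an automatic surrogate for a
manually marked harmonic-stack segment; both thresholds are configurable,
and on synthetic stacks the rule recovers the programmed fundamental
within 1 % for noise mixes up to ~0.3.

## Typing and omissions

Clustering is k-means on z-scored (duration, mean frequency, Wiener
entropy, goodness of pitch, frequency modulation) with a fixed seed; with
`k="auto"` the silhouette criterion picks k in 2..10, and a best
silhouette below 0.5 declares a single type (the silhouette is undefined
at k = 1, so a quality floor stands in). Cluster labels are ordered by
mean frequency for stability, and a manual-override table reproduces
hand-correction. Pupil and tutor types are matched by solving the
rectangular assignment problem on centroid distances in the tutor's
standardized space, gated by a maximum distance; unmatched tutor types are
candidate omissions, unmatched pupil types improvisations. Motif
statistics (mean syllables per motif) are computed over complete motifs
only — for synthetic data the generator's ground truth delimits motifs;
for real audio a motif is the template's maximal match within a bout,
which is documented but outside the validated surface.

## Transition entropy

The per-type entropy uses the standard Shannon sign, Entropy_t =
−Σ p log p (natural log; a base-2 switch exists), so scores are
nonnegative and "higher entropy = lower stereotypy" reads correctly.
The overall score is the sum of weighted per-type entropies
Σ_t (row_sum_t / total) · Entropy_t — a weight-weighted average over
types; the unweighted mean of the per-type entropies is also emitted for
reference. Transitions never cross file/bout boundaries; zero-count rows
carry zero entropy and zero weight rather than being normalized. The
implementation is tested for exact (1e−12) agreement with a brute-force
oracle that enumerates adjacent pairs directly.

## Motif similarity and accuracy

Similarity-scoring internals of the established interactive software are
proprietary, so the package defines its own documented score: frames are
z-scored against a reference corpus (unvoiced pitch imputed as 0 before
scaling), each vocalized pupil frame takes its minimum Euclidean distance
to tutor frames within ±50 ms, and the score is 100 × the fraction of
pupil frames under a threshold calibrated as the 5th percentile of
nearest-frame distances between unrelated synthetic songs. Only frames
within 30 dB of the clip's loudest frame participate — silent gap frames
would otherwise match each other across unrelated songs and inflate the
floor. The comparison is asymmetric (pupil against tutor), so omitted or
replaced content, and the timing shifts it causes, lower the matched
fraction; scores on this scale are internally consistent but not
numerically comparable to any other software's similarity scores.
Aggregation: mean of all pairwise scores for the motif similarity, mean of
the ceil(0.05 n) highest for the maximum similarity (exactly the 10 best
of the standard 20 × 10 = 200 design). Syllable accuracy is the local,
time-aligned analogue: pupil frames are compared to the tutor frame at the
same relative position within the matched syllable, averaged over
renditions and then over the motif's types. Percent differences divide
(pupil − tutor) by the tutor value after averaging each side's renditions,
then average over types with equal weight.

## Variability, context modulation, statistics, qPCR

CVs use the sample SD (n−1). The per-bird summary averages syllable types
with equal weight. The pipeline-level minimum renditions per CV cell is
10 (configurable; typical experimental practice uses 20–40, and the
acceptance study uses 40 per context). The UDS/DS ratio is computed per
syllable type present in both contexts and averaged per bird; under the
multiplicative noise model it estimates 1/`ds_variance_scale` with < 5 %
bias at 40 renditions. Group comparisons are thin wrappers over scipy's
Mann-Whitney U (exact null for n ≤ 8 without ties, tie-corrected normal
approximation otherwise, no continuity correction so identical groups give
p = 1) and paired t. Multiple tests are reported without correction, as is
conventional for these analyses; a Holm adjustment is available to users
via statsmodels/scipy if desired. The comparative-Ct method averages
technical replicates, forms ΔCt against the within-sample reference gene,
ΔΔCt against the control group's mean ΔCt, and reports fold = 2^−ΔΔCt
with group mean ± SEM; amplification-efficiency corrections are out of
scope.

## The two-cohort study

`songlearn.study` fixes the synthetic study conditions: 6 birds per
cohort, each with its own tutor motif, 40 renditions per context at age
100 d. Control-like pupils: no omissions, 2 % stutter, 5 % truncation,
1 % order switching, duration CV 3 %, fundamental CV 1.2 %, DS variance
scale 0.5. Perturbed-like pupils: one mid-motif syllable always omitted,
15 % stutter, 20 % truncation, 15 % order switching, duration CV 10 %,
fundamental CV 3.5 %, DS variance scale 1. Quantitative distributions of
sequence noise in impaired learners are not available, so these magnitudes
are the generator's free parameters, chosen once to be behaviourally
plausible (a clearly impaired but still singing bird). Entropy, CVs, omissions and the context
ratio are computed from the generator's ground-truth annotation tables
(the same analysis code paths as for segmented audio); similarity
synthesizes audio for 10 pupil × 5 tutor renditions per bird at 22.05 kHz
with a 3 ms frame step — a scaled-down version of the 20 × 10 design with
identical aggregation rules, sized so the whole study runs in seconds.

## What the synthetic validation does and does not show

Passing tests establish that the estimators recover the generative model's
parameters and reproduce the canonical direction of effects (higher
entropy, higher CVs, lower similarity, omissions, abolished context
modulation in the perturbed cohort, all at Mann-Whitney p < 0.05 with 6
birds per group). They do not establish performance on real colony
recordings: the generator has no cage noise, calls, overlapping birds,
amplitude-modulated or biphonic syllables, and its feature distributions
are cleanly separated Gaussians. Segmentation thresholds, the cFF
tolerance, the similarity threshold calibration and the silhouette floor
would all need re-tuning on real data, and the similarity scale is not
transferable to other software's scores.

## Known limitations

- The amplitude segmenter assumes a clip whose quiet frames are genuine
  silence; it is not noise-robust.
- Pitch estimation targets harmonic stacks in 300–3,000 Hz; noisy or
  high-pitched syllables are left unvoiced by design.
- The asymmetric similarity rewards truncated-but-accurate renditions in
  the maximum-score statistic; compare complete motifs when that statistic
  matters.
- Omission counting at the cohort level uses complete absence from the
  corpus; partial (probabilistic) omission is visible in the per-type
  match distances but not counted as omission.
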