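# Methods

`cohfo` implements an analysis chain for coincident bursts of high-frequency
oscillations (HFOs, 60–500 Hz) in multichannel intracranial EEG recorded
during verbal memory tasks, together with a synthetic data generator that
makes every stage testable by parameter recovery.  This note documents the
models, the parameters that matter, the numerical choices, and the known
limitations — including what the synthetic validation does and does not say
about real recordings.

## Burst detection

Each (optionally bipolar-re-referenced) channel is decomposed into **38
logarithmically spaced band-pass filters** spanning 60–800 Hz (39 log-spaced
edge frequencies, contiguous passbands).  Filters are windowed-sinc FIRs; the
stated 200-ms transition band is realized as a transition bandwidth of
1/0.200 s = 5 Hz with a Hamming-window order of about 3.3·fs/5 Hz.
Zero-phase filtering applies the squared magnitude response |H(f)|² in the
frequency domain — the exact circular equivalent of forward–backward FIR
filtering — so the −6 dB single-pass point at each band edge becomes −12 dB
for the two-pass response.  The analytic signal of each band is obtained from
the same FFT, giving the band waveform (real part) and its Hilbert envelope
(magnitude) in one inverse transform per band.

Envelopes are normalized by a **sliding z-score** with mean and SD over a
centred 10-s window, truncated (not padded) at the recording edges; a
relative floor on the local SD absorbs floating-point residue on
near-constant input, and zero-SD samples get z = 0.

Detection is dual-threshold:

1. **Candidates**: maximal runs with z > 2 lasting at least 3 cycles of the
   band centre frequency (geometric mean of the band edges).
2. **Cross-band merge**: candidates that overlap in time *and* lie in the
   same or adjacent bands merge transitively into one event.  Restricting
   direct links to adjacent bands is deliberate: at the 2-SD candidate
   threshold roughly one band is above threshold by chance at any instant,
   and unrestricted merging lets an unrelated distant-band excursion join
   the event and win the dominant-band vote, corrupting the dominant
   frequency and the peak time.  A burst whose energy occupies a contiguous
   run of bands still merges fully; `band_gap=None` restores unrestricted
   merging.
3. **Event acceptance**: peak z > 3 in the dominant band (the member band
   with the highest z), duration of at least 4 cycles at the dominant
   frequency, and a **cycle verification**: at least one full oscillation
   cycle of the dominant-band waveform — two consecutive same-direction zero
   crossings — lying entirely inside the z > 3 region.  Events with dominant
   frequency above 600 Hz are excluded from analysis by default
   (configurable), matching the convention of detecting up to 800 Hz but
   analysing 60–600 Hz.
4. **Spectral specificity**: k-means (k = 2, ten restarts, fixed seed) on
   the 1-D event frequency spans; the larger-centroid cluster is labelled
   spectrally diffuse and rejected.  Rejection is guarded: it requires (a)
   centroid separation of at least 2×, (b) a wide-cluster centroid of at
   least 150 Hz — "diffuse" is an absolute property of broadband transients,
   and a legitimate 6-cycle burst spans only a few tens of Hz of adjacent
   bands — and (c) the diffuse cluster being a minority.  Without these
   guards the filter discards about half of any homogeneous event
   population, or the genuine bursts themselves on an artifact-free
   background.

**Noise floor.**  At the 2/3-SD thresholds the detector is intentionally
liberal, and this has a quantifiable consequence on featureless noise: the
Hilbert envelope of a narrowband (Q ≈ 14) Gaussian process is
Rayleigh-distributed and stays above mean + 3 SD for several cycles at a
time (measured median ≈ 7.6 cycles), so pure 1/f noise yields roughly 3–6
events/s/channel after the full chain, most of them in the upper bands
(excursion rate scales with bandwidth).  A tail-probability estimate shows
the peak threshold would need to be ≈ 5.5 SD to silence Gaussian noise; at
3 SD the noise floor is irreducible.  This floor is of the same order as
baseline burst rates reported for real recordings at comparable thresholds
(≈ 0.8/s/channel in 60–250 Hz), which is why downstream analyses rely on
task-locked modulation and cross-channel coincidence rather than on the
detector being noise-free.  The acceptance suite reports the burst-free
false-detection rate honestly; it does not meet a near-zero bound, by the
physics above.

Burst SNR is expressed relative to the RMS of the background restricted to
the full 60–800 Hz detection range.  A 6-cycle Hann burst has a spectral
mainlobe of ~4/T ≈ 80 Hz, so any single ~8-Hz analysis band passes only
~10–20 % of its amplitude; quoting SNR against a single narrow band would
make nominally "6×" bursts undetectable by construction.

## Coincidence analysis

Detected bursts are reduced to points at their envelope peak and binned into
binary channels × bins rasters (10-ms bins, ±1.5 s around task-event onsets,
half-open bins; trials truncated by a recording edge are excluded).  An HFO
in channel i, bin t is a **co-HFO** when any other channel has an HFO within
±5 bins (±50 ms); each channel–bin is counted at most once regardless of the
number of partners.  The implementation uses windowed channel sums; tests
pin it to an exhaustive pair × lag scan.

Channels are classified by the **maximum off-diagonal Pearson correlation**
of their session-concatenated peri-event rasters: correlated if r > 0.5
(sensitivity settings 0.3 / 0.7), sorted descending with lexicographic
label tie-breaks.  Per-bin co-HFO counts are computed on the full raster and
summed within each class, averaged over trials within subject, averaged
across subjects, rescaled to per-second rates (×100 for 10-ms bins), and
normalized so each full trace sums to one.  Both the normalized probability
and the per-second display vector are emitted, since either ordering of
scaling and normalization yields the same normalized vector.

## Sequence clustering and controls

Channel similarity is 1 − r on the binarized rasters (constant channels are
flagged and put at distance 1); clustering is agglomerative with unweighted
average linkage (UPGMA), with the merge sequence validated against
brute-force enumeration in tests.  Flat labels default to the cluster count
in 2…min(10, n−1) that maximizes the mean silhouette on the precomputed
distances (a cut by count or height is available); the merge tree serializes
to Newick with branch lengths from merge heights.

Two controls assess whether modular structure is genuine:

- **Temporal jitter surrogate**: each burst time is shifted by an
  independent draw — magnitude uniform on [50, 100] ms, equiprobable sign —
  preserving per-channel counts exactly and reflecting at recording
  boundaries.  Synchrony, the mean pairwise Pearson correlation over
  non-degenerate channel pairs (reported unclipped, so slightly negative
  values are possible), drops sharply for genuinely co-bursting rasters.
- **Bootstrap stability**: per trial (per word), channels are resampled
  with replacement, the resampled raster re-clustered, and the Adjusted
  Rand Index computed between the original and replicate labels restricted
  to the unique channels present (replicates with fewer than two unique
  channels are redrawn); ARIs are summarized per trial and averaged across
  trials.  The across-trial average is essential for the noise baseline:
  a single noise raster can bootstrap to a spuriously reproducible
  singleton split, while the average over independent rasters concentrates
  near zero.

## Statistics

A Shapiro–Wilk gate (α = 0.05) selects parametric (ANOVA / t) versus
nonparametric (Kruskal–Wallis / Wilcoxon) families; constant or tiny samples
default to nonparametric with a flag.  Time-resolved contrasts are tested
independently at each 10-ms bin with the linear mixed model
`value ~ condition + (1 | subject)` fitted by REML (statsmodels MixedLM);
the omnibus p-value is a Wald test on the condition coefficients, pairwise
contrasts come from rotating the condition reference level, and singular or
failed fits fall back to a flagged fixed-effects-only OLS fit.
Benjamini–Hochberg FDR is applied across the bins of each contrast
separately.  Cohen's d uses the pooled-SD definition with a
normal-approximation 95 % CI (variance (n₁+n₂)/(n₁n₂) + d²/2(n₁+n₂)).
Family-wise permutation correction uses the max-|t| null over the statistic
map (label permutation, corrected p = rank of the observed statistic against
the null maxima, with the +1 convention).

Calibration is verified by simulation: pooled null omnibus p-values are
uniform (KS test), and bins with a planted 3-residual-SD condition effect
are recovered after FDR.  The calibration runs use 20 simulated subjects ×
4 conditions with 5–15 bins per replicate and 50–200 replicates — enough
fits to pin the null distribution while keeping the default validation run
in minutes.

## Anatomy

Channels arrive with atlas region labels already assigned; a configurable
label→lobe table (a default ships with the package) groups them into
occipital, parietal, temporal, frontal and limbic lobes, the limbic set
being hippocampus, amygdala, posterior cingulate and parahippocampal
cortex.  Unknown regions are excluded as `unassigned` with a count.  Spatial
extent of correlated co-bursting is summarized by pairwise Euclidean
distances in MNI mm (10-mm histogram bins, 0–200 mm); per-lobe correlated
proportions are complements summing to one per subject and lobe; per-channel
word engagement is the fraction of a subject's word pool in which the
channel participated in the correlated class, normalizable by implanted
channel count.  A gray-matter-only rerun is a single filter flag.

## Synthetic data generator

The generator emulates the statistical structure of the study recordings:

- **Background**: 1/f^α noise (α = 1 by default) by spectral shaping of
  white Gaussian noise, rescaled per channel to an exact RMS (20 µV
  default); fs = 5000 Hz default.
- **Task schedule** per list: 5-s countdown (five 1-s digits), twelve words
  shown 1.5 s with 1.0-s inter-stimulus interval, 20-s arithmetic
  distractor, 30-s free recall.  Words are recalled with probability 0.3
  (matching ≈30 % recall accuracy); recall-vocalization onsets are drawn
  uniformly in the recall block with a minimum separation of 1.5 s — the
  real inter-recall-interval distribution is unknown, so this is a
  stand-in, not an estimate.  A cued (paired-associate) variant encodes six
  pairs and emits CUE events.
- **Bursts**: sinusoids under a raised-cosine (Hann) envelope, ≥ 4 cycles
  (default 6), frequency uniform in a configurable range, amplitude set by
  the SNR convention above (default 6×).  The smooth envelope avoids filter
  ringing artifacts in detection tests.
- **Rates**: an inhomogeneous Poisson process per channel (baseline 0.8
  bursts/s/channel), thinned against a numerically bounded gain profile:
  ×`encode_gain` during word display, a Gaussian recall-onset bump
  (`recall_peak_gain`, SD 75 ms — FWHM ≈ 175 ms, a sharp onset peak), and a
  Gaussian pre-recall trough (`pre_recall_dip_gain`, centred 1 s before
  onset, SD 200 ms).
- **Coincidence groups**: member channels share group event times with
  Gaussian jitter (default SD 2 ms) and participation probability; members
  receive complementary independent background so the per-channel rate
  stays at baseline.  The sub-bin jitter default is what makes group
  members exceed the r > 0.5 classification on 10-ms rasters, as correlated
  channels do in real data; the ±50-ms coincidence window tolerates much
  coarser alignment.
- **Reproducibility**: one child RNG stream per subject from the master
  seed, with separate noise and event streams, so the background signal is
  bit-identical with and without bursts and the injected-burst sum is
  exactly recoverable.
- Every injected burst is recorded in a ground-truth table (channel, time,
  frequency, cycles, amplitude, phase, group id) for parameter-recovery
  tests.  A synthetic channel table (fabricated MNI coordinates along
  electrode shafts, regions drawn from the default lobe map, tissue labels)
  feeds the anatomy stage.

**What passing tests show — and what they do not.**  The generator produces
Gaussian backgrounds, stationary rates outside the programmed modulations,
and bursts with clean envelopes.  Recovery on this substrate validates the
algorithmic chain (binning, counting, classification, clustering,
statistics) and the detector's behaviour at known SNR; it does not certify
detector performance on real iEEG, which contains epileptiform transients,
line noise, movement artifacts and non-stationary spectra that the
generator deliberately omits.

## Problem sizes of the standing validation

The default validation runs at desk scale: detector recovery on 8 channels
× 120 s at 5000 Hz with 50 injected bursts; profile recovery on 4 subjects
× 10 lists × 12 channels of event-level simulation (≈10 runs); jitter
control on 20 paired runs; stability on 8 planted and 8 noise rasters × 100
bootstrap replicates; statistical calibration as above.  These sizes were
chosen so the complete validation recomputes in a few minutes while leaving
the recovered quantities stable across seeds.

## Known limitations

- The cycle-verification sentence of the detection procedure admits several
  readings; the implemented rule (one full cycle of the dominant-band
  waveform inside the z > 3 region) is one of them, and the candidate-stage
  cycle criterion uses the band centre frequency.
- The noise floor at the published thresholds is irreducible on Gaussian
  backgrounds (see *Noise floor* above).
- Synchrony can be slightly negative for anticorrelated rasters; values are
  not clipped to [0, 1].
- Whether correlated-class membership should be fixed per session or
  recomputed per task phase is unspecified in the source procedure; the
  default recomputes per phase (configurable by supplying align times).
- The per-channel word-engagement criterion ("participation") is membership
  in the correlated class for that word's raster; an event-count criterion
  can be substituted.
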