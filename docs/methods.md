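# Methods

## Model and procedure

The pipeline treats a continuous EEG recording as a linear mixture
`X = A s + ε` of a frontal blink source, a blink-locked evoked source, and
background activity, observed in µV at the scalp. All stages operate on
blink-peak-locked epochs (−500…+1000 ms, inclusive endpoints, time 0 exactly
at the blink-peak sample, 0-based indexing; 376 samples at 250 Hz).

**Blink component selection.** Component decompositions are pluggable: a
user-supplied unmixing matrix, the ground-truth mixing on simulations, or a
FastICA-style fit. Among the flagged eye candidates, each component is
back-projected onto the two anterior channels; because a single component's
two projections are exact scalar multiples of one another, their Pearson
correlation is ±1 up to numerical noise — positive when the anterior mixing
weights share a sign (blink-like, symmetric frontal topography) and negative
when they oppose (horizontal-saccade-like). The candidate with the largest
positive correlation wins; exact ties are broken by anterior back-projected
power, which prefers the component that actually dominates the frontal
channels.

**Blink detection.** Threshold = mean + 1.5 SD of the whole component
series. Each contiguous supra-threshold interval at least 50 ms long yields
one event at its maximum; events closer than 200 ms are merged (larger peak
wins). The duration guard and refractory period are not part of the
threshold rule itself; they prevent double counting on noisy pulses.
A zero-variance signal yields zero events rather than an error.

**Epoch rejection.** An epoch violates on either a 500 µV absolute
amplitude, or a per-series SD whose z-score against the across-epoch SD
distribution exceeds 5 (the z-of-SD statistic is this package's concrete
definition of the "SD threshold"; the max over series is used). Per
iteration at most ⌊10 % of the current epoch count⌋ epochs are removed
(minimum 1 while any violate), worst offenders first by
max(amplitude/500, z/5); scores are recomputed each iteration and the loop
stops when nothing violates, which makes the operation idempotent.

**Synchronization.** GFP is the Lehmann–Skrandies spatial standard
deviation across channels of the epoch-averaged signal — computed on
average-referenced data it is invariant to channel permutation and to
common offsets. The peak is searched in 0–500 ms post-blink by default
(blink-locked evoked responses live there; a peak on the search boundary is
flagged as possibly truncated). Δt = t_GFP_max − t_blink_max, with
t_blink_max re-estimated from the mean blink trace (≈0 by construction).
Per-condition offsets are averaged per participant and re-quantized to the
sample grid (round(Δt·fs/1000)).

**Alignment sign.** `shift_blink` *delays* the blink series by Δt:
out(t) = in(t − Δt). With blink-peak-locked epochs this moves the blink
maximum onto the GFP maximum, so one feature window contains both
modalities' informative segments; the opposite convention would move the
two peaks 2Δt apart and no window would ever see both. Vacated samples are
edge-replicated by default (zero fill optional) to avoid step artifacts
inside feature windows.

Δt is estimated from all of a participant's epochs before decoding (one
constant per participant). This mixes training and test trials; the
leakage is mild — a single scalar — but fold-wise re-estimation can be
performed by calling `compute_gfp`/`compute_offset` on training subsets
inside a custom loop.

**PCA.** Fit on the channels × (epochs·times) unfolding after per-channel
mean removal; the smallest k with cumulative explained variance ≥ 0.95 is
kept. Component signs follow the largest-|loading|-positive convention so
runs are reproducible.

**CCA.** Covariances pooled over epochs and time; a ridge
ε·trace/dim·I with ε = 1e-8 keeps them invertible (this is the one
deliberate departure from exact invariance to channel re-mixing). The
eigenproblem is solved in generalized symmetric form
(S_xb S_bb⁻¹ S_xbᵀ) u = λ² S_xx u via `scipy.linalg.eigh` for stability;
pairs are normalized to uᵀS_xx u = vᵀS_bb v = 1, ρ ≥ 0, sorted by
descending ρ. One pair is kept by default. The fused features are the
per-trial canonical variates (the weight vectors are also exported for
users who want them).

**Decoding.** Window length = ⌈window_ms·fs/1000⌉ rounded up to odd
(13 samples for 50 ms at 250 Hz); stride 1 sample by default. Classes are
balanced by downsampling majorities to the minority count before splitting
(for one-vs-rest contrasts, pool the "rest" first, then balance).
Cross-validation is a five-repetition stratified shuffle split (80/20);
features are z-scored with train-fold statistics (zero-SD features get
scale 1 with a log entry) and classified by a linear SVM with C = 1 — no
class weighting is needed on balanced data, and no hyperparameter search is
performed. Multi-class problems use a one-vs-rest ensemble; Sen/Spe are
macro-averaged over per-class one-vs-rest confusion counts, which on
balanced data satisfies Sen = Acc and Spe = 100 − (100 − Acc)/(k − 1)
(used as a self-check in the tests). Undefined metrics (no positives /
negatives) propagate as NaN with a flag and are excluded from macro means.
The temporal generalization matrix reuses the same folds at every
train/test window pair and normalizes test-window features with the
training window's train-fold statistics, so its diagonal reproduces the
decoding time course exactly. Dispersion across participants is available
as a 1000-resample bootstrap 95 % CI.

**Statistics.** Paired two-sided t-tests per comparison point with
Benjamini–Hochberg step-up FDR (Benjamini–Yekutieli available); points with
zero-variance nonzero differences are flagged undefined, and exactly-equal
points report t = 0, p = 1. The extreme-pixel permutation test flips the
sign of each participant's difference map independently (equivalent to
reallocating participants between two paired conditions), records the mean
map's single maximum and minimum pixel per permutation, and declares
observed pixels significant beyond the 1 − α/2 quantile of the maximum
distribution or the α/2 quantile of the minimum distribution (α = 0.01
two-tailed by default). Permutations are chunked to bound memory at large
map sizes.

## Synthetic data

The generator emulates a ~30-channel, 250 Hz mobile-EEG recording:

- **Blink source**: unipolar pulse with a half-cosine rise (100 ms) and a
  slower half-cosine fall (200 ms), ~100 µV, frontally weighted
  (Fp ≫ F > FC > C); blink times follow a renewal process with a 2 s
  minimum gap plus an exponential tail whose mean preserves the configured
  rate (12/min default), so counts stay Poisson-consistent while epochs
  remain separable.
- **Evoked response**: Hann-windowed 10 Hz cosine burst (150 ms) with a
  centro-parietal topography, centered at blink peak + a per-condition lag
  (defaults 160/200/240 ms for the three default conditions); its envelope
  maximum defines an unambiguous GFP argmax.
- **Noise**: per-channel SD = evoked_amplitude / snr; 80 % of that variance
  (configurable) rides on three shared 1/f background sources and the rest
  is channel-independent sensor noise. The structured share matters: it is
  what keeps the 95 %-variance PC set small, as in real EEG.
- **Class signals**: per-condition evoked lag (neural timing signal),
  optional per-condition evoked amplitude, and optional per-condition blink
  amplitude (an independent ocular signal). Conditions are interleaved in
  30 s blocks in the continuous simulator and shuffled per trial in the
  direct epoch simulator.

All randomness flows from one integer seed; outputs are bit-reproducible.
What the generator does **not** emulate: volume-conduction/head-model
realism, saccade or muscle artifact classes, non-stationary noise, blink
waveform variability within a condition, or amplifier drift. Tests passing
on this generator therefore demonstrate the *method's* correctness and
statistical calibration, not its performance on any particular real
dataset.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the
study: 60–100 epochs per condition for parameter-recovery checks, 80 per
condition over 10 seeds for the fusion-dominance property (peak accuracy
taken over windows centered 50–350 ms post-blink, stride 8 samples), a
single simulated participant (200 s per condition) for the end-to-end
pipeline, and 200 nested null runs at 200 permutations for the family-wise
error calibration. These sizes were chosen so the full suite runs in about
a minute while leaving every statistical margin comfortably wide.

## Known limitations

- EDF/BrainVision files are read (via mne); continuous exports are written
  as FIF, mne's native format — there is no EDF writer.
- The preprocessing bad-channel step flags flatline and low-correlation
  channels but does not interpolate or remove them; callers decide.
- Eye-candidate flags must come from ground truth, a label file, or the
  frontal-topography heuristic; no automated multi-class component
  taxonomy is included.
- No per-trial offset estimation (alignment uses epoch averages), no
  nonlinear/kernel CCA, no cluster-mass permutation variant.
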