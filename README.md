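# blinkfuse

Synchronization-based fusion of EEG and eye-blink signals for decoding
cognitive/locomotor state.

Spontaneous eye blinks recorded in the EEG are not just artifacts: the blink
component extracted by a linear decomposition carries task information of its
own, and the evoked EEG response that follows each blink peaks at a
task-dependent latency. `blinkfuse` implements a multimodal decoding pipeline
that exploits both facts. It is aimed at researchers running mobile-EEG or
simulator experiments who want to compare unimodal and fused blink-locked
decoding on their own recordings — and at anyone who wants a fully synthetic,
ground-truthed test bed for this class of method.

## Method

1. **Blink extraction.** Given a component decomposition of the continuous
   EEG (a supplied unmixing matrix, or ground truth on simulations), the
   blink component BC is identified among the eye candidates as the one whose
   back-projections onto the left and right anterior channels correlate
   positively. Blink peaks are detected where the component exceeds its mean
   by 1.5 SD; epochs from −500 ms to +1000 ms around each peak are cut, and
   artifact epochs (>500 µV absolute, or per-epoch SD z-score >5) are removed
   iteratively, at most 10 % per iteration.
2. **Synchronization.** Global field power, GFP(t) = SD across channels of
   the epoch-averaged signal, peaks at the blink-locked evoked response. The
   offset Δt = t_GFP_max − t_blink_max is estimated per condition, averaged
   per participant, and the blink trace is shifted so its peak falls on the
   GFP peak: BC_sync is the blink series delayed by Δt.
3. **Fusion.** EEG epochs are reduced to the smallest principal-component
   set capturing 95 % of the variance; concatenation fusion stacks them with
   the aligned blink series, `Fusion_concat(t) = [PC_1(t) … PC_k(t),
   BC_sync(t)]` ("pcEEG+"). Alternatively, CCA solves
   `S_xx⁻¹ S_xb S_bb⁻¹ S_xbᵀ u = λ² u` (and the v counterpart) between EEG
   and the aligned channel-space blink signal and fuses the canonical
   variates uᵀX(t), vᵀB(t).
4. **Decoding.** A 50 ms window (13 samples at 250 Hz) slides over the
   epoch; per window, trials are decoded with a linear SVM under a
   five-repetition stratified 80/20 cross-validation, z-scoring with
   train-set statistics only, after downsampling majority classes. Scores
   are Acc/Sen/Spe in percent; a temporal generalization matrix trains at
   one window and tests at all others on the same folds.
5. **Statistics.** Method contrasts use paired t-tests with
   Benjamini–Hochberg FDR across windows, and family-wise inference over
   generalization matrices uses an extreme-pixel permutation test (sign
   flips of per-participant difference maps; two-tailed α = 0.01 against the
   null distributions of the extreme pixels).

A synthetic-data module generates 30-channel recordings with a stereotyped
frontal blink source, condition-dependent blink-locked evoked bursts, 1/f
background activity and full ground truth, so every stage is testable
without any data download.

## Worked example

```python
import blinkfuse as bf

cfg = bf.RunConfig(sim=bf.SimConfig(duration=200.0, seed=1),
                   methods=("pcEEG+", "pcEEG", "syncBlink"),
                   step_samples=8, seed=1)
manifest = bf.run(cfg)
p = manifest["participants"][0]
print(p["offsets_by_condition"])
print(p["delta_t_true"])
print({m: round(v["acc"], 1) for m, v in p["peaks"].items()})
```

prints

```
{'stand': 160.0, 'walk': 200.0, 'walk_obstacles': 240.0}
{'stand': 160.0, 'walk': 200.0, 'walk_obstacles': 240.0}
{'pcEEG+': 100.0, 'pcEEG': 100.0, 'syncBlink': 46.7}
```

The estimated blink→GFP offsets recover the generator's true per-condition
lags exactly at this signal-to-noise ratio. The three simulated conditions
differ in their evoked lag, so EEG-based methods decode them essentially
perfectly here, while the blink trace alone (whose shape is
condition-independent in the default configuration) stays near the 33 %
chance level. Fusion gains appear when both streams are partially — not
perfectly — informative; `tests/_helpers.py::dominance_peaks` builds exactly
that regime.

The same pipeline runs from the shell:

```bash
blinkfuse simulate --seed 1 --out sim/
blinkfuse run --seed 1 --participants 1 --out results/
```

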