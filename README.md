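# cohfo

Detection and coincidence analysis of high-frequency oscillation (HFO)
bursts in multichannel intracranial EEG.

Transient oscillatory bursts in the high-gamma/ripple range (60–500 Hz)
co-occur across widely separated cortical sites during memory encoding and
recall. Testing hypotheses about this *coincident bursting* (co-HFOs)
requires a chain of analyses — per-channel burst detection, peri-event
coincidence counting, correlation-based channel classification, clustering
of co-bursting networks with surrogate controls, and mixed-model statistics
— and a way to validate every link against known ground truth. `cohfo`
provides that chain as a tested, reusable library plus CLI, together with a
synthetic LFP generator that injects bursts with controllable SNR,
coincidence structure and task-locked rate modulation, so the whole pipeline
is verifiable by parameter recovery without access-protected clinical data.

It is intended for electrophysiologists and methods developers working with
stereo-EEG / iEEG recordings during cognitive tasks.

## The method in brief

**Detection.** Each channel is decomposed into 38 log-spaced zero-phase FIR
bands (60–800 Hz). Hilbert envelopes are normalized by a sliding z-score
(10-s windows). Candidate segments exceed z > 2 for ≥ 3 cycles of the band
frequency; temporally overlapping candidates in contiguous bands merge into
events whose dominant frequency is the band with the highest z. Accepted
events need peak z > 3, a duration of ≥ 4 cycles at the dominant frequency
f_dom (Δt ≥ 4/f_dom), at least one full oscillation cycle inside the z > 3
region, and to survive a k-means (k = 2) filter on frequency span that
rejects spectrally diffuse transients.

**Coincidence.** Events become points at their envelope peak, binned into
binary channels × 10-ms-bin rasters within ±1.5 s of task events. An HFO is
a co-HFO when another channel bursts within ±50 ms (±5 bins). Channels are
*correlated* when their maximal pairwise Pearson correlation across rasters
exceeds r = 0.5. Per-bin co-HFO counts are averaged within subject, scaled
to per-second rates (×100), and normalized so each trace sums to one.

**Sequences.** Channels are clustered on d = 1 − r with average linkage
(UPGMA); a ±50–100 ms timestamp-jitter surrogate and a channel-bootstrap
Adjusted Rand Index quantify whether the modular, sequential structure is
genuine.

**Statistics.** Shapiro–Wilk gating between parametric and nonparametric
families; per-bin linear mixed models `value ~ condition + (1 | subject)`
with Benjamini–Hochberg FDR across bins; Tukey HSD post-hocs; Cohen's d;
max-statistic permutation FWER control.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from cohfo import sim, detect, experiments
from cohfo.types import BurstSpec

# -- detect injected bursts in pink noise --------------------------------
cfg = sim.SimConfig(n_channels=2, duration=95.0, n_lists=1, fs=2000.0, seed=21)
noise = sim.generate_pink_noise(cfg)
amp = 6.0 * detect.band_rms(noise.data[0], cfg.fs)   # 6x in-band noise RMS
bursts = [BurstSpec(channel=i % 2, center_time=t, frequency=120.0,
                    n_cycles=6, amplitude=amp)
          for i, t in enumerate(np.linspace(5.0, 90.0, 20))]
events = detect.detect_hfos(sim.inject_bursts(noise, bursts))
hits = sum(
    ((events.channel == noise.channels[b.channel])
     & (events.peak_time.sub(b.center_time).abs() < 0.02)
     & (events.freq_min <= 120.0) & (events.freq_max >= 120.0)).any()
    for b in bursts)
print(f"recovered {hits}/20 injected bursts "
      f"({len(events)} detections incl. noise floor)")

# -- recover a planted recall-locked co-HFO profile ----------------------
res = experiments.profile_recovery(seed=1)
print(f"co-HFO trace peak {res['peak_offset_bins']:+d} bins from recall "
      f"onset; pre-recall dip at {res['dip_ratio']:.2f}x the trace mean")
```

prints

```
recovered 19/20 injected bursts (1064 detections incl. noise floor)
co-HFO trace peak +0 bins from recall onset; pre-recall dip at 0.00x the trace mean
```

19 of 20 bursts injected at 6× the 60–800 Hz noise RMS are found with their
peak localized within 20 ms and a frequency extent covering 120 Hz. The
remaining detections are the detector's noise floor: at the liberal 2/3-SD
thresholds, narrowband envelope excursions of pure 1/f noise are themselves
detected at a few events/s/channel (see `docs/methods.md`, *Noise floor*) —
which is why the co-HFO analyses rest on task-locked modulation and
cross-channel coincidence rather than on a silent detector. The second
block simulates a multi-subject session whose burst rate peaks 4-fold at
recall onset and dips to 0.3× one second earlier, and recovers exactly that
profile from the correlated-class co-HFO probability trace: peak at the
recall-onset bin, near-empty trace in the dip window.

The same pipeline runs from the shell:

```sh
cohfo simulate --out run/ --seed 1
cohfo detect --signal run/signals/S01.bin --out run/events.tsv
cohfo coincide --events run/events.tsv --task run/task_events.tsv --out run/
cohfo run --config config.yaml --out run/ --seed 1   # full chain + manifest
```

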