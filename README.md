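# protrudyn

Quantification of dendritic protrusion dynamics from live-cell fluorescence
time-lapses of developing neurons, with a synthetic ground-truth generator
for validating every stage of the analysis.

## The problem

Dendritic spines develop from thin, highly motile membranous processes
("dendritic protrusions", 0.4–10 µm long) on the dendrites of immature
neurons. Their behaviour over a short recording — appearing, disappearing,
flickering in and out, partially extending and retracting — is quantified
from single-channel membrane-marker time-lapses (typically one frame every
5 s for 10 min at 0.06 µm/px). `protrudyn` automates the full chain:

1. **Preprocessing** (`protrudyn.imgpipe`): maximum *z*-projection, rigid
   *x-y* drift correction by cross-correlation, Gaussian low-pass
   (σ = 2 px), per-frame triangle-method thresholding, binary silhouettes
   and temporally colour-coded outlines.
2. **Detection** (`protrudyn.protdetect`): the dendrite shaft is recovered
   by morphological opening; every thin process attached to it is measured
   by geodesic length and gated to 0.4–10 µm.
3. **Tracking and events** (`protrudyn.protrack`): per-frame detections are
   linked into tracks (nearest-base matching with gap closing) and each
   track is classified by the four fundamental events:
   - *formation* — de novo appearance during the recording,
   - *elimination* — complete disappearance,
   - *lability* — appearance **and** disappearance within the recording,
   - *motility* — partial extension/retraction of a persisting protrusion.
4. **Metrics** (`protrudyn.dynmetrics`): with N0 protrusions at time 0 and
   N_end at the last frame, per segment:

   density = count / segment length × 10 (per 10 µm)
   formation% = F/N0·100 (similarly E, L, M)
   survival% = N_end/N0·100
   turnover% = (F+E+L)/N0·100
   Δmovement% = (F+E+L+M)/N0·100 = turnover% + motility%

5. **Estimation statistics** (`protrudyn.estimstats`): a Shapiro–Wilk gate
   routes each metric to a two-way ANOVA (genotype × plasmid) with
   Bonferroni-corrected pairwise t tests, or to Kruskal–Wallis with
   Bonferroni-corrected pairwise rank-sum tests; independently, every
   planned comparison gets a mean-difference effect size with a 95 %
   bias-corrected-and-accelerated (BCa) bootstrap interval (5000 resamples).
6. **Simulation** (`protrudyn.simdendrite`): a generator that draws a known
   stochastic event schedule and renders microscopy-like frames (Gaussian
   PSF, Poisson shot noise, Gaussian read noise), so that detection,
   tracking and the metrics can be validated against ground truth.

## Worked example

```python
from protrudyn.simdendrite import SimulationConfig, simulate
from protrudyn.pipeline import RunConfig, run_process

cfg = SimulationConfig(
    segment_length_um=45.0, n_frames=61, n_initial_protrusions=15,
    formation_count=3, elimination_count=2, lability_count=2,
    length_sampling_range_um=(1.5, 5.0), motility_fraction=0.5, seed=0,
)
stack, truth = simulate(cfg)
result = run_process(stack, RunConfig(register=False))
print("truth   :", truth.event_log())
print("detected:", result.event_log)
print({k: v for k, v in result.metrics.rounded().items()})
```

prints

```
truth   : EventLog(n0=15, n_end=16, formed=3, eliminated=2, labile=2, motile=8, recording_duration_min=5.0)
detected: EventLog(n0=15, n_end=16, formed=3, eliminated=2, labile=2, motile=8, recording_duration_min=5.0)
{'density_per_10um': 3.4, 'formation_pct': 20.0, 'elimination_pct': 13.3,
 'lability_pct': 13.3, 'motility_pct': 53.3, 'survival_pct': 106.7,
 'turnover_pct': 46.7, 'delta_movement_pct': 100.0}
```

i.e. the pipeline, run blind on the rendered images, recovers the simulated
event schedule exactly: 15 protrusions at time 0, of which 2 are eliminated,
3 form de novo, 2 are labile and 8 are motile, giving a 106.7 % survival
fraction and a 46.7 % turnover on this deliberately dynamic segment.

A shell interface wraps the same stages:

```sh
protrudyn simulate --config sim.yaml --seed 1 --out sim/
protrudyn process sim/timelapse.tif --out run/
protrudyn metrics run/event_log.json --out cells.csv
protrudyn stats cells.csv --seed 1 --out table.csv
```

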