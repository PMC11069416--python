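# nirsync

Dyadic fNIRS hyperscanning analysis: from raw two-brain optical intensities
to real-vs-pseudo-dyad permutation inference on inter-brain coherence.

## The problem

In a co-watching paradigm, two familiar participants watch a short video
side by side, hold a face-to-face conversation on unrelated topics, then
watch a second video, while both brains are recorded simultaneously with
continuous-wave fNIRS (780/805/830 nm, 8.33 Hz, 19 channels per
hemisphere each). Two questions drive the analysis:

1. Is inter-brain coherence during co-watching higher for people who are
   actually together than the level explained by watching the same video?
2. Does a conversation *with one another* raise coherence during a later,
   unrelated video?

The stimulus-only baseline comes from **pseudo-dyads**: surrogate pairings
of participants from different real dyads, matched on episode order, who
saw the same videos but not together.

## The method

- **Preprocessing** (fixed order): optical density → wavelet motion
  correction (Daubechies-5, detail coefficients outside Q1/Q3 ± 1.5·IQR
  zeroed) → zero-phase 5th-order Butterworth band-pass 0.01–0.4 Hz →
  modified Beer–Lambert inversion (d = 3 cm, DPF = 6) → CBSI activation
  x = (HbO − α·HbR)/2, α = σ(HbO)/σ(HbR).
- **Geometry**: optode registrations validated (neighbour distances within
  2.5–3.5 cm), channels located at MNI midpoints with cohort-mean
  fallbacks, then allocated to 8 ROIs (bilateral DLPF, vPM, TPJ, SPL;
  2 cm spheres) under a mutual-nearest rule — one channel per ROI, one ROI
  per channel.
- **Coherence**: Morlet (ω₀ = 6) wavelet transform coherence between the
  two participants' ROI activation signals per co-watching trial, smoothed
  cross-spectrum estimator, cone-of-influence aware, summarised into three
  bands: high 0.1–0.2 Hz, medium 0.03–0.1 Hz, low 0.02–0.03 Hz.
- **Inference**: per (measure, ROI, band) cell, a pooled-variance
  two-sample t between real and pseudo dyads with a label-permutation null
  (default 10,000 shuffles, two-sided, p = (1+#{|t*|≥|t|})/(1+n)), Cohen's
  d with normal-approximation CI, a paired pre/post t within real dyads,
  and optional Bonferroni/Benjamini–Hochberg adjustment. Measures:
  `cowatch1` (first-video coherence) and `change` (second minus first).
- **Synthetic data**: a first-class generator produces coupled two-brain
  sessions with known ground truth — band-limited latent mixing
  `x = a·stimulus + c·dyad_shared + √(1−a²−c²)·private`, Beer–Lambert
  forward model, heartbeat, drift, noise, motion artifacts, probe jitter —
  so every stage is testable without any external data.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from nirsync import PipelineConfig, SimulationConfig, run_full

config = PipelineConfig(
    simulation=SimulationConfig(
        n_dyads=8,
        phase_durations=(120.0, 20.0, 120.0),   # short conversation
        coupling={"video2": {"high": {"TPJ_R": 1.0}}},  # injected effect
        seed=101,
    ),
    n_perm=1000,
    seed=101,
)
result = run_full(config)
table = result.tables["change"]
best = table.loc[table["p_value"].idxmin()]
print(f"{len(table)} cells, {result.draws['change']} permutation draws")
print(best[["region", "band", "observed_diff", "p_value", "effect_size"]])
```

Output:

```
24 cells, 24000 permutation draws
region              TPJ_R
band                 high
observed_diff    0.233505
p_value          0.001998
effect_size      1.783471
Name: 12, dtype: object
```

Eight simulated dyads carry extra inter-brain coupling only while real
partners co-watch the *second* video, in the high band, at the right TPJ.
The change-measure grid (8 ROIs × 3 bands, 1000 label permutations per
cell) finds its smallest p-value exactly there: real dyads' coherence rose
by 0.23 more than pseudo-dyads' (Cohen's d ≈ 1.8), and only two of 1000 label
shuffles produced as extreme a t-statistic. The same run with
`coupling={}` is a null cohort whose p-values are roughly uniform.

The same pipeline is available from a shell:

```bash
nirsync simulate --n-dyads 4 --seed 7 --out cohort/
nirsync run-full --seed 7 --n-perm 1000 --out results/
```

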