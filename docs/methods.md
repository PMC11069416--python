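# Methods

`nirsync` analyses dyadic fNIRS hyperscanning recordings of a co-watching
paradigm: two participants watch a short video together (phase 1), hold a
conversation (phase 2), and watch a second video (phase 3). The pipeline
quantifies inter-brain coherence during each co-watching trial and asks, by
contrast with surrogate ("pseudo") dyads, whether being together — and
having conversed with one another — raises coherence beyond what the shared
stimulus alone explains.

## Signal model and preprocessing

Raw inputs are optical intensities at 780/805/830 nm, sampled at 8.33 Hz
over 38 channels per participant (7 sources + 7 detectors per hemisphere in
a staggered grid, 3 cm spacing, 19 channels per hemisphere). Preprocessing
follows a fixed order, each stage preserving the (channels × samples)
layout:

1. **Optical density.** `OD = −ln(I / mean_t I)` per channel and
   wavelength. The temporal mean is the baseline (first-sample baselines
   are noisier; any constant cancels downstream).
2. **Wavelet motion correction.** Daubechies-5 DWT at maximal dyadic
   depth; within each detail level, coefficients outside
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are zeroed before reconstruction. This
   removes most of a spike or step while leaving smooth hemodynamics within
   ~2% RMS. Coefficients below the fence are indistinguishable from noise,
   so a sub-sample delta retains ≲20% of its amplitude; physical motion
   events (a few hundred ms and longer) are suppressed below 10%.
3. **Band-pass.** Zero-phase (forward–backward) 5th-order Butterworth,
   0.01–0.4 Hz, with reflect-padding of three low-edge time constants so
   edge transients do not leak sub-band power. Zero-phase filtering is
   chosen so that filter lag cannot distort coherence phase.
4. **Modified Beer–Lambert inversion.** Per channel, least-squares solve
   of `OD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)` with d = 3 cm and
   DPF = (6, 6, 6). Extinction coefficients are compiled from the standard
   Prahl/OMLC hemoglobin tabulation (cm⁻¹·M⁻¹): (735.4, 1104.0) at 780 nm,
   (880.0, 851.6) at 805 nm, (974.0, 693.2) at 830 nm. The absolute
   concentration scale is therefore conventional; wavelet coherence is
   scale-invariant, so downstream results do not depend on it. Note the
   3-wavelength system has condition number ≈ 6.6: intensity noise is
   amplified into anti-correlated HbO/HbR noise, which CBSI further
   amplifies — the main reason raw-intensity SNR matters.
5. **CBSI activation.** `x = (HbO − α·HbR)/2` with `α = σ(HbO)/σ(HbR)`
   per channel. Channels with `σ(HbR) = 0` are flagged degenerate and
   excluded. `x` is invariant to rescaling HbR.

**Channel quality.** The study's visual screening is replaced by
deterministic gates: cardiac peak SNR (Welch PSD, heartbeat band 0.5–2 Hz,
peak over flanking-band median, threshold 4 dB — heavy segment averaging
keeps the no-peak null near 2–3 dB), light saturation (rail value or
flat-line run ≥ 1 s), and a first-difference jump count (|Δ| > 5·IQR,
more than 30 jumps excludes). Thresholds are configurable.

## Probe geometry and ROI allocation

Optode registrations are validated by requiring every montage-neighbour
distance to lie in [2.5, 3.5] cm (inclusive); the neighbour graph is the
channel-forming adjacency. Channel positions are MNI midpoints of their two
optodes; channels touching a mis-located optode fall back to the cohort
mean for that channel (computed over measured-midpoint participants only),
and participants with >50% mis-located optodes or no registration take
cohort means throughout.

Eight ROIs (bilateral DLPF, vPM, TPJ, SPL) are fixed MNI spheres of radius
20 mm. Channels are allocated under a mutual-nearest rule — at most one
channel per ROI and one ROI per channel, all assignments within 20 mm, a
nearer competitor displaces a farther one which falls back to its next
choice. Because both channels' and ROIs' preferences derive from one
distance matrix, the fixpoint of that rule is the unique stable matching,
implemented as globally-nearest-pair selection (ties broken by channel id,
then ROI table order). The test suite checks this against exhaustive
enumeration of stable assignments on small instances.

A cohort-level data-sufficiency report (`roi_data_sufficiency`) counts how
many participants feed each ROI and flags ROIs below a threshold
(default: the cohort mean availability). It reports rather than filters —
the 8-ROI table is fixed, and the sufficiency cut belongs to the original
ROI-selection step, not to routine analysis.

## Wavelet transform coherence

Analytic Morlet wavelet (ω₀ = 6), dyadic scales from 2/fs with 12 voices
per octave up to the trial length. Squared coherence follows the smoothed
cross-spectrum estimator:

    r² = |S(W_xy / s)|² / ( S(|W_x|² / s) · S(|W_y|² / s) )

with identical positive smoothing weights in all three terms: a Gaussian in
time with SD equal to **two** scales, and a 0.6-octave boxcar across scale.
Positivity of the weights gives `0 ≤ r² ≤ 1` by Cauchy–Schwarz; without
smoothing r² would be identically 1 (the suite asserts independent noise
stays well below the identity case). The time-SD constant is a free design
parameter ("proportional to scale"); two scales per SD was calibrated so
the no-coupling coherence floor sits at the 0.2–0.3 level typical of
published dyadic fNIRS baselines, while self-coherence remains 1 and a
shared sinusoid at 10:1 SNR still scores > 0.9. The cone of influence is
the Morlet e-folding time (√2·s); band means exclude out-of-cone cells by
default and record the excluded fraction.

Bands are half-open intervals tiling [0.02, 0.2) Hz: high [0.1, 0.2),
medium [0.03, 0.1), low [0.02, 0.03). Frequencies below 0.02 Hz and above
0.2 Hz are never summarized. On a 2-minute trial the low band is largely
out-of-cone (30–60 s periods); its mean rests on few cells and is the
noisiest summary — a limitation shared with the experimental design.

## Pseudo-dyads and inference

Real dyads are grouped by experimental features (episode order); within a
group of size k all k·(k−1) ordered cross-pairings of role-A and role-B
participants form pseudo-dyads. Two measures are computed per (ROI, band):
coherence while co-watching the first video (`cowatch1`) and the
post-minus-pre-conversation change (`change`).

For each cell, a pooled-variance two-sample t contrasts real vs pseudo
values (Welch available as an option); significance comes from shuffling
the real/pseudo labels over the concatenated values, preserving group
sizes, with `p = (1 + #{|t*| ≥ |t|}) / (1 + n_perm)` (two-sided; the +1
avoids p = 0; ties at |t| are counted with a relative tolerance of 1e-9).
Cohen's d uses the pooled SD, with a 95% CI from the normal approximation
`Var(d) ≈ (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`. A paired t on the real dyads'
pre/post values accompanies the grid, and Bonferroni/Benjamini–Hochberg
adjustments are available (`none` by default, matching the primary
analysis). The permutation engine counts its draws, so a full 8 ROI × 3
band grid at n_perm = 10,000 reports exactly 240,000 draws per measure.
Pseudo-dyad values share participants and are therefore not fully
independent; the label-permutation null ignores this, faithfully to the
procedure it implements — a known limitation.

## Synthetic data generator

The generator exists to give every stage a falsifiable ground truth; its
defaults define the simulated study conditions.

Per ROI, band and phase, three unit-variance band-limited Gaussian
processes (zero-phase 4th-order Butterworth on white noise) are mixed as

    x = a·stimulus + c·dyad_shared + √(1 − a² − c²)·private

where `a` (band-wise: 0.3 low, 0.3 medium, 0.2 high during video phases) is
shared by *everyone* watching the same episode — the stimulus-driven
component that makes pseudo-dyad coherence a meaningful baseline — and `c`
is the per-(phase, band, ROI) inter-brain coupling, default 0. If
`a² + c² > 1`, the dyad term wins and `a` is capped. For the smoothed
estimator the expected squared coherence of the shared component scales as
the square of the shared variance fraction (≈ c⁴ for pure dyad coupling),
so moderate coefficients produce small coherence lifts; a strong positive
control uses c = 1.

ROI activity has spatial extent: a channel at nominal distance d from its
nearest ROI centre carries weight `exp(−d²/(2·20 mm²))` of the ROI latent
(below 0.1, pure channel noise). HbR is −0.3·HbO plus 0.2 independent
broadband noise. Channel intensities follow the exact Beer–Lambert forward
model (`I = I₀·exp(−OD)`, baselines 500–2000 a.u.), plus: heartbeat
(~1.1 Hz sinusoid, 0.015 OD, per-participant frequency offset), slow drift
(< 0.01 Hz, 0.02 OD), multiplicative white noise (0.3% — the shot-noise
level of CW instruments; larger values are amplified by the MBLL inversion
into sub-unity in-band SNR), and Poisson motion artifacts (0.5/min;
Gaussian spikes ≥ 5× signal SD, < 2 s, and level shifts). Geometry gets
per-optode MNI jitter (isotropic SD 8 mm truncated at 15 mm) and small
real-space jitter; gross mis-locations can be injected at a configurable
rate. Everything derives from `(seed, dyad_index)` seed sequences:
identical configs are bit-identical, and the stimulus component depends
only on (episode, band, ROI) so it is consistent across sessions.

Because intensity is `I₀·exp(−OD)` while the OD baseline is the temporal
mean, round-trip recovery through intensity is exact only up to an additive
constant per channel/wavelength; the generator invariant is therefore
asserted on mean-centred concentrations (the pure OD-level MBLL round trip
is exact to 1e-9).

What the generator does **not** emulate: photon transport or head anatomy,
systemic physiology shared between participants (a known confound of real
hyperscanning), task-evoked responses locked to video events, non-Gaussian
artifact shapes, or behaviourally meaningful conversation dynamics. Passing
tests show the pipeline recovers what this model injects — not that real
co-watching data contains such effects.

## Problem sizes used in validation

Validation experiments scale the study design down to keep full runs cheap
while preserving every pipeline stage: conversation phases of 20–60 s
(only the two 2-minute co-watching trials are analysed), cohorts of 4–12
dyads for accounting/null experiments, and 20 replicate 8-dyad cohorts
(n_perm = 1000) for the injected-coupling recovery experiment. The
permutation-accounting run uses the full n_perm = 10,000 on a 4-dyad
cohort, exercising the complete 8 × 3 grid. Type-I-error calibration
resamples real/pseudo groups from an empirical pool of pipeline-computed
null dyad values (12-dyad uncoupled cohort, all cross-dyad pairings), then
runs 1000 permutation-test repetitions at n_perm = 999.

## Known limitations

- Exact numeric agreement with any particular WTC implementation (e.g. a
  commercial `wcoherence`) is not a goal; wavelet, voice count and COI
  policy are documented choices.
- The low band on 2-minute trials is estimated from few in-cone cells.
- The permutation null treats pseudo-dyad values as exchangeable with real
  ones despite shared participants.
- Automated quality gates approximate, but are not identical to, visual
  screening.
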