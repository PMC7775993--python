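# Methods

## Signal model

The acquisition is an inversion-prepared, gradient-spoiled SSFP (FISP-type)
fingerprinting sequence: an adiabatic inversion pulse followed by a train of
variable flip-angle hard pulses at constant TR and TE, with an unbalanced
z-spoiler each TR applying a whole number of dephasing cycles per voxel
(two cycles, i.e. 4π, by default). Constant TR avoids off-resonance encoding,
so neither B0 nor B1 is a dictionary dimension; both are fixed at nominal.

Signals are simulated with the extended phase graph (EPG) formalism. The
state is the set of configuration amplitudes (F⁺ₖ, F⁻ₖ, Zₖ); each TR applies

1. an instantaneous RF rotation (standard 3×3 mixing across every order k),
2. the echo readout F⁺₀ · exp(−TE/T2),
3. relaxation over TR (transverse decay exp(−TR/T2); longitudinal recovery
   toward unit equilibrium with exp(−TR/T1)),
4. one configuration-order shift for the spoiler — any integer number of
   full dephasing cycles acts as exactly one shift.

RF pulses have a constant phase (rotation about y, no RF spoiling), so for
real initial states all signals are real; the code nevertheless carries
complex state and complex matching, since measured data have arbitrary
receiver phase. The adiabatic inversion is modelled as an ideal longitudinal
flip (Z ← −Z, configurable efficiency) of zero duration; the same convention
is used in the isochromat oracle so that the two engines are comparable
state-for-state.

**Pseudo-steady state.** One simulation "iteration" is one full pass of the
pulse train; the magnetization at the end of iteration one seeds iteration
two, and the dictionary retains iteration two only. On the full 880-pulse
schedule the iteration-2 vs iteration-3 signal difference is at the 1e-12
relative level, which is why two iterations suffice. The 56 acquisition
segments enter the timing (duration = TR × pulses × segments) but not the
spin dynamics model: one iteration corresponds to one pulse-train pass.

**Truncation.** Configuration orders are capped at min(n_pulses, 160) and an
occupied-order window is tracked (orders whose amplitudes all fall below
1e-12 are dropped), bounding memory and time with error far below the 1e-3
oracle tolerance.

**Oracle.** `bloch.py` implements an independent brute-force isochromat
ensemble: N spins at per-TR precession angles 2πi/N evolved by explicit
rotation matrices. With N = 1000 spins, EPG and ensemble signals agree to
better than 1e-5 across T1 ∈ [300, 4000] ms × T2 ∈ [40, 2000] ms; the
discrepancy is pure order-aliasing (orders ≥ N) plus cap truncation.

## Schedule parameters

The printed sequence parameters are TR 12 ms, TE 0.5 ms, 880 pulses, 56
segments (591.36 s total). The flip-angle pattern — linear ramp up, linear
ramp down, constant plateau — is only known graphically, so the amplitudes
are package choices: start 1°, peak 70°, plateau 15°, ramps of 440/220
pulses. These are plausible for gradient-spoiled SSFP fingerprinting; every
physics test is parameterized over the schedule, so no correctness claim
depends on them.

## Dictionary and matching

The (T1, T2) grid is the piecewise product grid: T1 10–100 ms step 10,
100–1000 step 20, 1000–2000 step 50, 2000–6000 step 100; T2 2–100 ms step 2,
100–150 step 5, 160–300 step 10, 300–800 step 50, 800–1600 step 100,
1600–3000 step 200. Shared endpoints count once (duplicate atoms would make
the argmax ill-defined), giving 115 × 100 = 11,500 combinations. Pairs with
T2 > T1 are retained by default (fidelity to the printed grid over physical
plausibility); a flag drops them.

Atoms are unit L2-normalized second-iteration signals. Compression projects
atoms onto the leading r right singular vectors of the atom matrix
(temporal side) and renormalizes; r = 10 by default — at that rank,
subspace matching reproduces full matching on 100% of noiseless on-grid
queries of the reduced (every-3rd-point) dictionary. Matching is maximum
inner product search with complex conjugation and magnitude (phase- and
scale-invariant); ties break to the lowest atom index for bitwise
reproducibility; an all-zero voxel gets the 0 ms sentinel, which lies
outside both grid ranges.

## Synthetic T1-weighted contrast

S = 1 − 2·exp(−TI/T1), TI = 1300 ms, applied voxelwise to the matched T1
map; proton density is deliberately excluded so no bias-field correction is
needed. The signed signal crosses zero at T1 = TI/ln 2 ≈ 1875.5 ms — white
matter (T1 ≈ 800 ms) is bright, cortical gray (≈ 1300 ms) intermediate, CSF
(≈ 4000 ms) negative. Signed output is the default (the magnitude fold is
available) since the sign choice affects downstream thresholding.

## Phantom and study design

The phantom is deliberately geometric, not anatomical: an ellipsoidal WM
core, a cortical shell grown by a 2.5 mm distance criterion, a 2 mm CSF rim,
and four ellipsoidal subcortical blobs (thalamus/putamen/caudate/hippocampus
-like) with T1 1100–1400 ms, T2 60–80 ms; WM 800/40, GM 1300/80, CSF
4000/2000 ms. A cohort is created by per-subject multiplicative jitter
(±3%, uniform, seeded) of each tissue's T1/T2 and of structure radii, which
provides the between-subject variance the ICC needs.

A scan session resamples the continuous T1/T2 property fields through a
rigid transform (trilinear) and the labels by nearest neighbour (the
label resampling stands in for segmentation). Repositioning acts on the
property fields, not just the labels, so edge partial-volume mixing differs
between scan and rescan — the mechanism behind realistic nonzero wCV. Scan
one is at the reference position; the rescan draws rotations and
translations uniformly within ±2°/±2 mm. Resampled fields are quantized to
1 ms and simulated once per unique (T1, T2) pair (cached), then i.i.d.
complex Gaussian noise (σ = 0.002 of equilibrium magnetization per channel
by default) is added per voxel in the time domain before matching. Subjects
whose motion magnitude exceeds a configurable threshold can be excluded,
reducing n in the reports.

The conventional comparator arm returns ground-truth-derived morphometry
with a systematic bias — thickness +0.17 mm, volumes +3% by default — plus
seeded Gaussian measurement noise (0.05 mm / 2%), emulating the small but
consistent offset between fingerprinting-derived and conventional
T1-weighted morphometry.

What the phantom does **not** emulate: real cortical folding, k-space
undersampling/aliasing artifacts, coil sensitivities, B1 inhomogeneity, and
segmentation-algorithm variability. Passing tests therefore demonstrate the
correctness of the signal model, the matching, and the statistics, and the
internal consistency of the full pipeline — not performance on real brains.

## Morphometry operators

Volumes are voxel counts × voxel volume on label masks. Cortical thickness
uses a local-thickness estimator: each shell voxel receives the diameter of
the largest inscribed sphere (from the Euclidean distance transform,
measured to the mask surface) that covers it, and the region value is the
mean diameter. This is exact on odd-voxel slabs, floors to the next odd
value on even slabs (a half-voxel parity artifact), and is monotone in true
thickness; it is a desk-scale proxy, explicitly *not* equivalent to
surface-based cortical thickness. Region T1/T2 are arithmetic means over
matched voxels, with optional bilateral averaging via a pairing table.

## Reliability statistics

For subject pairs (x₁, x₂): wCV = √(mean(d²/2)) / grand mean × 100 (the
two-replicate root-mean-square within-subject SD form; the alternative
mean-of-per-subject-CVs is deliberately not used). ICC is the two-way
random-effects, absolute-agreement, single-measurement ICC(2,1) from ANOVA
mean squares, with the residual sum of squares computed from the residual
matrix directly so that exact agreement yields exactly 1.0; a zero-variance
table is defined as ICC 1 with a degeneracy flag. Cicchetti bands are
lower-edge inclusive: <0.40 poor, 0.40 fair, 0.60 good, 0.75 excellent.
Bland–Altman limits are mean ± 1.96 × sample SD (n−1) of the differences.
Cross-method percent relative difference uses the symmetric mean
denominator |a−b| / ((a+b)/2) × 100. Statistics are computed per region ×
metric across subjects.

## Problem sizes

Physics and matching tests run a 200-pulse schedule and an every-3rd-point
grid (1326 atoms); the pseudo-steady-state check uses the full 880-pulse
schedule (it is the length that drives convergence). The cohort experiments
run 20 subjects at 64³ voxels for the zero-noise null design and 6 subjects
at 32³ with a 200-pulse schedule for the noisy design; these sizes are the
package's desk-scale defaults and are configurable upward. The 1 ms
simulation-cache quantization introduces relaxation-time error far below
the dictionary grid spacing.

## Known limitations

- Geometric phantom; no realistic anatomy or atlas regions.
- No k-space trajectory, undersampling, or reconstruction modelling — the
  forward model goes directly from tissue properties to voxel signals.
- Thickness estimator parity floor on even-voxel-thick shells.
- Inversion modelled as instantaneous with ideal (configurable) efficiency;
  no slab profile, diffusion, or magnetization-transfer effects.
- Human-cohort effect sizes (e.g. published wCV/ICC values) are not
  reproducible from synthetic data; the pipeline reproduces the *structure*
  of that analysis, with ground truth available.
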