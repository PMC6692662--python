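# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `peristim`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Electrode-level dosimetry

**Metrics.**  For a session with peak-to-peak amplitude *a* (mA), per-contact
area *A* (cm²), duration *t* (s) and frequency *f* (Hz):
J = a/A (mA/cm²), Q = J·10⁻³·t (C/cm²), Q_ph = a·10⁻³/f (C),
CD_ph = Q_ph/A (C/(cm²·phase)).

**Conventions and why.**

- *Effective amplitude.*  The RMS-equivalent of a sine stimulus is taken as
  a_pp/√2, treating the peak-to-peak value as the driving amplitude — the
  convention of the clinical stimulators this models, whose amplitude dial
  is peak-to-peak.  Sampled stimuli use the numerical RMS of their samples;
  DC passes through unchanged.  A "mean value" reading of effectiveness is
  not used: it would be zero for any charge-balanced stimulus.
- *Charge over the full session.*  Q integrates over the whole session
  including 30 s pauses.  This deliberately over-estimates injected charge,
  which is the conservative direction for a safety analysis.  A
  duty-cycle-corrected variant exists (`duty_cycle_corrected=True`) but is
  off by default.
- *Charge per phase over a full cycle.*  Q_ph = a/f (one cycle), not a/2f.
  This is the convention under which every row of the literature comparison
  table is internally consistent.
- *Safety margins.*  OOM = ⌊log₁₀(limit/value)⌋; "two OOM below" therefore
  means the limit exceeds the value at least 100-fold.  A zero dose has an
  infinite margin.  Limit values from the literature are stored exactly as
  their sources print them and never recomputed.
- *Rounding.*  Raw double precision everywhere internally; rounding
  (half-away-from-zero, per-column decimals) is applied only at CSV
  serialization and in comparisons against printed values.

## Volume-conductor model

**Physics.**  At 10 Hz capacitive and inductive effects in tissue are
negligible (quasi-static regime), so the potential satisfies
∇·(σ∇V) = 0 with isotropic conductivities; E = −∇V and J = σE.
Conductivities are the representative isotropic averages tabulated in
`reference.CONDUCTIVITY_S_PER_M` (scalp 0.465, skull 0.01, CSF 1.65, gray
0.276, white 0.126, vitreous 1.55, retina/choroid/sclera 0.623 S/m, …).  No
frequency dependence and no anisotropic white-matter tensors are modelled.

**Phantom.**  A parametric voxel stand-in for an MRI-derived anatomical
model: nested spheres for scalp (85 mm), skull (75), CSF (70), gray (67) and
white matter (55), with the cranial-cavity shells displaced 9 mm posteriorly
so that the orbits sit in front of the skull, as in a real head, rather than
directly against the brain.  Each eye (radius 12 mm, centers ±30 mm lateral,
69 mm anterior) carries a 2 mm outer shell split into an anterior corneal
cap (45° half-angle) and a posterior retina/choroid/sclera shell, a 4.5 mm
lens, an anterior aqueous chamber and a vitreous body.  Optic nerves
(radius 2.5 mm) run from the posterior pole of each globe to a midline
chiasm and on towards the occipital white matter, carving a conductive canal
through the intervening bone — the analogue of the optic canal, and the
anatomical reason current reaches the nerve.  A posterior cap of gray matter
is labelled V1.  Electrode patches are sets of boundary voxel faces chosen
nearest the target points: four active patches of 0.35 cm² superior and
inferior to each eye (sharing the total current equally by default;
fractions are configurable because the per-channel split of real
multi-channel stimulators is device-specific) and one 9 cm² return patch at
the occiput.  Construction is fully deterministic.

**Discretization and solver.**  Cell-centered finite volumes on the uniform
voxel grid (default 2 mm): face conductance g = harmonic-mean(σ₁,σ₂)·A/d,
which is exact for layered media and conservative by construction.  Active
patches enter as area-weighted Neumann influx; the return patch is clamped
to V = 0 (Dirichlet gauge, matching a grounded return electrode); all other
surfaces are insulated (homogeneous Neumann).  Air voxels (σ = 10⁻⁷ S/m)
are excluded from the linear system — at seven orders of magnitude below
tissue they carry no meaningful current and would only ill-condition the
matrix.  The symmetric positive-definite system is solved with
Jacobi-preconditioned conjugate gradients to a relative residual of 10⁻⁶
(configurable); the default 2 mm head has ≈2.7·10⁵ unknowns and solves in a
few seconds on one CPU.  Gradients use central differences in the interior
and one-sided differences at the tissue boundary.

**Verification.**  The solver is checked against analytic oracles rather
than the published field magnitudes (see *Limitations*): exact linear ramp
and J = I/A in a uniform conductor; the series-resistance closed form in a
two-layer slab; the Legendre-series potential of two antipodal electrodes
on a homogeneous sphere (gauge-aligned relative L2 error < 2 % away from
the electrodes at 1.25 mm voxels, with the pointwise error dominated by the
O(h) staircase boundary and shrinking under refinement); exact conductivity
scaling and current linearity; mirror-exact behaviour under electrode swap;
and global current conservation across planes between the electrodes to
better than 0.1 %.

**Summaries.**  Per region (retina shell, optic nerve, cortex = gray + V1,
V1, scalp): max, mean, median and the 99.9th percentile of |J| (reported in
mA/cm²; 1 A/m² = 0.1 mA/cm²) and |E| (V/m).  The raw maximum — which
includes the electrode-edge overshoot intrinsic to voxelized patches — is
used for limit comparisons, the conservative choice; the 99.9th percentile
is the edge-robust alternative.

**Limitations.**  The published benchmark magnitudes for this montage come
from a >10-million-element anatomical FEM model; a parametric sphere phantom
cannot and does not reproduce them numerically.  They are used as a
qualitative ordering target only (retina > optic nerve > cortex in peak
|J|), which the default phantom reproduces.  Thin structures are at or below
the default voxel size (2 mm shell, 2.5 mm nerve radius), so their region
*means* are not grid-converged at desk-scale resolutions — refining the
default head from 2 mm to 1 mm moves thin-region means by tens of percent
while resolved-geometry means move ~1 % — which is a second reason the
distributed magnitudes are treated qualitatively.

## Adverse-event statistics

- *Fisher exact, two-sided.*  Margins fixed; p is the sum of hypergeometric
  point probabilities over all feasible tables of those no more probable
  than the observed one, with 10⁻⁷ relative slack for floating-point ties.
  This point-probability convention is what mainstream statistics packages
  report as "Exact Sig. (2-tailed)".  Degenerate tables (the event observed
  in neither arm, or in every subject, or an empty arm) give p = 1 and are
  serialized as "–" in the results table.
- *Wilcoxon signed-rank.*  Zero differences dropped; average ranks for tied
  magnitudes; tie-corrected variance; no continuity correction; two-sided p
  from the normal law — again the mainstream "Asymp. Sig." convention.  For
  ≤ 12 non-zero differences the exact sign-flip p is also computed (subset-sum
  dynamic program over doubled ranks).  The approximation tracks the exact
  permutation p to roughly the discreteness of the rank statistic (a few
  hundredths at n ≈ 12–20), which the suite verifies as a convergence
  property.
- *Incidence categories.*  very common > 1/10; common (1/100, 1/10];
  uncommon (1/1000, 1/100]; rare below; "not observed" at zero.
- *Multiplicity.*  Bonferroni adjustment over the event×phase family is
  available (`--bonferroni`) but off by default: uncorrected exact p-values
  are the primary report, corrected flags the secondary one.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised: 20 subjects per arm; phosphene thresholds from a zero-truncated
normal with mean 290.50 and SD 45.36 μA (peak-to-peak; the truncation is
6.4 SDs from zero and so practically inert); impedances likewise with mean
12.05 and SD 2.89 kΩ; stimulation amplitude exactly 1.2 × the measured
threshold for every subject; adverse-event indicators as independent
Bernoulli draws at the published per-event incidence rates; NRS-11 pain
ratings for affected subjects from a normal with the published
(mean, SD), rounded and clipped to 1–10.  All draws flow through one seeded
`numpy.random.Generator`.

Design notes:

- The published source gives only moments and rates, so the distributional
  forms (truncated normal, Bernoulli, discretized normal) are this package's
  choices — the simplest families consistent with those moments.
- The ascending method-of-limits simulator (logistic psychometric observer,
  amplitude rising stepwise until the first report, cap at 10× threshold)
  models the measurement procedure and is tested for its own properties
  (never stops more than a step below threshold for steep observers; mean
  positive bias ≤ one step).  It is *not* wired into `simulate_cohort`:
  the staircase's positive bias would shift the cohort mean away from the
  stated moments, which describe the measured thresholds themselves.
- The cohort-mean amplitude implied by the 120 % rule (1.2 × 290.50 =
  348.60 μA) differs slightly from the independently published amplitude
  moments (351.69 ± 63.95 μA).  The generator treats amplitude as strictly
  emergent from the rule and does not tune toward the published amplitude
  moments; whether per-subject device rounding explains the ~3 μA gap is
  unknown.
- What passing generator tests show: that the analysis stages behave
  correctly on data with the assumed statistical structure.  What they do
  not show: anything about correlations between events, learning effects
  across sessions, or non-normal threshold distributions in real cohorts —
  none of which the generator models.

## Problem sizes and tolerances used by the suite

Default phantom at 2 mm (≈2.7·10⁵ unknowns) for the solved-head checks;
4 mm for scaling/linearity laws (identical physics, smaller system); the
homogeneous-sphere oracle at 1.25 mm with the comparison region r ≤ 0.8 R
and ≥ 15 mm from either electrode; generator recovery at n = 10⁴ within
3 standard errors; exact-test reproductions at the printed 3-decimal
precision.  Solver comparisons use the tolerances stated above next to each
check.
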