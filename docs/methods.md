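# Methods

This note documents the models implemented in `strokevol`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
phantoms do and do not establish about real data.

## Relaxometry

**Signal model.** Each voxel's echo train is modeled as a single-compartment
mono-exponential magnitude decay, `S(TE) = S0·exp(−TE/T2)`, with no constant
offset. This is the minimal standard model for CPMG data; multi-component
T2, stimulated-echo (EPG) corrections and B1 effects are out of scope.

**Fitting.** Two estimators share one contract (`fit_t2_voxel`):

- `log_linear` — weighted linear regression of ln S on TE with weights S²,
  the first-order variance propagation that undoes the noise amplification
  of the log transform at late echoes. Closed-form, fast, the default for
  whole-volume maps.
- `nonlinear` — iterative least squares on the native signal scale,
  initialized from the log-linear solution. When the complex-channel noise
  SD σ is supplied, the fit instead maximizes the Rician likelihood of the
  magnitudes. Magnitude images rectify noise, biasing low-SNR (late-echo)
  samples upward; at first-echo SNR ≈ 50 this bias pushes plain
  least-squares T2 errors measurably above the Rician-likelihood fit, which
  both removes the bias and retains the information in low-SNR echoes
  rather than discarding them.

Echoes at or below a configurable noise floor are dropped per voxel before
fitting (the pipeline default is 3× the background SD estimated from the
image border); at least three usable echoes are required, otherwise the
voxel is flagged invalid — degenerate input never raises. Estimates outside
the physical window [1, 1000] ms (default, configurable) are flagged
invalid rather than clipped. R² is computed on the native signal scale for
both methods, for comparability, and clipped to [0, 1]; it is a diagnostic,
not part of validity.

**ROI readout.** ΔT2 = mean T2 over the ischemic-core ROI minus the mean
over its reflection across the sagittal midline plane, pooling all valid
voxels across every lesion-bearing slice (voxel-weighted, not
slice-averaged, which is unbiased when ROI size varies by slice). Invalid
fits are excluded from both means; an ROI with no valid voxel on either
side is an error naming the side. Reflected voxel indices are rounded to
the nearest voxel center; when twice the midline coordinate is an integer
the reflection is an exact involution.

## Volumetry

Volumes follow the planimetric rule: region voxel count ×
`in_plane_spacing² × (slice_thickness + slice_gap)`. The gap term
generalizes contiguous-slice protocols (gap 0, the default) to gapped ones;
percent values are computed from mm³, so they are invariant to resampling
that preserves volume.

`%HLVec` is evaluated from the published expression and cross-checked on
every call against the algebraically equivalent
`100·(LV − (HVi − HVc))/HVc` (tolerance 1e−9 relative). Negative corrected
values — swelling exceeding the lesion — are reported as-is with a logged
warning, never clipped: silent clipping would hide segmentation or
simulation errors.

Midline shift selects the landmark record maximizing (A − B)/2; ties break
to the lowest slice index for determinism. Landmarks are primary inputs
(the measurement is manual on real images); `landmarks_from_masks` derives
them from a third-ventricle label for synthetic data — ventricle centroid
vs the outer brain border (half a voxel beyond the outermost voxel center)
along x in the centroid row — and manually supplied files take precedence.

Manual tracing itself is out of scope: segmentations enter as integer label
masks. Labels are hierarchical — lesion and ischemic-core voxels count as
ipsilateral tissue, the contralateral reference ROI as contralateral
tissue — so the lesion-within-ipsilateral invariant is structural. A lesion
voxel embedded in the contralateral hemisphere (face-adjacent to
contralateral tissue with no ipsilateral neighbor) is rejected at
validation. The coordinate convention is 0-based (x, y, slice) with the
ipsilateral hemisphere on the high-x side, matching a right-sided
occlusion; this is overridable where it matters.

## Group statistics

Summaries are mean ± sample SD (n−1). The pooled-variance Student t-test is
the default, with the Welch/Satterthwaite variant always reported alongside:
at n = 8 per group the equal-variance assumption is untestable, and the two
can disagree near α. A summary-statistics-only t-test reproduces tests from
published mean ± SD values. Both-SDs-zero is handled by convention (p = 1
for equal means, p = 0 with a warning otherwise).

The Mann–Whitney U statistic uses midranks. For n1 + n2 ≤ 12 with no ties
the two-sided p is exact: the null distribution is enumerated over all
C(n1+n2, n1) rank assignments and p = 2·min(P(U ≤ u), P(U ≥ u)), capped at
1 — the standard two-sided convention for a discrete symmetric null.
Beyond that, a normal approximation with midrank tie correction and
continuity correction takes over; the enumeration cutoff (924 subsets)
keeps exactness where it is cheap. No multiple-testing correction is
applied across endpoints — a deliberate fidelity choice for reproducing
per-endpoint reports, and a documented limitation.

## Synthetic phantoms

The generator emulates what the pipeline consumes from a 24-hour MCAO scan,
not rat anatomy:

- **Brain**: one ellipse per coronal slice (aspect ratio 0.75, mild
  rostro-caudal area taper) inside a 37 mm field of view; 8 slices of 2 mm;
  12 echoes at TE 18–216 ms; default matrix 128 (in-plane spacing scales
  with the field of view) — a desk-scale resolution; the drawn geometry is
  resolution-independent. Default contralateral hemisphere volume 550 mm³,
  in the range of adult-rat hemispheres over an 16 mm slab.
- **Swelling and midline shift**: the brain outline is fixed
  (skull-constrained) and space-occupying edema shifts the interhemispheric
  plane toward the contralateral side; the shift is solved (bisection on
  the analytic cut-ellipse areas) so that HVi = HVc·(1+s) for the
  prescribed swelling factor s. The third ventricle sits at the displaced
  plane, so the midline shift equals the plane displacement by
  construction, and swelling and MLS co-vary the way a space-occupying
  process makes them. An explicit `midline_displacement` override decouples
  the drawn ventricle from the hemispheric partition when needed. Because
  the plane generally falls inside a voxel column, the boundary column is
  split row-by-row with a fixed golden-ratio phase (and likewise the
  ventricle slab edges): the realized volume ratio and ventricle centroid
  track their continuum targets instead of snapping to whole-column steps,
  at the cost of a one-voxel-ragged interface — not unlike a manual
  tracing. With zero swelling the construction is exactly symmetric.
- **Lesion**: the N ipsilateral voxels nearest a lateral cortico-striatal
  seed point, N = lesion_fraction × ipsilateral voxel count — contiguous,
  spanning the central slices, exact in fraction up to rounding. The
  ischemic-core ROI is the slice-wise morphological erosion of the lesion
  (3 iterations, falling back to 2, 1, then the full lesion so it is never
  empty).
- **Signal and noise**: per-voxel `S0·exp(−TE/T2)` with region values
  (defaults: tissue 50 ms, lesion 70 ms, CSF 150 ms; S0 1000/950/1100).
  Rician noise is the magnitude of a complex Gaussian perturbation; `snr`
  is defined as the *first-echo tissue* SNR, so σ = S0_tissue·exp(−TE1/
  T2_tissue)/snr. Gaussian noise (clipped at zero) and noiseless modes
  exist for testing. Identical specs produce bit-identical phantoms.

Ground-truth volumes are the voxel counts of the drawn masks (×voxel
volume): truth is what was actually rasterized, not the continuum target,
so recovery tests isolate pipeline error from rasterization error.

**Cohorts** draw per-animal lesion fraction, swelling factor and lesion T2
from per-group truncated normal distributions; per-animal seeds derive
deterministically from the master seed via `SeedSequence(master_seed,
spawn_key=(group, animal))`, so a whole study regenerates from one integer.
The `paperlike_cohort_defaults` preset (two groups, n = 8) uses group means
obtained by inverting typical 24-hour outcome values through the volumetry
formulas — treatment lesion fraction 0.33 ± 0.09 with swelling
0.088 ± 0.045 and lesion T2 69.5 ± 9.7 ms; control 0.17 ± 0.06,
0.045 ± 0.022, 59.2 ± 5.2 ms — so simulated %HLV and ΔT2 endpoints land
near commonly reported values (~27% vs ~14% corrected; ~19 vs ~9 ms). It
is a qualitative design preset, not a claim of equivalence to any real
cohort; in particular the simplified ellipse geometry yields midline shifts
of ~0.1–0.3 mm, smaller than typically reported for severe edema.

An optional mask perturbation (in-plane dilation/erosion of the lesion
boundary by k voxels) exists to study tracing variability; by default truth
masks feed the pipeline unperturbed, isolating the computation from
segmentation error.

**What passing phantom tests do not show.** Phantoms have piecewise-
constant T2, no partial-volume mixing at boundaries, no B0/B1
inhomogeneity, no motion, and segmentation-free masks. Recovery on phantoms
therefore validates the arithmetic of the pipeline and its noise behavior,
not robustness to real segmentation disagreement or field artifacts.

## Problem sizes and numerical choices

- Whole-volume map fits loop only over voxels with ≥3 echoes above the
  floor; the log-linear path is closed-form (no iteration).
- The Rician MLE uses Nelder–Mead on (S0, T2) with `log I0` evaluated via
  the exponentially scaled Bessel function for overflow safety.
- Test and acceptance runs use matrices of 48–128 and cohorts of 4–16
  animals, chosen to keep the full suite in seconds-to-minutes on one CPU;
  the power check simulates 100 replicate cohorts at the parameter level
  (endpoints computed through the volumetry formulas), which is exact for
  volumetric endpoints because masks are noise-free by construction.
- Bisection for the interhemispheric shift uses xtol 1e−10 on a bracket
  bounded by 60% of the smallest slice semi-axis; larger swelling factors
  are rejected as geometrically infeasible.

## Known limitations

- Single-compartment T2 only; no EPG/stimulated-echo correction, so real
  CPMG refocusing imperfections would bias absolute T2 (the ipsilateral−
  contralateral difference is less sensitive).
- The exact Mann–Whitney path is O(C(n,k)) and capped at n1+n2 = 12.
- Landmark-based MLS assumes the ventricle is identifiable; the mask-based
  derivation is a synthetic-data convenience, not a clinical method.
- The no-multiplicity convention means families of endpoints inflate the
  family-wise error rate; users comparing many endpoints should correct
  externally.
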