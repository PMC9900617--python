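# Methods

## Linear transformation between timepoints

Given n corresponding fixpoints `(pᵢ, qᵢ)` in the two studies (world
coordinates, mm, one shared right-handed axis convention per dataset — the
loader asserts the convention and never converts), the map `q ≈ A p + t` is
estimated by minimizing `Σᵢ ‖A pᵢ + t − qᵢ‖²` within one of three families:

- **rigid** — `A = R`, `R ∈ SO(3)`: Kabsch solution via SVD of the centered
  cross-covariance, with the determinant sign correction so reflections are
  never returned;
- **similarity** — `A = s R`, `s > 0`: Umeyama's scaled variant;
- **affine** (default) — unrestricted `A`: least squares on the homogeneous
  design `[p | 1]`.

Affine is the default because aneurysm growth implies non-rigid landmark
motion; a growing sac shifts nearby fixpoints outward, which a rigid map can
only absorb as residual. The fit is unweighted (no landmark is privileged),
deterministic, and reports `fit_rms`, the root-mean-square fit residual, an
analogue of the fiducial registration error.

*Minimum pairs*: 4 for affine (12 unknowns), 3 for rigid/similarity.
*Degeneracy*: the condition number of the centered source cloud must stay
below 1e6 — comparing the largest to the 3rd (affine) or 2nd
(rigid/similarity) singular value — otherwise a degenerate-geometry error
names the offending labels. Silent ill-conditioning would corrupt every
downstream motion distance.

One validation landmark (e.g. the inferior mesenteric artery or a calcified
plaque) is structurally held out of the fit. The transformation is accepted
iff its prediction error is **strictly** below 15 mm (configurable). Motion
of the tracked maxima — the target-registration-error analogue — is measured
in CT2 coordinates as `‖(A p + t) − q_actual‖`; measuring motion on a
rejected transformation requires an explicit, warned override. Patients
failing the gate stay in the change analyses but are excluded from all
motion analyses; the inclusion rule concerns the transformation step, not
the morphometry.

## Vessel model and morphometry

The vessel is a centerline polyline with per-station lumen and outer-contour
radii — the reduced form of what segmentation tools export. Definitions:

- **tortuosity index** = arclength / straight-line distance between two
  named stations (lowest renal artery → aortic bifurcation for the aortic
  index; bifurcation → inguinal ligament on a separate iliac branch for the
  iliac index, reported missing when no branch is supplied);
- **maximum diameter** = 2 × max radius of the chosen profile, perpendicular
  to the centerline by construction; ties break toward the proximal station
  and are logged;
- **ILT thickness** is radial per station (outer − lumen radius), a
  simplification of 3-D normal-distance thickness, adequate here because the
  synthetic generator uses the same definition;
- **α / β angles** = angles between mean unit tangents averaged over
  15 mm-arclength windows on either side of the lowest renal artery (α) and
  of the aneurysm start (β). Window averaging (rather than two-point chords)
  makes the angles robust to sampling density; the window length is a
  declared parameter of this package, not a reproduction of any clinical
  tool's internal setting;
- **volumes** by conical-frustum integration of the radius profiles along
  arclength; the vessel wall is not modelled separately, so vessel volume is
  everything inside the outer contour and ILT volume = vessel − lumen,
  exactly, by construction.

Volumes are carried in mm³ throughout (cohort-scale vessel volumes are
O(10⁵) mm³, i.e. 100–200 mL-scale × 10³).

## Biomechanical surrogate

Finite-element stress analysis is out of scope; the surrogate produces a
controllable stress/strength field over the centerline stations:

    σ(s) = P · r_outer(s) / (2 t_wall) · exp(−k · ILT(s))        [kPa]
    S(s) = max(floor, S₀ − c · ILT(s))                           [kPa]
    rupture index(s) = σ(s) / S(s);  PWS = max σ;  PWRI = max σ/S

Defaults: wall thickness `t_wall` = 2 mm, attenuation `k` = 0.03 /mm, base
strength `S₀` = 800 kPa, strength loss `c` = 15 kPa/mm, floor = 300 kPa.
The analysis pressure defaults to the mean arterial pressure of the
standardized 140/80 mm Hg (diastolic + pulse pressure/3, ×0.133322 kPa per
mm Hg ≈ 13.3 kPa); systolic analysis is a flag. The spherical Laplace factor
`r/2t` (not the cylindrical `r/t`) is used since a fusiform bulge is closer
to a spherical cap; the choice only scales the field. The exponential ILT
term buffers stress under thick thrombus and the strength loss concentrates
the rupture index there, so the PWS and PWRI locations can dissociate —
which the motion analysis needs. The field is linear in pressure and its
argmax locations are pressure-invariant, mirroring the clinical observation
that maxima positions are insensitive to blood pressure. "Mean ILT stress"
is exported as the mean stress over stations with ILT > 0 and labelled a
proxy. Surrogate magnitudes (PWS ≈ 60–80 kPa on the synthetic anatomy) are
not FEM magnitudes and are not meant to be.

## Synthetic cohort

What the generator emulates: paired-timepoint landmark sets and vessel
models with (i) a planted linear transformation between studies, (ii)
isotropic Gaussian landmark noise, default sd 1.5 mm — the slice-thickness
scale of usable CTA (studies at ≥2.5 mm slices being excluded from such
analyses), (iii) annual diameter growth lognormal with median 3.7 mm/y and
IQR 2.25–5.44 (σ solved from the quartile ratio), (iv) max-point motions
applied **tangentially** to the local surface in the CT2 frame so true
motion never aliases into radial growth, with lognormal magnitude (median
10 mm, σ 0.8) drawn **independently** of every geometric change, and (v) a
cohort-level correlation structure between the vessel-volume change and the
PWS/PWRI changes.

Correlation planting. Annual change rates of vessel volume, PWS and PWRI are
lognormal with a Gaussian copula. Absolute deltas are rate × interval
(interval uniform 6–24 months, shared across the three deltas of a patient).
The population Pearson correlation of two such deltas has a closed form in
the latent correlation ρ_z, the lognormal σ's and the first two moments of
the interval factor; the generator inverts it numerically (Brent) per pair
so the *delta-scale* Pearson correlation equals the configured target
(defaults 0.68 and 0.60 against volume, 0.75 between PWS and PWRI). The
3×3 latent matrix is checked for positive definiteness and infeasible
targets raise. The volume-rate median is calibrated once from the template
geometry so that the median rate corresponds to one median year of diameter
growth; the growth distribution stays the single dial.

Geometric realization. The drawn volume delta is realized exactly: outer
radii in the aneurysm region are scaled by `s`, the frustum volume is a
quadratic polynomial in `s`, and `s` is the positive root nearest 1. The
lumen scales by `1 + 0.45(s−1)`, so ILT volume grows faster than lumen
volume, as in growing aneurysms. The CT2 PWS/PWRI record values are the CT1
surrogate values plus the drawn deltas — emulating FEM outputs, which are
not a deterministic function of a reduced centerline model; the surrogate
itself stays fully deterministic and is what the measurement pipeline
computes on any model it is given. CT2 centerlines get small angulation and
tortuosity perturbations (β drifting upward a couple of degrees over an
interval) so the angle/tortuosity deltas are realistic rather than zero.

Reproducibility: one global seed; per-patient generators derive from
`(seed, patient_index)` via numpy `SeedSequence` stream splitting, so
generation is order-independent and bit-reproducible.

What it does *not* emulate: real segmentation error structure (noise is
isotropic and station-independent), wall thickness variation, non-fusiform
(saccular) morphology, iliac aneurysms, and any coupling between max-point
motion and growth. Passing tests therefore demonstrate the pipeline's
correctness and calibration under these stated conditions, not the clinical
magnitudes of real cohorts.

## Statistics

- Quartiles: linear interpolation (numpy default, R type 7) — stated because
  IQRs differ across conventions.
- Paired CT1→CT2 changes: two-sided Wilcoxon signed-rank; zero differences
  dropped (classic Wilcoxon convention) and counted; exact enumeration for
  n ≤ 25 without ties, else normal approximation with continuity and tie
  correction. All differences zero → degenerate result (p = 1, flagged).
- Group splits: two-sided Mann-Whitney rank-sum; exact for m + n ≤ 20
  without ties. High/low motion groups split at the median, ties assigned
  to the low group (logged).
- Correlations: Pearson r with two-sided t-based p (n − 2 df),
  pairwise-complete missing handling with effective n reported.
- Percent change and per-12-month normalization are computed **per patient
  first**, then summarized — never as ratios of cohort medians; patients
  with a zero CT1 value are excluded from that variable's percent change
  (logged).
- No multiple-testing correction in the primary tables; a Benjamini-Hochberg
  column is available opt-in and clearly labelled an extension.

The paired signed-rank test is used for CT1-vs-CT2 comparisons and the
rank-sum test only for independent group splits; labels in the outputs name
the test actually run.

## Problem sizes and numerical choices

Synthetic centerlines use 1 mm stations (~160 per aorta), enough that
refinement halves change tortuosity and volumes by < 0.1%. The acceptance
checks run 200 planted-transform recoveries, 500-patient gate calibrations,
and 1000–2000 replicate cohort draws for the correlation and type-I
calibrations; these sizes give Monte-Carlo standard errors comfortably
below the asserted tolerances. Angle computations clip cosines into
[−1, 1]; angles live in [0, 180). Tie-breaks everywhere are proximal
(smallest station index) and logged.

## Known limitations

- The surrogate is a per-station 1-D field; no circumferential stress
  variation, so max points sit on the outer contour at a station rather
  than anywhere on a 3-D surface.
- Radial ILT definition understates thickness on strongly curved segments.
- The affine mode absorbs uniform growth into the matrix; motion distances
  are therefore conservative for points far outside the fixpoint cloud.
- The iliac branch is a polyline for tortuosity only; no bifurcated 3-D
  iliac modelling.
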