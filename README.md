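# aaamotion

Landmark-based motion analysis of sequential abdominal aortic aneurysm (AAA)
imaging.

Abdominal aortic aneurysms are followed with repeated CT angiography until
repair. Beyond the maximum diameter, biomechanical markers — peak wall stress
(PWS) and the peak wall rupture index (PWRI, the maximum local ratio of wall
stress to wall strength) — and the intraluminal thrombus (ILT) are tracked
between studies. A natural question for anyone following these markers is
whether the *locations* of the maxima are stable while the aneurysm grows:
if the point of maximum stress wanders between two scans, pointwise
comparisons of "the" hotspot are comparing different places.

`aaamotion` implements the analysis pipeline for that question, for vascular
researchers working with paired-timepoint landmark and morphometry data:

1. **Registration.** From up to nine corresponding anatomical fixpoints
   (renal arteries, SMA, aortic bifurcation, iliac and lumbar arteries) with
   coordinates `x, y, z` in mm, the CT1→CT2 linear transformation
   `p ↦ A p + t` is estimated by least squares — rigid (orthogonal
   Procrustes), similarity, or full affine (default). A held-out validation
   landmark gates the fit: the transformation is accepted only if
   `‖A v₁ + t − v₂‖ < 15 mm` (strict).
2. **Motion.** The CT1 points of maximum ILT thickness, PWS and PWRI are
   projected into CT2 and their spatial motion measured as the Euclidean
   distance to where the maxima actually appear in CT2.
3. **Morphometry.** From a centerline + radius vessel model: maximum outer
   and lumen diameters, maximum ILT thickness, neck length/diameter, α and β
   neck angulation, aortic/iliac tortuosity indices (arclength/raceline),
   and lumen/vessel/ILT volumes by frustum integration.
4. **Biomechanical surrogate.** An analytic stand-in for finite-element
   stress analysis: thin-wall Laplace stress `σ = P·r/(2t)·exp(−k·ILT)` and
   a linear ILT strength loss clamped at a floor, at a standardized pressure
   of 140/80 mm Hg. It produces plausible, controllable maxima and their
   locations; it does not reproduce FEM magnitudes.
5. **Cohort statistics.** Per-variable change tables (median [IQR], Wilcoxon
   signed-rank p, per-patient changes normalized per 12 months), Pearson
   correlation of metric deltas with ΔPWS/ΔPWRI, motion-vs-delta
   correlations, and high-vs-low-motion rank-sum group comparisons.
6. **Synthetic cohort generator.** Paired-timepoint patients with planted
   transformations, tangential max-point motions drawn independently of all
   geometric change, landmark noise at slice-thickness scale, and a
   calibrated Gaussian copula giving the configured Pearson correlation
   between the vessel-volume and PWS/PWRI changes.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1   # 32 synthetic patients
python analysis/02_register_and_motion.py        # fit, gate, measure motion
python analysis/03_cohort_statistics.py          # cohort tables
python analysis/04_calibration_checks.py --seed 1
```

prints (abridged):

```
simulated 32 patients (seed 1)
annual diameter growth: median 4.80 mm/y [IQR 2.40-6.11]
32/32 patients passed the <15 mm validation gate
validation distance: median 3.09 mm
motion max_ilt: median 9.9 mm [IQR 6.1-12.5]; median recovery error vs planted 0.75 mm
motion max_pws: median 10.0 mm [IQR 5.4-14.6]; median recovery error vs planted 0.73 mm
...
  ilt_volume: delta 2.27e+04 (42.2%), p = 8.3e-07
delta vessel volume vs delta PWS: r = 0.43 (p = 0.013)
motion-vs-delta correlations significant: 1/48
gate pass rate at noise sd  1.5 mm: 1.000
gate pass rate at noise sd 10.0 mm: 0.300
mean sample r over 1000 cohorts (target 0.68): 0.693
motion-vs-delta false-positive rate at alpha 0.05: 0.047
```

Reading this: the transformation gate accepts every patient at realistic
landmark noise; the measured max-point motions recover the planted ones to
sub-millimetre target-registration error; volume and ILT changes are highly
significant while the motions of the maxima correlate with none of them
(1/48 nominally significant, consistent with chance), mirroring the
independence built into the generator. A single 32-patient cohort's sample
correlation (0.43 here) scatters widely around the planted 0.68; the mean
over 1000 cohorts recovers it.

The same pipeline runs from the command line on any landmark CSV with
columns `patient_id, timepoint, label, role, x_mm, y_mm, z_mm`:

```sh
aaamotion simulate --n 32 --seed 1 --out data/
aaamotion register --landmarks data/landmarks.csv --mode affine --threshold 15 --out reports.json
aaamotion analyze --records data/records.csv --out tables/
aaamotion run --seed 1 --out out/
```

## Layout

- `src/aaamotion/` — library: `registration`, `geometry`, `biomech`,
  `synthcohort`, `stats`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and acceptance tests (independent oracles:
  SVD Procrustes, explicit normal equations, brute-force enumeration of
  signed-rank and rank-sum null distributions).
- `docs/methods.md` — models, parameters, conventions and limitations.
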