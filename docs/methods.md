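# Methods

## Scope and data model

The package implements the analysis stages that run *after* spatial
normalisation: all volumes are assumed to live on one axis-aligned 0.5 mm
isotropic grid in a standard space. Registration, bias-field correction and
brainstem parcellation are deliberately out of scope; the pons mask and the
anatomical slab boundaries are inputs. Only diagonal (RAS+, axis-aligned)
NIfTI affines are accepted; anything else raises an unsupported-geometry
error rather than silently resampling.

World coordinates are voxel-centre based; x runs left→right, y
posterior→anterior, z inferior→superior. Axial slice numbering is a
configurable anchored convention, defaulting to slice 112 ↔ z = −16 mm at
0.5 mm spacing (so slice 86 ↔ z = −29 mm). Slice numbering drifts across
template versions, which is why it is a convention object rather than a
constant.

## Segmentation model

Within per-hemisphere searching areas (stacks of 2.5 mm discs, one per
axial slice over slices 86–112, following a per-slice centre path), voxels
are classified LC iff their repeat-averaged MT-on intensity is strictly
greater than

    T = Mean_REF + k · SD_REF,   k = 5 (default), k = 4 selectable.

Conventions that the printed geometry pins down or that we fixed once:

- **Disc membership** is centre-within-radius with a closed disc (≤). At
  0.5 mm resolution a 2.5 mm disc centred on a voxel centre covers exactly
  21 voxels, giving the 567-voxel / 70.88 mm³ searching area that matches
  the 72 mm³ cubic references. No other membership rule reproduces those
  matched volumes.
- **Strict inequality** at T: a voxel exactly at threshold is *not* LC
  ("greater by more than k SDs"); consequently a voxel at T has CNR
  exactly k, which the tests assert as an algebraic identity.
- **Sample SD (n−1)** everywhere. The estimator is not dictated by the
  formulas; the unbiased-variance default was chosen once and used
  consistently for SNR, thresholds and CNR.
- **Hemispheres**: world x < 0 left, x > 0 right, x = 0 excluded. The
  default grid places no voxel centre at x = 0.
- **Peaks** (per slice/hemisphere) are the segmented voxel of maximal CNR;
  ties break to the lowest (x, then y) scan-order index and are flagged.
  Slices with no suprathreshold voxel produce explicit missing records;
  downstream SDs use pairwise deletion, never imputation.

MTR maps pair a *single* MT-on repeat with the MT-off scan; segmentation and
CNR use the 3-repeat average. These are distinct pipelines on purpose: MTR
is a physical tissue ratio of one acquisition pair, while segmentation wants
the best available SNR. MT-off voxels below 1e-6 of the volume maximum are
flagged missing in the MTR map rather than producing infinities.

## Reference-region evaluation

Six candidates are scored per subject on the averaged MT-on image (mean,
SD, SNR) and on the MTR map (mean MTR). Paired two-sided t-tests (α = 0.05,
uncorrected — a known limitation, matching common practice for six regions)
compare left vs right mean signal for the tegmentum pair, the peduncle pair
and the two searching areas. The suitability rule — our formalisation of a
qualitative criterion — is: *gate out* lateral candidates whose pair shows a
significant asymmetry (a biased bilateral baseline), then *rank* the
survivors by cohort-mean SNR with cohort-mean MTR as tie-break. On the
default phantom this selects the central tegmentum cube: it is the only
pure-tissue candidate (the dorsal cube abuts the ventricle stripe, the
lateral cubes clip the peduncles, the peduncle clones have lower signal),
so its SNR is highest.

## Probabilistic atlas

The atlas is the voxelwise mean of n binary masks, computed from integer
subject counts so every probability is an exact multiple of 1/n.
Thresholding keeps voxels with probability ≥ p (implemented as count ≥
⌈p·n⌉ to avoid float-boundary artefacts); p may be a fraction or a percent;
p = 0 returns the union. ≥ rather than > is a documented convention — the
printed voxel counts of the reference templates cannot disambiguate it.
Slice profiles (mean / median / max) are computed over nonzero-probability
voxels only, with the median lower-interpolated on the discrete k/n grid so
it is itself an attainable probability.

Atlas-based CNR averages the CNR map within a fixed thresholded template,
identical for all subjects. The ablation driver (`analysis/04`) shows why:
removing the caudal half of the nucleus in half the cohort drops the
atlas-based CNR by ~2.2 while the segmentation-restricted mean CNR barely
moves (the segmentation shrinks around the surviving bright core) — i.e.
averaging over a subject's own suprathreshold voxels conflates volume loss
with contrast and can mask degeneration.

## The phantom cohort

The generator emulates the statistical structure the analysis assumes, not
the MR physics. Signal model: `MT_on = MT_off · (1 − MTR(tissue))`, so a
noiseless pair recovers the configured tissue MTRs exactly. Defaults, with
rationale:

| parameter | default | why |
|---|---|---|
| n_subjects / n_repeats | 53 / 3 | the study conditions being emulated (159 MT-on scans) |
| grid | 48×48×40 @ 0.5 mm, origin (−11.75, −11.75, −32) | pons-sized field; slab slices 86–112 on-grid; no voxel at x = 0 |
| tissue MTR | pons 0.45, SCP 0.55, LC 0.25, ventricle 0.02 | orders the MT-on intensities: ventricle > LC > pons > SCP, the contrast pattern the method exploits |
| MT-off baseline | 1000 (ventricle 800) | arbitrary scanner units |
| noise SD | 27.5 | single-repeat pontine MT-on SNR = 550/27.5 = 20 |
| nucleus radius | 0.6 → 1.25 → 0.6 mm (caudal → mid → rostral) | rod ~1–2.5 mm wide, thickest centrally |
| contrast amplitude | 0.55 → 1.0 → 0.75 | rostrocaudal contrast gradient, weakest caudally |
| radial droop | 0.3 at the tube edge | contrast peaks at the core, making per-slice peak localisation meaningful |
| jitter SD | 0.6 mm caudal → 0.25 mm central/rostral | caudally increasing between-subject spatial variability |
| ages / sex | uniform 52–84, 24/53 female | the emulated cohort's demographics |

Noise is additive Gaussian, not Rician: the pipeline consumes averaged
magnitude images at high SNR, where the Rician correction is negligible and
out of scope. Partial-volume fractions at the tube boundary come from the
*exact* disc/voxel-square overlap area (closed-form clipped-chord integral,
verified against Monte-Carlo), so sub-voxel jitter shifts edge-voxel
intensities smoothly; truth masks are voxels with in-plane fraction ≥ 0.5.
Per-slice jitter is drawn independently per subject, hemisphere and slice
from N(0, σ(z)²). Per-subject streams derive from
`SeedSequence([seed, subject_index])`: cohorts are reproducible and
subjects independent. A bright midline ventricle stripe and dark peduncle
rods exercise the searching-area placement and the reference gating.

What the phantom does **not** model — and what passing tests therefore do
not show about real data: registration error (the dominant real-world
uncertainty), B1/bias fields, motion, physiological noise, true
between-subject anatomical variability beyond translation jitter, and any
age or sex effect on contrast (by design, so null calibrations are exact).
Recovery numbers (Dice ≈ 0.90) are an upper bound for idealised geometry,
not a claim about in-vivo accuracy.

## Numerical and statistical choices

- Age effects: OLS of a CNR measure on age (statsmodels), reporting F with
  its (1, n−2) degrees of freedom, p, R², slope/intercept with SEs; an
  older-subgroup filter (age > 60) is supported. Sex: two-sided
  pooled-variance t-test, df = n−2. Left/right "collapsed" values are the
  hemispheric mean (the collapsing rule is not otherwise specified).
- Type-I calibration resamples pipeline CNR values against freshly drawn
  ages (independence by construction) over 2000 replicate cohorts of n = 53;
  the binomial SE of the rate estimate is then ~0.005, well inside the
  ±0.02 acceptance band around the nominal 0.05.
- Bayesian model comparison and canonical correlation analogues of the
  frequentist tests are out of scope; the report schema reserves a
  `bayesian` field so they can be added without a format change.
- Problem sizes: the shared test-suite recovery run uses 20 subjects; the
  acceptance script runs the full 53-subject, 3-repeat cohort (a few
  seconds on one CPU) plus 200 noise realisations for the averaging-gain
  check and 2000 replicates for the calibration. These sizes give
  Monte-Carlo errors comfortably below the tolerances they are checked
  against.
- Determinism: every stochastic quantity flows from one top-level seed; the
  report JSON (sorted keys, runtime excluded) and all TSV tables are
  byte-identical across reruns with the same seed and config.

## Known limitations

- The searching-area centre path defaults to the phantom's true mean
  centreline — a deliberate idealisation (the real protocol draws it
  manually on a group template). Mis-centred paths are configurable for
  robustness experiments.
- Thresholded-atlas voxel counts depend on the ≥ convention at the exact
  k/n boundaries; with other data or conventions counts may differ by the
  boundary voxels.
- Six uncorrected paired tests in the reference evaluation; with many more
  candidates a multiplicity correction would be needed.
- The phantom's amplitude profile is shape-matched, not fitted; absolute
  CNR values are not comparable to any particular scanner's output.
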