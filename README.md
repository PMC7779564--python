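# coeruleus

Semi-automated mapping of the locus coeruleus (LC) from magnetisation-
transfer (MT) weighted MRI: threshold-based segmentation, population
probabilistic atlas construction, and unbiased contrast-to-noise (CNR)
extraction — with a synthetic phantom cohort that provides ground truth for
every stage.

The LC is a small rod-shaped noradrenergic nucleus in the dorsal pons
(~1–2.5 mm wide, ~13.5 mm long). Because its magnetisation-transfer ratio is
low relative to the surrounding tegmentum, it appears *hyperintense* on
MT-on images, which makes a simple intensity threshold a viable segmentation
rule — provided the threshold is anchored to a well-chosen reference region.
This package is for neuroimaging researchers who want a tested, reproducible
implementation of that pipeline (and of the checks behind it), operating on
spatially normalised NIfTI volumes at 0.5 mm isotropic resolution.

## The method

Given a repeat-averaged MT-on volume and a reference region REF:

- **SNR** = Mean/SD over a region (sample SD throughout).
- **MTR(%)** = (MT_off − MT_on)/MT_off × 100, voxelwise.
- **Segmentation threshold** T = Mean_REF + k·SD_REF with k = 5
  (a more liberal k = 4 variant is selectable). A voxel inside the bilateral
  searching area belongs to the LC iff its intensity is strictly greater
  than T.
- **CNR** = (V − Mean_REF)/SD_REF, voxelwise; a voxel exactly at the k-SD
  threshold has CNR = k.
- **Searching area**: one 2.5 mm-diameter disc per axial slice over slices
  86–112 (z = −29 … −16 mm; 27 slices spanning 13.5 mm), per hemisphere —
  567 voxels = 70.88 mm³, volume-matched to the 4 × 4 × 4.5 mm (72 mm³)
  cubic reference candidates.
- **Reference choice**: among six candidates (central/dorsal/left/right
  pontine tegmentum, left/right superior cerebellar peduncle), pick the one
  with highest cohort SNR then MTR, after gating out laterally asymmetric
  candidates (paired left-right t-tests).
- **Probabilistic atlas**: voxelwise average of the cohort's binary masks
  (all probabilities are exact multiples of 1/n), thresholded at 5%
  (sensitive) and 25% (specific) to fixed templates.
- **Atlas-based CNR**: mean CNR inside the fixed template, the same volume
  for every subject — immune to the volume/contrast conflation that affects
  averaging over each subject's own suprathreshold voxels.
- **Cohort statistics**: per-slice peak-voxel coordinates and their group
  SDs (spatial variability), OLS regressions of CNR on age, and sex t-tests.

Overlap between masks is quantified by the Dice similarity coefficient
DSC = 2|I∩S|/(|I|+|S|).

Because no public per-subject dataset ships with the method, the
`coeruleus.phantom` module generates a 53-subject phantom cohort (3 MT-on
repeats each, 159 scans) whose contrast arises from the same MTR mechanism,
with a rostrocaudal amplitude/width gradient, caudally increasing spatial
jitter, exact sub-voxel partial-volume blending, and additive Gaussian noise
— so recovery of the known truth can be measured.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_recovery_experiment.py
```

prints (seed 1):

```
reference region chosen: central_pt
mean Dice vs truth:      0.900
mean volume error:       16.9%
peak localisation:       98.1% of central slices within one voxel of the true centre
atlas max probability:   100.0%
  5% template: 1012 voxels, 126.500 mm^3
  25% template: 674 voxels, 84.250 mm^3
peak spatial SD:         caudal 0.52 mm > central 0.42 mm (rostrocaudal gradient)
age effect on atlas CNR: F(1,51) = 0.782, p = 0.381, R^2 = 0.015 (no age effect built in)
```

Reading: the data-driven reference evaluation picks the central pontine
tegmentum (the only pure-tissue, symmetric candidate); the 5-SD threshold
recovers the phantom nuclei at Dice 0.90 with a 17% volume error; the peak
voxels track the jittered centreline; and the spatial-SD profile reproduces
the configured caudal > central variability gradient. The age regression is
null, as it must be — the phantom builds in no age effect.

Further drivers: `analysis/03_threshold_sensitivity.py` (4-SD vs 5-SD),
`analysis/04_ablation_experiment.py` (why CNR is extracted in a fixed atlas
volume), `analysis/05_null_calibration.py` (type-I error of the age
regression). Tables land in `results/`, bulky NIfTI output in `scratch/`.

## Layout

- `src/coeruleus/volumes.py` — grid/volume/mask model, NIfTI I/O, slice↔mm convention
- `src/coeruleus/rois.py` — disc rasterisation, searching areas, reference ROIs, Dice
- `src/coeruleus/phantom.py` — synthetic cohort generator with ground truth
- `src/coeruleus/metrics.py` — SNR/MTR/CNR, threshold, reference evaluation
- `src/coeruleus/atlas.py` — segmentation, peaks, probabilistic atlas
- `src/coeruleus/cohort.py` — spatial SD profiles, age/sex statistics
- `src/coeruleus/pipeline.py` — the end-to-end recovery experiment
- `docs/methods.md` — model, assumptions, parameter choices, limitations
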