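# ezdetect

Automatic 3D detection and quantification of photoreceptor **ellipsoid zone
(EZ) disruption** in macular SD-OCT volumes.

The EZ (formerly the IS/OS junction) is the second hyper-reflective band of
the outer retina; its focal loss marks photoreceptor damage after blunt
ocular trauma (commotio retinae) and in many other retinal diseases.  This
package implements a complete, tested voxel-classification pipeline for
measuring the 3D extent and volume of EZ disruption, aimed at researchers
who want a reproducible, scriptable alternative to manual slice-by-slice
grading:

1. **Denoising** — each B-scan is smoothed by a fast bilateral filter
   (range-sample approximation), suppressing speckle while preserving the
   layer boundaries.
2. **Layer segmentation** — 11 retinal surfaces are found by coarse-to-fine
   column-wise dynamic programming on a polarity-signed axial gradient with
   smoothness and ordering constraints, then smoothed by thin-plate splines.
   The volume is flattened to surface 11 (the bottom of the RPE) and the EZ
   slab between surfaces 7 and 8 becomes the volume of interest (VOI).
3. **Per-voxel description** — 57 features per VOI voxel: normalized
   intensity; 5×5×5 block mean and standard deviation; mean absolute
   intensity difference over the 13 half-axes of the 26-neighbourhood at
   steps 1 and 2; and grey-level co-occurrence (GLCM) contrast, correlation,
   energy and homogeneity in each of the 13 directions,

       contrast   = Σ p(x,y)(x−y)²            energy      = Σ p(x,y)²
       correlation = Σ (x−μx)(y−μy)p(x,y)/σxσy  homogeneity = Σ p(x,y)/(1+|x−y|)

   reduced to 10 scores by PCA on standardized features.
4. **Imbalanced classification** — disrupted voxels are rare (one to two
   orders of magnitude rarer than intact ones), so training balances the
   classes by random under-sampling of the majority and classifies with a
   discrete AdaBoost ensemble of decision stumps; evaluation uses
   leave-one-eye-out cross-validation.
5. **Post-processing** — vessel silhouettes (dark shadows that mimic
   disruption) are segmented by a KNN detector on an en face projection of
   the outer retina and removed from the detection; isolated specks and
   holes are cleaned by morphological opening/closing.  The disruption
   volume is `count × voxel volume`, and cohorts are compared with
   SEN/SPE/BAR, Pearson correlation, Bland–Altman limits of agreement and
   Student's *t*-test.

Because clinical OCT datasets cannot ship with the code, the package
includes a first-class **synthetic phantom generator**
(`ezdetect.synthetic_oct`) that renders layered retinas with known
surfaces, planted EZ lesions, vessel shadows and multiplicative speckle —
every stage of the pipeline is tested end-to-end against this exact ground
truth.

## Worked example

Run the whole pipeline on a simulated 6-eye cohort (4 trauma, 2 normal,
128×32×128 voxels, default speckle; leave-one-out training):

```python
from ezdetect import PipelineConfig, run_all

report = run_all(PipelineConfig(seed=1))
for e in report["eyes"]:
    print(e["id"], e["group"], e["sen_pct"], e["spe_pct"],
          e["detected_volume_mm3"], e["truth_volume_mm3"])
```

which prints (formatted):

```
eye        group      SEN%    SPE%    BAR%   det mm3  truth mm3
trauma_00  trauma    98.46   95.34   96.90    0.2077     0.1583
trauma_01  trauma    99.01   91.74   95.37    0.2754     0.2003
trauma_02  trauma    99.51   92.43   95.97    0.2528     0.1707
trauma_03  trauma    99.64   90.59   95.11    0.3560     0.2543
normal_00  normal       --  100.00      --    0.0000     0.0000
normal_01  normal       --  100.00      --    0.0000     0.0000
detected vs truth volume: r = 0.9827  (95% CI 0.3899 to 0.9997)
trauma vs normal volumes: t = 5.859, p = 0.0042
```

Per eye: SEN/SPE/BAR are the voxel-level sensitivity, specificity and
balanced accuracy inside the EZ VOI (normal eyes have no true positives,
so SEN and BAR are undefined and reported as `--`); the volumes are the
detected and planted disruption volumes in mm³.  Detection slightly
over-segments the lesion margin (a dark halo of block features around each
blob), visible as det > truth; the trauma/normal volume separation and the
detected-vs-truth correlation summarize cohort-level agreement (the wide
CI reflects n = 4 eyes).

The same run is available from the shell, along with per-stage subcommands
(`simulate`, `preprocess`, `segment`, `extract-features`, `train`,
`predict`, `postprocess`, `evaluate`):

```bash
ezdetect run-all --seed 1 --out-dir out/
```

`out/` then contains `report.json`, `per_eye.csv`, a Bland–Altman plot and
a manifest with content digests; reruns with the same config and seed are
byte-identical.

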