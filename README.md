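# cartus

Semi-automated femoral cartilage thickness measurement from segmented
ultrasound contours, plus the statistical chain used to interpret it:
test–retest reliability (ICC(2,k), SEM, MDC90), responder classification of
longitudinal change, and limb × time comparative statistics. A synthetic
phantom/cohort generator with analytic ground truth makes every stage
testable without any image data.

## What it does

1. **Geometry** (`cartus.geometry`) — a cartilage band is two x-monotone
   polylines (superior synovial–cartilage border, inferior cartilage–bone
   border) with a manually marked central point and pixel→mm calibration.
   The band is split into medial / intercondylar / lateral regions (the
   intercondylar region is the middle 25% of the medio-lateral extent,
   centred on the central point). Per region: cross-sectional area (shoelace
   on the clipped polygon), bone-interface arc length, and mean thickness
   = CSA / length. Anisotropic calibration is honoured.
2. **Reliability** (`cartus.reliability`) — ICC(2,k) (two-way random,
   absolute agreement, average of k sessions) with an F-based 95% CI,
   SEM = SD·√(1−ICC), MDC90 = 1.654·SEM·√2, and qualitative ICC classes.
3. **Change classification** (`cartus.change`) — per-knee/region
   thickening / thinning / no-change labels against MDC90 (strict
   exceedance), with per-limb participant-level frequency summaries.
4. **Group statistics** (`cartus.groupstats`) — 2×2 within-subject
   (limb × time) repeated-measures ANOVA, paired and independent t-tests,
   Fisher exact test.
5. **Synthetic data** (`cartus.synthetic`) — phantom contours (flat /
   sloped / bicondylar bone, per-region thickness profiles, optional border
   noise) with analytic regional truth, simulated variance-component
   cohorts with injected responders, and PNG mask rasterization.
6. **IO / CLI** (`cartus.io`, `cartus.imagej`, `cartus.cli`) — contour CSV
   + JSON sidecar, ImageJ `.roi` polygon reader, grayscale PNG masks,
   long-format measurement CSVs.

## CLI

```sh
# generate a synthetic cohort fixture
cartus simulate --kind cohort --seed 7 --out fixtures/

# regional thickness from a contour + sidecar
cartus thickness --contour contour.csv --sidecar contour.json --out metrics.csv

# per-region ICC / SEM / MDC table from long-format measurements
cartus reliability --measurements fixtures/measurements.csv --out table.csv

# responder labels and per-limb frequency summary
cartus change --measurements twosession.csv --mdc-table table.csv \
    --out labels.csv --summary-out summary.csv

# limb x time repeated-measures ANOVA per region
cartus compare --measurements long.csv --out anova.csv
```

Measurement CSVs are long-format with columns
`subject, limb, region, session, image_index, thickness_mm`; repeat images
are averaged within a session before any statistics. Rounding (half away
from zero, 2 decimals by default) happens only at the reporting layer.

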