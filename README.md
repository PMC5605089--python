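# balbiani

Quantification of **Balbiani body (Bb) disassembly** and **cytokeratin (CK)
puncta density** in confocal images of zebrafish stage I oocytes, with a
ground-truthed synthetic image generator for validation.

The Balbiani body is a large transient RNP aggregate whose docking and
progressive disassembly at the oocyte cortex defines the animal–vegetal
axis. Two image-derived measurements capture this biology:

1. **Disassembly ratio.** Bucky ball (Buc) immunofluorescence is segmented
   twice — Otsu's threshold for the *total* Buc area (Bb plus relocalised
   cortical signal) and the Intermodes threshold for the brighter Bb-only
   area. The ratio

   `R = area(Buc in Bb) / area(total Buc)`

   is ~1 for an intact Bb and falls toward 0 as Buc is unloaded at the
   vegetal cortex. Per oocyte, `R` is paired with the equivalent-circle
   diameter `d = 2*sqrt(A/pi)` of the oocyte (segmented from the DAPI
   follicle-cell ring with the Percentile threshold), and `R` is regressed
   on `d` by OLS per genotype. Wild-type cohorts show a significant
   negative trend; *macf1a*-mutant-like cohorts (Bb never disassembles) do
   not.

2. **CK puncta density per ROI.** DiOC6 intensity sections the oocyte into
   Bb, nucleus and cytoplasm (plus a perimeter band: cytoplasm within one
   Bb diameter of the membrane). CK-positive puncta are detected by a
   simple threshold and counted per region; density is puncta/µm².
   Region × genotype effects are tested by two-way ANOVA (type-II sums of
   squares) with Tukey HSD.

The three histogram threshold algorithms (Otsu, Intermodes, Percentile) are
implemented from their published definitions and verified against
exhaustive search. Since the study's raw microscopy is not deposited, the
`synth` module renders 4-channel oocyte scenes (DAPI / DiOC6 / Buc / CK)
with known geometry, disassembly fraction and puncta rates, providing the
ground truth for every recovery test. See `docs/methods.md` for the full
model.

## Worked example

Simulate a small wild-type cohort and quantify it:

```bash
balbiani simulate --n-wt 8 --seed 3 --xy-um-per-px 0.7 --out-dir sim
balbiani bb-ratio --manifest sim/manifest.csv --out-dir results
```

which prints (the regression row for the 8-oocyte cohort):

```
8 oocytes quantified, 0 failed
genotype     slope  intercept  r_squared   p_value  n  n_excluded
      WT -0.008571   1.636986   0.822289  0.001885  8           0
```

Reading: over these 8 oocytes, the disassembly ratio falls by ~0.0086 per
µm of oocyte growth; the fit explains 82% of the variance and the negative
slope is significant (p ≈ 0.002). Per-oocyte records land in
`results/bb_records.csv`:

```
oocyte_id,genotype,diameter_um,ratio,...
WT_3_000,WT,117.2,0.682,...
WT_3_001,WT,100.0,1.000,...
...
```

The puncta pipeline runs the same way (`balbiani puncta --manifest ...`)
and writes the density table, the ANOVA table and the Tukey comparisons.
`balbiani print-config` dumps every assumed default (pixel size, filter
radii, thresholds) as YAML; pass a edited copy back with `--config`. Note
the XY pixel calibration defaults to an assumed 0.35 µm/px and must be set
to the instrument's value for real data.

All of this is also available as a library:

```python
from balbiani import SceneParams, make_scene, render_scene
from balbiani.experiments import quantify_stack

scene = make_scene(SceneParams(oocyte_diameter_um=120,
                               disassembly_fraction_f=0.5,
                               bb_position="cortical"), seed=0)
record = quantify_stack(render_scene(scene))
print(record.diameter_um, record.ratio)   # -> 122.4 0.43
```

## Layout

```
src/balbiani/
  core.py         calibrated containers, TIFF I/O, preprocessing filters
  threshold.py    Otsu / Intermodes / Percentile on 256-bin histograms
  synth.py        ground-truthed synthetic oocyte scenes and cohorts
  disassembly.py  boundary, dual-threshold Buc ratio, regression
  puncta.py       ROI segmentation, puncta detection, ANOVA + Tukey
  pipeline.py     manifest-driven runs, reproducible CSV outputs
  experiments.py  simulation experiments behind tests and acceptance
  cli.py          simulate / bb-ratio / puncta / report / print-config
```
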