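# cardiohist

Automated quantification of cardiac structural remodeling from calibrated
three-channel fluorescence micrographs of transversely sectioned myocardium.

Many cardiac pathologies — atrial fibrillation, heart failure, AV block —
remodel the tissue itself: collagen accumulates between individual myocytes
(endomysial fibrosis), myocytes hypertrophy, capillaries rarefy, fibroblasts
proliferate. Quantifying these features by hand is slow and
observer-dependent. `cardiohist` analyzes sections triple-stained with

- **WGA** (wheat germ agglutinin, membranes + extracellular matrix),
- **CD31 / GS-IB4** (endothelium → capillaries),
- **anti-vimentin** (fibroblasts, with endothelial cross-reactivity),

and reports, per image: the overall **fibrosis fraction** (WGA-positive
pixel fraction after Phansalkar local adaptive thresholding), **myocyte
count and size** (seeded watershed segmentation; size as the minimal Feret
diameter `min_θ width_θ`, robust to oblique sectioning), **endomysial septum
width** per neighboring cell pair (sub-pixel intensity line profiles),
the per-cell **cardiomyocyte dissociation index**
`CDI = (# septa > μ_ref + 2σ_ref) / (# septa)`, the spatial **clustering of
enhanced fibrosis** (average local clustering coefficient `C̄` of the
enhanced-septum subgraph against a 1000-permutation null, with
`p = #(C̄_perm < C̄_obs)/N`), **capillary count, size and density per
myocyte** (1.5 µm² size gate, 0.35 circularity gate for sizing), and
**fibroblasts per myocyte** after subtracting the endothelial mask.
Detection quality against manual annotations is scored by centroid matching
(sensitivity, precision, FNR, F1) and Bland–Altman agreement.

Because no annotated micrographs ship with the package, it includes a
first-class synthetic-tissue generator (Voronoi mosaics with per-septum
ground-truth widths, planted enhanced-fibrosis patches, capillaries at
three-cell corners, cross-reactive fibroblast blobs) against which every
stage is tested. See `docs/methods.md` for the full model description.

## Worked example

Generate two synthetic scenes and analyze them unattended:

```bash
cardiohist simulate --out sim --seed 41 --n-images 2
cardiohist run --wga sim/wga --endo sim/endo --fibro sim/fibro \
               --out results --px-per-mm 2000
```

`results/` then contains per-structure tables (`myocytes.csv`, `septa.csv`,
`cdi.csv`, `clustering.csv`, `capillaries.csv`, `fibroblasts.csv`), control
overlays and CDI heat maps per image, and a one-row-per-image
`summary.csv`:

```
 source_id  fibrosis_fraction  myocyte_count  median_min_feret_um  median_septum_width_um  mean_cdi  capillary_count  capillaries_per_myocyte  fibroblasts_per_myocyte
scene_0041           0.245609            110            20.409314                   2.750  0.050498               66                      0.6                 0.745455
scene_0042           0.247112            110            20.494260                   2.625  0.050216               66                      0.6                 0.745455
```

Reading scene_0041: 24.6% of the field is WGA-positive (membranes + ECM);
all 110 cells of the scene were found; the typical myocyte is 20.4 µm
across; the typical endomysial septum is 2.75 µm wide; 5.0% of neighbor
septa exceed the healthy reference mean + 2 SD, so the mean CDI is 0.05 —
unremodeled tissue; 66 capillaries give 0.6 per myocyte; 82 fibroblasts
remain after endothelial subtraction (0.75 per myocyte). With no planted
fibrosis cluster the enhanced subgraph is nearly empty, so the observed
clustering coefficient is 0 (`clustering.csv` carries the permutation
expectation and p-score per image).

Detection can be validated against a manual (here: ground-truth) centroid
list:

```bash
cardiohist validate --manual sim/truth/scene_0041_myocytes.csv \
                    --auto results/myocytes.csv --max-dist 14
# tp=110, fp=0, fn=0, sensitivity=1.0, precision=1.0, fnr=0.0, f1=1.0
```

The same functionality is available as a library:

```python
import cardiohist as ch

spec = ch.SyntheticSpec(seed=1, enhanced_patch=((256., 256.), 80., 3.0))
wga, endo, fibro, truth = ch.generate(spec)
result = ch.analyze_image(wga, endo, fibro)
print(result.summary.mean_cdi, result.clustering.p_score)
```

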