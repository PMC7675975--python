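# Methods

`cardiohist` quantifies structural remodeling of myocardium from calibrated
three-channel fluorescence micrographs of transversely sectioned tissue:
membranes and extracellular matrix stained with wheat germ agglutinin (WGA),
endothelium with CD31 (human) or GS-IB4 (animal), and fibroblasts with an
anti-vimentin antibody. This note describes the analysis model, the choices
that were genuinely open, the synthetic-tissue generator used for testing,
and the limits of what the tests demonstrate.

## Image model and calibration

Input rasters (TIFF/PNG/JPEG/BMP, 8- or 16-bit, grayscale or RGB) are
min–max normalized to [0, 1] per image, so one parameter set serves both bit
depths and typical exposure differences. The user supplies the spatial
calibration in pixels per millimeter; all lengths are reported in µm
(conversion 1000 / resolution per axis, square pixels assumed), areas in
µm², and positions in 0-based pixel coordinates (origin top-left, x =
column, y = row; stated in every CSV header). The intended magnification
range is roughly 200–400×, i.e. pixel sizes around 0.3–1 µm; the defaults
below are tuned for ~0.5 µm pixels and should be rescaled with the
magnification (chiefly the threshold radius and blur sigmas).

## WGA channel: fibrosis and myocyte segmentation

**Thresholding.** WGA-positive pixels are delineated by Phansalkar local
adaptive thresholding, designed for low-contrast stained images: a pixel is
positive iff its intensity exceeds `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))`
with `m`, `s` the local mean and standard deviation over a disk (radius 15
px; k = 0.25, r = 0.5, p = 2, q = 10 — the widely used defaults for images
normalized to [0, 1]). Boundaries use symmetric (mirror) padding. The
overall fibrosis fraction is the fraction of positive pixels.

**Myocyte detection.** The intensity plane is Gaussian-blurred (σ = 2 px)
and cell interiors are found as local minima with prominence at least
`contrast_scale × (mean stained intensity − mean unstained intensity)`
(contrast_scale default 0.5) via the h-minima transform. Minima plateaus
are merged across gaps of up to ~3 px (the transform can split a flat
pocket on floating-point ties). Minima whose surrounding annulus (radii
2–6 px) is more than 60% stained are dark pockets inside solid fibrotic
patches, not cells, and are rejected. Surviving minima seed a watershed of
the blurred intensity over the whole frame, so region boundaries follow the
membrane ridges. Adjacent regions whose shared boundary is mostly (>80%)
unstained are two halves of one cell split by a spurious extra minimum and
are merged.

Each region's *interior* (region minus stained membrane) yields the cell
record: centroid, area, and minimal Feret diameter — the smallest caliper
width over all orientations, computed exactly on the convex hull of the
interior's pixel corners. The minimal Feret is preferred over maximal width
because sectioning is only approximately transverse; it under-estimates
true cell size slightly but consistently across groups. Cells touching the
image border (clipped) or smaller than 20 µm² are excluded from size
statistics but remain nodes of the neighbor graph.

## Neighbor graph and endomysial septum width

Two myocytes are *direct neighbors* when their watershed regions share a
boundary of at least ~6 px (8-connectivity). The length gate matters:
pairs that merely touch at a three-cell junction point are not separated by
a septum whose width could be measured, and treating them as neighbors
injects meaningless widths into the dissociation statistics.

The septum between two neighbors is measured on an intensity line profile.
The crossing point is where the seed-to-seed line selection meets the
shared boundary, preferring contact points at least 8 px away from
three-cell junctions (at a junction the ECM bands of adjacent septa
overlap, so a profile there conflates two septa). The profile is sampled
at 0.25-px steps by bilinear interpolation along the local boundary normal
(estimated from the contact points within 5 px), so the reported width is
the perpendicular septum thickness rather than an oblique chord. The width
is the contiguous above-half-maximum run through the crossing, with the
half-maximum level anchored to the image's membrane brightness (99th
percentile) so that septa narrower than ~2 px, which never reach full
brightness at pixel resolution, are not widened. The run is clipped where
the profile leaves the two cells' own regions or comes closer to a
different incident septum's boundary. For corner-grazing pairs whose seed
line misses the shared boundary entirely, the narrowest of three profiles
spread along the boundary is used, since junction contamination can only
inflate a profile there. A config flag (`profile_on_intensity = False`)
switches to measuring the run on the thresholded mask instead; this is
robust to staining-intensity gradients but inherits the thresholder's
systematic widening (the Phansalkar threshold falls below the
half-intensity level at membrane edges, ≈ +0.3 px per side at the default
parameters), which is why the intensity profile is the default.

## Dissociation index and spatial clustering

A septum is **enhanced** when wider than a reference mean plus two standard
deviations. The reference describes healthy tissue — ideally estimated
from a designated reference image set (`estimate_reference` pools all edge
widths; sample SD, n−1) or supplied in the config for cross-study
comparability. The config default (µ = 2.9 µm, σ = 0.5 µm → threshold
3.9 µm) is a placeholder in the range reported for non-remodeled atrial
myocardium and should be replaced by a cohort-specific estimate in any real
study.

The **cardiomyocyte dissociation index (CDI)** of a cell is the fraction of
its neighbor septa that are enhanced (undefined for isolated cells, which
are excluded from the image mean). The per-image summary also reports the
fraction of cells at least 50% dissociated.

**Clustering of enhanced fibrosis.** Cells joined by enhanced septa form a
threshold subgraph of the neighbor graph; its average local clustering
coefficient (per node `2T/(d(d−1))` for degree ≥ 2, else 0, averaged over
*all* cells) measures how strongly enhanced separations clump. The null
distribution is obtained by shuffling the measured widths over the fixed
edge set (1000 permutations by default): this randomizes which neighbor
pairs are enhanced while preserving the tissue geometry and the number of
enhanced septa. The expected coefficient is the permutation mean; the
p-score is the proportion of permuted coefficients strictly smaller than
the observed one (ties count as not smaller, making the score slightly
conservative). Deterministic given the config seed.

## Endothelial and vimentin channels

Capillaries are segmented by an HSB color gate after a light Gaussian blur
(σ = 1 px): hue in a circular interval (green [80°, 160°] by default),
saturation and brightness ≥ 0.15. Components smaller than 1.5 µm² are
noise and dropped from the count. Circularity is `4πA/P²` with the Crofton
four-direction perimeter estimate, which converges to the true perimeter
with resolution (the weighted chain-code estimate does not, and would make
a digitized disk's circularity *fall* with radius). Components with
circularity ≥ 0.35 are transversely cut and are additionally sized by their
minimal Feret diameter; elongated components still count toward the total.

Vimentin marks fibroblasts but cross-reacts with endothelium, so the
thresholded endothelial mask is subtracted pixel-wise from the thresholded
vimentin mask before counting; a component pushed below the size gate by
the subtraction is dropped entirely. Both counts are normalized per
myocyte from the paired WGA image — robust to concomitant hypertrophy,
unlike per-area densities, which are nevertheless also reported
(capillaries per mm²).

## Validation against manual annotations

Automatic detections are matched to manual centroids one-to-one by greedy
globally-nearest pairing under a distance cap
(`d = √(ΔCx² + ΔCy²)`; cap default: half the median myocyte minimal Feret
in pixels — an uncapped matching would pair distant spurious objects).
Greedy matching is deterministic and agrees with the optimal assignment in
≥ 99% of pairings at histology densities (verified against the Hungarian
algorithm in the tests). From TP/FP/FN: sensitivity TP/(TP+FN), precision
TP/(TP+FP), FNR FN/(FN+TP), F1 2TP/(2TP+FP+FN). Agreement of paired size
measurements is summarized as the mean relative difference (%) with its
t-based 95% CI (Bland–Altman style). Pearson correlation and a two-way
mixed absolute-agreement ICC are provided as thin conveniences.

## Synthetic tissue generator

Because no annotated tissue micrographs are distributed with the package,
every stage is exercised on synthetic scenes with exhaustive ground truth.
The geometric model is a Voronoi mosaic over Poisson-disk seeds: convex-ish
dark cell cross-sections separated by bright septa whose per-edge width is
a base value plus Gaussian jitter, rendered with a 1-px anti-aliased edge
so sub-pixel width recovery is genuinely tested. An optional *enhanced
patch* adds a fixed width to every septum whose midpoint falls inside a
disk (the planted-clustering alternative); optional *fibrotic patches*
replace cells with solid stained regions (optionally containing a dim
pocket that must be rejected by the annulus rule). Capillaries are bright
green disks at three-cell corners — anatomically where they sit, and
inside WGA-positive septa, which exercises channel independence;
fibroblasts are blue ellipses, a configurable fraction co-located with (and
fully covered by) capillaries to emulate endothelial cross-reactivity.

Default study conditions: 512×512 px at 2000 px/mm (0.5 µm pixels), 110
cells of ~14 µm mean diameter, septa 2.5 ± 0.35 µm, 0.6 capillaries and
1.0 fibroblasts per myocyte (25% endothelial-coincident), additive Gaussian
noise with σ = 5% of the membrane–interior contrast in the noisy
condition. These match reported atrial myocyte sizes and inter-myocyte
distances and typical capillary ratios. The clustering calibration uses a
larger 640-px, 170-cell geometry; its null draws widths i.i.d. N(3, 1) µm
against a reference threshold at 3.5 µm — a ~30% enhanced fraction typical
of remodeled tissue, which keeps the clustering coefficient away from the
degenerate all-zero regime; the planted alternative adds 3 µm to septa
inside a 90-px patch against a 2-SD reference threshold.

What the generator does *not* emulate: point-spread blur and vignetting,
chromatic shift between channels, staining-intensity gradients, perimysial
bundle structure, longitudinally cut fibers, and replacement-fibrosis
scars. Passing tests therefore demonstrate correctness of the measurement
machinery on idealized transverse mosaics, not performance on real
sections, which the original validation addressed with manual comparisons.

## Numerical choices and degenerate inputs

- Minimal Feret on pixel regions uses the pixel-corner convention (each
  pixel contributes its four corners), so an axis-aligned n-px-wide bar
  measures exactly n px; collinear regions return 0 with a warning.
- Ground-truth vs. detected cells are identified by the ground-truth label
  at the detected seed pixel (unambiguous), not by centroid proximity.
- At three-cell junctions the ECM bands of adjacent septa overlap, so a
  junction-squeezed pair has no single well-defined width; width-fidelity
  statements are made for cleanly crossed septa (the generator marks these
  `well_formed`: the seed-to-seed path crosses the shared band with no
  third cell involved).
- Degenerate inputs: an empty or full threshold mask aborts myocyte
  detection (no contrast); zero enhanced edges makes the clustering result
  degenerate (p-score undefined); a zero myocyte count flags per-myocyte
  ratios undefined; fewer than 10 pooled reference edges is rejected.
- Determinism: batch output is a pure function of input bytes, config and
  seed; the only stochastic component is the permutation test, seeded from
  the config.

## Problem sizes used in the automated checks

The test suite and the acceptance script size their simulations to run on
a single CPU in a few minutes: 12–20 noisy mosaics (~110 cells each) for
detection recovery, 3 noise-free mosaics for measurement fidelity and CDI
recovery, and 200 null + 50 planted-alternative runs (1000 permutations
each) for the clustering calibration. Larger runs only tighten the Monte
Carlo error of the reported rates.

## Known limitations

- The minimal Feret slightly under-estimates myocyte and capillary size
  for obliquely cut structures — systematic, similar across groups.
- Channels are assumed pixel-aligned; no registration is performed.
- Anisotropic pixels are not supported (a single px/mm calibration).
- The mask-based profile mode inherits the threshold's edge bias; the
  intensity mode assumes membranes reach a consistent brightness within an
  image (anchoring the half-maximum at the 99th percentile).
- Very pronounced replacement fibrosis yields few detectable myocytes;
  fibrosis fraction remains valid but per-myocyte ratios become unstable.
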