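"""Per-image orchestration of the full analysis.

Ties the channel analyses together: WGA thresholding -> fibrosis fraction ->
myocyte segmentation -> neighbor graph and septum widths -> CDI and
clustering; endothelial channel -> capillaries; vimentin channel (minus
endothelial) -> fibroblasts; counts normalized per myocyte.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clustering as clu
from . import septa as sep
from . import vessels as ves
from . import wga
from .config import AnalysisConfig
from .image_io import CalibratedImage


@dataclass
class ImageSummary:
    """One row of ``summary.csv``.

    Medians are taken over the per-structure records of the image (size
    statistics exclude border-clipped and sub-gate cells).  Fields that
    depend on an absent channel, or ratios with a zero myocyte count, are
    None (written as empty CSV cells).
    """

    source_id: str
    fibrosis_fraction: float | None = None
    myocyte_count: int | None = None
    median_min_feret_um: float | None = None
    median_area_um2: float | None = None
    median_septum_width_um: float | None = None
    mean_cdi: float | None = None
    fraction_cdi_ge_50: float | None = None
    observed_cc: float | None = None
    expected_cc: float | None = None
    cc_p_score: float | None = None
    capillary_count: int | None = None
    capillaries_per_myocyte: float | None = None
    capillaries_per_mm2: float | None = None
    median_capillary_feret_um: float | None = None
    fibroblast_count: int | None = None
    fibroblasts_per_myocyte: float | None = None


@dataclass
class ImageResult:
    """Full per-image analysis output (records plus the summary row)."""

    summary: ImageSummary
    wga: CalibratedImage | None = None
    wga_mask: wga.BinaryMask | None = None
    labels: np.ndarray | None = None
    myocytes: list = field(default_factory=list)
    graph: sep.MyocyteGraph | None = None
    cdi: list = field(default_factory=list)
    clustering: clu.ClusteringResult | None = None
    capillaries: list = field(default_factory=list)
    fibroblasts: list = field(default_factory=list)

    def tables(self) -> dict[str, list]:
        """Per-structure CSV rows, tagged with the image id."""
        sid = self.summary.source_id

        def tag(rows):
            return [{"image_id": sid, **r} for r in rows]

        myo = tag(
            {
                "myocyte_id": m.myocyte_id,
                "seed_x_px": m.seed_px[0], "seed_y_px": m.seed_px[1],
                "centroid_x_px": m.centroid_px[0], "centroid_y_px": m.centroid_px[1],
                "area_um2": m.area_um2, "min_feret_um": m.min_feret_um,
                "border_flag": m.border_flag,
            }
            for m in self.myocytes
        )
        septa = tag(
            {
                "id_a": e.id_a, "id_b": e.id_b,
                "septum_width_um": e.septum_width_um, "enhanced": e.enhanced,
            }
            for e in (self.graph.edges if self.graph else [])
        )
        cdi = tag(
            {
                "myocyte_id": r.myocyte_id, "n_neighbors": r.n_neighbors,
                "n_enhanced": r.n_enhanced, "cdi": r.cdi,
            }
            for r in self.cdi
        )
        cl = []
        if self.clustering is not None:
            c = self.clustering
            cl = [{
                "image_id": sid, "observed_cc": c.observed_cc,
                "expected_cc": c.expected_cc,
                "relative_deviation": c.relative_deviation, "p_score": c.p_score,
                "n_permutations": c.n_permutations, "seed": c.seed,
            }]
        caps = tag(
            {
                "capillary_id": c.capillary_id,
                "centroid_x_px": c.centroid_px[0], "centroid_y_px": c.centroid_px[1],
                "area_um2": c.area_um2, "circularity": c.circularity,
                "transverse": c.transverse, "min_feret_um": c.min_feret_um,
            }
            for c in self.capillaries
        )
        fibs = tag(
            {
                "centroid_x_px": f.centroid_px[0], "centroid_y_px": f.centroid_px[1],
                "area_um2": f.area_um2,
            }
            for f in self.fibroblasts
        )
        return {
            "myocytes": myo, "septa": septa, "cdi": cdi, "clustering": cl,
            "capillaries": caps, "fibroblasts": fibs,
        }


def _median(values) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.median(vals)) if vals else None


def analyze_image(
    wga_img: CalibratedImage | None = None,
    endothelial: CalibratedImage | None = None,
    fibroblast: CalibratedImage | None = None,
    config: AnalysisConfig | None = None,
    *,
    wga: CalibratedImage | None = None,
) -> ImageResult:
    """Run the full pipeline on one (partial) channel triple."""
    from . import wga as wga_mod

    if wga is not None:
        wga_img = wga
    config = config or AnalysisConfig()
    source = next(
        (c.source_id for c in (wga_img, endothelial, fibroblast) if c is not None), ""
    )
    summary = ImageSummary(source_id=source)
    result = ImageResult(summary=summary, wga=wga_img)

    myocyte_count: int | None = None
    if wga_img is not None:
        mask = wga_mod.phansalkar_threshold(wga_img, config.phansalkar)
        summary.fibrosis_fraction = wga_mod.fibrosis_fraction(mask)
        myocytes, labels = wga_mod.detect_myocytes(wga_img, mask, config)
        graph = sep.build_neighbor_graph(myocytes, labels)
        sep.measure_septa(wga_img, mask, labels, graph, config)
        cdi_records, mean_cdi = sep.compute_cdi(graph, config.reference)
        result.wga_mask, result.labels = mask, labels
        result.myocytes, result.graph, result.cdi = myocytes, graph, cdi_records

        myocyte_count = len(myocytes)
        summary.myocyte_count = myocyte_count
        sized = [m for m in myocytes if m.size_ok]
        summary.median_min_feret_um = _median(m.min_feret_um for m in sized)
        summary.median_area_um2 = _median(m.area_um2 for m in sized)
        summary.median_septum_width_um = _median(
            e.septum_width_um for e in graph.edges
        )
        summary.mean_cdi = mean_cdi
        summary.fraction_cdi_ge_50 = sep.fraction_dissociated(cdi_records)
        if any(e.enhanced for e in graph.edges):
            cres = clu.permutation_test(
                graph, config.reference, config.n_permutations, config.seed
            )
            result.clustering = cres
            summary.observed_cc = cres.observed_cc
            summary.expected_cc = cres.expected_cc
            summary.cc_p_score = cres.p_score

    endo_mask = None
    if endothelial is not None:
        endo_mask = ves.hsb_threshold(
            endothelial, config.capillary_hsb, blur_sigma_px=config.hsb_blur_sigma_px
        )
        caps = ves.detect_capillaries(
            endo_mask, endothelial.resolution_px_per_mm,
            config.capillary_min_area_um2, config.capillary_circularity_gate,
        )
        result.capillaries = caps
        summary.capillary_count = len(caps)
        summary.median_capillary_feret_um = _median(
            c.min_feret_um for c in caps if c.transverse
        )
        h, w = endothelial.shape
        area_mm2 = (h * w) / endothelial.resolution_px_per_mm**2
        summary.capillaries_per_mm2 = len(caps) / area_mm2
        if myocyte_count:
            summary.capillaries_per_myocyte = len(caps) / myocyte_count

    if fibroblast is not None:
        fib_hsb_mask = ves.hsb_threshold(
            fibroblast, config.fibroblast_hsb, blur_sigma_px=config.hsb_blur_sigma_px
        )
        if endo_mask is None:
            endo_mask = wga_mod.BinaryMask(
                np.zeros(fibroblast.shape, dtype=bool), "absent endothelial channel"
            )
        n_fib, fib_records = ves.fibroblast_count(
            fib_hsb_mask, endo_mask,
            config.fibroblast_min_area_um2, fibroblast.resolution_px_per_mm,
        )
        result.fibroblasts = fib_records
        summary.fibroblast_count = n_fib
        if myocyte_count:
            summary.fibroblasts_per_myocyte = n_fib / myocyte_count

    return result
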