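"""Capillary and fibroblast quantification.

Capillaries are segmented from the endothelial channel (CD31 in human
tissue, GS-IB4 in animal tissue) by HSB color thresholding after a light
Gaussian blur.  Components below 1.5 um^2 are noise; components rounder than
the circularity gate (4*pi*A/P^2 >= 0.35) are transversely cut and get a
minimal Feret diameter, while elongated (obliquely cut) components still
count toward the total.  Fibroblasts come from the vimentin channel after
pixel-wise subtraction of the endothelial mask, correcting for the known
endothelial cross-reactivity of vimentin.  Both counts are normalized per
myocyte, which is robust to concomitant hypertrophy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .config import HsbRange
from .image_io import CalibratedImage
from .wga import BinaryMask, min_feret


@dataclass
class CapillaryRecord:
    capillary_id: int
    centroid_px: tuple[float, float]
    area_um2: float
    circularity: float
    transverse: bool
    min_feret_um: float | None


@dataclass
class FibroblastRecord:
    fibroblast_id: int
    centroid_px: tuple[float, float]
    area_um2: float


@dataclass
class DensityResult:
    """Counts normalized per myocyte (from the paired WGA image).

    Ratios are None (undefined) when the myocyte count is 0.
    ``capillaries_per_mm2`` is the conventional per-area density, reported
    alongside for comparability.
    """

    capillary_count: int
    capillaries_per_myocyte: float | None
    fibroblast_count: int
    fibroblasts_per_myocyte: float | None
    capillaries_per_mm2: float | None = None


def hsb_threshold(
    image: CalibratedImage,
    hsb: HsbRange,
    *,
    blur_sigma_px: float = 1.0,
) -> BinaryMask:
    """Hue-Saturation-Brightness color threshold after Gaussian blur.

    A pixel is marked positive iff its hue lies in the configured circular
    interval, saturation >= ``sat_min`` and brightness >= ``bright_min``.
    """
    if not image.is_rgb:
        raise ValueError("HSB thresholding with a hue gate requires an RGB image")
    rgb = image.pixels
    if blur_sigma_px > 0:
        rgb = np.stack(
            [ndi.gaussian_filter(rgb[:, :, c], blur_sigma_px) for c in range(3)],
            axis=-1,
        )
    hsv = rgb2hsv(np.clip(rgb, 0, 1))
    hue_deg = hsv[:, :, 0] * 360.0
    lo, hi = hsb.hue_min_deg % 360.0, hsb.hue_max_deg % 360.0
    if lo <= hi:
        hue_ok = (hue_deg >= lo) & (hue_deg <= hi)
    else:  # interval wraps around 0 degrees
        hue_ok = (hue_deg >= lo) | (hue_deg <= hi)
    grid = hue_ok & (hsv[:, :, 1] >= hsb.sat_min) & (hsv[:, :, 2] >= hsb.bright_min)
    return BinaryMask(grid=grid, method_tag=f"hsb[{lo:.0f},{hi:.0f}]")


def detect_capillaries(
    mask: BinaryMask,
    resolution_px_per_mm: float,
    min_area_um2: float = 1.5,
    circ_gate: float = 0.35,
) -> list[CapillaryRecord]:
    """Particle analysis of the thresholded endothelial channel.

    8-connected components smaller than ``min_area_um2`` are dropped.  All
    surviving components count; only those with circularity >= ``circ_gate``
    (transversely cut) are sized by their minimal Feret diameter.
    Perimeter uses the Crofton four-direction estimate, which converges to
    the true perimeter with resolution (so a digitized disk's circularity
    approaches 1), making the gate reproducible and scale-consistent.
    """
    px_um = 1000.0 / resolution_px_per_mm
    px_area = px_um * px_um
    labels = sk_label(mask.grid, connectivity=2)
    records: list[CapillaryRecord] = []
    next_id = 1
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if area_um2 < min_area_um2:
            continue
        perim = prop.perimeter_crofton
        circ = 4.0 * np.pi * prop.area / (perim * perim) if perim > 0 else 1.0
        circ = min(float(circ), 1.0)
        transverse = circ >= circ_gate
        feret = min_feret(prop.coords, px_um) if transverse else None
        cy, cx = prop.centroid
        records.append(
            CapillaryRecord(
                capillary_id=next_id,
                centroid_px=(float(cx), float(cy)),
                area_um2=float(area_um2),
                circularity=circ,
                transverse=bool(transverse),
                min_feret_um=feret,
            )
        )
        next_id += 1
    return records


def fibroblast_count(
    vimentin_mask: BinaryMask,
    endothelial_mask: BinaryMask,
    min_area_um2: float = 1.5,
    resolution_px_per_mm: float = 1000.0,
) -> tuple[int, list[FibroblastRecord]]:
    """Count fibroblasts after correcting for endothelial cross-reactivity.

    Components of (vimentin AND NOT endothelial) passing the size gate; a
    component reduced below the gate by the subtraction is dropped entirely.
    The subtraction order is fixed -- vimentin minus endothelial.
    """
    if vimentin_mask.shape != endothelial_mask.shape:
        raise ValueError("vimentin and endothelial masks differ in shape")
    px_um = 1000.0 / resolution_px_per_mm
    px_area = px_um * px_um
    residual = vimentin_mask.grid & ~endothelial_mask.grid
    labels = sk_label(residual, connectivity=2)
    records: list[FibroblastRecord] = []
    next_id = 1
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if area_um2 < min_area_um2:
            continue
        cy, cx = prop.centroid
        records.append(
            FibroblastRecord(
                fibroblast_id=next_id,
                centroid_px=(float(cx), float(cy)),
                area_um2=float(area_um2),
            )
        )
        next_id += 1
    return len(records), records


def densities(
    capillaries: list[CapillaryRecord],
    fibroblasts: list[FibroblastRecord],
    myocyte_count: int,
    *,
    image_area_mm2: float | None = None,
) -> DensityResult:
    """Per-myocyte count ratios (undefined when no myocytes were found)."""
    cap_n, fib_n = len(capillaries), len(fibroblasts)
    if myocyte_count > 0:
        per_myo_cap: float | None = cap_n / myocyte_count
        per_myo_fib: float | None = fib_n / myocyte_count
    else:
        per_myo_cap = per_myo_fib = None
    per_mm2 = cap_n / image_area_mm2 if image_area_mm2 else None
    return DensityResult(
        capillary_count=cap_n,
        capillaries_per_myocyte=per_myo_cap,
        fibroblast_count=fib_n,
        fibroblasts_per_myocyte=per_myo_fib,
        capillaries_per_mm2=per_mm2,
    )
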