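"""WGA-channel analysis: local adaptive thresholding, fibrosis fraction and
cardiomyocyte segmentation.

The membrane/ECM stain (wheat germ agglutinin) is bright; cardiomyocyte
interiors are dark.  Thresholding the channel yields the overall fibrosis
fraction; seeded watershedding of the dark basins yields individual myocytes,
sized by their minimal Feret diameter (robust to slightly oblique
sectioning).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .config import AnalysisConfig, PhansalkarParams
from .image_io import CalibratedImage


@dataclass
class BinaryMask:
    """Boolean grid, same shape as the source image; ``True`` = stained."""

    grid: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class MyocyteRecord:
    """One segmented cardiomyocyte.

    ``seed_px`` is the detecting local minimum, ``centroid_px`` the centroid
    of the cell interior (watershed region minus stained membrane), both as
    (x, y) pixel coordinates.  ``size_ok`` is False for regions excluded from
    size statistics (touching the border, where clipping biases the Feret
    diameter low, or below the minimum area gate); such cells still act as
    nodes of the neighbor graph.
    """

    myocyte_id: int
    seed_px: tuple[float, float]
    centroid_px: tuple[float, float]
    area_um2: float
    min_feret_um: float
    border_flag: bool
    size_ok: bool
    feret_segment_px: tuple | None = field(default=None, repr=False)


# ------------------------------------------------------------- thresholding
def _disk_kernel(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    k = (xx * xx + yy * yy) <= radius * radius
    return k.astype(np.float64) / k.sum()


def phansalkar_threshold(
    image: CalibratedImage | np.ndarray, params: PhansalkarParams | None = None
) -> BinaryMask:
    """Phansalkar local adaptive threshold of the (red-plane) WGA intensity.

    A pixel is marked stained iff its intensity exceeds
    ``t = m * (1 + p*exp(-q*m) + k*(s/r - 1))`` where ``m`` and ``s`` are the
    local mean and standard deviation over a disk of ``radius_px`` around it
    (mirror/symmetric padding at the boundary).  Designed for low-contrast stained
    images normalized to [0, 1].
    """
    params = params or PhansalkarParams()
    if isinstance(image, CalibratedImage):
        plane = image.plane()
    else:
        plane = np.asarray(image, dtype=np.float64)
        if plane.ndim == 3:
            plane = plane[:, :, 0]
    h, w = plane.shape
    if params.radius_px > min(h, w) // 2:
        raise ValueError(
            f"radius_px={params.radius_px} exceeds half the smaller image side"
        )
    kernel = _disk_kernel(params.radius_px)
    m = ndi.convolve(plane, kernel, mode="reflect")
    m2 = ndi.convolve(plane * plane, kernel, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    t = m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1.0))
    return BinaryMask(grid=plane > t, method_tag=f"phansalkar(r={params.radius_px})")


def fibrosis_fraction(mask: BinaryMask) -> float:
    """Fraction of stained (WGA-positive) pixels over the total pixel count."""
    grid = mask.grid
    if grid.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(grid)) / grid.size


# ------------------------------------------------------------ minimal Feret
def min_feret_points(points: np.ndarray) -> tuple[float, tuple | None]:
    """Minimal width over all projection directions of a 2-D point set.

    Returns ``(width, caliper_segment)`` in the units of ``points``; the
    segment spans the minimal width through the hull centroid (for overlay
    rendering).  The minimum width of a convex polygon is always attained
    with one caliper flush against a hull edge, so scanning hull edges is
    exact.  Degenerate (collinear) input returns 0 with a warning.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        warnings.warn("degenerate region (fewer than 3 points); min Feret = 0")
        return 0.0, None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (collinear) region; min Feret = 0")
        return 0.0, None
    verts = pts[hull.vertices]
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    good = lengths > 0
    edges, bases, lengths = edges[good], verts[good], lengths[good]
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    # distance of every hull vertex from every edge line
    diffs = verts[None, :, :] - bases[:, None, :]          # (edges, verts, 2)
    dists = np.abs(np.einsum("kvj,kj->kv", diffs, normals))
    widths = dists.max(axis=1)
    k = int(np.argmin(widths))
    width = float(widths[k])
    center = verts.mean(axis=0)
    n = normals[k]
    seg = (tuple(center - n * width / 2), tuple(center + n * width / 2))
    return width, seg


def _pixel_corner_points(coords_rc: np.ndarray) -> np.ndarray:
    """Expand pixel-center coordinates (row, col) to the 4 corners of each
    pixel in (x, y) convention, so a 10-px-wide rectangle measures 10."""
    rc = np.asarray(coords_rc, dtype=np.float64)
    xy = np.stack([rc[:, 1], rc[:, 0]], axis=1)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (xy[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def min_feret(region, pixel_size_um: float = 1.0) -> float:
    """Minimal Feret diameter of a region, in micrometers.

    ``region`` may be a boolean mask, an (N, 2) array of pixel (row, col)
    coordinates, or an (N, 2) polygon in (x, y) convention when
    ``pixel_size_um`` is interpreted for point data.  Pixel regions are
    expanded to pixel corners before the caliper scan.
    """
    region = np.asarray(region)
    if region.ndim == 2 and region.shape[1] == 2:
        pts = _pixel_corner_points(region)
    elif region.ndim == 2 and region.dtype == bool:
        pts = _pixel_corner_points(np.argwhere(region))
    else:
        raise ValueError("region must be a boolean mask or an (N, 2) coordinate array")
    width, _ = min_feret_points(pts)
    return width * pixel_size_um


# ------------------------------------------------------------ segmentation
def _annulus_offsets(inner: float, outer: float) -> np.ndarray:
    r = int(np.ceil(outer))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.hypot(xx, yy)
    sel = (dist >= inner) & (dist <= outer)
    return np.stack([yy[sel], xx[sel]], axis=1)


def _merge_unstained_splits(
    labels: np.ndarray,
    stained: np.ndarray,
    seeds: dict[int, tuple[float, float]],
    blurred: np.ndarray,
    max_stained_fraction: float = 0.2,
) -> np.ndarray:
    """Resolve watershed over-segmentation.

    Two adjacent regions whose shared boundary is mostly unstained are
    halves of one cell split by a spurious second minimum (there is no
    membrane between them); merge them.  The merged region keeps the seed of
    the deeper minimum.
    """
    h, w = labels.shape
    frac: dict[tuple[int, int], list[int]] = {}
    for dr, dc in ((0, 1), (1, 0)):
        a = labels[: h - dr, : w - dc]
        b = labels[dr:, dc:]
        sa = stained[: h - dr, : w - dc]
        sb = stained[dr:, dc:]
        sel = (a != b) & (a > 0) & (b > 0)
        for u, v, s1, s2 in zip(a[sel], b[sel], sa[sel], sb[sel]):
            key = (int(min(u, v)), int(max(u, v)))
            counts = frac.setdefault(key, [0, 0])
            counts[0] += int(s1 or s2)
            counts[1] += 1
    parent = {int(l): int(l) for l in np.unique(labels) if l > 0}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, v), (n_stained, n_total) in frac.items():
        if n_total >= 4 and n_stained / n_total < max_stained_fraction:
            ru, rv = find(u), find(v)
            if ru != rv:
                # keep the deeper minimum as the surviving seed
                du = blurred[int(round(seeds[ru][1])), int(round(seeds[ru][0]))]
                dv = blurred[int(round(seeds[rv][1])), int(round(seeds[rv][0]))]
                winner, loser = (ru, rv) if du <= dv else (rv, ru)
                parent[loser] = winner
    mapping = {l: find(l) for l in parent}
    if all(k == v for k, v in mapping.items()):
        return labels
    out = labels.copy()
    for old, new in mapping.items():
        if old != new:
            out[labels == old] = new
            seeds.pop(old, None)
    return out


def detect_myocytes(
    image: CalibratedImage,
    mask: BinaryMask,
    config: AnalysisConfig | None = None,
) -> tuple[list[MyocyteRecord], np.ndarray]:
    """Segment individual cardiomyocytes from the WGA channel.

    Steps: (1) Gaussian-blur the intensity plane; (2) derive the detection
    prominence from the mean contrast between stained and unstained pixels;
    (3) find local minima at least that prominent (plateaus merge to one
    marker); (4) reject minima whose surrounding annulus is predominantly
    stained -- dim pockets inside solid fibrotic patches, not cells; (5) seed
    a watershed of the blurred intensity from the surviving minima, splitting
    the unstained space along membrane ridges; (6) measure each region's
    interior (region minus stained membrane).

    Returns the records and the full watershed label grid (0 = no region;
    used downstream for neighbor adjacency).
    """
    config = config or AnalysisConfig()
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    plane = image.plane()
    grid = mask.grid
    blurred = ndi.gaussian_filter(plane, config.blur_sigma_px)

    n_fg = int(np.count_nonzero(grid))
    if n_fg == 0 or n_fg == grid.size:
        raise ValueError("degenerate contrast: mask is empty or covers the image")
    contrast = float(blurred[grid].mean() - blurred[~grid].mean())
    prominence = config.contrast_scale * contrast
    if prominence <= 0:
        raise ValueError("degenerate contrast: stained pixels are not brighter")

    minima = h_minima(blurred, prominence)
    # minima separated by a few pixels belong to one basin plateau (the
    # h-transform can split a flat pocket on floating-point ties); label
    # with a small dilation for connectivity, keep the original pixels
    from skimage.morphology import dilation, disk

    conn = sk_label(dilation(minima, disk(3)), connectivity=2)
    markers = np.where(minima, conn, 0)
    if markers.max() == 0:
        return [], np.zeros_like(markers)

    # red-surround rejection: annulus around the plateau centroid mostly stained
    offsets = _annulus_offsets(config.reject_inner_px, config.reject_outer_px)
    h, w = grid.shape
    keep_ids = []
    seeds: dict[int, tuple[float, float]] = {}
    for prop in regionprops(markers):
        cy, cx = prop.centroid
        ring = offsets + np.array([round(cy), round(cx)])
        ring = ring[(ring[:, 0] >= 0) & (ring[:, 0] < h)
                    & (ring[:, 1] >= 0) & (ring[:, 1] < w)]
        frac = grid[ring[:, 0], ring[:, 1]].mean() if len(ring) else 1.0
        if frac > config.reject_fraction:
            continue
        keep_ids.append(prop.label)
        seeds[prop.label] = (cx, cy)
    if not keep_ids:
        return [], np.zeros_like(markers)
    markers = np.where(np.isin(markers, keep_ids), markers, 0)

    labels = watershed(blurred, markers=markers, connectivity=2)
    labels = _merge_unstained_splits(labels, grid, seeds, blurred)

    px_um = image.pixel_size_um
    px_area = px_um * px_um
    records: list[MyocyteRecord] = []
    for prop in regionprops(labels):
        region_mask = labels == prop.label
        interior = region_mask & ~grid
        coords = np.argwhere(interior)
        if len(coords) == 0:
            continue
        area_um2 = len(coords) * px_area
        cy, cx = coords.mean(axis=0)
        width_px, seg = min_feret_points(_pixel_corner_points(coords))
        r0, c0, r1, c1 = prop.bbox
        border = r0 == 0 or c0 == 0 or r1 == labels.shape[0] or c1 == labels.shape[1]
        records.append(
            MyocyteRecord(
                myocyte_id=int(prop.label),
                seed_px=seeds[prop.label],
                centroid_px=(float(cx), float(cy)),
                area_um2=float(area_um2),
                min_feret_um=float(width_px * px_um),
                border_flag=bool(border),
                size_ok=bool(not border and area_um2 >= config.min_cell_area_um2),
                feret_segment_px=seg,
            )
        )
    return records, labels
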