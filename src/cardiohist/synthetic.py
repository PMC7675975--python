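"""Synthetic three-channel micrographs of transverse myocardium with
exhaustive ground truth.

The geometric model is a Voronoi mosaic over Poisson-disk seed points:
transversely cut myocytes appear as convex-ish dark polygons separated by
bright membrane/ECM septa of controlled per-edge width (base width plus
jitter, plus an optional "enhanced patch" that widens all septa inside a
disk).  Optional solid fibrotic patches replace cells entirely.  Capillaries
are rendered as bright green disks at three-cell corners (where they sit
anatomically, inside the septal ECM); fibroblasts as blue ellipses, a
configurable fraction of them co-located with capillaries to emulate the
endothelial cross-reactivity of vimentin.  Membranes get a 1-px soft edge by
default so sub-pixel septum-width recovery is meaningfully exercised.

Everything the pipeline measures is also available as ground truth computed
from the generating geometry, never from the rendered pixels the pipeline
sees (except the membrane mask itself, which is defined by the noise-free
rendering at the half-intensity level).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, Voronoi, cKDTree

from .config import ReferenceStats
from .image_io import CalibratedImage
from .wga import min_feret_points, _pixel_corner_points


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic scene.

    Defaults emulate human atrial myocardium imaged at ~300x magnification:
    0.5 um pixels, ~14 um myocyte minimal diameter, 2.5 um endomysial septa
    with 0.35 um jitter, ~0.6 capillaries and ~1 fibroblast per myocyte.
    ``noise_sigma`` is additive Gaussian noise in intensity units of the
    [0, 1] scale (membrane-interior contrast is 0.8 by default).
    """

    image_px: tuple[int, int] = (512, 512)          # (width, height)
    resolution_px_per_mm: float = 2000.0
    n_cells: int = 110
    mean_cell_diameter_um: float = 14.0
    septum_width_base_um: float = 2.5
    septum_width_jitter_um: float = 0.35
    #: optional ((cx_px, cy_px), radius_px, added_width_um)
    enhanced_patch: tuple | None = None
    #: list of ((cx_px, cy_px), radius_px) solid fibrotic patches
    fibrotic_patches: list = field(default_factory=list)
    capillaries_per_myocyte_target: float = 0.6
    fibroblasts_per_myocyte_target: float = 1.0
    fibroblast_coloc_fraction: float = 0.25
    capillary_radius_um: float = 2.2
    noise_sigma: float = 0.04
    interior_level: float = 0.1
    membrane_level: float = 0.9
    soft_edge: bool = True
    dim_pocket: bool = False                        # dark pocket inside patch 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_px) < 64:
            raise ValueError("image sides must be >= 64 px")
        for name in ("resolution_px_per_mm", "mean_cell_diameter_um",
                     "septum_width_base_um", "capillary_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("septum_width_jitter_um", "capillaries_per_myocyte_target",
                     "fibroblasts_per_myocyte_target", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return 1000.0 / self.resolution_px_per_mm


@dataclass
class GtEdge:
    """True septum between two neighboring cells.

    ``well_formed`` is False when the direct seed-to-seed path does not cross
    the shared septum cleanly (it passes near a three-cell corner or through
    a fibrotic patch); width recovery is only meaningful on well-formed
    edges.
    """

    id_a: int
    id_b: int
    width_um: float
    in_patch: bool
    well_formed: bool


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, from the generating geometry."""

    seeds_px: np.ndarray                    # (n, 2) as (x, y)
    label_grid: np.ndarray                  # nearest-seed id (1-based), 0 in patches
    membrane_mask: np.ndarray               # noise-free rendering >= half level
    fibrosis_fraction: float
    edges: list[GtEdge]
    cell_centroid_px: dict[int, tuple[float, float]]
    cell_area_um2: dict[int, float]
    cell_min_feret_um: dict[int, float]
    cell_on_border: dict[int, bool]
    capillary_centers_px: np.ndarray        # (k, 2) as (x, y)
    capillary_areas_um2: np.ndarray
    fibroblast_centers_px: np.ndarray       # (m, 2) as (x, y), all blobs
    fibroblast_coloc: np.ndarray            # (m,) bool, endothelial-coincident
    spec: SyntheticSpec

    @property
    def n_cells(self) -> int:
        return len(self.seeds_px)

    @property
    def true_fibroblast_count(self) -> int:
        """Fibroblasts remaining after endothelial subtraction."""
        return int(np.count_nonzero(~self.fibroblast_coloc))

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i + 1: set() for i in range(self.n_cells)}
        for e in self.edges:
            adj[e.id_a].add(e.id_b)
            adj[e.id_b].add(e.id_a)
        return adj


# ------------------------------------------------------------------ helpers
def _poisson_disk(rng, width, height, n, min_dist):
    """Dart-throwing Poisson-disk sampling; raises when infeasible."""
    if n * np.pi * (min_dist / 2.0) ** 2 > 0.62 * width * height:
        raise ValueError("cell density infeasible for the Poisson-disk radius")
    pts: list[np.ndarray] = []
    tree_pts = np.empty((0, 2))
    attempts = 0
    max_attempts = 4000 * n
    while len(pts) < n and attempts < max_attempts:
        cand = rng.uniform((0, 0), (width, height))
        attempts += 1
        if len(pts) == 0:
            pts.append(cand)
            continue
        d = np.min(np.hypot(*(np.asarray(pts) - cand).T))
        if d >= min_dist:
            pts.append(cand)
    if len(pts) < n:
        raise ValueError("cell density infeasible for the Poisson-disk radius")
    del tree_pts
    return np.asarray(pts)


def _disk_level(shape_hw, center_xy, radius_px, soft):
    h, w = shape_hw
    cx, cy = center_xy
    r = int(np.ceil(radius_px)) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    if soft:
        level = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    else:
        level = (dist <= radius_px).astype(float)
    return (slice(y0, y1), slice(x0, x1)), level


# ----------------------------------------------------------------- generate
def generate(spec: SyntheticSpec):
    """Render one synthetic scene.

    Returns ``(wga_image, endothelial_image, fibroblast_image, ground_truth)``
    with the three channels as RGB :class:`CalibratedImage` objects.
    Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_px
    px_um = spec.pixel_size_um

    # --- seeds and geometry
    diam_px = spec.mean_cell_diameter_um / px_um
    seeds = _poisson_disk(rng, w, h, spec.n_cells, diam_px)
    for (pcx, pcy), pr in spec.fibrotic_patches:
        keep = np.hypot(seeds[:, 0] - pcx, seeds[:, 1] - pcy) > pr
        seeds = seeds[keep]
    n = len(seeds)
    if n < 2:
        raise ValueError("fewer than 2 cells remain after patch removal")

    # per-pair true septum widths (um): base everywhere, jitter on Delaunay
    # edges, patch addition where the edge midpoint falls inside the patch
    width_um = np.full((n, n), spec.septum_width_base_um)
    tri = Delaunay(seeds)
    d_edges = set()
    indptr, indices = tri.vertex_neighbor_vertices
    for i in range(n):
        for j in indices[indptr[i]:indptr[i + 1]]:
            if i < j:
                d_edges.add((i, j))
    for (i, j) in sorted(d_edges):
        jit = rng.normal(0.0, spec.septum_width_jitter_um)
        width_um[i, j] = width_um[j, i] = max(
            spec.septum_width_base_um + jit, 0.5
        )
    if spec.enhanced_patch is not None:
        (ecx, ecy), er, added = spec.enhanced_patch
        for (i, j) in sorted(d_edges):
            mid = (seeds[i] + seeds[j]) / 2.0
            if np.hypot(mid[0] - ecx, mid[1] - ecy) <= er:
                width_um[i, j] += added
                width_um[j, i] = width_um[i, j]

    # --- membrane rendering from the two nearest seeds
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    tree = cKDTree(seeds)
    dist, idx = tree.query(pix, k=2)
    d1, d2 = dist[:, 0], dist[:, 1]
    i1, i2 = idx[:, 0], idx[:, 1]
    w_pair_px = width_um[i1, i2] / px_um
    s = (d2 - d1 - w_pair_px) / 2.0          # signed distance to septum edge
    if spec.soft_edge:
        level = np.clip(0.5 - s, 0.0, 1.0)
    else:
        level = (s < 0).astype(float)
    level = level.reshape(h, w)
    label_grid = (i1 + 1).reshape(h, w).astype(np.int32)

    for (pcx, pcy), pr in spec.fibrotic_patches:
        dpatch = np.hypot(xx - pcx, yy - pcy)
        if spec.soft_edge:
            level = np.maximum(level, np.clip(pr - dpatch + 0.5, 0.0, 1.0))
        else:
            level = np.maximum(level, (dpatch <= pr).astype(float))
        label_grid[dpatch <= pr] = 0

    mid_level = (spec.interior_level + spec.membrane_level) / 2.0
    scene = spec.interior_level + (spec.membrane_level - spec.interior_level) * level
    if spec.dim_pocket:
        if not spec.fibrotic_patches:
            raise ValueError("dim_pocket requires at least one fibrotic patch")
        (pcx, pcy), _ = spec.fibrotic_patches[0]
        pocket = np.hypot(xx - pcx, yy - pcy) <= 4.0
        scene[pocket] = spec.interior_level + 0.3

    membrane_mask = scene >= mid_level
    fib_frac = float(np.count_nonzero(membrane_mask)) / membrane_mask.size

    # --- ground-truth neighbor graph from label-grid adjacency, with the
    # same minimum shared-boundary gate the pipeline applies (pairs touching
    # only at a junction point are not neighbors)
    from .septa import MIN_BOUNDARY_CONTACTS

    contact_count: dict[tuple[int, int], int] = {}
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = label_grid[r0:r1, c0:c1]
        b = label_grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        sel = (a != b) & (a > 0) & (b > 0)
        for u, v in zip(a[sel], b[sel]):
            kk = (int(min(u, v)), int(max(u, v)))
            contact_count[kk] = contact_count.get(kk, 0) + 1
    pairs = {k for k, c in contact_count.items() if c >= MIN_BOUNDARY_CONTACTS}
    edges: list[GtEdge] = []
    for (ua, ub) in sorted(pairs):
        i, j = ua - 1, ub - 1
        mid = (seeds[i] + seeds[j]) / 2.0
        # the direct seed-to-seed path crosses the shared septum cleanly iff,
        # everywhere inside (and just around) the septum band, the two
        # nearest seeds are exactly this pair -- otherwise the profile run
        # grazes a third cell's septum near a corner
        seg_len = float(np.hypot(*(seeds[j] - seeds[i])))
        n_samp = max(int(np.ceil(seg_len)), 2)
        ts = np.linspace(0.0, 1.0, n_samp + 1)[:, None]
        samples = seeds[i][None, :] * (1 - ts) + seeds[j][None, :] * ts
        sd, sidx = tree.query(samples, k=2)
        w_px = width_um[i, j] / px_um
        band = (sd[:, 1] - sd[:, 0]) <= w_px + 4.0
        pair_ok = (np.minimum(sidx[:, 0], sidx[:, 1]) == min(i, j)) & (
            np.maximum(sidx[:, 0], sidx[:, 1]) == max(i, j)
        )
        clean = bool(np.all(pair_ok[band])) if band.any() else False
        in_any_patch = any(
            np.hypot(mid[0] - pcx, mid[1] - pcy) <= pr + 2
            for (pcx, pcy), pr in spec.fibrotic_patches
        )
        in_epatch = False
        if spec.enhanced_patch is not None:
            (ecx, ecy), er, _ = spec.enhanced_patch
            in_epatch = bool(np.hypot(mid[0] - ecx, mid[1] - ecy) <= er)
        edges.append(
            GtEdge(
                id_a=ua, id_b=ub,
                width_um=float(width_um[i, j]),
                in_patch=in_epatch,
                well_formed=bool(clean and not in_any_patch),
            )
        )

    # --- per-cell interior geometry
    cell_centroid: dict[int, tuple[float, float]] = {}
    cell_area: dict[int, float] = {}
    cell_feret: dict[int, float] = {}
    cell_border: dict[int, bool] = {}
    interior = ~membrane_mask
    for cid in range(1, n + 1):
        sel = (label_grid == cid) & interior
        coords = np.argwhere(sel)
        if len(coords) == 0:
            continue
        cell_area[cid] = len(coords) * px_um * px_um
        cy, cx = coords.mean(axis=0)
        cell_centroid[cid] = (float(cx), float(cy))
        feret_px, _ = min_feret_points(_pixel_corner_points(coords))
        cell_feret[cid] = float(feret_px * px_um)
        region = label_grid == cid
        cell_border[cid] = bool(
            region[0, :].any() or region[-1, :].any()
            or region[:, 0].any() or region[:, -1].any()
        )

    # --- capillaries at three-cell corners (Voronoi vertices on septa)
    n_cap_target = int(round(spec.capillaries_per_myocyte_target * n))
    cap_centers: list[np.ndarray] = []
    cap_radii_px: list[float] = []
    if n_cap_target > 0:
        vor = Voronoi(seeds)
        margin = 6.0
        verts = [
            v for v in vor.vertices
            if margin <= v[0] < w - margin and margin <= v[1] < h - margin
            and not any(
                np.hypot(v[0] - pcx, v[1] - pcy) <= pr + 4
                for (pcx, pcy), pr in spec.fibrotic_patches
            )
        ]
        rng.shuffle(verts)
        min_sep = 4.0 * spec.capillary_radius_um / px_um
        for v in verts:
            if len(cap_centers) >= n_cap_target:
                break
            if cap_centers and np.min(
                np.hypot(*(np.asarray(cap_centers) - v).T)
            ) < min_sep:
                continue
            cap_centers.append(np.asarray(v, dtype=float))
            r_um = max(float(rng.normal(spec.capillary_radius_um, 0.3)), 1.2)
            cap_radii_px.append(r_um / px_um)
    cap_centers_arr = (
        np.asarray(cap_centers) if cap_centers else np.empty((0, 2))
    )
    cap_areas_um2 = np.array(
        [np.pi * (r * px_um) ** 2 for r in cap_radii_px]
    )

    # --- fibroblasts: ellipses, a fraction co-located with capillaries
    n_fib_target = int(round(spec.fibroblasts_per_myocyte_target * n))
    n_coloc = min(
        int(round(spec.fibroblast_coloc_fraction * n_fib_target)), len(cap_centers)
    )
    fib_centers: list[np.ndarray] = []
    fib_coloc: list[bool] = []
    coloc_pick = rng.choice(len(cap_centers), size=n_coloc, replace=False) if n_coloc else []
    for ci in coloc_pick:
        fib_centers.append(cap_centers_arr[ci].copy())
        fib_coloc.append(True)
    tries = 0
    # blobs have a 5 um major axis; keep them from touching each other
    min_sep_fib = 7.0 / px_um
    while len(fib_centers) < n_fib_target and tries < 4000 * max(n_fib_target, 1):
        tries += 1
        cand = rng.uniform((6, 6), (w - 6, h - 6))
        if len(cap_centers) and np.min(
            np.hypot(*(cap_centers_arr - cand).T)
        ) < min_sep_fib:
            continue
        free = [c for c, is_c in zip(fib_centers, fib_coloc) if not is_c]
        if free and np.min(np.hypot(*(np.asarray(free) - cand).T)) < min_sep_fib:
            continue
        if any(
            np.hypot(cand[0] - pcx, cand[1] - pcy) <= pr + 4
            for (pcx, pcy), pr in spec.fibrotic_patches
        ):
            continue
        fib_centers.append(cand)
        fib_coloc.append(False)
    fib_centers_arr = np.asarray(fib_centers) if fib_centers else np.empty((0, 2))
    fib_coloc_arr = np.asarray(fib_coloc, dtype=bool)

    # --- render channels
    def _noisy(mono_r, mono_g, mono_b):
        img = np.stack([mono_r, mono_g, mono_b], axis=-1)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        return np.clip(img, 0.0, 1.0)

    dark = np.full((h, w), 0.02)
    wga_rgb = _noisy(scene, dark, dark)

    green = np.full((h, w), 0.02)
    for center, r_px in zip(cap_centers, cap_radii_px):
        out = _disk_level((h, w), center, r_px, spec.soft_edge)
        if out is not None:
            sl, lvl = out
            green[sl] = np.maximum(green[sl], 0.02 + 0.88 * lvl)
    endo_rgb = _noisy(dark, green, dark)

    blue = np.full((h, w), 0.02)
    fib_a_um, fib_b_um = 2.5, 1.5
    for center, is_coloc in zip(fib_centers, fib_coloc):
        if is_coloc:
            # strictly inside the capillary disk so subtraction erases it
            ci = int(np.argmin(np.hypot(*(cap_centers_arr - center).T)))
            r_px = 0.55 * cap_radii_px[ci]
            out = _disk_level((h, w), center, r_px, spec.soft_edge)
            if out is not None:
                sl, lvl = out
                blue[sl] = np.maximum(blue[sl], 0.02 + 0.88 * lvl)
        else:
            theta = rng.uniform(0, np.pi)
            a_px, b_px = fib_a_um / px_um, fib_b_um / px_um
            r = int(np.ceil(a_px)) + 2
            cx, cy = center
            x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
            y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
            eyy, exx = np.mgrid[y0:y1, x0:x1]
            u = (exx - cx) * np.cos(theta) + (eyy - cy) * np.sin(theta)
            v = -(exx - cx) * np.sin(theta) + (eyy - cy) * np.cos(theta)
            q = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
            lvl = np.clip((1.0 - q) * a_px + 0.5, 0.0, 1.0) if spec.soft_edge \
                else (q <= 1.0).astype(float)
            blue[y0:y1, x0:x1] = np.maximum(blue[y0:y1, x0:x1], 0.02 + 0.88 * lvl)
    fibro_rgb = _noisy(dark, dark, blue)

    source = f"synthetic-seed{spec.seed}"
    wga_img = CalibratedImage(wga_rgb, spec.resolution_px_per_mm, "wga", source)
    endo_img = CalibratedImage(endo_rgb, spec.resolution_px_per_mm, "endothelial", source)
    fibro_img = CalibratedImage(fibro_rgb, spec.resolution_px_per_mm, "fibroblast", source)

    gt = GroundTruth(
        seeds_px=seeds,
        label_grid=label_grid,
        membrane_mask=membrane_mask,
        fibrosis_fraction=fib_frac,
        edges=edges,
        cell_centroid_px=cell_centroid,
        cell_area_um2=cell_area,
        cell_min_feret_um=cell_feret,
        cell_on_border=cell_border,
        capillary_centers_px=cap_centers_arr,
        capillary_areas_um2=cap_areas_um2,
        fibroblast_centers_px=fib_centers_arr,
        fibroblast_coloc=fib_coloc_arr,
        spec=spec,
    )
    return wga_img, endo_img, fibro_img, gt


def ground_truth_cdi(gt: GroundTruth, ref: ReferenceStats) -> dict[int, float | None]:
    """Apply the CDI definition to the TRUE septum widths.

    Returns per-cell CDI keyed by 1-based cell id (None for isolated cells),
    for pipeline-recovery comparisons.
    """
    threshold = ref.threshold_um
    n_nb: dict[int, int] = {i + 1: 0 for i in range(gt.n_cells)}
    n_enh: dict[int, int] = {i + 1: 0 for i in range(gt.n_cells)}
    for e in gt.edges:
        enh = e.width_um > threshold
        for node in (e.id_a, e.id_b):
            n_nb[node] += 1
            n_enh[node] += int(enh)
    return {
        i: (n_enh[i] / n_nb[i] if n_nb[i] > 0 else None) for i in sorted(n_nb)
    }
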