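"""Neighbor graph, endomysial septum widths and the cardiomyocyte
dissociation index (CDI).

Directly neighboring myocytes are pairs of watershed regions that share a
boundary.  The width of the collagen septum between two neighbors is read
off an intensity line profile between their seed minima: the length of the
contiguous stained run that contains the crossing of the shared region
boundary.  A septum is "enhanced" when it is wider than a healthy-reference
mean plus two standard deviations; the CDI of a cell is the fraction of its
neighbor septa that are enhanced.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import AnalysisConfig, ReferenceStats
from .image_io import CalibratedImage
from .wga import BinaryMask, MyocyteRecord


@dataclass
class NeighborEdge:
    """Adjacency between two myocytes, stored once with ``id_a < id_b``."""

    id_a: int
    id_b: int
    septum_width_um: float = np.nan
    enhanced: bool | None = None

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("self-loops are not allowed")
        if self.id_a > self.id_b:
            self.id_a, self.id_b = self.id_b, self.id_a


@dataclass
class MyocyteGraph:
    """Segmented cells plus the neighbor graph carrying septum widths.

    ``boundary_px`` optionally maps each edge ``(id_a, id_b)`` to the (x, y)
    midpoints of the pixel contacts along the shared watershed boundary;
    used to localize the septum crossing and correct profile obliquity.
    """

    nodes: dict[int, MyocyteRecord]
    edges: list[NeighborEdge] = field(default_factory=list)
    boundary_px: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.id_a not in self.nodes or e.id_b not in self.nodes:
                raise ValueError(f"edge ({e.id_a},{e.id_b}) references unknown node")
            key = (e.id_a, e.id_b)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def neighbors(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in self.nodes}
        for e in self.edges:
            adj[e.id_a].add(e.id_b)
            adj[e.id_b].add(e.id_a)
        return adj


@dataclass
class CdiRecord:
    """Per-cell dissociation index: fraction of enhanced neighbor septa.

    ``cdi`` is None (undefined) for cells without neighbors; such cells are
    excluded from the image mean.
    """

    myocyte_id: int
    n_neighbors: int
    n_enhanced: int
    cdi: float | None


# -------------------------------------------------------------------- graph
#: minimum number of pixel contacts for two regions to count as directly
#: neighboring (the 4-shift scan yields ~3 contacts per boundary pixel, so
#: this is ~6 px of shared boundary).  Pairs that merely touch at a
#: three-cell junction point are not separated by a measurable septum.
MIN_BOUNDARY_CONTACTS = 18


def build_neighbor_graph(
    myocytes: list[MyocyteRecord],
    watershed_labels: np.ndarray,
    min_contacts: int = MIN_BOUNDARY_CONTACTS,
) -> MyocyteGraph:
    """Connect every pair of watershed regions that share a boundary.

    The label grid is the full watershed tiling, so regions separated by a
    septum still meet along the membrane ridge line (8-connectivity).  Pairs
    whose shared boundary is shorter than ``min_contacts`` pixel contacts
    touch only at a corner and are not treated as direct neighbors.
    """
    nodes = {m.myocyte_id: m for m in myocytes}
    present = set(np.unique(watershed_labels)) - {0}
    if not set(nodes).issubset(present):
        raise ValueError("records reference labels absent from the label grid")
    boundary: dict[tuple[int, int], list] = {}
    lab = watershed_labels
    h, w = lab.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0a, r1a = max(0, -dr), h - max(0, dr)
        c0a, c1a = max(0, -dc), w - max(0, dc)
        a = lab[r0a:r1a, c0a:c1a]
        b = lab[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        diff = (a != b) & (a > 0) & (b > 0)
        rr, cc = np.nonzero(diff)
        for u, v, r, c in zip(a[diff].ravel(), b[diff].ravel(), rr, cc):
            u, v = int(u), int(v)
            if u in nodes and v in nodes:
                key = (min(u, v), max(u, v))
                # midpoint of the pixel contact, (x, y)
                x = c + c0a + dc / 2.0
                y = r + r0a + dr / 2.0
                boundary.setdefault(key, []).append((x, y))
    boundary = {k: v for k, v in boundary.items() if len(v) >= min_contacts}
    edges = [NeighborEdge(id_a=u, id_b=v) for u, v in sorted(boundary)]
    boundary_px = {k: np.asarray(v) for k, v in boundary.items()}
    return MyocyteGraph(nodes=nodes, edges=edges, boundary_px=boundary_px)


# ------------------------------------------------------------ line profiles
def septum_width(
    image: CalibratedImage,
    mask: BinaryMask,
    labels: np.ndarray,
    edge: NeighborEdge,
    graph: MyocyteGraph,
    *,
    step_px: float = 0.25,
    on_intensity: bool = True,
) -> float:
    """Width (um) of the endomysial septum between two neighboring cells.

    The septum is profiled perpendicular to the shared watershed boundary:
    at a handful of points spread along the interior of the boundary (its
    endpoints sit at three-cell junctions where neighboring septa overlap),
    an intensity profile is sampled at sub-pixel steps (bilinear) along the
    local boundary normal, and the width is the length of the contiguous
    stained run through the boundary.  The reported width is the median over
    the profiled points, robust to junction contamination at either end of
    the septum.  With ``on_intensity`` (default) the stained run is taken on
    the raw intensity profile at half its range (FWHM), which is unbiased
    with respect to the thresholder; otherwise on the thresholded mask.
    Either way the run is clipped where the profile leaves the two cells'
    own regions, and where a sample lies closer to a *different* incident
    septum's boundary than to this one.  Returns 0 when nothing stained lies
    at the crossing (no septum); falls back to the plain seed-to-seed line
    profile when no boundary contacts are available.
    """
    if edge.id_a not in graph.nodes or edge.id_b not in graph.nodes:
        raise ValueError("edge endpoints are not nodes of the graph")
    a = np.array(graph.nodes[edge.id_a].seed_px, dtype=float)  # (x, y)
    b = np.array(graph.nodes[edge.id_b].seed_px, dtype=float)
    seg = b - a
    seg_len = float(np.hypot(*seg))

    key = (edge.id_a, edge.id_b)
    contacts = graph.boundary_px.get(key)
    plane = image.plane() if on_intensity else mask.grid.astype(np.float64)
    bright_level = float(np.percentile(plane, 99.0)) if on_intensity else 1.0
    px_um = image.pixel_size_um
    half_px = max(10.0 / px_um, 8.0)
    n = max(int(np.ceil(2 * half_px / step_px)), 4)
    s = np.linspace(-half_px, half_px, n + 1)
    step = 2 * half_px / n

    other_pts = None
    if contacts is not None and graph.boundary_px:
        other = [
            pts2
            for k2, pts2 in graph.boundary_px.items()
            if k2 != key and (set(k2) & {edge.id_a, edge.id_b})
        ]
        if other:
            other_pts = np.concatenate(other, axis=0)

    def width_at(q: np.ndarray, direction: np.ndarray) -> float:
        xs = q[0] + s * direction[0]
        ys = q[1] + s * direction[1]
        coords = np.stack([ys, xs])  # map_coordinates wants (row, col)
        profile = ndi.map_coordinates(plane, coords, order=1, mode="nearest")
        if on_intensity:
            # half-maximum level anchored to the image's membrane brightness:
            # a sub-2-px septum has no saturated sample, so the per-profile
            # maximum alone would underestimate the peak and widen the run
            hi = max(profile.max(), bright_level)
            span = hi - profile.min()
            if span < 0.05:  # no membrane contrast here
                return 0.0
            stained = profile >= profile.min() + 0.5 * span
        else:
            stained = profile >= 0.5
        lab_line = ndi.map_coordinates(labels, coords, order=0, mode="nearest")
        own = (lab_line == edge.id_a) | (lab_line == edge.id_b)
        if contacts is not None and other_pts is not None:
            samples = np.stack([xs, ys], axis=1)
            d_own = np.sqrt(
                ((samples[:, None, :] - contacts[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            d_other = np.sqrt(
                ((samples[:, None, :] - other_pts[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            own &= d_own <= d_other
        cross = n // 2  # the profile is centered on the crossing point q
        if not stained[cross]:
            return 0.0
        lo = cross
        while lo > 0 and stained[lo - 1] and own[lo - 1]:
            lo -= 1
        hi = cross
        while hi < len(stained) - 1 and stained[hi + 1] and own[hi + 1]:
            hi += 1
        return (hi - lo + 1) * step * px_um

    if contacts is None or len(contacts) < 2:
        # degenerate: no recorded boundary; profile straight between seeds
        if seg_len == 0:
            return 0.0
        return width_at((a + b) / 2.0, seg / seg_len)

    def normal_at(q: np.ndarray) -> np.ndarray:
        # local boundary tangent from the contacts within a few px of q
        near = contacts[((contacts - q) ** 2).sum(axis=1) <= 25.0]
        if len(near) < 2:
            near = contacts
        cen = near - near.mean(axis=0)
        ev, evec = np.linalg.eigh(cen.T @ cen)
        tangent = evec[:, int(np.argmax(ev))]
        return np.array([-tangent[1], tangent[0]])

    # choose the profiling point on the shared boundary: stay clear of
    # three-cell junctions (where neighboring septa overlap and contaminate
    # the profile), and among junction-clear contacts cross where the
    # seed-to-seed line selection does
    rel = contacts - a[None, :]
    tt = np.clip(rel @ seg / max(seg_len**2, 1e-12), 0.0, 1.0)
    feet = a[None, :] + tt[:, None] * seg[None, :]
    miss = np.sqrt(((contacts - feet) ** 2).sum(axis=1))
    if other_pts is not None:
        d_junc = np.sqrt(
            ((contacts[:, None, :] - other_pts[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
    else:
        d_junc = np.full(len(contacts), np.inf)
    clear = d_junc >= min(8.0, float(np.max(d_junc)))
    ci = int(np.flatnonzero(clear)[np.argmin(miss[clear])])
    q = contacts[ci]
    return width_at(q, normal_at(q))


def measure_septa(
    image: CalibratedImage,
    mask: BinaryMask,
    labels: np.ndarray,
    graph: MyocyteGraph,
    config: AnalysisConfig | None = None,
) -> MyocyteGraph:
    """Fill ``septum_width_um`` on every edge of the graph, in place."""
    config = config or AnalysisConfig()
    for edge in graph.edges:
        edge.septum_width_um = septum_width(
            image, mask, labels, edge, graph,
            step_px=config.profile_step_px,
            on_intensity=config.profile_on_intensity,
        )
    return graph


# ---------------------------------------------------------------------- CDI
def compute_cdi(
    graph: MyocyteGraph, ref: ReferenceStats
) -> tuple[list[CdiRecord], float | None]:
    """Mark enhanced edges and compute the per-cell dissociation index.

    An edge is enhanced iff its septum width exceeds the reference mean plus
    two standard deviations.  Returns the per-cell records and the image
    mean CDI over cells with at least one neighbor (None if there are none).
    """
    threshold = ref.threshold_um
    n_enh: dict[int, int] = {i: 0 for i in graph.nodes}
    n_nb: dict[int, int] = {i: 0 for i in graph.nodes}
    for edge in graph.edges:
        if not np.isfinite(edge.septum_width_um):
            raise ValueError("all edges must carry septum widths before CDI")
        edge.enhanced = bool(edge.septum_width_um > threshold)
        for node in (edge.id_a, edge.id_b):
            n_nb[node] += 1
            n_enh[node] += int(edge.enhanced)
    records = []
    for i in sorted(graph.nodes):
        if n_nb[i] > 0:
            cdi = n_enh[i] / n_nb[i]
        else:
            cdi = None
        records.append(
            CdiRecord(myocyte_id=i, n_neighbors=n_nb[i], n_enhanced=n_enh[i], cdi=cdi)
        )
    defined = [r.cdi for r in records if r.cdi is not None]
    mean_cdi = float(np.mean(defined)) if defined else None
    return records, mean_cdi


def fraction_dissociated(records: list[CdiRecord], cutoff: float = 0.5) -> float | None:
    """Fraction of cells at least ``cutoff`` dissociated (CDI >= cutoff)."""
    defined = [r for r in records if r.cdi is not None]
    if not defined:
        return None
    return sum(r.cdi >= cutoff for r in defined) / len(defined)


def estimate_reference(
    graphs: list[MyocyteGraph], source_note: str = "estimated from reference images"
) -> ReferenceStats:
    """Pool all edge widths over the designated reference image set.

    Uses the sample standard deviation (n-1).  Fewer than 10 pooled edges is
    rejected as an unstable reference.
    """
    widths = np.array(
        [e.septum_width_um for g in graphs for e in g.edges if np.isfinite(e.septum_width_um)]
    )
    if widths.size < 10:
        raise ValueError("need at least 10 pooled edges for a stable reference")
    sd = float(widths.std(ddof=1))
    return ReferenceStats(
        mu_ref_um=float(widths.mean()), sd_ref_um=sd, source_note=source_note
    )
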