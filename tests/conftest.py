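"""Shared fixtures: constructed micro-scenes and generated mosaics."""
from __future__ import annotations

import numpy as np
import pytest

import cardiohist as ch
from cardiohist.septa import MyocyteGraph, NeighborEdge, build_neighbor_graph
from cardiohist.wga import BinaryMask, MyocyteRecord


def make_stripe_scene(width_px: float, center_x: float = 48.0, size: int = 96,
                      resolution: float = 1000.0, soft: bool = True):
    """Two dark cells separated by a vertical bright stripe of known width.

    A wide fully-resolved membrane band is drawn near the left edge so the
    scene carries a membrane brightness reference, as any stained section
    does.  Returns (image, mask, labels, graph, edge); at 1000 px/mm one
    pixel is one micrometer, so widths in px and um coincide.
    """
    xx = np.arange(size, dtype=float)[None, :].repeat(size, axis=0)
    if soft:
        level = np.clip(width_px / 2 - np.abs(xx - center_x) + 0.5, 0.0, 1.0)
    else:
        level = (np.abs(xx - center_x) <= width_px / 2).astype(float)
    level = np.maximum(level, np.clip(3.0 - np.abs(xx - 16.0) + 0.5, 0.0, 1.0))
    scene = 0.1 + 0.8 * level
    image = ch.CalibratedImage(scene, resolution, "wga", "stripe")
    mask = BinaryMask(scene >= 0.5, "constructed")
    labels = np.where(xx < center_x, 1, 2)
    mid = size / 2.0
    records = [
        MyocyteRecord(1, (center_x - 30, mid), (center_x - 30, mid), 900.0, 30.0, False, True),
        MyocyteRecord(2, (center_x + 30, mid), (center_x + 30, mid), 900.0, 30.0, False, True),
    ]
    graph = build_neighbor_graph(records, labels)
    return image, mask, labels, graph, graph.edges[0]


def graph_from_widths(pairs, widths, n_nodes):
    """Abstract myocyte graph with given edge widths (nodes on a line)."""
    nodes = {
        i: MyocyteRecord(i, (float(i), 0.0), (float(i), 0.0), 100.0, 10.0, False, True)
        for i in range(1, n_nodes + 1)
    }
    edges = [NeighborEdge(a, b, w) for (a, b), w in zip(pairs, widths)]
    return MyocyteGraph(nodes=nodes, edges=edges)


@pytest.fixture(scope="session")
def clean_scene():
    """One noise-free synthetic triple with its ground truth."""
    spec = ch.SyntheticSpec(seed=3, noise_sigma=0.0)
    wga_img, endo_img, fibro_img, gt = ch.generate(spec)
    return spec, wga_img, endo_img, fibro_img, gt


@pytest.fixture(scope="session")
def clean_analysis(clean_scene):
    """Full pipeline output on the noise-free scene."""
    _, wga_img, endo_img, fibro_img, _ = clean_scene
    return ch.analyze_image(wga_img, endo_img, fibro_img)


def map_detected_to_truth(myocytes, gt):
    """Detected myocyte id -> ground-truth cell id via the seed's location."""
    mapping = {}
    for m in myocytes:
        x = int(round(m.seed_px[0]))
        y = int(round(m.seed_px[1]))
        lab = gt.label_grid[y, x]
        if lab > 0:
            mapping[m.myocyte_id] = int(lab)
    return mapping
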