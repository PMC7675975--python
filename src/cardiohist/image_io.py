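"""Calibrated image loading, CSV output, control overlays and batch runs.

Conventions used throughout the package (and stated in every CSV header):
coordinates are 0-based pixel indices with origin at the top-left corner,
``x`` the column index and ``y`` the row index.  Positions are reported in
pixels; lengths in micrometers; areas in square micrometers.  The conversion
factor is ``1000 / resolution_px_per_mm`` per axis (square pixels assumed).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("cardiohist")

CHANNEL_ROLES = ("wga", "endothelial", "fibroblast")

#: image extensions accepted by batch discovery
IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp")


@dataclass
class CalibratedImage:
    """Pixel data plus spatial calibration and channel role.

    ``pixels`` is a float array in [0, 1], either 2-D (single intensity
    plane) or H x W x 3 (RGB).  Integer inputs are min-max normalized per
    image at load time so a single parameter set serves 8-bit and 16-bit
    acquisitions alike.
    """

    pixels: np.ndarray
    resolution_px_per_mm: float
    channel_role: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.resolution_px_per_mm <= 0:
            raise ValueError("resolution_px_per_mm must be positive")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be 2-D or an H x W x 3 RGB grid")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("both spatial dimensions must be >= 64 px")
        if np.min(px) < 0:
            raise ValueError("pixel values must be non-negative")
        self.pixels = px.astype(np.float64, copy=False)

    # ------------------------------------------------------------ geometry
    @property
    def pixel_size_um(self) -> float:
        """Side length of one pixel in micrometers."""
        return 1000.0 / self.resolution_px_per_mm

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    def plane(self) -> np.ndarray:
        """Return the single intensity plane relevant to this channel's role.

        For RGB input the WGA stain is carried by the red plane, the
        endothelial marker by green and vimentin by blue; grayscale input is
        returned as-is.
        """
        if not self.is_rgb:
            return self.pixels
        idx = {"wga": 0, "endothelial": 1, "fibroblast": 2}[self.channel_role]
        return self.pixels[:, :, idx]


def _normalize(px: np.ndarray) -> np.ndarray:
    """Min-max normalize integer images to [0, 1]; pass floats through."""
    px = np.asarray(px)
    if np.issubdtype(px.dtype, np.integer):
        px = px.astype(np.float64)
        lo, hi = px.min(), px.max()
        if hi > lo:
            px = (px - lo) / (hi - lo)
        else:
            px = np.zeros_like(px)
        return px
    return np.clip(px.astype(np.float64), 0.0, None)


def load_channel(
    path: str | Path, resolution_px_per_mm: float, channel_role: str
) -> CalibratedImage:
    """Load a micrograph with its spatial calibration.

    Parameters
    ----------
    path
        TIFF/PNG/JPEG/BMP raster, grayscale or RGB (an alpha plane is
        silently dropped).
    resolution_px_per_mm
        User-supplied calibration; the pixel size in um is
        ``1000 / resolution_px_per_mm``.
    channel_role
        One of ``"wga"``, ``"endothelial"``, ``"fibroblast"``.
    """
    path = Path(path)
    if resolution_px_per_mm <= 0:
        raise ValueError("resolution_px_per_mm must be positive")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"could not read image file {path}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.ndim not in (2, 3):
        raise IOError(f"{path} did not decode to a 2-D or RGB raster")
    return CalibratedImage(
        pixels=_normalize(raw),
        resolution_px_per_mm=resolution_px_per_mm,
        channel_role=channel_role,
        source_id=path.stem,
    )


# --------------------------------------------------------------------- CSV
_COORD_NOTE = (
    "coordinates: 0-based pixel indices, origin top-left, x=column, y=row; "
    "lengths um, areas um2"
)


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten a homogeneous list of record dataclasses to a DataFrame."""
    if not records:
        return pd.DataFrame()
    first = records[0]
    if not dataclasses.is_dataclass(first):
        return pd.DataFrame(list(records))
    if any(type(r) is not type(first) for r in records):
        raise ValueError("record list must be homogeneous")
    rows = []
    for rec in records:
        row = {}
        for f in dataclasses.fields(rec):
            val = getattr(rec, f.name)
            if isinstance(val, (tuple, list, np.ndarray)) and len(val) == 2:
                row[f"{f.name}_x"], row[f"{f.name}_y"] = float(val[0]), float(val[1])
            elif isinstance(val, (np.floating, np.integer)):
                row[f.name] = val.item()
            elif isinstance(val, (str, int, float, bool)) or val is None:
                row[f.name] = val
            # non-scalar payloads (pixel sets etc.) are not serialized
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_csv(records: Sequence, out_path: str | Path, columns=None) -> None:
    """Write one CSV row per structure, with a commented unit/coordinate note.

    Numeric fields round-trip through :func:`read_records_csv` to at least
    1e-6 relative precision.
    """
    out_path = Path(out_path)
    frame = records_to_frame(records)
    if columns is not None:
        frame = frame.reindex(columns=columns) if len(frame) else pd.DataFrame(columns=columns)
    try:
        with open(out_path, "w", newline="") as fh:
            fh.write(f"# {_COORD_NOTE}\n")
            frame.to_csv(fh, index=False, float_format="%.10g")
    except OSError as exc:
        raise IOError(f"could not write CSV to {out_path}") from exc


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ----------------------------------------------------------------- overlays
def _draw_segment(canvas: np.ndarray, p0, p1, color) -> None:
    from skimage.draw import line

    rr, cc = line(int(round(p0[1])), int(round(p0[0])), int(round(p1[1])), int(round(p1[0])))
    keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[keep], cc[keep]] = color


def render_overlay(image: CalibratedImage, mask, graph=None) -> np.ndarray:
    """Render the control image: thresholded membranes, minimal-Feret
    calipers and neighbor line selections over the original micrograph."""
    if hasattr(mask, "grid"):
        mask = mask.grid
    if mask.shape != image.shape:
        raise ValueError("image and mask dimensions do not match")
    base = image.plane()
    canvas = np.stack([base, base, base], axis=-1) * 0.6
    canvas[mask] = 0.6 * np.array([1.0, 1.0, 1.0])
    if graph is not None:
        for edge in graph.edges:
            a = graph.nodes[edge.id_a]
            b = graph.nodes[edge.id_b]
            _draw_segment(canvas, a.seed_px, b.seed_px, (1.0, 1.0, 0.0))
        for rec in graph.nodes.values():
            if rec.feret_segment_px is not None:
                p0, p1 = rec.feret_segment_px
                _draw_segment(canvas, p0, p1, (0.0, 1.0, 0.0))
    return np.clip(canvas, 0, 1)


def render_cdi_heatmap(labels: np.ndarray, cdi_records) -> np.ndarray:
    """Map per-cell CDI onto the segmentation: 0 -> white, 1 -> dark red."""
    h, w = labels.shape
    canvas = np.zeros((h, w, 3))
    dark_red = np.array([0.55, 0.0, 0.0])
    white = np.array([1.0, 1.0, 1.0])
    for rec in cdi_records:
        value = rec.cdi if rec.cdi is not None else 0.0
        color = white + (dark_red - white) * float(value)
        canvas[labels == rec.myocyte_id] = color
    return canvas


def write_overlay(
    image: CalibratedImage,
    graph,
    cdi,
    out_path: str | Path,
    *,
    mask: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> None:
    """Write the control overlay PNG and, when CDI records and a label grid
    are available, the companion CDI heat map (``*_cdi.png``)."""
    out_path = Path(out_path)
    if mask is None:
        mask = np.zeros(image.shape, dtype=bool)
    overlay = render_overlay(image, mask, graph)
    iio.imwrite(out_path, (overlay * 255).astype(np.uint8))
    if cdi and labels is not None:
        heat = render_cdi_heatmap(labels, cdi)
        iio.imwrite(out_path.with_name(out_path.stem + "_cdi.png"),
                    (heat * 255).astype(np.uint8))


# -------------------------------------------------------------------- batch
def _stem_index(folder: Path) -> dict[str, Path]:
    index: dict[str, Path] = {}
    for p in sorted(folder.iterdir()):
        if p.suffix.lower() in IMAGE_EXTENSIONS:
            index[p.stem.lower()] = p
    return index


def run_batch(
    wga_dir: str | Path | None,
    endothelial_dir: str | Path | None,
    fibroblast_dir: str | Path | None,
    out_dir: str | Path,
    resolution_px_per_mm: float,
    config=None,
    *,
    write_overlays: bool = True,
):
    """Analyze matched channel folders unattended and write all outputs.

    Images are matched across the supplied channel folders by base filename
    (case-insensitive, extension stripped).  Emits per-structure CSVs
    (``myocytes.csv``, ``septa.csv``, ``cdi.csv``, ``clustering.csv``,
    ``capillaries.csv``, ``fibroblasts.csv``), control overlays and a
    one-row-per-image ``summary.csv``.  Deterministic given ``config.seed``.

    Returns the list of per-image :class:`~cardiohist.pipeline.ImageSummary`.
    """
    from . import pipeline  # local import: pipeline depends on this module
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    dirs = {
        "wga": Path(wga_dir) if wga_dir else None,
        "endothelial": Path(endothelial_dir) if endothelial_dir else None,
        "fibroblast": Path(fibroblast_dir) if fibroblast_dir else None,
    }
    supplied = {role: d for role, d in dirs.items() if d is not None}
    if not supplied:
        raise ValueError("at least one channel folder must be supplied")
    indexes = {}
    for role, d in supplied.items():
        if not d.is_dir():
            raise ValueError(f"{role} folder {d} does not exist")
        idx = _stem_index(d)
        if not idx:
            raise ValueError(f"{role} folder {d} contains no images")
        indexes[role] = idx

    all_stems = sorted(set().union(*[set(ix) for ix in indexes.values()]))
    common = [s for s in all_stems if all(s in ix for ix in indexes.values())]
    for stem in all_stems:
        if stem not in common:
            missing = [r for r, ix in indexes.items() if stem not in ix]
            logger.warning("skipping %s: missing channel(s) %s", stem, missing)
    if not common:
        raise ValueError("no filenames matched across the supplied channel folders")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summaries = []
    collected: dict[str, list] = {
        "myocytes": [], "septa": [], "cdi": [], "clustering": [],
        "capillaries": [], "fibroblasts": [],
    }
    for i, stem in enumerate(common):
        channels = {
            role: load_channel(indexes[role][stem], resolution_px_per_mm, role)
            for role in indexes
        }
        result = pipeline.analyze_image(
            wga=channels.get("wga"),
            endothelial=channels.get("endothelial"),
            fibroblast=channels.get("fibroblast"),
            config=config,
        )
        summaries.append(result.summary)
        for key, rows in result.tables().items():
            collected[key].extend(rows)
        if write_overlays and result.wga is not None:
            write_overlay(
                result.wga, result.graph, result.cdi,
                out_dir / f"{stem}_overlay.png",
                mask=result.wga_mask, labels=result.labels,
            )
        logger.info("analyzed %s (%d/%d, %.0f%%)", stem, i + 1, len(common),
                    100.0 * (i + 1) / len(common))

    for key, rows in collected.items():
        write_records_csv(rows, out_dir / f"{key}.csv")
    write_records_csv(summaries, out_dir / "summary.csv")
    return summaries
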