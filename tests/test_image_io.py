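"""Calibrated loading, CSV round-trips, overlays and folder-level batch
analysis."""
from __future__ import annotations

import numpy as np
import pytest
import tifffile

import cardiohist as ch
from cardiohist.image_io import (
    read_records_csv,
    records_to_frame,
    render_cdi_heatmap,
    render_overlay,
    write_records_csv,
)
from cardiohist.septa import CdiRecord


@pytest.fixture(scope="module")
def scene_files(tmp_path_factory):
    """Three matched channel folders with two synthetic scenes each."""
    root = tmp_path_factory.mktemp("batch")
    dirs = {k: root / k for k in ("wga", "endo", "fibro")}
    for d in dirs.values():
        d.mkdir()
    for seed in (31, 32):
        spec = ch.SyntheticSpec(seed=seed, image_px=(320, 320), n_cells=42)
        wga_img, endo_img, fibro_img, _ = ch.generate(spec)
        for key, img in (("wga", wga_img), ("endo", endo_img), ("fibro", fibro_img)):
            tifffile.imwrite(dirs[key] / f"scene{seed}.tif",
                             (img.pixels * 255).astype(np.uint8))
    return root, dirs


class TestLoadChannel:
    def test_pixel_size_from_resolution(self, tmp_path):
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, np.zeros((64, 64), dtype=np.uint8))
        img = ch.load_channel(path, 2000.0, "wga")
        assert img.pixel_size_um == pytest.approx(0.5)
        assert img.source_id == "img"

    def test_loading_twice_is_identical(self, tmp_path):
        path = tmp_path / "img.png"
        rng = np.random.default_rng(0)
        import imageio.v3 as iio

        iio.imwrite(path, rng.integers(0, 255, (64, 64, 3), dtype=np.uint8))
        a = ch.load_channel(path, 1000.0, "wga")
        b = ch.load_channel(path, 1000.0, "wga")
        assert np.array_equal(a.pixels, b.pixels)

    def test_8bit_and_16bit_of_same_scene_give_same_mask(self, tmp_path):
        spec = ch.SyntheticSpec(seed=33, image_px=(256, 256), n_cells=28)
        wga_img, *_ = ch.generate(spec)
        scene = wga_img.plane()
        p8, p16 = tmp_path / "a8.tif", tmp_path / "a16.tif"
        tifffile.imwrite(p8, np.round(scene * 255).astype(np.uint8))
        tifffile.imwrite(p16, np.round(scene * 65535).astype(np.uint16))
        m8 = ch.phansalkar_threshold(ch.load_channel(p8, 2000.0, "wga"))
        m16 = ch.phansalkar_threshold(ch.load_channel(p16, 2000.0, "wga"))
        # both depths are min-max normalized; quantization can flip only a
        # vanishing fraction of borderline pixels
        assert (m8.grid != m16.grid).mean() < 1e-3

    def test_nonpositive_resolution_rejected(self, tmp_path):
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(ValueError):
            ch.load_channel(path, 0.0, "wga")

    def test_unreadable_file_raises_ioerror_naming_path(self, tmp_path):
        path = tmp_path / "missing.tif"
        with pytest.raises(IOError, match="missing.tif"):
            ch.load_channel(path, 1000.0, "wga")

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="64"):
            ch.CalibratedImage(np.zeros((32, 32)), 1000.0, "wga")

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="channel_role"):
            ch.CalibratedImage(np.zeros((64, 64)), 1000.0, "nuclear")


class TestRecordsCsv:
    def test_empty_list_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_records_csv([], out, columns=["image_id", "x"])
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("#")
        assert lines[1] == "image_id,x"
        assert len(lines) == 2

    def test_three_records_make_four_csv_lines(self, tmp_path):
        recs = [
            ch.MyocyteRecord(i, (1.0, 2.0), (3.0, 4.0), 55.5, 11.1, False, True)
            for i in range(3)
        ]
        out = tmp_path / "myo.csv"
        write_records_csv(recs, out)
        lines = [l for l in out.read_text().strip().splitlines()
                 if not l.startswith("#")]
        assert len(lines) == 4

    def test_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(1)
        rows = [
            {"image_id": f"img{i}", "x_px": rng.uniform(0, 512),
             "area_um2": rng.uniform(1, 1000) * 10.0 ** int(rng.integers(-3, 3))}
            for i in range(20)
        ]
        out = tmp_path / "round.csv"
        write_records_csv(rows, out)
        back = read_records_csv(out)
        for col in ("x_px", "area_um2"):
            orig = np.array([r[col] for r in rows])
            assert np.allclose(back[col].to_numpy(), orig, rtol=1e-6)

    def test_heterogeneous_records_rejected(self):
        recs = [ch.MyocyteRecord(1, (0, 0), (0, 0), 1.0, 1.0, False, True),
                CdiRecord(1, 2, 1, 0.5)]
        with pytest.raises(ValueError, match="homogeneous"):
            records_to_frame(recs)


class TestOverlays:
    def test_mismatched_mask_rejected(self):
        img = ch.CalibratedImage(np.zeros((64, 64)), 1000.0, "wga")
        with pytest.raises(ValueError, match="dimensions"):
            render_overlay(img, np.zeros((64, 65), dtype=bool))

    def test_empty_graph_overlay_is_background_rendering(self):
        img = ch.CalibratedImage(np.full((64, 64), 0.3), 1000.0, "wga")
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:20] = True
        canvas = render_overlay(img, mask, graph=None)
        assert canvas[15, 15, 0] > canvas[40, 40, 0]  # mask drawn brighter

    def test_cdi_colormap_endpoints(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[:32] = 1
        labels[32:] = 2
        heat = render_cdi_heatmap(labels, [CdiRecord(1, 3, 0, 0.0),
                                           CdiRecord(2, 3, 3, 1.0)])
        assert np.allclose(heat[10, 10], [1.0, 1.0, 1.0])      # CDI 0 -> white
        assert np.allclose(heat[50, 50], [0.55, 0.0, 0.0])     # CDI 1 -> dark red


class TestRunBatch:
    def test_full_triple_batch(self, scene_files, tmp_path):
        root, dirs = scene_files
        out = tmp_path / "out"
        summaries = ch.run_batch(dirs["wga"], dirs["endo"], dirs["fibro"], out,
                                 resolution_px_per_mm=2000.0)
        assert len(summaries) == 2
        for s in summaries:
            assert s.myocyte_count > 0
            assert s.capillary_count > 0
            assert s.fibroblasts_per_myocyte is not None
        for name in ("myocytes", "septa", "cdi", "capillaries",
                     "fibroblasts", "summary"):
            assert (out / f"{name}.csv").exists()
        assert (out / "scene31_overlay.png").exists()
        # summary median equals the median of the per-structure CSV column
        myo = read_records_csv(out / "myocytes.csv")
        summ = read_records_csv(out / "summary.csv")
        for sid, group in myo.groupby("image_id"):
            expect = group.loc[~group["border_flag"], "min_feret_um"]
            expect = expect[group["area_um2"] >= 20.0].median()
            got = summ.loc[summ["source_id"] == sid, "median_min_feret_um"].iloc[0]
            assert got == pytest.approx(expect, rel=1e-6)

    def test_wga_only_batch_flags_missing_channels(self, scene_files, tmp_path):
        _, dirs = scene_files
        out = tmp_path / "solo"
        summaries = ch.run_batch(dirs["wga"], None, None, out, 2000.0,
                                 write_overlays=False)
        assert all(s.capillary_count is None for s in summaries)
        assert all(s.fibroblasts_per_myocyte is None for s in summaries)

    def test_same_seed_batches_are_byte_identical(self, scene_files, tmp_path):
        _, dirs = scene_files
        outs = []
        for name in ("rep1", "rep2"):
            out = tmp_path / name
            ch.run_batch(dirs["wga"], None, None, out, 2000.0,
                         write_overlays=False)
            outs.append((out / "summary.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_unmatched_stems_skipped_with_warning(self, scene_files, tmp_path, caplog):
        root, dirs = scene_files
        extra = dirs["wga"] / "lonely.tif"
        tifffile.imwrite(extra, np.zeros((64, 64), dtype=np.uint8))
        try:
            with caplog.at_level("WARNING", logger="cardiohist"):
                summaries = ch.run_batch(dirs["wga"], dirs["endo"], None,
                                         tmp_path / "warn", 2000.0,
                                         write_overlays=False)
            assert len(summaries) == 2
            assert any("lonely" in rec.message for rec in caplog.records)
        finally:
            extra.unlink()

    def test_empty_folder_rejected(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(ValueError, match="no images"):
            ch.run_batch(empty, None, None, tmp_path / "o", 1000.0)

    def test_no_channels_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="at least one"):
            ch.run_batch(None, None, None, tmp_path / "o", 1000.0)


def test_config_yaml_round_trip(tmp_path):
    cfg = ch.AnalysisConfig(blur_sigma_px=3.0, seed=7)
    cfg.reference = ch.ReferenceStats(2.2, 0.4, "test ref")
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = ch.AnalysisConfig.from_yaml(path)
    assert back == cfg
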