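"""Preprocessing chain, histogram equalization, overlay rendering."""

import numpy as np
import pytest

import cinemv as cm
from cinemv.image_pipeline import (
    EPIDFrame,
    GainCalibration,
    PanelCorrectionTable,
    PipelineError,
    bin2x2,
    histogram_equalize,
    median3x3,
    render_overlay,
)


def _frame(pixels, ts=1.0):
    return EPIDFrame(pixels=pixels.astype(np.uint16), timestamp_s=ts)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def test_bin2x2_preserves_constants_and_averages_blocks():
    img = np.full((1024, 1024), 123.0)
    out = bin2x2(img)
    assert out.shape == (512, 512)
    assert np.all(out == 123.0)
    img = np.zeros((4, 4))
    img[0, 1] = img[1, 1] = 4.0
    assert bin2x2(img)[0, 0] == pytest.approx(2.0)
    with pytest.raises(PipelineError):
        bin2x2(np.zeros((3, 4)))


def test_median3x3_removes_hot_pixel_and_keeps_constant():
    img = np.full((32, 32), 50.0)
    assert np.all(median3x3(img) == 50.0)
    img[10, 10] = 5000.0
    assert median3x3(img)[10, 10] == 50.0


def test_median3x3_matches_brute_force_oracle(rng):
    img = rng.integers(0, 1000, size=(16, 16)).astype(float)
    out = median3x3(img)
    padded = np.pad(img, 1, mode="edge")
    for r in range(16):
        for c in range(16):
            window = padded[r : r + 3, c : c + 3].ravel()
            assert out[r, c] == np.sort(window)[4]


# ---------------------------------------------------------------------------
# Preprocess chain
# ---------------------------------------------------------------------------


def test_dark_frame_subtracts_to_zero():
    dark = np.full((1024, 1024), 300.0)
    cal = GainCalibration(dark=dark, floods=[(600.0, dark + 1000.0)])
    proc = cm.preprocess(_frame(dark), cal, PanelCorrectionTable.identity(), 0.0)
    assert np.all(proc.pixels == 0.0)


def test_flood_frame_flattens_to_its_mean():
    rng = np.random.default_rng(0)
    dark = np.zeros((1024, 1024))
    flood = rng.uniform(20000, 30000, size=(1024, 1024))
    cal = GainCalibration(dark=dark, floods=[(600.0, flood)])
    proc = cm.preprocess(_frame(flood), cal, PanelCorrectionTable.identity(), 0.0)
    assert np.allclose(proc.pixels, flood.mean(), rtol=1e-3)


def test_nearest_dose_rate_flood_selected():
    cal = GainCalibration(
        dark=np.zeros((4, 4)),
        floods=[(100.0, np.full((4, 4), 1.0)), (600.0, np.full((4, 4), 2.0))],
    )
    assert cal.flood_for(550.0)[0, 0] == 2.0
    assert cal.flood_for(120.0)[0, 0] == 1.0
    assert cal.flood_for(None)[0, 0] == 1.0


def test_translation_restores_sagged_bb_position(geom):
    """A frame rendered with a known 3-pixel AB sag plus a table holding the
    opposite offset recovers the no-sag centroid within 0.5 native pixel."""
    from dataclasses import replace
    from cinemv.simulator import SimConfig, TrajectorySegment, render_frame

    base = SimConfig(
        bb_center_cm=(0.0, 0.0, 0.0),
        segments=(TrajectorySegment(0.0, 40.0),),
        noise_sigma=0.0,
        message_jitter_s=0.0,
        field_size_cm=10.0,
    )
    sagged = replace(base, sag_amp_ab_px=3.0, sag_phase_ab_deg=90.0)  # dx = 3 px at theta=0
    cal = GainCalibration.ideal()
    table = PanelCorrectionTable(np.arange(0.0, 360.0), np.full(360, -3.0), np.zeros(360))
    f_ref = render_frame(base, 10.0)
    f_sag = render_frame(sagged, 10.0)
    ref = cm.detect_bb_centroid(cm.preprocess(f_ref, cal, PanelCorrectionTable.identity(), 0.0))
    fixed = cm.detect_bb_centroid(cm.preprocess(f_sag, cal, table, 0.0))
    assert fixed[0] == pytest.approx(ref[0], abs=0.5)
    assert fixed[1] == pytest.approx(ref[1], abs=0.5)


def test_pipeline_deterministic(rng):
    img = rng.integers(0, 60000, size=(1024, 1024)).astype(np.uint16)
    cal = GainCalibration.ideal()
    table = PanelCorrectionTable.identity()
    p1 = cm.preprocess(_frame(img), cal, table, 33.0)
    p2 = cm.preprocess(_frame(img), cal, table, 33.0)
    assert np.array_equal(p1.pixels, p2.pixels)


# ---------------------------------------------------------------------------
# Histogram equalization
# ---------------------------------------------------------------------------


def test_equalize_zeroes_pixels_below_threshold(rng):
    img = rng.uniform(0, 1000, size=(64, 64))
    out = histogram_equalize(img, 0.70)
    below = img < 0.70 * img.max()
    assert np.all(out[below] == 0)


def test_equalize_constant_image_maps_to_white():
    out = histogram_equalize(np.full((8, 8), 500.0))
    assert np.all(out == 255)


def test_equalize_all_zero_image_stays_zero():
    assert np.all(histogram_equalize(np.zeros((8, 8))) == 0)


def test_equalize_monotone_and_in_range(rng):
    img = rng.uniform(0, 4000, size=(64, 64))
    out = histogram_equalize(img)
    retained = img >= 0.7 * img.max()
    vals = img[retained]
    mapped = out[retained]
    order = np.argsort(vals)
    assert np.all(np.diff(mapped[order].astype(int)) >= 0)
    assert mapped.max() == 255


def test_equalize_invariant_under_intensity_scaling(rng):
    img = rng.uniform(100, 5000, size=(32, 32))
    assert np.array_equal(histogram_equalize(img), histogram_equalize(3.7 * img))


def test_equalize_threshold_validated():
    with pytest.raises(PipelineError):
        histogram_equalize(np.ones((4, 4)), 1.5)


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------


def _overlay(pixels, color=(255, 0, 0), name="roi"):
    arr = np.asarray(pixels, dtype=int).reshape(-1, 2)
    centroid = (float(arr[:, 0].mean()), float(arr[:, 1].mean())) if len(arr) else None
    return cm.ContourOverlay(
        boundary_pixels=arr, centroid=centroid, color=color, roi_name=name
    )


def test_render_empty_overlay_is_grayscale_expansion():
    disp = np.arange(64, dtype=np.uint8).reshape(8, 8)
    rgb = render_overlay(disp, [_overlay(np.empty((0, 2)))])
    assert np.array_equal(rgb[..., 0], disp)
    assert np.array_equal(rgb[..., 1], disp)


def test_render_paints_single_pixel_pure_red():
    disp = np.zeros((32, 32), dtype=np.uint8)
    rgb = render_overlay(disp, [_overlay([[10, 10]], (255, 0, 0))])
    assert tuple(rgb[10, 10]) == (255, 0, 0)
    assert rgb.sum() == 255


def test_render_visibility_toggle_roundtrips():
    disp = np.zeros((32, 32), dtype=np.uint8)
    ov = _overlay([[5, 6]], (0, 255, 0), "m")
    off = render_overlay(disp, [ov], visibility={"m": False})
    on = render_overlay(disp, [ov], visibility={"m": True})
    again = render_overlay(disp, [ov], visibility={"m": True})
    assert off.sum() == 0
    assert np.array_equal(on, again)
    assert tuple(on[6, 5]) == (0, 255, 0)


def test_render_resolution_mismatch_rejected():
    disp = np.zeros((16, 16), dtype=np.uint8)
    with pytest.raises(PipelineError):
        render_overlay(disp, [_overlay([[100, 100]])])


# ---------------------------------------------------------------------------
# Correction table plumbing
# ---------------------------------------------------------------------------


def test_correction_table_interpolates_wrap_aware(tmp_path):
    table = PanelCorrectionTable(
        np.array([0.0, 90.0, 180.0, 270.0]),
        np.array([1.0, 2.0, -1.0, 0.0]),
        np.array([0.0, 0.5, 0.0, -0.5]),
    )
    assert table.offset_at(45.0) == pytest.approx((1.5, 0.25))
    assert table.offset_at(315.0) == pytest.approx((0.5, -0.25))  # wraps 270 -> 360
    p = tmp_path / "table.csv"
    table.save(p)
    loaded = PanelCorrectionTable.load(p)
    assert np.array_equal(loaded.dx_ab_px, table.dx_ab_px)


def test_correction_table_offset_sanity_bound():
    with pytest.raises(PipelineError):
        PanelCorrectionTable(np.array([0.0]), np.array([20.0]), np.array([0.0]))
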