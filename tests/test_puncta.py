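"""Detection pipeline: thresholds, particle filters, watershed, invariances."""

import numpy as np
import pytest

from ribbonquant.geometry import circularity
from ribbonquant.puncta import (
    PRESETS,
    DetectionParams,
    _watershed_split,
    count_fish_puncta,
    detect_puncta,
    terminal_area,
)

PX = 0.043  # um/px, lateral-line acquisition


def _plateau_image(pixel_sets, value=150.0, shape=(64, 64)):
    """Flat-top blobs on a zero background (detected mask == planted mask)."""
    img = np.zeros(shape)
    for coords in pixel_sets:
        for r, c in coords:
            img[r, c] = value
    return img


def _bar(r0, c0, h, w):
    return [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)]


def test_all_zero_image_has_no_puncta():
    img = np.zeros((40, 40))
    mask = np.ones((40, 40), dtype=bool)
    assert detect_puncta(img, mask, PRESETS["zf_lateral_line"]["ctbp"], PX) == []


def test_size_floor_separates_channels():
    # 2 x 9 bar: 18 px = 0.0333 um^2, staircase circularity 0.467
    blob = _bar(20, 20, 2, 9)
    assert 0.1 <= circularity(_plateau_image([blob]) > 0) <= 0.5
    img = _plateau_image([blob])
    mask = np.ones(img.shape, dtype=bool)
    ctbp = detect_puncta(img, mask, PRESETS["zf_lateral_line"]["ctbp"], PX)
    maguk = detect_puncta(img, mask, PRESETS["zf_lateral_line"]["maguk"], PX)
    assert len(ctbp) == 1  # 0.033 um^2 clears the 0.025 um^2 floor
    assert len(maguk) == 0  # but not the 0.04 um^2 floor
    assert ctbp[0].area_um2 == pytest.approx(18 * PX**2)


def test_compact_square_blob_rejected_by_circularity_ceiling():
    img = np.zeros((64, 64))
    img[30:34, 30:34] = 150.0  # 16 px >= size floor, circularity ~0.79
    mask = np.ones(img.shape, dtype=bool)
    assert detect_puncta(img, mask, PRESETS["zf_lateral_line"]["ctbp"], PX) == []


def test_watershed_splits_fused_bodies_but_not_single_bars():
    yy, xx = np.mgrid[:40, :40]
    dumbbell = ((yy - 20) ** 2 + (xx - 14) ** 2 <= 25) | (
        (yy - 20) ** 2 + (xx - 22) ** 2 <= 25
    )
    assert _watershed_split(dumbbell).max() == 2
    bar = np.zeros((40, 40), dtype=bool)
    bar[18:21, 8:30] = True
    assert _watershed_split(bar).max() == 1


def test_two_separate_blobs_detected_individually():
    img = _plateau_image([_bar(10, 10, 2, 9), _bar(30, 20, 2, 9)])
    mask = np.ones(img.shape, dtype=bool)
    puncta = detect_puncta(img, mask, PRESETS["zf_lateral_line"]["ctbp"], PX)
    assert len(puncta) == 2
    # sorted by centroid row
    assert puncta[0].centroid[0] < puncta[1].centroid[0]


def test_empty_mask_warns_and_returns_nothing():
    img = _plateau_image([_bar(10, 10, 2, 9)])
    with pytest.warns(UserWarning, match="empty analysis mask"):
        out = detect_puncta(img, np.zeros(img.shape, dtype=bool), PRESETS["zf_lateral_line"]["ctbp"], PX)
    assert out == []


def test_mismatched_mask_shape_raises():
    with pytest.raises(ValueError, match="mask shape"):
        detect_puncta(np.zeros((10, 10)), np.ones((5, 5), dtype=bool),
                      PRESETS["zf_lateral_line"]["ctbp"], PX)


def test_offset_invariance(noiseless_stack):
    """Adding a constant to the raw image changes no detection output."""
    spec, stack, truth = noiseless_stack
    params = PRESETS["zf_lateral_line"]["ctbp"]
    base = detect_puncta(stack["pre"], truth.mask, params, spec.pixel_size_xy)
    shifted = detect_puncta(stack["pre"] + 37.0, truth.mask, params, spec.pixel_size_xy)
    assert len(base) == len(shifted)
    for a, b in zip(base, shifted):
        assert np.array_equal(a.coords, b.coords)
        assert a.mean_intensity == pytest.approx(b.mean_intensity, abs=1e-3)


def test_scale_covariance(noiseless_stack):
    """2x resampling: pixel areas quadruple, um^2 areas and counts hold."""
    spec, stack, truth = noiseless_stack
    params = PRESETS["zf_lateral_line"]["ctbp"]
    base = detect_puncta(stack["pre"], truth.mask, params, spec.pixel_size_xy)

    up = np.kron(stack["pre"], np.ones((1, 2, 2)))
    up_mask = np.kron(truth.mask, np.ones((2, 2), dtype=bool))
    # length-denominated knobs scale with the resampling
    params2 = DetectionParams(
        channel_name=params.channel_name,
        min_area_um2=params.min_area_um2,
        rolling_ball_radius=params.rolling_ball_radius * 2,
        adaptive_block=params.adaptive_block * 2 + 1,
        adaptive_offset=params.adaptive_offset,
    )
    fine = detect_puncta(up, up_mask, params2, spec.pixel_size_xy / 2)
    assert len(fine) == len(base)
    total_px_base = sum(len(p.coords) for p in base)
    total_px_fine = sum(len(p.coords) for p in fine)
    assert total_px_fine == pytest.approx(4 * total_px_base, rel=0.05)
    area_base = sum(p.area_um2 for p in base)
    area_fine = sum(p.area_um2 for p in fine)
    assert area_fine == pytest.approx(area_base, rel=0.05)


def test_fish_count_closure_and_size_floor():
    rng = np.random.default_rng(5)
    from ribbonquant.synth.blobs import render_punctum

    params = PRESETS["rna_fish"]["fish_coarse"]  # 0.03 um^2 floor
    floor_px = params.min_area_um2 / PX**2
    img = np.zeros((200, 200))
    n_planted = 12
    positions = [(25 + 40 * (i // 4), 25 + 45 * (i % 4)) for i in range(n_planted)]
    for y, x in positions:
        blob = render_punctum(rng, floor_px * 1.4, floor_px * 1.3)
        w = blob.window
        img[y : y + w, x : x + w] += 150.0 * blob.image
    mask = np.ones(img.shape, dtype=bool)
    n, puncta = count_fish_puncta(img, mask, params, PX)
    assert n == n_planted

    # an 11-px particle (0.020 um^2) is excluded under the 0.03 um^2 preset
    small = _plateau_image([_bar(50, 50, 2, 5) + [(52, 50)]])
    n_small, _ = count_fish_puncta(small, np.ones(small.shape, dtype=bool), params, PX)
    assert n_small == 0


class TestTerminalArea:
    def test_known_region_recovered(self):
        img = np.zeros((80, 80))
        img[10:30, 10:40] = 200.0  # 600 px
        area, degenerate = terminal_area(img[None], PX)
        assert not degenerate
        assert area == pytest.approx(600 * PX**2, rel=0.1)

    def test_two_regions_are_additive(self):
        img = np.zeros((80, 80))
        img[10:20, 10:20] = 200.0
        img[50:60, 50:70] = 200.0
        area, _ = terminal_area(img[None], PX)
        assert area == pytest.approx((100 + 200) * PX**2, rel=0.1)

    def test_uniform_image_flags_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            area, degenerate = terminal_area(np.full((1, 40, 40), 7.0), PX)
        assert degenerate and area == 0.0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DetectionParams("x", min_area_um2=0.0)
    with pytest.raises(ValueError):
        DetectionParams("x", min_area_um2=0.01, circularity_range=(0.5, 0.1))
    with pytest.raises(ValueError):
        DetectionParams("x", min_area_um2=0.01, adaptive_block=50)
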