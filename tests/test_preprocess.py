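"""Preprocessing stages against naive double-loop oracles on small images."""

import numpy as np
import pytest

from vicar.errors import PreprocessError, ValidationError
from vicar.io_frames import Frame
from vicar.preprocess import (
    BinaryMask,
    PreprocessConfig,
    adaptive_mean_threshold,
    apply_circle_mask,
    clahe,
    clear_border,
    denoise_bilateral,
    dilate,
    preprocess_frame,
)


def frame(arr, t=1):
    return Frame(pixels=np.asarray(arr, dtype=np.uint8), t=t)


def mask(arr, t=1):
    return BinaryMask(pixels=np.asarray(arr, dtype=bool), t=t)


# ---------------------------------------------------------------- bilateral

def bilateral_oracle(img, cfg):
    """Literal double-loop bilateral filter (reflect-padded)."""
    img = np.asarray(img, dtype=float)
    radius = cfg.bilateral_diameter / 2.0
    r_int = int(np.floor(radius))
    pad = np.pad(img, r_int, mode="reflect")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            num = den = 0.0
            for di in range(-r_int, r_int + 1):
                for dj in range(-r_int, r_int + 1):
                    if di * di + dj * dj > radius * radius:
                        continue
                    v = pad[i + di + r_int, j + dj + r_int]
                    w = np.exp(-(di * di + dj * dj) / (2 * cfg.sigma_spatial**2)) * np.exp(
                        -((v - img[i, j]) ** 2) / (2 * cfg.sigma_range**2)
                    )
                    num += w * v
                    den += w
            out[i, j] = round(num / den)
    return out


def test_bilateral_constant_image_is_identity():
    cfg = PreprocessConfig()
    out = denoise_bilateral(frame(np.full((20, 20), 99)), cfg)
    assert np.all(out.pixels == 99)


def test_bilateral_matches_double_loop_oracle(rng):
    cfg = PreprocessConfig()
    img = rng.integers(0, 256, size=(32, 32))
    got = denoise_bilateral(frame(img), cfg).pixels
    assert np.abs(got.astype(int) - bilateral_oracle(img, cfg)).max() <= 1


def test_bilateral_preserves_step_edge_position():
    cfg = PreprocessConfig()
    img = np.zeros((32, 32))
    img[:, 16:] = 200
    out = denoise_bilateral(frame(img), cfg).pixels.astype(float)
    # the 50% crossing stays within 1 px of column 16 in every row
    for row in out:
        crossing = np.argmax(row > 100)
        assert abs(crossing - 16) <= 1


def test_bilateral_attenuates_impulse_noise():
    cfg = PreprocessConfig()
    img = np.full((21, 21), 50.0)
    img[10, 10] = 250  # amplitude 200 >> sigma_range
    out = denoise_bilateral(frame(img), cfg).pixels.astype(float)
    assert out[10, 10] - 50 < 0.5 * 200


def test_bilateral_rejects_multichannel():
    rgb = np.zeros((4, 4, 3), dtype=np.uint8)
    f = Frame(pixels=rgb[..., 0], t=1, rgb=rgb)
    with pytest.raises(ValidationError):
        denoise_bilateral(f, PreprocessConfig())


# ------------------------------------------------------------------- clahe

def test_clahe_constant_image_unchanged():
    out = clahe(frame(np.full((40, 40), 120)), PreprocessConfig())
    assert np.all(out.pixels == 120)


def test_clahe_output_range_contract(rng):
    img = rng.integers(40, 200, size=(50, 50))
    out = clahe(frame(img), PreprocessConfig()).pixels
    assert out.min() >= 0 and out.max() <= 255


def test_clahe_widens_two_valued_image():
    img = np.full((40, 40), 50)
    img[:, 20:] = 200
    out = clahe(frame(img), PreprocessConfig()).pixels.astype(int)
    assert out.max() - out.min() >= 150  # dynamic range widened or preserved
    # populations pushed toward the extremes
    assert out[:, :10].mean() < 50 + 10
    assert out[:, 30:].mean() > 200


def test_clahe_tile_larger_than_image_rejected():
    with pytest.raises(ValidationError):
        clahe(frame(np.zeros((8, 8))), PreprocessConfig(clahe_tile=10))


# --------------------------------------------------------------- threshold

def local_mean_oracle(img, block):
    img = np.asarray(img, dtype=float)
    h = block // 2
    pad = np.pad(img, h, mode="reflect")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = pad[i : i + block, j : j + block].mean()
    return out


def test_threshold_constant_image_all_background():
    for invert in (False, True):
        cfg = PreprocessConfig(invert=invert)
        out = adaptive_mean_threshold(frame(np.full((15, 15), 77)), cfg)
        if invert:
            assert not out.pixels.any()  # no pixel falls below mean - 2
        else:
            assert out.pixels.all()  # every pixel exceeds mean - 2


def test_threshold_dark_square_matches_local_mean_oracle():
    cfg = PreprocessConfig(invert=True)
    img = np.full((11, 11), 200)
    img[4:7, 4:7] = 40
    got = adaptive_mean_threshold(frame(img), cfg).pixels
    oracle = img < (local_mean_oracle(img, cfg.thresh_block) - cfg.thresh_const)
    assert np.array_equal(got, oracle)
    # the dark square (up to a 1 px boundary) is the foreground
    assert got[5, 5]
    assert not got[0, 0]


def test_threshold_checkerboard_equals_oracle():
    cfg = PreprocessConfig(invert=True)
    img = np.indices((12, 12)).sum(axis=0) % 2 * 180
    got = adaptive_mean_threshold(frame(img), cfg).pixels
    oracle = img < (local_mean_oracle(img, cfg.thresh_block) - cfg.thresh_const)
    assert np.array_equal(got, oracle)


def test_threshold_even_block_rejected():
    with pytest.raises(ValidationError):
        PreprocessConfig(thresh_block=10)


# ------------------------------------------------------------ dilate et al.

def dilate_oracle(m, w):
    """Union of shifts of the foreground by all offsets in the window."""
    h = w // 2
    out = np.zeros_like(m)
    pad = np.pad(m, h)
    for di in range(-h, h + 1):
        for dj in range(-h, h + 1):
            out |= pad[h + di : h + di + m.shape[0], h + dj : h + dj + m.shape[1]]
    return out


def test_dilate_single_pixel_becomes_window():
    m = np.zeros((11, 11), dtype=bool)
    m[5, 5] = True
    out = dilate(mask(m), PreprocessConfig()).pixels
    expected = np.zeros_like(m)
    expected[4:7, 4:7] = True
    assert np.array_equal(out, expected)


def test_dilate_empty_stays_empty_and_superset_property(rng):
    cfg = PreprocessConfig()
    assert not dilate(mask(np.zeros((9, 9), dtype=bool)), cfg).pixels.any()
    m = rng.random((24, 24)) < 0.1
    out = dilate(mask(m), cfg).pixels
    assert np.all(out[m])  # never shrinks
    assert np.array_equal(out, dilate_oracle(m, cfg.dilation_window))


def flood_from_border_oracle(m):
    from scipy.ndimage import binary_propagation

    seed = np.zeros_like(m)
    seed[0, :] = m[0, :]
    seed[-1, :] = m[-1, :]
    seed[:, 0] = m[:, 0]
    seed[:, -1] = m[:, -1]
    reached = binary_propagation(seed, mask=m, structure=np.ones((3, 3)))
    return m & ~reached


def test_clear_border_removes_whole_touching_components():
    m = np.zeros((12, 12), dtype=bool)
    m[0, 3:6] = True  # touches row 0
    m[5:8, 5:8] = True  # interior
    out = clear_border(mask(m)).pixels
    assert not out[0].any()
    assert out[6, 6]


def test_clear_border_l_shaped_component_removed_entirely():
    m = np.zeros((15, 15), dtype=bool)
    m[0:8, 2] = True  # enters from border...
    m[7, 2:9] = True  # ...and reaches the center
    m[11:13, 11:13] = True  # unrelated interior blob
    out = clear_border(mask(m)).pixels
    assert np.array_equal(out, flood_from_border_oracle(m))
    assert not out[7, 7]
    assert out[11, 11]


def test_circle_mask_component_level_decision():
    cfg = PreprocessConfig(mask_diameter_fraction=0.5)  # radius 10 on 40x40
    inside = np.zeros((40, 40), dtype=bool)
    inside[18:22, 18:22] = True
    outside = inside.copy()
    outside[2:5, 2:5] = True
    straddle = np.zeros((40, 40), dtype=bool)
    straddle[19, 5:21] = True  # one component crossing the circle boundary
    assert apply_circle_mask(mask(inside), cfg).pixels.sum() == 16
    out = apply_circle_mask(mask(outside), cfg).pixels
    assert out.sum() == 16 and out[19, 19] and not out[3, 3]
    assert not apply_circle_mask(mask(straddle), cfg).pixels.any()


# ------------------------------------------------------------ full pipeline

def test_preprocess_frame_is_deterministic_and_shape_preserving(rng):
    cfg = PreprocessConfig(mask_diameter_fraction=1.2)
    img = rng.integers(0, 256, size=(48, 40), dtype=np.uint8)
    a = preprocess_frame(frame(img), cfg)
    b = preprocess_frame(frame(img), cfg)
    assert a.shape == (48, 40)
    assert np.array_equal(a.pixels, b.pixels)


def test_preprocess_all_zero_frame_gives_empty_mask():
    out = preprocess_frame(frame(np.zeros((32, 32))), PreprocessConfig())
    assert not out.pixels.any()


def test_preprocess_detects_rendered_spacers(small_series, small_scene,
                                             small_preprocess_config):
    series, truth = small_series
    out = preprocess_frame(series[0], small_preprocess_config)
    from skimage.measure import label

    labels = label(out.pixels, connectivity=2)
    # every spacer center lies inside some detected component
    for (x, y) in truth.cue_anchors[0]:
        assert labels[int(round(y)), int(round(x))] > 0


def test_stage_errors_name_the_stage():
    rgb = np.zeros((20, 20, 3), dtype=np.uint8)
    f = Frame(pixels=rgb[..., 0], t=1, rgb=rgb)
    bad = PreprocessConfig(clahe_tile=64)  # larger than the 20 px image
    with pytest.raises(PreprocessError, match="clahe"):
        preprocess_frame(f, bad)


def test_config_validation():
    with pytest.raises(ValidationError):
        PreprocessConfig(dilation_window=2)
    with pytest.raises(ValidationError):
        PreprocessConfig(mask_diameter_fraction=0.0)
    with pytest.raises(ValidationError):
        PreprocessConfig(thresh_block=1)
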