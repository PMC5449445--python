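"""Affine estimation, interval partitioning, chaining and warping."""

import numpy as np
import pytest

from vicar.cue_selection import ControlTriple
from vicar.errors import DegenerateGeometryError, ValidationError
from vicar.io_frames import Frame
from vicar.registration import (
    AffineTransform,
    SeriesRegistration,
    chain_to_reference,
    compose,
    estimate_affine,
    estimate_affine_lsq,
    partition_intervals,
    register_series,
    warp,
    warp_mask,
)
from vicar.preprocess import BinaryMask


TRIPLE = np.array([[0.0, 0.0], [100.0, 10.0], [20.0, 120.0]])


def triple(points, t=1):
    return ControlTriple(points=np.asarray(points, dtype=float), t=t)


# -------------------------------------------------------- estimate_affine

def test_identity_recovered():
    tf = estimate_affine(triple(TRIPLE), triple(TRIPLE))
    assert np.allclose(tf.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)


def test_pure_translation_recovered():
    tf = estimate_affine(triple(TRIPLE), triple(TRIPLE + (7, -3)))
    assert np.allclose(tf.matrix, [[1, 0, 7], [0, 1, -3]], atol=1e-9)


def test_rotation_about_point_matches_closed_form():
    ref = AffineTransform.rotation_about(np.deg2rad(10), center=(100, 100))
    tf = estimate_affine(triple(TRIPLE), triple(ref.apply(TRIPLE)))
    assert np.allclose(tf.matrix, ref.matrix, atol=1e-9)
    assert np.linalg.norm(tf.apply(TRIPLE) - ref.apply(TRIPLE), axis=1).max() < 1e-9


def test_collinear_triple_rejected():
    with pytest.raises(DegenerateGeometryError):
        ControlTriple(points=[(0, 0), (10, 10), (20, 20)])


def test_lsq_equals_exact_solve_for_three_points():
    ref = AffineTransform(np.array([[1.1, -0.2, 5.0], [0.15, 0.95, -2.0]]))
    exact = estimate_affine(triple(TRIPLE), triple(ref.apply(TRIPLE)))
    lsq = estimate_affine_lsq(TRIPLE, ref.apply(TRIPLE))
    assert np.allclose(exact.matrix, lsq.matrix, atol=1e-9)


def test_lsq_recovers_exact_affine_from_many_points(rng):
    ref = AffineTransform(np.array([[0.98, 0.05, -12.0], [-0.04, 1.02, 8.0]]))
    pts = rng.uniform(0, 500, size=(8, 2))
    tf = estimate_affine_lsq(pts, ref.apply(pts))
    assert np.allclose(tf.matrix, ref.matrix, atol=1e-9)
    with pytest.raises(DegenerateGeometryError):
        estimate_affine_lsq(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]),
                            np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))


# ----------------------------------------------------------------- algebra

def test_compose_identity_and_translations():
    A = AffineTransform(np.array([[0.9, 0.1, 3.0], [-0.1, 1.1, -4.0]]))
    assert np.allclose(compose(AffineTransform.identity(), A).matrix, A.matrix)
    t = compose(AffineTransform.translation(1, 2), AffineTransform.translation(3, 4))
    assert np.allclose(t.matrix, [[1, 0, 4], [0, 1, 6]])


def test_compose_with_inverse_is_identity():
    A = AffineTransform(np.array([[0.9, 0.2, 13.0], [-0.15, 1.05, -6.0]]))
    I = compose(A, A.invert())
    assert np.allclose(I.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-9)
    # oracle: homogeneous product with the numpy inverse
    oracle = A.homogeneous @ np.linalg.inv(A.homogeneous)
    assert np.allclose(I.homogeneous, oracle, atol=1e-9)


def test_singular_matrix_rejected():
    with pytest.raises(DegenerateGeometryError):
        AffineTransform(np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0]]))


def test_rigid_constructor_round_trip():
    tf = AffineTransform.rigid(0.1, 5.0, -3.0, center=(200, 300))
    assert tf.rotation_angle == pytest.approx(0.1)
    back = tf.invert()
    p = np.array([[10.0, 20.0]])
    assert np.allclose(back.apply(tf.apply(p)), p, atol=1e-9)


# ------------------------------------------------------------- partitioning

@pytest.mark.parametrize(
    "counts, expected",
    [
        ([3, 3, 3, 3], [(1, 4, 3)]),
        ([3, 3, 4, 4, 4], [(1, 2, 3), (3, 5, 4)]),
        ([2, 3, 2], [(1, 1, 2), (2, 2, 3), (3, 3, 2)]),
    ],
)
def test_partition_intervals(counts, expected):
    part = partition_intervals(counts)
    assert [(iv.t_start, iv.t_end, iv.J) for iv in part.intervals] == expected
    assert part.T == len(counts)


def test_partition_matches_rle_oracle(rng):
    counts = list(rng.integers(1, 4, size=30))
    part = partition_intervals(counts)
    # run-length-encoding oracle
    runs, start = [], 0
    for i in range(1, 31):
        if i == 30 or counts[i] != counts[start]:
            runs.append((start + 1, i, counts[start]))
            start = i
    assert [(iv.t_start, iv.t_end, iv.J) for iv in part.intervals] == runs
    assert all(iv.registrable == (iv.length >= 2) for iv in part.intervals)


def test_chain_identities_and_translations():
    I = AffineTransform.identity()
    assert all(
        np.allclose(tf.matrix, I.matrix)
        for tf in chain_to_reference([I, I, I])
    )
    chain = chain_to_reference([AffineTransform.translation(1, 0)] * 4)
    assert np.allclose(chain[4].matrix, [[1, 0, 4], [0, 1, 0]])


def test_chain_matches_homogeneous_product_oracle(rng):
    pairwise = []
    for _ in range(10):
        ang = rng.uniform(-0.05, 0.05)
        tx, ty = rng.uniform(-3, 3, 2)
        pairwise.append(AffineTransform.rigid(ang, tx, ty, center=(100, 100)))
    chain = chain_to_reference(pairwise)
    H = np.eye(3)
    for t, tf in enumerate(pairwise, start=1):
        H = H @ tf.homogeneous
        assert np.allclose(chain[t].homogeneous, H, atol=1e-9)


def test_chain_breaks_downstream_of_missing_pair():
    T = AffineTransform.translation(1, 1)
    chain = chain_to_reference([T, None, T])
    assert chain[0] is not None and chain[1] is not None
    assert chain[2] is None and chain[3] is None


# ----------------------------------------------------------------- warping

def test_warp_identity_is_bit_exact(rng):
    f = Frame(pixels=rng.integers(0, 256, size=(32, 40), dtype=np.uint8), t=1)
    out = warp(f, AffineTransform.identity())
    assert np.array_equal(out.pixels, f.pixels)


def test_warp_integer_translation_shifts_pixels(rng):
    img = rng.integers(0, 256, size=(40, 40), dtype=np.uint8)
    f = Frame(pixels=img, t=1)
    out = warp(f, AffineTransform.translation(5, 3)).pixels
    assert np.array_equal(out[3:, 5:], img[: 40 - 3, : 40 - 5])
    assert np.all(out[:3, :] == 0) and np.all(out[:, :5] == 0)


def test_warp_round_trip_within_interpolation_tolerance(rng):
    img = rng.integers(0, 256, size=(50, 50), dtype=np.uint8)
    f = Frame(pixels=img, t=1)
    once = warp(f, AffineTransform.translation(5.0, 0.0))
    back = warp(once, AffineTransform.translation(-5.0, 0.0))
    interior = (slice(10, 40), slice(10, 40))
    assert np.abs(back.pixels[interior].astype(int) - img[interior]).max() <= 1


def test_warp_constant_image_stays_constant_in_interior():
    f = Frame(pixels=np.full((40, 40), 91, dtype=np.uint8), t=1)
    out = warp(f, AffineTransform.rigid(0.05, 1.5, -2.0, center=(20, 20))).pixels
    assert np.all(out[10:30, 10:30] == 91)
    assert set(np.unique(out)) <= {0, 91}


def test_warp_rgb_channelwise(rng):
    rgbarr = rng.integers(0, 256, size=(30, 30, 3), dtype=np.uint8)
    f = Frame(pixels=rgbarr[..., 0], t=1, rgb=rgbarr)
    tf = AffineTransform.translation(2, 1)
    out = warp(f, tf)
    for k in range(3):
        ch = warp(Frame(pixels=rgbarr[..., k], t=1), tf).pixels
        assert np.array_equal(out.rgb[..., k], ch)


def test_warp_mask_stays_binary():
    m = np.zeros((30, 30), dtype=bool)
    m[10:20, 10:20] = True
    out = warp_mask(BinaryMask(pixels=m, t=1),
                    AffineTransform.rigid(0.1, 2, 1, center=(15, 15)))
    assert out.pixels.dtype == bool
    assert 50 < out.pixels.sum() < 150  # roughly area-preserving


# ------------------------------------------------------------ full series

def test_register_series_small_scene(small_series, small_preprocess_config):
    series, truth = small_series
    result = register_series(series, small_preprocess_config)
    assert len(result.transforms) == series.T
    assert np.allclose(result.transforms[0].matrix, [[1, 0, 0], [0, 1, 0]])
    assert result.statuses[0] == "reference"
    assert all(s == "registered" for s in result.statuses[1:])
    # recovered transforms map true anchors onto the reference anchors
    for t in range(1, series.T):
        err = np.linalg.norm(
            result.transforms[t].apply(truth.cue_anchors[t]) - truth.cue_anchors[0],
            axis=1,
        ).max()
        assert err < 1.0
    # warped output keeps geometry
    assert result.registered.shape == series.shape
    # log has one row per frame with the expected columns
    assert list(result.frame_log.t) == list(range(1, series.T + 1))
    assert {"a", "b", "tx", "c", "d", "ty", "scenario", "J", "status"} <= set(
        result.frame_log.columns
    )


def test_registration_is_deterministic(small_series, small_preprocess_config):
    series, _ = small_series
    r1 = register_series(series, small_preprocess_config)
    r2 = register_series(series, small_preprocess_config)
    for a, b in zip(r1.transforms, r2.transforms):
        assert np.array_equal(a.matrix, b.matrix)


def test_summary_mentions_frames_and_intervals(small_series, small_preprocess_config):
    series, _ = small_series
    model = SeriesRegistration(series, preprocess_config=small_preprocess_config)
    text = model.fit().summary()
    assert "frames:" in text and "registered:" in text and "J=" in text


def test_single_frame_series_rejected(small_series):
    from vicar.io_frames import FrameSeries

    series, _ = small_series
    solo = FrameSeries(frames=[series[0]])
    with pytest.raises(ValidationError):
        SeriesRegistration(solo)
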