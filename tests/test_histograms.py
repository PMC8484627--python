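"""Feature histograms: mass assignment, conservation, covariance laws."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sceneaffect import (
    BinSpec,
    Contour,
    ContourFeatureExtractor,
    FEATURE_NAMES,
    LineDrawing,
    angularity_histogram,
    feature_table,
    feature_vector,
    length_histogram,
    orientation_histogram,
    synth_pool,
)

from conftest import random_polyline


def drawing_of(*point_lists, w=2000.0, h=2000.0):
    return LineDrawing(
        tuple(Contour(p, id=f"c{i}") for i, p in enumerate(point_lists)), w, h
    )


def total_length(d):
    return d.total_length()


class TestOrientationHistogram:
    def test_horizontal_segment_in_first_bin(self):
        hist = orientation_histogram(drawing_of([(0, 0), (10, 0)]))
        np.testing.assert_allclose(hist.weights, [10, 0, 0, 0, 0, 0, 0, 0])

    def test_45_degree_segment_at_exact_center(self):
        d = drawing_of([(0, 10), (10, 0)])
        hist = orientation_histogram(d)
        assert hist.weights[2] == pytest.approx(np.sqrt(200))
        assert hist.total_mass == pytest.approx(np.sqrt(200))

    def test_halfway_orientation_splits_mass_equally(self):
        # 8 px at 11.25 degrees: split 4/4 between the 0 and 22.5 centers
        theta = np.radians(11.25)
        d = drawing_of([(0, 8 * np.sin(theta)), (8 * np.cos(theta), 0)])
        hist = orientation_histogram(d)
        assert hist.weights[0] == pytest.approx(4.0)
        assert hist.weights[1] == pytest.approx(4.0)

    def test_wraparound_between_last_and_first_center(self):
        # 168.75 degrees sits halfway between 157.5 and 180 (== 0)
        theta = np.radians(180 - 168.75)
        d = drawing_of([(0, 0), (10 * np.cos(theta), 10 * np.sin(theta))])
        hist = orientation_histogram(d)
        assert hist.weights[7] == pytest.approx(5.0)
        assert hist.weights[0] == pytest.approx(5.0)


class TestLengthHistogram:
    def test_contour_at_center_fills_single_bin(self):
        # single contour whose length equals the third bin center
        d = drawing_of([(0, 0), (12.02, 0)])
        hist = length_histogram(d)
        assert hist.weights[2] == pytest.approx(12.02)
        assert hist.weights.sum() == pytest.approx(12.02)

    def test_beyond_last_center_clamped(self):
        d = drawing_of([(0, 0), (2000, 0)])
        hist = length_histogram(d)
        assert hist.weights[7] == pytest.approx(2000.0)

    def test_below_first_center_clamped(self):
        d = drawing_of([(0, 0), (1.0, 0)])
        assert length_histogram(d).weights[0] == pytest.approx(1.0)

    def test_two_contours_at_two_centers(self):
        d = drawing_of([(0, 0), (4.47, 0)], [(0, 10), (87.10, 10)])
        hist = length_histogram(d)
        assert hist.weights[1] == pytest.approx(4.47)
        assert hist.weights[4] == pytest.approx(87.10)
        assert np.count_nonzero(hist.weights) == 2


class TestAngularityHistogram:
    def test_straight_two_point_contour_in_lowest_bin(self):
        hist = angularity_histogram(drawing_of([(0, 0), (50, 0)]))
        np.testing.assert_allclose(hist.weights, [50, 0, 0, 0, 0, 0, 0, 0])

    def test_right_angle_vertex_mass_split(self):
        # vertex angularity 9.0 deg/px; 10 px of half-segments near center
        # 9.77, endpoint halves (10 px) in bin 1
        d = drawing_of([(0, 0), (10, 0), (10, 10)])
        hist = angularity_histogram(d)
        assert hist.weights[0] == pytest.approx(10.0)
        # mass interpolated between centers 5.13 (bin 3) and 9.77 (bin 4)
        assert hist.weights[2] + hist.weights[3] == pytest.approx(10.0)
        assert hist.weights[3] > hist.weights[2]
        assert hist.total_mass == pytest.approx(20.0)

    def test_collinear_vertex_counts_as_zero_turn(self):
        d = drawing_of([(0, 0), (10, 0), (20, 0)])
        np.testing.assert_allclose(
            angularity_histogram(d).weights, [20, 0, 0, 0, 0, 0, 0, 0]
        )


def test_mass_conservation_on_random_drawings():
    """Each histogram's total mass equals the drawing's contour length."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        n_contours = int(rng.integers(1, 6))
        d = drawing_of(
            *[random_polyline(rng) for _ in range(n_contours)], w=200, h=200
        )
        total = total_length(d)
        for hist_fn in (orientation_histogram, length_histogram, angularity_histogram):
            assert hist_fn(d).total_mass == pytest.approx(total, rel=1e-6)


def test_90_degree_rotation_shifts_orientation_bins():
    rng = np.random.default_rng(4)
    pts = [random_polyline(rng) for _ in range(4)]
    d = drawing_of(*pts, w=200, h=200)
    rotated = drawing_of(
        *[np.column_stack([p[:, 1], 100.0 - p[:, 0]]) for p in pts], w=200, h=200
    )
    ow = orientation_histogram(d).weights
    ow_rot = orientation_histogram(rotated).weights
    np.testing.assert_allclose(ow_rot, np.roll(ow, 4), atol=1e-8)
    np.testing.assert_allclose(
        length_histogram(rotated).weights, length_histogram(d).weights, atol=1e-8
    )
    np.testing.assert_allclose(
        angularity_histogram(rotated).weights,
        angularity_histogram(d).weights,
        atol=1e-8,
    )


def test_scaling_shifts_length_up_and_angularity_down():
    """Uniform x3 scaling: cumulative length histogram dominates the original
    (mass moves to longer bins) and angularity moves to lower bins."""
    rng = np.random.default_rng(5)
    pts = [random_polyline(rng) for _ in range(6)]
    d = drawing_of(*pts, w=200, h=200)
    scaled = drawing_of(*[p * 3.0 for p in pts], w=600, h=600)

    lw = np.cumsum(length_histogram(d).weights / total_length(d))
    lw_s = np.cumsum(length_histogram(scaled).weights / total_length(scaled))
    assert np.all(lw_s <= lw + 1e-9)

    aw = np.cumsum(angularity_histogram(d).weights / total_length(d))
    aw_s = np.cumsum(angularity_histogram(scaled).weights / total_length(scaled))
    assert np.all(aw_s >= aw - 1e-9)


def test_nearest_and_triangular_agree_at_centers():
    d = drawing_of(
        [(0, 0), (12.02, 0)],  # length at a center, orientation 0
        [(20, 20), (20, 20 + 87.10)],  # length at a center, orientation 90
    )
    for fn in (orientation_histogram, length_histogram):
        np.testing.assert_allclose(
            fn(d, mode="nearest").weights, fn(d, mode="triangular").weights
        )


class TestFeatureVector:
    def test_length_and_order(self):
        d = drawing_of([(0, 0), (16, 0)])
        fv = feature_vector(d, apply_sqrt=False)
        assert fv.values.shape == (23,)
        assert fv.names == FEATURE_NAMES
        assert fv.values[0] == pytest.approx(16.0)  # O1

    def test_sqrt_transform(self):
        d = drawing_of([(0, 0), (16, 0)])
        fv = feature_vector(d, apply_sqrt=True)
        assert fv.values[0] == pytest.approx(4.0)

    def test_straight_lines_only_zero_upper_angularity(self):
        d = drawing_of([(0, 0), (50, 0)], [(0, 10), (60, 10)])
        fv = feature_vector(d, apply_sqrt=False)
        a_bins = fv.values[15:]
        assert a_bins[0] == pytest.approx(110.0)
        np.testing.assert_allclose(a_bins[1:], 0.0)

    def test_length8_dropped(self):
        # a contour beyond the L8 center contributes nothing to the vector's
        # length entries beyond L7
        d = drawing_of([(0, 0), (1900, 0)])
        fv = feature_vector(d, apply_sqrt=False)
        np.testing.assert_allclose(fv.values[8:15], 0.0)


def test_transformer_and_table_roundtrip():
    drawings = synth_pool(2, seed=0)[:5]
    X = ContourFeatureExtractor().fit(drawings).transform(drawings)
    assert X.shape == (5, 23)
    table = feature_table(drawings, [f"d{i}" for i in range(5)])
    np.testing.assert_allclose(table[list(FEATURE_NAMES)].to_numpy(), X)
    assert table.attrs["sqrt_applied"] is True
    assert list(
        ContourFeatureExtractor().get_feature_names_out()
    ) == list(FEATURE_NAMES)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    pts=hnp.arrays(
        float,
        st.tuples(st.integers(2, 10), st.just(2)),
        elements=st.floats(0.0, 150.0, allow_nan=False, width=32),
    ),
    mode=st.sampled_from(["triangular", "nearest"]),
)
def test_conservation_holds_for_any_valid_contour(pts, mode):
    """Histogram mass equals contour length for arbitrary valid polylines,
    in both binning modes."""
    assume(not np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)))
    d = drawing_of(pts, w=150, h=150)
    total = total_length(d)
    for fn in (orientation_histogram, length_histogram, angularity_histogram):
        assert fn(d, mode=mode).total_mass == pytest.approx(total, rel=1e-6)


def test_bin_spec_validation():
    with pytest.raises(ValueError):
        BinSpec(orientation_centers=(0, 1, 2))
    with pytest.raises(ValueError):
        BinSpec(length_centers=(8, 7, 6, 5, 4, 3, 2, 1))
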