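import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilchem3d.alignment import (
    AlignmentError,
    AlignmentSearch,
    PlaneOrientation,
    align_face,
    cumulative_correlation,
    pearson_r,
    reconstruct_plane,
    round_half_away,
)
from soilchem3d.data_model import ElementMap, GrayscaleVolume
from soilchem3d.synthetic_data import trend_law


def loop_reconstruct(volume, a, b, k0, center, shape, origin=(0, 0)):
    """Per-pixel loop oracle for the staircase plane."""
    i0, j0 = center
    rows, cols = shape
    out = np.empty(shape, dtype=volume.data.dtype)
    for j in range(rows):
        for i in range(cols):
            jj, ii = j + origin[0], i + origin[1]
            z = a * (ii - i0) + b * (jj - j0) + k0
            zi = int(np.sign(z) * np.floor(abs(z) + 0.5))
            out[j, i] = volume.data[jj, ii, zi]
    return out


class TestReconstructPlane:
    def test_identity_plane_is_bit_exact(self, small_volume):
        """a = b = 0 recovers the un-rotated slice exactly."""
        for k0 in (0, 17, 95):
            plane = reconstruct_plane(
                small_volume, 0.0, 0.0, k0, (47.0, 47.0), (96, 96)
            )
            assert np.array_equal(plane, small_volume.data[:, :, k0])

    def test_staircase_extent(self):
        """a=0.05 over 800 columns centred mid-plane spans 20 slices each way."""
        data = np.zeros((4, 800, 64), dtype=np.uint8)
        for k in range(64):
            data[:, :, k] = k
        vol = GrayscaleVolume(data)
        plane = reconstruct_plane(vol, 0.05, 0.0, 32, (399.5, 1.5), (4, 800))
        dz = plane.astype(int) - 32
        assert dz.max() == round(0.05 * 400) == 20
        assert dz.min() == -20
        oracle = loop_reconstruct(vol, 0.05, 0.0, 32, (399.5, 1.5), (4, 800))
        assert np.array_equal(plane, oracle)

    @pytest.mark.parametrize("a,b,k0", [(0.02, -0.01, 40), (-0.05, 0.05, 50), (0.013, 0.027, 30)])
    def test_matches_loop_oracle(self, small_volume, a, b, k0):
        center = (47.0, 47.0)
        plane = reconstruct_plane(small_volume, a, b, k0, center, (60, 60), (10, 12))
        oracle = loop_reconstruct(small_volume, a, b, k0, center, (60, 60), (10, 12))
        assert np.array_equal(plane, oracle)

    def test_out_of_bounds_reports_admissible_range(self, small_volume):
        with pytest.raises(AlignmentError, match="admissible k0 range"):
            reconstruct_plane(small_volume, 0.05, 0.0, 0, (47.0, 47.0), (96, 96))

    def test_round_half_away_from_zero(self):
        assert np.array_equal(round_half_away([0.5, -0.5, 1.5, -1.5, 0.49]), [1, -1, 2, -2, 0])


class TestPearson:
    def test_perfect_and_inverted(self, rng):
        x = rng.uniform(size=50)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # x=(1,2,3), y=(2,2,5): cov=1.5, sx=1, sy=sqrt(3) -> r=sqrt(3)/2
        assert pearson_r([1, 2, 3], [2, 2, 5]) == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_constant_input_is_explicit_error(self):
        with pytest.raises(AlignmentError, match="undefined correlation"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_mask_restricts_pairs(self, rng):
        x = np.array([1.0, 2.0, 3.0, 100.0])
        y = np.array([2.0, 2.0, 5.0, -7.0])
        m = np.array([True, True, True, False])
        assert pearson_r(x, y, m) == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    def test_affine_invariance(self, scale, shift):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0])
        r0 = pearson_r(x, y)
        assert pearson_r(scale * x + shift, y) == pytest.approx(r0, abs=1e-9)


class TestCumulativeCorrelation:
    def test_identical_map(self, rng):
        plane = rng.uniform(1, 10, size=(6, 6))
        cum, per = cumulative_correlation(plane, [ElementMap("C", plane.copy())])
        assert cum == pytest.approx(1.0)
        assert per["C"] == pytest.approx(1.0)

    def test_negation_invariance(self, rng):
        plane = rng.uniform(1, 10, size=(6, 6))
        m = rng.uniform(1, 5, size=(6, 6))
        inv = m.max() + m.min() - m  # flipped about its midrange, still >= 0
        c1, _ = cumulative_correlation(plane, [ElementMap("C", m)])
        c2, _ = cumulative_correlation(plane, [ElementMap("C", inv)])
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_sum_of_known_correlations(self, rng):
        """Four maps engineered to correlate 0.5, -0.5, 1, 0 -> cumulative 2."""
        n = 64
        p = rng.standard_normal(n * n)
        p -= p.mean()
        p /= p.std()
        q = rng.standard_normal(n * n)
        q -= q.mean()
        q -= q @ p / (p @ p) * p  # orthogonalize against centered p
        q /= q.std()
        plane = p.reshape(n, n) + 10

        maps = [
            ElementMap("A", (0.5 * p + np.sqrt(0.75) * q - (0.5 * p + np.sqrt(0.75) * q).min() + 1).reshape(n, n)),
            ElementMap("B", (-0.5 * p + np.sqrt(0.75) * q - (-0.5 * p + np.sqrt(0.75) * q).min() + 1).reshape(n, n)),
            ElementMap("D", (p - p.min() + 1).reshape(n, n)),
            ElementMap("E", (q - q.min() + 1).reshape(n, n)),
        ]
        cum, per = cumulative_correlation(plane, maps)
        assert per["A"] == pytest.approx(0.5, abs=1e-12)
        assert per["B"] == pytest.approx(-0.5, abs=1e-12)
        assert per["D"] == pytest.approx(1.0, abs=1e-12)
        assert per["E"] == pytest.approx(0.0, abs=1e-12)
        assert cum == pytest.approx(2.0, abs=1e-12)
        # invariant: cumulative equals sum of absolute per-element values
        assert cum == pytest.approx(sum(abs(v) for v in per.values()), abs=1e-15)


def _maps_from_plane(gray, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    laws = {
        "C": ((95, 180), (9.0, 3.5, 2.0)),
        "Si": ((95, 180), (3.5, 12.0, 6.0)),
        "Fe": ((95, 185), (0.4, 0.8, 3.5)),
        "O": ((95, 180), (1.8, 4.8, 3.5)),
    }
    maps = []
    for el, (th, lv) in laws.items():
        d = trend_law(gray, th, lv)
        if noise_sd > 0:
            d = d + rng.normal(0, noise_sd * d.std(), size=d.shape)
        maps.append(ElementMap(el, np.clip(d, 0, None)))
    return maps


def _gray_maps(gray):
    """Element maps carrying the extracted plane itself (|r| = 1 at truth):
    the plane, its inversion and two affine rescalings."""
    g = gray.astype(float)
    return [
        ElementMap("C", g + 1.0),
        ElementMap("Si", 256.0 - g),
        ElementMap("Fe", 0.5 * g + 3.0),
        ElementMap("O", 2.0 * g),
    ]


class TestAlignFace:
    def test_identity_extraction(self, small_volume):
        """Maps cut from an axis-aligned slice are located exactly."""
        maps = _gray_maps(small_volume.data[0:48, 0:48, 40])
        search = AlignmentSearch(
            a_range=(-0.01, 0.01), b_range=(-0.01, 0.01), step=0.005,
            k0_range=(38, 42), plane_shape=(56, 56), crop_shape=(48, 48),
        )
        res = align_face(small_volume, maps, search)
        o = res.orientation
        assert (o.a, o.b, o.k0, o.crop_offset) == (0.0, 0.0, 40, (0, 0))
        assert res.cumulative_corr == pytest.approx(4.0, abs=1e-9)
        assert res.per_element_corr["Si"] == pytest.approx(-1.0)
        assert res.cumulative_corr == pytest.approx(
            sum(abs(v) for v in res.per_element_corr.values())
        )

    def test_tilted_recovery(self, small_volume):
        center = (47.0, 47.0)
        truth = PlaneOrientation(0.02, -0.01, 48, center, (8, 6))
        gray = reconstruct_plane(
            small_volume, truth.a, truth.b, truth.k0, center, (64, 64), truth.crop_offset
        )
        maps = _gray_maps(gray)
        search = AlignmentSearch(
            a_range=(-0.05, 0.05), b_range=(-0.05, 0.05), step=0.001,
            k0_range=(47, 49), plane_shape=(80, 80), crop_shape=(64, 64), center=center,
        )
        res = align_face(small_volume, maps, search)
        o = res.orientation
        assert abs(o.a - truth.a) <= 0.001 and abs(o.b - truth.b) <= 0.001
        assert o.crop_offset == truth.crop_offset

    def test_reported_correlations_recomputed(self, small_volume):
        gray = small_volume.data[4:52, 6:54, 33]
        maps = _maps_from_plane(gray, noise_sd=0.1)
        search = AlignmentSearch(
            a_range=(-0.005, 0.005), b_range=(-0.005, 0.005), step=0.005,
            k0_range=(32, 34), plane_shape=(60, 60), crop_shape=(48, 48),
        )
        res = align_face(small_volume, maps, search)
        o = res.orientation
        plane = reconstruct_plane(small_volume, o.a, o.b, o.k0, o.center, (60, 60))
        crop = plane[o.crop_offset[0]:o.crop_offset[0]+48, o.crop_offset[1]:o.crop_offset[1]+48]
        cum, per = cumulative_correlation(crop, maps)
        for el in per:
            assert per[el] == pytest.approx(res.per_element_corr[el], abs=1e-12)

    def test_k0_tie_breaks_to_smallest(self):
        """Two slices with identical content tie; the smaller k0 wins."""
        rng = np.random.default_rng(3)
        sl = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        data = rng.integers(0, 256, size=(32, 32, 12)).astype(np.uint8)
        data[:, :, 5] = sl
        data[:, :, 9] = sl
        vol = GrayscaleVolume(data)
        maps = [ElementMap("C", sl[2:26, 3:27].astype(float) + 1.0)]
        search = AlignmentSearch(
            a_range=(0.0, 0.0), b_range=(0.0, 0.0), step=0.001,
            k0_range=(0, 11), plane_shape=(32, 32), crop_shape=(24, 24),
        )
        res = align_face(vol, maps, search)
        assert res.orientation.k0 == 5
        assert res.orientation.crop_offset == (2, 3)

    def test_all_masked_overlap_errors(self, small_volume):
        m = ElementMap("C", np.ones((16, 16)), mask=np.zeros((16, 16), dtype=bool))
        search = AlignmentSearch(
            a_range=(0, 0), b_range=(0, 0), step=0.001, k0_range=(10, 10),
            plane_shape=(20, 20), crop_shape=(16, 16),
        )
        with pytest.raises(AlignmentError, match="masked"):
            align_face(small_volume, [m], search)

    def test_empty_feasible_space_errors(self, small_volume):
        maps = _maps_from_plane(small_volume.data[0:48, 0:48, 40])
        search = AlignmentSearch(
            a_range=(0.05, 0.05), b_range=(0.05, 0.05), step=0.001,
            k0_range=(0, 0), plane_shape=(96, 96), crop_shape=(48, 48),
        )
        with pytest.raises(AlignmentError, match="feasible"):
            align_face(small_volume, maps, search)


def exhaustive_oracle(volume, maps, search):
    """Plain loop over every (a, b, k0, offset); same tie-break contract."""
    best = None
    avals = np.round(np.arange(search.a_range[0], search.a_range[1] + 1e-12, search.step), 9)
    bvals = np.round(np.arange(search.b_range[0], search.b_range[1] + 1e-12, search.step), 9)
    center = search.resolved_center()
    pr, pc = search.plane_shape
    cr, cc = search.crop_shape
    for a, b in itertools.product(avals, bvals):
        for k0 in range(search.k0_range[0], search.k0_range[1] + 1):
            try:
                plane = reconstruct_plane(volume, a, b, k0, center, search.plane_shape)
            except AlignmentError:
                continue
            for dr in range(pr - cr + 1):
                for dc in range(pc - cc + 1):
                    crop = plane[dr:dr + cr, dc:dc + cc]
                    try:
                        cum, _ = cumulative_correlation(crop, maps)
                    except AlignmentError:
                        continue
                    key = (-round(cum, 9), abs(a) + abs(b), k0, dr, dc)
                    if best is None or key < best[0]:
                        best = (key, a, b, k0, (dr, dc))
    return best[1:]


class TestSearchEquivalence:
    def test_coarse_to_fine_matches_exhaustive_loop(self, tiny_volume):
        center = (31.0, 31.0)
        truth = PlaneOrientation(0.01, -0.005, 32, center, (3, 2))
        gray = reconstruct_plane(
            tiny_volume, truth.a, truth.b, truth.k0, center, (40, 40), truth.crop_offset
        )
        maps = _maps_from_plane(gray, noise_sd=0.05)
        search = AlignmentSearch(
            a_range=(-0.02, 0.02), b_range=(-0.02, 0.02), step=0.005,
            k0_range=(31, 33), plane_shape=(48, 48), crop_shape=(40, 40),
            center=center, coarse_step=0.015,
        )
        res_ctf = align_face(tiny_volume, maps, search)
        res_exh = align_face(tiny_volume, maps, dataclasses.replace(search, exhaustive=True))
        oracle = exhaustive_oracle(tiny_volume, maps, search)
        got_ctf = (res_ctf.orientation.a, res_ctf.orientation.b,
                   res_ctf.orientation.k0, res_ctf.orientation.crop_offset)
        got_exh = (res_exh.orientation.a, res_exh.orientation.b,
                   res_exh.orientation.k0, res_exh.orientation.crop_offset)
        assert got_ctf == oracle
        assert got_exh == oracle
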