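import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartus.errors import (
    DegeneratePartitionError,
    GeometryError,
    ZeroAreaError,
    ZeroLengthError,
)
from cartus.geometry import (
    CartilageSegmentation,
    ImageCalibration,
    Polyline,
    bone_interface_length,
    compute_thickness,
    partition_regions,
    region_csa,
    split_closed_outline,
)
from cartus.synthetic import PhantomSpec, make_phantom

from conftest import arc_oracle_mm, area_oracle_mm2, make_band


class TestPolyline:
    def test_reversed_input_is_normalized(self):
        p = Polyline([(400, 80), (0, 80)])
        assert p.x_min == 0 and p.x_max == 400

    def test_non_monotone_rejected(self):
        with pytest.raises(GeometryError):
            Polyline([(0, 0), (10, 1), (5, 2)])

    def test_duplicate_x_rejected(self):
        with pytest.raises(GeometryError):
            Polyline([(0, 0), (0, 5), (10, 1)])

    def test_too_few_vertices(self):
        with pytest.raises(GeometryError):
            Polyline([(0, 0)])

    def test_non_finite_rejected(self):
        with pytest.raises(GeometryError):
            Polyline([(0, 0), (10, np.nan)])


class TestSegmentationInvariants:
    def test_mismatched_extent_rejected(self):
        with pytest.raises(GeometryError):
            make_band([(0, 80), (400, 80)], [(0, 100), (390, 100)])

    def test_crossing_borders_rejected(self):
        with pytest.raises(GeometryError):
            make_band([(0, 80), (400, 120)], [(0, 100), (400, 90)])

    def test_central_point_outside_extent_rejected(self):
        with pytest.raises(GeometryError):
            make_band(
                [(0, 80), (400, 80)], [(0, 100), (400, 100)], central=(400, 80)
            )

    def test_bad_calibration_rejected(self):
        with pytest.raises(GeometryError):
            ImageCalibration(0.0, 0.1)
        with pytest.raises(GeometryError):
            ImageCalibration(0.1, -1.0)


class TestPartition:
    def test_symmetric_midpoint(self, flat_band):
        part = partition_regions(flat_band)
        assert part.cut_lo == pytest.approx(150.0)
        assert part.cut_hi == pytest.approx(250.0)

    def test_shifted_center_keeps_width(self):
        seg = make_band(
            [(0, 80), (400, 80)], [(0, 100), (400, 100)], central=(180, 80)
        )
        part = partition_regions(seg)
        assert part.cut_lo == pytest.approx(130.0)
        assert part.cut_hi == pytest.approx(230.0)
        assert part.cut_hi - part.cut_lo == pytest.approx(0.25 * 400)

    def test_near_edge_center_is_degenerate(self):
        seg = make_band(
            [(0, 80), (400, 80)], [(0, 100), (400, 100)], central=(40, 80)
        )
        with pytest.raises(DegeneratePartitionError):
            partition_regions(seg)

    def test_custom_fraction(self, flat_band):
        part = partition_regions(flat_band, fraction=0.5)
        assert part.cut_hi - part.cut_lo == pytest.approx(200.0)


class TestRegionCSA:
    def test_rectangle_strip(self, flat_band):
        assert region_csa(flat_band, 150, 250) == pytest.approx(20.0)

    def test_full_extent_and_additivity(self, flat_band):
        full = region_csa(flat_band, 0, 400)
        assert full == pytest.approx(80.0)
        parts = (
            region_csa(flat_band, 0, 150)
            + region_csa(flat_band, 150, 250)
            + region_csa(flat_band, 250, 400)
        )
        assert parts == pytest.approx(full, rel=1e-12)

    def test_sloped_band_matches_rasterization_oracle(self, sloped_band):
        got = region_csa(sloped_band, 150, 250)
        want = area_oracle_mm2(sloped_band, 150, 250)
        assert got == pytest.approx(want, rel=1e-3)
        # uniform 20-px vertical gap over a 100-px strip: exactly 20 mm^2
        assert got == pytest.approx(20.0, rel=1e-12)

    def test_empty_strip_errors(self, flat_band):
        with pytest.raises(ZeroAreaError):
            region_csa(flat_band, 250, 250)
        with pytest.raises(ZeroAreaError):
            region_csa(flat_band, 250, 150)


class TestBoneLength:
    def test_flat_strip(self, flat_band):
        assert bone_interface_length(flat_band, 150, 250) == pytest.approx(10.0)

    def test_single_segment_pythagoras(self, sloped_band):
        got = bone_interface_length(sloped_band, 0, 400)
        assert got == pytest.approx(math.hypot(40.0, 4.0), rel=1e-12)

    def test_bicondylar_matches_dense_resampling_oracle(self):
        spec = PhantomSpec(bone_profile="bicondylar", seed=3)
        seg, _ = make_phantom(spec)
        got = bone_interface_length(seg, 50.0, 350.0)
        want = arc_oracle_mm(seg, 50.0, 350.0)
        assert got == pytest.approx(want, rel=1e-6)

    def test_empty_strip_errors(self, flat_band):
        with pytest.raises(ZeroLengthError):
            bone_interface_length(flat_band, 100, 100)

    def test_anisotropic_calibration(self):
        seg = make_band(
            [(0, 80), (400, 120)], [(0, 100), (400, 140)], cal=(0.1, 0.2)
        )
        got = bone_interface_length(seg, 0, 400)
        assert got == pytest.approx(math.hypot(400 * 0.1, 40 * 0.2), rel=1e-12)


class TestComputeThickness:
    def test_constant_band(self, flat_band):
        for m in compute_thickness(flat_band):
            assert m.thickness_mm == pytest.approx(2.0, abs=1e-12)
            assert m.thickness_mm == m.csa_mm2 / m.bone_length_mm

    def test_sloped_band_closed_form(self, sloped_band):
        metrics = {m.region: m for m in compute_thickness(sloped_band)}
        mid = metrics["intercondylar"]
        # area is the vertical-gap rectangle; arc exceeds the chord
        want = 20.0 / math.hypot(10.0, 1.0)
        assert mid.thickness_mm == pytest.approx(want, rel=1e-12)
        assert mid.thickness_mm < 2.0
        csa_oracle = area_oracle_mm2(sloped_band, 150, 250)
        arc_oracle = arc_oracle_mm(sloped_band, 150, 250)
        assert mid.thickness_mm == pytest.approx(csa_oracle / arc_oracle, rel=1e-3)

    def test_flat_bone_piecewise_truth(self):
        spec = PhantomSpec(
            thickness_profile={"medial": 2.0, "intercondylar": 2.5, "lateral": 2.0}
        )
        seg, truth = make_phantom(spec)
        got = {m.region: m.thickness_mm for m in compute_thickness(seg)}
        for region, want in truth.regional_thickness_mm.items():
            assert got[region] == pytest.approx(want, abs=0.01)
        assert got["intercondylar"] == pytest.approx(2.5, abs=0.01)

    def test_region_labels_follow_medial_direction(self):
        prof = {"medial": 2.0, "intercondylar": 2.5, "lateral": 3.0}
        seg_px, _ = make_phantom(PhantomSpec(thickness_profile=prof))
        seg_mx, _ = make_phantom(
            PhantomSpec(thickness_profile=prof, medial_direction="-x")
        )
        got_px = {m.region: m.thickness_mm for m in compute_thickness(seg_px)}
        got_mx = {m.region: m.thickness_mm for m in compute_thickness(seg_mx)}
        assert got_px["medial"] == pytest.approx(2.0, abs=0.01)
        assert got_mx["medial"] == pytest.approx(2.0, abs=0.01)
        assert got_px["lateral"] == pytest.approx(3.0, abs=0.01)


class TestProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_shoelace_vs_rasterization_on_random_phantoms(self, seed):
        rng = np.random.default_rng(seed)
        spec = PhantomSpec(
            bone_profile=rng.choice(["flat", "sloped", "bicondylar"]),
            slope=float(rng.uniform(-0.15, 0.15)),
            thickness_profile={
                "medial": float(rng.uniform(1.5, 3.0)),
                "intercondylar": float(rng.uniform(1.5, 3.0)),
                "lateral": float(rng.uniform(1.5, 3.0)),
            },
            border_noise_sd_px=float(rng.uniform(0.0, 1.0)),
            seed=seed,
        )
        seg, _ = make_phantom(spec)
        part = partition_regions(seg)
        for x_lo, x_hi in part.strips().values():
            got = region_csa(seg, x_lo, x_hi)
            want = area_oracle_mm2(seg, x_lo, x_hi)
            assert got == pytest.approx(want, rel=1e-3)

    def test_additivity_on_noisy_phantom(self):
        seg, _ = make_phantom(
            PhantomSpec(bone_profile="bicondylar", border_noise_sd_px=0.5, seed=11)
        )
        part = partition_regions(seg)
        strips = list(part.strips().values())
        csa_sum = sum(region_csa(seg, lo, hi) for lo, hi in strips)
        len_sum = sum(bone_interface_length(seg, lo, hi) for lo, hi in strips)
        assert csa_sum == pytest.approx(region_csa(seg, 0, 400), rel=1e-9)
        assert len_sum == pytest.approx(
            bone_interface_length(seg, 0, 400), rel=1e-9
        )

    @given(c=st.floats(min_value=0.01, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_calibration_equivariance(self, c):
        base = make_band([(0, 80), (400, 120)], [(0, 100), (400, 140)])
        scaled = make_band(
            [(0, 80), (400, 120)], [(0, 100), (400, 140)], cal=(0.1 * c, 0.1 * c)
        )
        a0 = region_csa(base, 150, 250)
        l0 = bone_interface_length(base, 150, 250)
        assert region_csa(scaled, 150, 250) == pytest.approx(a0 * c * c, rel=1e-9)
        assert bone_interface_length(scaled, 150, 250) == pytest.approx(
            l0 * c, rel=1e-9
        )
        t0 = {m.region: m.thickness_mm for m in compute_thickness(base)}
        t1 = {m.region: m.thickness_mm for m in compute_thickness(scaled)}
        for r in t0:
            assert t1[r] == pytest.approx(t0[r] * c, rel=1e-9)

    def test_reflection_swaps_medial_lateral(self):
        spec = PhantomSpec(
            bone_profile="sloped",
            slope=0.05,
            thickness_profile={"medial": 2.2, "intercondylar": 2.6, "lateral": 1.9},
            border_noise_sd_px=0.3,
            seed=7,
        )
        seg, _ = make_phantom(spec)
        mirrored = CartilageSegmentation(
            superior=Polyline(
                np.column_stack([400.0 - seg.superior.x, seg.superior.y])
            ),
            inferior=Polyline(
                np.column_stack([400.0 - seg.inferior.x, seg.inferior.y])
            ),
            central_point=(400.0 - seg.central_point[0], seg.central_point[1]),
            calibration=seg.calibration,
            medial_direction="-x",
        )
        orig = {m.region: m for m in compute_thickness(seg)}
        mirr = {m.region: m for m in compute_thickness(mirrored)}
        # mathematically an exact swap; binary interpolation weights are not
        # bit-symmetric under x -> 400 - x, so allow last-bits slack
        for region in orig:
            assert mirr[region].csa_mm2 == pytest.approx(
                orig[region].csa_mm2, rel=1e-9
            )
            assert mirr[region].bone_length_mm == pytest.approx(
                orig[region].bone_length_mm, rel=1e-9
            )

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_arc_chord_inequality(self, seed):
        seg, _ = make_phantom(
            PhantomSpec(bone_profile="bicondylar", border_noise_sd_px=0.4, seed=seed)
        )
        for lo, hi in [(0, 400), (150, 250), (10, 60)]:
            chord = (hi - lo) * seg.calibration.mm_per_px_x
            assert bone_interface_length(seg, lo, hi) >= chord - 1e-12


class TestSplitClosedOutline:
    def test_rectangle_roundtrip(self):
        ring = [(0, 100), (400, 100), (400, 80), (0, 80)]
        superior, inferior = split_closed_outline(np.array(ring, dtype=float))
        assert np.allclose(superior.y, 80)
        assert np.allclose(inferior.y, 100)

    def test_non_monotone_chain_rejected(self):
        ring = [(0, 100), (200, 110), (100, 105), (400, 100), (400, 80), (0, 80)]
        with pytest.raises(GeometryError):
            split_closed_outline(np.array(ring, dtype=float))
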