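"""Landmark detection, CCI and CCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from callidx.exceptions import LandmarkError
from callidx.metrics import (
    SliceLandmarks,
    aggregate_cci,
    cci_from_landmarks,
    compute_cca,
    detect_landmarks,
    is_open_arch,
    measure_stack,
)
from callidx.segmentation import AffineTransform
from conftest import half_disk


def make_landmarks(aa=2.0, bb=2.0, cc=2.0, ab=20.0):
    return SliceLandmarks(
        a=[ab / 2, 0.0],
        b=[-ab / 2, 0.0],
        c=[0.0, 10.0],
        a_prime=[ab / 2 - aa, 0.0],
        b_prime=[-ab / 2 + bb, 0.0],
        c_prime=[0.0, 10.0 - cc],
    )


class TestDetectLandmarks:
    def test_half_annulus_landmark_geometry(self, fine_stack, fine_phantom):
        """R=10, r=8 arch: landmarks near their analytic positions.

        The Y coordinates of a/b and all walk distances are voxel-accurate;
        the Z position of an extreme point on a circular arc is only
        determined to the quantised-column height ~ √(2·R·voxel)."""
        spec, _, truth = fine_phantom
        lm = detect_landmarks(fine_stack.slices[3], fine_stack.spacing, fine_stack.origin)
        vox = spec.voxel_size[1]
        col = np.sqrt(2 * 10.0 * vox) + vox
        for name in ("a", "b", "c", "a_prime", "b_prime", "c_prime"):
            got = np.asarray(getattr(lm, name))
            want = np.asarray(truth.landmarks[name])
            assert np.linalg.norm(got - want) <= col, name
        d = lm.distances()
        assert d["ab"] == pytest.approx(20.0, abs=2 * vox)
        for k in ("aa_prime", "bb_prime", "cc_prime"):
            assert d[k] == pytest.approx(2.0, abs=vox)

    def test_rotation_invariance_of_distances(self):
        """In-plane 30° rotation leaves the four CCI distances ~unchanged.

        The arch must extend past the half-circle so the anterior/posterior
        extremes stay on the smooth outer boundary under rotation (on an
        exact half-annulus the arch *ends* are the extremes, and rotation
        reassigns them — the measurement is anatomy-frame anchored)."""
        vox, R, r = 0.25, 10.0, 8.0

        def arc_mask(rot_rad):
            n = int(2 * (R + 3) / vox)
            y = (np.arange(n) - n / 2 + 0.5) * vox
            Y, Z = np.meshgrid(y, y, indexing="ij")
            cr, sr = np.cos(rot_rad), np.sin(rot_rad)
            Yr, Zr = cr * Y + sr * Z, -sr * Y + cr * Z
            ang = np.arctan2(Zr, Yr)
            rho = np.hypot(Y, Z)
            return (rho <= R) & (rho >= r) & ((ang >= -0.7) | (ang <= -np.pi + 0.7))

        lm0 = detect_landmarks(arc_mask(0.0), (vox, vox))
        lm1 = detect_landmarks(arc_mask(np.deg2rad(30)), (vox, vox))
        d0, d1 = lm0.distances(), lm1.distances()
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], abs=3 * vox), k
        assert cci_from_landmarks(lm1) == pytest.approx(
            cci_from_landmarks(lm0), abs=2 * vox / d0["ab"]
        )

    def test_translation_equivariance_exact(self, fine_stack):
        sl = fine_stack.slices[3]
        lm0 = detect_landmarks(sl, fine_stack.spacing, origin=(0.0, 0.0))
        lm1 = detect_landmarks(sl, fine_stack.spacing, origin=(7.0, -3.0))
        for name in ("a", "b", "c", "a_prime", "b_prime", "c_prime"):
            shift = getattr(lm1, name) - getattr(lm0, name)
            assert np.allclose(shift, [7.0, -3.0], atol=1e-9)

    def test_disconnected_input_rejected(self):
        m = np.zeros((30, 30), bool)
        m[2:10, 2:10] = True
        m[20:28, 20:28] = True
        with pytest.raises(LandmarkError, match="connected"):
            detect_landmarks(m, (1.0, 1.0))

    def test_tiny_mask_rejected(self):
        m = np.zeros((10, 10), bool)
        m[4:6, 4:6] = True
        with pytest.raises(LandmarkError, match="few"):
            detect_landmarks(m, (1.0, 1.0))

    def test_rectangle_has_no_superior_boundary(self):
        """A flat rectangle puts a and b on its top edge, leaving no apex."""
        m = np.zeros((50, 20), bool)
        m[4:45, 4:12] = True
        with pytest.raises(LandmarkError, match="superior"):
            detect_landmarks(m, (0.25, 0.25))

    def test_half_disk_flagged_open_arch(self):
        """On a filled semicircle the end walks cross the whole shape."""
        m = half_disk()
        lm = detect_landmarks(m, (0.25, 0.25))
        assert is_open_arch(lm)

    def test_annulus_not_flagged(self, fine_stack):
        lm = detect_landmarks(fine_stack.slices[3], fine_stack.spacing)
        assert not is_open_arch(lm)

    def test_nearest_mode_underestimates_thickness_on_arcs(self, fine_stack):
        """The nearest-boundary alternative latches onto the adjacent outer
        rim instead of the opposite border — why subpixel walking is the
        default."""
        sl = fine_stack.slices[3]
        walk = detect_landmarks(sl, fine_stack.spacing, opposite="walk")
        near = detect_landmarks(sl, fine_stack.spacing, opposite="nearest")
        assert near.distances()["aa_prime"] < walk.distances()["aa_prime"]


class TestCCIFormula:
    def test_formula_arithmetic(self):
        assert cci_from_landmarks(make_landmarks(2, 2, 2, 20)) == pytest.approx(0.300)

    def test_zero_thickness_gives_zero(self):
        assert cci_from_landmarks(make_landmarks(0, 0, 0, 20)) == 0.0

    def test_annulus_closed_form(self):
        """R=10, r=7.5 ideal landmarks give 3(R−r)/(2R) = 0.375."""
        lm = SliceLandmarks(
            a=[10, 0], b=[-10, 0], c=[0, 10],
            a_prime=[7.5, 0], b_prime=[-7.5, 0], c_prime=[0, 7.5],
        )
        assert cci_from_landmarks(lm) == pytest.approx(0.375)

    def test_coincident_ab_error(self):
        lm = make_landmarks()
        lm.b = lm.a.copy()
        with pytest.raises(LandmarkError):
            cci_from_landmarks(lm)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        ang=st.floats(0.0, 2 * np.pi),
        scale=st.floats(0.05, 20.0),
        tx=st.floats(-100.0, 100.0),
        ty=st.floats(-100.0, 100.0),
    )
    def test_similarity_invariance_property(self, ang, scale, tx, ty):
        """CCI is a length ratio: rigid motion + uniform scale leave it fixed."""
        base = make_landmarks(1.7, 2.2, 2.6, 21.0)
        Rm = scale * np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        t = np.array([tx, ty])
        moved = SliceLandmarks(
            **{
                k: Rm @ getattr(base, k) + t
                for k in ("a", "b", "c", "a_prime", "b_prime", "c_prime")
            }
        )
        assert cci_from_landmarks(moved) == pytest.approx(
            cci_from_landmarks(base), rel=1e-9
        )


class TestAggregation:
    def test_identical_slices_equal_single(self):
        lms = [make_landmarks() for _ in range(7)]
        cci, med, per = aggregate_cci(lms)
        assert cci == cci_from_landmarks(lms[0])
        assert per == [pytest.approx(0.3)] * 7

    @pytest.mark.parametrize("n_bad", [1, 2, 3])
    def test_median_rejects_corrupted_minority(self, n_bad):
        """≤3 corrupted slices out of 7 leave the aggregate exactly intact."""
        good = [make_landmarks() for _ in range(7 - n_bad)]
        bad = []
        for i in range(n_bad):
            lm = make_landmarks()
            shift = 5.0 if i % 2 == 0 else -5.0
            for name in ("a", "b", "c", "a_prime", "b_prime", "c_prime"):
                setattr(lm, name, getattr(lm, name) + np.array([shift, shift]))
            bad.append(lm)
        cci_clean, _, _ = aggregate_cci([make_landmarks() for _ in range(7)])
        cci_corrupt, _, _ = aggregate_cci(good + bad)
        assert cci_corrupt == pytest.approx(cci_clean, abs=1e-12)

    def test_symmetric_perturbation_centres_on_mean(self):
        lms = [make_landmarks(aa=2.0 + d, bb=2.0, cc=2.0) for d in (-0.4, -0.2, 0.0, 0.2, 0.4)]
        cci, _, _ = aggregate_cci(lms)
        assert cci == pytest.approx(0.300, abs=1e-12)

    def test_even_count_uses_lower_median(self):
        lms = [make_landmarks(aa=v) for v in (1.0, 3.0)]
        cci, med, _ = aggregate_cci(lms)
        # lower median of a_prime Y coords {9.0, 7.0} → 7.0 → aa' = 3.0
        assert np.linalg.norm(med.a - med.a_prime) == pytest.approx(3.0)

    def test_zero_slices_error(self):
        with pytest.raises(LandmarkError):
            aggregate_cci([])


class TestCCA:
    def test_full_square_counting(self):
        sl = np.ones((10, 10), bool)
        cca, norm = compute_cca([sl], (1.0, 1.0))
        assert cca == 100.0 and norm == 100.0

    def test_half_annulus_closed_form(self, fine_stack):
        cca, _ = compute_cca(fine_stack.slices, fine_stack.spacing)
        assert cca == pytest.approx(np.pi * (100 - 64) / 2, rel=0.02)

    def test_resolution_invariance(self):
        from callidx.segmentation import extract_midsagittal_slices
        from callidx.synthetic import CCShapeSpec, generate_cc_mask

        areas = []
        for v in (1.0, 0.5):
            vol, _ = generate_cc_mask(CCShapeSpec(voxel_size=(v,) * 3))
            st = extract_midsagittal_slices(vol, 7)
            areas.append(compute_cca(st.slices, st.spacing)[0])
        assert areas[0] == pytest.approx(areas[1], rel=0.02)

    def test_affine_scale_normalisation(self):
        sl = np.ones((10, 10), bool)
        tf = AffineTransform(np.eye(3) * 0.5, np.zeros(3))
        cca, norm = compute_cca([sl], (1.0, 1.0), tf)
        assert cca == 100.0
        assert norm == pytest.approx(25.0)

    def test_all_empty_error(self):
        with pytest.raises(LandmarkError):
            compute_cca([np.zeros((5, 5), bool)], (1.0, 1.0))


class TestMeasureStack:
    def test_full_phantom_measurement(self, fine_stack, fine_phantom):
        spec, _, truth = fine_phantom
        res = measure_stack(fine_stack)
        vox = spec.voxel_size[1]
        assert res.cci == pytest.approx(truth.cci, abs=2 * vox / (2 * truth.outer_radius))
        assert res.cca_mm2 == pytest.approx(truth.area_per_slice_mm2, rel=0.02)
        assert res.n_slices_used == 7
        assert 0 < res.cci < 1
        assert not any(res.qc["open_arch_flags"].values())

    def test_json_round_trip(self, fine_stack):
        import json

        res = measure_stack(fine_stack)
        blob = json.loads(res.to_json())
        assert blob["cci"] == pytest.approx(res.cci)
        assert len(blob["per_slice_cci"]) == res.n_slices_used
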