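import dataclasses
import math

import numpy as np
import pytest
import trimesh

import platemetry as pm
from platemetry.extension_metrics import (
    MeasureConfig,
    MeasurementError,
    SkeletonChain,
    cleft_candidates,
    compute_angles,
    compute_lengths,
    effective_volume,
    find_cleft_section,
)
from platemetry.mesh_io import LandmarkSet
from platemetry.synthetic_fixtures import PhantomSpec


class TestEffectiveSections:
    def test_equal_offsets_and_tip(self, default_result):
        sections = default_result.sections
        drop = default_result.frame.drop
        assert len(sections) == 5
        offsets = [s.offset for s in sections]
        assert np.allclose(np.diff(offsets), drop / 4, atol=1e-9)
        tip = sections[-1]
        assert tip.area is None and tip.width is None and tip.thickness is None
        assert np.allclose(tip.centroid, default_result.landmarks.end)

    def test_middle_sections_fully_measured(self, default_result):
        for sec in default_result.sections[:4]:
            assert sec.area > 0 and sec.width > 0 and sec.thickness > 0
            # centroid lies inside the loop bounding box
            uv = sec.plane.to_2d(sec.centroid)[0]
            assert uv[0] >= sec.loop[:, 0].min() and uv[0] <= sec.loop[:, 0].max()
            assert uv[1] >= sec.loop[:, 1].min() and uv[1] <= sec.loop[:, 1].max()


class TestLengths:
    def test_worked_example(self, canonical_frame):
        el, sl = compute_lengths(canonical_frame, {4: np.array([10.0, 3.0, -7.0])})
        assert el[4] == pytest.approx(7.0)
        assert sl[4] == pytest.approx(math.sqrt(109))

    def test_centroid_on_plane_has_zero_effective_length(self, canonical_frame):
        el, _ = compute_lengths(canonical_frame, {1: np.array([12.0, -4.0, 0.0])})
        assert el[1] == 0.0

    def test_rigid_invariance(self, canonical_frame):
        pts = {k: np.array([5.0 * k, k - 2.0, -3.0 * k]) for k in range(6)}
        el, sl = compute_lengths(canonical_frame, pts)
        matrix = trimesh.transformations.euler_matrix(0.9, 0.2, -1.3)
        matrix[:3, 3] = [4, 7, -2]
        R, t = matrix[:3, :3], matrix[:3, 3]
        frame2 = dataclasses.replace(
            canonical_frame,
            origin=R @ canonical_frame.origin + t,
            normal=R @ canonical_frame.normal,
            sagittal=R @ canonical_frame.sagittal,
            mediolateral=R @ canonical_frame.mediolateral,
        )
        el2, sl2 = compute_lengths(frame2, {k: R @ v + t for k, v in pts.items()})
        for k in pts:
            assert el2[k] == pytest.approx(el[k], abs=1e-9)
            assert sl2[k] == pytest.approx(sl[k], abs=1e-9)


class TestAngles:
    def test_collinear_chain_is_zero(self):
        chain = SkeletonChain(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float))
        assert np.allclose(compute_angles(chain), 0.0)

    def test_right_angle(self):
        chain = SkeletonChain(np.array([[0, 0, 0], [10, 0, 0], [10, 0, -10]], dtype=float))
        assert compute_angles(chain)[0] == pytest.approx(90.0)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            SkeletonChain(np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0]], dtype=float))

    def test_angles_bounded(self, default_result):
        alphas = compute_angles(default_result.skeleton)
        assert ((alphas >= 0) & (alphas <= 180)).all()

    def test_signed_variant_magnitude_matches(self, canonical_frame):
        chain = SkeletonChain(np.array([[0, 0, 0], [10, 0, 0], [15, 0, -10]], dtype=float))
        unsigned = compute_angles(chain)
        signed = compute_angles(chain, canonical_frame, signed=True)
        assert abs(signed[0]) == pytest.approx(unsigned[0], abs=1e-9)


def _frame_with_drop(drop):
    from platemetry.reference_frame import ReferenceFrame

    return ReferenceFrame(
        origin=np.zeros(3),
        normal=np.array([0.0, 0.0, -1.0]),
        sagittal=np.array([1.0, 0.0, 0.0]),
        mediolateral=np.array([0.0, 1.0, 0.0]),
        drop=drop,
    )


class TestEffectiveVolume:
    def test_hemisphere_closed_form(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5)
        lm = LandmarkSet(ip=[0, 0, 0], q1=[1, 1, 0], q2=[1, -1, 0], end=[0, 0, -5])
        volume = effective_volume(sphere, _frame_with_drop(5.0), lm)
        assert volume == pytest.approx((2 / 3) * math.pi * 125, rel=0.03)

    def test_straight_tube_closed_form(self):
        cyl = trimesh.creation.cylinder(radius=4, height=22, sections=128)
        cyl.apply_translation([10, 0, -9])  # spans z in [-20, +2]
        lm = LandmarkSet(ip=[0, 0, 0], q1=[1, 1, 0], q2=[1, -1, 0], end=[10, 0, -20])
        volume = effective_volume(cyl, _frame_with_drop(20.0), lm)
        assert volume == pytest.approx(320 * math.pi, rel=0.03)

    def test_open_mesh_returns_missing(self, caplog):
        cyl = trimesh.creation.cylinder(radius=4, height=22, sections=64)
        cyl.apply_translation([10, 0, -9])
        # tear a hole: drop a handful of faces from the lower half
        low = np.argsort(cyl.triangles_center[:, 2])[:5]
        keep = np.ones(len(cyl.faces), dtype=bool)
        keep[low] = False
        holed = trimesh.Trimesh(cyl.vertices, cyl.faces[keep], process=False)
        lm = LandmarkSet(ip=[0, 0, 0], q1=[1, 1, 0], q2=[1, -1, 0], end=[10, 0, -20])
        with caplog.at_level("WARNING", logger="platemetry"):
            volume = effective_volume(holed, _frame_with_drop(20.0), lm)
        assert volume is None
        assert "missing" in caplog.text


class TestCleftSection:
    def test_minimum_over_candidates(self, default_result, default_phantom):
        mesh, _, _ = default_phantom
        res = default_result
        candidates = cleft_candidates(res.prepared_mesh, res.frame, res.landmarks)
        assert len(candidates) == 4  # interior boundaries of 5 equal segments
        best = find_cleft_section(res.prepared_mesh, res.frame, res.landmarks)
        assert best.area == min(c.area for c in candidates)

    def test_neck_located_correctly(self, default_spec, default_result):
        # the generator's neck sits at 45% of the cleft run; the minimal
        # candidate must be the one nearest that position
        best = default_result.cleft_section
        candidates = cleft_candidates(
            default_result.prepared_mesh, default_result.frame, default_result.landmarks
        )
        neck_s = default_spec.neck_x() - default_spec.canonical_landmarks().ip[0]
        nearest = min(candidates, key=lambda c: abs(c.offset - neck_s))
        assert best.offset == pytest.approx(nearest.offset)

    def test_phantom_without_cleft_gives_missing(self, default_spec):
        mesh, lm, _ = pm.make_phantom(dataclasses.replace(default_spec, cleft=False))
        record = pm.measure_plate(mesh, lm)
        assert not record.is_populated("A_0")
        assert not record.is_populated("EL_0")
        # the effective side is still fully measured
        assert record.is_populated("EL_5") and record.is_populated("V_eff")


class TestMeasurePlate:
    def test_default_phantom_fully_populated(self, default_result):
        record = default_result.record
        assert sum(record.is_populated(c) for c in pm.RECORD_COLUMNS) == 32
        record.validate()

    def test_effective_lengths_equal_spacing(self, default_result):
        record = default_result.record
        drop = default_result.frame.drop
        els = [record[f"EL_{k}"] for k in range(1, 6)]
        assert els[0] == 0.0
        assert np.allclose(np.diff(els), drop / 4, atol=1e-6)
        assert record["EL_5"] == pytest.approx(drop, abs=1e-9)

    def test_q_swap_invariance(self, default_phantom):
        mesh, lm, _ = default_phantom
        swapped = LandmarkSet(ip=lm.ip, q1=lm.q2, q2=lm.q1, end=lm.end)
        a = pm.measure_plate(mesh, lm).as_array()
        b = pm.measure_plate(mesh, swapped).as_array()
        assert np.nanmax(np.abs(a - b)) <= 1e-6

    def test_rigid_invariance(self, default_phantom, rotated_phantom):
        mesh, lm, _ = default_phantom
        mesh_r, lm_r, _ = rotated_phantom
        a = pm.measure_plate(mesh, lm).as_array()
        b = pm.measure_plate(mesh_r, lm_r).as_array()
        assert np.nanmax(np.abs(a - b)) <= 1e-6

    def test_ground_truth_recovery(self, default_phantom):
        mesh, lm, truth = default_phantom
        record = pm.measure_plate(mesh, lm)
        for key, expected, atol in truth.expected_record():
            assert record[key] == pytest.approx(expected, abs=atol), key

    def test_nonstandard_section_count_rejected_for_record(self, default_phantom):
        mesh, lm, _ = default_phantom
        with pytest.raises(MeasurementError, match="32-value"):
            pm.measure_plate(mesh, lm, MeasureConfig(n_effective_sections=4))

    def test_config_file_parsing(self, tmp_path):
        path = tmp_path / "measure.cfg"
        path.write_text("target_faces = 5000\nclose_gap = 0.8  # mm\ndecimate = true\n")
        config = MeasureConfig.from_file(path)
        assert config.target_faces == 5000
        assert config.close_gap == 0.8
        assert config.decimate is True
        (tmp_path / "bad.cfg").write_text("nope = 1\n")
        with pytest.raises(ValueError, match="unknown option"):
            MeasureConfig.from_file(tmp_path / "bad.cfg")
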