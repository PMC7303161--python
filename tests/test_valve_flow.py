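"""Retrospective valve tracking: planes, reformatting, flow metrics."""

import numpy as np
import pytest

from rvkinergy import valve_flow as vf
from rvkinergy.errors import GeometryError
from rvkinergy.flow_preprocess import VelocityField
from rvkinergy.ke_mapping import CardiacTiming


def _square_annulus(n_phases=6, center=(30.0, 30.0, 15.0), r=10.0,
                    shift=None):
    c = np.asarray(center)
    base = np.array([[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0]]) + c
    lm = np.tile(base, (n_phases, 1, 1)).astype(float)
    apex = np.tile(c - [0, 0, 10.0], (n_phases, 1))
    if shift is not None:
        lm += np.asarray(shift)[:, None, :]
        apex += np.asarray(shift)
    return vf.AnnularTrack(lm, apex)


def _uniform_field(direction, n_phases=6, n=20, venc=150.0):
    v = np.zeros((n_phases, n, n, n, 3))
    v[...] = direction
    return VelocityField(v, (3.0, 3.0, 3.0), 100.0, venc)


def _square_aperture(n_phases=6, side=31.6228, center=(30.0, 30.0),
                     z=15.0):
    s = side / 2.0
    sq = np.array([[-s, -s], [s, -s], [s, s], [-s, s]]) + np.asarray(center)
    return [np.column_stack([sq, np.full(4, z)]) for _ in range(n_phases)]


def _timing():
    return CardiacTiming(1, np.arange(2), np.arange(2, 6),
                         np.arange(2, 4), np.arange(4, 6))


class TestTrackPlane:
    def test_static_landmarks_give_identical_planes(self):
        planes = vf.track_plane(_square_annulus())
        for p in planes[1:]:
            np.testing.assert_allclose(p.center_mm, planes[0].center_mm)
            np.testing.assert_allclose(p.normal, planes[0].normal)

    def test_plane_center_follows_translation(self):
        shift = np.zeros((6, 3))
        shift[3] = [0, 0, -5.0]  # apex-ward at ES
        planes = vf.track_plane(_square_annulus(shift=shift))
        np.testing.assert_allclose(planes[3].center_mm - planes[0].center_mm,
                                   [0, 0, -5.0])

    def test_normal_for_z_orthogonal_annulus(self):
        planes = vf.track_plane(_square_annulus())
        np.testing.assert_allclose(planes[0].normal, [0, 0, -1], atol=1e-12)

    def test_collinear_landmarks_rejected(self):
        lm = np.zeros((2, 4, 3))
        lm[:, :, 0] = [0, 1, 2, 3]
        with pytest.raises(GeometryError):
            vf.track_plane(vf.AnnularTrack(lm))


class TestReformat:
    def test_uniform_parallel_field_maps_to_speed(self):
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, -50.0]),
                                          planes, _square_aperture())
        assert maps.v_through[0][maps.inside_aperture[0]].mean() == \
            pytest.approx(50.0)

    def test_perpendicular_field_maps_to_zero(self):
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([50.0, 0, 0]),
                                          planes, _square_aperture())
        np.testing.assert_allclose(maps.v_through, 0.0, atol=1e-9)

    def test_45_degree_field_projects_by_cos(self):
        planes = vf.track_plane(_square_annulus())
        d = [50.0 / np.sqrt(2), 0, -50.0 / np.sqrt(2)]
        maps = vf.reformat_plane_velocity(_uniform_field(d), planes,
                                          _square_aperture())
        assert maps.v_through[0][maps.inside_aperture[0]].mean() == \
            pytest.approx(50.0 / np.sqrt(2))


class TestBackgroundCorrection:
    def test_constant_offset_removed_exactly(self):
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, -2.0]),
                                          planes, _square_aperture())
        ab0 = vf._project(_square_aperture()[0], planes[0])
        roi = vf.myocardial_ring_mask(maps, ab0)
        corrected = vf.background_correct_plane(maps, roi)
        # exact inside the aperture (grid margins beyond the FOV stay at
        # the padding value and are never integrated)
        np.testing.assert_allclose(
            corrected.v_through[:, corrected.inside_aperture[0]], 0.0,
            atol=1e-9)

    def test_zero_motion_identity(self):
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, 0.0]),
                                          planes, _square_aperture())
        ab0 = vf._project(_square_aperture()[0], planes[0])
        roi = vf.myocardial_ring_mask(maps, ab0)
        corrected = vf.background_correct_plane(maps, roi)
        np.testing.assert_allclose(corrected.v_through, maps.v_through)

    def test_empty_roi_skips_with_original_maps(self):
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, -3.0]),
                                          planes, _square_aperture())
        out = vf.background_correct_plane(maps,
                                          np.zeros_like(maps.inside_aperture[0]))
        np.testing.assert_allclose(out.v_through, maps.v_through)


class TestFlowMetrics:
    def test_plug_flow_stroke_volume(self):
        # 50 cm/s through 10 cm^2 for 400 ms of diastole -> 200 ml
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, -50.0]),
                                          planes, _square_aperture())
        tv = vf.tv_flow_metrics(maps, 100.0, _timing())
        assert tv.sv_ml == pytest.approx(200.0, rel=0.02)

    def test_zero_field_metrics(self):
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, 0.0]),
                                          planes, _square_aperture())
        tv = vf.tv_flow_metrics(maps, 100.0, _timing())
        assert tv.sv_ml == 0.0
        assert tv.ea_vel_ratio is None

    def test_reverse_flow_excluded_by_forward_only(self):
        planes = vf.track_plane(_square_annulus())
        f = _uniform_field([0, 0, -50.0])
        f.v[4:, ..., 2] = 30.0  # regurgitant in the late-diastole phases
        maps = vf.reformat_plane_velocity(f, planes, _square_aperture())
        tv_fwd = vf.tv_flow_metrics(maps, 100.0, _timing(), forward_only=True)
        tv_net = vf.tv_flow_metrics(maps, 100.0, _timing(), forward_only=False)
        assert tv_fwd.sv_ml > tv_net.sv_ml

    def test_sv_invariant_to_inplane_rotation(self):
        # rotating the in-plane basis must not change the flux integral
        track = _square_annulus()
        planes = vf.track_plane(track)
        rot = []
        c, a = np.cos(0.5), np.sin(0.5)
        for p in planes:
            e1 = c * p.e1 + a * p.e2
            e2 = np.cross(p.normal, e1)
            rot.append(vf.ValvePlane(p.center_mm, p.normal, e1, e2))
        f = _uniform_field([0, 0, -40.0])
        ap = _square_aperture()
        tv1 = vf.tv_flow_metrics(vf.reformat_plane_velocity(f, planes, ap),
                                 100.0, _timing())
        tv2 = vf.tv_flow_metrics(vf.reformat_plane_velocity(f, rot, ap),
                                 100.0, _timing())
        assert tv2.sv_ml == pytest.approx(tv1.sv_ml, rel=0.01)

    def test_annular_motion_corrected_to_zero_inflow(self):
        # annulus moving at 3 cm/s through static blood: after myocardial
        # background correction the inflow is zero
        planes = vf.track_plane(_square_annulus())
        maps = vf.reformat_plane_velocity(_uniform_field([0, 0, -3.0]),
                                          planes, _square_aperture())
        ab0 = vf._project(_square_aperture()[0], planes[0])
        corrected = vf.background_correct_plane(
            maps, vf.myocardial_ring_mask(maps, ab0))
        tv = vf.tv_flow_metrics(corrected, 100.0, _timing())
        assert tv.sv_ml == pytest.approx(0.0, abs=1e-6)
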