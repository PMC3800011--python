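"""Thickness engine: phantoms, harmonic potential, streamlines, ROI means."""

import numpy as np
import pytest

import corthick as ct
from corthick.errors import ParameterError, ShapeError
from corthick.laplace import (BOUNDARY, GRAY, INNER, OUTER, SEPARATION,
                              LabelVolume, ThicknessField, make_phantom,
                              read_label_volume, roi_mean_thickness,
                              solve_laplace, streamline_thickness, write_nifti)


class TestPhantoms:
    def test_slab_gray_voxel_count(self):
        vol = make_phantom("slab", thickness_voxels=5, cross_section=(20, 20))
        assert (vol.labels == GRAY).sum() == 2000

    def test_shell_volume_close_to_analytic(self):
        vol = make_phantom("spherical_shell", r1_mm=8, r2_mm=12)
        analytic = 4.0 / 3.0 * np.pi * (12 ** 3 - 8 ** 3)
        got = (vol.labels == GRAY).sum()
        assert abs(got - analytic) / analytic < 0.03

    def test_abutting_without_separation_has_no_wall_labels(self):
        vol = make_phantom("abutting_gyri", thickness_voxels=4,
                           separation=False)
        assert (vol.labels == SEPARATION).sum() == 0

    def test_abutting_with_separation_has_wall_plane(self):
        vol = make_phantom("abutting_gyri", thickness_voxels=4,
                           cross_section=(10, 10), separation=True)
        assert (vol.labels == SEPARATION).sum() == 100

    @pytest.mark.parametrize("kwargs", [
        dict(kind="spherical_shell", r1_mm=12, r2_mm=8),
        dict(kind="slab", thickness_voxels=0),
        dict(kind="nonsense"),
    ])
    def test_impossible_geometry_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            make_phantom(**kwargs)


class TestPotential:
    def test_slab_potential_is_linear_with_half_at_midplane(self):
        vol = make_phantom("slab", thickness_voxels=9, cross_section=(10, 10))
        f = solve_laplace(vol, tol=1e-8)
        # layers 1..9 between Dirichlet planes 0 and 10: psi_z = z/10
        profile = f.psi[5, 5, :]
        assert np.allclose(profile[1:10], np.arange(1, 10) / 10.0, atol=1e-4)
        assert abs(f.psi[5, 5, 5] - 0.5) < 1e-4

    def test_maximum_principle(self, solved_shell):
        _, f = solved_shell
        assert f.psi.min() >= 0.0 and f.psi.max() <= 1.0

    def test_shell_potential_tracks_harmonic_closed_form(self, solved_shell):
        """1/r harmonic profile, at the accuracy the voxelized boundary
        permits (boundary jaggedness ~ half a voxel times the gradient)."""
        vol, f = solved_shell
        c = vol.labels.shape[0] // 2
        idx = np.indices(vol.labels.shape) - c
        r = np.sqrt((idx ** 2).sum(axis=0)).astype(float)
        gray = vol.labels == GRAY
        closed = (1 / 8 - 1 / np.maximum(r, 1e-9)) / (1 / 8 - 1 / 12)
        err = np.abs(f.psi - closed)[gray]
        assert np.median(err) < 0.05
        mid = gray & (r >= 9) & (r <= 11)
        assert np.sqrt(np.mean(np.abs(f.psi - closed)[mid] ** 2)) < 0.08

    def test_non_convergence_raises(self):
        vol = make_phantom("spherical_shell", r1_mm=8, r2_mm=12)
        with pytest.raises(ct.errors.ConvergenceError):
            solve_laplace(vol, tol=1e-12, max_iter=3)

    def test_empty_gray_rejected(self):
        with pytest.raises(ParameterError):
            solve_laplace(LabelVolume(np.zeros((4, 4, 4), dtype=int)))


class TestStreamlines:
    def test_slab_thickness_exact_within_half_voxel(self):
        vol = make_phantom("slab", thickness_voxels=5, cross_section=(20, 20))
        th = streamline_thickness(solve_laplace(vol))
        ok = th.ok_values()
        assert ok.size == 2000
        assert np.abs(ok - 5.0).max() <= 0.5

    def test_shell_median_within_five_percent_of_analytic(self, solved_shell):
        _, f = solved_shell
        th = streamline_thickness(f)
        assert abs(np.median(th.ok_values()) - 4.0) / 4.0 < 0.05

    def test_resolution_convergence_halving_spacing(self, solved_shell):
        _, f1 = solved_shell
        err1 = abs(np.median(streamline_thickness(f1).ok_values()) - 4.0)
        vol2 = make_phantom("spherical_shell", r1_mm=8, r2_mm=12, spacing=0.5)
        th2 = streamline_thickness(solve_laplace(vol2))
        err2 = abs(np.median(th2.ok_values()) - 4.0)
        assert err2 < err1

    def test_widening_shell_increases_median_accordingly(self, solved_shell):
        _, f = solved_shell
        base = np.median(streamline_thickness(f).ok_values())
        vol13 = make_phantom("spherical_shell", r1_mm=8, r2_mm=13)
        wide = np.median(streamline_thickness(solve_laplace(vol13)).ok_values())
        assert abs((wide - base) - 1.0) <= 0.2

    def test_abutting_banks_merge_without_separation(self):
        vol = make_phantom("abutting_gyri", thickness_voxels=4,
                           cross_section=(12, 12), separation=False)
        th = streamline_thickness(solve_laplace(vol))
        assert abs(np.median(th.ok_values()) - 8.0) <= 0.5

    def test_separation_restores_isolated_slab_thickness(self):
        vol = make_phantom("abutting_gyri", thickness_voxels=4,
                           cross_section=(12, 12), separation=True)
        th = streamline_thickness(solve_laplace(vol))
        slab = make_phantom("slab", thickness_voxels=4, cross_section=(12, 12))
        oracle = np.median(streamline_thickness(solve_laplace(slab)).ok_values())
        assert abs(np.median(th.ok_values()) - oracle) <= 0.2
        # the far bank has no inner boundary once walled off: zero-gradient
        # voxels are excluded as 'boundary', not silently mismeasured
        assert (th.status == BOUNDARY).sum() > 0

    def test_separation_never_increases_any_voxel_thickness(self):
        merged = make_phantom("abutting_gyri", thickness_voxels=4,
                              cross_section=(10, 10), separation=False)
        walled = make_phantom("abutting_gyri", thickness_voxels=4,
                              cross_section=(10, 10), separation=True)
        tm = streamline_thickness(solve_laplace(merged))
        tw = streamline_thickness(solve_laplace(walled))
        both = tm.ok_mask() & tw.ok_mask()
        assert (tw.thickness[both] <= tm.thickness[both] + 1e-9).all()

    def test_slab_symmetric_under_label_swap(self):
        vol = make_phantom("slab", thickness_voxels=6, cross_section=(12, 12))
        swapped_labels = vol.labels.copy()
        swapped_labels[vol.labels == INNER] = OUTER
        swapped_labels[vol.labels == OUTER] = INNER
        swapped = LabelVolume(swapped_labels, vol.spacing)
        t1 = streamline_thickness(solve_laplace(vol, tol=1e-8))
        t2 = streamline_thickness(solve_laplace(swapped, tol=1e-8))
        g = vol.gray_mask
        assert np.allclose(t1.thickness[g], t2.thickness[g], atol=1e-6)


class TestROIMeans:
    def _uniform_field(self):
        vol = make_phantom("slab", thickness_voxels=3, cross_section=(6, 6))
        thick = np.full(vol.labels.shape, np.nan)
        status = np.zeros(vol.labels.shape, dtype=np.int8)
        thick[vol.gray_mask] = 3.0
        status[vol.gray_mask] = 1
        return ThicknessField(thickness=thick, status=status, volume=vol), vol

    def test_uniform_field_every_roi_mean_equal(self):
        field, vol = self._uniform_field()
        parcels = np.zeros(vol.labels.shape, dtype=int)
        parcels[vol.gray_mask] = 1
        parcels[3:, :, :][vol.gray_mask[3:, :, :]] = 2
        means = roi_mean_thickness(field, parcels)
        assert means[1][0] == pytest.approx(3.0)
        assert means[2][0] == pytest.approx(3.0)

    def test_two_roi_piecewise_slab(self):
        # one volume, two plates: ROI 1 is 4 voxels thick, ROI 2 is 6
        lab = np.zeros((20, 10, 8), dtype=np.int16)
        lab[:10, :, 0] = INNER; lab[:10, :, 1:5] = GRAY; lab[:10, :, 5] = OUTER
        lab[10:, :, 0] = INNER; lab[10:, :, 1:7] = GRAY; lab[10:, :, 7] = OUTER
        vol = LabelVolume(lab, spacing=1.0)
        th = streamline_thickness(solve_laplace(vol))
        parcels = np.zeros(lab.shape, dtype=int)
        parcels[:10][lab[:10] == GRAY] = 1
        parcels[10:][lab[10:] == GRAY] = 2
        means = roi_mean_thickness(th, parcels)
        assert abs(means[1][0] - 4.0) < 0.3
        assert abs(means[2][0] - 6.0) < 0.3

    def test_empty_roi_rejected(self):
        field, vol = self._uniform_field()
        parcels = np.zeros(vol.labels.shape, dtype=int)
        parcels[0, 0, 0] = 9  # a background voxel: no ok thickness there
        with pytest.raises(ParameterError, match="9"):
            roi_mean_thickness(field, parcels)

    def test_shape_mismatch_rejected(self):
        field, _ = self._uniform_field()
        with pytest.raises(ShapeError):
            roi_mean_thickness(field, np.zeros((2, 2, 2), dtype=int))


def test_nifti_roundtrip(tmp_path):
    vol = make_phantom("slab", thickness_voxels=4, cross_section=(8, 8),
                       spacing=0.5)
    path = tmp_path / "labels.nii.gz"
    write_nifti(path, vol.labels, vol.spacing)
    back = read_label_volume(path)
    assert back.spacing == pytest.approx(0.5)
    assert np.array_equal(back.labels, vol.labels)
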