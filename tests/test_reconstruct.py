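"""Projection/backprojection, symmetrization, hsearch, FSC, indexing."""

import numpy as np
import pandas as pd
import pytest

from barlattice.lattice import HelicalSymmetry
from barlattice.reconstruct import (
    DensityMap,
    OrientationAssignment,
    amplitude_correct,
    backproject,
    fsc,
    hsearch,
    index_layer_lines,
    make_reference_library,
    match_stack,
    noise_cylinder,
    project,
    projection_match,
    rank_candidates,
    resolution_at,
    run_ihrsr,
    symmetrize,
    Phase,
)
from barlattice.segments import SegmentStack

from conftest import correlation


def cylinder_map(box=48, voxel=3.0, radius_A=45.0, amp=1.0, edge_A=6.0):
    # smooth (tanh) edge: a hard-edged cylinder is not invariant under
    # resampling, which would confound interpolation-tolerance checks
    c = box // 2
    yy, xx = np.indices((box, box))
    r = np.hypot(yy - c, xx - c) * voxel
    mask = (0.5 * (1.0 - np.tanh((r - radius_A) / edge_A))).astype(np.float32)
    return DensityMap(np.broadcast_to(mask * amp, (box, box, box)).copy(), voxel)


class TestProject:
    def test_cylinder_projects_to_flat_band(self):
        img = project(cylinder_map(), 0.0)
        mid = img[:, 24]
        assert np.ptp(mid[4:-4]) < 1e-6 * abs(mid[10])  # constant along z
        # only the soft-edge tail reaches the box boundary
        assert img[:, 0].max() < 1e-2 * img.max()

    def test_periodic_in_azimuth(self, tube_volume):
        a = project(tube_volume, 33.0)
        b = project(tube_volume, 393.0)
        assert np.allclose(a, b, atol=1e-9)

    def test_adjoint_consistency(self):
        """<P v, i> == <v, B i> for the exact trilinear pair."""
        rng = np.random.default_rng(0)
        v = DensityMap(rng.standard_normal((32, 32, 32)), 3.0)
        img = rng.standard_normal((32, 32))
        for az, tilt in ((33.0, 7.0), (211.0, -4.0), (0.0, 0.0)):
            p = project(v, az, tilt)
            b = backproject(
                img[None],
                [OrientationAssignment(az, tilt, 0.0, 0.0, 0.0, 1.0)],
                32,
                3.0,
                normalize=False,
                weighting="none",
            )
            lhs = float((p * img).sum())
            rhs = float((v.grid.astype(np.float64) * b.grid).sum())
            assert abs(lhs - rhs) <= 1e-6 * abs(lhs)


class TestReferenceLibrary:
    @pytest.mark.parametrize(
        "az_step,tilt_range,tilt_step,expected",
        [(90.0, 0.0, 1.0, 4), (45.0, 10.0, 5.0, 8 * 5), (120.0, 2.0, 2.0, 3 * 3)],
    )
    def test_grid_counts(self, az_step, tilt_range, tilt_step, expected):
        refs, orients = make_reference_library(
            cylinder_map(box=24), az_step, tilt_range, tilt_step
        )
        assert len(orients) == expected
        assert refs.shape == (expected, 24, 24)

    def test_invalid_steps(self):
        with pytest.raises(ValueError):
            make_reference_library(cylinder_map(box=24), 0.0)


class TestProjectionMatch:
    def test_reference_matches_itself(self, tube_volume):
        refs, orients = make_reference_library(tube_volume, 45.0)
        a = projection_match(refs[3], refs, orients, tube_volume.voxel_size)
        assert (a.azimuth, a.tilt) == orients[3]
        assert a.score >= 0.999
        assert abs(a.shift_z) < 0.3 and abs(a.shift_x) < 0.3

    def test_off_grid_azimuth_snaps_to_nearest(self, tube_volume):
        refs, orients = make_reference_library(tube_volume, 8.0)
        seg = project(tube_volume, 41.5)
        a = projection_match(seg, refs, orients, tube_volume.voxel_size)
        assert abs(a.azimuth - 40.0) <= 4.0  # within half a grid step

    def test_pure_noise_scores_low(self, tube_volume):
        refs, orients = make_reference_library(tube_volume, 45.0)
        rng = np.random.default_rng(5)
        noise = rng.standard_normal((96, 96))
        a = projection_match(noise, refs, orients, 3.0)
        assert a.score < 0.2

    def test_shift_recovery(self, tube_volume):
        refs, orients = make_reference_library(tube_volume, 45.0)
        seg = project(tube_volume, 90.0, shifts=(6.0, -4.5))
        a = projection_match(seg, refs, orients, 3.0)
        assert a.shift_z == pytest.approx(6.0, abs=0.5)
        assert a.shift_x == pytest.approx(-4.5, abs=0.5)


class TestBackproject:
    def test_single_projection_smears_along_beam(self):
        img = project(cylinder_map(), 0.0)
        bp = backproject(
            img[None], [OrientationAssignment(0, 0, 0, 0, 0, 1)], 48, 3.0,
            weighting="none",
        )
        # density is uniform along the beam (y) inside the support
        mid = bp.grid[24, 10:-10, 24]
        assert np.ptp(mid) < 1e-6 * np.abs(bp.grid).max()

    def test_full_coverage_recovers_map(self, tube_volume):
        azimuths = np.arange(0.0, 360.0, 6.0)
        imgs = np.stack([project(tube_volume, a) for a in azimuths])
        assigns = [OrientationAssignment(a, 0, 0, 0, 0, 1) for a in azimuths]
        bp = backproject(imgs, assigns, 96, 3.0)

        # compare at half Nyquist inside the reconstruction support
        def lowpass(g, frac=0.125):
            f = np.fft.fftn(g.astype(np.float64))
            fr = [np.fft.fftfreq(n) for n in g.shape]
            r2 = (
                fr[0][:, None, None] ** 2
                + fr[1][None, :, None] ** 2
                + fr[2][None, None, :] ** 2
            )
            return np.real(np.fft.ifftn(f * (r2 <= frac**2)))

        lo_t, lo_b = lowpass(tube_volume.grid), lowpass(bp.grid)
        c = 48
        yy, xx = np.indices((96, 96))
        mask = np.broadcast_to((np.hypot(yy - c, xx - c) < 46)[None], (96, 96, 96)).copy()
        mask[:12] = mask[84:] = False
        assert correlation(lo_t[mask], lo_b[mask]) >= 0.95

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            backproject(np.empty((0, 8, 8)), [], 8, 1.0)


class TestSymmetrize:
    def test_idempotent(self, fine_symmetrized, fine_symmetrized_twice):
        inner = slice(40, 120)
        assert (
            correlation(
                fine_symmetrized.grid[inner], fine_symmetrized_twice.grid[inner]
            )
            >= 0.999
        )

    def test_cylinder_invariant_under_any_symmetry(self):
        cyl = cylinder_map()
        out = symmetrize(cyl, HelicalSymmetry(4.4, 61.7))
        inner = slice(10, 38)
        assert correlation(out.grid[inner], cyl.grid[inner]) >= 0.9999
        assert np.allclose(out.grid[inner], cyl.grid[inner], atol=0.02)

    def test_wrong_twist_degrades_correlation(self, tube_volume, sym):
        inner = slice(24, 72)
        right = symmetrize(tube_volume, sym)
        wrong = symmetrize(
            tube_volume, HelicalSymmetry(sym.rise, sym.twist + 3.0)
        )
        c_right = correlation(tube_volume.grid[inner], right.grid[inner])
        c_wrong = correlation(tube_volume.grid[inner], wrong.grid[inner])
        assert c_right - c_wrong >= 0.05

    def test_rise_exceeding_box_rejected(self, tube_volume):
        with pytest.raises(ValueError):
            symmetrize(tube_volume, HelicalSymmetry(500.0, 55.92))


class TestHsearch:
    def test_zero_window_returns_init(self, tube_volume, sym):
        res = hsearch(tube_volume, sym, window=(0.0, 0.0))
        assert res.symmetry == sym

    def test_flat_surface_flagged(self):
        flat = DensityMap(np.ones((48, 48, 48)), 3.0)
        init = HelicalSymmetry(3.81, 55.92)
        res = hsearch(flat, init, window=(0.2, 1.0), coarse_step=(0.1, 0.5),
                      k_steps=(1, 2))
        assert res.flat
        assert res.symmetry == init

    def test_recovers_truth_from_offset_init(self, tube_volume, sym):
        """Ground-truth map, init off by (+0.4 Å, −3°) -> truth recovered."""
        init = HelicalSymmetry(sym.rise + 0.4, sym.twist - 3.0)
        res = hsearch(tube_volume, init, window=(0.5, 4.0),
                      coarse_step=(0.1, 0.5))
        assert res.symmetry.rise == pytest.approx(sym.rise, abs=0.02)
        assert res.symmetry.twist == pytest.approx(sym.twist, abs=0.1)

    def test_truth_is_fixed_point(self, tube_volume, sym):
        res = hsearch(tube_volume, sym, window=(0.1, 0.5),
                      coarse_step=(0.02, 0.1), n_refine=1)
        assert res.symmetry.rise == pytest.approx(sym.rise, abs=0.02)
        assert res.symmetry.twist == pytest.approx(sym.twist, abs=0.1)


class TestFSC:
    def test_self_correlation_is_unity(self, tube_volume):
        curve = fsc(tube_volume, tube_volume)
        assert np.allclose(curve.fsc.to_numpy(), 1.0)

    def test_negated_map_is_minus_one(self, tube_volume):
        neg = DensityMap(-tube_volume.grid, tube_volume.voxel_size)
        curve = fsc(tube_volume, neg)
        assert np.allclose(curve.fsc.to_numpy()[1:], -1.0)

    def test_mismatched_grids_rejected(self, tube_volume):
        with pytest.raises(ValueError):
            fsc(tube_volume, cylinder_map(box=32))

    def test_resolution_interpolates_crossing(self):
        curve = pd.DataFrame(
            {"freq_invA": [0.0, 0.05, 0.10], "fsc": [1.0, 0.8, 0.2]}
        )
        # 0.5 crossing between 0.05 and 0.10: freq = 0.05 + 0.025
        assert resolution_at(curve) == pytest.approx(1.0 / 0.075)

    def test_noisy_half_maps_against_snr_prediction(self, tube_volume):
        """FSC of two noisy copies follows S/(S+N) per shell (20%)."""
        rng = np.random.default_rng(8)
        sigma = float(tube_volume.grid.std()) * 1.0
        a = DensityMap(
            tube_volume.grid + rng.normal(0, sigma, tube_volume.grid.shape),
            tube_volume.voxel_size,
        )
        b = DensityMap(
            tube_volume.grid + rng.normal(0, sigma, tube_volume.grid.shape),
            tube_volume.voxel_size,
        )
        measured = fsc(a, b)
        # expected per-shell FSC from the signal power spectrum
        f = np.fft.fftn(tube_volume.grid.astype(np.float64))
        from barlattice.reconstruct import _shell_indices

        shell, _ = _shell_indices(tube_volume.grid.shape, tube_volume.voxel_size)
        n_shell = tube_volume.box // 2 + 1
        sel = shell < n_shell
        sig = np.bincount(shell[sel], weights=np.abs(f[sel]) ** 2, minlength=n_shell)
        counts = np.bincount(shell[sel], minlength=n_shell)
        # white noise: power sigma^2 * N per Fourier mode, * count per shell
        expected = sig / (sig + sigma**2 * tube_volume.grid.size * counts)
        pred = pd.DataFrame({"freq_invA": measured.freq_invA, "fsc": expected})
        r_meas = resolution_at(measured)
        r_pred = resolution_at(pred)
        assert abs(r_meas - r_pred) / r_pred < 0.2


class TestAmplitudeCorrect:
    def test_identity_when_reference_is_self(self, tube_volume):
        out = amplitude_correct(tube_volume, tube_volume)
        assert np.allclose(out.grid, tube_volume.grid, atol=1e-4)

    def test_profile_matches_reference(self, tube_volume):
        rng = np.random.default_rng(2)
        ref = DensityMap(rng.standard_normal((96, 96, 96)), 3.0)
        out = amplitude_correct(tube_volume, ref)
        from barlattice.reconstruct import _shell_indices

        shell, _ = _shell_indices((96, 96, 96), 3.0)
        fo = np.abs(np.fft.fftn(out.grid.astype(np.float64)))
        fr = np.abs(np.fft.fftn(ref.grid.astype(np.float64)))
        n = shell.max() + 1
        counts = np.bincount(shell.ravel(), minlength=n)
        po = np.bincount(shell.ravel(), weights=fo.ravel(), minlength=n) / counts
        pr = np.bincount(shell.ravel(), weights=fr.ravel(), minlength=n) / counts
        ok = pr > 0
        assert np.allclose(po[ok][1:], pr[ok][1:], rtol=1e-6)

    def test_phases_unchanged(self, tube_volume):
        rng = np.random.default_rng(4)
        ref = DensityMap(rng.standard_normal((96, 96, 96)), 3.0)
        out = amplitude_correct(tube_volume, ref)
        fi = np.fft.fftn(tube_volume.grid.astype(np.float64))
        fo = np.fft.fftn(out.grid.astype(np.float64))
        sel = np.abs(fi) > 1e-3 * np.abs(fi).max()
        ratio = fo[sel] / fi[sel]
        assert np.allclose(ratio.imag / np.abs(ratio), 0.0, atol=1e-5)


class TestIndexing:
    def test_exact_spacings_recover_symmetry(self, sym):
        from barlattice.lattice import layer_lines

        table = {(L.n, L.m): L.axial_spacing for L in layer_lines(sym, 8, 1)}
        cands = index_layer_lines((table[(7, -1)], table[(6, -1)]))
        best = min(
            cands, key=lambda c: abs(c.rise - sym.rise) + abs(abs(c.twist) - sym.twist)
        )
        assert best.rise == pytest.approx(sym.rise, abs=0.01)
        assert abs(best.twist) == pytest.approx(sym.twist, abs=0.05)

    def test_ranking_prefers_generating_symmetry(self, tube_model, sym):
        from barlattice.preprocess import collapsed_power_spectrum
        from barlattice.simulate import lattice_projection_image

        img = lattice_projection_image(tube_model, 2.0, (256, 160))
        spec = collapsed_power_spectrum(img)
        cands = index_layer_lines((43.6, 56.0))
        ranked = rank_candidates(cands, spec, 256 * 2.0)
        top = ranked[0][0]
        assert abs(top.rise - sym.rise) < 0.2
        assert abs(abs(top.twist) - sym.twist) < 1.0


class TestRunIHRSR:
    def test_zero_iterations_returns_symmetrized_cylinder(self, ctf, tube_model):
        from barlattice.simulate import render_segments

        stack = render_segments(tube_model, ctf, 2, snr=1.0, seed=1, box=96)
        sym0 = HelicalSymmetry(3.81, 55.92)
        res = run_ihrsr(stack, sym0, schedule=(), seed=3, reindex_init=False)
        assert res.iterations == 0
        assert res.symmetry == sym0
        assert res.map.box == 96

    def test_empty_stack_rejected(self):
        stack = SegmentStack(np.empty((0, 8, 8)), 3.0)
        with pytest.raises(ValueError):
            run_ihrsr(stack, HelicalSymmetry(3.81, 55.92))
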