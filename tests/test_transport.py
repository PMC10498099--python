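import numpy as np
import pytest

from ordose import transport as tr
from ordose import xsections as xs
from ordose.phantoms import PhantomSpec, make_phantom
from ordose.quadrature import build_energy_grid, build_standard_angular_quadrature


class TestSweepCell:
    def test_vacuum_streaming_is_lossless(self):
        centre, outs = tr.sweep_cell(3.0, 0.0, 0.0, 0.0, 0.0, (5.0, 5.0, 5.0), (0.8, 0.0, 0.0))
        assert centre == pytest.approx(3.0)
        assert outs == (centre, centre, centre)

    def test_no_inflow_no_source_gives_zero(self):
        centre, _ = tr.sweep_cell(0.0, 0.0, 0.0, 0.0, 0.5, (5.0, 5.0, 5.0), (0.5, 0.5, 0.7))
        assert centre == 0.0

    def test_source_only(self):
        mu, eta, xi = 0.6, 0.48, 0.64
        dx = dy = dz = 2.5
        q = 7.0
        centre, _ = tr.sweep_cell(0.0, 0.0, 0.0, q, 0.0, (dx, dy, dz), (mu, eta, xi))
        expect = q / (2 * mu / dx + 2 * eta / dy + 2 * xi / dz)
        assert centre == pytest.approx(expect, rel=1e-12)

    def test_all_zero_cosines_rejected(self):
        with pytest.raises(ValueError):
            tr.sweep_cell(0.0, 0.0, 0.0, 1.0, 0.1, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


class TestSweepGrid:
    def test_vacuum_chain_streaming(self):
        # fluence entering at the boundary propagates unchanged (sigma=0)
        phi = np.zeros((1, 1, 4))
        q = np.zeros((1, 1, 4))
        q[0, 0, 0] = 1.0  # source in first voxel only
        sig = np.zeros((1, 1, 4))
        tr._sweep_grid(phi, q, sig, 0.0, 0.0, 1.0, (5.0, 5.0, 5.0))
        # centre of voxel 0: q / (2 xi/dz); downstream voxels stream it
        expect = 1.0 / (2.0 / 5.0)
        assert np.allclose(phi[0, 0, :], expect)

    def test_sweep_direction_follows_cosine_sign(self):
        q = np.zeros((1, 1, 4))
        q[0, 0, 3] = 1.0
        sig = np.zeros((1, 1, 4))
        phi_down = np.zeros((1, 1, 4))
        tr._sweep_grid(phi_down, q, sig, 0.0, 0.0, -1.0, (5.0, 5.0, 5.0))
        # sweeping towards -z: the source fills voxels 3, 2, 1, 0
        assert np.allclose(phi_down[0, 0, :], 2.5)
        phi_up = np.zeros((1, 1, 4))
        tr._sweep_grid(phi_up, q, sig, 0.0, 0.0, 1.0, (5.0, 5.0, 5.0))
        assert np.allclose(phi_up[0, 0, :3], 0.0)
        assert phi_up[0, 0, 3] == pytest.approx(2.5)

    def test_face_balance_in_vacuum(self):
        # exact streaming conservation: inflow face = outflow face per voxel
        phi = np.zeros((3, 3, 3))
        q = np.zeros((3, 3, 3))
        q[0, 0, 0] = 2.0
        sig = np.zeros((3, 3, 3))
        tr._sweep_grid(phi, q, sig, 0.5, 0.5, 1.0 / np.sqrt(2), (4.0, 4.0, 4.0))
        # step closure: outflow equals centre; downstream voxel inflow
        # equals the same value exactly
        assert phi[0, 0, 0] > 0


def _assemble_system(quad, diff, sigma_t, rho, dims, spacing):
    """Dense matrix of the one-group discretised transport equations.

    Unknowns Phi[n, i, j, k]; streaming part from the centre equation
    with step-closure upwinding, scatter coupling from the tables.
    Independent of the sweep implementation.
    """
    dirs = quad.directions()
    n = len(dirs)
    ni, nj, nk = dims
    size = n * ni * nj * nk

    def idx(o, i, j, k):
        return ((o * ni + i) * nj + j) * nk + k

    a = np.zeros((size, size))
    for o in range(n):
        mu, eta, xi = dirs[o]
        sx, sy, sz = (1 if c >= 0 else -1 for c in (mu, eta, xi))
        cx = 2.0 * abs(mu) / spacing[0]
        cy = 2.0 * abs(eta) / spacing[1]
        cz = 2.0 * abs(xi) / spacing[2]
        for i in range(ni):
            for j in range(nj):
                for k in range(nk):
                    row = idx(o, i, j, k)
                    a[row, row] += cx + cy + cz + rho[i, j, k] * sigma_t
                    if 0 <= i - sx < ni:
                        a[row, idx(o, i - sx, j, k)] -= cx
                    if 0 <= j - sy < nj:
                        a[row, idx(o, i, j - sy, k)] -= cy
                    if 0 <= k - sz < nk:
                        a[row, idx(o, i, j, k - sz)] -= cz
                    for o2 in range(n):
                        a[row, idx(o2, i, j, k)] -= rho[i, j, k] * diff[o2, o]
    return a


class TestLinearSystemOracle:
    def test_iterated_sweep_matches_assembled_solve(self, std_quad):
        # 3x3x3 grid, one group, elastic scatter; 5 sweeps vs dense solve
        dims = (3, 3, 3)
        spacing = (5.0, 5.0, 5.0)
        rho = np.full(dims, 1.0)
        grid1 = build_energy_grid("proton")
        tables = xs.build_proton_tables(grid1, std_quad)
        g = 25  # moderate scattering: source iteration contracts quickly
        diff = tables.mott_diff[:, :, g]
        sigma_t = tables.mott_tot[g]
        n = len(std_quad.active)
        rng = np.random.default_rng(7)
        q0 = rng.random((n, 1) + dims)

        # iterate: phi <- Sweep(q0 + S phi)
        phi = np.zeros_like(q0)
        sig = sigma_t * rho[None]
        for _ in range(5):
            q = q0 + tr._elastic_source(phi, diff[:, :, None], rho)
            phi_new = np.zeros_like(phi)
            tr.transport_sweep(phi_new, q, sig, std_quad, spacing)
            phi = phi_new

        a = _assemble_system(std_quad, diff, sigma_t, rho, dims, spacing)
        exact = np.linalg.solve(a, q0.reshape(-1)).reshape(phi.shape)
        nz = exact > 1e-12 * exact.max()
        rel = np.abs(phi[nz] - exact[nz]) / exact[nz]
        assert rel.max() < 1e-3

    def test_single_sweep_inverts_streaming_operator(self, std_quad):
        # with no scatter the sweep solves the system exactly in one pass
        dims = (3, 3, 3)
        spacing = (4.0, 4.0, 4.0)
        rho = np.full(dims, 0.8)
        sigma_t = 0.05
        n = len(std_quad.active)
        rng = np.random.default_rng(11)
        q0 = rng.random((n, 1) + dims)
        phi = np.zeros_like(q0)
        sig = sigma_t * rho[None]
        tr.transport_sweep(phi, q0, sig, std_quad, spacing)
        a = _assemble_system(
            std_quad, np.zeros((n, n)), sigma_t, rho, dims, spacing
        )
        exact = np.linalg.solve(a, q0.reshape(-1)).reshape(phi.shape)
        np.testing.assert_allclose(phi, exact, rtol=1e-10, atol=1e-12)


class TestScatterSources:
    def test_photon_source_zero_fluence(self, compton_tables):
        f = np.zeros((26, 14, 2, 2, 2))
        q = tr.photon_scatter_source(f, compton_tables, np.ones((2, 2, 2)))
        assert np.all(q == 0.0)

    def test_photon_source_matches_brute_force(self, compton_tables, rng):
        f = rng.random((26, 14, 2, 2, 2))
        rho = rng.random((2, 2, 2)) + 0.5
        q = tr.photon_scatter_source(f, compton_tables, rho)
        rho_abs = rho * tr.WATER_ELECTRONS_PER_MM3
        brute = np.zeros_like(q)
        for gf in range(14):
            for n_in in range(26):
                for n_out in range(26):
                    gs = compton_tables.init_group[n_in, n_out, gf]
                    if gs < 0:
                        continue
                    brute[n_out, gf] += (
                        compton_tables.diff_gamma[n_in, n_out, gf] * f[n_in, gs]
                    )
        brute *= rho_abs[None, None]
        np.testing.assert_allclose(q, brute, rtol=1e-12, atol=1e-300)

    def test_single_ordinate_single_group(self, compton_tables, rng):
        f = np.zeros((26, 14, 1, 1, 1))
        f[4, 9, 0, 0, 0] = 2.0
        rho = np.ones((1, 1, 1))
        q = tr.photon_scatter_source(f, compton_tables, rho)
        # contributions only where the kinematic map points at (4, 9)
        for gf in range(14):
            for n_out in range(26):
                expect = 0.0
                if compton_tables.init_group[4, n_out, gf] == 9:
                    expect = (
                        compton_tables.diff_gamma[4, n_out, gf] * 2.0
                        * tr.WATER_ELECTRONS_PER_MM3
                    )
                assert q[n_out, gf, 0, 0, 0] == pytest.approx(expect, rel=1e-12)

    def test_electron_fixed_source_brute_force(self, compton_tables, rng):
        f = rng.random((26, 14, 2, 2, 2))
        rho = rng.random((2, 2, 2)) + 0.5
        q = tr.electron_fixed_source(f, compton_tables, rho)
        brute = np.zeros_like(q)
        for gs in range(14):
            for n_in in range(26):
                for n_out in range(26):
                    ge = compton_tables.e_group[n_in, n_out, gs]
                    if ge < 0:
                        continue
                    brute[n_out, ge] += (
                        compton_tables.diff_e[n_in, n_out, gs] * f[n_in, gs]
                    )
        brute *= (rho * tr.WATER_ELECTRONS_PER_MM3)[None, None]
        np.testing.assert_allclose(q, brute, rtol=1e-12, atol=1e-300)

    def test_vacuum_gives_zero_fixed_source(self, compton_tables, rng):
        f = rng.random((26, 14, 2, 2, 2))
        q = tr.electron_fixed_source(f, compton_tables, np.zeros((2, 2, 2)))
        assert np.all(q == 0.0)


class TestSolvers:
    @pytest.fixture
    def tiny_phantom(self):
        return make_phantom(PhantomSpec("water", size_mm=(40.0, 40.0, 40.0), voxel_mm=10.0))

    def test_photon_zero_input(self, compton_tables, tiny_phantom):
        unscat = np.zeros((26, 14, 4, 4, 4))
        total, scat, _ = tr.solve_photon_transport(unscat, compton_tables, tiny_phantom, 3)
        assert np.all(total == 0.0) and np.all(scat == 0.0)

    def test_photon_vacuum_total_equals_unscattered(self, compton_tables, rng):
        ph = make_phantom(PhantomSpec("water", size_mm=(40.0, 40.0, 40.0), voxel_mm=10.0))
        ph.rho_e[:] = 0.0
        unscat = rng.random((26, 14, 4, 4, 4))
        total, scat, _ = tr.solve_photon_transport(unscat, compton_tables, ph, 3)
        np.testing.assert_allclose(total, unscat, rtol=1e-12)
        assert np.all(scat == 0.0)

    def test_photon_monotone_iteration(self, compton_tables, tiny_phantom, rng):
        unscat = rng.random((26, 14, 4, 4, 4)) * 1e-3
        prev = None
        for it in (1, 2, 3, 4):
            total, _, _ = tr.solve_photon_transport(
                unscat, compton_tables, tiny_phantom, it
            )
            if prev is not None:
                assert np.all(total >= prev - 1e-15)
            prev = total

    def test_electron_zero_fixed_source(self, electron_tables, tiny_phantom):
        q = np.zeros((26, 14, 4, 4, 4))
        phi, _ = tr.solve_electron_transport(q, electron_tables, tiny_phantom, 3)
        assert np.all(phi == 0.0)

    def test_electron_point_source_decays_with_distance(self, electron_tables):
        ph = make_phantom(PhantomSpec("water", size_mm=(70.0, 70.0, 70.0), voxel_mm=10.0))
        q = np.zeros((26, 14, 7, 7, 7))
        # isotropic fixed source at the centre, top group
        q[:, 13, 3, 3, 3] = 1.0
        phi, _ = tr.solve_electron_transport(q, electron_tables, ph, 5)
        # along the +z ordinate the fluence decays monotonically downstream
        active = list(electron_tables.quadrature.active)
        n_fwd = next(
            i for i, o in enumerate(active)
            if (o.couch_deg, o.gantry_deg) == (0.0, 0.0)
        )
        line = phi[n_fwd, 13, 3, 3, 3:]
        assert np.all(np.diff(line) <= 1e-12)
        assert line[0] > 0

    def test_proton_no_scatter_terms(self, proton_tables, tiny_phantom, rng):
        unscat = rng.random((26, 50, 4, 4, 4))
        total, scat, _ = tr.solve_proton_transport(
            unscat, proton_tables, tiny_phantom, 3, tau=0.0
        )
        np.testing.assert_allclose(total, unscat, rtol=1e-12)
        assert np.all(scat == 0.0)

    def test_proton_scattered_non_negative(self, proton_tables, tiny_phantom, rng):
        unscat = rng.random((26, 50, 4, 4, 4)).astype(np.float32)
        total, scat, _ = tr.solve_proton_transport(
            unscat, proton_tables, tiny_phantom, 3
        )
        assert scat.min() >= 0.0
        assert np.all(total >= unscat)

    def test_warm_start_equals_long_run(self, proton_tables, tiny_phantom, rng):
        unscat = rng.random((26, 50, 4, 4, 4))
        t10, s10, _ = tr.solve_proton_transport(
            unscat, proton_tables, tiny_phantom, 6
        )
        _, s3, _ = tr.solve_proton_transport(unscat, proton_tables, tiny_phantom, 3)
        t_rest, s_rest, _ = tr.solve_proton_transport(
            unscat, proton_tables, tiny_phantom, 3, initial_scattered=s3
        )
        np.testing.assert_allclose(t_rest, t10, rtol=1e-12)


class TestAdaptiveMask:
    def test_uniform_fluence_merges_nothing(self):
        f = np.ones((2, 3, 8, 8, 8))
        mask = tr.build_adaptive_mask(f, "photon")
        assert mask.n_clusters_merged == 0
        assert not mask.merged.any()

    def test_zero_outside_column_merges_outside(self):
        f = np.zeros((1, 1, 8, 8, 8))
        f[..., 4, 4, :] = 1.0
        mask = tr.build_adaptive_mask(f, "proton")
        # clusters not containing the column merge entirely
        assert mask.merged[0, 0, 0]
        assert not mask.merged[4, 4, 4]

    def test_partial_clusters_never_merge(self):
        f = np.zeros((1, 1, 6, 6, 6))
        f[..., 5, 5, 5] = 1.0
        mask = tr.build_adaptive_mask(f, "photon")
        # only the aligned 4x4x4 block can merge; the ragged remainder not
        assert not mask.merged[4:, :, :].any()
        assert not mask.merged[:, 4:, :].any()

    def test_thresholds(self):
        assert tr.ADAPTIVE_THRESHOLDS["photon"] == 0.20
        assert tr.ADAPTIVE_THRESHOLDS["proton"] == 0.05

    def test_masked_dose_close_in_high_region(self, proton_tables):
        from ordose import pipeline, sources

        ph = make_phantom(PhantomSpec("water", size_mm=(80.0, 80.0, 200.0), voxel_mm=5.0))
        beam = sources.ProtonBeamModel(
            field_mm=(40.0, 40.0), sobp_span_mm=(60.0, 120.0), n_layers=10
        )
        off = pipeline.run_proton(ph, beam, n_iterations=3)
        on = pipeline.run_proton(ph, beam, n_iterations=3, adaptive=True)
        hi = off.dose.values >= 0.5 * off.dose.values.max()
        rel = np.abs(on.dose.values[hi] - off.dose.values[hi]) / off.dose.values[hi]
        assert rel.max() < 0.01
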