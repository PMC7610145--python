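"""Anisotropic network construction, normal modes, RMSF and trajectories."""

import numpy as np
import pytest

import beadmodes as bm
from beadmodes.bead_models import LatticeModel
from beadmodes.elastic_network import (DisconnectedNetworkError, LatticeNetwork,
                                       build_hessian, build_network,
                                       compute_modes, rmsf)


def _grid_block(n, spacing=1.0, offset=(0.0, 0.0, 0.0)):
    axes = np.arange(n) * spacing
    pts = np.array(np.meshgrid(axes, axes, axes, indexing="ij")).reshape(3, -1).T
    return pts + np.asarray(offset)


def _lattice(centres, spacing):
    return LatticeModel(centres=np.asarray(centres, dtype=float),
                        bead_radius=spacing / 2.0, spacing=spacing,
                        origin=np.asarray(centres, dtype=float)[0])


def _dimer(gamma=1.0, d=2.0):
    net = build_network(_lattice([[0, 0, 0], [d, 0, 0]], spacing=d),
                        cutoff_factor=1.5, gamma=gamma)
    return compute_modes(build_hessian(net))


class TestNetwork:
    def test_cubic_block_interior_degrees(self):
        model = _lattice(_grid_block(3), spacing=1.0)
        deg_16 = build_network(model, cutoff_factor=1.6).degrees()
        interior = np.flatnonzero(np.all(np.abs(model.centres - 1.0) < 0.1, axis=1))
        assert deg_16[interior] == 18        # 6 nearest + 12 second-nearest
        deg_12 = build_network(model, cutoff_factor=1.2).degrees()
        assert deg_12[interior] == 6

    def test_disconnected_reports_component_sizes(self):
        pts = np.vstack([_grid_block(3), _grid_block(3, offset=(5.0, 0, 0))])
        with pytest.raises(DisconnectedNetworkError) as err:
            build_network(_lattice(pts, spacing=1.0), cutoff_factor=1.6)
        assert err.value.component_sizes == [27, 27]

    @pytest.mark.parametrize("factor", [0.9, 1.0, 2.0, 2.5])
    def test_cutoff_factor_bounds(self, factor, sphere30):
        with pytest.raises(ValueError):
            build_network(sphere30, cutoff_factor=factor)


class TestHessian:
    def test_dimer_spectrum(self):
        modes = _dimer(gamma=1.0)
        assert modes.n_zero == 5
        assert modes.eigenvalues[-1] == pytest.approx(2.0)
        # stretching mode lies along the bond (x) axis
        u = modes.eigenvectors[:, -1].reshape(2, 3)
        assert np.abs(u[:, 1:]).max() < 1e-10

    def test_dimer_eigenvalue_scales_with_gamma(self):
        assert _dimer(gamma=3.5).eigenvalues[-1] == pytest.approx(7.0)

    def test_collinear_chain_axial_spectrum(self):
        """Nearest-neighbour chain: axial eigenvalues {0, 1, 3}·gamma.

        A distance-only network on collinear beads has no transverse
        stiffness, so the remaining 7 modes are all zero.
        """
        net = build_network(_lattice([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]],
                                     spacing=1.0), cutoff_factor=1.2)
        modes = compute_modes(build_hessian(net))
        assert modes.n_zero == 7
        np.testing.assert_allclose(modes.eigenvalues[-2:], [1.0, 3.0], atol=1e-12)

    def test_translation_invariance_symmetry_and_psd(self, curved_results):
        h = build_hessian(bm.build_network(curved_results.model.model))
        n = h.shape[0] // 3
        np.testing.assert_allclose(h, h.T, atol=1e-12)
        # each coordinate slice of every row sums to zero (uniform translation)
        row_sums = h.reshape(3 * n, n, 3).sum(axis=1)
        np.testing.assert_allclose(row_sums, 0.0, atol=1e-9)
        evals = curved_results.modes.eigenvalues
        assert evals.min() >= -1e-8 * evals.max()

    def test_hessian_matches_complex_step_energy_derivative(self):
        """Independent oracle: H as the second derivative of the explicit
        harmonic spring energy, via complex-step differentiation of the
        analytic gradient."""
        model = bm.make_shape(bm.ShapeSpec("sphere", {"radius": 12.0}, spacing=6.0))
        net = build_network(model, gamma=1.7)
        h = build_hessian(net)
        n = model.n_beads
        x0 = model.centres.ravel().astype(complex)
        rest = {(i, j): np.linalg.norm(model.centres[i] - model.centres[j])
                for i, j in net.edges}

        def grad(x):
            pos = x.reshape(n, 3)
            g = np.zeros_like(pos)
            for (i, j), l0 in rest.items():
                d = pos[i] - pos[j]
                r = np.sqrt(np.sum(d * d))
                f = net.gamma * (1.0 - l0 / r) * d
                g[i] += f
                g[j] -= f
            return g.ravel()

        step = 1e-30
        numeric = np.empty_like(h)
        for k in range(3 * n):
            xp = x0.copy()
            xp[k] += 1j * step
            numeric[:, k] = np.imag(grad(xp)) / step
        np.testing.assert_allclose(h, numeric, atol=1e-10 * np.abs(h).max())


class TestModes:
    @pytest.mark.parametrize("fixture", ["sphere30", "rod", "curved", "composite"])
    def test_six_zero_modes_on_connected_fixtures(self, fixture, request):
        results = (request.getfixturevalue(fixture + "_results")
                   if fixture != "sphere30"
                   else bm.ElasticNetworkModel(request.getfixturevalue(fixture)).fit())
        assert results.modes.n_zero == 6

    def test_eigenvectors_orthonormal(self, curved_results):
        v = curved_results.modes.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-6)

    def test_expected_zero_count_enforced(self):
        net = build_network(_lattice([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]],
                                     spacing=1.0), cutoff_factor=1.2)
        with pytest.raises(ValueError, match="zero modes"):
            compute_modes(build_hessian(net), expected_n_zero=6)


class TestRMSF:
    def test_all_mode_rmsf_equals_pseudoinverse_blocks(self, sphere30):
        results = bm.ElasticNetworkModel(sphere30).fit()
        modes = results.modes
        prof = results.rmsf(mode_subset=range(1, modes.n_nonzero + 1))
        h = build_hessian(bm.build_network(sphere30))
        pinv = np.linalg.pinv(h, rcond=1e-10, hermitian=True)
        n = sphere30.n_beads
        oracle = np.sqrt(np.einsum("ii->i", pinv).reshape(n, 3).sum(axis=1))
        np.testing.assert_allclose(prof.rmsf, oracle, rtol=1e-8)

    def test_mirror_symmetric_rod_has_symmetric_profile(self, rod, rod_results):
        prof = rod_results.rmsf().rmsf
        # pair each bead with its z -> -z mirror image
        key = {tuple(np.round(c, 6)): i for i, c in enumerate(rod.centres)}
        mirror = np.array([key[tuple(np.round(c * [1, 1, -1], 6))]
                           for c in rod.centres])
        np.testing.assert_allclose(prof, prof[mirror], rtol=1e-6)

    def test_rod_ends_most_mobile_nodes_stiffest(self, rod, rod_results):
        """Free rod: maxima at the two ends, minima on the axis at the
        free-free bending nodes (~22% in from each end)."""
        prof = rod_results.rmsf().rmsf
        z = rod.centres[:, 2]
        ends = (z <= z.min() + 9.0) | (z >= z.max() - 9.0)
        assert prof[ends].max() == prof.max()
        argmin = int(np.argmin(prof))
        x, y, zmin = rod.centres[argmin]
        assert x == 0.0 and y == 0.0          # on the rod axis
        assert 36.0 <= abs(zmin) <= 72.0      # near the 0.224·L node

    def test_gamma_scaling(self, sphere30):
        base = bm.ElasticNetworkModel(sphere30, gamma=1.0).fit().rmsf().rmsf
        stiff = bm.ElasticNetworkModel(sphere30, gamma=4.0).fit().rmsf().rmsf
        np.testing.assert_allclose(stiff, base / 2.0, rtol=1e-9)

    def test_rotation_invariance(self, sphere30):
        net = bm.build_network(sphere30)
        modes = compute_modes(build_hessian(net))
        base = rmsf(modes, mode_subset=range(1, 7)).rmsf
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = bm.BeadModel(sphere30.centres @ q.T, sphere30.bead_radius)
        rot_net = LatticeNetwork(model=rotated, cutoff=net.cutoff,
                                 gamma=net.gamma, edges=net.edges)
        rot_modes = compute_modes(build_hessian(rot_net))
        np.testing.assert_allclose(rmsf(rot_modes, mode_subset=range(1, 7)).rmsf,
                                   base, rtol=1e-6, atol=1e-9)

    def test_zero_mode_request_rejected(self, curved_results):
        with pytest.raises(ValueError):
            curved_results.rmsf(mode_subset=[0, 1])

    def test_temperature_scale_multiplies_profile(self, sphere30):
        enm = bm.ElasticNetworkModel(sphere30)
        base = enm.fit(temperature_scale=1.0).rmsf().rmsf
        hot = enm.fit(temperature_scale=2.5).rmsf().rmsf
        np.testing.assert_allclose(hot, 2.5 * base, rtol=1e-12)


class TestTrajectory:
    def test_single_mode_displacements_collinear_with_eigenvector(self, curved,
                                                                  curved_results):
        traj = curved_results.trajectory(k=1, n_frames=16)
        u = curved_results.modes.mode_vector(1)
        for t in range(1, 16):
            d = (traj.frames[t] - curved.centres).ravel()
            if np.linalg.norm(d) < 1e-12:
                continue
            cosine = abs(d @ u) / np.linalg.norm(d)
            assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_frame0_is_equilibrium_and_scale_linear(self, curved, curved_results):
        t1 = curved_results.trajectory(k=4, scale=1.0)
        t2 = curved_results.trajectory(k=4, scale=2.0)
        np.testing.assert_allclose(t1.frames[0], curved.centres)
        np.testing.assert_allclose(t2.frames - curved.centres,
                                   2.0 * (t1.frames - curved.centres), atol=1e-12)

    def test_time_average_reproduces_rmsf_profile(self, curved, curved_results):
        traj = curved_results.trajectory(k=6, n_frames=40)
        disp2 = np.sum((traj.frames - curved.centres) ** 2, axis=2).mean(axis=0)
        rmsf2 = curved_results.rmsf(mode_subset=range(1, 7)).rmsf ** 2
        corr = np.corrcoef(disp2, rmsf2)[0, 1]
        assert corr >= 0.999

    def test_default_scale_peaks_at_5pct_dmax(self, curved, curved_results):
        traj = curved_results.trajectory(k=6)
        peak = np.max(np.linalg.norm(traj.frames - curved.centres, axis=2))
        assert peak == pytest.approx(0.05 * bm.model_geometry(curved).dmax,
                                     rel=1e-6)

    def test_trajectory_pdb_has_model_records(self, tmp_path, curved,
                                              curved_results):
        path = tmp_path / "traj.pdb"
        curved_results.trajectory(k=2, n_frames=8).write_pdb(curved, path)
        text = path.read_text()
        assert text.count("MODEL") == 8 and text.count("ENDMDL") == 8


def test_summary_reports_key_quantities(curved_results):
    text = curved_results.summary()
    assert "zero modes           6" in text
    assert "RMSF" in text
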