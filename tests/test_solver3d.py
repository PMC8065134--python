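"""3D solver: stencil, boundaries, conservation, stepping and projections."""

import numpy as np
import pytest

from scalerd.geometry import HeightField, VoxelDomain, voxelize
from scalerd.models import FieldState, KineticsSpec, init_uniform
from scalerd.solver3d import SolverConfig, laplacian7, project_plan_view, run_to_steady, step


def _slab(nz=4, ny=8, nx=8, eps=1.0, periodic=(True, True)):
    return VoxelDomain(mask=np.ones((nz, ny, nx), bool), spacing=eps, periodic_xy=periodic)


def _zero_reaction(D=(1.0, 1.0, 1.0), dt=0.01):
    # three-component kinetics with all production and decay terms zero
    return KineticsSpec(
        "nakamasu",
        params={
            "c1": 0, "c2": 0, "c3": 0, "c4": 0, "c5": 0, "c6": 0,
            "c7": 0, "c8": 0, "c9": 0, "c_u": 0, "c_v": 0, "c_w": 0,
            "D_u": D[0], "D_v": D[1], "D_w": D[2],
        },
        dt=dt,
    )


class TestLaplacian7:
    def test_annihilates_constants(self):
        dom = _slab()
        assert np.allclose(laplacian7(np.full(dom.shape, 3.7), dom), 0.0)

    def test_unit_impulse(self):
        dom = _slab(nz=5, ny=5, nx=5, periodic=(False, False))
        f = np.zeros(dom.shape)
        f[2, 2, 2] = 1.0
        lap = laplacian7(f, dom)
        assert lap[2, 2, 2] == -6.0
        for nb in ((1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)):
            assert lap[nb] == 1.0

    def test_periodic_sine_mode_eigenvalue(self):
        n = 64
        dom = _slab(nz=2, ny=4, nx=n)
        k = 2 * np.pi / n
        x = np.arange(n)
        f = np.broadcast_to(np.sin(k * x), dom.shape).copy()
        lap = laplacian7(f, dom)
        # discrete eigenvalue -(2 - 2 cos k) approaches -k^2 to O(eps^2)
        np.testing.assert_allclose(lap, -(k**2) * f, atol=k**2 * 5e-3)

    def test_mirror_equals_neumann_cosine_decay(self):
        # cosine mode on a non-periodic slab is an exact eigenvector of the
        # mirrored stencil; its decay must match the analytic Neumann solution
        n = 32
        dom = _slab(nz=1, ny=1, nx=n, periodic=(False, False))
        kin = _zero_reaction(D=(1.0, 1.0, 1.0), dt=0.01)
        k = np.pi / n
        f = np.cos(k * (np.arange(n) + 0.5)).reshape(1, 1, n)
        state = FieldState({"u": f.copy(), "v": f.copy(), "w": f.copy()}, dom)
        nsteps = 400
        for _ in range(nsteps):
            state = step(state, kin)
        analytic = f * np.exp(-k**2 * nsteps * 0.01)
        err = np.abs(state.components["u"] - analytic).max() / np.abs(analytic).max()
        assert err < 1e-2


class TestStep:
    def test_identity_with_zero_rates_and_diffusion(self, rng):
        dom = _slab()
        kin = _zero_reaction(D=(0, 0, 0))
        f = rng.random(dom.shape)
        st = FieldState({"u": f.copy(), "v": f.copy(), "w": f.copy()}, dom)
        out = step(st, kin)
        np.testing.assert_array_equal(out.components["u"], f)

    def test_diffusive_decay_of_sine_mode(self):
        n, D, dt = 64, 1.0, 0.01
        dom = _slab(nz=2, ny=4, nx=n)
        kin = _zero_reaction(D=(D, D, D), dt=dt)
        k = 2 * np.pi / n
        f = np.broadcast_to(np.sin(k * np.arange(n)), dom.shape).copy() + 2.0
        st = FieldState({"u": f.copy(), "v": f.copy(), "w": f.copy()}, dom)
        nsteps = 200
        for _ in range(nsteps):
            st = step(st, kin)
        expected = (f - 2.0) * np.exp(-D * k**2 * nsteps * dt) + 2.0
        np.testing.assert_allclose(st.components["u"], expected, atol=5e-3)

    def test_schnakenberg_fixed_point_is_stationary(self, schnakenberg):
        dom = _slab(eps=1.0)
        st = init_uniform(dom, schnakenberg, base_state=(1.0, 0.9), noise=0.0)
        out = step(st, schnakenberg, SolverConfig(dt=1e-3))
        np.testing.assert_array_equal(out.components["u"], st.components["u"])
        np.testing.assert_array_equal(out.components["v"], st.components["v"])

    def test_instability_raises(self):
        dom = _slab(eps=1.0)
        kin = KineticsSpec("nakamasu")  # D_w = 13.5 needs dt < eps^2/81
        st = init_uniform(dom, kin, base_state=(1.0, 1.0, 1.0), noise=0.01)
        with pytest.raises(ValueError, match="stability"):
            step(st, kin, SolverConfig(dt=0.1))


class TestRunToSteady:
    def test_uniform_zero_reaction_converges_immediately(self):
        dom = _slab()
        kin = _zero_reaction()
        st = init_uniform(dom, kin, base_state=(1.0, 1.0, 1.0), noise=0.0)
        out, steps, converged = run_to_steady(st, kin, SolverConfig(check_every=10, max_steps=100))
        assert converged and steps == 10

    def test_max_steps_cap_reports_nonconvergence(self, schnakenberg):
        dom = _slab(eps=1.0)
        st = init_uniform(dom, schnakenberg, base_state=(0.5, 0.5), noise=0.01, seed=2)
        out, steps, converged = run_to_steady(
            st, schnakenberg, SolverConfig(dt=1e-3, tol=0.0, check_every=5, max_steps=10)
        )
        assert not converged and steps == 10

    def test_mass_conservation_no_flux(self, rng):
        # no reaction, no-flux on every boundary: total mass is conserved
        hf = HeightField(
            z_top=rng.uniform(4.0, 8.0, (10, 12)).round(),
            z_bottom=np.zeros((10, 12)),
            spacing=1.0,
            periodic_xy=(False, False),
        )
        dom = voxelize(hf)
        kin = _zero_reaction(D=(1.0, 1.0, 1.0), dt=0.05)
        comps = {n: np.where(dom.mask, rng.random(dom.shape), 0.0) for n in ("u", "v", "w")}
        st = FieldState(comps, dom)
        total0 = comps["u"][dom.mask].sum()
        out, steps, _ = run_to_steady(st, kin, SolverConfig(dt=0.05, tol=0.0, check_every=10_000, max_steps=10_000))
        total = out.components["u"][dom.mask].sum()
        assert abs(total - total0) / total0 < 1e-10

    def test_kernel_matches_vectorised_reference(self, rng, nakamasu):
        # the compiled chunk update must agree with the numpy reference step
        hf = HeightField(
            z_top=rng.uniform(3.0, 6.0, (6, 7)).round(),
            z_bottom=np.zeros((6, 7)),
            spacing=1.0,
            periodic_xy=(True, False),
        )
        dom = voxelize(hf)
        st = init_uniform(dom, nakamasu, base_state=(1.2, 6.6, 2.3), noise=0.01, seed=9)
        for n, c in st.components.items():
            c[~dom.mask] = 0.0
        ref = st
        for _ in range(7):
            ref = step(ref, nakamasu, SolverConfig(dt=0.01))
        out, steps, _ = run_to_steady(st, nakamasu, SolverConfig(dt=0.01, tol=0.0, check_every=7, max_steps=7))
        for name in ("u", "v", "w"):
            np.testing.assert_allclose(
                out.components[name][dom.mask], ref.components[name][dom.mask], rtol=1e-12, atol=1e-13
            )


class TestProjection:
    def test_z_invariant_state_modes_agree(self, rng):
        dom = _slab(nz=5, ny=6, nx=6)
        plan_u = rng.random((6, 6))
        plan_v = rng.random((6, 6))
        st = FieldState(
            {"u": np.broadcast_to(plan_u, dom.shape).copy(),
             "v": np.broadcast_to(plan_v, dom.shape).copy()},
            dom,
        )
        imgs = [project_plan_view(st, dom, m) for m in ("mean", "top", "bottom")]
        np.testing.assert_allclose(imgs[0], imgs[1])
        np.testing.assert_allclose(imgs[0], imgs[2])

    def test_mean_mode_equals_column_average(self, rng):
        hf = HeightField(rng.integers(2, 6, (5, 5)).astype(float), np.zeros((5, 5)), 1.0)
        dom = voxelize(hf)
        u = np.where(dom.mask, rng.random(dom.shape), 0.0)
        v = np.where(dom.mask, rng.random(dom.shape), 0.0)
        st = FieldState({"u": u, "v": v}, dom)
        g = project_plan_view(st, dom, "mean")
        from scalerd.models import green_intensity

        for j in range(5):
            for i in range(5):
                col = dom.mask[:, j, i]
                expect = green_intensity(u[col, j, i].mean(), v[col, j, i].mean())
                assert g[j, i] == pytest.approx(expect)
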