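import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation
from scipy.special import spherical_jn

from lodekit.basis import BasisSpec, radial_projection
from lodekit.fields import InteractionSpec, evaluate_field_periodic
from lodekit.lode import compute_lode, compute_lode_gradients, compute_lode_multi
from lodekit.spherical import ball_grid, lm_index, real_sph_harm
from lodekit.structures import Structure


class TestRadialProjection:
    def test_monomial_l0_small_k(self):
        basis = BasisSpec("monomial", 1, 2, 3.0)
        # ∫ R_00 j0(kr) r² dr -> ∫ R_00 r² dr = 1 for the normalized
        # monomial ((2l+3)/r_c^{2l+3} · r^l at l = 0)
        assert np.isclose(radial_projection(basis, 0, 1e-8)[0], 1.0)

    @pytest.mark.parametrize("l", [0, 1, 2])
    def test_monomial_matches_quadrature(self, l):
        rc, k = 3.0, 1.0
        basis = BasisSpec("monomial", 1, 2, rc)
        norm = (2 * l + 3) / rc ** (2 * l + 3)
        ref = quad(lambda r: norm * r**l * spherical_jn(l, k * r) * r**2, 0, rc)[0]
        assert np.isclose(radial_projection(basis, l, k)[0], ref, rtol=1e-10)

    def test_gto_orthonormal(self):
        basis = BasisSpec("gto", 4, 2, 4.0)
        r, w = basis.quad_nodes()
        for l in range(3):
            vals = basis.evaluate(l, r)
            gram = (vals * w) @ vals.T
            np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)

    def test_gto_projection_matches_quadrature(self, rng):
        basis = BasisSpec("gto", 3, 2, 4.0)
        k = 1.7
        proj = radial_projection(basis, 2, k)
        for n in range(3):
            ref = quad(
                lambda r: basis.evaluate(2, np.array([r]))[n, 0]
                * spherical_jn(2, k * r) * r**2,
                0.0, 4.0, limit=200,
            )[0]
            assert np.isclose(proj[n], ref, rtol=1e-8)

    def test_l_beyond_lmax_rejected(self):
        with pytest.raises(ValueError):
            radial_projection(BasisSpec("monomial", 1, 1, 2.0), 2, 1.0)

    def test_monomial_forces_nmax_one(self):
        assert BasisSpec("monomial", 8, 2, 2.0).n_max == 1


class TestComputeLode:
    def test_zero_weights_give_zero(self, small_periodic):
        st = small_periodic.copy()
        st.weights[:] = 0.0
        blk = compute_lode(st, InteractionSpec(1.0, 0.6), BasisSpec("monomial", 1, 2, 1.2), 10.0)
        assert np.max(np.abs(blk.values)) < 1e-14

    def test_translation_invariance(self, small_periodic):
        spec = InteractionSpec(1.0, 0.6)
        basis = BasisSpec("gto", 2, 1, 1.2)
        b1 = compute_lode(small_periodic, spec, basis, 10.0)
        st = small_periodic.copy()
        st.positions += np.array([0.7, -1.1, 2.3])
        b2 = compute_lode(st, spec, basis, 10.0)
        np.testing.assert_allclose(b1.values, b2.values, atol=1e-9)

    @pytest.mark.parametrize("p", [1.0, 6.0])
    def test_matches_3d_quadrature(self, p):
        # reciprocal-space coefficients vs direct numerical quadrature of
        # the projection integral over the cutoff ball (both bases)
        st = Structure(
            np.array([[0.5, 0.6, 0.7], [2.8, 2.1, 3.2]]),
            ["A", "B"], np.eye(3) * 5.0, np.array([1.0, -0.7]),
        )
        kcut = 10.0
        spec = InteractionSpec(p, 0.5)
        basis = BasisSpec("gto", 2, 2, 1.5)
        blk = compute_lode(st, spec, basis, kcut)
        pts, wq = ball_grid(1.5, 32, 24)
        ylm = real_sph_harm(2, pts)
        rad = {
            l: basis.evaluate(l, np.linalg.norm(pts, axis=1)) for l in range(3)
        }
        scale = np.max(np.abs(blk.values))
        for a, sp_a in enumerate(blk.species_channels):
            wmask = st.weights * np.array([s == sp_a for s in st.species])
            fld = evaluate_field_periodic(st, spec, kcut, weights=wmask)
            for i in range(2):
                v = fld.evaluate(pts + st.positions[i])
                for l in range(3):
                    for m in range(-l, l + 1):
                        ref = np.sum(wq * v * rad[l][0] * ylm[:, lm_index(l, m)])
                        # n=0 only (rad[l][0]); compare against block
                        assert abs(ref - blk.values[i, a, 0, lm_index(l, m)]) < 1e-4 * scale

    def test_monomial_l0_is_ball_average(self, small_periodic, rng):
        # V_000/√(4π) equals the Monte-Carlo average of the potential
        # over the cutoff sphere (normalized monomial basis)
        spec = InteractionSpec(1.0, 0.6)
        rc = 1.0
        blk = compute_lode(small_periodic, spec, BasisSpec("monomial", 1, 0, rc), 9.0)
        fld = evaluate_field_periodic(small_periodic, spec, 9.0)
        n_mc = 100_000
        pts = rng.normal(size=(n_mc, 3))
        pts *= (rng.uniform(0, 1, n_mc) ** (1 / 3) * rc / np.linalg.norm(pts, axis=1))[:, None]
        avg = fld.evaluate(pts + small_periodic.positions[0]).mean()
        total = blk.values[0, :, 0, 0].sum() / np.sqrt(4 * np.pi)
        assert np.isclose(total, avg, atol=2e-3 * max(1.0, abs(avg)))

    def test_aperiodic_matches_3d_quadrature(self, random_cluster):
        spec = InteractionSpec(1.0, 0.5)
        basis = BasisSpec("gto", 2, 2, 1.5)
        blk = compute_lode(random_cluster, spec, basis, include_center=True)
        pts, wq = ball_grid(1.5, 50, 36)
        ylm = real_sph_harm(2, pts)
        from lodekit.fields import evaluate_field_direct

        scale = np.max(np.abs(blk.values))
        i = 0
        for a, sp_a in enumerate(blk.species_channels):
            wmask = random_cluster.weights * np.array(
                [s == sp_a for s in random_cluster.species]
            )
            fld = evaluate_field_direct(random_cluster, spec, 100.0, weights=wmask)
            v = fld.evaluate(pts + random_cluster.positions[i])
            for l in range(3):
                rad = basis.evaluate(l, np.linalg.norm(pts, axis=1))
                for n in range(2):
                    for m in range(-l, l + 1):
                        ref = np.sum(wq * v * rad[n] * ylm[:, lm_index(l, m)])
                        assert abs(ref - blk.values[i, a, n, lm_index(l, m)]) < 2e-6 * scale

    def test_rotation_equivariance_invariant_norm(self, random_cluster):
        # Σ_m V²_nlm is rotation invariant per (n, l) block
        spec = InteractionSpec(1.0, 0.5)
        basis = BasisSpec("gto", 2, 3, 1.5)
        b1 = compute_lode(random_cluster, spec, basis)
        rot = Rotation.random(random_state=4).as_matrix()
        st = Structure(
            random_cluster.positions @ rot.T,
            list(random_cluster.species), None, random_cluster.weights,
        )
        b2 = compute_lode(st, spec, basis)
        for l in range(4):
            sl = slice(lm_index(l, -l), lm_index(l, l) + 1)
            n1 = np.sum(b1.values[..., sl] ** 2, axis=-1)
            n2 = np.sum(b2.values[..., sl] ** 2, axis=-1)
            np.testing.assert_allclose(n1, n2, rtol=1e-8, atol=1e-12)

    @pytest.mark.parametrize("p", [1.0, 6.0])
    def test_far_charge_decay_exponent(self, p):
        # l-channel coefficients from one far unit weight fall as 1/d^{p+l}
        spec = InteractionSpec(p, 0.2)
        basis = BasisSpec("monomial", 1, 3, 0.5)
        ds = np.array([10.0, 14.0, 20.0, 28.0])
        u = np.array([0.26726, 0.53452, 0.80178])
        norms = []
        for d in ds:
            st = Structure(
                np.vstack([[0, 0, 0], d * u]), ["C", "C"], None, np.array([0.0, 1.0])
            )
            blk = compute_lode(st, spec, basis, include_center=False)
            norms.append(
                [
                    np.linalg.norm(
                        blk.values[0, 0, 0, lm_index(l, -l) : lm_index(l, l) + 1]
                    )
                    for l in range(4)
                ]
            )
        norms = np.array(norms)
        for l in range(4):
            slope = np.polyfit(np.log(ds), np.log(norms[:, l]), 1)[0]
            assert abs(slope + (p + l)) < 0.05

    def test_multi_consistent_with_single(self, small_periodic):
        entries = [
            (InteractionSpec(1.0, 0.6), BasisSpec("monomial", 1, 1, 1.0)),
            (InteractionSpec(6.0, 0.6), BasisSpec("gto", 3, 0, 1.0)),
        ]
        multi = compute_lode_multi(small_periodic, entries, 10.0)
        for (spec, basis), blk in zip(entries, multi):
            single = compute_lode(small_periodic, spec, basis, 10.0)
            np.testing.assert_allclose(blk.values, single.values, atol=1e-12)

    def test_gradients_unsupported_aperiodic(self, random_cluster):
        with pytest.raises(ValueError, match="reciprocal"):
            compute_lode(
                random_cluster, InteractionSpec(1.0, 0.5),
                BasisSpec("monomial", 1, 1, 1.0), with_gradients=True,
            )


class TestGradients:
    def test_finite_difference_and_sum_rule(self, small_periodic):
        spec = InteractionSpec(1.0, 0.6)
        basis = BasisSpec("gto", 2, 2, 1.2)
        blk = compute_lode_gradients(small_periodic, spec, basis, 10.0)
        # rigid-translation (acoustic) sum rule
        assert np.max(np.abs(blk.gradients.sum(axis=1))) < 1e-8
        scale = np.max(np.abs(blk.gradients))
        h = 1e-4
        for j in range(len(small_periodic)):
            for al in range(3):
                stp = small_periodic.copy()
                stp.positions[j, al] += h
                stm = small_periodic.copy()
                stm.positions[j, al] -= h
                fd = (
                    compute_lode(stp, spec, basis, 10.0).values
                    - compute_lode(stm, spec, basis, 10.0).values
                ) / (2 * h)
                assert np.max(np.abs(fd - blk.gradients[:, j, al])) < 1e-5 * scale

    def test_cubic_site_symmetry(self):
        # single-species simple-cubic crystal: forces-like gradients on the
        # center vanish by symmetry
        st = Structure(
            np.array([[0.0, 0, 0]]), ["X"], np.eye(3) * 3.0, np.array([1.0])
        )
        blk = compute_lode_gradients(
            st, InteractionSpec(1.0, 0.7), BasisSpec("monomial", 1, 2, 1.0), 10.0
        )
        assert np.max(np.abs(blk.gradients)) < 1e-8
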