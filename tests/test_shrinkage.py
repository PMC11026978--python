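"""Singular-value shrinkage: closed forms, thresholds, recovery, MP-PCA fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mccdenoise.shrinkage import (
    EigenSpectrum,
    ShrinkageResult,
    SingularSpectrum,
    denoise_matrix,
    hard_threshold_level,
    mp_pca_fit,
    mp_pca_shrink,
    normalize_spectrum,
    recover_matrix,
    shrink_fro,
    shrink_hard,
    shrink_nuc,
    shrink_op,
    shrink_soft,
    shrink_tsvd,
    z_transform,
)

Z31 = np.sqrt((7.0 + np.sqrt(45.0)) / 2.0)  # z(y=3, delta=1)


class TestClosedForms:
    """Each shrinker against direct evaluation of its closed form."""

    def test_z_transform(self):
        assert z_transform(3.0, 1.0) == pytest.approx(Z31, abs=1e-10)
        assert z_transform(3.0, 1.0) == pytest.approx(2.6180339887, abs=1e-9)
        # threshold point: discriminant vanishes, z = delta**(1/4)
        assert z_transform(2.0, 1.0) == pytest.approx(1.0, abs=1e-10)
        for delta in (0.04, 0.25, 0.5, 1.0):
            edge = 1.0 + np.sqrt(delta)
            assert z_transform(edge, delta) == pytest.approx(delta**0.25, abs=1e-9)
            assert z_transform(0.0, delta) == 0.0

    def test_fro(self):
        assert shrink_fro(3.0, 1.0) == pytest.approx(np.sqrt(5.0), abs=1e-10)
        assert shrink_fro(2.0, 1.0) == 0.0  # threshold point
        # delta -> 0 limit: (y^2 - 1)/y
        assert shrink_fro(2.0, 1e-12) == pytest.approx(1.5, rel=1e-5)

    def test_op(self):
        assert shrink_op(3.0, 1.0) == pytest.approx(Z31, abs=1e-10)
        assert shrink_op(1.4, 0.25) == 0.0  # below 1 + sqrt(0.25)

    def test_nuc(self):
        # y=2, delta=1: z=1, z^4 = 1 < 1 + 2 = condition fails -> 0
        assert shrink_nuc(2.0, 1.0) == 0.0
        z = Z31
        expected = (z**4 - 1.0 - 3.0 * z) / (z**2 * 3.0)
        assert shrink_nuc(3.0, 1.0) == pytest.approx(expected, abs=1e-10)
        assert shrink_nuc(3.0, 1.0) == pytest.approx(1.8541019662, abs=1e-9)
        assert shrink_nuc(0.0, 1.0) == 0.0

    def test_tsvd(self):
        assert shrink_tsvd(3.0, 1.0) == 3.0
        assert shrink_tsvd(1.9, 1.0) == 0.0
        # tie-break: the bulk edge itself is retained
        assert shrink_tsvd(2.0, 1.0) == 2.0
        assert shrink_tsvd(1.5, 0.25) == 1.5

    def test_hard_threshold_level(self):
        assert hard_threshold_level(1.0) == pytest.approx(np.sqrt(16.0 / 3.0), abs=1e-10)
        assert hard_threshold_level(1e-12) == pytest.approx(np.sqrt(2.0), rel=1e-5)
        deltas = np.linspace(0.01, 1.0, 50)
        levels = np.array([hard_threshold_level(d) for d in deltas])
        assert np.all(np.diff(levels) > 0)  # monotone increasing
        assert np.all(levels >= 1.0 + np.sqrt(deltas))

    def test_hard(self):
        assert shrink_hard(2.5, 1.0) == 2.5
        assert shrink_hard(2.2, 1.0) == 0.0
        assert shrink_hard(0.0, 1.0) == 0.0

    def test_soft(self):
        assert shrink_soft(3.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert shrink_soft(1.5, 0.25) == 0.0  # exactly at threshold
        assert shrink_soft(1.0, 1.0) == 0.0

    @pytest.mark.parametrize("func", [z_transform, shrink_fro, shrink_nuc, shrink_soft])
    def test_invalid_delta(self, func):
        with pytest.raises(ValueError):
            func(2.0, 0.0)
        with pytest.raises(ValueError):
            func(2.0, 1.5)


class TestShrinkerProperties:
    deltas = np.array([0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0])
    ys = np.linspace(0.0, 10.0, 400)

    @pytest.mark.parametrize(
        "func", [shrink_tsvd, shrink_hard, shrink_soft, shrink_fro, shrink_op, shrink_nuc]
    )
    def test_nonneg_thresholded_monotone(self, func):
        for d in self.deltas:
            vals = np.array([func(y, d) for y in self.ys])
            assert np.all(vals >= 0)
            assert np.all(vals[self.ys < 1.0 + np.sqrt(d)] == 0)
            assert np.all(np.diff(vals) >= -1e-12)

    def test_os_ordering(self):
        """nuc <= fro <= op <= y above the common bulk-edge threshold."""
        for d in self.deltas:
            above = self.ys[self.ys > 1.0 + np.sqrt(d)]
            nuc = np.array([shrink_nuc(y, d) for y in above])
            fro = np.array([shrink_fro(y, d) for y in above])
            op = np.array([shrink_op(y, d) for y in above])
            assert np.all(nuc <= fro + 1e-12)
            assert np.all(fro <= op + 1e-12)
            assert np.all(op <= above + 1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        y=st.floats(min_value=0.0, max_value=50.0),
        delta=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_soft_below_identity(self, y, delta):
        eta = shrink_soft(y, delta)
        assert eta == 0 or eta < y


class TestNormalizeSpectrum:
    def test_pure_noise_bulk_edge(self, rng):
        """Largest normalized value of pure noise sits at 1 + sqrt(delta)."""
        tops = []
        for _ in range(50):
            a = rng.standard_normal((100, 400))
            spec = SingularSpectrum.from_matrix(a)
            tops.append(normalize_spectrum(spec, 1.0).max())
        assert np.mean(tops) == pytest.approx(1.5, rel=0.05)

    def test_zeros_and_homogeneity(self):
        spec = SingularSpectrum(np.zeros(5), 5, 10)
        assert np.all(normalize_spectrum(spec, 1.0) == 0)
        vals = np.array([5.0, 3.0, 1.0])
        a = SingularSpectrum(vals, 3, 6)
        b = SingularSpectrum(2 * vals, 3, 6)
        np.testing.assert_allclose(
            normalize_spectrum(b, 1.0), 2 * normalize_spectrum(a, 1.0), rtol=1e-12
        )

    def test_sigma_validation(self):
        spec = SingularSpectrum(np.array([1.0]), 1, 4)
        with pytest.raises(ValueError):
            normalize_spectrum(spec, 0.0)
        with pytest.raises(ValueError):
            normalize_spectrum(spec, -1.0)


class TestMpPca:
    def test_pure_noise_fit(self, rng):
        ps, sigmas = [], []
        for _ in range(50):
            a = rng.standard_normal((50, 500))
            spec = SingularSpectrum.from_matrix(a)
            p, sigma = mp_pca_fit(EigenSpectrum.from_singular(spec))
            ps.append(p)
            sigmas.append(sigma)
        assert int(np.median(ps)) == 0
        assert np.mean(np.asarray(ps) == 0) >= 0.9
        assert np.all(np.abs(np.asarray(sigmas) - 1.0) < 0.1)

    def test_rank3_spikes(self, rng):
        m, n = 50, 500
        edge = (1.0 + np.sqrt(m / n)) * np.sqrt(n)
        ps = []
        for _ in range(50):
            u = np.linalg.qr(rng.standard_normal((m, 3)))[0]
            v = np.linalg.qr(rng.standard_normal((n, 3)))[0]
            a = u @ np.diag([10 * edge] * 3) @ v.T + rng.standard_normal((m, n))
            spec = SingularSpectrum.from_matrix(a)
            p, _ = mp_pca_fit(EigenSpectrum.from_singular(spec))
            ps.append(p)
        ps = np.asarray(ps)
        assert int(np.median(ps)) == 3
        assert np.all(ps >= 3)  # spikes this strong are never missed

    def test_zero_matrix(self):
        spec = SingularSpectrum(np.zeros(10), 10, 20)
        p, sigma = mp_pca_fit(EigenSpectrum.from_singular(spec))
        assert (p, sigma) == (0, 0.0)
        res = mp_pca_shrink(spec)
        assert np.all(res.shrunk_values == 0) and res.rank == 0

    def test_retained_value_not_debiased(self, rng):
        """MP-PCA keeps the noise-inflated spike; Fro shrinkage lowers it."""
        m, n = 100, 1000
        u = rng.standard_normal(m)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        a = 5.0 * np.sqrt(n) * np.outer(u, v) + rng.standard_normal((m, n))
        spec = SingularSpectrum.from_matrix(a)
        mp_res = mp_pca_shrink(spec)
        assert mp_res.rank == 1
        _, fro_res = denoise_matrix(a, "fro")
        assert mp_res.shrunk_values[0] > fro_res.shrunk_values[0]

    def test_degenerate_noise_free_diagonal(self):
        """A spectrum with no MP-consistent bulk must pass through intact."""
        spec = SingularSpectrum(np.full(6, 3.0), 6, 6)
        res = mp_pca_shrink(spec)
        np.testing.assert_array_equal(res.shrunk_values, spec.values)

    def test_rank_deficient_noise_free(self):
        vals = np.array([9.0, 4.0, 0.0, 0.0, 0.0, 0.0])
        spec = SingularSpectrum(vals, 6, 60)
        p, sigma = mp_pca_fit(EigenSpectrum.from_singular(spec))
        assert (p, sigma) == (2, 0.0)
        res = mp_pca_shrink(spec)
        np.testing.assert_array_equal(res.shrunk_values, vals)


class TestRecovery:
    def test_identity_roundtrip(self, rng):
        a = rng.standard_normal((30, 50))
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        res = ShrinkageResult(s, sigma_used=1.0, strategy="tsvd")
        out = recover_matrix(u, vt, res)
        assert np.linalg.norm(out - a) / np.linalg.norm(a) < 1e-10

    def test_zero_and_scalar_multiple(self, rng):
        a = rng.standard_normal((10, 20))
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        zero = recover_matrix(u, vt, ShrinkageResult(np.zeros_like(s), 1.0, "hard"))
        assert np.all(zero == 0)
        # rank-1 noise-free input: shrinking s1 scales the matrix
        x = rng.standard_normal(10)
        y = rng.standard_normal(20)
        r1 = np.outer(x, y)
        u, s, vt = np.linalg.svd(r1, full_matrices=False)
        shrunk = np.zeros_like(s)
        shrunk[0] = 0.4 * s[0]
        out = recover_matrix(u, vt, ShrinkageResult(shrunk, 1.0, "fro"))
        np.testing.assert_allclose(out, 0.4 * r1, atol=1e-10 * np.abs(r1).max())

    def test_dimension_mismatch(self, rng):
        a = rng.standard_normal((10, 20))
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        with pytest.raises(ValueError):
            recover_matrix(u[:, :5], vt, ShrinkageResult(s, 1.0, "fro"))


class TestOracles:
    def test_shrinkers_match_numerical_loss_minimization(self, rng):
        """The retained coefficient each OS shrinker produces agrees with a
        brute-force scan of the corresponding norm loss on planted-spike
        matrices (rank-1 truth + noise, the estimate restricted to the
        observed leading singular pair)."""
        n = 200
        y0 = 3.0
        t_grid = np.linspace(0.0, 4.0 * np.sqrt(n), 81)
        draws = 6
        opt = {"fro": [], "op": [], "nuc": []}
        mine = {"fro": [], "op": [], "nuc": []}
        for _ in range(draws):
            u = rng.standard_normal(n)
            u /= np.linalg.norm(u)
            v = rng.standard_normal(n)
            v /= np.linalg.norm(v)
            s0 = y0 * np.sqrt(n) * np.outer(u, v)
            a = s0 + rng.standard_normal((n, n))
            uu, ss, vvt = np.linalg.svd(a, full_matrices=False)
            pair = np.outer(uu[:, 0], vvt[0])
            losses = {k: [] for k in opt}
            for t in t_grid:
                diff_s = np.linalg.svd(t * pair - s0, compute_uv=False)
                losses["fro"].append(np.sqrt(np.sum(diff_s**2)))
                losses["op"].append(diff_s[0])
                losses["nuc"].append(np.sum(diff_s))
            for k in opt:
                opt[k].append(t_grid[int(np.argmin(losses[k]))])
            for k, func in (("fro", shrink_fro), ("op", shrink_op), ("nuc", shrink_nuc)):
                y = ss[0] / np.sqrt(n)
                mine[k].append(np.sqrt(n) * func(y, 1.0))
        for k in opt:
            assert np.mean(mine[k]) == pytest.approx(np.mean(opt[k]), rel=0.10), k

    @pytest.mark.parametrize("strategy", ["fro", "op", "nuc"])
    def test_pure_noise_nearly_annihilated(self, strategy, rng):
        """Optimal shrinkage of pure noise leaves under 5% of the energy."""
        ratios = []
        for _ in range(10):
            a = rng.standard_normal((100, 400))
            out, _ = denoise_matrix(a, strategy)
            ratios.append(np.linalg.norm(out) / np.linalg.norm(a))
        assert np.mean(ratios) < 0.05


class TestDenoiseMatrix:
    def test_transposed_input(self, rng):
        a = rng.standard_normal((50, 20))  # m > n: transposed internally
        out, res = denoise_matrix(a, "nuc")
        assert out.shape == a.shape

    def test_unknown_strategy(self, rng):
        with pytest.raises(ValueError):
            denoise_matrix(rng.standard_normal((5, 5)), "banana")

    def test_noise_free_passthrough(self, rng):
        """sigma = 0 blocks pass through unchanged for OS strategies."""
        x = rng.standard_normal(30)
        y = rng.standard_normal(60)
        r1 = np.outer(x, y)
        out, res = denoise_matrix(r1, "nuc")
        assert res.sigma_used == 0.0
        np.testing.assert_allclose(out, r1, atol=1e-10 * np.abs(r1).max())
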