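import numpy as np
import pytest

import balfprofiler as bp


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def grid_search_weights(s, basis, step=0.01, refinements=2):
    """Brute-force mixture recovery: grid over c in [0,1]^3, refined twice."""
    B = basis.matrix
    lo = np.zeros(3)
    hi = np.ones(3)
    best = None
    for _ in range(refinements + 1):
        axes = [np.arange(lo[i], hi[i] + 1e-12, step) for i in range(3)]
        g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        resid = g @ B - s.values
        obj = np.einsum("ij,ij->i", resid, resid)
        best = g[int(np.argmin(obj))]
        lo = np.maximum(best - step, 0.0)
        hi = best + step
        step /= 10.0
    return best


def projected_gradient_nnls(A, b, iterations=20000):
    """Reference minimizer of ||Ax - b||^2, x >= 0, by projected gradient."""
    L = np.linalg.norm(A.T @ A, 2)
    x = np.zeros(A.shape[1])
    step = 1.0 / L
    for _ in range(iterations):
        x = np.clip(x - step * (A.T @ (A @ x - b)), 0.0, None)
    return x


# ---------------------------------------------------------------------------
# solve_nnls
# ---------------------------------------------------------------------------

class TestSolveNnls:
    def test_basis_element_recovered_exactly(self, basis):
        s = bp.FingerprintVector.from_values("S", basis.m1.values)
        sol = bp.solve_nnls(s, basis)
        np.testing.assert_allclose(sol.coefficients, [0, 1, 0], atol=1e-9)
        assert sol.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_mixture_matches_grid_search_oracle(self, basis):
        true_w = np.array([0.5, 0.3, 0.2])
        s = bp.FingerprintVector.from_values("S", true_w @ basis.matrix)
        sol = bp.solve_nnls(s, basis)
        np.testing.assert_allclose(sol.coefficients, true_w, atol=1e-6)
        grid_w = grid_search_weights(s, basis)
        np.testing.assert_allclose(grid_w, true_w, atol=1e-3)

    def test_out_of_span_component_goes_entirely_to_residual(self, basis):
        Q, _ = np.linalg.qr(basis.matrix.T)
        w = np.array([3.0, -1.0, 2.0, 0.5, -2.0, 1.0, -0.5, 2.5, -1.5, 0.7])
        w -= Q @ (Q.T @ w)  # orthogonal to span(basis)
        s = bp.FingerprintVector.from_values(
            "S", np.clip(basis.m0.values + w, 0, 100)
        )
        assert np.all(basis.m0.values + w >= 0), "fixture must avoid clipping"
        sol = bp.solve_nnls(s, basis)
        np.testing.assert_allclose(sol.coefficients, [1, 0, 0], atol=1e-8)
        assert sol.residual_norm == pytest.approx(np.linalg.norm(w), rel=1e-9)

    def test_residual_vector_identity(self, basis, rng):
        s = bp.FingerprintVector.from_values("S", rng.uniform(0, 100, 10))
        sol = bp.solve_nnls(s, basis)
        recon = sol.coefficients @ basis.matrix
        np.testing.assert_allclose(
            sol.residual_vector, s.values - recon, atol=1e-9
        )
        assert sol.objective == pytest.approx(sol.residual_norm**2)

    def test_objective_matches_projected_gradient_oracle_on_random_problems(self):
        # random rank-3 bases in valid fingerprint space, 100 seeded problems
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            B = rng.uniform(5, 95, (3, 10))
            basis = bp.ReferenceBasis(
                m0=bp.FingerprintVector.from_values("M0", B[0]),
                m1=bp.FingerprintVector.from_values("M1", B[1]),
                m2a=bp.FingerprintVector.from_values("M2a", B[2]),
            )
            s = bp.FingerprintVector.from_values("S", rng.uniform(0, 100, 10))
            sol = bp.solve_nnls(s, basis)
            x_pg = projected_gradient_nnls(B.T, s.values)
            obj_pg = float(np.sum((B.T @ x_pg - s.values) ** 2))
            worst = max(worst, abs(sol.objective - obj_pg))
        assert worst <= 1e-8


# ---------------------------------------------------------------------------
# compose_fractions
# ---------------------------------------------------------------------------

class TestComposeFractions:
    def test_pure_basis_sample_is_all_one_phenotype(self, basis):
        s = bp.FingerprintVector.from_values("S", basis.m1.values)
        comp = bp.deconvolve(s, basis)
        np.testing.assert_allclose(comp.as_array(), [0, 100, 0, 0], atol=1e-6)

    def test_residual_allocation_arithmetic(self, basis):
        # c = (0.2, 0.5, 0.3) with residual_pct 20 -> (16, 40, 24, 20)
        coef = np.array([0.2, 0.5, 0.3])
        s_vals = coef @ basis.matrix
        s_norm = np.linalg.norm(s_vals)
        sol = bp.DeconvolutionSolution(
            coefficients=coef,
            residual_vector=np.zeros(10),
            residual_norm=0.2 * s_norm,
            objective=(0.2 * s_norm) ** 2,
        )
        s = bp.FingerprintVector.from_values("S", s_vals)
        comp = bp.compose_fractions(sol, s)
        np.testing.assert_allclose(comp.as_array(), [16, 40, 24, 20], atol=1e-9)

    def test_empty_span_case_is_all_residual(self, basis):
        sol = bp.DeconvolutionSolution(
            coefficients=np.zeros(3),
            residual_vector=np.full(10, 5.0),
            residual_norm=float(np.linalg.norm(np.full(10, 5.0))),
            objective=250.0,
        )
        s = bp.FingerprintVector.from_values("S", np.full(10, 5.0))
        comp = bp.compose_fractions(sol, s)
        np.testing.assert_allclose(comp.as_array(), [0, 0, 0, 100], atol=1e-9)

    def test_zero_norm_fingerprint_rejected(self, basis):
        s = bp.FingerprintVector.from_values("S", np.zeros(10))
        with pytest.raises(bp.DegenerateSampleError):
            bp.deconvolve(s, basis)

    def test_composition_always_sums_to_100(self, basis, rng):
        for _ in range(50):
            s = bp.FingerprintVector.from_values("S", rng.uniform(0, 100, 10))
            comp = bp.deconvolve(s, basis)
            assert comp.as_array().sum() == pytest.approx(100.0, abs=1e-6)
            assert np.all(comp.as_array() >= -1e-9)

    def test_scaling_fingerprint_scales_coefficients_not_split(self, basis, rng):
        vals = rng.uniform(5, 45, 10)
        s1 = bp.FingerprintVector.from_values("S", vals)
        s2 = bp.FingerprintVector.from_values("S", 2.0 * vals)
        sol1, sol2 = bp.solve_nnls(s1, basis), bp.solve_nnls(s2, basis)
        np.testing.assert_allclose(sol2.coefficients, 2 * sol1.coefficients, atol=1e-8)
        c1 = bp.compose_fractions(sol1, s1).as_array()
        c2 = bp.compose_fractions(sol2, s2).as_array()
        np.testing.assert_allclose(c1, c2, atol=1e-6)


# ---------------------------------------------------------------------------
# deconvolve_dataset
# ---------------------------------------------------------------------------

class TestDeconvolveDataset:
    def test_basis_vectors_as_samples(self, basis):
        table = bp.deconvolve_dataset([basis.m0, basis.m1, basis.m2a], basis)
        expected = np.eye(3) * 100
        got = table[["m0_pct", "m1_pct", "m2a_pct"]].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)
        np.testing.assert_allclose(table["residual_pct"], 0, atol=1e-6)

    def test_batch_equals_per_sample_loop(self, basis, rng):
        samples = [
            bp.FingerprintVector.from_values(f"S{i}", rng.uniform(0, 100, 10))
            for i in range(50)
        ]
        table = bp.deconvolve_dataset(samples, basis)
        for i, s in enumerate(samples):
            comp = bp.deconvolve(s, basis)
            np.testing.assert_array_equal(
                table.iloc[i, 1:].to_numpy(dtype=float), comp.as_array()
            )

    def test_empty_input_gives_empty_table(self, basis):
        table = bp.deconvolve_dataset([], basis)
        assert len(table) == 0
        assert tuple(table.columns) == (
            "sample_id", "m0_pct", "m1_pct", "m2a_pct", "residual_pct"
        )

    def test_residual_monotone_in_noise(self, basis):
        """Mean residual fraction is non-decreasing in injected noise sd."""
        rng = np.random.default_rng(77)
        weights = np.array([0.4, 0.35, 0.25])
        clean = weights @ basis.matrix
        means = []
        for sd in (0.0, 1.0, 3.0, 6.0):
            residuals = []
            for _ in range(200):
                vals = np.clip(clean + rng.normal(0, sd, 10), 0, 100)
                s = bp.FingerprintVector.from_values("S", vals)
                residuals.append(bp.deconvolve(s, basis).residual_pct)
            means.append(np.mean(residuals))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
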