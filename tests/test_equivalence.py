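"""Kalman decomposition, minimal realization and neutral-direction geometry."""

import numpy as np
import pytest

import sysdrift as sd
from sysdrift.equivalence import apply_generator, exp_neutral


class TestSubspaces:
    def test_oscillator_fully_reachable(self, osc):
        assert sd.reachable_subspace(osc).shape == (2, 2)

    def test_zero_B_unreachable(self, osc):
        sys = sd.make_system(osc.A, np.zeros((2, 1)), osc.C)
        assert sd.reachable_subspace(sys).shape == (2, 0)

    def test_block_diagonal_reachability(self):
        # B drives only the first 2x2 block, so the span stays there
        A = np.zeros((4, 4))
        A[:2, :2] = [[0, 1], [-1, 0]]
        A[2:, 2:] = [[-1, 0.5], [0, -2]]
        sys = sd.make_system(A, [1, 1, 0, 0], [1, 0, 0, 0])
        R = sd.reachable_subspace(sys)
        assert R.shape[1] == 2
        assert np.abs(R[2:]).max() < 1e-12

    def test_oscillator_fully_observable(self, osc):
        assert sd.unobservable_subspace(osc).shape == (2, 0)

    def test_zero_C_all_unobservable(self, osc):
        sys = sd.make_system(osc.A, osc.B, np.zeros((1, 2)))
        assert sd.unobservable_subspace(sys).shape == (2, 2)

    def test_unobservable_is_A_invariant_inside_null_C(self):
        sys = sd.pad_nonminimal(sd.oscillator(), 2, ["reach_unobs", "unreach_unobs"], seed=4)
        U = sd.unobservable_subspace(sys)
        assert U.shape[1] == 2
        assert np.abs(sys.C @ U).max() < 1e-8
        # A U must stay in span(U)
        resid = sys.A @ U - U @ (U.T @ (sys.A @ U))
        assert np.abs(resid).max() < 1e-8


class TestKalman:
    def test_oscillator_already_minimal(self, osc):
        dec = sd.kalman_decomposition(osc)
        assert tuple(dec.dims) == (0, 2, 0, 0)
        assert sd.phenotypically_equivalent(osc, dec.minimal)

    @pytest.mark.parametrize(
        "classes,expected",
        [
            (["reach_unobs"], (1, 2, 0, 0)),
            (["unreach_unobs"], (0, 2, 1, 0)),
            (["unreach_obs"], (0, 2, 0, 1)),
            (["reach_unobs", "unreach_unobs", "unreach_obs"], (1, 2, 1, 1)),
        ],
    )
    def test_padded_dimensions_recovered(self, osc, classes, expected):
        sys = sd.pad_nonminimal(osc, len(classes), classes, seed=8)
        dec = sd.kalman_decomposition(sys)
        assert tuple(dec.dims) == expected

    def test_zero_blocks_of_transformed_A(self, osc):
        sys = sd.pad_nonminimal(osc, 3, seed=3)
        dec = sd.kalman_decomposition(sys)
        At, Bt, Ct = dec.transformed
        d = dec.dims
        i = np.cumsum([0, *d])
        tol = 1e-8 * np.abs(At).max()
        # staircase zeros: reachable blocks invariant, unobservable blocks silent
        assert np.abs(At[i[1]:, : i[1]]).max() < tol  # below block 1
        assert np.abs(At[i[2]:, i[1]: i[2]]).max() < tol  # below block 2
        assert np.abs(At[i[1]: i[2], i[2]: i[3]]).max() < tol  # (ro, unreach-unobs)
        assert np.abs(At[i[3]:, i[2]: i[3]]).max() < tol  # (unreach-obs, unreach-unobs)
        assert np.abs(Bt[i[2]:]).max() < 1e-8 * max(np.abs(Bt).max(), 1)
        assert np.abs(Ct[:, : i[1]]).max() < 1e-8 * max(np.abs(Ct).max(), 1)
        assert np.abs(Ct[:, i[2]: i[3]]).max() < 1e-8 * max(np.abs(Ct).max(), 1)

    def test_zero_C_gives_empty_minimal_block(self, osc):
        sys = sd.make_system(osc.A, osc.B, np.zeros((1, 2)))
        dec = sd.kalman_decomposition(sys)
        assert dec.dims.reach_obs == 0
        t = np.linspace(0, 5, 20)
        assert np.abs(sd.impulse_response(dec.minimal, t).values).max() == 0


class TestMinimalRealization:
    def test_three_gene_padding_reduces_to_two(self, osc):
        sys = sd.pad_nonminimal(osc, 1, ["unreach_unobs"], seed=0)
        mini = sd.minimal_realization(sys)
        assert mini.n == 2
        t = np.linspace(0, 4 * np.pi, 100)
        h = sd.impulse_response(mini, t).values[:, 0, 0]
        np.testing.assert_allclose(h, np.sin(t) + np.cos(t), atol=1e-8)

    def test_already_minimal_unchanged_dimension(self):
        sys = sd.random_system(4, 1, 1, seed=5)
        assert sd.minimal_realization(sys).n == 4 == sd.hankel_rank(sys)

    def test_dimension_equals_hankel_rank_on_paddings(self, osc):
        for seed in range(10):
            sys = sd.pad_nonminimal(osc, 1 + seed % 3, seed=seed)
            mini = sd.minimal_realization(sys)
            assert mini.n == sd.hankel_rank(sys) == 2
            assert sd.phenotypically_equivalent(sys, mini)

    def test_markov_parameters_preserved(self, osc):
        sys = sd.pad_nonminimal(osc, 2, seed=12)
        mini = sd.minimal_realization(sys)
        m1 = sd.markov_parameters(sys, 6)
        m2 = sd.markov_parameters(mini, 6)
        np.testing.assert_allclose(m1, m2, atol=1e-8 * np.abs(m1).max())


class TestPadNonminimal:
    def test_equivalence_preserved(self, osc):
        for seed in range(10):
            padded = sd.pad_nonminimal(osc, 2, seed=seed)
            assert sd.phenotypically_equivalent(osc, padded)

    def test_zero_couplings_block_diagonal(self, osc):
        padded = sd.pad_nonminimal(osc, 1, ["unreach_unobs"], coupling_scale=0.0, mix=False)
        assert np.abs(padded.A[2, :2]).max() == 0 and np.abs(padded.A[:2, 2]).max() == 0

    def test_empty_classes_rejected(self, osc):
        with pytest.raises(ValueError, match="nonempty"):
            sd.pad_nonminimal(osc, 1, [])


class TestNeutralTangent:
    def test_oscillator_fixed_bc_dimension_one(self, osc):
        tan = sd.neutral_tangent(osc, "fixed_BC")
        assert tan.dimension == 1
        # generator algebra is spanned by Z ~ [[0, 0], [1, -1]]
        Z = tan.algebra_basis[0]
        expected = np.array([[0.0, 0.0], [1.0, -1.0]]) / np.sqrt(2)
        assert min(np.abs(Z - expected).max(), np.abs(Z + expected).max()) < 1e-10

    @pytest.mark.parametrize("n,m,l", [(4, 1, 1), (5, 2, 1), (6, 1, 2)])
    def test_generic_dimension_formula(self, n, m, l):
        sys = sd.random_system(n, m, l, seed=n + m + l)
        tan = sd.neutral_tangent(sys, "fixed_BC")
        assert tan.dimension == sd.generic_tangent_dimension(n, m, l) == (n - m) * (n - l)

    def test_fixed_bc_constraints_hold(self):
        sys = sd.random_system(4, 1, 1, seed=3)
        tan = sd.neutral_tangent(sys, "fixed_BC")
        for Z in tan.algebra_basis:
            assert np.abs(Z @ sys.B).max() < 1e-10
            assert np.abs(sys.C @ Z).max() < 1e-10
        for dA, dB, dC in tan.generators:
            assert np.abs(dB).max() < 1e-10 and np.abs(dC).max() < 1e-10

    def test_identity_direction_in_free_mode(self, osc):
        # Z = I commutes with A, so its direction is (0, B, -C): a pure
        # input/output rescaling with no regulatory change
        tan = sd.neutral_tangent(osc, "free")
        vec_I = np.eye(2).ravel() / np.sqrt(2)
        coords = np.array([vec_I @ Z.ravel() for Z in tan.algebra_basis])
        assert abs(np.linalg.norm(coords) - 1.0) < 1e-10  # I is in the free algebra
        # but I violates the fixed-B,C constraints (I B = B != 0), so it is
        # not contained in the constrained algebra
        tan_bc = sd.neutral_tangent(osc, "fixed_BC")
        proj = sum(
            (vec_I @ Z.ravel()) * Z.ravel() for Z in tan_bc.algebra_basis
        )
        assert np.linalg.norm(vec_I - proj) > 1e-3
        for Z in tan_bc.algebra_basis:
            assert np.abs(Z @ osc.B).max() < 1e-12

    def test_first_order_neutrality_quadratic_distance(self, osc):
        # stepping along any generator moves distance-to-optimum ~ eps^2
        spec = sd.DistanceSpec(optimum=osc, horizon=sd.DEFAULT_HORIZON)
        tan = sd.neutral_tangent(osc, "fixed_BC")
        eps = np.array([3e-2, 1e-2, 3e-3, 1e-3])
        d = np.array(
            [sd.distance_to_optimum(apply_generator(osc, tan.generators[0], e), spec)
             for e in eps]
        )
        slope = np.polyfit(np.log(eps), np.log(d), 1)[0]
        assert abs(slope - 2.0) < 0.1

    def test_exp_neutral_exactly_on_set(self, osc):
        tan = sd.neutral_tangent(osc, "fixed_BC")
        moved = exp_neutral(osc, 0.7 * tan.algebra_basis[0])
        assert sd.phenotypically_equivalent(osc, moved)
        np.testing.assert_allclose(moved.B, osc.B, atol=1e-12)
        np.testing.assert_allclose(moved.C, osc.C, atol=1e-12)
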