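"""The branch-length-constrained matrix samplers and the DLC machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dtphylosim as dps
from dtphylosim import matrix_sampler

from conftest import det4_cofactor, logdet_len_oracle


def k81_params(P):
    """(a, b, c, d) read off a K81-shaped matrix."""
    return P[0, 0], P[0, 1], P[0, 2], P[0, 3]


class TestBranchToDet:
    def test_values(self):
        assert dps.branch_to_det(0.25) == pytest.approx(math.exp(-1), abs=1e-15)
        assert dps.branch_to_det(0.5) == pytest.approx(0.1353352832366127, abs=1e-15)
        assert dps.branch_to_det(1e-9) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("bad", [0.0, -0.3, float("inf"), float("nan")])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            dps.branch_to_det(bad)


class TestJC69:
    def test_closed_form_at_l_03(self):
        P = dps.sample_jc69(0.3)
        e = math.exp(-0.4)
        assert P.entries[0, 0] == pytest.approx((1 + 3 * e) / 4, abs=1e-12)
        assert P.entries[0, 1] == pytest.approx((1 - e) / 4, abs=1e-12)
        assert P.entries[0, 0] == pytest.approx(0.752740, abs=1e-6)
        assert P.entries[0, 1] == pytest.approx(0.082420, abs=1e-6)

    def test_short_branch_approaches_identity(self):
        P = dps.sample_jc69(1e-9)
        assert np.allclose(P.entries, np.eye(4), atol=1e-8)

    @pytest.mark.parametrize("l", [0.01, 0.3, 1.0, 2.5])
    def test_determinant_is_exact(self, l):
        P = dps.sample_jc69(l)
        assert logdet_len_oracle(P.entries) == pytest.approx(l, abs=1e-9)
        assert dps.is_dlc(P)


class TestEigenvalueSamplers:
    @pytest.mark.parametrize("l", [0.05, 0.2, 0.7])
    def test_k81_eigenvalue_product_is_the_target_determinant(self, l, rng):
        D = dps.branch_to_det(l)
        for _ in range(50):
            P = dps.sample_k81(l, rng)
            a, b, c, d = k81_params(P.entries)
            x, y, z = a + b - c - d, a - b + c - d, a - b - c + d
            assert x * y * z == pytest.approx(D, abs=1e-12)
            assert dps.conforms_to_pattern(P.entries, P.model)

    def test_k81_numeric_eigenvalues_match_parameterization(self, rng):
        P = dps.sample_k81(0.2, rng)
        a, b, c, d = k81_params(P.entries)
        expected = sorted([1.0, a + b - c - d, a - b + c - d, a - b - c + d])
        observed = sorted(np.linalg.eigvals(P.entries).real)
        assert np.allclose(observed, expected, atol=1e-9)

    @pytest.mark.parametrize("l", [0.05, 0.7, 1.5])
    def test_k80_transversion_entries_equal(self, l, rng):
        D = dps.branch_to_det(l)
        for _ in range(50):
            P = dps.sample_k80(l, rng)
            a, b, c, d = k81_params(P.entries)
            assert b == d  # the two transversion parameters coincide
            x, y = a - c, a + c - 2 * b
            assert x * x * y == pytest.approx(D, abs=1e-12)

    def test_degenerate_eigenvalues_recover_jc69(self):
        e = math.exp(-4 * 0.3 / 3)
        P = matrix_sampler._k81_entries_from_eigs(e, e, e)
        assert np.allclose(P, dps.sample_jc69(0.3).entries, atol=1e-15)


class TestMixtureSampler:
    @pytest.mark.parametrize("name", ["ssm", "gmm"])
    @pytest.mark.parametrize("l", [0.1, 0.5, 1.0])
    def test_determinant_pattern_and_stochasticity(self, name, l, rng):
        model = dps.get_model(name)
        D = dps.branch_to_det(l)
        for _ in range(20):
            P = dps.sample_mixture(model, l, rng)
            assert det4_cofactor(P.entries) == pytest.approx(D, abs=1e-12)
            assert dps.conforms_to_pattern(P.entries, model)
            assert np.all(P.entries >= 0)
            assert np.allclose(P.entries.sum(axis=1), 1.0, atol=1e-12)

    def test_gmm_draws_are_distinct(self):
        rng = np.random.default_rng(42)
        model = dps.get_model("gmm")
        draws = [dps.sample_mixture(model, 0.1, rng).entries.tobytes() for _ in range(200)]
        assert len(set(draws)) == 200

    def test_mixture_is_deterministic_given_the_seed(self):
        model = dps.get_model("ssm")
        a = dps.sample_mixture(model, 0.4, np.random.default_rng(9)).entries
        b = dps.sample_mixture(model, 0.4, np.random.default_rng(9)).entries
        assert np.array_equal(a, b)

    def test_extreme_branch_length(self):
        # D ~ 6e-6: the crossing sits deep in the mixture path
        P = dps.sample_matrix(dps.get_model("gmm"), 2.9957, np.random.default_rng(3))
        assert logdet_len_oracle(P.entries) == pytest.approx(2.9957, abs=1e-9)


class TestDLC:
    def test_identity_is_dlc(self):
        assert dps.is_dlc(np.eye(4))

    def test_jc69_is_dlc(self):
        assert dps.is_dlc(dps.sample_jc69(0.5))

    def test_ties_are_rejected(self):
        M = np.full((4, 4), 0.25)
        assert not dps.is_dlc(M)

    def k81_matrix(self, a, b, c, d):
        return np.array([[a, b, c, d], [b, a, d, c], [c, d, a, b], [d, c, b, a]])

    def test_off_diagonal_dominance_is_not_dlc(self):
        assert not dps.is_dlc(self.k81_matrix(0.2, 0.5, 0.2, 0.1))

    def test_make_dlc_returns_dlc_input_unchanged(self):
        model = dps.get_model("k81")
        M = self.k81_matrix(0.7, 0.1, 0.1, 0.1)
        assert dps.make_dlc(M, model) is M

    def test_make_dlc_converts_k81_by_row_swap(self):
        # column maxima sit on the b cells; the (AC)(GT) swap moves them
        # onto the diagonal while keeping the K81 shape
        model = dps.get_model("k81")
        M = self.k81_matrix(0.2, 0.5, 0.2, 0.1)
        out = dps.make_dlc(M, model)
        assert out is not None
        assert np.allclose(np.diag(out), 0.5)
        assert dps.is_dlc(out)
        assert dps.conforms_to_pattern(out, model)
        assert np.array_equal(out, M[[1, 0, 3, 2], :])

    def test_make_dlc_fails_when_no_permutation_works(self):
        # two identical rows tie in every column they dominate: no row
        # permutation can make the maxima strict, even in the full GMM group
        model = dps.get_model("gmm")
        r = np.array([0.6, 0.2, 0.1, 0.1])
        M = np.vstack([r, r, [0.1, 0.1, 0.6, 0.2], [0.1, 0.1, 0.2, 0.6]])
        assert dps.make_dlc(M, model) is None


class TestSampleMatrix:
    @pytest.mark.parametrize("name", dps.MODEL_NAMES)
    @pytest.mark.parametrize("l", [0.01, 0.1, 0.5, 1.0])
    def test_full_contract(self, name, l, rng):
        model = dps.get_model(name)
        for _ in range(10):
            P = dps.sample_matrix(model, l, rng)
            assert logdet_len_oracle(P.entries) == pytest.approx(l, abs=1e-9)
            assert dps.is_dlc(P)
            assert dps.conforms_to_pattern(P.entries, model)

    def test_k81_succeeds_on_first_trial(self, rng):
        # positive-eigenvalue draws are DLC by construction
        assert dps.sample_matrix(dps.get_model("k81"), 0.2, rng).trials == 1

    def test_zero_length_gives_identity_matrix(self, rng):
        P = dps.sample_matrix(dps.get_model("gmm"), 0.0, rng)
        assert np.array_equal(P.entries, np.eye(4))

    def test_trial_cap_aborts_with_restart_error(self, rng, monkeypatch):
        calls = {"n": 0}

        def always_fail(P):
            calls["n"] += 1
            return False

        monkeypatch.setattr(matrix_sampler, "is_dlc", always_fail)
        with pytest.raises(dps.TrialBudgetExceededError, match="re-start"):
            dps.sample_matrix(dps.get_model("jc69"), 0.3, rng)
        # JC69's permutation group is trivial, so each of the 1000 trials
        # checks DLC exactly once before giving up
        assert calls["n"] == 1000

    def test_custom_trial_cap(self, rng, monkeypatch):
        monkeypatch.setattr(matrix_sampler, "is_dlc", lambda P: False)
        with pytest.raises(dps.TrialBudgetExceededError):
            dps.sample_matrix(dps.get_model("jc69"), 0.3, rng, max_trials=7)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    l=st.floats(min_value=0.01, max_value=2.0),
    name=st.sampled_from(list(dps.MODEL_NAMES)),
)
def test_determinant_contract_property(l, name):
    P = dps.sample_matrix(dps.get_model(name), l, np.random.default_rng(123))
    assert logdet_len_oracle(P.entries) == pytest.approx(l, abs=1e-9)
    assert dps.is_dlc(P)
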