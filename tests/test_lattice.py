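import json

import numpy as np
import pytest

from alseg.lattice import (
    PM1,
    ZERO_ONE,
    AutologisticModel,
    Coding,
    DesignMatrix,
    DimensionError,
    build_lattice,
    coding_from_name,
    conditional_probabilities,
    convert_coding,
    decode_field,
    encode_field,
    enumerate_pmf,
    exact_marginals,
    independence_expectation,
    load_model,
    neighbor_sum,
    negpotential,
    save_model,
    unary_field,
)

from conftest import ALL_VARIANTS, enumeration_conditional, random_model


class TestCoding:
    def test_named_codings(self):
        assert PM1.span == 2.0 and ZERO_ONE.span == 1.0
        assert coding_from_name("pm1") == PM1
        assert coding_from_name("01") == ZERO_ONE

    def test_rejects_unordered(self):
        with pytest.raises(ValueError):
            Coding(1.0, 0.0)

    def test_rejects_unsupported(self):
        with pytest.raises(ValueError):
            Coding(0.0, 2.0)
        with pytest.raises(ValueError):
            coding_from_name("pm2")


class TestBuildLattice:
    def test_single_pixel(self):
        g = build_lattice(1, 1)
        assert g.n_pixels == 1 and g.n_edges == 0
        assert g.degrees()[0, 0] == 0

    def test_2x2(self):
        g = build_lattice(2, 2)
        assert g.n_pixels == 4 and g.n_edges == 4
        assert np.all(g.degrees() == 2)

    def test_3x3(self):
        g = build_lattice(3, 3)
        assert g.n_pixels == 9 and g.n_edges == 12
        d = g.degrees()
        assert d[1, 1] == 4
        assert all(d[r, c] == 2 for r, c in [(0, 0), (0, 2), (2, 0), (2, 2)])
        assert all(d[r, c] == 3 for r, c in [(0, 1), (1, 0), (1, 2), (2, 1)])

    @pytest.mark.parametrize("shape", [(0, 3), (3, 0), (-1, 2)])
    def test_rejects_bad_dims(self, shape):
        with pytest.raises(DimensionError):
            build_lattice(*shape)

    @pytest.mark.parametrize("shape", [(1, 1), (2, 3), (4, 4), (1, 7)])
    def test_edge_count_formula(self, shape):
        g = build_lattice(*shape)
        r, c = shape
        assert g.n_edges == r * (c - 1) + c * (r - 1)
        assert g.adjacency().sum() == 2 * g.n_edges
        # symmetric, zero diagonal
        A = g.adjacency().toarray()
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)


class TestNeighborSum:
    def test_all_high_pm1(self):
        g = build_lattice(3, 3)
        s = neighbor_sum(np.ones((3, 3)), g)
        assert s[1, 1] == 4
        assert s[0, 0] == 2

    def test_striped_2x2_cancels(self):
        # column stripes: each pixel has one +1 and one -1 neighbour
        g = build_lattice(2, 2)
        z = np.array([[-1.0, 1.0], [-1.0, 1.0]])
        assert np.all(neighbor_sum(z, g) == 0)

    def test_chequerboard_2x2(self):
        # chequerboard: both neighbours carry the opposite value
        g = build_lattice(2, 2)
        z = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert np.array_equal(neighbor_sum(z, g), -2.0 * z)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            neighbor_sum(np.ones((2, 3)), build_lattice(3, 2))


class TestNegpotential:
    def test_zero_parameters(self, rng):
        g = build_lattice(2, 3)
        m = AutologisticModel(np.zeros(2), 0.0, PM1)
        X = rng.normal(size=(6, 2))
        z = encode_field(rng.random((2, 3)) > 0.5, PM1)
        assert negpotential(m, X, z, g) == 0.0

    def test_single_edge(self):
        g = build_lattice(1, 2)
        m = AutologisticModel(np.zeros(1), 1.0, PM1)
        X = np.zeros((2, 1))
        z = np.ones((1, 2))
        assert negpotential(m, X, z, g) == pytest.approx(1.0)

    def test_2x2_hand_sum(self):
        # unary 0.5 per pixel * 4 pixels + lam 0.8 * 4 edges * 1 = 5.2
        g = build_lattice(2, 2)
        m = AutologisticModel(np.array([0.5]), 0.8, ZERO_ONE)
        X = np.ones((4, 1))
        z = np.ones((2, 2))
        assert negpotential(m, X, z, g) == pytest.approx(2.0 + 3.2)


class TestIndependenceExpectation:
    def test_zero_predictor(self):
        m01 = AutologisticModel(np.zeros(1), 0.0, ZERO_ONE)
        mpm = AutologisticModel(np.zeros(1), 0.0, PM1)
        X = np.zeros((3, 1))
        assert np.allclose(independence_expectation(m01, X), 0.5)
        assert np.allclose(independence_expectation(mpm, X), 0.0)

    def test_tanh_identity_pm1(self):
        m = AutologisticModel(np.array([1.0]), 0.0, PM1)
        X = np.ones((1, 1))
        assert independence_expectation(m, X)[0] == pytest.approx(np.tanh(1.0))


class TestConditionalProbabilities:
    def test_half_at_zero_logit(self, rng):
        g = build_lattice(2, 2)
        X = np.zeros((4, 1))
        for coding, centred in ALL_VARIANTS:
            m = AutologisticModel(np.zeros(1), 0.0, coding, centred)
            z = encode_field(rng.random((2, 2)) > 0.5, coding)
            assert np.allclose(conditional_probabilities(m, X, z, g), 0.5)

    def test_closed_form_interior(self):
        # 4 high neighbours, pm1, lam=1 -> logit = 2 * 4 = 8
        g = build_lattice(3, 3)
        m = AutologisticModel(np.zeros(1), 1.0, PM1)
        X = np.zeros((9, 1))
        z = np.ones((3, 3))
        pi = conditional_probabilities(m, X, z, g)
        assert pi[1, 1] == pytest.approx(1.0 / (1.0 + np.exp(-8.0)))

    def test_saturates_without_nan(self):
        g = build_lattice(1, 2)
        m = AutologisticModel(np.array([500.0]), 0.0, PM1)
        X = np.array([[1.0], [-1.0]])
        pi = conditional_probabilities(m, X, np.ones((1, 2)), g)
        assert np.all(np.isfinite(pi))
        assert pi[0, 0] == 1.0 and pi[0, 1] == 0.0

    @pytest.mark.parametrize("shape", [(1, 2), (2, 2), (2, 3), (3, 3), (3, 4)])
    @pytest.mark.parametrize("coding,centred", ALL_VARIANTS)
    def test_matches_enumeration(self, shape, coding, centred, rng):
        g = build_lattice(*shape)
        n = g.n_pixels
        X = rng.normal(size=(n, 2))
        m = random_model(rng, 2, coding, centred)
        _, probs = enumerate_pmf(m, X, g)
        for _ in range(3):
            k = int(rng.integers(len(probs)))
            bits = (k >> np.arange(n)) & 1
            z = encode_field(bits.astype(bool).reshape(g.shape), coding)
            pi = conditional_probabilities(m, X, z, g).ravel()
            for i in range(n):
                expected = enumeration_conditional(probs, i, k, n)
                assert pi[i] == pytest.approx(expected, abs=1e-10)


class TestEnumeratePmf:
    def test_single_pixel_uniform(self):
        g = build_lattice(1, 1)
        m = AutologisticModel(np.zeros(1), 0.0, ZERO_ONE)
        states, probs = enumerate_pmf(m, np.zeros((1, 1)), g)
        assert np.allclose(probs, 0.5)
        assert set(states.ravel()) == {0.0, 1.0}

    def test_normalization(self, rng):
        g = build_lattice(2, 3)
        for coding, centred in ALL_VARIANTS:
            m = random_model(rng, 2, coding, centred)
            _, probs = enumerate_pmf(m, rng.normal(size=(6, 2)), g)
            assert abs(probs.sum() - 1.0) < 1e-12

    def test_joint_modes_by_flip_symmetry(self):
        g = build_lattice(2, 2)
        m = AutologisticModel(np.zeros(1), 0.5, PM1)
        states, probs = enumerate_pmf(m, np.zeros((4, 1)), g)
        top2 = np.argsort(probs)[-2:]
        mode_states = {tuple(states[k]) for k in top2}
        assert mode_states == {(1.0,) * 4, (-1.0,) * 4}
        assert probs[top2[0]] == pytest.approx(probs[top2[1]])

    def test_refuses_large_lattice(self):
        g = build_lattice(5, 5)
        m = AutologisticModel(np.zeros(1), 0.0, PM1)
        with pytest.raises(ValueError, match="refused"):
            enumerate_pmf(m, np.zeros((25, 1)), g)


class TestExactMarginals:
    def test_lambda0_closed_form(self, rng):
        from scipy.special import expit

        g = build_lattice(2, 3)
        X = rng.normal(size=(6, 2))
        for coding in (PM1, ZERO_ONE):
            m = AutologisticModel(rng.normal(size=2), 0.0, coding)
            expected = expit(coding.span * (X @ m.beta)).reshape(2, 3)
            assert np.allclose(exact_marginals(m, X, g), expected, atol=1e-12)

    def test_flip_symmetry_half(self):
        g = build_lattice(2, 2)
        for lam in (0.0, 0.4, 1.0):
            m = AutologisticModel(np.zeros(1), lam, PM1)
            assert np.allclose(exact_marginals(m, np.zeros((4, 1)), g), 0.5, atol=1e-12)

    def test_centre_exceeds_corner(self):
        g = build_lattice(3, 3)
        m = AutologisticModel(np.array([0.2]), 0.3, PM1)
        mar = exact_marginals(m, np.ones((9, 1)), g)
        assert mar[1, 1] > mar[0, 0]
        assert np.all((mar > 0.5) & (mar < 1.0))


class TestFlipSymmetry:
    def test_pmf_invariant_under_negation(self, rng):
        g = build_lattice(2, 3)
        m = AutologisticModel(np.zeros(2), 0.45, PM1)
        _, probs = enumerate_pmf(m, rng.normal(size=(6, 2)), g)
        # state k and its bitwise complement are negations of each other
        comp = (~np.arange(len(probs))) & (len(probs) - 1)
        assert np.allclose(probs, probs[comp], atol=1e-12)


class TestConvertCoding:
    def test_independence_case(self):
        g = build_lattice(2, 2)
        a = np.full((2, 2), 0.7)
        a01, lam01 = convert_coding(a, 0.0, g, PM1, ZERO_ONE)
        assert lam01 == 0.0
        assert np.allclose(a01, 2 * a)

    def test_lambda_factor(self):
        g = build_lattice(2, 2)
        _, lam01 = convert_coding(np.zeros((2, 2)), 0.5, g, PM1, ZERO_ONE)
        assert lam01 == 2.0

    def test_identity_pair(self):
        g = build_lattice(2, 2)
        a = np.arange(4.0).reshape(2, 2)
        a2, lam2 = convert_coding(a, 0.3, g, PM1, PM1)
        assert lam2 == 0.3 and np.array_equal(a2, a)

    @pytest.mark.parametrize("direction", ["01->pm1", "pm1->01"])
    def test_preserves_pmf(self, direction, rng):
        g = build_lattice(2, 2)
        src, dst = (ZERO_ONE, PM1) if direction == "01->pm1" else (PM1, ZERO_ONE)
        X = rng.normal(size=(4, 2))
        m = random_model(rng, 2, src, False)
        a = unary_field(m, X, g)
        a2, lam2 = convert_coding(a, m.lam, g, src, dst)
        m2 = AutologisticModel(a2.ravel(), lam2, dst)
        _, p1 = enumerate_pmf(m, X, g)
        _, p2 = enumerate_pmf(m2, np.eye(4), g)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_round_trip_identity(self, rng):
        g = build_lattice(3, 3)
        a = rng.normal(size=(3, 3))
        lam = 0.8
        a2, lam2 = convert_coding(a, lam, g, PM1, ZERO_ONE)
        a3, lam3 = convert_coding(a2, lam2, g, ZERO_ONE, PM1)
        assert np.allclose(a3, a, atol=1e-12)
        assert lam3 == pytest.approx(lam, abs=1e-14)

    def test_regression_form_not_closed_on_1x3(self):
        # With an intercept-only design the unary field is constant, but on
        # a path lattice the converted unary depends on the degree (1, 2, 1),
        # so it leaves the column span of the design.
        g = build_lattice(1, 3)
        beta, lam = 0.4, 0.6
        a = np.full((1, 3), beta)
        a01, _ = convert_coding(a, lam, g, PM1, ZERO_ONE)
        ones = np.ones(3)
        resid = a01.ravel() - ones * (a01.ravel() @ ones) / 3
        assert np.linalg.norm(resid) > 1e-8


class TestCentredCodingAgreement:
    """The centred variants define the same joint under either coding, once
    lambda is rescaled by the span factor (4) and beta by the span ratio."""

    def test_marginals_agree_exactly(self, rng):
        g = build_lattice(2, 3)
        X = rng.normal(size=(6, 2))
        raw = rng.normal(size=2)  # logit-scale coefficients
        for lam_pm in (0.1, 0.3, 0.7):
            m_pm = AutologisticModel(raw / 2.0, lam_pm, PM1, centred=True)
            m_01 = AutologisticModel(raw, 4.0 * lam_pm, ZERO_ONE, centred=True)
            assert np.allclose(
                exact_marginals(m_pm, X, g), exact_marginals(m_01, X, g), atol=1e-10
            )

    def test_standard_variants_differ(self, rng):
        g = build_lattice(2, 3)
        X = rng.normal(size=(6, 2))
        raw = rng.normal(size=2)
        m_pm = AutologisticModel(raw / 2.0, 0.5, PM1, centred=False)
        m_01 = AutologisticModel(raw, 2.0, ZERO_ONE, centred=False)
        diff = np.abs(exact_marginals(m_pm, X, g) - exact_marginals(m_01, X, g))
        assert diff.max() > 0.01


class TestSerialization:
    def test_round_trip(self, tmp_path):
        m = AutologisticModel(
            np.array([0.123456789012345, -2.5]), 0.75, PM1, True, ("intercept", "b0")
        )
        path = tmp_path / "model.json"
        save_model(m, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.beta, m.beta)
        assert loaded.lam == m.lam
        assert loaded.coding == m.coding
        assert loaded.centred == m.centred
        assert loaded.columns == m.columns

    def test_json_keys(self, tmp_path):
        m = AutologisticModel(np.array([1.0]), 0.5, ZERO_ONE)
        path = tmp_path / "m.json"
        save_model(m, path)
        d = json.loads(path.read_text())
        assert d["coding"] == "01"
        assert set(d) >= {"beta", "lambda", "coding", "centred"}


class TestValidation:
    def test_design_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            DesignMatrix(np.array([[1.0, np.nan]]))

    def test_model_rejects_negative_lambda(self):
        with pytest.raises(ValueError):
            AutologisticModel(np.zeros(1), -0.1, PM1)

    def test_decode_rejects_foreign_values(self):
        with pytest.raises(ValueError):
            decode_field(np.array([[0.5]]), PM1)

    def test_encode_decode_round_trip(self, rng):
        ind = rng.random((3, 4)) > 0.5
        for coding in (PM1, ZERO_ONE):
            assert np.array_equal(decode_field(encode_field(ind, coding), coding), ind)
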