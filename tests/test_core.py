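"""Unit and property tests for the triple-product chirality core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chiracal import (
    DegenerateGeometryError,
    InvalidInputError,
    PointChain,
    chi_norm,
    chi_total,
    classify_handedness,
    difference_vectors,
    evaluate_chain,
    mixed_product,
    normalization_factor,
    stepwise_chirality,
)
from chiracal.helix import IdealHelixSpec, chi_closed_form, generate_helix, step_length

from conftest import random_chain_coords, random_rotation


class TestPointChain:
    def test_rejects_bad_shapes_and_nonfinite(self):
        with pytest.raises(InvalidInputError):
            PointChain([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(InvalidInputError):
            PointChain([[0, 0, 0], [1, np.nan, 0]])

    def test_labels_must_match_length(self):
        with pytest.raises(InvalidInputError):
            PointChain([[0, 0, 0], [1, 0, 0]], labels=[("A", 1, "", "GLY")])

    def test_triple_count(self):
        assert PointChain(np.zeros((3, 3)) + np.arange(3)[:, None]).n_triples == 0
        assert PointChain(random_chain_coords(np.random.default_rng(0), 7)).n_triples == 4


class TestDifferenceVectors:
    def test_simple_l_shape(self):
        chain = PointChain([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        np.testing.assert_array_equal(
            difference_vectors(chain), [(1, 0, 0), (0, 1, 0)]
        )

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            difference_vectors(PointChain([(0, 0, 0)]))

    def test_duplicate_point_names_offending_index(self):
        chain = PointChain([(0, 0, 0), (1, 0, 0), (1, 0, 0), (2, 0, 0)])
        with pytest.raises(DegenerateGeometryError, match="step 1"):
            difference_vectors(chain)


class TestMixedProduct:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            ((1, 0, 0), (0, 1, 0), (0, 0, 1), 1.0),    # right-handed frame
            ((1, 0, 0), (0, 1, 0), (0, 0, -1), -1.0),  # mirrored frame
            ((1, 0, 0), (0, 1, 0), (3, -2, 0), 0.0),   # c coplanar with a, b
            ((2, 0, 0), (0, 3, 0), (0, 0, 4), 24.0),   # box volume
        ],
    )
    def test_reference_frames(self, a, b, c, expected):
        assert mixed_product(a, b, c) == pytest.approx(expected)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_swapping_any_two_arguments_flips_sign(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = r.normal(size=(3, 3))
        m = mixed_product(a, b, c)
        assert mixed_product(b, a, c) == pytest.approx(-m, abs=1e-9)
        assert mixed_product(c, b, a) == pytest.approx(-m, abs=1e-9)
        assert mixed_product(a, c, b) == pytest.approx(-m, abs=1e-9)


class TestChiTotal:
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_short_chains_are_exactly_zero(self, n, rng):
        assert chi_total(PointChain(random_chain_coords(rng, max(n, 1)))) == 0.0

    def test_planar_zigzag_is_zero(self):
        zigzag = [(i, i % 2, 0.0) for i in range(8)]
        assert chi_total(PointChain(zigzag)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_ideal_helix_closed_form(self):
        spec = IdealHelixSpec(R=2.3, H=5.4, N=10)
        assert chi_total(generate_helix(spec)) == pytest.approx(
            chi_closed_form(spec), rel=1e-9
        )


class TestNormalizationFactor:
    def test_unit_vectors(self):
        assert normalization_factor((1, 0, 0), (0, 1, 0), (0, 0, 1)) == 1.0

    def test_mean_of_1_2_3_to_the_5th(self):
        assert normalization_factor((1, 0, 0), (0, 2, 0), (0, 0, 3)) == pytest.approx(32.0)

    def test_common_length_gives_length_pow_k(self):
        v = (0.0, 0.0, 1.7)
        assert normalization_factor(v, v, v, k=5) == pytest.approx(1.7 ** 5)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            normalization_factor((0, 0, 0), (1, 0, 0), (0, 1, 0))


class TestChiNorm:
    def test_uniform_steps_equal_global_normalization(self, alpha_like_chain):
        spec = IdealHelixSpec(R=2.3, H=5.4, N=10)
        expected = chi_total(alpha_like_chain) / step_length(spec) ** 5
        assert chi_norm(alpha_like_chain) == pytest.approx(expected, rel=1e-12)

    def test_mirror_is_exact_negation(self, rng):
        chain = PointChain(random_chain_coords(rng, 12))
        assert chi_norm(chain.mirrored()) == -chi_norm(chain)

    def test_short_chain_zero(self):
        assert chi_norm(PointChain([(0, 0, 0), (1, 0, 0), (1, 1, 0)])) == 0.0


class TestClassifyHandedness:
    @pytest.mark.parametrize(
        "value,sign,symbol",
        [
            (1.219, "positive", "D"),
            (-1.082, "negative", "L"),
            (0.0, "zero", "achiral"),
            (5e-10, "zero", "achiral"),  # below default epsilon
        ],
    )
    def test_classification(self, value, sign, symbol):
        hand = classify_handedness(value)
        assert (hand.sign, hand.symbol) == (sign, symbol)

    def test_custom_epsilon_boundary(self):
        assert classify_handedness(0.05, epsilon=0.1).sign == "zero"
        assert classify_handedness(0.2, epsilon=0.1).sign == "positive"

    def test_negative_epsilon_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_handedness(1.0, epsilon=-1.0)


class TestEvaluateChain:
    def test_result_is_internally_consistent(self, alpha_like_chain):
        res = evaluate_chain(alpha_like_chain)
        assert res.n_points == 11
        assert res.n_triples == 8
        assert res.chi_total > 0 and res.chi_norm > 0
        assert (res.sign, res.symbol) == ("positive", "D")


class TestStepwiseChirality:
    def test_prefixes_up_to_three_points_contribute_nothing(self, rng):
        table = stepwise_chirality(PointChain(random_chain_coords(rng, 6)))
        assert list(table["n_residues"]) == [1, 2, 3, 4, 5, 6]
        assert list(table["n_vectors"]) == [0, 1, 2, 3, 4, 5]
        assert list(table["n_triples"]) == [0, 0, 0, 1, 2, 3]
        assert (table["step_addition"][:3] == 0).all()
        assert (table["running_total"][:3] == 0).all()

    @pytest.mark.parametrize("normalized", [True, False])
    def test_running_total_telescopes_to_full_chain_value(self, rng, normalized):
        chain = PointChain(random_chain_coords(rng, 9))
        table = stepwise_chirality(chain, normalized=normalized)
        full = chi_norm(chain) if normalized else chi_total(chain)
        assert table["running_total"].iloc[-1] == pytest.approx(full, rel=1e-12)
        # each addition is exactly the newly available triple's term
        np.testing.assert_allclose(
            np.diff(table["running_total"]), table["step_addition"][1:], rtol=1e-12
        )


class TestGeometricInvariances:
    """The measure is a pseudoscalar: rigid motions and traversal reversal
    preserve it, improper transforms negate it, uniform scaling maps
    chi_total by s^3 and chi_norm (k=5) by s^-2."""

    N_CASES = 30

    def test_rigid_motion_invariance(self, rng):
        for _ in range(self.N_CASES):
            chain = PointChain(random_chain_coords(rng, int(rng.integers(4, 15))))
            rot = random_rotation(rng)
            shift = rng.normal(scale=50.0, size=3)
            moved = PointChain(chain.coords @ rot.T + shift)
            assert chi_total(moved) == pytest.approx(chi_total(chain), rel=1e-9)
            assert chi_norm(moved) == pytest.approx(chi_norm(chain), rel=1e-9)

    def test_reversal_invariance(self, rng):
        # negating all three vectors of a triple and transposing the triple
        # cancel: a helix traversed from either end keeps its handedness
        for _ in range(self.N_CASES):
            chain = PointChain(random_chain_coords(rng, int(rng.integers(4, 15))))
            assert chi_total(chain.reversed()) == pytest.approx(
                chi_total(chain), rel=1e-12
            )
            assert chi_norm(chain.reversed()) == pytest.approx(
                chi_norm(chain), rel=1e-12
            )

    def test_scaling_covariance(self, rng):
        for _ in range(self.N_CASES):
            chain = PointChain(random_chain_coords(rng, int(rng.integers(4, 15))))
            s = float(rng.uniform(0.2, 5.0))
            scaled = PointChain(chain.coords * s)
            assert chi_total(scaled) == pytest.approx(
                s ** 3 * chi_total(chain), rel=1e-9
            )
            assert chi_norm(scaled) == pytest.approx(
                s ** -2 * chi_norm(chain), rel=1e-9
            )

    def test_coplanar_chains_are_achiral(self, rng):
        for _ in range(self.N_CASES):
            # random planar chain embedded in a random 3D plane
            uv = rng.normal(size=(int(rng.integers(4, 12)), 2)).cumsum(axis=0)
            basis = random_rotation(rng)[:, :2]
            coords = uv @ basis.T + rng.normal(size=3)
            assert chi_total(PointChain(coords)) == pytest.approx(0.0, abs=1e-6)
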