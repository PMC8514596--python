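"""Envelope-modulation amplitude: closed forms, identities and oracles."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tifield.envelope import (
    DirectionError,
    FieldPairSample,
    RatioError,
    canonicalize_pair,
    directional_envelope,
    fibonacci_sphere,
    max_envelope,
    max_envelope_field,
    oracle_direction_grid,
    oracle_time_domain,
    tacs_amplitude_field,
    tacs_currents,
)
from tifield.fields import (
    EnvelopeField,
    FieldAlignmentError,
    VectorFieldSample,
)

finite_vec = arrays(
    np.float64, 3,
    elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestDirectionalEnvelope:
    @pytest.mark.parametrize(
        "e1, e2, n, expected",
        [
            ([1, 0, 0], [0.5, 0, 0], [1, 0, 0], 1.0),
            ([1, 0, 0], [0, 1, 0], [0, 0, 1], 0.0),
            ([1, 0, 0], [0, 1, 0], _unit([1, 1, 0]), np.sqrt(2)),
        ],
    )
    def test_known_values(self, e1, e2, n, expected):
        assert directional_envelope(e1, e2, n) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rejects_non_unit_direction(self):
        with pytest.raises(DirectionError):
            directional_envelope([1, 0, 0], [0, 1, 0], [1, 1, 0])

    def test_equals_twice_min_projection(self, rng):
        """The printed formula collapses algebraically to 2*min(|e1.n|, |e2.n|)."""
        for _ in range(200):
            e1, e2 = rng.normal(size=(2, 3))
            n = _unit(rng.normal(size=3))
            expected = 2.0 * min(abs(e1 @ n), abs(e2 @ n))
            assert directional_envelope(e1, e2, n) == pytest.approx(
                expected, rel=1e-12, abs=1e-15
            )

    @given(e1=finite_vec, e2=finite_vec, raw_n=finite_vec)
    def test_sign_flip_invariance(self, e1, e2, raw_n):
        if np.linalg.norm(raw_n) < 1e-6:
            raw_n = np.array([0.0, 0.0, 1.0])
        n = _unit(raw_n)
        base = directional_envelope(e1, e2, n)
        for f1, f2, fn in [(-1, 1, 1), (1, -1, 1), (1, 1, -1), (-1, -1, -1)]:
            assert directional_envelope(f1 * e1, f2 * e2, fn * n) == pytest.approx(
                base, rel=1e-12, abs=1e-12
            )


class TestCanonicalization:
    def test_orders_and_aligns(self, rng):
        e1 = rng.normal(size=(50, 3))
        e2 = rng.normal(size=(50, 3)) * 3.0
        a1, a2 = canonicalize_pair(e1, e2)
        m1 = np.linalg.norm(a1, axis=1)
        m2 = np.linalg.norm(a2, axis=1)
        assert np.all(m1 >= m2)
        assert np.all(np.einsum("ij,ij->i", a1, a2) >= 0)

    def test_alpha_acute(self, rng):
        pair = FieldPairSample(rng.normal(size=3), rng.normal(size=3))
        assert 0.0 <= pair.alpha <= np.pi / 2 + 1e-12

    def test_alpha_matches_arccos(self, rng):
        e1, e2 = rng.normal(size=(2, 3))
        pair = FieldPairSample(e1, e2)
        cos_a = (pair.e1 @ pair.e2) / (
            np.linalg.norm(pair.e1) * np.linalg.norm(pair.e2)
        )
        assert pair.alpha == pytest.approx(np.arccos(np.clip(cos_a, -1, 1)),
                                           abs=1e-12)


class TestMaxEnvelope:
    @pytest.mark.parametrize(
        "e1, e2, expected",
        [
            ([1, 0, 0], [0.5, 0, 0], 1.0),     # collinear: first branch, 2|e2|
            ([1, 0, 0], [1, 0, 0], 2.0),       # degenerate equal fields
            ([1, 0, 0], [0, 1, 0], np.sqrt(2)),  # orthogonal: second branch
            ([1, 0, 0], [-0.6, 0, 0], 1.2),    # polarity flip then first branch
        ],
    )
    def test_known_values(self, e1, e2, expected):
        assert max_envelope(e1, e2) == pytest.approx(expected, abs=1e-12)

    def test_zero_fields(self):
        assert max_envelope([0, 0, 0], [0, 0, 0]) == 0.0

    @given(e1=finite_vec, e2=finite_vec)
    def test_symmetry_and_bound(self, e1, e2):
        v = max_envelope(e1, e2)
        assert v == pytest.approx(max_envelope(e2, e1), rel=1e-12, abs=1e-12)
        bound = 2.0 * min(np.linalg.norm(e1), np.linalg.norm(e2))
        assert v <= bound + 1e-9 * max(1.0, bound)

    def test_collinear_attains_bound(self, rng):
        for _ in range(20):
            e = rng.normal(size=3)
            c = rng.uniform(0.1, 2.0)
            assert max_envelope(e, c * e) == pytest.approx(
                2.0 * min(1.0, c) * np.linalg.norm(e), rel=1e-12
            )

    def test_homogeneity(self, rng):
        e1, e2 = rng.normal(size=(2, 3))
        base = max_envelope(e1, e2)
        for c in (0.5, 3.0, 100.0):
            assert max_envelope(c * e1, c * e2) == pytest.approx(
                c * base, rel=1e-12
            )

    def test_matches_direction_grid_oracle(self, rng):
        for _ in range(50):
            e1, e2 = rng.normal(size=(2, 3))
            closed = max_envelope(e1, e2)
            grid = oracle_direction_grid(e1, e2, m=20_000)
            assert grid <= closed * (1 + 1e-12)
            assert closed == pytest.approx(grid, rel=1e-2)

    def test_oracle_converges_with_grid_density(self, rng):
        e1, e2 = rng.normal(size=(2, 3))
        closed = max_envelope(e1, e2)
        gaps = [closed - oracle_direction_grid(e1, e2, m) for m in
                (500, 2_000, 8_000, 32_000)]
        assert all(g >= -1e-12 * closed for g in gaps)
        assert gaps[-1] < gaps[0]

    def test_vectorized_matches_scalar_loop(self, rng):
        e1 = rng.normal(size=(100, 3))
        e2 = rng.normal(size=(100, 3))
        vec = max_envelope(e1, e2)
        loop = np.array([max_envelope(a, b) for a, b in zip(e1, e2)])
        np.testing.assert_allclose(vec, loop, rtol=1e-14)


class TestEnvelopeFieldOps:
    def _sample(self, points, vectors):
        return VectorFieldSample(points, vectors)

    def test_identical_uniform_fields(self, rng):
        pts = rng.normal(size=(20, 3))
        vec = np.tile([0.0, 0.0, 0.3], (20, 1))
        env = max_envelope_field(self._sample(pts, vec), self._sample(pts, vec))
        np.testing.assert_allclose(env.amplitude, 0.6, rtol=1e-14)
        assert env.mode == "ttis_envelope"

    def test_zero_second_field(self, rng):
        pts = rng.normal(size=(20, 3))
        vec = rng.normal(size=(20, 3))
        env = max_envelope_field(
            self._sample(pts, vec), self._sample(pts, np.zeros((20, 3)))
        )
        np.testing.assert_allclose(env.amplitude, 0.0)

    def test_mismatched_points_rejected(self, rng):
        pts = rng.normal(size=(20, 3))
        vec = rng.normal(size=(20, 3))
        with pytest.raises(FieldAlignmentError):
            max_envelope_field(
                self._sample(pts, vec), self._sample(pts + 1.0, vec)
            )

    def test_tacs_collinear_and_cancelling(self, rng):
        pts = rng.normal(size=(10, 3))
        vec = np.tile([0.2, 0.0, 0.0], (10, 1))
        same = tacs_amplitude_field(
            self._sample(pts, vec), self._sample(pts, vec), ratio=1.0,
            total_mA=2.0,
        )
        np.testing.assert_allclose(same.amplitude, 0.4, rtol=1e-14)
        assert same.mode == "tacs_amplitude"
        opp = tacs_amplitude_field(
            self._sample(pts, vec), self._sample(pts, -vec), ratio=1.0,
            total_mA=2.0,
        )
        np.testing.assert_allclose(opp.amplitude, 0.0, atol=1e-15)

    def test_tacs_current_split(self):
        # ratio 0.1 under the 2 mA budget: approximately 0.18 / 1.8 mA
        i1, i2 = tacs_currents(0.1, 2.0)
        assert i1 == pytest.approx(0.18181818, rel=1e-6)
        assert i2 == pytest.approx(1.81818181, rel=1e-6)
        assert i1 + i2 == pytest.approx(2.0, rel=1e-12)
        assert i1 / i2 == pytest.approx(0.1, rel=1e-12)

    def test_invalid_ratio(self, rng):
        pts = rng.normal(size=(5, 3))
        f = self._sample(pts, rng.normal(size=(5, 3)))
        for bad in (0.0, -1.0, np.nan):
            with pytest.raises(RatioError):
                tacs_amplitude_field(f, f, ratio=bad)


class TestTimeDomainOracle:
    def test_full_modulation(self):
        # equal projections -> envelope swings between 2A and 0
        assert oracle_time_domain(
            [0.5, 0, 0], [0.5, 0, 0], [1, 0, 0]
        ) == pytest.approx(1.0, rel=1e-3)

    def test_unmodulated_carrier(self):
        assert oracle_time_domain([1, 0, 0], [0, 1, 0], [1, 0, 0]) == (
            pytest.approx(0.0, abs=1e-3)
        )

    def test_matches_formula_on_random_pairs(self, rng):
        for _ in range(20):
            e1, e2 = rng.normal(size=(2, 3))
            n = _unit(rng.normal(size=3))
            expected = directional_envelope(e1, e2, n)
            simulated = oracle_time_domain(e1, e2, n, f1=1000.0, f2=1010.0)
            assert simulated == pytest.approx(expected, rel=1e-3, abs=1e-6)

    def test_rejects_bad_sampling(self):
        with pytest.raises(ValueError):
            oracle_time_domain([1, 0, 0], [0, 1, 0], [1, 0, 0], fs=1000.0)
        with pytest.raises(ValueError):
            oracle_time_domain([1, 0, 0], [0, 1, 0], [1, 0, 0], duration=0.01)
        with pytest.raises(ValueError):
            oracle_time_domain([1, 0, 0], [0, 1, 0], [1, 0, 0],
                               f1=1010.0, f2=1000.0)


def test_fibonacci_sphere_is_unit_and_spread():
    dirs = fibonacci_sphere(1000)
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, rtol=1e-12)
    # quasi-uniform: mean direction near zero
    assert np.linalg.norm(dirs.mean(axis=0)) < 0.01


def test_envelope_field_rejects_negative_amplitude(rng):
    pts = rng.normal(size=(5, 3))
    with pytest.raises(ValueError):
        EnvelopeField(pts, np.array([0.1, -0.2, 0.3, 0.1, 0.0]))
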