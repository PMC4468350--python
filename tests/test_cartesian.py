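import numpy as np
import pytest

from liemarkov import (CartesianParams, basis_matrix, cartesian_to_rate,
                       enumerate_rays, get_model, in_model_span,
                       is_stochastic, rate_to_cartesian, raysum_sample,
                       sample_stochastic)
from liemarkov.rates import OFFDIAG_MASK

MODELS = ["1.1", "RY2.2b", "3.3a", "RY3.4", "4.4a", "RY5.6b",
          "WS5.7c", "MK6.6", "RY8.8", "9.20b", "RY10.12", "12.12"]


def test_b_zero_maps_to_jc():
    for name in MODELS:
        m = get_model(name)
        Q = cartesian_to_rate(CartesianParams(m, np.zeros(m.dimension - 1)))
        np.testing.assert_allclose(Q, basis_matrix("A"), atol=1e-12)


def test_wrong_parameter_count():
    with pytest.raises(ValueError, match="parameters"):
        CartesianParams(get_model("RY5.6b"), [0.1, 0.2])


def test_out_of_hypercube():
    with pytest.raises(ValueError, match=r"\[-1, 1\]"):
        CartesianParams(get_model("RY2.2b"), [1.5])


@pytest.mark.parametrize("name", MODELS)
def test_output_trace_minus_12_stochastic_in_model(name, rng):
    m = get_model(name)
    for _ in range(50):
        b = rng.uniform(-1, 1, m.dimension - 1)
        Q = cartesian_to_rate(CartesianParams(m, b))
        assert np.trace(Q) == pytest.approx(-12.0, abs=1e-9)
        assert is_stochastic(Q)
        ok, resid = in_model_span(Q, m)
        assert ok, (name, resid)


def test_boundary_gives_zero_offdiagonal(rng):
    for name in MODELS[1:]:
        m = get_model(name)
        b = rng.uniform(-1, 1, m.dimension - 1)
        b[rng.integers(m.dimension - 1)] = np.sign(rng.normal()) or 1.0
        Q = cartesian_to_rate(CartesianParams(m, b))
        assert abs(Q[OFFDIAG_MASK].min()) < 1e-10


@pytest.mark.parametrize("name", MODELS)
def test_round_trip(name, rng):
    m = get_model(name)
    for _ in range(100):
        b = rng.uniform(-1, 1, m.dimension - 1)
        Q = cartesian_to_rate(CartesianParams(m, b))
        b2 = rate_to_cartesian(Q, m).b
        Q2 = cartesian_to_rate(CartesianParams(m, b2))
        assert np.abs(Q2 - Q).max() < 1e-10, name


def test_inverse_rejects_wrong_trace():
    with pytest.raises(ValueError, match="trace"):
        rate_to_cartesian(2.0 * basis_matrix("A"), get_model("1.1"))


def test_inverse_rejects_outside_model():
    Q = cartesian_to_rate(CartesianParams(get_model("RY5.6b"),
                                          [0.5, 0.2, 0.1, -0.3]))
    with pytest.raises(ValueError, match="not in model"):
        rate_to_cartesian(Q, get_model("RY2.2b"))


def test_injectivity_on_grid_small_model():
    m = get_model("RY2.2b")
    grid = np.linspace(-1, 1, 41)
    outputs = [cartesian_to_rate(CartesianParams(m, [g])) for g in grid]
    for i in range(len(grid)):
        for j in range(i + 1, len(grid)):
            assert np.abs(outputs[i] - outputs[j]).max() > 1e-8


def test_sample_stochastic_trace_and_membership(rng):
    m = get_model("RY8.8")
    for Q in sample_stochastic(m, trace=-2.5, n=20, seed=rng):
        assert np.trace(Q) == pytest.approx(-2.5)
        assert is_stochastic(Q)
        assert in_model_span(Q, m)[0]


def test_sample_stochastic_jc_is_constant():
    Qs = sample_stochastic(get_model("1.1"), trace=-4.0, n=3, seed=0)
    for Q in Qs:
        np.testing.assert_allclose(Q, basis_matrix("A") / 3.0, atol=1e-12)


def test_sample_stochastic_reproducible():
    m = get_model("RY5.6b")
    a = sample_stochastic(m, -4.0, 5, seed=42)
    b = sample_stochastic(m, -4.0, 5, seed=42)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_sample_stochastic_requires_negative_trace():
    with pytest.raises(ValueError):
        sample_stochastic(get_model("1.1"), trace=1.0)


def test_ray_counts_spot():
    for name, count in (("RY5.6b", 6), ("RY3.4", 4), ("12.12", 12),
                        ("RY5.16", 16), ("1.1", 1)):
        assert len(enumerate_rays(get_model(name))) == count, name


def test_rays_are_stochastic_extreme(rng):
    m = get_model("RY5.6b")
    rays = enumerate_rays(m)
    for Q in rays:
        assert is_stochastic(Q)
        assert np.trace(Q) == pytest.approx(-4.0)
        assert in_model_span(Q, m)[0]
        # extreme: at least dim-1 active (zero) off-diagonal constraints
        assert (np.abs(Q[OFFDIAG_MASK]) < 1e-9).sum() >= m.dimension - 1
    # no ray is a nonnegative combination of the others
    from scipy.optimize import nnls
    for i, Q in enumerate(rays):
        others = np.array([r.ravel() for j, r in enumerate(rays)
                           if j != i]).T
        _, resid = nnls(others, Q.ravel())
        assert resid > 1e-6, f"ray {i} is redundant"


def test_12_12_rays_are_single_entry_generators():
    rays = enumerate_rays(get_model("12.12"))
    for Q in rays:
        off = Q[OFFDIAG_MASK]
        assert (off > 1e-9).sum() == 1


def test_raysum_sample_stochastic_and_in_model(rng):
    m = get_model("RY5.6b")
    rays = enumerate_rays(m)
    Q = raysum_sample(m, seed=3, rays=rays)
    assert is_stochastic(Q)
    assert in_model_span(Q, m)[0]
    # single-ray weights reproduce that ray
    w = np.zeros(len(rays))
    w[2] = 1.0
    np.testing.assert_allclose(raysum_sample(m, rays=rays, weights=w),
                               rays[2], atol=1e-12)
    with pytest.raises(ValueError):
        raysum_sample(m, rays=rays, weights=-w)


def test_coverage_random_weight_members_have_preimage(rng):
    # rejection-sample raw basis weights; every stochastic trace -12
    # member must round-trip through the hypercube
    m = get_model("RY5.6b")
    found = 0
    while found < 25:
        w = rng.normal(size=m.dimension)
        from liemarkov import from_weights, normalize
        Q = from_weights(m, w)
        if not is_stochastic(Q, tol=0.0) or np.trace(Q) >= -1e-9:
            continue
        Q = normalize(Q, -12.0)
        found += 1
        b = rate_to_cartesian(Q, m).b
        Q2 = cartesian_to_rate(CartesianParams(m, b))
        assert np.abs(Q2 - Q).max() < 1e-9
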