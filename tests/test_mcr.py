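"""The alternating-least-squares curve resolution solver: initialization,
exact factorizations, parameter recovery, convergence bookkeeping and
reference matching."""

import numpy as np
import pytest

from sersscreen import MCRConfig, fit, initialize, match_components, nnls_solve
from sersscreen.mcr import cosine_similarity, pure_variables


def lorentz(grid, c, fwhm=12.0):
    return 1.0 / (1.0 + (2.0 * (grid - c) / fwhm) ** 2)


GRID = np.arange(400.0, 1400.0, 2.0)


def two_component_truth(seed, n=30, noise=0.0):
    """Mixture of two spectra with disjoint band sets and random positive
    contributions — the generator truth for recovery tests."""
    rng = np.random.default_rng(seed)
    s1 = lorentz(GRID, 600) + 0.6 * lorentz(GRID, 700)
    s2 = lorentz(GRID, 1000) + 0.5 * lorentz(GRID, 1200)
    C = rng.uniform(0.1, 2.0, size=(n, 2))
    D = C @ np.vstack([s1, s2])
    if noise:
        D = D + noise * rng.standard_normal(D.shape)
    return np.maximum(D, 0.0), C, np.vstack([s1, s2])


def test_initialize_single_reference_is_the_reference():
    D, _, S_true = two_component_truth(0)
    ref = S_true[0] / S_true[0].max()
    _, S0 = initialize(D, {"a": ref}, MCRConfig(n_components=1))
    np.testing.assert_allclose(S0[0], ref)


def test_initialize_deterministic_under_seed():
    D, _, _ = two_component_truth(1, noise=0.05)
    cfg = MCRConfig(n_components=3, seed=5, init="random")
    C0a, S0a = initialize(D, None, cfg)
    C0b, S0b = initialize(D, None, cfg)
    np.testing.assert_array_equal(S0a, S0b)
    np.testing.assert_array_equal(C0a, C0b)


def test_pure_variables_pick_channels_of_distinct_components():
    """On a noiseless 2-component mixture the selected pure channels fall
    inside the band support of different true components."""
    D, _, S_true = two_component_truth(2)
    picks = pure_variables(D, 2)
    supports = [S_true[i] > 0.05 for i in range(2)]
    owners = set()
    for j in picks:
        owners.update(i for i in range(2) if supports[i][j])
    assert owners == {0, 1}


def test_k_too_large_rejected():
    D, _, _ = two_component_truth(0, n=4)
    with pytest.raises(ValueError):
        initialize(D, None, MCRConfig(n_components=5))


def test_rank_one_exact_factorization():
    rng = np.random.default_rng(0)
    c = rng.uniform(0.5, 2.0, size=12)
    s = lorentz(GRID, 800) + 0.3 * lorentz(GRID, 1100)
    D = np.outer(c, s)
    res = fit(D, refs=None, config=MCRConfig(n_components=1, init="random", seed=0))
    assert res.lof < 1e-6
    assert cosine_similarity(res.S[0], s) > 0.9999
    assert res.converged


def test_two_component_recovery_noiseless():
    D, C_true, S_true = two_component_truth(3)
    res = fit(D, refs=None, config=MCRConfig(n_components=2, init="random", seed=3))
    # match recovered to truth by best cosine
    for i in range(2):
        best = max(cosine_similarity(res.S[j], S_true[i]) for j in range(2))
        assert best >= 0.99


def test_lof_trace_monotone_nonincreasing():
    D, _, _ = two_component_truth(4, noise=0.02)
    res = fit(D, refs=None, config=MCRConfig(n_components=3, init="random", seed=4))
    trace = np.array(res.lof_percent)
    assert np.all(np.diff(trace) <= 1e-9 * trace[0] + 1e-12)


def test_scale_ambiguity_resolved_row_max_one():
    D, _, _ = two_component_truth(5, noise=0.02)
    res = fit(D, refs=None, config=MCRConfig(n_components=2, init="random", seed=5))
    np.testing.assert_allclose(res.S.max(axis=1), 1.0)
    assert res.C.min() >= 0.0 and res.S.min() >= 0.0
    # refitting the contributions from the returned S leaves the lack of fit
    # unchanged: the returned C is already the constrained minimizer
    C2 = nnls_solve(res.S.T, D.T).T
    lof2 = 100.0 * np.linalg.norm(D - C2 @ res.S) / np.linalg.norm(D)
    assert abs(lof2 - res.lof) < 1e-8


def test_objective_matches_multiplicative_update_oracle():
    """On tiny random matrices the ALS solution's objective agrees with
    sklearn's multiplicative-update NMF run to tight convergence from the
    same initialization."""
    from sklearn.decomposition import NMF

    rng = np.random.default_rng(0)
    for trial in range(8):
        D = rng.uniform(0.1, 1.0, size=(4, 3))
        cfg = MCRConfig(n_components=2, init="random", seed=trial, tol=1e-12, max_iter=2000)
        C0, S0 = initialize(D, None, cfg)
        res = fit(D, refs=None, config=cfg)
        obj_als = np.linalg.norm(D - res.C @ res.S)
        model = NMF(
            n_components=2, init="custom", solver="mu", beta_loss="frobenius",
            tol=1e-14, max_iter=200_000,
        )
        W = model.fit_transform(D, W=np.maximum(C0, 1e-6), H=np.maximum(S0, 1e-6))
        obj_mu = np.linalg.norm(D - W @ model.components_)
        assert obj_als <= obj_mu + 1e-6


def test_nonconvergence_reported():
    D, _, _ = two_component_truth(6, noise=0.05)
    res = fit(D, refs=None, config=MCRConfig(n_components=2, init="random", seed=6, max_iter=2))
    assert res.n_iter == 2 and not res.converged


def test_nonfinite_data_rejected():
    D = np.ones((4, 8))
    D[0, 0] = np.nan
    with pytest.raises(ValueError):
        fit(D, refs=None, config=MCRConfig(n_components=1))


def test_match_components_exact_and_orthogonal():
    s1 = lorentz(GRID, 600)
    s2 = lorentz(GRID, 1200)
    S = np.vstack([s1, s2])
    a = match_components(S, {"x": s1}, threshold=0.7)
    assert a.component_for("x") == 0
    assert a.similarity["x"] == pytest.approx(1.0)
    far = lorentz(GRID, 900, fwhm=8)
    b = match_components(S, {"y": far}, threshold=0.7)
    assert not b.is_assigned("y")
    assert b.similarity["y"] < 0.1


def test_match_components_tie_breaks_to_lower_index():
    s = lorentz(GRID, 800)
    S = np.vstack([s, s])
    a = match_components(S, {"x": s}, threshold=0.7)
    assert a.component_for("x") == 0
    assert a.components_matching("x", 0.99) == [0, 1]


@pytest.mark.parametrize(
    "kwargs", [{"n_components": 0}, {"max_iter": 0}, {"tol": 0.0}, {"init": "magic"}]
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        MCRConfig(**kwargs)
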