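"""OPLS-DA model: oracle equivalence, VIP normalization, screen semantics
and the correlation network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import organmap as om
from organmap.oplsda import predict, two_sample_pvalues

from conftest import make_metabolite_matrix


def _random_matrix(seed, n_feat=10, n_con=6, n_rpa=6, effect=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(10, 1, (n_feat, n_con + n_rpa))
    x[:, n_con:] += effect
    return make_metabolite_matrix(x, n_con, n_rpa)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def test_perfect_predictor_gives_r2y_one():
    """A feature equal to the class indicator makes the model separable:
    once the y-orthogonal X variation is filtered out (here all 4 possible
    orthogonal components of the 5-feature matrix), R2Y = 1 within
    numerical tolerance, and R2Y increases monotonically toward that limit
    as components are added."""
    rng = np.random.default_rng(1)
    x = rng.normal(10, 1, (5, 12))
    x[0] = np.r_[np.zeros(6), np.ones(6)]
    m = make_metabolite_matrix(x, 6, 6)
    r2y = [om.fit_oplsda(m, n_ortho=k, cv_folds=3).r2y for k in range(5)]
    assert r2y[4] == pytest.approx(1.0, abs=1e-6)
    assert all(b >= a - 1e-12 for a, b in zip(r2y, r2y[1:]))


def test_single_class_errors():
    x = np.random.default_rng(2).normal(size=(4, 6))
    m = make_metabolite_matrix(x, 6, 0)
    with pytest.raises(ValueError, match="[Ss]ingle|both"):
        om.fit_oplsda(m)


def test_constant_feature_dropped_with_warning():
    rng = np.random.default_rng(3)
    x = rng.normal(10, 1, (5, 12))
    x[2] = 7.0
    m = make_metabolite_matrix(x, 6, 6)
    with pytest.warns(UserWarning, match="constant"):
        model = om.fit_oplsda(m)
    assert "f2" in model.dropped_features
    assert len(model.feature_ids) == 4


def test_n_ortho_zero_matches_independent_nipals_pls_oracle():
    """With no orthogonal filtering the model is single-component PLS-DA;
    its predictions must equal an independently coded NIPALS PLS1 on a
    fixed 5-sample x 4-feature toy matrix (and sklearn's PLS as a second
    cross-check)."""
    x = np.array(
        [
            [1.0, 4.2, 0.5, 3.3],
            [2.1, 3.9, 0.7, 3.1],
            [1.4, 4.4, 0.9, 2.8],
            [3.6, 2.0, 2.2, 1.1],
            [3.9, 1.8, 2.0, 0.9],
        ]
    )  # samples x features
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
    m = make_metabolite_matrix(x.T, 3, 2)

    model = om.fit_oplsda(m, n_ortho=0, cv_folds=2, scaling="center")
    pred_model = predict(model, m)

    # independent NIPALS PLS1, one component, mean-centered
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    w = xc.T @ yc
    w = w / np.linalg.norm(w)
    t = xc @ w
    c = (yc @ t) / (t @ t)
    pred_oracle = (xc @ w) * c + y.mean()
    np.testing.assert_allclose(pred_model, pred_oracle, atol=1e-10)

    sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
    pls = sklearn_pls.PLSRegression(n_components=1, scale=False).fit(x, y)
    np.testing.assert_allclose(pred_model, pls.predict(x).ravel(), atol=1e-8)


def test_orthogonal_scores_are_orthogonal_to_predictive():
    for seed in range(5):
        m = _random_matrix(seed, n_feat=15, effect=1.0)
        model = om.fit_oplsda(m, n_ortho=2)
        for a in range(model.scores_ortho.shape[1]):
            inner = float(model.scores_pred @ model.scores_ortho[:, a])
            assert abs(inner) < 1e-8 * max(1, np.linalg.norm(model.scores_pred))


def test_r2x_nondecreasing_in_n_ortho():
    m = _random_matrix(7, n_feat=12, effect=0.8)
    r2x = [om.fit_oplsda(m, n_ortho=k).r2x for k in range(4)]
    assert all(b >= a - 1e-10 for a, b in zip(r2x, r2x[1:]))


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_vip_normalization_and_q2_bound_on_random_models(seed):
    """mean(VIP^2) = 1 and Q2 <= R2Y on arbitrary random data."""
    m = _random_matrix(seed, n_feat=8, effect=0.5)
    model = om.fit_oplsda(m, cv_folds=3)
    assert float(np.mean(model.vip**2)) == pytest.approx(1.0, abs=1e-9)
    assert model.q2 <= model.r2y + 1e-10


def test_vip_trivial_cases():
    # one-feature model: normalization forces VIP = 1
    m = _random_matrix(11, n_feat=1, effect=2.0)
    model = om.fit_oplsda(m, n_ortho=0)
    assert model.vip == pytest.approx([1.0])


def test_vip_matches_hand_computed_formula_on_toy_model():
    """Six-feature model: VIP_j = sqrt(p) * |w_j| / ||w|| with w computed
    directly from the preprocessed data by the defining formula."""
    m = _random_matrix(13, n_feat=6, effect=1.0)
    model = om.fit_oplsda(m, n_ortho=0, scaling="uv")
    x = m.x_samples_by_features()
    xc = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    y = m.y_binary()
    w = xc.T @ (y - y.mean())
    vip_hand = np.sqrt(6) * np.abs(w) / np.linalg.norm(w)
    np.testing.assert_allclose(om.compute_vip(model), vip_hand, atol=1e-10)


# --------------------------------------------------------------------------
# screen
# --------------------------------------------------------------------------


def test_screen_excludes_vip_exactly_at_threshold():
    m = _random_matrix(17, n_feat=5, effect=0.0)
    model = om.fit_oplsda(m)
    vip = model.vip_series()
    pvals = two_sample_pvalues(m)
    # thresholds chosen at one feature's exact values: strict inequalities
    # must exclude it
    probe = model.feature_ids[0]
    hits = om.screen_metabolites(
        model, m, vip_threshold=float(vip[probe]), alpha=float(pvals[probe])
    )
    assert probe not in [h.name for h in hits]


def test_screen_sorted_descending_and_order_invariant():
    m = _random_matrix(19, n_feat=12, effect=1.5)
    model = om.fit_oplsda(m)
    hits = om.screen_metabolites(model, m, vip_threshold=0.5, alpha=0.5)
    vips = [h.vip_score for h in hits]
    assert vips == sorted(vips, reverse=True)

    perm = np.random.default_rng(0).permutation(12)
    m_perm = make_metabolite_matrix(
        m.values.to_numpy()[perm], 6, 6,
        feature_ids=[m.feature_ids[i] for i in perm],
    )
    hits_perm = om.screen_metabolites(
        om.fit_oplsda(m_perm), m_perm, vip_threshold=0.5, alpha=0.5
    )
    assert {h.name for h in hits_perm} == {h.name for h in hits}


def test_screen_recovers_injected_differentials_with_no_false_positives():
    """16 injected features at large effect among 20: >= 14 recovered and
    no null feature screened in at this feature count."""
    config = om.SimulationConfig(
        n_metab_features=20, n_true_diff_metab=16, metab_effect_size=4.0, seed=23
    )
    m, truth = om.simulate_metabolome(config)
    model = om.fit_oplsda(m)
    hits = {h.name for h in om.screen_metabolites(model, m)}
    assert len(hits & set(truth.feature_ids)) >= 14
    assert not hits - set(truth.feature_ids)


# --------------------------------------------------------------------------
# correlation network
# --------------------------------------------------------------------------


def test_duplicated_feature_gives_perfect_edge():
    rng = np.random.default_rng(29)
    x = rng.normal(10, 1, (4, 9))
    x[1] = x[0]
    m = make_metabolite_matrix(x, 5, 4)
    net = om.correlation_network(m, r_threshold=0.9, alpha=0.05)
    edge = {(a, b): r for a, b, r, p, s in net.edges}
    assert edge.get(("f0", "f1")) == pytest.approx(1.0)


def test_constant_feature_excluded_with_warning():
    rng = np.random.default_rng(31)
    x = rng.normal(10, 1, (4, 9))
    x[3] = 2.0
    m = make_metabolite_matrix(x, 5, 4)
    with pytest.warns(UserWarning, match="constant"):
        net = om.correlation_network(m)
    assert "f3" not in net.nodes


def test_independent_features_rarely_linked_under_bonferroni():
    """Expected false edges < 1 in total over 100 null simulations at
    Bonferroni-corrected alpha."""
    n_feat, n_samp = 8, 12
    n_pairs = n_feat * (n_feat - 1) // 2
    total_edges = 0
    for seed in range(100):
        x = np.random.default_rng(1000 + seed).normal(0, 1, (n_feat, n_samp))
        m = make_metabolite_matrix(x, 6, 6)
        net = om.correlation_network(
            m, r_threshold=0.0, alpha=0.05 / n_pairs, adjust="none"
        )
        total_edges += len(net.edges)
    # expected false edges per network < 0.05 under Bonferroni; over 100
    # networks the expected total is ~5, so a generous Monte-Carlo bound:
    assert total_edges / 100 < 1

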