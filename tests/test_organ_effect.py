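"""Organ effect model: PC01 summary, amplification, fuzzy weighting and
radar scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import organmap as om
from organmap.containers import ExpressionMatrix
from organmap.organ_effect import contribution_rates, results_to_frame


def _expr(values, n_con, n_rpa, organ="liver"):
    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{i}" for i in range(n_con + n_rpa)]
    return ExpressionMatrix(
        values=pd.DataFrame(
            values, index=[f"g{i}" for i in range(values.shape[0])], columns=sample_ids
        ),
        group_labels=pd.Series(["CON"] * n_con + ["RPA"] * n_rpa, index=sample_ids),
        organ=organ,
    )


def _summary(con_scores, rpa_scores, organ="liver", rate=0.9):
    scores = list(con_scores) + list(rpa_scores)
    idx = [f"s{i}" for i in range(len(scores))]
    return om.PcaSummary(
        organ=organ,
        pc01_scores=pd.Series(scores, index=idx, dtype=float),
        contribution_rate=rate,
        group_labels=pd.Series(
            ["CON"] * len(con_scores) + ["RPA"] * len(rpa_scores), index=idx
        ),
    )


# --------------------------------------------------------------------------
# PCA summary
# --------------------------------------------------------------------------


def test_rank_one_data_has_unit_contribution_rate():
    base = np.full((5, 6), 3.0)
    base[0] = [1, 2, 3, 4, 5, 6]  # variation along a single gene only
    summary = om.pc01_summary(_expr(base, 3, 3))
    assert summary.contribution_rate == pytest.approx(1.0)


def test_contribution_rates_sum_to_one():
    rng = np.random.default_rng(2)
    rates = contribution_rates(_expr(np.exp2(rng.normal(5, 1, (40, 6))), 3, 3))
    assert rates.sum() == pytest.approx(1.0)


def test_constant_matrix_has_no_principal_axis():
    with pytest.raises(ValueError, match="principal axis"):
        om.pc01_summary(_expr(np.full((4, 6), 2.0), 3, 3))


def test_strong_group_shift_gives_high_contribution_rate():
    """A simulated organ with a strong treatment shift concentrates most
    variance on PC01 (> 0.7)."""
    config = om.SimulationConfig(seed=5)
    m, _ = om.simulate_organ_expression(config, "liver")
    summary = om.pc01_summary(m)
    assert summary.contribution_rate > 0.7


# --------------------------------------------------------------------------
# amplification
# --------------------------------------------------------------------------


def test_amplification_hand_example():
    # (3 - 0) / (5 - (-2)) = 3/7
    s = _summary([-2, 0, 2], [1, 3, 5])
    assert om.amplification(s) == pytest.approx(3 / 7)


def test_amplification_zero_for_identical_means():
    s = _summary([-1, 0, 1], [1, 0, -1])
    assert om.amplification(s) == pytest.approx(0.0)


def test_amplification_is_one_when_groups_sit_at_extremes():
    s = _summary([0], [1])
    assert om.amplification(s) == pytest.approx(1.0)


def test_amplification_zero_range_errors_naming_organ():
    s = _summary([2, 2], [2, 2], organ="spleen")
    with pytest.raises(ValueError, match="spleen"):
        om.amplification(s)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.floats(min_value=0.01, max_value=100),
    st.floats(min_value=-50, max_value=50),
)
def test_amplification_affine_invariance(slope, intercept):
    """y_i is invariant under positive affine transforms of the scores and
    flips sign under negative slope, so |y_i| is PCA-sign-proof."""
    s = _summary([-2.0, 0.5, 2.0], [1.0, 3.0, 4.5])
    base = om.amplification(s)
    s_pos = _summary(
        [slope * v + intercept for v in [-2.0, 0.5, 2.0]],
        [slope * v + intercept for v in [1.0, 3.0, 4.5]],
    )
    assert om.amplification(s_pos) == pytest.approx(base, rel=1e-9, abs=1e-12)
    s_neg = _summary(
        [-slope * v + intercept for v in [-2.0, 0.5, 2.0]],
        [-slope * v + intercept for v in [1.0, 3.0, 4.5]],
    )
    assert om.amplification(s_neg) == pytest.approx(-base, rel=1e-9, abs=1e-12)


def test_pc01_bounds_amplification():
    """|y_i| <= 1 by construction on simulated data."""
    config = om.SimulationConfig(seed=9)
    for organ in config.organs:
        m, _ = om.simulate_organ_expression(config, organ)
        assert abs(om.amplification(om.pc01_summary(m))) <= 1.0


# --------------------------------------------------------------------------
# fuzzy weighting
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected",
    [
        (920, (0.0, 0.0, 0.0, 1.0)),
        (350, (0.5, 0.5, 0.0, 0.0)),
        (626, (0.0, 0.24, 0.76, 0.0)),
        (0, (1.0, 0.0, 0.0, 0.0)),
        (475, (0.0, 1.0, 0.0, 0.0)),
        (700, (0.0, 0.0, 1.0, 0.0)),
    ],
)
def test_membership_values(x, expected):
    assert om.memberships(x) == pytest.approx(expected)


def test_negative_count_errors():
    with pytest.raises(ValueError):
        om.memberships(-1)


@settings(derandomize=True, max_examples=300, deadline=None)
@given(st.integers(min_value=0, max_value=2000))
def test_partition_of_unity(x):
    mu = om.memberships(x)
    assert sum(mu) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= v <= 1.0 for v in mu)


@pytest.mark.parametrize(
    "x, weight",
    [(920, 0.9), (626, 0.7), (350, 0.5), (0, 0.3), (250, 0.3), (850, 0.9)],
)
def test_assign_weight_examples(x, weight):
    assert om.assign_weight(x) == weight


def test_tie_rule_policies():
    spec_low = om.FuzzyWeightSpec(tie_rule="lower")
    assert om.assign_weight(350) == 0.5  # default: larger weight wins ties
    assert om.assign_weight(350, spec_low) == 0.3
    assert om.assign_weight(600, spec_low) == 0.5
    assert om.assign_weight(600) == 0.7


def test_assign_weight_monotone_under_default_tie_rule():
    weights = [om.assign_weight(x) for x in range(0, 1200)]
    assert all(b >= a for a, b in zip(weights, weights[1:]))


def test_invalid_fuzzy_specs_rejected():
    with pytest.raises(ValueError):
        om.FuzzyWeightSpec(breakpoints=(300, 400, 550, 650, 800))
    with pytest.raises(ValueError):
        om.FuzzyWeightSpec(weights=(0.9, 0.7, 0.5, 0.3))
    with pytest.raises(ValueError):
        om.FuzzyWeightSpec(tie_rule="random")


# --------------------------------------------------------------------------
# radar scores
# --------------------------------------------------------------------------


def test_zero_amplification_zeroes_radar_score():
    s = _summary([-1, 0, 1], [1, 0, -1], organ="heart")
    deg = om.OrganDegSummary("heart", 500, 400)
    (result,) = om.organ_effect_scores([(s, deg)])
    assert result.radar_score == 0.0
    assert result.weight == 0.9


def test_equal_amplification_scores_in_weight_ratio():
    s1 = _summary([-2, 0, 2], [1, 3, 5], organ="liver")
    s2 = _summary([-2, 0, 2], [1, 3, 5], organ="spleen")
    r1, r2 = om.organ_effect_scores(
        [(s1, om.OrganDegSummary("liver", 456, 464)),
         (s2, om.OrganDegSummary("spleen", 150, 100))]
    )
    assert r1.radar_score / r2.radar_score == pytest.approx(0.9 / 0.3)


def test_duplicate_organ_errors():
    s1 = _summary([-1, 0], [1, 2], organ="liver")
    s2 = _summary([-1, 0], [1, 2], organ="liver")
    deg = om.OrganDegSummary("liver", 10, 10)
    with pytest.raises(ValueError, match="duplicate"):
        om.organ_effect_scores([(s1, deg), (s2, deg)])


def test_results_frame_columns_and_order():
    pairs = []
    for organ in ("liver", "brain", "heart"):
        pairs.append(
            (_summary([-2, 0, 2], [1, 3, 5], organ=organ),
             om.OrganDegSummary(organ, 100, 100))
        )
    frame = results_to_frame(om.organ_effect_scores(pairs))
    assert list(frame["organ"]) == ["liver", "brain", "heart"]
    assert {"n_degs", "weight", "y_i", "radar_score", "contribution_rate"} <= set(
        frame.columns
    )


def test_radar_render_deterministic_and_validating(tmp_path):
    pairs = [
        (_summary([-2, 0, 2], [1, 3, 5], organ=o), om.OrganDegSummary(o, 300, 300))
        for o in ("liver", "brain", "heart", "lung")
    ]
    results = om.organ_effect_scores(pairs)
    p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
    om.render_radar(results, str(p1))
    om.render_radar(results, str(p2))
    assert p1.read_bytes() == p2.read_bytes()

    with pytest.raises(ValueError, match=">= 3"):
        om.render_radar(results[:2], str(tmp_path / "c.svg"))

    # all-zero scores render without crashing
    zero = [
        om.OrganEffectResult(o, 0.0, 0, (1, 0, 0, 0), 0.3, 0.0, 0.5)
        for o in ("a", "b", "c")
    ]
    om.render_radar(zero, str(tmp_path / "zero.svg"))
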