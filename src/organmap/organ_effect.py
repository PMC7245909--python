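"""Multi-organ effect-pattern model: PC01 amplification, fuzzy DEG-count
weighting and radar scores.

For each organ, the expression matrix is reduced by PCA and the first
principal component (PC01) summarizes each sample; its explained-variance
fraction is the "contribution rate".  The between-group shift is
normalized to the observed score range:

    y_i = (mean PC01 of treated - mean PC01 of control)
          / (max PC01 - min PC01 over both groups)

so |y_i| <= 1 by construction and y_i is invariant to positive affine
transforms of the scores (the PCA sign ambiguity only flips its sign,
which the radar score removes by taking |y_i|).

The organ's DEG total x is then fuzzified by four trapezoidal membership
functions over the count axis — linguistic terms "least", "less", "more",
"most" with knots at 300, 400, 550, 650, 800, 900 — and the max-operator
rule converts the winning term to its weight (0.3, 0.5, 0.7, 0.9).  The
per-organ radar score is |y_i| x weight; the seven scores drawn on a polar
radar chart give the drug's overall effect pattern at a glance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CONTROL_LABEL, TREATED_LABEL, ExpressionMatrix
from .degs import OrganDegSummary

DEFAULT_BREAKPOINTS = (300.0, 400.0, 550.0, 650.0, 800.0, 900.0)
DEFAULT_TERM_NAMES = ("least", "less", "more", "most")
DEFAULT_WEIGHTS = (0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class FuzzyWeightSpec:
    """Knots and plateau weights of the four trapezoidal membership terms.

    ``breakpoints`` (b1..b6) structure the four functions: term 1 is full
    below b1 and falls to 0 over [b1, b2]; term 2 rises over [b1, b2],
    plateaus on [b2, b3] and falls over [b3, b4]; term 3 likewise over
    [b3, b4], [b4, b5], [b5, b6]; term 4 rises over [b5, b6] and is full
    above b6.  ``tie_rule`` resolves exact membership ties at the crossover
    midpoints: "higher" (default) picks the larger weight — more DEGs read
    as stronger effect — "lower" the smaller.
    """

    breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS
    term_names: tuple[str, ...] = DEFAULT_TERM_NAMES
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    tie_rule: str = "higher"

    def __post_init__(self) -> None:
        if len(self.breakpoints) != 6:
            raise ValueError("exactly six breakpoints structure the four terms")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.weights) != 4 or len(self.term_names) != 4:
            raise ValueError("four terms require four names and four weights")
        if list(self.weights) != sorted(set(self.weights)):
            raise ValueError("weights must be strictly increasing")
        if self.tie_rule not in ("higher", "lower"):
            raise ValueError("tie_rule must be 'higher' or 'lower'")


@dataclass
class PcaSummary:
    organ: str
    pc01_scores: pd.Series  # per-sample PC01 score
    contribution_rate: float
    group_labels: pd.Series


@dataclass
class OrganEffectResult:
    organ: str
    y_i: float
    n_degs: int
    memberships: tuple[float, float, float, float]
    weight: float
    radar_score: float
    contribution_rate: float


# --------------------------------------------------------------------------
# PCA summary and amplification
# --------------------------------------------------------------------------


def pc01_summary(expr: ExpressionMatrix, scale: bool = False) -> PcaSummary:
    """First-principal-component summary of one organ's samples.

    Genes are mean-centered (not variance-scaled by default: FPKM
    magnitudes carry signal); PC01 is the leading right singular vector
    direction over samples, its contribution rate the leading
    explained-variance ratio.  The score sign is fixed so the treated-group
    mean is >= the control mean, removing the SVD sign ambiguity; the radar
    score is invariant to this choice in any case.
    """
    x = expr.x_samples_by_features()  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples for PCA")
    xc = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        xc = xc / np.where(sd > 0, sd, 1.0)
    total_var = float(np.sum(xc**2))
    if total_var == 0:
        raise ValueError(f"organ {expr.organ!r}: all-constant matrix has no principal axis")
    # SVD is exact and cheap at n_samples <= tens
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    rate = float(s[0] ** 2 / np.sum(s**2))
    scores_series = pd.Series(scores, index=expr.values.columns, name="PC01")
    treated = expr.group_labels == TREATED_LABEL
    if scores_series[treated].mean() < scores_series[~treated].mean():
        scores_series = -scores_series
    return PcaSummary(
        organ=expr.organ,
        pc01_scores=scores_series,
        contribution_rate=rate,
        group_labels=expr.group_labels,
    )


def contribution_rates(expr: ExpressionMatrix, scale: bool = False) -> np.ndarray:
    """Explained-variance ratios of all principal components (sum to 1)."""
    x = expr.x_samples_by_features()
    xc = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        xc = xc / np.where(sd > 0, sd, 1.0)
    s = np.linalg.svd(xc, compute_uv=False)
    ss = s**2
    total = ss.sum()
    if total == 0:
        raise ValueError("all-constant matrix has no principal axis")
    return ss / total


def amplification(summary: PcaSummary) -> float:
    """Normalized between-group PC01 shift, in [-1, 1].

    (treated mean - control mean) / (pooled max - pooled min); the range is
    taken over the per-sample scores of both groups pooled.
    """
    scores = summary.pc01_scores
    treated = summary.group_labels == TREATED_LABEL
    control = summary.group_labels == CONTROL_LABEL
    if not treated.any() or not control.any():
        raise ValueError(f"organ {summary.organ!r}: both groups must be non-empty")
    rng = float(scores.max() - scores.min())
    if rng == 0:
        raise ValueError(
            f"organ {summary.organ!r}: identical PC01 scores give zero range"
        )
    return float((scores[treated].mean() - scores[control].mean()) / rng)


# --------------------------------------------------------------------------
# fuzzy weighting
# --------------------------------------------------------------------------


def memberships(
    x: float, spec: FuzzyWeightSpec = FuzzyWeightSpec()
) -> tuple[float, float, float, float]:
    """Degrees of membership of DEG count x in the four trapezoidal terms.

    The four piecewise-linear functions partition unity: their sum is 1 for
    every x >= 0.
    """
    if x < 0:
        raise ValueError(f"DEG count must be non-negative; got {x}")
    b1, b2, b3, b4, b5, b6 = spec.breakpoints

    def rise(lo: float, hi: float) -> float:
        if x <= lo:
            return 0.0
        if x >= hi:
            return 1.0
        return (x - lo) / (hi - lo)

    mu1 = 1.0 - rise(b1, b2)
    mu2 = min(rise(b1, b2), 1.0 - rise(b3, b4))
    mu3 = min(rise(b3, b4), 1.0 - rise(b5, b6))
    mu4 = rise(b5, b6)
    return (mu1, mu2, mu3, mu4)


def assign_weight(x: float, spec: FuzzyWeightSpec = FuzzyWeightSpec()) -> float:
    """Weight of the maximal-membership term (max-operator rule).

    Exact ties at crossover midpoints resolve per ``spec.tie_rule``.
    """
    mu = memberships(x, spec)
    if spec.tie_rule == "higher":
        best = max(range(4), key=lambda k: (mu[k], k))
    else:
        best = max(range(4), key=lambda k: (mu[k], -k))
    return spec.weights[best]


# --------------------------------------------------------------------------
# radar scores
# --------------------------------------------------------------------------


def organ_effect_scores(
    organs: Sequence[tuple[PcaSummary, OrganDegSummary]],
    spec: FuzzyWeightSpec = FuzzyWeightSpec(),
    count_mode: str = "total",
) -> list[OrganEffectResult]:
    """Per-organ radar scores |y_i| x weight, in input organ order.

    ``count_mode`` selects which DEG count is fuzzified: "total" (default),
    "up" or "down".
    """
    seen: set[str] = set()
    results: list[OrganEffectResult] = []
    for pca_sum, deg_sum in organs:
        if pca_sum.organ != deg_sum.organ:
            raise ValueError(
                f"mismatched organs: PCA {pca_sum.organ!r} vs DEGs {deg_sum.organ!r}"
            )
        if pca_sum.organ in seen:
            raise ValueError(f"duplicate organ {pca_sum.organ!r}")
        seen.add(pca_sum.organ)
        if count_mode == "total":
            x = deg_sum.n_total
        elif count_mode == "up":
            x = deg_sum.n_up
        elif count_mode == "down":
            x = deg_sum.n_down
        else:
            raise ValueError("count_mode must be 'total', 'up' or 'down'")
        y_i = amplification(pca_sum)
        mu = memberships(x, spec)
        weight = assign_weight(x, spec)
        results.append(
            OrganEffectResult(
                organ=pca_sum.organ,
                y_i=y_i,
                n_degs=x,
                memberships=mu,
                weight=weight,
                radar_score=abs(y_i) * weight,
                contribution_rate=pca_sum.contribution_rate,
            )
        )
    return results


def results_to_frame(results: Sequence[OrganEffectResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "organ": r.organ,
                "n_degs": r.n_degs,
                "mu1": r.memberships[0],
                "mu2": r.memberships[1],
                "mu3": r.memberships[2],
                "mu4": r.memberships[3],
                "weight": r.weight,
                "y_i": r.y_i,
                "radar_score": r.radar_score,
                "contribution_rate": r.contribution_rate,
            }
        )
    return pd.DataFrame(rows)


def render_radar(results: Sequence[OrganEffectResult], path: str) -> None:
    """Polar radar chart of the per-organ scores; deterministic output.

    One axis per organ in input order, radial value = radar score.  SVG
    output uses a fixed hash salt and no creation date so identical inputs
    give identical bytes.
    """
    if len(results) < 3:
        raise ValueError("a radar chart needs >= 3 organ axes")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    organs = [r.organ for r in results]
    values = [r.radar_score for r in results]
    angles = np.linspace(0.0, 2.0 * np.pi, len(organs), endpoint=False)

    with plt.rc_context({"svg.hashsalt": "organmap"}):
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
        closed_angles = np.concatenate([angles, angles[:1]])
        closed_values = np.array(values + values[:1])
        ax.plot(closed_angles, closed_values, color="#2b6cb0")
        ax.fill(closed_angles, closed_values, color="#2b6cb0", alpha=0.25)
        ax.set_xticks(angles)
        ax.set_xticklabels(organs)
        ax.set_ylim(0, max(1e-9, max(values)) * 1.1)
        ax.set_title("Organ effect pattern")
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
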