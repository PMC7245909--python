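"""OPLS-DA, VIP scoring, the differential-metabolite screen and the
metabolite correlation network.

Orthogonal projections to latent structures (Trygg & Wold) splits the
predictor matrix X into variation correlated with the class vector y and
variation orthogonal to it.  For a single binary response the model is:
remove ``n_ortho`` y-orthogonal components from X, then fit one predictive
PLS component on the filtered matrix.  Because each orthogonal score vector
is exactly orthogonal to y, the predictive weight vector w is invariant
under the filtering and the decomposition is unique given the
preprocessing.

Model statistics follow chemometrics convention: R2X is the fraction of
(preprocessed) X variance captured by all components, R2Y the fraction of
class variance fitted, and Q2 = 1 - PRESS/SS under K-fold cross-validation
(default 7 folds).  VIP is computed on the predictive component only — the
discriminant-relevant variation — normalized so the mean squared VIP over
features equals 1; VIP > 1.0 is the conventional importance cutoff.

The screen retains features with VIP strictly above the threshold AND a
two-sample t-test p-value below alpha, sorted by descending VIP — the
standard tabulation of significant differential metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL_LABEL, TREATED_LABEL, MetaboliteMatrix

DEFAULT_N_ORTHO = 1
DEFAULT_CV_FOLDS = 7
DEFAULT_VIP_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05


# --------------------------------------------------------------------------
# model container
# --------------------------------------------------------------------------


@dataclass
class OplsDaModel:
    """Fitted OPLS-DA model for a two-class design."""

    feature_ids: list[str]
    scores_pred: np.ndarray  # t, per sample
    loadings_pred: np.ndarray  # p, per feature
    weights_pred: np.ndarray  # w (unit norm), per feature
    c_pred: float  # inner regression coefficient y ~ t
    scores_ortho: np.ndarray  # samples x n_ortho
    loadings_ortho: np.ndarray  # features x n_ortho
    weights_ortho: np.ndarray  # features x n_ortho
    r2x: float
    r2y: float
    q2: float
    vip: np.ndarray
    n_ortho: int
    scaling: str  # "uv" | "pareto" | "center"
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0
    dropped_features: list[str] = field(default_factory=list)

    def vip_series(self) -> pd.Series:
        return pd.Series(self.vip, index=self.feature_ids, name="VIP")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _preprocess(
    x: np.ndarray, scaling: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if scaling == "uv":
        scale = sd.copy()
    elif scaling == "pareto":
        scale = np.sqrt(sd)
    elif scaling == "center":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}; use 'uv', 'pareto' or 'center'")
    return mean, scale, sd


def _fit_core(
    xc: np.ndarray, yc: np.ndarray, n_ortho: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    """Trygg-Wold OPLS on centered/scaled X and centered y.

    Returns (t, p, w, c, T_ortho, P_ortho, W_ortho).
    """
    n, k = xc.shape
    w = xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("y is uncorrelated with every feature; no predictive axis")
    w = w / norm

    t_orthos, p_orthos, w_orthos = [], [], []
    x_work = xc.copy()
    for _ in range(n_ortho):
        t = x_work @ w
        p = x_work.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no orthogonal variation left
            break
        w_o = w_o / n_o
        t_o = x_work @ w_o
        p_o = x_work.T @ t_o / (t_o @ t_o)
        x_work = x_work - np.outer(t_o, p_o)
        t_orthos.append(t_o)
        p_orthos.append(p_o)
        w_orthos.append(w_o)

    t = x_work @ w
    p = x_work.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    T_o = np.column_stack(t_orthos) if t_orthos else np.empty((n, 0))
    P_o = np.column_stack(p_orthos) if p_orthos else np.empty((k, 0))
    W_o = np.column_stack(w_orthos) if w_orthos else np.empty((k, 0))
    return t, p, w, c, T_o, P_o, W_o


def _predict_core(
    x_new: np.ndarray,
    w: np.ndarray,
    c: float,
    P_o: np.ndarray,
    W_o: np.ndarray,
) -> np.ndarray:
    """Predict centered y for preprocessed new samples."""
    x_work = np.array(x_new, dtype=float, copy=True)
    for a in range(W_o.shape[1]):
        t_o = x_work @ W_o[:, a]
        x_work = x_work - np.outer(t_o, P_o[:, a])
    return (x_work @ w) * c


def _cv_q2(
    xc: np.ndarray,
    yc: np.ndarray,
    n_ortho: int,
    cv_folds: int,
    seed: int,
) -> float:
    """Q2 = 1 - PRESS/SS with stratified K-fold CV refitting the whole model
    per fold (stratification keeps both classes in every training set at the
    tiny sample sizes typical here)."""
    n = xc.shape[0]
    rng = np.random.default_rng(seed)
    # round-robin fold assignment within each class, after a seeded shuffle
    fold_of = np.empty(n, dtype=int)
    for cls in np.unique(yc):
        members = rng.permutation(np.flatnonzero(yc == cls))
        fold_of[members] = np.arange(len(members)) % cv_folds
    press = 0.0
    all_idx = np.arange(n)
    for f in range(cv_folds):
        held = all_idx[fold_of == f]
        if held.size == 0:
            continue
        train = all_idx[fold_of != f]
        y_tr = yc[train]
        if np.allclose(y_tr, y_tr[0]):
            raise ValueError("a CV training fold contains a single class")
        try:
            t, p, w, c, T_o, P_o, W_o = _fit_core(xc[train], y_tr - y_tr.mean(), n_ortho)
        except ValueError:
            return float("-inf")
        pred = _predict_core(xc[held], w, c, P_o, W_o) + y_tr.mean()
        press += float(np.sum((yc[held] - pred) ** 2))
    ss = float(np.sum(yc**2))
    return 1.0 - press / ss


def fit_oplsda(
    data: MetaboliteMatrix,
    n_ortho: int = DEFAULT_N_ORTHO,
    cv_folds: int = DEFAULT_CV_FOLDS,
    scaling: str = "uv",
    cv_seed: int = 0,
) -> OplsDaModel:
    """Fit OPLS-DA of group membership on the feature table.

    Parameters
    ----------
    data : MetaboliteMatrix
        Features x samples with CON/RPA labels.
    n_ortho : int
        Number of y-orthogonal components removed before the single
        predictive component.  0 gives plain one-component PLS-DA.
    cv_folds : int
        Folds for the Q2 cross-validation (chemometrics convention: 7).
    scaling : str
        'uv' (unit variance), 'pareto' or 'center'.
    """
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    y01 = data.y_binary()
    if len(np.unique(y01)) < 2:
        raise ValueError("single-class labels; OPLS-DA needs both groups")
    x = data.x_samples_by_features()
    n = x.shape[0]
    if not (2 <= cv_folds <= n - 1):
        raise ValueError(f"cv_folds must be in [2, n_samples - 1]; got {cv_folds}")

    mean, scale, sd = _preprocess(x, scaling)
    keep = sd > 0  # constant features are uninformative and break scaling
    dropped = [fid for fid, k in zip(data.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...",
            stacklevel=2,
        )
    feature_ids = [fid for fid, k in zip(data.feature_ids, keep) if k]
    x = x[:, keep]
    mean, scale = mean[keep], scale[keep]
    if x.shape[1] == 0:
        raise ValueError("no non-constant features left to model")

    xc = (x - mean) / scale
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    t, p, w, c, T_o, P_o, W_o = _fit_core(xc, yc, n_ortho)

    ssx = float(np.sum(xc**2))
    ssx_pred = float(np.sum(np.outer(t, p) ** 2))
    ssx_ortho = sum(
        float(np.sum(np.outer(T_o[:, a], P_o[:, a]) ** 2)) for a in range(T_o.shape[1])
    )
    r2x = (ssx_pred + ssx_ortho) / ssx
    r2y = 1.0 - float(np.sum((yc - t * c) ** 2)) / float(np.sum(yc**2))
    q2 = _cv_q2(xc, yc, n_ortho, cv_folds, cv_seed)

    vip = _vip_single_component(w)

    return OplsDaModel(
        feature_ids=feature_ids,
        scores_pred=t,
        loadings_pred=p,
        weights_pred=w,
        c_pred=c,
        scores_ortho=T_o,
        loadings_ortho=P_o,
        weights_ortho=W_o,
        r2x=r2x,
        r2y=r2y,
        q2=q2,
        vip=vip,
        n_ortho=T_o.shape[1],
        scaling=scaling,
        x_mean=mean,
        x_scale=scale,
        y_mean=y_mean,
        dropped_features=dropped,
    )


def predict(model: OplsDaModel, data: MetaboliteMatrix) -> np.ndarray:
    """Continuous class prediction (around 0 = CON, 1 = RPA) for new samples."""
    cols = [data.feature_ids.index(f) for f in model.feature_ids]
    x = data.x_samples_by_features()[:, cols]
    xc = (x - model.x_mean) / model.x_scale
    return (
        _predict_core(xc, model.weights_pred, model.c_pred,
                      model.loadings_ortho, model.weights_ortho)
        + model.y_mean
    )


# --------------------------------------------------------------------------
# VIP
# --------------------------------------------------------------------------


def _vip_single_component(w: np.ndarray) -> np.ndarray:
    # With one predictive component the sum over components collapses and the
    # SSY weights cancel: VIP_j = sqrt(p) * |w_j| / ||w||.
    k = len(w)
    return np.sqrt(k) * np.abs(w) / np.linalg.norm(w)


def compute_vip(model: OplsDaModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt( p * sum_a[ SSY_a * (w_ja/||w_a||)^2 ] / sum_a SSY_a ),
    normalized so mean(VIP^2) = 1.
    """
    if model.weights_pred is None:
        raise ValueError("model is not fitted")
    return _vip_single_component(model.weights_pred)


# --------------------------------------------------------------------------
# differential-metabolite screen
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialMetabolite:
    name: str
    vip_score: float
    p_value: float


def two_sample_pvalues(
    data: MetaboliteMatrix, equal_var: bool = False
) -> pd.Series:
    """Per-feature two-sample t-test p-values (Welch by default)."""
    con = data.group_columns(CONTROL_LABEL).to_numpy(dtype=float)
    rpa = data.group_columns(TREATED_LABEL).to_numpy(dtype=float)
    res = stats.ttest_ind(rpa, con, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=data.values.index, name="p_value")


def screen_metabolites(
    model: OplsDaModel,
    data: MetaboliteMatrix,
    vip_threshold: float = DEFAULT_VIP_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
) -> list[DifferentialMetabolite]:
    """Features with VIP strictly > threshold and t-test p < alpha,
    sorted by descending VIP."""
    vip = model.vip_series()
    pvals = two_sample_pvalues(data, equal_var=equal_var)
    hits = [
        DifferentialMetabolite(name=f, vip_score=float(vip[f]), p_value=float(pvals[f]))
        for f in model.feature_ids
        if float(vip[f]) > vip_threshold and float(pvals[f]) < alpha
    ]
    hits.sort(key=lambda m: -m.vip_score)
    return hits


def apply_screen_thresholds(
    table: pd.DataFrame,
    vip_threshold: float = DEFAULT_VIP_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Apply the VIP/p screen to a precomputed (metabolite, VIP, p) table.

    Expects columns 'metabolite', 'vip', 'p'; returns the retained rows
    sorted by descending VIP.  Used when the per-feature statistics come
    from an external model rather than a fit in this package.
    """
    kept = table[(table["vip"] > vip_threshold) & (table["p"] < alpha)]
    return kept.sort_values("vip", ascending=False).reset_index(drop=True)


def screen_to_frame(hits: list[DifferentialMetabolite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"Metabolite": h.name, "VIP": h.vip_score, "p": h.p_value} for h in hits],
        columns=["Metabolite", "VIP", "p"],
    )


# --------------------------------------------------------------------------
# correlation network
# --------------------------------------------------------------------------


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    #: (a, b, r, p_adjusted, sign) with a < b lexicographically
    edges: list[tuple[str, str, float, float, int]]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, r, p, sign in self.edges:
            g.add_edge(a, b, r=r, p=p, sign=sign)
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["a", "b", "r", "p_adj", "sign"]
        )


def correlation_network(
    data: MetaboliteMatrix,
    r_threshold: float = 0.6,
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "fdr_bh",
) -> CorrelationNetwork:
    """Pairwise Pearson correlation network across samples.

    Edges with |r| >= r_threshold and (BH-adjusted by default) p < alpha are
    retained; the sign records positive vs negative co-variation.  Constant
    features carry no correlation information and are excluded with a warning.
    """
    if data.n_samples < 3:
        raise ValueError("need >= 3 samples for correlation p-values")
    x = data.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant feature(s) from network",
            stacklevel=2,
        )
    ids = [f for f, k in zip(data.feature_ids, keep) if k]
    x = x[keep]
    m = len(ids)
    if m < 2:
        return CorrelationNetwork(nodes=ids, edges=[])

    corr = np.corrcoef(x)
    iu = np.triu_indices(m, k=1)
    r = np.clip(corr[iu], -1.0, 1.0)
    n = data.n_samples
    # exact two-sided p for Pearson r under bivariate normality (beta dist)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    if adjust == "none":
        p_adj = p
    else:
        p_adj = multipletests(p, method=adjust)[1]

    edges = []
    for (i, j), rv, pv in zip(zip(*iu), r, p_adj):
        if abs(rv) >= r_threshold and pv < alpha:
            a, b = sorted((ids[i], ids[j]))
            edges.append((a, b, float(rv), float(pv), 1 if rv > 0 else -1))
    return CorrelationNetwork(nodes=ids, edges=edges)
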