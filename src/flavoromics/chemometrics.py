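"""Multivariate and univariate chemometrics for two-group volatile profiles.

Covers the standard metabolomics screening stack:

* per-compound Z-scoring of peak areas across samples,
* agglomerative cluster ordering for heat-map display,
* PCA by singular-value decomposition,
* OPLS-DA — orthogonal-signal-corrected PLS with one predictive component
  for a two-class response — with cross-validated Q², VIP scores, and a
  permutation test of model validity,
* the independent two-sample t-test (pooled or Welch).

OPLS-DA splits the predictor variance into a single class-predictive
component and k orthogonal components that are uncorrelated with the class
label; VIP (variable importance in projection) summarizes each variable's
contribution with the mean-square-1 normalization, so VIP > 1 flags
above-average contributors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .model import PeakTable

__all__ = [
    "ZMatrix",
    "zscore",
    "zscore_rows",
    "hcluster_order",
    "PcaModel",
    "fit_pca",
    "OplsdaModel",
    "fit_oplsda",
    "compute_vip",
    "PermutationResult",
    "permutation_test",
    "ttest_independent",
]


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZMatrix:
    """Compound × sample matrix of row-standardized peak areas."""

    values: np.ndarray
    compound_ids: list[str]
    samples: list[str]
    groups: dict[str, str] = field(default_factory=dict)


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Standardize each row to mean 0, sample SD 1 (constant rows → zeros)."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples (SD undefined)")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(x)
    ok = sd[:, 0] > 0
    out[ok] = (x[ok] - mu[ok]) / sd[ok]
    return out


def zscore(table: PeakTable) -> ZMatrix:
    """Z-score all peak areas per compound across the full sample set."""
    return ZMatrix(
        values=zscore_rows(table.areas),
        compound_ids=table.compound_ids(),
        samples=list(table.samples),
        groups=dict(table.groups),
    )


# ---------------------------------------------------------------------------
# Hierarchical cluster ordering (heat-map leaf order)
# ---------------------------------------------------------------------------

def hcluster_order(z: ZMatrix | np.ndarray, axis: str = "rows") -> np.ndarray:
    """Deterministic dendrogram leaf order from average-linkage clustering.

    Euclidean distance, average linkage, leaves by the standard recursive
    dendrogram traversal.  ``axis`` is ``"rows"`` or ``"columns"``; an axis
    with a single item returns the identity permutation.
    """
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if axis == "columns":
        x = x.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    n = x.shape[0]
    if n < 2:
        return np.arange(n)
    link = sch.linkage(x, method="average", metric="euclidean")
    return np.asarray(sch.leaves_list(link), dtype=int)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """SVD-based principal components of the sample × variable matrix."""

    scores: np.ndarray          # (n_samples, k)
    loadings: np.ndarray        # (n_vars, k), orthonormal columns
    explained_percent: np.ndarray  # per component, sums to ≤ 100


def fit_pca(z: ZMatrix | np.ndarray, k: int) -> PcaModel:
    """PCA of samples over (z-scored) variables via SVD.

    The input is compound × sample (as stored); samples are the observations.
    Columns of the sample × variable matrix are centered before decomposition
    (a no-op when rows were z-scored over all samples).  Explained variance
    per component is the squared singular value over the total.
    """
    vals = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    x = vals.T  # samples × variables
    n, p = x.shape
    kmax = min(n - 1, p)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}] for {n} samples × {p} variables")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s ** 2).sum())
    scores = u[:, :k] * s[:k]
    return PcaModel(
        scores=scores,
        loadings=vt[:k].T,
        explained_percent=100.0 * (s[:k] ** 2) / total,
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """Fitted two-class OPLS-DA model.

    The predictive part is a single PLS component fit after orthogonal signal
    correction; ``weights`` stacks the predictive weight vector first, then
    the orthogonal ones, with ``ssy_per_component`` the Y-variance explained
    by each (orthogonal components explain essentially none by construction).
    """

    classes: tuple[str, str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w_pred: np.ndarray
    p_pred: np.ndarray
    q_pred: float
    t_pred: np.ndarray
    w_ortho: np.ndarray  # (n_vars, k_ortho)
    p_ortho: np.ndarray
    t_ortho: np.ndarray  # (n_samples, k_ortho)
    r2x: float
    r2y: float
    q2: float
    fitted_y: np.ndarray
    vip: np.ndarray
    ssy_per_component: np.ndarray
    cv_folds: int
    seed: int
    k_ortho: int

    @property
    def n_vars(self) -> int:
        return self.w_pred.size


def _encode_labels(y) -> tuple[np.ndarray, tuple[str, str]]:
    y = np.asarray(y)
    classes = []
    for lab in y:
        if lab not in classes:
            classes.append(lab)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 samples")
    enc = np.where(y == classes[0], 0.0, 1.0)
    return enc, (str(classes[0]), str(classes[1]))


def _opls_core(xc: np.ndarray, yc: np.ndarray, k_ortho: int):
    """Orthogonal signal correction then one predictive PLS component.

    Returns (w_pred, t, p, q, W_o, T_o, P_o, x_filtered).
    """
    x = xc.copy()
    p_vars = x.shape[1]
    W_o = np.zeros((p_vars, k_ortho))
    T_o = np.zeros((x.shape[0], k_ortho))
    P_o = np.zeros((p_vars, k_ortho))
    for a in range(k_ortho):
        w = x.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = x @ w
        p = x.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no orthogonal variation left
            W_o, T_o, P_o = W_o[:, :a], T_o[:, :a], P_o[:, :a]
            break
        w_o /= n_o
        t_o = x @ w_o
        p_o = x.T @ t_o / (t_o @ t_o)
        x = x - np.outer(t_o, p_o)
        W_o[:, a], T_o[:, a], P_o[:, a] = w_o, t_o, p_o
    w = x.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("degenerate response: X carries no covariance with y")
    w /= nw
    t = x @ w
    p = x.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    return w, t, p, q, W_o, T_o, P_o, x


def _cv_folds_assignment(y01: np.ndarray, folds: int, rng: np.random.Generator):
    """Stratified fold ids; guarantees no training fold loses a class."""
    n = y01.size
    fold_ids = np.empty(n, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.nonzero(y01 == cls)[0]
        idx = rng.permutation(idx)
        fold_ids[idx] = np.arange(idx.size) % folds
    return fold_ids


def _q2_cv(x: np.ndarray, y01: np.ndarray, k_ortho: int, folds: int,
           seed: int, scale: bool) -> float:
    """k-fold cross-validated Q² = 1 − PRESS/SS for the OPLS-DA model.

    Centering/scaling is re-estimated inside each training fold; held-out
    samples are orthogonal-filtered with the training loadings before the
    predictive projection.
    """
    rng = np.random.default_rng(seed)
    n = y01.size
    folds = min(folds, n)
    fold_ids = _cv_folds_assignment(y01, folds, rng)
    press = 0.0
    for f in range(folds):
        test = fold_ids == f
        train = ~test
        if len(np.unique(y01[train])) < 2:
            raise ValueError("a CV fold lost an entire class; reduce folds")
        mu = x[train].mean(axis=0)
        if scale:
            sd = x[train].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
        else:
            sd = np.ones(x.shape[1])
        xt = (x[train] - mu) / sd
        ym = y01[train].mean()
        yt = y01[train] - ym
        try:
            w, t, p, q, W_o, T_o, P_o, _ = _opls_core(xt, yt, k_ortho)
        except ValueError:
            return -np.inf
        xv = (x[test] - mu) / sd
        for a in range(W_o.shape[1]):
            t_o = xv @ W_o[:, a]
            xv = xv - np.outer(t_o, P_o[:, a])
        y_hat = (xv @ w) * q + ym
        press += float(((y01[test] - y_hat) ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / ss


def _vip_scores(weights: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    """Standard PLS VIP over the given components.

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ), which makes the
    mean of VIP² equal 1 exactly.
    """
    p, n_comp = weights.shape
    wnorm2 = (weights ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (weights ** 2) / wnorm2[None, :]
    denom = ssy.sum()
    if denom <= 0:
        return np.ones(p)
    return np.sqrt(p * (contrib @ ssy) / denom)


def fit_oplsda(
    X: np.ndarray,
    y,
    k_ortho: int | str = "auto",
    cv_folds: int | str = "auto",
    seed: int = 0,
    *,
    scale: bool = True,
    vip_mode: str = "total",
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model with cross-validated Q² and VIP.

    Parameters
    ----------
    X : (n_samples, n_vars) predictor matrix (raw scale; centering and
        optional unit-variance scaling happen inside, per CV fold too).
    y : length-n sequence of exactly two class labels, each with ≥ 2 samples.
    k_ortho : number of orthogonal components, or ``"auto"`` to add them
        while cross-validated Q² improves by more than 0.01 (capped at
        min(n_samples − 3, 5)).
    cv_folds : fold count for Q²; ``"auto"`` uses 7, reduced to leave-one-out
        when there are fewer samples than folds.  Folds are stratified and
        seeded.
    scale : unit-variance scale the columns (default, matching a Z-scored
        pipeline); disable for pre-scaled input.
    vip_mode : ``"total"`` (predictive + orthogonal components, the default)
        or ``"predictive"``.
    """
    X = np.asarray(X, dtype=float)
    y01, classes = _encode_labels(y)
    n, p_vars = X.shape
    if y01.size != n:
        raise ValueError("X and y length mismatch")

    folds = 7 if cv_folds == "auto" else int(cv_folds)
    if folds > n:
        folds = n  # leave-one-out
    if folds < 2:
        raise ValueError("cv_folds must be ≥ 2")

    cap = max(0, min(n - 3, 5, p_vars - 1))
    if k_ortho == "auto":
        best_k, best_q2 = 0, _q2_cv(X, y01, 0, folds, seed, scale)
        for k in range(1, cap + 1):
            q2 = _q2_cv(X, y01, k, folds, seed, scale)
            if q2 > best_q2 + 0.01:
                best_k, best_q2 = k, q2
            else:
                break
        k_o = best_k
    else:
        k_o = int(k_ortho)
        if k_o < 0:
            raise ValueError("k_ortho must be ≥ 0")

    mu = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(p_vars)
    xc = (X - mu) / sd
    ym = float(y01.mean())
    yc = y01 - ym

    w, t, p, q, W_o, T_o, P_o, x_filt = _opls_core(xc, yc, k_o)
    k_o = W_o.shape[1]  # may have shrunk if orthogonal variation ran out

    ss_x = float((xc ** 2).sum())
    r2x_comps = float((t @ t) * (p @ p))
    for a in range(k_o):
        r2x_comps += float((T_o[:, a] @ T_o[:, a]) * (P_o[:, a] @ P_o[:, a]))
    r2x = r2x_comps / ss_x if ss_x > 0 else 0.0

    fitted = t * q + ym
    ss_y = float((yc ** 2).sum())
    r2y = 1.0 - float(((y01 - fitted) ** 2).sum()) / ss_y

    q2 = _q2_cv(X, y01, k_o, folds, seed, scale)
    if q2 > r2y + 1e-9:
        warnings.warn(f"Q2 ({q2:.3f}) exceeds R2Y ({r2y:.3f})", stacklevel=2)

    # Y-variance explained per component: predictive first, then orthogonal
    # (orthogonal scores are uncorrelated with y, so their share is ~0).
    ssy = np.empty(1 + k_o)
    ssy[0] = ss_y - float(((yc - t * q) ** 2).sum())
    resid = yc - t * q
    for a in range(k_o):
        t_o = T_o[:, a]
        beta = float(resid @ t_o / (t_o @ t_o))
        ssy[1 + a] = max(0.0, float((resid ** 2).sum() - ((resid - beta * t_o) ** 2).sum()))
    weights = np.column_stack([w] + [W_o[:, a] for a in range(k_o)]) if k_o else w[:, None]
    if vip_mode == "predictive":
        vip = _vip_scores(w[:, None], ssy[:1])
    elif vip_mode == "total":
        vip = _vip_scores(weights, ssy)
    else:
        raise ValueError("vip_mode must be 'total' or 'predictive'")

    return OplsdaModel(
        classes=classes, x_mean=mu, x_scale=sd, y_mean=ym,
        w_pred=w, p_pred=p, q_pred=q, t_pred=t,
        w_ortho=W_o, p_ortho=P_o, t_ortho=T_o,
        r2x=r2x, r2y=r2y, q2=q2, fitted_y=fitted,
        vip=vip, ssy_per_component=ssy,
        cv_folds=folds, seed=seed, k_ortho=k_o,
    )


def compute_vip(model: OplsdaModel, mode: str = "total") -> np.ndarray:
    """Recompute VIP scores from a fitted model's weights and SSY shares."""
    if mode == "predictive":
        return _vip_scores(model.w_pred[:, None], model.ssy_per_component[:1])
    if mode != "total":
        raise ValueError("mode must be 'total' or 'predictive'")
    if model.k_ortho:
        weights = np.column_stack([model.w_pred, model.w_ortho])
    else:
        weights = model.w_pred[:, None]
    return _vip_scores(weights, model.ssy_per_component)


# ---------------------------------------------------------------------------
# Permutation validation
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Label-permutation diagnostics for an OPLS-DA model.

    ``triples`` holds (|label correlation|, R²Y, Q²) for each permuted refit;
    ``reference`` is the unpermuted model's triple (correlation exactly 1).
    ``r2y_intercept`` / ``q2_intercept`` are the least-squares regression
    intercepts at zero label correlation — the classic validation plot: an
    unoverfitted model shows a low (typically negative) Q² intercept.
    """

    n_perm: int
    triples: np.ndarray  # (n_perm, 3)
    reference: tuple[float, float, float]
    r2y_intercept: float
    q2_intercept: float


def permutation_test(
    X: np.ndarray,
    y,
    n_perm: int = 200,
    seed: int = 0,
    *,
    k_ortho: int | str = "auto",
    cv_folds: int | str = "auto",
    scale: bool = True,
) -> PermutationResult:
    """Refit the model under random label permutations.

    Each permutation refits with identical hyperparameters and records the
    absolute Pearson correlation between permuted and original dummy-coded
    labels, R²Y, and Q².  Intercepts come from least-squares lines of R²Y and
    Q² versus the correlation, over the permuted triples plus the reference
    point.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be ≥ 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y01, _ = _encode_labels(y)
    ref_model = fit_oplsda(X, y, k_ortho=k_ortho, cv_folds=cv_folds, seed=seed,
                           scale=scale)
    k_fixed = ref_model.k_ortho  # identical hyperparameters for every refit
    rng = np.random.default_rng(seed)
    triples = np.empty((n_perm, 3))
    for i in range(n_perm):
        while True:
            perm = rng.permutation(y01.size)
            y_p = y[perm]
            if len(np.unique(y_p)) == 2:
                break
        corr = abs(float(np.corrcoef(y01[perm], y01)[0, 1]))
        m = fit_oplsda(X, y_p, k_ortho=k_fixed, cv_folds=cv_folds,
                       seed=seed + 1 + i, scale=scale)
        triples[i] = (corr, m.r2y, m.q2)
    reference = (1.0, ref_model.r2y, ref_model.q2)
    pts = np.vstack([triples, reference])
    r2y_line = np.polyfit(pts[:, 0], pts[:, 1], 1)
    q2_line = np.polyfit(pts[:, 0], pts[:, 2], 1)
    return PermutationResult(
        n_perm=n_perm, triples=triples, reference=reference,
        r2y_intercept=float(np.polyval(r2y_line, 0.0)),
        q2_intercept=float(np.polyval(q2_line, 0.0)),
    )


# ---------------------------------------------------------------------------
# Univariate testing
# ---------------------------------------------------------------------------

def ttest_independent(a, b, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided independent two-sample t-test.

    ``variant="pooled"`` assumes equal variances (df = n_a + n_b − 2);
    ``"welch"`` uses the Satterthwaite df.  Degenerate zero-variance inputs
    follow the conventional limits: identical constant groups → (0, 1);
    constant groups with different means → (±inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: p → 0 limit", stacklevel=2)
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = st.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p)


def differential_ttests(table: PeakTable, variant: str = "pooled") -> "pd.DataFrame":
    """Per-compound t-tests between the table's two groups on raw areas.

    Returns a frame with id, name, t, p and a Benjamini–Hochberg FDR column
    (``p_bh``, informational — the screening path uses raw p).
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    g1, g2 = table.require_two_groups()
    i1 = table.group_sample_indices(g1)
    i2 = table.group_sample_indices(g2)
    rows = []
    for i, c in enumerate(table.compounds):
        t, p = ttest_independent(table.areas[i, i1], table.areas[i, i2], variant)
        rows.append({"id": c.id, "name": c.name, "t": t, "p": p})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
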