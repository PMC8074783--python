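"""Genotype-constrained morphometrics.

The morphology pipeline runs: collinearity pruning (|r| > 0.80 removed) ->
unconstrained Ward morphotypes -> association and rank statistics between
morphotypes and genotypic specimen units -> lasso-penalized variable
selection with comparative DA criteria -> canonical discriminant analysis
(DA) on the specimen units with Wilks' Lambda -> Stewart-Love canonical
redundancy of the constrained DA space against the full morphospace ->
centroid-linkage "morphocloud" clustering of the DA scores and an aberrance
classification of each accession against its genetic main cluster.

Ordinal and binary variables are treated as numeric throughout, matching the
use of Euclidean Ward clustering and linear DA on a mixed-type trait matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .integrate import pcf
from .io import MorphoTable, UnitAssignment

__all__ = [
    "DAModel",
    "VariableSubset",
    "MorphocloudResult",
    "prune_collinear",
    "ward_morphotypes",
    "goodman_kruskal_lambda",
    "kruskal_wallis_axes",
    "select_variables_lasso",
    "fit_da",
    "stewart_love",
    "glm_r2",
    "morphoclouds",
    "classify_aberrance",
]


# ---------------------------------------------------------------------------
# variable pruning


def _imputed_standardized(mt: MorphoTable) -> np.ndarray:
    X = mt.values.astype(float).copy()
    if np.isnan(X).any():
        warnings.warn("missing morphology cells mean-imputed")
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def prune_collinear(mt: MorphoTable, r_max: float = 0.80) -> MorphoTable:
    """Remove variables until no pair has |Pearson r| > ``r_max``.

    Greedy: repeatedly take the worst remaining pair and drop the member
    with the larger mean |r| to all other remaining variables (ties keep the
    earlier column). The survivors satisfy the bound by construction.
    """
    if not 0.0 < r_max < 1.0:
        raise ValueError("r_max must be in (0, 1)")
    if len(mt.variables) < 2:
        raise ValueError("need at least 2 variables")
    Z = _imputed_standardized(mt)
    R = np.corrcoef(Z, rowvar=False)
    np.fill_diagonal(R, 0.0)
    R = np.abs(np.nan_to_num(R))
    alive = list(range(len(mt.variables)))
    while True:
        sub = R[np.ix_(alive, alive)]
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] <= r_max:
            break
        i, j = alive[worst[0]], alive[worst[1]]
        mean_i = R[i, alive].sum() / (len(alive) - 1)
        mean_j = R[j, alive].sum() / (len(alive) - 1)
        # drop the larger mean |r|; on a tie drop the later column
        drop = j if mean_j >= mean_i else i
        alive.remove(drop)
        if len(alive) < 2:
            break
    return mt.subset([mt.variables[i] for i in alive])


# ---------------------------------------------------------------------------
# unconstrained morphotypes and association statistics


def ward_morphotypes(mt: MorphoTable, k: int = 7) -> dict[str, int]:
    """Ward-linkage Euclidean clustering of standardized morphology.

    Groups are ranked 1..k by the centroid of the first PCF axis of the same
    data, so the numbering is stable across runs and record orders.
    """
    if k > len(mt.accessions):
        raise ValueError("k exceeds the number of accessions")
    Z = _imputed_standardized(mt)
    if k == 1:
        return {a: 1 for a in mt.accessions}
    link = linkage(Z, method="ward")
    raw = fcluster(link, t=k, criterion="maxclust")
    axis1 = pcf(Z, labels=mt.accessions).scores[:, 0]
    centroids = {g: axis1[raw == g].mean() for g in np.unique(raw)}
    rank_of = {
        g: r + 1
        for r, g in enumerate(sorted(centroids, key=lambda g: centroids[g]))
    }
    return {a: rank_of[g] for a, g in zip(mt.accessions, raw)}


def goodman_kruskal_lambda(g1: dict[str, object], g2: dict[str, object]) -> float:
    """Goodman-Kruskal lambda: proportional error reduction predicting the
    ``g2`` category of an accession from its ``g1`` category."""
    keys = sorted(set(g1) & set(g2))
    if set(g1) != set(g2):
        warnings.warn("partitions cover different accessions; using intersection")
    cats1 = sorted({g1[k] for k in keys}, key=str)
    cats2 = sorted({g2[k] for k in keys}, key=str)
    if len(cats2) < 2:
        warnings.warn("single category in the predicted partition; lambda = 0")
        return 0.0
    table = np.zeros((len(cats1), len(cats2)))
    for k in keys:
        table[cats1.index(g1[k]), cats2.index(g2[k])] += 1
    N = table.sum()
    col_max = table.sum(axis=0).max()
    row_maxes = table.max(axis=1).sum()
    if N == col_max:
        return 0.0
    return float((row_maxes - col_max) / (N - col_max))


def kruskal_wallis_axes(
    scores: np.ndarray, labels: list[str], groups: dict[str, object]
) -> list[float]:
    """Kruskal-Wallis p-value per score axis across the given groups."""
    member_lists: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab in groups:
            member_lists.setdefault(groups[lab], []).append(i)
    used = {g: idx for g, idx in member_lists.items() if len(idx) >= 2}
    if len(used) < 2:
        raise ValueError("need at least 2 groups with at least 2 members")
    pvals = []
    for ax in range(scores.shape[1]):
        samples = [scores[idx, ax] for idx in used.values()]
        flat = np.concatenate(samples)
        if np.allclose(flat, flat[0]):
            warnings.warn(f"axis {ax + 1}: all scores tied; p = 1")
            pvals.append(1.0)
            continue
        pvals.append(float(stats.kruskal(*samples).pvalue))
    return pvals


# ---------------------------------------------------------------------------
# discriminant analysis


@dataclass
class DAModel:
    """Canonical discriminant axes over genotypic specimen units."""

    labels: list[str]
    units_of: dict[str, str]
    variables: list[str]
    loadings: np.ndarray  # variables x axes
    eigenvalues: np.ndarray
    scores: np.ndarray  # accessions x axes
    wilks_lambda: float
    wilks_p: float

    @property
    def dispersion_share(self) -> np.ndarray:
        """Per-axis share of between-unit dispersion, % (sums to 100)."""
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / total


def fit_da(
    mt: MorphoTable, units: UnitAssignment, ridge: float = 1e-8
) -> DAModel:
    """Canonical DA: eigen-decomposition of W^{-1} B.

    W is the pooled within-unit scatter, B the between-unit scatter; axes
    are the generalized eigenvectors of (B, W), capped at
    min(#units - 1, #variables). Wilks' Lambda = prod 1/(1 + eig_k) =
    det(W) / det(W + B), tested with Bartlett's chi-square approximation.
    Singular W receives a ridge jitter of ``ridge * trace(W)/p`` (warned).
    Accessions without a unit are dropped; single-member units contribute to
    B only (warned).
    """
    rows = [i for i, a in enumerate(mt.accessions) if a in units.unit_of]
    if len(rows) < len(mt.accessions):
        warnings.warn("accessions without a unit assignment dropped from DA")
    X = mt.values[rows].astype(float)
    if np.isnan(X).any():
        warnings.warn("missing cells mean-imputed for DA")
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
    labels = [mt.accessions[i] for i in rows]
    unit_of = {a: units.unit_of[a] for a in labels}
    unit_names = sorted(set(unit_of.values()))
    if len(unit_names) < 2:
        raise ValueError("DA needs at least 2 units")
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    singles = []
    for u in unit_names:
        idx = [i for i, a in enumerate(labels) if unit_of[a] == u]
        sub = X[idx]
        mu = sub.mean(axis=0)
        dev = mu - grand
        B += len(idx) * np.outer(dev, dev)
        if len(idx) == 1:
            singles.append(u)
        else:
            c = sub - mu
            W += c.T @ c
    if singles:
        warnings.warn(f"single-accession units contribute to B only: {singles}")
    eps = ridge * (np.trace(W) / p if np.trace(W) > 0 else 1.0)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError:
        warnings.warn("singular within-unit scatter; ridge jitter applied")
        W = W + eps * np.eye(p)
        evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(len(unit_names) - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    vecs = evecs[:, order][:, :n_axes]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = (X - grand) @ vecs

    wilks = float(np.prod(1.0 / (1.0 + evals)))
    g = len(unit_names)
    df = p * (g - 1)
    bartlett = -(n - 1 - (p + g) / 2.0) * np.log(max(wilks, np.finfo(float).tiny))
    wilks_p = float(stats.chi2.sf(bartlett, df))
    return DAModel(
        labels=labels,
        units_of=unit_of,
        variables=list(mt.variables),
        loadings=vecs,
        eigenvalues=evals,
        scores=scores,
        wilks_lambda=wilks,
        wilks_p=wilks_p,
    )


def glm_r2(da: DAModel, units: UnitAssignment) -> float:
    """Systematic (ranked) cohesion of axis-1 scores over the units.

    Units are ranked by their axis-1 score mean; the statistic is the R^2 of
    an ordinary least-squares fit of the axis-1 scores on the unit rank
    treated as a single ordinal regressor. Ties in unit means are broken by
    unit code order (warned).
    """
    unit_names = sorted(set(da.units_of.values()))
    if len(unit_names) < 3:
        raise ValueError("need at least 3 units")
    y = da.scores[:, 0]
    means = {
        u: y[[i for i, a in enumerate(da.labels) if da.units_of[a] == u]].mean()
        for u in unit_names
    }
    vals = sorted(means.values())
    if len(set(np.round(vals, 12))) < len(vals):
        warnings.warn("tied unit means; rank ties broken by unit code order")
    ranked = sorted(unit_names, key=lambda u: (means[u], u))
    rank_of = {u: r + 1.0 for r, u in enumerate(ranked)}
    x = np.array([rank_of[da.units_of[a]] for a in da.labels])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / tss)


def stewart_love(
    X: np.ndarray, Y: np.ndarray, m: int | None = None
) -> float:
    """Stewart-Love canonical redundancy: how well ``X`` predicts ``Y``.

    Canonical correlation analysis between the two score sets; the
    redundancy of Y given X is sum_k rho_k^2 * (mean squared correlation of
    the Y variables with the k-th Y canonical variate). With all canonical
    pairs retained this equals the mean over Y variables of the R^2 from
    regressing each on X. Rank-deficient blocks reduce the number of pairs
    (warned). Result lies in [0, 1] and is invariant to orthogonal rotation
    of either set.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if m is not None:
        X, Y = X[:, :m], Y[:, :m]
    Zx = StandardScaler().fit_transform(X)
    Zy = StandardScaler().fit_transform(Y)
    # drop zero-variance columns (StandardScaler leaves them at 0)
    Zx = Zx[:, Zx.std(axis=0) > 0]
    Zy = Zy[:, Zy.std(axis=0) > 0]
    if Zx.shape[1] == 0 or Zy.shape[1] == 0:
        return 0.0
    qx, rx = np.linalg.qr(Zx)
    qy, ry = np.linalg.qr(Zy)
    rank_x = np.linalg.matrix_rank(rx)
    rank_y = np.linalg.matrix_rank(ry)
    k = min(rank_x, rank_y)
    if k < min(Zx.shape[1], Zy.shape[1]):
        warnings.warn("rank deficiency: fewer canonical pairs retained")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    rho = np.clip(s[:k], 0.0, 1.0)
    # Y-side canonical variates
    V = qy @ vt.T[:, :k]
    q = Zy.shape[1]
    redundancy = 0.0
    for kk in range(k):
        v = V[:, kk]
        if v.std() == 0:
            continue
        corr = np.array([np.corrcoef(Zy[:, j], v)[0, 1] for j in range(q)])
        redundancy += rho[kk] ** 2 * np.mean(corr**2)
    return float(np.clip(redundancy, 0.0, 1.0))


# ---------------------------------------------------------------------------
# penalized variable selection


def _grouped_multinomial_lasso(
    X: np.ndarray,
    y_idx: np.ndarray,
    lam: float,
    max_iter: int = 3000,
    tol: float = 1e-7,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial logistic regression with a grouped (row-wise L2) lasso
    penalty: minimize NLL/n + lam * sum_j ||W_j||_2.

    The group penalty zeroes whole variables across all classes at once —
    the behavior needed for variable (not coefficient) selection. FISTA
    proximal gradient with the softmax Hessian bound as step size;
    deterministic. Returns (W: p x K, b: K).
    """
    n, p = X.shape
    K = int(y_idx.max()) + 1
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0
    if warm is not None:
        W, b = warm[0].copy(), warm[1].copy()
    else:
        W, b = np.zeros((p, K)), np.zeros(K)
    L = 0.5 * np.linalg.norm(X, 2) ** 2 / n + 1e-12
    step = 1.0 / L
    Wy, by, t = W.copy(), b.copy(), 1.0
    for _ in range(max_iter):
        logits = X @ Wy + by
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        G = X.T @ (P - Y) / n
        W_new = Wy - step * G
        norms = np.linalg.norm(W_new, axis=1, keepdims=True)
        W_new *= np.maximum(0.0, 1.0 - step * lam / np.maximum(norms, 1e-30))
        b_new = by - step * (P - Y).mean(axis=0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        Wy = W_new + ((t - 1) / t_new) * (W_new - W)
        by = b_new + ((t - 1) / t_new) * (b_new - b)
        delta = max(np.abs(W_new - W).max(), np.abs(b_new - b).max())
        W, b, t = W_new, b_new, t_new
        if delta < tol:
            break
    return W, b


def _ridge_multinomial(
    X: np.ndarray, y_idx: np.ndarray, K: int, alpha: float = 1e-2,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Small deterministic Newton-free multinomial fit with mild ridge,
    used for relaxed CV scoring of candidate supports."""
    n, p = X.shape
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0
    W = np.zeros((p, K))
    b = np.zeros(K)
    L = 0.5 * np.linalg.norm(X, 2) ** 2 / n + alpha + 1e-12
    step = 1.0 / L
    for _ in range(max_iter):
        logits = X @ W + b
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        G = X.T @ (P - Y) / n + alpha * W
        gb = (P - Y).mean(axis=0)
        W -= step * G
        b -= step * gb
        if max(np.abs(G).max(), np.abs(gb).max()) < 1e-6:
            break
    return W, b


def _softmax_deviance(X, y_idx, W, b) -> float:
    logits = X @ W + b
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    eps = 1e-12
    return float(-np.mean(np.log(P[np.arange(len(y_idx)), y_idx] + eps)))


@dataclass
class VariableSubset:
    """One candidate variable subset with its comparative DA criteria."""

    selector: str
    penalty: float
    variables: list[str]
    axis1_dispersion: float = float("nan")  # %
    cum_dispersion_1_3: float = float("nan")  # %
    stewart_love_1_6: float = float("nan")
    glm_r2: float = float("nan")

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def _subset_criteria(
    subset: VariableSubset,
    mt: MorphoTable,
    units: UnitAssignment,
    full_pcf_scores: np.ndarray,
    full_pcf_labels: list[str],
) -> None:
    da = fit_da(mt.subset(subset.variables), units)
    share = da.dispersion_share
    subset.axis1_dispersion = float(share[0]) if len(share) else float("nan")
    subset.cum_dispersion_1_3 = float(share[: min(3, len(share))].sum())
    m = min(6, da.scores.shape[1], full_pcf_scores.shape[1])
    row = {lab: i for i, lab in enumerate(full_pcf_labels)}
    idx = [row[a] for a in da.labels]
    subset.stewart_love_1_6 = stewart_love(
        da.scores[:, :m], full_pcf_scores[idx, :m]
    )
    try:
        subset.glm_r2 = glm_r2(da, units)
    except ValueError:
        subset.glm_r2 = float("nan")


def select_variables_lasso(
    mt: MorphoTable,
    units: UnitAssignment,
    penalty_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[VariableSubset]:
    """Grouped-lasso multinomial selection of discriminating variables.

    Fits a multinomial logistic classifier of the specimen unit on the
    standardized morphology with a grouped lasso penalty (one group per
    variable across all classes, so whole variables are zeroed), over a
    data-driven penalty grid from lambda_max (the smallest penalty zeroing
    everything) down three decades, scored by ``n_folds``-fold
    cross-validated deviance. Two candidate subsets are returned: the
    nonzero variables at (i) the penalty minimizing CV deviance and (ii)
    the strongest penalty within one standard error of that minimum. Units
    with fewer than 2 accessions are excluded (cannot be cross-validated).
    Each candidate carries the comparative criteria (axis-1 and cumulative
    DA dispersion, Stewart-Love over six dimensions against the
    full-morphospace PCF, and the ranked cohesion R^2).
    """
    keep_units = {
        u for u in set(units.unit_of.values())
        if sum(1 for a in mt.accessions if units.unit_of.get(a) == u) >= 2
    }
    dropped = set(units.unit_of.values()) - keep_units
    if dropped:
        warnings.warn(f"units with < 2 accessions excluded: {sorted(dropped)}")
    rows = [
        i
        for i, a in enumerate(mt.accessions)
        if units.unit_of.get(a) in keep_units
    ]
    if len(keep_units) < 2:
        raise ValueError("need at least 2 units with >= 2 accessions")
    X = _imputed_standardized(mt)[rows]
    classes = sorted(keep_units)
    y = np.array(
        [classes.index(units.unit_of[mt.accessions[i]]) for i in rows]
    )

    if penalty_grid is None:
        # glmnet-style grid: from the smallest all-zero penalty downward
        n, K = len(y), len(classes)
        Y = np.zeros((n, K))
        Y[np.arange(n), y] = 1.0
        G0 = X.T @ (1.0 / K - Y) / n
        lam_max = float(np.linalg.norm(G0, axis=1).max())
        penalty_grid = np.geomspace(lam_max, lam_max / 100.0, 15)
    penalty_grid = np.sort(np.asarray(penalty_grid, dtype=float))[::-1]

    def _relaxed_deviance(tr, te, active) -> float:
        # relaxed scoring: refit on the active set without the lasso
        # shrinkage (mild ridge keeps separable folds finite), so CV judges
        # the support rather than the shrunken coefficients
        if len(active) == 0:
            prior = np.bincount(y[tr], minlength=len(classes)) / len(tr)
            return float(-np.mean(np.log(prior[y[te]] + 1e-12)))
        Wr, br = _ridge_multinomial(X[tr][:, active], y[tr], len(classes))
        return _softmax_deviance(X[te][:, active], y[te], Wr, br)

    n_folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    dev = np.zeros((len(penalty_grid), cv.get_n_splits()))
    nonempty = np.ones(len(penalty_grid), dtype=bool)
    for f, (tr, te) in enumerate(cv.split(X, y)):
        warm = None
        for c, lam in enumerate(penalty_grid):
            W, b = _grouped_multinomial_lasso(
                X[tr], y[tr], lam, max_iter=1200, tol=1e-6, warm=warm
            )
            warm = (W, b)
            active = np.where(np.linalg.norm(W, axis=1) > 1e-6)[0]
            dev[c, f] = _relaxed_deviance(tr, te, active)
    warm = None
    full_path = {}
    for c, lam in enumerate(penalty_grid):
        W, b = _grouped_multinomial_lasso(X, y, lam, warm=warm)
        warm = (W, b)
        full_path[c] = W
        nonempty[c] = bool((np.linalg.norm(W, axis=1) > 1e-6).any())
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(dev.shape[1])
    i_min = int(np.argmin(np.where(nonempty, mean_dev, np.inf)))
    limit = mean_dev[i_min] + se_dev[i_min]
    within = [
        i for i in range(len(penalty_grid))
        if mean_dev[i] <= limit and nonempty[i]
    ]
    i_1se = max(within, key=lambda i: penalty_grid[i])

    full = pcf(_imputed_standardized(mt)[rows], labels=[mt.accessions[i] for i in rows])
    sub_units = UnitAssignment(
        unit_of={a: u for a, u in units.unit_of.items() if u in keep_units},
        cluster_of=dict(units.cluster_of),
    )

    candidates = []
    for name, i in (("cv_min", i_min), ("cv_1se", i_1se)):
        nz = np.where(np.linalg.norm(full_path[i], axis=1) > 1e-6)[0]
        variables = [mt.variables[j] for j in nz]
        subset = VariableSubset(
            selector=f"grouped-lasso/{name}",
            penalty=float(penalty_grid[i]),
            variables=variables,
        )
        if len(variables) >= 2:
            _subset_criteria(subset, mt, sub_units, full.scores, full.labels)
        candidates.append(subset)
    return candidates


# ---------------------------------------------------------------------------
# morphoclouds and aberrance


@dataclass
class MorphocloudResult:
    cloud_of: dict[str, int]
    label_of: dict[str, str] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)
    mixed_clouds: list[int] = field(default_factory=list)


def morphoclouds(
    da: DAModel, k_range: tuple[int, int] = (2, 12), n_axes: int = 3
) -> MorphocloudResult:
    """Centroid-linkage clustering of the first DA axes into morphoclouds.

    The cut is chosen by maximal mean silhouette over ``k_range``. With flat
    low silhouettes everywhere the smallest k is kept and a low-structure
    warning raised. Membership is invariant to accession order.
    """
    if len(da.labels) < 4:
        raise ValueError("need at least 4 accessions")
    use = min(n_axes, da.scores.shape[1])
    if use < n_axes:
        warnings.warn(f"only {use} DA axes available; using all")
    X = da.scores[:, :use]
    Z = linkage(X, method="centroid")
    lo, hi = k_range
    best_k, best_sil, best_assign = None, -np.inf, None
    for k in range(max(2, lo), min(hi, len(da.labels) - 1) + 1):
        assign = fcluster(Z, t=k, criterion="maxclust")
        if len(set(assign)) < 2:
            continue
        sil = silhouette_score(X, assign)
        if sil > best_sil + 1e-12:
            best_k, best_sil, best_assign = k, sil, assign
    if best_assign is None:
        best_assign = np.ones(len(da.labels), dtype=int)
    # low-structure diagnostic: compare with Ward cuts of Gaussian noise
    # sharing the score covariance (raw silhouettes of noise are ~0.3-0.45,
    # so a flat threshold cannot tell structure from none)
    rng = np.random.default_rng(0)
    cov = np.cov(X, rowvar=False)
    chol = np.linalg.cholesky(np.atleast_2d(cov) + 1e-10 * np.eye(X.shape[1]))
    null_best = []
    for _ in range(10):
        Xn = rng.standard_normal(X.shape) @ chol.T
        Zn = linkage(Xn, method="centroid")
        sils = [
            silhouette_score(Xn, a)
            for k in range(max(2, lo), min(hi, len(da.labels) - 1) + 1)
            if len(set(a := fcluster(Zn, t=k, criterion="maxclust"))) >= 2
        ]
        if sils:
            null_best.append(max(sils))
    if best_sil < 0.25 or (
        null_best and best_sil <= float(np.quantile(null_best, 0.9))
    ):
        warnings.warn("weak cloud structure (silhouette within the noise range)")
    return MorphocloudResult(
        cloud_of={a: int(c) for a, c in zip(da.labels, best_assign)}
    )


def classify_aberrance(
    clouds: MorphocloudResult,
    units: UnitAssignment,
    da: DAModel,
    purity: float = 0.90,
    borderline_eps_factor: float = 0.5,
    lookalikes: list[str] | None = None,
    n_axes: int = 3,
) -> MorphocloudResult:
    """Label each accession by the concordance of its morphocloud with its
    genetic main cluster.

    A cloud is *pure* when at least ``purity`` of its members share one main
    cluster, otherwise *mixed* (all its members labeled ``mixed``). In a
    pure cloud, majority members are ``consistent``; minority members are
    ``aberrant`` unless (a) they appear on the ``lookalikes`` override list
    (an expert call -> ``lookalike``) or (b) their score lies within
    ``borderline_eps_factor`` pooled within-cloud SDs of the midpoint to the
    nearest cloud dominated by their own cluster (``borderline``).
    Percentages per label sum to 100.
    """
    lookalikes = set(lookalikes or [])
    use = min(n_axes, da.scores.shape[1])
    X = da.scores[:, :use]
    pos = {a: X[i] for i, a in enumerate(da.labels)}
    cluster = {a: units.main_cluster(a) for a in clouds.cloud_of}
    if any(v is None for v in cluster.values()):
        missing = sorted(a for a, v in cluster.items() if v is None)
        raise ValueError(f"accessions without a genetic main cluster: {missing}")

    members: dict[int, list[str]] = {}
    for a, c in clouds.cloud_of.items():
        members.setdefault(c, []).append(a)
    majority: dict[int, str] = {}
    pure: dict[int, bool] = {}
    centroid: dict[int, np.ndarray] = {}
    sds = []
    for c, accs in members.items():
        counts: dict[str, int] = {}
        for a in accs:
            counts[cluster[a]] = counts.get(cluster[a], 0) + 1
        top = max(counts, key=lambda k: (counts[k], k))
        majority[c] = top
        pure[c] = counts[top] / len(accs) >= purity
        pts = np.vstack([pos[a] for a in accs])
        centroid[c] = pts.mean(axis=0)
        if len(accs) > 1:
            sds.append(np.sqrt(((pts - centroid[c]) ** 2).sum(axis=1).mean()))
    eps = borderline_eps_factor * (np.mean(sds) if sds else 0.0)

    label_of: dict[str, str] = {}
    for c, accs in members.items():
        if not pure[c]:
            for a in accs:
                label_of[a] = "mixed"
            continue
        own_clouds = {
            c2: centroid[c2]
            for c2 in members
            if c2 != c and pure[c2]
        }
        for a in accs:
            if cluster[a] == majority[c]:
                label_of[a] = "consistent"
                continue
            if a in lookalikes:
                label_of[a] = "lookalike"
                continue
            homes = [
                cen for c2, cen in own_clouds.items() if majority[c2] == cluster[a]
            ]
            label = "aberrant"
            for cen in homes:
                midpoint = (centroid[c] + cen) / 2.0
                if np.linalg.norm(pos[a] - midpoint) <= eps:
                    label = "borderline"
                    break
            label_of[a] = label
    n = len(label_of)
    proportions = {
        lab: 100.0 * sum(1 for v in label_of.values() if v == lab) / n
        for lab in ("consistent", "aberrant", "borderline", "lookalike", "mixed")
    }
    return MorphocloudResult(
        cloud_of=dict(clouds.cloud_of),
        label_of=label_of,
        proportions=proportions,
        mixed_clouds=sorted(c for c in members if not pure[c]),
    )
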