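"""Distance-matrix factoring and the double factorization fusing two markers.

A distance matrix is first turned into coordinates by principal coordinates
analysis (Gower double-centering of -1/2 D^2 followed by an
eigen-decomposition; scores are eigenvectors scaled by sqrt(eigenvalue)).
Principal components factoring (PCF) of a data matrix is the
eigen-decomposition of its correlation matrix. The *double factorization*
factors the sequence-distance block and the band-distance block separately,
retains the leading factors of each, z-standardizes and concatenates them,
and runs a second PCF on the concatenation — so the combined ordination
carries both marker signals and supports finer subcluster splits.

Eigenvector signs are fixed by making the largest-magnitude loading
positive, so repeated runs produce identical plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .distances import DistanceMatrix

__all__ = [
    "FactorModel",
    "CombinedOrdination",
    "distance_to_scores",
    "pcf",
    "double_factorize",
    "refine_subclusters",
]


@dataclass
class FactorModel:
    """Scores, eigenvalues and variance shares of one factoring."""

    labels: list[str]
    scores: np.ndarray  # individuals x retained factors
    eigenvalues: np.ndarray  # all non-negative eigenvalues, non-increasing
    n_retained: int

    @property
    def variance_share(self) -> np.ndarray:
        """Per-factor share of total variance, in % (sums to 100)."""
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / total


@dataclass
class CombinedOrdination:
    model: FactorModel
    block_of: list[str] = field(default_factory=list)  # input column -> source block
    block_models: dict[str, FactorModel] = field(default_factory=dict)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for k in range(out.shape[1]):
        j = np.argmax(np.abs(out[:, k]))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def distance_to_scores(dm: DistanceMatrix, n_axes: int | None = None) -> FactorModel:
    """Principal coordinates of a distance matrix (Gower centering).

    Negative eigenvalues (non-Euclidean input) are reported via a warning
    and their axes dropped. For Euclidean-embeddable input the scores
    reproduce the distances exactly.
    """
    D = np.asarray(dm.D, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("PCoA needs a finite distance matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-8 * max(abs(evals[0]), 1.0))
    n_neg = int((evals < -tol).sum())
    if n_neg:
        warnings.warn(f"{n_neg} negative PCoA eigenvalues dropped")
    pos = evals > tol
    if not pos.any():
        warnings.warn("rank-0 distance matrix: all points coincide")
        return FactorModel(
            labels=list(dm.labels),
            scores=np.zeros((n, 1)),
            eigenvalues=np.zeros(1),
            n_retained=1,
        )
    evals_pos = evals[pos]
    vecs = _fix_signs(evecs[:, pos])
    scores = vecs * np.sqrt(evals_pos)
    k = len(evals_pos) if n_axes is None else min(n_axes, len(evals_pos))
    return FactorModel(
        labels=list(dm.labels),
        scores=scores[:, :k],
        eigenvalues=evals_pos,
        n_retained=k,
    )


def pcf(
    X: np.ndarray, labels: list[str] | None = None, n_factors: int | None = None
) -> FactorModel:
    """Principal components factoring: eigen-decomposition of the correlation
    matrix of ``X``. Columns are standardized internally; zero-variance
    columns are dropped with a warning. Scores are the standardized data
    projected on the eigenvectors.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCF needs at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance columns dropped")
    if not keep.any():
        raise ValueError("no variable with positive variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    k = len(evals) if n_factors is None else min(n_factors, len(evals))
    scores = Z @ evecs[:, :k]
    return FactorModel(
        labels=list(labels) if labels is not None else [str(i) for i in range(X.shape[0])],
        scores=scores,
        eigenvalues=evals,
        n_retained=k,
    )


def _retain_mean_rule(model: FactorModel, minimum: int = 2) -> int:
    """Retain factors with eigenvalue >= the mean eigenvalue, at least
    ``minimum`` (bounded by what is available)."""
    lam = model.eigenvalues
    k = int((lam >= lam.mean()).sum())
    return max(min(minimum, len(lam)), min(k, model.scores.shape[1]))


def double_factorize(
    its_dm: DistanceMatrix,
    scot_dm: DistanceMatrix,
    retain_rule=None,
) -> CombinedOrdination:
    """Fuse two marker distance matrices into one ordination.

    Each block is factored by :func:`distance_to_scores`; the retained block
    scores (default rule: eigenvalue above the block mean, minimum 2) are
    z-standardized, concatenated and re-factored with :func:`pcf`. Labels
    present in only one block are dropped with a warning. The result is
    invariant to block order up to axis sign.
    """
    retain_rule = retain_rule or _retain_mean_rule
    shared = [lab for lab in its_dm.labels if lab in set(scot_dm.labels)]
    if not shared:
        raise ValueError("the two distance matrices share no individuals")
    if len(shared) < len(its_dm.labels) or len(shared) < len(scot_dm.labels):
        warnings.warn(
            f"restricting to the {len(shared)} individuals present in both blocks"
        )

    def subset(dm: DistanceMatrix) -> DistanceMatrix:
        idx = [dm.labels.index(lab) for lab in shared]
        return DistanceMatrix(
            labels=shared, D=dm.D[np.ix_(idx, idx)], metric_name=dm.metric_name
        )

    blocks = {}
    cols: list[np.ndarray] = []
    block_of: list[str] = []
    for name, dm in (("its", subset(its_dm)), ("scot", subset(scot_dm))):
        model = distance_to_scores(dm)
        k = retain_rule(model)
        blocks[name] = model
        S = model.scores[:, :k]
        sd = S.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        cols.append((S - S.mean(axis=0)) / sd)
        block_of.extend([name] * k)
    X = np.hstack(cols)
    combined = pcf(X, labels=shared)
    return CombinedOrdination(model=combined, block_of=block_of, block_models=blocks)


def refine_subclusters(
    ordination: CombinedOrdination,
    base: dict[str, str] | None = None,
    k_range: tuple[int, int] = (2, 6),
    min_silhouette: float = 0.25,
    n_axes: int | None = None,
) -> dict[str, str]:
    """Split each base cluster on the combined scores where structure exists.

    Within each base cluster, Ward hierarchical clustering on the leading
    combined factors (eigenvalue above the mean, at least 2, unless
    ``n_axes`` overrides) is cut at the k in ``k_range`` maximizing the mean
    silhouette. The cluster is left unsplit when the best silhouette falls
    below ``min_silhouette`` or fails to beat the 90th percentile of the
    best silhouette found in 20 Gaussian-noise replicates with the cluster's
    own covariance (a gap-statistic-style reference: a raw silhouette
    threshold cannot separate structure from noise at desk-scale n).
    Returns individual -> subcluster code ``"<base>.<split>"``.
    """
    lo, hi = k_range
    if lo < 1:
        raise ValueError("k_range lower bound must be >= 1")
    model = ordination.model
    if n_axes is None:
        lam = model.eigenvalues[: model.scores.shape[1]]
        n_axes = max(2, int((lam >= lam.mean()).sum()))
    S = model.scores[:, :n_axes]
    labels = model.labels
    if base is None:
        base = {lab: "all" for lab in labels}
    rng = np.random.default_rng(0)

    def best_cut(X: np.ndarray) -> tuple[int, float, np.ndarray]:
        Z = linkage(X, method="ward")
        cuts: list[tuple[int, float, np.ndarray]] = []
        for k in range(max(2, lo), min(hi, len(X) - 1) + 1):
            assign = fcluster(Z, t=k, criterion="maxclust")
            if len(set(assign)) < 2:
                continue
            cuts.append((k, silhouette_score(X, assign), assign))
        if not cuts:
            return 1, -1.0, np.ones(len(X), dtype=int)
        s_max = max(s for _, s, _ in cuts)
        # parsimony: the smallest k within 0.05 silhouette of the maximum
        return min(
            (c for c in cuts if c[1] >= s_max - 0.05), key=lambda c: c[0]
        )

    out: dict[str, str] = {}
    for cluster in sorted(set(base.values())):
        members = [i for i, lab in enumerate(labels) if base[lab] == cluster]
        X = S[members]
        best_k, best_sil, best_assign = 1, -1.0, np.ones(len(members), dtype=int)
        if len(members) > 3:
            best_k, best_sil, best_assign = best_cut(X)
            cov = np.cov(X, rowvar=False)
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(X.shape[1]))
            null_sils = [
                best_cut(rng.standard_normal(X.shape) @ chol.T)[1]
                for _ in range(20)
            ]
            if best_sil <= max(min_silhouette, float(np.quantile(null_sils, 0.9))):
                best_k, best_assign = 1, np.ones(len(members), dtype=int)
        for idx, a in zip(members, best_assign):
            out[labels[idx]] = f"{cluster}.{a}" if best_k > 1 else cluster
    return out
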