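"""Community-ecology statistics: alpha diversity, Bray-Curtis, PCoA,
single-factor PERMANOVA, and species-accumulation (rarefaction) curves.

PERMANOVA follows Anderson's distance-based decomposition with a seeded
permutation stream and the add-one permutation p estimator,
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p never returns 0 and has
resolution 1/(n_perm + 1). PCoA reports negative eigenvalues uncorrected and
builds coordinates from the positive ones only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


def alpha_diversity(matrix: pd.DataFrame | np.ndarray, index: str = "shannon"
                    ) -> pd.Series:
    """Per-sample Shannon (H = -sum p ln p) or Simpson (1 - sum p^2) diversity."""
    X = pd.DataFrame(matrix).astype(float)
    if (X.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    P = X.div(totals, axis=0).to_numpy()
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(P > 0, P * np.log(P), 0.0)
        vals = -terms.sum(axis=1)
    elif index == "simpson":
        vals = 1.0 - (P ** 2).sum(axis=1)
    else:
        raise ValueError("index must be 'shannon' or 'simpson'")
    return pd.Series(vals, index=X.index, name=index)


def diversity_comparison(matrix: pd.DataFrame, groups: pd.Series,
                         index: str = "shannon") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of a diversity index between
    every pair of groups."""
    div = alpha_diversity(matrix, index)
    groups = groups.reindex(div.index)
    levels = sorted(groups.dropna().unique())
    rows = []
    for i, ga in enumerate(levels):
        for gb in levels[i + 1:]:
            a = div[groups == ga]
            b = div[groups == gb]
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append({"index": index, "group_a": ga, "group_b": gb,
                         "median_a": float(a.median()), "median_b": float(b.median()),
                         "p_value": p})
    return pd.DataFrame(rows)


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    X = pd.DataFrame(matrix).astype(float)
    v = X.to_numpy()
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = v.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis is undefined between two all-zero samples")
    D = squareform(pdist(v, metric="braycurtis"))
    return pd.DataFrame(D, index=X.index, columns=X.index)


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _check_distance(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    D = np.asarray(pd.DataFrame(dist), dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return D


def _permanova_f(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R2) from squared distances and integer group labels."""
    n = len(labels)
    sst = D2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    a = 0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        ng = len(idx)
        a += 1
        if ng > 1:
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(ng, 1)].sum() / ng
    ssa = sst - ssw
    if ssw == 0.0:  # perfect within-group identity
        return np.inf, ssa / sst
    f = (ssa / (a - 1)) / (ssw / (n - a))
    return f, ssa / sst


def permanova(dist: pd.DataFrame | np.ndarray, labels, n_perm: int = 1000,
              seed: int = 0, factor: str = "factor") -> PermanovaResult:
    """Single-factor PERMANOVA on a distance matrix.

    Requires at least two groups, each with at least two samples. The
    permutation stream is seeded, so results are reproducible.
    """
    D = _check_distance(dist)
    labels = np.asarray(pd.factorize(pd.Series(np.asarray(labels)))[0])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    D2 = D ** 2
    f_obs, r2 = _permanova_f(D2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _r = _permanova_f(D2, rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(factor=str(factor), r2=float(r2), pseudo_f=float(f_obs),
                           p_value=float(p), n_permutations=n_perm)


class PCoA(BaseEstimator, TransformerMixin):
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Gower double-centering followed by eigendecomposition; coordinates are
    eigenvector * sqrt(eigenvalue) for positive eigenvalues, ordered by
    decreasing eigenvalue. Negative eigenvalues are kept in ``eigenvalues_``
    (no Lingoes/Cailliez correction); ``proportion_explained_`` is over the
    positive-eigenvalue sum.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        D = _check_distance(X)
        n = D.shape[0]
        if n < 3:
            raise ValueError("PCoA needs at least three samples")
        ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(n))
        A = -0.5 * D ** 2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        G = (G + G.T) / 2
        eigval, eigvec = np.linalg.eigh(G)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        pos = eigval > max(1e-12 * abs(eigval).max(), 0.0)
        coords = eigvec[:, pos] * np.sqrt(eigval[pos])
        m = coords.shape[1] if self.n_components is None \
            else min(self.n_components, coords.shape[1])
        self.eigenvalues_ = eigval
        self.coordinates_ = pd.DataFrame(
            coords[:, :m], index=ids,
            columns=[f"PC{i + 1}" for i in range(m)])
        self.proportion_explained_ = eigval[pos][:m] / eigval[pos].sum()
        return self

    def transform(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "coordinates_"):
            raise AttributeError("PCoA is not fitted")
        return self.coordinates_

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def pcoa(dist: pd.DataFrame | np.ndarray, n_components: int | None = None) -> PCoA:
    return PCoA(n_components=n_components).fit(dist)


def rarefaction(presence_matrix: pd.DataFrame, n_perm: int = 100,
                seed: int = 0) -> pd.DataFrame:
    """Mean species-accumulation curve over random sample orderings.

    For m = 1..n_samples, the mean (over permutations) number of species in
    the union of the first m samples. The curve is nondecreasing and ends at
    the total observed species count.
    """
    P = pd.DataFrame(presence_matrix).to_numpy(dtype=bool)
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.cumsum(P[order], axis=0) > 0
        acc += seen.sum(axis=1)
    return pd.DataFrame({"n_samples": np.arange(1, n + 1),
                         "mean_species": acc / n_perm})
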