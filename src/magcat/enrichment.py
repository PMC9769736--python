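"""Group-contrast enrichment: per-KO rank-sum tests, BH adjustment,
inverse-normal z transform, and the module reporter score.

The procedure, applied to a samples x KO relative-abundance matrix with a
two-group sample labelling:

1. Every KO with nonzero abundance in strictly more than ``min_samples``
   samples is tested with a one-tailed Wilcoxon rank-sum test, in each
   direction (group A enriched; group B enriched).
2. P-values are adjusted with Benjamini-Hochberg within each direction.
3. Each KO's adjusted value is mapped to z = Phi^-1(1 - q), with q clamped to
   [1e-15, 1 - 1e-15] so z stays finite.
4. A module aggregates its tested member KOs: Z_module = (sum z) / sqrt(k)
   (default; the plain 1/k mean is selectable), and Z_module >= 1.6 flags the
   module as significantly differentiated in that direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

_CLAMP = 1e-15


def z_transform(q) -> float | np.ndarray:
    """Standard-normal quantile of 1 - q, clamped to stay finite.

    q = 0.5 maps to 0; q -> 0 maps to +7.94, q -> 1 to -7.94 (the clamp
    boundary quantiles).
    """
    q = np.clip(np.asarray(q, dtype=float), _CLAMP, 1.0 - _CLAMP)
    z = stats.norm.ppf(1.0 - q)
    return float(z) if z.ndim == 0 else z


def rank_sum_one_tailed(x: np.ndarray, y: np.ndarray, alternative: str = "greater"
                        ) -> float:
    """One-tailed Wilcoxon rank-sum p-value for x vs y.

    Exact for small tie-free samples; otherwise the midrank normal
    approximation with tie correction and continuity correction. Fully
    degenerate input (every pooled value identical) returns 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.5
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class KOTestResult:
    ko: str
    direction: str
    p_value: float
    q_value: float
    z: float


def ko_tests(abundance: pd.DataFrame, groups: Sequence[str] | pd.Series,
             min_samples: int = 3, adjust: str = "bh") -> pd.DataFrame:
    """Directional rank-sum tests for every sufficiently prevalent KO.

    ``groups`` labels each row of ``abundance`` with one of exactly two
    levels; the lexicographically smaller level is direction "A". KOs nonzero
    in strictly more than ``min_samples`` samples are tested one-tailed in
    both directions; BH adjustment is applied within each direction
    (``adjust='none'`` leaves q = p, used for calibration work).
    """
    groups = pd.Series(np.asarray(groups), index=abundance.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    a_mask = (groups == levels[0]).to_numpy()
    if a_mask.sum() < 2 or (~a_mask).sum() < 2:
        raise ValueError("each group needs at least two samples")
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")

    X = abundance.to_numpy(dtype=float)
    tested = [j for j in range(X.shape[1]) if (X[:, j] != 0).sum() > min_samples]
    rows: list[KOTestResult] = []
    for direction, alt in ((str(levels[0]), "greater"), (str(levels[1]), "less")):
        ps = [rank_sum_one_tailed(X[a_mask, j], X[~a_mask, j], alt) for j in tested]
        qs = bh_adjust(ps) if adjust == "bh" else np.asarray(ps, dtype=float)
        zs = z_transform(qs) if len(tested) else np.empty(0)
        for j, p, q, z in zip(tested, ps, np.atleast_1d(qs), np.atleast_1d(zs)):
            rows.append(KOTestResult(abundance.columns[j], direction,
                                     float(p), float(q), float(z)))
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["ko", "direction", "p_value", "q_value", "z"])


def reporter_scores(ko_results: pd.DataFrame,
                    catalog: Mapping[str, frozenset[str] | set[str]],
                    normalization: str = "sqrt_k",
                    threshold: float = 1.6) -> pd.DataFrame:
    """Module reporter scores from directional KO z-values.

    Each module keeps only member KOs that were tested; with k such KOs,
    Z_module = (sum z) / sqrt(k) under 'sqrt_k' (default) or (sum z) / k
    under 'k'. Modules with k = 0 are reported untested (NaN score).
    """
    if normalization not in ("sqrt_k", "k"):
        raise ValueError("normalization must be 'sqrt_k' or 'k'")
    rows = []
    for direction, sub in ko_results.groupby("direction"):
        z_of = sub.set_index("ko")["z"]
        for mid in sorted(catalog):
            members = [ko for ko in catalog[mid] if ko in z_of.index]
            k = len(members)
            if k == 0:
                rows.append({"module_id": mid, "direction": direction, "k": 0,
                             "z_module": np.nan, "significant": False})
                continue
            total = float(z_of.loc[members].sum())
            zm = total / np.sqrt(k) if normalization == "sqrt_k" else total / k
            rows.append({"module_id": mid, "direction": direction, "k": k,
                         "z_module": zm, "significant": bool(zm >= threshold)})
    return pd.DataFrame(rows, columns=["module_id", "direction", "k",
                                       "z_module", "significant"])


class ReporterScoreEnrichment(BaseEstimator):
    """Sklearn-style estimator for the full KO-test + reporter-score chain.

    ``fit(X, y)`` takes the samples x KO abundance frame and the two-level
    group labels; fitted attributes hold the per-KO test table and the
    per-module reporter scores.

    Parameters
    ----------
    catalog : module -> KO-set mapping (or long-format DataFrame).
    min_samples : int, prevalence filter (strictly greater than).
    normalization : 'sqrt_k' or 'k'.
    threshold : float, detection threshold on Z_module.
    adjust : 'bh' or 'none'.
    """

    def __init__(self, catalog=None, min_samples: int = 3,
                 normalization: str = "sqrt_k", threshold: float = 1.6,
                 adjust: str = "bh"):
        self.catalog = catalog
        self.min_samples = min_samples
        self.normalization = normalization
        self.threshold = threshold
        self.adjust = adjust

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("group labels y are required")
        if isinstance(self.catalog, pd.DataFrame):
            from .functions import catalog_from_table
            cat = catalog_from_table(self.catalog)
        elif self.catalog:
            cat = {m: frozenset(k) for m, k in dict(self.catalog).items()}
        else:
            raise ValueError("a module catalog is required")
        self.ko_results_ = ko_tests(X, y, min_samples=self.min_samples,
                                    adjust=self.adjust)
        self.module_scores_ = reporter_scores(
            self.ko_results_, cat, normalization=self.normalization,
            threshold=self.threshold)
        return self

    def significant_modules_(self, direction: str | None = None) -> pd.DataFrame:
        ms = self.module_scores_
        sig = ms[ms["significant"]]
        return sig if direction is None else sig[sig["direction"] == direction]
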