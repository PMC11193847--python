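"""Statistical primitives shared by the quantification and network modules.

Two-sample location tests (Wilcoxon rank-sum and Student's t), Benjamini-
Hochberg FDR adjustment, PLS-DA with variable-importance-in-projection (VIP)
scores, and a deterministic PCA projection.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "VipResult",
    "wilcoxon_rank_sum",
    "student_t",
    "bh_adjust",
    "plsda_vip",
    "pca_project",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, int]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class VipResult:
    """VIP scores from a PLS-DA fit.

    The scores satisfy the normalisation identity sum(VIP^2) = n_variables,
    so VIP > 1 marks variables contributing more than average to the
    class separation.
    """

    vip: np.ndarray
    n_components: int
    explained_y_variance: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def wilcoxon_rank_sum(x, y, exact_below_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact permutation null when the combined sample size is at most
    ``exact_below_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Ties receive average
    ranks.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # Degenerate: every observation identical; no evidence of a shift.
        ranks = sps.rankdata(combined)
        return TestResult(
            statistic=float(ranks[: x.size].sum()),
            p_value=1.0,
            method="wilcoxon_rank_sum/degenerate",
            n_per_group=(x.size, y.size),
            degenerate=True,
        )
    has_ties = np.unique(combined).size < combined.size
    use_exact = (combined.size <= exact_below_n) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    rank_sum = float(sps.rankdata(combined)[: x.size].sum())
    return TestResult(
        statistic=rank_sum,
        p_value=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon_rank_sum/{method}",
        n_per_group=(x.size, y.size),
    )


def student_t(x, y, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test (classical pooled-variance by default)."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = (np.var(x, ddof=1) * (x.size - 1) + np.var(y, ddof=1) * (y.size - 1))
    if pooled_var == 0.0 and not welch:
        equal_means = np.mean(x) == np.mean(y)
        return TestResult(
            statistic=0.0 if equal_means else np.inf,
            p_value=1.0 if equal_means else 0.0,
            method="student_t/degenerate",
            n_per_group=(x.size, y.size),
            degenerate=True,
        )
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="welch_t" if welch else "student_t",
        n_per_group=(x.size, y.size),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def plsda_vip(X, y, n_components: int = 1) -> VipResult:
    """Fit PLS-DA on a binary contrast and return per-variable VIP scores.

    X is samples x variables; columns are centred and unit-variance scaled
    internally.  The response is the 0/1 class indicator.  VIP for variable j:

        VIP_j = sqrt( p * sum_a SS_a * (w_ja / ||w_a||)^2 / sum_a SS_a )

    where SS_a is the response variance explained by component a and w_a the
    a-th weight vector.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    y01 = (y == classes[1]).astype(float)
    if np.bincount(y01.astype(int)).min() < 2:
        raise ValueError("each class needs at least 2 samples")
    col_sd = X.std(axis=0, ddof=1)
    dead = np.where(col_sd == 0)[0]
    if dead.size:
        raise ValueError(f"constant column(s) at index {dead.tolist()}: "
                         "VIP undefined for zero-variance variables")
    n, p = X.shape
    n_components = min(n_components, p, n - 1)
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y01)
    W = pls.x_weights_           # p x A
    T = pls.x_scores_            # n x A
    q = pls.y_loadings_.ravel()  # A

    # Response variance captured per component: SS_a = q_a^2 * t_a' t_a.
    ss = q**2 * np.einsum("ij,ij->j", T, T)
    if ss.sum() == 0:
        vip = np.ones(p)
    else:
        w_norm2 = np.einsum("ij,ij->j", W, W)
        w_norm2[w_norm2 == 0] = 1.0
        vip = np.sqrt(p * ((W**2 / w_norm2) @ ss) / ss.sum())
    total_y_var = np.var(y01) * n
    explained = ss / total_y_var if total_y_var > 0 else np.zeros_like(ss)
    return VipResult(vip=vip, n_components=n_components,
                     explained_y_variance=explained)


def pca_project(X, n_components: int, scale: bool = False):
    """Centered PCA by SVD with a deterministic sign convention.

    Returns ``(scores, loadings, explained_variance)`` where loadings has
    shape (variables, n_components).  Each component is flipped so that its
    largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 samples")
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)="
                         f"{min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_components].T
    # Sign convention: largest-|loading| entry of each component positive.
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = Xc @ V
    explained = (s[:n_components] ** 2) / (n - 1)
    return scores, V, explained
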