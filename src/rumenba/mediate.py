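"""Linear causal mediation analysis with bootstrap intervals.

The linear structural-equation model:

    M = alpha_1 + a * T + e_M
    Y = alpha_2 + c' * T + b * M + e_Y

gives the average causal mediation effect ACME = a*b (the indirect path), the
average direct effect ADE = c', the total effect a*b + c', and the proportion
mediated ACME / total.  Uncertainty comes from nonparametric case resampling
with percentile intervals.  Sensitivity to the sequential-ignorability
assumption is probed by fixing the correlation rho between the two error
terms and recomputing ACME(rho); under the linear model

    ACME(rho) = a * (sigma_2 / sigma_1) *
                (rho_tilde - rho * sqrt((1 - rho_tilde^2) / (1 - rho^2)))

where sigma_1, sigma_2 are the residual SDs of the mediator model and the
reduced-form outcome model (Y on T alone) and rho_tilde the correlation of
their residuals.  ACME crosses zero at rho = rho_tilde.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MediationInput",
    "MediationFit",
    "SensitivityCurve",
    "fit_mediation",
    "bootstrap_mediation",
    "sensitivity_curve",
]


@dataclass(frozen=True)
class MediationInput:
    """Aligned treatment / mediator / outcome vectors, optional covariates.

    A continuous treatment is standardised to unit SD by default so effects
    are per 1-SD change; binary treatments are left on their 0/1 scale.
    """

    treatment: np.ndarray
    mediator: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray | None = None
    scale_continuous_treatment: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.treatment, dtype=float).ravel()
        m = np.asarray(self.mediator, dtype=float).ravel()
        y = np.asarray(self.outcome, dtype=float).ravel()
        if not (t.size == m.size == y.size):
            raise ValueError("treatment, mediator, outcome lengths differ")
        if t.size < 4:
            raise ValueError("need at least 4 observations")
        if np.std(t) == 0:
            raise ValueError("treatment is constant")
        cov = self.covariates
        if cov is not None:
            cov = np.atleast_2d(np.asarray(cov, dtype=float))
            if cov.shape[0] != t.size:
                cov = cov.T
            if cov.shape[0] != t.size:
                raise ValueError("covariate rows do not match n")
        is_binary = set(np.unique(t)) <= {0.0, 1.0}
        if not is_binary and self.scale_continuous_treatment:
            t = t / np.std(t, ddof=1)
        object.__setattr__(self, "treatment", t)
        object.__setattr__(self, "mediator", m)
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return self.treatment.size


@dataclass
class MediationFit:
    """Point estimates (and optionally bootstrap CIs) of the mediation model."""

    a: float
    b: float
    c_prime: float
    acme: float
    ade: float
    total: float
    prop_mediated: float
    prop_flag: str = ""            # set when |prop| > 1 or total ~ 0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_mediation: float | None = None
    sims: int = 0
    seed: int | None = None
    conf_level: float = 0.95


def _ols(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residuals; errors on rank deficiency."""
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(design, response, rcond=None)
    return coef, response - design @ coef


def _point_estimates(t, m, y, cov) -> tuple[float, float, float]:
    n = t.size
    ones = np.ones((n, 1))
    blocks = [ones, t[:, None]]
    if cov is not None:
        blocks.append(cov)
    Xm = np.hstack(blocks)
    coef_m, _ = _ols(Xm, m)
    a = coef_m[1]
    Xy = np.hstack([ones, t[:, None], m[:, None]] +
                   ([cov] if cov is not None else []))
    coef_y, _ = _ols(Xy, y)
    c_prime, b = coef_y[1], coef_y[2]
    return float(a), float(b), float(c_prime)


def _assemble(a: float, b: float, c_prime: float) -> MediationFit:
    acme = a * b
    total = acme + c_prime
    if total == 0.0:
        prop, flag = np.nan, "total effect is zero; proportion undefined"
    else:
        prop = acme / total
        flag = "abs(proportion) > 1" if abs(prop) > 1 else ""
    return MediationFit(a=a, b=b, c_prime=c_prime, acme=acme, ade=c_prime,
                        total=total, prop_mediated=prop, prop_flag=flag)


def fit_mediation(X: MediationInput) -> MediationFit:
    """OLS point estimates: a, b, c', ACME = a*b, ADE = c', total, proportion."""
    a, b, c_prime = _point_estimates(X.treatment, X.mediator, X.outcome,
                                     X.covariates)
    return _assemble(a, b, c_prime)


def _fast_boot_estimates(t, m, y, idx) -> np.ndarray:
    """Vectorised (a, b, c') for many bootstrap index rows (no covariates).

    Closed-form OLS per resample: a from the simple regression of M on T;
    (c', b) from the bivariate regression of Y on (T, M).
    """
    T = t[idx]
    M = m[idx]
    Y = y[idx]
    T = T - T.mean(axis=1, keepdims=True)
    M = M - M.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)

    def cov(u, v):   # centred: avoids cancellation at tiny noise levels
        return (u * v).mean(axis=1)

    s_tt = cov(T, T)
    s_tm = cov(T, M)
    s_mm = cov(M, M)
    s_ty = cov(T, Y)
    s_my = cov(M, Y)
    a = s_tm / s_tt
    det = s_tt * s_mm - s_tm**2
    c_prime = (s_mm * s_ty - s_tm * s_my) / det
    b = (s_tt * s_my - s_tm * s_ty) / det
    return np.column_stack([a, b, c_prime])


def bootstrap_mediation(X: MediationInput, sims: int = 1000,
                        conf: float = 0.95, ci_type: str = "percentile",
                        seed: int = 0) -> MediationFit:
    """Nonparametric bootstrap of the mediation fit.

    Resamples rows with replacement ``sims`` times; percentile intervals at
    ``conf`` for ACME, ADE, total and proportion mediated.  The mediation
    p-value is the two-sided bootstrap sign test on ACME, floored at 1/sims.
    Resamples with a constant treatment are redrawn (at most 100 attempts
    each).  Deterministic for a fixed seed.
    """
    if ci_type != "percentile":
        raise ValueError("only percentile intervals are supported")
    if not (0.0 < conf < 1.0):
        raise ValueError("conf must be in (0, 1)")
    fit = fit_mediation(X)
    rng = np.random.default_rng(seed)
    n = X.n
    t, m, y = X.treatment, X.mediator, X.outcome

    idx = rng.integers(0, n, size=(sims, n))
    bad = np.ptp(t[idx], axis=1) == 0
    for _ in range(100):
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        bad = np.ptp(t[idx], axis=1) == 0
    else:
        raise RuntimeError("could not draw a resample with varying treatment")

    if X.covariates is None:
        abc = _fast_boot_estimates(t, m, y, idx)
    else:
        abc = np.empty((sims, 3))
        for k in range(sims):
            abc[k] = _point_estimates(t[idx[k]], m[idx[k]], y[idx[k]],
                                      X.covariates[idx[k]])
    acme_star = abc[:, 0] * abc[:, 1]
    ade_star = abc[:, 2]
    total_star = acme_star + ade_star
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_star = np.where(total_star != 0, acme_star / total_star, np.nan)

    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2

    def ci(v):
        v = v[~np.isnan(v)]
        return (float(np.quantile(v, lo_q)), float(np.quantile(v, hi_q)))

    fit.ci = {"acme": ci(acme_star), "ade": ci(ade_star),
              "total": ci(total_star), "prop_mediated": ci(prop_star)}
    frac_le = float(np.mean(acme_star <= 0))
    frac_ge = float(np.mean(acme_star >= 0))
    fit.p_mediation = float(np.clip(2 * min(frac_le, frac_ge), 1.0 / sims, 1.0))
    fit.sims = sims
    fit.seed = seed
    fit.conf_level = conf
    return fit


@dataclass
class SensitivityCurve:
    """ACME as a function of the assumed error correlation rho."""

    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    rho_zero: float | None

    def acme_at(self, rho: float) -> float:
        j = int(np.argmin(np.abs(self.rho_grid - rho)))
        if abs(self.rho_grid[j] - rho) > 1e-9:
            raise ValueError(f"rho={rho} not on the grid")
        return float(self.acme_at_rho[j])


def sensitivity_curve(X: MediationInput,
                      rho_grid=None) -> SensitivityCurve:
    """ACME(rho) under a fixed mediator/outcome error correlation rho.

    Linear-linear models only.  rho_zero is the grid-interpolated crossing of
    ACME through 0 (analytically rho_tilde, the observed residual
    correlation); None if the curve does not change sign on the grid.
    """
    if rho_grid is None:
        rho_grid = np.round(np.arange(-0.9, 0.9 + 1e-9, 0.1), 10)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho_grid) >= 1.0):
        raise ValueError("all rho values must satisfy |rho| < 1")

    t, m, y, cov = X.treatment, X.mediator, X.outcome, X.covariates
    n = t.size
    ones = np.ones((n, 1))
    ext = [cov] if cov is not None else []
    _, res_m = _ols(np.hstack([ones, t[:, None]] + ext), m)
    a, _, _ = _point_estimates(t, m, y, cov)
    # Reduced form: Y on T (and covariates) only.
    _, res_y = _ols(np.hstack([ones, t[:, None]] + ext), y)
    k = 2 + (cov.shape[1] if cov is not None else 0)
    dof = n - k
    sigma1 = np.sqrt(res_m @ res_m / dof)
    sigma2 = np.sqrt(res_y @ res_y / dof)
    rho_tilde = float(res_m @ res_y / np.sqrt((res_m @ res_m) * (res_y @ res_y)))

    acme = a * (sigma2 / sigma1) * (
        rho_tilde - rho_grid * np.sqrt((1 - rho_tilde**2) / (1 - rho_grid**2)))

    rho_zero = None
    sign = np.sign(acme)
    for j in range(len(rho_grid) - 1):
        if sign[j] == 0:
            rho_zero = float(rho_grid[j])
            break
        if sign[j] * sign[j + 1] < 0:
            r0, r1 = rho_grid[j], rho_grid[j + 1]
            a0, a1 = acme[j], acme[j + 1]
            rho_zero = float(r0 - a0 * (r1 - r0) / (a1 - a0))
            break
    return SensitivityCurve(rho_grid=rho_grid, acme_at_rho=acme,
                            rho_zero=rho_zero)
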