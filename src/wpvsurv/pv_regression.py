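"""Weighted GLM of pseudo-value responses on a binary group indicator.

The model has mean ``mu = exp(-exp(beta0 + beta1 * z))`` — a
log-minus-log link, so that ``beta0 = log(-log S0(t*))`` and the group
contrast ``beta1`` equals the log cumulative hazard ratio
``log[log S1(t*) / log S0(t*)]``'s linear-predictor difference, i.e.
``exp(beta1)`` is the cHR — with an identity (normal) variance function
and a cluster-robust sandwich covariance.

Because the design is saturated (intercept plus one binary indicator),
the weighted quasi-likelihood estimating equations are solved exactly by
the weighted group means of the responses; the closed form is used as
the default fitting path and an iterative Fisher-scoring path is kept as
a cross-check.  Pseudo-value responses may lie outside [0, 1] and are
never clipped; only the fitted group *means* must lie in (0, 1) for the
link to be defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ResponseRow",
    "FitResult",
    "FitError",
    "fit",
    "fit_irls",
    "sandwich_cov",
    "wald_interval",
    "probability_interval",
    "ratio_interval",
]


class FitError(ValueError):
    """The weighted GLM cannot be fitted on the given rows."""


@dataclass(frozen=True)
class ResponseRow:
    """One regression row: pseudo-value, weight, group indicator, cluster.

    Rows sharing a ``cluster_id`` originate from the same patient (the
    weighted approach duplicates unknown-membership patients into both
    groups) and have their score contributions summed before entering
    the sandwich's meat matrix.
    """

    value: float
    weight: float
    z: int
    cluster_id: str

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if self.z not in (0, 1):
            raise ValueError(f"z must be 0 or 1, got {self.z}")


@dataclass(frozen=True)
class FitResult:
    """Estimates on the log(-log S) scale with back-transformed summaries.

    ``S0_hat = exp(-exp(beta0))``, ``S1_hat = exp(-exp(beta0 + beta1))``,
    ``cHR = exp(beta1)``; confidence intervals are Wald intervals on the
    link scale mapped through the (monotone) back-transformations, and
    ``p_value`` is the two-sided Wald test of ``beta1 = 0``.
    """

    beta0: float
    beta1: float
    cov: np.ndarray
    S0_hat: float
    S1_hat: float
    cHR: float
    ci_level: float
    S0_ci: tuple[float, float]
    S1_ci: tuple[float, float]
    cHR_ci: tuple[float, float]
    beta0_se: float
    beta1_se: float
    p_value: float
    n_clusters: int
    iterations: int
    converged: bool

    def report(self) -> str:
        """Human-readable fit summary."""
        lo = 100 * self.ci_level
        lines = [
            f"clusters: {self.n_clusters}",
            f"S0(t*) = {self.S0_hat:.4f}  ({lo:.0f}% CI "
            f"{self.S0_ci[0]:.4f}-{self.S0_ci[1]:.4f})",
            f"S1(t*) = {self.S1_hat:.4f}  ({lo:.0f}% CI "
            f"{self.S1_ci[0]:.4f}-{self.S1_ci[1]:.4f})",
            f"cHR    = {self.cHR:.4f}  ({lo:.0f}% CI "
            f"{self.cHR_ci[0]:.4f}-{self.cHR_ci[1]:.4f}; "
            f"p = {self.p_value:.4g})",
            f"beta0  = {self.beta0:.6f} (se {self.beta0_se:.6f})",
            f"beta1  = {self.beta1:.6f} (se {self.beta1_se:.6f})",
        ]
        return "\n".join(lines)


def _arrays(rows):
    v = np.array([r.value for r in rows], dtype=float)
    w = np.array([r.weight for r in rows], dtype=float)
    z = np.array([r.z for r in rows], dtype=float)
    cl = np.array([r.cluster_id for r in rows])
    return v, w, z, cl


def _group_means(v, w, z):
    means = []
    for g in (0.0, 1.0):
        sel = z == g
        total = w[sel].sum()
        if total <= 0:
            raise FitError(f"group z={int(g)} has zero total weight")
        means.append(float(np.dot(w[sel], v[sel]) / total))
    return means


def _check_open_unit(mu: float, g: int) -> None:
    if not (0.0 < mu < 1.0):
        raise FitError(
            f"weighted mean pseudo-value of group z={g} is {mu:.6g}, "
            "outside (0,1): log(-log) link undefined"
        )


def wald_interval(estimate: float, se: float, level: float) -> tuple[float, float]:
    """Symmetric normal-quantile interval ``estimate +/- z * se``."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0,1)")
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return (estimate - zq * se, estimate + zq * se)


def probability_interval(link_interval: tuple[float, float]) -> tuple[float, float]:
    """Map a link-scale interval through ``exp(-exp(.))`` (decreasing:
    endpoints swap so the probability interval stays ordered)."""
    lo, hi = link_interval
    return (math.exp(-math.exp(hi)), math.exp(-math.exp(lo)))


def ratio_interval(link_interval: tuple[float, float]) -> tuple[float, float]:
    """Map a link-scale interval for ``beta1`` through ``exp``."""
    lo, hi = link_interval
    return (math.exp(lo), math.exp(hi))


def sandwich_cov(rows, beta) -> np.ndarray:
    """Cluster-robust sandwich covariance ``A^{-1} B A^{-T}``.

    ``A`` is the weighted quasi-information ``sum_i w_i (dmu/deta)_i^2
    x_i x_i'`` and ``B`` sums outer products of *per-cluster* score sums
    ``sum_{i in c} w_i (V_i - mu_i) (dmu/deta)_i x_i``.  With singleton
    clusters this is the ordinary heteroscedasticity-robust estimator.
    """
    v, w, z, cl = _arrays(rows)
    beta = np.asarray(beta, dtype=float)
    X = np.column_stack([np.ones_like(z), z])
    eta = X @ beta
    mu = np.exp(-np.exp(eta))
    dmu = mu * np.log(mu)  # dmu/deta = -exp(eta) exp(-exp(eta))

    A = (X * (w * dmu**2)[:, None]).T @ X
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular quasi-information matrix") from exc

    score = (w * (v - mu) * dmu)[:, None] * X
    # sum scores within cluster before squaring
    _, inverse = np.unique(cl, return_inverse=True)
    n_clusters = inverse.max() + 1
    cluster_scores = np.zeros((n_clusters, 2))
    np.add.at(cluster_scores, inverse, score)
    B = cluster_scores.T @ cluster_scores
    return A_inv @ B @ A_inv.T


def fit_irls(rows, *, max_iter: int = 100, tol: float = 1e-12) -> tuple[np.ndarray, int]:
    """Iterative Fisher-scoring solution of the estimating equations.

    Exists as a cross-check of the closed form; starts from the
    no-effect point (both group probabilities 0.5).  Returns ``(beta,
    iterations)``; raises :class:`FitError` with the iteration log on
    non-convergence.
    """
    v, w, z, _ = _arrays(rows)
    X = np.column_stack([np.ones_like(z), z])
    beta = np.array([math.log(-math.log(0.5)), 0.0])
    log: list[str] = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(-np.exp(eta))
        dmu = mu * np.log(mu)
        U = X.T @ (w * (v - mu) * dmu)
        A = (X * (w * dmu**2)[:, None]).T @ X
        try:
            step = np.linalg.solve(A, U)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information during Fisher scoring") from exc
        beta = beta + step
        log.append(f"iter {it}: beta={beta}, |step|={np.abs(step).max():.3e}")
        if np.abs(step).max() < tol:
            return beta, it
    raise FitError(
        "Fisher scoring did not converge in "
        f"{max_iter} iterations:\n" + "\n".join(log)
    )


def fit(rows, ci_level: float = 0.95, *, method: str = "closed_form") -> FitResult:
    """Fit the two-group weighted pseudo-value GLM.

    The saturated design makes the fit exact: the fitted group means are
    the weighted group means of the responses, and ``beta0``/``beta1``
    follow by the log(-log) transform.  ``method='irls'`` runs the
    iterative path instead (identical to numerical tolerance).
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0,1)")
    rows = list(rows)
    v, w, z, cl = _arrays(rows)
    n_clusters = len(set(cl.tolist()))
    if n_clusters < 2:
        raise FitError("need at least 2 clusters")

    mu0, mu1 = _group_means(v, w, z)
    _check_open_unit(mu0, 0)
    _check_open_unit(mu1, 1)

    if method == "closed_form":
        beta = np.array(
            [
                math.log(-math.log(mu0)),
                math.log(-math.log(mu1)) - math.log(-math.log(mu0)),
            ]
        )
        iterations, converged = 0, True
    elif method == "irls":
        beta, iterations = fit_irls(rows)
        converged = True
    else:
        raise ValueError(f"unknown method {method!r}")

    cov = sandwich_cov(rows, beta)
    se0 = math.sqrt(max(cov[0, 0], 0.0))
    var_eta1 = cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1]
    se_eta1 = math.sqrt(max(var_eta1, 0.0))
    se1 = math.sqrt(max(cov[1, 1], 0.0))

    beta0, beta1 = float(beta[0]), float(beta[1])
    s0 = math.exp(-math.exp(beta0))
    s1 = math.exp(-math.exp(beta0 + beta1))
    chr_ = math.exp(beta1)

    s0_ci = probability_interval(wald_interval(beta0, se0, ci_level))
    s1_ci = probability_interval(wald_interval(beta0 + beta1, se_eta1, ci_level))
    chr_ci = ratio_interval(wald_interval(beta1, se1, ci_level))
    if se1 > 0:
        p_val = 2.0 * stats.norm.sf(abs(beta1) / se1)
    else:
        p_val = 0.0 if beta1 != 0 else 1.0

    return FitResult(
        beta0=beta0,
        beta1=beta1,
        cov=cov,
        S0_hat=s0,
        S1_hat=s1,
        cHR=chr_,
        ci_level=ci_level,
        S0_ci=s0_ci,
        S1_ci=s1_ci,
        cHR_ci=chr_ci,
        beta0_se=se0,
        beta1_se=se1,
        p_value=float(p_val),
        n_clusters=n_clusters,
        iterations=iterations,
        converged=converged,
    )
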