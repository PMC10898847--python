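"""Maximum-likelihood logistic mixed models by adaptive Gauss-Hermite
quadrature.

Supports a random intercept per group (subject) and optionally an
additional independent random slope on one covariate — the structures the
stay/switch analyses need (``(1 | subject)`` and ``(1 + time || subject)``
in lme4 notation).  Random effects are integrated out with per-group
adaptive quadrature (mode + curvature found by Newton's method), and the
marginal likelihood is maximized by quasi-Newton.  Wald standard errors
come from the numerical Hessian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["SeparationError", "MixedLogitResult", "fit_mixed_logit"]


class SeparationError(ValueError):
    """The outcome is (quasi-)separated; the MLE does not exist."""


@dataclass
class MixedLogitResult:
    """Fitted fixed effects with Wald inference and random-effect SDs."""

    params: pd.Series          # fixed-effect estimates (log-odds)
    bse: pd.Series
    cov_params: pd.DataFrame   # fixed-effect covariance (Wald)
    re_sd: dict[str, float]    # random-effect standard deviations
    loglike: float
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "z": self.zvalues,
            "p": self.pvalues,
            "OR": np.exp(self.params),
            "OR_lo": np.exp(self.params - z * self.bse),
            "OR_hi": np.exp(self.params + z * self.bse),
        })

    def summary(self) -> str:
        df = self.odds_ratios()
        lines = [f"Mixed logistic regression  (n={self.n_obs}, "
                 f"groups={self.n_groups}, loglik={self.loglike:.1f})"]
        for name in ("intercept", "slope"):
            if name in self.re_sd:
                lines.append(f"  random {name} sd: {self.re_sd[name]:.3f}")
        lines.append(df.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def _check_separation(y: np.ndarray, groups: np.ndarray,
                      cells: Optional[pd.DataFrame]) -> None:
    if y.min() == y.max():
        raise SeparationError(
            f"outcome is constant (= {int(y[0])}) over all observations"
        )
    if cells is not None and len(cells.columns):
        grouped = pd.Series(y).groupby(
            [cells[c] for c in cells.columns]
        )
        for key, vals in grouped:
            if vals.min() == vals.max() and len(vals) > 1:
                cell = ", ".join(
                    f"{c}={k}" for c, k in zip(cells.columns, np.atleast_1d(key))
                )
                raise SeparationError(
                    f"outcome is constant (= {int(vals.iloc[0])}) in cell "
                    f"[{cell}]"
                )


def fit_mixed_logit(
    X: pd.DataFrame,
    y: Sequence[int],
    groups: Sequence,
    slope: Optional[Sequence[float]] = None,
    n_quad: int = 12,
    check_cells: Optional[pd.DataFrame] = None,
    maxiter: int = 300,
) -> MixedLogitResult:
    """Fit a logistic mixed model with logit link.

    Parameters
    ----------
    X : fixed-effect design matrix (include a constant column yourself).
    y : binary outcome.
    groups : cluster labels (random-intercept grouping factor).
    slope : optional covariate carrying an independent random slope.
    check_cells : optional design-cell frame; a constant outcome within
        any cell raises :class:`SeparationError` naming the cell.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    gv = pd.factorize(np.asarray(groups))[0]
    n_groups = gv.max() + 1
    _check_separation(yv, gv, check_cells)

    has_slope = slope is not None
    zv = np.asarray(slope, dtype=float) if has_slope else None

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights)
    if has_slope:
        NX, NY = np.meshgrid(nodes, nodes, indexing="ij")
        node_grid = np.column_stack([NX.ravel(), NY.ravel()])
        log_w_grid = (log_w[:, None] + log_w[None, :]).ravel()
        node_sq = (node_grid ** 2).sum(axis=1)
        order = np.argsort(gv, kind="stable")
        bounds = np.searchsorted(gv[order], np.arange(n_groups + 1))
        gX = [Xv[order[bounds[k]:bounds[k + 1]]] for k in range(n_groups)]
        gy = [yv[order[bounds[k]:bounds[k + 1]]] for k in range(n_groups)]
        gz = [zv[order[bounds[k]:bounds[k + 1]]] for k in range(n_groups)]

    p_fe = Xv.shape[1]
    # modes are warm-started across objective evaluations
    mode_cache = np.zeros(n_groups)

    def negloglik(par):
        beta = par[:p_fe]
        sd0 = np.exp(par[p_fe])
        if has_slope:
            sd1 = np.exp(par[p_fe + 1])
            total = 0.0
            for k in range(n_groups):
                total += _group_loglik_2d(
                    gX[k] @ beta, gy[k], gz[k], sd0, sd1,
                    node_grid, log_w_grid, node_sq,
                )
            return -total
        return -_loglik_1d_all(
            Xv @ beta, yv, gv, n_groups, sd0, nodes, log_w, mode_cache
        )

    start = np.zeros(p_fe + 1 + int(has_slope))
    start[:p_fe] = _glm_start(Xv, yv)
    start[p_fe:] = np.log(0.5)
    res = optimize.minimize(
        negloglik, start, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    if not res.success:
        warnings.warn(f"mixed-logit optimizer: {res.message}", stacklevel=2)
    par = res.x
    H = _num_hessian(negloglik, par)
    cov_all = _safe_inv(H)
    cov_fe = cov_all[:p_fe, :p_fe]
    bse = np.sqrt(np.maximum(np.diag(cov_fe), 0.0))
    re_sd = {"intercept": float(np.exp(par[p_fe]))}
    if has_slope:
        re_sd["slope"] = float(np.exp(par[p_fe + 1]))
    return MixedLogitResult(
        params=pd.Series(par[:p_fe], index=names),
        bse=pd.Series(bse, index=names),
        cov_params=pd.DataFrame(cov_fe, index=names, columns=names),
        re_sd=re_sd,
        loglike=-float(res.fun),
        n_obs=len(yv),
        n_groups=int(n_groups),
        converged=bool(res.success),
    )


def _glm_start(X, y):
    """Plain logistic regression starting values (ridge fallback)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=50
            ).params
        except Exception:
            return np.zeros(X.shape[1])


def _bernoulli_loglik(eta, y):
    # y*eta - log(1 + e^eta), numerically safe
    return y * eta - np.logaddexp(0.0, eta)


def _loglik_1d_all(eta0, y, g, n_groups, sd, nodes, log_w, mode_cache):
    """Adaptive 1-D Gauss-Hermite marginal log-likelihood, all groups at
    once (Newton mode search vectorized across groups via bincount)."""
    prec = 1.0 / sd ** 2
    b = mode_cache.copy()
    for _ in range(50):
        p = special.expit(eta0 + b[g])
        grad = np.bincount(g, weights=y - p, minlength=n_groups) - b * prec
        curv = np.bincount(g, weights=p * (1 - p), minlength=n_groups) + prec
        step = grad / curv
        b += step
        if np.max(np.abs(step)) < 1e-9:
            break
    mode_cache[:] = b
    p = special.expit(eta0 + b[g])
    curv = np.bincount(g, weights=p * (1 - p), minlength=n_groups) + prec
    tau = 1.0 / np.sqrt(curv)
    # vals[k, q]: group-k joint log density at quadrature point q
    pts = b[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    vals = np.empty((n_groups, nodes.shape[0]))
    for q in range(nodes.shape[0]):
        bb = pts[:, q]
        vals[:, q] = np.bincount(
            g, weights=_bernoulli_loglik(eta0 + bb[g], y),
            minlength=n_groups,
        ) + stats.norm.logpdf(bb, scale=sd)
    per_group = (np.log(np.sqrt(2.0) * tau)
                 + special.logsumexp(log_w[None, :] + nodes[None, :] ** 2
                                     + vals, axis=1))
    return float(per_group.sum())


def _group_loglik_2d(eta0, y, z, sd0, sd1, node_grid, log_w_grid, node_sq):
    """Adaptive 2-D quadrature: independent random intercept and slope."""
    b = np.zeros(2)
    prec = np.array([1.0 / sd0 ** 2, 1.0 / sd1 ** 2])
    Z = np.column_stack([np.ones_like(z), z])
    for _ in range(25):
        p = special.expit(eta0 + Z @ b)
        g = Z.T @ (y - p) - prec * b
        W = p * (1 - p)
        H = -(Z.T * W) @ Z - np.diag(prec)
        step = np.linalg.solve(H, g)
        b -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(eta0 + Z @ b)
    W = p * (1 - p)
    curv = (Z.T * W) @ Z + np.diag(prec)            # -Hessian at mode
    L = np.linalg.cholesky(np.linalg.inv(curv))
    pts = b + np.sqrt(2.0) * node_grid @ L.T
    eta = eta0[None, :] + pts @ Z.T
    vals = (_bernoulli_loglik(eta, y[None, :]).sum(axis=1)
            + stats.norm.logpdf(pts[:, 0], scale=sd0)
            + stats.norm.logpdf(pts[:, 1], scale=sd1))
    log_det = np.log(2.0) + np.log(np.abs(np.diag(L))).sum()
    return log_det + special.logsumexp(log_w_grid + node_sq + vals)


def _num_hessian(f, x, step=1e-4):
    d = x.shape[0]
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step ** 2)
    return H


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)
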