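"""Hierarchical empirical-Bayes MAP estimation of the hybrid model.

Each subject's per-session parameters are estimated by maximum a
posteriori under a Gaussian population prior on unconstrained parameters
(alpha through a logistic transform, the non-negative betas through an
exponential, the repetition bias untransformed).  The prior itself is
estimated from the cohort by expectation-maximization: the E-step computes
per-subject MAP estimates and Laplace posterior covariances given the
current prior, the M-step re-estimates the prior mean and covariance from
those.  Sessions of the same subject are fitted jointly — the prior lives
on the stacked (two-session) parameter vector with a full covariance, so
information is shared both across subjects and across sessions.

A likelihood-ratio screen against the random-choice null model flags
subjects whose data the model fits no better than chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from . import _kernels
from .agent import PARAM_NAMES, ParameterSet, chance_loglik
from .task import SESSIONS, SessionData

__all__ = [
    "to_unconstrained",
    "to_natural",
    "PriorModel",
    "FitResult",
    "map_fit_subject",
    "em_fit_population",
    "lrt_vs_chance",
    "HierarchicalMAPEstimator",
    "parameter_table",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


def to_unconstrained(params: ParameterSet) -> np.ndarray:
    """Map natural parameters to the real line.

    alpha -> logit(alpha); beta_mb, beta_mf, beta_consistency -> log;
    beta_rep unchanged.  Boundary values are clipped with a warning.
    """
    a = params.alpha
    if a <= 0.0 or a >= 1.0:
        warnings.warn(f"alpha={a} clipped away from the boundary",
                      stacklevel=2)
        a = np.clip(a, _EPS, 1.0 - _EPS)
    out = np.empty(5)
    out[0] = np.log(a / (1.0 - a))
    for i, name in ((1, "beta_mb"), (2, "beta_mf"), (4, "beta_consistency")):
        b = getattr(params, name)
        if b <= 0.0:
            warnings.warn(f"{name}={b} clipped away from zero", stacklevel=2)
            b = _EPS
        out[i] = np.log(b)
    out[3] = params.beta_rep
    return out


def to_natural(theta: Sequence[float]) -> ParameterSet:
    """Inverse of :func:`to_unconstrained`."""
    theta = np.asarray(theta, dtype=float)
    return ParameterSet(
        alpha=float(1.0 / (1.0 + np.exp(-theta[0]))),
        beta_mb=float(np.exp(theta[1])),
        beta_mf=float(np.exp(theta[2])),
        beta_rep=float(theta[3]),
        beta_consistency=float(np.exp(theta[4])),
    )


@dataclass
class PriorModel:
    """Gaussian population prior on unconstrained parameters.

    ``dim`` is 5 for single-session cohorts or 10 for joint two-session
    fitting (baseline block first, follow-up block second).
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.dim, self.dim):
            raise ValueError("sigma shape does not match mu")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        # positive-definiteness is required for logpdf/sampling
        np.linalg.cholesky(self.sigma)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    def logpdf(self, theta: np.ndarray) -> float:
        return float(stats.multivariate_normal.logpdf(
            theta, mean=self.mu, cov=self.sigma
        ))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.multivariate_normal(self.mu, self.sigma, size=n)

    def marginal(self, idx: Sequence[int]) -> "PriorModel":
        idx = np.asarray(idx)
        return PriorModel(self.mu[idx], self.sigma[np.ix_(idx, idx)])

    @classmethod
    def default(cls, dim: int = 5, scale: float = 1.5) -> "PriorModel":
        return cls(np.zeros(dim), np.eye(dim) * scale ** 2)


@dataclass
class FitResult:
    """Per-subject MAP output."""

    subject_id: str
    session_labels: list[str]
    theta: np.ndarray                      # 5 * n_sessions, unconstrained
    params: dict[str, ParameterSet]        # by session label
    map_loglik: float                      # penalized objective (maximized)
    data_loglik: float                     # unpenalized, summed over sessions
    data_loglik_by_session: dict[str, float]
    chance_loglik: float
    post_cov: Optional[np.ndarray]         # Laplace posterior covariance
    n_restarts_used: int
    converged: bool
    lrt_stat: float = np.nan
    lrt_df: int = 0
    lrt_p: float = np.nan
    excluded_by_lrt: bool = False

    @property
    def n_sessions(self) -> int:
        return len(self.session_labels)


def _stack_sessions(sessions: Sequence[SessionData]):
    """Flatten 1-2 sessions into the kernel's concatenated-array layout,
    ordered baseline before follow-up."""
    ordered = sorted(sessions, key=lambda s: SESSIONS.index(s.session))
    arrs = [s.to_arrays() for s in ordered]
    offsets = np.zeros(len(ordered) + 1, dtype=np.int64)
    for i, a in enumerate(arrs):
        offsets[i + 1] = offsets[i] + a["c1"].shape[0]
    cat = {
        k: np.concatenate([a[k] for a in arrs])
        for k in ("c1", "s", "c2", "r", "valid1", "valid2")
    }
    return ordered, cat, offsets


def _neg_penalized(theta, n_sessions, cat, offsets, prior):
    nll = _kernels.negloglik_multi(
        theta, n_sessions, cat["c1"], cat["s"], cat["c2"], cat["r"],
        cat["valid1"], cat["valid2"], offsets,
    )
    return nll - prior.logpdf(theta)


def _numerical_hessian(f, x, step=1e-3):
    d = x.shape[0]
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step
            ej[j] = step
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step ** 2)
    return H


def map_fit_subject(
    sessions: Sequence[SessionData],
    prior: PriorModel,
    n_starts: int = 10,
    n_fits: int = 50,
    rng: Optional[np.random.Generator] = None,
    warm_start: Optional[np.ndarray] = None,
    opt_tol: float = 1e-6,
    compute_hessian: bool = True,
) -> FitResult:
    """MAP-fit one subject's 1-2 sessions under a Gaussian prior.

    Runs up to ``n_fits`` quasi-Newton optimizations started from
    ``n_starts`` distinct prior draws (each run jitters its base start) and
    keeps the best penalized objective.  An optional ``warm_start`` vector
    is always tried first.
    """
    if rng is None:
        rng = np.random.default_rng()
    ordered, cat, offsets = _stack_sessions(sessions)
    n_sessions = len(ordered)
    dim = 5 * n_sessions
    if prior.dim != dim:
        raise ValueError(
            f"prior dimension {prior.dim} does not match {n_sessions} "
            f"session(s) (need {dim})"
        )

    def objective(theta):
        return _neg_penalized(theta, n_sessions, cat, offsets, prior)

    base_starts = prior.sample(rng, n_starts)
    starts: list[np.ndarray] = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    for i in range(max(0, n_fits - len(starts))):
        jitter = 0.0 if i < n_starts else rng.normal(0.0, 0.25, size=dim)
        starts.append(base_starts[i % n_starts] + jitter)

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"ftol": opt_tol, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    data_by_session = {}
    for k, sess in enumerate(ordered):
        block = theta[5 * k: 5 * (k + 1)]
        nll = _kernels.negloglik_multi(
            block, 1, *(cat[c][offsets[k]:offsets[k + 1]] for c in
                        ("c1", "s", "c2", "r", "valid1", "valid2")),
            np.array([0, offsets[k + 1] - offsets[k]], dtype=np.int64),
        )
        data_by_session[sess.session] = -float(nll)
    data_ll = sum(data_by_session.values())

    post_cov = None
    if compute_hessian:
        H = _numerical_hessian(objective, theta)
        post_cov = _robust_inverse(H)

    fit = FitResult(
        subject_id=ordered[0].subject_id,
        session_labels=[s.session for s in ordered],
        theta=theta,
        params={
            s.session: to_natural(theta[5 * k: 5 * (k + 1)])
            for k, s in enumerate(ordered)
        },
        map_loglik=-float(best.fun),
        data_loglik=float(data_ll),
        data_loglik_by_session=data_by_session,
        chance_loglik=sum(chance_loglik(s) for s in ordered),
        post_cov=post_cov,
        n_restarts_used=len(starts),
        converged=any_converged,
    )
    stat, p, excluded = lrt_vs_chance(fit)
    fit.lrt_stat, fit.lrt_p, fit.excluded_by_lrt = stat, p, excluded
    fit.lrt_df = dim
    return fit


def _robust_inverse(H: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Invert a Hessian, ridge-regularizing if it is not positive-definite."""
    d = H.shape[0]
    try:
        np.linalg.cholesky(H)
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(H)
        shift = max(ridge, ridge - w.min())
        logger.warning("Hessian not positive-definite; ridge %.2e applied",
                       shift)
        return np.linalg.inv(H + shift * np.eye(d))


def lrt_vs_chance(
    fit: FitResult, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Likelihood-ratio screen of the fitted model against random choice.

    The chance model assigns probability one half to every observed choice
    and is the betas-to-zero limit of the hybrid model, so the statistic
    2*(data_loglik - chance_loglik) is referred to a chi-square with five
    degrees of freedom per fitted session.  Subjects with p >= alpha are
    flagged for exclusion from parameter-level analyses.
    """
    stat = 2.0 * (fit.data_loglik - fit.chance_loglik)
    df = 5 * fit.n_sessions
    p = float(stats.chi2.sf(stat, df))
    return float(stat), p, p >= alpha


def em_fit_population(
    subjects: Sequence[Sequence[SessionData]],
    init: Optional[PriorModel] = None,
    max_iter: int = 40,
    tol: float = 1e-3,
    n_starts: int = 10,
    n_fits: int = 50,
    n_refine_fits: int = 5,
    covariance: str = "full",
    seed: Optional[int] = None,
    opt_tol: float = 1e-6,
    ridge: float = 1e-4,
) -> tuple[PriorModel, list[FitResult]]:
    """Fit the population prior and all subjects by EM.

    ``subjects`` is a list of per-subject session lists (1 or 2 sessions
    each).  With any two-session subject present the prior is the 10-dim
    joint model; baseline-only subjects are then fitted under its 5-dim
    marginal.  After the first E-step, subject fits are warm-started from
    their previous optimum with ``n_refine_fits`` fresh restarts.
    """
    if len(subjects) < 2:
        raise ValueError("EM requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    n_max = max(len(s) for s in subjects)
    dim = 5 * n_max
    prior = init if init is not None else PriorModel.default(dim)
    if prior.dim != dim:
        raise ValueError(f"init prior dim {prior.dim}, expected {dim}")

    slot_idx = {label: np.arange(5 * i, 5 * (i + 1))
                for i, label in enumerate(SESSIONS[:n_max])}
    fits: list[Optional[FitResult]] = [None] * len(subjects)
    history: list[float] = []
    converged = False
    for it in range(max_iter):
        # E-step: per-subject MAP under the current prior
        marg_ll = 0.0
        for i, sessions in enumerate(subjects):
            labels = sorted({s.session for s in sessions},
                            key=SESSIONS.index)
            idx = np.concatenate([slot_idx[lab] for lab in labels])
            sub_prior = prior.marginal(idx) if len(idx) < dim else prior
            warm = fits[i].theta if fits[i] is not None else None
            fits[i] = map_fit_subject(
                sessions, sub_prior,
                n_starts=n_starts if it == 0 else max(2, n_refine_fits),
                n_fits=n_fits if it == 0 else n_refine_fits,
                rng=rng, warm_start=warm, opt_tol=opt_tol,
            )
            d_i = fits[i].theta.shape[0]
            sign, logdet = np.linalg.slogdet(fits[i].post_cov)
            if sign > 0:
                marg_ll += (fits[i].map_loglik
                            + 0.5 * (d_i * np.log(2 * np.pi) + logdet))
        history.append(marg_ll)
        # M-step: prior mean/covariance from MAP estimates + Laplace terms
        new_mu, new_sigma = _m_step(
            subjects, fits, slot_idx, dim, covariance, ridge
        )
        delta = float(np.max(np.abs(new_mu - prior.mu)))
        prior = PriorModel(new_mu, new_sigma)
        logger.info("EM iter %d: marg_ll=%.2f, max|dmu|=%.4g",
                    it + 1, marg_ll, delta)
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    prior.em_history = history          # attached diagnostics
    prior.em_converged = converged
    return prior, [f for f in fits if f is not None]


def _m_step(subjects, fits, slot_idx, dim, covariance, ridge):
    mu = np.zeros(dim)
    counts = np.zeros(dim)
    per_subject = []
    for fit in fits:
        idx = np.concatenate([slot_idx[lab] for lab in fit.session_labels])
        per_subject.append((idx, fit.theta, fit.post_cov))
        mu[idx] += fit.theta
        counts[idx] += 1
    counts = np.maximum(counts, 1)
    mu = mu / counts
    sigma = np.zeros((dim, dim))
    pair_counts = np.zeros((dim, dim))
    for idx, theta, cov in per_subject:
        dev = theta - mu[idx]
        contrib = np.outer(dev, dev) + cov
        sigma[np.ix_(idx, idx)] += contrib
        pair_counts[np.ix_(idx, idx)] += 1
    pair_counts = np.maximum(pair_counts, 1)
    sigma = sigma / pair_counts
    if covariance == "diag":
        sigma = np.diag(np.diag(sigma))
    sigma = 0.5 * (sigma + sigma.T)
    # guarantee positive-definiteness
    w = np.linalg.eigvalsh(sigma)
    if w.min() < ridge:
        sigma += (ridge - min(w.min(), 0.0)) * np.eye(dim)
    return mu, sigma


def parameter_table(fits: Sequence[FitResult]):
    """Flat per-session parameter table (one row per subject-session)."""
    import pandas as pd

    rows = []
    for fit in fits:
        for label in fit.session_labels:
            p = fit.params[label]
            # per-session chance comparison with 5 df
            d_ll = fit.data_loglik_by_session[label]
            rows.append({
                "subject_id": fit.subject_id,
                "session": label,
                **p.as_dict(),
                "data_loglik": d_ll,
                "lrt_p": fit.lrt_p,
                "excluded": fit.excluded_by_lrt,
            })
    return pd.DataFrame(rows)


class HierarchicalMAPEstimator(BaseEstimator):
    """Hierarchical empirical-Bayes MAP fitter, sklearn-style.

    Parameters
    ----------
    n_starts, n_fits : int
        Distinct starting points and total optimizer runs per subject on
        the first E-step (defaults are desk scale; raise ``n_fits`` toward
        500 for a heavy-duty fit).
    n_refine_fits : int
        Restarts per subject on warm-started later E-steps.
    max_em_iter, em_tol : EM stopping rule (max-abs change of prior mean).
    covariance : "full" or "diag" population covariance.
    lrt_alpha : float
        Significance level of the chance-model screen.
    seed : int or None
        Seeds start-point draws; fixed seed gives reproducible fits.

    Attributes (after ``fit``)
    --------------------------
    prior_ : PriorModel — estimated population prior.
    results_ : list[FitResult] — per-subject MAP fits, LRT flags included.
    history_ : list[float] — approximate marginal log-likelihood per EM
        iteration.
    converged_ : bool
    """

    def __init__(self, n_starts: int = 10, n_fits: int = 50,
                 n_refine_fits: int = 5, max_em_iter: int = 40,
                 em_tol: float = 1e-3, opt_tol: float = 1e-6,
                 covariance: str = "full", prior_scale: float = 1.5,
                 lrt_alpha: float = 0.05, seed: Optional[int] = None):
        self.n_starts = n_starts
        self.n_fits = n_fits
        self.n_refine_fits = n_refine_fits
        self.max_em_iter = max_em_iter
        self.em_tol = em_tol
        self.opt_tol = opt_tol
        self.covariance = covariance
        self.prior_scale = prior_scale
        self.lrt_alpha = lrt_alpha
        self.seed = seed

    def fit(self, sessions: Sequence[SessionData], y=None):
        """Group sessions by subject and run the EM-MAP procedure."""
        by_subject: dict[str, list[SessionData]] = {}
        for s in sessions:
            by_subject.setdefault(s.subject_id, []).append(s)
        subjects = list(by_subject.values())
        n_max = max(len(s) for s in subjects)
        init = PriorModel.default(5 * n_max, self.prior_scale)
        prior, fits = em_fit_population(
            subjects, init=init, max_iter=self.max_em_iter,
            tol=self.em_tol, n_starts=self.n_starts, n_fits=self.n_fits,
            n_refine_fits=self.n_refine_fits, covariance=self.covariance,
            seed=self.seed, opt_tol=self.opt_tol,
        )
        for f in fits:
            f.excluded_by_lrt = f.lrt_p >= self.lrt_alpha
        self.prior_ = prior
        self.results_ = fits
        self.history_ = prior.em_history
        self.converged_ = prior.em_converged
        return self

    def parameter_table(self):
        """DataFrame of fitted parameters, one row per subject-session."""
        if not hasattr(self, "results_"):
            raise RuntimeError("estimator is not fitted")
        return parameter_table(self.results_)
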