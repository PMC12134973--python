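"""Bayesian logistic regression with optional group random intercepts.

The model is a binomial GLM(M) with a logit link,

    y_i ~ Bernoulli(logit^-1(x_i' beta + u_{g_i})),
    beta_k ~ Normal(m_k, s_k),   u_j ~ Normal(0, sigma_u),
    sigma_u ~ HalfNormal(1),

where the coefficient priors (m_k, s_k) are either weakly informative
defaults or transferred from a previously fitted model.

Posterior sampling uses emcee with posterior-specific proposals.  For fixed
effects only, the space is whitened with the exact Hessian at the mode and
sampled with a Student-t independence proposal mixed with random-walk
Metropolis; the whitened posterior is close to standard normal, so mixing
is fast.  With a random intercept the posterior has the well-known funnel
in (u, log sigma_u) — no single Gaussian approximation fits both the
sigma_u -> 0 neck and the wide regime — so the independence proposal is a
*mixture of conditional Laplace approximations*: log sigma_u is gridded,
the conditional mode and Hessian of (beta, u) are computed analytically at
every grid point (Newton), grid weights come from the conditional Laplace
evidence, and proposals draw a grid cell, a jittered log sigma_u and a
Student-t perturbation of the conditional mode.  A covariance-matched
random-walk move guards local exploration in both cases.

Walkers evolve independently under all moves used here, so they are treated
as parallel chains for split-Rhat, effective sample size and Monte Carlo
standard errors (via ArviZ).  WAIC is computed from the pointwise posterior
log-likelihood of the fitted data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

_LS_BOUNDS = (-7.0, 2.0)  # log sigma_u grid range (sigma_u ~ 0.001 .. 7.4)
_N_GRID = 28


@dataclass
class SamplerSettings:
    """MCMC budget; defaults are tuned for desk-scale problems (n ~ 10^3-10^4)."""

    n_walkers: int = 32
    n_adapt: int = 400
    adapt_discard: int = 150
    n_steps: int = 900
    n_discard: int = 100
    thin: int = 2
    seed: int = 0
    t_df: float = 15.0
    t_scale: float = 1.02
    independence_weight: float = 0.6
    max_loglik_draws: int = 4000
    rhat_threshold: float = 1.05

    def scaled(self, factor: float) -> "SamplerSettings":
        """A cheaper/heavier copy with step counts scaled by ``factor``."""
        return SamplerSettings(
            n_walkers=self.n_walkers,
            n_adapt=max(200, int(self.n_adapt * factor)),
            adapt_discard=max(80, int(self.adapt_discard * factor)),
            n_steps=max(300, int(self.n_steps * factor)),
            n_discard=max(50, int(self.n_discard * factor)),
            thin=self.thin,
            seed=self.seed,
            t_df=self.t_df,
            t_scale=self.t_scale,
            independence_weight=self.independence_weight,
            max_loglik_draws=self.max_loglik_draws,
            rhat_threshold=self.rhat_threshold,
        )


class _TIndependenceMove(emcee.moves.MHMove):
    """Independence MH with a multivariate-t proposal in whitened coordinates."""

    def __init__(self, df: float, scale: float):
        self.df = df
        self.scale = scale
        super().__init__(self.get_proposal)

    def _logq(self, x: np.ndarray) -> np.ndarray:
        d = x.shape[1]
        return -(self.df + d) / 2.0 * np.log1p(
            (x**2).sum(axis=1) / (self.df * self.scale**2)
        )

    def get_proposal(self, x0, random):
        nw, nd = x0.shape
        z = random.standard_normal((nw, nd))
        w = random.chisquare(self.df, nw) / self.df
        xn = self.scale * z / np.sqrt(w)[:, None]
        return xn, self._logq(x0) - self._logq(xn)


class _GridMixtureMove(emcee.moves.MHMove):
    """Independence MH from a mixture of conditional Laplace approximations.

    State layout: theta = (phi, ls) with phi = (beta, u) and ls = log
    sigma_u.  For each grid value ls_k the proposal holds the conditional
    mode phi*_k, a Cholesky factor of the conditional covariance, and a
    Laplace-evidence weight w_k.  A proposal draws k ~ w, ls uniform within
    the grid cell, and phi from a Student-t around phi*_k.
    """

    def __init__(self, ls_grid, log_evidence, phi_star, chols, df=15.0, scale=1.02):
        self.ls_grid = ls_grid
        self.delta = float(ls_grid[1] - ls_grid[0])
        logw = log_evidence - log_evidence.max()
        w = np.exp(logw)
        self.w = w / w.sum()
        self.logw = np.log(np.maximum(self.w, 1e-300))
        self.phi_star = phi_star  # (K, pd)
        self.chols = chols  # list of (pd, pd) upper factors A, Sigma = A A^T
        self.logdets = np.array([np.log(np.diag(L)).sum() for L in chols])
        self.df = df
        self.scale = scale
        super().__init__(self.get_proposal)

    def _logq(self, x: np.ndarray) -> np.ndarray:
        pd_ = self.phi_star.shape[1]
        ls = x[:, -1]
        phi = x[:, :-1]
        k = np.round((ls - self.ls_grid[0]) / self.delta).astype(int)
        inside = (k >= 0) & (k < len(self.ls_grid))
        k = np.clip(k, 0, len(self.ls_grid) - 1)
        out = np.full(len(x), -1e12)
        from scipy.linalg import solve_triangular

        for kk in np.unique(k[inside]):
            sel = inside & (k == kk)
            d = (phi[sel] - self.phi_star[kk]) / self.scale
            # chols holds upper-triangular factors A with Sigma = A A^T
            z = solve_triangular(self.chols[kk], d.T, lower=False).T
            out[sel] = (
                self.logw[kk]
                - np.log(self.delta)
                - self.logdets[kk]
                - pd_ * np.log(self.scale)
                - (self.df + pd_) / 2.0 * np.log1p((z**2).sum(axis=1) / self.df)
            )
        return out

    def get_proposal(self, x0, random):
        nw = x0.shape[0]
        pd_ = self.phi_star.shape[1]
        ks = random.choice(len(self.w), size=nw, p=self.w)
        ls = self.ls_grid[ks] + random.uniform(-self.delta / 2, self.delta / 2, nw)
        z = random.standard_normal((nw, pd_))
        chi = random.chisquare(self.df, nw) / self.df
        phi = np.empty((nw, pd_))
        for kk in np.unique(ks):
            sel = ks == kk
            phi[sel] = (
                self.phi_star[kk]
                + self.scale * (z[sel] / np.sqrt(chi[sel])[:, None]) @ self.chols[kk].T
            )
        xn = np.column_stack([phi, ls])
        return xn, self._logq(x0) - self._logq(xn)


@dataclass
class LogisticPosterior:
    """Posterior draws and diagnostics of one fitted logistic model."""

    coef_names: List[str]
    beta_chain: np.ndarray  # (chain, draw, p)
    u_chain: Optional[np.ndarray]  # (chain, draw, J) or None
    sigma_chain: Optional[np.ndarray]  # (chain, draw)
    group_labels: Optional[List] = None
    prior_mean: Optional[np.ndarray] = None
    prior_sd: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    waic: float = np.nan
    waic_se: float = np.nan
    p_waic: float = np.nan
    pointwise_waic: Optional[np.ndarray] = None
    diagnostics: Optional[pd.DataFrame] = None
    converged: bool = False
    acceptance: float = np.nan
    map_estimate: Optional[np.ndarray] = None

    @property
    def beta(self) -> np.ndarray:
        """Flattened coefficient draws, shape (n_draws, p)."""
        return self.beta_chain.reshape(-1, self.beta_chain.shape[-1])

    @property
    def u(self) -> Optional[np.ndarray]:
        if self.u_chain is None:
            return None
        return self.u_chain.reshape(-1, self.u_chain.shape[-1])

    @property
    def sigma_u(self) -> Optional[np.ndarray]:
        if self.sigma_chain is None:
            return None
        return self.sigma_chain.reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def coef_summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central quantiles per coefficient."""
        b = self.beta
        qs = np.percentile(b, [5, 10, 50, 90, 95], axis=0)
        return pd.DataFrame(
            {
                "mean": b.mean(0),
                "sd": b.std(0, ddof=1),
                "q05": qs[0],
                "q10": qs[1],
                "q50": qs[2],
                "q90": qs[3],
                "q95": qs[4],
            },
            index=self.coef_names,
        )

    def credible_interval(self, level: float = 0.90) -> pd.DataFrame:
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.beta, [a, 100 - a], axis=0)
        return pd.DataFrame({"low": lo, "high": hi}, index=self.coef_names)

    def predict_prob(
        self,
        X: np.ndarray,
        groups: Optional[np.ndarray] = None,
        max_draws: int = 500,
    ) -> np.ndarray:
        """Posterior-mean presence probability for new design rows.

        ``groups`` gives each row's random-intercept index into
        ``group_labels`` (use -1 for rows outside every fitted group).
        """
        b = self.beta
        u = self.u
        step = max(1, b.shape[0] // max_draws)
        b = b[::step]
        eta = X @ b.T
        if u is not None and groups is not None:
            usub = u[::step]
            ug = np.where(
                (groups >= 0)[:, None], usub.T[np.clip(groups, 0, None)], 0.0
            )
            eta = eta + ug
        return expit(eta).mean(axis=1)


def _require_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


def fit_logistic_mcmc(
    X: np.ndarray,
    y: np.ndarray,
    prior_mean: Sequence[float],
    prior_sd: Sequence[float],
    coef_names: Optional[Sequence[str]] = None,
    groups: Optional[np.ndarray] = None,
    group_labels: Optional[Sequence] = None,
    settings: Optional[SamplerSettings] = None,
) -> LogisticPosterior:
    """Sample the posterior of a Bayesian logistic GLM(M).

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column explicitly).
    y : (n,) binary response.
    prior_mean, prior_sd : per-coefficient normal prior parameters.
    groups : optional (n,) integer group index for a random intercept.
    """
    settings = settings or SamplerSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_sd = np.asarray(prior_sd, dtype=float)
    n, p = X.shape if X.ndim == 2 else (0, len(prior_mean))
    _require_finite("X", X)
    _require_finite("prior_sd", prior_sd)
    if np.any(prior_sd <= 0):
        raise ValueError("prior sds must be > 0")
    if coef_names is None:
        coef_names = [f"b{k}" for k in range(p)]

    has_groups = groups is not None and n > 0
    if has_groups:
        groups = np.asarray(groups, dtype=int)
        J = int(groups.max()) + 1
        G = np.zeros((n, J))
        G[np.arange(n), groups] = 1.0
        if group_labels is None:
            group_labels = list(range(J))
    else:
        J = 0
        G = None
    D = p + (J + 1 if has_groups else 0)
    rng = np.random.default_rng(settings.seed)

    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, :p]
        eta = beta @ X.T if n else np.zeros((theta.shape[0], 0))
        lp = -0.5 * (((beta - prior_mean) / prior_sd) ** 2).sum(axis=1)
        if has_groups:
            u = theta[:, p : p + J]
            ls = np.clip(theta[:, -1], *_LS_BOUNDS)
            eta = eta + u[:, groups]
            lp += -J * ls - 0.5 * (u**2).sum(axis=1) / np.exp(2 * ls)
            lp += -0.5 * np.exp(2 * ls) + ls  # HalfNormal(1) sigma + Jacobian
        if n:
            lp += (y * eta - np.logaddexp(0, eta)).sum(axis=1)
        return lp

    if has_groups:
        theta_chain, acceptance, map_beta = _sample_grouped(
            X, y, G, groups, prior_mean, prior_sd, J, log_post, settings, rng
        )
    else:
        theta_chain, acceptance, map_beta = _sample_fixed(
            X, y, prior_mean, prior_sd, log_post, settings, rng
        )

    beta_chain = theta_chain[:, :, :p]
    if has_groups:
        u_chain = theta_chain[:, :, p : p + J]
        sigma_chain = np.exp(np.clip(theta_chain[:, :, -1], *_LS_BOUNDS))
    else:
        u_chain = None
        sigma_chain = None

    post = {"beta": beta_chain}
    if has_groups:
        post["u"] = u_chain
        post["sigma_u"] = sigma_chain

    # --- pointwise log-likelihood and WAIC -------------------------------
    W_eff, T_eff = beta_chain.shape[:2]
    ll_thin = max(1, (W_eff * T_eff) // settings.max_loglik_draws)
    bsub = beta_chain[:, ::ll_thin, :]
    if n:
        eta = np.einsum("ctk,nk->ctn", bsub, X)
        if has_groups:
            eta = eta + u_chain[:, ::ll_thin, :][:, :, groups]
        ll = y * eta - np.logaddexp(0, eta)
    else:
        ll = np.zeros((W_eff, bsub.shape[1], 0))

    idata = az.from_dict(posterior=post, log_likelihood={"y": ll})
    if n:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wres = az.waic(idata, pointwise=True, scale="deviance")
        waic = float(wres.elpd_waic)
        waic_se = float(wres.se)
        p_waic = float(wres.p_waic)
        pointwise = np.asarray(wres.waic_i.values, dtype=float)
    else:
        waic = waic_se = p_waic = np.nan
        pointwise = None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        mcse = az.mcse(idata)
    rows = []
    for k, name in enumerate(coef_names):
        rows.append(
            {
                "parameter": name,
                "mean": float(beta_chain[:, :, k].mean()),
                "sd": float(beta_chain[:, :, k].std(ddof=1)),
                "rhat": float(rhat["beta"].values[k]),
                "n_eff": float(ess["beta"].values[k]),
                "mcse": float(mcse["beta"].values[k]),
            }
        )
    if has_groups:
        for j in range(J):
            rows.append(
                {
                    "parameter": f"u[{group_labels[j]}]",
                    "mean": float(u_chain[:, :, j].mean()),
                    "sd": float(u_chain[:, :, j].std(ddof=1)),
                    "rhat": float(rhat["u"].values[j]),
                    "n_eff": float(ess["u"].values[j]),
                    "mcse": float(mcse["u"].values[j]),
                }
            )
        rows.append(
            {
                "parameter": "sigma_u",
                "mean": float(sigma_chain.mean()),
                "sd": float(sigma_chain.std(ddof=1)),
                "rhat": float(rhat["sigma_u"].values),
                "n_eff": float(ess["sigma_u"].values),
                "mcse": float(mcse["sigma_u"].values),
            }
        )
    diagnostics = pd.DataFrame(rows).set_index("parameter")
    converged = bool((diagnostics["rhat"] <= settings.rhat_threshold).all())
    if not converged:
        logger.warning(
            "fit flagged non-converged: max Rhat = %.3f", diagnostics["rhat"].max()
        )

    return LogisticPosterior(
        coef_names=list(coef_names),
        beta_chain=beta_chain,
        u_chain=u_chain,
        sigma_chain=sigma_chain,
        group_labels=list(group_labels) if has_groups else None,
        prior_mean=prior_mean,
        prior_sd=prior_sd,
        y=y if n else None,
        waic=waic,
        waic_se=waic_se,
        p_waic=p_waic,
        pointwise_waic=pointwise,
        diagnostics=diagnostics,
        converged=converged,
        acceptance=acceptance,
        map_estimate=map_beta,
    )


def _sample_fixed(X, y, prior_mean, prior_sd, log_post, settings, rng):
    """Whitened two-stage sampling for the fixed-effects-only posterior."""
    n, p = (X.shape if X.ndim == 2 else (0, len(prior_mean)))

    def grad(beta):
        g = -(beta - prior_mean) / prior_sd**2
        if n:
            g = g + X.T @ (y - expit(X @ beta))
        return g

    res = minimize(
        lambda th: -log_post(th)[0],
        prior_mean.copy(),
        jac=lambda th: -grad(th),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    mu0 = res.x
    eps = 1e-5
    H = np.zeros((p, p))
    for i in range(p):
        e = np.zeros(p)
        e[i] = eps
        H[:, i] = (grad(mu0 + e) - grad(mu0 - e)) / (2 * eps)
    H = (H + H.T) / 2
    evals, evecs = np.linalg.eigh(-H)
    L0 = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-8)))

    moves = [
        (_TIndependenceMove(settings.t_df, settings.t_scale), settings.independence_weight),
        (emcee.moves.GaussianMove(2.38**2 / p), 1.0 - settings.independence_weight),
    ]
    W = max(settings.n_walkers, 2 * p + 2)

    def lp_white0(Z):
        return log_post(mu0 + Z @ L0.T)

    s1 = emcee.EnsembleSampler(W, p, lp_white0, vectorize=True, moves=moves)
    s1.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
    z0 = 0.5 * rng.normal(size=(W, p))
    s1.run_mcmc(z0, settings.n_adapt, progress=False)
    discard1 = min(settings.adapt_discard, settings.n_adapt // 2)
    th1 = mu0 + s1.get_chain(discard=discard1).reshape(-1, p) @ L0.T

    mu = th1.mean(axis=0)
    C = np.atleast_2d(np.cov(th1.T)) + 1e-9 * np.eye(p)
    L = np.linalg.cholesky(C)

    def lp_white(Z):
        return log_post(mu + Z @ L.T)

    s2 = emcee.EnsembleSampler(W, p, lp_white, vectorize=True, moves=moves)
    s2.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
    z_start = np.linalg.solve(L, (th1[-W:] - mu).T).T
    s2.run_mcmc(z_start, settings.n_steps, progress=False)
    discard2 = min(settings.n_discard, settings.n_steps // 2)
    chain = s2.get_chain(discard=discard2, thin=settings.thin)
    theta = np.moveaxis(mu + chain @ L.T, 0, 1)  # (chain, draw, p)
    return theta, float(np.mean(s2.acceptance_fraction)), mu0


def _sample_grouped(X, y, G, groups, prior_mean, prior_sd, J, log_post, settings, rng):
    """Grid-mixture sampling for the random-intercept posterior."""
    n, p = X.shape
    pd_ = p + J
    ls_grid = np.linspace(_LS_BOUNDS[0], _LS_BOUNDS[1], _N_GRID)

    def conditional_newton(ls, phi0):
        """Mode and Hessian of (beta, u) given log sigma (damped Newton)."""
        s2 = np.exp(2 * ls)
        phi = phi0.copy()

        def lp_cond(ph):
            beta, u = ph[:p], ph[p:]
            eta = X @ beta + u[groups]
            return (
                (y * eta - np.logaddexp(0, eta)).sum()
                - 0.5 * (((beta - prior_mean) / prior_sd) ** 2).sum()
                - 0.5 * (u**2).sum() / s2
            )

        cur = lp_cond(phi)
        for _ in range(60):
            beta, u = phi[:p], phi[p:]
            eta = X @ beta + u[groups]
            pr = expit(eta)
            r = y - pr
            g = np.r_[X.T @ r - (beta - prior_mean) / prior_sd**2, G.T @ r - u / s2]
            w = pr * (1 - pr) + 1e-12
            Xw = X * w[:, None]
            H = np.zeros((pd_, pd_))
            H[:p, :p] = Xw.T @ X + np.diag(1.0 / prior_sd**2)
            H[:p, p:] = Xw.T @ G
            H[p:, :p] = H[:p, p:].T
            H[p:, p:] = np.diag(np.bincount(groups, weights=w, minlength=J) + 1.0 / s2)
            step = np.linalg.solve(H, g)
            t = 1.0
            for _ in range(30):
                new = lp_cond(phi + t * step)
                if new >= cur - 1e-12:
                    break
                t /= 2
            phi = phi + t * step
            if new - cur < 1e-8 and np.abs(g).max() < 1e-5:
                cur = new
                break
            cur = new
        return phi, H

    phi_star = np.empty((_N_GRID, pd_))
    chols = []
    log_ev = np.empty(_N_GRID)
    phi0 = np.r_[prior_mean, np.zeros(J)]
    # sweep from wide sigma down so warm starts stay in basin
    order = np.argsort(ls_grid)[::-1]
    for k in order:
        phi_k, H_k = conditional_newton(ls_grid[k], phi0)
        phi_star[k] = phi_k
        phi0 = phi_k
        Lh = np.linalg.cholesky(H_k + 1e-10 * np.eye(pd_))
        cov_chol = np.linalg.inv(Lh).T  # chol of H^-1 (lower)
        chols.append((k, cov_chol))
        theta_k = np.r_[phi_k, ls_grid[k]]
        # conditional Laplace evidence: joint density at mode + 0.5 log|H^-1|
        log_ev[k] = float(log_post(theta_k[None])[0]) - np.log(np.diag(Lh)).sum()
    chols = [c for _, c in sorted(chols, key=lambda t: t[0])]

    mix = _GridMixtureMove(
        ls_grid, log_ev, phi_star, chols, df=settings.t_df, scale=settings.t_scale
    )

    # moment-matched covariance of the mixture for the random-walk move
    w = mix.w
    mean_phi = w @ phi_star
    cov_phi = np.zeros((pd_, pd_))
    for k in range(_N_GRID):
        d = phi_star[k] - mean_phi
        cov_phi += w[k] * (chols[k] @ chols[k].T + np.outer(d, d))
    mean_ls = w @ ls_grid
    var_ls = w @ (ls_grid - mean_ls) ** 2 + mix.delta**2 / 12
    cov = np.zeros((pd_ + 1, pd_ + 1))
    cov[:pd_, :pd_] = cov_phi
    cov[:pd_, -1] = cov[-1, :pd_] = (w * (ls_grid - mean_ls)) @ (phi_star - mean_phi)
    cov[-1, -1] = var_ls
    cov += 1e-9 * np.eye(pd_ + 1)
    D = pd_ + 1
    W = max(settings.n_walkers, 2 * D + 2)

    def draw_start(count, rstate):
        ks = rstate.choice(_N_GRID, size=count, p=w)
        ls = ls_grid[ks] + rstate.uniform(-mix.delta / 2, mix.delta / 2, count)
        phi = np.empty((count, pd_))
        for kk in np.unique(ks):
            sel = ks == kk
            phi[sel] = phi_star[kk] + rstate.standard_normal((sel.sum(), pd_)) @ chols[kk].T
        return np.column_stack([phi, ls])

    rstate = np.random.RandomState(int(rng.integers(2**31 - 1)))
    start = draw_start(W, rstate)

    moves1 = [
        (mix, settings.independence_weight),
        (emcee.moves.GaussianMove(cov * 2.38**2 / D), 1.0 - settings.independence_weight),
    ]
    s1 = emcee.EnsembleSampler(W, D, log_post, vectorize=True, moves=moves1)
    s1.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
    s1.run_mcmc(start, settings.n_adapt, progress=False)
    discard1 = min(settings.adapt_discard, settings.n_adapt // 2)
    th1 = s1.get_chain(discard=discard1).reshape(-1, D)

    cov2 = np.atleast_2d(np.cov(th1.T)) + 1e-9 * np.eye(D)
    moves2 = [
        (mix, settings.independence_weight),
        (emcee.moves.GaussianMove(cov2 * 2.38**2 / D), 1.0 - settings.independence_weight),
    ]
    s2 = emcee.EnsembleSampler(W, D, log_post, vectorize=True, moves=moves2)
    s2.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
    s2.run_mcmc(th1[-W:], settings.n_steps, progress=False)
    discard2 = min(settings.n_discard, settings.n_steps // 2)
    chain = s2.get_chain(discard=discard2, thin=settings.thin)
    theta = np.moveaxis(chain, 0, 1)  # (chain, draw, D)
    best_k = int(np.argmax(mix.w))
    return theta, float(np.mean(s2.acceptance_fraction)), phi_star[best_k][:p]


def waic_difference(
    a: LogisticPosterior, b: LogisticPosterior
) -> Tuple[float, float]:
    """WAIC(a) - WAIC(b) with a standard error from the pointwise values.

    Both models must have been fitted to the identical response vector.
    """
    if a.pointwise_waic is None or b.pointwise_waic is None:
        raise ValueError("both models need pointwise WAIC")
    if a.y is None or b.y is None or len(a.y) != len(b.y) or not np.array_equal(a.y, b.y):
        raise ValueError("models were fitted to different response vectors")
    d = a.pointwise_waic - b.pointwise_waic
    return float(d.sum()), float(np.sqrt(len(d) * np.var(d, ddof=1)))
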