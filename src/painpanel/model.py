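"""Random-intercept ordered-probit panel regression of latent pain.

The model: within episode ``i``, observation ``j`` at time ``t_ij`` carries a
latent pain level

    y*_ij = mu_ij + u_i + e_ij,      u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, 1)

with systematic part

    mu_ij = b0 + x_i' beta
            + I{t_ij >= t0(arm)} * [ level(arm) + (g1 + d1*d_i) t_ij
                                               + (g2 + d2*d_i) t_ij^2 ]

where ``d_i`` indicates the methoxyflurane arm, ``t0(arm)`` is the arm's
onset lag, ``level(arm)`` the latent jump at onset, and ``g1, g2`` (``d1,
d2``) the shared (methoxyflurane-interaction) linear and quadratic time
coefficients. The observed VNPS is the ordinal category whose cut-point
interval contains ``y*``: score ``k`` iff ``c_k < y* <= c_{k+1}`` with
``c_0 = -inf`` and ``c_K = +inf``. Identification is the standard ordered
probit: residual scale fixed to 1, no free intercept (``b0`` fixed at 0 when
fitting, the cut-points absorb the level), all ``K-1`` cut-points estimated.

The marginal likelihood integrates the episode random intercept out by
Gauss-Hermite quadrature; estimation is quasi-Newton with an analytic
gradient, cut-point monotonicity enforced by a log-increment
reparameterisation, and the covariance taken from the inverse observed
information. :class:`PainPanelModel` / :class:`PainPanelResults` follow the
familiar model/results split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .episodes import Episode, frame_to_episodes
from .scale import categorize_vnps

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Onset lags (minutes from administration to analgesic effect) used when a
#: spec does not override them: inhaled agents act within half a minute,
#: intravenous morphine within a minute, intravenous paracetamol within five.
DEFAULT_ONSET_LAGS = {
    "methoxyflurane": 0.5,
    "entonox": 0.5,
    "morphine_iv": 1.0,
    "paracetamol_iv": 5.0,
}

PATHWAY_PARAM_NAMES = ("t", "t2", "d_t", "d_t2")


class SpecificationError(ValueError):
    """Invalid model specification (unknown covariate, bad category count)."""


class DegenerateDataError(ValueError):
    """Outcome data cannot identify the model (e.g. a single category)."""


@dataclass(frozen=True)
class ModelSpec:
    """Covariate design and structural settings of the panel model.

    ``covariates`` names episode-level regressors: ``sex``, ``age``,
    ``trauma`` (expands to indicator contrasts for classes 2-7 against the
    limb-injury reference class 1) or any episode flag name. Entries also in
    ``per_arm_covariates`` get one coefficient per arm rather than a shared
    one. ``n_categories`` selects the full 11-level VNPS outcome or the
    4-level clinical classification.
    """

    covariates: tuple[str, ...] = ()
    per_arm_covariates: tuple[str, ...] = ()
    onset_lags: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_LAGS)
    )
    n_categories: int = 11
    quadrature_nodes: int = 20

    def __post_init__(self) -> None:
        if self.n_categories not in (4, 11):
            raise SpecificationError("n_categories must be 4 or 11")
        if self.quadrature_nodes < 1:
            raise SpecificationError("quadrature_nodes must be positive")
        for arm, lag in self.onset_lags.items():
            if lag < 0:
                raise SpecificationError(f"onset lag for {arm} must be >= 0")

    def onset_lag(self, arm: str) -> float:
        try:
            return self.onset_lags[arm]
        except KeyError:
            raise SpecificationError(f"no onset lag configured for arm {arm!r}")


@dataclass
class ModelParams:
    """Natural parameters of the panel model.

    ``coef`` maps design-column names (``level:<arm>``, ``t``, ``t2``,
    ``d_t``, ``d_t2`` and covariate columns) to coefficients. ``cutpoints``
    are the K-1 strictly increasing latent thresholds. ``baseline_level`` is
    a fixed latent offset used by the simulator and scenario machinery; it is
    not a free parameter when fitting (the cut-points absorb it).
    """

    coef: dict[str, float]
    cutpoints: np.ndarray
    sigma_u: float
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        validate_cutpoints(self.cutpoints)
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")

    def pathway(self, arm: str) -> tuple[float, float, float]:
        """Effective (onset level, linear, quadratic) coefficients for an arm."""
        is_m = arm == "methoxyflurane"
        level = self.coef.get(f"level:{arm}", 0.0)
        lin = self.coef.get("t", 0.0) + (self.coef.get("d_t", 0.0) if is_m else 0.0)
        quad = self.coef.get("t2", 0.0) + (self.coef.get("d_t2", 0.0) if is_m else 0.0)
        return level, lin, quad

    def to_dict(self) -> dict:
        return {
            "coef": dict(self.coef),
            "cutpoints": self.cutpoints.tolist(),
            "sigma_u": self.sigma_u,
            "baseline_level": self.baseline_level,
        }


def validate_cutpoints(cutpoints: np.ndarray) -> None:
    c = np.asarray(cutpoints, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise ValueError("cutpoints must be a non-empty 1-D array")
    if not np.all(np.diff(c) > 0):
        raise ValueError("cutpoints must be strictly increasing")


# ---------------------------------------------------------------------------
# latent mean and category probabilities

def _covariate_value(episode: Episode, name: str) -> float:
    if name == "sex":
        return float(episode.sex)
    if name == "age":
        return float(episode.age_years)
    if name.startswith("trauma_"):
        return float(episode.trauma_class == int(name.split("_")[1]))
    if hasattr(episode, name):
        return float(bool(getattr(episode, name)))
    raise SpecificationError(f"unknown covariate: {name!r}")


def _expand_covariates(names: Iterable[str]) -> list[str]:
    out: list[str] = []
    for name in names:
        if name == "trauma":
            out.extend(f"trauma_{k}" for k in range(2, 8))
        else:
            out.append(name)
    return out


def latent_mean(
    episode: Episode, params: ModelParams, spec: ModelSpec, t: float
) -> float:
    """Systematic latent pain at time ``t`` minutes, excluding the random effect.

    Before the arm's onset lag the pathway bracket is inactive and the value
    is the baseline level plus covariate effects only.
    """
    mu = params.baseline_level
    is_m = episode.arm == "methoxyflurane"
    for name in _expand_covariates(spec.covariates):
        x = _covariate_value(episode, name)
        if name in spec.per_arm_covariates:
            mu += params.coef.get(f"{name}:{episode.arm}", 0.0) * x
        else:
            mu += params.coef.get(name, 0.0) * x
    if t >= spec.onset_lag(episode.arm):
        level, lin, quad = params.pathway(episode.arm)
        mu += level + lin * t + quad * t * t
    return mu


def category_probabilities(mu, cutpoints) -> np.ndarray:
    """Ordered-probit category probabilities for latent mean(s) ``mu``.

    ``p_k = Phi(c_{k+1} - mu) - Phi(c_k - mu)`` with the outer cut-points at
    +/- infinity; each row sums to 1.
    """
    validate_cutpoints(cutpoints)
    mu_arr = np.asarray(mu, dtype=float)
    scalar = mu_arr.ndim == 0
    mu2 = np.atleast_1d(mu_arr)
    c = np.concatenate(([-np.inf], np.asarray(cutpoints, float), [np.inf]))
    cdf = special.ndtr(c[None, :] - mu2[:, None])
    probs = np.diff(cdf, axis=1)
    return probs[0] if scalar else probs


# ---------------------------------------------------------------------------
# stable log interval probabilities and their derivative kernels

def _log_interval_prob(z0: np.ndarray, z1: np.ndarray) -> np.ndarray:
    """log(Phi(z1) - Phi(z0)) elementwise, stable in both tails (z0 < z1)."""
    flip = (z0 + z1) > 0
    a = np.where(flip, -z1, z0)
    b = np.where(flip, -z0, z1)
    # now the interval [a, b] sits in the lower tail: log Phi(b) dominates
    log_b = special.log_ndtr(b)
    log_a = special.log_ndtr(a)
    with np.errstate(invalid="ignore"):
        diff = np.exp(log_a - log_b)
    diff = np.where(np.isfinite(log_a), diff, 0.0)
    return log_b + np.log1p(-diff)


def _log_phi(z: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", over="ignore"):
        out = -0.5 * z * z - _LOG_SQRT_2PI
    return np.where(np.isinf(z), -np.inf, out)


# ---------------------------------------------------------------------------
# model data: design matrix construction

class _PanelData:
    """Arrays for vectorised likelihood evaluation."""

    def __init__(self, episodes: Sequence[Episode], spec: ModelSpec):
        if not episodes:
            raise DegenerateDataError("no episodes")
        self.spec = spec
        self.arms = tuple(dict.fromkeys(ep.arm for ep in episodes))
        two_arm = "methoxyflurane" in self.arms and len(self.arms) > 1

        names: list[str] = [f"level:{arm}" for arm in self.arms]
        names += ["t", "t2"]
        if two_arm:
            names += ["d_t", "d_t2"]
        cov_names = _expand_covariates(spec.covariates)
        for name in cov_names:
            if name in spec.per_arm_covariates:
                names += [f"{name}:{arm}" for arm in self.arms]
            else:
                names.append(name)
        self.coef_names = tuple(names)

        rows, ys, ep_idx = [], [], []
        for i, ep in enumerate(episodes):
            lag = spec.onset_lag(ep.arm)
            is_m = ep.arm == "methoxyflurane"
            cov_row = []
            for name in cov_names:
                x = _covariate_value(ep, name)
                if name in spec.per_arm_covariates:
                    cov_row.extend(x if arm == ep.arm else 0.0 for arm in self.arms)
                else:
                    cov_row.append(x)
            for obs in ep.observations:
                t = obs.time_min
                on = 1.0 if t >= lag else 0.0
                row = [on if arm == ep.arm else 0.0 for arm in self.arms]
                row += [on * t, on * t * t]
                if two_arm:
                    m = on if is_m else 0.0
                    row += [m * t, m * t * t]
                row.extend(cov_row)
                rows.append(row)
                if spec.n_categories == 11:
                    ys.append(obs.score)
                else:
                    ys.append(int(categorize_vnps(obs.score)))
                ep_idx.append(i)

        self.X = np.asarray(rows, dtype=float)
        self.y = np.asarray(ys, dtype=np.intp)
        self.ep_idx = np.asarray(ep_idx, dtype=np.intp)
        self.n_episodes = len(episodes)
        self.n_obs = len(ys)
        self.K = spec.n_categories
        if np.unique(self.y).size < 2:
            raise DegenerateDataError(
                "outcome takes a single category; the model is not identified"
            )
        nodes, weights = np.polynomial.hermite.hermgauss(spec.quadrature_nodes)
        self.gh_nodes = nodes
        self.gh_logw = np.log(weights) - 0.5 * math.log(math.pi)
        # column scales for optimizer conditioning (t and t^2 columns span
        # two orders of magnitude; optimisation runs on beta * scale)
        self.col_scale = np.maximum(np.abs(self.X).max(axis=0), 1.0)

    def loglike_and_grad(
        self, beta: np.ndarray, cutpoints: np.ndarray, sigma_u: float
    ) -> tuple[float, np.ndarray, np.ndarray, float]:
        """Marginal log-likelihood and its gradient wrt (beta, cutpoints, sigma)."""
        K = self.K
        cpad = np.concatenate(([-np.inf], cutpoints, [np.inf]))
        mu = self.X @ beta
        u = math.sqrt(2.0) * sigma_u * self.gh_nodes  # (Q,)
        z0 = cpad[self.y][None, :] - mu[None, :] - u[:, None]  # (Q, N)
        z1 = cpad[self.y + 1][None, :] - mu[None, :] - u[:, None]
        logp = _log_interval_prob(z0, z1)

        # per-episode, per-node log products and the log marginal
        S = np.zeros((self.gh_nodes.size, self.n_episodes))
        np.add.at(S.T, self.ep_idx, logp.T)  # S[q, i] = sum_j logp[q, j]
        A = S + self.gh_logw[:, None]
        ll_i = special.logsumexp(A, axis=0)
        ll = float(ll_i.sum())

        # posterior node weights per episode, broadcast to observations
        omega = np.exp(A - ll_i[None, :])  # (Q, M)
        W = omega[:, self.ep_idx]  # (Q, N)

        lphi0 = _log_phi(z0)
        lphi1 = _log_phi(z1)
        r0 = np.exp(lphi0 - logp)  # phi(z0)/p
        r1 = np.exp(lphi1 - logp)  # phi(z1)/p
        dmu = r0 - r1  # dlogp/dmu

        g_mu = np.einsum("qn,qn->n", W, dmu)
        grad_beta = self.X.T @ g_mu

        a1 = np.einsum("qn,qn->n", W, r1)  # coefficient of upper cut c[y]
        a0 = -np.einsum("qn,qn->n", W, r0)  # coefficient of lower cut c[y-1]
        grad_c = np.zeros(K - 1)
        upper = self.y <= K - 2
        np.add.at(grad_c, self.y[upper], a1[upper])
        lower = self.y >= 1
        np.add.at(grad_c, self.y[lower] - 1, a0[lower])

        g_sigma = math.sqrt(2.0) * float(
            np.einsum("q,qn->", self.gh_nodes, W * dmu)
        )
        return ll, grad_beta, grad_c, g_sigma


# ---------------------------------------------------------------------------
# public likelihood on episodes (spec operation surface)

def log_likelihood(
    params: ModelParams, episodes: Sequence[Episode], spec: ModelSpec
) -> float:
    """Marginal log-likelihood of ``episodes`` under ``params``.

    The episode random intercept is integrated out by Gauss-Hermite
    quadrature with ``spec.quadrature_nodes`` nodes; with ``sigma_u = 0``
    this reduces to the pooled independent-observation ordered probit.
    """
    if params.sigma_u < 0:
        raise ValueError("sigma_u must be non-negative")
    data = _PanelData(episodes, spec)
    beta = np.array([params.coef.get(n, 0.0) for n in data.coef_names])
    cut = params.cutpoints - params.baseline_level
    ll, *_ = data.loglike_and_grad(beta, cut, params.sigma_u)
    return ll


# ---------------------------------------------------------------------------
# model / results

class PainPanelModel:
    """Random-intercept ordered-probit panel model of pain trajectories.

    Parameters
    ----------
    episodes
        Filtered, baseline-imputed episodes (one or two treatment arms; a
        two-arm set must include methoxyflurane for the interaction terms).
    spec
        Covariate design and structural settings.
    """

    def __init__(self, episodes: Sequence[Episode], spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.episodes = list(episodes)
        self.data = _PanelData(self.episodes, self.spec)
        self.exog_names = list(self.data.coef_names)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, spec: ModelSpec | None = None
    ) -> "PainPanelModel":
        return cls(frame_to_episodes(frame), spec)

    # -- parameter packing ---------------------------------------------------
    @property
    def k_beta(self) -> int:
        return len(self.data.coef_names)

    @property
    def param_names(self) -> list[str]:
        return (
            list(self.data.coef_names)
            + [f"cut_{k}" for k in range(1, self.spec.n_categories)]
            + ["sigma_u"]
        )

    def _unpack_natural(self, theta: np.ndarray):
        p = self.k_beta
        K = self.spec.n_categories
        return theta[:p], theta[p : p + K - 1], float(theta[-1])

    def loglike(self, theta: np.ndarray) -> float:
        beta, cut, sigma = self._unpack_natural(np.asarray(theta, float))
        return self.data.loglike_and_grad(beta, cut, sigma)[0]

    def score(self, theta: np.ndarray) -> np.ndarray:
        beta, cut, sigma = self._unpack_natural(np.asarray(theta, float))
        _, gb, gc, gs = self.data.loglike_and_grad(beta, cut, sigma)
        return np.concatenate([gb, gc, [gs]])

    # -- transformed (unconstrained) scale -----------------------------------
    def _to_transformed(self, theta: np.ndarray) -> np.ndarray:
        beta, cut, sigma = self._unpack_natural(theta)
        incr = np.diff(cut)
        return np.concatenate(
            [
                beta * self.data.col_scale,
                [cut[0]],
                np.log(incr),
                [np.log(max(sigma, 1e-8))],
            ]
        )

    def _from_transformed(self, eta: np.ndarray):
        p = self.k_beta
        K = self.spec.n_categories
        beta = eta[:p] / self.data.col_scale
        c0 = eta[p]
        incr = np.exp(eta[p + 1 : p + K - 1])
        cut = c0 + np.concatenate([[0.0], np.cumsum(incr)])
        sigma = math.exp(eta[-1])
        return beta, cut, sigma

    def _neg_loglike_grad_transformed(self, eta, fixed_sigma=None):
        beta, cut, sigma = self._from_transformed(eta)
        if fixed_sigma is not None:
            sigma = fixed_sigma
        ll, gb, gc, gs = self.data.loglike_and_grad(beta, cut, sigma)
        K = self.spec.n_categories
        # chain rule: c_k = c_1 + sum_{m<=k} exp(eta_m)
        rev = np.cumsum(gc[::-1])[::-1]  # sum_{k>=m} gc[k]
        g_eta = np.concatenate(
            [
                gb / self.data.col_scale,
                [rev[0]],
                np.exp(eta[self.k_beta + 1 : self.k_beta + K - 1]) * rev[1:],
                [0.0 if fixed_sigma is not None else sigma * gs],
            ]
        )
        return -ll, -g_eta

    def _start_values(self) -> np.ndarray:
        K = self.spec.n_categories
        counts = np.bincount(self.data.y, minlength=K).astype(float)
        cum = np.clip(np.cumsum(counts)[:-1] / counts.sum(), 1e-4, 1 - 1e-4)
        cut = special.ndtri(cum)
        cut = np.maximum.accumulate(cut)
        cut += 1e-3 * np.arange(K - 1)  # break ties from empty categories
        beta = np.zeros(self.k_beta)
        return np.concatenate([beta, cut, [0.3]])

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 1000,
        gtol: float = 1e-7,
        ftol: float = 1e-13,
        compute_cov: bool = True,
    ) -> "PainPanelResults":
        """Maximise the marginal likelihood.

        A pooled fit (``sigma_u`` pinned near zero) supplies starting values
        for the full fit. Non-convergence is flagged on the result, not
        raised. The covariance is the inverse observed information, from
        central finite differences of the analytic score.
        """
        theta0 = (
            np.asarray(start_params, float)
            if start_params is not None
            else self._start_values()
        )
        eta0 = self._to_transformed(theta0)

        pooled = optimize.minimize(
            self._neg_loglike_grad_transformed,
            eta0,
            args=(1e-8,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": 1e-5, "ftol": 1e-11},
        )
        eta1 = pooled.x.copy()
        eta1[-1] = math.log(0.3)
        res = optimize.minimize(
            self._neg_loglike_grad_transformed,
            eta1,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
        )
        beta, cut, sigma = self._from_transformed(res.x)
        theta = np.concatenate([beta, cut, [sigma]])
        cov = None
        if compute_cov:
            cov = self._covariance(theta)
        params = ModelParams(
            coef=dict(zip(self.data.coef_names, beta)),
            cutpoints=cut,
            sigma_u=sigma,
        )
        return PainPanelResults(
            model=self,
            params=params,
            theta=theta,
            cov=cov,
            loglik=-float(res.fun),
            converged=bool(res.success),
            optimizer_message=str(res.message),
        )

    def _covariance(self, theta: np.ndarray) -> np.ndarray:
        n = theta.size
        H = np.zeros((n, n))
        h = 1e-5 * np.maximum(np.abs(theta), 1.0)
        for k in range(n):
            tp = theta.copy()
            tm = theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            if k == n - 1:  # keep sigma_u positive
                tm[k] = max(tm[k], 1e-10)
            H[:, k] = (self.score(tp) - self.score(tm)) / (tp[k] - tm[k])
        H = 0.5 * (H + H.T)
        info = -H
        try:
            cov = np.linalg.inv(info)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info, hermitian=True)
        return 0.5 * (cov + cov.T)


@dataclass
class WaldTestResult:
    statistic: float
    df: int
    p_value: float
    z: float | None = None  # for single-row contrasts


class PainPanelResults:
    """Estimates, covariance and inference for a fitted panel model."""

    def __init__(
        self,
        model: PainPanelModel,
        params: ModelParams,
        theta: np.ndarray,
        cov: np.ndarray | None,
        loglik: float,
        converged: bool,
        optimizer_message: str = "",
    ):
        self.model = model
        self.params = params
        self.theta = np.asarray(theta, float)
        self.cov = cov
        self.loglik = loglik
        self.converged = converged
        self.optimizer_message = optimizer_message
        self.param_names = model.param_names
        self.n_episodes = model.data.n_episodes
        self.n_obs = model.data.n_obs
        self.arms = model.data.arms

    @property
    def bse(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("covariance was not computed")
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = special.ndtri(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.theta - z * se, self.theta + z * se])

    def __getitem__(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.bse[self.param_names.index(name)])

    def wald_test(
        self, constraints: np.ndarray, value: np.ndarray | None = None
    ) -> WaldTestResult:
        """Wald chi-square test of ``R theta = r``.

        ``constraints`` is the restriction matrix ``R`` (rows must be
        linearly independent); ``value`` defaults to zero. Single-row
        contrasts also report a two-sided ``z``.
        """
        R = np.atleast_2d(np.asarray(constraints, float))
        r = np.zeros(R.shape[0]) if value is None else np.asarray(value, float)
        if np.linalg.matrix_rank(R) < R.shape[0]:
            raise ValueError("constraint matrix is rank deficient")
        diff = R @ self.theta - r
        V = R @ self.cov @ R.T
        stat = float(diff @ np.linalg.solve(V, diff))
        df = R.shape[0]
        p = float(special.chdtrc(df, stat))
        z = None
        if df == 1:
            z = float(diff[0] / math.sqrt(V[0, 0]))
        return WaldTestResult(statistic=stat, df=df, p_value=p, z=z)

    def contrast(self, weights: dict[str, float]) -> WaldTestResult:
        """One-row Wald contrast given as name -> weight."""
        R = np.zeros(len(self.param_names))
        for name, w in weights.items():
            R[self.param_names.index(name)] = w
        return self.wald_test(R[None, :])

    def summary(self) -> str:
        lines = [
            "Random-intercept ordered-probit panel model",
            f"  arms: {', '.join(self.arms)}",
            f"  episodes: {self.n_episodes}   observations: {self.n_obs}",
            f"  log-likelihood: {self.loglik:.4f}   converged: {self.converged}",
            "",
            f"  {'parameter':<24s}{'estimate':>12s}{'std err':>12s}{'z':>10s}",
        ]
        se = self.bse if self.cov is not None else np.full_like(self.theta, np.nan)
        for name, est, s in zip(self.param_names, self.theta, se):
            z = est / s if s > 0 else np.nan
            lines.append(f"  {name:<24s}{est:>12.4f}{s:>12.4f}{z:>10.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "arms": list(self.arms),
            "param_names": list(self.param_names),
            "estimates": self.theta.tolist(),
            "bse": self.bse.tolist() if self.cov is not None else None,
            "covariance": self.cov.tolist() if self.cov is not None else None,
            "log_likelihood": self.loglik,
            "converged": self.converged,
            "n_episodes": self.n_episodes,
            "n_observations": self.n_obs,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def fit(
    episodes: Sequence[Episode],
    spec: ModelSpec | None = None,
    **options,
) -> PainPanelResults:
    """Convenience wrapper: build a :class:`PainPanelModel` and fit it."""
    return PainPanelModel(episodes, spec).fit(**options)
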