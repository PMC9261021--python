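"""Nonlinear functionals of fitted pain pathways and their inference.

After the onset lag, each arm's latent pathway is the quadratic

    p(t) = b + I{t >= t0} [ a + l t + q t^2 ]

(baseline ``b``, onset level ``a``, effective linear ``l`` and quadratic
``q``). The quantities of clinical interest are nonlinear functions of the
fitted coefficients: the time to trough (least) pain is the vertex
``-l / (2 q)``, the trough level is the pathway's drop from baseline there,
and the duration in severe pain is the first post-onset root of
``p(t) = c_severe`` where ``c_severe`` is the fitted latent boundary between
moderate and severe pain. Standard errors come from the delta method with
central-difference gradients; the prespecified faster-relief hypothesis is a
one-sided z-test on the trough-time difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special

from .model import PainPanelResults, category_probabilities

#: Search horizon for troughs and severe exits, minutes; beyond every
#: plausible prehospital observation window.
HORIZON_MIN = 120.0

#: Default latent height of the scenario start above the severe boundary,
#: calibrated so the default scenario begins in clearly severe pain.
SEVERE_START_OFFSET = 0.912


@dataclass(frozen=True)
class ArmPathway:
    """Effective post-onset quadratic for one arm."""

    onset_level: float
    linear: float
    quadratic: float
    onset_lag: float


@dataclass
class PathwayScenario:
    """A hypothetical patient pathway per arm, starting from a set latent level."""

    baseline_latent: float
    arm_coefficients: dict[str, ArmPathway]
    severe_cutpoint: float
    time_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 50.0, 201)
    )

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("time grid must be non-empty")
        if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("time grid must be nonnegative and increasing")
        self.time_grid = grid

    def value(self, arm: str, t: float) -> float:
        c = self.arm_coefficients[arm]
        v = self.baseline_latent
        if t >= c.onset_lag:
            v += c.onset_level + c.linear * t + c.quadratic * t * t
        return v


@dataclass
class FunctionalEstimate:
    """Point estimate of a pathway functional with delta-method uncertainty."""

    value: float
    se: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    never_flag: bool = False
    boundary_flag: bool = False

    def __float__(self) -> float:
        return float(self.value)

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "se": self.se,
            "ci95": list(self.ci95) if self.ci95 else None,
            "p_value": self.p_value,
            "never_flag": self.never_flag,
            "boundary_flag": self.boundary_flag,
        }


# ---------------------------------------------------------------------------
# deterministic functionals of quadratic pathways

def trough_time(
    linear: float,
    quadratic: float,
    onset: float,
    horizon: float = HORIZON_MIN,
) -> FunctionalEstimate:
    """Time of least pain on ``[onset, horizon]``.

    For a convex pathway with an interior vertex at or after onset the trough
    is the vertex ``-linear / (2 quadratic)``. A pathway that never improves
    after onset has its trough at the onset boundary (flagged); a concave or
    unboundedly decreasing pathway bottoms out at the horizon (flagged).
    """
    if not (math.isfinite(linear) and math.isfinite(quadratic)):
        raise ValueError("pathway coefficients must be finite")
    if quadratic > 0:
        vertex = -linear / (2.0 * quadratic)
        if vertex >= onset:
            return FunctionalEstimate(value=min(vertex, horizon))
        return FunctionalEstimate(value=onset, boundary_flag=True)
    if quadratic == 0.0:
        if linear < 0:
            return FunctionalEstimate(value=horizon, boundary_flag=True)
        return FunctionalEstimate(value=onset, boundary_flag=True)
    # concave: minimum at one of the interval ends
    at_onset = linear * onset + quadratic * onset * onset
    at_hor = linear * horizon + quadratic * horizon * horizon
    if at_hor <= at_onset:
        return FunctionalEstimate(value=horizon, boundary_flag=True)
    return FunctionalEstimate(value=onset, boundary_flag=True)


def trough_level(
    scenario: PathwayScenario, arm: str, horizon: float = HORIZON_MIN
) -> FunctionalEstimate:
    """Latent change from the scenario baseline at the time of least pain."""
    c = scenario.arm_coefficients[arm]
    tt = trough_time(c.linear, c.quadratic, c.onset_lag, horizon)
    level = scenario.value(arm, tt.value) - scenario.baseline_latent
    return FunctionalEstimate(value=level, boundary_flag=tt.boundary_flag)


def _quad_min_on(a: float, l: float, q: float, lo: float, hi: float) -> float:
    """Minimum of a + l t + q t^2 over [lo, hi]."""
    cands = [lo, hi]
    if q > 0:
        v = -l / (2.0 * q)
        if lo <= v <= hi:
            cands.append(v)
    return min(a + l * t + q * t * t for t in cands)


def severe_exit_time(
    scenario: PathwayScenario, arm: str, horizon: float = HORIZON_MIN
) -> FunctionalEstimate:
    """First post-onset time at which the pathway leaves severe pain.

    Solves ``pathway(t) <= severe_cutpoint`` by the quadratic root formula.
    ``never_flag`` is set when the pathway minimum over the horizon stays
    above the cut-point (the arm is not predicted to exit severe pain).
    """
    c = scenario.arm_coefficients[arm]
    cut = scenario.severe_cutpoint
    t0 = c.onset_lag
    a = scenario.baseline_latent + c.onset_level  # constant term after onset
    l, q = c.linear, c.quadratic
    if scenario.value(arm, t0) <= cut:
        return FunctionalEstimate(value=t0)
    if _quad_min_on(a - cut, l, q, t0, horizon) > 0.0:
        return FunctionalEstimate(value=math.nan, never_flag=True)
    if q == 0.0:
        t = (cut - a) / l  # l < 0 here, else the minimum check caught it
        return FunctionalEstimate(value=t)
    disc = l * l - 4.0 * q * (a - cut)
    sq = math.sqrt(disc)
    roots = sorted(((-l - sq) / (2.0 * q), (-l + sq) / (2.0 * q)))
    for t in roots:
        if t >= t0 and a + l * t + q * t * t <= cut + 1e-9:
            # crossing downwards into the at-or-below-cut region
            eps_after = a + l * (t + 1e-6) + q * (t + 1e-6) ** 2
            if eps_after <= cut + 1e-6:
                return FunctionalEstimate(value=t)
    return FunctionalEstimate(value=math.nan, never_flag=True)


# ---------------------------------------------------------------------------
# scenario construction from a fitted model

def scenario_from_results(
    results: PainPanelResults,
    baseline_latent: float | None = None,
    severe_cutpoint: float | None = None,
    time_grid: np.ndarray | None = None,
) -> PathwayScenario:
    """Build the 'begin in severe pain' scenario from fitted parameters.

    The severe/moderate boundary defaults to the fitted cut-point between
    scores 6 and 7 (11-level model) or between the moderate and severe
    categories (4-level); the scenario start defaults to a fixed latent
    offset above that boundary.
    """
    params = results.params
    if severe_cutpoint is None:
        idx = 6 if results.model.spec.n_categories == 11 else 2
        severe_cutpoint = float(params.cutpoints[idx])
    if baseline_latent is None:
        baseline_latent = severe_cutpoint + SEVERE_START_OFFSET
    coeffs = {}
    for arm in results.arms:
        level, lin, quad = params.pathway(arm)
        coeffs[arm] = ArmPathway(
            onset_level=level,
            linear=lin,
            quadratic=quad,
            onset_lag=results.model.spec.onset_lag(arm),
        )
    kwargs = {} if time_grid is None else {"time_grid": np.asarray(time_grid, float)}
    return PathwayScenario(
        baseline_latent=float(baseline_latent),
        arm_coefficients=coeffs,
        severe_cutpoint=float(severe_cutpoint),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# delta method

def delta_method(
    results: PainPanelResults,
    functional: Callable[[np.ndarray], float],
    rel_step: float = 1e-5,
) -> FunctionalEstimate:
    """Delta-method estimate of a smooth scalar functional of the parameters.

    ``functional`` maps the natural parameter vector (coefficients,
    cut-points, sigma_u, in ``results.param_names`` order) to a scalar. The
    gradient is by central finite differences with a relative step.
    """
    theta = results.theta
    value = float(functional(theta))
    g = np.zeros_like(theta)
    for k in range(theta.size):
        h = rel_step * max(abs(theta[k]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        g[k] = (functional(tp) - functional(tm)) / (2.0 * h)
    if not np.all(np.isfinite(g)):
        raise ValueError("functional gradient is not finite at the estimate")
    var = float(g @ results.cov @ g)
    se = math.sqrt(max(var, 0.0))
    return FunctionalEstimate(
        value=value, se=se, ci95=(value - 1.96 * se, value + 1.96 * se)
    )


def _arm_pathway_from_theta(
    results: PainPanelResults, theta: np.ndarray, arm: str
) -> tuple[float, float, float]:
    names = results.param_names
    is_m = arm == "methoxyflurane"

    def get(name: str) -> float:
        return float(theta[names.index(name)]) if name in names else 0.0

    level = get(f"level:{arm}")
    lin = get("t") + (get("d_t") if is_m else 0.0)
    quad = get("t2") + (get("d_t2") if is_m else 0.0)
    return level, lin, quad


def trough_time_estimate(
    results: PainPanelResults, arm: str
) -> FunctionalEstimate:
    """Delta-method estimate of the time to trough pain for one arm."""
    onset = results.model.spec.onset_lag(arm)
    point = _trough_from_theta(results, results.theta, arm)
    if point.boundary_flag:
        return point

    def functional(theta: np.ndarray) -> float:
        _, lin, quad = _arm_pathway_from_theta(results, theta, arm)
        return -lin / (2.0 * quad)

    return delta_method(results, functional)


def _trough_from_theta(results, theta, arm) -> FunctionalEstimate:
    onset = results.model.spec.onset_lag(arm)
    _, lin, quad = _arm_pathway_from_theta(results, theta, arm)
    return trough_time(lin, quad, onset)


def faster_relief_test(results: PainPanelResults) -> FunctionalEstimate:
    """One-sided test that methoxyflurane reaches trough pain earlier.

    H0: equal trough times; H1: the methoxyflurane trough is earlier. The
    statistic is the delta-method z for the comparator-minus-methoxyflurane
    trough-time difference; p = 1 - Phi(z).
    """
    arms = results.arms
    if "methoxyflurane" not in arms or len(arms) != 2:
        raise ValueError("faster-relief test needs a two-arm fit with methoxyflurane")
    comparator = next(a for a in arms if a != "methoxyflurane")
    for arm in arms:
        if _trough_from_theta(results, results.theta, arm).boundary_flag:
            raise ValueError(
                f"trough for arm {arm!r} is at a boundary; the trough-time "
                "contrast is not defined"
            )

    def functional(theta: np.ndarray) -> float:
        _, lc, qc = _arm_pathway_from_theta(results, theta, comparator)
        _, lm, qm = _arm_pathway_from_theta(results, theta, "methoxyflurane")
        return (-lc / (2.0 * qc)) - (-lm / (2.0 * qm))

    est = delta_method(results, functional)
    z = est.value / est.se if est.se and est.se > 0 else 0.0
    est.p_value = float(special.ndtr(-z))  # 1 - Phi(z)
    return est


def severe_exit_estimate(
    results: PainPanelResults,
    arm: str,
    scenario: PathwayScenario | None = None,
) -> FunctionalEstimate:
    """Delta-method estimate of the duration in severe pain for one arm."""
    scenario = scenario or scenario_from_results(results)
    point = severe_exit_time(scenario, arm)
    if point.never_flag:
        return point

    base_offset = scenario.baseline_latent - scenario.severe_cutpoint
    names = results.param_names
    cut_idx = 6 if results.model.spec.n_categories == 11 else 2
    onset = results.model.spec.onset_lag(arm)

    def functional(theta: np.ndarray) -> float:
        level, lin, quad = _arm_pathway_from_theta(results, theta, arm)
        cut = float(theta[names.index(f"cut_{cut_idx + 1}")])
        scen = PathwayScenario(
            baseline_latent=cut + base_offset,
            arm_coefficients={
                arm: ArmPathway(level, lin, quad, onset)
            },
            severe_cutpoint=cut,
        )
        return severe_exit_time(scen, arm).value

    return delta_method(results, functional)


# ---------------------------------------------------------------------------
# predicted pathways with confidence bands

def predict_pathway(
    results: PainPanelResults,
    scenario: PathwayScenario | None = None,
    transform_to_vnps: bool = False,
) -> pd.DataFrame:
    """Pointwise predicted pathway and 95% delta-method band per arm.

    Returns a long DataFrame with columns ``arm, t, mean, lo, hi`` (latent
    scale). With ``transform_to_vnps`` an ``expected_vnps`` column adds the
    expected pain score ``sum_k k p_k`` at the band centre, marginalised over
    the episode random intercept by Gauss-Hermite quadrature.
    """
    scenario = scenario or scenario_from_results(results)
    names = results.param_names
    frames = []
    for arm in scenario.arm_coefficients:
        c = scenario.arm_coefficients[arm]
        grid = scenario.time_grid
        on = (grid >= c.onset_lag).astype(float)
        mean = scenario.baseline_latent + on * (
            c.onset_level + c.linear * grid + c.quadratic * grid**2
        )
        # the pathway is linear in the coefficients, so the delta band is exact
        G = np.zeros((grid.size, results.theta.size))
        for name, col in (
            (f"level:{arm}", on),
            ("t", on * grid),
            ("t2", on * grid**2),
        ):
            if name in names:
                G[:, names.index(name)] = col
        if arm == "methoxyflurane":
            for name, col in (("d_t", on * grid), ("d_t2", on * grid**2)):
                if name in names:
                    G[:, names.index(name)] = col
        var = np.einsum("tp,pq,tq->t", G, results.cov, G)
        se = np.sqrt(np.clip(var, 0.0, None))
        df = pd.DataFrame(
            {
                "arm": arm,
                "t": grid,
                "mean": mean,
                "lo": mean - 1.96 * se,
                "hi": mean + 1.96 * se,
            }
        )
        if transform_to_vnps:
            df["expected_vnps"] = expected_vnps(
                mean, results.params.cutpoints, results.params.sigma_u
            )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def expected_vnps(
    mu, cutpoints, sigma_u: float = 0.0, n_nodes: int = 20
) -> np.ndarray:
    """Expected pain score at latent mean(s) ``mu``.

    ``E[S] = sum_k k p_k(mu + u)`` marginalised over the episode random
    intercept ``u ~ N(0, sigma_u^2)`` by Gauss-Hermite quadrature.
    """
    mu = np.atleast_1d(np.asarray(mu, float))
    scores = np.arange(len(cutpoints) + 1, dtype=float)
    if sigma_u == 0.0:
        probs = np.atleast_2d(category_probabilities(mu, cutpoints))
        return probs @ scores
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    w = weights / math.sqrt(math.pi)
    out = np.zeros_like(mu)
    for x, wq in zip(nodes, w):
        probs = np.atleast_2d(
            category_probabilities(mu + math.sqrt(2.0) * sigma_u * x, cutpoints)
        )
        out += wq * (probs @ scores)
    return out
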