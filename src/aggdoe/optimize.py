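"""Multi-response desirability optimization over fitted interaction models.

Each response gets a Derringer–Suich style desirability d(y) in [0, 1]
(piecewise linear by default); the overall desirability D is the weighted
geometric mean across criteria.  The setpoint search maximizes D over the
coded factor cube with a multi-start Nelder–Mead local search.  Around a
setpoint the module reports process-capability style summaries: Cpk from the
regression prediction SD, probability of failure against specification
limits (closed form and Monte Carlo), per-factor contributions
(span-normalized sensitivities, a documented reconstruction — the commercial
formula is proprietary), and one-factor sweep profiles with tolerance bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt
from scipy import stats

from .modeling import FittedModel, invert_transform

__all__ = [
    "Criterion",
    "SetpointResult",
    "desirability",
    "overall_desirability",
    "optimize_setpoint",
    "cpk",
    "probability_of_failure",
    "factor_contributions",
    "setpoint_profile",
]


@dataclass(frozen=True)
class Criterion:
    """Desirability goal for one response (on the model's fitted scale).

    goal 'maximize': d ramps 0→1 from lower to upper (target side = upper).
    goal 'minimize': d ramps 1→0 from lower to upper.
    goal 'target':   d peaks at target, ramping from both limits.
    goal 'range':    d = 1 inside [lower, upper], 0 outside.
    """

    response: str
    goal: str
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in {"maximize", "minimize", "target", "range"}:
            raise ValueError(f"unknown goal {self.goal!r}")
        if not self.lower < self.upper:
            raise ValueError("criterion limits must satisfy lower < upper")
        if self.goal == "target":
            if self.target is None:
                raise ValueError("target goal needs a target value")
            if not self.lower <= self.target <= self.upper:
                raise ValueError("target must lie inside the limits")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


def desirability(y: float, c: Criterion, s: float = 1.0) -> float:
    """Per-response desirability in [0, 1]; linear ramps for s = 1."""
    lo, hi = c.lower, c.upper
    if c.goal == "maximize":
        if y <= lo:
            return 0.0
        if y >= hi:
            return 1.0
        return ((y - lo) / (hi - lo)) ** s
    if c.goal == "minimize":
        if y >= hi:
            return 0.0
        if y <= lo:
            return 1.0
        return ((hi - y) / (hi - lo)) ** s
    if c.goal == "target":
        t = c.target
        if y <= lo or y >= hi:
            return 0.0 if y != t else 1.0
        if y == t:
            return 1.0
        if y < t:
            return ((y - lo) / (t - lo)) ** s
        return ((hi - y) / (hi - t)) ** s
    # range
    return 1.0 if lo <= y <= hi else 0.0


def overall_desirability(ds, weights=None) -> float:
    """Weighted geometric mean of per-criterion desirabilities; 0 if any is 0."""
    ds = np.asarray(ds, dtype=float)
    if np.any((ds < 0) | (ds > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    if weights is None:
        weights = np.ones_like(ds)
    w = np.asarray(weights, dtype=float)
    if np.any(ds == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(ds)) / np.sum(w)))


@dataclass
class SetpointResult:
    coded: np.ndarray
    actual: dict[str, float]
    predicted: dict[str, float]  # back-transformed predictions
    predicted_sd: dict[str, float]  # on the fitted scale
    per_criterion_d: dict[str, float]
    desirability: float
    cpk: dict[str, float]
    probability_of_failure: dict[str, float]  # percent
    factor_contributions: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "coded": self.coded.tolist(),
            "actual": self.actual,
            "predicted": self.predicted,
            "predicted_sd": self.predicted_sd,
            "per_criterion_d": self.per_criterion_d,
            "desirability": self.desirability,
            "cpk": self.cpk,
            "probability_of_failure": self.probability_of_failure,
            "factor_contributions": self.factor_contributions,
        }


def _criterion_d_at(x, models, criteria) -> list[float]:
    ds = []
    for c in criteria:
        y = float(models[c.response].predict(x)[0])
        ds.append(desirability(y, c))
    return ds


def _overall_at(x, models, criteria) -> float:
    ds = _criterion_d_at(x, models, criteria)
    return overall_desirability(ds, [c.weight for c in criteria])


def cpk(pred_mean: float, pred_sd: float, lower_spec=None, upper_spec=None) -> float:
    """Process capability: distance from mean to the nearest spec limit / 3σ."""
    if pred_sd <= 0:
        raise ValueError("pred_sd must be > 0")
    vals = []
    if upper_spec is not None and np.isfinite(upper_spec):
        vals.append((upper_spec - pred_mean) / (3.0 * pred_sd))
    if lower_spec is not None and np.isfinite(lower_spec):
        vals.append((pred_mean - lower_spec) / (3.0 * pred_sd))
    if not vals:
        raise ValueError("at least one finite spec limit is required")
    return float(min(vals))


def probability_of_failure(
    pred_mean: float,
    pred_sd: float,
    lower_spec=None,
    upper_spec=None,
    n_draws: int = 0,
    seed: int = 0,
) -> float:
    """P(response outside spec limits) under a normal predictive law, percent.

    Closed form via the normal CDF; if ``n_draws`` > 0 a Monte-Carlo estimate
    is returned instead (the closed form is the cross-check in tests).
    """
    if pred_sd <= 0:
        raise ValueError("pred_sd must be > 0")
    lo = -math.inf if lower_spec is None else lower_spec
    hi = math.inf if upper_spec is None else upper_spec
    if n_draws > 0:
        rng = np.random.default_rng(seed)
        draws = rng.normal(pred_mean, pred_sd, size=n_draws)
        return 100.0 * float(np.mean((draws < lo) | (draws > hi)))
    p_fail = stats.norm.cdf(lo, pred_mean, pred_sd) + stats.norm.sf(hi, pred_mean, pred_sd)
    return 100.0 * float(p_fail)


def factor_contributions(
    model: FittedModel,
    setpoint: np.ndarray,
    bounds: tuple[float, float] = (-1.0, 1.0),
    n_grid: int = 21,
) -> dict[str, float]:
    """Span-normalized sensitivity of one response to each factor, percent.

    For each factor the predicted response is swept over its coded range with
    the other factors pinned at the setpoint; the prediction span (max−min)
    is normalized across factors to sum to 100.  Interactions make the
    contribution depend on where the partners sit.
    """
    setpoint = np.asarray(setpoint, dtype=float)
    grid = np.linspace(bounds[0], bounds[1], n_grid)
    spans = []
    for j in range(len(model.factor_names)):
        pts = np.tile(setpoint, (n_grid, 1))
        pts[:, j] = grid
        pred = model.predict(pts)
        spans.append(float(pred.max() - pred.min()))
    total = sum(spans)
    if total == 0:
        return {name: 0.0 for name in model.factor_names}
    return {
        name: 100.0 * s / total for name, s in zip(model.factor_names, spans)
    }


def optimize_setpoint(
    models: dict[str, FittedModel],
    criteria: list[Criterion],
    bounds: tuple[float, float] = (-1.0, 1.0),
    n_starts: int = 20,
    seed: int = 0,
    factors=None,
) -> SetpointResult:
    """Maximize overall desirability over the coded cube.

    Multi-start Nelder–Mead with box projection; start points are the cube
    center plus seeded uniform draws, so the reported D is never below the D
    at any start point.  Deterministic for a given seed.
    """
    for c in criteria:
        if c.response not in models:
            raise ValueError(f"criterion references unfitted response {c.response!r}")
    first = models[criteria[0].response]
    k = len(first.factor_names)
    lo, hi = bounds
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)] + [rng.uniform(lo, hi, size=k) for _ in range(n_starts - 1)]

    def neg_D(x):
        xc = np.clip(x, lo, hi)
        return -_overall_at(xc, models, criteria)

    best_x, best_D = np.zeros(k), _overall_at(np.zeros(k), models, criteria)
    for x0 in starts:
        res = sciopt.minimize(
            neg_D, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
        )
        xc = np.clip(res.x, lo, hi)
        D = _overall_at(xc, models, criteria)
        D0 = _overall_at(np.clip(x0, lo, hi), models, criteria)
        if D0 > D:  # local search must never lose to its own start
            xc, D = np.clip(x0, lo, hi), D0
        if D > best_D + 1e-12:
            best_x, best_D = xc, D

    per_d = dict(
        zip([c.response for c in criteria], _criterion_d_at(best_x, models, criteria))
    )
    predicted, predicted_sd, cpks, pofs = {}, {}, {}, {}
    for c in criteria:
        m = models[c.response]
        mu = float(m.predict(best_x)[0])
        sd = float(m.predict_sd(best_x)[0])
        predicted[c.response] = float(invert_transform(mu, m.transform))
        predicted_sd[c.response] = sd
        # spec limits are the unacceptable ends; for one-sided goals the
        # saturated (best) end of the ramp is not a limit
        if c.goal == "maximize":
            lo_spec, hi_spec = c.lower, None
        elif c.goal == "minimize":
            lo_spec, hi_spec = None, c.upper
        else:
            lo_spec, hi_spec = c.lower, c.upper
        if sd > 0:
            cpks[c.response] = cpk(mu, sd, lo_spec, hi_spec)
            pofs[c.response] = probability_of_failure(mu, sd, lo_spec, hi_spec)
    contrib = {
        c.response: factor_contributions(models[c.response], best_x, bounds)
        for c in criteria
    }
    actual = {}
    if factors is not None:
        for j, f in enumerate(factors):
            actual[f.name] = float(f.to_actual(best_x[j]))
    return SetpointResult(
        coded=best_x,
        actual=actual,
        predicted=predicted,
        predicted_sd=predicted_sd,
        per_criterion_d=per_d,
        desirability=best_D,
        cpk=cpks,
        probability_of_failure=pofs,
        factor_contributions=contrib,
    )


def setpoint_profile(
    model: FittedModel,
    setpoint: np.ndarray,
    factor: str,
    n_points: int = 41,
    bounds: tuple[float, float] = (-1.0, 1.0),
    criteria: list[Criterion] | None = None,
    n_mc: int = 0,
    seed: int = 0,
):
    """Sweep one factor across its range with the others pinned at the setpoint.

    Returns a dict with the grid, predicted response and prediction-SD band
    (fitted scale).  With ``criteria`` and ``n_mc`` > 0, a Monte-Carlo
    acceptable-range mask is added: the fraction of predictive draws meeting
    every criterion at each grid point.
    """
    if factor not in model.factor_names:
        raise ValueError(f"factor {factor!r} not in model")
    j = model.factor_names.index(factor)
    setpoint = np.asarray(setpoint, dtype=float)
    grid = np.linspace(bounds[0], bounds[1], n_points)
    pts = np.tile(setpoint, (n_points, 1))
    pts[:, j] = grid
    pred = model.predict(pts)
    sd = model.predict_sd(pts)
    out = {"factor": factor, "grid": grid, "predicted": pred, "sd": sd}
    if criteria and n_mc > 0:
        rng = np.random.default_rng(seed)
        ok = np.ones(n_points)
        draws = rng.normal(pred[None, :], sd[None, :], size=(n_mc, n_points))
        for c in criteria:
            if c.response != model.response:
                continue
            lo = c.lower if c.goal in {"maximize", "target", "range"} else -math.inf
            hi = c.upper if c.goal in {"minimize", "target", "range"} else math.inf
            ok = ok * np.mean((draws >= lo) & (draws <= hi), axis=0)
        out["acceptable_fraction"] = ok
    return out
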