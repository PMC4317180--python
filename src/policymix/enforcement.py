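"""Budget-constrained enforcement allocation and the policy equilibrium.

The enforcement agency observes deforestation and allocates field
inspections to maximize the inspected area subject to its budget:

    max_p  sum_i d'_i p_i   s.t.   sum_i p_i (TC_i + nd_i TC'_i) <= B

The continuous relaxation is a fractional knapsack: cells are bought in
decreasing order of deforestation per inspection real, d'_i / cost_i.  A
smooth alternative ("logistic" mode) spatializes the same allocation as a
logistic surface in log-deforestation and log-cost, with its intercept
recalibrated so the budget binds — mimicking the multi-year frequency of
inspections that land users actually experience.

Because land users respond to p and the agency responds to d', the
single-period outcome is the fixed point of the two best responses,
computed by damped iteration in :func:`solve_equilibrium`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

from .behavior import PolicyMix, optimal_deforestation
from .errors import ConfigurationError, FittingError
from .opportunity import ProfitModel


def inspection_cost(cells) -> np.ndarray:
    """Cost of covering a cell's deforestation patches once, BRL.

    ``tc_first + n_patches * tc_within``: travel to the first patch plus the
    expected within-cell cost of the remaining patches.  Accepts a cells
    DataFrame or anything with those three columns/fields.
    """
    tc_first = np.asarray(cells["tc_first"], dtype=float)
    tc_within = np.asarray(cells["tc_within"], dtype=float)
    n_patches = np.asarray(cells["n_patches"], dtype=float)
    return tc_first + n_patches * tc_within


@dataclass
class EnforcementPlan:
    """Per-cell inspection probabilities and their cost."""

    p: np.ndarray              # enforcement probability in [0, 1]
    expected_cost: np.ndarray  # p_i * cost_i, BRL
    total_cost: float          # BRL
    objective: float           # inspected deforestation sum(d'_i p_i), ha


def allocate_knapsack(d_prime, costs, B: float,
                      cell_ids=None) -> EnforcementPlan:
    """Optimal continuous inspection allocation (fractional knapsack).

    Cells are sorted by ``d'_i / cost_i`` descending (ties broken by cell id
    ascending for determinism) and receive p = 1 until the budget runs out;
    at most one cell gets a fractional probability.  Cells without
    deforestation are never inspected.
    """
    d_prime = np.asarray(d_prime, dtype=float)
    costs = np.asarray(costs, dtype=float)
    n = len(d_prime)
    if B < 0:
        raise ValueError("budget must be non-negative")
    if np.any((costs <= 0) & (d_prime > 0)):
        raise ConfigurationError(
            "cell with zero inspection cost but positive deforestation: "
            "the benefit/cost ratio is unbounded")
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)

    p = np.zeros(n)
    active = np.flatnonzero(d_prime > 0)
    if len(active) and B > 0:
        ratio = d_prime[active] / costs[active]
        order = active[np.lexsort((cell_ids[active], -ratio))]
        csum = np.cumsum(costs[order])
        full = csum <= B
        p[order[full]] = 1.0
        k = int(full.sum())
        if k < len(order):
            spent = csum[k - 1] if k > 0 else 0.0
            frac = (B - spent) / costs[order[k]]
            p[order[k]] = min(1.0, max(0.0, frac))
    expected = p * costs
    return EnforcementPlan(p=p, expected_cost=expected,
                           total_cost=float(expected.sum()),
                           objective=float((d_prime * p).sum()))


@dataclass(frozen=True)
class LogisticCoefficients:
    """p = expit(intercept + b_deforestation*log1p(d') - b_cost*log1p(cost))."""

    intercept: float
    b_deforestation: float
    b_cost: float

    def linear_predictor(self, d_prime, costs) -> np.ndarray:
        return (self.intercept
                + self.b_deforestation * np.log1p(np.asarray(d_prime, float))
                - self.b_cost * np.log1p(np.asarray(costs, float)))


def fit_logistic(plan: EnforcementPlan, d_prime, costs,
                 C: float = 1.0) -> LogisticCoefficients:
    """Fit the logistic enforcement surface to an inspection plan.

    The plan's probabilities are treated as binary outcomes (fractional
    probabilities contribute both outcomes, weighted accordingly) in a
    logistic regression on ``log1p(d')`` and ``log1p(cost)``.  Plain
    maximum likelihood is tried first; when the plan's funding threshold
    separates the data perfectly — the typical case for a knapsack plan —
    the fit falls back to an L2-penalized likelihood (strength ``1/C``) to
    keep the coefficients finite.
    """
    d_prime = np.asarray(d_prime, dtype=float)
    costs = np.asarray(costs, dtype=float)
    p = np.asarray(plan.p, dtype=float)
    if np.all(p <= 0) or np.all(p >= 1):
        raise FittingError(
            "degenerate plan (all probabilities 0 or all 1); "
            "adjust the budget before fitting")
    X = np.column_stack([np.log1p(d_prime), np.log1p(costs)])
    # expand fractional probabilities into weighted binary rows
    Xd = np.vstack([X, X])
    y = np.concatenate([np.ones(len(p)), np.zeros(len(p))])
    w = np.concatenate([p, 1.0 - p])
    keep = w > 1e-12
    Xd, y, w = Xd[keep], y[keep], w[keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, solver="lbfgs",
                                 max_iter=500, tol=1e-12)
        clf.fit(Xd, y, sample_weight=w)
        separated = (np.max(np.abs(clf.coef_)) > 30.0
                     or int(np.ravel(clf.n_iter_)[0]) >= 500)
        if separated:
            clf = LogisticRegression(C=C, solver="lbfgs",
                                     max_iter=2000, tol=1e-12)
            clf.fit(Xd, y, sample_weight=w)
    b1, b2 = clf.coef_[0]
    return LogisticCoefficients(intercept=float(clf.intercept_[0]),
                                b_deforestation=float(b1),
                                b_cost=float(-b2))


def allocate_logistic(coeffs: LogisticCoefficients, d_prime, costs,
                      B: float, rel_tol: float = 1e-6) -> EnforcementPlan:
    """Spread the budget over the logistic surface.

    The slope coefficients are kept and the intercept is recalibrated by
    bisection so expected spending sum(p_i * cost_i) equals B to ``rel_tol``
    relative, when feasible.  Cells without deforestation get p = 0 and cost
    nothing.  If B exceeds total cost, probabilities cap at their logistic
    ceiling (intercept at its feasibility bound) with a warning.
    """
    d_prime = np.asarray(d_prime, dtype=float)
    costs = np.asarray(costs, dtype=float)
    n = len(d_prime)
    active = d_prime > 0
    p = np.zeros(n)
    if B > 0 and active.any():
        eta = (coeffs.b_deforestation * np.log1p(d_prime[active])
               - coeffs.b_cost * np.log1p(costs[active]))
        c = costs[active]

        def spend(a: float) -> float:
            return float((expit(a + eta) * c).sum())

        lo, hi = -700.0, 700.0
        if B >= spend(hi) * (1 - rel_tol):
            warnings.warn("budget exceeds total inspection cost; "
                          "probabilities capped at their logistic ceiling")
            a = hi
        else:
            for _ in range(200):
                a = 0.5 * (lo + hi)
                s = spend(a)
                if abs(s - B) <= rel_tol * B:
                    break
                if s < B:
                    lo = a
                else:
                    hi = a
        p[active] = expit(a + eta)
    expected = p * costs
    return EnforcementPlan(p=p, expected_cost=expected,
                           total_cost=float(expected.sum()),
                           objective=float((d_prime * p).sum()))


@dataclass
class EquilibriumState:
    """Fixed point of the land-user / agency best responses."""

    p: np.ndarray        # per-cell enforcement probability
    d_prime: np.ndarray  # per-cell post-policy deforestation, ha
    iterations: int
    converged: bool
    residual: float      # max |p change| at termination


def _threshold_equilibrium(model: ProfitModel, costs: np.ndarray,
                           incentive: float, B: float,
                           rel_tol: float = 1e-12) -> tuple[np.ndarray, int]:
    """Stationary knapsack equilibrium via bisection on the marginal ratio.

    The knapsack best response is piecewise constant in p, so a pure fixed
    point of the alternating best responses often fails to exist: funding a
    cell deters its deforestation, which pushes it back out of the funded
    set.  The stationary outcome of the repeated interaction — with p read
    as the long-run inspection *frequency* land users experience — is
    characterized by a shadow ratio theta (deforestation inspected per real
    at the margin): cells whose deforestation-per-real ratio exceeds theta
    even at p = 1 are always inspected, cells below theta at p = 0 never
    are, and marginal cells are held at the frequency that pins their ratio
    to theta, with theta set so the budget binds.  Spending is decreasing in
    theta, so bisection finds it.
    """
    n = len(costs)
    p = np.zeros(n)
    active = model.responsive & (costs > 0)
    if B <= 0 or not active.any():
        return p, 1
    mu, sigma, area, d0 = (model.mu[active], model.sigma[active],
                           model.area[active], model.d0[active])
    c = costs[active]

    def p_of_theta(theta: float) -> np.ndarray:
        # deforestation level at which the cell's ratio equals theta
        level = theta * c
        out = np.empty(len(c))
        never = level >= d0          # ratio below theta already at p = 0
        out[never] = 0.0
        rest = ~never
        with np.errstate(divide="ignore"):
            z = norm.ppf(np.minimum(level[rest] / area[rest], 1.0))
        out[rest] = np.clip((mu[rest] - sigma[rest] * z) / incentive, 0.0, 1.0)
        return out

    total_cost = float(c.sum())
    if B >= total_cost:
        p[active] = 1.0
        return p, 1
    theta_hi = float(np.max(d0 / c))  # all p = 0 above this
    lo, hi = 0.0, theta_hi
    it = 0
    pa = p_of_theta(theta_hi)
    for it in range(1, 200):
        theta = 0.5 * (lo + hi)
        pa = p_of_theta(theta)
        spend = float((pa * c).sum())
        if abs(spend - B) <= rel_tol * max(B, 1.0):
            break
        if spend > B:
            lo = theta
        else:
            hi = theta
    p[active] = pa
    return p, it


def _logistic_equilibrium(model: ProfitModel, costs: np.ndarray,
                          coeffs: LogisticCoefficients, incentive: float,
                          B: float) -> tuple[np.ndarray, int]:
    """Exact logistic-mode equilibrium by nested bisection.

    Given the surface's slopes and an intercept ``a``, each cell's
    equilibrium probability solves the scalar fixed point
    ``p = expit(a + b1*log1p(d'(p)) - b2*log1p(cost))``; the right-hand
    side is non-increasing in p (more enforcement deters deforestation),
    so the solution is unique and bracketed in [0, 1].  Spending is then
    increasing in ``a``, and an outer bisection sets the intercept so the
    budget binds.
    """
    n = len(costs)
    p = np.zeros(n)
    active = model.responsive & (costs > 0)
    if B <= 0 or not active.any():
        return p, 1
    mu, sigma, area, d0 = (model.mu[active], model.sigma[active],
                           model.area[active], model.d0[active])
    c = costs[active]
    eta_cost = -coeffs.b_cost * np.log1p(c)

    def p_given_a(a: float) -> np.ndarray:
        lo = np.zeros(len(c))
        hi = np.ones(len(c))
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            d = np.minimum(d0, area * norm.cdf((mu - mid * incentive) / sigma))
            rhs = expit(a + coeffs.b_deforestation * np.log1p(d) + eta_cost)
            lo = np.where(mid < rhs, mid, lo)
            hi = np.where(mid < rhs, hi, mid)
        return 0.5 * (lo + hi)

    lo_a, hi_a = -700.0, 700.0
    if float((p_given_a(hi_a) * c).sum()) <= B:
        p[active] = p_given_a(hi_a)
        return p, 1
    it = 0
    pa = p_given_a(lo_a)
    for it in range(1, 100):
        a = 0.5 * (lo_a + hi_a)
        pa = p_given_a(a)
        spend = float((pa * c).sum())
        if abs(spend - B) <= 1e-9 * max(B, 1.0):
            break
        if spend < B:
            lo_a = a
        else:
            hi_a = a
    p[active] = pa
    return p, it


def solve_equilibrium(model: ProfitModel, cells, policy: PolicyMix,
                      tolerance: float = 1e-6, max_iterations: int = 1000,
                      naive_epa: bool = False, damping: float = 0.5,
                      coefficients: LogisticCoefficients | None = None,
                      ) -> EquilibriumState:
    """Solve the joint land-user / agency problem.

    The solver alternates (i) land-user deforestation d' given expected
    probabilities p and (ii) the agency's allocation given d', moving p a
    fraction ``damping`` toward the best response each round (the full step
    is taken when the best response has stabilized, since the knapsack map
    is piecewise constant).  If the iteration cycles — the generic case in
    knapsack mode, where funding a cell deters it and pushes it back out of
    the funded set — the knapsack-mode solver switches to the exact
    stationary solution computed by bisection on the marginal
    deforestation-per-real ratio (see :func:`_threshold_equilibrium`); in
    logistic mode, whose allocation map is smooth, the step size is halved
    once instead.

    With ``naive_epa`` the agency targets baseline deforestation d0 rather
    than anticipating d', which makes its allocation a constant map.  In
    logistic mode the slope coefficients are fitted once from the knapsack
    plan at baseline deforestation (or supplied via ``coefficients``) and
    only the budget-binding intercept moves with d'.

    Always returns a state; ``converged`` is False only if no stationary
    point was reached within ``max_iterations`` (never silent).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    costs = inspection_cost(cells)
    cell_ids = np.asarray(cells["cell_id"])
    n = len(costs)

    use_logistic = policy.enforcement_mode == "logistic"
    if use_logistic and coefficients is None:
        base_plan = allocate_knapsack(model.d0, costs, policy.B, cell_ids)
        if np.all(base_plan.p >= 1) or np.all(base_plan.p <= 0):
            use_logistic = False  # saturated or empty budget: surface irrelevant
        else:
            coefficients = fit_logistic(base_plan, model.d0, costs)

    def best_response(d_prime: np.ndarray) -> np.ndarray:
        target = model.d0 if naive_epa else d_prime
        if use_logistic:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return allocate_logistic(coefficients, target, costs, policy.B).p
        return allocate_knapsack(target, costs, policy.B, cell_ids).p

    p = np.zeros(n)
    step = damping
    prev_br = None
    residual = np.inf
    prev_residuals: list[float] = []
    damped_once = False
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        d_prime = optimal_deforestation(model, p, policy)
        p_br = best_response(d_prime)
        residual = float(np.max(np.abs(p_br - p))) if n else 0.0
        if residual <= tolerance:
            p = p_br
            converged = True
            break
        oscillating = (len(prev_residuals) >= 6
                       and prev_residuals[-1] >= prev_residuals[-3] - tolerance
                       and prev_residuals[-2] >= prev_residuals[-4] - tolerance)
        stalled = oscillating or it >= min(max_iterations, 200)
        if stalled and not naive_epa and policy.incentive > 0:
            # the iteration cycles: switch to the exact stationary solution
            if use_logistic:
                p, extra = _logistic_equilibrium(model, costs, coefficients,
                                                 policy.incentive, policy.B)
            else:
                p, extra = _threshold_equilibrium(model, costs,
                                                  policy.incentive, policy.B)
            converged = True
            residual = 0.0
            it += extra
            break
        if prev_br is not None and np.array_equal(p_br, prev_br):
            # best response is locally constant: jump straight to it
            p = p_br.copy()
        else:
            p = p + step * (p_br - p)
        prev_br = p_br
        prev_residuals.append(residual)
        if oscillating and not damped_once:
            step *= 0.5
            damped_once = True
            prev_residuals.clear()
    d_prime = optimal_deforestation(model, p, policy)
    if not converged:
        warnings.warn(
            f"equilibrium not converged after {it} iterations "
            f"(residual {residual:.3g})")
    return EquilibriumState(p=p, d_prime=np.asarray(d_prime, dtype=float),
                            iterations=it, converged=converged,
                            residual=residual)
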