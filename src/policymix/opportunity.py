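"""Disaggregation of district opportunity costs into cell-level profit models.

Within each grid cell, per-hectare profits of deforestation are assumed to
be spatially normally distributed, Normal(mu_i, sigma).  Land with positive
profit is cleared, so the baseline deforestation rate identifies the
positive-profit share:

    Phi(mu_i / sigma) = rate_i  =>  mu_i = sigma * Phi^{-1}(rate_i)

One equation per cell cannot pin down two parameters per cell, so the scale
sigma is taken common within a district and identified by the district-level
constraint: the deforestation-area weighted average of the conditional
positive mean E[X | X > 0] over a district's cells equals the district's
mean per-hectare profit.  With mu_i = sigma * z_i this constraint is linear
in sigma and solves in closed form:

    sigma_D = mean_profit_D * sum_i d0_i / sum_i d0_i * (z_i + phi(z_i)/Phi(z_i))

The marginal profit of the d-th cleared hectare is the (1 - d/area) quantile
of the cell's profit distribution, which is zero exactly at d = d0: absent
policy, land users clear precisely the profitable land.  Shifting the
effective incentive ``s`` moves the clearing threshold, giving the avoided-
deforestation cost curve in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .landscape import Landscape

_norm = stats.norm

#: baseline rates are clamped to this open interval before the probit
#: transform, which diverges at 0 and 1
RATE_CLAMP = 1e-6


@dataclass
class ProfitModel:
    """Calibrated per-cell profit distributions (vectorized over cells).

    Fields are aligned numpy arrays of length ``n_cells``.  Cells with zero
    baseline deforestation are marked unresponsive: they have no positive-
    profit land and never react to any incentive.  ``clamped`` flags cells
    whose baseline rate was clamped before the probit transform.
    """

    mu: np.ndarray        # location, BRL/ha
    sigma: np.ndarray     # scale, BRL/ha (district-common)
    area: np.ndarray      # denominator land area, ha
    d0: np.ndarray        # baseline deforestation, ha
    responsive: np.ndarray = field(default=None)  # bool mask, d0 > 0
    clamped: np.ndarray = field(default=None)     # bool mask

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.area = np.atleast_1d(np.asarray(self.area, dtype=float))
        self.d0 = np.atleast_1d(np.asarray(self.d0, dtype=float))
        n = len(self.mu)
        if self.responsive is None:
            self.responsive = self.d0 > 0
        self.responsive = np.atleast_1d(np.asarray(self.responsive, dtype=bool))
        if self.clamped is None:
            self.clamped = np.zeros(n, dtype=bool)
        self.clamped = np.atleast_1d(np.asarray(self.clamped, dtype=bool))

    def __len__(self) -> int:
        return len(self.mu)

    @classmethod
    def single(cls, mu: float, sigma: float, area: float, d0: float | None = None):
        """Convenience constructor for a one-cell model.

        If ``d0`` is omitted it is set to the baseline optimum implied by
        (mu, sigma): ``area * Phi(mu/sigma)``.
        """
        if d0 is None:
            d0 = float(area * _norm.cdf(mu / sigma))
        return cls(mu=[mu], sigma=[sigma], area=[area], d0=[d0])

    def conditional_positive_mean(self) -> np.ndarray:
        """E[profit | profit > 0] per cell (nan for unresponsive cells)."""
        z = self.mu / self.sigma
        out = np.full(len(self), np.nan)
        r = self.responsive
        out[r] = self.sigma[r] * (z[r] + _norm.pdf(z[r]) / _norm.cdf(z[r]))
        return out


def calibrate_cell_distributions(landscape: Landscape,
                                 denominator_column: str = "area") -> ProfitModel:
    """Calibrate per-cell normal profit distributions from a landscape.

    Parameters
    ----------
    landscape
        Validated landscape with districts carrying ``mean_profit``.
    denominator_column
        Cells column used as the rate denominator (``rate = d0 / denom``).
        Defaults to total cell area; pass e.g. a remaining-forest column if
        rates should be relative to forested land.

    Returns
    -------
    ProfitModel
        One entry per cell, in the landscape's cell order.  Cells with
        ``d0 = 0`` are unresponsive and carry zero weight in the district
        constraint; districts whose cells all have ``d0 = 0`` are skipped
        with a warning.
    """
    cells = landscape.cells
    districts = landscape.districts.set_index("district_id")
    if (districts["mean_profit"] < 0).any():
        raise ValidationError("mean_profit must be non-negative")
    denom = cells[denominator_column].to_numpy(float)
    d0 = cells["d0"].to_numpy(float)
    n = len(cells)

    rate = np.zeros(n)
    pos = d0 > 0
    rate[pos] = d0[pos] / denom[pos]
    clamped = pos & ((rate < RATE_CLAMP) | (rate > 1 - RATE_CLAMP))
    rate_c = np.clip(rate, RATE_CLAMP, 1 - RATE_CLAMP)
    z = _norm.ppf(rate_c)
    # per-unit-sigma conditional positive mean; strictly positive
    k = z + _norm.pdf(z) / _norm.cdf(z)

    mu = np.zeros(n)
    sigma = np.ones(n)
    for district_id, idx in cells.groupby("district_id").groups.items():
        idx = np.asarray(idx)
        sel = idx[pos[idx]]
        if len(sel) == 0:
            warnings.warn(
                f"district {district_id} has no deforesting cells; skipped")
            continue
        mean_profit = float(districts.loc[district_id, "mean_profit"])
        if mean_profit <= 0:
            raise ValidationError(
                f"district {district_id} deforests but mean_profit <= 0")
        sigma_d = mean_profit * d0[sel].sum() / (d0[sel] * k[sel]).sum()
        sigma[idx] = sigma_d
        mu[sel] = sigma_d * z[sel]
        mu[idx[~pos[idx]]] = 0.0

    return ProfitModel(mu=mu, sigma=sigma, area=denom, d0=d0,
                       responsive=pos, clamped=clamped)


def marginal_profit(model: ProfitModel, d):
    """Marginal per-hectare profit of the d-th cleared hectare, BRL/ha.

    This is the (1 - d/area) quantile of Normal(mu, sigma): strictly
    decreasing in d, and exactly zero at d = d0 for calibrated cells.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d >= model.area):
        raise ValueError("d must satisfy 0 <= d < area (quantile diverges)")
    out = np.asarray(model.mu + model.sigma * _norm.ppf(1.0 - d / model.area))
    return float(out.item()) if out.size == 1 else out


def total_profit(model: ProfitModel, d):
    """Total profit f(d) of clearing the most profitable d hectares, BRL.

    Closed-form antiderivative of the quantile:
    f(d) = mu*d + sigma*area*phi(Phi^{-1}(1 - d/area)); concave with its
    maximum at the baseline optimum d0.  Unresponsive cells return 0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any((d > 0) & (d >= model.area)):
        raise ValueError("d must satisfy 0 <= d < area")
    q = 1.0 - d / model.area
    out = model.mu * d + model.sigma * model.area * _norm.pdf(_norm.ppf(q))
    out = np.asarray(np.where(np.atleast_1d(model.responsive), out, 0.0))
    return float(out.item()) if out.size == 1 else out


def deforestation_at_incentive(model: ProfitModel, incentive):
    """Deforestation when the effective per-hectare incentive is ``incentive``.

    d(s) = area * Phi((mu - s)/sigma), capped at the baseline d0 so that a
    clamped rate cannot push the implied level above the observed one.
    """
    s = np.asarray(incentive, dtype=float)
    if np.any(s < 0):
        raise ValueError("incentive must be non-negative")
    raw = model.area * _norm.cdf((model.mu - s) / model.sigma)
    out = np.asarray(np.where(model.responsive, np.minimum(raw, model.d0), 0.0))
    return float(out.item()) if out.size == 1 else out


@dataclass(frozen=True)
class CostCurvePoint:
    """One point of the avoided-deforestation cost curve."""

    incentive: float  # effectively delivered incentive, BRL/ha
    avoided: float    # total avoided deforestation, ha


def cost_curve(model: ProfitModel, incentives) -> tuple[list[CostCurvePoint], np.ndarray]:
    """Avoided deforestation as a function of the delivered incentive.

    Parameters
    ----------
    model
        Calibrated cell profit models.
    incentives
        Non-negative grid of effectively delivered incentives, BRL/ha.

    Returns
    -------
    (points, per_cell)
        ``points`` is the aggregate curve; ``per_cell`` is an
        ``(n_incentives, n_cells)`` array of avoided hectares for
        percentile banding across cells.
    """
    incentives = np.asarray(incentives, dtype=float)
    if np.any(incentives < 0):
        raise ValueError("incentives must be non-negative")
    per_cell = np.empty((len(incentives), len(model)))
    for j, s in enumerate(incentives):
        per_cell[j] = model.d0 - deforestation_at_incentive(model, s)
    totals = per_cell.sum(axis=1)
    points = [CostCurvePoint(float(s), float(a))
              for s, a in zip(incentives, totals)]
    return points, per_cell
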