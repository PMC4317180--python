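"""Land-user response to a policy mix.

A risk-neutral land user in cell i facing enforcement probability p chooses
post-policy deforestation d' to maximize

    f(d') - d' * p * F + PES * (d0 - d' * p)

where F is the per-hectare fine (or equivalent coercion) and PES the
per-hectare payment conditional on avoided deforestation, with conditionality
enforced at the same probability p as the fine.  The first-order condition
sets the marginal profit equal to the expected policy incentive
p * (F + PES), so only that product matters for the chosen level:

    d' = area * Phi((mu - p*(F + PES)) / sigma)  <=  d0
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .opportunity import ProfitModel, deforestation_at_incentive, total_profit

#: simulation ranges used in the source data context; exceeding them is
#: legal but unusual enough to warrant a warning
MAX_BUDGET = 5e7
MAX_FINE = 5000.0
MAX_PES = 5000.0


@dataclass(frozen=True)
class PolicyMix:
    """The three policy levers plus accounting/solver flags.

    Attributes
    ----------
    B : float
        Enforcement agency budget, BRL.
    F : float
        Per-hectare disincentive (fine or in-situ coercion of equal value),
        BRL/ha.
    PES : float
        Per-hectare payment conditional on avoided deforestation, BRL/ha.
    fines_collected : bool
        Whether fines generate agency revenue (they do not under in-situ
        coercion such as asset confiscation).
    enforcement_mode : str
        ``"knapsack"`` for the budget-constrained allocation optimum,
        ``"logistic"`` for its smooth logistic spatialization.
    """

    B: float
    F: float = 0.0
    PES: float = 0.0
    fines_collected: bool = False
    enforcement_mode: str = "knapsack"

    def __post_init__(self):
        if self.B < 0 or self.F < 0 or self.PES < 0:
            raise ValueError("B, F and PES must be non-negative")
        if self.enforcement_mode not in ("knapsack", "logistic"):
            raise ValueError(f"unknown enforcement_mode {self.enforcement_mode!r}")
        if self.B > MAX_BUDGET or self.F > MAX_FINE or self.PES > MAX_PES:
            warnings.warn(
                "policy parameters exceed the simulated ranges "
                f"(B<={MAX_BUDGET:g}, F<={MAX_FINE:g}, PES<={MAX_PES:g})",
                stacklevel=2)

    @property
    def incentive(self) -> float:
        """Total per-hectare incentive F + PES, BRL/ha."""
        return self.F + self.PES


def optimal_deforestation(model: ProfitModel, p, policy: PolicyMix):
    """Optimal post-policy deforestation d' per cell, ha.

    ``p`` may be a scalar or an array aligned with the model's cells.
    d' equals d0 when the expected incentive p*(F+PES) is zero, decreases
    strictly in the incentive while interior, and is zero for cells without
    baseline deforestation.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("enforcement probability must lie in [0, 1]")
    return deforestation_at_incentive(model, p * policy.incentive)


def expected_land_user_income(model: ProfitModel, p, policy: PolicyMix, d_prime):
    """Expected land-user income under the mix, evaluated at ``d_prime``, BRL.

    f(d') - d'*p*F + PES*(d0 - d'*p): profit from residual clearing, minus
    expected fines, plus expected payments (received in full on avoided
    hectares and with probability 1-p on undetected residual hectares).
    """
    p = np.asarray(p, dtype=float)
    d_prime = np.asarray(d_prime, dtype=float)
    if np.any(d_prime > np.asarray(model.d0) + 1e-9):
        raise ValueError("d_prime may not exceed the baseline d0")
    out = (total_profit(model, d_prime)
           - d_prime * p * policy.F
           + policy.PES * (model.d0 - d_prime * p))
    out = np.asarray(out)
    return float(out.item()) if out.size == 1 else out
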