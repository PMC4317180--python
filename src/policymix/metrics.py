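"""Outcome metrics of a policy mix at equilibrium.

Cost-effectiveness of a mix is avoided deforestation per real of
implementation cost,

    CE = sum_i (d0_i - d'_i) / (B + sum_i PES*(d0_i - d'_i p_i) [- fines]),

where the denominator is the agency budget plus all expected payment
outlays, optionally net of collected fines.  The land-user income change
relative to laissez-faire is

    W_i = PES*(d0_i - d'_i p_i) - p_i F d'_i - (f_i(d0) - f_i(d')),

and the payment leakage ("PES loss") is the share paid on undetected
residual deforestation, PES * d'_i * (1 - p_i) — an imperfect-enforcement
rent that buys no conservation.  Exact accounting identities link the
three: total payments = PES*avoided + PES loss, and with fines collected
all transfers cancel between the agency and land users.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import PolicyMix
from .enforcement import EquilibriumState, inspection_cost
from .landscape import Landscape
from .opportunity import ProfitModel, total_profit


@dataclass
class ScenarioResult:
    """Aggregate and per-cell outcomes of one policy mix at equilibrium."""

    policy: PolicyMix
    avoided_total: float          # ha
    implementation_cost: float    # BRL (B + PES outlays - collected fines)
    fine_revenue: float           # BRL (0 unless fines_collected)
    fines_paid_total: float       # BRL paid by land users regardless
    CE: float                     # ha per BRL (nan if self-financing)
    self_financing: bool          # denominator <= 0 with positive numerator
    W_total: float                # BRL, negative = land-user loss
    pes_paid_total: float         # BRL
    pes_loss_total: float         # BRL
    inspection_spending: float    # realized sum p_i * cost_i, BRL
    per_cell: pd.DataFrame = field(repr=False, default=None)
    converged: bool = True

    @property
    def ce_per_1000(self) -> float:
        """Cost-effectiveness in hectares per 1000 BRL, as usually reported."""
        return self.CE * 1000.0

    def summary(self) -> dict:
        """Aggregate metrics as a plain JSON-serializable dict."""
        return {
            "B": self.policy.B,
            "F": self.policy.F,
            "PES": self.policy.PES,
            "fines_collected": self.policy.fines_collected,
            "enforcement_mode": self.policy.enforcement_mode,
            "avoided_total_ha": self.avoided_total,
            "implementation_cost_brl": self.implementation_cost,
            "fine_revenue_brl": self.fine_revenue,
            "fines_paid_brl": self.fines_paid_total,
            "ce_ha_per_brl": None if np.isnan(self.CE) else self.CE,
            "ce_ha_per_1000brl": None if np.isnan(self.CE) else self.ce_per_1000,
            "self_financing": self.self_financing,
            "income_change_total_brl": self.W_total,
            "pes_paid_total_brl": self.pes_paid_total,
            "pes_loss_total_brl": self.pes_loss_total,
            "inspection_spending_brl": self.inspection_spending,
            "converged": self.converged,
        }


def income_change(state: EquilibriumState, policy: PolicyMix,
                  model: ProfitModel) -> np.ndarray:
    """Per-cell land-user income change vs laissez-faire, BRL (negative = loss)."""
    p, d_prime = state.p, state.d_prime
    delta_f = total_profit(model, model.d0) - total_profit(model, d_prime)
    return (policy.PES * (model.d0 - d_prime * p)
            - p * policy.F * d_prime
            - delta_f)


def pes_loss(state: EquilibriumState, policy: PolicyMix) -> np.ndarray:
    """Per-cell payments lost to imperfect enforcement, PES*d'*(1-p), BRL."""
    return policy.PES * state.d_prime * (1.0 - state.p)


def net_revenue_map(state: EquilibriumState, policy: PolicyMix,
                    landscape: Landscape) -> np.ndarray:
    """Per-cell agency net revenue: collected fines minus costs and payments."""
    p, d_prime = state.p, state.d_prime
    d0 = landscape.cells["d0"].to_numpy(float)
    costs = inspection_cost(landscape.cells)
    fines = p * policy.F * d_prime if policy.fines_collected else 0.0
    return fines - p * costs - policy.PES * (d0 - d_prime * p)


def compute_metrics(state: EquilibriumState, policy: PolicyMix,
                    landscape: Landscape, model: ProfitModel) -> ScenarioResult:
    """Assemble the full per-cell table and aggregate metrics for one run."""
    p, d_prime = state.p, state.d_prime
    d0 = model.d0
    avoided = d0 - d_prime
    avoided_total = float(avoided.sum())

    pes_paid = policy.PES * (d0 - d_prime * p)
    fines_paid = p * policy.F * d_prime
    loss = pes_loss(state, policy)
    w = income_change(state, policy, model)
    net_rev = net_revenue_map(state, policy, landscape)

    fine_revenue = float(fines_paid.sum()) if policy.fines_collected else 0.0
    denominator = policy.B + float(pes_paid.sum()) - fine_revenue
    self_financing = False
    if denominator > 0:
        ce = avoided_total / denominator
    elif avoided_total <= 0:
        ce = 0.0
    else:
        # fine revenue covers all outlays: a ratio is meaningless
        ce = float("nan")
        self_financing = True

    per_cell = pd.DataFrame({
        "cell_id": landscape.cells["cell_id"].to_numpy(),
        "p": p,
        "d0": d0,
        "d_prime": d_prime,
        "income_change": w,
        "net_revenue": net_rev,
        "pes_paid": pes_paid,
        "pes_loss": loss,
        "fines_paid": fines_paid,
    })
    return ScenarioResult(
        policy=policy,
        avoided_total=avoided_total,
        implementation_cost=denominator,
        fine_revenue=fine_revenue,
        fines_paid_total=float(fines_paid.sum()),
        CE=ce,
        self_financing=self_financing,
        W_total=float(w.sum()),
        pes_paid_total=float(pes_paid.sum()),
        pes_loss_total=float(loss.sum()),
        inspection_spending=float((p * inspection_cost(landscape.cells)).sum()),
        per_cell=per_cell,
        converged=state.converged,
    )
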