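"""Scenario runs and parameter sweeps over the policy levers (B, F, PES).

Calibration of the cell profit distributions depends only on the landscape,
so it is performed once per landscape and reused across sweep points; every
sweep row equals an independent :func:`run_scenario` call at that point.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .behavior import PolicyMix
from .enforcement import solve_equilibrium
from .landscape import Landscape
from .metrics import ScenarioResult, compute_metrics
from .opportunity import ProfitModel, calibrate_cell_distributions

#: parameter presets mirroring commonly used simulation settings
PRESETS: dict[str, dict] = {
    "fig4": {"kind": "tradeoff", "B": 5e7, "total_incentive": 5000.0,
             "steps": 50, "fines_collected": False},
    "fig5": {"kind": "scenario", "B": 5e7, "F": 5000.0, "PES": 500.0},
    "fig6": {"kind": "budget",
             "policies": [(5000.0, 0.0), (2500.0, 0.0), (1000.0, 0.0),
                          (0.0, 100.0), (0.0, 500.0), (0.0, 1000.0),
                          (2500.0, 10.0), (2500.0, 50.0), (2500.0, 100.0)],
             "budgets": list(np.linspace(0.0, 5e7, 11))},
    "fig7": {"kind": "income", "F": 5000.0,
             "pes_grid": [0.0, 100.0, 500.0, 1000.0],
             "budgets": list(np.linspace(5e6, 5e7, 10))},
    "fig8": {"kind": "scenario", "B": 5e7, "F": 4500.0, "PES": 500.0},
}


def run_scenario(landscape: Landscape, policy: PolicyMix,
                 model: ProfitModel | None = None,
                 naive_epa: bool = False, tolerance: float = 1e-6,
                 max_iterations: int = 1000) -> ScenarioResult:
    """Calibrate (unless given), solve the equilibrium, and compute metrics."""
    if model is None:
        model = calibrate_cell_distributions(landscape)
    state = solve_equilibrium(model, landscape.cells, policy,
                              tolerance=tolerance,
                              max_iterations=max_iterations,
                              naive_epa=naive_epa)
    return compute_metrics(state, policy, landscape, model)


def sweep_tradeoff(landscape: Landscape, B: float, total_incentive: float,
                   steps: int = 50, enforcement_mode: str = "knapsack",
                   model: ProfitModel | None = None,
                   **solver_kwargs) -> pd.DataFrame:
    """Replace the fine with payments at a constant sum F + PES.

    Because land users respond only to p*(F+PES), avoided deforestation is
    constant along the sweep while cost-effectiveness falls and land-user
    income rises as the payment share grows.  Fines are not collected
    (reflecting in-situ coercion), so the pure-disincentive endpoint is the
    cost-effectiveness maximum.
    """
    if total_incentive <= 0:
        raise ValueError("total_incentive must be positive")
    if model is None:
        model = calibrate_cell_distributions(landscape)
    rows = []
    for share in np.linspace(0.0, 1.0, steps):
        pes = share * total_incentive
        policy = PolicyMix(B=B, F=total_incentive - pes, PES=pes,
                           fines_collected=False,
                           enforcement_mode=enforcement_mode)
        res = run_scenario(landscape, policy, model=model, **solver_kwargs)
        avoided = res.avoided_total
        rows.append({
            "pes_share": share,
            "F": policy.F,
            "PES": pes,
            "avoided_ha": avoided,
            "ce_ha_per_1000brl": res.ce_per_1000,
            "W_total_brl": res.W_total,
            "W_per_avoided_ha": res.W_total / avoided if avoided > 0 else np.nan,
            "pes_loss_total_brl": res.pes_loss_total,
            "converged": res.converged,
        })
    df = pd.DataFrame(rows)
    base = df.loc[0, "avoided_ha"]
    if base > 0 and not np.allclose(df["avoided_ha"], base, rtol=1e-9):
        warnings.warn("avoided deforestation varied along a constant-sum sweep")
    return df


def sweep_budget(landscape: Landscape, policies, budget_grid,
                 enforcement_mode: str = "knapsack",
                 fines_collected: bool = False,
                 model: ProfitModel | None = None,
                 **solver_kwargs) -> pd.DataFrame:
    """Cost-effectiveness of (F, PES) pairs across enforcement budgets."""
    if model is None:
        model = calibrate_cell_distributions(landscape)
    rows = []
    for fine, pes in policies:
        for budget in budget_grid:
            policy = PolicyMix(B=float(budget), F=float(fine), PES=float(pes),
                               fines_collected=fines_collected,
                               enforcement_mode=enforcement_mode)
            res = run_scenario(landscape, policy, model=model, **solver_kwargs)
            rows.append({
                "B": float(budget), "F": float(fine), "PES": float(pes),
                "avoided_ha": res.avoided_total,
                "ce_ha_per_1000brl": res.ce_per_1000,
                "W_total_brl": res.W_total,
                "converged": res.converged,
            })
    return pd.DataFrame(rows)


def sweep_income(landscape: Landscape, F: float, pes_grid, budget_grid,
                 enforcement_mode: str = "knapsack",
                 model: ProfitModel | None = None,
                 **solver_kwargs) -> pd.DataFrame:
    """Income and payment-leakage effects across budgets and payment levels."""
    if model is None:
        model = calibrate_cell_distributions(landscape)
    rows = []
    for pes in pes_grid:
        for budget in budget_grid:
            policy = PolicyMix(B=float(budget), F=float(F), PES=float(pes),
                               fines_collected=False,
                               enforcement_mode=enforcement_mode)
            res = run_scenario(landscape, policy, model=model, **solver_kwargs)
            avoided = res.avoided_total
            rows.append({
                "B": float(budget), "PES": float(pes), "F": float(F),
                "avoided_ha": avoided,
                "W_total_brl": res.W_total,
                "W_per_avoided_ha": res.W_total / avoided if avoided > 0 else np.nan,
                "pes_loss_total_brl": res.pes_loss_total,
                "pes_loss_per_avoided_ha":
                    res.pes_loss_total / avoided if avoided > 0 else np.nan,
                "converged": res.converged,
            })
    return pd.DataFrame(rows)
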