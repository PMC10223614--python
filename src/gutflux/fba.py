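"""Steady-state flux solvers: FBA, cooperative trade-off growth, minimal intake.

All problems share the constraint set of flux balance analysis,

    S v = 0,   lb <= v <= ub,

with fluxes in mmol/gDW/h (biomass flux in 1/h).  Three solvers are exposed:

``fba``
    maximize the biomass flux (single model) or the abundance-weighted
    community growth ``mu_c = sum_i a_i mu_i`` (community) — a linear program.
``cooperative_tradeoff``
    two-stage community allocation: stage 1 finds the maximal community growth
    ``mu_c*``; stage 2 minimizes the sum of squared per-taxon growth rates
    subject to ``mu_c >= tau * mu_c*``, spreading growth across taxa instead of
    letting the fastest taxon take everything.  The quadratic stage makes the
    per-taxon growth rates unique (strict convexity in mu); remaining flux
    degeneracy is removed by a final minimal-intake polish at the fixed growth
    rates, so returned solutions are fully pinned down.
``minimize_intake``
    minimize total environment import magnitude subject to a community growth
    floor — the parsimonious choice when resources are scarce.

Linear programs are solved with HiGHS (deterministic); the quadratic stage
uses SLSQP on the exact gradient with the stage-1 vertex as the start point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .errors import SolverError
from .model import (
    BIG,
    CommunityModel,
    ROLE_BIOMASS,
    ROLE_LUMEN_EXCHANGE,
    TaxonModel,
)

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

_LP_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}

#: fluxes below this magnitude are treated as zero (direction undefined)
FLUX_EPSILON = 1e-6


@dataclass
class TradeoffConfig:
    """Parameters of the cooperative trade-off program."""

    tau: float = 0.7
    tolerance: float = 1e-9

    def __post_init__(self):
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")


@dataclass
class FluxSolution:
    """A solved flux vector with growth bookkeeping.

    ``fluxes`` is indexed by community (or taxon) reaction id.  ``status`` is
    one of optimal/infeasible/unbounded; non-optimal solutions carry empty
    fluxes.  ``balance_residual`` is the steady-state violation ``‖S v‖∞``.
    """

    fluxes: pd.Series
    growth_per_taxon: dict[str, float] = field(default_factory=dict)
    community_growth: float | None = None
    objective_value: float | None = None
    status: str = STATUS_OPTIMAL
    balance_residual: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def direction(self, reaction_id: str) -> str:
        """import/export/none classification of an exchange flux."""
        v = self.fluxes.get(reaction_id, 0.0)
        if v > FLUX_EPSILON:
            return "export"
        if v < -FLUX_EPSILON:
            return "import"
        return "none"


def solve_lp(S, lb, ub, objective, sense: str = "max"):
    """Solve max/min objective·v s.t. S v = 0, lb <= v <= ub with HiGHS.

    Returns ``(x, objective_value, status)``; ``x`` is None unless optimal.
    """
    S = np.asarray(S, dtype=float)
    c = np.asarray(objective, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if np.any(lb > ub):
        raise ValueError("lb > ub in LP bounds")
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, STATUS_INFEASIBLE)
    if status != STATUS_OPTIMAL:
        return None, None, status
    return res.x, float(c @ res.x), status


def _solution_from_vector(model: CommunityModel | TaxonModel, x, objective_value, status):
    if x is None:
        return FluxSolution(
            fluxes=pd.Series(dtype=float), status=status, objective_value=None,
            balance_residual=np.inf,
        )
    if isinstance(model, CommunityModel):
        fluxes = pd.Series(x, index=model.reaction_ids)
        growth = {t: float(x[col]) for t, col in model.biomass_cols.items()}
        mu_c = float(sum(model.abundances[t] * g for t, g in growth.items()))
        residual = float(np.abs(model.S @ x).max()) if model.S.size else 0.0
        return FluxSolution(
            fluxes=fluxes, growth_per_taxon=growth, community_growth=mu_c,
            objective_value=objective_value, status=status, balance_residual=residual,
        )
    S, lb, ub, rids, _ = _taxon_arrays(model)
    fluxes = pd.Series(x, index=rids)
    mu = float(fluxes[model.biomass_id])
    residual = float(np.abs(S @ x).max()) if S.size else 0.0
    return FluxSolution(
        fluxes=fluxes, growth_per_taxon={model.taxon: mu}, community_growth=mu,
        objective_value=objective_value, status=status, balance_residual=residual,
    )


def _taxon_arrays(model: TaxonModel):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n_mets, n_rxns = len(met_index), len(model.reactions)
    S = np.zeros((n_mets, n_rxns))
    lb = np.zeros(n_rxns)
    ub = np.zeros(n_rxns)
    rids = []
    biomass_col = None
    for j, r in enumerate(model.reactions):
        rids.append(r.id)
        lb[j], ub[j] = r.lb, r.ub
        if r.role == ROLE_BIOMASS:
            biomass_col = j
        for met, coeff in r.stoichiometry.items():
            S[met_index[met], j] += coeff
    return S, lb, ub, rids, biomass_col


def fba(model: CommunityModel | TaxonModel) -> FluxSolution:
    """Maximize growth: biomass flux (taxon) or abundance-weighted growth (community)."""
    if isinstance(model, CommunityModel):
        x, obj, status = solve_lp(model.S, model.lb, model.ub, model.growth_objective())
        return _solution_from_vector(model, x, obj, status)
    model.validate()
    S, lb, ub, rids, biomass_col = _taxon_arrays(model)
    c = np.zeros(len(rids))
    c[biomass_col] = 1.0
    x, obj, status = solve_lp(S, lb, ub, c)
    return _solution_from_vector(model, x, obj, status)


def cooperative_tradeoff(
    community: CommunityModel, config: TradeoffConfig | None = None
) -> FluxSolution:
    """Two-stage cooperative trade-off allocation of community growth.

    Stage 1 maximizes ``mu_c`` (LP).  Stage 2 minimizes ``sum_i mu_i**2``
    subject to ``mu_c >= tau * mu_c*`` and all FBA constraints (convex QP via
    SLSQP).  A final LP pins the remaining fluxes by fixing the per-taxon
    growth rates and minimizing total environment intake.
    """
    config = config or TradeoffConfig()
    c = community.growth_objective()
    x1, mu_star, status = solve_lp(community.S, community.lb, community.ub, c)
    if status != STATUS_OPTIMAL:
        raise SolverError(f"community growth LP returned {status}", stage="tradeoff-stage1")
    if mu_star <= FLUX_EPSILON:
        # nothing can grow; the zero allocation is the trade-off optimum
        sol = minimize_intake(community, growth_floor=0.0)
        sol.objective_value = 0.0
        return sol

    bcols = np.array([community.biomass_cols[t.taxon] for t in community.taxa])
    floor = config.tau * mu_star

    def objective(x):
        mu = x[bcols]
        return float(mu @ mu)

    def grad(x):
        g = np.zeros_like(x)
        g[bcols] = 2.0 * x[bcols]
        return g

    S = community.S
    constraints = [
        {"type": "eq", "fun": lambda x: S @ x, "jac": lambda x: S},
        {"type": "ineq", "fun": lambda x: c @ x - floor, "jac": lambda x: c},
    ]
    res = minimize(
        objective, x1, jac=grad, method="SLSQP",
        bounds=np.column_stack([community.lb, community.ub]),
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success and np.abs(S @ res.x).max() > 1e-6:
        raise SolverError(
            f"quadratic stage failed: {res.message}", stage="tradeoff-stage2"
        )
    mu = res.x[bcols]

    # pin the remaining fluxes: fix growth rates, minimize environment intake;
    # a tight slack keeps the polish from perturbing downstream finite
    # differences, with a looser retry when the QP point is less precise
    sol = None
    for slack in (1e-9, 1e-6):
        fixed = community.copy()
        for t, m in zip(community.taxa, mu):
            col = fixed.biomass_cols[t.taxon]
            lo = max(community.lb[col], m - slack)
            hi = min(community.ub[col], m + slack)
            if hi < lo:
                hi = lo
            fixed.lb[col], fixed.ub[col] = lo, hi
        sol = minimize_intake(fixed, growth_floor=0.0, _model_for_report=community)
        if sol.optimal:
            break
    if sol is None or not sol.optimal:  # pragma: no cover - safety net
        sol = _solution_from_vector(community, res.x, objective(res.x), STATUS_OPTIMAL)
    sol.objective_value = float(np.dot(
        [sol.growth_per_taxon[t.taxon] for t in community.taxa],
        [sol.growth_per_taxon[t.taxon] for t in community.taxa],
    ))
    return sol


def minimize_intake(
    community: CommunityModel,
    growth_floor: float,
    _model_for_report: CommunityModel | None = None,
) -> FluxSolution:
    """Minimize total environment import magnitude at a community growth floor.

    Import slack variables ``s_j >= max(0, -v_env_j)`` turn the piecewise
    objective into an LP.  Reports infeasible status when the floor cannot be
    met.
    """
    report_model = _model_for_report or community
    n = len(community.reaction_ids)
    env = list(community.env_cols.values())
    m_env = len(env)
    n_tot = n + m_env
    c_obj = np.zeros(n_tot)
    c_obj[n:] = 1.0
    # equality rows: S v = 0 (slack coefficients zero)
    A_eq = np.hstack([community.S, np.zeros((community.S.shape[0], m_env))])
    # inequalities (as A_ub x <= b): -s_j - v_j <= 0 ; -mu_c <= -floor
    A_ub = np.zeros((m_env + 1, n_tot))
    for k, col in enumerate(env):
        A_ub[k, col] = -1.0
        A_ub[k, n + k] = -1.0
    growth = community.growth_objective()
    A_ub[m_env, :n] = -growth
    b_ub = np.zeros(m_env + 1)
    b_ub[m_env] = -growth_floor
    lb = np.concatenate([community.lb, np.zeros(m_env)])
    ub = np.concatenate([community.ub, np.full(m_env, BIG)])
    res = linprog(
        c_obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lb, ub]), method="highs",
    )
    status = _LP_STATUS.get(res.status, STATUS_INFEASIBLE)
    if status != STATUS_OPTIMAL:
        return FluxSolution(
            fluxes=pd.Series(dtype=float), status=status, balance_residual=np.inf,
        )
    sol = _solution_from_vector(report_model, res.x[:n], float(c_obj @ res.x), status)
    return sol


def total_intake(solution: FluxSolution, community: CommunityModel) -> float:
    """Total environment import magnitude of a solution (mmol/gDW/h)."""
    imports = [
        -float(solution.fluxes[rid])
        for rid in community.env_cols
        if solution.fluxes.get(rid, 0.0) < 0
    ]
    return float(sum(imports))


def solution_to_frame(solution: FluxSolution, community: CommunityModel) -> pd.DataFrame:
    """Tabulate a solution as reaction_id / taxon / flux / direction."""
    rows = []
    for rid, taxon, role in zip(
        community.reaction_ids, community.reaction_taxon, community.reaction_role
    ):
        v = float(solution.fluxes.get(rid, 0.0))
        direction = ""
        if role in (ROLE_LUMEN_EXCHANGE, "taxon-exchange"):
            direction = solution.direction(rid)
        rows.append({"reaction_id": rid, "taxon": taxon or "", "flux": v,
                     "direction": direction})
    return pd.DataFrame(rows)
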