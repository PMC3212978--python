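"""Per-time-step LP solves: growth maximization and total-flux minimization.

Each quasi-steady-state step of the batch dynamics solves

    maximize   mu            (biomass reaction flux)
    subject to S v = 0,  vmin <= v <= vmax

and then, keeping the optimal ``mu`` fixed (within a relative tolerance),
minimizes the enzymatic cost ``sum(|v|)``.  The second stage makes the
secretion fluxes read from ``v`` as reproducible as possible across solver
runs; remaining degeneracy among equal-cost optima is broken by the backend
and is documented as a caveat rather than removed.

Absolute values are handled with the standard forward/reverse variable split
that the solver interface already maintains per reaction; the stored model is
never rewritten.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
import pandas as pd
from optlang.symbolics import Zero

from .errors import SolverError
from .model_io import biomass_reaction

__all__ = ["FluxSolution", "maximize_growth", "minimize_total_flux", "solve_growth"]

#: growth rates below this are treated as zero (no growth, no enforced flux)
GROWTH_ZERO = 1e-12

#: relative slack when re-fixing the stage-1 optimum in stage 2
MU_FIX_EPSILON = 1e-9


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``mu`` is the growth rate (1/h), ``fluxes`` the full flux vector
    (mmol/gDW/h; positive exchange flux = secretion), ``status`` one of
    ``optimal`` / ``infeasible`` / ``unbounded``.
    """

    mu: float
    fluxes: pd.Series
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _apply_uptake_bounds(model: cobra.Model, uptake_bounds: dict[str, float]) -> None:
    for rxn_id, lb in uptake_bounds.items():
        model.reactions.get_by_id(rxn_id).lower_bound = lb


def _zero_solution(model: cobra.Model, status: str) -> FluxSolution:
    fluxes = pd.Series(0.0, index=[r.id for r in model.reactions])
    return FluxSolution(mu=0.0, fluxes=fluxes, status=status)


def _set_l1_objective(model: cobra.Model) -> None:
    """Replace the objective with min sum of forward+reverse flux variables."""
    model.objective = model.problem.Objective(Zero, direction="min", sloppy=True)
    coefficients = {}
    for rxn in model.reactions:
        coefficients[rxn.forward_variable] = 1.0
        coefficients[rxn.reverse_variable] = 1.0
    model.objective.set_linear_coefficients(coefficients)


def maximize_growth(model: cobra.Model, uptake_bounds: dict[str, float] | None = None
                    ) -> FluxSolution:
    """Stage 1: maximize the growth rate under the given uptake bounds.

    ``uptake_bounds`` maps exchange-reaction ids to lower bounds (negative =
    uptake allowed).  Infeasible models come back with ``mu = 0`` and status
    ``infeasible`` rather than raising.
    """
    with model:
        if uptake_bounds:
            _apply_uptake_bounds(model, uptake_bounds)
        solution = model.optimize()
        if solution.status == "infeasible":
            return _zero_solution(model, "infeasible")
        if solution.status != "optimal":
            raise SolverError(
                f"growth maximization did not converge: {solution.status}",
                status=solution.status,
            )
        bm = biomass_reaction(model)
        return FluxSolution(
            mu=max(float(solution.fluxes[bm.id]), 0.0),
            fluxes=solution.fluxes,
            status="optimal",
        )


def minimize_total_flux(
    model: cobra.Model,
    uptake_bounds: dict[str, float] | None,
    mu_fixed: float,
    epsilon: float = MU_FIX_EPSILON,
) -> FluxSolution:
    """Stage 2: minimize ``sum(|v|)`` at growth rate >= ``mu_fixed``·(1-eps).

    ``mu_fixed`` normally comes from :func:`maximize_growth` under identical
    bounds.  If the re-fixed problem is infeasible at ``epsilon`` the solve is
    retried once with a looser 1e-6 slack before raising
    :class:`~crossfeed.errors.SolverError` (which suggests a larger epsilon).
    """
    last_status = "unknown"
    retry = (epsilon,) if epsilon >= 1e-6 else (epsilon, 1e-6)
    for eps in retry:
        with model:
            if uptake_bounds:
                _apply_uptake_bounds(model, uptake_bounds)
            bm = biomass_reaction(model)
            bm.lower_bound = max(bm.lower_bound, mu_fixed * (1.0 - eps))
            _set_l1_objective(model)
            solution = model.optimize()
            last_status = solution.status
            if solution.status == "optimal":
                return FluxSolution(
                    mu=max(float(solution.fluxes[bm.id]), 0.0),
                    fluxes=solution.fluxes,
                    status="optimal",
                )
    raise SolverError(
        f"flux minimization infeasible at mu={mu_fixed:.6g} "
        f"(status {last_status}); consider a larger epsilon",
        status=last_status,
    )


def solve_growth(
    model: cobra.Model,
    uptake_bounds: dict[str, float] | None = None,
    minimize_flux: bool = True,
) -> FluxSolution:
    """Convenience two-stage solve used at every dynamics step.

    Non-growing strains (``mu`` below :data:`GROWTH_ZERO`) short-circuit to
    the all-zero flux vector, which is the L1 minimizer when no growth is
    enforced.
    """
    stage1 = maximize_growth(model, uptake_bounds)
    if not stage1.optimal or stage1.mu < GROWTH_ZERO:
        return _zero_solution(model, stage1.status)
    if not minimize_flux:
        return stage1
    return minimize_total_flux(model, uptake_bounds, stage1.mu)
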