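"""Time-stepped batch dynamics for monocultures and multi-strain co-cultures.

The simulation divides the batch-culture time course into intervals of
length ``dt`` within which each strain is assumed to sit at an intracellular
steady state.  Per interval and per strain an LP is solved (growth
maximization followed by total-flux minimization, see
:mod:`crossfeed.fba_core`), then biomass grows exponentially,

    b_i[t + dt] = b_i[t] * exp(mu_i * dt),

and every tracked medium concentration is updated with the exact integral of
the exponentially growing consumption/production over the interval,

    exC[t + dt] = exC[t] + sum_i  vex_i * b_i[t] * (exp(mu_i dt) - 1) / mu_i,

with the closed-form linear limit ``vex_i * b_i * dt`` taken for
``mu_i -> 0`` (the printed formula is 0/0 there; a non-growing strain can in
principle still consume at steady state).

All strains in a co-culture are independent competitors: each maximizes its
own growth, and every strain sees the same per-gDW uptake bound computed
from the *total* population biomass,

    vmin_ex = -exC / (dt * sum_i b_i)        (for every strain),

capped by the per-substrate maximal uptake rate when one is configured.
There is no per-strain partitioning of the pool; because of this, the
exponential within-step growth can overdraw a nearly empty pool by at most
the factor ``(exp(mu dt) - 1)/(mu dt)``.  Overdrawn concentrations are
clamped to zero and the clamped mass is recorded on the trajectory.

Secreted metabolites join the tracked medium pool as soon as they appear and
become consumable by every strain in later steps, which is what lets
cross-feeding interactions develop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import cobra
import numpy as np
import pandas as pd

from .errors import DomainError
from .fba_core import solve_growth
from .model_io import GrowthCondition, StrainSpec, list_exchanges

logger = logging.getLogger(__name__)

__all__ = [
    "MediumState",
    "BatchTrajectory",
    "step_uptake_bounds",
    "update_biomass",
    "update_medium",
    "simulate_monoculture",
    "simulate_coculture",
]

#: default growth-rate threshold below which a strain counts as not growing
MU_TOL = 1e-6

#: fluxes below this magnitude are treated as zero in the medium update
FLUX_EPS = 1e-9

#: stand-in for an uncapped uptake rate (mmol/gDW/h)
UNBOUNDED_UPTAKE = 1000.0


@dataclass
class MediumState:
    """Concentrations (mmol/L) of the tracked external metabolites.

    In-excess metabolites (oxygen, ammonia, ...) are never tracked; they are
    available at their uptake cap throughout.
    """

    concentrations: dict[str, float]
    in_excess: frozenset[str] = frozenset()

    def __post_init__(self):
        overlap = set(self.concentrations) & set(self.in_excess)
        if overlap:
            raise DomainError(
                f"in-excess metabolites cannot carry tracked concentrations: "
                f"{sorted(overlap)}"
            )
        if any(c < 0 for c in self.concentrations.values()):
            raise DomainError("concentrations must be non-negative")

    def copy(self) -> "MediumState":
        return MediumState(dict(self.concentrations), self.in_excess)


@dataclass
class BatchTrajectory:
    """Result of one batch simulation.

    ``times`` has T entries; ``biomass`` is (T, n_strains); ``growth_rates``
    and ``exchange_fluxes`` describe the T-1 intervals between recorded
    times (entry k covers [times[k], times[k+1])).  Exchange fluxes are keyed
    by external-metabolite id; positive = secretion.
    """

    strain_ids: tuple[str, ...]
    times: np.ndarray
    biomass: np.ndarray
    growth_rates: np.ndarray
    medium_series: list[dict[str, float]]
    exchange_fluxes: list[list[dict[str, float]]]
    condition: GrowthCondition
    termination: str
    clamped_mass: dict[str, float] = field(default_factory=dict)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def endpoint_biomass(self) -> float:
        """Total population biomass at termination, gDW/L."""
        return float(self.biomass[-1].sum())

    def strain_endpoint(self, strain_id: str) -> float:
        return float(self.biomass[-1, self.strain_ids.index(strain_id)])

    def biomass_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.biomass, index=self.times, columns=self.strain_ids)

    def medium_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.medium_series, index=self.times).fillna(0.0)

    def exchange_frame(self, strain_id: str) -> pd.DataFrame:
        """Per-interval exchange-flux profile of one strain (rows = interval
        start times, columns = external metabolites)."""
        i = self.strain_ids.index(strain_id)
        rows = [step[i] for step in self.exchange_fluxes]
        return pd.DataFrame(rows, index=self.times[:-1]).fillna(0.0)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (time, strain, variable, value) table for export."""
        records = []
        for k, t in enumerate(self.times):
            for i, sid in enumerate(self.strain_ids):
                records.append((t, sid, "biomass", self.biomass[k, i]))
                if k < len(self.times) - 1:
                    records.append((t, sid, "growth_rate", self.growth_rates[k, i]))
                    for met, v in self.exchange_fluxes[k][i].items():
                        records.append((t, sid, f"flux:{met}", v))
            for met, conc in self.medium_series[k].items():
                records.append((t, "<medium>", f"conc:{met}", conc))
        return pd.DataFrame(records, columns=["time", "strain", "variable", "value"])


# --------------------------------------------------------------------------- #
# elementary steps
# --------------------------------------------------------------------------- #

def metabolite_uptake_bounds(
    medium: MediumState,
    total_biomass: float,
    dt: float,
    caps: dict[str, float],
) -> dict[str, float]:
    """Per-gDW uptake lower bound for every available external metabolite.

    Tracked metabolite with concentration C:  max(-C/(b_total*dt), -cap);
    in-excess metabolite: -cap (or the unbounded stand-in without one).
    Metabolites neither tracked nor in excess are absent (bound 0 is applied
    by the caller for those).
    """
    if total_biomass <= 0:
        raise DomainError("population extinct: total biomass must be > 0")
    if dt <= 0:
        raise DomainError("time step must be > 0")
    bounds: dict[str, float] = {}
    for met, conc in medium.concentrations.items():
        availability = -conc / (total_biomass * dt)
        cap = caps.get(met)
        bounds[met] = max(availability, -cap) if cap is not None else availability
    for met in medium.in_excess:
        bounds[met] = -caps.get(met, UNBOUNDED_UPTAKE)
    return bounds


def step_uptake_bounds(
    medium: MediumState,
    total_biomass: float,
    dt: float,
    caps: dict[str, float],
    exchange_map: dict[str, str],
) -> dict[str, float]:
    """Exchange-reaction lower bounds for one strain's LP at this step.

    ``exchange_map`` maps the strain's exchange-reaction ids to external
    metabolite ids (see :func:`crossfeed.model_io.list_exchanges`).  Exchange
    reactions whose metabolite is unavailable get a lower bound of 0 (only
    secretion possible).
    """
    per_met = metabolite_uptake_bounds(medium, total_biomass, dt, caps)
    return {rxn: per_met.get(met, 0.0) for rxn, met in exchange_map.items()}


def update_biomass(b: float, mu: float, dt: float) -> float:
    """Exponential within-interval biomass growth."""
    return b * math.exp(mu * dt)


def _growth_integral(b: float, mu: float, dt: float) -> float:
    """Integral of b*exp(mu*t) over one interval, with the mu->0 limit."""
    if mu < 1e-9:
        return b * dt
    return b * math.expm1(mu * dt) / mu


def update_medium(
    medium: MediumState,
    strains: Sequence[tuple[dict[str, float], float, float]],
    dt: float,
) -> tuple[MediumState, dict[str, float]]:
    """Apply one interval of exchange to the medium.

    ``strains`` is a sequence of ``(vex_by_metabolite, biomass, mu)`` triples
    with biomass taken at the interval start.  Returns the new medium state
    plus the mass (mmol/L, per metabolite) clamped away where exponential
    within-step growth overdrew a pool.  Newly secreted metabolites enter the
    tracked pool at their produced concentration.
    """
    new_conc = dict(medium.concentrations)
    clamped: dict[str, float] = {}
    for vex, b, mu in strains:
        if b <= 0:
            continue
        integral = _growth_integral(b, mu, dt)
        for met, flux in vex.items():
            if met in medium.in_excess or abs(flux) < FLUX_EPS:
                continue
            new_conc[met] = new_conc.get(met, 0.0) + flux * integral
    for met, conc in list(new_conc.items()):
        if conc < 0:
            clamped[met] = -conc
            new_conc[met] = 0.0
    if clamped:
        logger.debug("clamped overdrawn medium mass: %s", clamped)
    return MediumState(new_conc, medium.in_excess), clamped


# --------------------------------------------------------------------------- #
# simulation drivers
# --------------------------------------------------------------------------- #

def simulate_coculture(
    strains: Sequence[tuple[StrainSpec, cobra.Model]],
    initial_biomasses: Sequence[float],
    condition: GrowthCondition,
    mu_tol: float = MU_TOL,
    minimize_flux: bool = True,
) -> BatchTrajectory:
    """Simulate competing strains sharing one batch medium.

    Each entry of ``strains`` pairs a strain specification with the strain's
    (already gene-deleted) model.  Every strain is solved independently per
    interval against the shared per-gDW uptake bounds; the simulation stops
    when no strain can grow further (``stalled``) or the clock reaches
    ``condition.max_time`` (``max-time``).
    """
    if not strains:
        raise DomainError("at least one strain is required")
    if len(initial_biomasses) != len(strains):
        raise DomainError("one initial biomass per strain is required")
    if any(b < 0 for b in initial_biomasses):
        raise DomainError("initial biomasses must be non-negative")

    specs = [spec for spec, _ in strains]
    models = [model for _, model in strains]
    exchange_maps = [list_exchanges(m) for m in models]
    n = len(strains)
    dt = condition.time_step

    medium = MediumState(
        {condition.carbon_source: condition.initial_concentration},
        condition.in_excess,
    )
    b = np.asarray(initial_biomasses, dtype=float)

    times = [0.0]
    biomass_rows = [b.copy()]
    medium_rows = [dict(medium.concentrations)]
    mu_rows: list[np.ndarray] = []
    flux_rows: list[list[dict[str, float]]] = []
    clamped_total: dict[str, float] = {}
    termination = "max-time"

    t = 0.0
    while t < condition.max_time - 1e-12:
        total_b = float(b.sum())
        if total_b <= 0:
            raise DomainError("population extinct at t=%.3f h" % t)
        per_met = metabolite_uptake_bounds(medium, total_b, dt, condition.uptake_caps)

        mus = np.zeros(n)
        vex: list[dict[str, float]] = [{} for _ in range(n)]
        for i in range(n):
            if b[i] <= 0:
                continue
            bounds = {
                rxn: per_met.get(met, 0.0)
                for rxn, met in exchange_maps[i].items()
            }
            try:
                sol = solve_growth(models[i], bounds, minimize_flux=minimize_flux)
            except Exception as exc:
                raise type(exc)(
                    f"strain {specs[i].strain_id!r} at t={t:.3f} h: {exc}"
                ) from exc
            mus[i] = sol.mu
            vex[i] = {
                met: float(sol.fluxes[rxn])
                for rxn, met in exchange_maps[i].items()
                if abs(sol.fluxes[rxn]) >= FLUX_EPS
            }

        if np.all(mus < mu_tol):
            termination = "stalled"
            break

        medium, clamped = update_medium(
            medium, [(vex[i], b[i], mus[i]) for i in range(n)], dt
        )
        for met, mass in clamped.items():
            clamped_total[met] = clamped_total.get(met, 0.0) + mass
        b = b * np.exp(mus * dt)
        t += dt

        times.append(t)
        biomass_rows.append(b.copy())
        medium_rows.append(dict(medium.concentrations))
        mu_rows.append(mus)
        flux_rows.append(vex)

    return BatchTrajectory(
        strain_ids=tuple(s.strain_id for s in specs),
        times=np.asarray(times),
        biomass=np.vstack(biomass_rows),
        growth_rates=(
            np.vstack(mu_rows) if mu_rows else np.zeros((0, n))
        ),
        medium_series=medium_rows,
        exchange_fluxes=flux_rows,
        condition=condition,
        termination=termination,
        clamped_mass=clamped_total,
    )


def simulate_monoculture(
    model: cobra.Model,
    condition: GrowthCondition,
    strain_id: str | None = None,
    mu_tol: float = MU_TOL,
    minimize_flux: bool = True,
) -> BatchTrajectory:
    """Simulate one strain alone; the co-culture dynamics reduce exactly to
    the classic single-population dynamic FBA in this case."""
    spec = StrainSpec(strain_id or model.id or "strain")
    return simulate_coculture(
        [(spec, model)],
        [condition.initial_biomass],
        condition,
        mu_tol=mu_tol,
        minimize_flux=minimize_flux,
    )
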