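"""Growth efficiency of strain communities and cross-feeding detection.

Growth performance of a culture is its endpoint (maximum) total biomass
concentration.  A community's benefit compares the group endpoint ``g``
against monoculture endpoints ``m_i`` under identical initial conditions:

    benefit = (g - max_i m_i) / max_i m_i,

where the ``i`` range over the community members (*relative* benefit) or
over every strain of the condition's diversity graph (*absolute* benefit).
A negative value means the co-culture grew no better than the best
monoculture.

Cross-feeding interactions are read off the exchange-flux time profiles of a
co-culture: strain A feeds strain B through metabolite s if A secretes s
during some window and B takes s up during a window that does not end before
A's begins.  Pairs are classified as bi-directional, unidirectional, or
non-interacting.  Communities only ever outperform their monocultures when
such interactions are present.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from scipy import stats

from .batch_dynamics import BatchTrajectory, simulate_coculture
from .communities import Community
from .errors import DomainError, UndefinedStatisticError
from .model_io import GrowthCondition, StrainSpec

__all__ = [
    "InteractionRecord",
    "CommunityResult",
    "growth_performance",
    "benefit",
    "simulate_community",
    "relative_and_absolute",
    "ratio_scan",
    "detect_interactions",
    "classify_pair",
    "pair_mean_prediction",
    "prediction_correlation",
]

#: sustained |flux| below this (mmol/gDW/h) is treated as LP noise
INTERACTION_FLUX_TOL = 1e-6

#: default composition grid for ratio scans, in ninths (1:9 ... 9:1)
DEFAULT_RATIOS = tuple(i / 10 for i in range(1, 10))


@dataclass(frozen=True)
class InteractionRecord:
    """One directed cross-feeding link: ``producer`` secretes ``metabolite``
    over ``producer_window`` (h) and ``consumer`` takes it up over
    ``consumer_window``."""

    metabolite: str
    producer: str
    consumer: str
    producer_window: tuple[float, float]
    consumer_window: tuple[float, float]


@dataclass
class CommunityResult:
    """Benefit bookkeeping for one simulated community."""

    community: Community
    initial_split: dict[str, float]
    group_biomass: float
    mono_endpoints: dict[str, float]
    relative_benefit: float
    absolute_benefit: float | None
    interactions: list[InteractionRecord] = field(default_factory=list)
    comparable: bool = True  # False when the co-culture hit max-time

    @property
    def interacting(self) -> bool:
        return bool(self.interactions)


def growth_performance(traj: BatchTrajectory) -> float:
    """Endpoint total biomass (gDW/L) of a finished trajectory."""
    return traj.endpoint_biomass


def benefit(g: float, monos: Sequence[float]) -> float:
    """(g - max_i m_i) / max_i m_i; negative when the group underperforms."""
    if len(monos) == 0:
        raise DomainError("benefit needs at least one monoculture endpoint")
    best = max(monos)
    if best <= 0:
        raise UndefinedStatisticError(
            "benefit undefined: best monoculture endpoint is not positive"
        )
    return (g - best) / best


def simulate_community(
    strains: Sequence[tuple[StrainSpec, cobra.Model]],
    condition: GrowthCondition,
    split: Sequence[float] | None = None,
) -> BatchTrajectory:
    """Co-culture with the condition's total inoculum divided over members
    (equally unless ``split`` fractions are given)."""
    n = len(strains)
    if split is None:
        fractions = np.full(n, 1.0 / n)
    else:
        fractions = np.asarray(split, dtype=float)
        if len(fractions) != n or abs(fractions.sum() - 1.0) > 1e-9:
            raise DomainError("split must give one fraction per strain, summing to 1")
    return simulate_coculture(
        strains, condition.initial_biomass * fractions, condition
    )


def relative_and_absolute(
    strains: Sequence[tuple[StrainSpec, cobra.Model]],
    condition: GrowthCondition,
    mono_endpoints: Mapping[str, float],
    split: Sequence[float] | None = None,
    condition_id: str | None = None,
) -> CommunityResult:
    """Run one co-culture and score both benefit variants.

    ``mono_endpoints`` must cover every member (for the relative benefit);
    when it covers additional strains of the diversity graph, the absolute
    benefit is computed over all of them, otherwise it is left ``None``.
    """
    member_ids = [spec.strain_id for spec, _ in strains]
    missing = [m for m in member_ids if m not in mono_endpoints]
    if missing:
        raise DomainError(f"monoculture endpoints missing for members: {missing}")
    traj = simulate_community(strains, condition, split)
    g = growth_performance(traj)
    member_monos = [mono_endpoints[m] for m in member_ids]
    relative = benefit(g, member_monos)
    extra = set(mono_endpoints) - set(member_ids)
    absolute = benefit(g, list(mono_endpoints.values())) if extra else None
    return CommunityResult(
        community=Community(
            tuple(member_ids),
            condition_id=condition_id or condition.condition_id,
        ),
        initial_split={
            sid: float(b) for sid, b in zip(member_ids, traj.biomass[0])
        },
        group_biomass=g,
        mono_endpoints={m: mono_endpoints[m] for m in member_ids},
        relative_benefit=relative,
        absolute_benefit=absolute,
        interactions=detect_interactions(traj),
        comparable=traj.termination != "max-time",
    )


def ratio_scan(
    pair: Sequence[tuple[StrainSpec, cobra.Model]],
    condition: GrowthCondition,
    mono_endpoints: Mapping[str, float],
    ratios: Sequence[float] = DEFAULT_RATIOS,
) -> tuple[pd.DataFrame, float]:
    """Relative benefit of a pair across initial composition fractions.

    ``ratios`` are first-member fractions in (0, 1); the total inoculum is
    fixed by the condition.  Returns the scan table and the argmax fraction.
    """
    if len(pair) != 2:
        raise DomainError("ratio_scan expects exactly two strains")
    if any(not 0.0 < r < 1.0 for r in ratios):
        raise DomainError("ratios must lie strictly between 0 and 1")
    rows = []
    for r in ratios:
        result = relative_and_absolute(
            pair, condition, mono_endpoints, split=(r, 1.0 - r)
        )
        rows.append(
            {
                "fraction_first": r,
                "group_biomass": result.group_biomass,
                "relative_benefit": result.relative_benefit,
                "interacting": result.interacting,
            }
        )
    frame = pd.DataFrame(rows)
    best = float(frame.loc[frame["relative_benefit"].idxmax(), "fraction_first"])
    return frame, best


# --------------------------------------------------------------------------- #
# interaction detection
# --------------------------------------------------------------------------- #

def _activity_window(
    times: np.ndarray, series: np.ndarray, sign: int,
    tol: float,
) -> tuple[float, float] | None:
    active = np.flatnonzero(sign * series > tol)
    if active.size == 0:
        return None
    return float(times[active[0]]), float(times[active[-1]])


def detect_interactions(
    traj: BatchTrajectory,
    flux_tol: float = INTERACTION_FLUX_TOL,
) -> list[InteractionRecord]:
    """Directed cross-feeding links in a co-culture trajectory.

    For every non-primal tracked metabolite, a (producer, consumer) record is
    emitted when the producer sustains secretion and the consumer sustains
    uptake for at least one step each, and the consumer's uptake window does
    not end before the producer's secretion window begins (the pool mediates,
    so consumption may follow production — e.g. after the primal source is
    exhausted — or overlap it).  Monocultures yield no records.
    """
    if traj.n_strains < 2:
        return []
    primal = traj.condition.carbon_source
    interval_times = traj.times[:-1]
    records: list[InteractionRecord] = []
    frames = {sid: traj.exchange_frame(sid) for sid in traj.strain_ids}
    metabolites = sorted(
        {met for frame in frames.values() for met in frame.columns if met != primal}
    )
    for met in metabolites:
        windows = {}
        for sid, frame in frames.items():
            series = (
                frame[met].to_numpy() if met in frame.columns
                else np.zeros(len(interval_times))
            )
            windows[sid] = (
                _activity_window(interval_times, series, +1, flux_tol),
                _activity_window(interval_times, series, -1, flux_tol),
            )
        for producer, consumer in itertools.permutations(traj.strain_ids, 2):
            secretion = windows[producer][0]
            uptake = windows[consumer][1]
            if secretion is None or uptake is None:
                continue
            if uptake[1] < secretion[0]:
                continue  # consumed only before anything was provided
            records.append(
                InteractionRecord(met, producer, consumer, secretion, uptake)
            )
    return records


def classify_pair(
    records: Sequence[InteractionRecord], strain_a: str, strain_b: str
) -> str:
    """'bi-directional', 'unidirectional', or 'none' for one strain pair."""
    a_to_b = any(
        r.producer == strain_a and r.consumer == strain_b for r in records
    )
    b_to_a = any(
        r.producer == strain_b and r.consumer == strain_a for r in records
    )
    if a_to_b and b_to_a:
        return "bi-directional"
    if a_to_b or b_to_a:
        return "unidirectional"
    return "none"


# --------------------------------------------------------------------------- #
# pair-mean growth prediction
# --------------------------------------------------------------------------- #

def pair_mean_prediction(
    members: Sequence[str],
    pair_performances: Mapping[frozenset, float],
    pair_interactions: Mapping[frozenset, bool] | None = None,
) -> tuple[float, bool]:
    """Predict a community's growth performance as the mean of its
    constituent pairs' performances.

    The prediction is trusted only when every constituent pair interacts;
    the second return value flags that condition (``True`` = all pairs
    interact) so that batch correlations can exclude the rest.  Missing pair
    simulations are reported by name.
    """
    pairs = [frozenset(p) for p in itertools.combinations(sorted(members), 2)]
    missing = [tuple(sorted(p)) for p in pairs if p not in pair_performances]
    if missing:
        raise DomainError(f"pair performances missing: {missing}")
    prediction = float(np.mean([pair_performances[p] for p in pairs]))
    all_interact = True
    if pair_interactions is not None:
        all_interact = all(pair_interactions.get(p, False) for p in pairs)
    return prediction, all_interact


def prediction_correlation(
    predictions: Sequence[float], simulations: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, p-value) between predicted and simulated
    community performances."""
    if len(predictions) != len(simulations) or len(predictions) < 3:
        raise DomainError("need >= 3 matched (prediction, simulation) pairs")
    r, p = stats.pearsonr(predictions, simulations)
    return float(r), float(p)
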