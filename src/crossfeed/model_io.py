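"""Loading, validation, and perturbation of stoichiometric models.

Models are carried as :class:`cobra.Model` objects (the field's standard
in-memory container).  This module adds the structural validation used by
the rest of the package, gene-knockout application through GPR (gene-
protein-reaction) boolean rules, exchange-reaction discovery, and the
structured-text configuration types for growth conditions and strains.

Sign convention, fixed repo-wide: a positive exchange flux secretes the
metabolite into the medium, a negative one takes it up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import cobra.io
import yaml

from .errors import ConditionError, ModelFormatError, ModelValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCondition",
    "StrainSpec",
    "load_model",
    "save_model",
    "validate_model",
    "biomass_reaction",
    "apply_knockout",
    "list_exchanges",
    "external_compartment",
]


# --------------------------------------------------------------------------- #
# configuration types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class GrowthCondition:
    """A single-carbon-source batch growth condition.

    Parameters
    ----------
    carbon_source
        External-metabolite id of the limiting carbon source.
    initial_concentration
        Starting concentration of the carbon source, mmol/L.
    in_excess
        External metabolites assumed never to deplete (oxygen, ammonia,
        inorganics); they are bounded only by their uptake cap and are not
        tracked in the medium.
    uptake_caps
        Maximal uptake rate per external metabolite, mmol/gDW/h.  Metabolites
        without an entry are limited only by availability.
    initial_biomass
        Inoculum, gDW/L (total across strains in a co-culture).
    time_step
        Quasi-steady-state interval length, h.
    max_time
        Hard stop for the simulation clock, h.
    """

    carbon_source: str
    initial_concentration: float = 10.0
    in_excess: frozenset[str] = frozenset()
    uptake_caps: dict[str, float] = field(default_factory=dict)
    initial_biomass: float = 0.003
    time_step: float = 0.1
    max_time: float = 100.0
    condition_id: str = ""

    def __post_init__(self):
        if self.initial_concentration <= 0:
            raise ConditionError("initial_concentration must be > 0")
        if self.time_step <= 0:
            raise ConditionError("time_step must be > 0")
        if self.carbon_source in self.in_excess:
            raise ConditionError(
                f"carbon source {self.carbon_source!r} cannot be in excess"
            )
        if not self.condition_id:
            object.__setattr__(self, "condition_id", self.carbon_source)
        object.__setattr__(self, "in_excess", frozenset(self.in_excess))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GrowthCondition":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            carbon_source=raw["carbon_source"],
            initial_concentration=float(raw.get("initial_concentration", 10.0)),
            in_excess=frozenset(raw.get("in_excess", [])),
            uptake_caps={k: float(v) for k, v in raw.get("uptake_caps", {}).items()},
            initial_biomass=float(raw.get("initial_biomass", 0.003)),
            time_step=float(raw.get("time_step", 0.1)),
            max_time=float(raw.get("max_time", 100.0)),
            condition_id=raw.get("condition_id", ""),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "carbon_source": self.carbon_source,
            "initial_concentration": self.initial_concentration,
            "in_excess": sorted(self.in_excess),
            "uptake_caps": dict(sorted(self.uptake_caps.items())),
            "initial_biomass": self.initial_biomass,
            "time_step": self.time_step,
            "max_time": self.max_time,
            "condition_id": self.condition_id,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class StrainSpec:
    """A strain defined by its set of knocked-out genes (empty = wild type).

    Strains are conventionally named after the deleted gene(s).
    """

    strain_id: str
    knockouts: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))

    def validate_against(self, model: cobra.Model) -> set[str]:
        """Return (and warn about) knockout genes absent from the model."""
        known = {g.id for g in model.genes}
        unknown = set(self.knockouts) - known
        if unknown:
            warnings.warn(
                f"strain {self.strain_id!r}: genes not in model, ignored: "
                f"{sorted(unknown)}",
                stacklevel=2,
            )
        return unknown


# --------------------------------------------------------------------------- #
# model loading and validation
# --------------------------------------------------------------------------- #

def load_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read a stoichiometric model from SBML or BiGG-style JSON.

    ``format`` is inferred from the file suffix when not given.  The loaded
    model is validated (see :func:`validate_model`) before being returned.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    try:
        if format == "json":
            model = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {format!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # parser errors name the offending element
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    validate_model(model)
    return model


def save_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        cobra.io.save_json_model(model, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ModelFormatError(f"unknown model format {format!r}")


def biomass_reaction(model: cobra.Model) -> cobra.Reaction:
    """The unique reaction carrying the growth objective."""
    objective = [
        rxn for rxn in model.reactions
        if rxn.objective_coefficient not in (0, 0.0)
    ]
    if len(objective) != 1:
        raise ModelValidationError(
            f"model {model.id!r} must have exactly one biomass/objective "
            f"reaction, found {[r.id for r in objective]}"
        )
    return objective[0]


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants every model must satisfy.

    Raises :class:`ModelValidationError` naming the first offending element:
    reversed bounds, a missing or ambiguous biomass reaction, or an empty
    non-boundary reaction.  Multi-metabolite boundary reactions only warn
    (they are excluded from the exchange map, see :func:`list_exchanges`).
    """
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        if len(rxn.metabolites) == 0 and not rxn.boundary:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has no stoichiometric entries and is "
                "not a declared boundary reaction"
            )
    biomass_reaction(model)  # existence + uniqueness


def external_compartment(model: cobra.Model) -> str:
    """Infer the external compartment: the one boundary metabolites live in."""
    counts: dict[str, int] = {}
    for rxn in model.boundary:
        for met in rxn.metabolites:
            counts[met.compartment] = counts.get(met.compartment, 0) + 1
    if not counts:
        raise ModelValidationError(
            f"model {model.id!r} has no boundary reactions"
        )
    return max(sorted(counts), key=counts.get)


def list_exchanges(model: cobra.Model) -> dict[str, str]:
    """Map exchange-reaction id -> external-metabolite id, in stable order.

    Exchange reactions are single-metabolite boundary reactions whose
    metabolite sits in the external compartment.  Boundary reactions touching
    more than one metabolite are excluded with a warning.
    """
    ext = external_compartment(model)
    mapping: dict[str, str] = {}
    for rxn in sorted(model.boundary, key=lambda r: r.id):
        mets = list(rxn.metabolites)
        if len(mets) != 1:
            warnings.warn(
                f"boundary reaction {rxn.id!r} touches {len(mets)} metabolites; "
                "excluded from the exchange map",
                stacklevel=2,
            )
            continue
        if mets[0].compartment != ext:
            continue
        mapping[rxn.id] = mets[0].id
    return mapping


# --------------------------------------------------------------------------- #
# knockouts
# --------------------------------------------------------------------------- #

def apply_knockout(model: cobra.Model, spec: StrainSpec) -> cobra.Model:
    """Return a copy of ``model`` with the strain's gene deletions applied.

    A reaction whose GPR rule evaluates false with the knocked-out genes set
    absent has both flux bounds set to zero (deletion treated as reaction
    removal).  Genes unknown to the model warn and are skipped, so that
    genome-wide sweeps tolerate annotation drift.  The input model is never
    modified; applying the same spec twice is idempotent.
    """
    unknown = spec.validate_against(model)
    knocked = set(spec.knockouts) - unknown
    mutant = model.copy()
    mutant.id = f"{model.id}__{spec.strain_id}" if spec.strain_id else model.id
    if not knocked:
        return mutant
    for rxn in mutant.reactions:
        if not rxn.gene_reaction_rule:
            continue
        if not rxn.gpr.eval(knocked):
            logger.debug(
                "strain %s: reaction %s disabled by knockout of %s",
                spec.strain_id, rxn.id, sorted(knocked),
            )
            rxn.bounds = (0.0, 0.0)
    return mutant
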