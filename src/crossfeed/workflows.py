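"""End-to-end orchestration: knockout sweep -> graph -> communities -> benefit.

The genome-wide stages reuse monoculture results heavily, so the sweep is
resumable through a content-addressed cache keyed on (model fingerprint,
strain, condition): warm re-runs perform zero LP solves.  Every output file
is reproducible from config plus inputs; the manifest records parameters,
thresholds, and the solver backend for each run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import networkx as nx
import pandas as pd
import yaml

from . import fixtures
from .batch_dynamics import MU_TOL, simulate_monoculture
from .benefit_analysis import relative_and_absolute
from .communities import cliques_via_compression
from .diversity_graph import (
    DEFAULT_EXCLUDED,
    ByproductProfile,
    binarize,
    build_graph,
    byproduct_profile,
    clustering_coefficient,
    compress,
    fast_graph_from_fba,
    network_centralization,
    strength_centrality,
    write_edge_list,
)
from .errors import CrossfeedError, SolverError
from .model_io import GrowthCondition, StrainSpec, apply_knockout, load_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "strain_universe", "sweep_knockouts", "full_pipeline"]

#: model ids resolvable without a file, for desk-scale runs
FIXTURE_MODELS = {
    "fixture:crossfeed": fixtures.make_crossfeed_model,
    "fixture:chain": fixtures.make_chain_model,
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; documented defaults mirror the
    standard batch settings (0.003 gDW/L inoculum, 10 mmol/L source,
    dt = 0.1 h, binarization threshold 0.6)."""

    model_path: str
    condition: GrowthCondition
    knockout_genes: list[str] | None = None  # None = every model gene
    binarize_threshold: float = 0.6
    mu_tol: float = MU_TOL
    centrality_cutoff: float = 0.9
    attributes: dict[str, float] = field(default_factory=dict)
    fast_graph: bool = False
    max_communities: int = 10
    expand_representatives: bool = False
    output_dir: str = "crossfeed_out"
    cache_dir: str | None = None

    def __post_init__(self):
        if not 0.0 < self.binarize_threshold <= 1.0:
            raise CrossfeedError("binarize_threshold must lie in (0, 1]")
        if not 0.0 <= self.centrality_cutoff <= 1.0:
            raise CrossfeedError("centrality_cutoff must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: Mapping[str, str] | None = None
                  ) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, value in (overrides or {}).items():
            raw[key] = yaml.safe_load(value)
        condition = raw.pop("condition")
        if isinstance(condition, str):
            condition = GrowthCondition.from_yaml(
                Path(path).parent / condition
            )
        else:
            condition = GrowthCondition(**condition)
        return cls(condition=condition, **raw)

    def resolve_model(self) -> cobra.Model:
        if self.model_path in FIXTURE_MODELS:
            return FIXTURE_MODELS[self.model_path]()
        return load_model(self.model_path)


def strain_universe(
    model: cobra.Model, genes: Sequence[str] | None = None
) -> list[StrainSpec]:
    """Wild type plus one single-gene deletion strain per gene."""
    gene_ids = sorted(genes) if genes is not None else sorted(
        g.id for g in model.genes
    )
    return [StrainSpec("wild_type")] + [
        StrainSpec(g, frozenset({g})) for g in gene_ids
    ]


# --------------------------------------------------------------------------- #
# knockout sweep
# --------------------------------------------------------------------------- #

def _model_fingerprint(model: cobra.Model) -> str:
    parts = []
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        stoich = ";".join(
            f"{m.id}:{c:g}" for m, c in sorted(
                rxn.metabolites.items(), key=lambda mc: mc[0].id
            )
        )
        parts.append(
            f"{rxn.id}|{rxn.lower_bound:g}|{rxn.upper_bound:g}|"
            f"{rxn.gene_reaction_rule}|{stoich}"
        )
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


def _condition_key(condition: GrowthCondition) -> str:
    return json.dumps(
        {
            "carbon": condition.carbon_source,
            "c0": condition.initial_concentration,
            "excess": sorted(condition.in_excess),
            "caps": dict(sorted(condition.uptake_caps.items())),
            "b0": condition.initial_biomass,
            "dt": condition.time_step,
            "tmax": condition.max_time,
        },
        sort_keys=True,
    )


def sweep_knockouts(
    model: cobra.Model,
    specs: Sequence[StrainSpec],
    condition: GrowthCondition,
    cache_dir: str | Path | None = None,
    mu_tol: float = MU_TOL,
    exclude: frozenset[str] = DEFAULT_EXCLUDED,
) -> tuple[pd.DataFrame, dict[str, ByproductProfile], dict[str, float]]:
    """Monoculture endpoint and by-product profile for every strain.

    Returns the summary table, the blueprint per strain, and the endpoint
    biomasses.  Solver failures are isolated per strain (the run continues,
    the row is marked).  With a cache directory, finished strains are loaded
    instead of re-simulated.
    """
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    fingerprint = _model_fingerprint(model)
    condition_key = _condition_key(condition)

    rows = []
    profiles: dict[str, ByproductProfile] = {}
    endpoints: dict[str, float] = {}
    for spec in specs:
        key = hashlib.sha256(
            "|".join(
                [fingerprint, spec.strain_id, ",".join(sorted(spec.knockouts)),
                 condition_key, str(mu_tol)]
            ).encode()
        ).hexdigest()
        cache_file = cache / f"{key}.json" if cache else None
        if cache_file and cache_file.exists():
            payload = json.loads(cache_file.read_text())
        else:
            try:
                mutant = apply_knockout(model, spec)
                traj = simulate_monoculture(
                    mutant, condition, spec.strain_id, mu_tol=mu_tol
                )
                profile = byproduct_profile(traj, exclude=exclude)
                payload = {
                    "strain": spec.strain_id,
                    "viable": len(traj.times) > 1,
                    "endpoint": traj.endpoint_biomass,
                    "cmax": profile.cmax,
                    "termination": traj.termination,
                    "error": "",
                }
            except SolverError as exc:
                logger.warning("strain %s failed: %s", spec.strain_id, exc)
                payload = {
                    "strain": spec.strain_id,
                    "viable": False,
                    "endpoint": float("nan"),
                    "cmax": {},
                    "termination": "error",
                    "error": str(exc),
                }
            if cache_file:
                cache_file.write_text(json.dumps(payload, sort_keys=True))
        profiles[spec.strain_id] = ByproductProfile(
            spec.strain_id, dict(payload["cmax"])
        )
        endpoints[spec.strain_id] = payload["endpoint"]
        rows.append(
            {
                "strain": payload["strain"],
                "viable": payload["viable"],
                "endpoint_biomass": payload["endpoint"],
                "n_byproducts": len(payload["cmax"]),
                "byproducts": ",".join(sorted(payload["cmax"])),
                "termination": payload["termination"],
                "error": payload["error"],
            }
        )
    return pd.DataFrame(rows), profiles, endpoints


# --------------------------------------------------------------------------- #
# full pipeline
# --------------------------------------------------------------------------- #

def full_pipeline(config: RunConfig) -> dict:
    """Run sweep -> graph -> stats -> compression -> communities -> benefits.

    Writes all artifacts plus a machine-readable manifest into
    ``config.output_dir`` and returns the manifest.  A stage failure halts
    the downstream stages; the partial manifest is still written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "model": config.model_path,
            "condition": config.condition.condition_id,
            "binarize_threshold": config.binarize_threshold,
            "mu_tol": config.mu_tol,
            "centrality_cutoff": config.centrality_cutoff,
            "fast_graph": config.fast_graph,
            "solver": cobra.Configuration().solver.__name__,
        },
        "stages": {},
    }

    def record(stage: str, files: list[str], **extra) -> None:
        manifest["stages"][stage] = {"files": files, **extra}
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2)
        )

    try:
        model = config.resolve_model()
        condition = config.condition
        specs = strain_universe(model, config.knockout_genes)

        # 1. monoculture sweep
        table, profiles, endpoints = sweep_knockouts(
            model, specs, condition,
            cache_dir=config.cache_dir, mu_tol=config.mu_tol,
        )
        table.to_csv(out / "sweep.tsv", sep="\t", index=False)
        record("sweep", ["sweep.tsv"], n_strains=len(specs))

        # 2. diversity graph
        viability = dict(zip(table["strain"], table["viable"]))
        if config.fast_graph:
            strain_models = [
                (spec, apply_knockout(model, spec)) for spec in specs
            ]
            graph = fast_graph_from_fba(
                strain_models, condition, attributes=config.attributes or None
            )
        else:
            graph = build_graph(
                list(profiles.values()), viability,
                attributes=config.attributes or None,
                condition_id=condition.condition_id,
            )
        nx.write_graphml(graph, out / "graph.graphml")
        write_edge_list(graph, out / "edges.tsv")
        record("graph", ["graph.graphml", "edges.tsv"],
               n_nodes=graph.number_of_nodes())

        # 3. statistics
        binary = binarize(graph, config.binarize_threshold)
        centrality = strength_centrality(graph)
        _, mean_clustering = clustering_coefficient(binary)
        stats: dict = {
            "n_nodes": graph.number_of_nodes(),
            "mean_clustering_binary": mean_clustering,
            "n_central": sum(
                1 for c in centrality.values() if c >= config.centrality_cutoff
            ),
            "strength_centrality": dict(sorted(centrality.items())),
        }
        if graph.number_of_nodes() >= 3:
            stats["network_centralization"] = network_centralization(graph)
        (out / "graph_stats.json").write_text(
            json.dumps(stats, sort_keys=True, indent=2)
        )
        record("stats", ["graph_stats.json"])

        # 4. compression
        compressed = compress(binary)
        pd.DataFrame(
            [
                {"supernode": i, "size": len(members),
                 "members": ",".join(str(m) for m in members)}
                for i, members in enumerate(compressed.supernodes)
            ]
        ).to_csv(out / "supernodes.tsv", sep="\t", index=False)
        record("compression", ["supernodes.tsv"],
               n_supernodes=len(compressed.supernodes))

        # 5. communities
        communities, _, truncated = cliques_via_compression(
            binary,
            expand_representatives=config.expand_representatives,
            max_count=config.max_communities,
            condition_id=condition.condition_id,
        )
        pd.DataFrame(
            [
                {"size": c.size, "members": ",".join(str(m) for m in c.members)}
                for c in communities
            ]
        ).to_csv(out / "communities.tsv", sep="\t", index=False)
        record("communities", ["communities.tsv"],
               n_communities=len(communities), truncated=truncated)

        # 6. community benefits
        benefit_rows = []
        for community in communities:
            strains = [
                (StrainSpec(m, next(
                    s.knockouts for s in specs if s.strain_id == m
                )), apply_knockout(model, next(
                    s for s in specs if s.strain_id == m
                )))
                for m in community.members
            ]
            result = relative_and_absolute(strains, condition, endpoints)
            benefit_rows.append(
                {
                    "members": ",".join(str(m) for m in community.members),
                    "group_biomass": result.group_biomass,
                    "relative_benefit": result.relative_benefit,
                    "absolute_benefit": result.absolute_benefit,
                    "interacting": result.interacting,
                    "comparable": result.comparable,
                }
            )
        pd.DataFrame(benefit_rows).to_csv(
            out / "benefits.tsv", sep="\t", index=False
        )
        record("benefits", ["benefits.tsv"])
    except CrossfeedError as exc:
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2)
        )
        raise
    return manifest
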