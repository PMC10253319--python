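"""End-to-end two-condition comparison: one config in, a report bundle out.

``run_compare`` sequences the full analysis exactly as a comparative MD
study would: load structure and replicas → RMSD series (core fit and
scaffold-fit/subdomain-calc) → pooled PCA → per-replica DCCM averaged per
condition → correlation networks, communities and suboptimal paths per
condition → interface distances → one pooled SOM with per-condition
population maps, neuron clustering and torus unrolling. Every artifact is
written under the output directory together with a manifest recording the
config hash, seeds and stage list; a stage failure aborts with the stage
name and leaves the partial outputs flagged ``incomplete``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distances import DistanceSet, compute_distances, load_distance_definitions
from .geometry import Series, pca_modes, rmsd_series
from .network import (
    CorrelationMatrix,
    average_dccm,
    build_network,
    compute_dccm,
    detect_communities,
    suboptimal_paths,
    write_edge_list,
)
from .som import (
    GridSpec,
    assign_bmu,
    cluster_neurons,
    neuron_statistics,
    train_som,
    unroll_torus,
)
from .structure import DomainMap, Ensemble, load_ensembles, load_structure, resolve_selection

log = logging.getLogger("allosom")

#: protocol defaults: distance stride 100 ps, |c| cutoff 0.5, 50 paths,
#: 10×10 toroidal hexagonal SOM grid
DEFAULT_PARAMETERS = {
    "stride_ps": 100.0,
    "cutoff": 0.5,
    "k_paths": 50,
    "grid": [10, 10],
    "epochs": 50,
    "seed": 0,
    "silhouette_k": [2, 15],
    "n_modes": 3,
    "stride": 1,
    "dccm_fit": True,
    "dt_ps": 100.0,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    structure_path: Path
    condition_paths: dict[str, list[Path]]  # condition -> replica trajectory files
    domain_map: DomainMap
    distance_config: Path
    selections: dict[str, str]  # fit / calc / analysis / sources / sinks
    parameters: dict
    out_dir: Path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        params = dict(DEFAULT_PARAMETERS)
        params.update(raw.get("parameters", {}))
        config = cls(
            structure_path=resolve(raw["structure"]),
            condition_paths={
                cond: [resolve(p) for p in paths]
                for cond, paths in raw["conditions"].items()
            },
            domain_map=DomainMap.from_dict(raw["domain_map"])
            if isinstance(raw.get("domain_map"), dict)
            else DomainMap.from_yaml(resolve(raw["domain_map"])),
            distance_config=resolve(raw["distances"]),
            selections=dict(raw["selections"]),
            parameters=params,
            out_dir=resolve(raw.get("output", "allosom_out")),
        )
        config.validate()
        return config

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.structure_path, self.distance_config]
            + [p for paths in self.condition_paths.values() for p in paths]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        if len(self.condition_paths) != 2:
            raise ValueError("comparison requires exactly two conditions")
        p = self.parameters
        if not (0 <= p["cutoff"] < 1):
            raise ValueError("cutoff must lie in [0, 1)")
        if p["k_paths"] < 1 or p["epochs"] < 1:
            raise ValueError("k_paths and epochs must be positive")

    def digest(self) -> str:
        # file basenames, not absolute paths: the same study relocated on
        # disk keeps its hash
        payload = {
            "structure": Path(self.structure_path).name,
            "conditions": {c: [Path(p).name for p in ps] for c, ps in self.condition_paths.items()},
            "domain_map": self.domain_map.to_dict(),
            "distances": Path(self.distance_config).name,
            "selections": self.selections,
            "parameters": self.parameters,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclasses.dataclass
class ConditionReport:
    condition: str
    rmsd_core: list[Series]
    rmsd_subdomain: list[Series]
    dccm: CorrelationMatrix
    network: nx.Graph
    partition: object
    paths: object


@dataclasses.dataclass
class ReportBundle:
    config_digest: str
    conditions: dict[str, ConditionReport]
    dccm_difference: pd.DataFrame  # second condition minus first, per site pair
    pca: object
    distance_set: DistanceSet
    som_model: object
    clustering: object
    maps: object
    layout: pd.DataFrame
    manifest: dict


def _series_frame(series_list: list[Series]) -> pd.DataFrame:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "time_ps": s.times,
                    "value": s.values,
                    "condition": s.condition,
                    "replica": s.replica,
                    "name": s.name,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_compare(config: RunConfig) -> ReportBundle:
    """Execute the full two-condition comparison and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters
    seed = int(params["seed"])
    manifest: dict = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seeds": {"pipeline": seed},
        "parameters": params,
        "stages": [],
        "incomplete": True,
    }
    conditions = list(config.condition_paths)
    t_start = time.time()

    def stage(name: str):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        structure = load_structure(config.structure_path)
        config.domain_map.validate(structure)
        ensembles: dict[str, list[Ensemble]] = {
            cond: load_ensembles(
                paths, structure, stride=int(params["stride"]),
                condition=cond, dt_ps=float(params["dt_ps"]),
            )
            for cond, paths in config.condition_paths.items()
        }
        sel = {
            key: resolve_selection(structure, config.domain_map, expr)
            for key, expr in config.selections.items()
        }
        fit_set = sel["fit"]
        calc_set = sel.get("calc", fit_set)
        analysis_set = sel.get("analysis", fit_set)

        stage("rmsd")
        rmsd_core: dict[str, list[Series]] = {c: [] for c in conditions}
        rmsd_sub: dict[str, list[Series]] = {c: [] for c in conditions}
        for cond in conditions:
            for e in ensembles[cond]:
                reference = e.coords[0]
                rmsd_core[cond].append(rmsd_series(e, reference, fit_set))
                rmsd_sub[cond].append(rmsd_series(e, reference, fit_set, calc_set))
        _series_frame(sum(rmsd_core.values(), [])).to_csv(out / "rmsd_core.csv", index=False)
        _series_frame(sum(rmsd_sub.values(), [])).to_csv(out / "rmsd_subdomain.csv", index=False)

        stage("pca")
        flat_ensembles = [e for cond in conditions for e in ensembles[cond]]
        pca = pca_modes(flat_ensembles, analysis_set, n_modes=int(params["n_modes"]))
        _series_frame(pca.projections).to_csv(out / "pca_projections.csv", index=False)
        np.savetxt(out / "pca_eigenvalues.txt", pca.eigenvalues)
        np.savetxt(out / "pca_eigenvectors.txt", pca.eigenvectors)

        stage("dccm")
        dccm_by_condition: dict[str, CorrelationMatrix] = {}
        for cond in conditions:
            replicas = [
                compute_dccm(e, analysis_set, fit=bool(params["dccm_fit"]))
                for e in ensembles[cond]
            ]
            dccm_by_condition[cond] = average_dccm(replicas)
            dccm_by_condition[cond].to_csv(out / f"dccm_{cond}.csv")
        a, b = conditions
        difference = pd.DataFrame(
            dccm_by_condition[b].values - dccm_by_condition[a].values,
            index=dccm_by_condition[a].labels,
            columns=dccm_by_condition[a].labels,
        )
        difference.to_csv(out / f"dccm_difference_{b}_minus_{a}.csv")

        stage("network")
        reports: dict[str, ConditionReport] = {}
        node_sets = {}
        for key in ("sources", "sinks"):
            expr_set = sel.get(key)
            node_sets[key] = (
                structure.residue_labels(expr_set.indices) if expr_set is not None else None
            )
        for cond in conditions:
            net = build_network(dccm_by_condition[cond], cutoff=float(params["cutoff"]))
            nx.write_graphml(net, out / f"network_{cond}.graphml")
            write_edge_list(net, out / f"network_{cond}_edges.csv")
            partition = detect_communities(net, seed=seed)
            partition.to_csv(out / f"communities_{cond}.csv")
            path_ens = None
            if node_sets["sources"] and node_sets["sinks"]:
                src = [n for n in dict.fromkeys(node_sets["sources"]) if n in net]
                snk = [n for n in dict.fromkeys(node_sets["sinks"]) if n in net]
                path_ens = suboptimal_paths(net, src, snk, k=int(params["k_paths"]))
                (out / f"paths_{cond}.json").write_text(
                    json.dumps(path_ens.to_json_dict(), indent=1)
                )
            reports[cond] = ConditionReport(
                cond, rmsd_core[cond], rmsd_sub[cond],
                dccm_by_condition[cond], net, partition, path_ens,
            )

        stage("distances")
        definitions = load_distance_definitions(config.distance_config)
        blocks = [
            compute_distances(e, definitions, stride_ps=float(params["stride_ps"]))
            for cond in conditions
            for e in ensembles[cond]
        ]
        distance_set = DistanceSet.concatenate(blocks)
        distance_set.to_csv(out / "distances.csv")

        stage("som")
        rows, cols = params["grid"]
        grid = GridSpec(rows=int(rows), cols=int(cols), toroidal=True)
        model = train_som(
            distance_set.values, grid, epochs=int(params["epochs"]), seed=seed
        )
        model.to_json(out / "som_model.json")
        bmu = assign_bmu(model, distance_set.values)
        k_lo, k_hi = params["silhouette_k"]
        clustering = cluster_neurons(model, (int(k_lo), int(k_hi)))
        pd.DataFrame(
            {"neuron": range(grid.n_neurons), "cluster": clustering.assignment}
        ).to_csv(out / "som_clusters.csv", index=False)
        maps = neuron_statistics(
            model, bmu, distance_set.conditions, distance_set.values,
            feature_names=distance_set.names,
        )
        maps.counts.to_csv(out / "neuron_counts.csv")
        maps.feature_means.to_csv(out / "neuron_feature_means.csv")
        maps.contrast.rename("contrast").to_csv(out / "feature_contrast.csv")
        layout = unroll_torus(model, maps)
        layout.to_csv(out / "som_layout.csv", index=False)

        stage("report")
        manifest["incomplete"] = False
        manifest["wall_time_s"] = round(time.time() - t_start, 2)
        manifest["silhouette_chosen_k"] = int(clustering.chosen_k)
        manifest["n_communities"] = {
            cond: reports[cond].partition.n_communities for cond in conditions
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return ReportBundle(
            config_digest=manifest["config_digest"],
            conditions=reports,
            dccm_difference=difference,
            pca=pca,
            distance_set=distance_set,
            som_model=model,
            clustering=clustering,
            maps=maps,
            layout=layout,
            manifest=manifest,
        )
    except StageError:
        raise
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(failed, exc) from exc
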