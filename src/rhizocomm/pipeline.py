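"""End-to-end pipeline: config validation, stage orchestration, manifest.

A single structured config (YAML) governs every stage; all randomized
stages take explicit seeds so a rerun with the same config is
byte-identical.  Outputs are TSV/Newick/JSON files under the configured
output directory, listed exhaustively in ``manifest.json``.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import rhizocomm
from rhizocomm import assembly as assembly_mod
from rhizocomm import diversity as diversity_mod
from rhizocomm import network as network_mod
from rhizocomm import trends as trends_mod
from rhizocomm import functions as functions_mod
from rhizocomm.matrix import (
    CommunityMatrix,
    SampleMetadata,
    TaxonomyTable,
    normalize_depth,
    read_community_matrix,
    write_community_matrix,
)
from rhizocomm.simulate import SimulationConfig, simulate_dataset, write_dataset
from rhizocomm.tree import PhyloTree

log = logging.getLogger("rhizocomm")

_STAGES = ("diversity", "assembly", "network", "trends", "functions")

_DEFAULTS = {
    "seed": None,
    "output_dir": "rhizocomm_out",
    "simulate": None,  # SimulationConfig fields
    "inputs": None,  # matrix/tree/taxonomy/metadata/rules paths
    "stages": {s: True for s in _STAGES},
    "normalize": {"enabled": True, "depth": None, "seed": None},
    "diversity": {"n_perm": 999, "seed": None, "factor": "compartment"},
    "assembly": {
        "n_null": 999,
        "seed": None,
        "null_scope": "pair_union",
        "missing_taxa": "error",
        "group_by": "compartment",
    },
    "network": {
        "prevalence": 0.5,
        "rho_min": 0.7,
        "p_max": 0.01,
        "method": "greedy",
        "seed": None,
        "per": "compartment",
    },
    "trends": {"alpha": 0.05},
    "functions": {},
}


@dataclass
class PipelineConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)


def _merge_defaults(user: dict, defaults: dict, errors: list, prefix: str = ""):
    merged = {}
    for key, default in defaults.items():
        if isinstance(default, dict) and isinstance(user.get(key), dict):
            merged[key] = _merge_defaults(
                user[key], default, errors, f"{prefix}{key}."
            )
        elif key in user:
            merged[key] = user[key]
        else:
            merged[key] = default
    for key in user:
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
    return merged


def validate_config(config) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a config dict (or YAML path); all errors are collected and
    returned at once rather than failing on the first."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        return None, ["config must be a mapping"]
    errors: list[str] = []
    merged = _merge_defaults(config, _DEFAULTS, errors)

    sim, inputs = merged["simulate"], merged["inputs"]
    if sim is None and inputs is None:
        errors.append("either a 'simulate' block or an 'inputs' block is required")
    if sim is not None:
        if merged["seed"] is None and "seed" not in sim:
            errors.append("simulate block requires a seed (top-level or in block)")
        else:
            sim = dict(sim)
            sim.setdefault("seed", merged["seed"])
            try:
                known = set(SimulationConfig.__dataclass_fields__)
                unknown = set(sim) - known
                if unknown:
                    errors.append(f"unknown simulate keys: {sorted(unknown)}")
                else:
                    SimulationConfig(**{**sim})
                    merged["simulate"] = sim
            except (TypeError, ValueError) as exc:
                errors.append(f"simulate: {exc}")
    if inputs is not None:
        for key in ("matrix", "metadata"):
            if key not in inputs:
                errors.append(f"inputs missing required path: {key}")
        unknown = set(inputs) - {"matrix", "tree", "taxonomy", "metadata", "rules"}
        if unknown:
            errors.append(f"unknown input keys: {sorted(unknown)}")

    stages = merged["stages"]
    for name in stages:
        if name not in _STAGES:
            errors.append(f"unknown stage: {name}")
    net = merged["network"]
    if not 0 <= net["prevalence"] <= 1:
        errors.append("network.prevalence must be in [0, 1]")
    if not 0 <= net["rho_min"] <= 1:
        errors.append("network.rho_min must be in [0, 1]")
    if not 0 < net["p_max"] <= 1:
        errors.append("network.p_max must be in (0, 1]")
    if merged["assembly"]["n_null"] < 1:
        errors.append("assembly.n_null must be >= 1")
    if merged["diversity"]["n_perm"] < 1:
        errors.append("diversity.n_perm must be >= 1")

    # dependency checks when stages are enabled on file inputs
    if inputs is not None:
        if stages.get("assembly") and "tree" not in inputs:
            errors.append("assembly stage enabled but inputs.tree is missing")
        if (stages.get("trends") or stages.get("functions")) and (
            "taxonomy" not in inputs
        ):
            errors.append("trends/functions stages need inputs.taxonomy")
        if stages.get("functions") and "rules" not in inputs:
            errors.append("functions stage enabled but inputs.rules is missing")

    # fill per-stage seeds from the top-level seed
    if merged["seed"] is not None:
        root = int(merged["seed"])
        for i, name in enumerate(("normalize", "diversity", "assembly", "network")):
            if merged[name].get("seed") is None:
                merged[name]["seed"] = (root * 7919 + i) % (2**31)
    else:
        for name in ("normalize", "diversity", "assembly", "network"):
            if merged[name].get("seed") is None:
                errors.append(f"{name}.seed required when no top-level seed is set")

    if errors:
        return None, errors
    return PipelineConfig(merged), []


@dataclass
class RunReport:
    version: str
    config: dict
    runtimes: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "version": self.version,
            "config": self.config,
            "runtimes": {k: round(v, 3) for k, v in self.runtimes.items()},
            "warnings": self.warnings,
            "tables": self.tables,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(doc, indent=1, default=str))


def _load_inputs(cfg: PipelineConfig):
    inputs = cfg["inputs"]
    matrix = read_community_matrix(inputs["matrix"])
    meta = SampleMetadata.from_tsv(inputs["metadata"])
    tree = (
        PhyloTree.from_newick(inputs["tree"]) if inputs.get("tree") else None
    )
    taxonomy = (
        TaxonomyTable.from_tsv(inputs["taxonomy"])
        if inputs.get("taxonomy")
        else None
    )
    rules = inputs.get("rules")
    return matrix, meta, tree, taxonomy, rules


def run_pipeline(config) -> RunReport:
    """Execute the enabled stages in order and write all outputs.

    Stage order: ingest/simulate -> normalize -> diversity -> assembly ->
    network -> trends -> functions -> report.  A stage failure aborts with
    the stage name; outputs written so far stay on disk next to an
    ``INCOMPLETE`` marker.
    """
    cfg, errors = (
        (config, [])
        if isinstance(config, PipelineConfig)
        else validate_config(config)
    )
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "INCOMPLETE").write_text("pipeline running\n")
    report = RunReport(version=rhizocomm.__version__, config=cfg.raw)
    outputs: list[str] = []

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.append(name)
        return path

    stage = "ingest"
    try:
        t0 = time.perf_counter()
        taxonomy = rules = tree = None
        if cfg["simulate"] is not None:
            stage = "simulate"
            log.info("simulate: seed=%s", cfg["simulate"].get("seed"))
            ds = simulate_dataset(SimulationConfig(**cfg["simulate"]))
            matrix, meta, tree = ds.matrix, ds.metadata, ds.tree
            paths = write_dataset(ds, outdir / "simulated")
            outputs.extend(
                str(Path(p).relative_to(outdir)) for p in paths.values()
            )
            inputs_cfg = cfg.raw.get("inputs") or {}
            if inputs_cfg.get("taxonomy"):
                taxonomy = TaxonomyTable.from_tsv(inputs_cfg["taxonomy"])
            rules = inputs_cfg.get("rules")
        else:
            matrix, meta, tree, taxonomy, rules = _load_inputs(cfg)
        meta.check_matches(matrix)
        report.runtimes[stage] = time.perf_counter() - t0

        stage = "normalize"
        t0 = time.perf_counter()
        norm = cfg["normalize"]
        if norm["enabled"] and matrix.semantics != "relative":
            depth = norm["depth"] or int(matrix.data.sum(axis=0).min())
            log.info("normalize: rarefying to depth=%d seed=%d", depth, norm["seed"])
            matrix = normalize_depth(matrix, depth, norm["seed"])
            _write(
                "normalized_matrix.tsv",
                lambda p: write_community_matrix(matrix, p),
            )
        report.runtimes[stage] = time.perf_counter() - t0

        stages = cfg["stages"]
        if stages.get("diversity"):
            stage = "diversity"
            t0 = time.perf_counter()
            div = cfg["diversity"]
            alpha = diversity_mod.alpha_diversity_table(matrix)
            _write("alpha_diversity.tsv", lambda p: alpha.to_csv(p, sep="\t"))
            bc = diversity_mod.bray_curtis(matrix)
            _write(
                "bray_curtis.tsv",
                lambda p: pd.DataFrame(
                    bc.data, index=list(bc.ids), columns=list(bc.ids)
                ).to_csv(p, sep="\t"),
            )
            ord_res = diversity_mod.pcoa(bc)
            _write(
                "pcoa_coordinates.tsv",
                lambda p: ord_res.coordinates.to_csv(p, sep="\t"),
            )
            perm_rows = []
            for factor in ("compartment", "stage"):
                res = diversity_mod.permanova(
                    bc, meta, factor, n_perm=div["n_perm"], seed=div["seed"]
                )
                perm_rows.append(
                    {
                        "factor": res.factor,
                        "pseudo_F": res.pseudo_f,
                        "r_squared": res.r_squared,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                    }
                )
            perm_df = pd.DataFrame(perm_rows)
            _write(
                "permanova.tsv", lambda p: perm_df.to_csv(p, sep="\t", index=False)
            )
            report.tables["permanova"] = perm_rows
            report.tables["alpha_mean_by_compartment"] = (
                alpha.join(meta.table.set_index("sample_id")["compartment"])
                .groupby("compartment")
                .mean()
                .round(4)
                .to_dict()
            )
            report.runtimes[stage] = time.perf_counter() - t0

        if stages.get("assembly"):
            stage = "assembly"
            t0 = time.perf_counter()
            if tree is None:
                raise ValueError("assembly stage needs a phylogenetic tree input")
            asm = cfg["assembly"]
            result = assembly_mod.assembly_analysis(
                matrix,
                tree,
                n_null=asm["n_null"],
                seed=asm["seed"],
                null_scope=asm["null_scope"],
                missing_taxa=asm["missing_taxa"],
            )
            _write(
                "assembly_pairs.tsv",
                lambda p: result.pairs.to_csv(p, sep="\t", index=False),
            )
            summary = assembly_mod.process_summary(
                result, meta, group_by=asm["group_by"]
            )
            _write(
                "assembly_summary.tsv",
                lambda p: summary.to_csv(p, sep="\t", index=False),
            )
            report.tables["process_summary"] = summary.round(2).to_dict(
                orient="records"
            )
            report.runtimes[stage] = time.perf_counter() - t0

        if stages.get("network"):
            stage = "network"
            t0 = time.perf_counter()
            net = cfg["network"]
            groups = (
                pd.unique(meta.factor(net["per"]))
                if net["per"]
                else [None]
            )
            topo_rows = []
            for group in groups:
                if group is None:
                    sub, tag = matrix, "all"
                else:
                    samples = meta.table.loc[
                        meta.table[net["per"]] == group, "sample_id"
                    ]
                    sub = matrix.select_samples(list(samples))
                    tag = str(group)
                graph = network_mod.build_network(
                    sub,
                    prevalence=net["prevalence"],
                    rho_min=net["rho_min"],
                    p_max=net["p_max"],
                    taxonomy=taxonomy,
                )
                if graph.n_edges == 0:
                    warnings.warn(f"network {tag!r} has no edges; skipped")
                    continue
                network_mod.detect_modules(
                    graph, method=net["method"], seed=net["seed"]
                )
                topo = network_mod.topology_metrics(graph)
                topo["group"] = tag
                topo_rows.append(topo)
                roles = network_mod.zi_pi(graph)
                nodes = network_mod.node_table(graph, roles)
                edges = graph.edge_table()
                _write(
                    f"network_{tag}_edges.tsv",
                    lambda p, e=edges: e.to_csv(p, sep="\t", index=False),
                )
                _write(
                    f"network_{tag}_nodes.tsv",
                    lambda p, nd=nodes: nd.to_csv(p, sep="\t", index=False),
                )
                keystones = network_mod.keystone_report(roles, taxonomy)
                _write(
                    f"network_{tag}_keystones.tsv",
                    lambda p, ks=keystones: ks.to_csv(p, sep="\t", index=False),
                )
                _write(
                    f"network_{tag}.graphml",
                    lambda p, gg=graph.graph: nx_write_graphml(gg, p),
                )
            if topo_rows:
                topo_df = pd.DataFrame(topo_rows)
                _write(
                    "network_topology.tsv",
                    lambda p: topo_df.to_csv(p, sep="\t", index=False),
                )
                report.tables["network_topology"] = topo_df.round(4).to_dict(
                    orient="records"
                )
            report.runtimes[stage] = time.perf_counter() - t0

        if stages.get("trends"):
            stage = "trends"
            t0 = time.perf_counter()
            if taxonomy is None:
                raise ValueError("trends stage needs a taxonomy input")
            fits = []
            for gradient in ("spatial", "temporal"):
                try:
                    fits.extend(
                        trends_mod.classify_trends(
                            matrix,
                            taxonomy,
                            meta,
                            gradient=gradient,
                            alpha=cfg["trends"]["alpha"],
                        )
                    )
                except ValueError as exc:
                    warnings.warn(f"trend fits ({gradient}) skipped: {exc}")
            tdf = trends_mod.trend_table(fits)
            _write("trends.tsv", lambda p: tdf.to_csv(p, sep="\t", index=False))
            report.tables["n_trend_fits"] = len(fits)
            report.runtimes[stage] = time.perf_counter() - t0

        if stages.get("functions"):
            stage = "functions"
            t0 = time.perf_counter()
            if taxonomy is None or rules is None:
                raise ValueError("functions stage needs taxonomy and rules inputs")
            ftable = functions_mod.annotate_functions(taxonomy, matrix, rules)
            _write(
                "function_table.tsv", lambda p: ftable.table.to_csv(p, sep="\t")
            )
            if ftable.table.shape[0] >= 2:
                ords = functions_mod.function_ordination(ftable)
                _write(
                    "function_pca.tsv", lambda p: ords.scores.to_csv(p, sep="\t")
                )
                _write(
                    "function_zscores.tsv",
                    lambda p: ords.zscored.to_csv(p, sep="\t"),
                )
            report.tables["n_function_groups"] = int(ftable.table.shape[0])
            report.runtimes[stage] = time.perf_counter() - t0

    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report.outputs = sorted(outputs)
    manifest = {"outputs": sorted(outputs) + ["report.json", "manifest.json"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report.to_json(outdir / "report.json")
    (outdir / "INCOMPLETE").unlink()
    return report


def nx_write_graphml(graph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph, path)
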