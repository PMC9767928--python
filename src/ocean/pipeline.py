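"""End-to-end pipeline driver with config validation and provenance.

A run config is a nested dict (usually from YAML) with per-stage blocks;
unknown keys are rejected so typos fail loudly.  Identical config + inputs
produce byte-identical outputs: every stage sorts its rows and writes
floats with a fixed format.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import OceanError
from .forest import build_forest, build_instance_graph, forest_to_json, graph_to_sif_edges
from .network import read_reaction_table, write_reaction_table, write_sif
from .reduction import FilterConfig, apply_filters, load_species_list
from .scoring import collapse_to_base_names, footprint_scatter, imbalance_score, read_mapping
from .stats import AbundanceMatrix, differential_pipeline
from .weights import signed_weights, write_weights

logger = logging.getLogger("ocean.pipeline")

_STAGE_KEYS = {
    "network": {"dir"},
    "filter": {"cofactors", "min_atoms", "max_promiscuity", "enabled"},
    "stats": {"abundance", "design", "contrast", "qc_rsd"},
    "weights": {"penalty"},
    "footprint": {"enzyme", "mapping", "seed_product", "seed_reactant"},
    "out": {"dir"},
}


def _validate_config(config: dict) -> None:
    unknown = set(config) - set(_STAGE_KEYS)
    if unknown:
        raise OceanError(f"unknown config section(s): {sorted(unknown)}")
    for section, keys in _STAGE_KEYS.items():
        extra = set(config.get(section, {}) or {}) - keys
        if extra:
            raise OceanError(f"unknown key(s) in [{section}]: {sorted(extra)}")
    for required in ("network", "stats", "footprint", "out"):
        if required not in config:
            raise OceanError(f"missing config section [{required}]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, base_dir: Path | str = ".") -> dict:
    """Execute filter -> sif -> forest -> weights -> stats -> footprint.

    Returns a manifest dict (also written to ``<out>/manifest.json``) with
    input checksums, parameters and the tool version.
    """
    base = Path(base_dir)
    _validate_config(config)

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    net_dir = resolve(config["network"]["dir"])
    out_dir = resolve(config["out"]["dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs = [net_dir / "reactions.csv", net_dir / "metabolites.csv"]
    network = read_reaction_table(net_dir)

    fcfg = config.get("filter", {}) or {}
    if fcfg.get("enabled", True):
        cof_path = fcfg.get("cofactors")
        cofactors = load_species_list(resolve(cof_path)) if cof_path else frozenset()
        if cof_path:
            inputs.append(resolve(cof_path))
        filter_config = FilterConfig(
            cofactor_classes=cofactors,
            min_atoms=int(fcfg.get("min_atoms", 4)),
            promiscuity_threshold=int(fcfg.get("max_promiscuity", 100)),
        )
        network, report = apply_filters(network, filter_config)
        report.to_csv(out_dir / "filter_report.csv", index=False)
        write_reaction_table(network, out_dir / "filtered")
        logger.info("filter: removed %d metabolites", len(report))

    graph = build_instance_graph(network)
    write_sif(graph_to_sif_edges(graph), out_dir / "network.sif")
    forest = build_forest(graph)
    forest_to_json(forest, out_dir / "forest.json")

    penalty = float((config.get("weights", {}) or {}).get("penalty", 0.8))
    weights = signed_weights(forest, penalty)
    write_weights(weights, out_dir / "weights.csv")
    weights_base = collapse_to_base_names(weights, network.base_names(), penalty)
    weights_base.to_csv(out_dir / "weights_base.csv", index=False, float_format="%.12g")

    scfg = config["stats"]
    abundance_path, design_path = resolve(scfg["abundance"]), resolve(scfg["design"])
    inputs += [abundance_path, design_path]
    matrix = AbundanceMatrix.from_csv(abundance_path, design_path)
    g1, _, g2 = str(scfg["contrast"]).partition("-")
    if not g1 or not g2:
        raise OceanError("stats.contrast must be GROUP1-GROUP2")
    qc_rsd = scfg.get("qc_rsd", 0.30)
    stats_df = differential_pipeline(
        matrix, (g1, g2), None if qc_rsd in (None, "none") else float(qc_rsd)
    )
    stats_df.to_csv(out_dir / "stats.csv", index=False, float_format="%.12g")

    pcfg = config["footprint"]
    mapping = read_mapping(resolve(pcfg["mapping"])) if pcfg.get("mapping") else None
    if pcfg.get("mapping"):
        inputs.append(resolve(pcfg["mapping"]))
    enzyme = pcfg["enzyme"]
    scatter = footprint_scatter(weights_base, stats_df, mapping, enzyme)
    scatter.to_csv(out_dir / "scatter.csv", index=False, float_format="%.12g")
    score = imbalance_score(weights_base, stats_df, mapping, enzyme)
    logger.info("imbalance score for %s: %.4f", enzyme, score)

    manifest = {
        "tool": "ocean",
        "version": __version__,
        "parameters": {
            "penalty": penalty,
            "contrast": f"{g1}-{g2}",
            "enzyme": enzyme,
            "filter": {k: v for k, v in fcfg.items() if k != "cofactors"},
        },
        "inputs": {str(p): _sha256(p) for p in sorted(set(inputs)) if p.is_file()},
        "imbalance_score": score,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
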