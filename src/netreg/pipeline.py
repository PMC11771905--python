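"""End-to-end pipeline: DEG screen -> network -> topology -> power-law fits
-> recursive LEV decomposition -> key regulators -> optional enrichment.

A single config dict drives everything; unknown keys are rejected and the
config is serialized verbatim into the report for provenance.  The report
contains no wall-clock fields, so a rerun with the same config and seeds is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, degs, enrichment, keyreg, network, powerlaw, synthetic, topology
from .expression import read_expression_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "default_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "mode": "synthetic",  # synthetic | files
    "seed": 0,
    "out_dir": "netreg_out",
    # file-mode inputs
    "expression_tsv": None,
    "groups_tsv": None,
    "interactions_tsv": None,
    "interactions_dialect": "string_tsv",
    "gmt": None,
    # synthetic-mode generator settings
    "synthetic": {
        "n_genes": 2000,
        "n_per_group": 10,
        "n_deg": 100,
        "effect_lfc": 2.0,
        "graph": {"model": "triangle_hierarchy", "levels": 5, "pendants": 4},
        "n_gene_sets": 8,
        "gene_set_size": 25,
    },
    # stage parameters
    "scale": "log2",
    "test": "moderated",
    "lfc_min": 1.0,
    "p_max": 0.05,
    "padj_max": 0.05,
    "score_min": 0.4,
    "n_boot": 200,
    "max_level": None,
    "refine": "none",
    "bridge_k_max": 11,
    "hub_k_min": 17,
}


def default_config(**overrides) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in overrides.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _validate_config(config: dict) -> dict:
    cfg = default_config()
    for key, value in config.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            for sub in value:
                if sub not in cfg[key]:
                    raise ValueError(f"unknown config key {key}.{sub}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def _synthetic_inputs(cfg: dict):
    """Expression matrix + interaction table + gene sets with planted truth.

    The interaction graph is generated over the planted DEG genes (emulating
    the interaction neighbourhood the study's DEGs form in STRING); the
    default triangle-hierarchy model has nested community structure
    terminating in triangle motifs, so every downstream stage has real
    signal to find.
    """
    syn = cfg["synthetic"]
    seed = int(cfg["seed"])
    matrix, truth = synthetic.gen_expression(
        n_genes=syn["n_genes"],
        n_per_group=syn["n_per_group"],
        n_deg=syn["n_deg"],
        effect_lfc=syn["effect_lfc"],
        seed=seed,
    )
    graph_params = dict(syn["graph"])
    model = graph_params.pop("model", "triangle_hierarchy")
    g, _ = synthetic.gen_graph(model, seed=seed + 1, **graph_params)
    planted = truth.index[truth["planted"]].tolist()
    names = {i: planted[i] for i in range(min(g.number_of_nodes(), len(planted)))}
    g = g.subgraph(list(names)).copy()
    interactions = synthetic.graph_to_interactions(g, score=0.9, names=names)

    # deterministic toy gene-set collection over the planted genes
    rng = np.random.default_rng(seed + 2)
    all_genes = truth.index.tolist()
    sets = {}
    for i in range(int(syn["n_gene_sets"])):
        members = rng.choice(all_genes, size=int(syn["gene_set_size"]), replace=False)
        sets[f"SET{i:02d}"] = (f"synthetic gene set {i}", frozenset(map(str, members)))
    # one set deliberately concentrated on planted genes (a true signal)
    sets["SET_PLANTED"] = (
        "synthetic set enriched in planted genes",
        frozenset(map(str, planted[: int(syn["gene_set_size"])])),
    )
    collection = enrichment.GeneSetCollection(sets, frozenset(map(str, all_genes)))
    return matrix, interactions, collection, truth


def run_pipeline(config: dict | None = None, **overrides) -> dict:
    """Run every stage in order, writing per-stage TSV/JSON artifacts and a
    consolidated ``report.json`` under ``out_dir``.  Returns the report."""
    cfg = _validate_config(config or {})
    for key, value in overrides.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        cfg[key] = value

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    logging.getLogger("netreg").addHandler(counter)

    report: dict = {"config": cfg, "stages": {}, "files": {}}
    stage = "inputs"
    try:
        collection = None
        if cfg["mode"] == "synthetic":
            matrix, interactions, collection, truth = _synthetic_inputs(cfg)
            truth.to_csv(out_dir / "truth.tsv", sep="\t")
        elif cfg["mode"] == "files":
            if not cfg["expression_tsv"] or not cfg["groups_tsv"]:
                raise PipelineError("deg_screen", "expression_tsv and groups_tsv required")
            matrix = read_expression_tsv(cfg["expression_tsv"], cfg["groups_tsv"])
            stage = "network_build"
            if not cfg["interactions_tsv"] or not Path(cfg["interactions_tsv"]).exists():
                raise PipelineError(
                    "network_build", f"missing interaction file {cfg['interactions_tsv']!r}"
                )
            interactions = network.read_interactions(
                cfg["interactions_tsv"], dialect=cfg["interactions_dialect"]
            )
            if cfg["gmt"]:
                collection = enrichment.read_gmt(cfg["gmt"])
        else:
            raise ValueError(f"unknown mode {cfg['mode']!r}")

        stage = "deg_screen"
        table = degs.deg_table(
            matrix,
            test=cfg["test"],
            scale=cfg["scale"],
            lfc_min=cfg["lfc_min"],
            p_max=cfg["p_max"],
            padj_max=cfg["padj_max"],
        )
        deg_hits = degs.filter_degs(
            table, lfc_min=cfg["lfc_min"], p_max=cfg["p_max"], padj_max=cfg["padj_max"]
        )
        degs.write_deg_tsv(table, out_dir / "degs_all.tsv")
        degs.write_deg_tsv(deg_hits, out_dir / "degs.tsv")
        report["stages"]["deg_screen"] = {
            "n_genes": int(len(table)),
            "n_deg": int(len(deg_hits)),
            "n_up": deg_hits.attrs["n_up"],
            "n_down": deg_hits.attrs["n_down"],
        }

        stage = "network_build"
        g = network.build_network(
            interactions, set(deg_hits.index), score_min=cfg["score_min"]
        )
        network.write_network_tsv(g, out_dir / "network.tsv")
        comps = network.connected_components(g)
        report["stages"]["network_build"] = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "n_components": len(comps),
            "largest_component": len(comps[0]),
            "n_isolated_whitelist": g.graph.get("n_isolated_whitelist", 0),
        }

        stage = "topology_metrics"
        metrics = topology.node_metrics(g)
        profile = topology.degree_profile(metrics)
        topology.write_metrics_tsv(metrics, out_dir / "metrics.tsv")
        topology.write_profile_tsv(profile, out_dir / "profile.tsv")
        report["stages"]["topology_metrics"] = {
            "n_nodes": int(len(metrics)),
            "n_degree_bins": int(len(profile)),
        }

        stage = "powerlaw_fit"
        degrees = metrics["k"].to_numpy()
        fits = {
            "P": powerlaw.fit_clauset(
                degrees[degrees > 0],
                discrete=True,
                n_boot=int(cfg["n_boot"]),
                seed=int(cfg["seed"]) + 10,
            )
        }
        ks = profile.index.to_numpy(dtype=float)
        for col in ("C", "C_N", "C_B", "C_C", "C_E"):
            fits[col] = powerlaw.loglog_slope(ks, profile[col].to_numpy())
        classification = powerlaw.classify(fits)
        fits_doc = {
            "fits": {name: fit.to_dict() for name, fit in fits.items()},
            "classification": classification.to_dict(),
        }
        (out_dir / "fits.json").write_text(json.dumps(fits_doc, indent=1, sort_keys=True))
        report["stages"]["powerlaw_fit"] = fits_doc

        stage = "community_decomposition"
        tree = community.recursive_decompose(
            g, max_level=cfg["max_level"], refine=cfg["refine"]
        )
        tree.to_json(out_dir / "tree.json")
        motifs = community.label_paths(tree)
        pd.DataFrame(
            [(label, ", ".join(genes)) for label, genes in motifs],
            columns=["leaf_label", "genes"],
        ).to_csv(out_dir / "motifs.tsv", sep="\t", index=False)
        report["stages"]["community_decomposition"] = {
            "max_level": tree.max_level,
            "n_motif_leaves": len(tree.motif_leaves),
            "n_leaves": len(tree.leaves()),
        }

        stage = "key_regulators"
        records = keyreg.extract_key_regulators(tree)
        summary = keyreg.regulator_summary(
            records,
            metrics,
            bridge_k_max=int(cfg["bridge_k_max"]),
            hub_k_min=int(cfg["hub_k_min"]),
        )
        if len(summary):
            summary = summary.join(table[["log2fc", "direction"]], how="left")
        keyreg.write_keyreg_tsv(summary, out_dir / "keyreg.tsv")
        report["stages"]["key_regulators"] = {
            "n_regulators": int(len(summary)),
            "n_bridges": int(summary["low_degree_bridge"].sum()) if len(summary) else 0,
            "regulators": sorted(map(str, summary.index)),
        }

        stage = "enrichment_ora"
        if collection is not None and len(summary):
            # universe: the analyzed network's genes (file mode); the synthetic
            # collection already carries its own full-gene universe
            if cfg["mode"] == "files":
                coll = collection.restrict(set(map(str, g.nodes)))
            else:
                coll = collection
            result = enrichment.hypergeom_ora(set(map(str, summary.index)), coll)
            enrichment.write_enrichment_tsv(result, out_dir / "enrich.tsv")
            top = result.iloc[0] if len(result) else None
            report["stages"]["enrichment_ora"] = {
                "n_sets": int(len(result)),
                "top_set": None if top is None else str(top["set_name"]),
                "top_p": None if top is None else float(top["p_value"]),
                "top_fold": None if top is None else float(top["fold_enrichment"]),
            }
        else:
            report["stages"]["enrichment_ora"] = {"n_sets": 0, "skipped": True}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logging.getLogger("netreg").removeHandler(counter)

    report["n_warnings"] = counter.count
    for f in sorted(out_dir.iterdir()):
        if f.name != "report.json" and f.is_file():
            report["files"][f.name] = _sha256(f)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
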