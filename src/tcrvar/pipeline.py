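"""Config-driven orchestration of the full analysis.

Stages communicate only through files under the output directory, so any
stage can be re-run on its own:

``simulate``  write synthetic clonotype tables and the pair manifest
``repstats``  per-sample summaries and cumulative curves
``tvi``       per-pair overlap table with the variation index
``screen``    expression simulation + index/expression correlation screen
``network``   interaction table simulation, filtering, module detection
``survive``   cohort simulation, clustering, Kaplan-Meier and log-rank

All randomness derives from the single top-level seed through per-stage
seed sequences, so a rerun with the same config and seed reproduces
byte-identical tabular outputs.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from .expression import ExpressionMatrix, correlate_with_tvi, partition_gene_sets
from .network import (
    filter_edges_by_coexpression,
    filter_string_edges,
    graph_to_edge_frame,
    hub_network,
    maximal_connected_subnetwork,
    scale_free_fit,
    select_module,
)
from .overlap_tvi import compute_tvi, overlap_ratio, topn_overlap
from .repertoire_io import Stage, read_clonotype_table, write_clonotype_table
from .repertoire_stats import cumulative_frequency_curve, sample_summary
from .survival import km_estimate, logrank_test, two_group_clustering
from .synthetic import (
    simulate_paired_repertoires,
    simulate_ppi,
    simulate_survival,
    simulate_two_group_expression,
    simulate_expression,
    stage_params,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "repstats", "tvi", "screen", "network", "survive")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {name: True for name in STAGES},
    "simulate": {
        "pairs_per_stage": 4,
        "repertoire": {
            "n_clones_lesion": 4000,
            "n_clones_adjacent": 4000,
            "total_reads": 80000,
        },
    },
    "repstats": {"top_n": 100, "bin_edges": [1e-1, 1e-2, 1e-3, 1e-4]},
    "tvi": {"top_n": 100},
    "screen": {
        "n_genes": 600,
        "n_pos": 40,
        "n_neg": 40,
        "effect": 1.2,
        "noise_sd": 0.5,
        "fdr_threshold": 0.05,
    },
    "network": {
        "textmining_min": 200,
        "combined_min": 400,
        "rho_min": 0.5,
        "top_fraction": 0.05,
        "k_min": 3,
        "module_size": 11,
        "module_k": 5,
        "background_edge_prob": 0.03,
        "decoy_fraction": 0.1,
    },
    "survive": {
        "n_per_group": 40,
        "hazard_ratio": 2.5,
        "censoring_rate": 0.2,
        "separation": 2.5,
        "noise_sd": 1.0,
        "linkage": "average",
        "metric": "euclidean",
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Default configuration, optionally overridden by a YAML file."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError("config file must hold a mapping")
        config = _deep_merge(config, user)
    unknown = set(config["stages"]) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage toggles: {sorted(unknown)}")
    return config


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the top-level seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0])


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            stage,
            f"missing input {path.name!r}; run the '{produced_by}' stage first "
            f"or enable it in the config",
        )
    return path


# -- stages ----------------------------------------------------------------


def run_simulate(config: dict, outdir: Path) -> dict:
    seed = stage_seed(config["seed"], "simulate")
    rep_dir = outdir / "repertoires"
    rep_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    pair_index = 0
    for stage_name in ("LGIN", "HGIN", "EGC"):
        for _ in range(int(config["simulate"]["pairs_per_stage"])):
            pair_index += 1
            patient = f"P{pair_index:03d}"
            params = stage_params(
                stage_name,
                seed=seed + pair_index,
                **config["simulate"]["repertoire"],
            )
            pair = simulate_paired_repertoires(
                params, patient_id=patient, lesion_stage=stage_name
            )
            lesion_path = rep_dir / f"{pair.lesion.sample_id}.tsv"
            adjacent_path = rep_dir / f"{pair.adjacent.sample_id}.tsv"
            write_clonotype_table(pair.lesion, lesion_path)
            write_clonotype_table(pair.adjacent, adjacent_path)
            manifest.append(
                {
                    "patient_id": patient,
                    "stage": stage_name,
                    "lesion_sample": pair.lesion.sample_id,
                    "adjacent_sample": pair.adjacent.sample_id,
                    "lesion_file": lesion_path.name,
                    "adjacent_file": adjacent_path.name,
                }
            )
    pd.DataFrame(manifest).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    return {"n_pairs": len(manifest)}


def _load_pairs(outdir: Path, stage: str) -> pd.DataFrame:
    return pd.read_csv(_require(outdir / "pairs.tsv", stage, "simulate"), sep="\t")


def _read_pair_repertoires(row, outdir: Path):
    rep_dir = outdir / "repertoires"
    lesion = read_clonotype_table(
        rep_dir / row.lesion_file, sample_id=row.lesion_sample, stage=row.stage
    )
    adjacent = read_clonotype_table(
        rep_dir / row.adjacent_file,
        sample_id=row.adjacent_sample,
        stage=Stage.ADJACENT,
    )
    return lesion, adjacent


def run_repstats(config: dict, outdir: Path) -> dict:
    pairs = _load_pairs(outdir, "repstats")
    n = int(config["repstats"]["top_n"])
    stats_dir = outdir / "repstats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    summaries = []
    curves = []
    for row in pairs.itertuples(index=False):
        for rep in _read_pair_repertoires(row, outdir):
            summaries.append(sample_summary(rep, n=n))
            frame = cumulative_frequency_curve(rep, n).to_frame()
            frame.insert(0, "sample_id", rep.sample_id)
            curves.append(frame)
    pd.DataFrame(summaries).to_csv(stats_dir / "sample_summary.tsv", sep="\t", index=False)
    pd.concat(curves, ignore_index=True).to_csv(
        stats_dir / "cumulative_curves.tsv", sep="\t", index=False
    )
    return {"n_samples": len(summaries)}


def run_tvi(config: dict, outdir: Path) -> dict:
    pairs = _load_pairs(outdir, "tvi")
    n = int(config["tvi"]["top_n"])
    from .repertoire_io import LesionAdjacentPair

    rows = []
    for row in pairs.itertuples(index=False):
        lesion, adjacent = _read_pair_repertoires(row, outdir)
        pair = LesionAdjacentPair(row.patient_id, lesion, adjacent)
        whole = overlap_ratio(lesion, adjacent)
        top = topn_overlap(lesion, adjacent, n=n)
        res = compute_tvi(pair, n=n)
        rows.append(
            {
                "patient_id": row.patient_id,
                "stage": row.stage,
                "lesion_sample": row.lesion_sample,
                "n_shared": whole.n_shared,
                "overlap_ratio": whole.overlap_ratio,
                "common_cum_freq": whole.common_cum_freq,
                f"top{n}_ratio": top.overlap_ratio,
                "F": res.F,
                "C": res.C if res.C is not None else np.nan,
                "n_common_top": res.n_common_top,
                "tvi": res.tvi if res.tvi is not None else np.nan,
            }
        )
    tvi_dir = outdir / "tvi"
    tvi_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(tvi_dir / "pair_tvi.tsv", sep="\t", index=False)
    n_defined = sum(1 for r in rows if not pd.isna(r["tvi"]))
    return {"n_pairs": len(rows), "n_tvi_defined": n_defined}


def run_screen(config: dict, outdir: Path) -> dict:
    cfg = config["screen"]
    seed = stage_seed(config["seed"], "screen")
    table = pd.read_csv(
        _require(outdir / "tvi" / "pair_tvi.tsv", "screen", "tvi"), sep="\t"
    )
    table = table.dropna(subset=["tvi"])
    tvi = pd.Series(
        table["tvi"].astype(float).to_numpy(), index=table["lesion_sample"]
    )
    expr, truth = simulate_expression(
        tvi,
        n_genes=int(cfg["n_genes"]),
        n_pos=int(cfg["n_pos"]),
        n_neg=int(cfg["n_neg"]),
        effect=float(cfg["effect"]),
        noise_sd=float(cfg["noise_sd"]),
        seed=seed,
    )
    results = correlate_with_tvi(expr, tvi, fdr_threshold=float(cfg["fdr_threshold"]))
    positive, negative = partition_gene_sets(results, float(cfg["fdr_threshold"]))
    screen_dir = outdir / "screen"
    screen_dir.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(screen_dir / "expression.tsv")
    results.to_csv(screen_dir / "gene_correlations.tsv", sep="\t", index=False)
    payload = {
        "positive": sorted(positive),
        "negative": sorted(negative),
        "truth": {
            "positive": sorted(truth.positive_genes),
            "negative": sorted(truth.negative_genes),
        },
    }
    (screen_dir / "gene_sets.json").write_text(json.dumps(payload, indent=2))
    return {"n_positive": len(positive), "n_negative": len(negative)}


def run_network(config: dict, outdir: Path) -> dict:
    cfg = config["network"]
    seed = stage_seed(config["seed"], "network")
    sets_path = _require(outdir / "screen" / "gene_sets.json", "network", "screen")
    gene_sets = json.loads(sets_path.read_text())
    universe = sorted(set(gene_sets["positive"]) | set(gene_sets["negative"]))
    if len(universe) < int(cfg["module_size"]):
        raise PipelineError(
            "network",
            f"gene universe of {len(universe)} significant genes is smaller "
            f"than the module size {cfg['module_size']}",
        )
    expr = ExpressionMatrix.from_tsv(
        _require(outdir / "screen" / "expression.tsv", "network", "screen")
    )
    edge_table, truth = simulate_ppi(
        universe,
        planted_module_size=int(cfg["module_size"]),
        planted_k=int(cfg["module_k"]),
        background_edge_prob=float(cfg["background_edge_prob"]),
        decoy_fraction=float(cfg["decoy_fraction"]),
        seed=seed,
    )
    net_dir = outdir / "network"
    net_dir.mkdir(parents=True, exist_ok=True)
    edge_table.to_csv(net_dir / "edge_table.tsv", sep="\t", index=False)

    graph = filter_string_edges(
        edge_table,
        textmining_min=float(cfg["textmining_min"]),
        combined_min=float(cfg["combined_min"]),
        gene_universe=universe,
    )
    graph = filter_edges_by_coexpression(
        graph, expr, rho_min=float(cfg["rho_min"]), missing="drop"
    )
    sub = maximal_connected_subnetwork(graph)
    try:
        fit = scale_free_fit(sub)
        fit_report = {"r_squared": fit.r_squared, "exponent": fit.exponent,
                      "n_points": fit.n_points, "degenerate": fit.degenerate}
    except Exception as exc:  # fit is reported best-effort
        fit_report = {"error": str(exc)}
    hub = hub_network(sub, top_fraction=float(cfg["top_fraction"]))
    result = select_module(hub, k_min=int(cfg["k_min"]))

    graph_to_edge_frame(sub).to_csv(net_dir / "maximal_subnetwork.tsv", sep="\t", index=False)
    graph_to_edge_frame(hub).to_csv(net_dir / "hub_network.tsv", sep="\t", index=False)
    report = {
        "n_nodes_filtered": graph.number_of_nodes(),
        "n_edges_filtered": graph.number_of_edges(),
        "n_nodes_maximal": sub.number_of_nodes(),
        "n_edges_maximal": sub.number_of_edges(),
        "scale_free_fit": fit_report,
        "hubs": hub.graph.get("hubs", []),
        "k": result.k,
        "communities": [sorted(c) for c in result.communities],
        "selected_module": sorted(result.selected_module),
        "planted_module": sorted(truth.planted_module),
        "planted_k": truth.planted_k,
    }
    (net_dir / "community_report.json").write_text(json.dumps(report, indent=2))
    return {
        "k": result.k,
        "module_size": len(result.selected_module),
        "module_matches_planted": set(result.selected_module) == set(truth.planted_module),
    }


def run_survive(config: dict, outdir: Path) -> dict:
    cfg = config["survive"]
    seed = stage_seed(config["seed"], "survive")
    report_path = _require(
        outdir / "network" / "community_report.json", "survive", "network"
    )
    module = json.loads(report_path.read_text())["selected_module"]
    if not module:
        raise PipelineError("survive", "network stage selected an empty module")
    surv_table, surv_truth = simulate_survival(
        n_per_group=int(cfg["n_per_group"]),
        hazard_ratio=float(cfg["hazard_ratio"]),
        censoring_rate=float(cfg["censoring_rate"]),
        seed=seed,
    )
    expr, true_labels = simulate_two_group_expression(
        module,
        n_per_group=int(cfg["n_per_group"]),
        separation=float(cfg["separation"]),
        noise_sd=float(cfg["noise_sd"]),
        seed=seed + 1,
    )
    # align: cohort sample ids of the two generators coincide by construction
    labels = two_group_clustering(
        expr, metric=cfg["metric"], linkage_method=cfg["linkage"]
    )
    table = surv_table.drop(columns=["group"]).copy()
    table["group"] = labels.loc[table["sample_id"]].to_numpy()
    result = logrank_test(table)

    surv_dir = outdir / "survival"
    surv_dir.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(surv_dir / "cohort_expression.tsv")
    table.to_csv(surv_dir / "survival.tsv", sep="\t", index=False)
    for label in (0, 1):
        km = km_estimate(table[table["group"] == label])
        km.to_frame().to_csv(surv_dir / f"km_group{label}.tsv", sep="\t", index=False)
    agreement = float((labels == true_labels).mean())
    agreement = max(agreement, 1.0 - agreement)  # label-permutation invariant
    payload = {
        "chi_square": result.chi_square,
        "p": result.p,
        "group_sizes": list(result.group_sizes),
        "clustering_agreement": agreement,
        "true_hazard_ratio": surv_truth.true_hazard_ratio,
    }
    (surv_dir / "logrank.json").write_text(json.dumps(payload, indent=2))
    return {"p": result.p, "clustering_agreement": agreement}


_STAGE_RUNNERS = {
    "simulate": run_simulate,
    "repstats": run_repstats,
    "tvi": run_tvi,
    "screen": run_screen,
    "network": run_network,
    "survive": run_survive,
}


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the enabled stages in order and write ``run_report.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tcrvar_version": __version__,
        "seed": config["seed"],
        "config": config,
        "stages": {},
    }
    for name in STAGES:
        if not config["stages"].get(name, True):
            report["stages"][name] = {"status": "skipped"}
            log.info("stage %s skipped", name)
            continue
        log.info("stage %s running", name)
        try:
            info = _STAGE_RUNNERS[name](config, outdir)
        except PipelineError:
            (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
            raise
        except Exception as exc:
            (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
            raise PipelineError(name, str(exc)) from exc
        report["stages"][name] = {"status": "complete", **info}
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
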