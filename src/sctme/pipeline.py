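"""End-to-end orchestration: simulate → qc → markers → OR → CNV → GSEA →
interactions → survival, driven by a single validated config.

Every stage writes its outputs under the run directory and contributes to a
machine-readable ``summary.json``; identical config + seed yields a
byte-identical summary.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import yaml

from . import cnv as cnv_mod
from . import enrichment, gsea, interactions, markers, qc, survival
from .core_io import ValidationError, write_dataset
from .synthetic import (
    ClusterSpec,
    CNVSimulationConfig,
    SimulationConfig,
    SubcloneSpec,
    SurvivalSimulationConfig,
    generate_cnv_profiles,
    generate_dataset,
    generate_survival_cohort,
    make_toy_genome,
)

__all__ = ["default_config", "validate_config", "run_pipeline"]

_ALLOWED_KEYS: dict[str, set[str]] = {
    "": {"seed", "out_dir", "stages", "simulate", "qc", "markers", "enrichment",
         "cnv", "gsea", "interactions", "survival"},
    "stages": {"qc", "markers", "enrichment", "cnv", "gsea", "interactions", "survival"},
    "simulate": {"n_genes", "cells_per_sample", "samples_per_group", "nb_mean",
                 "nb_dispersion", "marker_log2_shift", "planted_cluster_proportion",
                 "baseline_proportion"},
    "qc": {"min_genes", "max_genes", "max_umi", "max_pct_mito", "scale_factor"},
    "markers": {"min_pct", "max_p_adj", "min_log2fc", "top_n"},
    "enrichment": {"by"},
    "cnv": {"n_cells", "noise_sd", "n_reference_cells", "effect_size"},
    "gsea": {"n_perm", "weight_p"},
    "interactions": {"n_perm"},
    "survival": {"n_patients", "true_hr", "baseline_hazard", "censor_rate"},
}


def default_config() -> dict:
    """The shipped default run: a planted three-cluster study."""
    return {
        "seed": 0,
        "out_dir": "sctme_run",
        "stages": {k: True for k in _ALLOWED_KEYS["stages"]},
        "simulate": {
            "n_genes": 150,
            "cells_per_sample": 250,
            "samples_per_group": 4,
            "nb_mean": 0.5,
            "nb_dispersion": 2.0,
            "marker_log2_shift": 2.0,
            "planted_cluster_proportion": 0.30,
            "baseline_proportion": 0.10,
        },
        "qc": {"min_genes": 5, "max_genes": 5000, "max_umi": 30000,
               "max_pct_mito": 30.0, "scale_factor": 10000.0},
        "markers": {"min_pct": 0.25, "max_p_adj": 0.05, "min_log2fc": 0.25, "top_n": 10},
        "enrichment": {"by": "cells"},
        "cnv": {"n_cells": 300, "noise_sd": 0.1, "n_reference_cells": 150,
                "effect_size": 1.0},
        "gsea": {"n_perm": 200, "weight_p": 1.0},
        "interactions": {"n_perm": 100},
        "survival": {"n_patients": 400, "true_hr": 1.5, "baseline_hazard": 0.05,
                     "censor_rate": 0.2},
    }


def validate_config(config: dict) -> dict:
    """Merge onto defaults, rejecting unknown keys by name."""
    merged = default_config()
    for key, value in config.items():
        if key not in _ALLOWED_KEYS[""]:
            raise ValidationError(f"unknown config key {key!r}")
        if isinstance(value, dict):
            allowed = _ALLOWED_KEYS.get(key, set())
            for sub in value:
                if sub not in allowed:
                    raise ValidationError(f"unknown config key {key}.{sub!r}")
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(config: dict | str) -> dict:
    """Execute the configured stages; returns the summary dict.

    ``config`` may be a dict or a path to a YAML file.  Outputs land under
    ``config["out_dir"]``: the simulated dataset, per-stage TSVs and
    ``summary.json``.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    summary: dict[str, Any] = {"seed": seed, "stages": {}}

    # --- simulate --------------------------------------------------------
    sim = cfg["simulate"]
    shift = float(sim["marker_log2_shift"])
    clusters = (
        ClusterSpec("planted", ("MK0", "MK1", "MK2"), shift),
        ClusterSpec("other_a", ("MK3", "MK4", "MK5"), shift),
        ClusterSpec("other_b", ("MK6", "MK7", "MK8"), shift),
    )
    p_hi = float(sim["planted_cluster_proportion"])
    p_lo = float(sim["baseline_proportion"])
    rest_hi = (1 - p_hi) / 2
    rest_lo = (1 - p_lo) / 2
    composition = {
        "MPLC_Tumour": (p_hi, rest_hi, rest_hi),
        "MPLC_Normal": (p_lo, rest_lo, rest_lo),
        "SPLC_Tumour": (p_lo, rest_lo, rest_lo),
        "SPLC_Normal": (p_lo, rest_lo, rest_lo),
    }
    sim_cfg = SimulationConfig(
        n_genes=int(sim["n_genes"]),
        clusters=clusters,
        composition=composition,
        cells_per_sample=int(sim["cells_per_sample"]),
        samples_per_group=int(sim["samples_per_group"]),
        nb_mean=float(sim["nb_mean"]),
        nb_dispersion=float(sim["nb_dispersion"]),
        seed=seed,
    )
    dataset, truth = generate_dataset(sim_cfg)
    write_dataset(dataset, os.path.join(out_dir, "dataset"))
    summary["stages"]["simulate"] = {
        "n_cells": dataset.n_cells,
        "n_genes": dataset.n_genes,
        "planted_cluster": "planted",
        "planted_group": "MPLC_Tumour",
    }

    # --- qc --------------------------------------------------------------
    if cfg["stages"]["qc"]:
        qcp = cfg["qc"]
        cell_qc = qc.compute_cell_qc(dataset)
        kept, removed = qc.apply_qc_filters(
            cell_qc,
            qc.QCThresholds(
                min_genes=int(qcp["min_genes"]),
                max_genes=int(qcp["max_genes"]),
                max_umi=int(qcp["max_umi"]),
                max_pct_mito=float(qcp["max_pct_mito"]),
            ),
        )
        dataset = dataset.subset_cells(kept)
        cell_qc.to_csv(os.path.join(out_dir, "qc_report.tsv"), sep="\t")
        summary["stages"]["qc"] = {"n_kept": len(kept), "removed": removed}
    qc.normalize_log1p(dataset, float(cfg["qc"]["scale_factor"]))

    clusters_vec = dataset.meta["cluster"].to_numpy()

    # --- markers ---------------------------------------------------------
    marker_table = None
    if cfg["stages"]["markers"]:
        mp = cfg["markers"]
        marker_table = markers.find_all_markers(
            dataset.norm,
            clusters_vec,
            gene_ids=dataset.gene_ids,
            min_pct=float(mp["min_pct"]),
            max_p_adj=float(mp["max_p_adj"]),
            min_log2fc=float(mp["min_log2fc"]),
        )
        marker_table.to_csv(os.path.join(out_dir, "markers.tsv"), sep="\t", index=False)
        planted = marker_table[marker_table["cluster"] == "planted"]
        sig = markers.top_n_signature(planted, n=int(mp["top_n"])) if len(planted) else []
        summary["stages"]["markers"] = {
            "n_markers": int(len(marker_table)),
            "planted_signature": sig,
            "planted_markers_recovered": sorted(
                set(sig) & {"MK0", "MK1", "MK2"}
            ),
        }

    # --- enrichment ------------------------------------------------------
    if cfg["stages"]["enrichment"]:
        orres = enrichment.or_preference_matrix(dataset.meta, by=cfg["enrichment"]["by"])
        orres.to_csv(os.path.join(out_dir, "or_preference.tsv"), sep="\t", index=False)
        enriched = orres[orres["label"] == "enriched"]
        summary["stages"]["enrichment"] = {
            "enriched": [
                {"cluster": r.cluster, "group": r.group, "odds_ratio": _round(r.odds_ratio)}
                for r in enriched.itertuples()
            ]
        }

    # --- cnv -------------------------------------------------------------
    if cfg["stages"]["cnv"]:
        cp = cfg["cnv"]
        windows, centromeres, cyto = make_toy_genome(n_chroms=3, windows_per_arm=10)
        cnv_cfg = CNVSimulationConfig(
            windows=windows,
            centromeres=centromeres,
            subclones=(
                SubcloneSpec(
                    frozenset({("chr1", "q", "gain")}), 0.4, float(cp["effect_size"])
                ),
                SubcloneSpec(
                    frozenset({("chr1", "q", "gain"), ("chr2", "p", "loss")}),
                    0.3,
                    float(cp["effect_size"]),
                ),
            ),
            n_cells=int(cp["n_cells"]),
            noise_sd=float(cp["noise_sd"]),
            n_reference_cells=int(cp["n_reference_cells"]),
            seed=seed,
        )
        profile, cnv_truth = generate_cnv_profiles(cnv_cfg)
        scores = cnv_mod.cnv_score(profile)
        malignant = cnv_mod.call_malignant(scores, profile.reference_cell_ids)
        events = cnv_mod.map_events_to_arms(profile, cyto)
        tumour_mask = ~profile.reference_mask()
        subs = cnv_mod.collapse_subclones(
            [e for e, t in zip(events, tumour_mask) if t]
        )
        tree = cnv_mod.build_clonal_tree(subs)
        newick = cnv_mod.serialize_newick(tree)
        with open(os.path.join(out_dir, "clonal_tree.nwk"), "w") as fh:
            fh.write(newick + "\n")
        summary["stages"]["cnv"] = {
            "n_malignant": int(malignant[tumour_mask].sum()),
            "n_tumour_cells": int(tumour_mask.sum()),
            "subclones": [
                {"label": s.label(), "fraction": _round(s.fraction)} for s in subs
            ],
            "newick": newick,
        }

    # --- gsea ------------------------------------------------------------
    if cfg["stages"]["gsea"] and marker_table is not None:
        gp = cfg["gsea"]
        in_cells = np.flatnonzero(clusters_vec == "planted")
        out_cells = np.flatnonzero(clusters_vec != "planted")
        stats = markers.wilcoxon_auc(
            dataset.norm, in_cells, out_cells, gene_ids=dataset.gene_ids
        )
        ranked = gsea.rank_by_auc(stats.reset_index())
        sets = {"planted_markers": ["MK0", "MK1", "MK2"],
                "other_markers": ["MK3", "MK4", "MK5"]}
        res = gsea.nes_fdr(
            ranked, sets, n_perm=int(gp["n_perm"]), seed=seed,
            weight_p=float(gp["weight_p"]),
        )
        summary["stages"]["gsea"] = {
            r.set_name: {"es": _round(r.es), "nes": _round(r.nes), "fdr": _round(r.fdr)}
            for r in res
        }

    # --- interactions ----------------------------------------------------
    if cfg["stages"]["interactions"]:
        from .core_io import LRDatabase, LRPair

        db = LRDatabase(
            [
                LRPair("MK0_MK3", "MK0", ("MK3",)),
                LRPair("G0000_G0001", "G0000", ("G0001",)),
            ]
        )
        ires = interactions.interaction_test(
            dataset.counts,
            dataset.norm,
            dataset.meta,
            dataset.gene_ids,
            db,
            sender="planted",
            receiver="other_a",
            n_perm=int(cfg["interactions"]["n_perm"]),
            seed=seed,
        )
        ires.to_csv(os.path.join(out_dir, "interactions.tsv"), sep="\t", index=False)
        summary["stages"]["interactions"] = {
            "retained": sorted(ires.loc[ires["retained"], "pair_name"])
        }

    # --- survival --------------------------------------------------------
    if cfg["stages"]["survival"]:
        sv = cfg["survival"]
        surv_cfg = SurvivalSimulationConfig(
            n_patients=int(sv["n_patients"]),
            baseline_hazard=float(sv["baseline_hazard"]),
            true_hr=float(sv["true_hr"]),
            censor_rate=float(sv["censor_rate"]),
            seed=seed,
        )
        cohort = generate_survival_cohort(surv_cfg)
        sig_genes = list(surv_cfg.signature_genes)
        score = survival.signature_score_bulk(cohort.set_index("patient_id")[sig_genes], sig_genes)
        split = survival.median_split(score)
        x = (split == "high").astype(int).to_numpy()
        stat, p = survival.logrank_test(split.values, cohort["time"], cohort["event"])
        cox = survival.cox_univariate(x, cohort["time"], cohort["event"])
        summary["stages"]["survival"] = {
            "logrank_stat": _round(stat),
            "logrank_p": _round(p),
            "hr": _round(cox.hr),
            "hr_ci": [_round(cox.ci_low), _round(cox.ci_high)],
        }

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
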