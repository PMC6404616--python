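"""End-to-end orchestration of the simulated screen pipeline.

``run_simulate`` writes a synthetic screen bundle (density tables, layouts,
one rendered demo plate image, ground truth); ``run_full`` runs the whole
chain — scoring, sensitivity calls, cross-compound overlaps, profile
clustering, gene-set enrichment, dose-response ICs — into a run directory
with a manifest of SHA-256 checksums, so identical config + seed yields
identical manifests for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import doseresponse, enrich, fitness, profiles, synthdata
from .errors import ConfigError, EmptyInputError
from .screenio import write_gene_sets, write_plate_layout, write_results_table

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "screen": {
        "n_strains": 1000,
        "compounds": ["BHA", "BHT", "BPA"],
        "frac_sensitive": 0.1,
        "frac_resistant": 0.02,
        "noise_cv": 0.15,
        "n_replicates": 3,
    },
    "thresholds": {"t_sens": 0.5, "t_res": 2.0},
    "profile": {"floor": 0.05, "metric": "euclidean", "linkage": "average"},
    "enrichment": {
        "n_terms": 100,
        "term_size_range": [20, 200],
        "alpha": 0.05,
        "method": "bonferroni",
        "planted_folds": [4.0, 3.0],
    },
    "dose_response": {
        "ic50_mM": 0.4,
        "hill_slope": 2.0,
        "concentrations_mM": [0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2],
        "noise_sd": 0.01,
        "levels": [50, 80],
    },
    "render_demo_image": True,
}


def merge_config(user: dict | None) -> dict:
    """Overlay a user config onto the defaults, validating key paths."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            for sub, sval in val.items():
                if sub not in cfg[key]:
                    raise ConfigError(f"unknown config key {key}.{sub}")
                cfg[key][sub] = sval
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, cfg: dict) -> dict:
    manifest = {
        "config": cfg,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_simulate(config: dict | None, outdir: str | Path) -> dict:
    """Generate a synthetic screen bundle under ``outdir``."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = cfg["screen"]
    if sc["n_strains"] < 1:
        raise EmptyInputError("n_strains must be >= 1")
    truth, tables = synthdata.simulate_screen(
        n_strains=sc["n_strains"],
        compounds=tuple(sc["compounds"]),
        frac_sensitive=sc["frac_sensitive"],
        frac_resistant=sc["frac_resistant"],
        noise_cv=sc["noise_cv"],
        n_replicates=sc["n_replicates"],
        seed=cfg["seed"],
    )
    for comp, pair in tables.items():
        pair["treated"].to_csv(outdir / f"density_{comp}_treated.tsv", sep="\t")
        pair["control"].to_csv(outdir / f"density_{comp}_control.tsv", sep="\t")
    truth.effect.to_csv(outdir / "truth_effects.tsv", sep="\t")

    if cfg["render_demo_image"]:
        n_rows, n_cols = 8, 12
        layout = synthdata.layout_for_grid(
            n_rows, n_cols, strains=truth.strains[: n_rows * n_cols - 4]
        )
        rng = np.random.default_rng(cfg["seed"])
        grid = rng.uniform(200, 1200, size=(n_rows, n_cols))
        params = synthdata.RenderParams(seed=cfg["seed"])
        img = synthdata.render_plate_image(grid, layout, params)
        synthdata.write_plate_image(img, outdir / "demo_plate.png")
        write_plate_layout(layout, outdir / "demo_layout.tsv")

    _write_manifest(outdir, cfg)
    return {"truth": truth, "tables": tables, "outdir": outdir}


def run_full(config: dict | None, outdir: str | Path) -> dict:
    """Run the full simulated chain and write one table/figure per stage."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = run_simulate(cfg, outdir)
    truth, tables = bundle["truth"], bundle["tables"]

    # --- scoring and calls ------------------------------------------------
    screen_cfg = fitness.ScreenConfig(
        t_sens=cfg["thresholds"]["t_sens"], t_res=cfg["thresholds"]["t_res"]
    )
    scores = fitness.score_screen(tables, screen_cfg)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    call_counts = scores.groupby(["compound", "call"]).size().unstack(fill_value=0)

    # --- overlaps ---------------------------------------------------------
    sens_sets = fitness.sensitive_sets(scores)
    summary = profiles.overlap_analysis(sens_sets)
    write_results_table(
        profiles.overlap_records(summary),
        outdir / "overlap.tsv",
        columns=["quantity", "count", "fraction_of_union"],
    )

    # --- profile clustering (called strains only, for a readable tree) ----
    called = scores[scores["call"] != fitness.NORMAL]
    keep = sorted(set(called["strain"]))[:200]
    sub = scores[scores["strain"].isin(keep)]
    cluster_newick = ""
    if len(keep) >= 2:
        pm = profiles.build_profile_matrix(sub, floor=cfg["profile"]["floor"])
        cl = profiles.hierarchical_cluster(
            pm, metric=cfg["profile"]["metric"], method=cfg["profile"]["linkage"]
        )
        cluster_newick = profiles.to_newick(cl)
        (outdir / "clusters.nwk").write_text(cluster_newick + "\n")
        profiles.plot_heatmap(pm, cl, outdir / "heatmap.png")

    # --- enrichment against a synthetic annotation universe ---------------
    en = cfg["enrichment"]
    planted = [(f"term{i:04d}", f) for i, f in enumerate(en["planted_folds"])]
    n_genes = cfg["screen"]["n_strains"]
    lo, hi = en["term_size_range"]
    hi = min(hi, max(2, n_genes // 2))  # keep term sizes inside small universes
    lo = min(lo, hi)
    annotation, ann_truth = synthdata.simulate_annotation_universe(
        n_genes=n_genes,
        n_terms=en["n_terms"],
        term_size_range=(lo, hi),
        planted=planted,
        query_size=max(
            len(next(iter(sens_sets.values()), set())), 10
        ),
        seed=cfg["seed"] + 1,
    )
    results = enrich.enrich_gene_sets(
        ann_truth["query"], annotation, alpha=en["alpha"], method=en["method"]
    )
    write_results_table(
        enrich.results_records(results),
        outdir / "enrichment.tsv",
        columns=["term_id", "term_name", "k", "n", "K", "N", "p_raw",
                 "p_corrected", "significant"],
    )
    sig = [r for r in results if r.significant]
    layout = enrich.bubble_layout(sig)
    enrich.plot_bubbles(layout, outdir / "bubbles.png")
    write_gene_sets(annotation.term_map, outdir / "gene_sets.gmt")

    # --- dose-response -----------------------------------------------------
    dr = cfg["dose_response"]
    curve_df = synthdata.simulate_dose_response(
        dr["ic50_mM"], dr["hill_slope"], dr["concentrations_mM"],
        noise_sd=dr["noise_sd"], seed=cfg["seed"] + 2,
    )
    curve = doseresponse.DoseResponseCurve(points=curve_df, compound="demo")
    ic_rows = []
    for level in dr["levels"]:
        for method in ("interp", "logistic"):
            try:
                ic = doseresponse.estimate_ic(curve, level, method=method)
            except Exception as exc:  # noqa: BLE001 - report, don't abort
                logger.warning("IC%s (%s) failed: %s", level, method, exc)
                continue
            ic_rows.append(
                {"level": level, "method": method, "ic_mM": float(ic)}
            )
    write_results_table(ic_rows, outdir / "ic_estimates.tsv",
                        columns=["level", "method", "ic_mM"])
    doseresponse.plot_curve(curve, outdir / "dose_response.png")

    # --- report ------------------------------------------------------------
    n_truth = len(truth.sensitive_truth)
    called_set = {
        (s, c) for c, genes in sens_sets.items() for s in genes
    }
    tp = len(called_set & truth.sensitive_truth)
    report = {
        "call_counts": call_counts.to_dict(),
        "overlap": {
            "union": summary.union,
            "unique": summary.unique,
        },
        "recovery": {
            "sensitivity": tp / n_truth if n_truth else None,
            "precision": tp / len(called_set) if called_set else None,
        },
        "n_significant_terms": len(sig),
        "ic_estimates": ic_rows,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    manifest = _write_manifest(outdir, cfg)
    return {
        "scores": scores,
        "overlap": summary,
        "enrichment": results,
        "report": report,
        "manifest": manifest,
        "outdir": outdir,
    }
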