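"""End-to-end orchestration: simulate/load → gate → profiles → scores →
stratification → differential tests, with CSV/JSON artifacts and a
machine-readable run log.

The configuration is a plain dict (YAML-friendly). Either ``inputs`` names
existing event-table CSVs or ``simulate`` gives generator settings. All
stage randomness derives deterministically from the single run-level seed.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ScenmepError
from .io import (GatingConfig, SCMEP_MARKERS, apply_gate, read_event_table,
                 write_event_table)
from .scenith import (adjust_profile, classify_oligomycin_cells,
                      geometric_mfi, phospho_ratio, profiles_from_events,
                      profiles_to_frame)
from .scmep import (builtin_pathways, correlate_scores, population_medians,
                    population_pathway_score)
from .simulate import (DonorModel, builtin_archetypes,
                       generate_scenith_dataset, generate_scmep_dataset)
from .stats import differential_markers
from .stratify import class_frequencies, maturation_classes

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "outdir": "scenmep_out",
    "simulate": {
        "n_cells_per_well": 1000,
        "scmep_n_cells": 1000,
        "n_donors": 3,
        "donor_sigma": 0.1,
        "cell_sigma": 0.2,
    },
    "min_cells": 200,
    "gate": [],  # optional [marker, comparator, threshold] triples
    "differential_contrast": {
        "stage": "mono_24h", "reference": "ctrl", "test": "vitd3"},
    "oligomycin_group": {"condition": "ctrl", "stage": "mDC"},
}


def _stage(name):
    """Decorator adding stage-labelled context to propagated errors."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ScenmepError as exc:
                exc.args = (f"[stage: {name}] {exc.args[0]}",
                            *exc.args[1:])
                raise
        return wrapper
    return deco


def _merged(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


@_stage("simulate")
def _obtain_tables(cfg: dict, outdir: Path):
    inputs = cfg.get("inputs")
    if inputs:
        scenith = read_event_table(inputs["scenith_csv"], "scenith")
        scmep = (read_event_table(inputs["scmep_csv"], "scmep")
                 if "scmep_csv" in inputs else None)
        return scenith, scmep
    sim = cfg["simulate"]
    donor_model = DonorModel(sim["n_donors"], sim["donor_sigma"])
    archetypes = builtin_archetypes(cell_sigma=sim["cell_sigma"])
    seed = int(cfg["seed"])
    scenith = generate_scenith_dataset(
        archetypes, n_cells_per_well=sim["n_cells_per_well"],
        donor_model=donor_model, seed=seed)
    scmep = generate_scmep_dataset(
        archetypes, donor_model=donor_model,
        n_cells=sim["scmep_n_cells"], seed=seed + 1, volume_scaling=True)
    write_event_table(scenith, outdir / "scenith_events.csv", "scenith")
    write_event_table(scmep, outdir / "scmep_events.csv", "scmep")
    return scenith, scmep


@_stage("scenith")
def _scenith_outputs(events: pd.DataFrame, cfg: dict, outdir: Path):
    profiles = profiles_from_events(
        events, by=("donor_id", "condition", "stage"),
        min_cells=cfg["min_cells"])
    frame = profiles_to_frame(profiles)
    frame.to_csv(outdir / "scenith_profiles.csv", index=False)
    adjusted = []
    for p in profiles:
        row = dict(p.group)
        row.update({f"adj_{k}": v for k, v in adjust_profile(p).items()})
        adjusted.append(row)
    pd.DataFrame(adjusted).to_csv(outdir / "scenith_adjusted.csv",
                                  index=False)
    return profiles


@_stage("scmep")
def _scmep_outputs(scmep_events: pd.DataFrame, profiles, cfg: dict,
                   outdir: Path):
    ref_radius = float(
        scmep_events.query("condition == 'ctrl' and stage == 'mono_0h'")
        ["cell_radius"].mean())
    medians = population_medians(
        scmep_events, SCMEP_MARKERS, by=("condition", "stage"),
        volume_reference=ref_radius)
    medians.to_csv(outdir / "scmep_population_medians.csv", index=False)

    score_rows = []
    for _, row in medians.iterrows():
        out = {"condition": row["condition"], "stage": row["stage"]}
        for definition in builtin_pathways():
            out[definition.name] = population_pathway_score(row, definition)
        score_rows.append(out)
    scores = pd.DataFrame(score_rows)
    scores.to_csv(outdir / "scmep_pathway_scores.csv", index=False)

    # Spearman of pathway scores vs pooled adjusted parameters across groups
    prof_frame = profiles_to_frame(profiles)
    pooled = prof_frame.groupby(["condition", "stage"]).mean(
        numeric_only=True).reset_index()
    merged = scores.merge(pooled, on=["condition", "stage"])
    pairs = [("TCA/ETC", "mitochondrial_dependence"),
             ("GLYC-UP", "glycolytic_capacity"),
             ("AA", "glutaminolysis_dependence"),
             ("FAO", "fao_dependence")]
    corr_rows = []
    for score_name, param in pairs:
        adj = merged[param] * merged["background_window"]
        rho, p = correlate_scores(merged[score_name], adj)
        corr_rows.append({"score": score_name, "parameter": param,
                          "spearman_rho": rho, "p_value": p})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(outdir / "scmep_scenith_correlations.csv", index=False)
    return scores, corr


@_stage("stratify")
def _stratification_outputs(events: pd.DataFrame, cfg: dict, outdir: Path):
    gate = GatingConfig.from_triples(cfg.get("gate") or [])
    c_well = events[events["inhibitor"] == "C"]
    gated = apply_gate(c_well, gate)
    classes = maturation_classes(gated, marker="HLA-DR")
    freq = class_frequencies(
        classes, gated[["condition", "stage"]].reset_index(drop=True))
    freq.to_csv(outdir / "maturation_class_frequencies.csv", index=False)
    return freq


@_stage("oligomycin")
def _oligomycin_outputs(events: pd.DataFrame, cfg: dict, outdir: Path):
    sel = cfg["oligomycin_group"]
    group = events[(events["condition"] == sel["condition"]) &
                   (events["stage"] == sel["stage"])]
    o = group[group["inhibitor"] == "O"]
    labels = classify_oligomycin_cells(
        o, c_puromycin=group.loc[group["inhibitor"] == "C", "puromycin"],
        dgo_puromycin=group.loc[group["inhibitor"] == "DGO", "puromycin"],
        min_cells=cfg["min_cells"])
    labels.to_csv(outdir / "oligomycin_cell_labels.csv", index=False)

    merged = o.merge(labels, on="cell_id")
    rows = []
    for tertile, cells in merged.groupby("puromycin_tertile", observed=True):
        ratio = phospho_ratio(geometric_mfi(cells["p-mTOR"]),
                              geometric_mfi(cells["p-AMPK"]))
        rows.append({"puromycin_tertile": tertile,
                     "p_mtor_p_ampk_ratio": ratio, "n": len(cells)})
    ratios = pd.DataFrame(rows)
    ratios.to_csv(outdir / "tertile_phospho_ratios.csv", index=False)
    return labels, ratios


@_stage("differential")
def _differential_outputs(events: pd.DataFrame, cfg: dict, outdir: Path):
    sel = cfg["differential_contrast"]
    c_well = events[(events["inhibitor"] == "C") &
                    (events["stage"] == sel["stage"]) &
                    (events["condition"].isin([sel["reference"],
                                               sel["test"]]))]
    markers = [m for m in ("CD14", "HLA-DR", "CD86", "CD1c", "PD-L1",
                           "ILT3", "CD141", "p-mTOR", "p-AMPK")
               if m in c_well.columns]
    rows = []
    for (donor, condition), group in c_well.groupby(
            ["donor_id", "condition"], observed=True):
        row = {"donor_id": donor, "group": condition}
        for m in markers:
            row[m] = float(np.median(np.arcsinh(
                group[m].to_numpy(dtype=float) / 5.0)))
        rows.append(row)
    summaries = pd.DataFrame(rows)
    result = differential_markers(
        summaries, (sel["reference"], sel["test"]), markers=markers)
    result.insert(0, "contrast",
                  f"{sel['test']} vs {sel['reference']} @ {sel['stage']}")
    result.to_csv(outdir / "differential_markers.csv", index=False)
    return result


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full analysis and write all artifacts to ``outdir``.

    Returns a manifest dict (also written as ``run_log.json``) listing the
    seed, package version, effective configuration and artifact paths.
    Identical configurations produce identical outputs.
    """
    cfg = _merged(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    scenith_events, scmep_events = _obtain_tables(cfg, outdir)
    profiles = _scenith_outputs(scenith_events, cfg, outdir)
    if scmep_events is not None:
        _scmep_outputs(scmep_events, profiles, cfg, outdir)
    _stratification_outputs(scenith_events, cfg, outdir)
    _oligomycin_outputs(scenith_events, cfg, outdir)
    _differential_outputs(scenith_events, cfg, outdir)

    artifacts = sorted(p.name for p in outdir.glob("*.csv"))
    manifest = {
        "package": "scenmep",
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg["seed"],
        "config": cfg,
        "artifacts": artifacts,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
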