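"""End-to-end orchestration: simulate -> preprocess -> QC -> (denoise) ->
segment -> call -> filter -> chimera -> report.

A run is driven by a single config mapping (typically loaded from YAML) and
writes every stage artifact plus a JSON run manifest recording the config,
the seed and each stage's outputs, so any output file can be reproduced.
Existing artifacts are reused on re-run unless ``force`` is set.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import chimera, coverage, denoise, filters, qc, segment, simulate, stats
from ._util import stable_hash

log = logging.getLogger("scwga_cnv")

DEFAULT_CONFIG = {
    "cohort": {
        "genome": [["chr1", 50_000_000], ["chr2", 50_000_000],
                   ["chr3", 40_000_000], ["chr4", 40_000_000],
                   ["chr5", 30_000_000]],
        "bin_size": 250_000,
        "mean_reads_per_bin": 500.0,
        "cells": [{"individual": "MSA1", "method": "picoplex", "n": 8},
                  {"individual": "MSA2", "method": "picoplex", "n": 6},
                  {"individual": "Control", "method": "pta", "n": 6}],
        "cnv_menu": [{"size": 3_000_000, "cn": 3, "frequency": 0.4},
                     {"size": 2_500_000, "cn": 1, "frequency": 0.3}],
        "artifact_cnvs": [],
    },
    "qc": {"mad_max": 0.3, "conf_min": 0.7},
    "denoise": {"enabled": "auto", "variance_fraction": 0.4},
    "calling": {"alpha": 0.01, "min_width": 5, "n_perm": 10_000,
                "loss_thr": segment.DEFAULT_LOSS_THR,
                "gain_thr": segment.DEFAULT_GAIN_THR,
                "derive_thresholds": True, "min_bins": 5},
    "filter": {"share_fraction": 0.5,
               "tolerances": {"picoplex": 2_500_000, "pta": 5_000_000},
               "subtelomeric_window_bins": 2},
    "chimera": {"n_pairs": 4000, "mq_min": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def _cohort_spec(cfg: dict, seed: int) -> simulate.CohortSpec:
    c = cfg["cohort"]
    return simulate.CohortSpec(
        cells=[(g["individual"], g["method"], int(g["n"])) for g in c["cells"]],
        genome=[(str(ch), int(ln)) for ch, ln in c["genome"]],
        bin_size=int(c["bin_size"]),
        mean_reads_per_bin=float(c["mean_reads_per_bin"]),
        cnv_menu=[(int(m["size"]), int(m["cn"]), float(m["frequency"]))
                  for m in c.get("cnv_menu", [])],
        artifact_cnvs=[simulate.ArtifactCnv(
            a["chrom"], int(a["start"]), int(a["end"]), int(a["cn"]),
            float(a.get("carrier_fraction", 0.6)), a.get("individuals"))
            for a in c.get("artifact_cnvs", [])],
        shared_artifact_seed=seed,
        rng_seed=seed,
    )


def run_pipeline(config: dict, outdir, seed: int = 1,
                 force: bool = False) -> Path:
    """Run every stage on a synthetic cohort; returns the artifact directory.

    Deterministic given ``config`` and ``seed``. Stage outputs already on
    disk are reused unless ``force``; the manifest records parameters and
    artifacts for every stage that ran.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed), "config": config, "stages": {}}

    methods = {g["method"] for g in config["cohort"]["cells"]}
    den_cfg = config["denoise"]
    denoise_on = den_cfg["enabled"] in ("auto", "all", True)
    if "dmda" in methods and not denoise_on:
        warnings.warn("dMDA cells present with denoising disabled: read-depth "
                      "CNV calling is unsupported for dMDA without denoising")

    # --- simulate -----------------------------------------------------------
    spec = _cohort_spec(config, seed)
    counts_path = outdir / "counts.tsv"
    if force or not counts_path.exists():
        counts, truths, bins = simulate.simulate_cohort(spec)
        counts.to_csv(counts_path, sep="\t", index=False)
        simulate.truth_to_bed(truths).to_csv(outdir / "truth.bed", sep="\t",
                                             header=False, index=False)
        bins.to_bed(outdir / "bins.bed")
        log.info("simulated %d cells x %d bins", counts.shape[1], bins.n_bins)
    else:
        counts = pd.read_csv(counts_path, sep="\t")
        bins = coverage.BinScheme.from_bed(outdir / "bins.bed")
        log.info("reusing existing cohort artifacts")
    manifest["stages"]["simulate"] = {
        "outputs": ["counts.tsv", "truth.bed", "bins.bed"],
        "params": {"rng_seed": spec.rng_seed, "bin_size": spec.bin_size}}

    roster = spec.cell_ids()

    # --- preprocess ---------------------------------------------------------
    corrected = {}
    unusable = []
    for cell_id, individual, method in roster:
        raw = counts[cell_id].to_numpy()
        try:
            prof = coverage.make_profile(cell_id, individual, method, raw, bins)
        except ValueError:
            unusable.append(cell_id)
            continue
        corrected[cell_id] = prof.corrected
    matrix = pd.DataFrame(corrected)

    # --- denoise ------------------------------------------------------------
    if denoise_on:
        for method in sorted(methods):
            if den_cfg["enabled"] == "auto" and method != "dmda":
                continue
            cols = [cid for cid, _, m in roster
                    if m == method and cid in matrix.columns]
            if len(cols) >= 3:
                matrix[cols] = denoise.pca_denoise(
                    matrix[cols].to_numpy(),
                    float(den_cfg["variance_fraction"]))
                log.info("denoised %d %s cells", len(cols), method)
    manifest["stages"]["denoise"] = {"params": dict(den_cfg)}

    # --- segment + ploidy ---------------------------------------------------
    cal = config["calling"]
    segsets = {}
    for cell_id in matrix.columns:
        segs = segment.cbs_segment(
            matrix[cell_id].to_numpy(), bins.chrom_labels,
            alpha=float(cal["alpha"]), min_width=int(cal["min_width"]),
            n_perm=int(cal["n_perm"]),
            rng_seed=seed * 100_003 + stable_hash(cell_id) % 100_003)
        segsets[cell_id] = segment.assign_copy_numbers(segs)
    seg_rows = []
    for cell_id, ss in segsets.items():
        sdf = ss.df.copy()
        sdf.insert(0, "cell_id", cell_id)
        seg_rows.append(sdf)
    pd.concat(seg_rows, ignore_index=True).to_csv(
        outdir / "segments.tsv", sep="\t", index=False)
    manifest["stages"]["segment"] = {
        "outputs": ["segments.tsv"],
        "params": {k: cal[k] for k in ("alpha", "min_width", "n_perm")}}

    # --- QC -----------------------------------------------------------------
    qcfg = config["qc"]
    reports = []
    for cell_id, individual, method in roster:
        if cell_id not in matrix.columns:
            reports.append(qc.QcReport(cell_id, float("nan"), float("nan"),
                                       float("nan"), False))
            continue
        reports.append(qc.qc_cell(cell_id, matrix[cell_id].to_numpy(), bins,
                                  segsets[cell_id],
                                  mad_max=float(qcfg["mad_max"]),
                                  conf_min=float(qcfg["conf_min"])))
    qc_df = qc.qc_table(reports)
    qc_df["individual_id"] = [ind for _, ind, _ in roster]
    qc_df["method"] = [m for _, _, m in roster]
    qc_df.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = {"outputs": ["qc.tsv"], "params": dict(qcfg)}

    passed = qc_df[qc_df["passes"]]
    passed_ids = list(passed["cell_id"])

    # --- thresholds + calls -------------------------------------------------
    loss_thr, gain_thr = segment.derive_thresholds(
        [segsets[c] for c in passed_ids],
        min_bins=int(cal["min_bins"]),
        defaults=(float(cal["loss_thr"]), float(cal["gain_thr"])),
        derive=bool(cal["derive_thresholds"]))
    by_cell = {cid: (ind, m) for cid, ind, m in roster}
    call_frames = []
    for cell_id in passed_ids:
        ind, method = by_cell[cell_id]
        call_frames.append(segment.extract_cnvs(
            segsets[cell_id], bins, loss_thr, gain_thr,
            min_bins=int(cal["min_bins"]), cell_id=cell_id,
            individual_id=ind, method=method))
    call_frames = [f for f in call_frames if len(f)]
    calls = pd.concat(call_frames, ignore_index=True) if call_frames else \
        pd.DataFrame(columns=segment.CALL_COLUMNS)
    calls.to_csv(outdir / "calls.bed", sep="\t", index=False)
    manifest["stages"]["call"] = {
        "outputs": ["calls.bed"],
        "params": {"loss_thr": loss_thr, "gain_thr": gain_thr,
                   "derived": bool(cal["derive_thresholds"])}}

    # --- filter -------------------------------------------------------------
    fcfg = config["filter"]
    n_per_ind = passed.groupby("individual_id").size().to_dict()
    if len(calls):
        grouped = filters.match_shared(calls, fcfg["tolerances"])
        retained = filters.filter_artifacts(grouped, n_per_ind,
                                            float(fcfg["share_fraction"]))
        window = int(fcfg["subtelomeric_window_bins"]) * spec.bin_size
        retained = filters.annotate_subtelomeric(retained, spec.genome, window)
        _, retained = filters.aneusomy_check(retained, spec.genome)
    else:
        retained = calls.copy()
    retained.to_csv(outdir / "calls_filtered.bed", sep="\t", index=False)
    manifest["stages"]["filter"] = {"outputs": ["calls_filtered.bed"],
                                    "params": dict(fcfg,
                                                   tolerances=dict(
                                                       fcfg["tolerances"]))}

    # --- chimera ------------------------------------------------------------
    ccfg = config["chimera"]
    chim_rows = []
    for cell_id, individual, method in roster:
        pairs = simulate.simulate_method_pairs(
            method, int(ccfg["n_pairs"]),
            rng_seed=seed * 100_003 + stable_hash(cell_id) % 100_003)
        summary = chimera.summarize_chimeras(pairs, int(ccfg["mq_min"]))
        chim_rows.append(dict(cell_id=cell_id, method=method,
                              **{k: summary[k]
                                 for k in ("inward", "outward", "interchrom",
                                           "other")}))
    chim_df = pd.DataFrame(chim_rows)
    chim_df.to_csv(outdir / "chimera.tsv", sep="\t", index=False)
    manifest["stages"]["chimera"] = {"outputs": ["chimera.tsv"],
                                     "params": dict(ccfg)}

    # --- report -------------------------------------------------------------
    table, rollup = stats.summarize_cohort(qc_df, retained)
    table.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    manifest["stages"]["report"] = {"outputs": ["summary.tsv"],
                                    "rollup": {k: float(v) for k, v in
                                               rollup.items()}}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
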