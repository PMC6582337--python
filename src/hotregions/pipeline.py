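"""Pipeline orchestration: call -> features -> model -> enrich -> methyl.

A single YAML config drives the whole analysis; every constant of the method
(500 bp window, 2000/1000 bp suppression, 99th/85th percentiles, 50 bins,
0.5/99 winsorization, 200 bp read extension, 3000 windows per stratum)
surfaces as a named key with that default. Stages whose inputs are absent
are skipped and recorded; a manifest lists every output file with a content
checksum so reruns are verifiably deterministic.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import time
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .calling import CallerConfig, call_hot_regions, summits_from_peaks
from .enrichment import (
    ReadSet,
    coverage_track,
    extend_reads,
    per_bp_log2_track,
    profile_matrix,
    region_log2_enrichment,
    stratified_window_sample,
)
from .features import build_feature_matrix, standardize_features
from .methylation import hot_vs_nonhot_cgi, nonhot_cgis, summarize_region_set
from .model import (
    cpg_matched_sampling,
    pca_top_features,
    sample_controls,
    top_features,
    train_elastic_net,
    variable_importance,
)
from .simulate import BundleParams, make_bundle

logger = logging.getLogger("hotregions")

DEFAULT_CONFIG: dict[str, Any] = {
    "paths": {
        "peak_dir": None,
        "genome": None,
        "chrom_sizes": None,
        "cgi": None,
        "ip_reads": None,
        "control_reads": None,
        "methylation_dir": None,
    },
    "caller": {
        "window_size": 500,
        "step": 50,
        "suppression_span": 2000,
        "hot_percentile": 99.0,
        "mild_percentile": 75.0,
        "control_ceiling_percentile": 85.0,
    },
    "features": {"window": 2000},
    "model": {"alpha": 0.5, "folds": 10, "seed": 0, "cpg_matched": True},
    "enrichment": {
        "epsilon": None,
        "control_kind": "input",
        "strata": [[0, 75, 3000], [75, 99, 3000], [99, 100, 3000]],
        "nbins": 50,
        "winsor": [0.5, 99.0],
        "profile_flank": 1000,
        "extend_to": None,
        "seed": 0,
    },
    "simulate": {"seed": 0},
    "outdir": "hotregions_out",
}


def _deep_update(base: dict, extra: Mapping) -> dict:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | None = None, overrides: Mapping | None = None) -> dict:
    """Defaults <- YAML file <- overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        _deep_update(cfg, loaded)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: str, config: Mapping):
        self.outdir = outdir
        self.data: dict[str, Any] = {
            "config": json.loads(json.dumps(config)),
            "stages": {},
            "outputs": {},
        }

    def record_stage(self, name: str, status: str, seconds: float, **extra) -> None:
        self.data["stages"][name] = {"status": status, "seconds": round(seconds, 3), **extra}

    def record_output(self, path: str) -> None:
        rel = os.path.relpath(path, self.outdir)
        self.data["outputs"][rel] = _sha256(path)

    def write(self) -> str:
        path = os.path.join(self.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path


def _caller_config(cfg: Mapping) -> CallerConfig:
    c = cfg["caller"]
    return CallerConfig(
        window_size=int(c["window_size"]),
        step=int(c["step"]),
        suppression_span=int(c["suppression_span"]),
        hot_percentile=float(c["hot_percentile"]),
        mild_percentile=float(c["mild_percentile"]),
        control_ceiling_percentile=float(c["control_ceiling_percentile"]),
    )


def stage_call(cfg: Mapping, outdir: str) -> pd.DataFrame:
    paths = cfg["paths"]
    files = sorted(
        glob.glob(os.path.join(paths["peak_dir"], "*.narrowPeak"))
        + glob.glob(os.path.join(paths["peak_dir"], "*.bed"))
    )
    if not files:
        raise FileNotFoundError(f"no peak files in {paths['peak_dir']}")
    chrom_sizes = hio.read_chrom_sizes(paths["chrom_sizes"])
    summit_sets = [
        summits_from_peaks(hio.read_narrowpeak(f), os.path.basename(f)) for f in files
    ]
    regions = call_hot_regions(summit_sets, chrom_sizes, _caller_config(cfg))
    hio.write_regions_bed(regions, os.path.join(outdir, "regions.bed"))
    regions.to_csv(os.path.join(outdir, "regions.tsv"), sep="\t", index=False)
    logger.info(
        "called %d regions (%d HOT) from %d experiments",
        len(regions),
        int((regions["label"] == "HOT").sum()),
        len(files),
    )
    return regions


def stage_features(cfg: Mapping, outdir: str, regions: pd.DataFrame) -> pd.DataFrame:
    """Features for HOT regions and an equal-size control sample."""
    paths = cfg["paths"]
    seed = int(cfg["model"]["seed"])
    hot = regions[regions["label"] == "HOT"].reset_index(drop=True)
    if hot.empty:
        raise ValueError("no HOT regions called")
    ceiling = float(cfg["caller"]["control_ceiling_percentile"])
    pool = regions[regions["percentile"] < ceiling].reset_index(drop=True)
    if cfg["model"].get("cpg_matched") and paths.get("cgi"):
        cgi = hio.read_bed(paths["cgi"])
        controls = cpg_matched_sampling(hot, pool, cgi, seed=seed)
    else:
        controls = sample_controls(regions, len(hot), ceiling, seed=seed)
    labelled = pd.concat(
        [hot.assign(cls="HOT"), controls.assign(cls="CONTROL")], ignore_index=True
    )
    mat = build_feature_matrix(
        labelled, paths["genome"], window=int(cfg["features"]["window"])
    )
    mat.insert(0, "label", labelled["cls"])
    for col in ("chrom", "start", "end"):
        mat.insert(0, col, labelled[col])
    mat.to_csv(os.path.join(outdir, "features.tsv"), sep="\t", index=False)
    return mat


def stage_model(cfg: Mapping, outdir: str, features: pd.DataFrame) -> dict:
    meta_cols = ["chrom", "start", "end", "label"]
    matrix = features.drop(columns=meta_cols)
    labels = features["label"].to_numpy()
    std, zero_var = standardize_features(matrix)
    fit = train_elastic_net(
        std,
        labels,
        folds=int(cfg["model"]["folds"]),
        alpha=float(cfg["model"]["alpha"]),
        seed=int(cfg["model"]["seed"]),
    )
    importance = variable_importance(fit, feature_names=list(matrix.columns))
    payload = {
        "alpha": fit.alpha,
        "lambda": fit.lambda_,
        "cv_auc": fit.cv_auc_,
        "intercept": fit.intercept_,
        "coefficients": dict(zip(matrix.columns, fit.coef_.tolist())),
        "zero_variance_features": zero_var,
        "seed": int(cfg["model"]["seed"]),
    }
    with open(os.path.join(outdir, "model.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
    importance.rename("importance").to_csv(
        os.path.join(outdir, "importance.tsv"), sep="\t", header=True
    )
    top10 = top_features(importance, 10)
    coords, evr = pca_top_features(std, top10)
    coords = coords.assign(label=labels)
    coords.to_csv(os.path.join(outdir, "pca.tsv"), sep="\t", index=False)
    payload["pca_explained_variance"] = evr.tolist()
    payload["top_features"] = top10
    logger.info("model: cv_auc=%.3f lambda=%.4g", fit.cv_auc_, fit.lambda_)
    return payload


def stage_enrich(cfg: Mapping, outdir: str, regions: pd.DataFrame) -> pd.DataFrame:
    paths = cfg["paths"]
    ecfg = cfg["enrichment"]
    chrom_sizes = hio.read_chrom_sizes(paths["chrom_sizes"])
    ip = ReadSet("ip", hio.read_reads_bed(paths["ip_reads"]))
    control = ReadSet("control", hio.read_reads_bed(paths["control_reads"]))
    if ecfg.get("extend_to"):
        ip = extend_reads(ip, int(ecfg["extend_to"]), chrom_sizes)
        control = extend_reads(control, int(ecfg["extend_to"]), chrom_sizes)
    result = region_log2_enrichment(
        ip,
        control,
        regions,
        epsilon=ecfg["epsilon"],
        control_kind=ecfg.get("control_kind", "input"),
    )
    table = pd.concat(
        [regions[["chrom", "start", "end", "occupancy", "percentile", "label"]], result.table],
        axis=1,
    )
    table.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
    # boxplot numbers: quartiles of log2 ratio per occupancy stratum
    strata = [tuple(s) for s in ecfg["strata"]]
    sampled, shortfall = stratified_window_sample(
        table, strata=strata, seed=int(ecfg["seed"])
    )
    summary = (
        sampled.groupby("stratum")["log2_ratio"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
    )
    summary.to_csv(os.path.join(outdir, "stratum_summary.tsv"), sep="\t", index=False)
    # 50-bin metaregion profile of the per-bp log2(IP/control) track
    flank = int(ecfg["profile_flank"])
    mid = (sampled["start"] + sampled["end"]) // 2
    windows = sampled.assign(start=mid - flank, end=mid + flank)
    ip_cov = coverage_track(ip, chrom_sizes)
    ct_cov = coverage_track(control, chrom_sizes)
    track = {
        c: per_bp_log2_track(ip_cov[c], ct_cov[c], epsilon=1.0) for c in chrom_sizes
    }
    prof = profile_matrix(
        track, windows, nbins=int(ecfg["nbins"]), winsor=tuple(ecfg["winsor"])
    )
    prof_df = pd.DataFrame(
        prof.values, columns=[f"bin{j + 1}" for j in range(prof.values.shape[1])]
    )
    prof_df.insert(0, "stratum", prof.windows["stratum"].to_numpy())
    prof_df.to_csv(os.path.join(outdir, "profile_matrix.tsv"), sep="\t", index=False)
    if shortfall:
        logger.info("stratified sampling shortfalls: %s", shortfall)
    return table


def stage_methyl(cfg: Mapping, outdir: str, regions: pd.DataFrame) -> dict:
    paths = cfg["paths"]
    files = sorted(glob.glob(os.path.join(paths["methylation_dir"], "*.tsv")))
    if not files:
        raise FileNotFoundError(f"no methylation tables in {paths['methylation_dir']}")
    calls = {
        os.path.splitext(os.path.basename(f))[0]: hio.read_methylation_table(f)
        for f in files
    }
    hot = regions[regions["label"] == "HOT"].reset_index(drop=True)
    cgi = hio.read_bed(paths["cgi"])
    nonhot = nonhot_cgis(cgi, hot)
    hot_summary = summarize_region_set(calls, hot)
    nonhot_summary = summarize_region_set(calls, nonhot)
    hot_summary.assign(region_set="HOT").to_csv(
        os.path.join(outdir, "methylation_hot.tsv"), sep="\t", index=False
    )
    nonhot_summary.assign(region_set="nonHOT_CGI").to_csv(
        os.path.join(outdir, "methylation_nonhot_cgi.tsv"), sep="\t", index=False
    )
    table, ratio = hot_vs_nonhot_cgi(hot_summary, nonhot_summary)
    table.to_csv(os.path.join(outdir, "methylation_comparison.tsv"), sep="\t", index=False)
    out = {"iqr_ratio": ratio, "n_hot": len(hot), "n_nonhot_cgi": len(nonhot)}
    with open(os.path.join(outdir, "methylation_summary.json"), "w") as fh:
        json.dump(out, fh, indent=1)
    logger.info("methylation IQR ratio (nonHOT CGI / HOT): %.3g", ratio)
    return out


def run(cfg: Mapping) -> tuple[int, str]:
    """Run all stages whose inputs exist; return (exit status, manifest path)."""
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    _setup_logging(outdir)
    manifest = Manifest(outdir, cfg)
    paths = cfg["paths"]
    regions: pd.DataFrame | None = None
    status = 0

    def _run_stage(name, available, fn):
        nonlocal status
        if status != 0:
            manifest.record_stage(name, "not-run", 0.0)
            return None
        if not available:
            manifest.record_stage(name, "skipped", 0.0, reason="inputs absent")
            logger.info("stage %s skipped: inputs absent", name)
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage failure ends the run
            manifest.record_stage(
                name, "failed", time.perf_counter() - t0, error=str(exc)
            )
            logger.error("stage %s failed: %s", name, exc)
            status = 1
            return None
        manifest.record_stage(name, "ok", time.perf_counter() - t0)
        return result

    def _have(*keys: str) -> bool:
        return all(paths.get(k) and os.path.exists(paths[k]) for k in keys)

    regions = _run_stage("call", _have("peak_dir", "chrom_sizes"), lambda: stage_call(cfg, outdir))
    features = _run_stage(
        "features",
        regions is not None and _have("genome"),
        lambda: stage_features(cfg, outdir, regions),
    )
    _run_stage(
        "model",
        features is not None,
        lambda: stage_model(cfg, outdir, features),
    )
    _run_stage(
        "enrich",
        regions is not None and _have("ip_reads", "control_reads", "chrom_sizes"),
        lambda: stage_enrich(cfg, outdir, regions),
    )
    _run_stage(
        "methyl",
        regions is not None and _have("methylation_dir", "cgi"),
        lambda: stage_methyl(cfg, outdir, regions),
    )
    for root, _, files in os.walk(outdir):
        for f in sorted(files):
            p = os.path.join(root, f)
            if f not in ("manifest.json", "pipeline.log"):
                manifest.record_output(p)
    path = manifest.write()
    return status, path


def simulate(cfg: Mapping) -> tuple[str, dict]:
    """Generate a synthetic bundle; returns (bundle dir, config pointing at it)."""
    sim = dict(cfg.get("simulate") or {})
    seed = int(sim.pop("seed", 0))
    outdir = cfg["outdir"]
    valid = {f.name for f in dataclasses.fields(BundleParams)}
    unknown = set(sim) - valid
    if unknown:
        raise ValueError(f"unknown simulate parameters: {sorted(unknown)}")
    params = BundleParams(**{k: v for k, v in sim.items()})
    if params.n_experiments <= 0:
        raise ValueError("n_experiments must be positive")
    bundle_dir = os.path.join(outdir, "bundle")
    make_bundle(bundle_dir, seed=seed, params=params)
    run_cfg = json.loads(json.dumps(cfg))
    run_cfg["paths"] = {
        "peak_dir": os.path.join(bundle_dir, "peaks"),
        "genome": os.path.join(bundle_dir, "genome.fa"),
        "chrom_sizes": os.path.join(bundle_dir, "chrom.sizes"),
        "cgi": os.path.join(bundle_dir, "cgi.bed"),
        "ip_reads": os.path.join(bundle_dir, "ip.bed"),
        "control_reads": os.path.join(bundle_dir, "control.bed"),
        "methylation_dir": os.path.join(bundle_dir, "methylation"),
    }
    return bundle_dir, run_cfg


def _setup_logging(outdir: str) -> None:
    logger.setLevel(logging.INFO)
    have = {getattr(h, "_hotregions_tag", None) for h in logger.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        h._hotregions_tag = "stderr"
        logger.addHandler(h)
    logfile = os.path.abspath(os.path.join(outdir, "pipeline.log"))
    for h in list(logger.handlers):
        if getattr(h, "_hotregions_tag", None) == "file":
            logger.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    fh._hotregions_tag = "file"
    logger.addHandler(fh)
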