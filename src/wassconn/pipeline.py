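"""Staged pipeline: simulate/extract -> similarity/connectivity -> match ->
ensemble -> cam -> report.

Each stage reads and writes under one output directory; a manifest records
the validated config, per-stage input hashes, seeds and timings.  Exact
(deterministic) stages are idempotent: when their recorded input hash is
unchanged and their outputs exist, they are skipped and rerunning yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .config import RunConfig
from .encoding import Instance
from .features import (
    RegionalSampleSet,
    TimeseriesTable,
    extract_regional_samples,
    pearson_connectivity,
    regional_dropout_fraction,
    regional_mean_volumes,
)
from .matching import MatchConfig, match_controls, split_4_1_1, balance_report
from .nn import ModelSpec
from .similarity import structural_similarity_matrix, tile_vector

__all__ = ["run_pipeline", "OrderedStageError", "STAGE_ORDER"]

STAGE_ORDER = ("simulate", "extract", "similarity", "connectivity", "match",
               "ensemble", "cam", "report")
_DEPENDS = {
    "similarity": ("samples",),
    "connectivity": ("timeseries",),
    "match": ("covariates",),
    "ensemble": ("matrices", "covariates"),
    "cam": ("ensemble_result",),
    "report": (),
}


class OrderedStageError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


def _hash_paths(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(x) for x in paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _write_samples(out: Path, sample_sets: dict[str, RegionalSampleSet]) -> None:
    d = out / "samples"
    d.mkdir(parents=True, exist_ok=True)
    for sid, ss in sample_sets.items():
        rows = [
            {"region_id": rid, "value": float(v)}
            for rid, vals in ss.samples.items()
            for v in vals
        ]
        pd.DataFrame(rows, columns=["region_id", "value"]).to_csv(
            d / f"{sid}.tsv", sep="\t", index=False, float_format="%.10g"
        )


def _read_samples(out: Path) -> dict[str, RegionalSampleSet]:
    sets = {}
    for p in sorted((out / "samples").glob("*.tsv")):
        df = pd.read_csv(p, sep="\t")
        samples = {
            int(rid): g["value"].to_numpy()
            for rid, g in df.groupby("region_id")
        }
        sets[p.stem] = RegionalSampleSet(samples=samples, subject_ref=p.stem)
    return sets


def run_pipeline(cfg: RunConfig, stages, seed: int | None = None) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    stages = set(stages)
    unknown = stages - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = cfg.seed if seed is None else seed
    out = Path(cfg.paths.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("stages", {})
    manifest["config"] = cfg.model_dump()
    manifest["seed"] = seed
    ctx: dict = {}

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        skipped = _run_stage(stage, cfg, out, seed, ctx, manifest)
        entry = manifest["stages"].setdefault(stage, {})
        entry["skipped"] = bool(skipped)
        entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage, cfg: RunConfig, out: Path, seed, ctx, manifest) -> bool:
    if stage == "simulate":
        return _stage_simulate(cfg, out, seed, ctx, manifest)
    if stage == "extract":
        return _stage_extract(cfg, out, manifest)
    if stage == "similarity":
        return _stage_similarity(cfg, out, manifest)
    if stage == "connectivity":
        return _stage_connectivity(cfg, out, manifest)
    if stage == "match":
        return _stage_match(cfg, out, seed, manifest)
    if stage == "ensemble":
        return _stage_ensemble(cfg, out, seed, ctx, manifest)
    if stage == "cam":
        return _stage_cam(cfg, out, seed, ctx, manifest)
    if stage == "report":
        return _stage_report(out, manifest)
    raise AssertionError(stage)


def _stage_simulate(cfg, out, seed, ctx, manifest) -> bool:
    from .synthetic import SyntheticConfig, generate_cohort

    syn = cfg.synthetic
    scfg = SyntheticConfig(
        n_regions=syn.n_regions, n_cases=syn.n_cases, n_controls=syn.n_controls,
        planted_regions=tuple(syn.planted_regions),
        struct_effect=syn.struct_effect, func_effect=syn.func_effect,
        n_timepoints=syn.n_timepoints,
        match_yield_floor=syn.match_yield_floor, seed=seed,
    )
    cohort = generate_cohort(scfg)
    _write_samples(out, cohort.sample_sets)
    d = out / "timeseries"
    d.mkdir(exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        pd.DataFrame(ts.series.T, columns=[str(r) for r in ts.region_ids]).to_csv(
            d / f"{sid}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    wio.write_covariates_tsv(out / "covariates.tsv", cohort.records)
    (out / "synthetic_manifest.json").write_text(
        json.dumps(cohort.manifest, indent=2)
    )
    ctx["cohort"] = cohort
    manifest["stages"].setdefault("simulate", {})["seed"] = seed
    return False


def _stage_extract(cfg, out, manifest) -> bool:
    if not (cfg.paths.atlas and cfg.paths.grey_matter_dir):
        raise OrderedStageError(
            "extract requires paths.atlas and paths.grey_matter_dir"
        )
    from .features import GreyMatterMap

    gm_paths = sorted(Path(cfg.paths.grey_matter_dir).glob("*.nii*"))
    inputs_hash = _hash_paths([cfg.paths.atlas, *gm_paths])
    entry = manifest["stages"].get("extract", {})
    if entry.get("inputs_hash") == inputs_hash and (out / "samples").exists():
        return True
    atlas = wio.read_atlas(cfg.paths.atlas)
    sets = {}
    for p in gm_paths:
        sid = p.name.split(".")[0].removeprefix("gm_")
        gm = GreyMatterMap(values=wio.read_grey_matter(p))
        sets[sid] = extract_regional_samples(gm, atlas, subject_ref=sid)
    _write_samples(out, sets)
    manifest["stages"].setdefault("extract", {})["inputs_hash"] = inputs_hash
    return False


def _stage_similarity(cfg, out, manifest) -> bool:
    if not (out / "samples").exists():
        raise OrderedStageError("similarity requires the samples/ artifact "
                                "(run simulate or extract first)")
    sample_paths = sorted((out / "samples").glob("*.tsv"))
    inputs_hash = _hash_paths(sample_paths)
    entry = manifest["stages"].get("similarity", {})
    if entry.get("inputs_hash") == inputs_hash and (out / "structural").exists():
        return True
    d = out / "structural"
    d.mkdir(exist_ok=True)
    excluded = []
    univariate = {}
    for sid, ss in _read_samples(out).items():
        frac, excl = regional_dropout_fraction(ss)
        if excl:
            excluded.append({"subject_id": sid, "dropout_fraction": frac})
            continue
        sim = structural_similarity_matrix(ss)
        wio.write_matrix_tsv(d / f"{sid}.tsv", sim.values, sim.region_ids,
                             meta={"metric": "wasserstein_1d"})
        univariate[sid] = regional_mean_volumes(ss)
    if univariate:
        ids = next(iter(univariate.values())).region_ids
        df = pd.DataFrame(
            {sid: v.values for sid, v in univariate.items()},
            index=[str(r) for r in ids],
        )
        df.to_csv(out / "univariate.tsv", sep="\t", float_format="%.10g")
    (out / "structural_exclusions.json").write_text(json.dumps(excluded, indent=2))
    manifest["stages"].setdefault("similarity", {})["inputs_hash"] = inputs_hash
    return False


def _stage_connectivity(cfg, out, manifest) -> bool:
    if not (out / "timeseries").exists():
        raise OrderedStageError("connectivity requires the timeseries/ artifact")
    ts_paths = sorted((out / "timeseries").glob("*.tsv"))
    inputs_hash = _hash_paths(ts_paths)
    entry = manifest["stages"].get("connectivity", {})
    if entry.get("inputs_hash") == inputs_hash and (out / "functional").exists():
        return True
    d = out / "functional"
    d.mkdir(exist_ok=True)
    excluded = []
    for p in ts_paths:
        df = pd.read_csv(p, sep="\t")
        ts = TimeseriesTable(
            series=df.to_numpy().T, region_ids=tuple(int(c) for c in df.columns)
        )
        frac, excl = regional_dropout_fraction(ts)
        if excl:
            excluded.append({"subject_id": p.stem, "dropout_fraction": frac})
            continue
        fm = pearson_connectivity(ts)
        wio.write_matrix_tsv(d / f"{p.stem}.tsv", fm.values, fm.region_ids,
                             meta={"metric": "pearson"})
    (out / "functional_exclusions.json").write_text(json.dumps(excluded, indent=2))
    manifest["stages"].setdefault("connectivity", {})["inputs_hash"] = inputs_hash
    return False


def _stage_match(cfg, out, seed, manifest) -> bool:
    cov = out / "covariates.tsv"
    if cfg.paths.covariates:
        cov = Path(cfg.paths.covariates)
    if not cov.exists():
        raise OrderedStageError(f"match requires the covariate table {cov}")
    records = wio.read_covariates(cov)
    mc = MatchConfig(caliper_age=cfg.match.caliper_age,
                     caliper_fwd=cfg.match.caliper_fwd,
                     caliper_icv=cfg.match.caliper_icv, seed=seed)
    balanced = match_controls(
        [r for r in records if r.group == "case"],
        [r for r in records if r.group == "control"], mc,
    )
    split = split_4_1_1(balanced, records, seed=seed)
    d = out / "match"
    d.mkdir(exist_ok=True)
    pd.DataFrame(balanced.pairs, columns=["case_id", "control_id"]).to_csv(
        d / "pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(split.assignment.items()), columns=["subject_id", "set"]
    ).to_csv(d / "splits.tsv", sep="\t", index=False)
    report = balance_report(balanced, records)
    (d / "balance.json").write_text(json.dumps(
        {"seed": seed, "calipers": mc.__dict__, **report}, indent=2))
    return False


def _load_instances(out: Path, channels) -> tuple[dict[str, Instance], list]:
    records = wio.read_covariates(out / "covariates.tsv")
    group_of = {r.subject_id: r.group for r in records}
    instances = {}
    for rec in records:
        sid = rec.subject_id
        chans = {}
        ok = True
        for name, sub in (("structural", "structural"), ("functional", "functional")):
            if name not in channels:
                continue
            p = out / sub / f"{sid}.tsv"
            if not p.exists():
                ok = False
                break
            chans[name] = wio.read_matrix_tsv(p)[0]
        if "univariate" in channels and ok:
            uni = pd.read_csv(out / "univariate.tsv", sep="\t", index_col=0)
            if sid in uni.columns:
                chans["univariate"] = tile_vector(uni[sid].to_numpy()).values
            else:
                ok = False
        if not ok or any(np.isnan(m).any() for m in chans.values()):
            continue  # excluded upstream or missing entries: never imputed
        iid = rec.instance_ids[0]
        instances[iid] = Instance(instance_id=iid, subject_id=sid,
                                  channels=chans, label=group_of[sid])
    kept = {i.subject_id for i in instances.values()}
    return instances, [r for r in records if r.subject_id in kept]


def _stage_ensemble(cfg, out, seed, ctx, manifest) -> bool:
    from .ensemble import aggregate_auroc, run_ensemble

    channels = tuple(cfg.model.channels)
    for ch in channels:
        marker = {"structural": out / "structural", "functional": out / "functional",
                  "univariate": out / "univariate.tsv"}[ch]
        if not marker.exists():
            raise OrderedStageError(f"ensemble requires the {marker.name} artifact")
    instances, records = _load_instances(out, channels)
    spec = ModelSpec(
        n_filters=cfg.model.n_filters, dense_units=cfg.model.dense_units,
        n_dense=cfg.model.n_dense, dropout=cfg.model.dropout,
        epochs=cfg.model.epochs, batch_size=cfg.model.batch_size,
        learning_rate=cfg.model.learning_rate, seed=seed,
    )
    mc = MatchConfig(caliper_age=cfg.match.caliper_age,
                     caliper_fwd=cfg.match.caliper_fwd,
                     caliper_icv=cfg.match.caliper_icv, seed=seed)
    result = run_ensemble(records, instances, cfg.model.n_models, spec, mc,
                          seed=seed, channels=channels,
                          redraw_permutation=cfg.model.redraw_permutation)
    d = out / "ensemble"
    d.mkdir(exist_ok=True)
    result.predictions.to_csv(d / "predictions.tsv", sep="\t", index=False)
    labels_df = pd.DataFrame(
        sorted(result.labels.items()), columns=["instance_id", "label"]
    )
    labels_df.to_csv(d / "labels.tsv", sep="\t", index=False)
    auroc = aggregate_auroc(result.predictions, result.labels)
    (d / "run_manifest.json").write_text(
        json.dumps({"auroc": auroc, "channels": list(channels),
                    **result.manifest()}, indent=2)
    )
    ctx["ensemble_result"] = result
    ctx["instances"] = instances
    manifest["stages"].setdefault("ensemble", {})["auroc"] = auroc
    return False


def _stage_cam(cfg, out, seed, ctx, manifest) -> bool:
    from .saliency import (
        communities_by_modularity, edge_betweenness_matrix, ensemble_cam,
        hub_report,
    )

    if "ensemble_result" not in ctx:
        raise OrderedStageError(
            "cam requires the in-memory ensemble result: run the ensemble "
            "stage in the same invocation"
        )
    result = ctx["ensemble_result"]
    instances = ctx["instances"]
    channels = tuple(cfg.model.channels)
    cam = ensemble_cam(result, instances, channels=channels)
    d = out / "cam"
    d.mkdir(exist_ok=True)
    n = cam.n_regions
    ids = list(range(1, n + 1))
    wio.write_matrix_tsv(d / "cam.tsv", cam.values, ids,
                         meta={"n_contributions": cam.n_contributions})
    bw = edge_betweenness_matrix(cam)
    wio.write_matrix_tsv(d / "betweenness.tsv", bw, ids, meta={})
    part = communities_by_modularity(bw, seed=seed)
    hubs = hub_report(part, cam, k=cfg.saliency.top_k_hubs)
    (d / "hubs.json").write_text(json.dumps(
        {"modularity": part.modularity,
         "communities": {str(k): v for k, v in part.assignment.items()},
         "top_hubs": hubs.top_hubs}, indent=2))
    manifest["stages"].setdefault("cam", {})["top_hubs"] = hubs.top_hubs
    return False


def _stage_report(out, manifest) -> bool:
    summary = {"stages_run": sorted(manifest["stages"].keys())}
    for name in ("ensemble/run_manifest.json", "cam/hubs.json",
                 "match/balance.json", "synthetic_manifest.json"):
        p = out / name
        if p.exists():
            summary[name] = json.loads(p.read_text())
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    return False
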