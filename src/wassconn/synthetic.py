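"""Synthetic cohorts with known ground truth.

Generates everything the pipeline consumes — per-region voxel-value
distributions, region-averaged timeseries, matching covariates, and (for the
voxel-level path) NIfTI atlas + grey-matter volumes — with planted effects:

* structural: in designated regions, cases' voxel-value distributions are
  shifted (location mode) or reshaped mean-preservingly (shape mode) by a
  configurable multiple of the region's voxel-value s.d.;
* functional: cases gain extra shared latent-factor loading on designated
  region pairs;
* covariates: case-control offsets on age, motion and intracranial volume,
  plus sex and site imbalance, to exercise the matching scheme.

Every generator is a pure function of (config, seed): the same config
regenerates the cohort bit-exactly, and the manifest records the ground
truth (planted regions/edges, effect sizes, seed).

The base voxel-value law is a region-specific shifted gamma — right-skewed,
strictly positive, with shape varying across regions so that distributional
comparisons (not just means) carry signal.  It does not attempt to imitate
real MRI texture, smoothing, or scanner effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import RegionalSampleSet, TimeseriesTable
from .matching import MatchConfig, SubjectRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_covariates",
    "generate_structural",
    "generate_functional",
    "generate_cohort",
    "cohort_instances",
    "shuffle_group_labels",
    "emit_voxel_volumes",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``struct_effect`` is in units of the affected region's voxel-value
    standard deviation; ``func_effect`` is an extra latent loading (0 = no
    functional group difference).  Covariate offsets are case minus control
    means in natural units (years, mm, mm^3).
    """

    n_regions: int = 16
    voxels_per_region: tuple[int, int] = (60, 150)
    n_cases: int = 200
    n_controls: int = 200
    planted_regions: tuple[int, ...] = (1, 2)  # region ids, 1-based
    struct_effect: float = 1.5
    planted_mode: str = "shift"  # "shift" | "shape" (mean-preserving)
    planted_edges: tuple[tuple[int, int], ...] = ()
    func_effect: float = 0.0
    n_timepoints: int = 120
    n_factors: int = 4
    factor_loading: float = 0.6
    age_offset: float = 3.0
    fwd_offset: float = 0.03
    icv_offset: float = 50_000.0
    n_sites: int = 3
    male_fraction: float = 0.7
    match_yield_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 4")
        if not set(self.planted_regions) <= set(range(1, self.n_regions + 1)):
            raise ValueError("planted_regions must be region ids in 1..n_regions")
        if self.struct_effect < 0 or self.func_effect < 0:
            raise ValueError("effects must be >= 0")
        if self.planted_mode not in ("shift", "shape"):
            raise ValueError("planted_mode must be 'shift' or 'shape'")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        lo, hi = self.voxels_per_region
        if not (1 <= lo <= hi):
            raise ValueError("invalid voxels_per_region range")


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    records: list[SubjectRecord]
    sample_sets: dict[str, RegionalSampleSet]
    timeseries: dict[str, TimeseriesTable]

    @property
    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "planted_regions": list(self.config.planted_regions),
            "planted_edges": [list(e) for e in self.config.planted_edges],
            "struct_effect": self.config.struct_effect,
            "func_effect": self.config.func_effect,
            "seed": self.config.seed,
            "n_subjects": len(self.records),
        }


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _subject_ids(cfg: SyntheticConfig) -> list[tuple[str, str]]:
    ids = [(f"case_{i:04d}", "case") for i in range(cfg.n_cases)]
    ids += [(f"control_{i:04d}", "control") for i in range(cfg.n_controls)]
    return ids


def generate_covariates(cfg: SyntheticConfig) -> list[SubjectRecord]:
    """Subject records with configurable case-control confounds.

    Raises with diagnostics when the confound settings leave fewer than
    ``match_yield_floor`` of cases with any eligible control under the
    default calipers.
    """
    rng = _rng(cfg, 0)
    records = []
    for sid, group in _subject_ids(cfg):
        off = group == "case"
        age = max(1.0, rng.normal(30.0 + cfg.age_offset * off, 8.0))
        fwd = max(0.005, rng.normal(0.15 + cfg.fwd_offset * off, 0.08))
        icv = max(8e5, rng.normal(1.5e6 + cfg.icv_offset * off, 1.2e5))
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                sex="M" if rng.random() < cfg.male_fraction else "F",
                collection=f"site_{rng.integers(cfg.n_sites)}",
                age=float(age),
                mean_fwd=float(fwd),
                icv=float(icv),
                instance_ids=(f"{sid}_01",),
            )
        )
    _check_matchability(records, cfg)
    return records


def _check_matchability(records: list[SubjectRecord], cfg: SyntheticConfig) -> None:
    m = MatchConfig()
    cases = [r for r in records if r.group == "case"]
    controls = [r for r in records if r.group == "control"]
    icv_sd = np.std([r.icv for r in records], ddof=1)
    n_ok = 0
    for c in cases:
        for k in controls:
            if (
                k.sex == c.sex
                and k.collection == c.collection
                and abs(k.age - c.age) <= m.caliper_age
                and abs(k.mean_fwd - c.mean_fwd) <= m.caliper_fwd
                and abs(k.icv - c.icv) <= m.caliper_icv * icv_sd
            ):
                n_ok += 1
                break
    hit = n_ok / max(len(cases), 1)
    if hit < cfg.match_yield_floor:
        raise ValueError(
            f"confound settings leave only {hit:.0%} of cases with an eligible "
            f"control (floor {cfg.match_yield_floor:.0%}); reduce offsets or "
            f"widen calipers"
        )


def generate_structural(cfg: SyntheticConfig) -> dict[str, RegionalSampleSet]:
    """Per-subject regional voxel-value multisets with planted group shifts.

    Region r's base law: value = loc + Gamma(shape_r, theta_r), with
    region-specific location, scale and shape drawn once per cohort, plus a
    per-subject location jitter (s.d. 0.3 x region scale) giving
    within-group variability.  Cases in planted regions get, per
    ``planted_mode``, either a location shift of struct_effect pooled
    between-subject standard deviations (pooled across regions, so every
    planted region carries the same standardized effect regardless of its
    own nuisance scale) or a mean-preserving reshaping of the gamma law.
    """
    region_rng = _rng(cfg, 1)
    n = cfg.n_regions
    loc = region_rng.uniform(0.05, 0.25, size=n)
    scale = region_rng.uniform(0.05, 0.15, size=n)
    shape = region_rng.uniform(2.0, 5.0, size=n)
    theta = scale / np.sqrt(shape)  # gamma s.d. = sqrt(shape) * theta = scale
    jitter_sd = 0.3 * scale
    pooled_sd = float(np.sqrt(np.mean(jitter_sd**2)))  # one unit per cohort
    planted = np.array([r - 1 for r in cfg.planted_regions], dtype=int)

    rng = _rng(cfg, 2)
    lo, hi = cfg.voxels_per_region
    out: dict[str, RegionalSampleSet] = {}
    for sid, group in _subject_ids(cfg):
        samples: dict[int, np.ndarray] = {}
        jitter = rng.normal(0.0, jitter_sd)
        for r in range(n):
            n_vox = int(rng.integers(lo, hi + 1))
            sh, th = shape[r], theta[r]
            extra = 0.0
            if group == "case" and r in planted and cfg.struct_effect > 0:
                if cfg.planted_mode == "shift":
                    extra = cfg.struct_effect * pooled_sd
                else:  # mean-preserving: same mean, inflated spread/skew
                    sh = shape[r] / (1.0 + cfg.struct_effect)
                    th = theta[r] * (1.0 + cfg.struct_effect)
            vals = loc[r] + jitter[r] + extra + rng.gamma(sh, th, size=n_vox)
            samples[r + 1] = np.maximum(vals, 1e-6)  # strictly positive
        out[sid] = RegionalSampleSet(samples=samples, subject_ref=sid)
    return out


def generate_functional(cfg: SyntheticConfig) -> dict[str, TimeseriesTable]:
    """Per-subject region x time tables from a block latent-factor model.

    Regions are split into ``n_factors`` contiguous blocks; each region
    loads on its block factor with ``factor_loading`` plus unit noise.  With
    ``func_effect`` > 0, cases gain an extra shared factor on each planted
    edge's two regions, raising their correlation.
    """
    rng = _rng(cfg, 3)
    n, t = cfg.n_regions, cfg.n_timepoints
    block = np.arange(n) * cfg.n_factors // n
    region_ids = tuple(range(1, n + 1))
    out: dict[str, TimeseriesTable] = {}
    for sid, group in _subject_ids(cfg):
        factors = rng.standard_normal((cfg.n_factors, t))
        series = cfg.factor_loading * factors[block] + rng.standard_normal((n, t))
        if group == "case" and cfg.func_effect > 0:
            for i, j in cfg.planted_edges:
                shared = rng.standard_normal(t)
                series[i - 1] += cfg.func_effect * shared
                series[j - 1] += cfg.func_effect * shared
        out[sid] = TimeseriesTable(series=series, region_ids=region_ids)
    return out


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Full cohort: covariates + structural samples + functional timeseries."""
    return SyntheticCohort(
        config=cfg,
        records=generate_covariates(cfg),
        sample_sets=generate_structural(cfg),
        timeseries=generate_functional(cfg),
    )


def cohort_instances(
    cohort: SyntheticCohort,
    include: tuple[str, ...] = ("structural", "functional", "univariate"),
    records: list[SubjectRecord] | None = None,
):
    """Build classifier instances (channel stacks) from a synthetic cohort.

    Computes, per subject, the structural similarity matrix, the Pearson
    functional matrix and/or the tiled univariate volume matrix.  ``records``
    may override the cohort's own (e.g. after label shuffling) to relabel
    instances.  Returns {instance_id: Instance}.
    """
    from .encoding import Instance
    from .features import pearson_connectivity, regional_mean_volumes
    from .similarity import structural_similarity_matrix, tile_vector

    recs = records if records is not None else cohort.records
    group_of = {r.subject_id: r.group for r in recs}
    instances: dict[str, Instance] = {}
    for rec in recs:
        sid = rec.subject_id
        channels: dict[str, np.ndarray] = {}
        if "structural" in include:
            channels["structural"] = structural_similarity_matrix(
                cohort.sample_sets[sid]
            ).values
        if "functional" in include:
            channels["functional"] = pearson_connectivity(
                cohort.timeseries[sid]
            ).values
        if "univariate" in include:
            channels["univariate"] = tile_vector(
                regional_mean_volumes(cohort.sample_sets[sid])
            ).values
        iid = rec.instance_ids[0]
        instances[iid] = Instance(
            instance_id=iid, subject_id=sid, channels=channels,
            label=group_of[sid],
        )
    return instances


def shuffle_group_labels(
    records: list[SubjectRecord], seed: int
) -> list[SubjectRecord]:
    """Permute group labels across subjects (null-model cohorts)."""
    rng = np.random.default_rng(seed)
    groups = [r.group for r in records]
    perm = rng.permutation(len(groups))
    return [
        SubjectRecord(
            subject_id=r.subject_id, group=groups[perm[i]], sex=r.sex,
            collection=r.collection, age=r.age, mean_fwd=r.mean_fwd,
            icv=r.icv, instance_ids=r.instance_ids,
        )
        for i, r in enumerate(records)
    ]


def emit_voxel_volumes(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    grid_size: int = 16,
    subjects: list[str] | None = None,
):
    """Write a NIfTI label atlas and per-subject grey-matter maps.

    Each region gets a contiguous block of voxels (compact parcels on a
    ``grid_size``^3 grid, background label 0); each subject map places the
    subject's regional sample values into its parcel's voxels, so a round
    trip through ``extract_regional_samples`` reproduces the samples as
    multisets.  Returns (atlas_path, {subject_id: map_path}).
    """
    import nibabel as nib

    cfg = cohort.config
    if grid_size > 32:
        raise ValueError("grid_size must be <= 32 (fixture-scale only)")
    n_vox = grid_size**3
    capacity = n_vox // (cfg.n_regions + 1)  # +1 keeps some background
    if capacity < cfg.voxels_per_region[1]:
        raise ValueError(
            f"grid {grid_size}^3 too small for {cfg.n_regions} regions of up "
            f"to {cfg.voxels_per_region[1]} voxels"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.zeros(n_vox, dtype=np.int32)
    starts = {}
    for r in range(cfg.n_regions):
        start = r * capacity
        labels[start : start + capacity] = r + 1
        starts[r + 1] = start
    atlas_img = nib.Nifti1Image(labels.reshape((grid_size,) * 3), np.eye(4))
    atlas_path = out_dir / "atlas.nii.gz"
    nib.save(atlas_img, atlas_path)

    map_paths = {}
    todo = subjects if subjects is not None else list(cohort.sample_sets)
    for sid in todo:
        vol = np.zeros(n_vox, dtype=np.float32)
        for rid, vals in cohort.sample_sets[sid].samples.items():
            vol[starts[rid] : starts[rid] + vals.size] = vals
        img = nib.Nifti1Image(vol.reshape((grid_size,) * 3), np.eye(4))
        path = out_dir / f"gm_{sid}.nii.gz"
        nib.save(img, path)
        map_paths[sid] = path
    return atlas_path, map_paths
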