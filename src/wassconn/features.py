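"""Regional feature extraction from labelled grey-matter volumes and fMRI timeseries.

Turns voxel-level inputs into the per-region objects the rest of the pipeline
consumes: multisets of nonzero grey-matter voxel values (one per atlas region),
univariate mean-volume vectors, region-averaged timeseries and Pearson
functional connectivity matrices.  Also applies the regional-dropout exclusion
rule (instances with strictly more than 10% of regions empty or constant are
excluded).

Conventions
-----------
* "Nonzero" means strictly positive: zeros are background and negative values
  (possible after interpolation of probability maps) are treated as background.
* Region order everywhere is ascending region id; all matrices inherit it.
* Missing entries (dropout regions) are represented as ``numpy.nan`` and are
  never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RegionAtlas",
    "GreyMatterMap",
    "RegionalSampleSet",
    "TimeseriesTable",
    "FunctionalMatrix",
    "VolumeVector",
    "GridIncompatibilityError",
    "InvalidAtlasError",
    "InsufficientDataError",
    "DROPOUT_THRESHOLD",
    "extract_regional_samples",
    "regional_mean_volumes",
    "average_regional_timeseries",
    "pearson_connectivity",
    "regional_dropout_fraction",
]

#: Fraction of dropped regions above which (strictly) an instance is excluded.
DROPOUT_THRESHOLD = 0.10


class GridIncompatibilityError(ValueError):
    """Voxel grids of two inputs do not share a shape."""


class InvalidAtlasError(ValueError):
    """Atlas volume carries no usable region labels."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True)
class RegionAtlas:
    """Integer-labelled parcellation volume.

    Parameters
    ----------
    label_volume : 3-D integer array, 0 = background.
    region_names : optional mapping region id -> name.
    affine : optional 4x4 voxel-to-world transform (recorded, not used).
    """

    label_volume: np.ndarray
    region_names: Mapping[int, str] | None = None
    affine: np.ndarray | None = None
    region_ids: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_volume)
        if lab.ndim != 3:
            raise InvalidAtlasError(f"atlas must be 3-D, got ndim={lab.ndim}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise InvalidAtlasError("atlas labels must be integers")
        ids = np.unique(lab)
        ids = ids[ids > 0]
        if ids.size < 2:
            raise InvalidAtlasError(
                f"atlas must contain at least 2 regions, found {ids.size}"
            )
        object.__setattr__(self, "label_volume", lab)
        object.__setattr__(self, "region_ids", tuple(int(i) for i in ids))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_volume.shape

    def name_of(self, region_id: int) -> str:
        if self.region_names and region_id in self.region_names:
            return self.region_names[region_id]
        return f"region_{region_id}"


@dataclass(frozen=True)
class GreyMatterMap:
    """Voxelwise grey-matter volume/probability estimates on an atlas grid."""

    values: np.ndarray
    kind: str = "unspecified"  # "modulated_volume" | "probability" | "unspecified"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"grey-matter map must be 3-D, got ndim={v.ndim}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RegionalSampleSet:
    """Per-region multisets of strictly positive grey-matter voxel values.

    ``samples[region_id]`` is the empirical distribution u (or v) entering the
    Wasserstein comparison; an empty array marks regional dropout.
    """

    samples: Mapping[int, np.ndarray]
    subject_ref: str = ""

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for rid, vals in self.samples.items():
            arr = np.asarray(vals, dtype=float).ravel()
            if arr.size and not np.all(arr > 0):
                raise ValueError(f"region {rid}: retained values must be > 0")
            clean[int(rid)] = arr
        object.__setattr__(self, "samples", dict(sorted(clean.items())))

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(self.samples.keys())

    @property
    def n_regions(self) -> int:
        return len(self.samples)

    def empty_regions(self) -> tuple[int, ...]:
        return tuple(r for r, v in self.samples.items() if v.size == 0)


@dataclass(frozen=True)
class TimeseriesTable:
    """Region x timepoint matrix of region-averaged BOLD signal."""

    series: np.ndarray
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2:
            raise ValueError("series must be 2-D (regions x timepoints)")
        if s.shape[1] < 2:
            raise InsufficientDataError("need at least 2 timepoints")
        if s.shape[0] != len(self.region_ids):
            raise ValueError("row count must match region_ids")
        object.__setattr__(self, "series", s)
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))

    def dropout_rows(self) -> np.ndarray:
        """Boolean mask of all-constant (zero-variance) rows, NaN rows included."""
        s = self.series
        const = np.nanstd(s, axis=1) == 0
        allnan = np.all(np.isnan(s), axis=1)
        return const | allnan


@dataclass(frozen=True)
class FunctionalMatrix:
    """Symmetric Pearson connectivity matrix; dropout rows/cols are NaN."""

    values: np.ndarray
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("functional matrix must be square")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class VolumeVector:
    """Per-region mean of nonzero grey-matter voxel values; NaN = dropout."""

    values: np.ndarray
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.region_ids):
            raise ValueError("values must be 1-D and aligned to region_ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))


def extract_regional_samples(
    gm: GreyMatterMap, atlas: RegionAtlas, subject_ref: str = ""
) -> RegionalSampleSet:
    """Collect, per atlas region, the strictly positive voxel values of ``gm``.

    Zero and negative voxels are excluded; an empty result for a region marks
    dropout.  Output order of values within a region is unspecified
    (distributions are order-free multisets).
    """
    if gm.values.shape != atlas.shape:
        raise GridIncompatibilityError(
            f"grey-matter grid {gm.values.shape} != atlas grid {atlas.shape}"
        )
    lab = atlas.label_volume.ravel()
    val = gm.values.ravel()
    samples: dict[int, np.ndarray] = {}
    for rid in atlas.region_ids:
        v = val[lab == rid]
        samples[rid] = v[v > 0]
    return RegionalSampleSet(samples=samples, subject_ref=subject_ref)


def regional_mean_volumes(samples: RegionalSampleSet) -> VolumeVector:
    """Arithmetic mean of each region's nonzero voxel values (NaN if empty)."""
    vals = np.array(
        [s.mean() if s.size else np.nan for s in samples.samples.values()]
    )
    return VolumeVector(values=vals, region_ids=samples.region_ids)


def average_regional_timeseries(
    fmri: np.ndarray, atlas: RegionAtlas
) -> TimeseriesTable:
    """Average a 4-D (x, y, z, t) volume within each atlas region.

    Empty regions yield all-NaN rows (dropout).
    """
    fmri = np.asarray(fmri, dtype=float)
    if fmri.ndim != 4:
        raise ValueError(f"fMRI volume must be 4-D, got ndim={fmri.ndim}")
    if fmri.shape[:3] != atlas.shape:
        raise GridIncompatibilityError(
            f"fMRI spatial grid {fmri.shape[:3]} != atlas grid {atlas.shape}"
        )
    n_t = fmri.shape[3]
    lab = atlas.label_volume.ravel()
    flat = fmri.reshape(-1, n_t)
    rows = np.full((atlas.n_regions, n_t), np.nan)
    for i, rid in enumerate(atlas.region_ids):
        mask = lab == rid
        if mask.any():
            rows[i] = flat[mask].mean(axis=0)
    return TimeseriesTable(series=rows, region_ids=atlas.region_ids)


def pearson_connectivity(ts: TimeseriesTable) -> FunctionalMatrix:
    """Pearson correlation between region-averaged timeseries.

    Constant (zero-variance) rows are dropout: their row and column are NaN.
    The diagonal is 1 for valid regions.
    """
    s = ts.series
    if s.shape[1] < 3:
        raise InsufficientDataError(
            f"need >= 3 timepoints for Pearson correlation, got {s.shape[1]}"
        )
    bad = ts.dropout_rows()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(s)
    r = np.asarray(r, dtype=float)
    r = (r + r.T) / 2.0  # enforce exact symmetry against fp asymmetry
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    return FunctionalMatrix(values=r, region_ids=ts.region_ids)


def regional_dropout_fraction(
    x: RegionalSampleSet | TimeseriesTable,
) -> tuple[float, bool]:
    """Dropout fraction and exclusion flag.

    For structural samples a dropped region is an empty one; for timeseries a
    zero-variance row.  The exclusion flag is True iff the fraction strictly
    exceeds :data:`DROPOUT_THRESHOLD`.
    """
    if isinstance(x, RegionalSampleSet):
        n_bad = len(x.empty_regions())
        n = x.n_regions
    elif isinstance(x, TimeseriesTable):
        n_bad = int(x.dropout_rows().sum())
        n = x.series.shape[0]
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported input type {type(x)!r}")
    frac = n_bad / n
    return frac, frac > DROPOUT_THRESHOLD
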