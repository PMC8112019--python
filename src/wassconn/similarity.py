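"""Single-participant structural similarity via the 1-D Wasserstein distance.

The core idea: for one subject, compare every pair of atlas regions by the
Wasserstein-1 (Earth-Mover's) distance between their empirical distributions
of nonzero grey-matter voxel values.  The resulting symmetric region x region
matrix plays the role a connectivity matrix plays for fMRI, but is computable
from a single T1 image.  Note the matrix is distance-valued: larger entries
mean *less* similar regions; no inversion or normalisation is applied.

The distance between two empirical samples u, v is the closed form

    W1(u, v) = integral over x of |F_u(x) - F_v(x)| dx

where F_u, F_v are the empirical CDFs.  This attains the optimal-transport
infimum over all couplings of u and v, handles unequal sample sizes without
binning, and reduces to the mean absolute difference of aligned order
statistics when |u| = |v|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import FunctionalMatrix, InsufficientDataError, RegionalSampleSet

__all__ = [
    "SimilarityMatrix",
    "TiledMatrix",
    "PairingTestResult",
    "UndefinedDistributionError",
    "wasserstein_1d",
    "structural_similarity_matrix",
    "tile_vector",
    "matrix_correlation",
    "paired_vs_random_test",
]


class UndefinedDistributionError(ValueError):
    """An empirical distribution with no observations has no distance."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric region x region matrix of pairwise Wasserstein distances.

    Entries for pairs involving a dropout (empty) region are NaN.
    """

    values: np.ndarray
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TiledMatrix:
    """Univariate volume vector repeated into a square matrix.

    Row orientation: entry (i, j) = vec[j], so every row carries the full
    regional profile (each row-spanning convolution window sees all regions).
    Column orientation is available via ``orientation="columns"``.
    """

    values: np.ndarray
    region_ids: tuple[int, ...]
    orientation: str = "rows"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))


@dataclass(frozen=True)
class PairingTestResult:
    """Matched vs mismatched structure/function correlation comparison."""

    matched_r: np.ndarray
    random_r: np.ndarray
    t_statistic: float
    p_value: float
    n_pairs: int
    seed: int


def wasserstein_1d(u, v) -> float:
    """Wasserstein-1 distance between the empirical distributions of u and v.

    Computed by the pooled-order-statistic closed form: sort the union of
    sample values, and integrate |F_u - F_v| over the segments between
    consecutive pooled values.  Symmetric, translation-invariant and
    positively homogeneous; equals the optimal-transport cost.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size == 0 or v.size == 0:
        raise UndefinedDistributionError("empirical distribution with no values")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("sample values must be finite")
    us = np.sort(u)
    vs = np.sort(v)
    pooled = np.sort(np.concatenate([us, vs]))
    if pooled[0] == pooled[-1]:
        return 0.0
    x = pooled[:-1]
    dx = np.diff(pooled)
    # empirical CDFs evaluated on the left endpoints of the pooled segments
    cdf_u = np.searchsorted(us, x, side="right") / us.size
    cdf_v = np.searchsorted(vs, x, side="right") / vs.size
    return float(np.sum(np.abs(cdf_u - cdf_v) * dx))


def structural_similarity_matrix(samples: RegionalSampleSet) -> SimilarityMatrix:
    """Pairwise Wasserstein distances between all regional voxel distributions.

    Diagonal is 0; pairs involving an empty region are NaN.  Raises if every
    region is empty.
    """
    ids = samples.region_ids
    n = len(ids)
    arrs = [samples.samples[r] for r in ids]
    if all(a.size == 0 for a in arrs):
        raise UndefinedDistributionError("all regions empty: no structural data")
    out = np.zeros((n, n))
    for i in range(n):
        if arrs[i].size == 0:
            out[i, :] = np.nan
            out[:, i] = np.nan
    for i in range(n):
        if arrs[i].size == 0:
            continue
        for j in range(i + 1, n):
            if arrs[j].size == 0:
                continue
            d = wasserstein_1d(arrs[i], arrs[j])
            out[i, j] = d
            out[j, i] = d
    for i in range(n):
        if arrs[i].size:
            out[i, i] = 0.0
    return SimilarityMatrix(values=out, region_ids=ids)


def tile_vector(vec, region_ids=None, orientation: str = "rows") -> TiledMatrix:
    """Repeat a univariate per-region vector into a square matrix.

    Matches the dimensionality of the connectivity matrices so the univariate
    channel can enter the same encoder.  Raises on missing (NaN) entries.
    """
    from .features import VolumeVector

    if isinstance(vec, VolumeVector):
        region_ids = vec.region_ids
        vec = vec.values
    v = np.asarray(vec, dtype=float).ravel()
    if region_ids is None:
        region_ids = tuple(range(1, v.size + 1))
    if np.isnan(v).any():
        raise ValueError("vector has missing entries; cannot tile")
    if orientation == "rows":
        m = np.tile(v, (v.size, 1))
    elif orientation == "columns":
        m = np.tile(v[:, None], (1, v.size))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return TiledMatrix(values=m, region_ids=region_ids, orientation=orientation)


def _upper_triangle_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def matrix_correlation(a, b, method: str = "pearson") -> tuple[float, float]:
    """Correlation of two symmetric matrices over their strict upper triangles.

    Missing (NaN) cells are dropped pairwise.  Returns (r, p).
    """
    a = np.asarray(getattr(a, "values", a), dtype=float)
    b = np.asarray(getattr(b, "values", b), dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and share a shape")
    x, y = _upper_triangle_pair(a, b)
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 valid cell pairs, got {x.size}"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("constant matrix: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def paired_vs_random_test(
    structs, funcs, n_pairs: int, seed: int, method: str = "pearson"
) -> PairingTestResult:
    """Do structure and function share information, beyond chance pairing?

    Draws ``n_pairs`` same-instance (matched) structure/function pairs and
    ``n_pairs`` mismatched pairs, both with replacement, correlates each pair
    over the upper triangle, and compares the two sets of correlations with
    Welch's two-sample t-test (two-sided).

    Note that with replacement the draws resample a finite pool of instances,
    so ``n_pairs`` far in excess of the instance count inflates the effective
    sample size of the t-test; keep ``n_pairs`` comparable to the number of
    instances for a calibrated null.
    """
    if n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {n_pairs}")
    if len(structs) != len(funcs) or len(structs) < 2:
        raise ValueError("need >= 2 index-aligned instances")
    rng = np.random.default_rng(seed)
    n = len(structs)
    matched_idx = rng.integers(0, n, size=n_pairs)
    matched_r = np.array(
        [matrix_correlation(structs[i], funcs[i], method)[0] for i in matched_idx]
    )
    random_r = np.empty(n_pairs)
    for k in range(n_pairs):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1  # uniform over indices != i
        random_r[k] = matrix_correlation(structs[i], funcs[j], method)[0]
    t, p = stats.ttest_ind(matched_r, random_r, equal_var=False)
    return PairingTestResult(
        matched_r=matched_r,
        random_r=random_r,
        t_statistic=float(t),
        p_value=float(p),
        n_pairs=n_pairs,
        seed=seed,
    )
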