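"""Scrambled-rectangle encoding of symmetric connectivity matrices.

A symmetric n x n matrix with an uninformative diagonal has n(n-1)/2 unique
entries.  Those entries are laid out, in a seeded uniformly random order, into
an (n-1) x (n/2) rectangle fed to the CNN (115 x 58 for the 116-region
atlas).  Scrambling discards spatial adjacency on purpose: saliency maps then
cannot inherit spatial biases from convolution geometry, while the
convolution itself keeps its regularising effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EdgePermutation", "encode_instance", "decode_rectangle", "Instance"]


@dataclass(frozen=True)
class EdgePermutation:
    """Seeded bijection between unordered region pairs and rectangle cells.

    ``pair_index[r, c]`` gives, for rectangle cell (r, c), the index of the
    region pair in the canonical upper-triangle (row-major) enumeration;
    ``rows``/``cols`` hold the corresponding (i, j) region indices per cell.
    """

    n_regions: int
    seed: int
    pair_index: np.ndarray = field(init=False, repr=False)
    rows_i: np.ndarray = field(init=False, repr=False)
    rows_j: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.n_regions
        if n < 4 or n % 2 != 0:
            raise ValueError(
                f"n_regions must be even and >= 4 for an (n-1) x (n/2) "
                f"rectangle, got {n}; pad the atlas with an extra region "
                f"if the parcellation is odd"
            )
        n_pairs = n * (n - 1) // 2
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n_pairs)
        iu = np.triu_indices(n, k=1)
        shape = self.rect_shape
        object.__setattr__(self, "pair_index", perm.reshape(shape))
        object.__setattr__(self, "rows_i", iu[0][perm].reshape(shape))
        object.__setattr__(self, "rows_j", iu[1][perm].reshape(shape))

    @property
    def rect_shape(self) -> tuple[int, int]:
        return (self.n_regions - 1, self.n_regions // 2)

    @property
    def n_pairs(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def encode_matrix(self, m: np.ndarray) -> np.ndarray:
        """Scramble one symmetric matrix into the rectangle."""
        m = np.asarray(m, dtype=float)
        n = self.n_regions
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        return m[self.rows_i, self.rows_j]

    def decode_rectangle(self, rect: np.ndarray) -> np.ndarray:
        """Back-project a rectangle to a symmetric matrix (zero diagonal)."""
        rect = np.asarray(rect, dtype=float)
        if rect.shape != self.rect_shape:
            raise ValueError(f"rectangle shape {rect.shape} != {self.rect_shape}")
        n = self.n_regions
        out = np.zeros((n, n))
        out[self.rows_i, self.rows_j] = rect
        out[self.rows_j, self.rows_i] = rect
        return out


@dataclass(frozen=True)
class Instance:
    """One subject-scan's stack of channel matrices plus label.

    Channels are drawn from {"structural", "functional", "univariate",
    "covariate"}; all must be symmetric, share the region order and contain
    no missing entries (instances with missing data are excluded upstream,
    never imputed).
    """

    instance_id: str
    subject_id: str
    channels: dict[str, np.ndarray]
    label: str  # "case" | "control"

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ValueError(f"label must be case/control, got {self.label!r}")
        if not self.channels:
            raise ValueError("instance needs at least one channel")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def n_regions(self) -> int:
        return next(iter(self.channels.values())).shape[0]


def encode_instance(
    inst: Instance, perm: EdgePermutation, channel_order: tuple[str, ...] | None = None
) -> np.ndarray:
    """Encode an instance into a (rows, cols, channels) rectangle stack.

    The diagonal is never encoded.  Raises on any missing (NaN) entry.
    """
    names = channel_order or tuple(sorted(inst.channels))
    rects = []
    for name in names:
        m = np.asarray(inst.channels[name], dtype=float)
        # tiled univariate channels are not symmetric; symmetrise the edge
        # value as the mean of (i,j) and (j,i) so every channel shares the
        # unordered-pair semantics of the rectangle
        if not np.allclose(m, m.T, equal_nan=True):
            m = (m + m.T) / 2.0
        if np.isnan(m).any():
            raise ValueError(
                f"instance {inst.instance_id}: channel {name!r} has missing entries"
            )
        rects.append(perm.encode_matrix(m))
    return np.stack(rects, axis=-1)


def decode_rectangle(rect: np.ndarray, perm: EdgePermutation) -> np.ndarray:
    """Module-level convenience for :meth:`EdgePermutation.decode_rectangle`."""
    return perm.decode_rectangle(rect)
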