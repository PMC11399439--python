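"""Per-channel particle point clouds and pairwise distances.

A multi-color coordinate dataset is an ordered list of per-channel point
clouds X^(1), ..., X^(k).  Channels are referred to by the letters
A, B, C, ... in chain order.  Distances between adjacent channels default
to Euclidean but can be overridden by explicit user-supplied matrices, as
produced e.g. by segmentation tools that define their own particle-to-
particle proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

CHANNEL_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def channel_name(j: int) -> str:
    """Letter label of channel index ``j`` (0 -> 'A')."""
    return CHANNEL_LETTERS[j]


def span_name(span: tuple[int, int]) -> str:
    """Structure label of a contiguous channel span, e.g. (0, 2) -> 'ABC'."""
    j0, j1 = span
    return CHANNEL_LETTERS[j0 : j1 + 1]


@dataclass
class PointCloudSet:
    """Ordered per-channel particle coordinates.

    Parameters
    ----------
    clouds
        One ``(n_j, d)`` float array per channel, ``d`` in {2, 3}.  All
        channels must share dimensionality.
    unit
        ``"px"`` or ``"nm"``; purely declarative, distances are computed in
        this unit.
    pixel_size_nm
        Physical pixel size; required only to convert between units.
    distance_matrices
        Optional explicit distances for adjacent channel pairs, keyed by
        ``(j, j+1)``; each of shape ``(n_j, n_{j+1})``, nonnegative.  When
        present for a pair it overrides the Euclidean distance.
    """

    clouds: list[np.ndarray]
    unit: str = "px"
    pixel_size_nm: float | None = None
    distance_matrices: dict[tuple[int, int], np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.clouds) < 2:
            raise ValueError("need at least two channels")
        if self.unit not in ("px", "nm"):
            raise ValueError(f"unit must be 'px' or 'nm', got {self.unit!r}")
        cleaned = []
        dim = None
        for j, cloud in enumerate(self.clouds):
            arr = np.asarray(cloud, dtype=float)
            if arr.size == 0:
                arr = arr.reshape(0, dim if dim is not None else 2)
            if arr.ndim != 2 or arr.shape[1] not in (2, 3):
                raise ValueError(
                    f"channel {channel_name(j)}: expected (n, 2) or (n, 3) "
                    f"coordinates, got shape {arr.shape}"
                )
            if dim is None and arr.shape[0] > 0:
                dim = arr.shape[1]
            elif dim is not None and arr.shape[0] > 0 and arr.shape[1] != dim:
                raise ValueError(
                    f"channel {channel_name(j)} has dimensionality "
                    f"{arr.shape[1]}, expected {dim}"
                )
            cleaned.append(arr)
        self.clouds = cleaned
        if self.distance_matrices is not None:
            for (j0, j1), mat in self.distance_matrices.items():
                if j1 != j0 + 1:
                    raise ValueError("distance matrices only for adjacent channel pairs")
                mat = np.asarray(mat, dtype=float)
                expected = (self.counts[j0], self.counts[j1])
                if mat.shape != expected:
                    raise ValueError(
                        f"distance matrix for pair ({j0},{j1}) has shape "
                        f"{mat.shape}, expected {expected}"
                    )
                if np.any(mat < 0):
                    raise ValueError("distance matrices must be nonnegative")
                self.distance_matrices[(j0, j1)] = mat

    @property
    def k(self) -> int:
        return len(self.clouds)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.clouds)

    @property
    def dim(self) -> int:
        for c in self.clouds:
            if len(c):
                return c.shape[1]
        return 2

    def subset(self, keep: list[np.ndarray]) -> "PointCloudSet":
        """Restrict to per-channel boolean masks ``keep`` (no distance matrices)."""
        sub = [c[m] for c, m in zip(self.clouds, keep)]
        dmats = None
        if self.distance_matrices is not None:
            dmats = {
                (j0, j1): mat[np.ix_(keep[j0], keep[j1])]
                for (j0, j1), mat in self.distance_matrices.items()
            }
        return PointCloudSet(sub, unit=self.unit, pixel_size_nm=self.pixel_size_nm,
                             distance_matrices=dmats)


def pairwise_distances(clouds: PointCloudSet, pair: tuple[int, int]) -> np.ndarray:
    """Distance matrix between the two channels of an adjacent pair.

    Returns the user-supplied matrix when one was given for ``pair``,
    otherwise Euclidean distances in the cloud's declared unit.
    """
    j0, j1 = pair
    if j1 != j0 + 1:
        raise ValueError(f"pair {pair} is not an adjacent channel pair")
    if not (0 <= j0 < clouds.k - 1):
        raise ValueError(f"pair {pair} out of range for k={clouds.k}")
    if clouds.distance_matrices is not None and pair in clouds.distance_matrices:
        return clouds.distance_matrices[pair]
    a, b = clouds.clouds[j0], clouds.clouds[j1]
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    return cdist(a, b)
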