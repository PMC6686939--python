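"""D-dimensional pooling grids for multiplexed mutation screening.

Individuals are arrayed in a ``pools_per_dim ** n_dims`` grid (the study
design is 16x16x16: 4096 plants, 48 pools of 256, each plant in exactly
three pools, one per dimension).  A variant observed in exactly one pool
of every dimension identifies its carrier: the coordinate tuple is a
bijection onto sample indices.

Conventions (fixed, deterministic):

* sample index is row-major over coordinates:
  ``index = sum(c_d * pools_per_dim ** (n_dims - 1 - d))``;
* global pool IDs are 1-based and dimension-major: pools
  ``1..pools_per_dim`` are dimension 1, the next block dimension 2, etc.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PoolingDesign",
    "build_design",
    "pools_for_sample",
    "resolve_sample",
]


@dataclass(frozen=True)
class PoolingDesign:
    n_dims: int
    pools_per_dim: int

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError(f"n_dims must be >= 1, got {self.n_dims}")
        if self.pools_per_dim < 1:
            raise ValueError(f"pools_per_dim must be >= 1, got {self.pools_per_dim}")

    @property
    def n_samples(self) -> int:
        return self.pools_per_dim**self.n_dims

    @property
    def n_pools(self) -> int:
        return self.n_dims * self.pools_per_dim

    @property
    def samples_per_pool(self) -> int:
        return self.pools_per_dim ** (self.n_dims - 1)

    @property
    def pool_ids(self) -> range:
        """Global pool identifiers, 1-based."""
        return range(1, self.n_pools + 1)

    # -- coordinate arithmetic -------------------------------------------

    def coords_of(self, sample: int) -> tuple[int, ...]:
        """Per-dimension pool coordinates (0-based) of a sample index."""
        if not 0 <= sample < self.n_samples:
            raise ValueError(
                f"sample index {sample} out of range [0, {self.n_samples})"
            )
        coords = []
        rem = sample
        for d in range(self.n_dims):
            power = self.pools_per_dim ** (self.n_dims - 1 - d)
            coords.append(rem // power)
            rem %= power
        return tuple(coords)

    def sample_at(self, coords: Sequence[int]) -> int:
        """Inverse of :meth:`coords_of`."""
        if len(coords) != self.n_dims:
            raise ValueError(
                f"expected {self.n_dims} coordinates, got {len(coords)}"
            )
        index = 0
        for d, c in enumerate(coords):
            if not 0 <= c < self.pools_per_dim:
                raise ValueError(
                    f"coordinate {c} in dimension {d} out of range "
                    f"[0, {self.pools_per_dim})"
                )
            index += c * self.pools_per_dim ** (self.n_dims - 1 - d)
        return index

    # -- global pool IDs -------------------------------------------------

    def pool_id(self, dim: int, coord: int) -> int:
        """Global 1-based pool ID for (dimension, coordinate), both 0-based."""
        if not 0 <= dim < self.n_dims:
            raise ValueError(f"dimension {dim} out of range [0, {self.n_dims})")
        if not 0 <= coord < self.pools_per_dim:
            raise ValueError(
                f"coordinate {coord} out of range [0, {self.pools_per_dim})"
            )
        return dim * self.pools_per_dim + coord + 1

    def dim_and_coord(self, pool_id: int) -> tuple[int, int]:
        """Inverse of :meth:`pool_id`: (dimension, coordinate), 0-based."""
        if not 1 <= pool_id <= self.n_pools:
            raise ValueError(
                f"pool id {pool_id} out of range [1, {self.n_pools}]"
            )
        return divmod(pool_id - 1, self.pools_per_dim)

    def pool_ids_for_sample(self, sample: int) -> tuple[int, ...]:
        """The n_dims global pool IDs that contain a sample."""
        return tuple(
            self.pool_id(d, c) for d, c in enumerate(self.coords_of(sample))
        )

    def samples_in_pool(self, pool_id: int) -> np.ndarray:
        """Sorted sample indices belonging to a global pool."""
        dim, coord = self.dim_and_coord(pool_id)
        idx = np.arange(self.n_samples)
        power = self.pools_per_dim ** (self.n_dims - 1 - dim)
        return idx[(idx // power) % self.pools_per_dim == coord]

    # -- serialisation ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "sample_index": np.arange(self.n_samples),
        }
        for d in range(self.n_dims):
            rows[f"pool_d{d + 1}"] = [
                self.pool_id(d, self.coords_of(s)[d]) for s in range(self.n_samples)
            ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_design(n_dims: int, pools_per_dim: int) -> PoolingDesign:
    """Construct the pooling grid (deterministic; no randomness involved)."""
    return PoolingDesign(n_dims=n_dims, pools_per_dim=pools_per_dim)


def pools_for_sample(design: PoolingDesign, sample: int) -> tuple[int, ...]:
    """Coordinate tuple (one 0-based pool coordinate per dimension)."""
    return design.coords_of(sample)


def resolve_sample(design: PoolingDesign, coords: Sequence[int]) -> int:
    """The unique sample identified by one pool coordinate per dimension."""
    return design.sample_at(coords)
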