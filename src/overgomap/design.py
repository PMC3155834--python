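"""Four-dimensional pooling layouts for combinatorial library screening.

Probes are arranged in a virtual grid of P plates, each with R rows and
C columns, and pooled along four dimensions: plate, row, column and
diagonal. Each probe enters exactly one pool per dimension, so a probe's
identity is recoverable from the intersection of the pools that light up
for a clone. The diagonal dimension is redundant with the other three
(for any occupied cell, diag = (row + col) mod n_diag) and serves as a
parity check that makes any single miscalled pool detectable.

The reference layout is 6 plates x 6 rows x 6 columns = 216 probe slots,
giving 24 pools of 36 probes each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dimension",
    "PoolId",
    "ProbeAddress",
    "PoolingDesign",
    "build_design",
    "diagonal_index",
    "pools_for_address",
    "probes_for_pool",
]


class ConfigurationError(ValueError):
    """Invalid design geometry or capacity."""


class Dimension(str, Enum):
    PLATE = "PLATE"
    ROW = "ROW"
    COL = "COL"
    DIAG = "DIAG"


DIMENSIONS: tuple[Dimension, ...] = (
    Dimension.PLATE,
    Dimension.ROW,
    Dimension.COL,
    Dimension.DIAG,
)


@dataclass(frozen=True, order=True)
class PoolId:
    """One hybridization pool: a dimension and an index within it."""

    dimension: Dimension
    index: int

    @property
    def label(self) -> str:
        return f"{self.dimension.value}{self.index}"

    @classmethod
    def parse(cls, label: str) -> "PoolId":
        for dim in DIMENSIONS:
            if label.startswith(dim.value):
                return cls(dim, int(label[len(dim.value):]))
        raise KeyError(f"not a pool label: {label!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True, order=True)
class ProbeAddress:
    """A probe slot: (plate, row, col), all 0-based."""

    plate: int
    row: int
    col: int


def diagonal_index(row: int, col: int, n_diag: int) -> int:
    """Diagonal pool index of a grid cell: ``(row + col) mod n_diag``.

    The modular anti-diagonal keeps pool sizes equal on square grids and
    assigns every cell to exactly one diagonal. The rule is isolated here
    so an alternative convention (e.g. ``(row - col) mod n``) is a
    one-line swap.
    """
    if n_diag <= 0:
        raise ConfigurationError(f"n_diag must be positive, got {n_diag}")
    if row < 0 or col < 0:
        raise ConfigurationError("row/col indices must be non-negative")
    return (row + col) % n_diag


@dataclass
class PoolingDesign:
    """Probe -> pool incidence structure of a 4-dimensional pooled screen.

    ``probe_order`` lists probe ids in slot order (plate-major, then row,
    then column); the grid may be partially filled. Pool count is
    ``n_plates + n_rows + n_cols + n_diag`` with
    ``n_diag = max(n_rows, n_cols)``.
    """

    n_plates: int
    n_rows: int
    n_cols: int
    probe_order: list[str]
    _addr_of: dict[str, ProbeAddress] = field(init=False, repr=False)
    _probe_at: dict[ProbeAddress, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_plates, self.n_rows, self.n_cols) <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if len(self.probe_order) > self.capacity:
            raise ConfigurationError(
                f"{len(self.probe_order)} probes exceed capacity "
                f"{self.capacity} ({self.n_plates}x{self.n_rows}x{self.n_cols})"
            )
        if len(set(self.probe_order)) != len(self.probe_order):
            raise ValueError("duplicate probe ids in probe_order")
        self._addr_of = {}
        self._probe_at = {}
        for i, pid in enumerate(self.probe_order):
            plate, rem = divmod(i, self.n_rows * self.n_cols)
            row, col = divmod(rem, self.n_cols)
            addr = ProbeAddress(plate, row, col)
            self._addr_of[pid] = addr
            self._probe_at[addr] = pid

    # -- geometry -----------------------------------------------------
    @property
    def capacity(self) -> int:
        return self.n_plates * self.n_rows * self.n_cols

    @property
    def n_probes(self) -> int:
        return len(self.probe_order)

    @property
    def n_diag(self) -> int:
        return max(self.n_rows, self.n_cols)

    @property
    def pools(self) -> list[PoolId]:
        """All pools in canonical order: plates, rows, cols, diagonals."""
        counts = {
            Dimension.PLATE: self.n_plates,
            Dimension.ROW: self.n_rows,
            Dimension.COL: self.n_cols,
            Dimension.DIAG: self.n_diag,
        }
        return [PoolId(d, i) for d in DIMENSIONS for i in range(counts[d])]

    @property
    def n_pools(self) -> int:
        return self.n_plates + self.n_rows + self.n_cols + self.n_diag

    # -- lookups ------------------------------------------------------
    def address_of(self, probe_id: str) -> ProbeAddress:
        try:
            return self._addr_of[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id: {probe_id!r}") from None

    def probe_at(self, addr: ProbeAddress) -> str:
        try:
            return self._probe_at[addr]
        except KeyError:
            raise KeyError(f"unoccupied slot: {addr}") from None

    def pools_for_address(self, addr: ProbeAddress) -> set[PoolId]:
        """The 4 pools containing the probe at ``addr`` (one per dimension)."""
        if addr not in self._probe_at:
            raise KeyError(f"unoccupied slot: {addr}")
        return {
            PoolId(Dimension.PLATE, addr.plate),
            PoolId(Dimension.ROW, addr.row),
            PoolId(Dimension.COL, addr.col),
            PoolId(Dimension.DIAG, diagonal_index(addr.row, addr.col, self.n_diag)),
        }

    def pools_for_probe(self, probe_id: str) -> set[PoolId]:
        return self.pools_for_address(self.address_of(probe_id))

    def probes_for_pool(self, pool: PoolId) -> set[str]:
        """All probe ids in ``pool`` (inverse of :meth:`pools_for_address`)."""
        if pool not in set(self.pools):
            raise KeyError(f"unknown pool: {pool.label}")
        return {
            pid
            for pid, addr in self._addr_of.items()
            if pool in self.pools_for_address(addr)
        }

    # -- matrix form --------------------------------------------------
    def membership_matrix(self) -> np.ndarray:
        """0/1 incidence matrix of shape (n_probes, n_pools).

        Rows follow ``probe_order``; columns follow :attr:`pools`. Each
        row has exactly four ones, one per dimension.
        """
        index = {pool: j for j, pool in enumerate(self.pools)}
        m = np.zeros((self.n_probes, self.n_pools), dtype=np.uint8)
        for i, pid in enumerate(self.probe_order):
            for pool in self.pools_for_probe(pid):
                m[i, index[pool]] = 1
        return m

    # -- serialization ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.probe_order:
            a = self._addr_of[pid]
            rows.append(
                (pid, a.plate, a.row, a.col, diagonal_index(a.row, a.col, self.n_diag))
            )
        return pd.DataFrame(rows, columns=["probe_id", "plate", "row", "col", "diag"])

    def pool_members_frame(self) -> pd.DataFrame:
        rows = [
            (pool.label, pid)
            for pool in self.pools
            for pid in sorted(self.probes_for_pool(pool))
        ]
        return pd.DataFrame(rows, columns=["pool_id", "probe_id"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_pool_members(self, path: str | Path) -> None:
        self.pool_members_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PoolingDesign":
        df = pd.read_csv(path, sep="\t", comment="#")
        n_plates = int(df["plate"].max()) + 1
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        order = df.sort_values(["plate", "row", "col"])["probe_id"].tolist()
        return build_design(len(order), n_plates, n_rows, n_cols, order)


def build_design(
    n_probes: int,
    n_plates: int,
    n_rows: int,
    n_cols: int,
    probe_ids: Sequence[str],
) -> PoolingDesign:
    """Assign ``probe_ids`` to grid slots in row-major order.

    Probes fill plate 0 row by row, then plate 1, and so on; a final
    partial plate is allowed (pool sizes are then unequal).
    """
    if n_probes > n_plates * n_rows * n_cols:
        raise ConfigurationError(
            f"{n_probes} probes exceed capacity {n_plates * n_rows * n_cols}"
        )
    ids = list(probe_ids)
    if len(ids) != n_probes:
        raise ValueError(f"expected {n_probes} probe ids, got {len(ids)}")
    return PoolingDesign(n_plates, n_rows, n_cols, ids)


def pools_for_address(addr: ProbeAddress, design: PoolingDesign) -> set[PoolId]:
    return design.pools_for_address(addr)


def probes_for_pool(pool: PoolId, design: PoolingDesign) -> set[str]:
    return design.probes_for_pool(pool)
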