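"""Hexagonal spot-lattice geometry and adjacency.

Spot-based spatial transcriptomics arrays (Visium dialect) place 55 um
capture spots on a hexagonal lattice with 100 um centre-to-centre spacing,
so each interior spot has six first-order neighbours.  Array indices follow
the Visium convention: ``array_row`` and ``array_col`` share parity, the
column index advances by 2 between horizontally adjacent spots, and the two
rows interleave.  Physical coordinates are micrometres, origin at the
top-left spot centre, y increasing downward (image convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .errors import ValidationError

DEFAULT_SPACING_UM = 100.0
DEFAULT_DIAMETER_UM = 55.0

#: axial (row, col) offsets of the six hexagonal first-order neighbours
HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))

ZONE_CATEGORIES = ("RZ", "BZ", "IZ", "BZ-high", "unassigned")


def array_to_um(array_row, array_col, spacing_um: float = DEFAULT_SPACING_UM):
    """Convert Visium array indices to micrometre coordinates.

    x = col * spacing / 2, y = row * spacing * sqrt(3) / 2 — with the
    shared-parity indexing this yields exactly ``spacing_um`` between the
    centres of adjacent spots, both within a row and across rows.
    """
    x = np.asarray(array_col, dtype=float) * spacing_um / 2.0
    y = np.asarray(array_row, dtype=float) * spacing_um * math.sqrt(3) / 2.0
    return x, y


@dataclass
class SpotLattice:
    """A hexagonal lattice of capture spots.

    ``table`` columns: spot_id (unique str), array_row, array_col (ints of
    equal parity), x_um, y_um (floats), in_tissue (bool).
    """

    table: pd.DataFrame
    spacing_um: float = DEFAULT_SPACING_UM
    diameter_um: float = DEFAULT_DIAMETER_UM

    def __post_init__(self):
        required = {"spot_id", "array_row", "array_col", "x_um", "y_um", "in_tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"SpotLattice table missing columns: {sorted(missing)}")
        if not (self.spacing_um > self.diameter_um > 0):
            raise ValidationError(
                f"require spacing > diameter > 0, got spacing={self.spacing_um}, "
                f"diameter={self.diameter_um}"
            )
        ids = self.table["spot_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate spot_id {dup!r}")
        parity = (self.table["array_row"].to_numpy() % 2) != (
            self.table["array_col"].to_numpy() % 2
        )
        if parity.any():
            bad = self.table.loc[parity].iloc[0]
            raise ValidationError(
                f"row/col parity violation at spot {bad['spot_id']!r} "
                f"(row={bad['array_row']}, col={bad['array_col']})"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def n_spots(self) -> int:
        return len(self.table)

    @property
    def spot_ids(self) -> np.ndarray:
        return self.table["spot_id"].to_numpy()

    @property
    def coords_um(self) -> np.ndarray:
        """(n, 2) array of spot-centre coordinates in micrometres."""
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def in_tissue(self) -> np.ndarray:
        return self.table["in_tissue"].to_numpy(dtype=bool)

    def tissue(self) -> "SpotLattice":
        """Return the sub-lattice of in-tissue spots."""
        return SpotLattice(
            self.table[self.table["in_tissue"]].reset_index(drop=True),
            spacing_um=self.spacing_um,
            diameter_um=self.diameter_um,
        )


def full_hex_lattice(
    rows: int,
    cols: int,
    spacing_um: float = DEFAULT_SPACING_UM,
    diameter_um: float = DEFAULT_DIAMETER_UM,
) -> SpotLattice:
    """Build a fully in-tissue hexagonal lattice of ``rows`` x ``cols`` spots."""
    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be positive")
    rr, cc = [], []
    for r in range(rows):
        start = r % 2
        for j in range(cols):
            rr.append(r)
            cc.append(start + 2 * j)
    rr = np.array(rr)
    cc = np.array(cc)
    x, y = array_to_um(rr, cc, spacing_um)
    table = pd.DataFrame(
        {
            "spot_id": [f"spot_{r:03d}_{c:03d}" for r, c in zip(rr, cc)],
            "array_row": rr,
            "array_col": cc,
            "x_um": x,
            "y_um": y,
            "in_tissue": True,
        }
    )
    return SpotLattice(table, spacing_um=spacing_um, diameter_um=diameter_um)


@dataclass
class AdjacencyGraph:
    """First-order contiguity graph over the in-tissue spots of a lattice.

    ``matrix`` is a symmetric boolean CSR adjacency matrix without
    self-edges; row/column order matches ``spot_ids``.  Interior spots of a
    full hexagonal lattice have exactly six neighbours.
    """

    spot_ids: np.ndarray
    matrix: sp.csr_matrix
    tolerance_um: float = 1.0
    coords_um: np.ndarray | None = None

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.spot_ids):
            raise ValidationError("adjacency matrix shape does not match spot_ids")
        if m.diagonal().sum() != 0:
            raise ValidationError("adjacency matrix has self-edges")
        if (m != m.T).nnz != 0:
            raise ValidationError("adjacency matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def degree(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(int)

    def neighbors(self, i: int) -> np.ndarray:
        m = self.matrix
        return m.indices[m.indptr[i] : m.indptr[i + 1]]

    def neighbor_lists(self) -> list[np.ndarray]:
        return [self.neighbors(i) for i in range(self.n)]


def build_adjacency(lattice: SpotLattice, tolerance_um: float = 1.0) -> AdjacencyGraph:
    """Connect in-tissue spots whose centre distance is ``spacing +/- tolerance``.

    Isolated spots are allowed (degree 0).
    """
    tissue = lattice.table[lattice.table["in_tissue"]].reset_index(drop=True)
    coords = tissue[["x_um", "y_um"]].to_numpy(dtype=float)
    n = len(tissue)
    s = lattice.spacing_um
    if n == 0:
        raise ValidationError("lattice has no in-tissue spots")
    rows, cols = [], []
    if n > 1:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=s + tolerance_um, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            keep = d >= s - tolerance_um
            pairs = pairs[keep]
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return AdjacencyGraph(
        spot_ids=tissue["spot_id"].to_numpy(),
        matrix=matrix,
        tolerance_um=tolerance_um,
        coords_um=coords,
    )


@dataclass
class ZoneLabels:
    """Per-spot categorical zone assignment with provenance.

    ``labels`` aligns with ``spot_ids``; values are drawn from
    ``ZONE_CATEGORIES``.  ``provenance`` records whether the labels are
    simulation ground truth or inferred from expression.
    """

    spot_ids: np.ndarray
    labels: np.ndarray
    provenance: str = "truth"

    def __post_init__(self):
        if len(self.spot_ids) != len(self.labels):
            raise ValidationError("zone labels length mismatch")
        bad = set(np.unique(self.labels)) - set(ZONE_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown zone categories: {sorted(bad)}")

    def mask(self, zone: str) -> np.ndarray:
        return np.asarray(self.labels) == zone

    def to_series(self) -> pd.Series:
        return pd.Series(
            pd.Categorical(self.labels, categories=ZONE_CATEGORIES),
            index=self.spot_ids,
            name="zone",
        )


def grow_random_connected(
    rng: np.random.Generator,
    size: int,
    neighbor_lists: list[np.ndarray],
    eligible: np.ndarray | None = None,
    blocked: set | None = None,
    start: int | None = None,
    max_restarts: int = 100,
) -> set[int] | None:
    """Grow a random connected spot set by uniform first-order accretion.

    Starts from ``start`` (or a uniformly random eligible spot) and
    repeatedly adds a uniformly random unoccupied eligible lattice
    neighbour of the current set.  Returns ``None`` after ``max_restarts``
    stalled attempts.  This accretion process is shared between the
    synthetic colony generator and the Monte Carlo localization null so
    that planted and simulated colonies have identical geometry.
    """
    n = len(neighbor_lists)
    blocked = blocked or set()
    if start is None:
        if eligible is None:
            pool = [i for i in range(n) if i not in blocked]
        else:
            pool = [i for i in np.flatnonzero(eligible) if i not in blocked]
        if not pool:
            return None
    for _ in range(max_restarts):
        s = pool[rng.integers(len(pool))] if start is None else start
        members = {s}
        frontier = {
            j
            for j in neighbor_lists[s]
            if j not in blocked and (eligible is None or eligible[j])
        }
        stalled = False
        while len(members) < size:
            if not frontier:
                stalled = True
                break
            cand = sorted(frontier)
            nxt = cand[rng.integers(len(cand))]
            members.add(nxt)
            frontier.discard(nxt)
            for j in neighbor_lists[nxt]:
                if (
                    j not in members
                    and j not in blocked
                    and (eligible is None or eligible[j])
                ):
                    frontier.add(j)
        if not stalled:
            return members
        if start is not None:
            # caller pinned the start; a stall is terminal for this attempt
            return None
    return None
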