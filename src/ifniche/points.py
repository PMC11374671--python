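"""Single-molecule point-cloud analyses.

Density-based clustering (DBSCAN, default eps = 70 um, min_samples = 10)
separates densely clustered interferon-stimulated-gene transcripts —
IFNIC colonies — from scattered low-density expression; the neighbourhood
radius can be selected from the knee of the sorted k-nearest-neighbour
distance curve.  Decoded DNA loci are classified as nuclear when at least
ten decoded points fall within a 5 um radius (the query point included)
and extranuclear otherwise, after excluding the first and last 5 um of
the section thickness to control cryosectioning shear artifacts.
Nuclear morphology is summarized by solidity: mask area divided by
convex-hull area, 1 for convex nuclei and lower for deformed ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import MultiPoint, Point
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .containers import CellTable, NucleusMaskSet, PointTable
from .errors import SampleSizeError, ValidationError

logger = logging.getLogger("ifniche")

#: default interferon-stimulated species for point-level colony calling
ISG_POINT_SPECIES = ("Ifit1", "Ifit2", "Ifit3", "Cxcl10")


@dataclass
class DbscanParams:
    eps: float = 70.0
    min_samples: int = 10

    def __post_init__(self):
        if self.eps <= 0:
            raise ValidationError("eps must be positive")
        if self.min_samples < 2:
            raise ValidationError("min_samples must be >= 2")


@dataclass
class ExtranuclearParams:
    radius_um: float = 5.0
    min_neighbors: int = 10  # total points within radius, query point included
    z_edge_um: float = 5.0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValidationError("radius must be positive")
        if self.min_neighbors < 2:
            raise ValidationError("min_neighbors must be >= 2")


@dataclass
class EpsSelection:
    eps: float
    k: int
    knn_distances: np.ndarray  # sorted ascending; emitted for inspection

    def __float__(self):
        return float(self.eps)


def select_eps(points: PointTable, k: int) -> EpsSelection:
    """Select a DBSCAN radius from the k-nearest-neighbour distance curve.

    The distances to each point's k-th nearest neighbour are sorted
    ascending and the knee of the curve is located kneedle-style: after
    normalizing both axes to [0, 1], the index maximizing the deviation of
    the (lightly smoothed) curve from the straight chord between its
    endpoints is the point of maximum curvature, where within-cluster
    spacing gives way to between-cluster gaps.
    """
    n = points.n
    if n < k + 1:
        raise SampleSizeError(f"select_eps needs >= k+1 = {k + 1} points, got {n}")
    coords = points.coords(dims=2)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)
    curve = np.sort(dists[:, k])
    if len(curve) < 3 or curve[-1] == curve[0]:
        return EpsSelection(float(curve[-1]), k, curve)
    window = max(1, len(curve) // 50)
    kernel = np.ones(window) / window
    smooth = np.convolve(curve, kernel, mode="same")
    smooth[: window // 2 + 1] = curve[: window // 2 + 1]
    smooth[-(window // 2 + 1) :] = curve[-(window // 2 + 1) :]
    x = np.linspace(0.0, 1.0, len(curve))
    y = (smooth - smooth[0]) / (smooth[-1] - smooth[0])
    knee = int(np.argmax(np.abs(y - x)))
    return EpsSelection(float(curve[knee]), k, curve)


def dbscan(points: PointTable, params: DbscanParams) -> np.ndarray:
    """Classical DBSCAN labels over the xy coordinates (-1 = noise).

    A point is core iff at least ``min_samples`` points (itself included)
    lie within ``eps``; clusters are the connected components of core
    points within eps, with border points attached to a core's cluster.
    """
    if points.n < 1:
        raise ValidationError("dbscan needs at least one point")
    model = DBSCAN(eps=params.eps, min_samples=params.min_samples)
    return model.fit_predict(points.coords(dims=2))


@dataclass
class ClusterResult:
    labels: np.ndarray
    clusters: list[np.ndarray]           # point indices per cluster
    scattered: np.ndarray                # noise point indices
    points: PointTable

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def classify_isg_clusters(
    isg_points: PointTable,
    params: DbscanParams | None = None,
    species: tuple[str, ...] | None = None,
) -> ClusterResult:
    """DBSCAN clusters of ISG transcripts = IFNIC colonies; noise = scattered."""
    params = params or DbscanParams()
    if species is not None:
        isg_points = isg_points.filter_species(species)
    labels = dbscan(isg_points, params)
    clusters = [np.flatnonzero(labels == c) for c in range(labels.max() + 1)]
    scattered = np.flatnonzero(labels == -1)
    return ClusterResult(labels=labels, clusters=clusters, scattered=scattered, points=isg_points)


def cluster_jaccard(cluster_idx: np.ndarray, truth_idx: np.ndarray) -> float:
    a, b = set(map(int, cluster_idx)), set(map(int, truth_idx))
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def colony_composition(
    clusters: ClusterResult,
    cell_table: CellTable,
    positive_min_transcripts: int = 1,
) -> pd.DataFrame:
    """Cell-type composition of each point cluster.

    A cell is positive for the clustered species when at least
    ``positive_min_transcripts`` of the cluster's points are assigned to
    it; composition is the cell-type proportion among positive cells.
    Cells without a type label are excluded (count logged).  The convex
    hull of the cluster's points is reported as its spatial extent.
    """
    if "cell_id" not in clusters.points.table.columns:
        raise ValidationError("points carry no cell assignments")
    types = cell_table.types()
    rows = []
    n_untyped = 0
    for ci, idx in enumerate(clusters.clusters):
        sub = clusters.points.table.iloc[idx]
        per_cell = sub.groupby("cell_id").size()
        positive = per_cell[per_cell >= positive_min_transcripts]
        cell_types = []
        for cell_id in positive.index:
            if cell_id in types.index and pd.notna(types.loc[cell_id]):
                cell_types.append(types.loc[cell_id])
            else:
                n_untyped += 1
        counts = pd.Series(cell_types).value_counts()
        total = int(counts.sum())
        hull_area = np.nan
        if len(sub) >= 3:
            hull = MultiPoint(sub[["x_um", "y_um"]].to_numpy()).convex_hull
            hull_area = float(hull.area)
        for cell_type, cnt in counts.items():
            rows.append(
                {
                    "cluster": ci,
                    "cell_type": cell_type,
                    "n_positive_cells": int(cnt),
                    "proportion": cnt / total,
                    "n_cells_total": total,
                    "hull_area_um2": hull_area,
                }
            )
    if n_untyped:
        logger.info("colony_composition: %d positive cells lacked a type label", n_untyped)
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "cell_type",
            "n_positive_cells",
            "proportion",
            "n_cells_total",
            "hull_area_um2",
        ],
    )


# ---------------------------------------------------------------------------
# extranuclear DNA


EXTRANUCLEAR_LABELS = ("nuclear", "extranuclear", "edge_excluded")


@dataclass
class ExtranuclearResult:
    labels: np.ndarray  # str per locus
    neighbor_counts: np.ndarray

    @property
    def n_nuclear(self) -> int:
        return int((self.labels == "nuclear").sum())

    @property
    def n_extranuclear(self) -> int:
        return int((self.labels == "extranuclear").sum())

    @property
    def n_edge_excluded(self) -> int:
        return int((self.labels == "edge_excluded").sum())

    @property
    def extranuclear_fraction(self) -> float:
        kept = self.n_nuclear + self.n_extranuclear
        return self.n_extranuclear / kept if kept else np.nan


def classify_extranuclear(
    loci: PointTable,
    params: ExtranuclearParams | None = None,
    section_thickness_um: float | None = None,
) -> ExtranuclearResult:
    """Label decoded DNA loci as nuclear / extranuclear / edge_excluded.

    When a z coordinate is present, loci within ``z_edge_um`` of either
    section face are excluded first (section thickness taken from
    ``section_thickness_um`` or the maximum observed z).  The remaining
    loci are nuclear iff at least ``min_neighbors`` loci (self included)
    fall within ``radius_um`` in the xy plane.  Adding points near a locus
    can only flip it extranuclear -> nuclear, never the reverse.
    """
    params = params or ExtranuclearParams()
    n = loci.n
    labels = np.empty(n, dtype=object)
    kept = np.ones(n, dtype=bool)
    if loci.has_z:
        z = loci.table["z_um"].to_numpy(dtype=float)
        thickness = section_thickness_um if section_thickness_um is not None else float(z.max())
        edge = (z < params.z_edge_um) | (z > thickness - params.z_edge_um)
        labels[edge] = "edge_excluded"
        kept = ~edge
    coords = loci.coords(dims=2)
    counts = np.zeros(n, dtype=int)
    if kept.any():
        kept_idx = np.flatnonzero(kept)
        tree = cKDTree(coords[kept_idx])
        neigh = tree.query_ball_point(coords[kept_idx], r=params.radius_um)
        counts[kept_idx] = np.array([len(nb) for nb in neigh])  # self included
        nuclear = counts[kept_idx] >= params.min_neighbors
        labels[kept_idx[nuclear]] = "nuclear"
        labels[kept_idx[~nuclear]] = "extranuclear"
    return ExtranuclearResult(labels=labels.astype(str), neighbor_counts=counts)


# ---------------------------------------------------------------------------
# nuclear solidity


@dataclass
class SolidityResult:
    table: pd.DataFrame  # nucleus_id, mask_area_um2, hull_area_um2, solidity

    def solidity(self) -> pd.Series:
        return self.table.set_index("nucleus_id")["solidity"]


def nuclear_solidity(masks: NucleusMaskSet) -> SolidityResult:
    """Solidity (mask area / convex-hull area) per nucleus mask.

    Area is the pixel count times the pixel area; the hull is the convex
    hull of the mask's pixel centres (shoelace area).  Solidity is 1 for
    convex shapes up to raster tolerance and decreases with lobed or
    deformed contours.  Multi-component masks are rejected.
    """
    px2 = masks.um_per_px**2
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    rows = []
    for nid in masks.nucleus_ids:
        mask = masks.mask(int(nid))
        _, n_comp = ndimage.label(mask, structure=structure)
        if n_comp != 1:
            raise ValidationError(
                f"nucleus {int(nid)} mask has {n_comp} connected components"
            )
        yy, xx = np.nonzero(mask)
        pts = np.column_stack([xx, yy]).astype(float) * masks.um_per_px
        mask_area = len(pts) * px2
        if len(pts) < 3:
            raise ValidationError(f"nucleus {int(nid)} mask too small for a hull")
        hull = ConvexHull(pts)
        hull_area = float(hull.volume)  # 2D hull: volume is the area
        rows.append(
            {
                "nucleus_id": int(nid),
                "mask_area_um2": float(mask_area),
                "hull_area_um2": hull_area,
                "solidity": float(mask_area / hull_area),
            }
        )
    return SolidityResult(pd.DataFrame(rows))
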