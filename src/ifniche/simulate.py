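"""Synthetic samples with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without simulating images or sequencing reads:

* a fully in-tissue hexagonal spot lattice (55 um spots, 100 um spacing)
  with concentric infarct geometry — an ischaemic core (IZ) disk, a
  borderzone (BZ) annulus around it and remote tissue (RZ) beyond;
* negative-binomial per-zone gene programs over a small named panel, with
  contiguous interferon-stimulated-gene (ISG) colonies planted at the BZ
  by random first-order accretion (the same accretion process the Monte
  Carlo localization null uses, so planted and simulated colonies share
  geometry);
* a matched negative-control genotype: the identical generative process
  with zero colonies and unchanged ISG baseline, standing in for hearts
  genetically unable to mount a type I interferon response;
* MERFISH-like labelled point clouds: non-overlapping cell disks with a
  33-gene probe panel, ISG transcripts strongly enriched in cells inside
  planted colony disks;
* DNA-locus point patterns with a known extranuclear escape fraction; and
* convex-to-deformed nucleus masks with exact polygon-derived solidity.

All randomness flows from a single integer seed expanded into independent
substreams per component, so identical (config, seed) yields bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely import contains_xy
from shapely.geometry import Polygon

from .containers import CellTable, CountsMatrix, NucleusMaskSet, PointTable
from .errors import PlacementError, ValidationError
from .lattice import (
    SpotLattice,
    ZoneLabels,
    build_adjacency,
    full_hex_lattice,
    grow_random_connected,
)

# ---------------------------------------------------------------------------
# default gene panels

#: the 33-gene single-molecule probe panel
MERFISH_PANEL = (
    "Tnnt2", "Ttn", "Ankrd1", "Nppa", "Shroom3", "Nppb", "Xirp2", "Flnc",
    "Col1a1", "Col6a3", "Postn", "Cxcl5", "Adgre1", "Cd68", "Ccr2", "Chil3",
    "S100a4", "Ly6c2", "Timd4", "Lyve1", "Cxcr2", "Csf3r", "Ly6g", "Retnlg",
    "S100a8", "Pecam1", "Flt1", "Ifna2", "Ifnb1", "Ifit1", "Ifit2", "Ifit3",
    "Cxcl10",
)

DEFAULT_ISG_GENES = (
    "Ifit1", "Ifit2", "Ifit3", "Rsad2", "Cxcl10", "Isg15", "Irf7", "Oasl1",
    "Ifi27", "Mx1",
)
DEFAULT_BZ_GENES = ("Nppa", "Ankrd1", "Flnc", "Xirp2", "Nppb", "Shroom3")
DEFAULT_IZ_GENES = ("Cd68", "Adgre1", "Ly6c2", "S100a8", "Ccr2", "Lyz2")
DEFAULT_MATRICELLULAR_GENES = ("Postn", "Acta2", "Sparc", "Col1a1", "Bgn")
DEFAULT_BACKGROUND_GENES = (
    "Gapdh", "Actb", "Tnnt2", "Ttn", "Pecam1", "Flt1", "Col6a3", "Myh6",
    "Tpm1", "Ryr2", "Des", "Vim", "Tcap",
)

MERFISH_CELL_TYPES = ("BZ CM", "RZ CM", "FB", "Mac", "Neut", "EC")

#: marker-gene weights per MERFISH cell type (relative transcript rates)
MERFISH_TYPE_PROFILES: dict[str, dict[str, float]] = {
    "BZ CM": {"Tnnt2": 2, "Ttn": 2, "Nppa": 3, "Ankrd1": 3, "Flnc": 2, "Xirp2": 1, "Nppb": 1, "Shroom3": 1},
    "RZ CM": {"Tnnt2": 4, "Ttn": 4},
    "FB": {"Col1a1": 3, "Col6a3": 3, "Postn": 2, "S100a4": 1},
    "Mac": {"Adgre1": 3, "Cd68": 3, "Ccr2": 1, "Chil3": 1, "Timd4": 1, "Lyve1": 1},
    "Neut": {"Cxcr2": 2, "Csf3r": 2, "S100a8": 3, "Ly6g": 1, "Retnlg": 1, "Cxcl5": 1},
    "EC": {"Pecam1": 4, "Flt1": 3},
}

ISG_POINT_GENES = ("Ifit1", "Ifit2", "Ifit3", "Cxcl10")
#: relative competence to express the initiator interferon transcript:
#: borderzone cardiomyocytes dominate, fibroblasts are a secondary source.
#: With the default cell mix and a per-cell mean of 1.0 in colony
#: cardiomyocytes, these weights make ~80% of initiator-positive cells
#: cardiomyocytes and ~20% fibroblasts in expectation.
IFNA2_SOURCE_WEIGHTS = {"BZ CM": 1.0, "FB": 0.21}
IFNA2_SOURCE_TYPES = tuple(IFNA2_SOURCE_WEIGHTS)

# named RNG substreams
_STREAMS = {"placement": 0, "counts": 1, "points": 2, "cells": 3, "dna": 4, "nuclei": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator per simulation component."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic spot-lattice sample.

    Defaults describe a mid-ventricle short-axis section at the scale the
    analysis targets: ~3,000 spots, an infarct core of 700 um radius, a
    300 um borderzone annulus (~6% of the tissue), and borderzone ISG
    colonies of 4-8 spots with an 8-fold ISG induction inside colonies.
    """

    lattice_rows: int = 54
    lattice_cols: int = 56
    spot_spacing_um: float = 100.0
    spot_diameter_um: float = 55.0
    infarct_center: tuple[float, float] | None = None  # None = lattice centroid
    iz_radius_um: float = 700.0
    bz_width_um: float = 300.0
    n_colonies: int = 5
    colony_size_range: tuple[int, int] = (4, 8)
    colony_placement: str = "bz"
    isg_effect: float = 8.0
    bz_effect: float = 4.0
    iz_effect: float = 4.0
    matricellular_effect: float = 3.0
    isg_halo_decay: float = 0.0  # per-ring ISG carry-over outside colonies
    nb_mean: float = 2.0
    isg_baseline_mean: float = 5.0
    background_mean: float = 20.0  # housekeeping mass dominates spot totals
    nb_dispersion: float = 5.0
    isg_genes: tuple[str, ...] = DEFAULT_ISG_GENES
    bz_genes: tuple[str, ...] = DEFAULT_BZ_GENES
    iz_genes: tuple[str, ...] = DEFAULT_IZ_GENES
    matricellular_genes: tuple[str, ...] = DEFAULT_MATRICELLULAR_GENES
    panel: tuple[str, ...] | None = None  # None = roles + background genes
    seed: int = 0

    def __post_init__(self):
        if not (self.spot_spacing_um > self.spot_diameter_um > 0):
            raise ValidationError("require spacing > diameter > 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.isg_effect < 1:
            raise ValidationError("isg_effect must be >= 1")
        lo, hi = self.colony_size_range
        if not (1 <= lo <= hi <= 12):
            raise ValidationError("colony_size_range must lie within [1, 12]")
        if self.colony_placement not in ("bz", "uniform"):
            raise ValidationError("colony_placement must be 'bz' or 'uniform'")
        if not (0 <= self.isg_halo_decay < 1):
            raise ValidationError("isg_halo_decay must be in [0, 1)")
        width = (2 * (self.lattice_cols - 1)) * self.spot_spacing_um / 2
        height = (self.lattice_rows - 1) * self.spot_spacing_um * math.sqrt(3) / 2
        if 2 * (self.iz_radius_um + self.bz_width_um) > max(width, height):
            raise ValidationError("iz_radius + bz_width does not fit in the lattice")
        if self.panel is None:
            self.panel = tuple(
                dict.fromkeys(
                    self.isg_genes
                    + self.bz_genes
                    + self.iz_genes
                    + self.matricellular_genes
                    + DEFAULT_BACKGROUND_GENES
                )
            )
        for role, genes in (
            ("ISG", self.isg_genes),
            ("BZ", self.bz_genes),
            ("IZ", self.iz_genes),
        ):
            missing = set(genes) - set(self.panel)
            if missing:
                raise ValidationError(f"panel lacks designated {role} genes: {sorted(missing)}")


@dataclass
class GroundTruth:
    """Truth labels for parameter-recovery tests."""

    zone_of_spot: ZoneLabels | None = None
    colony_membership: dict[str, int] = field(default_factory=dict)
    colony_spot_indices: dict[int, np.ndarray] = field(default_factory=dict)
    merfish_cell_types: dict[str, str] = field(default_factory=dict)
    cell_in_colony: dict[str, bool] = field(default_factory=dict)
    colony_centers_um: np.ndarray | None = None
    colony_radius_um: float | None = None
    extranuclear_flags: np.ndarray | None = None
    extranuclear_fraction: float | None = None
    nucleus_solidity: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# spot-lattice samples


def _zone_labels(lattice: SpotLattice, config: SimulationConfig) -> tuple[ZoneLabels, np.ndarray]:
    coords = lattice.coords_um
    center = (
        np.asarray(config.infarct_center, dtype=float)
        if config.infarct_center is not None
        else coords.mean(axis=0)
    )
    d = np.linalg.norm(coords - center, axis=1)
    labels = np.full(len(coords), "RZ", dtype=object)
    labels[d <= config.iz_radius_um + config.bz_width_um] = "BZ"
    labels[d <= config.iz_radius_um] = "IZ"
    return ZoneLabels(lattice.spot_ids, labels.astype(str), provenance="truth"), center


def _plant_colonies(
    config: SimulationConfig,
    graph_nbrs: list[np.ndarray],
    eligible: np.ndarray,
    rng: np.random.Generator,
) -> dict[int, set[int]]:
    """Grow non-adjacent connected colonies by random accretion."""
    colonies: dict[int, set[int]] = {}
    blocked: set[int] = set()
    lo, hi = config.colony_size_range
    for ci in range(config.n_colonies):
        size = int(rng.integers(lo, hi + 1))
        members = grow_random_connected(
            rng, size, graph_nbrs, eligible=eligible, blocked=blocked, max_restarts=100
        )
        if members is None:
            raise PlacementError(
                f"colony {ci} (size {size}) could not be placed without overlap"
            )
        colonies[ci] = members
        # colonies must stay mutually non-adjacent so segmentation can
        # recover them as distinct components
        blocked |= members
        for m in members:
            blocked.update(int(j) for j in graph_nbrs[m])
    return colonies


def _mean_matrix(
    config: SimulationConfig,
    zones: ZoneLabels,
    colonies: dict[int, set[int]],
    graph_nbrs: list[np.ndarray],
    n_spots: int,
) -> np.ndarray:
    """Per-gene x per-spot negative-binomial mean surface.

    Baselines: ISG genes start at ``isg_baseline_mean``; genes with no
    designated role are housekeeping background at ``background_mean`` so
    that, as in real spot data, the bulk of each spot's library is not
    interferon-responsive and per-spot total normalization does not cancel
    the colony effect; all zoned program genes start at ``nb_mean``.
    """
    panel = list(config.panel)
    role_genes = (
        set(config.isg_genes)
        | set(config.bz_genes)
        | set(config.iz_genes)
        | set(config.matricellular_genes)
    )
    base = np.array(
        [
            config.isg_baseline_mean
            if g in config.isg_genes
            else (config.nb_mean if g in role_genes else config.background_mean)
            for g in panel
        ]
    )
    mu = np.tile(base[:, None], (1, n_spots)).astype(float)
    zl = np.asarray(zones.labels)
    bz = zl == "BZ"
    iz = zl == "IZ"
    colony_spots = sorted(set().union(*colonies.values())) if colonies else []
    in_colony = np.zeros(n_spots, dtype=bool)
    in_colony[colony_spots] = True

    isg_mult = np.ones(n_spots)
    isg_mult[in_colony] = config.isg_effect
    if config.isg_halo_decay > 0 and colony_spots:
        # ISG expression decays ring by ring outside colonies
        ring = np.full(n_spots, -1, dtype=int)
        ring[in_colony] = 0
        frontier = list(colony_spots)
        k = 0
        while frontier and k < 6:
            k += 1
            nxt = []
            for u in frontier:
                for v in graph_nbrs[u]:
                    v = int(v)
                    if ring[v] == -1:
                        ring[v] = k
                        nxt.append(v)
            frontier = nxt
            halo = ring == k
            isg_mult[halo] = 1.0 + (config.isg_effect - 1.0) * config.isg_halo_decay**k

    for gi, g in enumerate(panel):
        if g in config.isg_genes:
            mu[gi] *= isg_mult
        if g in config.bz_genes:
            mu[gi, bz] *= config.bz_effect
        if g in config.iz_genes:
            mu[gi, iz] *= config.iz_effect
        if g in config.matricellular_genes:
            # activated-fibroblast program: elevated in the borderzone but
            # suppressed (baseline) inside ISG colonies
            mu[gi, bz & ~in_colony] *= config.matricellular_effect
    return mu


def _draw_nb(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial via the gamma-Poisson mixture, mean mu, dispersion theta."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def make_lattice_sample(
    config: SimulationConfig,
) -> tuple[SpotLattice, CountsMatrix, GroundTruth]:
    """Simulate a zoned spot lattice with planted ISG colonies."""
    lattice = full_hex_lattice(
        config.lattice_rows,
        config.lattice_cols,
        spacing_um=config.spot_spacing_um,
        diameter_um=config.spot_diameter_um,
    )
    zones, _ = _zone_labels(lattice, config)
    graph = build_adjacency(lattice)
    nbrs = graph.neighbor_lists()
    rng_place = substream(config.seed, "placement")
    if config.n_colonies > 0:
        eligible = zones.mask("BZ") if config.colony_placement == "bz" else None
        if eligible is not None and eligible.sum() == 0:
            raise PlacementError("no borderzone spots available for colony placement")
        colonies = _plant_colonies(config, nbrs, eligible, rng_place)
    else:
        colonies = {}
    mu = _mean_matrix(config, zones, colonies, nbrs, lattice.n_spots)
    rng_counts = substream(config.seed, "counts")
    counts = _draw_nb(mu, config.nb_dispersion, rng_counts)
    X = sp.csr_matrix(counts)
    cm = CountsMatrix(list(config.panel), list(lattice.spot_ids), X, layer="raw")
    membership = {}
    colony_spot_indices = {}
    for ci, members in colonies.items():
        idx = np.array(sorted(members), dtype=int)
        colony_spot_indices[ci] = idx
        for m in idx:
            membership[str(lattice.spot_ids[m])] = ci
    truth = GroundTruth(
        zone_of_spot=zones,
        colony_membership=membership,
        colony_spot_indices=colony_spot_indices,
    )
    return lattice, cm, truth


def make_control_sample(
    config: SimulationConfig,
) -> tuple[SpotLattice, CountsMatrix, GroundTruth]:
    """Matched negative control: same generative process, zero colonies,
    unchanged ISG baseline."""
    return make_lattice_sample(replace(config, n_colonies=0))


# ---------------------------------------------------------------------------
# MERFISH-like point clouds


DEFAULT_CELLS_PER_TYPE = {
    "BZ CM": 500,
    "RZ CM": 420,
    "FB": 420,
    "Mac": 300,
    "Neut": 130,
    "EC": 230,
}
DEFAULT_TRANSCRIPTS_PER_CELL = {t: 60.0 for t in MERFISH_CELL_TYPES}


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radius: float,
    field_xy: tuple[float, float],
    min_separation: float | None = None,
    max_tries_per_disk: int = 200,
) -> np.ndarray:
    """Dart-throwing placement of non-overlapping disks.

    A uniform grid with bucket size equal to the separation keeps each
    rejection test local, so placement stays fast at thousands of disks.
    """
    sep = 2 * radius if min_separation is None else min_separation
    w, h = field_xy
    if radius * 2 > min(w, h):
        raise PlacementError("disk diameter exceeds field")
    centers: list[tuple[float, float]] = []
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    sep2 = sep * sep
    for i in range(n):
        for _ in range(max_tries_per_disk):
            cx = rng.uniform(radius, w - radius)
            cy = rng.uniform(radius, h - radius)
            gx, gy = int(cx // sep), int(cy // sep)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for ox, oy in grid.get((gx + dx, gy + dy), ()):
                        if (cx - ox) ** 2 + (cy - oy) ** 2 < sep2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers.append((cx, cy))
                grid.setdefault((gx, gy), []).append((cx, cy))
                break
        else:
            raise PlacementError(
                f"could not place disk {i + 1}/{n}: density exceeds packing feasibility"
            )
    return np.array(centers) if centers else np.empty((0, 2))


def make_merfish_sample(
    config: SimulationConfig,
    cells_per_type: dict[str, int] | None = None,
    transcripts_per_cell: dict[str, float] | None = None,
    field_um: tuple[float, float] = (1500.0, 1500.0),
    cell_radius_um: float = 8.0,
    colony_radius_um: float = 75.0,
    colony_min_separation_um: float = 320.0,
    isg_baseline_mean: float = 0.1,
    isg_enrichment: float = 100.0,
    ifna2_mean: float = 1.0,
) -> tuple[PointTable, CellTable, GroundTruth]:
    """Simulate a labelled single-molecule sample.

    Cells are non-overlapping disks of known type; each cell's transcripts
    are Poisson draws from its type profile, scattered uniformly inside
    its disk.  ``config.n_colonies`` circular colony regions are planted;
    cells inside them express ISG transcripts at ``isg_enrichment`` times
    the (low) baseline, and colony cells of interferon-competent types
    also express the initiator transcript Ifna2.  Every point carries its
    true cell id.
    """
    cells_per_type = cells_per_type or DEFAULT_CELLS_PER_TYPE
    transcripts_per_cell = transcripts_per_cell or DEFAULT_TRANSCRIPTS_PER_CELL
    unknown = set(cells_per_type) - set(MERFISH_CELL_TYPES)
    if unknown:
        raise ValidationError(f"unknown cell types: {sorted(unknown)}")
    rng_cells = substream(config.seed, "cells")
    rng_points = substream(config.seed, "points")

    colony_centers = _place_disks(
        rng_cells,
        config.n_colonies,
        colony_radius_um,
        field_um,
        min_separation=colony_min_separation_um,
        max_tries_per_disk=2000,
    )
    n_cells = int(sum(cells_per_type.values()))
    centers = _place_disks(rng_cells, n_cells, cell_radius_um, field_um)
    types = np.concatenate(
        [np.repeat(t, k) for t, k in cells_per_type.items()]
    )
    rng_cells.shuffle(types)
    in_colony = np.zeros(n_cells, dtype=bool)
    for c in colony_centers:
        in_colony |= np.linalg.norm(centers - c, axis=1) <= colony_radius_um

    cell_ids = np.array([f"cell_{i:05d}" for i in range(n_cells)])
    per_isg_gene = isg_baseline_mean / len(ISG_POINT_GENES)
    type_of = pd.Series(types)
    # per-gene expected transcript count for every cell, then one vectorized
    # Poisson + uniform-in-disk draw per gene
    frames = []
    for g in MERFISH_PANEL:
        mean_vec = np.zeros(n_cells)
        for t in cells_per_type:
            profile = MERFISH_TYPE_PROFILES[t]
            if g in profile:
                wsum = sum(profile.values())
                mean_vec[type_of.to_numpy() == t] += (
                    transcripts_per_cell.get(t, 0.0) * profile[g] / wsum
                )
        if g in ISG_POINT_GENES:
            mean_vec += per_isg_gene * np.where(in_colony, isg_enrichment, 1.0)
        if g == "Ifna2":
            for t, wt in IFNA2_SOURCE_WEIGHTS.items():
                mean_vec += ifna2_mean * wt * (in_colony & (types == t))
        k = rng_points.poisson(mean_vec)
        total = int(k.sum())
        if total == 0:
            continue
        owner = np.repeat(np.arange(n_cells), k)
        r = cell_radius_um * np.sqrt(rng_points.random(total))
        th = rng_points.random(total) * 2 * np.pi
        frames.append(
            pd.DataFrame(
                {
                    "x_um": centers[owner, 0] + r * np.cos(th),
                    "y_um": centers[owner, 1] + r * np.sin(th),
                    "species": g,
                    "cell_id": cell_ids[owner],
                }
            )
        )
    points = PointTable(
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["x_um", "y_um", "species", "cell_id"])
    )
    cells = CellTable(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "x_um": centers[:, 0],
                "y_um": centers[:, 1],
                "radius_um": cell_radius_um,
                "cell_type": types,
            }
        )
    )
    truth = GroundTruth(
        merfish_cell_types=dict(zip(cell_ids, types)),
        cell_in_colony=dict(zip(cell_ids, map(bool, in_colony))),
        colony_centers_um=colony_centers,
        colony_radius_um=colony_radius_um,
    )
    return points, cells, truth


# ---------------------------------------------------------------------------
# DNA loci


def make_dna_sample(
    n_nuclei: int,
    loci_per_nucleus: int,
    extranuclear_fraction: float,
    section_thickness_um: float = 16.0,
    seed: int = 0,
    nucleus_radius_um: float = 4.0,
    clearance_um: float = 5.0,
    field_um: tuple[float, float] | None = None,
) -> tuple[PointTable, GroundTruth]:
    """Simulate decoded DNA loci with a known extranuclear escape fraction.

    Nuclear loci are scattered densely inside non-overlapping nucleus
    disks; each locus independently escapes with probability
    ``extranuclear_fraction`` and is relocated uniformly outside all
    nuclei, at least ``clearance_um`` beyond every nucleus boundary.  A z
    coordinate uniform over the section thickness is attached to every
    locus.
    """
    if not (0 <= extranuclear_fraction < 1):
        raise ValidationError("extranuclear_fraction must be in [0, 1)")
    if loci_per_nucleus < 10:
        raise ValidationError("loci_per_nucleus must be >= 10")
    rng = substream(seed, "dna")
    if field_um is None:
        side = max(150.0, math.ceil(math.sqrt(n_nuclei)) * 12 * nucleus_radius_um)
        field_um = (side, side)
    centers = _place_disks(
        rng,
        n_nuclei,
        nucleus_radius_um + clearance_um,
        field_um,
        min_separation=2 * nucleus_radius_um + 1.0,
    )
    rows = []
    flags = []
    n_total = n_nuclei * loci_per_nucleus
    escape = rng.random(n_total) < extranuclear_fraction
    keep_out = nucleus_radius_um + clearance_um
    li = 0
    for ni in range(n_nuclei):
        for _ in range(loci_per_nucleus):
            if escape[li]:
                while True:
                    x = rng.uniform(0, field_um[0])
                    y = rng.uniform(0, field_um[1])
                    if np.all(
                        np.linalg.norm(centers - np.array([x, y]), axis=1) > keep_out
                    ):
                        break
                flags.append(True)
            else:
                r = nucleus_radius_um * np.sqrt(rng.random())
                th = rng.random() * 2 * np.pi
                x = centers[ni, 0] + r * np.cos(th)
                y = centers[ni, 1] + r * np.sin(th)
                flags.append(False)
            z = rng.uniform(0, section_thickness_um)
            rows.append((x, y, z, f"locus_{li % 260:03d}", f"nucleus_{ni:03d}"))
            li += 1
    points = PointTable(
        pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "species", "cell_id"])
    )
    truth = GroundTruth(
        extranuclear_flags=np.array(flags, dtype=bool),
        extranuclear_fraction=extranuclear_fraction,
    )
    return points, truth


# ---------------------------------------------------------------------------
# nucleus masks


def _star_polygon(
    radius_um: float,
    deformation: float,
    rotation: float,
    lobes: int = 5,
    lobe_depth: float = 0.6,
    axis_ratio: float = 0.85,
    n_vertices: int = 256,
) -> Polygon:
    """Template family from convex ellipse (deformation 0) to a lobed,
    concave star (deformation 1)."""
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius_um * (1.0 + lobe_depth * deformation * np.cos(lobes * (phi - rotation)))
    x = r * np.cos(phi)
    y = r * np.sin(phi) * axis_ratio
    return Polygon(np.column_stack([x, y]))


def polygon_solidity(poly: Polygon) -> float:
    return float(poly.area / poly.convex_hull.area)


def make_nucleus_set(
    n: int,
    deformation: float,
    seed: int = 0,
    um_per_px: float = 0.05,
    radius_um: float = 5.0,
    lobes: int = 5,
    lobe_depth: float = 0.6,
) -> tuple[NucleusMaskSet, GroundTruth]:
    """Rasterized nucleus masks at a known deformation level.

    Each nucleus is a randomly rotated, slightly size-jittered instance of
    the template family; truth solidity is computed exactly from the
    generating polygon (area / convex-hull area).  Masks are laid out on a
    shared label image in non-overlapping tiles.
    """
    if not (0 <= deformation <= 1):
        raise ValidationError("deformation must be in [0, 1]")
    rng = substream(seed, "nuclei")
    max_r = radius_um * (1 + lobe_depth) * 1.1
    tile_px = int(math.ceil(2 * max_r / um_per_px)) + 4
    cols = int(math.ceil(math.sqrt(n)))
    rows_n = int(math.ceil(n / cols))
    label_img = np.zeros((rows_n * tile_px, cols * tile_px), dtype=np.int32)
    truth_solidity: dict[int, float] = {}
    for i in range(n):
        rot = rng.uniform(0, 2 * np.pi)
        jitter = 1.0 + rng.uniform(-0.1, 0.1)
        poly = _star_polygon(
            radius_um * jitter, deformation, rot, lobes=lobes, lobe_depth=lobe_depth
        )
        truth_solidity[i + 1] = polygon_solidity(poly)
        r0 = (i // cols) * tile_px
        c0 = (i % cols) * tile_px
        # pixel centres of the tile, in polygon-local um coordinates
        jj, ii = np.meshgrid(np.arange(tile_px), np.arange(tile_px))
        xs = (jj.ravel() - tile_px / 2 + 0.5) * um_per_px
        ys = (ii.ravel() - tile_px / 2 + 0.5) * um_per_px
        inside = contains_xy(poly, xs, ys).reshape(tile_px, tile_px)
        label_img[r0 : r0 + tile_px, c0 : c0 + tile_px][inside] = i + 1
    masks = NucleusMaskSet(labels=label_img, um_per_px=um_per_px)
    return masks, GroundTruth(nucleus_solidity=truth_solidity)
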