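"""Microenvironment analysis around IFNIC colonies.

Each colony's highest-scoring spot is its centroid; spots at lattice graph
distance 1, 2 and 3 from the nearest centroid are its primary, secondary
and tertiary neighbours (one ring = one 100 um lattice step).  Ring-wise
differential expression against the centroids recovers the inverse
patterning of interferon-stimulated versus matricellular programs; line
scans report a gene score as a function of distance along an
infarct-to-borderzone vector; and neighbour-fraction profiles give the
fraction of query-positive spots in successive 100 um shells (0-400 um)
around a reference spot set.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .colony import ColonySet
from .containers import CountsMatrix
from .errors import ValidationError
from .lattice import AdjacencyGraph, SpotLattice
from .scoring import MarkerTable, ScoreVector

logger = logging.getLogger("ifniche")

RING_LABELS = {0: "centroid", 1: "primary", 2: "secondary", 3: "tertiary"}


@dataclass
class RingAssignment:
    """Per-spot ring index (0 = centroid, -1 = none) and owning colony id."""

    spot_ids: np.ndarray
    ring: np.ndarray
    colony_id: np.ndarray
    max_ring: int

    def label(self) -> np.ndarray:
        return np.array(
            [RING_LABELS.get(int(r), "none") if r >= 0 else "none" for r in self.ring]
        )

    def spots_in_ring(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.ring == k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spot_ids,
                "ring": self.ring,
                "label": self.label(),
                "colony_id": self.colony_id,
            }
        )


def _bfs_distances(graph: AdjacencyGraph, source: int, cutoff: int) -> dict[int, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        if dist[u] == cutoff:
            continue
        for v in graph.neighbors(u):
            v = int(v)
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def assign_rings(colonies: ColonySet, graph: AdjacencyGraph, max_ring: int = 3) -> RingAssignment:
    """Breadth-first rings of lattice distance 0..max_ring around colony centroids.

    Every spot takes the ring of its nearest centroid (ties broken toward
    the lower colony id), except that spots belonging to a colony always
    keep their own colony's assignment.
    """
    for c in colonies.colonies:
        if c.centroid_index is None:
            raise ValidationError(
                "colonies lack centroid annotation; run colony_stats first"
            )
    n = graph.n
    ring = np.full(n, -1, dtype=int)
    owner = np.full(n, -1, dtype=int)
    own_colony = np.full(n, -1, dtype=int)
    for c in colonies.colonies:
        own_colony[c.spot_indices] = c.colony_id
    # nearest-centroid assignment, lower colony id wins ties
    for c in colonies.colonies:
        dist = _bfs_distances(graph, int(c.centroid_index), max_ring)
        for spot, d in dist.items():
            if ring[spot] == -1 or d < ring[spot]:
                ring[spot] = d
                owner[spot] = c.colony_id
    # colony members keep their own colony's assignment
    for c in colonies.colonies:
        dist = _bfs_distances(graph, int(c.centroid_index), max(max_ring, n))
        for spot in c.spot_indices:
            spot = int(spot)
            ring[spot] = dist.get(spot, -1)
            owner[spot] = c.colony_id
    return RingAssignment(
        spot_ids=graph.spot_ids, ring=ring, colony_id=owner, max_ring=max_ring
    )


def ring_de(
    counts: CountsMatrix,
    rings: RingAssignment,
    min_group: int = 3,
    max_adj_p: float = 1.0,
) -> dict[int, MarkerTable]:
    """Per-ring Wilcoxon rank-sum differential expression against centroids.

    For each ring k = 1..max_ring, every gene is tested (ring-k spots vs
    centroid spots, pooled across colonies), BH-adjusted over genes.  The
    effect size is the natural-log fold change of de-logged means (+1
    pseudocount); under-sized groups are skipped with a warning.
    """
    if counts.layer != "lognorm":
        raise ValidationError("ring_de expects the lognorm layer")
    if counts.n_units != len(rings.spot_ids):
        raise ValidationError("counts units do not match ring assignment")
    X = np.asarray(counts.X.todense())
    centroid_idx = rings.spots_in_ring(0)
    out: dict[int, MarkerTable] = {}
    if len(centroid_idx) < min_group:
        logger.warning("ring_de: fewer than %d centroid spots; nothing tested", min_group)
        return out
    Xc = X[:, centroid_idx]
    for k in range(1, rings.max_ring + 1):
        ring_idx = rings.spots_in_ring(k)
        if len(ring_idx) < min_group:
            logger.warning("ring_de: ring %d has %d spots; skipped", k, len(ring_idx))
            continue
        Xk = X[:, ring_idx]
        mean_k = np.expm1(Xk).mean(axis=1)
        mean_c = np.expm1(Xc).mean(axis=1)
        ln_fc = np.log(mean_k + 1.0) - np.log(mean_c + 1.0)
        constant = np.ptp(X[:, np.concatenate([ring_idx, centroid_idx])], axis=1) == 0
        p = np.ones(counts.n_genes)
        var_genes = np.flatnonzero(~constant)
        if len(var_genes):
            res = mannwhitneyu(
                Xk[var_genes], Xc[var_genes], axis=1, alternative="two-sided",
                method="asymptotic",
            )
            p[var_genes] = res.pvalue
        p_adj = multipletests(p, method="fdr_bh")[1]
        p_adj = np.maximum(p_adj, p)
        df = pd.DataFrame(
            {
                "gene": counts.genes,
                "ln_fc": ln_fc,
                "frac_a": (Xk > 0).mean(axis=1),
                "frac_b": (Xc > 0).mean(axis=1),
                "p_value": p,
                "p_adj": p_adj,
            }
        )
        df = df[df["p_adj"] <= max_adj_p].reset_index(drop=True)
        out[k] = MarkerTable(df)
    return out


@dataclass
class LineScanProfile:
    bins: pd.DataFrame  # distance_lo_um, distance_hi_um, mean, se, n

    def __post_init__(self):
        lo = self.bins["distance_lo_um"].to_numpy()
        hi = self.bins["distance_hi_um"].to_numpy()
        if not (hi > lo).all():
            raise ValidationError("line-scan bins must be non-degenerate")


def line_scan(
    scores: ScoreVector,
    lattice: SpotLattice,
    p0,
    p1,
    bin_um: float = 100.0,
    band_halfwidth_um: float = 200.0,
) -> LineScanProfile:
    """Score profile along the vector p0 -> p1.

    Spots within ``band_halfwidth_um`` of the segment are projected onto
    it; per ``bin_um`` distance bin the mean score, its standard error and
    the spot count are reported.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    v = p1 - p0
    length = float(np.linalg.norm(v))
    if length == 0:
        raise ValidationError("line scan endpoints coincide")
    coords = lattice.coords_um
    if len(scores.values) != len(coords):
        raise ValidationError("score length != lattice size")
    rel = coords - p0
    t = rel @ (v / length)                     # along-track distance
    perp = np.abs(rel @ (np.array([-v[1], v[0]]) / length))
    in_band = (perp <= band_halfwidth_um) & (t >= 0) & (t <= length)
    if not in_band.any():
        raise ValidationError("no spots fall inside the line-scan band")
    edges = np.arange(0.0, length + bin_um, bin_um)
    if edges[-1] < length:
        edges = np.append(edges, length)
    rows = []
    which = np.clip(np.digitize(t[in_band], edges) - 1, 0, len(edges) - 2)
    vals = scores.values[in_band]
    for b in range(len(edges) - 1):
        sel = vals[which == b]
        n = len(sel)
        rows.append(
            {
                "distance_lo_um": edges[b],
                "distance_hi_um": edges[b + 1],
                "mean": float(sel.mean()) if n else np.nan,
                "se": float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            }
        )
    return LineScanProfile(pd.DataFrame(rows))


def neighbor_fraction_profile(
    reference_states,
    query_states,
    graph: AdjacencyGraph,
    max_distance_um: float = 400.0,
    spacing_um: float = 100.0,
) -> pd.DataFrame:
    """Fraction of query-positive spots per lattice-distance shell around a
    reference spot set (shells of one lattice step each, ~100 um)."""
    ref = np.asarray(reference_states, dtype=bool)
    query = np.asarray(query_states, dtype=bool)
    if len(ref) != graph.n or len(query) != graph.n:
        raise ValidationError("state vectors must match graph size")
    if not ref.any():
        raise ValidationError("reference set is empty")
    max_ring = int(round(max_distance_um / spacing_um))
    dist = np.full(graph.n, -1, dtype=int)
    sources = np.flatnonzero(ref)
    dist[sources] = 0
    frontier = deque(int(i) for i in sources)
    while frontier:
        u = frontier.popleft()
        if dist[u] == max_ring:
            continue
        for vtx in graph.neighbors(u):
            vtx = int(vtx)
            if dist[vtx] == -1:
                dist[vtx] = dist[u] + 1
                frontier.append(vtx)
    rows = []
    for k in range(1, max_ring + 1):
        shell = np.flatnonzero(dist == k)
        frac = float(query[shell].mean()) if len(shell) else np.nan
        rows.append(
            {
                "distance_um": k * spacing_um,
                "ring": k,
                "fraction": frac,
                "n_spots": len(shell),
            }
        )
    return pd.DataFrame(rows)
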