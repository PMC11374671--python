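"""DBSCAN colony calling, epsilon selection, extranuclear DNA, solidity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gamma as gamma_fn

from ifniche.containers import CellTable, NucleusMaskSet, PointTable
from ifniche.errors import SampleSizeError, ValidationError
from ifniche.points import (
    DbscanParams,
    ExtranuclearParams,
    classify_extranuclear,
    classify_isg_clusters,
    cluster_jaccard,
    colony_composition,
    dbscan,
    nuclear_solidity,
    select_eps,
)
from ifniche.simulate import make_dna_sample, make_nucleus_set


def _points(coords, species="Ifit1", cell_id=None):
    coords = np.asarray(coords, float)
    df = pd.DataFrame({"x_um": coords[:, 0], "y_um": coords[:, 1], "species": species})
    if cell_id is not None:
        df["cell_id"] = cell_id
    return PointTable(df)


def dbscan_oracle(coords, eps, min_samples):
    """Brute-force density-reachability oracle (quadratic)."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    within = d <= eps
    core = within.sum(axis=1) >= min_samples  # self included
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            u = stack.pop()
            if not core[u]:
                continue
            for v in np.flatnonzero(within[u]):
                if labels[v] == -1:
                    labels[v] = cid
                    if core[v]:
                        stack.append(v)
        cid += 1
    return labels, core


def labels_equivalent(a, b, a_core=None):
    """Same partition up to renaming; border points may tie-break differently
    between valid DBSCAN labelings, so compare core points and noise."""
    a, b = np.asarray(a), np.asarray(b)
    if a_core is None:
        return ((a == -1) == (b == -1)).all()
    noise_match = ((a == -1) == (b == -1)).all()
    mapping = {}
    for i in np.flatnonzero(a_core):
        la, lb = a[i], b[i]
        if la in mapping and mapping[la] != lb:
            return False
        mapping[la] = lb
    return noise_match and len(set(mapping.values())) == len(mapping)


class TestSelectEps:
    def test_two_separated_blobs_select_intra_scale(self, rng):
        blob1 = rng.uniform(0, 30, size=(60, 2))
        blob2 = rng.uniform(0, 30, size=(60, 2)) + np.array([230.0, 0.0])
        res = select_eps(_points(np.vstack([blob1, blob2])), k=4)
        assert 1.0 < res.eps < 200.0

    def test_uniform_poisson_field_near_theory(self, rng):
        from scipy.stats import gamma as gamma_dist

        lam = 0.02  # points per um^2
        side = 300.0
        n = rng.poisson(lam * side * side)
        pts = rng.uniform(0, side, size=(n, 2))
        k = 10
        res = select_eps(_points(pts), k=k)
        # For a 2D Poisson process the squared k-NN distance is
        # Gamma(k, 1/(pi*lam)); the knee of a homogeneous sorted curve sits
        # where the upper tail departs, near the distribution's 90th
        # percentile (closed-form oracle).
        mean_d = gamma_fn(k + 0.5) / (gamma_fn(k) * math.sqrt(math.pi * lam))
        q90_d = math.sqrt(gamma_dist(k, scale=1.0 / (math.pi * lam)).ppf(0.90))
        assert abs(res.eps - q90_d) / q90_d < 0.2
        # and it stays at the field's intrinsic scale, not the extreme tail
        assert 0.5 * mean_d < res.eps < 2.0 * mean_d

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(SampleSizeError):
            select_eps(_points(rng.random((5, 2))), k=5)


class TestDbscan:
    def test_dense_disk_single_cluster(self, rng):
        r = 5.0 * np.sqrt(rng.random(20))
        th = rng.random(20) * 2 * np.pi
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        labels = dbscan(_points(pts), DbscanParams(eps=70.0, min_samples=10))
        assert (labels == 0).all()

    def test_isolated_point_is_noise(self, rng):
        pts = np.vstack([rng.random((20, 2)) * 5, [[500.0, 500.0]]])
        labels = dbscan(_points(pts), DbscanParams(eps=70.0, min_samples=10))
        assert labels[-1] == -1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 120))
            pts = rng.uniform(0, 100, size=(n, 2))
            eps = float(rng.uniform(3, 25))
            ms = int(rng.integers(2, 8))
            labels = dbscan(_points(pts), DbscanParams(eps=eps, min_samples=ms))
            oracle, core = dbscan_oracle(pts, eps, ms)
            assert labels_equivalent(labels, oracle, core)

    def test_invariant_to_reordering_and_rigid_motion(self, rng):
        pts = rng.uniform(0, 50, size=(80, 2))
        params = DbscanParams(eps=8.0, min_samples=4)
        base = dbscan(_points(pts), params)
        perm = rng.permutation(len(pts))
        shuffled = dbscan(_points(pts[perm]), params)
        assert ((base == -1)[perm] == (shuffled == -1)).all()
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = dbscan(_points(pts @ R.T + 1000.0), params)
        assert ((base == -1) == (moved == -1)).all()
        # partition identical up to cluster renaming
        df = pd.DataFrame({"a": base, "b": moved})
        grouped = df[df["a"] >= 0].groupby("a")["b"].nunique()
        assert (grouped == 1).all()


class TestIsgClusters:
    def test_all_background_no_clusters(self, rng):
        pts = rng.uniform(0, 1000, size=(100, 2))
        res = classify_isg_clusters(_points(pts))
        assert res.n_clusters == 0 and len(res.scattered) == 100

    def test_planted_point_colonies_recovered(self, rng):
        centers = np.array([[200.0, 200.0], [800.0, 200.0], [500.0, 800.0]])
        blobs = [c + rng.normal(scale=20.0, size=(120, 2)) for c in centers]
        noise = rng.uniform(0, 1000, size=(40, 2))
        pts = np.vstack(blobs + [noise])
        res = classify_isg_clusters(_points(pts))
        assert res.n_clusters == 3
        truth_sets = [np.arange(i * 120, (i + 1) * 120) for i in range(3)]
        for ts in truth_sets:
            best = max(cluster_jaccard(c, ts) for c in res.clusters)
            assert best >= 0.9


class TestComposition:
    def _cells(self, type_map):
        rows = [
            {"cell_id": cid, "x_um": 0.0, "y_um": 0.0, "radius_um": 8.0, "cell_type": t}
            for cid, t in type_map.items()
        ]
        return CellTable(pd.DataFrame(rows))

    def test_pure_fibroblast_cluster(self):
        pts = _points(np.random.default_rng(0).random((30, 2)) * 5,
                      cell_id=["c1"] * 15 + ["c2"] * 15)
        res = classify_isg_clusters(pts, DbscanParams(eps=10.0, min_samples=5))
        comp = colony_composition(res, self._cells({"c1": "FB", "c2": "FB"}))
        assert (comp["cell_type"] == "FB").all()
        assert comp["proportion"].sum() == pytest.approx(1.0)

    def test_min_transcripts_rule(self):
        coords = np.vstack([np.random.default_rng(1).random((20, 2)) * 5, [[2.0, 2.0]]])
        pts = _points(coords, cell_id=["c1"] * 20 + ["c2"])
        res = classify_isg_clusters(pts, DbscanParams(eps=10.0, min_samples=5))
        comp = colony_composition(res, self._cells({"c1": "FB", "c2": "Mac"}),
                                  positive_min_transcripts=2)
        assert set(comp["cell_type"]) == {"FB"}

    def test_planted_mixture_recovered(self, rng):
        # an 80/20 cardiomyocyte/fibroblast split among interferon-expressing
        # cells inside a colony, recovered within binomial error
        n_cells = 200
        types = np.where(rng.random(n_cells) < 0.8, "BZ CM", "FB")
        cells = self._cells({f"c{i}": t for i, t in enumerate(types)})
        coords, ids = [], []
        for i in range(n_cells):
            k = 1 + rng.poisson(2)
            center = rng.uniform(0, 60, size=2)
            coords.append(center + rng.normal(scale=2.0, size=(k, 2)))
            ids += [f"c{i}"] * k
        pts = _points(np.vstack(coords), cell_id=ids)
        res = classify_isg_clusters(pts, DbscanParams(eps=15.0, min_samples=5))
        comp = colony_composition(res, cells)
        big = comp[comp["cluster"] == comp.groupby("cluster")["n_cells_total"].idxmax().index[0]]
        cm = comp[comp["cell_type"] == "BZ CM"]["n_positive_cells"].sum()
        total = comp.groupby("cluster")["n_cells_total"].first().sum()
        se = math.sqrt(0.8 * 0.2 / max(total, 1))
        assert abs(cm / total - 0.8) < 4 * se + 0.02


class TestExtranuclear:
    def test_dense_nucleus_all_nuclear(self, rng):
        r = 4.0 * np.sqrt(rng.random(50))
        th = rng.random(50) * 2 * np.pi
        pts = _points(np.column_stack([r * np.cos(th), r * np.sin(th)]), species="locus")
        res = classify_extranuclear(pts)
        assert res.n_nuclear == 50 and res.n_extranuclear == 0

    def test_isolated_locus_extranuclear(self, rng):
        coords = np.vstack([rng.random((50, 2)) * 4, [[100.0, 100.0]]])
        res = classify_extranuclear(_points(coords, species="locus"))
        assert res.labels[-1] == "extranuclear"

    def test_adding_neighbors_never_flips_to_extranuclear(self, rng):
        coords = rng.uniform(0, 40, size=(60, 2))
        res1 = classify_extranuclear(_points(coords, species="locus"))
        extra = coords[:20] + rng.normal(scale=0.5, size=(20, 2))
        res2 = classify_extranuclear(_points(np.vstack([coords, extra]), species="locus"))
        was_nuclear = res1.labels == "nuclear"
        assert (res2.labels[:60][was_nuclear] == "nuclear").all()

    def test_label_partition_complete(self):
        loci, _ = make_dna_sample(10, 30, 0.2, seed=3)
        res = classify_extranuclear(loci, section_thickness_um=16.0)
        assert res.n_nuclear + res.n_extranuclear + res.n_edge_excluded == loci.n

    def test_escape_fraction_recovered(self):
        estimates = []
        for seed in range(10):
            loci, truth = make_dna_sample(10, 100, 0.10, seed=seed)
            res = classify_extranuclear(loci, section_thickness_um=16.0)
            estimates.append(res.extranuclear_fraction)
        assert abs(np.mean(estimates) - 0.10) < 0.03

    def test_zero_escape_zero_extranuclear(self):
        loci, _ = make_dna_sample(10, 100, 0.0, seed=1)
        res = classify_extranuclear(loci, section_thickness_um=16.0)
        assert res.n_extranuclear == 0


class TestSolidity:
    def _raster_ellipse(self, a=40, b=25, um_per_px=0.1):
        n = 2 * max(a, b) + 5
        yy, xx = np.mgrid[:n, :n]
        c = n / 2
        mask = ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0
        return NucleusMaskSet(mask.astype(np.int32), um_per_px)

    def test_convex_ellipse_solidity_near_one(self):
        res = nuclear_solidity(self._raster_ellipse(a=100, b=60, um_per_px=0.05))
        assert res.table["solidity"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_cross_shape_matches_polygon_oracle(self):
        # plus sign: two 3x9 bars -> area 45 px^2; hull is the octagon over
        # the outer corners
        from shapely.geometry import Polygon

        mask = np.zeros((13, 13), dtype=np.int32)
        mask[5:8, 2:11] = 1
        mask[2:11, 5:8] = 1
        res = nuclear_solidity(NucleusMaskSet(mask, 1.0))
        row = res.table.iloc[0]
        assert row["mask_area_um2"] == pytest.approx(45.0)
        # oracle: shoelace area of the convex hull of the pixel centres
        yy, xx = np.nonzero(mask)
        hull = Polygon(
            [(2, 5), (5, 2), (7, 2), (10, 5), (10, 7), (7, 10), (5, 10), (2, 7)]
        )
        assert row["hull_area_um2"] == pytest.approx(hull.convex_hull.area)
        assert row["solidity"] == pytest.approx(45.0 / hull.convex_hull.area)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[0:2, 0:2] = 1
        mask[7:9, 7:9] = 1
        with pytest.raises(ValidationError, match="components"):
            nuclear_solidity(NucleusMaskSet(mask, 1.0))

    def test_generator_truth_recovered_and_ordered(self):
        sols = {}
        for d in (0.0, 0.4, 0.8):
            masks, truth = make_nucleus_set(6, d, seed=7)
            measured = nuclear_solidity(masks).solidity()
            expected = pd.Series(truth.nucleus_solidity)
            assert np.allclose(measured, expected.loc[measured.index], atol=0.03)
            sols[d] = measured.mean()
        assert sols[0.0] > sols[0.4] > sols[0.8]

    def test_deformation_zero_truth_is_one(self):
        _, truth = make_nucleus_set(3, 0.0, seed=0)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in truth.nucleus_solidity.values())
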