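"""Ground-truth contracts of the synthetic-data generator."""

import dataclasses
import io

import numpy as np
import pytest

from ifniche.errors import PlacementError, ValidationError
from ifniche.lattice import build_adjacency
from ifniche.simulate import (
    MERFISH_PANEL,
    SimulationConfig,
    make_control_sample,
    make_dna_sample,
    make_lattice_sample,
    make_merfish_sample,
    make_nucleus_set,
)


def _serialize(counts):
    import scipy.io

    buf = io.BytesIO()
    scipy.io.mmwrite(buf, counts.X.tocoo())
    return buf.getvalue()


class TestLatticeSample:
    def test_null_configuration(self):
        cfg = SimulationConfig(seed=0, n_colonies=0)
        _, counts, truth = make_lattice_sample(cfg)
        assert truth.colony_membership == {}
        # ISG gene means equal across zones (no colony, no zone program)
        zl = np.asarray(truth.zone_of_spot.labels)
        vals = counts.gene_values("Ifit1").astype(float)
        means = [vals[zl == z].mean() for z in ("IZ", "BZ", "RZ")]
        pooled_se = vals.std() / np.sqrt(min((zl == z).sum() for z in ("IZ", "BZ", "RZ")))
        assert max(means) - min(means) < 6 * pooled_se

    def test_bz_colonies_lie_in_annulus(self):
        cfg = SimulationConfig(seed=4, n_colonies=3)
        lat, _, truth = make_lattice_sample(cfg)
        coords = lat.coords_um
        center = coords.mean(axis=0)
        for idx in truth.colony_spot_indices.values():
            d = np.linalg.norm(coords[idx] - center, axis=1)
            assert (d > cfg.iz_radius_um).all()
            assert (d <= cfg.iz_radius_um + cfg.bz_width_um).all()

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=123, n_colonies=4)
        lat1, c1, t1 = make_lattice_sample(cfg)
        lat2, c2, t2 = make_lattice_sample(cfg)
        assert _serialize(c1) == _serialize(c2)
        assert t1.colony_membership == t2.colony_membership
        assert (np.asarray(t1.zone_of_spot.labels) == np.asarray(t2.zone_of_spot.labels)).all()

    def test_colonies_are_connected_components(self):
        cfg = SimulationConfig(seed=8, n_colonies=5)
        lat, _, truth = make_lattice_sample(cfg)
        g = build_adjacency(lat)
        nbrs = g.neighbor_lists()
        for idx in truth.colony_spot_indices.values():
            members = set(map(int, idx))
            seen = {next(iter(members))}
            stack = list(seen)
            while stack:
                u = stack.pop()
                for v in nbrs[u]:
                    if int(v) in members and int(v) not in seen:
                        seen.add(int(v))
                        stack.append(int(v))
            assert seen == members

    def test_count_marginals_match_nb_parameters(self):
        cfg = SimulationConfig(seed=13, n_colonies=0)
        _, counts, truth = make_lattice_sample(cfg)
        zl = np.asarray(truth.zone_of_spot.labels)
        rz = zl == "RZ"  # no zone programs, pure baseline
        n = int(rz.sum())
        assert n >= 2000
        theta = cfg.nb_dispersion
        for gene, mu in (("Ifit1", cfg.isg_baseline_mean), ("Gapdh", cfg.background_mean)):
            x = counts.gene_values(gene).astype(float)[rz]
            var = mu + mu**2 / theta
            se_mean = np.sqrt(var / n)
            assert abs(x.mean() - mu) < 3 * se_mean
            # variance of the sample variance of an overdispersed count
            m4 = ((x - x.mean()) ** 4).mean()
            se_var = np.sqrt((m4 - var**2 * (n - 3) / (n - 1)) / n)
            assert abs(x.var(ddof=1) - var) < 3 * se_var

    def test_control_matches_stimulated_baseline(self):
        cfg = SimulationConfig(seed=17, n_colonies=3)
        lat, counts, truth = make_lattice_sample(cfg)
        _, ctrl, ctrl_truth = make_control_sample(cfg)
        assert ctrl_truth.colony_membership == {}
        colony = np.zeros(counts.n_units, bool)
        for idx in truth.colony_spot_indices.values():
            colony[idx] = True
        stim = counts.gene_values("Ifit1").astype(float)[~colony]
        con = ctrl.gene_values("Ifit1").astype(float)
        se = np.sqrt(stim.var() / len(stim) + con.var() / len(con))
        assert abs(stim.mean() - con.mean()) < 4 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(spot_spacing_um=50.0, spot_diameter_um=55.0)
        with pytest.raises(ValidationError):
            SimulationConfig(colony_size_range=(0, 5))
        with pytest.raises(ValidationError):
            SimulationConfig(nb_dispersion=0.0)
        with pytest.raises(ValidationError):
            SimulationConfig(iz_radius_um=5000.0, bz_width_um=1000.0)

    def test_impossible_placement_raises(self):
        # a borderzone too small for 40 non-adjacent colonies
        cfg = SimulationConfig(seed=0, n_colonies=40, iz_radius_um=700.0,
                               bz_width_um=120.0)
        with pytest.raises(PlacementError, match="colony"):
            make_lattice_sample(cfg)


@pytest.fixture(scope="module")
def sample():
    cfg = SimulationConfig(seed=31, n_colonies=8)
    return cfg, make_merfish_sample(cfg)


class TestMerfishSample:
    def test_panel_has_33_genes(self):
        assert len(MERFISH_PANEL) == 33
        assert len(set(MERFISH_PANEL)) == 33

    def test_points_inside_parent_cell_disk(self, sample):
        _, (points, cells, truth) = sample
        merged = points.table.merge(cells.table, on="cell_id", suffixes=("", "_cell"))
        d = np.hypot(merged["x_um"] - merged["x_um_cell"], merged["y_um"] - merged["y_um_cell"])
        assert (d <= merged["radius_um"] + 1e-9).all()

    def test_cell_disks_do_not_overlap(self, sample):
        from scipy.spatial import cKDTree

        _, (points, cells, truth) = sample
        xy = cells.table[["x_um", "y_um"]].to_numpy()
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=2 * cells.table["radius_um"].iloc[0] - 1e-9)
        assert len(pairs) == 0

    def test_isg_enrichment_ratio_in_colony(self, sample):
        cfg, (points, cells, truth) = sample
        isg = points.table[points.table["species"].isin(["Ifit1", "Ifit2", "Ifit3", "Cxcl10"])]
        per_cell = isg.groupby("cell_id").size()
        in_colony = np.array([truth.cell_in_colony[c] for c in cells.table["cell_id"]])
        counts = cells.table["cell_id"].map(per_cell).fillna(0).to_numpy()
        n_in = int(in_colony.sum())
        assert n_in >= 50
        ratio = counts[in_colony].mean() / max(counts[~in_colony].mean(), 1e-9)
        # planted enrichment is 100x; Monte Carlo mean over >= 100 cells
        assert 50 < ratio < 200

    def test_species_all_from_panel(self, sample):
        _, (points, _, _) = sample
        assert set(points.table["species"]) <= set(MERFISH_PANEL)

    def test_single_cell_all_points_in_disk(self):
        cfg = SimulationConfig(seed=2, n_colonies=0)
        points, cells, _ = make_merfish_sample(
            cfg, cells_per_type={"FB": 1}, transcripts_per_cell={"FB": 10.0}
        )
        assert points.n > 0
        c = cells.table.iloc[0]
        d = np.hypot(points.table["x_um"] - c["x_um"], points.table["y_um"] - c["y_um"])
        assert (d <= c["radius_um"]).all()

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(seed=0, n_colonies=0)
        with pytest.raises(PlacementError):
            make_merfish_sample(cfg, cells_per_type={"FB": 5000},
                                field_um=(100.0, 100.0))


class TestDnaSample:
    def test_zero_fraction_all_nuclear_flags(self):
        _, truth = make_dna_sample(10, 30, 0.0, seed=0)
        assert not truth.extranuclear_flags.any()

    def test_escape_count_binomial(self):
        loci, truth = make_dna_sample(10, 100, 0.1, seed=5)
        k = int(truth.extranuclear_flags.sum())
        se = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(k - 100) < 4 * se

    def test_escaped_points_clear_of_nuclei(self):
        loci, truth = make_dna_sample(10, 50, 0.2, seed=2, nucleus_radius_um=4.0)
        tab = loci.table
        nuclei = tab[~truth.extranuclear_flags].groupby("cell_id")[["x_um", "y_um"]]
        centers = nuclei.mean()  # approximate centres suffice: clearance is 5 um
        esc = tab[truth.extranuclear_flags]
        for _, row in esc.iterrows():
            d = np.hypot(centers["x_um"] - row["x_um"], centers["y_um"] - row["y_um"])
            assert (d > 4.0).all()

    def test_reproducible(self):
        a, _ = make_dna_sample(5, 20, 0.1, seed=9)
        b, _ = make_dna_sample(5, 20, 0.1, seed=9)
        assert a.table.equals(b.table)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            make_dna_sample(5, 20, 1.0, seed=0)


class TestNucleusSet:
    def test_truth_solidity_monotone_in_deformation(self):
        means = []
        for d in np.linspace(0, 1, 6):
            _, truth = make_nucleus_set(5, float(d), seed=3)
            means.append(np.mean(list(truth.nucleus_solidity.values())))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_masks_are_disjoint_labels(self):
        masks, _ = make_nucleus_set(7, 0.5, seed=1)
        ids = masks.nucleus_ids
        assert len(ids) == 7
        total = sum(masks.mask(int(i)).sum() for i in ids)
        assert total == (masks.labels > 0).sum()

    def test_reproducible(self):
        m1, t1 = make_nucleus_set(4, 0.3, seed=11)
        m2, t2 = make_nucleus_set(4, 0.3, seed=11)
        assert np.array_equal(m1.labels, m2.labels)
        assert t1.nucleus_solidity == t2.nucleus_solidity
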