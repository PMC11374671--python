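"""End-to-end orchestration with a single config and seed.

Stage order mirrors the analysis: QC -> normalization -> ISG scoring ->
threshold (negative-control calibration or published default) -> colony
segmentation and quantification -> spatial autocorrelation (Moran's I,
diffusion time) -> Monte Carlo borderzone localization -> niche rings and
ring differential expression -> optional single-molecule stages (point
colony calling and composition, extranuclear DNA, nuclear solidity).
Every randomized stage consumes an independent substream of the master
seed; a manifest records the config hash, seed, declared substitutions
and a content hash for every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ifio
from .colony import ColonySet, colony_stats, localization_test, segment_colonies
from .containers import GeneSet
from .errors import PipelineStageError, ValidationError
from .lattice import build_adjacency
from .niche import assign_rings, neighbor_fraction_profile, ring_de
from .points import (
    DbscanParams,
    classify_isg_clusters,
    classify_extranuclear,
    colony_composition,
    nuclear_solidity,
)
from .scoring import (
    ScoreVector,
    binarize_score,
    calibrate_threshold,
    published_default_threshold,
    score_gene_set,
)
from .simulate import (
    SimulationConfig,
    make_control_sample,
    make_dna_sample,
    make_lattice_sample,
    make_merfish_sample,
    make_nucleus_set,
)
from .spatial_stats import moran_results_frame, morans_test_genomewide, sepal_score

logger = logging.getLogger("ifniche")

#: colony-calling calibration quantile: per-spot false-positive rate of
#: ~1e-4, i.e. at most about one false ISG+ spot per ~3,000-spot section
COLONY_CALIBRATION_QUANTILE = 0.9999


@dataclass
class PipelineConfig:
    outdir: str = "ifniche_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    counts_mtx: str | None = None
    features_tsv: str | None = None
    barcodes_tsv: str | None = None
    positions_csv: str | None = None
    gene_sets_path: str | None = None
    threshold_mode: str = "calibrate"  # or "published_default"
    calibration_quantile: float = COLONY_CALIBRATION_QUANTILE
    qc_min_genes: int = 10  # panel-scale default; use 200 for transcriptome data
    qc_min_units_per_gene: int = 3
    qc_max_mito_fraction: float = 0.05
    n_top_variable: int = 2000
    n_permutations: int = 999
    localization_trials: int = 500
    localization_max_size: int = 12
    run_morans: bool = True
    run_sepal: bool = True
    run_localization: bool = True
    run_niche: bool = True
    run_merfish: bool = False
    run_dna: bool = False
    run_nuclei: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        file_inputs = [self.counts_mtx, self.features_tsv, self.barcodes_tsv, self.positions_csv]
        has_files = any(x is not None for x in file_inputs)
        if has_files and self.simulation is not None:
            raise ValidationError("config must give either input paths or a simulation block, not both")
        if not has_files and self.simulation is None:
            raise ValidationError("config needs input paths or a simulation block")
        if has_files and not all(x is not None for x in file_inputs):
            raise ValidationError("file input requires counts, features, barcodes and positions paths")
        if self.threshold_mode not in ("calibrate", "published_default"):
            raise ValidationError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_mode == "calibrate" and self.simulation is None:
            raise ValidationError("calibrated thresholds require a simulated control sample")


def load_pipeline_config(path) -> PipelineConfig:
    path = Path(path)
    raw = (
        json.loads(path.read_text())
        if path.suffix.lower() == ".json"
        else yaml.safe_load(path.read_text())
    )
    sim = raw.pop("simulation", None)
    config = PipelineConfig(**raw, simulation=None if sim is None else SimulationConfig(**sim))
    return config


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(str(type(o)))

    fields = dataclasses.asdict(config)
    fields.pop("outdir", None)  # where results land is not part of the analysis
    fields.pop("log_level", None)
    payload = json.dumps(fields, default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineReport:
    outdir: Path
    manifest: dict

    def file_hashes(self) -> dict[str, str]:
        return dict(self.manifest["files"])


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every enabled stage and return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "substitutions": [ifio.NORMALIZATION_NOTE],
        "stages": [],
        "files": {},
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    outputs: list[Path] = []

    def emit_frame(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)

    def emit_json(obj, name: str):
        path = outdir / name
        ifio.write_report(obj, path)
        outputs.append(path)

    stage = "input"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            lattice, counts, truth = make_lattice_sample(sim)
            _, control_counts, _ = make_control_sample(sim)
        else:
            counts = ifio.read_counts_mtx(
                config.counts_mtx, config.features_tsv, config.barcodes_tsv
            )
            lattice = ifio.read_spot_positions(config.positions_csv)
            truth = None
            control_counts = None
        manifest["stages"].append(stage)

        stage = "qc"
        counts = ifio.qc_filter(
            counts,
            min_genes=config.qc_min_genes,
            min_units_per_gene=config.qc_min_units_per_gene,
            max_mito_fraction=config.qc_max_mito_fraction,
        )
        keep = lattice.table["spot_id"].isin(counts.units).to_numpy()
        lattice = dataclasses.replace(
            lattice, table=lattice.table[keep].reset_index(drop=True)
        )
        manifest["stages"].append(stage)

        stage = "normalize"
        lognorm = ifio.normalize_log10k(counts)
        manifest["stages"].append(stage)

        stage = "score"
        if config.gene_sets_path is not None:
            sets = {s.role: s for s in ifio.read_gene_sets(config.gene_sets_path)}
            isg_set = sets.get("ISG") or next(iter(sets.values()))
            bz_set = sets.get("BZ")
        else:
            sim = config.simulation
            isg_set = GeneSet("ISG score", [g for g in sim.isg_genes if g in counts.genes], "ISG")
            bz_set = GeneSet("BZ score", [g for g in sim.bz_genes if g in counts.genes], "BZ")
        isg_scores = score_gene_set(counts, isg_set, basis="summed_counts")
        emit_frame(
            pd.DataFrame({"spot_id": counts.units, "isg_score_counts": isg_scores.values}),
            "isg_scores.tsv",
        )
        manifest["stages"].append(stage)

        stage = "threshold"
        if config.threshold_mode == "calibrate":
            control_scores = score_gene_set(control_counts, isg_set, basis="summed_counts")
            threshold = calibrate_threshold(
                control_scores, quantile=config.calibration_quantile,
                control_sample_id="matched_control",
            )
        else:
            threshold = published_default_threshold("isg_score", "summed_counts")
        emit_json(
            {
                "threshold": threshold.value,
                "basis": threshold.basis,
                "provenance": threshold.provenance,
                "quantile": config.calibration_quantile
                if threshold.provenance == "calibrated"
                else None,
            },
            "threshold.json",
        )
        states = binarize_score(isg_scores, threshold)
        manifest["stages"].append(stage)

        stage = "colonies"
        graph = build_adjacency(lattice)
        colonies = segment_colonies(states, graph)
        colonies = colony_stats(colonies, lattice, scores=isg_scores.values)
        emit_frame(colonies.to_frame(), "colony_spots.tsv")
        emit_json(
            {
                "n_colonies": colonies.n_colonies,
                "n_scattered": int(len(colonies.scattered_indices)),
                "sizes": colonies.sizes().tolist(),
                "areas_um2_circle": [c.area_um2_circle for c in colonies.colonies],
                "areas_um2_hex": [c.area_um2_hex for c in colonies.colonies],
                "centroids": [c.centroid_spot for c in colonies.colonies],
            },
            "colony_summary.json",
        )
        manifest["stages"].append(stage)

        if config.run_morans:
            stage = "morans"
            results = morans_test_genomewide(
                lognorm,
                graph,
                n_top_variable=min(config.n_top_variable, lognorm.n_genes),
                n_permutations=config.n_permutations,
                seed=config.seed + 1,
            )
            emit_frame(moran_results_frame(results), "morans_i.tsv")
            manifest["stages"].append(stage)

        if config.run_sepal:
            stage = "sepal"
            sep = sepal_score(np.maximum(isg_scores.values, 0.0), graph)
            emit_json(
                {
                    "diffusion_time": sep.diffusion_time,
                    "converged": sep.converged,
                    "iterations": sep.iterations,
                },
                "sepal_isg_score.json",
            )
            manifest["stages"].append(stage)

        bz_high = None
        if truth is not None and truth.zone_of_spot is not None:
            bz_high = truth.zone_of_spot.mask("BZ")
        elif bz_set is not None:
            bz_scores = score_gene_set(counts, bz_set, basis="summed_counts")
            bz_high = bz_scores.values >= np.quantile(bz_scores.values, 0.85)

        if config.run_localization and colonies.n_colonies and bz_high is not None:
            stage = "localization"
            loc = localization_test(
                colonies,
                bz_high,
                graph,
                trials_per_size=config.localization_trials,
                max_size=config.localization_max_size,
                seed=config.seed + 2,
            )
            emit_frame(loc.per_size, "localization_per_size.tsv")
            emit_json(
                {
                    "pooled_odds_ratio": loc.pooled_odds_ratio,
                    "pooled_p_fisher": loc.pooled_p_fisher,
                    "pooled_p_chi2_yates": loc.pooled_p_chi2_yates,
                    "trials_per_size": loc.trials_per_size,
                },
                "localization_pooled.json",
            )
            manifest["stages"].append(stage)

        if config.run_niche and colonies.n_colonies:
            stage = "niche"
            rings = assign_rings(colonies, graph)
            emit_frame(rings.to_frame(), "rings.tsv")
            de = ring_de(lognorm, rings)
            for k, table in de.items():
                emit_frame(table.table, f"ring_de_k{k}.tsv")
            if bz_high is not None:
                profile = neighbor_fraction_profile(
                    bz_high, states, graph, spacing_um=lattice.spacing_um
                )
                emit_frame(profile, "neighbor_fractions.tsv")
            manifest["stages"].append(stage)

        if config.run_merfish and config.simulation is not None:
            stage = "merfish"
            points, cells, mtruth = make_merfish_sample(
                dataclasses.replace(config.simulation, seed=config.seed + 3)
            )
            clusters = classify_isg_clusters(
                points, DbscanParams(), species=("Ifit1", "Ifit2", "Ifit3", "Cxcl10")
            )
            comp = colony_composition(clusters, cells)
            emit_frame(comp, "merfish_composition.tsv")
            emit_json(
                {
                    "n_point_clusters": clusters.n_clusters,
                    "n_scattered_points": int(len(clusters.scattered)),
                },
                "merfish_clusters.json",
            )
            manifest["stages"].append(stage)

        if config.run_dna:
            stage = "dna"
            loci, dtruth = make_dna_sample(
                n_nuclei=20,
                loci_per_nucleus=50,
                extranuclear_fraction=0.1,
                seed=config.seed + 4,
            )
            res = classify_extranuclear(loci, section_thickness_um=16.0)
            emit_json(
                {
                    "estimated_extranuclear_fraction": res.extranuclear_fraction,
                    "true_fraction": dtruth.extranuclear_fraction,
                    "n_nuclear": res.n_nuclear,
                    "n_extranuclear": res.n_extranuclear,
                    "n_edge_excluded": res.n_edge_excluded,
                },
                "dna_extranuclear.json",
            )
            manifest["stages"].append(stage)

        if config.run_nuclei:
            stage = "nuclei"
            out = {}
            for name, deform in (("rz_convex", 0.0), ("bz_deformed", 0.8)):
                masks, ntruth = make_nucleus_set(20, deform, seed=config.seed + 5)
                sol = nuclear_solidity(masks)
                out[name] = {
                    "mean_solidity": float(sol.table["solidity"].mean()),
                    "mean_truth_solidity": float(np.mean(list(ntruth.nucleus_solidity.values()))),
                }
            emit_json(out, "nucleus_solidity.json")
            manifest["stages"].append(stage)

    except Exception as exc:  # noqa: BLE001 — stage failure policy
        for path in outputs:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineStageError(stage, exc) from exc

    for path in outputs:
        manifest["files"][path.name] = _file_hash(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return PipelineReport(outdir=outdir, manifest=manifest)
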