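# ifniche

Spatial analysis of interferon-induced-cell (IFNIC) colonies in injured
tissue: detection, segmentation and statistical localization of
contiguous interferon-stimulated-gene (ISG) expressing colonies at
infarct borderzones in spot-based spatial transcriptomics, microenvironment
analysis around them, and single-molecule (MERFISH-style) point-cloud
analyses of colony composition, extranuclear DNA and nuclear morphology.

The package is written for computational biologists working with
spot-lattice data (Visium-style: 55 um spots, 100 um hexagonal spacing)
and decoded single-molecule tables who need the full chain from raw
counts to calibrated, testable statements such as "these ISG colonies
localize to the borderzone beyond chance" — together with a synthetic
generator that plants known colonies, zones and escape fractions so every
estimator can be validated by parameter recovery.

## The statistics at its core

**ISG score and binary state.** Per spot, the ISG score is the sum of
counts over an ISG set; a spot is ISG+ iff its score reaches a threshold
calibrated as an extreme quantile of the score distribution in a negative
control (a genotype unable to mount the type I interferon response).

**Colonies.** An IFNIC colony is a connected component (first-order
hexagonal contiguity, up to 6 neighbours) of ISG+ spots with >= 2
members; isolated ISG+ spots are "scattered". Colony area is n_spots
times the per-spot area (both the 55 um capture-circle and the hexagonal
lattice-cell conventions are reported).

**Spatial clustering.** Moran's I with binary contiguity weights,

    I = (n/W) * sum_ij w_ij (x_i - x̄)(x_j - x̄) / sum_i (x_i - x̄)²,

tested one-sided against both the analytic normal null (E[I] = -1/(n-1))
and a seeded permutation null, BH-adjusted over the top variable genes; a
diffusion-time ("sepal"-style) score — the time for a pattern to
homogenize under lattice diffusion — gives an orthogonal ranking.

**Localization.** A Monte Carlo test grows 500 random connected spot sets
per size 1..12 by the same accretion process used to plant colonies and
compares their borderzone contact rate against the observed colonies with
two-sided Fisher exact tests (per size and pooled).

**Niche.** Rings at lattice distance 1-3 (100-300 um) around colony
centroids, per-ring Wilcoxon differential expression against centroids,
line scans along an infarct-to-borderzone vector, and query-positive
fractions in 100 um shells around a reference spot set.

**Point clouds.** DBSCAN (eps = 70 um, min_samples = 10; eps selectable
from the k-NN distance-curve knee) separates clustered from scattered ISG
transcripts; per-colony cell-type composition; extranuclear DNA via local
density (>= 10 decoded loci within 5 um = nuclear, with 5 um section-face
exclusion); nuclear solidity = mask area / convex-hull area.

## Worked example

```python
import numpy as np
from ifniche import (SimulationConfig, make_lattice_sample, make_control_sample,
                     GeneSet, score_gene_set, calibrate_threshold, binarize_score,
                     build_adjacency, segment_colonies, colony_stats,
                     localization_test)

config = SimulationConfig(seed=7, n_colonies=5)          # ~3,000-spot section
lattice, counts, truth = make_lattice_sample(config)
_, control, _ = make_control_sample(config)              # interferon-null control

isg = GeneSet("ISG score", list(config.isg_genes), "ISG")
threshold = calibrate_threshold(score_gene_set(control, isg, "summed_counts"),
                                quantile=0.9999)
states = binarize_score(score_gene_set(counts, isg, "summed_counts"), threshold)

graph = build_adjacency(lattice)
colonies = colony_stats(segment_colonies(states, graph), lattice)
print(threshold.value, colonies.n_colonies, colonies.sizes())

loc = localization_test(colonies, truth.zone_of_spot.mask("BZ"), graph, seed=1)
print(loc.pooled_p_fisher)
```

This prints

```
94.0 5 [6 4 6 5 7]
7.744579436287073e-05
```

— the calibrated threshold (94 summed ISG counts, the most extreme value
seen in the ~3,000-spot control), exact recovery of the 5 planted
colonies with their sizes in spots, and a pooled Fisher p of ~8e-5: the
detected colonies touch the borderzone far more often than size-matched
random connected sets, exactly as planted.

The `examples/` directory holds one short narrative script per
capability (simulation and segmentation, spatial autocorrelation,
localization, niche rings, point-cloud colonies and composition, DNA
escape and nuclear shape); each prints its numbers with a line on what
they mean. A thin CLI is included for the end-to-end pipeline:
`ifniche run --seed 7 --outdir out/` writes per-stage TSV/JSON outputs
plus a manifest with content hashes, and `ifniche simulate` writes a
synthetic sample in the standard formats (MatrixMarket + features/
barcodes TSVs + positions CSV).

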