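"""Microenvironment rings around colony centroids.

Assigns primary/secondary/tertiary neighbour rings (one lattice step =
100 um) around each colony centroid and tests every gene per ring against
the centroids.  With a planted diffusive ISG halo the interferon program
decays with distance while the matricellular fibroblast program (Postn,
Acta2) rises away from the centroids — an inverse spatial patterning.
"""

import numpy as np

from ifniche import (
    GeneSet,
    SimulationConfig,
    assign_rings,
    build_adjacency,
    colony_stats,
    make_lattice_sample,
    neighbor_fraction_profile,
    ring_de,
    score_gene_set,
    segment_colonies,
)
from ifniche.io import normalize_log10k

config = SimulationConfig(seed=21, n_colonies=8, colony_size_range=(2, 2),
                          isg_halo_decay=0.5)
lattice, counts, truth = make_lattice_sample(config)
graph = build_adjacency(lattice)

states = np.zeros(graph.n, dtype=bool)
for idx in truth.colony_spot_indices.values():
    states[idx] = True
isg_scores = score_gene_set(counts, GeneSet("ISG", list(config.isg_genes), "ISG"),
                            basis="summed_counts")
colonies = colony_stats(segment_colonies(states, graph), lattice,
                        scores=isg_scores.values)
rings = assign_rings(colonies, graph, max_ring=3)
de = ring_de(normalize_log10k(counts), rings)

print("natural-log fold change vs centroid spots:")
print(f"{'ring':>6s} {'Ifit1':>8s} {'Rsad2':>8s} {'Postn':>8s} {'Acta2':>8s}")
for k in (1, 2, 3):
    t = de[k].table.set_index("gene")
    print(f"{k:>6d} " + " ".join(f"{t.loc[g, 'ln_fc']:+8.3f}"
                                 for g in ("Ifit1", "Rsad2", "Postn", "Acta2")))

profile = neighbor_fraction_profile(truth.zone_of_spot.mask("IZ"), states, graph)
print("\nfraction of ISG+ spots per 100-um shell around the ischaemic core:")
print(profile.to_string(index=False))
print("Negative ISG fold changes that deepen with ring distance, against")
print("positive matricellular fold changes, reproduce the planted inverse gradient.")
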