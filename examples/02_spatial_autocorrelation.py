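"""Rank genes by spatial clustering: Moran's I and diffusion time.

On a section with planted ISG colonies (plus a diffusive interferon halo),
interferon-stimulated genes score high on both statistics, while spatially
unstructured genes sit near the null expectation of -1/(n-1).
"""

import numpy as np

from ifniche import (
    SimulationConfig,
    build_adjacency,
    make_lattice_sample,
    morans_test_genomewide,
    sepal_score,
)
from ifniche.io import normalize_log10k

config = SimulationConfig(seed=7, n_colonies=8, isg_halo_decay=0.5)
lattice, counts, truth = make_lattice_sample(config)
graph = build_adjacency(lattice)
lognorm = normalize_log10k(counts)

results = morans_test_genomewide(lognorm, graph, n_top_variable=counts.n_genes, seed=0)
results.sort(key=lambda r: -r.I)

print(f"expected I under the null: {results[0].expected_I:.5f} (n = {graph.n} spots)")
print("top 8 genes by Moran's I (one-sided p, BH-adjusted):")
for r in results[:8]:
    tag = "ISG" if r.gene in config.isg_genes else "   "
    print(f"  {tag} {r.gene:8s} I = {r.I:+.4f}  p_adj = {r.p_adj:.4f}")

x = counts.gene_values("Ifit1").astype(float)
sep = sepal_score(x, graph)
flat = sepal_score(np.ones(graph.n), graph)
print(f"\ndiffusion time to homogeneity: Ifit1 {sep.diffusion_time:.1f}, "
      f"uniform field {flat.diffusion_time:.1f}")
print("A long diffusion time means the pattern is far from spatially uniform —")
print("the same ranking signal Moran's I captures, by an independent mechanism.")
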