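"""Extranuclear DNA classification and nuclear solidity.

Simulates decoded DNA loci with a known 10% escape fraction, classifies
each locus by local point density (>= 10 decoded points within 5 um =
nuclear) after excluding the 5-um section faces, and measures nuclear
solidity on convex versus deformed synthetic nuclei.
"""

import numpy as np

from ifniche import (
    classify_extranuclear,
    make_dna_sample,
    make_nucleus_set,
    nuclear_solidity,
)

loci, truth = make_dna_sample(
    n_nuclei=10, loci_per_nucleus=100, extranuclear_fraction=0.10, seed=5
)
res = classify_extranuclear(loci, section_thickness_um=16.0)
print(f"{loci.n} decoded loci: {res.n_nuclear} nuclear, "
      f"{res.n_extranuclear} extranuclear, {res.n_edge_excluded} edge-excluded")
print(f"estimated escape fraction: {res.extranuclear_fraction:.3f} "
      f"(planted {truth.extranuclear_fraction:.2f})")

for label, deformation in (("remote-zone (convex)", 0.0), ("borderzone (deformed)", 0.8)):
    masks, ntruth = make_nucleus_set(20, deformation, seed=3)
    sol = nuclear_solidity(masks)
    print(f"{label}: measured solidity {sol.table['solidity'].mean():.3f} "
          f"(truth {np.mean(list(ntruth.nucleus_solidity.values())):.3f})")
print("Solidity near 1 marks intact convex nuclei; the deformed family drops")
print("well below 1, the morphological signature of mechanically stressed nuclei.")
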