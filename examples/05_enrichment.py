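"""Test whether a gene category resists introgression: exact 2x3 tests of
category topology counts against the genome-wide census."""

import numpy as np

from introtrio import census, topology_enrichment
from introtrio.simulate import (
    SimParams,
    simulate_dataset,
    triplet_record_from_sim,
)

params = SimParams(gamma=0.3, n_genes=5000, seed=51)
genes = simulate_dataset(params, n_resistant=150)  # e.g. mito-interacting genes
records = [triplet_record_from_sim(g) for g in genes]
background = census(records)

rng = np.random.default_rng(52)
control = rng.choice([g.gene_id for g in genes if not g.resistant], 150,
                     replace=False)
assignments = {g.gene_id: "resistant" for g in genes if g.resistant}
assignments.update({gid: "control" for gid in control})

print(f"background census: {background.counts}")
for row in topology_enrichment(assignments, records, background):
    print(f"  {row.category:10s} counts={row.counts}  raw p={row.raw_p:.4f}  "
          f"Holm p={row.holm_p:.4f}  ({row.direction})")
print()
print("The resistant category keeps the species-tree (AB) topology far more")
print("often than the introgressed genome-wide background — the pattern")
print("expected for genes under cytonuclear incompatibility constraints —")
print("while the random control matches the background.")
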