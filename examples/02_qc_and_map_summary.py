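"""Genotype quality control and linkage-map summary arithmetic.

Applies the chip QC filters (individual call rate > 0.9, marker call
frequency > 0.9, MAF > 0.05, inheritance-error rate < 0.05) to a simulated
cross with injected missingness and Mendelian errors, then reproduces the
published per-chromosome summary of the real cross's linkage map.
"""

import numpy as np

import crossqtl as cq
from crossqtl.core import MISSING
from crossqtl.datasets import linkage_map_summary
from crossqtl.studies import reduced_map

gmap = reduced_map(n_groups=2, length_cm=60, marker_step=2)
design = cq.CrossDesign(n_f2=200, seed=3, missing_rate=0.02)
founders = cq.FounderModel.random(gmap.n_markers, rng=3)
genos = cq.simulate_cross(gmap, design, founders)

# sabotage one bird's call rate and one marker's genotypes
rng = np.random.default_rng(0)
victim = genos.col_index([genos.generation_ids("F2")[0]])[0]
genos.calls[: int(0.2 * gmap.n_markers), victim] = MISSING
genos.calls[5, genos.col_index(genos.generation_ids("F2"))] = 0  # monomorphic

filtered, report = cq.apply_qc(genos)
print(report.to_log())
print(f"retained: {len(filtered.ids)} individuals, {filtered.gmap.n_markers} markers\n")

# published map of the real cross: 29 autosomal linkage groups
ms = cq.summarize_map(linkage_map_summary())
print(ms.per_group.head(3).to_string(index=False))
print("...")
print("totals:", ms.totals.to_dict())
print("\nThe totals row is the column sums (957.8 Mb, 41278 SNPs, 3068.4 cM)")
print("with the overall recombination rate 3.2 cM/Mb from the summed columns.")
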