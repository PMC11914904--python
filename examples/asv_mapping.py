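"""Map 16S ASVs to reference genomes and derive relative abundances.

Three ASVs are derived from a genome's 16S gene at 100%, 97% and 96%
identity; the mapping thresholds (97% identity, 95% query coverage,
inclusive) retain exactly the first two, and the counts of the retained
ASVs become genome relative abundances.
"""

import numpy as np
import pandas as pd

from auxopep import ASVTable, assign_abundance, map_asvs
from auxopep.model_io import GenomeEntry, ReferenceGenomeCatalog

rng = np.random.default_rng(7)
gene = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
window = gene[50:250]


def mutate(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


catalog = ReferenceGenomeCatalog({
    "G1": GenomeEntry([gene], {"G1_p": "MKL"}, 100.0),
})
asvs = ASVTable(
    sequences={
        "asv_100": window,                                # identical
        "asv_97": mutate(window, list(range(20, 80, 10))),   # 6/200 mutated
        "asv_96": mutate(window, list(range(20, 100, 10))),  # 8/200 mutated
    },
    counts=pd.DataFrame({"sample1": [70, 30, 500]},
                        index=pd.Index(["asv_100", "asv_97", "asv_96"],
                                       name="asv_id")),
)

hits = map_asvs(asvs, catalog)
for h in hits:
    print(f"{h.asv_id} -> {h.genome_id}  identity {h.identity:.1f}%  "
          f"coverage {h.query_coverage:.1f}%")

(sample,) = assign_abundance(asvs, hits)
print(f"relative abundances: {sample.abundances}")

# asv_96 falls below the 97% identity threshold, so its 500 reads are
# ignored; the 100 mapped reads all belong to G1, giving it abundance 1.0.
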