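"""Community metrics on a hand-checkable three-genome sample.

Auxotrophy abundance is the summed relative abundance of genomes
auxotrophic for an amino acid; weighted averages use relative abundances
as weights; Bray-Curtis quantifies dissimilarity between profiles.
"""

from auxopep import (
    auxotrophy_abundance,
    bray_curtis,
    range_scale,
    weighted_avg_auxotrophies,
    weighted_avg_peptidases,
)
from auxopep.fba import AuxotrophyProfile, GenomeAuxotrophy
from auxopep.aminoacids import AMINO_ACIDS
from auxopep.mapping import SampleAbundance
from auxopep.peptidases import GenomePeptidases, PeptidaseProfile

sample = SampleAbundance("s1", {"A": 0.5, "B": 0.3, "C": 0.2})

aux = AuxotrophyProfile()
for gid, aas in {"A": {"His"}, "B": set(), "C": {"His", "Trp"}}.items():
    aux.entries[gid] = GenomeAuxotrophy(
        gid, {aa: aa in aas for aa in AMINO_ACIDS}, 10.0
    )

pep = PeptidaseProfile()
pep.genomes["A"] = GenomePeptidases({"S09.075"}, 4, set())
pep.genomes["B"] = GenomePeptidases(set(), 0, set())
pep.genomes["C"] = GenomePeptidases({"S09.075", "M16.001"}, 2, set())

print(f"His auxotrophy abundance: {auxotrophy_abundance(sample, aux, 'His'):.2f}")
print(f"weighted avg auxotrophies: {weighted_avg_auxotrophies(sample, aux):.2f}")
print(f"weighted avg peptidase copies: {weighted_avg_peptidases(sample, pep):.2f}")
print(f"Bray-Curtis {{2,1,0}} vs {{1,1,1}}: "
      f"{bray_curtis({'a': 2, 'b': 1}, {'a': 1, 'b': 1, 'c': 1}):.4f}")
print(f"range-scaled [2, 4, 6]: {range_scale([2, 4, 6]).tolist()}")

# His abundance 0.70 = 0.5 (A) + 0.2 (C); the weighted auxotrophy mean
# 0.90 = 0.5*1 + 0.3*0 + 0.2*2; peptidase copies 2.40 = 0.5*4 + 0.2*2;
# the Bray-Curtis worked example equals 1/3.
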