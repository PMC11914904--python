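"""Call extracellular peptidase genes against a MEROPS-style scan
database.

One genome carries a secreted copy (signal-peptide leader + slightly
mutated domain), a cytoplasmic copy (no leader) and a scrambled decoy of
the same scan sequence.  Homology filtering retains the two real copies;
signal-peptide flagging keeps only the secreted one.
"""

import numpy as np

from auxopep import call_peptidases, flag_extracellular, toy_signal_peptide
from auxopep.model_io import GenomeEntry, ReferenceGenomeCatalog
from auxopep.peptidases import ScanSequence
from auxopep.synthetic import SIGNAL_PREFIX

AA20 = "ARNDCQEGHILKMFPSTWYV"
rng = np.random.default_rng(5)
scan_seq = "".join(AA20[i] for i in rng.integers(0, 20, 200))

mutated = list(scan_seq)
for p in rng.choice(200, size=4, replace=False):  # 2% mutation
    mutated[p] = AA20[(AA20.index(mutated[p]) + 3) % 20]
mutated = "".join(mutated)
decoy = "".join(rng.permutation(list(scan_seq)))

proteins = {
    "secreted": SIGNAL_PREFIX + mutated,
    "cytoplasmic": "MST" + mutated,
    "decoy": SIGNAL_PREFIX + decoy,
}
catalog = ReferenceGenomeCatalog({"G1": GenomeEntry(["ACGT"], proteins, 100.0)})
scan_db = [ScanSequence("S09.075", scan_seq, (11, 190))]

hits = call_peptidases(catalog, scan_db)
for h in hits:
    print(f"hit: {h.protein_id}  {h.merops_id}  bitscore {h.bitscore:.0f}  "
          f"evalue {h.evalue:.1e}  unit coverage {h.unit_coverage:.0f}%")

signal_table = {pid: toy_signal_peptide(seq) for pid, seq in proteins.items()}
profile = flag_extracellular(hits, signal_table, genome_ids=["G1"])
print(f"extracellular gene copies in G1: {profile.count('G1', 'copies')}")
print(f"peptidase species present:       {profile.genomes['G1'].merops_ids_present}")

# Both real copies pass the four homology filters (the decoy passes
# none), but only the secreted copy carries a signal peptide, so the
# extracellular profile counts one S09.075 gene.
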