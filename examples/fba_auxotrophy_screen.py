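"""Leave-one-out auxotrophy screening of a small model catalog.

Builds the prototrophic template model, knocks out histidine and
tryptophan biosynthesis in one copy, and screens both models on the full
medium: growth is re-solved 20 times per model, each time removing one
amino acid from the medium.
"""

from auxopep import (
    amino_acid_exchange_map,
    full_medium,
    knockout,
    make_template_model,
    screen_catalog,
    solve_fba,
)

template = make_template_model()
mutant = knockout(make_template_model(), {"His", "Trp"})
mutant.model_id = "his_trp_mutant"

print(f"template growth on full medium: "
      f"{solve_fba(template, full_medium()).growth_rate:.1f}")
print(f"mutant growth on full medium:   "
      f"{solve_fba(mutant, full_medium()).growth_rate:.1f}")

profile = screen_catalog([template, mutant], full_medium(),
                         amino_acid_exchange_map())
for gid, entry in profile.entries.items():
    called = sorted(aa for aa, v in entry.calls.items() if v)
    print(f"{gid}: {entry.n_auxotrophies} auxotrophies {called}")

# The mutant grows on the full medium (it imports His and Trp) but its
# growth collapses when either is withheld -> exactly those two amino
# acids are called auxotrophic; the intact template is called for none.
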