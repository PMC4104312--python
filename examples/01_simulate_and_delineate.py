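"""Generate a small synthetic PIN family and delineate its domains.

Canonical PIN proteins split into an N-terminal transmembrane domain ending
at the FLFEFRAAR anchor, a central loop, and a C-terminal transmembrane
domain starting at the VWRKLIRN anchor.
"""

from collections import Counter

from pin_architect import GeneratorConfig, generate_family, delineate, loop_length_class

family = generate_family(GeneratorConfig(seed=0, members_per_clade=10))
print(f"generated {len(family.records)} sequences in "
      f"{len(family.clade_map.clades())} clades")

n_lengths, classes = Counter(), Counter()
for record in family.records:
    part = delineate(record)
    if part.n_domain is not None and record.n_complete:
        n_lengths[len(part.n_domain)] += 1
    classes[loop_length_class(part)] += 1

print("N-domain length spectrum (complete N-termini):",
      dict(sorted(n_lengths.items())))
print("loop length classes:", dict(classes))
print("-> the modal N-domain length is 158 (the canonical N1..N158 frame); "
      "lengths above 158 carry insertions between N97 and N98. Short loops "
      "(32-120 aa) mark noncanonical proteins, long loops (>150 aa) canonical ones.")
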