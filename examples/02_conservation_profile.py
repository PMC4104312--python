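"""Per-position conservation of the transmembrane domains.

Builds the 312-position canonical profile (N1..N158 + C1..C154) over the
canonical members of a synthetic family, prints the identity-band table and
checks the invariant tyrosine at C123.
"""

from pin_architect import (
    GeneratorConfig, generate_family, delineate,
    build_profile, band_counts, consensus, TABLE3_BANDS,
)

family = generate_family(GeneratorConfig(seed=0))
truth = family.members.set_index("id")
canonical = [delineate(r) for r in family.records
             if truth.loc[r.id, "label"] == "canonical"]

profile = build_profile(canonical, "tm")
counts, insufficient = band_counts(profile, TABLE3_BANDS, min_coverage=10)
print(f"profile over {len(profile.labels)} canonical positions "
      f"({len(canonical)} canonical sequences)")
print("identity bands:", counts, f"(+{insufficient} with <10 observations)")

idx = profile.position_index()
print(f"C123 modal residue: {profile.modal_residue[idx['C123']]} at "
      f"{profile.modal_identity[idx['C123']]:.3f} identity")
print("consensus around C123:", consensus(profile, floor=0.5)[158 + 118:158 + 128])
print("-> most transmembrane positions sit in the high-identity bands; the "
      "tyrosine at C123, invariant across all PIN proteins, lands in the 100% band.")
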