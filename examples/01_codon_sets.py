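"""Deduce m2A-tRNA-dependent codon sets from anticodon identity.

The cytosolic set comes from the two m2A37-modified cytosolic tRNAs
(Arg-ACG with inosine at position 34, Gln-UUG) under wobble pairing, with
CGA removed because reporter assays show it is decoded independently of the
modification. The chloroplast set is deduced from the four modified
chloroplast tRNAs under either wobble or two-out-of-three pairing.
"""

import json

from m2acodon import chloroplast_codon_set, cytosolic_codon_set

cyto = cytosolic_codon_set()
print("cytosolic m2A-dependent codons:", ", ".join(sorted(cyto.codons)))
print("excluded:", dict(cyto.exclusions))

for rule in ("wobble", "two_out_of_three"):
    cs = chloroplast_codon_set(rule)
    print(f"chloroplast ({rule}): {len(cs.codons)} codons ->",
          ", ".join(sorted(cs.codons)))

print("\nmanifest for the cytosolic set:")
print(json.dumps(cyto.to_manifest(), indent=2))
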