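"""Encode a few peptides under the seven sequence descriptor schemes.

Each scheme maps a peptide to a fixed-length numeric vector: residue
composition (AAC), dipeptide composition (DPC), grouped physicochemical
composition/transition/distribution (CTDC/CTDT/CTDD), and pseudo
amino-acid composition with sequence-order correlation (PAAC/APAAC).
"""

import umamistack as us

peptides = [
    us.Peptide("glutamate_rich", "EDEEDGSE"),   # umami-like composition
    us.Peptide("bitter_like", "FLWPFLGL"),      # bitter-like composition
]

for p in peptides:
    print(f"{p.id} ({p.sequence}):")
    for scheme in us.SCHEMES:
        v = us.encode_peptide(p, scheme)
        print(f"  {scheme:>5}: dim={v.shape[0]:3d}  first values {v[:3].round(3)}")

# AAC entries are residue fractions: E = 4/8 for the first peptide
aac = us.encode_peptide(peptides[0], "AAC")
e_index = us.feature_names("AAC").index("E")
print(f"\nfraction of glutamate in {peptides[0].id}: {aac[e_index]:.3f}")
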