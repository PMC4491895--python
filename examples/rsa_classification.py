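"""Classify residue exposure from accessible surface areas.

RSA divides each residue's ASA by the theoretical maximum for its
amino-acid type; residues below 5% are buried, 5-20% partially buried,
and 20% or more exposed.
"""

from jrpnet import rsa

asa_records = [
    (49, "ASP", 48.3),   # a solvent-exposed loop residue
    (71, "TRP", 25.0),
    (74, "PHE", 30.1),
    (108, "VAL", 0.0),   # fully packed core residue
    (142, "GLY", 89.4),
]

table = rsa.exposure_table(asa_records)
print(table.round(3).to_string(index=False))
print(f"\nmean RSA over the set: {rsa.mean_rsa(table):.3f}")
print("Buried residues are candidates for structural roles; hotspot residues")
print("of promiscuous binding surfaces are often partially or fully exposed,")
print("so exposure context matters when interpreting high-centrality residues.")
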