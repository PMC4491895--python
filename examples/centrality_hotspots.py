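"""Compare the three residue networks on one structure.

Builds the unweighted 7 Angstrom contact network, a contact-count
weighted network, and a joint-recurrence weighted network over the same
residues, and shows how the centrality rankings differ.
"""

import numpy as np

from jrpnet import network

rng = np.random.default_rng(5)
n = 15
coords = {i: np.array([3.8 * i, 2.0 * np.sin(i / 2), 0.0]) for i in range(1, n + 1)}

unweighted = network.build_unweighted_network(coords, cutoff=7.0)

contacts = {
    (i, j): int(rng.integers(1, 12))
    for i in range(1, n + 1) for j in range(i + 1, n + 1)
    if abs(i - j) <= 2
}
contact_net = network.build_contact_network(coords, contacts=contacts)

# joint-recurrence counts: chance level everywhere plus one strong
# long-range pair bridging the two chain halves
counts = {
    (i, j): int(rng.integers(200, 400))
    for i in range(1, n + 1) for j in range(i + 1, n + 1)
}
counts[(4, 12)] = 2500
jrp = network.build_jrp_network(counts, coords)

annotations = {4: "known hotspot", 12: "known hotspot"}
for name, g in [("unweighted 7A", unweighted),
                ("contact-weighted", contact_net),
                ("JRP-weighted", jrp)]:
    table = network.centrality_table(g)
    records = network.significant_residues(table, g, annotations=annotations)
    ids = [r["residue_id"] for r in records]
    print(f"{name:>17}: significant residues {ids or '(none)'}")

print("\nThe cutoff-based networks only see local chain contacts; the")
print("joint-recurrence network has no cutoff, so the strong long-range pair")
print("(4, 12) creates a shortcut that lifts those residues' centralities.")
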