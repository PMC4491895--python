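"""Residue interaction networks and centrality analysis.

Three network flavors over the same residue nodes (C-alpha positions):

* ``jrp_weighted``  -- edge weight = accumulated joint recurrences of the
  pair divided by the C-alpha distance; no distance cutoff, so long-range
  and solvent-mediated couplings are retained.
* ``unweighted_cutoff`` -- classical contact network: weight-1 edges
  between residues within a cutoff (7 Angstrom by default).
* ``contact_weighted`` -- edge weight = number of inter-residue atomic
  contacts, supplied as a table or approximated as heavy-atom pairs
  within 4.5 Angstrom of a full-atom structure.

Hotspot candidates are residues whose betweenness B (shortest paths
routed through the node) or closeness C = (j-1)/sum of shortest-path
distances stand out after z-score standardization (z_B > 2 or
z_C > 1.5 by default).

Shortest paths on weighted graphs need a weight-to-length conversion the
residue-network literature leaves implicit; the default here is
path_length = 1/weight (stronger interaction = shorter path), isolated in
:func:`edge_path_length` so alternatives (e.g. -log weight) can be chosen.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

__all__ = [
    "edge_path_length",
    "build_jrp_network",
    "build_unweighted_network",
    "build_contact_network",
    "closeness",
    "betweenness",
    "closeness_all",
    "betweenness_all",
    "standardize",
    "centrality_table",
    "significant_residues",
    "DegenerateDistributionError",
]

DEFAULT_CUTOFF = 7.0          # Angstrom, unweighted contact network
CONTACT_ATOM_CUTOFF = 4.5     # Angstrom, heavy-atom contact stand-in
Z_B_THRESHOLD = 2.0
Z_C_THRESHOLD = 1.5


class DegenerateDistributionError(ValueError):
    """All values identical: z-scores are undefined."""


def edge_path_length(weight: float, mode: str = "reciprocal") -> float:
    """Convert an interaction weight into a shortest-path edge length.

    ``reciprocal`` (default): 1/weight.  ``neglog``: -log(w / (1 + w)),
    a strictly positive alternative for users who prefer multiplicative
    path costs.
    """
    if weight <= 0:
        raise ValueError(f"edge weight must be > 0, got {weight}")
    if mode == "reciprocal":
        return 1.0 / weight
    if mode == "neglog":
        return float(-np.log(weight / (1.0 + weight)))
    raise ValueError(f"unknown path-length mode {mode!r}")


def _base_graph(coords: dict, kind: str) -> nx.Graph:
    g = nx.Graph(kind=kind)
    for rid, xyz in coords.items():
        g.add_node(rid, coord=np.asarray(xyz, dtype=float))
    return g


def _distance(coords, a, b) -> float:
    return float(np.linalg.norm(np.asarray(coords[a], float) - np.asarray(coords[b], float)))


def build_jrp_network(counts: dict, coords: dict, length_mode: str = "reciprocal") -> nx.Graph:
    """Joint-recurrence weighted network.

    ``counts`` maps unordered residue pairs to accumulated joint
    recurrences; an edge exists for every pair with a positive count,
    with weight = count / C-alpha distance.  No cutoff distance.
    """
    g = _base_graph(coords, "jrp_weighted")
    for (a, b), count in counts.items():
        if count < 0:
            raise ValueError(f"negative joint-recurrence count for pair ({a},{b})")
        if count == 0:
            continue
        for r in (a, b):
            if r not in coords:
                raise KeyError(f"no reference coordinate for residue {r!r}")
        dist = _distance(coords, a, b)
        if dist == 0.0:
            raise ValueError(f"zero C-alpha distance between distinct residues {a} and {b}")
        w = count / dist
        g.add_edge(a, b, weight=w, path_length=edge_path_length(w, length_mode))
    return g


def build_unweighted_network(coords: dict, cutoff: float = DEFAULT_CUTOFF) -> nx.Graph:
    """Unweighted contact network: weight-1 edges at C-alpha distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    g = _base_graph(coords, "unweighted_cutoff")
    ids = list(coords)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if _distance(coords, a, b) <= cutoff:
                g.add_edge(a, b, weight=1.0, path_length=1.0)
    return g


def build_contact_network(
    coords: dict,
    contacts: dict | None = None,
    atoms: dict | None = None,
    atom_cutoff: float = CONTACT_ATOM_CUTOFF,
    length_mode: str = "reciprocal",
) -> nx.Graph:
    """Contact-count weighted network.

    ``contacts`` maps unordered residue pairs to contact counts
    (pass-through).  Alternatively ``atoms`` maps each residue to an
    (n_atoms x 3) array of heavy-atom coordinates and contacts are
    counted as atom pairs within ``atom_cutoff``.  This generic distance
    count does not reproduce surface-complementarity contact
    classification (CSU-style); it is a plain geometric stand-in.
    """
    if contacts is None and atoms is None:
        raise ValueError("either a contact table or full-atom coordinates are required")
    if contacts is None:
        contacts = count_atomic_contacts(atoms, atom_cutoff)
    g = _base_graph(coords, "contact_weighted")
    for (a, b), count in contacts.items():
        if count <= 0:
            continue
        w = float(count)
        g.add_edge(a, b, weight=w, path_length=edge_path_length(w, length_mode))
    return g


def count_atomic_contacts(atoms: dict, atom_cutoff: float = CONTACT_ATOM_CUTOFF) -> dict:
    """Heavy-atom contact counts: atom pairs of distinct residues within cutoff."""
    from scipy.spatial import cKDTree

    ids = list(atoms)
    contacts = {}
    trees = {r: cKDTree(np.atleast_2d(np.asarray(atoms[r], float))) for r in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            n = trees[a].count_neighbors(trees[b], atom_cutoff)
            if n > 0:
                contacts[(a, b)] = int(n)
    return contacts


def closeness(net: nx.Graph, node) -> float:
    """Closeness centrality C = (r-1) / sum of shortest-path distances.

    Path distances sum edge ``path_length`` attributes.  On a
    disconnected graph only the r nodes reachable from ``node`` enter,
    with (r-1)/sum scaling; an isolated node has C = 0.
    """
    lengths = nx.single_source_dijkstra_path_length(net, node, weight="path_length")
    r = len(lengths)
    if r <= 1:
        return 0.0
    return (r - 1) / sum(lengths.values())


def closeness_all(net: nx.Graph) -> dict:
    return {n: closeness(net, n) for n in net.nodes}


def betweenness_all(net: nx.Graph) -> dict:
    """Raw (unnormalized) betweenness over unordered pairs, endpoints
    excluded, with fractional credit for tied shortest paths."""
    return nx.betweenness_centrality(net, normalized=False, weight="path_length")


def betweenness(net: nx.Graph, node) -> float:
    return betweenness_all(net)[node]


def standardize(values) -> np.ndarray:
    """z-scores with the population standard deviation (mean 0, SD 1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = v.std()  # population SD
    if sd == 0.0:
        raise DegenerateDistributionError("all values identical; z-scores undefined")
    return (v - v.mean()) / sd


def centrality_table(
    net: nx.Graph,
    z_b_threshold: float = Z_B_THRESHOLD,
    z_c_threshold: float = Z_C_THRESHOLD,
) -> pd.DataFrame:
    """Per-residue betweenness/closeness with z-scores and significance flags.

    Columns: residue_id, betweenness, closeness, z_B, z_C,
    significant_B (z_B > threshold), significant_C (z_C > threshold).
    """
    ids = sorted(net.nodes, key=lambda x: (str(type(x)), x))
    b = betweenness_all(net)
    c = closeness_all(net)
    bv = np.array([b[i] for i in ids])
    cv = np.array([c[i] for i in ids])
    z_b = standardize(bv)
    z_c = standardize(cv)
    return pd.DataFrame(
        {
            "residue_id": ids,
            "betweenness": bv,
            "closeness": cv,
            "z_B": z_b,
            "z_C": z_c,
            "significant_B": z_b > z_b_threshold,
            "significant_C": z_c > z_c_threshold,
        }
    )


def significant_residues(
    table: pd.DataFrame,
    net: nx.Graph,
    z_b_threshold: float = Z_B_THRESHOLD,
    z_c_threshold: float = Z_C_THRESHOLD,
    annotations: dict | None = None,
) -> list[dict]:
    """Residues exceeding either z threshold, ranked by max(z_B, z_C).

    Each record lists the residue's first-degree network neighbors that
    are themselves significant or carry a user annotation (e.g. known
    hotspots), mirroring how hotspot neighborhoods are reported.
    """
    annotations = annotations or {}
    sig_b = set(table.loc[table["z_B"] > z_b_threshold, "residue_id"])
    sig_c = set(table.loc[table["z_C"] > z_c_threshold, "residue_id"])
    significant = sig_b | sig_c
    records = []
    for _, row in table.iterrows():
        rid = row["residue_id"]
        if rid not in significant:
            continue
        neighbors = []
        for nb in net.neighbors(rid):
            if nb in significant or nb in annotations:
                neighbors.append(
                    {"residue_id": nb, "annotation": annotations.get(nb)}
                )
        records.append(
            {
                "residue_id": rid,
                "z_B": float(row["z_B"]),
                "z_C": float(row["z_C"]),
                "significant_B": rid in sig_b,
                "significant_C": rid in sig_c,
                "annotation": annotations.get(rid),
                "neighbors": sorted(neighbors, key=lambda d: str(d["residue_id"])),
            }
        )
    records.sort(key=lambda r: max(r["z_B"], r["z_C"]), reverse=True)
    return records
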