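"""End-to-end pipeline: time series + reference structure -> hotspot report.

Stages, each with its own file artifact so partial reruns are cheap:

1. embedding parameters per residue (delay via first MI minimum,
   dimension via false nearest neighbors);
2. recurrence matrices with per-residue threshold calibrated to the
   target recurrence rate, then all-pairs joint-recurrence counts;
3. residue networks (joint-recurrence weighted, unweighted 7 A cutoff,
   and optionally contact-count weighted);
4. betweenness/closeness centralities, z-scores and a significant-residue
   report.

A manifest (JSON) records the full configuration, per-residue achieved
recurrence rates and flags, and the common state count used for joint
counting, so any run can be re-executed exactly from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import embedding, network, recurrence, rsa

__all__ = [
    "RunConfig",
    "ReconciliationError",
    "run_pipeline",
    "run_from_manifest",
    "load_config_file",
    "read_series_tsv",
    "read_ca_coords",
    "read_contacts_tsv",
    "read_annotations_tsv",
]


class ReconciliationError(ValueError):
    """Residue sets of the time-series matrix and reference structure differ."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults follow the method's standard operating point: threshold
    calibrated to a 3% recurrence rate, 7 Angstrom unweighted cutoff,
    significance at z_B > 2 and z_C > 1.5.
    """

    series_path: str
    pdb_path: str
    out_dir: str
    asa_path: str | None = None
    contacts_path: str | None = None
    annotations_path: str | None = None
    target_recurrence_rate: float = 0.03
    cutoff_distance: float = network.DEFAULT_CUTOFF
    z_b_threshold: float = network.Z_B_THRESHOLD
    z_c_threshold: float = network.Z_C_THRESHOLD
    n_bins: int | None = None
    max_lag: int | None = None
    max_dim: int = 10
    fnn_threshold: float = embedding.FNN_THRESHOLD
    networks: tuple = ("jrp_weighted", "unweighted_cutoff")
    length_mode: str = "reciprocal"
    global_embedding: bool = False
    chain: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_recurrence_rate < 1.0:
            raise ValueError("target_recurrence_rate must be in (0, 1)")
        if self.cutoff_distance <= 0:
            raise ValueError("cutoff_distance must be > 0")
        for name in ("z_b_threshold", "z_c_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        self.networks = tuple(self.networks)


# ---------------------------------------------------------------- readers

def read_series_tsv(path) -> tuple[list, np.ndarray]:
    """Read the residue x frame matrix; returns (residue_ids, matrix)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - message formatting
        raise ValueError(f"cannot parse time-series TSV {path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "residue_id":
        raise ValueError(
            f"time-series TSV {path}: first column must be 'residue_id' "
            f"followed by one column per frame"
        )
    ids = [_coerce_id(v) for v in df["residue_id"]]
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if mat.shape[1] < 50:
        raise ValueError(f"time-series TSV {path}: fewer than 50 frames")
    return ids, mat


def _coerce_id(v):
    try:
        return int(v)
    except (TypeError, ValueError):
        return str(v)


def read_ca_coords(path, chain: str | None = None) -> dict:
    """C-alpha coordinates {residue_number: xyz} from a PDB file.

    First model only; one chain, selectable (defaults to the first chain
    containing CA atoms).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"PDB file {path}: no models found")
    chains = [ch for ch in model if chain is None or ch.id == chain]
    if not chains:
        raise ValueError(f"PDB file {path}: chain {chain!r} not found")
    coords = {}
    for ch in chains:
        for res in ch:
            if "CA" in res:
                coords[int(res.id[1])] = np.array(res["CA"].coord, dtype=float)
        if coords:
            break  # one chain only
    if not coords:
        raise ValueError(f"PDB file {path}: no CA atoms found")
    return coords


def read_contacts_tsv(path) -> dict:
    """Contact counts {(res_a, res_b): count} from a three-column TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"res_a", "res_b", "count"}
    if missing := required - set(df.columns):
        raise ValueError(f"contact table {path} is missing columns {sorted(missing)}")
    contacts = {}
    for _, row in df.iterrows():
        a, b = _coerce_id(row["res_a"]), _coerce_id(row["res_b"])
        contacts[tuple(sorted((a, b), key=str))] = int(row["count"])
    return contacts


def read_annotations_tsv(path) -> dict:
    """Residue annotations {residue_id: label} (e.g. known hotspots)."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"residue_id", "label"} - set(df.columns):
        raise ValueError(f"annotation table {path} is missing columns {sorted(missing)}")
    return {_coerce_id(r["residue_id"]): str(r["label"]) for _, r in df.iterrows()}


# ------------------------------------------------------------- stage logic

def compute_embedding_params(
    mat: np.ndarray,
    ids: list,
    n_bins=None,
    max_lag=None,
    max_dim=10,
    fnn_threshold=embedding.FNN_THRESHOLD,
    global_embedding=False,
) -> pd.DataFrame:
    """Per-residue (delay, dimension) table with fallback flags.

    With ``global_embedding`` every residue is forced to the maximum
    (d, m) over residues so all state counts align.
    """
    rows = []
    for rid, series in zip(ids, mat):
        params, flagged = embedding.select_embedding(
            series, max_lag=max_lag, n_bins=n_bins,
            max_dim=max_dim, fnn_threshold=fnn_threshold,
        )
        rows.append(
            {"residue_id": rid, "delay": params.delay,
             "dimension": params.dimension, "flagged": flagged}
        )
    df = pd.DataFrame(rows)
    if global_embedding:
        df["delay"] = df["delay"].max()
        df["dimension"] = df["dimension"].max()
    return df


def compute_recurrence_matrices(
    mat: np.ndarray, ids: list, params: pd.DataFrame, target_rate: float
) -> tuple[dict, pd.DataFrame]:
    """Calibrate epsilon and build the recurrence matrix for each residue.

    Returns ({residue_id: RecurrenceMatrix}, per-residue rate table).
    """
    by_id = params.set_index("residue_id")
    matrices, rows = {}, []
    for rid, series in zip(ids, mat):
        p = embedding.EmbeddingParams(int(by_id.loc[rid, "delay"]),
                                      int(by_id.loc[rid, "dimension"]))
        states = embedding.embed(series, p)
        cal = recurrence.calibrate_epsilon(states, target_rate)
        matrices[rid] = recurrence.recurrence_matrix(states, cal.epsilon, rid)
        rows.append(
            {"residue_id": rid, "epsilon": cal.epsilon,
             "achieved_rate": cal.achieved_rate, "n_states": states.shape[0],
             "degenerate": cal.flagged}
        )
    return matrices, pd.DataFrame(rows)


def _edges_frame(g) -> pd.DataFrame:
    rows = [
        {"res_a": a, "res_b": b, "weight": d["weight"], "path_length": d["path_length"]}
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["res_a", "res_b", "weight", "path_length"])


def _render_report(kind: str, records: list, cfg: RunConfig) -> str:
    lines = [
        f"## Significant residues — {kind} network",
        "",
        f"Thresholds: z_B > {cfg.z_b_threshold}, z_C > {cfg.z_c_threshold}.",
        "",
        "| residue | z_B | z_C | significant by | annotation | significant/annotated neighbors |",
        "|---|---|---|---|---|---|",
    ]
    for r in records:
        by = "+".join(
            k for k, f in (("B", r["significant_B"]), ("C", r["significant_C"])) if f
        )
        nbs = ", ".join(
            f"{n['residue_id']}" + (f" ({n['annotation']})" if n["annotation"] else "")
            for n in r["neighbors"]
        )
        lines.append(
            f"| {r['residue_id']} | {r['z_B']:.2f} | {r['z_C']:.2f} | {by} "
            f"| {r['annotation'] or '-'} | {nbs or '-'} |"
        )
    if not records:
        lines.append("| (none) | | | | | |")
    lines.append("")
    return "\n".join(lines)


# ------------------------------------------------------------------ runner

def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write every artifact under ``config.out_dir``.

    Returns a dict of the in-memory results (embedding-parameter table,
    rate table, joint counts, graphs, centrality tables, significant
    records and the manifest).  Deterministic given inputs and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ids, mat = read_series_tsv(config.series_path)
    coords = read_ca_coords(config.pdb_path, chain=config.chain)

    missing_in_pdb = [r for r in ids if r not in coords]
    if missing_in_pdb:
        raise ReconciliationError(
            "residues present in the time series but absent from the "
            f"reference structure: {missing_in_pdb}"
        )
    coords = {r: coords[r] for r in ids}  # restrict and order to series residues

    params = compute_embedding_params(
        mat, ids, n_bins=config.n_bins, max_lag=config.max_lag,
        max_dim=config.max_dim, fnn_threshold=config.fnn_threshold,
        global_embedding=config.global_embedding,
    )
    params.to_csv(out / "embedding_params.tsv", sep="\t", index=False)

    matrices, rates = compute_recurrence_matrices(
        mat, ids, params, config.target_recurrence_rate
    )
    rates.to_csv(out / "recurrence_rates.tsv", sep="\t", index=False)

    counts, n_common = recurrence.joint_recurrence_counts(matrices)
    pd.DataFrame(
        [{"res_a": a, "res_b": b, "count": c} for (a, b), c in counts.items()]
    ).to_csv(out / "jr_counts.tsv", sep="\t", index=False)

    annotations = (
        read_annotations_tsv(config.annotations_path)
        if config.annotations_path else {}
    )

    graphs, tables, reports = {}, {}, []
    for kind in config.networks:
        if kind == "jrp_weighted":
            g = network.build_jrp_network(counts, coords, config.length_mode)
        elif kind == "unweighted_cutoff":
            g = network.build_unweighted_network(coords, config.cutoff_distance)
        elif kind == "contact_weighted":
            if not config.contacts_path:
                raise ValueError("contact_weighted network requires contacts_path")
            g = network.build_contact_network(
                coords, contacts=read_contacts_tsv(config.contacts_path),
                length_mode=config.length_mode,
            )
        else:
            raise ValueError(f"unknown network kind {kind!r}")
        graphs[kind] = g
        _edges_frame(g).to_csv(out / f"edges_{kind}.tsv", sep="\t", index=False)
        table = network.centrality_table(g, config.z_b_threshold, config.z_c_threshold)
        tables[kind] = table
        table.to_csv(out / f"centrality_{kind}.csv", index=False)
        records = network.significant_residues(
            table, g, config.z_b_threshold, config.z_c_threshold, annotations
        )
        reports.append(_render_report(kind, records, cfg=config))

    (out / "report.md").write_text("# Residue network hotspot report\n\n" + "\n".join(reports))

    if config.asa_path:
        rsa.read_asa_tsv(config.asa_path).to_csv(out / "exposure.csv", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "n_residues": len(ids),
        "n_frames": int(mat.shape[1]),
        "n_states_common": int(n_common),
        "achieved_rates": {
            str(r["residue_id"]): float(r["achieved_rate"]) for _, r in rates.iterrows()
        },
        "flagged_embeddings": [
            _coerce_id(r["residue_id"]) for _, r in params.iterrows() if r["flagged"]
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if manifest["flagged_embeddings"]:
        warnings.warn(
            f"fallback delay/dimension used for residues {manifest['flagged_embeddings']}",
            stacklevel=2,
        )

    return {
        "params": params, "rates": rates, "counts": counts,
        "graphs": graphs, "tables": tables, "manifest": manifest,
    }


def run_from_manifest(manifest_path) -> dict:
    """Re-execute a run exactly from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = manifest["config"]
    cfg["networks"] = tuple(cfg["networks"])
    return run_pipeline(RunConfig(**cfg))


def load_config_file(path) -> dict:
    """Flat key=value config file -> dict of RunConfig field overrides."""
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    overrides = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        overrides[key] = _parse_value(key, value)
    return overrides


def _parse_value(key, value: str):
    if key == "networks":
        return tuple(v.strip() for v in value.split(",") if v.strip())
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    if value.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value
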