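"""Relative solvent accessibility (RSA) and exposure classification.

RSA is a residue's accessible surface area (ASA) divided by the
theoretical maximum ASA of its amino-acid type (Tien et al. 2013
theoretical set).  Residues are classified as buried (RSA < 5%),
partially buried (5% <= RSA < 20%) or exposed (RSA >= 20%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "BURIED",
    "PARTIALLY_BURIED",
    "EXPOSED",
    "MAX_ASA",
    "ResidueExposure",
    "compute_rsa",
    "classify_exposure",
    "exposure_table",
    "read_asa_tsv",
    "mean_rsa",
]

BURIED = "buried"
PARTIALLY_BURIED = "partially_buried"
EXPOSED = "exposed"

BURIED_MAX = 0.05    # RSA below this -> buried
EXPOSED_MIN = 0.20   # RSA at or above this -> exposed


def _load_max_asa() -> dict[str, float]:
    with resources.files("jrpnet.data").joinpath("max_asa_theoretical.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    table = {}
    for _, row in df.iterrows():
        table[row["three_letter"].upper()] = float(row["max_asa"])
        table[row["one_letter"].upper()] = float(row["max_asa"])
    return table


#: Max ASA (square Angstrom) keyed by both three- and one-letter codes.
MAX_ASA = _load_max_asa()


@dataclass(frozen=True)
class ResidueExposure:
    residue_id: object
    residue_type: str
    asa: float
    max_asa: float
    rsa: float
    category: str


def compute_rsa(asa: float, residue_type: str) -> float:
    """ASA divided by the theoretical maximum for the residue type.

    Values above 1 can occur for unusual conformations; they are
    permitted but trigger a warning.
    """
    if asa < 0:
        raise ValueError(f"ASA must be non-negative, got {asa}")
    key = residue_type.strip().upper()
    if key not in MAX_ASA:
        raise KeyError(f"unknown residue type {residue_type!r}")
    rsa = asa / MAX_ASA[key]
    if rsa > 1.0:
        warnings.warn(
            f"RSA {rsa:.3f} > 1 for residue type {residue_type} (ASA {asa})",
            stacklevel=2,
        )
    return rsa


def classify_exposure(rsa: float) -> str:
    """buried (< 5%), partially_buried (5-20%) or exposed (>= 20%)."""
    if rsa < 0:
        raise ValueError(f"RSA must be non-negative, got {rsa}")
    if rsa < BURIED_MAX:
        return BURIED
    if rsa < EXPOSED_MIN:
        return PARTIALLY_BURIED
    return EXPOSED


def exposure_table(records) -> pd.DataFrame:
    """Build the exposure table from (residue_id, residue_type, asa) rows."""
    rows = []
    for rid, rtype, asa in records:
        rsa = compute_rsa(asa, rtype)
        rows.append(
            {
                "residue_id": rid,
                "residue_type": rtype,
                "asa": asa,
                "rsa": rsa,
                "category": classify_exposure(rsa),
            }
        )
    return pd.DataFrame(rows)


def read_asa_tsv(path) -> pd.DataFrame:
    """Read an ASA table (columns residue_id, residue_type, asa) and
    return the exposure table."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue_id", "residue_type", "asa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ASA table {path} is missing columns {sorted(missing)}")
    return exposure_table(df[["residue_id", "residue_type", "asa"]].itertuples(index=False))


def mean_rsa(table: pd.DataFrame, residue_ids=None) -> float:
    """Arithmetic mean RSA over a residue subset (all residues if None)."""
    if residue_ids is not None:
        table = table[table["residue_id"].isin(set(residue_ids))]
    if len(table) == 0:
        raise ValueError("no residues selected for mean RSA")
    return float(table["rsa"].mean())
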