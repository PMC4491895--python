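"""Synthetic trajectory generator with known coupling structure.

Real inputs to the joint-recurrence network method are per-residue scalar
time series (e.g. per-residue C-alpha RMSD traces sampled from a molecular
dynamics trajectory) plus a reference structure.  This module generates a
stand-in with a *known* interaction topology: each "residue" emits a
stationary AR(1) series, and selected residue pairs additionally share a
latent AR(1) driver, which produces simultaneous recurrences -- exactly the
signal the joint-recurrence edge weight accumulates.  Reference coordinates
are placed on a straight chain so every geometric expectation is analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticSystem",
    "generate_series",
    "generate_reference_coordinates",
    "write_series_tsv",
    "write_ca_pdb",
]


@dataclass(frozen=True)
class SyntheticSystem:
    """Specification of a synthetic coupled-residue system.

    Parameters
    ----------
    n_residues : int
        Number of residues (chain positions), at least 3.
    n_frames : int
        Number of time frames per series, at least 100.
    coupling_pairs : frozenset of 2-tuples
        Unordered residue-index pairs (1-based ids) that share a latent
        driver.  No self-pairs.
    coupling_strength : float
        Fraction of each coupled residue's variance contributed by the
        shared driver, in [0, 1).
    noise_sd : float
        Innovation standard deviation of the AR(1) processes.
    seed : int
        Seed for the generator; identical systems produce identical output.
    autocorrelation : float
        AR(1) coefficient of both base and driver processes.  0.9 by
        default, giving series with non-trivial embedding structure.
    chain_spacing : float
        Consecutive C-alpha distance in Angstrom (3.8 by default, the
        spacing of a real polypeptide chain).
    """

    n_residues: int
    n_frames: int
    coupling_pairs: frozenset = field(default_factory=frozenset)
    coupling_strength: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    autocorrelation: float = 0.9
    chain_spacing: float = 3.8

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError(f"n_residues must be >= 3, got {self.n_residues}")
        if self.n_frames < 100:
            raise ValueError(f"n_frames must be >= 100, got {self.n_frames}")
        if not 0.0 <= self.coupling_strength < 1.0:
            raise ValueError(
                f"coupling_strength must be in [0, 1), got {self.coupling_strength}"
            )
        if not 0.0 <= self.autocorrelation < 1.0:
            raise ValueError("autocorrelation must be in [0, 1)")
        pairs = frozenset(tuple(sorted(p)) for p in self.coupling_pairs)
        for a, b in pairs:
            if a == b:
                raise ValueError(f"coupling pair ({a},{b}) is a self-pair")
            if not (1 <= a <= self.n_residues and 1 <= b <= self.n_residues):
                raise ValueError(f"coupling pair ({a},{b}) outside residue range")
        object.__setattr__(self, "coupling_pairs", pairs)

    @property
    def residue_ids(self) -> list[int]:
        return list(range(1, self.n_residues + 1))


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1): x_t = phi x_{t-1} + e_t, initialized from the
    stationary distribution so the whole series is stationary."""
    e = rng.normal(0.0, sd, size=n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def generate_series(sys: SyntheticSystem) -> np.ndarray:
    """Generate the (n_residues x n_frames) scalar time-series matrix.

    Each residue's series is a stationary AR(1) base process.  For every
    coupling pair a shared latent AR(1) driver is mixed into both members
    with variance-preserving weights::

        z_i = sqrt(1 - c) * base_i + sum_p sqrt(c / k_i) * driver_p

    where ``c`` is the coupling strength and ``k_i`` the number of pairs
    containing residue ``i``.  With c = 0 the series are independent; as c
    grows, coupled pairs recur simultaneously far above chance while each
    series keeps the same stationary variance.

    Returns an array whose row order follows ``sys.residue_ids``.
    """
    rng = np.random.default_rng(sys.seed)
    phi = sys.autocorrelation
    base = np.vstack(
        [_ar1(rng, sys.n_frames, phi, sys.noise_sd) for _ in range(sys.n_residues)]
    )
    c = sys.coupling_strength
    if c == 0.0 or not sys.coupling_pairs:
        return base
    pairs = sorted(sys.coupling_pairs)
    drivers = {p: _ar1(rng, sys.n_frames, phi, sys.noise_sd) for p in pairs}
    n_pairs_of = np.zeros(sys.n_residues, dtype=int)
    for a, b in pairs:
        n_pairs_of[a - 1] += 1
        n_pairs_of[b - 1] += 1
    out = base.copy()
    coupled = n_pairs_of > 0
    out[coupled] *= np.sqrt(1.0 - c)
    for (a, b), drv in drivers.items():
        for idx in (a - 1, b - 1):
            out[idx] += np.sqrt(c / n_pairs_of[idx]) * drv
    return out


def generate_reference_coordinates(sys: SyntheticSystem) -> np.ndarray:
    """Straight-chain C-alpha coordinates: residue i at (i-1)*spacing on x.

    Consecutive residues are exactly ``chain_spacing`` apart, so with the
    3.8 Angstrom default only consecutive residues fall inside a 7 Angstrom
    cutoff and the unweighted network of the chain is a path graph.
    """
    coords = np.zeros((sys.n_residues, 3))
    coords[:, 0] = np.arange(sys.n_residues) * sys.chain_spacing
    return coords


def write_series_tsv(path, series: np.ndarray, residue_ids=None) -> None:
    """Write the series matrix as TSV: header of frame indices, first column
    residue id, one row per residue."""
    series = np.asarray(series)
    if residue_ids is None:
        residue_ids = range(1, series.shape[0] + 1)
    with open(path, "w") as fh:
        header = "residue_id\t" + "\t".join(str(j) for j in range(series.shape[1]))
        fh.write(header + "\n")
        for rid, row in zip(residue_ids, series):
            fh.write(str(rid) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_ca_pdb(path, coords: np.ndarray, residue_ids=None, chain_id: str = "A") -> None:
    """Write coordinates as a minimal PDB: one CA ATOM record per residue."""
    coords = np.asarray(coords)
    if residue_ids is None:
        residue_ids = range(1, coords.shape[0] + 1)
    with open(path, "w") as fh:
        for serial, (rid, (x, y, z)) in enumerate(zip(residue_ids, coords), start=1):
            fh.write(
                f"ATOM  {serial:>5}  CA  ALA {chain_id}{rid:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
        fh.write("END\n")
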