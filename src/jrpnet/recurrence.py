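"""Recurrence matrices and joint-recurrence counting.

The recurrence plot of an embedded trajectory marks time pairs (i, j)
whose states lie within a threshold distance:

    R_ij(eps) = Theta(eps - ||X_i - X_j||),

with the Euclidean norm and Theta(x) = 0 for x < 0 and 1 otherwise, so a
distance exactly equal to eps recurs.  The threshold is calibrated per
residue so the recurrence rate -- ones over total matrix cells, diagonal
included -- hits a target (3% by default in the pipeline).

The joint recurrence plot of two residues is the elementwise product of
their recurrence matrices; accumulating its strictly-upper-triangle ones
counts the time pairs at which both residues simultaneously revisit
earlier states.  That count, later divided by the geometric C-alpha
distance, is the edge weight of the joint-recurrence network.

Counting is done on bit-packed upper triangles (one byte per 8 cells,
AND + popcount), which keeps the all-pairs accumulation for ~165 residues
by ~1000 states in the seconds range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EpsilonCalibration",
    "RecurrenceMatrix",
    "JointRecurrenceCount",
    "calibrate_epsilon",
    "recurrence_matrix",
    "joint_recurrence_count",
    "joint_recurrence_counts",
]

_POPCOUNT = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(axis=1)


@dataclass(frozen=True)
class EpsilonCalibration:
    """Calibrated threshold with the rate it actually achieves."""

    epsilon: float
    achieved_rate: float
    flagged: bool = False  # degenerate trajectory (all states identical)


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Symmetric binary recurrence matrix with its threshold and rate."""

    bits: np.ndarray  # (n_states, n_states) bool
    epsilon: float
    recurrence_rate: float
    residue_id: object = None

    @property
    def n_states(self) -> int:
        return self.bits.shape[0]

    def upper_triangle_count(self) -> int:
        """Number of strictly-upper-triangle recurrences."""
        n = self.n_states
        return int(self.bits[np.triu_indices(n, 1)].sum())

    def truncated(self, n: int) -> "RecurrenceMatrix":
        """Leading n x n window (recurrence_rate recomputed)."""
        if n > self.n_states:
            raise ValueError(f"cannot truncate {self.n_states} states to {n}")
        if n == self.n_states:
            return self
        b = self.bits[:n, :n]
        return RecurrenceMatrix(b, self.epsilon, float(b.mean()), self.residue_id)


@dataclass(frozen=True)
class JointRecurrenceCount:
    """Accumulated simultaneous recurrences of an unordered residue pair."""

    pair: tuple
    count: int
    n_states: int


def calibrate_epsilon(states, target_rate: float) -> EpsilonCalibration:
    """Smallest threshold whose achieved recurrence rate is >= target.

    Exact quantile selection on the sorted list of all pairwise state
    distances: with n states and k symmetric off-diagonal pairs recurring,
    the rate is (n + 2k) / n^2 (diagonal included).  The returned epsilon
    realizes the smallest achievable rate at or above ``target_rate``;
    ties at the chosen distance all recur, so the achieved rate is
    recomputed after selection.

    A degenerate trajectory (all states identical) has rate 1 for any
    non-negative threshold; it is flagged and a tiny positive epsilon is
    returned.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError(f"target_rate must be in (0, 1), got {target_rate}")
    X = np.atleast_2d(np.asarray(states, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n = X.shape[0]
    d = np.sort(pdist(X))
    if d.size == 0 or d[-1] == 0.0:
        return EpsilonCalibration(np.finfo(float).tiny, 1.0, flagged=True)
    # minimum number of off-diagonal symmetric pairs needed
    k_min = int(np.ceil((target_rate * n * n - n) / 2.0))
    n_zero = int(np.searchsorted(d, 0.0, side="right"))
    if k_min <= n_zero:
        # floor rate already meets the target: epsilon below the smallest
        # positive distance (zero-distance pairs recur regardless)
        eps = d[n_zero] / 2.0 if n_zero < d.size else np.finfo(float).tiny
        eps = max(eps, np.finfo(float).tiny)
    else:
        eps = float(d[k_min - 1])
    k = int(np.searchsorted(d, eps, side="right"))
    rate = (n + 2 * k) / (n * n)
    return EpsilonCalibration(float(eps), float(rate), flagged=False)


def recurrence_matrix(states, epsilon: float, residue_id=None) -> RecurrenceMatrix:
    """Binary recurrence matrix: R_ij = 1 iff ||X_i - X_j|| <= epsilon.

    Euclidean norm; symmetric with unit diagonal for any epsilon > 0.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    X = np.atleast_2d(np.asarray(states, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    dm = squareform(pdist(X))
    bits = dm <= epsilon
    return RecurrenceMatrix(bits, float(epsilon), float(bits.mean()), residue_id)


def _pack_upper(rm: RecurrenceMatrix) -> np.ndarray:
    n = rm.n_states
    return np.packbits(rm.bits[np.triu_indices(n, 1)])


def joint_recurrence_count(rx: RecurrenceMatrix, ry: RecurrenceMatrix) -> JointRecurrenceCount:
    """Count strictly-upper-triangle cells where both residues recur.

    Matrices of unequal size (per-residue embedding parameters give
    different state counts) are truncated to their common leading window
    first, preserving simultaneity of time indices.  The self-recurrence
    diagonal is excluded: it is all-ones for every residue and carries no
    pairwise information.
    """
    n = min(rx.n_states, ry.n_states)
    bx = _pack_upper(rx.truncated(n))
    by = _pack_upper(ry.truncated(n))
    count = int(_POPCOUNT[bx & by].sum())
    pair = tuple(sorted((rx.residue_id, ry.residue_id), key=str))
    return JointRecurrenceCount(pair, count, n)


def joint_recurrence_counts(matrices: dict) -> tuple[dict, int]:
    """All-pairs joint-recurrence counts for {residue_id: RecurrenceMatrix}.

    Every matrix is truncated to the minimum state count across residues,
    then each pair is AND-counted on packed bits.  Returns
    ({(a, b): count}, n_states_common) with a < b in residue-id order.
    """
    ids = list(matrices)
    n_min = min(m.n_states for m in matrices.values())
    packed = {rid: _pack_upper(matrices[rid].truncated(n_min)) for rid in ids}
    counts = {}
    for i, a in enumerate(ids):
        pa = packed[a]
        for b in ids[i + 1 :]:
            counts[(a, b)] = int(_POPCOUNT[pa & packed[b]].sum())
    return counts, n_min
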