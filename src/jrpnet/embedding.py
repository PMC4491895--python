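"""Phase-space reconstruction by time-delay embedding.

A scalar observable Z_1..Z_N sampled at even spacing is lifted to state
vectors

    X_i = (Z_i, Z_{i+d}, ..., Z_{i+(m-1)d}),   i = 1..N - (m-1)d,

where the delay d is chosen at the first local minimum of the time-lagged
mutual information and the dimension m by the false-nearest-neighbor
criterion of Kennel et al.  Each residue's series gets its own (d, m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "DelaySelection",
    "DimensionSelection",
    "mutual_information",
    "select_delay",
    "false_nearest_neighbors_fraction",
    "select_dimension",
    "select_embedding",
    "embed",
]

#: Kennel double criterion defaults: a neighbor is false when the extra-
#: coordinate increment exceeds R_TOL times the current distance, or when
#: the (m+1)-dimensional distance exceeds A_TOL_FACTOR series standard
#: deviations.
R_TOL = 15.0
A_TOL_FACTOR = 2.0

#: Fraction of false neighbors considered "very small" -> dimension accepted.
FNN_THRESHOLD = 0.01


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay d (frames) and embedding dimension m."""

    delay: int
    dimension: int

    def __post_init__(self):
        if self.delay < 1:
            raise ValueError(f"delay must be >= 1, got {self.delay}")
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")

    def n_states(self, n: int) -> int:
        return n - (self.dimension - 1) * self.delay


@dataclass(frozen=True)
class DelaySelection:
    delay: int
    flagged: bool  # True when no strict local MI minimum existed in range
    mi: tuple = ()


@dataclass(frozen=True)
class DimensionSelection:
    dimension: int
    flagged: bool  # True when the FNN fraction never dropped below threshold
    fractions: tuple = ()


def _default_bins(n: int) -> int:
    return min(32, max(2, int(np.sqrt(n))))


def mutual_information(values, lag: int, n_bins: int | None = None) -> float:
    """Histogram mutual information (nats) between Z_t and Z_{t+lag}.

    Equal-width bins over each marginal's observed range, with the
    Miller-Madow correction for the positive bias of plug-in histogram
    estimates (clamped at zero, so independent noise reads near zero
    instead of ~(B-1)^2/2N nats).  A constant series occupies a single
    bin and has MI zero (0 log 0 := 0).  Lag 0 is permitted and returns
    the self-information of the binned series.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if not 0 <= lag < n / 2:
        raise ValueError(f"lag {lag} out of range [0, {n / 2})")
    if n_bins is None:
        n_bins = _default_bins(n - lag)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = z[: n - lag]
    y = z[lag:]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    n_samples = joint.sum()
    joint /= n_samples
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    # Miller-Madow: plug-in MI is biased upward by about
    # (occupied_joint - occupied_x - occupied_y + 1) / (2 n)
    bias = (nz.sum() - (px > 0).sum() - (py > 0).sum() + 1) / (2.0 * n_samples)
    return max(0.0, mi - bias)


def select_delay(values, max_lag: int | None = None, n_bins: int | None = None) -> DelaySelection:
    """Delay at the first strict local minimum of MI(lag).

    Scans lags 0..max_lag+1 and returns the smallest L >= 1 with
    MI(L-1) > MI(L) < MI(L+1).  Series dominated by noise may have no
    such minimum in range; then the conservative fallback of lag 1 is
    returned with ``flagged=True``.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 50:
        raise ValueError(f"series too short for delay selection (N={n} < 50)")
    if max_lag is None:
        max_lag = min(100, n // 2 - 2)
    if max_lag >= n / 2 - 1:
        raise ValueError(f"max_lag {max_lag} too large for series of length {n}")
    mi = np.array([mutual_information(z, lag, n_bins) for lag in range(max_lag + 2)])
    for lag in range(1, max_lag + 1):
        if mi[lag - 1] > mi[lag] < mi[lag + 1]:
            return DelaySelection(lag, False, tuple(mi))
    return DelaySelection(1, True, tuple(mi))


def false_nearest_neighbors_fraction(
    values,
    delay: int,
    dim: int,
    r_tol: float = R_TOL,
    a_tol_factor: float = A_TOL_FACTOR,
) -> float:
    """Fraction of nearest neighbors at dimension ``dim`` that are false.

    For each state in the dim-dimensional embedding, its nearest neighbor
    is found; the pair is declared false when appending the (dim+1)-th
    delay coordinate either stretches the distance by more than ``r_tol``
    relative to the dim-distance, or pushes the (dim+1)-distance beyond
    ``a_tol_factor`` series standard deviations.  Only states for which
    the extra coordinate exists are examined.

    A series of identical values has all-zero distances and no
    distinguishable false neighbors; the fraction is defined as 0.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    n_use = n - dim * delay  # states with an existing (dim+1)-th coordinate
    if n_use < 2:
        raise ValueError(
            f"too few states ({n_use}) to test dimension {dim} with delay {delay}"
        )
    sd = z.std()
    if sd == 0.0:
        return 0.0
    X = embed(z, EmbeddingParams(delay, dim))[:n_use]
    extra = z[dim * delay : dim * delay + n_use]
    tree = cKDTree(X)
    dist, idx = tree.query(X, k=2)
    d_nn = dist[:, 1]
    j = idx[:, 1]
    incr = np.abs(extra - extra[j])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_nn > 0, incr / d_nn, np.where(incr > 0, np.inf, 0.0))
    d_next = np.sqrt(d_nn * d_nn + incr * incr)
    false = (ratio > r_tol) | (d_next > a_tol_factor * sd)
    return float(false.mean())


def select_dimension(
    values,
    delay: int,
    max_dim: int = 10,
    threshold: float = FNN_THRESHOLD,
    fnn_fn=false_nearest_neighbors_fraction,
) -> DimensionSelection:
    """Smallest m <= max_dim whose FNN fraction is below ``threshold``.

    When no dimension qualifies, ``max_dim`` is returned with
    ``flagged=True``.  ``fnn_fn`` is injectable for testing.
    """
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    fractions = []
    for m in range(1, max_dim + 1):
        f = fnn_fn(values, delay, m)
        fractions.append(f)
        if f < threshold:
            return DimensionSelection(m, False, tuple(fractions))
    return DimensionSelection(max_dim, True, tuple(fractions))


def select_embedding(
    values,
    max_lag: int | None = None,
    n_bins: int | None = None,
    max_dim: int = 10,
    fnn_threshold: float = FNN_THRESHOLD,
) -> tuple[EmbeddingParams, bool]:
    """Select (d, m) for one series; second return is the combined fallback flag."""
    ds = select_delay(values, max_lag=max_lag, n_bins=n_bins)
    dm = select_dimension(values, ds.delay, max_dim=max_dim, threshold=fnn_threshold)
    return EmbeddingParams(ds.delay, dm.dimension), ds.flagged or dm.flagged


def embed(values, params: EmbeddingParams) -> np.ndarray:
    """Delay-embed a series into an (n_states x m) state matrix.

    Row i is (Z_i, Z_{i+d}, ..., Z_{i+(m-1)d}); n_states = N - (m-1)d.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    d, m = params.delay, params.dimension
    n_states = n - (m - 1) * d
    if n_states < 1:
        raise ValueError(
            f"series of length {n} too short to embed with d={d}, m={m} "
            f"(would leave {n_states} states)"
        )
    return np.column_stack([z[k * d : k * d + n_states] for k in range(m)])
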