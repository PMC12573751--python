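"""Permutationally invariant collective variables from sorted distance matrices.

For a configuration of N molecules in a periodic box, the matrix of
pairwise minimum-image Euclidean distances is invariant under translations
and rotations.  Sorting that matrix ascending first inside each column and
then inside each row yields a matrix that is additionally invariant under
any relabelling of the molecules, so each element ``d̄_ij`` defines a
symmetry-respecting scalar collective variable (CV).  The time series of
these elements form the CV pool sampled by the variational optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVSeries",
    "CVPool",
    "min_image_distance",
    "distance_matrix",
    "sorted_distance_matrix",
    "sorted_cv_stack",
    "build_cv_pool",
    "sample_cv",
]


def min_image_distance(p1, p2, L: float) -> float:
    """Euclidean distance with per-axis displacement wrapped into [-L/2, L/2]."""
    delta = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    delta -= L * np.round(delta / L)
    return float(np.sqrt(np.sum(delta**2)))


def distance_matrix(positions: np.ndarray, L: float) -> np.ndarray:
    """N x N minimum-image distance matrix (zero diagonal, symmetric)."""
    p = np.asarray(positions, dtype=np.float64)
    delta = p[:, None, :] - p[None, :, :]
    delta -= L * np.round(delta / L)
    return np.sqrt(np.sum(delta**2, axis=-1))


def sorted_distance_matrix(d: np.ndarray) -> np.ndarray:
    """Sort ascending within each column, then within each row.

    The result depends only on the multiset structure of ``d``, not on the
    molecule labels: relabelling molecules permutes rows and columns
    simultaneously, which the two sorting passes erase.
    """
    return np.sort(np.sort(d, axis=0), axis=1)


def sorted_cv_stack(positions: np.ndarray, L: float,
                    dtype=np.float32) -> np.ndarray:
    """Sorted distance matrices for a whole trajectory: (T, N, N) array."""
    T, N = positions.shape[0], positions.shape[1]
    out = np.empty((T, N, N), dtype=dtype)
    for k in range(T):
        out[k] = sorted_distance_matrix(distance_matrix(positions[k], L))
    return out


@dataclass
class CVSeries:
    """One scalar CV per frame, aligned with the source trajectory."""

    values: np.ndarray
    segment_ids: np.ndarray
    channel_id: object  # (i, j) tuple or a named observable such as "n"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.segment_ids = np.asarray(self.segment_ids)
        if len(self.values) != len(self.segment_ids):
            raise ValueError("values and segment_ids must have equal length")


@dataclass
class CVPool:
    """A set of CV channels the optimizer can draw from uniformly.

    Channels are (i, j) indices into the sorted distance matrix, plus any
    named observables registered with :meth:`add_observable` (e.g. the
    largest-cluster size ``n``).  Zero-variance channels (such as the
    all-zero first row produced by the sorted diagonal) are dropped at
    construction and recorded in ``dropped``.
    """

    segment_ids: np.ndarray
    channels: list = field(default_factory=list)
    dropped: list = field(default_factory=list)
    _cache: np.ndarray | None = None  # (T, N, N) sorted stack, optional
    _positions: np.ndarray | None = None
    _L: float | None = None
    _named: dict = field(default_factory=dict)

    def add_observable(self, name: str, values: np.ndarray,
                       sampled: bool = True) -> None:
        values = np.asarray(values, dtype=np.float64)
        if np.std(values) == 0:
            self.dropped.append(name)
            return
        self._named[name] = values
        if sampled:
            self.channels.append(name)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def series(self, channel) -> CVSeries:
        if isinstance(channel, str):
            return CVSeries(self._named[channel], self.segment_ids, channel)
        i, j = channel
        if self._cache is not None:
            vals = self._cache[:, i, j].astype(np.float64)
        else:
            T = len(self.segment_ids)
            vals = np.empty(T)
            for k in range(T):
                vals[k] = sorted_distance_matrix(
                    distance_matrix(self._positions[k], self._L))[i, j]
        return CVSeries(vals, self.segment_ids, channel)

    def sample(self, rng: np.random.Generator) -> CVSeries:
        """Uniform seeded draw over surviving channels."""
        if not self.channels:
            raise ValueError("empty CV pool")
        return self.series(self.channels[int(rng.integers(self.n_channels))])


def build_cv_pool(traj, channels="all", cache: bool = True,
                  max_cache_bytes: int = 2_000_000_000,
                  var_tol: float = 1e-12) -> CVPool:
    """Build the sorted-distance CV pool for a lattice trajectory.

    Parameters
    ----------
    traj : lattice.Trajectory
    channels : "all" or an explicit list of (i, j) index pairs.
    cache : precompute the full (T, N, N) sorted stack when it fits in
        ``max_cache_bytes``; otherwise channels are evaluated lazily from
        the stored configurations (variance then screened on a frame
        subsample).  Lazy evaluation keeps the random-channel semantics at
        bounded memory for large systems.
    """
    T, N = traj.positions.shape[0], traj.positions.shape[1]
    L = float(traj.config.L)
    pool = CVPool(segment_ids=traj.segment_ids)

    use_cache = cache and T * N * N * 4 <= max_cache_bytes
    if use_cache:
        stack = sorted_cv_stack(traj.positions, L)
        var = stack.astype(np.float64).var(axis=0)
        pool._cache = stack
    else:
        sub = traj.positions[:: max(1, T // 256)]
        var = sorted_cv_stack(sub, L).astype(np.float64).var(axis=0)
        pool._positions = traj.positions
        pool._L = L

    if channels == "all":
        requested = [(i, j) for i in range(N) for j in range(N)]
    else:
        requested = [tuple(c) for c in channels]
    for i, j in requested:
        if var[i, j] > var_tol:
            pool.channels.append((i, j))
        else:
            pool.dropped.append((i, j))
    if not pool.channels:
        raise ValueError("all requested CV channels are constant")
    return pool


def sample_cv(pool: CVPool, rng: np.random.Generator) -> CVSeries:
    """Module-level alias for :meth:`CVPool.sample`."""
    return pool.sample(rng)
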