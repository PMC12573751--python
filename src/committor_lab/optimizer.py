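"""Nonparametric variational optimization of a reaction coordinate toward
the committor.

The putative reaction coordinate (RC) is represented only by its time
series r(k dt0) in [0, 1], with r = 0 on boundary state A and r = 1 on B.
Each iteration draws a collective-variable series x, adds a polynomial
variation

    delta_r = sum_{i+j <= l} a_ij r^i x^j     (zero on A and B frames)

and picks the coefficients a_ij that minimize the total squared
displacement (TSD) of the updated series at the finest lag,

    TSD = sum_k [r(k+1) - r(k)]^2,

a linear least-squares problem.  Among all functions with the clamped
boundary values the committor minimizes the expected TSD (the discrete
Dirichlet form of the sampled dynamics), so iterating over a rich CV pool
drives r toward the committor without ever parametrizing r(X) explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .cvs import CVPool, CVSeries

__all__ = [
    "RCSeries",
    "OptimizerConfig",
    "BoundaryStates",
    "tsd",
    "variation_basis",
    "solve_update",
    "optimize",
    "committor_of_n",
    "define_boundary_states",
    "initial_rc",
    "soft_boundary_optimize",
]


@dataclass
class RCSeries:
    """A putative reaction-coordinate time series with boundary masks.

    Invariants: r in [0, 1]; r = 0 exactly on A frames and 1 on B frames;
    the masks are disjoint; segmentation matches the source trajectory.
    """

    r: np.ndarray
    segment_ids: np.ndarray
    in_A: np.ndarray
    in_B: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.segment_ids = np.asarray(self.segment_ids)
        self.in_A = np.asarray(self.in_A, dtype=bool)
        self.in_B = np.asarray(self.in_B, dtype=bool)

    def validate(self) -> None:
        if np.any(self.in_A & self.in_B):
            raise ValueError("A and B masks overlap")
        if np.any(self.r[self.in_A] != 0.0) or np.any(self.r[self.in_B] != 1.0):
            raise ValueError("boundary frames not clamped to 0/1")
        if self.r.min() < 0.0 or self.r.max() > 1.0:
            raise ValueError("r leaves [0, 1]")

    def copy(self) -> "RCSeries":
        return RCSeries(self.r.copy(), self.segment_ids, self.in_A.copy(),
                        self.in_B.copy())


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the variational iteration.

    l : polynomial order of the variation (basis size (l+1)(l+2)/2).
    m_max : iteration budget.
    seed : seed for the channel-sampling RNG.
    rcond : relative singular-value cutoff of the least-squares solve.
    clip_enabled : clip the updated series back into [0, 1] (a 1-Lipschitz
        map, so it cannot increase the TSD).
    """

    l: int = 4
    m_max: int = 100
    seed: int = 0
    rcond: float = 1e-10
    clip_enabled: bool = True

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("polynomial order l must be >= 1")
        if self.m_max < 0:
            raise ValueError("m_max must be >= 0")


@dataclass(frozen=True)
class BoundaryStates:
    """A and B as terminal intervals of a reference coordinate:
    A = {v <= a_max}, B = {v >= b_min}."""

    a_max: float
    b_min: float
    reference: str = "n"

    def __post_init__(self) -> None:
        if not self.a_max < self.b_min:
            raise ValueError("need a_max < b_min for disjoint states")

    def masks(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = np.asarray(values, dtype=np.float64)
        return v <= self.a_max, v >= self.b_min


# ---------------------------------------------------------------------------
# TSD and the variational update


def _pair_index(segment_ids: np.ndarray, lag: int) -> np.ndarray:
    """Start indices k of within-segment pairs (k, k+lag)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = len(segment_ids)
    if lag >= n:
        return np.empty(0, dtype=np.int64)
    k = np.arange(n - lag)
    return k[segment_ids[k] == segment_ids[k + lag]]


def tsd(rc: RCSeries, lag: int = 1) -> float:
    """Total squared displacement over within-segment pairs at the lag."""
    if len(rc.r) == 0:
        raise ValueError("empty RC series")
    k = _pair_index(rc.segment_ids, lag)
    d = rc.r[k + lag] - rc.r[k]
    return float(np.dot(d, d))


def variation_basis(rc: RCSeries, x: CVSeries, l: int) -> np.ndarray:
    """Per-frame values of the (l+1)(l+2)/2 monomials r^i x^j, i+j <= l.

    The CV is standardized (zero mean, unit spread) before exponentiation:
    a pure reparametrization of the basis span that avoids catastrophic
    conditioning with raw, large-magnitude CVs.
    """
    xv = np.asarray(x.values, dtype=np.float64)
    if not np.all(np.isfinite(xv)):
        raise ValueError("non-finite CV values")
    if len(xv) != len(rc.r):
        raise ValueError("CV series not aligned with RC series")
    s = xv.std()
    xs = (xv - xv.mean()) / s if s > 0 else np.zeros_like(xv)
    r = rc.r
    r_pow = [np.ones_like(r)]
    x_pow = [np.ones_like(xs)]
    for _ in range(l):
        r_pow.append(r_pow[-1] * r)
        x_pow.append(x_pow[-1] * xs)
    cols = [r_pow[i] * x_pow[j] for i in range(l + 1) for j in range(l + 1 - i)]
    return np.column_stack(cols)


def solve_update(rc: RCSeries, basis: np.ndarray,
                 cfg: OptimizerConfig) -> tuple[np.ndarray, RCSeries]:
    """One analytic variational step.

    Boundary frames are held fixed (their variation is zero), the
    coefficients minimize the lag-1 TSD of r + delta_r via an SVD-based
    least squares, and the update is clipped back to [0, 1].  The TSD can
    never increase: the zero update is always admissible, and both the clip
    and the re-clamp are TSD-non-increasing; a numerical safeguard reverts
    the step otherwise.
    """
    free = ~(rc.in_A | rc.in_B)
    Z = basis * free[:, None]
    k = _pair_index(rc.segment_ids, 1)
    A = Z[k + 1] - Z[k]
    b = -(rc.r[k + 1] - rc.r[k])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficiency chatter
        try:
            coef, _, _, _ = np.linalg.lstsq(A, b, rcond=cfg.rcond)
        except np.linalg.LinAlgError:
            coef = np.zeros(basis.shape[1])
    if not np.all(np.isfinite(coef)):
        coef = np.zeros(basis.shape[1])

    r_new = rc.r + Z @ coef
    if cfg.clip_enabled:
        np.clip(r_new, 0.0, 1.0, out=r_new)
    r_new[rc.in_A] = 0.0
    r_new[rc.in_B] = 1.0
    out = RCSeries(r_new, rc.segment_ids, rc.in_A, rc.in_B)
    if tsd(out) > tsd(rc) * (1 + 1e-12) + 1e-12:  # numerical safeguard
        return np.zeros(basis.shape[1]), rc.copy()
    return coef, out


def optimize(r0: RCSeries, pool: CVPool, cfg: OptimizerConfig) -> tuple[RCSeries, dict]:
    """Iterate {sample CV -> build basis -> analytic TSD-minimizing update}.

    Returns the final RC series and a log with the TSD after every
    iteration and the channels drawn.  Boundary membership is taken from
    the masks carried by ``r0`` and preserved exactly throughout.
    """
    r0.validate()
    rng = np.random.default_rng(cfg.seed)
    rc = r0.copy()
    log = {"tsd": [tsd(rc)], "channels": [], "fallbacks": 0}
    for _ in range(cfg.m_max):
        x = pool.sample(rng)
        basis = variation_basis(rc, x, cfg.l)
        coef, rc = solve_update(rc, basis, cfg)
        if not np.any(coef):
            log["fallbacks"] += 1
        log["tsd"].append(tsd(rc))
        log["channels"].append(x.channel_id)
    return rc, log


def committor_of_n(n_series: CVSeries, boundary: BoundaryStates,
                   cfg: OptimizerConfig | None = None) -> tuple[RCSeries, dict]:
    """The n-based baseline coordinate q(n): optimize with x = n at every
    iteration (default budget m = 20).

    Every update is a polynomial in (r, n) and the initial ramp is itself a
    function of n, so the result is a reparametrization q(n) of the
    largest-cluster coordinate; projecting on q(n) therefore probes the
    optimality of n itself.
    """
    if cfg is None:
        cfg = OptimizerConfig(m_max=20)
    rc = initial_rc(n_series.values, n_series.segment_ids, boundary)
    log = {"tsd": [tsd(rc)], "channels": [], "fallbacks": 0}
    for _ in range(cfg.m_max):
        basis = variation_basis(rc, n_series, cfg.l)
        coef, rc = solve_update(rc, basis, cfg)
        if not np.any(coef):
            log["fallbacks"] += 1
        log["tsd"].append(tsd(rc))
        log["channels"].append(n_series.channel_id)
    return rc, log


def initial_rc(values: np.ndarray, segment_ids: np.ndarray,
               boundary: BoundaryStates) -> RCSeries:
    """Linear ramp of the reference coordinate between the A and B
    thresholds, clipped to [0, 1] and clamped on the boundary frames."""
    v = np.asarray(values, dtype=np.float64)
    in_A, in_B = boundary.masks(v)
    if not in_A.any() or not in_B.any():
        raise ValueError("boundary states empty in the data")
    r = np.clip((v - boundary.a_max) / (boundary.b_min - boundary.a_max), 0.0, 1.0)
    r[in_A] = 0.0
    r[in_B] = 1.0
    return RCSeries(r, segment_ids, in_A, in_B)


# ---------------------------------------------------------------------------
# boundary-state definition from a free-energy profile


def define_boundary_states(values: np.ndarray, nbins: int | None = None,
                           depth: float = 1.0,
                           thresholds: tuple[float, float] | None = None,
                           min_barrier: float = 0.5,
                           reference: str = "n") -> BoundaryStates:
    """Define A and B around the two minima of the free-energy profile
    F = -ln histogram of ``values``.

    With explicit ``thresholds`` = (a_max, b_min) this is a pass-through.
    Otherwise the barrier is located as the position maximizing the
    prominence relative to the shallower flanking minimum; profiles whose
    best barrier is below ``min_barrier`` (k_B T) are rejected as unimodal.
    The thresholds sit where F first rises by ``depth`` (k_B T) above each
    basin minimum moving toward the barrier, capped so they always stay
    strictly below the barrier top; ``depth`` = 0 puts them at the minima
    themselves (boundary states = the free-energy minima).
    """
    if thresholds is not None:
        return BoundaryStates(thresholds[0], thresholds[1], reference)
    v = np.asarray(values, dtype=np.float64)
    if nbins is None:
        # integer-valued observables get unit bins, else 50
        is_int = np.allclose(v, np.round(v))
        if is_int:
            edges = np.arange(v.min() - 0.5, v.max() + 1.5)
        else:
            edges = np.linspace(v.min(), v.max(), 51)
    else:
        edges = np.linspace(v.min(), v.max(), nbins + 1)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # light boxcar smoothing + an occupancy floor keep sparsely sampled
    # tail bins from masquerading as minima or barriers
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    floor = max(3.0, 1e-4 * len(v))
    sampled = smooth >= floor
    F = np.full(len(counts), np.inf)
    F[sampled] = -np.log(smooth[sampled])

    idx = np.flatnonzero(sampled)
    best_depth, best_j = 0.0, None
    for j in idx:
        left = idx[idx < j]
        right = idx[idx > j]
        if len(left) == 0 or len(right) == 0:
            continue
        d = F[j] - max(F[left].min(), F[right].min())
        if d > best_depth:
            best_depth, best_j = d, j
    if best_j is None or best_depth < min_barrier:
        raise ValueError(
            f"free-energy profile not bimodal (best barrier "
            f"{best_depth:.2f} k_BT < {min_barrier} k_BT)")
    left = idx[idx < best_j]
    right = idx[idx > best_j]
    iA = left[np.argmin(F[left])]
    iB = right[np.argmin(F[right])]
    # walk from each minimum toward the barrier while F stays within the
    # (capped) depth of the basin minimum
    dA = min(depth, 0.9 * (F[best_j] - F[iA]))
    dB = min(depth, 0.9 * (F[best_j] - F[iB]))
    jA = iA
    for j in range(iA, best_j + 1):
        if sampled[j] and F[j] <= F[iA] + dA:
            jA = j
    jB = iB
    for j in range(best_j, iB + 1):
        if sampled[j] and F[j] <= F[iB] + dB:
            jB = j
            break
    return BoundaryStates(float(centers[jA]), float(centers[jB]), reference)


def soft_boundary_optimize(values: np.ndarray, segment_ids: np.ndarray,
                           boundary: BoundaryStates, pool: CVPool,
                           cfg: OptimizerConfig, rounds: int = 5,
                           depth: float = 1.0,
                           min_change: float = 0.01) -> tuple[RCSeries, dict]:
    """Soft-committor boundary refinement.

    Starting from fixed boundary states on the reference coordinate,
    optimize; then redefine A and B as terminal intervals of the current r
    around its free-energy minima and re-optimize, iterating to a fixed
    point (membership change below ``min_change`` of frames) or the round
    budget.
    """
    rc, log = optimize(initial_rc(values, segment_ids, boundary), pool, cfg)
    logs = [log]
    for rnd in range(1, rounds):
        try:
            b_r = define_boundary_states(rc.r, nbins=100, depth=depth,
                                         reference="r")
        except ValueError:
            break  # profile over r no longer bimodal at this depth; keep rc
        in_A, in_B = b_r.masks(rc.r)
        changed = np.mean((in_A != rc.in_A) | (in_B != rc.in_B))
        r = rc.r.copy()
        r[in_A] = 0.0
        r[in_B] = 1.0
        rc_new = RCSeries(r, segment_ids, in_A, in_B)
        cfg_round = replace(cfg, seed=cfg.seed + rnd)
        rc, log = optimize(rc_new, pool, cfg_round)
        logs.append(log)
        if changed < min_change:
            break
    return rc, {"rounds": logs}
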