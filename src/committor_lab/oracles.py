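"""Synthetic dynamics with exactly known committors and kinetics.

Two desk-scale oracle families make every estimator in the package
testable without external data:

* discrete Markov chains, whose committor q(A->B) solves the harmonic
  system q = Pq with q(A) = 0, q(B) = 1 by direct linear algebra, and
  whose MFPTs solve an analogous linear system;
* 1D overdamped (Euler-Maruyama) Brownian dynamics in a double-well
  potential V(x) with constant diffusion coefficient D0 and reflecting
  walls, whose committor between the wells has the closed form
  q(x) = int_a^x e^{V/kT} dy / int_a^b e^{V/kT} dy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .cvs import CVSeries
from .optimizer import RCSeries

__all__ = [
    "MarkovChainSpec",
    "DoubleWellSpec",
    "markov_committor",
    "markov_mfpt",
    "simulate_chain",
    "symmetric_walk_spec",
    "analytic_committor_1d",
    "simulate_double_well",
    "project_on_committor",
]


@dataclass(frozen=True)
class MarkovChainSpec:
    """A row-stochastic transition matrix with disjoint boundary subsets."""

    P: np.ndarray
    A: tuple
    B: tuple
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        object.__setattr__(self, "P", P)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of P must sum to 1")
        if set(self.A) & set(self.B) or not self.A or not self.B:
            raise ValueError("A and B must be nonempty and disjoint")


def markov_committor(spec: MarkovChainSpec) -> np.ndarray:
    """Committor per state by direct linear solve of q = Pq on the
    interior with q(A) = 0, q(B) = 1."""
    P, S = spec.P, spec.P.shape[0]
    q = np.zeros(S)
    q[list(spec.B)] = 1.0
    interior = np.setdiff1d(np.arange(S), np.concatenate([spec.A, spec.B]))
    if len(interior) == 0:
        return q
    M = np.eye(len(interior)) - P[np.ix_(interior, interior)]
    rhs = P[np.ix_(interior, list(spec.B))].sum(axis=1)
    try:
        q[interior] = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular committor system (absorbing states outside A u B?)") from e
    return q


def markov_mfpt(P: np.ndarray, targets) -> np.ndarray:
    """Expected hitting time of the target set from every state (steps)."""
    P = np.asarray(P, dtype=np.float64)
    S = P.shape[0]
    t = np.zeros(S)
    interior = np.setdiff1d(np.arange(S), np.asarray(targets))
    M = np.eye(len(interior)) - P[np.ix_(interior, interior)]
    t[interior] = np.linalg.solve(M, np.ones(len(interior)))
    return t


def simulate_chain(spec: MarkovChainSpec, T_frames: int,
                   init_state: int = 0) -> np.ndarray:
    """Seeded trajectory of the chain (state indices)."""
    rng = np.random.default_rng(spec.seed)
    cum = np.cumsum(spec.P, axis=1)
    u = rng.random(T_frames)
    out = np.empty(T_frames, dtype=np.int64)
    s = init_state
    for k in range(T_frames):
        out[k] = s
        s = int(np.searchsorted(cum[s], u[k], side="right"))
    return out


def symmetric_walk_spec(n_states: int = 5, seed: int = 0) -> MarkovChainSpec:
    """Unbiased nearest-neighbour walk on {0..n-1} with lazy reflecting
    ends; committor to the last state is i/(n-1)."""
    P = np.zeros((n_states, n_states))
    for i in range(n_states):
        if i == 0:
            P[i, 0] = P[i, 1] = 0.5
        elif i == n_states - 1:
            P[i, i] = P[i, i - 1] = 0.5
        else:
            P[i, i - 1] = P[i, i + 1] = 0.5
    return MarkovChainSpec(P, A=(0,), B=(n_states - 1,), seed=seed)


# ---------------------------------------------------------------------------
# 1D double well


@dataclass(frozen=True)
class DoubleWellSpec:
    """Quartic double well V(x) = barrier * (x^2 - 1)^2 (k_B T units) with
    wells at x = -1, +1 taken as the boundary states a, b; reflecting walls
    at +-wall keep the sampling in equilibrium."""

    barrier: float = 3.0
    D0: float = 1.0
    dt: float = 1e-3
    a: float = -1.0
    b: float = 1.0
    wall: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")
        if not self.a < self.b:
            raise ValueError("need a < b")

    def V(self, x):
        return self.barrier * (np.asarray(x) ** 2 - 1.0) ** 2

    def dV(self, x):
        return 4.0 * self.barrier * np.asarray(x) * (np.asarray(x) ** 2 - 1.0)


def analytic_committor_1d(spec: DoubleWellSpec, n_grid: int = 4001):
    """Closed-form committor q(x) = int_a^x e^V / int_a^b e^V on a grid
    (k_B T = 1, constant D); 0 left of a, 1 right of b."""
    from scipy.integrate import cumulative_trapezoid

    x = np.linspace(spec.a, spec.b, n_grid)
    w = np.exp(spec.V(x))
    c = cumulative_trapezoid(w, x, initial=0.0)
    return x, c / c[-1]


@njit(cache=True)
def _dw_run_nb(barrier, D0, dt, wall, x0, n_steps, seed):
    np.random.seed(seed)
    out = np.empty(n_steps)
    x = x0
    amp = np.sqrt(2.0 * D0 * dt)
    for k in range(n_steps):
        f = -4.0 * barrier * x * (x * x - 1.0)
        x = x + D0 * f * dt + amp * np.random.normal()
        # reflecting walls
        if x > wall:
            x = 2.0 * wall - x
        elif x < -wall:
            x = -2.0 * wall - x
        out[k] = x
    return out


def simulate_double_well(spec: DoubleWellSpec, T_frames: int,
                         x0: float | None = None) -> np.ndarray:
    """Euler-Maruyama trajectory of overdamped dynamics in the well;
    stationary density ~ exp(-V) within sampling error."""
    if x0 is None:
        x0 = spec.a
    seed = int(np.random.default_rng(spec.seed).integers(2**31 - 1))
    return _dw_run_nb(spec.barrier, spec.D0, spec.dt, spec.wall,
                      float(x0), int(T_frames), seed)


def project_on_committor(x_series: np.ndarray, spec: DoubleWellSpec,
                         transform=None, n_grid: int = 4001,
                         segment_ids: np.ndarray | None = None) -> RCSeries:
    """Project a double-well trajectory onto the analytic committor (or a
    monotone distortion of it, for negative controls), with the boundary
    states A = {x <= a}, B = {x >= b}."""
    xg, qg = analytic_committor_1d(spec, n_grid)
    r = np.interp(x_series, xg, qg)
    if transform is not None:
        r = transform(r)
    in_A = x_series <= spec.a
    in_B = x_series >= spec.b
    r = np.clip(r, 0.0, 1.0)
    r[in_A] = 0.0
    r[in_B] = 1.0
    if segment_ids is None:
        segment_ids = np.zeros(len(x_series), dtype=np.int32)
    return RCSeries(r, segment_ids, in_A, in_B)


def chain_cv(states: np.ndarray, segment_ids: np.ndarray | None = None,
             name: str = "state") -> CVSeries:
    """Wrap a state-index series as a CV series."""
    if segment_ids is None:
        segment_ids = np.zeros(len(states), dtype=np.int32)
    return CVSeries(np.asarray(states, dtype=np.float64), segment_ids, name)
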