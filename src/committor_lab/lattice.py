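"""Anisotropic 2D lattice aggregation model and Metropolis Monte Carlo driver.

The model: ``N`` molecules live on an ``L x L`` periodic square lattice, at
most one molecule per site.  Each molecule carries a binary orientation.
Nearest-neighbour (von Neumann) pairs form attractive bonds whose strength
depends on relative orientation: ``-psi_s`` for aligned pairs, ``-psi_w``
otherwise, with anisotropy ratio ``xi = psi_s / psi_w >= 1``.  Energies are
in units of ``psi_w`` and temperatures in the same units (k_B = 1).

Dynamics are local Metropolis Monte Carlo in the NVT ensemble: one
elementary attempt ("MCs") selects a molecule uniformly and proposes either
a translation to a uniformly chosen nearest-neighbour site (rejected
outright if occupied) or an orientation flip, accepted with probability
``min(1, exp(-dE/T))``.  At the coexistence temperature ``T*`` the system
hops between a diluted phase and a single large aggregate, which is the
two-state process analysed by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "Trajectory",
    "pair_energy",
    "total_energy",
    "mc_attempt",
    "random_dilute_state",
    "run",
    "run_ensemble",
    "largest_cluster_size",
    "cluster_size_series",
    "calibrate_coexistence_temperature",
    "load_calibrated_tstar",
]

_DATA_DIR = Path(__file__).parent / "data"

# directions for the 4-neighbour (von Neumann) topology, used everywhere
_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1], dtype=np.int64)


@dataclass(frozen=True)
class LatticeConfig:
    """Parameters of a lattice simulation.

    Attributes
    ----------
    L : lattice side length (sites).
    N : number of molecules.
    psi_w : weak (non-aligned) bond energy, > 0; sets the energy unit.
    xi : anisotropy ratio psi_s/psi_w, >= 1.
    T : temperature in energy units (k_B = 1).
    dt0 : frame spacing in elementary MC attempts.
    n_steps : total elementary MC attempts in the production run.
    seed : RNG seed.
    move_mix : probability that an attempt is a translation (else a flip).
    eq_fraction : discarded equilibration prefix, as a fraction of n_steps,
        run before recording starts.
    """

    L: int = 200
    N: int = 400
    psi_w: float = 1.0
    xi: float = 1.0
    T: float = 0.5
    dt0: int = 400
    n_steps: int = 100_000_000
    seed: int = 0
    move_mix: float = 0.5
    eq_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.N <= self.L * self.L):
            raise ValueError(f"need 0 < N <= L^2, got N={self.N}, L={self.L}")
        if self.xi < 1:
            raise ValueError("anisotropy ratio xi must be >= 1")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.dt0 < 1:
            raise ValueError("dt0 must be >= 1")
        if not (0.0 <= self.move_mix <= 1.0):
            raise ValueError("move_mix must be in [0, 1]")

    @property
    def psi_s(self) -> float:
        return self.xi * self.psi_w


@dataclass
class LatticeState:
    """Positions + orientations of the molecules and the occupancy map.

    ``occupancy[x, y]`` holds the molecule id at site (x, y) or -1.
    """

    positions: np.ndarray  # (N, 2) int
    orientations: np.ndarray  # (N,) uint8 in {0, 1}
    L: int
    occupancy: np.ndarray = field(default=None)  # (L, L) int32

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.orientations = np.asarray(self.orientations, dtype=np.uint8)
        if self.occupancy is None:
            self.occupancy = _build_occupancy(self.positions, self.L)

    @property
    def N(self) -> int:
        return len(self.positions)

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.positions.copy(), self.orientations.copy(), self.L, self.occupancy.copy()
        )

    def validate(self) -> None:
        occ = _build_occupancy(self.positions, self.L)
        if not np.array_equal(occ, self.occupancy):
            raise ValueError("occupancy map inconsistent with positions")


def _build_occupancy(positions: np.ndarray, L: int) -> np.ndarray:
    occ = np.full((L, L), -1, dtype=np.int32)
    for i, (x, y) in enumerate(positions):
        if occ[x, y] != -1:
            raise ValueError(f"site ({x},{y}) doubly occupied")
        occ[x, y] = i
    return occ


@dataclass
class Trajectory:
    """Time-ordered configurations at spacing ``dt0``, possibly several
    independent runs (segments).  Cross-segment frame pairs are never
    dynamical transitions."""

    positions: np.ndarray  # (T, N, 2) uint16
    orientations: np.ndarray  # (T, N) uint8
    segment_ids: np.ndarray  # (T,) int32
    config: LatticeConfig

    @property
    def n_frames(self) -> int:
        return len(self.segment_ids)

    def frame(self, k: int) -> LatticeState:
        return LatticeState(
            self.positions[k].astype(np.int64), self.orientations[k].copy(), self.config.L
        )

    def save(self, path) -> None:
        """Single-file HDF5 container: positions[T,N,2] uint16,
        orientations[T,N] uint8, segment_ids[T], config as attributes."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions, compression="gzip")
            f.create_dataset("orientations", data=self.orientations, compression="gzip")
            f.create_dataset("segment_ids", data=self.segment_ids)
            for k, v in vars(self.config).items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            cfg = LatticeConfig(**{k: f.attrs[k].item() if hasattr(f.attrs[k], "item")
                                   else f.attrs[k] for k in f.attrs})
            return cls(
                positions=f["positions"][:],
                orientations=f["orientations"][:],
                segment_ids=f["segment_ids"][:],
                config=cfg,
            )

    def export_text(self, path) -> None:
        """Plain-text exporter, one frame per block, for interoperability."""
        with open(path, "w") as f:
            f.write(f"# L={self.config.L} N={self.config.N} dt0={self.config.dt0}\n")
            for k in range(self.n_frames):
                f.write(f"# frame {k} segment {self.segment_ids[k]}\n")
                for (x, y), o in zip(self.positions[k], self.orientations[k]):
                    f.write(f"{x} {y} {o}\n")

    @staticmethod
    def concatenate(trajs: list["Trajectory"]) -> "Trajectory":
        """Stack independent runs as separate segments."""
        seg_ids = []
        for s, t in enumerate(trajs):
            seg_ids.append(np.full(t.n_frames, s, dtype=np.int32))
        return Trajectory(
            positions=np.concatenate([t.positions for t in trajs]),
            orientations=np.concatenate([t.orientations for t in trajs]),
            segment_ids=np.concatenate(seg_ids),
            config=trajs[0].config,
        )


# ---------------------------------------------------------------------------
# energies


def pair_energy(o1: int, o2: int, cfg: LatticeConfig) -> float:
    """Bond energy of an adjacent pair: -psi_s if aligned, -psi_w otherwise."""
    return -cfg.psi_s if o1 == o2 else -cfg.psi_w


def total_energy(state: LatticeState, cfg: LatticeConfig) -> float:
    """Sum of bond energies over occupied nearest-neighbour pairs, each pair
    counted once, with periodic wrap."""
    occ, ori, L = state.occupancy, state.orientations, state.L
    e = 0.0
    for i, (x, y) in enumerate(state.positions):
        # count each pair once via the +x and +y neighbours only
        for dx, dy in ((1, 0), (0, 1)):
            j = occ[(x + dx) % L, (y + dy) % L]
            if j >= 0:
                e += pair_energy(ori[i], ori[j], cfg)
    return e


def _site_energy(occ, ori, L, x, y, o, psi_w, psi_s, skip_site=None):
    """Interaction energy of a (virtual) molecule with orientation o at
    (x, y); ``skip_site`` masks the vacated origin site during a move."""
    e = 0.0
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nx, ny = (x + dx) % L, (y + dy) % L
        if skip_site is not None and (nx, ny) == skip_site:
            continue
        j = occ[nx, ny]
        if j >= 0:
            e += -psi_s if ori[j] == o else -psi_w
    return e


def mc_attempt(state: LatticeState, cfg: LatticeConfig, rng: np.random.Generator) -> bool:
    """One elementary Metropolis attempt, mutating ``state`` in place.

    Returns True if the proposal was accepted.  Reference (pure Python)
    implementation of the same dynamics as the compiled bulk kernel; used
    for unit-level checks and tiny systems.
    """
    occ, pos, ori, L = state.occupancy, state.positions, state.orientations, state.L
    psi_w, psi_s = cfg.psi_w, cfg.psi_s
    m = int(rng.integers(state.N))
    x, y = pos[m]
    o = ori[m]
    if rng.random() < cfg.move_mix:
        d = int(rng.integers(4))
        nx, ny = (x + _DX[d]) % L, (y + _DY[d]) % L
        if occ[nx, ny] >= 0:
            return False  # excluded volume: immediate rejection
        e_old = _site_energy(occ, ori, L, x, y, o, psi_w, psi_s)
        e_new = _site_energy(occ, ori, L, nx, ny, o, psi_w, psi_s, skip_site=(x, y))
        dE = e_new - e_old
        if rng.random() < np.exp(-dE / cfg.T):
            occ[x, y] = -1
            occ[nx, ny] = m
            pos[m, 0], pos[m, 1] = nx, ny
            return True
        return False
    # orientation flip
    o_new = 1 - o
    dE = (
        _site_energy(occ, ori, L, x, y, o_new, psi_w, psi_s)
        - _site_energy(occ, ori, L, x, y, o, psi_w, psi_s)
    )
    if rng.random() < np.exp(-dE / cfg.T):
        ori[m] = o_new
        return True
    return False


# ---------------------------------------------------------------------------
# compiled bulk kernel


@njit(cache=True)
def _site_energy_nb(occ, ori, L, x, y, o, psi_w, psi_s, skip_x, skip_y):
    e = 0.0
    for d in range(4):
        nx = (x + _DX[d]) % L
        ny = (y + _DY[d]) % L
        if nx == skip_x and ny == skip_y:
            continue
        j = occ[nx, ny]
        if j >= 0:
            if ori[j] == o:
                e -= psi_s
            else:
                e -= psi_w
    return e


@njit(cache=True)
def _mc_run_nb(occ, pos, ori, psi_w, psi_s, T, move_mix, n_steps, dt0, seed,
               pos_out, ori_out):
    np.random.seed(seed)
    L = occ.shape[0]
    N = pos.shape[0]
    frame = 0
    n_frames = pos_out.shape[0]
    for step in range(n_steps):
        m = np.random.randint(N)
        x = pos[m, 0]
        y = pos[m, 1]
        o = ori[m]
        if np.random.random() < move_mix:
            d = np.random.randint(4)
            nx = (x + _DX[d]) % L
            ny = (y + _DY[d]) % L
            if occ[nx, ny] < 0:
                e_old = _site_energy_nb(occ, ori, L, x, y, o, psi_w, psi_s, -1, -1)
                e_new = _site_energy_nb(occ, ori, L, nx, ny, o, psi_w, psi_s, x, y)
                dE = e_new - e_old
                if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                    occ[x, y] = -1
                    occ[nx, ny] = m
                    pos[m, 0] = nx
                    pos[m, 1] = ny
        else:
            o_new = 1 - o
            dE = (_site_energy_nb(occ, ori, L, x, y, o_new, psi_w, psi_s, -1, -1)
                  - _site_energy_nb(occ, ori, L, x, y, o, psi_w, psi_s, -1, -1))
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                ori[m] = o_new
        if (step + 1) % dt0 == 0 and frame < n_frames:
            for i in range(N):
                pos_out[frame, i, 0] = pos[i, 0]
                pos_out[frame, i, 1] = pos[i, 1]
                ori_out[frame, i] = ori[i]
            frame += 1
    return frame


def random_dilute_state(cfg: LatticeConfig, rng: np.random.Generator) -> LatticeState:
    """Random non-overlapping placement with random orientations."""
    idx = rng.choice(cfg.L * cfg.L, size=cfg.N, replace=False)
    pos = np.column_stack(np.unravel_index(idx, (cfg.L, cfg.L))).astype(np.int64)
    ori = rng.integers(0, 2, size=cfg.N).astype(np.uint8)
    return LatticeState(pos, ori, cfg.L)


def run(cfg: LatticeConfig, init_state: LatticeState | None = None,
        segment_id: int = 0) -> Trajectory:
    """Execute ``cfg.n_steps`` elementary attempts, recording a frame every
    ``dt0`` attempts; deterministic for a given seed.

    An equilibration prefix of ``eq_fraction * n_steps`` attempts is run
    (and discarded) before recording starts, unless an explicit
    ``init_state`` is supplied.
    """
    rng = np.random.default_rng(cfg.seed)
    if init_state is None:
        state = random_dilute_state(cfg, rng)
        eq_steps = int(cfg.eq_fraction * cfg.n_steps)
    else:
        state = init_state.copy()
        eq_steps = 0

    n_frames = cfg.n_steps // cfg.dt0
    pos_out = np.empty((n_frames, cfg.N, 2), dtype=np.uint16)
    ori_out = np.empty((n_frames, cfg.N), dtype=np.uint8)
    # two independent 31-bit streams for the kernel: equilibration + production
    kseed_eq = int(rng.integers(2**31 - 1))
    kseed = int(rng.integers(2**31 - 1))
    occ = state.occupancy
    if eq_steps > 0:
        dummy_p = np.empty((0, cfg.N, 2), dtype=np.uint16)
        dummy_o = np.empty((0, cfg.N), dtype=np.uint8)
        _mc_run_nb(occ, state.positions, state.orientations, cfg.psi_w, cfg.psi_s,
                   cfg.T, cfg.move_mix, eq_steps, eq_steps + 1, kseed_eq,
                   dummy_p, dummy_o)
    _mc_run_nb(occ, state.positions, state.orientations, cfg.psi_w, cfg.psi_s,
               cfg.T, cfg.move_mix, cfg.n_steps, cfg.dt0, kseed, pos_out, ori_out)
    seg = np.full(n_frames, segment_id, dtype=np.int32)
    return Trajectory(pos_out, ori_out, seg, cfg)


def run_ensemble(cfg: LatticeConfig, n_runs: int) -> Trajectory:
    """Several independent runs concatenated as separate segments; run ``s``
    uses seed ``cfg.seed + s`` (streams never overlap in practice)."""
    trajs = []
    for s in range(n_runs):
        trajs.append(run(replace(cfg, seed=cfg.seed + s), segment_id=s))
    return Trajectory.concatenate(trajs)


# ---------------------------------------------------------------------------
# cluster-size observable


@njit(cache=True)
def _largest_cluster_nb(occ, pos, L):
    N = pos.shape[0]
    visited = np.zeros(N, dtype=np.uint8)
    stack = np.empty(N, dtype=np.int64)
    best = 0
    for start in range(N):
        if visited[start]:
            continue
        visited[start] = 1
        stack[0] = start
        top = 1
        size = 0
        while top > 0:
            top -= 1
            i = stack[top]
            size += 1
            x = pos[i, 0]
            y = pos[i, 1]
            for d in range(4):
                nx = (x + _DX[d]) % L
                ny = (y + _DY[d]) % L
                j = occ[nx, ny]
                if j >= 0 and not visited[j]:
                    visited[j] = 1
                    stack[top] = j
                    top += 1
        if size > best:
            best = size
    return best


def largest_cluster_size(state: LatticeState) -> int:
    """Number of molecules in the largest 4-connected aggregate (periodic
    wrap); an isolated molecule counts as a cluster of size 1."""
    return int(_largest_cluster_nb(state.occupancy, state.positions.astype(np.int64),
                                   state.L))


@njit(cache=True)
def _cluster_series_nb(positions, L):
    T = positions.shape[0]
    N = positions.shape[1]
    out = np.empty(T, dtype=np.int64)
    occ = np.full((L, L), -1, dtype=np.int32)
    for k in range(T):
        pos = positions[k].astype(np.int64)
        for i in range(N):
            occ[pos[i, 0], pos[i, 1]] = i
        out[k] = _largest_cluster_nb(occ, pos, L)
        for i in range(N):
            occ[pos[i, 0], pos[i, 1]] = -1
    return out


def cluster_size_series(traj: Trajectory) -> np.ndarray:
    """Largest-cluster size n(k dt0) for every frame."""
    return _cluster_series_nb(traj.positions, traj.config.L)


# ---------------------------------------------------------------------------
# coexistence-temperature calibration


def _basin_weights(n_series: np.ndarray, n_split: float) -> tuple[float, float]:
    agg = float(np.mean(n_series >= n_split))
    return 1.0 - agg, agg


def calibrate_coexistence_temperature(
    cfg_base: LatticeConfig,
    T_lo: float,
    T_hi: float,
    run_length: int = 2_000_000,
    n_split: float | None = None,
    tol: float = 0.05,
    max_iter: int = 12,
    min_transitions: int = 4,
) -> dict:
    """Locate T* where the largest-cluster-size histogram is bimodal with
    equal weight in the diluted (n < n_split) and aggregated (n >= n_split)
    basins, by bisection on the basin-weight imbalance.

    Returns a dict with ``tstar``, the scan diagnostics, and a ``bimodal``
    flag; raises ``RuntimeError`` when no temperature in [T_lo, T_hi]
    yields two-basin behaviour (e.g. grid entirely above or below the
    transition).
    """
    if n_split is None:
        n_split = cfg_base.N / 2.0
    history = []

    def weight_imbalance(T: float, seed_offset: int) -> tuple[float, int]:
        cfg = replace(cfg_base, T=T, n_steps=run_length,
                      seed=cfg_base.seed + seed_offset)
        traj = run(cfg)
        n = cluster_size_series(traj)
        w_dil, w_agg = _basin_weights(n, n_split)
        agg_state = n >= n_split
        n_trans = int(np.sum(agg_state[1:] != agg_state[:-1]))
        history.append({"T": T, "w_dilute": w_dil, "w_agg": w_agg,
                        "transitions": n_trans})
        return w_agg - w_dil, n_trans

    f_lo, _ = weight_imbalance(T_lo, 1)  # low T -> aggregated -> f > 0
    f_hi, _ = weight_imbalance(T_hi, 2)
    if f_lo < 0 or f_hi > 0:
        raise RuntimeError(
            f"no coexistence bracket in [{T_lo}, {T_hi}]: "
            f"imbalance {f_lo:+.2f} at T={T_lo}, {f_hi:+.2f} at T={T_hi}")
    a, b = T_lo, T_hi
    best_T, best_f, best_trans = None, np.inf, 0
    for it in range(max_iter):
        mid = 0.5 * (a + b)
        f_mid, n_trans = weight_imbalance(mid, 3 + it)
        if abs(f_mid) < abs(best_f):
            best_T, best_f, best_trans = mid, f_mid, n_trans
        if abs(f_mid) <= tol and n_trans >= min_transitions:
            break
        if f_mid > 0:
            a = mid
        else:
            b = mid
    bimodal = best_trans >= min_transitions
    if not bimodal:
        raise RuntimeError(
            "calibration failed: fewer than "
            f"{min_transitions} basin transitions at best T={best_T}")
    return {"tstar": best_T, "imbalance": best_f, "transitions": best_trans,
            "n_split": n_split, "run_length": run_length, "history": history,
            "L": cfg_base.L, "N": cfg_base.N, "xi": cfg_base.xi}


def load_calibrated_tstar(L: int, N: int, xi: float) -> float:
    """Look up a coexistence temperature calibrated in-repo (data/tstar.json)."""
    path = _DATA_DIR / "tstar.json"
    table = json.loads(path.read_text())
    key = f"L{L}_N{N}_xi{xi:g}"
    if key not in table:
        raise KeyError(f"no calibrated T* for {key}; run calibrate_coexistence_temperature")
    return float(table[key]["tstar"])
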