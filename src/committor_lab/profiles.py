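"""Histogram and cut profiles, the Z_C,1 committor validation test,
diffusion-coefficient estimation, free-energy profiles, unit-diffusion
rescaling and kinetics (MFPT, N_AB, flux, MTPT).

Conventions
-----------
Time is measured in frames (one frame = dt0 elementary MC attempts or one
integrator step of a synthetic model).  Lags are dyadic multiples of the
frame spacing, lag = 2^i frames.  For lag > 1 the series is subsampled
with stride ``lag`` at each of the ``lag`` possible phases and profiles
are averaged over phases (the phase-summed single-pass variant is
selectable).  With this convention the total histogram count at lag 2*dt
is exactly half that at dt, mirroring the Z_H ~ 1/dt scaling of a
continuously sampled density.

Z_C,1(r*, dt) sums |r(k+dt) - r(k)| over the transitions whose interval
straddles r*.  It is accumulated per bin with fractional overlap weights,
which makes the identity  integral of Z_C,1(r, dt0) dr = TSD(dt0)  exact
to machine precision.  For a time series of the true committor Z_C,1 is
flat and equal to the number N_AB of A<->B transitions, at every lag; the
free energy is F = -ln Z_H and the diffusion coefficient is
D = Z_C,1 / (dt * Z_H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .optimizer import RCSeries, tsd, _pair_index

__all__ = [
    "ProfileSet",
    "DiffusiveModel",
    "histogram_zh",
    "zc1",
    "compute_profiles",
    "validation_scan",
    "diffusion_coefficient",
    "rescale_unit_diffusion",
    "RescaledRC",
    "mfpt_model",
    "mfpt_direct",
    "mtpt_direct",
    "nab_direct",
    "nab_integral",
    "flux_profile",
    "passage_events",
]


def _uniform_grid(edges: np.ndarray) -> tuple[float, float, int]:
    edges = np.asarray(edges, dtype=np.float64)
    h = np.diff(edges)
    if not np.allclose(h, h[0]):
        raise ValueError("profile grid must be uniform")
    return float(edges[0]), float(h[0]), len(edges) - 1


def _segment_slices(segment_ids: np.ndarray):
    seg = np.asarray(segment_ids)
    starts = np.flatnonzero(np.r_[True, seg[1:] != seg[:-1]])
    ends = np.r_[starts[1:], len(seg)]
    return list(zip(starts, ends))


@njit(cache=True)
def _zc1_accumulate(sub, lo, h, nbins, out):
    for i in range(len(sub) - 1):
        a = sub[i]
        b = sub[i + 1]
        if a < b:
            lo_, hi_ = a, b
        else:
            lo_, hi_ = b, a
        w = hi_ - lo_
        if w <= 0.0:
            continue
        il = int((lo_ - lo) / h)
        ih = int((hi_ - lo) / h)
        if il < 0:
            il = 0
        if ih > nbins - 1:
            ih = nbins - 1
        for k in range(il, ih + 1):
            e0 = lo + k * h
            e1 = e0 + h
            ov = min(hi_, e1) - max(lo_, e0)
            if ov > 0.0:
                out[k] += w * ov / h


def zc1(r: np.ndarray, segment_ids: np.ndarray, lag: int,
        edges: np.ndarray, phase_average: bool = True) -> np.ndarray:
    """Cut profile Z_C,1 at the given lag, one value per bin.

    A bin fully inside a transition interval receives the full |delta r|
    of that transition; partially covered bins receive the overlap
    fraction.  ``phase_average=False`` keeps only the phase-0 strided pass.
    """
    lo, h, nbins = _uniform_grid(edges)
    out = np.zeros(nbins)
    r = np.asarray(r, dtype=np.float64)
    for start, end in _segment_slices(segment_ids):
        n_phases = lag if phase_average else 1
        for p in range(n_phases):
            sub = np.ascontiguousarray(r[start + p:end:lag])
            if len(sub) >= 2:
                _zc1_accumulate(sub, lo, h, nbins, out)
    if phase_average and lag > 1:
        out /= lag
    return out


def histogram_zh(r: np.ndarray, segment_ids: np.ndarray, lag: int,
                 edges: np.ndarray, phase_average: bool = True) -> np.ndarray:
    """Non-normalized histogram Z_H at the given lag.

    Phase-averaged: every frame is counted in exactly one phase, so the
    average over the ``lag`` phases is the plain histogram divided by the
    lag — the total count halves exactly when the lag doubles.
    """
    r = np.asarray(r, dtype=np.float64)
    if phase_average:
        counts, _ = np.histogram(r, bins=edges)
        return counts / lag if lag > 1 else counts.astype(np.float64)
    parts = np.zeros(len(edges) - 1)
    for start, end in _segment_slices(segment_ids):
        c, _ = np.histogram(r[start:end:lag], bins=edges)
        parts += c
    return parts


@dataclass
class ProfileSet:
    """Binned functions of the RC at one lag: histogram Z_H, cut profile
    Z_C,1, free energy F = -ln Z_H (k_B T units, arbitrary constant) and
    diffusion coefficient D = Z_C,1/(lag * Z_H); unsampled bins are NaN."""

    edges: np.ndarray
    Z_H: np.ndarray
    Z_C1: np.ndarray
    F: np.ndarray
    D: np.ndarray
    lag: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def diffusion_coefficient(Z_C1: np.ndarray, Z_H: np.ndarray, lag: int) -> np.ndarray:
    """Elementwise D = Z_C,1/(lag * Z_H); bins with Z_H = 0 are NaN-masked.

    For the ratio to be the physical diffusion coefficient, ``Z_H`` must be
    the density of transition endpoints per unit RC — i.e. twice the
    per-bin frame count divided by the bin width (each transition deposits
    its start and its end).  :func:`compute_profiles` applies that
    normalization; with it, a free diffusion with coefficient D0 satisfies
    Z_C,1 = rho * <dr^2> = (Z_H/2) * 2 D0 lag, recovering D = D0, and for
    a committor series D * p_eq equals the constant flux N_AB/(2 T).
    """
    if not np.any(Z_H > 0):
        raise ValueError("profile entirely unsampled")
    D = np.full(len(Z_H), np.nan)
    ok = Z_H > 0
    D[ok] = Z_C1[ok] / (lag * Z_H[ok])
    return D


def compute_profiles(rc: RCSeries, lag: int = 1, nbins: int = 100,
                     edges: np.ndarray | None = None,
                     phase_average: bool = True) -> ProfileSet:
    if edges is None:
        edges = np.linspace(0.0, 1.0, nbins + 1)
    zh = histogram_zh(rc.r, rc.segment_ids, lag, edges, phase_average)
    zc = zc1(rc.r, rc.segment_ids, lag, edges, phase_average)
    F = np.where(zh > 0, -np.log(np.where(zh > 0, zh, 1.0)), np.nan)
    _, h, _ = _uniform_grid(edges)
    D = diffusion_coefficient(zc, 2.0 * zh / h, lag)
    return ProfileSet(np.asarray(edges, float), zh, zc, F, D, lag)


# ---------------------------------------------------------------------------
# boundary-state passage bookkeeping


def passage_events(segment_ids: np.ndarray, in_A: np.ndarray,
                   in_B: np.ndarray) -> dict:
    """Scan the series once, collecting first-passage and transition-path
    events between A and B within each segment.

    Returns per-event durations (in frames) of B->A and A->B first
    passages (first entry into the origin state to the next first entry
    into the destination), transition-path durations (last exit from the
    origin to first entry into the destination) and the total number of
    completed A<->B crossings.
    """
    fp_BA, fp_AB, tp = [], [], []
    n_cross = 0
    for start, end in _segment_slices(segment_ids):
        last = 0  # 0 unknown, 1 = A, 2 = B
        t_entry = -1  # first entry into the current boundary state
        t_exit = -1  # most recent frame spent in the current boundary state
        for k in range(start, end):
            if in_A[k]:
                if last == 2:
                    fp_BA.append(k - t_entry)
                    tp.append(k - t_exit)
                    n_cross += 1
                if last != 1:
                    t_entry = k
                    last = 1
                t_exit = k
            elif in_B[k]:
                if last == 1:
                    fp_AB.append(k - t_entry)
                    tp.append(k - t_exit)
                    n_cross += 1
                if last != 2:
                    t_entry = k
                    last = 2
                t_exit = k
    return {
        "fp_BA": np.array(fp_BA, dtype=np.int64),
        "fp_AB": np.array(fp_AB, dtype=np.int64),
        "tp": np.array(tp, dtype=np.int64),
        "n_AB": n_cross,
    }


def nab_direct(rc: RCSeries) -> int:
    """Number of completed A<->B crossings (both directions) in the series."""
    return passage_events(rc.segment_ids, rc.in_A, rc.in_B)["n_AB"]


def nab_integral(Z_C1: np.ndarray, edges: np.ndarray) -> float:
    """N_AB estimate as the integral of the lag-dt0 cut profile; by the
    bin-overlap accumulation this equals TSD(dt0) identically."""
    _, h, _ = _uniform_grid(edges)
    return float(np.sum(Z_C1) * h)


def mfpt_direct(rc: RCSeries, direction: str = "B->A") -> tuple[float, np.ndarray]:
    """Mean first passage time from the time series, in frames.

    The B->A time averages, over events, the span from each first entry
    into B to the next first entry into A (within segments); zero events
    raise.  Also returns the per-event durations for bootstrapping.
    """
    ev = passage_events(rc.segment_ids, rc.in_A, rc.in_B)
    key = {"B->A": "fp_BA", "A->B": "fp_AB"}[direction]
    times = ev[key]
    if len(times) == 0:
        raise ValueError(f"no completed {direction} events in the series")
    return float(times.mean()), times


def mtpt_direct(rc: RCSeries) -> tuple[float, np.ndarray]:
    """Mean transition-path time: mean duration of reactive segments (last
    exit from one boundary state to first entry into the other)."""
    ev = passage_events(rc.segment_ids, rc.in_A, rc.in_B)
    if len(ev["tp"]) == 0:
        raise ValueError("no reactive events in the series")
    return float(ev["tp"].mean()), ev["tp"]


# ---------------------------------------------------------------------------
# validation scan


def validation_scan(rc: RCSeries, i_max: int = 10, nbins: int = 100,
                    interior: tuple[float, float] = (0.05, 0.95),
                    n_sigma: float = 3.0,
                    phase_average: bool = True) -> dict:
    """The Z_C,1 committor validation test across dyadic lags.

    For each lag 2^i (i = 0..i_max) the profile -ln Z_C,1(r, lag) is
    summarized by its mean and spread over interior bins (boundary-state
    intervals excluded).  For the true committor every profile is flat at
    -ln N_AB, so both the offset of the mean from -ln N_AB (lag
    dependence) and the spread across bins (r dependence) must stay within
    ``n_sigma`` times the statistical uncertainty 1/sqrt(2 N_AB) for the
    verdict to pass; the per-lag deviation reported is the larger of the
    two.
    """
    edges = np.linspace(0.0, 1.0, nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_interior = (centers > interior[0]) & (centers < interior[1])
    n_ab = nab_direct(rc)
    if n_ab == 0:
        raise ValueError("no A<->B transitions; validation undefined")
    expected = -np.log(n_ab)
    tol = 1.0 / np.sqrt(2.0 * n_ab)
    lags, means, spreads, profiles = [], [], [], []
    T = len(rc.r)
    for i in range(i_max + 1):
        lag = 2 ** i
        if lag >= T:
            break
        z = zc1(rc.r, rc.segment_ids, lag, edges, phase_average)
        ok = in_interior & (z > 0)
        if not np.any(ok):
            break
        neg_ln = -np.log(z[ok])
        lags.append(lag)
        means.append(float(neg_ln.mean()))
        spreads.append(float(neg_ln.std()))
        profiles.append(z)
    deviations = np.maximum(np.abs(np.array(means) - expected),
                            np.array(spreads))
    return {
        "lags": lags,
        "means": means,
        "spreads": spreads,
        "profiles": profiles,
        "edges": edges,
        "n_AB": n_ab,
        "expected": float(expected),
        "tol": float(tol),
        "max_deviation": float(deviations.max()),
        "flatness": float(deviations.max()),
        "passed": bool(np.all(deviations <= n_sigma * tol)),
    }


# ---------------------------------------------------------------------------
# diffusive model, MFPT and rescaling


def _bridge_nan(y: np.ndarray, log_space: bool = True) -> np.ndarray:
    """Interpolate NaN gaps inside the sampled support (log-space for
    positive quantities); edge NaNs take the nearest sampled value."""
    y = np.asarray(y, dtype=np.float64).copy()
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("nothing sampled")
    idx = np.arange(len(y))
    if log_space:
        vals = np.log(np.maximum(y[ok], 1e-300))
        y[~ok] = np.exp(np.interp(idx[~ok], idx[ok], vals))
    else:
        y[~ok] = np.interp(idx[~ok], idx[ok], y[ok])
    return y


@dataclass
class DiffusiveModel:
    """A 1D diffusive model (p_eq, D) on bin centers; p_eq integrates to 1
    and D > 0 on the sampled support."""

    q: np.ndarray
    p_eq: np.ndarray
    D: np.ndarray
    lag: int = 1

    @classmethod
    def from_rc(cls, rc: RCSeries, nbins: int = 100, lag: int = 1,
                edges: np.ndarray | None = None) -> "DiffusiveModel":
        prof = compute_profiles(rc, lag=lag, nbins=nbins, edges=edges)
        _, h, _ = _uniform_grid(prof.edges)
        p = prof.Z_H / (prof.Z_H.sum() * h)
        # unsampled bins inside the support would put zeros in p_eq * D;
        # bridge both factors by interpolation in log space
        p = np.where(p > 0, p, np.nan)
        p = _bridge_nan(p)
        p /= p.sum() * h
        D = _bridge_nan(prof.D)
        return cls(prof.centers, p, D, lag)


def mfpt_model(model: DiffusiveModel, frm: float = 1.0, to: float = 0.0) -> float:
    """MFPT of the 1D diffusive model between two RC values, by the double
    integral  tau = int dq' / (p_eq D) int p_eq dq''  (absorbing at ``to``,
    reflecting at ``frm``).

    The model lives on uniform bin centers with p_eq piecewise constant, so
    both integrals use the bin-consistent midpoint rule (the point q' sees
    half of its own bin's occupancy); trapezoids would halve the
    boundary-state delta mass that histogram densities concentrate in the
    terminal bins.
    """
    q, p, D = model.q, model.p_eq, model.D
    lo, hi = (to, frm) if frm > to else (frm, to)
    sel = (q >= lo) & (q <= hi)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 grid points between the endpoints")
    qs, ps, Ds = q[sel], p[sel], D[sel]
    if np.any(~np.isfinite(Ds)) or np.any(Ds <= 0):
        raise ValueError("diffusion profile not positive on the interval")
    dq = np.diff(qs)
    if not np.allclose(dq, dq[0]):
        raise ValueError("model grid must be uniform")
    h = float(dq[0])
    mass = ps * h
    if frm > to:  # occupancy between q' and frm
        inner = np.cumsum(mass[::-1])[::-1] - 0.5 * mass
    else:  # occupancy between frm and q'
        inner = np.cumsum(mass) - 0.5 * mass
    return float(np.sum(h * inner / (ps * Ds)))


def flux_profile(model: DiffusiveModel,
                 interior: tuple[float, float] | None = None) -> dict:
    """Equilibrium flux J(q) = D(q) p_eq(q); flat over the interior for a
    validated committor.  Returns the profile and its interior coefficient
    of variation."""
    J = model.D * model.p_eq
    if interior is None:
        lo, hi = model.q.min(), model.q.max()
        span = hi - lo
        interior = (lo + 0.05 * span, hi - 0.05 * span)
    ok = (model.q > interior[0]) & (model.q < interior[1]) & np.isfinite(J)
    cv = float(J[ok].std() / J[ok].mean())
    return {"q": model.q, "J": J, "cv_interior": cv}


@dataclass
class RescaledRC:
    """An RC series after the unit-diffusion change of variable q~(r)."""

    values: np.ndarray
    segment_ids: np.ndarray
    edges_r: np.ndarray
    edges_qt: np.ndarray
    qt_max: float
    delta_q: float | None  # separation between free-energy minima, if bimodal


def rescale_unit_diffusion(rc: RCSeries, nbins: int = 100) -> RescaledRC:
    """Monotone map q~(r) = int_0^r dr'/sqrt(D(r', dt0)) with
    piecewise-constant per-bin D, applied to the series.

    On the rescaled coordinate the re-estimated diffusion coefficient is
    ~1 on interior bins, so the free-energy profile alone specifies the
    diffusive model; the separation Delta q~ between the two free-energy
    minima is reported when the rescaled profile is bimodal.
    """
    prof = compute_profiles(rc, lag=1, nbins=nbins)
    D = _bridge_nan(prof.D)
    h = prof.edges[1] - prof.edges[0]
    qt_edges = np.concatenate([[0.0], np.cumsum(h / np.sqrt(D))])
    values = np.interp(rc.r, prof.edges, qt_edges)
    qt_max = float(qt_edges[-1])
    delta_q = None
    try:
        from .optimizer import define_boundary_states

        b = define_boundary_states(values, nbins=nbins, depth=0.5, reference="qt")
        # positions of the two minima, not the thresholds
        counts, e = np.histogram(values, bins=np.linspace(0, qt_max, nbins + 1))
        c = 0.5 * (e[:-1] + e[1:])
        mid = 0.5 * (b.a_max + b.b_min)
        left, right = (c <= mid) & (counts > 0), (c > mid) & (counts > 0)
        delta_q = float(c[right][np.argmax(counts[right])]
                        - c[left][np.argmax(counts[left])])
    except ValueError:
        pass
    return RescaledRC(values, rc.segment_ids, prof.edges, qt_edges, qt_max, delta_q)
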