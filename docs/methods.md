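# Methods

This note records the models, estimators, conventions and design choices
behind `committor_lab`, at the level of detail a user needs to interpret
results or extend the package.

## Lattice aggregation model

N molecules occupy distinct sites of an L×L square lattice with periodic
boundaries.  Each molecule carries a binary orientation.  Occupied
4-neighbour (von Neumann) pairs contribute −ψ_s if aligned and −ψ_w
otherwise; ψ_w = 1 defines the energy unit, k_B = 1, and ξ = ψ_s/ψ_w ≥ 1
is the anisotropy.  One elementary Monte Carlo attempt selects a molecule
uniformly and, with probability `move_mix` (default 0.5), proposes a
translation to a uniformly chosen nearest-neighbour site (rejected
outright if occupied), otherwise an orientation flip; acceptance is
Metropolis, min(1, e^(−ΔE/T)).  The time unit is one attempt; frames are
recorded every Δt₀ attempts (default 400).  Local single-site moves are
the natural choice for diffusive aggregation dynamics; the same
4-neighbour adjacency with periodic wrap is used for the energy and for
cluster analysis, so "bonded" and "clustered" always agree.  Runs start
from a random dilute placement followed by a discarded equilibration
prefix (default 10% of the production length); independent runs are kept
as separate trajectory segments and never spliced dynamically.

### Coexistence temperature

T* is located by bisection on the basin-weight imbalance of the
largest-cluster-size histogram: a run at temperature T is classified
frame-by-frame as diluted (n < n_split) or aggregated (n ≥ n_split,
default n_split = N/2) and T* is the temperature of equal weight, with a
minimum-transition-count requirement so that a metastable run cannot fake
coexistence.  The value shipped for the desk-scale system (L = 40,
N = 40, ξ = 1) is T* = 0.3775, calibrated with 3×10^7-attempt runs
(metadata, including the full bisection history, in
`data/tstar.json`).

At this small size the evaporation/condensation transition is close to
its finite-size critical point: the free-energy profile F(n) shows two
shallow basins (gas with transient clusters of ~5–12 molecules vs a
single droplet of ~25–35) separated by a barrier of only 0–0.4 k_BT
depending on the run.  Boundary-state detection therefore falls back to
the terminal deciles of the sampled n range when no ≥ 0.5 k_BT barrier is
resolvable (see below).  The full-scale system (L = 200, N = 400) has a
well-developed barrier and does not need the fallback.

## Invariant collective variables

For each frame the N×N matrix of pairwise minimum-image Euclidean
distances is computed (per-axis displacements wrapped into [−L/2, L/2];
Euclidean rather than lattice-graph distance so the construction carries
over to off-lattice systems) and sorted ascending first within each
column, then within each row.  Relabelling molecules permutes rows and
columns simultaneously, which the two sorting passes erase, so each entry
d̄_ij is a translation-, rotation- and permutation-invariant CV.  The
zero diagonal survives sorting as an all-zero first row; these and any
other constant channels are removed by a zero-variance filter rather than
by ad-hoc index exclusion.  For desk-scale systems the full sorted stack
is cached in memory (float32); above a configurable size the pool
evaluates channels lazily per optimizer draw, preserving the
random-channel semantics at bounded memory.  Named scalar observables
(e.g. the largest-cluster size n) can be registered in the same pool.

## Nonparametric committor optimization

The RC is its time series r(kΔt₀) ∈ [0, 1] with r = 0 on A-frames and 1 on
B-frames.  Each iteration draws a CV series x, standardizes it (zero
mean, unit spread — a reparametrization of the basis span that prevents
catastrophic conditioning at order 4 with raw distances), builds the
(l+1)(l+2)/2 monomials r^i x^j (i+j ≤ l, default l = 4), zeroes their
rows on boundary frames, and solves for the coefficients minimizing the
lag-1 TSD of the updated series by SVD-based least squares (relative
cutoff 1e−10; a singular or non-finite solve falls back to the zero
update and is logged, never aborts).  The TSD is minimized at the finest
available lag because the validation then probes all coarser lags.  The
update is clipped to [0, 1] (clipping is 1-Lipschitz and monotone, so it
cannot increase the TSD) and boundary values are re-clamped exactly; a
numerical safeguard reverts any step that would raise the TSD.  The TSD
sequence is therefore non-increasing by construction.

The expected TSD of a series that is a function of the sampled state is
the Dirichlet form of the (symmetrized) empirical transition kernel, whose
clamped minimizer is the committor of that kernel; this is the sense in
which TSD minimization over a rich CV pool converges to the committor,
and it is what the Markov-chain tests verify exactly.

The initial coordinate is a linear ramp of a reference observable between
the A and B thresholds.  The baseline coordinate q(n) is produced by the
same machinery with x = n at every iteration (20 iterations suffice);
since every update is then a function of n, the result is a
reparametrization of n and inherits its (sub)optimality.

### Boundary states

`define_boundary_states` histograms a reference coordinate, lightly
smooths the counts (width-3 boxcar, with an occupancy floor so sparse
tail bins cannot masquerade as minima), finds the barrier position of
maximal prominence, and rejects profiles whose prominence is below
`min_barrier` (default 0.5 k_BT).  Thresholds sit where F first rises by
`depth` (default 1 k_BT, capped strictly below the barrier top) above
each basin minimum.  Explicit thresholds pass through unchanged.  The
soft-committor mode re-derives A and B as terminal intervals of the
current r around its free-energy minima and re-optimizes, iterating to a
fixed point (< 1% membership change) or a round budget (default 5); it is
exercised on oracle data but disabled by default in the desk-scale
lattice pipeline, where the nearly flat profile along r makes repeated
redefinition unstable.

## Profiles, validation and kinetics

All profile estimators share one lag convention: at lag Δt = 2^i Δt₀ the
series is subsampled with stride 2^i at each of the 2^i phases and the
profiles are averaged over phases (a single-pass variant is selectable).
Hence the total histogram count at lag 2Δt is exactly half that at Δt,
reproducing the Z_H ∼ Δt^−1 scaling of the underlying density, and the
phase-averaged cut profile integrates to TSD(Δt)/2^i — exactly TSD at the
base lag.

Z_C,1 is accumulated per bin with fractional-overlap weights: a step from
a to b deposits |b−a| into every bin its interval covers, prorated by
overlap.  This makes ∫ Z_C,1 dr = Σ|Δr|² an identity at machine precision
and agrees with the straddling-count definition on fully covered bins.

The free energy is F = −ln Z_H (k_BT units, arbitrary constant).  The
diffusion coefficient is the cut/histogram ratio D = Z_C,1/(Δt Z_H) with
Z_H entering as the *density of transition endpoints per unit RC*, i.e.
2 × counts / bin width — each transition deposits its start and its end.
With that normalization free Brownian motion returns D = D₀ (verified to
1% in the tests) and D·p_eq equals the flux N_AB/(2T) for a committor
series; with raw per-bin counts the ratio would be off by 2/bin-width.

The validation scan computes −ln Z_C,1 for i = 0..i_max and summarizes
each lag by the mean and spread over interior bins (default interior:
bin centers in (0.05, 0.95), excluding the boundary-state spikes; the
exact interior choice only enters the scalar summary).  For the committor
both the offset of the mean from −ln N_AB (lag dependence) and the spread
(r dependence) are within the statistical uncertainty 1/√(2 N_AB); the
verdict requires every lag's larger deviation to stay within 3 of those
uncertainties.  Monotone distortions of the committor fail through the
spread (e.g. q² adds ≈ |ln 2q| of r-dependence), suboptimal coordinates
fail through the lag drift.

Kinetics: the model MFPT evaluates the double integral of the 1D
diffusive model with the bin-consistent midpoint rule — p_eq is a
histogram density with delta-like mass in the terminal bins, and a
trapezoid would halve exactly that boundary mass (a ~30% error on the
double-well oracle; the midpoint rule is exact for the closed-form test
cases).  Unsampled bins inside the support are bridged by log-space
interpolation in both p_eq and D.  Direct MFPTs use
first-entry-to-first-entry events (the time from each first entry into
the origin state to the next first entry into the destination), which
makes τ_{A→B} + τ_{B→A} consistent with total time per round trip;
per-event durations are returned for bootstrapping.  N_AB is counted as
completed crossings in either direction, and independently estimated as
∫ Z_C,1(r, Δt₀) dr.  Transition-path times average the reactive segments
(last exit from one state to first entry into the other).  The
unit-diffusion rescaling q̃(r) = ∫₀^r dr′/√D(r′) uses piecewise-constant
per-bin D; the re-estimated diffusion coefficient on q̃ is ≈ 1 on
interior bins (5% in the tests) and the separation Δq̃ between the
free-energy minima is reported when the rescaled profile is bimodal.

## Synthetic oracles

Two families provide exactly solvable ground truth.  (i) Discrete Markov
chains: the committor solves q = Pq with q(A) = 0, q(B) = 1 by direct
linear algebra, hitting times solve the analogous system; trajectories
are sampled from the cumulative rows.  The standard example is the lazy
unbiased walk on {0..4} with committor i/4.  (ii) A quartic double well
V(x) = barrier·(x²−1)² (default barrier 3 k_BT, wells at ±1 taken as A/B
boundaries) with overdamped Euler–Maruyama dynamics (constant D₀,
dt = 10⁻³, reflecting walls at ±1.6 to keep equilibrium sampling) and the
closed-form committor q(x) ∝ ∫ e^{V} between the wells.  These oracles
emulate equilibrium two-state dynamics with known answers; they do not
emulate the permutation-symmetry aspect of multimolecular data (that is
exercised by the lattice model) nor rare-event sampling limitations, so
passing them certifies the estimators and the optimizer, not sampling
adequacy on hard systems.

## Problem sizes and defaults

Oracle tests use 10^6-step trajectories (committor recovery to RMSE
< 0.02 with distorted CV pools; per-state errors ~10⁻³ on the walk).  The
desk-scale lattice study uses L = 40, N = 40, ξ = 1 at the calibrated
T* = 0.3775 with 10^7 attempts (25 000 frames at Δt₀ = 400), 200
optimizer iterations over all ~1 500 surviving sorted-distance channels
plus n, and 30-bin profiles (~800 frames per bin; the model/direct MFPT
ratio of the optimized coordinate is insensitive to the bin count, while
coarse-grained baselines like q(n) are not, so the bin choice is made on
occupancy grounds).  At these sizes the full workflow runs in ~15 s.  The
full-scale configuration (L = 200, N = 400, six 10^8-attempt runs,
ξ ∈ {1, 3, 5, 7}) runs through the same pipeline unchanged; its CV pool
is evaluated lazily.

## Known limitations

- The desk-scale lattice system is near-critical: F(n) bimodality is
  marginal (0–0.4 k_BT) and kinetic estimates rest on ~5–20 transitions
  per 10^7-attempt run, so desk-scale kinetics carry large (reported)
  bootstrap errors.
- Committor estimates are only as good as the sampled transitions; the
  package targets long equilibrium trajectories and does not implement
  nonequilibrium reweighting, path sampling, or memory-kernel models.
- The Z_C,1 = N_AB constancy degrades at lags approaching the boundary
  recrossing time (visible even for a perfect telegraph signal when the
  lag approaches the dwell time); the scan's dyadic ladder should be kept
  below that scale.
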