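# committor-lab

Nonparametric determination of the committor — the optimal one-dimensional
reaction coordinate — for multimolecular aggregation, with the full
diffusive-model validation and kinetics toolchain around it.

## The problem

Transitions between two long-lived states A and B (a diluted solution vs a
molecular aggregate, an unfolded vs folded protein, ...) are usually
described by projecting the high-dimensional dynamics onto a scalar
reaction coordinate (RC) r(X) and modelling the projected motion as
diffusion on a free-energy profile.  A poorly chosen RC makes that model
quantitatively wrong: the projected dynamics is non-Markovian and the model
predicts kinetics that are too fast.  The committor

    q(X) = P( reach B before A | start at X )

is the optimal RC for equilibrium two-state kinetics: the diffusive model
along q, specified by the equilibrium density p_eq(q) and the diffusion
coefficient D(q), reproduces the equilibrium flux J = D(q) p_eq(q), mean
first-passage times (MFPT)

    tau_{B->A} = ∫₀¹ dq' / (p_eq(q') D(q')) ∫_{q'}¹ p_eq(q'') dq''

and mean transition-path times of the original dynamics.

For multimolecular systems the committor must respect translation,
rotation and permutation symmetry.  This package implements a systematic
solution: compute the N×N matrix of minimum-image intermolecular distances
and sort it ascending first within each column, then within each row.  The
entries d̄_ij of the sorted matrix are symmetry-invariant collective
variables (CVs).  The committor is then found *nonparametrically*: the RC
is represented only by its time series r(kΔt₀) with r(A)=0, r(B)=1
clamped, and is improved by iterated variations

    δr = Σ_{i+j≤l} a_ij r^i x^j     (δr = 0 on A and B frames)

where x is a randomly drawn CV series and the coefficients a_ij are the
analytic minimizers of the total squared displacement
TSD = Σ_k [r(k+1) − r(k)]² — the discrete Dirichlet form whose minimizer
under the clamped boundary conditions is the committor.

Convergence is checked by a stringent criterion: the cut profile

    Z_C,1(r*, Δt) = Σ'_k |r(kΔt+Δt) − r(kΔt)|    (sum over steps straddling r*)

is constant in r* and in Δt, equal to the number N_AB of A↔B transitions,
if and only if r is the committor.  The package scans Δt = 2^i Δt₀ and
issues a pass/fail verdict with tolerance 1/√(2 N_AB).  From the histogram
Z_H and the cut profile it also builds the free energy F = −ln Z_H, the
diffusion coefficient D = Z_C,1/(Δt Z_H) (with Z_H as the density of
transition endpoints), unit-diffusion rescalings q̃, and kinetics
(Eq.-style model MFPT, direct MFPT, N_AB by counting and by ∫Z_C,1 dr,
transition-path times).

As a benchmark application the package ships a 2D lattice aggregation
model: N molecules with binary orientations on an L×L periodic lattice,
anisotropic nearest-neighbour attractions (−ψ_s aligned, −ψ_w otherwise,
ξ = ψ_s/ψ_w), simulated by Metropolis Monte Carlo at the coexistence
temperature T* where diluted and aggregated phases have equal weight.
The largest-aggregate size n — the classical-nucleation-theory coordinate
— serves as the baseline RC q(n) that the optimized committor is compared
against.

## Worked example

Brownian dynamics in a quartic double well (barrier 3 k_BT) with known
committor; the optimizer sees only the position x and nonlinear
distortions of it:

```python
import numpy as np
import committor_lab as cl
from committor_lab.cvs import CVPool

spec = cl.DoubleWellSpec(barrier=3.0, D0=1.0, dt=1e-3, seed=11)
x = cl.simulate_double_well(spec, 500_000)
seg = np.zeros(len(x), np.int32)

pool = CVPool(segment_ids=seg)
pool.add_observable("x", x)
pool.add_observable("x3", x**3)

r0 = cl.initial_rc(x, seg, cl.BoundaryStates(-1.0, 1.0, "x"))
rc, log = cl.optimize(r0, pool, cl.OptimizerConfig(l=4, m_max=20, seed=0))
print(f"TSD: {log['tsd'][0]:.1f} -> {log['tsd'][-1]:.1f}")

q_true = cl.project_on_committor(x, spec).r
print(f"RMSE vs analytic committor: {np.sqrt(np.mean((rc.r - q_true)**2)):.4f}")

scan = cl.validation_scan(rc, i_max=6)
print(f"N_AB = {scan['n_AB']}, -ln N_AB = {scan['expected']:.2f}")
print("per-lag -ln Z_C1 means:", np.round(scan["means"], 2))
print("verdict:", "PASS" if scan["passed"] else "FAIL")

model = cl.DiffusiveModel.from_rc(rc, nbins=50)
tau_model = cl.mfpt_model(model, frm=1.0, to=0.0)
tau_direct, _ = cl.mfpt_direct(rc, "B->A")
print(f"MFPT B->A: model {tau_model:.0f} vs direct {tau_direct:.0f} steps")
```

Output:

```
TSD: 145.1 -> 57.7
RMSE vs analytic committor: 0.0040
N_AB = 57, -ln N_AB = -4.04
per-lag -ln Z_C1 means: [-4.06 -4.05 -4.05 -4.05 -4.04 -4.06 -4.08]
verdict: PASS
MFPT B->A: model 7826 vs direct 7294 steps
```

The TSD drops to ≈ N_AB (its theoretical floor for a committor series at
fine sampling), the recovered coordinate matches the closed-form committor
to RMSE 0.004, the −ln Z_C,1 profiles are flat at −ln N_AB across lags
(verdict PASS), and the diffusive model reproduces the directly measured
MFPT within the sampling error of 57 events.

The lattice workflow (simulate → CVs → optimize q(n) and q → validate →
kinetics) runs end to end via

```python
report = cl.run_pipeline({"seed": 1})       # desk-scale: L=40, N=40, xi=1
```

or from the shell: `committor-lab pipeline --seed 1 --out report/`.
`committor-lab simulate|calibrate-T|cvs|optimize|validate|kinetics` expose
the individual stages.

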