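# Methods

## Model and assumptions

A lineage model is a continuous-time Markov jump process on nonnegative
integer cell counts. Each process fires as a Poisson stream whose total
intensity responds linearly to deviations of the populations from their
equilibrium values, clipped at zero:

    Q_k(i) = max(0, Q_k0 + Σ_q c_kq (i_q − i*_q)),

with c_kq the control derivative of process k with respect to
compartment q (units: events per unit time per cell). Rates are total
process intensities, never per-cell rates — this is applied uniformly,
including to cell death, so a "death" process with no controls removes
cells at a constant rate regardless of how many remain. The analysis
layer (constraints, Jacobian, covariances) is local to the equilibrium
and uses the unclipped linear form; the simulator uses the clipped form.
Populations are real-valued in analysis and integer-valued in
simulation. Compartment order is declaration order everywhere.

The fluctuation theory is the linear noise approximation: the stationary
covariance solves the Lyapunov equation J Y + Y Jᵀ = −S with
J = D·C (increments times controls) and S = D·diag(Q₀)·Dᵀ. Its validity
requires small deviations from equilibrium and weak control
nonlinearity; see "Clipping bias" below for where this audibly fails.

## Numerical choices

- **Constraint rank** is the rank of the increment matrix computed from
  singular values with relative tolerance 1e-10 (increments are small
  integers, so the spectral gap is enormous). The number of independent
  constraints is the rank, not the compartment count — they differ for
  rank-deficient increment matrices, and the degrees of freedom always
  satisfy rank + dof = K.
- **Free/dependent partition**: pivoted QR by default; the airway
  presets pin the partition (full model: Q5, Q6, Q8 dependent; reduced:
  Q6, Q9, Q10; two-compartment: Q5, Q6) so that the derived formulas
  match the forms usually quoted for this system. Infeasible (negative)
  derived rates are returned as a flagged result, supporting the
  rejection sampling used by the random-system generator.
- **Stability** is strict: stable iff max Re λ < −1e-12. Marginal
  systems report `stable=False` with the margin printed.
- **Covariance flattening** is row-major, y⃗ = Y.flatten(), and the
  Kronecker sum W = kron(J, I) + kron(I, J) matches it; the pairwise-sum
  eigenvalue property of W is under test as the single point of truth.
  The dense Lyapunov (Bartels–Stewart) solve is primary; the n²-system
  solve and the matrix-exponential quadrature (quad_vec to a horizon set
  by the stability margin, tolerance 1e-10) are retained as independent
  oracles, and the three agree to 1e-6 relative on every preset. The
  solved Y is symmetrised; PSD is checked to 1e-8 relative to the trace.
- **Simulation** draws the process selection and the waiting time from
  two separate seeded streams, so the exponential-clock and
  discrete-update modes share an identical embedded jump chain at equal
  seeds. A selected process that would drive a count negative raises an
  error naming the process (well-posed clipped models prevent this).
  Empirical moments are time-weighted (event-weighted in discrete mode)
  over the post-burn-in segment, with batch-means standard errors
  (default 20 batches, burn-in 50%). Recovery time is first passage into
  ±10% of equilibrium (configurable).
- **Division-symmetry optimisation** exploits exact structure: the
  Jacobian depends only on controls, so the stationary variances are
  affine in the equilibrium rates; two-point differences give exact
  derivatives and scipy's HiGHS linear programming solves the
  minimisation over the feasibility polytope {Q1, Q3 ≥ 0, derived Q5,
  Q6 ≥ 0}. A grid-search oracle validates the LP in the tests.

## Airway presets and parameter provenance

Equilibrium populations are (250, 200, 550) for (SC, SecrC, CilC). The
often-quoted 30%–15%–55% homeostatic ratio is inconsistent with these
numbers (which are 25%–20%–55%); the presets use (250, 200, 550) and the
discrepancy is documented rather than resolved.

Two published parameter sets of the reduced model ship as named presets:

- **Variance-scan set** (`fig3_params`): free rates Q4 = 0.00078,
  Q5 = 0.041, Q7 = 0.937, Q8 = 0.0056; derived Q9 = 0.89678,
  Q10 = 0.00404. Feasible as published. The two scanned controls default
  to −0.005.
- **Recovery-dynamics set** (`fig4_params`): the published free rates
  (Q4 = 0.0089, Q8 = 0.0019) violate the ciliated-cell balance — the
  derived Q10 would be −0.0159. The preset keeps all published controls
  and the Q5, Q7, Q8 rates and clamps Q4 to Q8/2 = 0.00095, the
  feasibility boundary (derived Q10 = 0). This keeps both slow rates
  within the ε = 0.01 smallness bound that the slow-ciliated-turnover
  argument rests on. The verbatim rate set remains available
  (`fig4_params_raw`) and raises the infeasibility error.

The reduced preset keeps process Q9 (asymmetric SC division into SecrC):
dropping it would contradict the balance relation that derives a nonzero
Q9 rate. The more literal alternative reading (no Q9 at all) is
available via `include_q9=False`, with Q5 derived instead of free. The
Q5–SecrC self-inhibition control is optional; the recovery-dynamics
preset includes it, the variance-scan preset does not. The published
closed-form SecrC/CilC variances of the reduced model are shipped as
provenance-flagged formulas only (`reduced_closed_forms`): their
transcription is ambiguous (the SecrC formula lacks terms that direct
assembly of S produces), so the Lyapunov solver — cross-validated
against simulation — is the authority, and the printed values are
reported alongside, never asserted.

The full-model default (`full_default_params`) is this package's choice:
fast SecrC turnover (Q7 = 0.9, Q9 = 0.7), slow symmetric divisions and
CilC-side rates (order 1e-2 to 1e-3), and ε-scale controls with the
admissible signs; it is feasible and stable, and exists because no full
11-process parameterisation is published.

The random-system generator reproduces the published procedure exactly:
Q5, Q7 ~ U[0, 1]; Q4, Q8 ~ U[0, ε] with ε = 0.01; rejection of draws
with a negative derived rate; negative controls ~ U[−ε, 0] and the CilC
death control ~ U[0, ε]. Every accepted draw is stable by construction.

## Clipping bias (known limitation)

The ε-scale parameterisations put the slow rates (Q8, Q10, Q4) within
one stationary fluctuation of zero, so the max(0, ·) clipping is active
a substantial fraction of the time. For such parameter sets the
simulated ciliated-cell marginal deviates from the linear-noise
solution: at the recovery-dynamics preset the CilC mean sits ~14 cells
above 550 and its variance well below the Lyapunov value, because the
clipped replenishment rate Q10 = max(0, −0.0094·(y − 200)) has a
positive mean even though its equilibrium rate is zero. This is a
genuine property of the piecewise-linear model at a boundary-feasible
equilibrium, not a solver defect: the SecrC marginal (whose rates are
far from the clip) matches the analytic variance to within sampling
error, and on a validation parameter set with all rates > 4σ from the
clipping boundary the simulator matches the full analytic diagonal. The
simulation-versus-theory tests are therefore formulated on the
clipping-free side; the analytic covariances for ε-scale presets should
be read as the linear-noise idealisation.

## Problem sizes

The shipped analyses use desk-scale sizes chosen for tight statistics:
homeostatic runs of 1e5–1.2e5 events (about 6×10⁴ time units, several
hundred SecrC relaxation times), 6-replicate ensembles for
variance validation, 3-replicate ensembles for recovery-time ordering
(horizons 4×10⁴ for ciliated-cell recovery, 2×10³ for secretory
recovery), and 1000-draw robustness samples. Batch-means standard errors
make the stochastic assertions self-calibrating (3 SE criteria).

## What the synthetic models do and do not capture

All worked inputs are synthetic: either the published parameter sets
above or models drawn by the stated random procedure. They emulate a
well-mixed tissue patch with linear feedback near equilibrium. They do
not capture spatial structure (niche geometry, local signalling),
per-cell age or lineage identity, strongly nonlinear rate laws, or
measured recovery time-courses; passing tests therefore demonstrate the
mathematical consistency of the framework and its qualitative agreement
with the depletion experiments (slow ciliated recovery, de-differentiation
rescue of stem cells, fast joint recovery), not a quantitative fit to
airway data.
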