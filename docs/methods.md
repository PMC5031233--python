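# Methods and conventions

This document records the exact formulas, unit conventions, and algorithmic
choices implemented in `krigfield`. File-format details live in the
`krigfield.chem_io` docstrings.

## Units

Internal calculations are in Hartree atomic units: lengths in bohr, energies
in hartree, masses in electron masses (m_e). Boundaries:

- XYZ files are in **Å** (converted on read/write; 1 Å = 1.8897261254578281 bohr).
- Vibrational frequencies are reported in **cm⁻¹**:
  ν = √λ · 219474.6313632, with λ the mass-weighted Hessian eigenvalue in
  hartree/(m_e·bohr²). Negative eigenvalues map to negative wavenumbers.
- Validation energies are reported in **kJ/mol** (1 hartree = 2625.49964 kJ/mol).
- Atomic masses use standard atomic weights, converted via
  1 amu = 1822.888486209 m_e.

## Normal-mode analysis (`normal_modes`)

1. Mass-weight: `H_q[i,j] = H[i,j] / sqrt(m_i m_j)` with per-coordinate masses.
2. Build six external vectors: three mass-weighted translations and three
   Eckart/Sayvetz rotational vectors about the centre of mass in the
   principal-axis frame; orthonormalise. Linear molecules (a near-zero
   principal moment) are rejected.
3. Complete to a full orthonormal basis `D` by Gram–Schmidt over coordinate
   unit vectors, discarding candidates with residual norm < 1e-8; the final
   basis must satisfy `|DᵀD − I|_max < 1e-8`.
4. `H_int = D_vibᵀ H_q D_vib` (the 3N−6 internal block); diagonalise.
   Because `D` is orthogonal this is a similarity transform: the spectrum —
   including the count of zero modes — is that of `H_q` itself. A valid
   free-molecule Hessian must show exactly six near-zero eigenvalues
   (|λ| < 1e-8·max|λ|); any negative vibrational eigenvalue raises
   `SaddlePointError`.
5. Conventions (Gaussian-style): reduced mass `μ_i = 1 / Σ_k (L_cart)²_{ki}`
   where `L_cart = M^{-1/2} L_q` column-normalised; force constant
   `k_i = λ_i μ_i`.

## Normal-mode conformational sampling (`sampler`)

Total energy `E = N_vib · k_B · T / 2` is split across modes by a flat
Dirichlet draw (uniform simplex). Mode i gets amplitude `A_i = √(2 E_i / λ_i)`
and a uniform random phase φ_i. Sample s (1-based within its block)
displaces along mass-weighted mode vectors:

```
q_i(s) = A_i sin(2π s / ncycle + φ_i),   x = x_0 + M^{-1/2} L_q q
```

Every `nreset` samples the energy partition and phases are redrawn. T = 0
reproduces the seed geometry exactly. `generate_multi` round-robins a sample
budget over several minima (used for multi-minimum experiments).

## Atomic local frames and features (`alf`)

Bonds are assigned where `r_ij < 1.2 (r_cov,i + r_cov,j)`; the covalent graph
must be connected. Each atom's frame: x-axis towards its heaviest bonded
neighbour, xy-plane defined by the next-priority neighbour, priorities broken
Cahn–Ingold–Prelog-style by exploring substituent spheres outward. The frame
is a proper rotation (det +1). Features per atom: distance to the x-axis
atom, distance and polar angle of the xy-plane atom, then spherical
coordinates (r, θ, φ) of every remaining atom — 3N−6 values, invariant
to rigid motions. Multipole moments are stored either in the global frame or
rotated into each atom's ALF (`frame` tag "global"/"ALF").

## Solid harmonics and multipole electrostatics (`solid_harmonics`, `electrostatics`)

Moments are real Racah solid-harmonic components up to rank 4
(25 components: Q00; Q10=z, Q11c=x, Q11s=y; ...). Rank-l components
transform under rotation by dense `(2l+1)×(2l+1)` operators generated from
the Cartesian rotation matrix. The pair interaction energy uses the
spherical-tensor formula

```
E_AB = Σ_{l1+l2 ≤ 4}  Q^A · T_{l1 l2}(R_AB) · Q^B
```

with pre-generated interaction tensors `T` (exact polynomial tables in the
inter-site vector; `T_{l1l2}(r) = T_{l2l1}(−r)ᵀ`, scaling `r^−(l1+l2+1)`).
The molecular topology restricts the sum to atom pairs at bonded-path
separation ≥ `min_sep` (default 4, i.e. 1-5 interactions and beyond).
Truncation error against an exact point-charge sum decays with separation:
for two random 4-charge clusters the relative error is 3.8e-2 / 9.0e-4 /
2.7e-5 / 8.7e-7 at 5/10/20/40× the cluster radius.

## Kriging (`kriging`)

Correlation kernel between feature vectors x, x′:

```
R(x, x′) = exp( − Σ_h θ_h |x_h − x′_h|^{p_h} ),  θ_h ≥ 0, 1 ≤ p_h ≤ 2
```

Given training data (X, y), the process mean and variance are profiled out:

```
μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1),   σ̂² = (y−μ̂1)ᵀR⁻¹(y−μ̂1)/n
log L = −(n/2) ln σ̂² − (1/2) ln|R|     (constants dropped)
```

computed via Cholesky factorisation. A nugget (default 1e-10) is added to
the diagonal and escalated ×10 up to 1e-6 if factorisation fails; beyond
that a `ConditioningError` names the most nearly duplicate rows. Degenerate
(constant) targets short-circuit to a flagged constant predictor. Prediction:
`ŷ(x*) = μ̂ + r(x*)ᵀ R⁻¹ (y − μ̂1)`, reverting to μ̂ far from the data.
For `p = 2` the fit uses a precomputed squared-difference matrix so each
likelihood evaluation is a single matrix exponential; the final weight
vector gets one step of iterative refinement so zero-nugget models
interpolate their training data to ~1e-9 relative error even when `R` is
near-singular.

Hyperparameters are searched in `log10 θ ∈ [−6, 3]` per dimension (and
`p ∈ [1, 2]` unless pinned) by PSO.

## Particle swarm optimization (`pso`)

Constricted PSO: inertia w = 0.72, cognitive/social c1 = c2 = 1.49,
positions clipped to bounds, NaN objective values treated as −∞ (an
all-NaN swarm raises). Defaults: 50 particles, 200 iterations, early
termination after 20 iterations with best-value improvement < 1e-8.
The best-value trace is non-decreasing by construction.

## Validation (`validation`)

- **S-curve**: cumulative distribution of |E_pred − E_ref| in kJ/mol;
  `percentile_below(x)` is inclusive.
- **Learning curve**: least-squares fit of ε(n) = A + B/n with an
  R² diagnostic in 1/n space.
- **Extrapolation flag**: a query is flagged when its nearest-neighbour
  feature distance to the training set exceeds the training set's own
  q-th percentile (default 99) of nearest-neighbour distances; on i.i.d.
  data the false-positive rate is ≈ 1 − q/100 (measured 1.6 % at q = 99).

## Surrogate systems (`surrogate`)

Fixtures are harmonic spring networks (Hessians analytic from a pair
potential at its own minimum) with multipole moments defined as smooth
affine functions of local descriptors — bond-length-driven charge transfer
(net charge conserved exactly), bond-direction dipoles, quadratic
combinations for higher ranks — so the "ab initio" labels are exactly
learnable from ALF features. Kinds: `triatomic` (3 atoms),
`chain16`/`ring16` (16 atoms; the ring is a furanose-like C4O cycle with
substituents: 16 bonds, one 5-cycle, 39 pairs at ≥ 4 bond separation),
and `double_well` (a triatomic with n well-separated minima for
multi-minimum sampling studies).

## End-to-end behaviour (`pipeline`)

`scurve_experiment` samples an ensemble, trains per-atom per-component
models on a training split, predicts moments for held-out conformers, and
compares multipolar energies. On the furanose surrogate the mean S-curve
error decreases as the training set grows from 100 to 400 conformers, and
spreading the same sampling budget over 5 well-separated minima instead of
1 degrades prediction accuracy — both reproduced in
`tests/test_acceptance.py` and `scripts/acceptance.py`.
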