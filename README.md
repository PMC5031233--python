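# krigfield

Machine-learned, conformation-dependent atomic multipole electrostatics.

A molecule's atomic multipole moments change as its geometry distorts.
`krigfield` builds models that predict those moments for any conformer:

1. **Normal-mode sampling** — mass-weight the Hessian, project out the six
   translational/rotational modes (Eckart/Sayvetz frame), then generate
   conformer ensembles by evolving every vibrational mode harmonically with
   randomly partitioned thermal energy (`N_vib·k_B·T/2` in total).
2. **Atomic local frames (ALF)** — each atom gets a right-handed frame
   anchored on its covalent graph (heaviest neighbour on the x-axis,
   Cahn–Ingold–Prelog-style tie-breaking), giving 3N−6 rotation-invariant
   features per atom and rotating its moments into a conformation-only
   representation.
3. **Kriging** — one Gaussian-process model per atom per multipole component
   (25 components through hexadecapole), with the p-exponential kernel
   `R = exp(−Σ_h θ_h |Δx_h|^{p_h})`; hyperparameters maximise the
   concentrated log-likelihood via constricted particle swarm optimization.
4. **Multipolar electrostatics** — predicted moments are validated through
   the spherical-tensor interaction energy over all atom pairs separated by
   ≥ 4 bonds (plus 1–5 and higher paths), with rank combinations up to
   `l1 + l2 ≤ 4`, summarised as S-curves (cumulative |ΔE| distributions)
   and learning curves `ε(n) ≈ A + B/n`.

Everything runs on built-in analytic **surrogate systems** (a bent
triatomic, a 16-atom furanose-like ring, a 16-atom chain, and a multi-minimum
double-well variant) whose moments are smooth closed-form functions of
geometry — so the full pipeline is testable without any quantum-chemistry
engine. Real data enters through plain-text XYZ (Å), Hessian, and multipole
CSV readers in `krigfield.chem_io`.

## Quick start (library)

```python
import krigfield as kf

fx = kf.make_fixture("triatomic")
modes = kf.vibrational_analysis(fx.geometry, fx.hessian)
# -> 3 modes at 850.0, 3146.1, 3305.2 cm^-1

res = kf.scurve_experiment(
    fx, n_train=100, n_test=50, seed=0,
    sampler=kf.SamplerConfig(n_samples=150),
    training=kf.TrainingConfig(pso=kf.PSOConfig(swarm_size=15, max_iters=40),
                               fixed_p=2.0),
    min_sep=1,
)
print(res.scurve.mean)   # ~1e-4 kJ/mol: the smooth surrogate is learnable
```

See `examples/` for annotated walkthroughs of each stage; running
`examples/02_train_and_predict_moments.py` trains 75 models on the triatomic
and reports max component errors ~1e-6–1e-5 e·a0^l and a mean energy error
of ~0.0001 kJ/mol on held-out conformers.

## Quick start (CLI)

```bash
krigfield sample  --surrogate triatomic --out ens.xyz --moments-out moms.csv
krigfield features --xyz ens.xyz --out feats.csv
krigfield train   --features feats.csv --moments moms.csv --out models/
krigfield predict --models models/ --features feats.csv --out pred.csv
krigfield energy  --xyz frame.xyz --moments moms.csv --out pairs.csv
krigfield scurve  --pred pred_E.csv --ref ref_E.csv --out scurve.csv
```

Shared options (temperature, sampler cycle lengths, PSO budget, hyperparameter
bounds, train size) live in a YAML config passed with `--config`.

## Testing

```bash
python -m pytest -q tests/                 # full suite incl. slow experiments
python -m pytest -q -m "not slow" tests/   # fast subset (~20 s)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reruns the headline experiments (closed-form oracles,
interpolation/relevance-recovery checks, the learning-curve study on the
furanose surrogate, and the multi-minimum degradation study) and writes all
computed quantities to JSON.

## Layout

- `src/krigfield/` — library: `chem_io`, `normal_modes`, `sampler`, `alf`,
  `solid_harmonics`, `kriging`, `pso`, `electrostatics`, `validation`,
  `surrogate`, `pipeline`, `cli`
- `examples/` — narrative scripts
- `docs/methods.md` — conventions and formulas (units, frequency/force-constant
  conventions, kernel and likelihood definitions, ALF rules, tensor ordering)
- `tests/` — unit tests plus `tests/test_acceptance.py` end-to-end properties

Units are atomic units (bohr, hartree, electron mass) internally; XYZ files
are Å, frequencies cm⁻¹, and energy summaries kJ/mol.
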