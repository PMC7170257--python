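# tumortx

Simulator for a free-boundary, radially symmetric PDE model of melanoma
growth under combined anti-PD-1 / anti-TNF-α therapy.

The model evolves eight fields on a growing sphere of radius `R(t)` —
dendritic cells `D`, cytotoxic lymphocytes `T`, cancer cells `C`, the
cytokines IL-12 and TNF-α, the checkpoint receptor PD-1 `P`, and the two
drugs `A` (anti-PD-1) and `B` (anti-TNF-α) — under the constraint that
the total cell density `D + T + C` is constant (0.4014 g/cm³), which
closes a radial cell-velocity field that advects the tumor boundary.
PD-L1, TIM-3, Gal-9 and the two receptor–ligand complexes are
quasi-steady algebraic fields; TNF-α upregulates PD-L1 and TIM-3, and
anti-PD-1 further upregulates TIM-3 (the modeled resistance mechanism).

## Layout

| module                | contents |
|-----------------------|----------|
| `tumortx.parameters`  | all model constants with provenance tags, the derivation rules (cube-root molecular-weight diffusion scaling, half-life conversion, steady-state rate closures), config loading/validation |
| `tumortx.model_core`  | `RadialMesh`, `TumorState`, algebraic ligand/checkpoint fields, reaction terms, velocity closure, boundary and initial conditions |
| `tumortx.solver`      | nonuniform three-point stencils, CFL bound, moving-mesh explicit Euler step, regridding, `simulate` (driven by the jitted kernel in `tumortx._kernel`) |
| `tumortx.treatment`   | dose schedules (mouse day lists; 21-day human cycles S1/S2/S3), pulse-decay dose rates, the TVRR endpoint |
| `tumortx.experiments` | control run, dose-grid TVRR efficacy maps, Latin-hypercube sampling, PRCC sensitivity analysis |
| `tumortx.cli`         | `tumortx` command line, config fixtures, run manifests |

Units are g/cm³, cm and day throughout.

## CLI

```bash
tumortx control --days 30 --r0 0.5 --out runs            # no-drug run
tumortx mouse --days 6,10,13 --gammaA 1e-10 --gammaB 1e-6
tumortx efficacy --schedule S2 --cycles 5 --r0 1.0
tumortx sensitivity --n 200 --seed 7
tumortx make-fixtures --out configs                      # example configs
```

Every run writes CSV/JSON outputs plus a `manifest.json` (config hash,
parameter provenance, seed, wall time, clip counts) into a run directory
(timestamp + config hash, or `--run-dir`). Configs are flat YAML; keys
in the `params` section use ASCII transliterations of the model symbols
(`delta_D`, `lambda_C_mouse`, `K_TQ1`, ...).

## Numerical notes

- The moving mesh absorbs cell advection into node motion; the large-
  diffusivity cytokine/drug fields neglect advection and are
  re-interpolated onto the moved grid each step.
- `div(u)` in the compression term uses the closure identity
  `div(u) = (F_D + F_T + F_C) / 0.4014`, which keeps `D + T + C`
  conserved to machine precision (the suite checks ~1e-14 over 30 days).
- The explicit step obeys `safety / (2 D_max / h_min² + r_max)` where
  `r_max` is the fastest linear reaction rate (TNF-α turnover at 216/day
  dominates once the tumor has grown); the `r = 0` symmetry node takes
  its diffusion exchange semi-implicitly, which is what the stricter
  `h²/6D` center-stencil bound would otherwise force globally.
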