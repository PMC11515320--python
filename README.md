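# chemopde

Tools for learning macroscopic chemotaxis PDEs from spatiotemporal data.

The package simulates an extended Keller–Segel system (bacterial density
`b(r, t)` coupled to a consumable chemoattractant `c(r, t)` with logarithmic
sensing) on a 1-D radial grid, extracts coordinate-invariant local operators
(`u`, `∇u·r̂`, `Δu`, delayed copies, an arctan observable), and fits
data-driven surrogates for PDE right-hand sides:

- **black box**: the full right-hand side of one or both equations,
- **gray box**: only the unknown chemotactic term, diffusion handled
  analytically,
- **parametric gray box**: the chemotactic term as a function of the
  logarithmic-sensing bounds `p = (c₊, c₋)`, enabling recovery of those
  bounds by quasi-Newton minimization of a residual loss,
- **delay models**: discrete-time steppers using only a short history of
  `b` when `c` is unmeasured (Takens-style closure),
- **observer**: a soft sensor estimating the unmeasured `c` field from
  local `b` history,
- **second-order-in-time model**: `b_tt = f(b, ∇b·r̂, Δb, b_t)` for
  noisy, coarsely sampled, `b`-only (experimental-style) data.

Two regression backends sit behind one train/predict contract: a tanh
multilayer perceptron trained full-batch with Adam, and Gaussian-process
regression with a constant × Matérn-3/2 ARD kernel fitted by marginal
likelihood. Learned models are integrated forward with a stiff BDF (or RK45)
method-of-lines scheme, optionally with data corridors at sub-domain edges
and SVD filtering of the learned time derivative.

## Layout

| module | contents |
| --- | --- |
| `chemopde.simulate` | ground-truth finite-volume simulator, response functions, analytic right-hand-side oracles |
| `chemopde.features` | stencil operators, delay embedding, feature matrices, scaling |
| `chemopde.surrogates` | ANN and GPR backends |
| `chemopde.models` | model constructors for every variant above, sensing-bound estimation |
| `chemopde.rollout` | forward integration, delay stepping, SVD projection, error maps |
| `chemopde.preprocess` | experimental-style fixture generation, smoothing, RBF time interpolation, domain partitioning |
| `chemopde.workflows` | end-to-end named experiments with JSON reports |
| `chemopde.io` | HDF5 / CSV / YAML serialization |
| `chemopde.cli` | `chemopde` command-line interface |

## CLI

```bash
chemopde simulate --out run.h5 [--fidelity paper|fast] [--config table3.yaml] [--csv run.csv]
chemopde fixture  --in run.h5 --out exp.h5 --dt 10 --noise 0.05
chemopde train    --model graybox --backend ann --data run.h5 --window 200,230,0,250 --out model.json
chemopde repro    --experiment parametric_recovery --seed 0 --out report.json
```

`chemopde repro` experiments: `blackbox_full`, `blackbox_single_ann`,
`blackbox_single_gpr`, `graybox`, `graybox_gpr`, `parametric_recovery`,
`delay_partial`, `observer`, `experimental_style`.

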