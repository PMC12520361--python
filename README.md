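# cycletime

Pseudo-time ordering of multiplexed single-cell immunofluorescence
snapshots around the cell cycle, and training of a six-variable cell-cycle
ODE model on the reconstructed trajectories under mixed
oscillatory/arrest constraints.

The package covers:

- **`cycletime.synthetic`** — a generator of single-cell snapshot tables
  with the statistical structure the analysis assumes: cells scattered
  along a noisy limit cycle (ergodic or exponential-age sampling), plus
  drug-arrested endpoint snapshots obtained by simulating nocodazole /
  palbociclib / growth-factor-starvation switches for a fixed treatment
  duration. Hidden `__`-prefixed columns carry ground truth for testing.
- **`cycletime.pseudotime`** — log/z-score preprocessing, classical
  multidimensional scaling (CMD) to 2-D, Kåsa circle fit, deterministic
  angle orientation (cyclin A peak precedes cyclin B), ergodic and
  exponential-age (Kafri) angle-to-time maps, circular moving
  median/MAD trajectories, angle-histogram phase boundaries,
  leave-one-marker-out robustness with Benjamini–Hochberg FDR control.
- **`cycletime.multicondition`** — arrest-angle estimation for treated
  (unimodal) populations by repeated joint embedding of all untreated
  cells with small disjoint subsets of treated cells, Procrustes-anchored
  to the untreated reference frame; von Mises KDE mode + circular SD.
- **`cycletime.model`** — the 6-ODE model (p21/p27, cyclin D, active E2F,
  cyclins E/A/B) with binary drug switches and a growth-factor input;
  stiff integration, regime classification (oscillating / arrested /
  undetermined), growth-factor scans, and nearest-neighbour mapping of
  arrested states onto the cycle.
- **`cycletime.training`** — soft-constraint training sets (four copies of
  the reconstructed cycle + ten temporally spaced copies of each arrest
  state, two initial conditions), Gaussian likelihood that stays finite in
  non-oscillatory parameter regions, multistart trust-region least squares
  in log space, profile-likelihood confidence intervals, and
  sensitivity-matrix structural identifiability.
- **`cycletime.pipeline` / `cycletime.cli`** — a config-driven workflow
  writing plain CSV/JSON artefacts.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test (class) per acceptance
criterion; the remaining files are per-module unit and property tests.
The full suite takes a few minutes on one CPU (parameter-recovery
replicates and numba compilation dominate).

## CLI

```sh
cycletime generate --n-cells 5000 --seed 1 --outdir out/
cycletime embed --input-csv out/snapshot_untreated.csv --outdir out/
cycletime arrest --input-csv combined.csv --treated-condition palbociclib \
    --seed 1 --outdir out/
cycletime identifiability --outdir out/
cycletime predict-gf --outdir out/
cycletime run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
outdir: out/run1
seed: 7
period: 22.8566
generate:
  snapshots:
    - {n_cells: 5000, noise_cv: 0.2, condition: untreated}
    - {n_cells: 600, noise_cv: 0.2, condition: nocodazole}
    - {n_cells: 600, noise_cv: 0.2, condition: palbociclib}
n_starts: 2
profile_parameters: [Vsp, IEn]
```

`run-all` executes generate → embed → arrest → fit → profile → predict-gf
and writes `summary.json` (arrest times, parameter estimates, profile
CIs, growth-factor oscillation-loss threshold) plus per-stage CSVs and a
log with versions and seeds.

## Notes

- Concentrations are in arbitrary units; time in hours; the default
  generator period is ≈ 22.86 h (one cell cycle ≈ 24 h).
- The assay noise law is not known; the generator uses multiplicative
  lognormal noise with configurable CV as a stand-in.
- `model.simulate` is the stiff-solver contract (`solve_ivp`/LSODA,
  rtol 1e-8); `cycletime._fast` provides a numba RK4 used for the
  ~10⁴–10⁵ likelihood evaluations during training, validated against the
  stiff solver in the tests.
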