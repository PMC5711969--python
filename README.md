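# alseg

Autologistic regression for binary segmentation of multi-band images.

The package implements an Ising-type Markov random field regression model
for per-pixel binary classification on 4-neighbour lattices, together with
the machinery to build, tune, and evaluate such classifiers at scale:

- **`alseg.lattice`** — model algebra: `{0,1}` / `{-1,1}` codings, lattice
  graphs, joint negpotential, full-conditional probabilities (standard and
  centred variants), exact `2^n` enumeration oracles for small lattices, and
  exact coding conversion.
- **`alseg.estimation`** — balanced pixel sampling, stage-1 logistic fits
  (optionally L1-penalized), log pseudolikelihood with analytic gradients,
  joint maximum-pseudolikelihood (MPL) estimation, and the two-stage
  "plug-in" selection of the association parameter lambda on a grid.
- **`alseg.prediction`** — marginal probability estimation by vectorized
  chequerboard Gibbs sampling (Rao-Blackwellised by default, exact closed
  form at lambda = 0), cutoff classification, and confusion summaries.
- **`alseg.features`** — triangular (tent) basis expansions for additive
  models, main-effect/interaction term sets, and fixed-size genetic
  algorithm subset search with per-size model search.
- **`alseg.simulate`** — labelled synthetic RGB scenes: random elliptical
  foreground regions over class-dependent Gaussian Markov random field
  textures (FFT torus sampling, 3x3 stencils), with full train/validation/
  test suite generation under recorded seeds.
- **`alseg.pipeline` / `alseg.cli`** — end-to-end orchestration of the
  two-stage flow, the plug-in vs MPL image-size comparison, and the
  coding/centring comparison experiment; file I/O for suites (float TIFF or
  NPZ + PNG masks + JSON manifest), models (JSON), and metrics (CSV).

## CLI

```sh
alseg simulate --size 100 --n-images 90 --split 30,30,30 --seed 1 --out suite/
alseg fit      --suite suite/ --n 100000 --seed 2 --out model.json
alseg tune     --suite suite/ --model model.json --lambda-grid 0:0.05:2 \
               --criterion error --seed 3 --out tuned.json
alseg mpl      --suite suite/ --out mpl.json
alseg evaluate --suite suite/ --model tuned.json --seed 4 --out metrics.csv
alseg predict  --image suite/test/scene_0060.tif --model tuned.json --seed 5 --out probs.npy
alseg experiment-table1 --sizes 100,200 --seed 1 --out results/table1/
alseg experiment-fig6   --lambda-grid 0:0.1:1 --seed 1 --out results/fig6/
```

`--criterion` selects the stage-2 tuning objective (`error` = overall
misclassification at the cutoff, `deviance` = Bernoulli deviance of the
estimated marginals). Experiment commands accept a YAML/JSON config file
(`--config`) whose keys mirror `alseg.pipeline.ExperimentConfig`; CLI flags
override file values. All artefacts embed the config hash and seeds.

## Conventions

- Pixel ordering is row-major, 0-based `(row, col)` everywhere.
- Regression coefficients are stored on the conditional-logit scale: a raw
  logistic fit's coefficients are divided by the coding span `H - L`, which
  makes lambda = 0 predictions identical under either coding.
- The classification cutoff is strict (`p > c`); ties go to the low class.
- Lambda grids, Gibbs sweep counts, and generator knobs are configuration;
  defaults are documented on `ExperimentConfig`, `GibbsConfig`, `GmrfSpec`,
  and `EllipseParams`.
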