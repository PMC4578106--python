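# cmzcycle

Cell-cycle kinetics of asynchronously cycling stem-cell populations:
simulation and estimation for EdU labeling experiments, replication-foci
S-phase staging, and digital (barcode-counting) expression normalization.

The package is written for quantitative biologists who score labeled cells
on tissue sections — for example retinal stem cells in the ciliary marginal
zone (CMZ) of fish or amphibian eyes — and want the classical cell-cycle
readouts with honest uncertainties, plus generators of synthetic data on
which every estimator is validated by parameter recovery.

## The model

A fraction GF (*growth fraction*) of the population cycles through
G1 → S → G2 → M with durations T_G1, T_S, T_G2, T_M summing to T_C.  At
steady state, cycle positions are uniform, which gives closed forms for the
three classical experiments:

* cumulative EdU labeling: LI(t) = GF·min((T_S + t)/T_C, 1), rising from
  LI_0 = GF·T_S/T_C to a plateau GF at T_plateau = T_C − T_S, so that
  T_C = T_plateau·GF/(GF − LI_0) and T_S = T_C − T_plateau;
* percentage of labeled mitoses (PLM): PLM(t) = clamp((t − T_G2)/T_M, 0, 1),
  whose half-rise time estimates the G2 duration;
* mitotic index: MI = GF·T_M/T_C.

`cmzcycle.popsim` simulates the experiments (per-cell phase durations,
analytic label resolution, per-replicate scoring noise);
`cmzcycle.kinetics` fits the hinge model to cumulative curves and a
logistic to PLM curves and inverts the identities above;
`cmzcycle.foci` simulates, detects (multiscale Laplacian-of-Gaussian) and
classifies early vs mid/late S-phase replication-foci patterns;
`cmzcycle.counts_norm` implements negative-control background subtraction
(mean + 2·SD) and geometric-mean scaling against positive spikes then
housekeeping probes, with a negative-binomial count simulator for
fold-change recovery tests.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

Simulate a cumulative-labeling experiment (control preset: GF 0.8,
T_C 20 h, T_S 4 h; 10% per-cell duration variability; 5 retinas × 50
scored cells at 7 exposure times) and fit it back:

```sh
cmzcycle simulate --config sim.toml --out obs.tsv --seed 1
cmzcycle fit-cumulative --input obs.tsv --out fit.json
```

with `sim.toml`:

```toml
[cycle]
preset = "control"
cv = 0.1
n_cells = 10000

[design]
mode = "cumulative"
observation_times = [0.5, 0.75, 1.0, 1.25, 14.0, 24.0, 32.0]
n_replicates = 5
cells_scored_per_replicate = 50
seed = 1
```

`obs.tsv` holds one row per retina per time (`time_h`, `replicate`,
`n_scored`, `n_edu_pos`, `n_ph3_pos`, `n_double_pos`), and `fit.json`
prints:

```json
{
  "schema_version": "1",
  "gf_hat": 0.8080000000055476,
  "li0_hat": 0.16431155850265294,
  "t_plateau_hat": 16.541346780342884,
  "t_c_hat": 20.763784677262546,
  "t_s_hat": 4.222437896919661,
  "rss": 0.02117680060708771,
  "plateau_reached": true
}
```

i.e. from 1750 scored cells the growth fraction is recovered as 0.808
(truth 0.8), the total cycle as 20.8 h (truth 20) and the S phase as 4.2 h
(truth 4).  The identities T_plateau = T_C − T_S and LI_0 = GF·T_S/T_C
hold exactly in every returned fit.  The same workflow with
`mode = "plm"` and `cmzcycle fit-plm` estimates G2 from the half-rise of
the labeled-mitosis fraction.

The library surface mirrors the CLI, e.g.:

```python
from cmzcycle import PRESETS, ExperimentDesign, simulate_experiment
from cmzcycle import labeling_index, fit_cumulative

design = ExperimentDesign(mode="cumulative",
                          observation_times=(0.5, 0.75, 1.0, 1.25, 14, 24, 32),
                          n_replicates=5, cells_scored_per_replicate=50, seed=1)
obs = simulate_experiment(PRESETS["control"], design)
fit = fit_cumulative(labeling_index(obs))
```

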