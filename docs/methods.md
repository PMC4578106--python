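# Methods

`cmzcycle` packages the quantitative machinery used to characterize the
cell cycle of a slowly cycling, asynchronous stem-cell population — the
kind of analysis done on retinal stem cells of the ciliary marginal zone
(CMZ) with EdU labeling — together with synthetic-data generators that make
every estimator testable by parameter recovery.

## The deterministic-cycle labeling model

Each cycling cell traverses G1 → S → G2 → M with durations T_G1, T_S,
T_G2, T_M (hours); T_C is their sum.  A fraction GF of the population (the
*growth fraction*) cycles; the rest is quiescent.  At steady state a
cycling cell's position in its own cycle is uniform on [0, T_C), so the
expected fraction of cells in any phase is that phase's duration divided by
T_C.  Three classical readouts follow in closed form:

* **Cumulative labeling index.**  With EdU constantly available from t=0,
  a cell is labeled once its S interval overlaps [0, t]:

      LI(t) = GF · min((T_S + t) / T_C, 1)

  LI rises linearly from LI_0 = GF·T_S/T_C and plateaus at GF at
  T_plateau = T_C − T_S.  Inverting: T_C = T_plateau·GF/(GF − LI_0),
  T_S = T_C − T_plateau.

* **Percentage of labeled mitoses (PLM).**  A mitotic cell of mitosis-age
  a left S-phase T_G2 + a hours ago, so the labeled fraction among PH3+
  cells is

      PLM(t) = clamp((t − T_G2) / T_M, 0, 1),

  a ramp whose half-rise sits at T_G2 + T_M/2.

* **Mitotic index.**  MI = GF · T_M / T_C.

These closed forms are implemented in `kinetics` and double as the oracles
against which the simulator is validated (agreement within 3 binomial
standard errors at every design time point is asserted in the test suite).

## The population simulator (`popsim`)

`Population` holds per-cell phase durations and a uniform steady-state
cycle position.  Heterogeneity is a lognormal per cell per phase with mean
equal to the nominal duration and coefficient of variation `cv` (default 0
for oracle work; 0.15 is a reasonable realism preset; recovery studies here
use 0.1).  Label acquisition is resolved analytically — a cell is EdU+ iff
its waiting time to the next S entry is at most min(t, label window) — so
there is no time-step discretization anywhere.  Division wraps M back to G1
and keeps the census fixed, which is adequate because every estimator
consumes fractions.  Label dilution over divisions is ignored; experiment
horizons are ≲ 2 T_C.  PH3 positivity is equated with M-phase occupancy.

Scoring emulates sectioned-tissue counting purely as a small
sample-without-replacement per replicate per time (default 50 cells, 5
replicates); no spatial geometry is modeled.  Each replicate gets an
independent population and an independent, reproducible RNG stream derived
from the design seed.

Two parameter presets ship as configuration (not as claims): `control`
(GF 0.8, T_G1 12.5, T_S 4, T_G2 2.5, T_M 1; T_C = 20 h) and
`yap_morphant` (T_G2 4.5, T_S 2, T_G1 16.5; T_C = 24 h), matching the
reported direction of a G2/total-cycle lengthening with S-phase shortening
upon Yap knockdown.  T_M is not measured by these experiment designs and is
exposed as a free parameter (default 1 h); it shifts the PLM half-rise by
T_M/2 and scales the expected mitotic index linearly.

## Estimators (`kinetics`)

**Cumulative fit.**  The hinge model LI(t) = min(LI_0 + b·t, GF) is fitted
to replicate-mean LIs (mean ± SEM per time, SEM with the n−1 standard
deviation) by least squares with the breakpoint scanned on a 512-point grid
between the observed times and refined by bounded scalar minimization
(xatol 1e-10); noiseless curves are recovered to ~1e-8 relative error.  The
plateau is constrained to (0, `max_gf`] (default 1).  By construction the
returned fit satisfies T_plateau = T_C − T_S and LI_0 = GF·T_S/T_C exactly.
If no interior breakpoint improves on a straight line the fit reports
`plateau_reached=False` with the cycle parameters absent; constant or
non-rising curves raise "no rising phase".

By default a single reweighted pass with inverse binomial-variance weights
1/(p̂(1−p̂)) (p̂ from the first pass, clipped to [0.02, 0.98]) follows the
unweighted search: fractions near 0 or 1 are intrinsically better measured,
and at realistic scoring depth the T_S estimate sits close to the
information bound, so the efficiency matters.  `weighting="none"` restores
plain OLS.

**PLM fit.**  A three-parameter logistic P/(1+exp(−(t−t50)/s)) is fitted to
the pooled labeled-mitosis fraction (P ∈ (0,1], t50 within the observed
range, tolerance 1e-8), initialized from the linear-interpolation crossing
of the half-plateau; if the fit fails to converge the interpolation
crossing itself is returned (`fit_kind` records which).  `t_g2_hat` is the
raw half-max abscissa — the conventional G2 estimate — which for a
deterministic cycle equals T_G2 + T_M/2; the corrected value
`t_g2_corrected_hat = t50 − T_M/2` is reported alongside when T_M is
supplied, rather than silently choosing one convention.  Mitoses are pooled
across replicates before forming the fraction because mitotic cells are
scarce (~2 per 50 scored at MI 4%).

**Degenerate inputs.**  All-zero PLM curves raise "half-maximum not
bracketed"; curves saturated from the first time point return the boundary
estimate with a warning; fits require ≥3 distinct times (cumulative) or ≥4
points (PLM).

## Recovery-study design and measured performance

The recovery studies (tests and acceptance script) run 100 simulated
experiments at 5 replicates × 50 scored cells × 7 time points, cv = 0.1,
populations of 10⁴ cells — a deliberate emulation of per-retina scoring
depth.  Observation times are a designed layout, chosen on optimal-design
grounds for the target quantities and fixed in `DESIGN_PRESETS`:

* cumulative: 0.5, 0.75, 1, 1.25 h (a short-exposure cluster measuring
  LI_0 almost directly), 14 h (slope lever just below the expected
  plateau onset), 24 and 32 h (plateau / GF);
* PLM: 0.5–6 h bracketing the expected half-rise at 3 h densely.

With the control preset this yields median relative errors of roughly
1.5–2% (GF), 4–5% (T_C) and 8–9.5% (T_S), and a median absolute error of
~0.07 h for the PLM half-rise time, stable across seed batches.  T_S is the
hard quantity: its error is dominated by the extrapolated intercept and, at
this depth, approaches the Cramér–Rao bound (~8% median) — a binomial MLE
gives no further improvement — so estimates from ~250 cells per time point
should always be reported with that uncertainty in mind.

## Replication-foci staging (`foci`)

Early S nuclei show numerous small replication foci dispersed through the
nucleus; mid/late S nuclei show a limited number of large foci.  The
synthetic generator renders 128×128 16-bit images: constant background of
100 counts with Poisson shot noise, foci as 2-D Gaussians.  Early: count ~
Poisson(35) truncated ≥20, σ ~ N(1.2, 0.2) px, centers uniform in the
nucleus disk (radius 50 px).  Mid/late: count ~ Poisson(6) truncated ≥2,
σ ~ N(3.5, 0.5) px, clustered around ≤3 attractor points — a visual, not
mechanistic, emulation of late-replicating domains.  Peak amplitudes ~
N(400, 80) counts, floored at 50.

Detection standardizes the image by its median and robust noise scale
(1.4826·MAD) and runs multiscale Laplacian-of-Gaussian blob detection
(σ 0.8–6 px, 14 scales, overlap pruning 0.5) at a threshold of 5 noise-sd
units — far above the LoG response of pure background (zero detections on
100 blank images) and far below that of the dimmest rendered focus.
Because the threshold is noise-relative, detection and hence classification
are invariant to global intensity rescaling.  Centers are refined to
sub-pixel precision by intensity-weighted centroids ((row, col) order,
0-based).

Classification uses an explicit, configurable rule in place of the visual
criteria of a human scorer: early iff n ≥ 20 and median σ ≤ 2 px; mid/late
iff n ≤ 12 and median σ > 2 px; otherwise ambiguous (reported, excluded
from stage proportions).  The published criteria are qualitative, so these
cutoffs are placeholders operationalizing "numerous small" vs "limited
large"; they achieve >99% correct non-ambiguous calls with <1% ambiguity on
the synthetic defaults but must be recalibrated for real micrographs, where
optics, z-projection and chromatin texture violate the generator's
assumptions.  What passing synthetic tests shows is that the
detection+rule machinery is self-consistent — not that the defaults match
any particular microscope.

## Digital count normalization (`counts_norm`)

The pipeline follows the vendor-convention workflow for barcode-counting
assays: per-lane background threshold = mean + 2·SD (sample SD, n−1) of the
lane's negative probes, subtracted from endogenous and housekeeping counts
and clamped at 0; then per-lane scaling to equalize the geometric mean of
the positive spike-ins (factor = across-lane arithmetic mean of lane
geomeans / this lane's geomean; a geometric combine is an option); then the
same scaling computed on housekeeping probes of the already-scaled matrix.
Zeros are floored at 1 inside geometric means only, keeping control
geomeans finite without discarding lanes.

The synthetic generator draws counts as NB1 negative binomials,
var = μ·(1 + dispersion): digital counting is near-Poisson and
`dispersion` is the fractional extra-Poisson variance (default 0.1).
Negative probes are low-mean Poisson, unaffected by lane scale or
condition.  `example_codeset()` provides a realistic panel (15 endogenous
probes at 200–2000 counts, 8 negatives, a 6-step positive titration
ladder, 3 housekeeping probes).  Fold changes are ratios of mean normalized
counts with a percentile bootstrap over lanes when ≥3 lanes per condition;
with 4 lanes per condition, lane scales spread over 0.5–2× and dispersion
0.1, a true 2-fold change is recovered within ±10% in ~100% of seeds with
~1% bias of the log-fold estimate.

## Numerical and I/O conventions

Hours everywhere; fractions in [0, 1] internally (percentages only at
presentation).  Canonical tables are TSV (UTF-8, '.' decimal; CSV accepted
on read) with schema validation that reports offending line numbers.  JSON
reports carry a `schema_version`.  Logging goes to stderr, results to
files/stdout; every CLI run echoes its resolved configuration and seed.
All randomness flows through `numpy.random.Generator` seeded explicitly;
identical inputs and seeds give bit-identical outputs.

## Known limitations

* The uniform steady-state age distribution ignores the length bias of an
  expanding population; for slowly renewing stem compartments this is the
  standard and appropriate premise, but it understates curvature of LI(t)
  in rapidly growing tissues.
* No spatial model of the CMZ, no differentiation/exit, no apoptosis, no
  lineage trees; label dilution is ignored.
* The PLM plateau is assumed to approach 1 (cycling mitoses only); growth
  fractions < 1 do not affect PLM because quiescent cells never enter M.
* The foci generator does not emulate real-microscope optics (PSF
  anisotropy, z-projection, uneven illumination) — see above.
* Group comparisons are plain Welch t-tests; no multiple-testing machinery
  is included.
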