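# Methods

## The model

`crmacro` simulates the temporal macroecology of a microbial community as a
coarse-grained consumer-resource (CR) system. N consumers compete for M
effective resources through batch growth dynamics

    dX_i/dt =  X_i * sum_j R_ij Y_j
    dY_j/dt = -Y_j * sum_i R_ij X_i ,

where `X_i` is the abundance of consumer i, `Y_j` the amount of resource j,
and `R_ij` the consumption rate. Growth and consumption are coupled
one-to-one, so `sum(X) + sum(Y)` is exactly conserved within a batch. The
rates are not specified microscopically: each `R_ij` is drawn uniform on
[0, Rmax] and zeroed with probability `S` (the sparsity of resource
competition), so an entire community is parametrized by a handful of
ensemble-level numbers.

Community turnover between longitudinal samples is modeled as serial
dilution. Within one sampling interval the community grows to complete
resource depletion, is diluted by a factor `D` (default 200), and resources
are replenished, repeatedly, until the approximate ecological steady state:
every consumer's within-cycle growth ratio changes by less than
`steady_frac * D` (default 5%) between successive cycles. The first cycle
of each interval is seeded from an external reservoir with all N consumers
at equal abundance; relative abundances at that sampling time are read from
the final pre-dilution state.

Temporal variability enters only through the supplied resource amounts,
which follow a biased random walk about per-resource set points `ybar_j`
(uniform on [0, Ymax]):

    Y_j(T) = | Y_j(T-1) - k * (Y_j(T-1) - ybar_j) + sigma * ybar_j * xi_j(T) | ,

with standard-normal `xi`. `sigma` sets the fluctuation magnitude and `k`
the restoring force; `k = 1` is memoryless, `k -> 0` approaches an unbiased
random walk, and the absolute value keeps supplies non-negative.

## Parameters that matter

| parameter | meaning | default |
|---|---|---|
| `N` | consumers in the reservoir (from data: taxa ever detected) | — |
| `M` | coarse-grained resources | — |
| `S` | sparsity of the consumption matrix, in [0, 1] | — |
| `sigma` | supply-noise magnitude (fraction of the set point) | — |
| `k` | supply restoring force, in [0, 1] | — |
| `Rmax`, `Ymax` | uniform-distribution bounds; absolute scale drops out of relative abundances | 1 |
| `D` | dilution factor per growth cycle | 200 |
| `steady_frac` | steady-state threshold as a fraction of D | 0.05 |
| `detect` | presence threshold on relative abundance | 1e-4 |
| `T` | sampling times per series | 300 |
| `n_instances` | replicate random instances per parameter set | 20 |

The human-gut reference regime used throughout the benchmarks is
`(N, M, S, sigma, k) = (50, 30, 0.1, 0.2, 0.8)`.

## Statistics

All statistics are computed on the thresholded series (below-detection
entries count as absent/zero; an alternative masking mode exists but is not
the default, since the choice is a convention): richness; the Taylor
(variance-mean) exponent beta by OLS of log10 variance on log10 mean across
taxa; pooled log10 abundance changes Delta_l restricted to consecutive
presence pairs, their sample SD, and the Laplace maximum-likelihood scale
(mean absolute deviation from the median) for the fitted exponential shape;
per-taxon restoring slopes (OLS of Delta_l on log10 abundance, at least 10
pairs); completed residence/return runs (boundary-censored runs dropped —
the exponential cutoff in the interval fit is what accounts for finite
sampling, and keeping censored runs would double-count it) with discrete
maximum-likelihood fits of P(t) ~ t^nu exp(-t/tau); prevalence, time-mean
abundance and the rank curve; and Pearson correlations of taxon pairs over
at least 10 shared-presence times. Experimental tables read from TSV/CSV
pass through exactly the same code.

## Fitting and susceptibilities

The four free parameters (M, S, sigma, k) are estimated by exhaustive grid
scan: at every grid point, replicate instances are simulated and the four
core statistics (mean richness, beta, SD of abundance changes, mean
restoring slope) recorded. The model-data error is the sum of absolute
differences normalized by each statistic's SD across the whole scan table;
the best fit is the argmin row, with per-parameter bounds found by
piecewise-linear interpolation along each axis until the error exceeds the
best value plus 5% of the scan-mean error. The global susceptibility
C(z, w) is the endpoint change of statistic z along parameter w (an
endpoint difference, not a regression — the simplest reading consistent
with the +-3 normalized range), averaged over all combinations of the other
parameters and divided by the scan-wide SD of z; for the resource axis the
parameter is reported as N/M, so the endpoint order reverses.

One-dimensional refits (e.g. re-estimating k alone with the other
parameters fixed) need two departures from the plain recipe, both exposed
as options: the error normalization must come from a full multi-axis scan
(`norm_sds`), because along a single axis the unresponsive statistics have
scan SDs of pure replicate noise; and the axis scan supports common random
numbers (identical instance streams at every level), so row-to-row
differences reflect the parameter rather than which instances a row drew.
Scan rows are simulated at the data's series length, since the
restoring-slope estimator carries a finite-length bias that must cancel
between model rows and data. Note that |C|
depends on the grid design: on a 4-level-per-axis scan a perfectly linear
exclusive response yields |C| ~ 2.7 against ~3.5 on a 10-level axis,
because intermediate levels shrink the scan-wide SD. Scaled-down scans
therefore read systematically slightly lower than fine ones.

## Numerical choices

Batch integration uses an adaptive Dormand-Prince RK45 compiled with numba
(rtol 1e-8, atol 1e-10), terminated when every consumable resource falls
below 1e-6 of the largest initial amount, with the residual clamped to
zero. Two stiffness-type pathologies required care:

* Depleted resources keep decaying exponentially at the community
  consumption rate, which bounds the stable step size of an explicit method
  long after the resource has stopped mattering. Resources are clamped to
  exactly zero once below 1e-3 of the depletion tolerance (mass error
  ~1e-9, two orders below the 1e-6 conservation contract).
* Consumers diluted to astronomically small abundances would, at
  high-sparsity/high-M corners of the parameter scan, stretch batch
  durations by orders of magnitude while they regrow to deplete a private
  resource. Consumers below `extinct_frac = 1e-12` of the total supply are
  therefore treated as extinct for the rest of the sampling interval (the
  reservoir re-seeds them at the next sampling time). The floor sits eight
  decades below the detection threshold and leaves every statistic
  unchanged.

A scipy `solve_ivp` (LSODA) path with a terminal depletion event is kept as
an independent reference integrator; the test suite cross-checks the two
backends against each other and against the conservation law, and the fast
path falls back to LSODA in the rare event its step budget is exhausted.
Growth ratios of extinct consumers are defined as zero; a division floor of
1e-300 avoids 0/0. Resources consumable by no extant consumer ("inert",
which arise at high sparsity and in the disjoint-set no-competition mode)
are excluded from the depletion criterion and held constant; the low-level
batch API can instead raise on them.

The reservoir inoculum totals `sum(Y0) / (D - 1)`, the self-consistent
value for which the community-wide growth ratio per cycle is exactly D
(about log2(200) ~ 7.6 generations per cycle); its relative size is
exposed as `reservoir_scale`. The supply chain starts at the set points and
discards 50 burn-in steps before recording. In the saturating variant the
Monod constant `Ys` is shared by all resources and defaults to one third of
the mean set point (the per-resource alternative conflicts with a shared
constant; the mean-based reading honors both). The sign convention of the
CR-to-gLV conversion is `A_ij = -(1/Rmax) sum_k R_ik R_jk Y_k0`; the
magnitude is the supply-weighted niche overlap, and the negative sign makes
the replicator-form dynamics competitive. The gLV integration duration is
calibrated once per parameter set so the 10th-90th percentile spread of
log10 abundance matches the CR steady states of the same instance.
Trade-off capacities are resampled with replacement (keeps instances
i.i.d.). Power-law-with-cutoff fits use discrete MLE (robust at small
samples) from three Nelder-Mead starts; degenerate all-equal samples are
flagged with NaN.

## What the generator does and does not emulate

Synthetic series reproduce the statistical structure the model generates:
Taylor scaling with beta ~ 1.5 in the reference regime, exponential-shaped
pooled abundance changes, restoring slopes tracking k, power-law-with-
cutoff residence/return times, and broad pairwise correlations. They do not
contain sequencing noise, compositional sampling error, irregular sampling
gaps, true immigration/speciation, or host-specific effects — so passing
tests demonstrate internal consistency of the method, not that any real
community satisfies the model's assumptions.

Two emergent quantities deserve caution. The restoring-slope relation
-s_bar ~ k is tight for k >= 0.5 but steepens below (at k = 0.2 the slope
reads ~0.4): extra variance injected by the resource-to-abundance map
regresses log abundances toward their mean faster than the supply
autocorrelation alone. And the serial-dilution effort to reach the 5%
steady-state criterion measures ~7 growth cycles (~54 generations) per
sampling interval at the reference parameters: the dominant consumer's
overshoot after equal-abundance re-seeding decays roughly twofold per
cycle, so the count depends logarithmically on that overshoot and is
insensitive to the reservoir size (a 100-fold change moves it by less than
one cycle). The count is a convergence diagnostic, not an observable: no
abundance statistic depends on it (beta changes by <0.01 across
steady_frac in [0.01, 0.1] and D in [100, 400]).

## Benchmark problem sizes

The reproduction script and acceptance tests run, on one CPU: 20 instances
x 300 sampling times at the reference parameters (~3 min); no-competition
limits at 5 x 200 and 3 x 150 (~1.5 min); a 4-level-per-axis susceptibility
scan (256 grid points, 2 instances x 30 times each, ~10 min); and a
shuffle-refit with a 10-level k axis (~2 min). These sizes were chosen so
replicate noise stays well inside the tolerances being checked.

## Known limitations

No chemostat mode, mortality, cross-feeding, inhibition, or evolutionary
dynamics; supply noise is independent across resources; sampling times are
treated as equally spaced; no confidence intervals on beta beyond OLS
standard errors; fitting is restricted to the exhaustive grid (no gradient
or Bayesian refinement).
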