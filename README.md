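# crmacro

Coarse-grained consumer-resource modeling of microbiota time-series
macroecology.

Longitudinal 16S/metagenomic surveys show that species abundances in
microbiotas fluctuate with reproducible statistical signatures: the
temporal variance of a taxon scales as a power of its mean (Taylor's law,
exponent β), pooled log10 abundance changes look exponential, taxa revert
to host-specific mean abundances, and residence/return times follow power
laws with exponential cutoffs. `crmacro` is for ecologists and modelers who
want to ask whether effective resource competition can generate those
patterns — and to infer, from a relative-abundance table alone, the
macroscopic parameters of that competition.

The model: N consumers compete for M coarse-grained resources,

    dXᵢ/dt =  Xᵢ Σⱼ Rᵢⱼ Yⱼ ,       dYⱼ/dt = -Yⱼ Σᵢ Rᵢⱼ Xᵢ ,

with consumption rates Rᵢⱼ drawn uniform on [0, Rmax] and zeroed with
probability S. Communities are simulated under serial dilution (dilution
factor D = 200) to an approximate ecological steady state at each sampling
time, while initial resource amounts fluctuate between sampling times as a
biased random walk Y(T) = |Y(T-1) − k(Y(T-1) − Ȳ) + σ Ȳ ξ(T)|. Four free
ensemble parameters (M, S, σ, k) are fit to four summary statistics (mean
richness ᾱ, Taylor exponent β, SD of log10 abundance changes σ_Δl, mean
restoring slope s̄) by exhaustive grid scan; susceptibilities C(z, w)
quantify which parameter controls which statistic. Alternative models
(no-competition limits, saturating kinetics, metabolic trade-off,
CR-converted and random gLV, a non-interacting null) are included for
comparison.

## Worked example

```python
import numpy as np
from crmacro import EnsembleParams, simulate_timeseries
from crmacro.stats import summarize

params = EnsembleParams(N=50, M=30, S=0.1, sigma=0.2, k=0.8, T=300, seed=1)
series = simulate_timeseries(params)          # 50 taxa x 300 sampling times
stats = summarize(series)
print(f"mean richness     {stats.alpha_bar:.1f}")
print(f"Taylor exponent   {stats.beta:.2f}")
print(f"sigma_dl          {stats.sigma_dl:.2f}")
print(f"mean restoring s  {stats.s_bar:.2f}")
```

Output:

```
mean richness     22.6
Taylor exponent   1.47
sigma_dl          0.42
mean restoring s  -0.85
```

At these best-fit human-gut parameters a single random instance already
shows the experimental signatures: ~23 of 50 families detectable per day,
variance scaling with mean abundance with β ≈ 1.5, abundance changes of
typical magnitude 0.42 decades, and log abundances regressing ~85% of the
way to their mean per sampling interval (tracking the supply restoring
force k = 0.8).

The same machinery runs from the shell:

```bash
crmacro simulate --config params.yml --seed 1 --out series.tsv
crmacro stats series.tsv
crmacro scan --config params.yml --grid 'k=0.1,0.4,0.7,1.0' --out scan.tsv
crmacro fit series.tsv --scan scan.tsv
```

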