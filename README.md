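# posturesim

Simulation toolkit for a question that matters to anyone assessing working
postures from short measurements: **how badly do short, consecutive
sampling windows bias and blur full-shift posture percentile variables?**

In ergonomics and occupational epidemiology, an exposure amplitude
distribution — typically upper-arm elevation measured by inclinometer — is
summarised by its 10th percentile (neutral/"static" exposure), 50th
percentile (average), 90th percentile ("peak"), and the 10th–90th
percentile range (amplitude of posture variation). These are routinely
estimated from samples of 5–240 min rather than a whole shift. Percentiles,
unlike means and time proportions, are **not** unbiasedly estimable by
averaging over sub-periods: short windows systematically overestimate the
10th percentile and underestimate the 90th percentile and the range, and
the error grows with the true exposure level. `posturesim` reproduces and
quantifies this behaviour on synthetic full-shift data with realistic task
autocorrelation (long elevated periods with a customer alternating with
long near-neutral idle periods).

## Model and statistics

For a shift of duration *T* minutes and a window duration *w*, every
consecutive window at 1-min start intervals (windows #1..*T*−*w*+1) yields
an estimate *y* of the true full-shift value *M* of a posture variable.
Performance per shift, strategy and variable:

- bias *B* = *μ<sub>y</sub>* − *M*, with *μ<sub>y</sub>* the mean of all window estimates;
- precision *s<sub>y</sub>* = SD of the window estimates (n−1 denominator);
- dispersion limits *D*<sub>2.5</sub> = *P*<sub>2.5</sub> − *M* and
  *D*<sub>97.5</sub> = *P*<sub>97.5</sub> − *M*, where *P*<sub>2.5</sub>/*P*<sub>97.5</sub> are
  the empirical 2.5th/97.5th percentiles of the estimates — 95% of
  single-window estimates fall in [*M* + *D*<sub>2.5</sub>, *M* + *D*<sub>97.5</sub>].

Across shifts these are compared as empirical cumulative distribution
curves, aggregated into a median/mean bias-correction table, and related to
the true exposure via Spearman rank correlations of *M* vs *B* and *M* vs
*s<sub>y</sub>* with Fisher-z 95% CIs (arctanh(ρ) ± z<sub>0.975</sub>/√(n−3)).

Shifts are simulated as a two-state alternating-renewal process
(exponential dwell times, Gaussian within-state angles clamped to
[0°, 180°]) with between-subject and between-shift exposure-level
variation; an iid generator provides the control obeying the
√-duration precision law. All quantiles use linear interpolation at rank
1 + q(n−1). See `docs/methods.md` for details and assumptions.

## Worked example

`python examples/02_window_bias.py` slides 5-min and 120-min windows
across one simulated 480-min shift:

```
5-min windows:
variable           M    mu_y       B    s_y    D2.5   D97.5
p10              6.8    18.2   +11.4   12.9    -5.6   +35.1
p50             29.1    30.1    +1.0   15.2   -21.4   +28.4
p90             57.8    43.8   -14.0   17.2   -44.4   +10.5
range_10_90     51.1    25.6   -25.4   12.0   -44.3    -1.5

120-min windows:
variable           M    mu_y       B    s_y    D2.5   D97.5
p10              6.8     7.2    +0.4    2.1    -3.1    +4.3
p50             29.1    28.8    -0.3    5.4    -8.4   +10.3
p90             57.8    57.2    -0.6    1.7    -4.3    +1.8
range_10_90     51.1    50.0    -1.0    1.7    -4.7    +2.3
```

With 5-min windows the 10th percentile is overestimated by 11° on average
and the percentile range underestimated by 25° — half of all single 5-min
estimates of the range land more than 25° below the truth. At 120 min the
bias nearly vanishes. The other examples build the 73-shift population
(`01`), demonstrate the broken √-duration precision law under
autocorrelation (`03`), compute the exposure-error correlation table with
CIs (`04`), and run the full experiment bundle (`05`).

The same study is scriptable from the shell:

```bash
posturesim run --seed 1 --out results/study          # full chain
posturesim simulate --seed 1 --out population.csv    # population only
posturesim analyze --recordings population.csv --out results/study
posturesim correlate --performance results/study/performance.csv --out corr.csv
```

Outputs are plain CSV (performance table; ECDF curves per statistic;
correlation table; median-bias table) plus a run log with config hash and
seed; reruns with the same config are byte-identical.

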