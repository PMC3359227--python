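# Methods

## The estimation problem

A full-shift posture recording is a time series of upper-arm elevation
angles (degrees above gravity-vertical, 0° = arm hanging) sampled at a
fixed rate over one work shift. The exposure variables of interest are the
10th, 50th and 90th percentiles of the shift's amplitude distribution, the
10th–90th percentile range, the mean angle, and the proportions of time in
named angle sectors (default partition: neutral [0°, 20°), intermediate
[20°, 60°), elevated [60°, 180°]).

A *sampling strategy* is a window duration *w* (minutes) plus a step
between candidate start minutes (default 1). Every whole window inside the
shift — minutes #s..s+w−1 for s = 1, 1+step, … — yields one estimate of
each variable; a *T*-minute shift with step 1 yields *T*−*w*+1 windows.
Windows are aligned to whole-minute boundaries; partial trailing windows
are never formed. Minute indexing is 1-based and inclusive externally; the
internal sample mapping (minute *m* ↔ samples (m−1)·rate … m·rate−1) is
tested explicitly.

Per shift, strategy and variable we compute bias B = μ_y − M, precision
s_y (SD of window estimates, n−1 denominator), and dispersion limits
D2.5 = P2.5 − M and D97.5 = P97.5 − M from the empirical 2.5th/97.5th
percentiles of the estimates. For a single window (w = T) the spread
statistics are reported as NaN rather than 0: the spread of one estimate
is undefined. Across shifts, per-shift values are reported as ECDF curves
(step heights i/n), a median/mean bias table per (duration, variable), and
Spearman correlations of M vs B and M vs s_y.

Why percentile estimates from short windows are biased: a window's
percentile is a monotone function of its local amplitude distribution, and
with strong task autocorrelation a short window often falls entirely inside
one regime. Windows inside the elevated regime give a high "10th
percentile"; windows inside the idle regime give a low "90th percentile".
Averaging over window positions therefore pulls the 10th percentile up and
the 90th percentile (and the range) down — an inward bias towards the
centre of the distribution that no amount of averaging across windows
removes. Time-proportion (sector) metrics are linear in the sample
indicator and hence exactly unbiased under tiling windows, which the test
suite verifies to machine precision.

## Quantile convention

All quantiles — posture percentiles, dispersion-limit percentiles, ECDF
medians — use linear interpolation between order statistics at rank
1 + q(n−1) (numpy's default). At full-shift n the convention is
immaterial; at 5-min windows (n = 5·rate samples) it is pinned by
hand-computed fixtures so any future change is caught. Ties in the
Spearman ranks get average ranks; no tie correction is applied to the
denominator (shifts have continuous-valued summaries, so ties are
improbable). Fisher CIs use arctanh(ρ) ± z_{1−α/2}/√(n−3), the standard
large-sample interval; at the study's n = 73 it reproduces published
interval endpoints computed from 2-decimal ρ values to within one unit in
the last printed decimal (the residual being the rounding of ρ itself).

## Synthetic shift generator

The generator is a two-state alternating-renewal (semi-Markov) process:

- **Regimes.** Elevated (customer work) and neutral (idle) states
  alternate; dwell times are exponential by default (lognormal with
  configurable CV optionally), with means in minutes
  (`elevated_dwell_mean`, `neutral_dwell_mean`, default 12/12 — dwells
  long relative to a 5-min window, short relative to a shift). Dwells are
  rounded to whole samples, minimum 1. The start state is drawn from the
  stationary occupancy d_e/(d_e+d_n), and long-run elevated occupancy
  converges to that ratio (tested at 10,000 min, ±0.02).
- **Angles.** Within a regime, angles are iid Gaussian with per-state mean
  and SD (defaults 45°±15° elevated, 12°±8° neutral), clamped — not
  resampled — to [0°, 180°]; clamping preserves the dwell structure and
  the physical bounds. These defaults put full-shift p10/p50/p90 near
  5°/25°/60°, the single-digit/low-20s/mid-50s pattern typical of
  customer-service work.
- **Exposure heterogeneity.** Each shift carries an exposure offset in
  degrees (subject offset + shift offset, drawn from centred normals with
  SDs 6°/3° by default). The offset is applied as a proportional
  rescaling of both state means and SDs by 1 + offset/μ₀, where μ₀ is
  the dwell-weighted baseline mean angle, so the shift mean moves by
  approximately the offset (the between-subject SD is recoverable from
  per-subject mean angles, which the tests check). A scale family — rather
  than an additive shift — is the deliberate choice here: angles are
  bounded below at 0°, and a high-exposure shift plausibly has *both*
  higher angles and a wider elevated/neutral separation. Under scaling,
  bias and s_y grow with the true exposure level, producing the
  characteristic correlation sign pattern (M-vs-B positive for p10,
  negative for p90 and the range; M-vs-s_y positive throughout); a purely
  additive offset would leave the separation, and hence the bias, the same
  on every shift.
- **Population layout.** The default campaign is 73 shifts from 20
  subjects (14×4 + 5×3 + 1×2) with durations uniform on 300–595 min,
  mirroring a full-week inclinometry campaign after exclusion of shifts
  under 300 min. Reproducibility: entity k (0 = population-level draws,
  k = shift slot + 1) is seeded from `SeedSequence((master_seed, k))`, so
  any shift can be regenerated in isolation and populations are
  bit-reproducible per seed.

The iid generator (uniform on an interval, or normal truncated to
[0°, 180°] by rejection) produces the control series for which classical
theory holds: s_y of the mean angle scales as 1/√w, so
s_y(10 min)/s_y(40 min) ≈ 2 (slightly above 2 in practice because sliding
windows within a finite shift are negatively correlated, deflating s_y
more at longer w). For the regime-switching process the ratio is
materially below 2 (~1.65 at the defaults): with correlation time ~6 min,
quadrupling the window adds partly redundant samples.

### What the generator does not emulate

No sensor noise, drift or calibration error; no within-regime
nonstationarity (fatigue, time-of-day trends); no breaks or scheduled
structure; no multi-axis postures; dwell distributions are memoryless by
default whereas real customer-handling times are not. Passing tests
demonstrate that the *statistical mechanism* — inward percentile bias,
exposure-dependent error, sub-√w precision gain — follows from regime
autocorrelation and exposure scaling alone; they do not calibrate the
magnitude of bias expected in any specific real occupation, for which the
dwell/amplitude parameters would need fitting to field recordings.

## Numerical and design choices

- s_y uses the n−1 denominator (pinned by a hand-computed toy fixture:
  estimates {0, 30, 60, 30, 0} ⇒ s_y = √630).
- Sector membership is half-open [lower, upper); 180° is included in a
  sector whose upper bound is 180 so partitions tile the physical range
  exactly. Partition proportions sum to 1 exactly.
- Shifts shorter than a window are skipped with a logged warning under the
  default policy; `strict` raises instead and additionally requires the
  duration filter to cover the longest window.
- Degenerate inputs error loudly: empty sequences, q outside [0, 1],
  windows longer than the shift, constant inputs to rank correlation,
  |ρ| = 1 in the Fisher interval.
- Experiment outputs are plain CSV; figures (`posturesim.plots`) are a
  convenience layer over the ECDF CSVs, never a data contract. The run log
  embeds a config hash, seed and version so bundles are self-describing,
  and contains no timestamps so reruns are byte-identical.

## Problem sizes

The shipped study sizes are those of the emulated campaign: 73 shifts of
300–595 min at 1 sample/min, seven window durations, four variables
(2,044 performance records, 56 correlation cells; ~2 s on one core).
Property tests that need many replicates use 100 iid/regime shifts of 480
min (precision-law ratios) or 500 replicates of n = 30 pairs (CI
coverage). The sample rate is configurable; all reported statistics are
rate-insensitive given whole-minute windows, which is why 1/min is the
default.

## Known limitations

- The bias-correction table transfers only to settings with a similar
  regime structure and exposure level; the exposure-dependence of bias
  (the nonzero M-vs-B correlations) is precisely the reason a single
  subtraction is approximate.
- Dispersed (non-consecutive) allocation of the same total sampling time
  is out of scope; only consecutive windows are modelled.
- Between/within-subject variance decomposition of the true values is not
  estimated; offsets are generative knobs, not fitted components.
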