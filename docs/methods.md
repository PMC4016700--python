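# Methods

This note records the statistical model behind each component, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic data do and do not establish.

## The IQRray statistic

Given one array's probe intensities, the score is the interquartile
range of per-probe-set average ranks (see the README for the formula).
Conventions fixed here:

- **Ranking**: ascending, midranks for ties (`scipy.stats.rankdata`,
  `method="average"`), so the rank sum is exactly `N(N+1)/2` and the
  score is invariant under strictly increasing intensity transforms.
- **Probe scope**: the default `all_probes` ranks every probe on the
  array — PM, MM and probes outside any probe set — because the
  statistic is defined on all probe intensities. MM probes contribute
  to their probe set's average; unassigned probes occupy rank mass but
  contribute to no average. `pm_only` restricts ranking to PM probes
  (N counts only ranked probes); `assigned_only` additionally drops
  unassigned probes from the rank mass. Both alternative scopes exist
  because public platform descriptions are ambiguous about MM
  membership; the quality report shows `all_probes` and `pm_only` side
  by side.
- **Quantiles**: linear interpolation between order statistics —
  quantile `q` of `n` sorted values sits at fractional position
  `1 + (n−1)q`. This is numpy's default and keeps scores comparable
  across runs; probe sets are unweighted in the IQR regardless of size.
- **Null scale**: the average rank of `k` probes drawn without
  replacement from `{1..N}` has variance `(N+1)(N−k)/(12k)`; a normal
  approximation gives `IQR ≈ 1.3490 · sd`. The acceptance suite checks
  the implemented score against both a direct Monte-Carlo null and this
  closed form at `N = 10^5, k = 20` (50 score replicates vs. a
  10,000-replicate Monte-Carlo sample).
- For `G` equal-size sets with perfectly consistent (block-consecutive)
  ranks, the averages form an arithmetic sequence with spacing `k` and
  the IQR is exactly `k(G−1)/2`; with linear interpolation this holds
  in exact floating point, and the tests assert equality, not
  approximation.

## Single-array QC metrics

All metrics run on raw cell intensities — no background correction,
saturation handling or ideal-mismatch adjustment anywhere — because
they are meant to characterize the raw array.

- **PM/MM paired t**: `t = mean(d) / (sd(d)/√n)` over all PM/MM pairs,
  `d = PM − MM`, `sd` with `n−1` denominator. Raw scale by default
  (log2 behind a flag; the choice is a convention, not a model claim).
  Zero variance with nonzero mean reports signed infinity as an
  overflow sentinel. Direction: ascending.
- **Average background**: mean of the `floor(0.02 N)` lowest cells
  (minimum 1 cell), over *all* cells whether or not they belong to a
  probe set. Descending.
- **Scaling factor**: `target / trimmed_mean`, trimming
  `floor(0.02 N)` cells at each end. The target constant defaults to
  500, the value GCOS-era pipelines commonly scaled to; it cancels in
  rank-based comparisons. Descending.
- **RNA degradation slope**: probes are ordered 5′→3′ within each
  probe set by `position_index`; only probe sets whose PM count equals
  the modal PM count participate, so each position averages over the
  same sets. The metric is the OLS slope of mean PM intensity against
  position ordinal. Default is the plain slope on raw means; an
  optional standardization (shift so position 0 is 0, scale by the
  mean standard error of the position means) mirrors the convention of
  classic degradation plots. The direction registry ships this metric
  as ascending. The honest caveat: with 3′-biased labeling chemistry
  every sample shows a positive slope and degradation *steepens* it,
  so the informative failure mode in practice is loss of the coherent
  positional trend rather than a small slope per se. The benchmark
  honors whatever direction a report declares, so users can re-register
  it for their chemistry.
- **3′/5′ control ratios**: mean PM intensity of the 3′ control probe
  set over the 5′ one, per registered control pair (actin/GAPDH style).
  Descending (1 ≈ intact RNA).
- **Percent present**: the MAS5 detection call in reduced form. Per
  probe set, discrimination scores `R_i = (PM_i − MM_i)/(PM_i + MM_i)`
  (pairs with `PM + MM = 0` skipped) are tested one-sided against
  `tau = 0.015` with a Wilcoxon signed-rank test; Present iff
  `p < alpha1 = 0.04`; the metric is 100 × Present / tested.
  The marginal-call band (alpha2) is omitted: only the Present
  percentage is used as a quality score. Exact signed-rank tails come
  from a dynamic program over the rank-sum generating function for
  `n ≤ 25` without ties; otherwise a normal approximation with
  continuity and tie corrections (cross-checked against
  `scipy.stats.wilcoxon` in the tests). Zeros are dropped, the standard
  signed-rank convention. Ascending.
  Note the discrimination score is ratio-based on the raw scale, so
  percent present is *not* invariant under nonlinear monotone
  transforms of the intensities — unlike IQRray and the HOC score.
  The tests assert this scale dependence explicitly.

## Expression summarization

Gene profiles are deliberately primitive, because the conservation
score downstream is rank-based: per probe set, the arithmetic mean of
raw PM intensities; probe sets matching more than one gene dropped;
surviving probe sets of the same gene averaged with no further
independence screening (none is definable from the inputs); genes kept
only if they belong to a 1:1 ortholog pair. Gene maps and ortholog
tables are plain TSV inputs — no external database is bundled or
queried.

## The HOC benchmark

- **HOC score**: Spearman correlation of a query profile against every
  reference profile of the homologous organ in the other species, over
  ortholog pairs present in both profiles; the maximum is kept, so
  biological variability among references (age, sex, sampling) does
  not depress the score. Pairings with fewer than 3 common genes are
  skipped with a warning.
- **Quantile transform**: HOC scores are converted to empirical
  quantile ranks `(midrank − 0.5)/n` within each organ, so organs with
  different baseline conservation pool fairly. A coarse 4-bin quartile
  mode exists behind a flag; the continuous version is the default
  because selection cutoffs below 25% need resolution.
- **Metric correlations**: each metric is sign-adjusted (descending
  metrics multiplied by −1) and Spearman-correlated with the pooled
  HOC quantiles. Constant metrics are reported as missing rather than
  NaN-propagated.
- **Selection efficiency** at cutoff `c`: take the worst
  `floor(c·n)` arrays by the sign-adjusted metric (boundary ties broken
  lexicographically by array id, for determinism) and report the
  fraction with HOC quantile `< c`. Note a structural ceiling: the
  selection is global but quantiles are per-organ, so even a perfect
  metric scores below 1 whenever the truly worst arrays are unevenly
  distributed across organs. With 120 arrays and a 5% cutoff the
  granularity is 1/6 per array.
- **Thresholds**: collection-level cutoffs are empirical quantiles of
  the sign-adjusted score after capping each experiment's contribution
  at 10 arrays (uniform subsample, seeded; the seed is recorded in the
  threshold table). An array fails the screen when it falls strictly
  below the cutoff for any listed metric, so a constant collection
  flags nothing.

## The synthetic generators

**Arrays** (`simulate_array`): probe log-intensities are sorted
Gaussian draws (`log_mean = 6.0`, `log_sd = 1.2`, i.e. a log-normal
with median ≈ 400 and a realistic 4-decade dynamic range) dealt to
probe sets in consecutive blocks — the perfectly consistent extreme.
`corruption ∈ [0, 1]` globally reshuffles that fraction of probe
values (PM and MM alike); corruption 1 reproduces the random-rank
null exactly. This single dial stands in for every noise source that
mixes ranks between probe sets. MM partners are the PM value
attenuated toward a background floor
(`bg + (PM − bg)·e^(−pm_mm_shift)`, background at `log_mean − 2
log_sd`) with log-normal noise (`mm_noise_sd = 0.1`); degradation
subtracts up to `degradation_strength` log-units at the 5′ end,
linearly in position. What this does *not* model: spatial artifacts
(bubbles, scratches, gradients), probe-sequence GC affinity, and
saturation. Tests passing on these arrays show the statistics respond
to rank mixing, PM/MM separation and positional attenuation as
designed — not that real arrays fail in exactly these ways.

**Collections** (`simulate_two_species_collection`): per organ, a
latent gene signature `mu_o ~ N(0, 1)` shared between species through
the ortholog map (default 2000 genes, 80% with 1:1 orthologs, 3
organs, 40 arrays each, 4 references per organ with gene noise
sd 0.25). Each species-A array has a quality `q ∈ [0, 1]` driving two
channels at once: gene-level noise with sd log-interpolated across
`noise_sd_range = (0.25, 2.5)`, and probe-level corruption `1 − q`.
Probe intensities are `exp(6 + gene value + fixed probe affinity
N(0, 0.5) + N(0, 0.15))` with MM partners as above (MM noise grows
with corruption). Species-A profiles are produced by the package's own
summarization pipeline, so corruption propagates into HOC exactly as
it would for real data. The `noise_sd_range` is calibrated so that the
quality range maps to HOC roughly spanning 0.1–0.95. The default
quality law is a mixture — about 90% good arrays (Beta(6, 2)) and a
10% tail of degraded ones (0.4 · Beta(1.5, 8)) — mirroring what organ
compendia actually look like: mostly usable arrays plus a minority of
clear failures. This matters for interpreting selection efficiency:
with a uniform quality gradient the worst-array ranking is
noise-dominated at the tail and no metric can score well.

Problem sizes used in the automated checks (chosen as the smallest
sizes at which the asymptotic claims are visible): null comparison at
`N = 10^5` probes, 5000 sets of 20, 50 score replicates against a
10,000-replicate Monte-Carlo sample; monotonicity at 200 sets × 11
probes, 20 replicates per corruption level; the benchmark at the
default collection (120 arrays, 2000 genes); 200 permutations for the
random-metric baseline.

## File formats

- Layout TSV: `probe_id, x, y, probe_set_id, is_pm, partner_probe_id,
  position_index` (empty = null); control pairs in a companion
  YAML/TSV (`label, probe_set_3, probe_set_5`). Probes are addressed
  by 0-based `(x, y)` matching CEL cell indexing; `probe_id` is a
  convenience alias. Converters from vendor CDF files are out of
  scope — the methods need only membership, pairing and position.
- Intensity TSV: `probe_id` (or `x, y`) + `intensity`. Intensity 0 is
  accepted (it ranks lowest); negative values are rejected.
- CEL: version-4 binary only (little-endian, magic 64; cells addressed
  `y·n_cols + x`; the per-cell MEAN is the intensity, stored float32 —
  the fixture writer returns the float32-cast array so round-trips are
  bit-exact). ASCII v3 and AGCC/Calvin dialects are not parsed.
- All TSV output: '.' decimals, fixed column order, floats at 6
  significant digits, so identical config + seed gives byte-identical
  files.

## Scope notes and limitations

- RLE, NUSE and GNUSE are not computed here: they require multi-array
  model fits (RMA/PLM) or frozen parameter vectors and existing
  packages already provide them. The benchmark accepts externally
  computed scores through the report tables, so they remain
  comparable.
- MAS5 expression summarization, spatial pseudo-images and platform
  auto-detection are out of scope.
- The benchmark's absolute numbers depend on the synthetic generator's
  noise model; the package's claims are the *relative* ones (ordering
  with corruption, agreement with the conservation reference, null
  calibration), which are asserted by the tests.
- All randomness flows from explicit integer seeds; no global
  generator state is used anywhere.
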