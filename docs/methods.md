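# Methods

## Model

All simulations are discrete-generation Wright–Fisher: a diploid population
of `N(t)` individuals carries `2N(t)` gene copies, and the copies of
generation `t` are drawn from the post-selection allele frequency of
generation `t − 1`.  Selection is genic (no dominance): with coefficient `s`
the genotypes carrying 0, 1, 2 copies of the tracked allele have fitnesses
`1`, `1 + s/2`, `1 + s`, giving the deterministic update

    x' = x (1 + s(1 + x)/2) / (1 + s x).

There is no mutation, so frequencies 0 and 1 are absorbing.  The focal locus
(index 0) may be selected; reference loci are neutral by default but accept
their own coefficients (used to study how selection at references biases the
test).

### Population-size histories

`DemographicModel` supports constant, exponential (geometric interpolation
between endpoints, rounded to integers per generation) and piecewise-
constant sizes.  Two conventions needed fixing where the sources of this
design were ambiguous:

- **Which size governs a draw.**  The binomial (or pseudo-sampling) draw
  that forms generation `t` uses `N(t)`, the size of the newly formed
  generation — its count of gene copies is what bounds the sampling
  variance of the increment over `(t − 1, t]`.
- **Epoch boundaries.**  A piecewise segment declared on fractions
  `(f0, f1)` of the duration holds for generations `f0·T < t ≤ f1·T` (the
  first segment is closed at 0).  The left-open convention ties each
  generation's drift to the epoch that produced it, so an epoch change
  coinciding with a sampling time does not leak drift into the preceding
  sampling interval.  This matters: with a closed-left bottleneck starting
  exactly at a sampling time, the first post-boundary draw contaminates the
  earlier interval and measurably distorts power in the severe-bottleneck
  scenario (about five percentage points at `L = 2`).

Seven canonical scenarios are built in: constant 10⁴; exponential
10⁴ → 10⁵; moderate bottleneck 5×10⁴/10⁴/5×10⁴ on the middle-late quarter
`(0.5 T, 0.75 T]`; exponential 10⁴ → 10⁸; severe bottleneck 10⁶/10⁴/10⁶;
and two down-scaled validation variants, constant 100 and the severe
bottleneck divided by 200 (5000/50/5000).  The down-scaled variants exist so
that exact binomial reproduction — and the individual-based linked-loci
simulator — are affordable at 10⁴ replicates.

### Pseudo-sampling

Exact binomial reproduction at `N = 10⁶`–10⁸ is wasteful; the pseudo-
sampling engine replaces the binomial draw with

- a **normal** draw, mean `x'` and variance `x'(1 − x')/(2N)`, clipped to
  `[0, 1]`, when the expected minor-allele count `2N·min(x', 1 − x')`
  exceeds 5 copies;
- a **Poisson** draw of the minor-allele count (mean `2N·min(x', 1 − x')`,
  capped at `2N`, converted back to a frequency of the tracked allele)
  otherwise.

The 5-copy threshold is where the normal approximation to the binomial
becomes unreliable; the Poisson branch preserves the absorption probability
(`P(loss) ≈ e^{−λ}`) that a clipped normal would overstate.  A normal draw
clipped to exactly 0 or 1 is treated as absorbed — the probability mass
involved is negligible because near-boundary states are already routed to
the Poisson branch.  Moment agreement with the exact binomial engine at
`N ≤ 500` and distributional agreement of downstream rejection rates are
asserted in the test suite.

### Linked loci

The individual-based simulator keeps `N(t)` diploids as haplotype pairs
over `R + 1` ordered loci, initialised in linkage equilibrium (independent
per-locus Bernoulli draws).  Each offspring picks two parents with
probability proportional to fitness (multiplicative across loci); each
parent transmits a gamete with crossovers between adjacent loci occurring
independently with probability `r ∈ [0, 0.5]`.  `r = 0.5` reproduces the
independent-loci engine distributionally (asserted by a two-sample test).
A guard refuses census sizes above 10⁵, where enumerating individuals stops
being sensible; free recombination should be used instead.  Multiplicative
fitness composition across loci is the standard genic choice; nothing in
the calibration experiments is sensitive to it because at most one locus is
selected there.

## The tests

`fit_test` computes `t_FIT = Ȳ/√(S²/L)` with the unbiased (`L − 1`)
variance estimator — required for the exact Student-*t*(L − 1) null — and a
two-sided p-value.  Two-sided testing is used throughout: it is the only
symmetric choice that yields the nominal level under neutrality for both
tests without an a-priori direction of selection.

`fitr_test` runs the pipeline: standardized increments → removal of
degenerate references → `t_FITR` → p-value.

- **Reference removal** is all-or-nothing per locus: a reference whose
  frequency is exactly 0 or 1 at *any* sampled time `t_0 … t_L` is removed,
  and the surviving count `R_used` sets the degrees of freedom.  (Absorption
  makes this equivalent to "absorbed by the end of the observation window",
  which is why the mean surviving count depends on `T` but not on `L`.)  A
  focal locus fixed anywhere before `t_{L−1}` is a distinct degenerate
  error — the drivers count such replicates separately rather than
  truncating the series.
- **The p-value** for `L = 1` is the analytic two-sided Student-*t*(R_used)
  probability; for `L ≥ 2` it is the add-one Monte-Carlo estimator
  `(1 + #{|null| ≥ |t_obs|})/(M + 1)` against `M = 10⁵` draws of
  `(1/√L) Σ t_i` with `t_i ~ t(R_used)`.  The `1/√L` standardization is
  cosmetic (the null uses the identical constant) but makes the statistic
  asymptotically standard normal in `R`.  Null samples are cached in memory
  keyed by `(L, R, M, seed)`, mirroring how the calibration drivers reuse
  one null across 10⁴ replicates of a design.

## Monte-Carlo drivers

`rejection_rate` simulates all replicates and loci of a design in lock-step
(one vectorised draw per generation), applies the designated test in batch,
and reports the rejection fraction at the nominal level with its binomial
standard error.  Degenerate replicates are excluded from the denominator
and reported; per-cell seeds are derived from the master seed by hashing
the cell parameters, so any cell is reproducible in isolation.  The
built-in grids reproduce the calibration study's four tables; replicate
counts default to 10⁴, which resolves a 5% level to ±0.22 percentage points
(1 SE) and keeps every cell from sub-second to a few seconds on one CPU —
the 1000-generation, 11-locus power cells are the slowest at roughly five
seconds.  One printed design was internally inconsistent (a duration of 20
generations with five intervals of five); it is implemented as five
intervals of four generations, which preserves the stated duration and
interval count — power is insensitive to the difference at these scales.

## What the simulations do and do not emulate

The generators produce exactly the idealised data the tests assume:
diallelic loci, known population frequencies (optionally degraded by
binomial sampling of `n` diploids per time point), independent reference
loci (optionally linked via the individual-based engine), no mutation, and
selection constant in time.  Real data add pooled-sequencing read noise,
mispolarised alleles, linked selection and time-varying selection, none of
which are modelled; passing calibration here demonstrates correctness of
the statistics under their own assumptions, not robustness to those
violations.  Known limitations of the tests themselves, visible in the
calibration output: the FITR's level inflates by 1–2 percentage points when
references start at low frequency (removal of absorbed references biases
the surviving drift estimate downward), so references with moderate
starting frequencies (≳ 10%) should be preferred; and the FIT — included
as the single-locus baseline — is severely conservative under rapid growth
or severe bottlenecks.

Estimation of the selection coefficient, likelihood-ratio machinery,
mutation, dominance, and multiple-testing across focal loci are out of
scope.
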