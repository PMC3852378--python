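# fitr — frequency increment tests for time-series allele frequencies

Experimental evolution, ancient DNA and evolve-and-resequence studies
produce *time series* of allele frequencies: the frequency of an allele at a
diallelic locus observed at generations `t_0 = 0 < t_1 < … < t_L`.  The
question is whether the trajectory shows natural selection or is compatible
with genetic drift alone.  Drift-only inference is confounded by the
population size `N(t)`: a bottleneck or a growth phase changes how far a
neutral frequency wanders, and a test calibrated for a constant size becomes
badly conservative (and therefore weak) when the size fluctuates.

This package implements two neutrality tests and the Wright–Fisher
simulation machinery used to calibrate them.

**FIT** (frequency increment test, single locus).  The standardized
increments

    Y_i = (x_i − x_{i−1}) / √(2 x_{i−1}(1 − x_{i−1}) (t_i − t_{i−1}))

are approximately i.i.d. N(0, 1/(2N)) under neutrality in a constant-size
Wright–Fisher population, so `t_FIT = Ȳ / √(S²/L)` follows a Student-*t*
distribution with `L − 1` degrees of freedom whatever `N` is — but only if
every interval shares the same variance.

**FITR** (frequency increment test with reference loci).  With `R`
independent, neutral *reference* loci genotyped at the same times, the
per-interval drift scale can be cancelled instead of pooled.  Writing
`Δx_{h,i} = (x_{h,i} − x_{h,i−1}) / √(x_{h,i−1}(1 − x_{h,i−1}))`, the
statistic

    t^(i) = Δx_{0,i} / √( (1/R) Σ_h Δx_{h,i}² )

is Student-*t* with `R` degrees of freedom under neutrality of the focal
locus *regardless of `N_i` and Δt_i* (both cancel between numerator and
denominator), and

    t_FITR = (1/√L) Σ_i t^(i)

is referred to an empirical null built by summing `L` independent
Student-*t*(R) draws.  Reference loci whose frequency reaches 0 or 1 at any
sampled time are removed before the computation and the degrees of freedom
adjusted.  The result: nominal type-I error under constant size, growth and
bottleneck scenarios alike, and substantially more power than the FIT when
`N(t)` fluctuates.

## Worked example

Simulate 11 loci (1 focal under genic selection `s₀ = 0.05`, 10 neutral
references, all starting at frequency 0.5) through a severe bottleneck
(5000 → 50 → 5000 diploids over 10 generations), sampled every 2
generations, then test the focal locus:

```sh
fitr simulate --model model5p --T 10 --samples 0,2,4,6,8,10 \
     --R 10 --s0 0.05 --method pseudo --seed 11 --out example.tsv
fitr test example.tsv --seed 0
```

```
FITR: statistic=2.63246  p=0.02054  references_used=10
test=FITR
statistic=2.6324642
p_value=0.0205397946
references_used=10
removed_loci=none
reject_at_alpha=yes
```

The focal increments are consistently positive and about 2.6× larger than
the drift scale estimated from the 10 references, so the FITR rejects
neutrality at the 5% level (two-sided empirical p = 0.021).  The
single-locus FIT on the same trajectory reports `p = 0.75`: the bottleneck
inflates the increment variance it pools across intervals, and the signal is
lost — exactly the failure mode the reference loci repair.

Larger calibration experiments (type-I error and power tables over five
demographic scenarios) are available from the library
(`fitr.experiments.run_table`) and the CLI:

```sh
fitr table --id 2 --reps 10000 --seed 42 --out table2.tsv
fitr power --model model5 --T 1000 --L 10 --R 10 --s 0:0.001:0.0002 \
     --reps 10000 --seed 42 --out power.tsv
```

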