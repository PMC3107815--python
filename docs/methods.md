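# Methods

## Scope and data model

`clamarray` analyses one-color oligo arrays in which a transcript may be
represented by a single sense probe, by a sense/antisense probe pair
(when strand orientation was unknown at design time), and/or by a
duplicated probe printed twice on the array. Signals are nonnegative
linear-scale fluorescences with a per-cell boolean detection flag
("found", i.e. signal above local background) exported by the scanner
software; the flag is taken as given and never recomputed. Negative
background-subtracted signals are clamped to zero on ingest (and
counted), because downstream ratios require nonnegative input.

## Normalization

*Quantile* normalization forces every array to share the mean
order-statistic distribution: the value at rank r becomes the mean over
arrays of their rank-r order statistics; tied input values receive the
mean of the reference values across their rank span, which makes the
transform deterministic and idempotent. *Cyclic loess* fits, for each
array pair, a lowess trend of the log2 ratio (M) against the mean log2
intensity (A) on log2(x+1) — the +1 offset makes zero signals safe — and
removes half the fitted trend from each member; the cycle repeats
`iterations` times (defaults span 0.3, 3 iterations, both exposed).
Between the two methods, the one yielding the smaller summed spike-in
coefficient of variation across arrays is selected, quantile on ties.
Negative-control features are excluded from normalization; spike-ins are
kept because they are the selection criterion.

Quantile normalization assumes most probes are unchanged between groups
and that ranks are comparable across arrays. On small arrays (a few
thousand probes) with a sizable fraction of strongly differential probes,
the sparse upper tail of the reference distribution makes normalized
values of high-intensity probes sensitive to small rank shifts; spike-in
selection will then prefer cyclic loess. This is a property of the
normalization, not of the downstream tests, but it means FDR calibration
measurements of the testing engine are performed on data already on a
common scale (see below).

## SAM differential expression

All test statistics are computed on log2(x+1) of normalized signals; fold
changes are reported on the linear scale as 2^|mean log2 difference| with
a direction label. Probes undetected in at least half the arrays of
either group are excluded from testing and tallied.

The relative difference for probe i is
d_i = (x̄₂ᵢ − x̄₁ᵢ) / (sᵢ + s₀), with sᵢ the pooled standard error
√[(1/n₁ + 1/n₂) · SSᵢ / (n₁ + n₂ − 2)]. The fudge factor s₀ is selected
from candidates {0} ∪ {percentiles of the s distribution} as the value
minimizing the coefficient of variation of window-wise spreads of d
(scaled median absolute deviation within ~100 s-quantile windows); ties
go to the smallest candidate, and a tiny floor (1e-8) is applied if the
winning candidate is 0 while some probes have zero pooled variance
(possible on noiseless synthetic data).

The null ensemble enumerates all distinct group-label assignments when
there are at most 1,000 of them (true for the 3 vs 3 and 4 vs 4 designs
this package targets; the observed labelling is included, per standard
SAM practice) and otherwise draws `n_permutations` seeded assignments.
Sorted null statistics are averaged into expected order statistics d̄.
For each threshold Δ on a swept grid, the called set comprises probes
whose sorted d departs from d̄ by more than Δ, with separate (asymmetric)
cutoffs per tail. The FDR of a called set is estimated as
π̂₀ · (average number of null statistics beyond the cutoffs over
permutations) / max(1, called), with
π̂₀ = min(1, 2 · fraction of observed d inside the interquartile range of
the pooled null statistics). The average (rather than the median) number
of falsely called probes is used because with the min-over-Δ q-value
definition the median estimator lets a single extreme probe reach q ≈ 0
whenever more than half the permutations show no exceedance at the top
cutoff, which measurably breaks null calibration; with the average, the
identity assignment alone guarantees a positive false-call estimate at
every cutoff. The delta table reports both counts, plus the raw and the
monotonized (running-minimum) FDR; a probe's q-value is the smallest FDR
over all Δ whose called set contains it, which is the monotone FDR at the
largest Δ still calling the probe. A probe is *called* when
q ≤ fdr_target and its linear fold change meets `fc_threshold` (1
disables the filter; the tissue-contrast default, since large arrays can
reach significance below 1.5-fold).

Transcript-level summaries mark a transcript significant if any of its
probes is called, take the direction of its best-q called probe, and flag
exact q ties with conflicting directions as ambiguous. Direction bias in
a call set (e.g. up- vs down-regulated at a polluted site) is tested with
the exact two-sided binomial test at p = 0.5.

With exhaustive 4 vs 4 permutations (70 assignments), the attainable
q-value floor is ≈ π̂₀/70; roughly one null dataset in six yields one or
two false calls at a 10% FDR target, so the realized false discovery
proportion on pure-null data averages ≈ 0.15–0.2 over seed batches of 50.

## Sense/antisense pairs and NAT candidates

Transcripts with at least one probe of each orientation form pairs;
duplicate copies are averaged first so a pair is one-vs-one. Probe means
are taken across the biological replicate arrays of one tissue after
normalization. A pair is excluded (and tallied) when any constituent
probe is undetected in any replicate — the strictest reading of
missing-data exclusion. Means are floored at ε = 1 fluorescence unit so
ratios stay finite; a zero minor strand therefore lands in the top ratio
class. Classification uses the *minor* (lower-mean) strand's fluorescence
with half-open, left-inclusive bins [0,10), [10,100), [100,1000),
[1000,∞) — the top bin read as f ≥ 1000, the only reading consistent with
the lower three — and the max/min ratio with bins [1,1.5), [1.5,3),
[3,10), [10,∞). The ratio is orientation-agnostic (max/min, not
sense/antisense), so relabelling strands changes nothing. NAT candidates
are pairs with ratio < 3 and minor-strand fluorescence ≥ 100, i.e. both
strands substantially transcribed; thresholds are parameters. Concordance
analysis counts pairs in which *both* probes pass a q-value threshold and
a fold-change threshold in a differential-expression contrast, split into
concordant (same direction, by direction) and discordant.

## EASE enrichment

For a gene list drawn from a background (all transcripts on the array —
the background is the array, not a genome), each gene set is scored by
the EASE tail: the one-tailed Fisher exact (hypergeometric upper tail)
with one list hit removed, P[X ≥ count − 1] for
X ~ Hypergeom(pop_total, pop_hits, list_total); a single-hit term scores
1. This is deliberately conservative for small counts and never smaller
than the plain Fisher p. Fold enrichment is
(count/list_total)/(pop_hits/pop_total). Records are filtered by
min_count and max_ease (raw EASE p, matching common practice) and sorted
by p; a Benjamini–Hochberg column over the reported terms is included for
reference. Term identifiers are opaque — ontology structure and ID
mapping are out of scope.

## Synthetic data generator

The generator emulates the platform at configurable scale; defaults
mirror the real design (≈24K transcripts, ~66% with probe pairs, 2,000
duplicated probes, ten spike-in levels, 4 digestive-gland vs 3 gill
arrays). On the log2 scale: sense abundance a_s ~ N(baseline_log2_mean,
baseline_log2_sd); a `frac_de` fraction of transcripts gets a group-2
effect of random sign with magnitude ~ U(de_log2fc_range); the antisense
strand of a non-NAT pair is a_s − δ with δ ~ U(3.5, 8), placing such
pairs overwhelmingly in the ratio ≥ 10 class; a planted NAT's antisense
abundance is drawn independently from the baseline law and may carry its
own DE effect. Linear signal is 2^(a + scale_j + ε) + background, with
per-array scale ~ N(0, array_scale_sd) and per-cell noise
ε ~ N(0, noise_log2_sd); duplicate copies share a but draw independent ε;
spike-ins carry the array scale but no per-cell noise, so they are
identical across arrays before scaling. The detection flag is
signal > 2 × background. Each array consumes its own random stream
spawned from the master seed by array index, so adding arrays never
perturbs existing ones. Random gene sets are emitted alongside, a few of
them over-sampling DE transcripts 5:1 so enrichment has planted signal.

Baseline defaults are log2 mean 8.5, sd 1.0 (expressed transcripts
centred near 360 fluorescence units with a typical two-fold spread):
the baseline law describes *expressed* transcripts — planted NAT
antisense strands are drawn from it, while the silenced strand of
ordinary pairs is generated by the separate suppression gap — so its
spread is deliberately narrower than the full dynamic range of an array,
which in this model arises jointly from the baseline, the suppression
gap, DE effects and the spike range. Background is 5 units and noise
defaults to 0.25 log2 units, comparable to duplicate-probe scatter on
real arrays.

What the generator does **not** emulate: probe-sequence effects
(GC/affinity biases), spatial artifacts, intensity-dependent (nonlinear)
dye response, correlated biological variation between pools beyond the
planted group effects, and heavy-tailed outliers. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to every artifact of real scanner data.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations of 1,000–2,000
probes with 6–8 arrays (seconds per SAM run with exhaustive permutations;
the 50-dataset null calibration takes ~30 s), which is ample for the
permutation ensembles involved since calibration depends on the number of
label assignments, not the probe count. Quantile normalization is exact
(no numerical tolerance beyond float arithmetic); cyclic loess inherits
statsmodels' lowess; FDR and q-value computations use bisection over
monotone cutoff arrays; all tie-breaks (s₀ candidates, transcript
direction, candidate ordering) are deterministic and documented in the
code. Degenerate inputs fail loudly: empty matrices, all-zero spikes,
zero-variance arrays in correlation, groups with fewer than two arrays,
and designs with fewer than ten distinct label assignments are errors,
not silent results.
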