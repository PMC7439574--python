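# Methods

## Epigenetic clock

The packaged clock is a fixed linear predictor of chronological age from
blood methylation beta values (fractions in [0, 1]) at three CpGs:
intercept 38.0 years and weights −26.4 (cg02228185, *ASPA*), −23.7
(cg25809905, *ITGA2B*) and +164.7 years per beta-unit for a CpG directly
upstream of cg17861230 (*PDE4C*). That CpG is not on the Illumina BeadChip,
so we name it `cg17861230_upstream`. The package does not train clocks; the
model is a constant, and arbitrary linear clocks can be supplied as YAML
configs.

Predictions are reported unclamped: the linear form can return negative
ages (iPSC-derived samples sit near 0), and clamping at zero is an explicit
opt-in flag. Betas are validated to [0, 1]; percent-scale input (0–100) is
only accepted behind an explicit `percent=True` flag, never auto-detected,
because silent rescaling corrupts clock output by an order of magnitude.

Cohort statistics over delta age x = predicted − chronological:
MAE = (1/n)Σ|xᵢ|, mean delta = (1/n)Σxᵢ, and R² as the squared Pearson
correlation of predicted versus chronological age. Whether the original
patient R² values were computed against the identity line or a refit
regression is ambiguous; squared Pearson correlation is our choice and is
invariant to that distinction up to the refit intercept/slope. Group
comparisons use a two-sided unpaired t test, Welch flavour by default
(robust to unequal variances, which the patient groups clearly have), with
`equal_var=True` available for the pooled-variance Student variant.

## Telomere age

Healthy-donor granulocyte telomere length (kb) is fit on age by OLS
(statsmodels), with residual standard deviation on an n−2 denominator.
"Telomere age" is the inversion of that line: the age at which the healthy
regression attains the observed length. Delta telomere age may exceed the
human lifespan for severely attrited samples and is deliberately not
clamped. The fit uses age as the only covariate and raw kb (telomere loss
in adult blood is approximately linear on this scale); a `log_scale` option
exposes a multiplicative alternative. Inversion requires a nonzero slope,
which the model type enforces at construction.

## Bisulfite amplicon epialleles

Coordinates are 0-based half-open; a CpG is pinned to the offset of its C on
the top strand. In-silico conversion implements both bisulfite strands: on
the original-top (OT) strand every cytosine outside the protected
(methylated) CpG set becomes T; the original-bottom (OB) strand applies the
same rule to the reverse complement and is reported in read orientation.

Alignment is pairwise dynamic programming (Biopython's `PairwiseAligner`),
global in the read with free reference end gaps, scored +1 match / −1
mismatch / −4 gap open / −2 gap extend, with bisulfite ambiguity scored as a
match: read T opposite any reference C on OT, and — after bringing the read
into top-strand orientation — read A opposite any reference G on OB. Both
strands are aligned and the better score kept (ties resolve to OT). Reads
scoring below 0.8 of the maximum attainable for their length (tunable) are
reported as rejected, never fatal. This is an amplicon-scale aligner by
design; genome-scale bisulfite alignment (indexing, multi-mapping, MAPQ
filtering) is out of scope, and the aligner is documented as a replacement
for, not a reproduction of, genome-wide tools.

Pattern calling reads the CpG cytosine on OT (C→M, T→U) and the CpG guanine
on OB (G→A logic); any other base — i.e. a sequencing error at the CpG — or
an uncovered CpG yields N. Pattern tables count exact M/U strings over reads;
reads containing N are excluded from pattern tables by default (complete
epialleles only) but still contribute per-CpG to the methylation means, and
both tallies are reported. Pattern grouping is a greedy agglomeration:
visit patterns in descending frequency, each unvisited pattern seeds a group
absorbing all ungrouped patterns within Hamming distance 1 (tunable;
0 reproduces raw counting), capped at 20 groups plus an "other" bucket.
The grouping rule for "similar patterns" is inherently a convention; this
one conserves total frequency and never shrinks the most abundant group.
Read classification is exact: all-U, all-M, else stochastic, over complete
reads.

Primer/barcode trimming and paired-end merging are assumed done upstream;
the package consumes single-end, merged reads.

## Differential filters

Probe filtering excludes X/Y-chromosome and SNP-overlapping probes from a
user-supplied annotation (we do not ship an array manifest; the simulator
fabricates annotations). Thresholds are strict inequalities on both sides:
beta difference > 0.2 / < −0.2, log2FC > 2 / < −2, so boundary-equal
features are excluded. log2 fold changes are computed on RPM with a 0.1 RPM
pseudocount; the handling of zero-RPM genes is the main source of count
discrepancies when comparing against tables produced under other
conventions. Array preprocessing (normalisation) is out of scope — the
module consumes normalised betas.

## Synthetic-data generators

All generators take explicit seeds (numpy `default_rng`), are byte-identical
on rerun, and emit truth tables sufficient to score every downstream
operation.

**Cohorts.** Ages are uniform on 18–80 years (adult blood donors). Each
subject's target epigenetic age is age + group offset + N(0, group scatter).
Default offsets are the point estimates characteristic of the emulated
diseases: +6.06 y (AA) and +16.36 y (DKC) for the epigenetic clock, +19.05 y
(AA) and +84.14 y (DKC) for telomere age; healthy 0. Scatter defaults are
6.83 y (healthy; chosen so E|N(0,σ)| = σ√(2/π) gives an MAE near 5.45 y),
11.6 y (AA) and 12.0 y (DKC), sized to reproduce the weaker age correlation
of patient cohorts. These parameterise the simulator as study conditions;
they are not claims of distributional fidelity.

Betas are obtained by inverting the clock, which is underdetermined (one
age, three betas). Our convention: anchor all betas at 0.5 and shift each by
`sign(wᵢ)·(target − f(0.5))/Σ|w|`, so every marker contributes an equal
|weight|-proportional share of the deviation in prediction space. The round
trip is exact, and betas stay inside [0, 1] for targets in roughly
[−12, 203] years; out-of-range targets clip and are flagged as saturated in
the truth table. Measurement noise N(0, 0.01) per beta (clipped to [0, 1])
adds ~1.7 y of prediction noise through the weights. Telomere length is
intercept + slope·(age + telomere offset) + N(0, sd), defaults 9.5 kb,
−0.06 kb/y and 0.5 kb, floored at 0.1 kb. Epigenetic and telomere offsets
are drawn independently, so within-group delta correlations are zero in
expectation — pooled across groups, the shared disease labels induce a
between-group correlation, which is why independence checks are per group.

**Amplicon reads.** Each molecule draws a class from (w_U, w_S, w_M), a
pattern (all-U, all-M, or iid Bernoulli(θ) per CpG), and a strand; the
reference is converted with the pattern's CpGs protected, optionally
truncated, and hit with iid substitution errors (no indels — an acceptable
approximation for amplicon sequencing on short inserts). Qualities are
constant Q37. Note the class-vs-pattern distinction: a stochastic-class
molecule is all-U with probability (1−θ)^L, so classification recovers the
mixture weights only after this analytically computed leakage correction —
the tests apply it.

**Matrices.** Null probes: wt ~ U(0.05, 0.95), ko = wt + N(0, 0.02) clipped;
at that noise level a spurious |Δβ| > 0.2 has probability < 1e−12, so
planted counts are recovered exactly. Planted probes get exactly ±0.3 (wt
drawn so the shift stays in [0, 1]); X/Y and SNP flags are assigned disjoint
from planted probes by construction. Expression: null genes share an RPM
value (lognormal, median 10); planted genes multiply/divide wt by 8, with wt
floored at 1 RPM so the pseudocount cannot mask the effect.

## What the simulations do and do not show

The generators emulate the *structure* of the real data — linear age
dependence with group offsets, independent attrition, three-component
epiallele mixtures, planted effect sizes — not its full complexity: no cell
composition shifts, batch effects, bisulfite conversion failure, PCR bias,
heavy-tailed patient scatter, or correlated methylation between neighbouring
CpGs (real stochastic epialleles are spatially correlated; ours are iid per
CpG). Passing tests therefore demonstrate correctness of the computations
under the stated model, not performance guarantees on real cohorts.

## Problem sizes and numerical choices

Test and analysis runs use cohorts of ~200 per group, 1 500–2 000 reads per
amplicon sample and 10 000-probe matrices — sizes at which all statistical
checks (±2 SE on means and slopes, ±3 binomial SE on frequencies) are
informative while the whole suite runs in seconds. Pattern-table invariants
hold to 1e−9; clock round trips to 1e−9 years; tables are written with
6-significant-digit floats, sorted deterministically, so reruns are
byte-identical. Degenerate inputs fail loudly: zero age variance, fewer than
three telomere training records, zero-CpG amplicons, empty pattern tables,
betas or RPM outside their domains.
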