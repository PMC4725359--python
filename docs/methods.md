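# Methods

## Data model

All analyses operate on an `AbundanceTable` — a taxa × samples matrix of
counts or relative percentages (percent columns must sum to 100 within
1e-6; on reading, sums within 0.5 of 100 are renormalised, anything further
off is rejected).  Sample class (lesional vs non-lesional) is decoded from
the `<subject><N|V><site>` naming scheme or supplied as metadata.  Lineage
(phylum…genus) and phenotype annotations (Gram nature, sporulation, oxygen
requirement, cell shape) are read from a TSV keyed by taxon id; phenotype
values are validated against closed vocabularies, and missing ranks are
stored as absent rather than as empty strings.

"Relative contribution" of a taxon in a sample class is the class-pooled
percentage of assignments: the sum of the taxon's counts over the class's
samples divided by the class total (for percent tables, the unweighted mean
of per-sample percentages).  Pooling is used because the quantity is
reported per class, not per sample.

Rank normalisation ranks each taxon's abundances **across samples** (the
orientation a taxon-by-taxon correlation over samples requires), with
average midranks for ties, divided by the sample count so values lie in
(0, 1].  The division is an affine rescaling and leaves correlations
unchanged.

## Diversity panel

Per sample: observed richness, bias-corrected Chao-1
(`S_obs + F1(F1−1)/(2(F2+1))`; the bias-corrected form is chosen so F2 = 0
is defined), Fisher's alpha (bracketed Brent root of
`α ln(1+N/α) = S`, tolerance 1e-9; undefined when S = N), Shannon in
natural log (base not dictated by the source analyses; nats are the
package's convention), Simpson 1−D, and Good's coverage `1 − F1/N`.
Rarefaction uses multivariate-hypergeometric subsampling without
replacement (Monte-Carlo, reps and seed configurable) with the exact
hypergeometric expectation `Σᵢ (1 − C(N−nᵢ,d)/C(N,d))` available as a
closed-form alternative; at full depth the curve equals observed richness
for any seed.

Class-level comparisons of the indices use the two-sided Wilcoxon
signed-rank test on subject-paired values, respecting the paired design.

The evenness curve retains genera at ≥ 1% relative contribution, sorts
them descending, and emits adjacent differences; the "logarithmic trend"
slope is a least-squares fit of difference against ln(position index)
(positions 1..m over the m differences).  A steep negative slope marks a
community dominated by a few genera.

## Core taxa

A taxon is core for a class when its per-sample relative abundance is
≥ 0.1% (inclusive, "minimum abundance") in at least ⌈0.8 · n_class⌉ samples
(ceiling, because "at least 80%" of 10 samples means 8).  Cores are
computed per class independently and compared as set intersection and
differences.  Raising either threshold can only shrink a core set.

## Bootstrapped differential abundance

For percent tables with ≥ 2 samples per class:

1. draw ⌊0.5 · n_class⌋ samples from each class, without replacement (one
   draw per repetition, shared by all taxa);
2. record each taxon's median abundance in each class's subset;
3. repeat 40 times, giving two 40-vectors of medians per taxon;
4. two-sided Wilcoxon rank-sum test per taxon between the vectors
   (normal approximation with tie and continuity corrections — at n = 40+40
   with heavily tied medians the exact null is neither available nor
   needed);
5. Benjamini–Hochberg step-up across taxa; mark taxa with adjusted
   p ≤ 10⁻⁴ (inclusive).

The block is bootstrapped 1000 times; a taxon is significant when marked in
≥ 99.5% of the outer iterations.  Direction is the sign of the difference
of overall class medians of per-sample abundance.  Taxa with zero abundance
in every sample of both classes are excluded from testing (constant-zero
medians; p undefined) and reported with retention 0.  If both median
vectors are constant (e.g. with subsample fraction 1, where all inner
repetitions coincide), the test is undefined and the taxon is not marked.

Randomness: each class group owns substreams keyed by (master seed, CRC32
of the group's sorted sample ids, outer-iteration index).  Keying by group
membership rather than by class label makes label-swapping reuse each
physical group's draws, so swapping the class labels flips every direction
while leaving retention and significance bit-identical — the procedure has
no built-in class asymmetry.

**Known limitation.**  The 40 inner medians are pseudo-replicates of the
same fixed samples, so the rank-sum test certifies *any* stable difference
between the two empirical distributions, including differences produced
purely by unpaired sampling noise.  On sparse taxa (expected counts near
zero, or strongly overdispersed counts) this inflates the false-discovery
behaviour beyond what the nominal FDR suggests; the 99.5% retention filter
does not remove such flags because they recur in every bootstrap of the
same data.  The synthetic-data defaults below are calibrated so that
between-subject variation dominates counting noise for every taxon, which
keeps the null false-positive rate near zero; on real overdispersed data
the procedure should be expected to return sparse low-abundance hits whose
robustness deserves independent scrutiny.

## Co-occurrence networks

Association between two taxa is the tie-aware Spearman coefficient: the
Pearson product-moment correlation of their normalised rank vectors,
`r = Σ(xᵢ−x̄)(yᵢ−ȳ) / ((n−1) sₓ s_y)` with sample standard deviations.
Zero-variance (all-tied) taxa have undefined correlations; they are
excluded pairwise and listed on the network object rather than aborting
the matrix.

An undirected edge joins taxa with `|r| ≥ r_crit`, where `r_crit` is the
critical r at 99% confidence.  Default method: invert
`t = r√((n−2)/(1−r²))` at the two-tailed t critical value with n−2 degrees
of freedom (r_crit = 0.765 at n = 10, 0.561 at n = 20).  A permutation
alternative takes the (1−α) quantile of |r| over random rank permutations
(|r| folds both tails, so the quantile is 1−α, not 1−α/2); at n = 20 the
two agree within 0.01.  Edge sign (positive/negative interaction) is kept
as metadata; topology ignores it.

Summaries count nodes incident to at least one edge (isolated taxa are not
drawn, matching plotted networks): density `2E/(V(V−1))`, diameter of the
largest connected component (undefined for an edgeless graph), degree, and
shortest-path betweenness normalised by `(V−1)(V−2)/2`.  Hub analysis
collects nodes with degree ≥ N% of the maximum degree for N = 60, 70, 80,
90 — sets are nested by construction and never empty — together with their
phylum and phenotype composition.  Two networks are compared through the
edges they share with equal sign (core interactions).

## Synthetic data generator

Per sample, counts are drawn as: (i) a per-subject normal perturbation
(log scale, sd `subject_effect_sd`) of the base log-mean vector, shared by
the subject's two samples; (ii) planted log-fold-changes added to lesional
samples; (iii) softmax to a composition; (iv) a Dirichlet-multinomial draw
at the sequencing depth with total concentration `overdispersion`
(`inf` = plain multinomial).  The master seed spawns one substream per
subject effect and per sample, so draws are independent of generation
order and datasets are bit-reproducible.

Defaults (the study-like conditions): 10 subjects (20 paired samples),
220 taxa, 40,000 reads/sample (the order of ~870k reads over 20 samples),
power-law base abundances with exponent 0.9 plus log-normal jitter
(sd 0.25) per seed — putting ≈ 41% of expected mass on the top eight
genera, matching "a bit over one-third" — phyla assigned greedily by
descending taxon mass so the four major phyla hold ≈ 85% of expected mass
with Actinobacteria ≈ 50%, subject log-sd 1.3, multinomial counting noise.
Subject effect sd 1.3 gives per-taxon cross-sample ranges of 2–3 orders of
magnitude, the scale visible in the packaged reference table's per-OTU
ranges;
it also keeps subject signatures dominant over (sparse) class signatures,
and — together with the multinomial counting layer — keeps the
bootstrapped procedure's null false-positive rate near zero (see the
limitation above: with strong unpaired overdispersion the procedure
certifies sampling noise; biological overdispersion in this model is
carried by the shared subject effect, where it belongs in a paired
design).  `expected_composition()` reports the population-level softmax of
the base log-means, which is what the phylum-mass checks assert.

What the generator does **not** emulate: a realistic ultra-sparse tail
(the flattest taxa sit near 0.05%, so the 0.01% contribution threshold
retains everything), strain-level OTU splitting, chimeras or primer bias,
and site-specific (body-location) effects.  Passing tests therefore show
the pipeline's statistical behaviour under subject-dominant paired
structure, not performance on arbitrarily sparse real tables.

## Pipeline

`run_pipeline(PipelineConfig)` sequences load/generate → diversity →
evenness/thresholds → core taxa → bootstrapped differential abundance →
per-class networks, hubs and core interactions, writing TSV/GraphML/JSON
artifacts plus a manifest (package version, seed, full configuration,
stage summaries).  One master seed drives fixed named offsets per stage,
so toggling one stage leaves the others' substreams untouched and a fixed
config reproduces every artifact byte-for-byte.  Output tables are sorted
by taxon id for stable diffs.  Any stage failure aborts with the stage
name in the error.

## Numerical choices

- Ranks: average midranks everywhere (scipy `rankdata`), the convention a
  Pearson-on-ranks formula presumes.
- Rank-sum p-values: exact enumeration when the combined sample is ≤ 20
  without ties, else normal approximation with tie correction (recovered
  from the midrank variance) and 0.5 continuity correction; signed-rank:
  exact for ≤ 25 untied nonzero differences, zeros dropped.
- Degenerate inputs return NaN (undefined) rather than raising wherever a
  larger computation should continue: zero-variance correlations,
  constant rank-sum inputs.  Comparisons treat NaN as "not significant".
- Chao-1 requires integer counts; compositions are renormalised when they
  sum to within 1e-8 of 1 and rejected when negative.
- Float-fuzz guards: prevalence counts use `ceil(x − 1e-9)`; retention
  uses a 1e-12 slack on the ≥ 99.5% comparison.

## Problem sizes used in the checks

The test suite and the acceptance script run the bootstrapped procedure at
100 outer bootstraps (the full default is 1000) on 200-taxon datasets, 20
datasets per property; the network null uses 100 taxa at n = 20.  These
sizes are the package's chosen verification conditions; all statistics
scale to the full defaults unchanged.
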