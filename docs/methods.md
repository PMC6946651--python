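# Methods

`camelscan` implements a variant-to-phylogeny inference chain for detecting
and removing localized interspecies gene flow before estimating a population
tree, together with a synthetic-data generator that provides ground truth for
every stage.  This note records the models, the estimators, the numerical
choices, and what the synthetic data does and does not establish.

## The synthetic cohort (simpop)

Allele frequencies evolve on a rooted population tree under the
Balding–Nichols model: along a branch with drift coefficient F ∈ [0, 1), the
child frequency is Beta-distributed with mean p (the parent frequency) and
variance F·p·(1−p), i.e. Beta(p(1−F)/F, (1−p)(1−F)/F).  Boundary frequencies
are absorbing: once an allele is fixed or lost it stays so, because drift
cannot resurrect variation.  We chose this frequency-level model over a
coalescent because its expectations are analytically checkable — the
Weir–Cockerham Fst between two populations is, to first order, the mean of
their compound drift since their common ancestor, with compounding
F_total = 1 − Π(1 − F_i) along a path — which makes every calibration and
recovery test an exact statement rather than a fitted one.  A coalescent
backend (msprime) could be added behind the same interface.

Admixture is a pulse: after all drift, the recipient's frequency becomes
q' = (1 − f)·q + f·p_donor at sites inside a configured window set, and is
untouched elsewhere.  Pulses consume no random draws, so a scenario and its
pulse-free twin share every draw at unaffected sites; the masking test below
exploits this matched-seed design.  Real admixture is not purely pulse-like —
continuous migration over a time span would leave tracts of varying age and
length — so the generator's truth windows are sharper-edged than real
introgressed haplotypes; recovery rates on this truth are an upper bound on
what tract-level inference would achieve.

Genotypes are two Bernoulli(p) allele draws per diploid (fixed-shape uniform
draws, for the matched-seed property), with independent missingness and
per-site covariates: QUAL ~ Normal(80, 15) clipped at 0, total depth ~
Poisson(13 per sample), RMS mapping quality ~ Normal(55, 5), and ref/alt base
pairs drawn so the expected transition:transversion ratio is 2.4.  Sites are
evenly spaced (default 100 bp) so window occupancy is deterministic.

The default scenario is an eight-population camel-like cohort of 128
diploids: 4 dromedaries (`drom`, the outgroup and admixture donor), 19 wild
Bactrian camels (`wild`), and domestic Bactrian populations IRAN (6), KAZA
(6), RUS (10), MG (28), IMG (30) and XJ (25), grouped as `central_asian`
(IRAN, KAZA, RUS) and `east_asian` (MG, IMG, XJ).  Per-branch drift
coefficients were calibrated once, with the compounding rule above, so that
realized pairwise Fst lands in the observed ranges for this system:
dromedary–Bactrian ≈ 0.54–0.64, wild–domestic ≈ 0.27–0.31, IRAN versus the
other domestics ≈ 0.05–0.06, and < 0.03 among the remaining domestics, with
IRAN as the earliest-splitting domestic population.  Default pulses send 4–6%
dromedary ancestry into IRAN/KAZA/RUS, confined to a random 20% of 100 kb
windows (the same window set for every recipient, for a well-defined truth
track).  The genome is scaled to one 10 Mb chromosome (~1e5 SNPs, 100
non-overlapping 100 kb scan windows): large enough that window-level
jackknife statistics behave as in a full genome, small enough that the whole
chain runs in seconds.

## Variant filtering (variants)

A variant survives iff all enabled rules hold: QUAL > 40, 200 < summed
DP < 5000, minor allele frequency > 1%, fraction of individuals with a
missing genotype < 20%, RMS mapping quality > 30, and exactly one alternate
allele.  Rules are conjunctive, so filtering is idempotent and rule-order
invariant; a record failing several rules is tallied in each.  MAF uses
non-missing alleles across all samples jointly; half-calls count as missing.
Inequalities are strict, as conventionally printed.  Indels survive I/O but
are excluded from Ts/Tv and all downstream statistics.

LD pruning is the standard greedy windowed procedure (50 variants, step 5,
r² > 0.5): within each window, while any kept pair exceeds the threshold the
later variant of the worst pair is dropped.  r² is the squared correlation of
genotype dosages with missing entries excluded pairwise — dosage rather than
haplotype EM because the data are unphased.  Neutral-locus selection places
1 kb loci at random outside merged exclusion intervals with ≥ 30 kb between
consecutive loci, deterministically given a seed.

## Diversity and differentiation (popstats)

Per site with x alternate alleles among n non-missing, π_site =
2x(n−x)/(n(n−1)); a window's π is Σ π_site over the full window length in bp.
Watterson's θ is S/a_{n−1}/L with S the segregating sites in the window and n
the modal non-missing allele count over the window's usable sites (ties
broken toward the larger n; whether per-window modal n or per-site averaging
is the "right" choice is genuinely open — modal n was chosen and is flagged
here).  Window denominators use the full window size, not callable sites,
matching the common VCF tooling convention; a different denominator would
scale all windows of a dataset equally and cancel from the comparisons made
here.  Windows are non-overlapping by default.

Fst is the Weir & Cockerham (1984) variance-components estimator for two
populations with observed sample sizes, frequencies and heterozygote
proportions; window and overall values are ratios of sums Σa/Σ(a+b+c), never
means of per-site ratios, and raw (possibly negative) estimates are reported.
Sites need at least two called diploids in each population; sites
monomorphic in both contribute zero to both sums and drop out.  IBS distance
is the mean of |g_i − g_j|/2 over sites called in both individuals, and MDS
is classical Torgerson scaling (double-center −D²/2, top-k eigenpairs, axes
sign-fixed so the first nonzero loading is positive; negative eigenvalues are
dropped with a warning, zero eigenvalues remain as zero coordinates).

## The introgression scan (admixscan)

For a quartet (Y, Z; W, X) — two ingroups, their outgroup, and a candidate
donor — Patterson's D is

    D = E[(p_Y − p_Z)(p_W − p_X)] / E[(p_Y + p_Z − 2p_Y p_Z)(p_W + p_X − 2p_W p_X)]

with expectations averaged over the sites used.  Group labels pool all
non-missing alleles of their member populations; sites where any of the four
frequencies is undefined are excluded (the alternative — imputing zero —
would bias D at missing-heavy sites).  The window-local statistic f_d
replaces the denominator with the expectation of the larger of two "complete
replacement" terms, branch-chosen by the sign of D (the D < 0 branch swaps
the roles of Y and Z); at D = 0 exactly, f_d is defined as 0 for continuity.
f_d approximates the introgressed ancestry proportion of a region and is
bounded for small windows where D itself is wild.

Window significance uses the delete-one block jackknife: f̂_i is the
statistic with the i-th 10 kb block removed, and

    Z = mean(f̂) / sqrt(var(f̂) · n),   n = number of blocks,

with var the sample variance.  This standardization is implemented exactly
as stated, with the note that the textbook delete-one jackknife would use
(n−1)²/n in place of n; the stated form is slightly conservative (for n = 10,
about 11% larger standard errors), and a flag (`convention="delete-one"`)
switches to the textbook form.  "n is the repetition times" is read as the
number of blocks, which equals the number of delete-one repetitions.
Degenerate cases: all pseudo-values zero → Z = 0 by convention; zero variance
with nonzero mean → ±inf.

The scan covers non-overlapping 100 kb windows (a trailing partial window is
kept if at least half-size), computes D, f_d, and the jackknife Z within each,
and classifies Z > 2 as introgression into Z, Z < −2 into Y.  Masking removes
all sites in windows significant in **either** direction before distances are
recomputed — removing only the Z-direction would leave the complementary
signal in place and the remaining-window counts would not add up.  F3(Z; X, Y)
= mean (p_Z − p_X)(p_Z − p_Y) and F4(Y, Z; W, X) = mean (p_Y − p_Z)(p_W − p_X)
use the same jackknife over 500-SNP blocks; F3 requires the target's own
drift to be small relative to the admixture signal, so a weakly admixed,
drifted target can show positive F3 while F4 is already decisive (example
05 demonstrates both regimes).  The helper M = m·τ_m converts a
mutation-scaled migration rate and time span into a total migration rate.

## Phylogeny (phylo)

Population distances are average 10 kb-window Weir–Cockerham Fst (ratio of
sums within a window, mean over windows), floored at zero for distance use;
no Reynolds-type transformation is applied because the chain compares trees
built from Fst directly.  Neighbor joining is the Saitou–Nei algorithm with
the standard Q-criterion, exact on additive matrices; Q-ties are broken
toward the lexicographically smallest pair of cluster labels so the output is
deterministic, and negative branch lengths are clamped to zero with a
warning.  Bootstrap support resamples, per replicate, a fixed number of
10 kb windows whose intervals are at least a configured spacing apart
(greedy acceptance on a shuffled candidate list, without replacement,
seeded), rebuilds the distance matrix and tree, and reports for each
bipartition of the full-data tree the percentage of replicates containing
it.  The consensus is strict majority rule (> 50%); such splits are mutually
compatible, and conflicting 50/50 splits are deliberately dropped rather
than greedily completed.  Newick serialization goes through dendropy with
integer-percent supports as internal node labels.

## Pipeline

Stages run in dependency order (simulate/ingest → filter → prune → stats →
scan → mask → restat → tree → compare); configuration is validated before
anything runs, so e.g. enabling mask without scan fails up front.  Every
stage's randomness derives from the single manifest seed XOR'd with a CRC of
the stage name (stage-local substreams keep stages reproducible in
isolation), all intermediate artifacts are standard text formats, and the
manifest records per-stage output checksums so a rerun can be verified bit
for bit.

## What the tests establish — and what they do not

The test suite checks three layers: exact agreement of every estimator with
independent loop-based oracles and closed-form toy values; algebraic
invariants (polarization invariance of D and f_d, F4 antisymmetry, NJ
exactness on additive matrices); and parameter recovery on the synthetic
cohort (scan sensitivity/specificity against the truth track, f_d near the
true pulse proportion, Fst restoration after masking against the
matched-seed control, and bootstrap support for the configured
earliest-splitting population).  Problem sizes in the recovery tests are the
default scenario's (10 Mb, ~1e5 SNPs, 128 diploids, 100 scan windows, 200
windows × 100 bootstrap replicates) — chosen as the smallest scale at which
the window/block/jackknife geometry matches a full-genome analysis.

Because the generator draws sites independently, it has no linkage
disequilibrium beyond the pulse-window locality: the jackknife's robustness
to LD is therefore exercised structurally (blocks, spacing constraints) but
not stressed by realistic correlation, and LD pruning is tested on
constructed correlations only.  Passing these tests shows the estimators and
the chain are implemented correctly and recover truth under the stated
model; it does not by itself establish power or calibration on sequence data
with recombination, selection, or calling artifacts.
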