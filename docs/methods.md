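# Methods

## The problem

Ancient-DNA amplicon studies recover a target gene as many short
overlapping PCR fragments, clone each amplicon and sequence several
clones per clone library. Three artefacts must be removed before the
sequence can be used: miscoding lesions from post-mortem cytosine
deamination, co-amplified nuclear-mitochondrial paralogs (numts), and
unreplicated amplifications that could reflect contamination or sporadic
error. `paleoamp` implements that authentication workflow as testable
code, with a synthetic-library generator standing in for the subfossil
extracts so every stage can be scored against known truth.

## Synthetic clone libraries (`simdata`)

The generator draws a mitochondrial protein-coding gene (default
1,140 bp, stop-free under the vertebrate mitochondrial code, which reads
AGA/AGG as stops besides TAA/TAG), with third codon positions drawn from
the composition typical of mammalian cytochrome b (A 0.39, C 0.36,
G 0.03, T 0.21), so the simulated gene behaves realistically under the
composition screen. The numt paralog substitutes exactly
`round(divergence · L)` random sites (uniform over the three alternative
bases); substitutions creating in-frame stops are resampled by default,
because intact-ORF numts are the difficult, realistic case — a flag
disables the repair to produce stop-bearing numts for classifier tests.
Fixing the substitution *count* rather than the per-site probability
keeps the realized divergence within the ±0.02 invariant deterministically.
A separate nuclear gene (default 1,206 bp, standard code) backs the
nuclear amplicons.

Amplification success follows exponential template survival above the
shortest designed amplicon, s(L) = exp(−max(0, L−97)/λ), with separate
half-lives λ for the mitochondrial (default 180 bp) and nuclear
(default 90 bp) fractions — two parameters that give the qualitative
asymmetry between an abundant, better-surviving mitochondrial fraction
and a sparser nuclear one. For a mitochondrial fragment the PCR sees a
template pool with relative abundances 1 (mt) and w = `numt_weight`
(numt, default 0.1) thinned by survival: the amplification succeeds with
the pool-averaged probability (s_mt + w·s_nuc)/(1 + w) and, on success,
the whole amplicon derives from the numt with probability
w·s_nuc/(w·s_nuc + s_mt) — template choice is per PCR, matching the
observation that co-amplified paralog amplicons are homogeneous.

Each clone then receives, per site, deamination (C→T and G→A at equal
rates, default 0.02 per site) followed by a uniform polymerase error
(default 0.001 per site, uniform over the three alternative bases).
Damage is modelled on the reported strand only and without fragment-end
enrichment, because the quantities this package computes (type spectra,
not positional profiles) do not resolve position. Truth labels (template
class, lesion sites) are retained per clone.

Randomness: one root seed; each sample × fragment × session derives its
own `numpy` generator from `[seed, stage, sample, fragment, session]`, so
outputs are bit-identical at a fixed seed and invariant to evaluation
order.

What the generator does *not* emulate: indels, chimeric PCR products,
fragment-end damage enrichment, heteroplasmy, contamination from related
species, and clone-count overdispersion (clones per PCR is a constant,
default 8, rather than a fitted distribution — observed clone counts in
real tables vary roughly 6–37). Passing tests therefore demonstrate the
*logic* of the screen under the stated statistical structure, not its
performance on every real-world pathology.

## Consensus rules (`consensus`)

Coordinates are 1-based inclusive throughout; an amplicon spanning
positions 1–159 has length 159. Clones are assumed pre-aligned and
indel-free (gapped clones are rejected, not realigned). Per-column calls
use strict plurality; ties emit the IUPAC code of the tied set, so no
arbitrary base is ever invented — at every position the emitted base set
is a subset of the observed bases. Replication status per sample ×
fragment: two amplicons from distinct PCR sessions are independent
replicates; two amplicons with *different* coordinate spans overlapping
at least half of the shorter span validate each other even when each ran
once; a single amplicon is rescued when IUPAC-compatible with another
sample's validated consensus over the shared span (compatibility, not
equality, so damage-derived R/Y codes do not block validation).
Replicate merging keeps agreeing positions and codes conflicts as the
2-fold IUPAC letter (3-way conflicts get the 3-fold code plus a warning),
listing every such position. Fragment assembly intersects IUPAC sets in
overlaps (R over A narrows to A) and treats an empty intersection as a
hard error naming the fragment pair and position; cross-sample
combination instead falls back to the union code with a warning, keeping
disagreement visible as ambiguity.

## Damage spectra (`damage`)

A change is a distinct (position, consensus base → clone base) event: the
same mutation seen in several clones at one position counts once, two
different changes at one position each count once. Events are scored
against each amplicon's own consensus — so a PCR that amplified a
divergent paralog contributes only its clones' damage, not the paralog's
divergence — and deduplicated across all clones of the sample × fragment.
Ambiguous consensus columns are excluded from counting and reported.
Summary percentages are %TS (the four transitions), %C\* (C→T + G→A,
the deamination signal) and %TV, rounded half-away-from-zero to integers
(93.75→94, 87.5→88, 12.5→13) — the only rounding rule consistent with
all cleanly verifiable published rows. A zero-total spectrum reports
(0, 0, 0).

## Numt screening (`numtscreen`)

Per fragment, amplicon consensuses are partitioned into sequence classes
by single-linkage clustering on p-distance, with IUPAC-compatible
positions counting as matches and a class threshold of 0.03 — above the
damage scale, below the 5–21% divergence range observed for real numts.
Classes are ordered by clone count.

The decisive evidence, in order:

1. **Length anchoring.** If an explicit nuclear attempt/success table
   defines a per-sample preservation threshold L\* (the smallest nuclear
   fragment length with at least one attempt, zero successes, and no
   longer fragment succeeding), then mitochondrial classes longer than
   L\* cannot be numts and are anchors. The screen never derives this
   table silently from a simulated library: under the default survival
   parameters nuclear fragments amplify often, and a vacuous L\* (the
   longest nuclear fragment failing by chance) would make length
   anchoring actively misleading. Supplying the table is the caller's
   assertion that the taphonomic premise holds.
2. **The consistency backbone.** Classes from all fragments and samples
   are linked whenever they overlap by ≥ 20 columns with identity ≥ 0.98;
   connected components of this graph are the study's distinct haplotype
   groups. The backbone is the component containing an anchor (when L\*
   is available), else the component with the largest total clone count —
   the "obtained at high frequency and consistent across overlapping
   fragments and samples" criterion. Every other class is scored by a
   weighted vote of its pairwise identities to backbone classes (weight =
   clone count × overlap length): the weighted mean identity of the
   winning side is compared to the anchor thresholds, ≥ 0.98 GENUINE,
   ≤ 0.97 NUMT, between them AMBIGUOUS. The graph formulation is what
   resolves the two situations a purely per-fragment rule cannot: an
   equal-depth split between one genuine and one paralog amplicon, and a
   fragment whose neighbours failed to amplify in its own sample.
3. **Within-fragment frequency rule** (fallback when no backbone
   comparison exists): a minority class (< 0.5 of the fragment's clones)
   diverging ≥ 5% from the majority class is a NUMT; a majority class is
   GENUINE; a single class with no comparator at all is GENUINE with an
   explicit unreplicated-class caveat.

Reading-frame intactness, third-codon-position composition (total
variation distance to the mammalian cytb reference, "typical" at ≤ 0.15)
and the 3>1>2 codon-position rate ordering are recorded as corroborating
flags only — real numts are known to pass all three, so they never
overturn the frequency/anchor evidence. The published reference
composition is stored as printed (39/36/3/21, summing to 99%) and
normalized inside the distance so an exactly matching composition scores
zero.

On 100 synthetic libraries per run with divergence drawn uniformly from
[0.05, 0.21] and numt weight from [0.05, 0.3] (all else at defaults),
class-level NUMT precision and recall both exceed 0.95 at the default
thresholds, and a numt-free world (weight 0) produces no NUMT calls; the
acceptance script recomputes these numbers on every run. Residual misses
are numt classes with no comparator anywhere in the study (an isolated
fragment amplified only as the paralog), which no frequency- or
consistency-based rule can detect.

## Topology tests (`topotest`)

Site log-likelihoods on fixed trees use Felsenstein pruning under
per-partition GTR+I+Γ: the GTR generator is scaled to one expected
substitution per unit branch length at stationarity and exponentiated via
the symmetrized eigendecomposition D^{1/2}QD^{-1/2}; the discrete Γ uses
mean-per-category rates (4 categories by default), the convention of the
standard ML programs; with invariant sites, the variable-category rates
are divided by (1 − p_inv) so branch lengths keep their
substitutions-per-site meaning. Ambiguity codes contribute the indicator
of their base set, gaps and missing data a vector of ones. Correctness is
pinned by two independent oracles: exhaustive internal-state enumeration
on 4–5-taxon trees (agreement to 1e-8; observed ~1e-15) and
`scipy.linalg.expm` for the transition matrices. Likelihood totals are
invariant under re-rooting of the unrooted topology (time reversibility),
which is tested because it is exactly the property a wrong
symmetrization breaks.

RELL resamples ⌈r·n⌉ site columns with replacement (the same columns for
all trees) and re-sums stored site log-likelihoods. The SH test centres
each tree's replicate totals on their own mean and compares
max_j L_j − L_i against that null; identical rows therefore give p = 1.
The AU test tracks the bootstrap proportion BP(r) over scales
r ∈ {0.5, …, 1.4}, fits z(r) = Φ⁻¹(1 − BP) to d√r + c/√r by weighted
least squares (binomial-variance weights) and reports p = 1 − Φ(d − c).
Ties for the replicate maximum are split evenly so proportions sum to
one, which makes the two-identical-trees case give p = 0.5 exactly.
Degenerate proportions at a single scale get the 1/(2B) continuity
correction; a tree at BP = 0 (or 1) at *every* scale is reported as p = 0
(or 1) directly, because the regression on a correction-induced constant
would otherwise return a meaningless ≈ 0.37 for a hopeless tree.

The harmonic-mean marginal-likelihood estimator is computed as
−(logsumexp(−lnL) − ln n) over pooled post-burn-in samples — exact for a
constant trace, permutation-invariant, and used only to rank topologies
on the 2lnBF scale (> 10 very strong, > 6 strong, > 2 positive,
otherwise weak; positive favours the first model). It is a rough
estimator with well-known upward bias and is deliberately kept at the
arithmetic/threshold layer: no MCMC is performed here, traces are inputs.

## Pipeline and problem sizes

The pipeline runs simulate → consensus → damage → numt-screen, writes a
JSON manifest (config snapshot, seed, SHA-256 per output file, per-stage
status) and halts on the first failing stage with the partial manifest on
disk. The consensus stage assembles each sample only from classes
consistent with the study-wide backbone, so a paralog-only fragment
leaves a coverage gap rather than corrupting the sample sequence; the
divergent classes surface in the screen's evidence table instead.

Problem sizes in the test suite and acceptance script are chosen to make
the statistical assertions sharp while keeping runs desk-scale: 100
libraries for the precision/recall benchmark (≈ 4,000 classes), 10⁴–10⁵
clone sites for rate-recovery checks (3 binomial σ), 200 random sites
against the enumeration oracle, and B = 1,000–5,000 bootstrap replicates
for the resampling tests.

## Known limitations

- The screen's backbone assumes the genuine haplotype is the most
  abundant consistent sequence study-wide; a library overwhelmingly
  dominated by one paralog would invert it. With paralog template weight
  ≤ 0.3 per PCR this failure mode was not observed in 300 benchmark
  libraries.
- p-distances on ≤ 20-column overlaps are too noisy to use; such pairs
  are simply not linked, which can leave short terminal fragments
  unjudged (reported as GENUINE-with-caveat or AMBIGUOUS, never silently
  dropped).
- The damage model has no positional structure, so the package cannot
  (and does not claim to) reproduce fragment-end enrichment statistics.
- `topotest` evaluates fixed hypotheses only; it is not a substitute for
  tree search or model selection.
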