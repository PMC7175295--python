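# Methods

This note records the models, conventions and parameter choices behind
`biopanml`, in the order the pipeline runs them.

## Selection model for simulated panning

Panning is modeled as exponential tilting of clonotype frequencies. Each
clonotype $i$ has a capture strength $s_i > 0$; after the wash of round
$r \ge 1$ the frequency vector updates as

$$ p_i' \;\propto\; p_i \, s_i^{\,w_r}, $$

where $w_r \ge 0$ is the wash-stringency exponent of that round, and
sequencing is a multinomial draw of the configured read depth from the
updated frequencies. Only sequencing is stochastic: the frequency chain
itself is the deterministic expectation, so per-round counts are
unbiased multinomial samples of a closed-form trajectory, which the
tests exploit.

This is a stand-in: no quantitative enrichment model is established for
bio-panning, and exponential tilting is the simplest family that is
neutral at $w_r=0$, orders clones by affinity at any $w_r>0$, and
compounds across rounds. Two consequences worth knowing:

* **Diversity.** Repeated tilting concentrates mass on the strongest
  clones, so Shannon entropy falls over the campaign. It is *not*
  step-wise monotone: a single weak tilt can transiently raise entropy
  when the initially dominant clones happen to be weak binders (initial
  frequencies and capture strengths are drawn independently). The tests
  assert the true property — an overall fall, strict once enrichment
  dominates — not per-step monotonicity.
* **Wash schedule.** The default exponents $(0, 0.1, 0.3, 0.3, 0.5)$
  keep the 1/3/3/5 shape of a typical wash schedule at 0.1 per wash.
  The scale matters: with a 10× binder advantage, exponents equal to
  the wash counts drive the library to fixation by round 4 and every
  retrieved clone is a binder, which no real campaign shows (a
  realistic final pool is strongly but partially enriched, and the
  retrieved-clone dataset must contain both classes to train on).

## Simulated repertoires, reads and ELISA

* Binder status is Bernoulli(`binder_fraction`, default 0.23 — the
  validated hit rate among retrieved clones in the emulated campaign).
  Capture strengths are lognormal with scale 10.0 for binders vs 1.0
  for non-binders (σ = 0.5), so the binder law is stochastically larger
  but overlapping. Initial frequencies are heavy-tailed (lognormal,
  σ = 1.2), normalized per chain.
* CDR3s are uniform over the 20 standard amino acids with lengths
  uniform on 8–18. The generator only emits *junction-unambiguous*
  sequences: a candidate whose residues complete a premature
  `WG.G`/`FG.G` FR4 motif (internally or across the CDR3–FR4 junction)
  is redrawn, because the extractor's first-match boundary convention
  would truncate it and the exact read round trip would be impossible
  by construction. Real repertoires contain such sequences; see
  Limitations.
* Reads are `5' primer + FR3-tail codons + CDR3 codons + FR4-head
  codons + revcomp(3' primer)`, with synonymous codons uniform per
  read, per-base substitution errors at `read_error_rate` (default
  1e-3), and Phred strings at a constant baseline of 38 with rare
  (2%) low-quality positions. No indels, chimeras or PCR bias.
* ELISA absorbances are Gaussian triplets truncated at zero: antigen
  wells at mean 2.0 for binders and at the blocked-well background
  (0.2) for non-binders, anti-tag wells at 1.0, noise SD 0.1. A paired
  clone is a binder iff every chain present is a true binder; paired
  repertoires share one binder flag per index so clone-level labels
  are consistent across chains.

What passing these tests shows is that the analysis recovers structure
*of this generative family*; it does not validate the pipeline against
PCR bias, indel errors, plate effects, or affinity–avidity confounds
that real campaigns contain.

## Read preprocessing conventions

* Filter order is fixed — mean-Phred, primer, frame, CDR3 — and a read
  is charged to the first filter it fails, so the rejection statistics
  partition the input exactly.
* The quality filter is the mean Phred over the read, default cutoff
  20 (the cutoff itself is configurable; any reasonable value passes
  the simulated baseline-38 reads and rejects junk).
* Primers are found exactly first, then by a Hamming scan allowing
  `max_primer_mismatches` (default 1) substitutions; the 3' primer is
  searched as its reverse complement after the 5' primer's end.
  Leftmost qualifying positions win. No indel-tolerant alignment.
* The translation frame is anchored at the end of the 5' primer (the
  amplicon design places the primer flush with a codon boundary);
  "out of frame" means the inter-primer span is not a multiple of 3.
* The CDR3 is the translation strictly between the first `YYC` match
  and the first following `WG.G` (heavy) / `FG.G` (light) match, with
  length bounds 4–40 and no internal stop codon. Junction conventions
  differ between annotation tools; the anchors are amino-acid regular
  expressions and fully configurable. Coordinates are 0-based
  half-open throughout.
* Pair merging scores every ungapped overlap of at least `min_overlap`
  by mismatch fraction, keeps the best (longest on ties), and resolves
  disagreements toward the higher-quality base (forward read on
  quality ties).

## Clonotypes, validity and entropy

A clonotype is an exact CDR3 amino-acid sequence; no near-identity
clustering is performed. The validity rule — count ≥ 2 in at least one
round — removes singleton artifacts. Rows sort by total count
descending with lexicographic tie-break, so tables are deterministic.
Entropy is natural-log by default (base-2 via `base=2`); rounds with
zero total are reported as NaN, never 0, since an empty library has no
defined diversity. Downstream features default to raw per-round counts
(frequencies via `use_frequencies=True`): both normalizations are
defensible and the forest is insensitive to monotone per-column
rescaling, but raw counts match the "times a clonotype appeared"
bookkeeping of the collation step.

## Reactivity calling

The AR threshold is $\bar B + 3\,\mathrm{SD}(B)$ with the sample
(n−1) SD computed **across the clones of a batch** (a per-plate batch in
practice), not across a clone's replicates: the background band should
reflect clone-to-clone variation in non-specific signal. The comparison
is strict (`A > threshold`), so degenerate batches where every A equals
its B yield zero AR calls. Batches need at least two clones for the SD
to exist.

## The TR dataset

A clonotype seen in several clones inherits its label by the **any-AR
rule**: one reactive clone suffices. Light chains especially are shared
across pairings, and a chain that supports binding in any context is the
positive the panels are after. A `majority` rule is available (ties
resolve AR). Calls whose CDR3 is absent from the clonotype table are
returned in `dataset.unmatched` and logged — never silently dropped.
Splits take `floor(f·n)` training rows uniformly without replacement,
unstratified by default (a stratified option exists); train and
validation always partition the data.

## Modeling choices

* The forest is grown by scikit-learn (bootstrap per tree, `mtry`
  candidate features per split), but every fitted forest is exported to
  a neutral node-list encoding — split variable, threshold, children,
  depth, leaf class per node — and *all* downstream consumers
  (prediction, serialization, introspection) read only that encoding.
  JSON-serialized models therefore predict identically after reload
  with no fitted estimator attached.
* Predicted class is the strict tree-vote majority; an exact 0.5 tie is
  called NR (conservative: a synthesis panel should not spend a slot on
  a coin flip). Confidence is the winning vote fraction, hence ≥ 0.5.
* The benchmark roster is RF, RDA, LDA, SVM, NB and AdaBoost with
  library defaults (no manual tuning at the benchmark stage). RDA is
  realized as shrinkage quadratic discriminant analysis
  (`reg_param=0.5`), the closest available estimator to regularized
  discriminant analysis. Cross-validation folds are stratified by
  label, which stabilizes κ when positives are ~23% of rows. Cohen's κ
  is computed from the fold confusion matrix; the degenerate
  $p_e = 1$ case (all mass in one cell) returns 1.
* Tuning evaluates every (sampling ratio, mtry, ntree) cell on
  `replicates` fresh splits (default 10), returns the full
  one-row-per-model table, and reports the cell maximizing the mean of
  the chosen metric; ties resolve to the first cell in grid order. The
  default grid (3 ratios × 4 mtry × 2 ntree × 10 replicates = 240
  models) is a desk-scale default, not a recommendation.

## Forest introspection conventions

* Minimum depth counts the root as 0 and uses the first (shallowest)
  occurrence per tree. By default a variable's mean is taken over the
  trees that contain it; `fill="max_plus_one"` substitutes (tree max
  depth + 1) for absent variables, penalizing rarely used ones. Both
  conventions are in circulation, which is why published mean-depth
  values are comparable only qualitatively across tools.
* A maximal subtree of $u$ is rooted at a $u$-split with no $u$-split
  ancestor. Conditional depth is measured relative to the subtree root
  (= 0), so any $v$-split at its child scores 1; the root's own split is
  excluded, so self-pairs $(u,u)$ score the *second* occurrence and all
  conditional depths are ≥ 1. Pairs never observed are absent rather
  than zero. The reported offset convention is a parameter of the
  statistic, not of the forest.
* Both statistics are verified exactly against an independent
  exhaustive recursive tree-walk (which recomputes depths from path
  lengths) on random forests.

## Panel selection

Eligibility is strict confidence `> min_confidence` (default 0.9) plus
the requested label, optionally restricted to clonotypes whose full
V-gene sequence was recovered (`full_sequence_available`, an input
boolean standing in for full-length assembly, which is out of scope).
Sorting is confidence-descending with lexicographic CDR3 tie-break, so
panels are deterministic; an under-filled panel is returned short with a
logged warning. Promiscuity in the pairing report is defined on exact
CDR3 identity: a light chain paired with ≥ 2 distinct heavy partners.

## Problem sizes and determinism

The test-suite and acceptance runs use desk-scale campaigns — 50–2,000
clonotypes, read depths of 300–20,000 per round, forests of 8–500
trees, 10-seed replications — chosen so the whole suite completes in a
few minutes while every statistical check retains comfortable margins
(e.g. recovery criteria that hold 10/10 at these sizes). Every
stochastic call threads an explicit integer seed through
`numpy.random.default_rng`; per-operation substreams are derived as
`(seed, stream_tag)` pairs, so identical configurations reproduce
byte-identical FASTQ/TSV/JSON outputs.

## Known limitations

* The enrichment model has no PCR bias, chimeras, indels, clone
  dropout, or cross-round contamination; absolute performance numbers
  on simulated data do not transfer to real campaigns.
* Clonotypes are exact sequences; somatic variants and sequencing
  near-duplicates are distinct rows.
* The junction-unambiguity constraint of the generator means the exact
  round-trip guarantee applies to the simulated repertoire family, not
  to arbitrary CDR3s; on real data a small fraction of clonotypes with
  motif-completing junctions will be truncated or rejected under the
  first-match convention.
* Per-chain models only: no paired H+L joint features, no sequence-
  content features, no probability calibration.
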