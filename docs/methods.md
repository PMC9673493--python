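# Methods

This note documents the models, rules and numerical choices behind each
stage of the curation pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Read filtering

A HiFi read is kept iff its length is strictly over 2,000 bp **and** its
accuracy is strictly over 0.99. Accuracy is defined as one minus the mean
per-base error probability, `1 − mean(10^(−Q/10))`, not one minus the error
probability of the mean Q: averaging probabilities matches the meaning of
"average read accuracy" and penalises a few very poor bases appropriately.
Totals are conserved: kept + removed bases always equals input bases.

## Graph topology triage

Connectivity is computed on the undirected multigraph of segments; link
orientation is ignored for connectivity because the three classes are
topological (what the graph looks like in a viewer), not walk-constrained.
Reverse-complement restatements of the same junction (`A+ B+` vs `B− A−`)
are collapsed to a single edge before cycle counting, otherwise every
ordinary join would look like a two-edge cycle. A connected component with
`E > V − 1` edges contains a cycle and is called **tangled**; an acyclic
component is **linear**; a single segment whose self-link has matching
orientation signs is **circular**. A lone segment with only a `(+,−)`
self-link joins the sequence to its own reverse complement — that is not a
circular chromosome, so the call is conservative: linear. Mean component
depth is the length-weighted mean of segment depths; depth is read from the
`rd:i:` GFA tag (hifiasm-meta's convention), falling back to `dp:f:`, then 0
— depth is never inferred from reads.

## Fragment ANI

The estimator follows the FastANI recipe with explicit, configurable
internals:

* fragment length 3,000 bp (non-overlapping; the trailing partial fragment
  is dropped), k-mer size 16, fragment-identity floor 80%;
* each fragment is located by voting: every shared 16-mer votes for a
  diagonal (reference position − fragment position), diagonals are pooled in
  64 bp bins so small indel drift votes together, both fragment orientations
  are tried (the reverse scan is skipped when the forward vote is already
  decisive), and at least 2 votes are required;
* the fragment is then aligned to the winning reference window (±64 bp pad)
  by infix edit alignment (edlib); identity = matches / alignment columns,
  gaps counted;
* ANI is the mean identity over fragments at or above the 80% floor, is
  directional, and is *undefined* (not zero) when nothing maps — two random
  genomes share essentially no 16-mers, so unrelated pairs are undefined by
  construction.

On substitution-only mutants the estimator tracks the exact position-wise
identity to well under 0.1 percentage points (the acceptance sweep bounds it
at 0.3 across 0.5–5% substitution rates).

## Dereplication

Directional ANIs are symmetrized by the **minimum** of the two defined
values — the conservative choice, never under-reporting divergence; a pair
with no defined estimate sits at distance 1.0. Distances are
`(100 − identity)/100`. Complete-linkage agglomeration merges the closest
pair of clusters while that distance is **strictly below** the stop distance
(0.01 strain level, 0.05 species level). The strict rule means a pair at
exactly 99.0% ANI is *not* merged at strain level, consistent with retained
representatives being allowed mutual ANI up to and including 99%. Ties are
broken by the lexicographically smallest pair of cluster labels (a cluster's
label is its smallest member id), which makes the result bit-for-bit
reproducible and invariant to input order. The implementation updates
distances by the Lance–Williams maximum rule; the test suite checks it
against a from-scratch agglomerative reference on hundreds of random
matrices.

Representative selection orders cluster members by: circular first, then
larger CheckM score (completeness − 5 × contamination), then larger
assembly size, then smaller genome id. The last two keys are deterministic
tie-breaks so equal-quality clusters always resolve the same way.

## Quality ranks and RNA completeness

Rank boundaries are `≥` on completeness and strict `<` on contamination
(near complete `≥90 / <5`, high `≥70 / <10`, medium `≥50 / <10`); the first
matching rank wins, otherwise `fail`. An inclusive-contamination variant
(`≤`) is exposed because the two conventions differ only at the exact
boundary and both appear in practice; the default is the strict reading.

rRNA operons are maximal same-contig, same-strand chains of rRNA genes with
inter-gene gaps ≤5 kb; typical bacterial operons span ~5–7 kb, and the gap
is configurable because no universal colocation rule exists. A chain counts
as an operon only if it contains a *full-length* copy of each of 5S, 16S
and 23S; full-length status is consumed as an annotation attribute, not
recomputed. The tRNA criterion defaults to ≥18 full-length *copies* (the
literal criterion), with a distinct-isotype mode provided because
MIMAG-style checklists count distinct tRNAs.

## Novelty

Genome novelty takes the best symmetrized ANI over the reference set; a
match requires ANI strictly *above* the threshold (99% strain, 95% species),
so `novel_strain = not (ANI > 99)`. An undefined best ANI (nothing maps)
makes the genome novel at both levels. 16S novelty uses the best
local-alignment identity (match +1, mismatch −1, gap open −2, gap extend −1
— a simple default; at the 94–98% identity range the calls are insensitive
to the exact scoring, which is configurable) and requires at least 100
aligned columns to be defined; identity below 97% suggests a novel species,
below 95% a novel genus, strict inequalities throughout.

## Gene catalog

Greedy clustering visits genes longest-first, screens candidate
representatives by at least one shared exact 10-mer, and joins the **first**
representative (in creation order — the documented CD-HIT behaviour; a
join-best mode exists for sensitivity analysis) whose best local alignment
reaches ≥95% identity with an aligned span covering ≥90% of the shorter
gene. Identity counts gap columns in the denominator, consistent with
local-alignment identity. Representatives are therefore always the longest
member of their cluster. Catalog comparison marks a gene shared when *any*
gene of the other catalog meets the same two criteria (both inclusive);
reciprocity is not required. The structure-completeness ratio is the
fraction of genes whose partial flags are `"00"` (both start and stop edges
present).

## Synthetic communities

The generator encodes the study conditions the pipeline assumes:

* **Genomes.** Each species has an independent uniform-random ancestor
  (background inter-species identity ≈25%, far below the 80% ANI
  detectability floor — deep-divergence simulation would add nothing at
  these thresholds). Strains mutate from the ancestor at per-site rate
  `(100 − intra_ANI)/100` (default target 99.3, matching strain-level
  divergence in real communities), plus indels at one tenth that rate with
  lengths 1–5 so the aligner is exercised on non-trivially alignable
  sequence; a substitution-only mode keeps identities closed-form. Pairwise
  strain identity is ~2× the per-strain divergence from 100. A single strain
  per species is the ancestor itself. Abundances are normalised lognormal
  draws (realistically skewed).
* **Graphs.** Circular genomes are one self-linked segment; tangled species
  cut each strain into 4–8 pieces routed through one shared segment, giving
  a multi-segment cyclic component; linear genomes are 1–3 segment open
  paths. Depth = abundance × 300 (the scale is arbitrary and nothing depends
  on its absolute value).
* **Annotations.** Operons place full-length 16S (1.5 kb), 23S (2.9 kb) and
  5S (0.12 kb) on one strand with gaps ≤500 bp; a broken operon drops or
  truncates one gene. tRNAs fall uniformly outside operons, isotypes cycling
  through the 20 amino acids. Features are positional fixtures — the
  sequence under them is not homologous to real RNA genes, so these test
  the criteria, not the predictors.
* **Gene families.** `within_family_identity` is the expected *pairwise*
  identity between members (each diverges half that rate from the founder);
  the default 98% keeps families ≥3 points above the 95% clustering
  criterion, so truth recovery is well-posed rather than a sampling coin
  flip. Member lengths vary ±10% as prefixes of a longer founder, so the
  shorter of any pair is always fully covered.

What the generator does **not** emulate: read-level errors, real gene
content or rRNA/tRNA homology, repeat structure, uneven within-genome
coverage, or chimeric binning artifacts. Passing recovery tests therefore
demonstrates correctness of the decision rules and estimators under the
assumed statistical structure, not robustness to every failure mode of real
assemblies.

## Problem sizes and determinism

The test and acceptance workloads use 20–50 kb genomes (identity estimates
on 50 kb sequence have sampling noise ≈0.04 percentage points at the default
rates, comfortably inside the generator's ±0.3 tolerance), communities up to
5 species × 3 strains, 200 random matrices (n ≤ 12) for the clustering
oracle, and 100 random gene sets (≤60 genes, 120–260 bp) for the catalog
oracle — sizes at which every quantity is recomputed from scratch in well
under a minute per stage. All randomness flows through
`numpy.random.default_rng` seeded from a single `--seed`/argument, and every
clustering and selection rule carries explicit deterministic tie-breaks, so
identical inputs give byte-identical outputs.

## Known limitations

* The ANI estimator has no minimizer acceleration; all-pairs dereplication
  is quadratic in community size and intended for hundreds, not tens of
  thousands, of genomes.
* The tangled/linear boundary is one consistent cycle-based reading of a
  visual classification; a large acyclic aggregate of many strains would be
  called linear.
* Whether clusters should merge at `<` or `≤` the stop distance, and whether
  directional ANIs should be symmetrized before clustering, are genuinely
  open conventions; both choices here (`<`, min-symmetrization) are
  documented above and configurable in code rather than asserted as the only
  possibility.
* completeness/contamination are consumed as inputs; the package does not
  recompute marker-gene statistics.
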