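# Methods

## Model and procedure

The package infers physical clustering of biosynthetic domains from their
co-occurrence pattern across the subpools of an arrayed cosmid library. The
underlying physical model: an insert of length *L* that covers a locus also
covers a second locus *d* bp downstream with probability max(0, (L−d)/L)
(the insert's start is uniform over the window covering the first locus).
With ~38 kb inserts and domains 2–8 kb apart, most captures of one domain
co-capture its neighbours, so clustered domains share subpools far above
chance; unlinked domains land in subpools independently.

The analysis pipeline has five stages, each usable on its own:

1. **Demultiplexing** (`debarcode`). Forward reads carry one of 24 column
   barcodes, reverse reads one of 16 row barcodes (8 or 12 nt), addressing
   24×16 = 384 subpools per plate. Barcode prefixes are matched by Hamming
   distance (default: exact matching; 8–12 nt barcodes with pairwise
   distance ≥ 3 make one mismatch tolerable, but exact is the conservative
   default). A unique best match is required on both axes; reads with `N`
   in the barcode window, no match, or tied matches are set aside with a
   categorical reason. Only the forward read continues: after barcode
   removal it is truncated to `total_len` and stripped of `primer_len`
   leading bases (covering spacer plus degenerate primer), so all retained
   reads have identical length; shorter reads are discarded. Coordinates
   are 0-based half-open throughout.

2. **Variant table** (`variant_table`). Reads are dereplicated per subpool
   into (sequence, subpool, count) records, pooled, sorted by count
   (descending, ties lexicographic) and greedily clustered: each record
   joins the first centroid at ≥ 95% identity, else founds a new cluster.
   Identity is identical columns over alignment columns (gaps count as
   columns) from a global alignment under match +1 / mismatch −1 / gap −2.
   Three filters follow: (i) members with < `min_reads` reads are dropped
   (default 2 — the per-domain cut-offs of the original datasets are
   dataset-specific, so this is a required config with a conservative
   default); (ii) members with < 5% of the centroid record's count are
   dropped (the centroid record itself is exempt); (iii) clusters spanning
   < 3 distinct wells are discarded, as two wells cannot support a
   co-occurrence test. The result is a boolean variant × subpool matrix
   over the **full** subpool universe — empty subpools still count in the
   test population. Per-domain tables from different primer systems merge
   by row union with domain-type-namespaced ids.

3. **Linkage** (`linkage`). Candidate pairs (sharing ≥ 3 subpools, found
   via a sparse presence product, never a dense all-pairs loop) get a
   one-sided Fisher exact p — the hypergeometric right tail — computed in
   log-space with log-gamma binomial coefficients and summed relative to
   the largest term, keeping relative error near machine precision even
   for p below 1e−300 and populations of thousands of subpools. The
   enrichment direction is one-sided because only *excess* co-occurrence
   indicates linkage. The multiple-testing family is the set of pairs
   actually tested. Adjustment is the two-stage Benjamini–Krieger–Yekutieli
   step-up: BH at q′ = q/(1+q); if it rejects r₁ of m hypotheses
   (0 < r₁ < m), BH again at q′·m/(m−r₁). Reported adjusted values are the
   smallest q at which the two-stage procedure rejects (found by bisection;
   the rejection set is monotone in q), so "adjusted p < 10⁻⁶" is a single
   comparison. Rejection flags at a given q are computed directly by the
   step-up, not thresholded from adjusted values, so boundary semantics are
   exact. The FDR level q defaults to the significance threshold alpha
   (10⁻⁶) but is exposed separately.

4. **Networks** (`network`). Significant links form a graph; connected
   components with ≥ 3 nodes are domain networks (named deterministically
   after their smallest member). `merge_similar_nodes` collapses same-type
   nodes above 90% identity by single linkage within each network; the
   representative is the highest-read constituent, subpools are unioned,
   parallel edges keep the smallest adjusted p. The size filter applies
   after merging (merging is an anti-redundancy step; a component that
   merges below 3 nodes no longer evidences 3 distinct domains). Exports
   (GraphML, edge/node TSV) are byte-deterministic and round-trip.

5. **Similarity and validation** (`similarity`). Node centroids are
   translated in the frame with fewest internal stops (ties to the lowest
   frame; stops retained as `*` so junk frames score poorly rather than
   truncating silently) and locally aligned to reference BGC proteins
   (BLOSUM62, gap open −11 / extend −1, query coverage ≥ 80%). No E-value
   is computed: the original gate's E-value depends on database size,
   which is irrelevant to threshold-based classification; coverage plus
   the downstream identity thresholds carry the same intent. Hits on one
   protein group into independent positions by single linkage over > 25%
   reciprocal interval overlap (the overlap rule is our operationalization
   of "independent positions"); nodes are assigned to positions by exact
   maximum-weight matching (Hungarian algorithm). If ≥ 50% of a network's
   domains are matched, the similarity score is the median percent
   identity over **all** domains, unmatched domains entering as 0 — the
   only reading that makes "taking into account non-matching domains"
   operative; the convention is switchable. A network is *known* if some
   reference scores ≥ 75%, else *novel*; two networks are closely related
   (asymmetric, from the query side) when ≥ 50% of the query's domains
   match at ≥ 90% identity. Contig validation aligns centroids at the
   nucleotide level against both strands (coverage ≥ 80%) and counts nodes
   at ≥ 93% identity as validated; validated + false = node count always.

`abundance` implements the two coverage extrapolations for shallow
untargeted sequencing of the pooled library: required output to reach a
target depth (`sequenced_output / depth × target_depth`, default
15.5 Gbp → 20×) and source-genome frequency (`depth × genome_size /
sequenced_output`, default genome 10 Mbp). Read mapping and duplicate
removal happen upstream; this module consumes a depth table.

## Simulator

`simulator` generates libraries with known truth. Genome abundances are
log-normal (σ = 1.5 by default) — a standing model for skewed community
composition; the exact law in real soils is unknown, so σ is exposed.
Genomes are circular coordinate systems (10 Mbp by default, a typical
soil-actinomycete scale; sequence is materialized only for domains);
each carries one BGC of 4 domains (230 nt each, matching the trimmed
amplicon length) with 2–8 kb between domains. Clones sample a genome
proportionally to abundance, an insert start uniformly, and a length from
a normal (mean 38 kb, sd 4 kb) truncated to 20–45 kb. Partitioning deals
clones round-robin over a random permutation — exact arraying, subpool
sizes within one clone — with an i.i.d.-uniform (`poisson`) mode as a flag.
Detection applies i.i.d. per-(domain, subpool) dropout (default 10%); the
real data's differential amplification efficiencies have no published
model, and this simplification biases toward false negatives, the
direction the statistics tolerate. Read mode emits barcoded read pairs
per detection (5–15 reads) with substitution-only errors, so fixed-length
trimming semantics hold exactly; quality scores, chimeras and
vector/host contamination are not modeled. Presets: `small`
(384 × 1000 clones — the scale used throughout the tests), `tiny`
(96 × 200, read-mode scale), `arizona` (2304 × 5000).

What passing simulator-based tests shows: the statistics recover planted
co-capture structure at realistic library geometry and noise, and the
read-level front end is exactly consistent with the matrix-level model.
What it does not show: robustness to cross-contamination, index switching,
chimeric amplicons, indel sequencing errors, primer bias correlated with
sequence, or non-log-normal abundance structure in real soils.

Ground-truth scoring: a predicted variant maps to a true domain at ≥ 95%
identity. Precision is over mapped predicted pairs; recall's denominator
is restricted to true pairs co-captured in ≥ 3 distinct subpools, since
pairs below the candidate floor are statistically invisible by
construction. Empty predictions report precision 1.0 with a zero-support
flag. A BGC counts as recovered when ≥ 3 of its domains land in one
network.

## Numerical choices and edge cases

- Fisher tails: vectorized over pairs, term-by-term in log space; n₁₁ = 0
  returns exactly 1; results clamped to [0, 1].
- Greedy clustering: for equal-length sequences the ungapped identity is a
  provable lower bound on aligned identity under the +1/−1/−2 scheme (a
  gapped alignment only wins by *raising* identity), so a Hamming pass
  accepts immediately and exact alignment runs only within a band of 0.10
  below threshold or for unequal lengths (length-ratio bound prunes
  hopeless pairs). `prescreen_band=None` forces full alignment. Identical
  sequences share one cached clustering decision.
- Tie-breaks: clustering order is (count desc, sequence, subpool);
  merge representatives break read-count ties by variant id; network ids
  come from the lexicographically smallest member.
- Empty candidate sets, empty networks and empty exports are valid
  results, not errors; unassignable reads are data with a reason code.
- BKY adjusted values use 60 bisection steps (absolute error < 1e−15);
  hypotheses not rejected even at q = 1 report 1.0.

## Known limitations

- Recall of detectable pairs at the default desk-scale conditions is
  seed-dependent (roughly 0.78–0.97 across seeds): the rarest genomes'
  widest-spaced domain pairs sit exactly at the significance boundary, and
  per-(domain, subpool) dropout can push their observed overlap below the
  candidate floor. Precision is insensitive to this (measured 1.0
  throughout).
- The greedy clustering is single-pass with static centroids (the cited
  clustering tool's semantics, chosen for determinism); it does not
  re-centroid and is order-dependent by design.
- Cross-domain-type pairs are tested identically to within-type pairs;
  merging never crosses domain types (non-homologous amplicons).
- The similarity scorer's 25% reciprocal-overlap rule and the
  unmatched-as-zero median are conventions; both are parameters.
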