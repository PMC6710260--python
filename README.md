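# conkatseq

Co-occurrence network analysis of targeted amplicon sequences: inference of
physically clustered biosynthetic domains from a partitioned metagenomic
clone library.

## The problem

Soil metagenomes hold thousands of bacterial species, and most of their
secondary-metabolite potential sits in biosynthetic gene clusters (BGCs) of
rare genomes that shotgun sequencing cannot reach at any practical depth.
When a metagenomic library of ~38 kb cosmid inserts is arrayed into a few
thousand subpools, two conserved biosynthetic domains (e.g. NRPS adenylation
or PKS ketosynthase domains) that sit a few kilobases apart on the same
chromosome are co-captured onto the same inserts — and therefore appear
together in the same subpools far more often than independent loci would.
This package turns that observation into a statistical screen: amplify the
domains from every subpool with barcoded degenerate primers, record which
domain sequence variants occur in which subpools, and test every candidate
pair for non-random co-occurrence.

## The statistic

For variants *A* and *B* over *N* subpools, the 2×2 contingency table
(n₁₁, n₁₀, n₀₁, n₀₀) counts subpools with both, one, or neither variant.
Under the null of independent dispersal, n₁₁ follows a hypergeometric law
with population *N* and margins k_A = n₁₁+n₁₀, k_B = n₁₁+n₀₁; the one-sided
(enrichment) Fisher exact p-value is

p = Σ_{k ≥ n₁₁} C(k_A, k) · C(N−k_A, k_B−k) / C(N, k_B),

computed in log-space via log-gamma so populations of thousands of subpools
are exact. Only pairs sharing ≥ 3 subpools are tested; p-values are adjusted
with the two-stage Benjamini–Krieger–Yekutieli step-up, and pairs with
adjusted p < 10⁻⁶ become edges. Connected components of ≥ 3 variants are
domain networks — each a (partial) BGC prediction — with near-identical
nodes (> 90% identity) merged. Networks are scored against reference BGC
proteins (local alignment, ≥ 80% query coverage, best combination of matches
to independent reference positions; the score is the median percent identity
over all domains, unmatched domains counting as 0) and validated against
assembled contigs at 93% nucleotide identity.

A fully seeded simulator generates partitioned libraries with known
clustered-domain ground truth — skewed (log-normal) genome abundances,
insert co-capture geometry P(co-capture) = (L−d)/L, per-subpool
amplification dropout and per-base sequencing error — so every stage is
testable without external data, at either the occurrence-matrix or the raw
barcoded-read level.

## Worked example

```python
import dataclasses
from conkatseq import (PRESETS, simulate_run, detect_links, build_networks,
                       score_recovery, count_recovered_bgcs)

params = dataclasses.replace(PRESETS["small"], seed=1)   # 384 subpools x 1000 clones
run = simulate_run(params)                               # 20 genomes, one 4-domain BGC each
matrix = run.occurrence_matrix()
print(matrix.n_variants, "variants across", matrix.n_subpools, "subpools")

links = detect_links(matrix, alpha=1e-6, min_shared=3)
print(len(links.tests), "pairs tested,", len(links.significant_links()), "linked")

nets = build_networks(links, matrix, min_size=3)
score = score_recovery(links, run.truth)
print(f"precision {score.precision:.3f}  recall {score.recall:.3f}  "
      f"networks {len(nets)}  BGCs {count_recovered_bgcs(nets, run.truth)}/20")
```

prints

```
76 variants across 384 subpools
1544 pairs tested, 102 linked
precision 1.000  recall 0.895  networks 19  BGCs 19/20
```

All 102 linked pairs are genuinely co-clustered (precision 1.0) and 19 of
the 20 simulated BGCs come back as ≥3-node networks; recall over
statistically detectable true pairs is 0.895 — the missed pairs are the
rarest genomes' terminal domain pairs, whose co-occurrence counts sit at
the edge of significance.

The same flow is available from the shell:

```sh
conkatseq simulate --preset tiny --seed 3 --mode reads --out sim/
conkatseq demux --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --scheme sim/scheme.tsv --out-dir demux/
conkatseq cluster --in-dir demux/ --scheme sim/scheme.tsv --out occurrence.tsv
conkatseq links --matrix occurrence.tsv --out links.tsv
conkatseq networks --links links.tsv --matrix occurrence.tsv --out nets
```

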