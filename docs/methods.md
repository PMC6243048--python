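# Methods

This document records the algorithmic model, the parameter defaults and their
boundary semantics, the numerical choices, and the deliberate design
decisions behind `isocore`.

## 1. Colored De Bruijn graph (`isocore.graph`)

- **Nodes** are canonical k-mers: the lexicographic minimum of a k-mer and
  its reverse complement. k must be odd (no self-reverse-complement k-mers)
  and defaults to **47**.
- **Colors** are data sources — one per sample, seed set, or long-read
  group — each carrying its own per-node coverage and its own edge set, over
  a shared node space. Edges are stored Cortex-style as per-color incoming
  and outgoing base sets on each node, oriented relative to the canonical
  strand; this keeps the graph strand-symmetric: traversing a node forward
  or in reverse complement yields mirrored neighbor sets.
- Windows containing non-ACGT characters are skipped (not an error); reads
  shorter than k contribute nothing.
- `merge_graphs` unions graphs with disjoint color sets; `flatten_colors`
  sums coverages and unions edges into a single color (used for the
  long-read "joined view", see §6).

## 2. Unitigs and coverage filtering (`isocore.unitigs`)

- A **unitig** is a maximal non-branching run of nodes with respect to a
  designated set of *collapse colors*; its sequence is reported in canonical
  orientation (lexicographically ≤ its reverse complement) and its
  **mean coverage** per color is the arithmetic mean over its k-mers.
- Unitig-level links are oriented `(unitig, ±) → (unitig, ±)` pairs stored
  per color. Links from colors outside the collapse set that would enter a
  unitig mid-sequence are dropped (they do not exist at unitig resolution).
- `filter_unitigs_by_mean_coverage(ug, threshold, color)` removes unitigs
  with mean coverage **strictly below** the threshold (default 4: a mean of
  exactly 4.0 survives, 3.99 does not) and re-collapses the survivors with
  the original collapse colors, since removing a junction neighbor can make
  previously separate unitigs mergeable.

## 3. Seed subgraphs, tip pruning, candidates (`isocore.seeds`)

- A **seed** ("core region") is a known conserved sequence. Its k-mers are
  located in the unitig graph and the undirected connected component around
  them is extracted; a component hit by several seeds is returned once with
  all seed names.
- **Tip pruning** iteratively removes unitigs that lack predecessors or
  successors (in oriented unitig space) and span **fewer than 47 k-mers**
  (strict: a 47-k-mer tip survives). Unitigs containing seed k-mers are
  exempt, so pruning can never disconnect the anchor. Iteration runs to a
  fixed point because removing a tip can expose a new one.
- **Candidate transcripts** are all tip-to-tip **simple paths** (no unitig
  visited twice, in either orientation) through the pruned subgraph,
  enumerated by DFS from oriented incoming tips. Each path and its reverse
  complement are one candidate. Enumeration is capped (default 10 000
  paths); exceeding the cap raises `PathExplosionError` rather than
  returning a silently truncated set.
- Across samples, retained candidates are deduplicated
  reverse-complement-aware; the representative is the lexicographically
  smaller strand.

## 4. Pseudoalignment, EM, bootstrap filter (`isocore.quant`)

- A read (or read pair) **pseudoaligns** to the intersection, over its
  k-mers, of the candidate sets containing each k-mer. K-mers absent from
  every candidate are skipped rather than forcing emptiness (errors and
  untouched flanks should not unassign a read); a read with no indexed k-mer
  at all is unassigned. Pairs with identical compatibility sets form
  **equivalence classes**.
- The original workflow pre-mapped reads externally and kept pairs with both
  mates mapped; this package replaces that external step with an optional
  internal prefilter (`require_both_mates_indexed`: both mates must share at
  least one k-mer with some candidate), off by default.
- **EM**: E-step allocates each class count to member transcripts
  proportionally to `θ_t / ℓ̃_t`; M-step renormalizes. Effective length
  `ℓ̃_t = max(1, L_t − fragment_mean + 1)` with `fragment_mean = 200`.
  Estimated counts are allocated read counts (they sum to the assigned
  total), not TPM. Convergence: relative change below `em_tolerance`
  (1e-8) or `em_max_iter` (1000).
- **Bootstrap**: class counts are resampled multinomially
  (`numpy.random.default_rng(rng_seed)`, deterministic), EM re-run per
  replicate; a candidate's **support** is the number of replicates with
  estimated count ≥ `min_count` (default 1). Resampling equivalence-class
  counts is distributionally identical to resampling reads and costs
  O(classes) per replicate.
- **Retention rule**: support ≥ 95 of 100 (inclusive: 95 retained, 94
  rejected).

## 5. Similarity evaluation (`isocore.evaluation`)

- `cigar_match_length(cigar, substitutions)` = sum of `M`/`=` operation
  lengths minus substitution mismatches (floor 0). Insertions, deletions,
  clips, `N`, and padding contribute nothing.
- `similarity_proportion = match_length / reference_length`, capped at 1.0
  (a CIGAR whose M ops span inserted bases can nominally exceed the
  reference; a warning is logged). **Design decision:** the prose definition
  this statistic descends from is stated as reference length divided by
  match length, but the published values are only reproduced by the inverse;
  this package defines and ships match_length / reference_length.
- Substitution counts can be recovered from an alignment's NM tag:
  `substitutions = max(0, NM − inserted bases − deleted bases)`.
- `best_match_similarity(assembled, references)` aligns every assembled
  sequence (both strands) against every reference with edlib infix
  alignment in both containment directions and keeps the best match length
  per reference. CIGAR tokenization is a small regex (a free-standing CIGAR
  string cannot be parsed by pysam without a full alignment record); the
  test oracle is an independent character-walker.
- `isocore.benchmarks` packages 16 published best-match alignment records
  (four assembly strategies × four cloned DAL19 isoform references). 12 rows
  are fully determined by CIGAR + reference length under zero substitutions
  and must recompute exactly; 4 rows would need unpublished per-alignment
  substitution counts and are marked `evaluable = 0`.

## 6. Long-read (CCS) rules (`isocore.longread`)

- **Edit-distance filter**: keep alignments with NM **strictly below 5**
  (4 kept, 5 dropped).
- **Region grouping** (which alternative 5' exon does a read carry):
  *primary and supplementary* alignments count; secondary alignments do
  not. A read touching neither alternative region is "neither" (core-only,
  e.g. 5'-truncated molecules); a read touching both is "excluded".
- **Unique-locus counting**: *primary and secondary* alignments count; a
  read counts once for a locus only if **all** its alignments fall in that
  locus, otherwise it counts for none. The two rules intentionally use
  different alignment roles, mirroring the workflow they reproduce.
- **Threading**: each CCS read becomes its own graph color; per group the
  read colors are flattened into one, merged into the short-read graph, and
  unitigs whose **total** (summed over all colors) mean coverage is below 2
  are pruned. The source workflow did not state which color the post-join
  prune reads; summing is the only choice that lets high-coverage short-read
  unitigs protect the graph while dropping single-pass CCS error k-mers.
- `align_ccs_reads` produces alignments with edlib (infix mode), ranking
  hits per read: best is primary, others secondary.

## 7. Synthetic locus generator (`isocore.simulate`)

- `make_mutually_exclusive_gene` draws a locus with two alternative 5' exons
  (α, β), a shared core (ψ), and two alternative 3' exons (γ, δ); default
  lengths 200/200/500/250/300. Sequences are uniform random with rejection
  until **no two parts share a canonical k-mer**, so the unitig graph of the
  four long isoforms is an exact 5-unitig diamond — topology is a designed
  invariant, not a probabilistic hope.
- **UTR-like flanks** (default 100 bp) are attached outside the alternative
  exons on the *transcribed* molecules only, while reference isoforms are
  exon-only. Reads are simulated from the flanked molecules; assembled
  candidates therefore overhang the references (soft-clipped/inserted ends
  in the evaluation alignment) while covering them completely — matching
  how real assembled transcripts relate to cloned CDS references, and what
  makes exact similarity 1.00 achievable: without flanks the terminal
  reference bases have near-zero expected read depth and candidates fall a
  few bases short.
- Short reads: shotgun fragment model (normal fragment length, mean 250,
  sd 25, 2×125 bp), fragment counts length×abundance-weighted to hit a
  target mean depth, optional substitution errors, resampling of fragments
  longer than the molecule, truth labels per pair. CCS reads: full-length
  copies with optional indel noise and uniform 5'-end truncation, truth
  labels per read.
- Everything is deterministic given its seed.

## 8. Testing strategy

Every behavior with an external ground truth is checked against an
**independent oracle** implemented differently from the library code:

| Component | Oracle |
|---|---|
| k-mer counting | plain hash tally |
| unitig decomposition | greedy bidirectional extension |
| component extraction | `networkx.connected_components` |
| simple-path enumeration | `networkx.all_simple_paths` (graphs ≤ 12 unitigs) |
| pseudoalignment | substring search |
| EM | likelihood grid search (coarse-to-fine) |
| bootstrap support | independent Monte-Carlo (10⁴ replicates, own vectorized EM, binomial 99 % bounds) |
| CIGAR parsing | character-by-character token walker |
| similarity benchmarks | packaged published values, exact |

Boundary semantics (4.0 / 3.99 coverage, 47 / 46 k-mer tips, 95 / 94
support, NM 4 / 5) each have explicit two-sided tests. `hypothesis` runs
derandomized. `tests/test_acceptance.py` holds one test per acceptance
criterion; `scripts/acceptance.py` emits the exact recomputed benchmark
values.

## 9. Scope and limitations

- Study-scale results (transcriptome-wide assembly counts, differential
  expression tallies, per-gene CCS counts) depend on unreleased read sets
  and manual curation; they are *declared out of scope* and covered only by
  the property/oracle suites. No study-scale number is claimed anywhere in
  this package.
- Simple-path enumeration is exponential in branch count; the cap turns
  pathological loci into an explicit error. Cyclic components yield the
  acyclic simple paths only.
- The generator models substitution and indel errors but not coverage
  biases, quality-score structure, adapter artifacts, or fusion reads.
- Pseudoalignment skips unindexed k-mers; with very short candidates and
  long reads this is more permissive than a full aligner.
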