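# Methods

This note defines the algorithm implemented by `synclust` precisely
enough to reimplement it. Defaults in parentheses are the values the
CLI ships with.

## Data model

A **gene** is a located, stranded, translated coding feature: genome
id, contig id, 0-based half-open nucleotide interval `[start, end)`,
strand, and protein sequence. Genomes are read from nucleotide FASTA
plus GFF3: CDS records are used, joined features (several CDS lines
sharing one `ID`) contribute a union span and concatenated
translation, a `translation` attribute is preferred over translating
the extracted sequence, and an internal stop codon triggers a warning
and is stripped. A CDS on a contig absent from the FASTA is a hard
error naming the contig.

The **neighbourhood** of a gene is the set of other genes on the same
contig whose edge-to-edge gap (0 for overlapping features) is at most
the window (6000 bp). Neighbourhoods are symmetric by construction
and computed with a linear sweep over start-sorted genes.

## Guide tree and schedule

The guide tree is a rooted Newick phylogeny whose leaves are genome
ids (duplicates are an error). Unlabelled internal nodes receive
generated names. Non-binary nodes are resolved into a deterministic
ladder, joining the two subtrees with the lexicographically smallest
leaf names first. Internal nodes are processed in post-order, with
children ordered by smallest descendant leaf name; any node whose
children are complete may run, so independent subtrees parallelize
(`--jobs`) without affecting results.

## Similarity model

Two interchangeable backends produce hits between the representative
sequences of two sibling nodes:

- **builtin**: Smith-Waterman local alignment (BLOSUM62, gap open 11,
  extend 1). A raw score `S` becomes a bitscore
  `(λS − ln K)/ln 2` with fixed `λ = 0.267`, `K = 0.041`, and the
  E-value is `m·n·2^(−bit)` where `m`, `n` are the total residue
  counts of the two sets. These constants make scores internally
  consistent — every downstream use is relative — without claiming
  BLAST calibration. Pairs sharing no 4-mer are skipped without
  alignment; at the divergences the pipeline operates on, genuinely
  homologous pairs always share 4-mers, so this is purely a speed
  optimization.
- **blast**: NCBI `blastp` (tabular output, 12 columns), run in both
  directions. Precomputed per-node tables can be supplied with
  `--hits-dir`.

Per (query, subject) pair only the best-bitscore hit is kept;
self-hits are dropped. Filtering then applies a lenient E-value
cut-off (1e-5) followed by per-query retention of hits scoring at
least a fraction (0.8) of that query's best retained hit, measured on
bitscore by default or percent identity (`--best-hit-metric`); ties
at the boundary are kept, and the filter is idempotent. A pair is
**reciprocal** when hits survive in both directions.

## Per-node merge

At an internal node with child orthogroup sets `P` and `Q`:

1. **Initial clustering.** Reciprocal gene pairs are lifted to
   orthogroup-level edges via the representative → orthogroup map.
   Connected components with ≥ 2 orthogroups become initial
   clusters; singleton components pass through unmerged.
2. **Synteny scoring.** Every descendant gene is projected to a
   common label space: its initial-cluster id if its orthogroup
   joined one, else its orthogroup id. For two genes with
   neighbourhoods `N_a`, `N_b`, the **syntenic fraction** is

       shared / (|N_a| + |N_b| − shared)

   where `shared` is the multiset intersection of the projected
   labels (a gene missing from the projection counts as its own
   unique label; two empty windows score 0). The orthogroup-pair
   score is the mean over all cross-child member-gene pairs.
3. **Finalization**, per initial cluster:
   - *Phase 1 (synteny).* Cross-child pairs with syntenic fraction ≥
     the threshold (0.5) are merged greedily, highest fraction first,
     ties broken by descending orthogroup-level bitscore (the
     maximum over representative pairs), then lexicographic ids;
     each orthogroup merges at most once.
   - *Phase 2 (RBH).* Among the phase-1 survivors, orthogroup pairs
     that are each other's highest-bitscore surviving partner are
     merged, best score first, same discipline.
   - *Phase 3 (marking).* Each still-unmerged orthogroup passes
     through carrying a **paralogue mark**: the gene id of its best
     hit within the cluster. A marked orthogroup that merges at a
     later node loses its mark; orthogroups that never entered a
     cluster keep any existing mark (absence of homology evidence is
     not evidence of paralogy).
4. **Representatives.** For every merged parent, candidates (the
   union of the children's representatives) are placed in a distance
   matrix and covered greedily: the longest uncovered sequence
   becomes a representative and claims all candidates within
   `rep_distance` (0.3). Distances come from a 4-mer count-vector
   cosine dissimilarity in `[0, 1]` (builtin) or from patristic
   distances on a FastTree tree of an external alignment
   (`--rep-backend external`, `--aligner-cmd` template with `{in}`
   and `{out}`); the two scales differ, so the threshold is
   backend-specific.

Genes are never lost or duplicated: at every node the parent
orthogroups partition exactly the union of the children's members
(violations raise an assertion error).

## Root resolution

Marks that survive to the root denote potential inparalogues.
`--root-policy annotate` (default) reports each marked orthogroup as
its own cluster with a `paralogue_of` reference to the cluster of its
best hit — keeping the single-copy core strict. `--root-policy
merge` folds marked orthogroups into their targets (chains of marks
collapse together), yielding family-level clusters. Both policies
partition the gene set. Final cluster ids `OG######` are assigned by
the smallest member gene id, making outputs byte-identical across
repeat runs, worker counts, and catalog orderings.

## Outputs

`clusters.tsv` (cluster, genome, gene, `paralogue_of`),
`presence_absence.tsv` (per-genome member counts), `scc.txt`
(single-copy core: exactly one member in every genome; multi-copy
core and accessory are derived from the same counts), optional
per-cluster FASTA, and `run_manifest.json` (version, full
configuration, summary statistics). Per-node state is checkpointed
as atomically written JSON under `--workdir`, enabling `--resume`.
Two QC metrics are provided: within-cluster annotation consistency
(mean Jaccard similarity of functional-term sets over annotated
intra-cluster pairs, or averaged per cluster; unannotated genes are
excluded, not scored zero) and per-cluster length spread
`(max − min)/max`.

## Simulator

A root genome of random proteins (mean length 150 aa, Gaussian
spread, always starting with M) evolves along the guide tree. Per
branch of length `t` with `n` genes, event counts are Poisson with
means `rate·t·n`: tandem (or random) duplication, loss, gain of a
novel gene (a horizontal-transfer stand-in), and rearrangement
(inversion or translocation of a geometric-length segment);
per-site substitution applies with probability `1 − exp(−rate·t)`.
Every emitted gene carries its ancestral family label, the planted
truth.

Six independent generator streams (root sequences, content events,
rearrangement, substitution, gain sequences, emission) are seeded as
`(seed, stream_index)`, and duplication/loss/substitution targets are
keyed by gene lineage rather than contig position. Consequence:
changing `rearr_rate` alone reorders genes but leaves gene content
and protein sequences bit-identical — rearrangement is a pure
synteny knob, which the monotonicity acceptance test exploits. Leaf
genomes are emitted as FASTA + GFF3 (uniform synonymous
back-translation, geometric intergenic gaps, minus-strand genes
reverse-complemented), read back by the same parsers the pipeline
uses.

Three scripted scenarios encode the corner cases the algorithm is
designed around, each with its expected final clustering: an ancient
duplication with one copy lost in one genome (the survivor must
rejoin its orthologues below the root, leaving no mark), a
horizontally acquired singleton, and a recent tandem duplication
(whose extra copy stays marked to the root, where policy decides).

## Evaluation

An inferred clustering is scored against the planted families on the
identical gene universe: adjusted Rand index, pairwise precision and
recall from the contingency table, and the fraction of planted
single-copy families recovered exactly as single-copy-core clusters.
Because planted families are root-level (they include inparalogues),
family-level comparisons use the `merge` root policy; the `annotate`
policy intentionally splits such families and caps below ARI 1.0 even
when every decision is correct.
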