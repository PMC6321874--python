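# synclust

Synteny-aware orthogroup clustering for bacterial pan-genomes.

`synclust` groups the protein-coding genes of a set of annotated
genome assemblies into **orthogroups** — clusters of genes descended
from a single ancestral gene — using both sequence similarity and the
conservation of gene neighbourhoods (synteny). From the final
clustering it derives the standard pan-genome summaries: the
single-copy core (SCC), the multi-copy core, the accessory genome,
and a presence/absence matrix.

## How it works

Closely related bacterial genomes are full of recent duplications and
highly similar paralogues that defeat similarity-only clustering.
`synclust` resolves them hierarchically along a **guide tree** (a
rooted phylogeny of the input genomes):

1. **Leaves.** Every gene starts as its own singleton orthogroup.
2. **Internal nodes** (visited leaves-to-root). The orthogroups of
   the two child nodes are compared:
   - an all-vs-all protein search between the children's
     *representative* sequences (builtin Smith-Waterman or NCBI
     `blastp`), filtered by a lenient E-value cut-off (1e-5) and an
     80 %-of-best-hit retention rule;
   - reciprocal hits are lifted to orthogroup-level edges; connected
     components form initial clusters;
   - inside each cluster, every cross-child orthogroup pair gets a
     **syntenic fraction**: the two genes' neighbourhoods (all genes
     within a 6 kb edge-to-edge window) are projected onto cluster
     labels and the fraction of shared neighbours is averaged over
     member pairs;
   - highly syntenic pairs merge first (greedily, best first), then
     remaining orthogroup-level reciprocal best hits; anything left
     unmerged is passed through carrying a **paralogue mark**
     pointing at its best hit — deferring the orthologue/inparalogue
     decision to a deeper node, where more genomes provide context.
3. **Representatives.** Each merged orthogroup is reduced to a few
   representative sequences (greedy longest-first cover under a
   distance threshold), keeping the per-node search cost bounded as
   clusters grow.
4. **Root.** A mark that survived to the root denotes a potential
   inparalogue. The `--root-policy` flag decides its fate:
   `annotate` (default) reports it as its own cluster with a
   `paralogue_of` reference; `merge` folds it into its best hit's
   cluster, yielding family-level clusters.

The package also ships a genome-evolution **simulator** (duplication,
loss, gene gain, rearrangement, substitution along the guide tree)
that plants ground-truth family labels, and an **evaluator** (adjusted
Rand index, pairwise precision/recall, SCC recovery) so the whole
method is testable end to end without external data.

## Worked example

Simulate four genomes along a guide tree, cluster them, and score the
result against the planted truth:

```
$ printf '((EC1:1,EC2:1)N1:1,(EC3:1,EC4:1)N2:1)R;\n' > tree.nwk
$ synclust simulate --tree tree.nwk --out sim --n-genes 30 --seed 4
wrote 4 genomes; catalog at sim/catalog.tsv

$ synclust run --catalog sim/catalog.tsv --tree tree.nwk --out run
42 clusters over 124 genes -> run

$ synclust evaluate --clusters run/clusters.tsv --truth sim/truth.tsv
ARI	0.8363
precision	1.0000
recall	0.7241
SCC_recovered	1.0000
```

The output directory contains the clustering and the pan-genome
summaries:

```
$ head -8 run/clusters.tsv
cluster_id	genome_id	gene_id	paralogue_of
OG000000	EC1	EC1_0000	.
OG000000	EC2	EC2_0000	.
OG000000	EC3	EC3_0004	.
OG000000	EC4	EC4_0000	.
OG000001	EC1	EC1_0001	.
OG000001	EC2	EC2_0001	.
OG000001	EC3	EC3_0006	.

$ head -4 run/presence_absence.tsv
cluster_id	EC1	EC2	EC3	EC4
OG000000	1	1	1	1
OG000001	1	1	1	1
OG000002	1	1	1	1

$ wc -l run/scc.txt        # single-copy core clusters
19 run/scc.txt
```

Precision is 1.0 but recall is not: under the default `annotate`
policy, surviving copies of within-tree duplications are reported as
separate clusters annotated with `paralogue_of`, which deliberately
splits the ancestral families the simulator uses as truth labels. The
`merge` policy produces family-level clusters directly comparable to
that truth:

```
$ synclust run --catalog sim/catalog.tsv --tree tree.nwk --out run_merge --root-policy merge
32 clusters over 124 genes -> run_merge

$ synclust evaluate --clusters run_merge/clusters.tsv --truth sim/truth.tsv
ARI	1.0000
precision	1.0000
recall	1.0000
SCC_recovered	1.0000
```

Other commands: `synclust validate` dry-checks a catalog + tree, and
`synclust run --workdir W --resume` checkpoints per-node state so an
interrupted run restarts where it stopped. Output files are
byte-identical across repeat runs, `--jobs` settings, and catalog
orderings.

## Reproduction

All results in this repository regenerate from scratch:

```
pytest -q                                             # full suite incl. acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite covers, per module, the documented behaviours plus
property tests (neighbourhood symmetry, filter idempotence, matching
validity, determinism), and `tests/test_acceptance.py` holds one test
per release criterion: null-process identity, planted-truth recovery
(median ARI ≥ 0.95 over seeds, scored with the family-comparable
`merge` policy as explained above), brute-force oracle equivalence of
the core primitives, the inparalogue-loss scenario, representative
selection limits, bytewise determinism, and monotone response of
synteny merges to rearrangement. `scripts/acceptance.py` re-runs the
headline computations for any seed and writes the quantities as JSON.

See `docs/methods.md` for the precise definitions (scoring model,
syntenic fraction, merge rules, simulator design).

## Limitations

- The builtin search scores with fixed Karlin–Altschul-style
  constants; E-values are internally consistent rather than
  BLAST-calibrated (the BLAST backend is available when calibrated
  statistics matter).
- The builtin representative distance is a 4-mer cosine
  dissimilarity; its scale differs from the patristic distances of
  the external backend, so `--rep-distance` must be chosen per
  backend.
- Guide-tree polytomies are resolved deterministically
  (lexicographically), not phylogenetically.
- Gene calls are taken as given; fragmented or missing annotations
  propagate into the clustering (the `size_discrepancy` QC metric
  helps flag affected clusters).
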