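"""Genome evolution simulator with planted orthogroup truth.

A root genome of random protein-coding genes is evolved along the
guide tree.  On every branch, gene-level events are drawn from Poisson
processes (rates per gene per branch-length unit): tandem duplication,
loss, gain of a novel gene (a horizontal-transfer stand-in),
rearrangement (segment inversion or translocation, destroying local
synteny), plus per-site amino-acid substitution.  Leaf genomes are
written in the same FASTA + GFF3 dialect the pipeline reads
(back-translated coding sequences with uniform synonymous codon
choice), and every emitted gene carries its ancestral family label, so
inferred clusterings can be scored against the planted truth.

Three small scripted scenarios reproduce the narrative corner cases
the clustering algorithm is designed around: a paralogue lost in one
clade, a horizontally acquired gene, and a tandem duplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from sklearn.metrics import adjusted_rand_score

from synclust.genome_model import Gene, Genome, write_genome
from synclust.guide_tree import GuideTree, TreeNode, parse_newick

_AA = "ACDEFGHIKLMNPQRSTVWY"

# reverse standard codon table: amino acid -> sorted synonymous codons
_CODONS: Dict[str, List[str]] = {}
for codon, aa in CodonTable.standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(CodonTable.standard_dna_table.stop_codons)


@dataclass
class SimParams:
    """Event rates and genome geometry for the simulator.

    Rates are events per gene per branch-length unit;
    ``subst_rate`` is amino-acid substitutions per site per unit.
    """

    n_root_genes: int = 100
    gene_len_aa: int = 150
    dup_rate: float = 0.05
    loss_rate: float = 0.05
    gain_rate: float = 0.02
    rearr_rate: float = 0.02
    subst_rate: float = 0.1
    intergenic_bp: int = 100
    seed: int = 0
    dup_placement: str = "tandem"  # or "random": destroys the synteny signal

    def __post_init__(self) -> None:
        if self.n_root_genes < 1:
            raise ValueError("n_root_genes must be >= 1")
        for name in ("dup_rate", "loss_rate", "gain_rate", "rearr_rate", "subst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dup_placement not in ("tandem", "random"):
            raise ValueError("dup_placement must be 'tandem' or 'random'")


@dataclass
class SimTruth:
    """Planted labels: each emitted gene's ancestral family, plus the
    event log that produced the leaf genomes."""

    family_of: Dict[str, str] = field(default_factory=dict)
    event_log: List[Tuple[str, str, str]] = field(default_factory=list)  # (branch, event, detail)


@dataclass
class SimResult:
    genomes: Dict[str, Genome]
    contig_seqs: Dict[str, Dict[str, str]]  # genome -> contig -> nucleotide sequence
    truth: SimTruth
    tree: GuideTree


@dataclass
class _SimGene:
    lineage: int
    family: str
    protein: str
    strand: str


def _random_protein(rng: np.random.Generator, mean_len: int) -> str:
    length = max(30, int(round(rng.normal(mean_len, 0.15 * mean_len))))
    body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length - 1))
    return "M" + body


def _substitute(protein: str, n_sub: int, rng: np.random.Generator) -> str:
    if n_sub <= 0:
        return protein
    seq = list(protein)
    positions = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for pos in sorted(positions):
        current = seq[pos]
        alternatives = [a for a in _AA if a != current]
        seq[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(seq)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))] for aa in protein
    ]
    codons.append(_STOPS[int(rng.integers(0, len(_STOPS)))])
    return "".join(codons)


def _evolve_branch(
    genes: List[_SimGene],
    branch_id: str,
    bl: float,
    params: SimParams,
    rngs: Dict[str, np.random.Generator],
    counters: Dict[str, int],
    log_: List[Tuple[str, str, str]],
) -> List[_SimGene]:
    """Apply one branch's events.

    Separate generator streams are used per process (events /
    rearrangement / substitution / gain sequences), and duplication,
    loss and substitution targets are keyed by gene lineage rather
    than contig position.  Consequence: changing ``rearr_rate`` alone
    changes gene order but leaves gene content and protein sequences
    identical -- rearrangement becomes a pure synteny knob.
    """
    genes = list(genes)
    n0 = len(genes)
    ev = rngs["events"]

    n_dup = ev.poisson(params.dup_rate * bl * n0)
    n_loss = ev.poisson(params.loss_rate * bl * n0)
    n_gain = ev.poisson(params.gain_rate * bl * n0)
    n_rearr = rngs["rearr"].poisson(params.rearr_rate * bl * n0)

    def by_lineage() -> List[int]:
        order = sorted(range(len(genes)), key=lambda i: genes[i].lineage)
        return order

    for _ in range(n_dup):
        order = by_lineage()
        pos = order[int(ev.integers(0, len(order)))]
        src = genes[pos]
        counters["lineage"] += 1
        copy = _SimGene(counters["lineage"], src.family, src.protein, src.strand)
        if params.dup_placement == "tandem":
            genes.insert(pos + 1, copy)
        else:
            genes.insert(int(rngs["rearr"].integers(0, len(genes) + 1)), copy)
        log_.append((branch_id, "duplication", src.family))

    for _ in range(n_loss):
        if len(genes) <= 1:
            raise RuntimeError(
                f"simulated genome emptied by losses on branch {branch_id}; lower loss_rate"
            )
        order = by_lineage()
        pos = order[int(ev.integers(0, len(order)))]
        lost = genes.pop(pos)
        log_.append((branch_id, "loss", lost.family))

    for _ in range(n_gain):
        counters["hgt"] += 1
        counters["lineage"] += 1
        fam = f"HGT{counters['hgt']:04d}"
        gained = _SimGene(
            counters["lineage"],
            fam,
            _random_protein(rngs["gain"], params.gene_len_aa),
            "+" if ev.random() < 0.5 else "-",
        )
        genes.insert(int(ev.integers(0, len(genes) + 1)), gained)
        log_.append((branch_id, "gain", fam))

    rr = rngs["rearr"]
    for _ in range(n_rearr):
        n = len(genes)
        if n < 2:
            continue
        start = int(rr.integers(0, n))
        length = min(1 + int(rr.geometric(0.2)), n - start)
        segment = genes[start:start + length]
        kind = "inversion" if rr.random() < 0.5 else "translocation"
        if kind == "inversion":
            flipped = [
                _SimGene(g.lineage, g.family, g.protein, "-" if g.strand == "+" else "+")
                for g in reversed(segment)
            ]
            genes[start:start + length] = flipped
        else:
            del genes[start:start + length]
            pos = int(rr.integers(0, len(genes) + 1))
            genes[pos:pos] = segment
        log_.append((branch_id, kind, f"{length} genes"))

    p_sub = 1.0 - math.exp(-params.subst_rate * bl)
    if p_sub > 0:
        sub = rngs["subst"]
        mutated: Dict[int, str] = {}
        for g in sorted(genes, key=lambda g: g.lineage):
            mutated[g.lineage] = _substitute(
                g.protein, int(sub.binomial(len(g.protein), p_sub)), sub
            )
        genes = [_SimGene(g.lineage, g.family, mutated[g.lineage], g.strand) for g in genes]
    return genes


def _emit_leaf(
    genome_id: str,
    genes: Sequence[_SimGene],
    params: SimParams,
    rng: np.random.Generator,
    truth: SimTruth,
) -> Tuple[Genome, Dict[str, str]]:
    contig_id = f"{genome_id}_c1"
    pieces: List[str] = []
    gene_objs: List[Gene] = []
    pos = 1 + int(rng.geometric(1.0 / max(1, params.intergenic_bp)))
    pieces.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=pos)))
    for i, g in enumerate(genes):
        gid = f"{genome_id}_{i:04d}"
        coding = _back_translate(g.protein, rng)
        placed = coding if g.strand == "+" else str(Seq(coding).reverse_complement())
        start = pos
        end = pos + len(placed)
        pieces.append(placed)
        gene_objs.append(
            Gene(
                gene_id=gid,
                genome_id=genome_id,
                contig_id=contig_id,
                start=start,
                end=end,
                strand=g.strand,
                protein=g.protein,
            )
        )
        truth.family_of[gid] = g.family
        gap = 1 + int(rng.geometric(1.0 / max(1, params.intergenic_bp)))
        pieces.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=gap)))
        pos = end + gap
    contig = "".join(pieces)
    genome = Genome(genome_id=genome_id, contigs={contig_id: gene_objs})
    return genome, {contig_id: contig}


def simulate(tree: GuideTree, params: SimParams) -> SimResult:
    """Evolve a root genome down the guide tree; returns leaf genomes,
    their nucleotide contigs, and the planted truth.

    Deterministic for a fixed seed: generators are consumed in a
    fixed traversal order (children sorted by smallest descendant leaf
    name).  Independent streams per process and lineage-keyed event
    targets mean that varying ``rearr_rate`` alone changes gene order
    but not gene content or sequences.  Branches without lengths count
    as length zero (no events).
    """
    rngs = {
        name: np.random.default_rng([params.seed, i])
        for i, name in enumerate(("root", "events", "rearr", "subst", "gain", "emit"))
    }
    counters = {"lineage": 0, "hgt": 0}
    truth = SimTruth()

    root_rng = rngs["root"]
    root_genes: List[_SimGene] = []
    for i in range(params.n_root_genes):
        counters["lineage"] += 1
        root_genes.append(
            _SimGene(
                counters["lineage"],
                f"F{i:04d}",
                _random_protein(root_rng, params.gene_len_aa),
                "+" if root_rng.random() < 0.5 else "-",
            )
        )

    genomes: Dict[str, Genome] = {}
    contig_seqs: Dict[str, Dict[str, str]] = {}

    def walk(node: TreeNode, genes: List[_SimGene]) -> None:
        if node.is_leaf:
            genome, seqs = _emit_leaf(node.node_id, genes, params, rngs["emit"], truth)
            genomes[node.node_id] = genome
            contig_seqs[node.node_id] = seqs
            return
        for child in sorted(node.children, key=lambda c: c.min_leaf_name()):
            bl = child.branch_length or 0.0
            evolved = _evolve_branch(
                genes, f"{node.node_id}->{child.node_id}", bl, params, rngs, counters, truth.event_log
            )
            walk(child, evolved)

    walk(tree.root, root_genes)
    return SimResult(genomes=genomes, contig_seqs=contig_seqs, truth=truth, tree=tree)


def write_simulation(result: SimResult, outdir) -> Path:
    """Write leaf genomes as FASTA + GFF3, a genome catalog, the guide
    tree, and the truth table under ``outdir``; returns the catalog
    path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = outdir / "catalog.tsv"
    with open(catalog, "w") as fh:
        for genome_id in sorted(result.genomes):
            fa = outdir / f"{genome_id}.fna"
            gff = outdir / f"{genome_id}.gff3"
            write_genome(result.genomes[genome_id], fa, gff, result.contig_seqs[genome_id])
            fh.write(f"{genome_id}\t{fa}\t{gff}\n")
    (outdir / "tree.nwk").write_text(result.tree.to_newick() + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gid in sorted(result.truth.family_of):
            fh.write(f"{gid}\t{result.truth.family_of[gid]}\n")
    return catalog


# ---------------------------------------------------------------------------
# Scripted scenarios


@dataclass
class Scenario:
    """A deterministic mini-dataset with its expected final clustering
    (as a set of frozensets of gene ids, per root policy)."""

    name: str
    genomes: Dict[str, Genome]
    contig_seqs: Dict[str, Dict[str, str]]
    tree: GuideTree
    truth: SimTruth
    expected_clusters: Dict[str, Set[frozenset]]
    expect_no_marks_at_root: bool = False


def _layout_genome(
    genome_id: str,
    entries: Sequence[Tuple[str, str]],  # (family, protein)
    truth: SimTruth,
    rng: np.random.Generator,
    intergenic_bp: int = 100,
) -> Tuple[Genome, Dict[str, str]]:
    genes = [_SimGene(i, fam, prot, "+") for i, (fam, prot) in enumerate(entries)]
    params = SimParams(n_root_genes=1, intergenic_bp=intergenic_bp)
    genome, seqs = _emit_leaf(genome_id, genes, params, rng, truth)
    return genome, seqs


def scripted_scenario(name: str) -> Scenario:
    """Build one of the hand-crafted corner-case fixtures.

    * ``inparalogue_loss``: an ancient duplication with one copy lost
      in one genome; the surviving copy must rejoin its orthologues at
      an ancestral node so no paralogue mark survives to the root.
    * ``hgt_gain``: a foreign gene present in a single genome; expected
      to come out as an unmarked singleton accessory cluster.
    * ``tandem_dup``: a recent tandem duplication in one genome; the
      extra copy stays marked to the root, where policy decides between
      an annotated singleton and a merged family cluster.

    Genes are spaced so the default 6 kb window covers about two
    neighbours on each side, keeping the synteny signal local.
    """
    known = ("inparalogue_loss", "hgt_gain", "tandem_dup")
    if name not in known:
        raise ValueError(f"unknown scenario {name!r}; options: {', '.join(known)}")
    rng = np.random.default_rng(12345)
    mean_len = 120
    spacing = 2000

    n_background = 8
    background = [_random_protein(rng, mean_len) for _ in range(n_background)]

    def bg_entries(order: Sequence[int]) -> List[Tuple[str, str]]:
        return [(f"B{i}", background[i]) for i in order]

    truth = SimTruth()
    genomes: Dict[str, Genome] = {}
    seqs: Dict[str, Dict[str, str]] = {}

    if name == "inparalogue_loss":
        f1 = _random_protein(rng, mean_len)
        f2 = _substitute(f1, 15, rng)  # ancient paralogue: similar but distinct
        b0_extra = _substitute(background[0], 3, rng)

        def build(genome_id: str, with_f2: bool) -> None:
            entries = bg_entries(range(4))
            entries.append(("F", _substitute(f1, 3, rng)))
            entries += bg_entries(range(4, 8))
            if with_f2:
                # second copy in its own syntenic context at the contig
                # end, flanked by an extra copy of the first background
                # family so its window is informative
                entries.append(("F2", _substitute(f2, 3, rng)))
                entries.append(("B0x", b0_extra))
            genomes[genome_id], seqs[genome_id] = _layout_genome(
                genome_id, entries, truth, rng, intergenic_bp=spacing
            )

        # A lost the second copy; B, C, D retain it
        for gid, with_f2 in (("A", False), ("B", True), ("C", True), ("D", True)):
            build(gid, with_f2)
        tree = parse_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)R;")

        def bg_cluster(i: int) -> frozenset:
            pos = i if i < 4 else i + 1
            return frozenset(f"{g}_{pos:04d}" for g in "ABCD")

        expected = {bg_cluster(i) for i in range(8)}
        expected.add(frozenset({"A_0004", "B_0004", "C_0004", "D_0004"}))  # copy 1
        expected.add(frozenset({"B_0009", "C_0009", "D_0009"}))            # surviving copy 2
        expected.add(frozenset({"B_0010", "C_0010", "D_0010"}))            # extra B0
        return Scenario(
            name=name, genomes=genomes, contig_seqs=seqs, tree=tree, truth=truth,
            expected_clusters={"annotate": expected, "merge": expected},
            expect_no_marks_at_root=True,
        )

    if name == "hgt_gain":
        foreign = _random_protein(rng, mean_len)

        def build(genome_id: str, with_foreign: bool) -> None:
            entries = bg_entries(range(8))
            if with_foreign:
                entries.insert(4, ("X", foreign))
            entries = [(fam, _substitute(p, 3, rng)) for fam, p in entries]
            genomes[genome_id], seqs[genome_id] = _layout_genome(
                genome_id, entries, truth, rng, intergenic_bp=spacing
            )

        for gid, with_x in (("A", True), ("B", False), ("C", False)):
            build(gid, with_x)
        tree = parse_newick("((A:1,B:1)N1:1,C:1)R;")

        def bg_cluster(i: int) -> frozenset:
            a_pos = i if i < 4 else i + 1
            return frozenset({f"A_{a_pos:04d}", f"B_{i:04d}", f"C_{i:04d}"})

        expected = {bg_cluster(i) for i in range(8)}
        expected.add(frozenset({"A_0004"}))  # the foreign singleton
        return Scenario(
            name=name, genomes=genomes, contig_seqs=seqs, tree=tree, truth=truth,
            expected_clusters={"annotate": expected, "merge": expected},
            expect_no_marks_at_root=True,
        )

    # tandem_dup
    f1 = _random_protein(rng, mean_len)

    def build(genome_id: str, with_dup: bool) -> None:
        entries = bg_entries(range(4))
        entries.append(("F", _substitute(f1, 2, rng)))
        if with_dup:
            entries.append(("Fdup", _substitute(f1, 6, rng)))
        entries += bg_entries(range(4, 8))
        entries = [(fam, _substitute(p, 2, rng)) for fam, p in entries]
        genomes[genome_id], seqs[genome_id] = _layout_genome(
            genome_id, entries, truth, rng, intergenic_bp=spacing
        )

    for gid, with_dup in (("A", True), ("B", False), ("C", False)):
        build(gid, with_dup)
    tree = parse_newick("((A:1,B:1)N1:1,C:1)R;")

    def bg_cluster(i: int) -> frozenset:
        a_pos = i if i < 4 else i + 2
        b_pos = i if i < 4 else i + 1
        return frozenset({f"A_{a_pos:04d}", f"B_{b_pos:04d}", f"C_{b_pos:04d}"})

    background_clusters = {bg_cluster(i) for i in range(8)}
    main_copy = frozenset({"A_0004", "B_0004", "C_0004"})
    extra_copy = frozenset({"A_0005"})
    return Scenario(
        name="tandem_dup", genomes=genomes, contig_seqs=seqs, tree=tree, truth=truth,
        expected_clusters={
            "annotate": background_clusters | {main_copy, extra_copy},
            "merge": background_clusters | {main_copy | extra_copy},
        },
        expect_no_marks_at_root=False,
    )


# ---------------------------------------------------------------------------
# Evaluation against planted truth


def evaluate(
    inferred: Iterable,
    truth: SimTruth,
    gene_genome: Mapping[str, str],
) -> Dict[str, float]:
    """Score an inferred clustering against the planted families.

    ``inferred`` is an iterable of clusters, each a collection of gene
    ids (FinalCluster objects are accepted).  Returns the adjusted
    Rand index, pairwise precision and recall, and the fraction of
    planted single-copy families recovered exactly as single-copy-core
    clusters (1.0 when no such family was planted).
    """
    clusters: List[frozenset] = []
    for c in inferred:
        members = getattr(c, "members", c)
        clusters.append(frozenset(members))

    universe = sorted(truth.family_of)
    got = sorted(g for c in clusters for g in c)
    if got != universe:
        raise ValueError("inferred clustering does not cover the same gene universe as the truth")

    cluster_of: Dict[str, int] = {}
    for i, c in enumerate(clusters):
        for g in c:
            cluster_of[g] = i
    labels_true = [truth.family_of[g] for g in universe]
    labels_pred = [cluster_of[g] for g in universe]
    ari = float(adjusted_rand_score(labels_true, labels_pred))

    # pairwise precision/recall from the contingency table
    from collections import Counter

    cont = Counter(zip(labels_true, labels_pred))
    tp = sum(n * (n - 1) // 2 for n in cont.values())
    pred_pairs = sum(n * (n - 1) // 2 for n in Counter(labels_pred).values())
    true_pairs = sum(n * (n - 1) // 2 for n in Counter(labels_true).values())
    precision = tp / pred_pairs if pred_pairs else 1.0
    recall = tp / true_pairs if true_pairs else 1.0

    genome_ids = sorted(set(gene_genome.values()))
    members_of_family: Dict[str, List[str]] = {}
    for g in universe:
        members_of_family.setdefault(truth.family_of[g], []).append(g)
    scc_families = []
    for fam, members in members_of_family.items():
        counts = Counter(gene_genome[g] for g in members)
        if len(members) == len(genome_ids) and all(counts.get(g, 0) == 1 for g in genome_ids):
            scc_families.append(frozenset(members))
    cluster_set = set(clusters)
    recovered = sum(1 for fam in scc_families if fam in cluster_set)
    scc_recovered = recovered / len(scc_families) if scc_families else 1.0

    return {
        "ARI": ari,
        "precision": precision,
        "recall": recall,
        "SCC_recovered": scc_recovered,
    }
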