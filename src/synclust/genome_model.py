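"""Genome and gene data model plus FASTA/GFF3 I/O.

Genes are coding features located on contigs.  Internally all
coordinates are 0-based half-open; the GFF3 reader/writer converts
from/to the 1-based inclusive convention at the boundary.

The neighbourhood of a gene -- all other genes on the same contig
within a base-pair window -- is the unit of evidence for synteny
scoring.  The window is measured edge-to-edge: the gap between the
closest interval ends of the two genes must not exceed the window
(overlapping genes have gap zero).  Strand does not affect
neighbourhood membership.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Set

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Gene:
    """A located, stranded, translated coding feature on a contig.

    ``start``/``end`` are 0-based half-open base-pair coordinates.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A genome: ordered gene lists per contig, sorted by start."""

    genome_id: str
    contigs: Dict[str, List[Gene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig_id, genes in self.contigs.items():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            for g in genes:
                if g.genome_id != self.genome_id:
                    raise ValueError(
                        f"gene {g.gene_id} has genome_id {g.genome_id!r}, "
                        f"expected {self.genome_id!r}"
                    )
                if g.contig_id != contig_id:
                    raise ValueError(f"gene {g.gene_id} filed under wrong contig")

    @property
    def genes(self) -> List[Gene]:
        """All genes, ordered by (contig, start)."""
        out: List[Gene] = []
        for contig_id in sorted(self.contigs):
            out.extend(self.contigs[contig_id])
        return out

    def gene_by_id(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


@dataclass(frozen=True)
class Neighbourhood:
    """The set of genes within a window of a focal gene, same contig."""

    focal_gene_id: str
    neighbour_ids: frozenset

    def __post_init__(self) -> None:
        if self.focal_gene_id in self.neighbour_ids:
            raise ValueError("focal gene cannot be its own neighbour")


def _parse_gff3_attributes(attr_field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = _gff3_unescape(value.strip())
    return attrs


def _gff3_unescape(value: str) -> str:
    from urllib.parse import unquote

    return unquote(value)


def read_genome(fasta_path, gff_path, genome_id: str) -> Genome:
    """Read a genome from a contig FASTA and a GFF3 of CDS features.

    One :class:`Gene` is created per CDS ID.  A CDS split over several
    segments (a joined feature, all lines sharing one ID) uses the
    union span for its coordinates and the concatenated translation.
    Proteins come from the ``translation`` attribute when present,
    otherwise from translating the strand-corrected nucleotide
    sequence with the standard code.  Trailing stop residues are
    stripped; internal stops trigger a warning but the gene is kept
    with stops removed.

    Raises
    ------
    ValueError
        If a CDS references a contig absent from the FASTA.
    """
    contig_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    # Collect CDS segments grouped by ID, in file order.
    segments: Dict[str, List[dict]] = {}
    order: List[str] = []
    with open(gff_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}: line {line_no}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_field = fields
            if ftype != "CDS":
                continue
            attrs = _parse_gff3_attributes(attr_field)
            if "ID" not in attrs:
                raise ValueError(f"{gff_path}: line {line_no}: CDS feature lacks an ID attribute")
            gid = attrs["ID"]
            if gid not in segments:
                segments[gid] = []
                order.append(gid)
            segments[gid].append(
                {
                    "contig": seqid,
                    "start": int(start) - 1,  # GFF3 1-based inclusive -> 0-based half-open
                    "end": int(end),
                    "strand": strand,
                    "translation": attrs.get("translation"),
                }
            )

    contigs: Dict[str, List[Gene]] = {}
    for gid in order:
        segs = segments[gid]
        contig = segs[0]["contig"]
        if contig not in contig_seqs:
            raise ValueError(
                f"GFF3 references contig {contig!r} absent from FASTA for genome {genome_id!r}"
            )
        strand = segs[0]["strand"]
        start = min(s["start"] for s in segs)
        end = max(s["end"] for s in segs)

        provided = [s["translation"] for s in segs if s["translation"]]
        if provided:
            protein = "".join(provided)
        else:
            segs_sorted = sorted(segs, key=lambda s: s["start"])
            nt = "".join(contig_seqs[contig][s["start"]:s["end"]] for s in segs_sorted)
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            protein = str(Seq(nt).translate())
        if protein.endswith("*"):
            protein = protein[:-1]
        if "*" in protein:
            warnings.warn(f"gene {gid}: internal stop codon(s) stripped", stacklevel=2)
            protein = protein.replace("*", "")
        gene = Gene(
            gene_id=gid,
            genome_id=genome_id,
            contig_id=contig,
            start=start,
            end=end,
            strand=strand,
            protein=protein,
        )
        contigs.setdefault(contig, []).append(gene)

    return Genome(genome_id=genome_id, contigs=contigs)


def write_protein_fasta(genes: Iterable[Gene], path) -> None:
    """Write one protein record per gene, header = gene_id."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.protein}\n")


def write_genome(genome: Genome, fasta_path, gff_path, contig_seqs: Dict[str, str]) -> None:
    """Write a genome back to FASTA + GFF3 (coordinates re-converted to
    1-based inclusive).  ``contig_seqs`` supplies the nucleotide
    contigs, which the gene model does not retain."""
    with open(fasta_path, "w") as fh:
        for contig_id in sorted(contig_seqs):
            fh.write(f">{contig_id}\n")
            seq = contig_seqs[contig_id]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id in sorted(genome.contigs):
            for g in genome.contigs[contig_id]:
                attrs = f"ID={g.gene_id};translation={g.protein}"
                fh.write(
                    f"{contig_id}\tsynclust\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
                )


def _gap_bp(a: Gene, b: Gene) -> int:
    """Edge-to-edge gap between two gene intervals; 0 if they overlap."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def neighbourhood(gene: Gene, genome: Genome, window_bp: int = 6000) -> Neighbourhood:
    """All other genes on the focal gene's contig within ``window_bp``.

    Membership uses the inter-gene gap (closest edge to closest edge),
    ignoring strand.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    contig_genes = genome.contigs.get(gene.contig_id)
    if contig_genes is None or gene not in contig_genes:
        raise ValueError(f"gene {gene.gene_id} not found in genome {genome.genome_id}")
    neighbours = frozenset(
        g.gene_id
        for g in contig_genes
        if g.gene_id != gene.gene_id and _gap_bp(gene, g) <= window_bp
    )
    return Neighbourhood(focal_gene_id=gene.gene_id, neighbour_ids=neighbours)


def all_neighbourhoods(genome: Genome, window_bp: int = 6000) -> Dict[str, Set[str]]:
    """Neighbour-id sets for every gene in the genome, computed with a
    sweep over each start-sorted contig (linear in practice)."""
    out: Dict[str, Set[str]] = {}
    for genes in genome.contigs.values():
        n = len(genes)
        for i, g in enumerate(genes):
            hood: Set[str] = set()
            # intervals may nest, so the left side is scanned fully
            for j in range(i):
                if _gap_bp(g, genes[j]) <= window_bp:
                    hood.add(genes[j].gene_id)
            # start-sorted order allows an early break on the right
            for j in range(i + 1, n):
                if genes[j].start > g.end + window_bp:
                    break
                if _gap_bp(g, genes[j]) <= window_bp:
                    hood.add(genes[j].gene_id)
            out[g.gene_id] = hood
    return out
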