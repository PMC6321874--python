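"""Gene/genome model, GFF3 + FASTA I/O, neighbourhood extraction."""

import warnings

import numpy as np
import pytest

from synclust.genome_model import (
    Gene,
    Genome,
    all_neighbourhoods,
    neighbourhood,
    read_genome,
    write_genome,
    write_protein_fasta,
)

from conftest import make_gene, make_genome


def _write(tmp_path, fasta_text, gff_text):
    fa = tmp_path / "g.fna"
    gff = tmp_path / "g.gff3"
    fa.write_text(fasta_text)
    gff.write_text(gff_text)
    return fa, gff


class TestReadGenome:
    def test_coordinate_convention_and_translation_length(self, tmp_path):
        # GFF3 is 1-based inclusive: start=11,end=40 covers 30 nt -> 10 aa
        contig = "A" * 10 + "ATGGCTGCTGCTGCTGCTGCTGCTGCTGCT" + "A" * 20
        fa, gff = _write(
            tmp_path,
            f">c1\n{contig}\n",
            "##gff-version 3\nc1\tsrc\tCDS\t11\t40\t.\t+\t0\tID=g1\n",
        )
        genome = read_genome(fa, gff, "G1")
        (gene,) = genome.genes
        assert (gene.start, gene.end) == (10, 40)
        assert len(gene.protein) == 10
        assert gene.protein.startswith("M")

    def test_empty_gff_gives_zero_genes(self, tmp_path):
        fa, gff = _write(tmp_path, ">c1\nACGTACGT\n", "##gff-version 3\n")
        assert read_genome(fa, gff, "G1").genes == []

    def test_minus_strand_matches_hand_translation(self, tmp_path):
        # hand-built CDS: protein MKF -> ATG AAA TTT TAA, placed reverse
        # complemented on the plus strand of the contig
        coding = "ATGAAATTTTAA"
        revcomp = coding[::-1].translate(str.maketrans("ACGT", "TGCA"))
        contig = "GGGG" + revcomp + "CCCC"
        fa, gff = _write(
            tmp_path,
            f">c1\n{contig}\n",
            f"##gff-version 3\nc1\tsrc\tCDS\t5\t{4 + len(coding)}\t.\t-\t0\tID=g1\n",
        )
        genome = read_genome(fa, gff, "G1")
        assert genome.genes[0].protein == "MKF"

    def test_translation_attribute_preferred(self, tmp_path):
        fa, gff = _write(
            tmp_path,
            ">c1\n" + "A" * 30 + "\n",
            "##gff-version 3\nc1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=g1;translation=MSPECIAL\n",
        )
        assert read_genome(fa, gff, "G1").genes[0].protein == "MSPECIAL"

    def test_missing_contig_is_hard_error_naming_it(self, tmp_path):
        fa, gff = _write(
            tmp_path, ">c1\nACGT\n",
            "##gff-version 3\nc2\tsrc\tCDS\t1\t3\t.\t+\t0\tID=g1\n",
        )
        with pytest.raises(ValueError, match="c2"):
            read_genome(fa, gff, "G1")

    def test_internal_stop_warns_and_strips(self, tmp_path):
        # ATG TAA AAA TAA: internal stop after the initial Met
        fa, gff = _write(
            tmp_path, ">c1\nATGTAAAAATAA\n",
            "##gff-version 3\nc1\tsrc\tCDS\t1\t12\t.\t+\t0\tID=g1\n",
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            genome = read_genome(fa, gff, "G1")
        assert any("stop" in str(w.message) for w in caught)
        assert "*" not in genome.genes[0].protein

    def test_roundtrip_preserves_genes(self, tmp_path):
        contig = "A" * 10 + "ATGGCTGCTTAA" + "C" * 10 + "ATGTTTAAATAA" + "G" * 5
        fa, gff = _write(
            tmp_path,
            f">c1\n{contig}\n",
            "##gff-version 3\n"
            "c1\tsrc\tCDS\t11\t22\t.\t+\t0\tID=g1\n"
            "c1\tsrc\tCDS\t33\t44\t.\t-\t0\tID=g2\n",
        )
        genome = read_genome(fa, gff, "G1")
        out_fa = tmp_path / "out.fna"
        out_gff = tmp_path / "out.gff3"
        write_genome(genome, out_fa, out_gff, {"c1": contig})
        back = read_genome(out_fa, out_gff, "G1")
        assert [(g.gene_id, g.start, g.end, g.strand, g.protein) for g in back.genes] == [
            (g.gene_id, g.start, g.end, g.strand, g.protein) for g in genome.genes
        ]


class TestGeneInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(start=10, end=10),
            dict(start=10, end=40, strand="?"),
            dict(start=10, end=40, protein=""),
        ],
    )
    def test_bad_gene_rejected(self, kwargs):
        base = dict(
            gene_id="g", genome_id="G", contig_id="c", start=0, end=9,
            strand="+", protein="M",
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            Gene(**base)


class TestNeighbourhood:
    def test_sole_gene_has_empty_neighbourhood(self):
        genome = make_genome([(0, 900)])
        hood = neighbourhood(genome.genes[0], genome, 6000)
        assert hood.neighbour_ids == frozenset()

    def test_edge_gap_window(self):
        # gaps from focal g1 [1000,1900): g0 100, g2 100, g3 7100, g4 18100
        genome = make_genome([(0, 900), (1000, 1900), (2000, 2900), (9000, 9900), (20000, 20900)])
        hood = neighbourhood(genome.genes[1], genome, 6000)
        assert hood.neighbour_ids == {"g0", "g2"}

    def test_window_saturation(self):
        genome = make_genome([(0, 100), (200, 300), (400, 500)])
        hood = neighbourhood(genome.genes[0], genome, 10_000)
        assert hood.neighbour_ids == {"g1", "g2"}

    def test_gene_not_in_genome_is_error(self):
        genome = make_genome([(0, 100)])
        stray = make_gene("x", 0, 50, contig_id="c9")
        with pytest.raises(ValueError):
            neighbourhood(stray, genome, 6000)

    def test_symmetry_and_sweep_agree_with_bruteforce(self, rng):
        """b in hood(a) iff a in hood(b); sweep equals the O(n^2) oracle."""
        for _ in range(20):
            n = int(rng.integers(2, 15))
            starts = np.sort(rng.integers(0, 30_000, size=n))
            lengths = rng.integers(50, 4000, size=n)
            genome = make_genome([(int(s), int(s + l)) for s, l in zip(starts, lengths)])
            window = int(rng.integers(100, 10_000))

            def gap(a, b):
                if a.end <= b.start:
                    return b.start - a.end
                if b.end <= a.start:
                    return a.start - b.end
                return 0

            oracle = {
                g.gene_id: {
                    h.gene_id
                    for h in genome.genes
                    if h.gene_id != g.gene_id and gap(g, h) <= window
                }
                for g in genome.genes
            }
            sweep = all_neighbourhoods(genome, window)
            assert sweep == oracle
            for a in genome.genes:
                for b in genome.genes:
                    if a.gene_id == b.gene_id:
                        continue
                    assert (b.gene_id in sweep[a.gene_id]) == (a.gene_id in sweep[b.gene_id])


def test_protein_fasta_writer(tmp_path):
    genes = [make_gene("g1", 0, 30, protein="MABC"), make_gene("g2", 50, 80, protein="MDEF")]
    path = tmp_path / "p.faa"
    write_protein_fasta(genes, path)
    assert path.read_text() == ">g1\nMABC\n>g2\nMDEF\n"
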