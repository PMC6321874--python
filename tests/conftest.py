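"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from synclust.genome_model import Gene, Genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    protein: str = "MAAAA",
    genome_id: str = "G1",
    contig_id: str = "c1",
    strand: str = "+",
) -> Gene:
    return Gene(
        gene_id=gene_id,
        genome_id=genome_id,
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        protein=protein,
    )


def make_genome(
    intervals: Sequence[Tuple[int, int]],
    genome_id: str = "G1",
    contig_id: str = "c1",
    prefix: str = "g",
) -> Genome:
    genes = [
        make_gene(f"{prefix}{i}", s, e, genome_id=genome_id, contig_id=contig_id)
        for i, (s, e) in enumerate(intervals)
    ]
    return Genome(genome_id=genome_id, contigs={contig_id: genes})


def random_protein(rng: np.random.Generator, length: int = 80) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "M" + "".join(aas[i] for i in rng.integers(0, 20, size=length - 1))
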