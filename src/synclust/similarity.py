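"""Pairwise protein similarity search and hit filtering.

Two interchangeable search backends produce a :class:`HitTable`
between the representative sequences of two sibling nodes:

* ``blast`` shells out to NCBI ``blastp`` and parses its 12-column
  tabular output (outfmt 6);
* ``builtin`` is a deterministic in-process Smith-Waterman search
  (BLOSUM62, gap open 11 / extend 1) so the whole pipeline runs with
  no external executables.

Hits are filtered with a lenient E-value cut-off (default 1e-5), then
per query only hits scoring at least a fraction (default 0.8) of that
query's best retained bitscore are kept; finally only reciprocal hits
feed the orthogroup graph.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from synclust.genome_model import Gene, write_protein_fasta

log = logging.getLogger(__name__)

# Karlin-Altschul style scaling constants for the builtin aligner's raw
# Smith-Waterman scores.  They only need to be internally consistent:
# every comparison downstream is relative.
_LAMBDA = 0.267
_K = 0.041
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Hit:
    """A directed similarity record between two gene products."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    pct_identity: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


@dataclass
class HitTable:
    hits: List[Hit] = field(default_factory=list)

    @property
    def queries(self) -> Set[str]:
        return {h.query_id for h in self.hits}

    @property
    def subjects(self) -> Set[str]:
        return {h.subject_id for h in self.hits}

    def by_query(self) -> Dict[str, List[Hit]]:
        out: Dict[str, List[Hit]] = {}
        for h in self.hits:
            out.setdefault(h.query_id, []).append(h)
        return out

    def __len__(self) -> int:
        return len(self.hits)


def _dedup(hits: Iterable[Hit]) -> List[Hit]:
    """Keep the best-bitscore hit per (query, subject) pair, drop
    self-hits; deterministic output order."""
    best: Dict[Tuple[str, str], Hit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or h.bitscore > prev.bitscore:
            best[key] = h
    return [best[k] for k in sorted(best)]


def read_blast_tab(path) -> HitTable:
    """Parse BLAST tabular output (outfmt 6, 12 columns):
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
    """
    hits: List[Hit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {line_no}: expected 12 columns, got {len(fields)}"
                )
            hits.append(
                Hit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return HitTable(hits=_dedup(hits))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner

_SEED_K = 4


def _kmer_set(seq: str, k: int = _SEED_K) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def builtin_search(
    set_a: Sequence[Gene],
    set_b: Sequence[Gene],
    evalue_report_max: float = 10.0,
) -> HitTable:
    """Deterministic all-vs-all local alignment between two gene sets.

    Smith-Waterman with BLOSUM62, gap open 11 / extend 1.  The raw
    score S is converted to a bitscore (lambda*S - ln K)/ln 2 with
    fixed lambda=0.267, K=0.041, and the E-value is m*n*2^(-bitscore)
    with m, n the total residue counts of the two sets.  Hits are
    emitted in both directions (scores are symmetric).  Pairs sharing
    no 4-mer are seeded out without alignment -- unrelated random
    proteins almost never pass, genuinely homologous ones always do at
    the divergences the pipeline operates on.
    """
    aligner = _make_aligner()
    a_ok = [g for g in set_a if g.protein]
    b_ok = [g for g in set_b if g.protein]
    for g in list(set_a) + list(set_b):
        if not g.protein:
            log.warning("builtin_search: skipping %s (empty sequence)", g.gene_id)
    m = sum(len(g.protein) for g in a_ok)
    n = sum(len(g.protein) for g in b_ok)
    if m == 0 or n == 0:
        return HitTable()

    b_kmers = [(g, _kmer_set(g.protein)) for g in b_ok]
    hits: List[Hit] = []
    for ga in a_ok:
        ka = _kmer_set(ga.protein)
        for gb, kb in b_kmers:
            if ga.gene_id == gb.gene_id or ka.isdisjoint(kb):
                continue
            score = aligner.score(ga.protein, gb.protein)
            if score <= 0:
                continue
            bitscore = (_LAMBDA * score - math.log(_K)) / _LN2
            evalue = m * n * math.pow(2.0, -bitscore)
            if evalue > evalue_report_max:
                continue
            hits.append(Hit(ga.gene_id, gb.gene_id, bitscore=bitscore, evalue=evalue))
            hits.append(Hit(gb.gene_id, ga.gene_id, bitscore=bitscore, evalue=evalue))
    return HitTable(hits=_dedup(hits))


def blast_search(
    set_a: Sequence[Gene],
    set_b: Sequence[Gene],
    workdir=None,
    blastp_exe: str = "blastp",
    makeblastdb_exe: str = "makeblastdb",
    evalue_report_max: float = 10.0,
) -> HitTable:
    """All-vs-all ``blastp`` between two gene sets via temporary FASTA
    files; both search directions are run so reciprocity can be
    assessed.  Requires NCBI BLAST+ on the PATH (or explicit paths)."""
    if shutil.which(blastp_exe) is None:
        raise RuntimeError(
            f"{blastp_exe!r} not found; install NCBI BLAST+ or use the builtin search backend"
        )
    tmp_ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(tmp_ctx.name) if tmp_ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        fa = wd / "set_a.faa"
        fb = wd / "set_b.faa"
        write_protein_fasta(set_a, fa)
        write_protein_fasta(set_b, fb)
        all_hits: List[Hit] = []
        for query, subject, tag in ((fa, fb, "a_vs_b"), (fb, fa, "b_vs_a")):
            db = wd / f"db_{tag}"
            subprocess.run(
                [makeblastdb_exe, "-in", str(subject), "-dbtype", "prot", "-out", str(db)],
                check=True, capture_output=True,
            )
            out = wd / f"hits_{tag}.tsv"
            subprocess.run(
                [
                    blastp_exe, "-query", str(query), "-db", str(db),
                    "-outfmt", "6", "-evalue", str(evalue_report_max),
                    "-out", str(out),
                ],
                check=True, capture_output=True,
            )
            all_hits.extend(read_blast_tab(out).hits)
        return HitTable(hits=_dedup(all_hits))
    finally:
        if tmp_ctx:
            tmp_ctx.cleanup()


def filter_hits(
    table: HitTable,
    evalue_max: float = 1e-5,
    best_fraction: float = 0.8,
    best_hit_metric: str = "score",
) -> HitTable:
    """Apply the lenient E-value cut-off, then per-query retention of
    hits close to the query's best hit.

    With ``best_hit_metric='score'`` (default) a hit survives if its
    bitscore is at least ``best_fraction`` of the query's best
    retained bitscore; with ``'identity'`` the percent identity column
    is compared instead.  Ties at the boundary are kept.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    if not (0 < best_fraction <= 1):
        raise ValueError("best_fraction must be in (0, 1]")
    if best_hit_metric not in ("score", "identity"):
        raise ValueError("best_hit_metric must be 'score' or 'identity'")

    kept = [h for h in table.hits if h.evalue <= evalue_max]
    metric = (lambda h: h.bitscore) if best_hit_metric == "score" else (lambda h: h.pct_identity)
    best: Dict[str, float] = {}
    for h in kept:
        v = metric(h)
        if h.query_id not in best or v > best[h.query_id]:
            best[h.query_id] = v
    out = [h for h in kept if metric(h) >= best_fraction * best[h.query_id]]
    return HitTable(hits=_dedup(out))


def reciprocal_pairs(table: HitTable) -> Set[frozenset]:
    """Unordered gene pairs {a, b} with both a->b and b->a present."""
    edges = {(h.query_id, h.subject_id) for h in table.hits}
    return {frozenset((q, s)) for (q, s) in edges if (s, q) in edges}
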