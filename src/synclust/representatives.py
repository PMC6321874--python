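"""Representative-sequence selection for parent orthogroups.

To bound the next level's similarity search, each parent orthogroup is
reduced to a small set of representative sequences: candidates (the
child orthogroups' representatives) are placed in a pairwise distance
matrix, then covered greedily -- the longest uncovered sequence is
promoted to representative and claims every candidate within a
distance threshold, until all candidates are represented.

Two distance backends are provided:

* ``external``: align the candidates (MUSCLE-compatible command, MAFFT
  works too), build a tree with FastTree, take patristic path lengths;
* ``builtin``: 4-mer count-vector cosine dissimilarity in [0, 1] --
  deterministic and dependency-free, the default.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np

from synclust.genome_model import Gene


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with zero diagonal."""

    ids: List[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any() or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distances must be >= 0 with zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def _kmer_counts(seq: str, k: int = 4) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_cosine_distance(seq_a: str, seq_b: str, k: int = 4) -> float:
    """1 - cosine similarity of k-mer count vectors, in [0, 1].

    Identical sequences score 0; sequences sharing no k-mer score 1.
    A sequence shorter than k has an empty k-mer vector and is
    maximally distant from everything except an identical copy of
    itself (the equality shortcut fires first).
    """
    if seq_a == seq_b:
        return 0.0
    ca, cb = _kmer_counts(seq_a, k), _kmer_counts(seq_b, k)
    if not ca or not cb:
        return 1.0
    dot = sum(v * cb[kmer] for kmer, v in ca.items() if kmer in cb)
    norm = np.sqrt(sum(v * v for v in ca.values())) * np.sqrt(sum(v * v for v in cb.values()))
    return float(np.clip(1.0 - dot / norm, 0.0, 1.0))


def _builtin_distances(genes: Sequence[Gene], k: int = 4) -> DistanceMatrix:
    ids = [g.gene_id for g in genes]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_cosine_distance(genes[i].protein, genes[j].protein, k)
    return DistanceMatrix(ids=ids, d=d)


def _external_distances(
    genes: Sequence[Gene],
    aligner_cmd: str,
    fasttree_exe: str,
    workdir: Optional[str],
) -> DistanceMatrix:
    """Align candidates, infer a tree, return patristic distances.

    ``aligner_cmd`` is a shell template with ``{in}`` and ``{out}``
    placeholders, e.g. ``muscle -in {in} -out {out}`` or
    ``mafft --quiet {in} > {out}``.  Alignments are cached under the
    work directory keyed by a content hash.
    """
    exe = aligner_cmd.split()[0]
    if shutil.which(exe) is None or shutil.which(fasttree_exe) is None:
        raise RuntimeError(
            f"external tools not found ({exe!r} / {fasttree_exe!r}); "
            "use --rep-backend builtin"
        )
    content = "".join(f">{g.gene_id}\n{g.protein}\n" for g in genes)
    key = hashlib.sha256(content.encode()).hexdigest()[:16]

    tmp_ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(tmp_ctx.name) if tmp_ctx else Path(workdir) / "alignments"
    wd.mkdir(parents=True, exist_ok=True)
    try:
        fa = wd / f"{key}.faa"
        aln = wd / f"{key}.aln"
        tre = wd / f"{key}.nwk"
        if not tre.exists():
            fa.write_text(content)
            cmd = aligner_cmd.replace("{in}", str(fa)).replace("{out}", str(aln))
            if "{out}" not in aligner_cmd and ">" not in cmd:
                cmd += f" > {aln}"
            subprocess.run(cmd, shell=True, check=True, capture_output=True)
            with open(aln) as ain, open(tre, "w") as tout:
                subprocess.run(
                    [fasttree_exe, "-quiet", "-nosupport"],
                    stdin=ain, stdout=tout, stderr=subprocess.DEVNULL, check=True,
                )
        tree = dendropy.Tree.get(path=str(tre), schema="newick", preserve_underscores=True)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        ids = [g.gene_id for g in genes]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
        return DistanceMatrix(ids=ids, d=d)
    finally:
        if tmp_ctx:
            tmp_ctx.cleanup()


def intra_og_distances(
    genes: Sequence[Gene],
    backend: str = "builtin",
    aligner_cmd: Optional[str] = None,
    fasttree_exe: str = "FastTree",
    workdir: Optional[str] = None,
) -> DistanceMatrix:
    """Pairwise distances among an orthogroup's candidate sequences.

    ``backend='builtin'`` uses the 4-mer cosine dissimilarity;
    ``'external'`` aligns with a MUSCLE-style command and measures
    patristic distances on a FastTree tree (distance scale is then
    backend-dependent; so is a sensible ``rep_distance``).
    """
    if len(genes) < 2:
        raise ValueError("distance matrix needs at least 2 sequences")
    if backend == "builtin":
        return _builtin_distances(genes)
    if backend == "external":
        return _external_distances(
            genes,
            aligner_cmd=aligner_cmd or "muscle -in {in} -out {out}",
            fasttree_exe=fasttree_exe,
            workdir=workdir,
        )
    raise ValueError(f"unknown distance backend {backend!r}")


def select_representatives(
    genes: Sequence[Gene],
    dm: DistanceMatrix,
    rep_distance: float = 0.3,
) -> List[str]:
    """Greedy longest-first cover of an orthogroup's candidates.

    While unrepresented sequences remain, the longest one (ties broken
    by lexicographic gene id) becomes a representative and claims
    every unrepresented sequence within ``rep_distance`` of it.
    Returns the representatives in selection order.  ``rep_distance=0``
    makes every distinct sequence its own representative; a threshold
    at or above the matrix maximum yields a single representative.
    """
    if rep_distance < 0:
        raise ValueError("rep_distance must be >= 0")
    by_id = {g.gene_id: g for g in genes}
    if set(dm.ids) != set(by_id):
        raise ValueError("distance matrix ids do not match the gene set")
    index = {gid: i for i, gid in enumerate(dm.ids)}
    pending = sorted(by_id, key=lambda gid: (-len(by_id[gid].protein), gid))
    covered: set = set()
    reps: List[str] = []
    for gid in pending:
        if gid in covered:
            continue
        reps.append(gid)
        covered.add(gid)
        i = index[gid]
        for other in pending:
            if other not in covered and dm.d[i, index[other]] <= rep_distance:
                covered.add(other)
    return reps
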