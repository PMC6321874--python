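"""Final deliverables: cluster tables, pan-genome summaries, metrics.

The final clustering is written as plain TSV (clusters, counts
presence/absence matrix, single-copy-core list), optional per-cluster
protein FASTA, and a JSON run manifest for reproducibility.  The
annotation-consistency metric is the mean Jaccard similarity of
functional term sets (e.g. KEGG orthology or Pfam) within clusters.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple


@dataclass(frozen=True)
class FinalCluster:
    """One cluster of the root-level partition."""

    cluster_id: str
    members: frozenset
    per_genome_counts: Dict[str, int] = field(default_factory=dict)
    paralogue_of: Optional[str] = None

    def __post_init__(self) -> None:
        if sum(self.per_genome_counts.values()) != len(self.members):
            raise ValueError(
                f"cluster {self.cluster_id}: per-genome counts do not sum to member count"
            )


def core_partition(
    clusters: Sequence[FinalCluster],
    genome_ids: Sequence[str],
) -> Dict[str, Set[str]]:
    """Split clusters into single-copy core (exactly one member in
    every genome), multi-copy core (present in every genome, more than
    one copy in at least one), and accessory (missing somewhere)."""
    genome_ids = list(genome_ids)
    scc: Set[str] = set()
    mcc: Set[str] = set()
    accessory: Set[str] = set()
    for c in clusters:
        counts = [c.per_genome_counts.get(g, 0) for g in genome_ids]
        if all(n == 1 for n in counts):
            scc.add(c.cluster_id)
        elif all(n >= 1 for n in counts):
            mcc.add(c.cluster_id)
        else:
            accessory.add(c.cluster_id)
    return {"SCC": scc, "MCC": mcc, "accessory": accessory}


def write_outputs(
    clusters: Sequence[FinalCluster],
    genome_ids: Sequence[str],
    outdir,
    gene_genome: Optional[Mapping[str, str]] = None,
    proteins: Optional[Mapping[str, str]] = None,
    manifest: Optional[dict] = None,
    write_fasta: bool = False,
) -> None:
    """Write clusters.tsv, presence_absence.tsv, scc.txt, optional
    per-cluster FASTA, and run_manifest.json under ``outdir``.

    All rows are emitted in deterministic sorted order so identical
    runs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_ids = sorted(genome_ids)
    clusters = sorted(clusters, key=lambda c: c.cluster_id)

    if gene_genome is None:
        raise ValueError("gene_genome mapping is required to write clusters.tsv")

    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tgenome_id\tgene_id\tparalogue_of\n")
        for c in clusters:
            for gid in sorted(c.members):
                fh.write(f"{c.cluster_id}\t{gene_genome[gid]}\t{gid}\t{c.paralogue_of or '.'}\n")

    with open(outdir / "presence_absence.tsv", "w") as fh:
        fh.write("cluster_id\t" + "\t".join(genome_ids) + "\n")
        for c in clusters:
            row = "\t".join(str(c.per_genome_counts.get(g, 0)) for g in genome_ids)
            fh.write(f"{c.cluster_id}\t{row}\n")

    parts = core_partition(clusters, genome_ids)
    with open(outdir / "scc.txt", "w") as fh:
        for cid in sorted(parts["SCC"]):
            fh.write(cid + "\n")

    if write_fasta:
        if proteins is None:
            raise ValueError("proteins mapping required for per-cluster FASTA")
        fadir = outdir / "cluster_fasta"
        fadir.mkdir(exist_ok=True)
        for c in clusters:
            with open(fadir / f"{c.cluster_id}.faa", "w") as fh:
                for gid in sorted(c.members):
                    fh.write(f">{gid}\n{proteins[gid]}\n")

    if manifest is not None:
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_clusters(path) -> List[FinalCluster]:
    """Read back clusters.tsv, reconstructing the identical partition."""
    rows: Dict[str, List[Tuple[str, str, Optional[str]]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["cluster_id", "genome_id", "gene_id"]:
            raise ValueError(f"{path}: unexpected clusters.tsv header")
        for line in fh:
            cid, genome, gid, paralogue_of = line.rstrip("\n").split("\t")
            rows.setdefault(cid, []).append((genome, gid, None if paralogue_of == "." else paralogue_of))
    out = []
    for cid in sorted(rows):
        counts: Dict[str, int] = {}
        members = set()
        paralogue_of = rows[cid][0][2]
        for genome, gid, _p in rows[cid]:
            counts[genome] = counts.get(genome, 0) + 1
            members.add(gid)
        out.append(
            FinalCluster(
                cluster_id=cid,
                members=frozenset(members),
                per_genome_counts=counts,
                paralogue_of=paralogue_of,
            )
        )
    return out


@dataclass(frozen=True)
class JaccardResult:
    mean: float
    sd: float
    n: int  # number of pairs (pairs mode) or clusters (clusters mode)


def _jaccard(a: Set[str], b: Set[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def annotation_jaccard(
    clusters: Sequence[FinalCluster],
    annotations: Mapping[str, Set[str]],
    mode: str = "pairs",
) -> Optional[JaccardResult]:
    """Within-cluster annotation consistency.

    ``pairs`` averages the Jaccard similarity of term sets over all
    annotated intra-cluster gene pairs; ``clusters`` first averages
    within each cluster (with >= 2 annotated genes), then over
    clusters.  Genes without annotations are excluded rather than
    scored zero.  Returns ``None`` when no cluster has two annotated
    genes ("not computable").
    """
    if mode not in ("pairs", "clusters"):
        raise ValueError("mode must be 'pairs' or 'clusters'")
    per_pair: List[float] = []
    per_cluster: List[float] = []
    for c in clusters:
        annotated = sorted(g for g in c.members if annotations.get(g))
        if len(annotated) < 2:
            continue
        scores = [
            _jaccard(set(annotations[a]), set(annotations[b]))
            for i, a in enumerate(annotated)
            for b in annotated[i + 1:]
        ]
        per_pair.extend(scores)
        per_cluster.append(sum(scores) / len(scores))
    values = per_pair if mode == "pairs" else per_cluster
    if not values:
        return None
    mean = sum(values) / len(values)
    sd = statistics.pstdev(values) if len(values) > 1 else 0.0
    return JaccardResult(mean=mean, sd=sd, n=len(values))


def size_discrepancy(clusters: Sequence[FinalCluster], proteins: Mapping[str, str]) -> Dict[str, float]:
    """Per-cluster QC: length spread relative to the longest member,
    (max - min) / max amino-acid length.  Large values flag clusters
    mixing full-length genes with fragments."""
    out: Dict[str, float] = {}
    for c in clusters:
        lengths = [len(proteins[g]) for g in c.members]
        out[c.cluster_id] = (max(lengths) - min(lengths)) / max(lengths) if max(lengths) else 0.0
    return out
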