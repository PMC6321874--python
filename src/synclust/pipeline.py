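"""End-to-end orchestration: schedule, per-node merges, checkpoints.

The guide tree defines a dependency DAG over internal nodes; any node
whose children are both complete can run, serially or in a thread
pool.  Node results are checkpointed as JSON (written atomically), so
interrupted runs resume and datasets can be extended by re-processing
only the nodes on the new genome's root path.  All orderings are
canonicalized, making output byte-identical across worker counts and
catalog permutations.
"""

from __future__ import annotations

import json
import logging
import os
import time
from concurrent.futures import FIRST_COMPLETED, Future, ThreadPoolExecutor, wait
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from synclust import __version__
from synclust.genome_model import Gene, Genome, all_neighbourhoods, read_genome
from synclust.guide_tree import GuideTree, TreeNode, binarize, parse_newick, postorder_schedule
from synclust.node_clustering import (
    MergeConfig,
    NodeState,
    Orthogroup,
    leaf_state,
    merge_node,
    resolve_at_root,
)
from synclust.outputs import FinalCluster, write_outputs
from synclust.similarity import HitTable, blast_search, builtin_search, read_blast_tab

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of a clustering run, with the defaults users get."""

    window_bp: int = 6000
    evalue_max: float = 1e-5
    best_fraction: float = 0.8
    best_hit_metric: str = "score"
    syn_threshold: float = 0.5
    rep_distance: float = 0.3
    rep_backend: str = "builtin"
    search_backend: str = "builtin"
    root_policy: str = "annotate"
    aligner_cmd: Optional[str] = None
    fasttree_exe: str = "FastTree"
    blastp_exe: str = "blastp"
    makeblastdb_exe: str = "makeblastdb"
    workdir: Optional[str] = None
    hits_dir: Optional[str] = None
    seed: int = 0
    jobs: int = 1
    resume: bool = False
    write_fasta: bool = False

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not (0 < self.best_fraction <= 1):
            raise ValueError("best_fraction must be in (0, 1]")
        if not (0 <= self.syn_threshold <= 1):
            raise ValueError("syn_threshold must be in [0, 1]")
        if self.rep_distance < 0:
            raise ValueError("rep_distance must be >= 0")
        if self.search_backend not in ("builtin", "blast"):
            raise ValueError("search_backend must be 'builtin' or 'blast'")
        if self.root_policy not in ("annotate", "merge"):
            raise ValueError("root_policy must be 'annotate' or 'merge'")
        if self.jobs < 1:
            raise ValueError("jobs must be >= 1")

    def merge_config(self) -> MergeConfig:
        return MergeConfig(
            evalue_max=self.evalue_max,
            best_fraction=self.best_fraction,
            best_hit_metric=self.best_hit_metric,
            syn_threshold=self.syn_threshold,
            rep_distance=self.rep_distance,
            rep_backend=self.rep_backend,
            aligner_cmd=self.aligner_cmd,
            fasttree_exe=self.fasttree_exe,
            workdir=self.workdir,
        )


@dataclass
class RunResult:
    clusters: List[FinalCluster]
    node_states: Dict[str, NodeState]
    gene_genome: Dict[str, str]
    stats: Dict[str, int] = field(default_factory=dict)


def read_catalog(path) -> List[Tuple[str, str, str]]:
    """Read the genome catalog: one ``genome_id<TAB>fasta<TAB>gff``
    line per genome.  Order does not matter (it is canonicalized)."""
    rows: List[Tuple[str, str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {line_no}: expected 3 tab-separated fields")
            rows.append((fields[0], fields[1], fields[2]))
    return sorted(rows)


def validate_inputs(catalog_path, tree_path) -> List[str]:
    """Dry-run check of catalog and tree; returns all problems found
    (empty list = good to go)."""
    problems: List[str] = []
    try:
        rows = read_catalog(catalog_path)
    except (OSError, ValueError) as exc:
        return [f"catalog: {exc}"]
    ids = [r[0] for r in rows]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        problems.append(f"catalog: duplicate genome_id {dup!r}")
    genomes: Dict[str, Genome] = {}
    for genome_id, fasta, gff in rows:
        for p in (fasta, gff):
            if not Path(p).exists():
                problems.append(f"catalog: {genome_id}: missing file {p}")
        if all(Path(p).exists() for p in (fasta, gff)):
            try:
                genomes[genome_id] = read_genome(fasta, gff, genome_id)
            except Exception as exc:
                problems.append(f"{genome_id}: cannot parse: {exc}")
    seen: Dict[str, str] = {}
    for genome_id, genome in genomes.items():
        for g in genome.genes:
            if g.gene_id in seen:
                problems.append(
                    f"duplicate gene_id {g.gene_id!r} in genomes {seen[g.gene_id]} and {genome_id}"
                )
            seen[g.gene_id] = genome_id
    try:
        tree = parse_newick(Path(tree_path).read_text())
        tree_leaves = set(tree.leaf_names)
        catalog_ids = set(ids)
        for missing in sorted(tree_leaves - catalog_ids):
            problems.append(f"tree leaf {missing!r} missing from catalog")
        for missing in sorted(catalog_ids - tree_leaves):
            problems.append(f"catalog genome {missing!r} missing from tree")
    except (OSError, ValueError) as exc:
        problems.append(f"tree: {exc}")
    return problems


def _state_to_json(state: NodeState) -> dict:
    return {
        "node_id": state.node_id,
        "orthogroups": [
            {
                "og_id": og.og_id,
                "members": sorted(og.members),
                "representatives": list(og.representatives),
                "paralogue_mark": og.paralogue_mark,
            }
            for og in state.orthogroups
        ],
        "stats": state.stats,
    }


def _state_from_json(data: dict) -> NodeState:
    return NodeState(
        node_id=data["node_id"],
        orthogroups=[
            Orthogroup(
                og_id=o["og_id"],
                node_id=data["node_id"],
                members=frozenset(o["members"]),
                representatives=tuple(o["representatives"]),
                paralogue_mark=o.get("paralogue_mark"),
            )
            for o in data["orthogroups"]
        ],
        stats=data.get("stats", {}),
    )


def _checkpoint_path(workdir: Path, node_id: str) -> Path:
    return workdir / "nodes" / f"{node_id}.json"


def _write_checkpoint(workdir: Path, state: NodeState) -> None:
    path = _checkpoint_path(workdir, state.node_id)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(".json.tmp")
    with open(tmp, "w") as fh:
        json.dump(_state_to_json(state), fh, indent=1, sort_keys=True)
    os.replace(tmp, path)


def _load_checkpoint(workdir: Path, node_id: str) -> Optional[NodeState]:
    path = _checkpoint_path(workdir, node_id)
    if not path.exists():
        return None
    try:
        with open(path) as fh:
            return _state_from_json(json.load(fh))
    except (ValueError, KeyError) as exc:
        log.warning("checkpoint for node %s unreadable (%s); recomputing", node_id, exc)
        return None


def cluster_genomes(
    genomes: Mapping[str, Genome],
    tree: GuideTree,
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Run the full leaves-to-root clustering on in-memory genomes.

    This is the library entry point; the CLI wraps it with file I/O.
    """
    tree = binarize(tree)
    tree_leaves = set(tree.leaf_names)
    if tree_leaves != set(genomes):
        diff = sorted(tree_leaves ^ set(genomes))
        raise ValueError(f"tree leaves and genome set differ: {', '.join(diff)}")

    gene_lookup: Dict[str, Gene] = {}
    gene_genome: Dict[str, str] = {}
    hoods: Dict[str, Set[str]] = {}
    for genome_id in sorted(genomes):
        genome = genomes[genome_id]
        for g in genome.genes:
            if g.gene_id in gene_lookup:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} across genomes")
            gene_lookup[g.gene_id] = g
            gene_genome[g.gene_id] = genome_id
        hoods.update(all_neighbourhoods(genome, config.window_bp))

    workdir = Path(config.workdir) if config.workdir else None
    merge_cfg = config.merge_config()
    states: Dict[str, NodeState] = {}

    for leaf in tree.root.leaves():
        states[leaf.node_id] = NodeState(
            node_id=leaf.node_id,
            orthogroups=leaf_state(leaf.node_id, genomes[leaf.node_id].genes),
        )

    def node_hits(node: TreeNode, reps1: List[Gene], reps2: List[Gene]) -> HitTable:
        if config.hits_dir:
            pre = Path(config.hits_dir) / f"{node.node_id}.tsv"
            if pre.exists():
                return read_blast_tab(pre)
        if config.search_backend == "blast":
            wd = workdir / "blast" / node.node_id if workdir else None
            return blast_search(
                reps1, reps2, workdir=wd,
                blastp_exe=config.blastp_exe, makeblastdb_exe=config.makeblastdb_exe,
            )
        return builtin_search(reps1, reps2)

    def process(node: TreeNode) -> NodeState:
        if config.resume and workdir:
            cached = _load_checkpoint(workdir, node.node_id)
            if cached is not None:
                return cached
        c1, c2 = sorted(node.children, key=lambda c: c.min_leaf_name())
        ogs1 = states[c1.node_id].orthogroups
        ogs2 = states[c2.node_id].orthogroups
        reps1 = [gene_lookup[r] for og in ogs1 for r in og.representatives]
        reps2 = [gene_lookup[r] for og in ogs2 for r in og.representatives]
        t0 = time.monotonic()
        hits = node_hits(node, reps1, reps2)
        state = merge_node(
            node.node_id, ogs1, ogs2, hits, hoods, gene_lookup, merge_cfg
        )
        log.info(
            "node %s: %d orthogroups (%d merged, %d marked) in %.1fs",
            node.node_id, state.stats["n_orthogroups"], state.stats["n_merged"],
            state.stats["n_marked"], time.monotonic() - t0,
        )
        if workdir:
            _write_checkpoint(workdir, state)
        return state

    schedule = postorder_schedule(tree)
    if config.jobs <= 1:
        for node in schedule:
            states[node.node_id] = process(node)
    else:
        pending = {n.node_id: n for n in schedule}
        futures: Dict[Future, str] = {}
        with ThreadPoolExecutor(max_workers=config.jobs) as pool:
            while pending or futures:
                ready = [
                    n for nid, n in sorted(pending.items())
                    if all(c.node_id in states for c in n.children)
                ]
                for n in ready:
                    del pending[n.node_id]
                    futures[pool.submit(process, n)] = n.node_id
                done, _ = wait(futures, return_when=FIRST_COMPLETED)
                for fut in done:
                    states[futures.pop(fut)] = fut.result()

    root_state = states[tree.root.node_id]
    clusters = resolve_at_root(root_state.orthogroups, gene_genome, policy=config.root_policy)

    totals = {
        "n_genes": len(gene_lookup),
        "n_clusters": len(clusters),
        "n_phase1_merges": sum(
            s.stats.get("n_phase1_merges", 0) for s in states.values()
        ),
        "n_phase2_merges": sum(
            s.stats.get("n_phase2_merges", 0) for s in states.values()
        ),
        "n_marked_at_root": sum(
            1 for og in root_state.orthogroups if og.paralogue_mark
        ),
    }
    return RunResult(
        clusters=clusters,
        node_states=states,
        gene_genome=gene_genome,
        stats=totals,
    )


def run(catalog_path, tree_path, outdir, config: RunConfig = RunConfig()) -> RunResult:
    """File-level entry point: read catalog + tree, cluster, write the
    output tables under ``outdir``."""
    problems = validate_inputs(catalog_path, tree_path)
    if problems:
        raise ValueError("invalid inputs:\n" + "\n".join(problems))
    rows = read_catalog(catalog_path)
    genomes = {gid: read_genome(fa, gff, gid) for gid, fa, gff in rows}
    tree = parse_newick(Path(tree_path).read_text())
    result = cluster_genomes(genomes, tree, config)

    proteins = {gid: g.protein for gid, g in (
        (g.gene_id, g) for genome in genomes.values() for g in genome.genes
    )}
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_genomes": len(genomes),
        "stats": result.stats,
    }
    write_outputs(
        result.clusters,
        sorted(genomes),
        outdir,
        gene_genome=result.gene_genome,
        proteins=proteins,
        manifest=manifest,
        write_fasta=config.write_fasta,
    )
    return result
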