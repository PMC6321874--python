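"""Per-internal-node merge of child orthogroups -- the algorithmic core.

At an internal node of the guide tree the orthogroups of the two
children are combined in four stages:

1. *Initial clustering*: reciprocal similarity hits between child
   representatives are lifted to orthogroup-level edges; connected
   components with at least two orthogroups become initial clusters.
2. *Synteny scoring*: for every cross-child orthogroup pair in a
   cluster, the mean pairwise syntenic fraction over all member genes.
3. *Finalization*: highly syntenic pairs merge first (greedy,
   descending score), then remaining orthogroup-level reciprocal best
   hits; orthogroups left unmerged inside a cluster are marked as
   potential inparalogues of their best hit.
4. *Representative selection* for each merged parent orthogroup (see
   :mod:`synclust.representatives`).

Paralogue marks travel up the tree: a marked orthogroup that merges at
a later node loses its mark; one that never finds a partner keeps it
until the root, where it is either reported as an annotation or merged
into its best hit's cluster, by policy.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from synclust.genome_model import Gene
from synclust.outputs import FinalCluster
from synclust.representatives import intra_og_distances, select_representatives
from synclust.similarity import HitTable, filter_hits, reciprocal_pairs

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Orthogroup:
    """A node-scoped cluster of genes.

    ``paralogue_mark`` holds the gene id of the orthogroup's best
    similarity hit when the group was left unmerged (a potential
    inparalogue); ``None`` otherwise.
    """

    og_id: str
    node_id: str
    members: frozenset
    representatives: Tuple[str, ...]
    paralogue_mark: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("orthogroup must have members")
        if not set(self.representatives) <= set(self.members):
            raise ValueError("representatives must be members")


@dataclass
class InitialCluster:
    cluster_id: str
    child_ogs: List[Orthogroup]


@dataclass
class SyntenyMatrix:
    """Mean syntenic fraction per cross-child orthogroup pair."""

    entries: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def set(self, og_i: str, og_j: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError("syntenic fraction must be in [0, 1]")
        self.entries[(og_i, og_j)] = value
        self.entries[(og_j, og_i)] = value

    def get(self, og_i: str, og_j: str) -> float:
        return self.entries.get((og_i, og_j), 0.0)


def leaf_state(node_id: str, genes: Sequence[Gene]) -> List[Orthogroup]:
    """At a leaf every gene is its own singleton orthogroup and its own
    representative."""
    return [
        Orthogroup(
            og_id=f"{node_id}|{g.gene_id}",
            node_id=node_id,
            members=frozenset([g.gene_id]),
            representatives=(g.gene_id,),
        )
        for g in sorted(genes, key=lambda g: g.gene_id)
    ]


def initial_clusters(
    child1_ogs: Sequence[Orthogroup],
    child2_ogs: Sequence[Orthogroup],
    pairs: Iterable[frozenset],
) -> List[InitialCluster]:
    """Lift gene-level reciprocal pairs to orthogroup-level edges and
    return connected components with >= 2 orthogroups.  Orthogroups in
    singleton components are not returned; they pass through the merge
    unmerged."""
    og_of_rep: Dict[str, str] = {}
    og_by_id: Dict[str, Orthogroup] = {}
    for og in list(child1_ogs) + list(child2_ogs):
        og_by_id[og.og_id] = og
        for r in og.representatives:
            og_of_rep[r] = og.og_id

    graph = nx.Graph()
    graph.add_nodes_from(og_by_id)
    for pair in pairs:
        a, b = sorted(pair)
        for g in (a, b):
            if g not in og_of_rep:
                raise ValueError(f"reciprocal pair gene {g!r} is not a representative of any child orthogroup")
        if og_of_rep[a] != og_of_rep[b]:
            graph.add_edge(og_of_rep[a], og_of_rep[b])

    clusters: List[InitialCluster] = []
    components = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    idx = 0
    for comp in components:
        if len(comp) < 2:
            continue
        clusters.append(
            InitialCluster(
                cluster_id=f"C{idx}",
                child_ogs=[og_by_id[i] for i in comp],
            )
        )
        idx += 1
    return clusters


def syntenic_fraction(
    hood_a: Set[str],
    hood_b: Set[str],
    og_of: Mapping[str, str],
) -> float:
    """Fraction of shared neighbours between two genes' windows.

    Each neighbour set is projected through ``og_of`` to a multiset of
    cluster labels (a gene absent from ``og_of`` projects to its own
    id, a unique sentinel).  Shared count is the multiset
    intersection; the denominator counts every neighbour, shared or
    not, exactly once: ``|N_a| + |N_b| - shared``.  Two empty windows
    give 0.
    """
    labels_a = Counter(og_of.get(g, g) for g in hood_a)
    labels_b = Counter(og_of.get(g, g) for g in hood_b)
    shared = sum(min(labels_a[l], labels_b[l]) for l in labels_a if l in labels_b)
    total = len(hood_a) + len(hood_b) - shared
    if total == 0:
        return 0.0
    return shared / total


def synteny_matrix(
    cluster: InitialCluster,
    child1_ids: Set[str],
    hoods: Mapping[str, Set[str]],
    og_of: Mapping[str, str],
) -> SyntenyMatrix:
    """Mean pairwise syntenic fraction for every (child1 og, child2 og)
    pair in the cluster, averaged over all member-gene pairs."""
    ogs1 = [og for og in cluster.child_ogs if og.og_id in child1_ids]
    ogs2 = [og for og in cluster.child_ogs if og.og_id not in child1_ids]
    syn = SyntenyMatrix()
    for og_i in ogs1:
        for og_j in ogs2:
            fracs = [
                syntenic_fraction(hoods[ga], hoods[gb], og_of)
                for ga in sorted(og_i.members)
                for gb in sorted(og_j.members)
            ]
            syn.set(og_i.og_id, og_j.og_id, sum(fracs) / len(fracs))
    return syn


def _og_level_scores(
    cluster: InitialCluster,
    hits: HitTable,
) -> Dict[Tuple[str, str], float]:
    """Orthogroup-level bitscore = max bitscore over representative
    pairs; symmetric."""
    rep_og: Dict[str, str] = {}
    for og in cluster.child_ogs:
        for r in og.representatives:
            rep_og[r] = og.og_id
    scores: Dict[Tuple[str, str], float] = {}
    for h in hits.hits:
        oq = rep_og.get(h.query_id)
        os_ = rep_og.get(h.subject_id)
        if oq is None or os_ is None or oq == os_:
            continue
        for key in ((oq, os_), (os_, oq)):
            if h.bitscore > scores.get(key, float("-inf")):
                scores[key] = h.bitscore
    return scores


def _best_hit_gene(og: Orthogroup, cluster_gene_ids: Set[str], hits: HitTable) -> Optional[str]:
    """The single best-hit gene (highest bitscore, ties by subject id)
    from any of the orthogroup's representatives to a gene of another
    orthogroup in the same cluster."""
    own = set(og.members)
    reps = set(og.representatives)
    best: Optional[Tuple[float, str]] = None
    for h in hits.hits:
        if h.query_id in reps and h.subject_id in cluster_gene_ids and h.subject_id not in own:
            cand = (-h.bitscore, h.subject_id)
            if best is None or cand < best:
                best = cand
    return best[1] if best else None


@dataclass
class FinalizeResult:
    merged: List[Tuple[Orthogroup, Orthogroup, int]]
    marked: List[Tuple[Orthogroup, str]]


def finalize(
    cluster: InitialCluster,
    syn: SyntenyMatrix,
    hits: HitTable,
    child1_ids: Set[str],
    syn_threshold: float = 0.5,
) -> "FinalizeResult":
    """Resolve one initial cluster into parent orthogroup skeletons.

    Phase 1 greedily merges cross-child pairs whose mean syntenic
    fraction reaches ``syn_threshold``, highest first (ties broken by
    descending orthogroup-level bitscore, then lexicographic pair id);
    each orthogroup merges at most once per phase.  Phase 2 merges the
    remaining orthogroup-level reciprocal best hits under the same
    greedy discipline.  Orthogroups still unmerged are returned with
    the gene id of their best hit, to be passed through as marked
    potential inparalogues.

    Returns a :class:`FinalizeResult`: ``merged`` holds
    ``(child og, child og, phase)`` triples (phase 1 = synteny, phase
    2 = RBH) and ``marked`` holds ``(child og, best-hit gene id)``
    pairs for the orthogroups passed through with a paralogue mark.
    """
    if not (0.0 <= syn_threshold <= 1.0):
        raise ValueError("syn_threshold must be in [0, 1]")
    og_by_id = {og.og_id: og for og in cluster.child_ogs}
    ids1 = sorted(i for i in og_by_id if i in child1_ids)
    ids2 = sorted(i for i in og_by_id if i not in child1_ids)
    scores = _og_level_scores(cluster, hits)

    merged: List[Tuple[Orthogroup, Orthogroup, int]] = []
    used: Set[str] = set()

    # Phase 1: synteny-first greedy matching.
    candidates = [
        (i, j)
        for i in ids1
        for j in ids2
        if syn.get(i, j) >= syn_threshold
    ]
    candidates.sort(
        key=lambda p: (
            -syn.get(p[0], p[1]),
            -scores.get(p, float("-inf")),
            p[0],
            p[1],
        )
    )
    for i, j in candidates:
        if i in used or j in used:
            continue
        merged.append((og_by_id[i], og_by_id[j], 1))
        used.update((i, j))

    # Phase 2: reciprocal best hits among the remainder.
    def best_partner(i: str, pool: Sequence[str]) -> Optional[str]:
        options = [(-(scores[(i, j)]), j) for j in pool if (i, j) in scores]
        return min(options)[1] if options else None

    rem1 = [i for i in ids1 if i not in used]
    rem2 = [j for j in ids2 if j not in used]
    rbh = []
    for i in rem1:
        j = best_partner(i, rem2)
        if j is not None and best_partner(j, rem1) == i:
            rbh.append((i, j))
    rbh.sort(key=lambda p: (-scores[p], p[0], p[1]))
    for i, j in rbh:
        if i in used or j in used:
            continue
        merged.append((og_by_id[i], og_by_id[j], 2))
        used.update((i, j))

    # Phase 3: unmerged orthogroups are marked with their best hit.
    cluster_genes: Set[str] = set()
    for og in cluster.child_ogs:
        cluster_genes |= og.members
    marked: List[Tuple[Orthogroup, str]] = []
    for i in ids1 + ids2:
        if i in used:
            continue
        og = og_by_id[i]
        target = _best_hit_gene(og, cluster_genes, hits)
        if target is None:
            # cluster membership implies at least one reciprocal pair,
            # so a best hit normally exists; fall back to any prior mark
            target = og.paralogue_mark or ""
        marked.append((og, target))
    return FinalizeResult(merged=merged, marked=marked)


@dataclass
class NodeState:
    """Result of processing one tree node."""

    node_id: str
    orthogroups: List[Orthogroup]
    stats: Dict[str, int] = field(default_factory=dict)


@dataclass
class MergeConfig:
    """Knobs of the per-node merge (see the run configuration for the
    full pipeline-level set)."""

    evalue_max: float = 1e-5
    best_fraction: float = 0.8
    best_hit_metric: str = "score"
    syn_threshold: float = 0.5
    rep_distance: float = 0.3
    rep_backend: str = "builtin"
    aligner_cmd: Optional[str] = None
    fasttree_exe: str = "FastTree"
    workdir: Optional[str] = None


def merge_node(
    node_id: str,
    child1_ogs: Sequence[Orthogroup],
    child2_ogs: Sequence[Orthogroup],
    hits: HitTable,
    hoods: Mapping[str, Set[str]],
    gene_lookup: Mapping[str, Gene],
    config: MergeConfig = MergeConfig(),
) -> NodeState:
    """Merge two children's orthogroups into the parent node's set.

    ``hits`` is the unfiltered similarity table between the children's
    representative sequences; ``hoods`` maps every descendant gene to
    its neighbour-id set.  Genes are never lost or duplicated: the
    union of parent members equals the union of child members.
    """
    filtered = filter_hits(
        hits,
        evalue_max=config.evalue_max,
        best_fraction=config.best_fraction,
        best_hit_metric=config.best_hit_metric,
    )
    pairs = reciprocal_pairs(filtered)
    clusters = initial_clusters(child1_ogs, child2_ogs, pairs)

    clustered_og_ids = {og.og_id for c in clusters for og in c.child_ogs}
    child1_ids = {og.og_id for og in child1_ogs}

    # Project every descendant gene to a common label space: the
    # initial-cluster id when its child orthogroup joined one, else the
    # child orthogroup id itself.
    og_of: Dict[str, str] = {}
    for og in list(child1_ogs) + list(child2_ogs):
        label = og.og_id
        for c in clusters:
            if og in c.child_ogs:
                label = f"{node_id}/{c.cluster_id}"
                break
        for g in og.members:
            og_of[g] = label

    merged_pairs: List[Tuple[Orthogroup, Orthogroup, int]] = []
    marked_list: List[Tuple[Orthogroup, str]] = []
    for cluster in clusters:
        syn = synteny_matrix(cluster, child1_ids, hoods, og_of)
        res = finalize(cluster, syn, hits=filtered, child1_ids=child1_ids, syn_threshold=config.syn_threshold)
        merged_pairs.extend(res.merged)
        marked_list.extend(res.marked)

    parents: List[Orthogroup] = []
    for og_a, og_b, _phase in merged_pairs:
        pair = (og_a, og_b)
        members = frozenset().union(*(og.members for og in pair))
        candidates = sorted({r for og in pair for r in og.representatives})
        genes = [gene_lookup[g] for g in candidates]
        if len(genes) > 1:
            dm = intra_og_distances(
                genes,
                backend=config.rep_backend,
                aligner_cmd=config.aligner_cmd,
                fasttree_exe=config.fasttree_exe,
                workdir=config.workdir,
            )
            reps = tuple(select_representatives(genes, dm, config.rep_distance))
        else:
            reps = tuple(candidates)
        parents.append(
            Orthogroup(
                og_id="",  # assigned below
                node_id=node_id,
                members=members,
                representatives=reps,
                paralogue_mark=None,
            )
        )

    for og, target in marked_list:
        parents.append(
            Orthogroup(
                og_id="",
                node_id=node_id,
                members=og.members,
                representatives=og.representatives,
                paralogue_mark=target or None,
            )
        )

    # Orthogroups in no initial cluster pass through untouched (keeping
    # any existing mark: absence of homology evidence is not paralogy).
    for og in list(child1_ogs) + list(child2_ogs):
        if og.og_id not in clustered_og_ids:
            parents.append(replace(og, og_id="", node_id=node_id))

    # Deterministic parent ids, ordered by smallest member gene id.
    parents.sort(key=lambda og: min(og.members))
    parents = [replace(og, og_id=f"{node_id}_{i:05d}") for i, og in enumerate(parents)]

    child_union = frozenset().union(*(og.members for og in list(child1_ogs) + list(child2_ogs)))
    parent_union: Set[str] = set()
    total = 0
    for og in parents:
        parent_union |= og.members
        total += len(og.members)
    if parent_union != child_union or total != len(child_union):
        raise AssertionError(f"gene conservation violated at node {node_id}")

    stats = {
        "n_initial_clusters": len(clusters),
        "n_merged": len(merged_pairs),
        "n_marked": sum(1 for _, t in marked_list if t),
        "n_pass_through": len(parents) - len(merged_pairs) - len(marked_list),
        "n_orthogroups": len(parents),
        "n_phase1_merges": sum(1 for *_a, p in merged_pairs if p == 1),
        "n_phase2_merges": sum(1 for *_a, p in merged_pairs if p == 2),
    }
    return NodeState(node_id=node_id, orthogroups=parents, stats=stats)


def resolve_at_root(
    root_ogs: Sequence[Orthogroup],
    gene_genome: Mapping[str, str],
    policy: str = "annotate",
) -> List[FinalCluster]:
    """Turn the root node's orthogroups into the final clustering.

    ``annotate`` (default) reports marked orthogroups as distinct
    clusters carrying a ``paralogue_of`` reference to the cluster of
    their best hit; ``merge`` folds each marked orthogroup into that
    cluster.  Either way the clusters partition all input genes.
    """
    if policy not in ("annotate", "merge"):
        raise ValueError("policy must be 'annotate' or 'merge'")

    og_of_gene: Dict[str, str] = {}
    for og in root_ogs:
        for g in og.members:
            og_of_gene[g] = og.og_id

    # target orthogroup of each mark (may be dangling if the gene is
    # somehow absent; then the annotation is dropped with a warning)
    target_of: Dict[str, Optional[str]] = {}
    for og in root_ogs:
        if og.paralogue_mark:
            tgt = og_of_gene.get(og.paralogue_mark)
            if tgt is None:
                log.warning(
                    "orthogroup %s: paralogue mark references unknown gene %s; annotation dropped",
                    og.og_id, og.paralogue_mark,
                )
            target_of[og.og_id] = tgt

    og_by_id = {og.og_id: og for og in root_ogs}

    if policy == "merge":
        # union-find over the mark edges (chains collapse together)
        graph = nx.Graph()
        graph.add_nodes_from(og_by_id)
        for src, tgt in target_of.items():
            if tgt is not None:
                graph.add_edge(src, tgt)
        groups = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    else:
        groups = [[i] for i in sorted(og_by_id)]

    clusters: List[FinalCluster] = []
    raw: List[Tuple[frozenset, Optional[str]]] = []
    for group in groups:
        members = frozenset().union(*(og_by_id[i].members for i in group))
        if policy == "annotate":
            tgt = target_of.get(group[0])
        else:
            tgt = None
        raw.append((members, tgt))

    raw.sort(key=lambda t: min(t[0]))
    gene_cluster: Dict[str, str] = {}
    for idx, (members, _tgt) in enumerate(raw):
        for g in members:
            gene_cluster[g] = f"OG{idx:06d}"
    cluster_of_og = {og.og_id: gene_cluster[min(og.members)] for og in root_ogs}

    for idx, (members, tgt) in enumerate(raw):
        per_genome: Dict[str, int] = {}
        for g in members:
            per_genome[gene_genome[g]] = per_genome.get(gene_genome[g], 0) + 1
        clusters.append(
            FinalCluster(
                cluster_id=f"OG{idx:06d}",
                members=members,
                per_genome_counts=per_genome,
                paralogue_of=cluster_of_og.get(tgt) if tgt else None,
            )
        )
    return clusters
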