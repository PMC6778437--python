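"""Per-gene-tree curation: midpoint rooting, paralogous-subfamily
detection, and in-paralogue restriction.

A *paralogous subfamily* is an internal node whose two child clades each
contain at least two distinct species and share at least one species —
evidence of a gene duplication predating speciation.  Within such a
subfamily, multiple leaves from one non-query species are in-paralogues
(lineage-specific duplicates) or sequence variants; only the leaf closest
to the query (by patristic distance, the only metric available given trees
as input) is retained.  Query-proteome in-paralogues are always kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

from .core import (
    DEFAULT_QUERY_CODE,
    GeneTree,
    ValidationError,
    species_code,
)


@dataclass(frozen=True)
class ParalogSubfamily:
    """An internal node flagged as a gene-duplication (paralogous) node."""

    leaf_labels: tuple[str, ...]
    left_species: frozenset[str]
    right_species: frozenset[str]
    shared: frozenset[str]


def _adjacency(tree: dendropy.Tree) -> dict[dendropy.Node, list]:
    adj: dict[dendropy.Node, list] = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        for child in nd.child_nodes():
            w = child.edge.length or 0.0
            adj[nd].append((child, w))
            adj.setdefault(child, []).append((nd, w))
    return adj


def _sweep(adj, start):
    """Distances and predecessors from ``start`` over the undirected tree."""
    dist = {start: 0.0}
    pred: dict = {start: None}
    stack = [start]
    while stack:
        nd = stack.pop()
        for nb, w in adj[nd]:
            if nb not in dist:
                dist[nb] = dist[nd] + w
                pred[nb] = nd
                stack.append(nb)
    return dist, pred


def midpoint_root(gt: GeneTree, eps: float = 1e-12) -> GeneTree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Returns a new, rooted tree; the input is not modified.  Patristic
    distances between leaves are preserved exactly.  The longest path is
    found by a double sweep (farthest leaf from an arbitrary leaf is one
    end of the diameter); the root bisects it, splitting an edge when the
    midpoint falls inside one.
    """
    if len(gt.tree.leaf_nodes()) < 2:
        raise ValidationError("midpoint rooting needs at least 2 leaves")
    out = gt.clone()
    tree = out.tree
    adj = _adjacency(tree)
    leaves = tree.leaf_nodes()
    dist0, _ = _sweep(adj, leaves[0])
    a = max(leaves, key=lambda lf: dist0[lf])
    dist, pred = _sweep(adj, a)
    b = max(leaves, key=lambda lf: dist[lf])
    diameter = dist[b]
    if diameter <= 0.0:
        raise ValidationError("all branch lengths are zero: no unique midpoint")

    path = [b]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    path.reverse()  # a ... b

    half = diameter / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        step = dist[v] - dist[u]
        if cum + step >= half - eps:
            offset = half - cum  # distance from u into the u-v edge
            if offset <= eps:
                tree.reroot_at_node(u, suppress_unifurcations=True)
            elif step - offset <= eps:
                tree.reroot_at_node(v, suppress_unifurcations=True)
            else:
                # locate the dendropy edge between u and v
                if v.parent_node is u:
                    edge, from_tail = v.edge, offset
                else:
                    edge, from_tail = u.edge, step - offset
                # length1 attaches to the tail side, length2 to the head
                tree.reroot_at_edge(
                    edge,
                    length1=from_tail,
                    length2=(edge.length or 0.0) - from_tail,
                    suppress_unifurcations=True,
                )
            break
        cum += step
    tree.is_rooted = True
    return out


def _child_species_sets(node: dendropy.Node) -> list[set[str]]:
    return [
        {species_code(lf.taxon.label) for lf in child.leaf_iter()}
        for child in node.child_nodes()
    ]


def find_paralog_subfamilies(gt: GeneTree) -> list[ParalogSubfamily]:
    """All internal nodes whose two child clades each hold >=2 distinct
    species and share >=1 species.

    Only strictly bifurcating nodes are considered; a polytomy does not
    define the two ancestral clades the rule speaks of.
    """
    if not gt.is_rooted:
        raise ValidationError("paralog detection requires a rooted tree")
    found: list[ParalogSubfamily] = []
    for nd in gt.tree.preorder_internal_node_iter():
        children = nd.child_nodes()
        if len(children) != 2:
            continue
        left, right = _child_species_sets(nd)
        shared = left & right
        if len(left) >= 2 and len(right) >= 2 and shared:
            found.append(
                ParalogSubfamily(
                    leaf_labels=tuple(lf.taxon.label for lf in nd.leaf_iter()),
                    left_species=frozenset(left),
                    right_species=frozenset(right),
                    shared=frozenset(shared),
                )
            )
    return found


def filter_inparalogs(gt: GeneTree, query_code: str = DEFAULT_QUERY_CODE) -> GeneTree:
    """Restrict non-query in-paralogues to the single closest homologue.

    Within each paralogous subfamily, every non-query species with multiple
    leaves keeps only the leaf with the smallest patristic distance to the
    nearest query leaf (ties broken by lexicographic leaf identifier).
    Query leaves are always kept; same-species duplicates outside any
    paralogous subfamily are kept.  Degree-2 nodes created by pruning are
    suppressed with their branch lengths summed.
    """
    if not gt.is_rooted:
        raise ValidationError("in-paralogue filtering requires a rooted tree")
    out = gt.clone()
    query_leaves = out.query_leaves(query_code)
    if not query_leaves:
        raise ValidationError(f"no query leaf with code {query_code!r} in tree")

    subfamilies = _subfamily_nodes(out)
    if not subfamilies:
        return out

    pdm = out.tree.phylogenetic_distance_matrix()
    query_taxa = [nd.taxon for nd in query_leaves]

    def dist_to_query(leaf: dendropy.Node) -> float:
        return min(pdm.patristic_distance(leaf.taxon, qt) for qt in query_taxa)

    to_prune: set[str] = set()
    for node in subfamilies:
        by_species: dict[str, list[dendropy.Node]] = {}
        for lf in node.leaf_iter():
            code = species_code(lf.taxon.label)
            if code != query_code:
                by_species.setdefault(code, []).append(lf)
        for leaves in by_species.values():
            if len(leaves) < 2:
                continue
            keep = min(leaves, key=lambda lf: (dist_to_query(lf), lf.taxon.label))
            to_prune.update(
                lf.taxon.label for lf in leaves if lf is not keep
            )

    if to_prune:
        taxa = [
            t for t in out.tree.taxon_namespace if t.label in to_prune
        ]
        out.tree.prune_taxa(taxa, suppress_unifurcations=True)
        out.tree.taxon_namespace = dendropy.TaxonNamespace(
            [lf.taxon for lf in out.tree.leaf_node_iter()]
        )
    return out


def _subfamily_nodes(gt: GeneTree) -> list[dendropy.Node]:
    nodes = []
    for nd in gt.tree.preorder_internal_node_iter():
        children = nd.child_nodes()
        if len(children) != 2:
            continue
        left, right = _child_species_sets(nd)
        if len(left) >= 2 and len(right) >= 2 and (left & right):
            nodes.append(nd)
    return nodes


def patristic_distances(gt: GeneTree) -> dict[tuple[str, str], float]:
    """All pairwise leaf-to-leaf path lengths, keyed by sorted label pair."""
    pdm = gt.tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in gt.tree.leaf_node_iter()]
    out = {}
    for a, b in itertools.combinations(sorted(taxa, key=lambda t: t.label), 2):
        out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out
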