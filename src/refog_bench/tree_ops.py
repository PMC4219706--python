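"""Automatable tree-based steps of the orthologous-group curation protocol.

A gene tree for a homologous family contains sequences from the ingroup
clade under study (e.g. gamma-proteobacteria) and from progressively more
distant outgroups (beta-, then alpha-proteobacteria and beyond).  Given a
species-to-clade map this module

* roots a gene tree on its largest pure distant-outgroup clade,
* extracts the maximal ingroup-only clades — candidate orthologous groups
  relative to the ingroup's last common ancestor,
* flags ingroup sequences nested deep within the outgroups as xenolog
  (horizontal-transfer) candidates, and
* applies the bit-score-range recruitment rule used to pull additional
  family members from profile-HMM searches.

The original curation of such datasets is manual; everything here is the
decidable part and outputs are candidates for human review.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

import dendropy

from refog_bench.ids import DEFAULT_SEP, species_of

__all__ = [
    "INGROUP",
    "CLOSE_OUTGROUP",
    "DISTANT_OUTGROUP",
    "leaf_clade",
    "root_with_outgroup",
    "maximal_ingroup_clades",
    "DelineationResult",
    "delineate_ogs",
    "flag_xenologs",
    "recruit_by_score_range",
    "collapse_low_support",
]

INGROUP = "ingroup"
CLOSE_OUTGROUP = "close_outgroup"
DISTANT_OUTGROUP = "distant_outgroup"
_VALID_CLADES = {INGROUP, CLOSE_OUTGROUP, DISTANT_OUTGROUP}

CladeMap = Mapping[str, str]


def leaf_clade(leaf: dendropy.Node, clades: CladeMap, sep: str = DEFAULT_SEP) -> str:
    """Clade label of a leaf, resolved through its species token."""
    label = leaf.taxon.label
    species = species_of(label, sep)
    try:
        clade = clades[species]
    except KeyError:
        raise KeyError(f"species {species!r} (leaf {label!r}) missing from clade map")
    if clade not in _VALID_CLADES:
        raise ValueError(f"unknown clade label {clade!r} for species {species!r}")
    return clade


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def root_with_outgroup(
    tree: dendropy.Tree,
    clades: CladeMap,
    fallback: Literal["midpoint", None] = "midpoint",
    sep: str = DEFAULT_SEP,
) -> dendropy.Tree:
    """Root a gene tree on its largest pure distant-outgroup clade.

    All edges are scanned; among edges whose leaf-side bipartition consists
    only of distant-outgroup leaves, the one separating the most such leaves
    wins (ties broken by the lexicographically smallest leaf-label tuple).
    The root is placed at the midpoint of that edge, which preserves all
    leaf-to-leaf path lengths.  Without any distant-outgroup leaf the tree
    is midpoint-rooted (``fallback="midpoint"``) or a ``ValueError`` is
    raised (``fallback=None``).  The input tree is left untouched.
    """
    tree = tree.clone(depth=1)
    distant = {
        l.taxon.label
        for l in tree.leaf_node_iter()
        if leaf_clade(l, clades, sep) == DISTANT_OUTGROUP
    }
    if not distant:
        if fallback == "midpoint":
            if sum(1 for _ in tree.leaf_node_iter()) >= 3:
                _midpoint_root(tree)
            tree.is_rooted = True
            return tree
        raise ValueError("tree has no distant-outgroup leaves and fallback disabled")

    best: tuple[int, tuple[str, ...], dendropy.Edge] | None = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = _leaf_labels(node)
        if below <= distant:
            key = (-len(below), tuple(sorted(below)))
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], node.edge)
    assert best is not None  # at least each distant leaf edge qualifies
    edge = best[2]
    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0,
                        suppress_unifurcations=True)
    tree.is_rooted = True
    return tree


def _midpoint_root(tree: dendropy.Tree) -> None:
    """Reroot in place at the midpoint of the longest leaf-to-leaf path."""
    tree.seed_node.edge.length = None
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    best = None  # (-dist, label_a, label_b, a, b, lca)
    anc_cache = {l: ancestors(l) for l in leaves}
    for i, a in enumerate(leaves):
        anc_a = set(anc_cache[a])
        for b in leaves[i + 1 :]:
            lca = next(n for n in anc_cache[b] if n in anc_a)
            dist = depth[a] + depth[b] - 2.0 * depth[lca]
            key = (-dist, a.taxon.label, b.taxon.label)
            if best is None or key < best[:3]:
                best = (*key, a, b, lca)
    _, _, _, a, b, lca = best
    half = (depth[a] + depth[b] - 2.0 * depth[lca]) / 2.0
    # walk a -> lca -> b accumulating until the midpoint's edge is found
    path_edges: list[dendropy.Edge] = []
    node = a
    while node is not lca:
        path_edges.append(node.edge)
        node = node.parent_node
    down = []
    node = b
    while node is not lca:
        down.append(node.edge)
        node = node.parent_node
    path_edges.extend(reversed(down))
    acc = 0.0
    for edge in path_edges:
        length = edge.length or 0.0
        if acc + length >= half - 1e-12:
            from_a = edge.head_node in anc_cache[a] or edge.head_node is a
            offset = half - acc  # distance from the end of the path walked so far
            l_head = offset if from_a else length - offset
            tree.reroot_at_edge(
                edge,
                length1=length - l_head,
                length2=l_head,
                suppress_unifurcations=True,
            )
            return
        acc += length


def maximal_ingroup_clades(
    tree: dendropy.Tree, clades: CladeMap, sep: str = DEFAULT_SEP
) -> list[frozenset[str]]:
    """Leaf sets of the maximal pure-ingroup clades of a rooted tree.

    A clade qualifies when all its leaves are ingroup and its parent clade
    contains at least one outgroup leaf (or it is the root of an all-ingroup
    tree).  Both close and distant outgroups break purity.  The returned
    sets partition the ingroup leaves; ordering is deterministic (by
    smallest leaf label).
    """
    pure: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[node] = leaf_clade(node, clades, sep) == INGROUP
        else:
            pure[node] = all(pure[c] for c in node.child_nodes())
    out: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        if pure[node] and (node.parent_node is None or not pure[node.parent_node]):
            out.append(_leaf_labels(node))
    return sorted(out, key=lambda s: min(s))


class DelineationResult:
    """Candidate orthologous groups plus xenolog candidates from one tree."""

    def __init__(
        self,
        ogs: list[frozenset[str]],
        xenolog_candidates: frozenset[str],
        flank_composition: dict[str, tuple[int, int]] | None = None,
    ) -> None:
        self.ogs = ogs
        self.xenolog_candidates = xenolog_candidates
        #: per xenolog-candidate gene: (n ingroup, n outgroup) flanking leaves
        self.flank_composition = flank_composition or {}

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DelineationResult(ogs={len(self.ogs)}, "
            f"xenolog_candidates={len(self.xenolog_candidates)})"
        )


def delineate_ogs(
    tree: dendropy.Tree,
    clades: CladeMap,
    min_og_size: int = 2,
    sep: str = DEFAULT_SEP,
) -> DelineationResult:
    """Delineate candidate orthologous groups relative to the ingroup LCA.

    Maximal pure-ingroup clades of at least ``min_og_size`` leaves become
    candidate groups; smaller clades (typically single sequences stranded
    among outgroups) are routed to the xenolog-candidate pool.  Every
    ingroup leaf lands in exactly one group or the pool.
    """
    clades_list = maximal_ingroup_clades(tree, clades, sep)
    ogs = [c for c in clades_list if len(c) >= min_og_size]
    pool = frozenset(g for c in clades_list if len(c) < min_og_size for g in c)
    return DelineationResult(ogs=ogs, xenolog_candidates=pool)


def _nearest_outside_leaves(
    node: dendropy.Node, k: int, skip: frozenset | None = None
) -> list[dendropy.Node]:
    """The k leaves outside ``node``'s subtree nearest by edge walks rootward.

    Subtrees rooted at nodes in ``skip`` are not descended into (used to
    look past the immediate sister clade).
    """
    skip = skip or frozenset()
    collected: list[dendropy.Node] = []
    came_from = node
    anc = node.parent_node
    while anc is not None and len(collected) < k:
        siblings = [
            c for c in anc.child_nodes() if c is not came_from and c not in skip
        ]
        # breadth-first within each sibling subtree: nearest leaves first
        frontier = sorted(siblings, key=lambda n: min(_leaf_labels(n)))
        while frontier and len(collected) < k:
            nxt: list[dendropy.Node] = []
            for n in frontier:
                if n.is_leaf():
                    collected.append(n)
                    if len(collected) >= k:
                        break
                else:
                    nxt.extend(n.child_nodes())
            frontier = nxt
        came_from = anc
        anc = anc.parent_node
    return collected


def flag_xenologs(
    tree: dendropy.Tree,
    clades: CladeMap,
    min_flank: int = 3,
    sep: str = DEFAULT_SEP,
) -> frozenset[str]:
    """Flag ingroup clades nested within the outgroups as xenolog candidates.

    A maximal pure-ingroup clade is flagged when (a) its sister (the other
    children of its parent, polytomies included) contains only outgroup
    leaves, the majority of them distant, and (b) the nearest ``min_flank``
    leaves *beyond* that sister, walking toward the root, are majority
    outgroup — the clade must sit in outgroup territory, not merely touch a
    stray outgroup branch (a transfer out of the ingroup produces exactly
    such stray outgroup sisters next to perfectly vertical clades; when no
    leaves exist beyond the sister the sister itself decides).  Requiring a
    majority of distant outgroups in the sister is what makes
    "nested within the close *and* distant outgroups" operational: an
    ingroup clade whose sister is purely the close outgroup is the normal
    species topology (and close-outgroup-boundary signals are deliberately
    left unflagged), whereas a clade directly sister to distant-outgroup
    sequences sits where no vertically inherited gene can.  A clade whose
    parent is the tree root is likewise exempt: an ingroup clade sister to
    the basal outgroup is the normal rooted topology, not a nesting.
    """
    pure: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[node] = leaf_clade(node, clades, sep) == INGROUP
        else:
            pure[node] = all(pure[c] for c in node.child_nodes())

    flagged: set[str] = set()
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if not pure[node] or parent is None or (
            parent.parent_node is not None and pure[parent]
        ):
            continue  # not a maximal ingroup clade
        if parent.parent_node is None:
            continue  # root-adjacent exemption
        sisters = [c for c in parent.child_nodes() if c is not node]
        sister_leaves = [l for s in sisters for l in s.leaf_iter()]
        sister_labels = [leaf_clade(l, clades, sep) for l in sister_leaves]
        if INGROUP in sister_labels:
            continue
        n_distant = sum(1 for c in sister_labels if c == DISTANT_OUTGROUP)
        if n_distant * 2 <= len(sister_labels):
            continue  # sister not majority-distant: normal ladder or boundary
        flank = _nearest_outside_leaves(node, min_flank, skip=frozenset(sisters))
        if not flank:
            flank = sister_leaves
        n_out = sum(1 for l in flank if leaf_clade(l, clades, sep) != INGROUP)
        if n_out * 2 > len(flank):
            flagged |= _leaf_labels(node)
    return frozenset(flagged)


def recruit_by_score_range(
    member_scores: Mapping[str, float],
    candidate_scores: Mapping[str, float],
    mode: Literal["range", "floor"] = "range",
) -> frozenset[str]:
    """Recruit candidate sequences by profile-HMM bit score.

    ``mode="range"`` (the literal reading of "within the range of bit scores
    of already known members") recruits candidates with
    ``min <= score <= max`` over the members, boundaries inclusive;
    ``mode="floor"`` recruits everything scoring at least the member
    minimum, since scores above the member maximum are biologically stronger
    matches.
    """
    if not member_scores:
        raise ValueError("member_scores must be non-empty")
    lo = min(member_scores.values())
    hi = max(member_scores.values())
    if mode == "range":
        return frozenset(g for g, s in candidate_scores.items() if lo <= s <= hi)
    if mode == "floor":
        return frozenset(g for g, s in candidate_scores.items() if s >= lo)
    raise ValueError(f"unknown mode {mode!r}")


def collapse_low_support(tree: dendropy.Tree, min_support: float) -> dendropy.Tree:
    """Collapse internal edges with support below ``min_support`` into polytomies.

    Support values are read from internal node labels (the usual Newick
    convention).  Returns a modified clone; edges without a numeric label
    are kept.
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None or node.label is None:
            continue
        try:
            support = float(node.label)
        except ValueError:
            continue
        if support < min_support:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return tree
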