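"""Gene-family evolution simulator with full ground truth.

Gene families are evolved along an ultrametric species tree by a
birth-death-transfer process (Gillespie simulation): each live gene lineage
on a branch draws exponential waiting times for duplication (rate ``dup_rate``
per lineage per unit time), loss (``loss_rate``) and transfer-out
(``transfer_rate``); a transfer copies the lineage onto a uniformly random
contemporaneous other branch of the species tree; at speciations lineages
are copied into both daughter branches.

Ground-truth orthologous groups are defined relative to a named *reference
node* of the species tree (the ingroup's last common ancestor): two extant
ingroup genes belong to the same group iff they descend vertically —
speciations and duplications only — from the same gene copy present at that
node.  Ingroup genes whose ancestry entered the ingroup through a transfer
from outside are *xenologs* and belong to no group.

Around the gene trees the simulator fabricates everything the benchmarking
and function-test modules consume: operon-like circular genomes (with
xenologs always randomly relocated), inherited domain and EC annotations
(xenologs inherit their family's architecture, mirroring the empirical
observation that domain content rarely exposes them), pairwise homology
hits, and error-injected predicted groups whose expected true/false/missing
assignment counts are recorded per reference group.

All randomness flows from explicit seeds; identical configuration gives a
bit-identical world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import dendropy
import numpy as np

from refog_bench.benchmark_core import PredictedOGSet, RefOG
from refog_bench.function_tests import FeatureMap, Genome, HomologyHit
from refog_bench.ids import make_gene_id
from refog_bench.tree_ops import CLOSE_OUTGROUP, DISTANT_OUTGROUP, INGROUP

__all__ = [
    "SimConfig",
    "PerturbationConfig",
    "Lineage",
    "EventLog",
    "SimWorld",
    "random_species_tree",
    "simulate_family",
    "ground_truth_ogs",
    "simulate_genomes",
    "simulate_annotations",
    "simulate_hits",
    "perturb_predictions",
    "simulate_world",
]

_MAX_LINEAGES = 200_000


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of the birth-death-transfer simulation.

    Rates are per gene lineage per unit branch-length time; the bundled
    random species trees have depth 1.0, so a rate of 0.3 means ~0.3
    expected events per lineage over the whole tree height.
    """

    species_tree: dendropy.Tree
    reference_node: str = "ING"
    dup_rate: float = 0.3
    loss_rate: float = 0.3
    transfer_rate: float = 0.15
    n_families: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "transfer_rate"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass
class PerturbationConfig:
    """Error-injection probabilities for predicted groups.

    Each true group independently receives at most one structural
    perturbation, drawn from split / merge / contaminate / drop with the
    given probabilities (their sum must be <= 1; the remainder is "leave
    intact").  ``drop_fraction`` and ``split_max_fraction`` bound how many
    members a drop removes and a split breaks off; splits always break off
    a strict minority so the intended match stays unambiguous.
    ``include_xenologs`` adds each family's xenologs to the predicted group
    of its largest true group, emulating homology-based predictions that
    cannot see horizontal transfer.
    """

    p_split: float = 0.15
    p_merge: float = 0.10
    p_contaminate: float = 0.15
    p_drop: float = 0.15
    drop_fraction: float = 0.4
    contaminate_max: int = 4
    include_xenologs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_split", "p_merge", "p_contaminate", "p_drop"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_split + self.p_merge + self.p_contaminate + self.p_drop > 1.0:
            raise ValueError("perturbation probabilities must sum to <= 1")


# ---------------------------------------------------------------------------
# species tree scaffolding
# ---------------------------------------------------------------------------

def _random_ultrametric(
    taxa: Sequence[str], t_start: float, t_end: float, rng: np.random.Generator
):
    """Random ultrametric subtree over taxa on the time interval [t_start, t_end].

    Returns a nested-tuple topology annotated with split times; used by
    :func:`random_species_tree`.
    """
    if len(taxa) == 1:
        return taxa[0]
    split = t_start + (t_end - t_start) * rng.uniform(0.15, 0.6)
    k = int(rng.integers(1, len(taxa)))
    left, right = list(taxa[:k]), list(taxa[k:])
    return (
        split,
        _random_ultrametric(left, split, t_end, rng),
        _random_ultrametric(right, split, t_end, rng),
    )


def random_species_tree(
    n_ingroup: int = 20,
    n_close: int = 6,
    n_distant: int = 6,
    seed: int = 0,
    depth: float = 1.0,
    ingroup_age: float = 0.6,
    close_split: float = 0.75,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Random ultrametric species tree with ingroup and two outgroup clades.

    Topology: ``((ingroup, close_outgroup), distant_outgroup)`` with the
    distant outgroup splitting at the root (time 0), the close outgroup at
    ``depth - close_split`` and the ingroup LCA (internal node labelled
    ``"ING"``, the default reference node) at ``depth - ingroup_age``.  All
    leaves lie at time ``depth``.  Ingroup taxids are ``101, 102, ...``,
    close outgroups ``501...``, distant outgroups ``901...``.

    Returns the tree plus the matching species-to-clade map.
    """
    rng = np.random.default_rng(seed)
    ingroup = [str(101 + i) for i in range(n_ingroup)]
    close = [str(501 + i) for i in range(n_close)]
    distant = [str(901 + i) for i in range(n_distant)]

    def render(sub, t_parent: float) -> str:
        if isinstance(sub, str):
            return f"{sub}:{depth - t_parent:.8f}"
        t, left, right = sub
        return f"({render(left, t)},{render(right, t)}):{t - t_parent:.8f}"

    t_ing = depth - ingroup_age
    t_close = depth - close_split
    ing_sub = _random_ultrametric(ingroup, t_ing, depth, rng)
    if isinstance(ing_sub, str):
        ing_str = f"{ing_sub}:{depth - t_close:.8f}ING"  # degenerate 1-taxon ingroup
    else:
        _, l, r = ing_sub
        ing_str = f"({render(l, t_ing)},{render(r, t_ing)})ING:{t_ing - t_close:.8f}"
    close_sub = _random_ultrametric(close, t_close, depth, rng)
    close_str = render(close_sub, t_close) if isinstance(close_sub, str) else (
        f"({render(close_sub[1], close_sub[0])},{render(close_sub[2], close_sub[0])})"
        f":{close_sub[0] - t_close:.8f}"
    )
    dist_sub = _random_ultrametric(distant, 0.0, depth, rng)
    dist_str = render(dist_sub, 0.0) if isinstance(dist_sub, str) else (
        f"({render(dist_sub[1], dist_sub[0])},{render(dist_sub[2], dist_sub[0])})"
        f":{dist_sub[0]:.8f}"
    )
    newick = f"(({ing_str},{close_str}):{t_close:.8f},{dist_str}):0.0;"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = True
    clades = {s: INGROUP for s in ingroup}
    clades.update({s: CLOSE_OUTGROUP for s in close})
    clades.update({s: DISTANT_OUTGROUP for s in distant})
    return tree, clades


class _BranchTable:
    """Species-tree branches as (id, parent, taxon, time interval) records."""

    def __init__(self, tree: dendropy.Tree, reference_node: str) -> None:
        depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            depths[node] = (depths[parent] + edge) if parent is not None else 0.0
        self.depth = max(depths[l] for l in tree.leaf_node_iter())
        leaf_depths = [depths[l] for l in tree.leaf_node_iter()]
        self.is_ultrametric = (
            max(leaf_depths) - min(leaf_depths) <= 1e-5 * max(self.depth, 1.0)
        )

        self.parent: dict[int, int | None] = {}
        self.children: dict[int, list[int]] = {}
        self.t0: dict[int, float] = {}
        self.t1: dict[int, float] = {}
        self.taxon: dict[int, str | None] = {}
        self.ref_branch: int | None = None
        node_ids: dict[dendropy.Node, int] = {}
        ref = None
        for i, node in enumerate(tree.preorder_node_iter()):
            node_ids[node] = i
            parent = node.parent_node
            pid = node_ids[parent] if parent is not None else None
            self.parent[i] = pid
            self.children[i] = []
            if pid is not None:
                self.children[pid].append(i)
            self.t0[i] = depths[parent] if parent is not None else 0.0
            self.t1[i] = depths[node]
            self.taxon[i] = node.taxon.label if node.is_leaf() else None
            label = node.label or (node.taxon.label if node.taxon else None)
            if label == reference_node:
                ref = i
        if ref is None:
            raise ValueError(
                f"reference node {reference_node!r} not found in species tree"
            )
        self.ref_branch = ref
        # branches strictly below the reference node
        self.in_ingroup: dict[int, bool] = {}
        for i in sorted(self.parent):
            pid = self.parent[i]
            self.in_ingroup[i] = (
                pid is not None and (pid == ref or self.in_ingroup.get(pid, False))
            )
        self.root = node_ids[tree.seed_node]
        self.leaves = [i for i in self.taxon if self.taxon[i] is not None]

    def contemporaries(self, branch: int, t: float) -> list[int]:
        return [
            b
            for b in sorted(self.t0)
            if b != branch and b != self.root and self.t0[b] < t < self.t1[b]
        ]


# ---------------------------------------------------------------------------
# the Gillespie process and its event log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lineage:
    """One gene-lineage segment living on a single species-tree branch.

    ``birth`` is how the segment began (``root``, ``speciation``,
    ``duplication``, ``continuation`` — the donor side of a transfer — or
    ``transfer`` — the transferred copy) and ``fate`` how it ended
    (``speciation``, ``duplication``, ``transfer``, ``loss`` or
    ``extant``).
    """

    lineage_id: int
    parent_id: int | None
    branch: int
    t_start: float
    t_end: float
    birth: str
    fate: str
    gene_id: str | None = None  # set for extant lineages


@dataclass
class EventLog:
    """Complete bookkeeping of one family simulation.

    ``lineages`` records every gene-lineage segment; ``events`` is a flat,
    time-ordered convenience view (type, time, branch, lineage, extra).
    The log also carries the branch table facts needed to re-derive ground
    truth: which branches are inside the ingroup and which branch is the
    reference edge.
    """

    family_id: str
    lineages: list[Lineage] = field(default_factory=list)
    events: list[tuple[str, float, int, int, int | None]] = field(default_factory=list)
    ref_branch: int = -1
    in_ingroup: dict[int, bool] = field(default_factory=dict)
    branch_taxon: dict[int, str | None] = field(default_factory=dict)

    def extant(self) -> list[Lineage]:
        return [l for l in self.lineages if l.fate == "extant"]

    def by_id(self, lineage_id: int) -> Lineage:
        return self.lineages[lineage_id]


def simulate_family(
    config: SimConfig,
    family_id: str = "F0001",
    rng: np.random.Generator | None = None,
) -> tuple[dendropy.Tree | None, EventLog]:
    """Evolve one gene family along the species tree.

    Returns the extant gene tree (``None`` when the family went extinct)
    and the full event log.  Extant leaves are labelled
    ``"<taxid>.<family>_<lineage>"``.  With all rates zero the gene tree is
    congruent with the species tree, one gene per species.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    table = _BranchTable(config.species_tree, config.reference_node)
    if config.transfer_rate > 0 and not table.is_ultrametric:
        raise ValueError(
            "transfer events require an ultrametric species tree "
            "(contemporaneity is undefined otherwise)"
        )
    lam, mu, eta = config.dup_rate, config.loss_rate, config.transfer_rate
    total_rate = lam + mu + eta
    log = EventLog(
        family_id=family_id,
        ref_branch=table.ref_branch,
        in_ingroup=dict(table.in_ingroup),
        branch_taxon=dict(table.taxon),
    )

    class _Node:
        __slots__ = ("lineage_id", "children", "t", "kind", "taxon")

        def __init__(self, lineage_id, t, kind, taxon=None):
            self.lineage_id = lineage_id
            self.children: list[_Node] = []
            self.t = t
            self.kind = kind
            self.taxon = taxon

    def new_lineage(parent_id, branch, t_start, birth) -> int:
        lid = len(log.lineages)
        if lid >= _MAX_LINEAGES:
            raise RuntimeError("lineage explosion: rates too high for this tree")
        log.lineages.append(None)  # placeholder, finalised below
        return lid

    def finalise(lid, parent_id, branch, t_start, t_end, birth, fate, gene_id=None):
        log.lineages[lid] = Lineage(
            lineage_id=lid, parent_id=parent_id, branch=branch,
            t_start=t_start, t_end=t_end, birth=birth, fate=fate, gene_id=gene_id,
        )

    def simulate_lineage(branch, t, parent_id, birth):
        """Simulate one lineage segment; returns a gene-tree node or None."""
        lid = new_lineage(parent_id, branch, t, birth)
        t_now = t
        while True:
            wait = (
                rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            )
            t_event = t_now + wait
            if t_event >= table.t1[branch]:
                t_end = table.t1[branch]
                taxon = table.taxon[branch]
                if taxon is not None:  # extant leaf
                    gene = make_gene_id(taxon, f"{family_id}_{lid}")
                    finalise(lid, parent_id, branch, t, t_end, birth, "extant", gene)
                    return _Node(lid, t_end, "extant", taxon)
                # speciation into both daughters
                finalise(lid, parent_id, branch, t, t_end, birth, "speciation")
                log.events.append(("speciation", t_end, branch, lid, None))
                kids = [
                    simulate_lineage(cb, t_end, lid, "speciation")
                    for cb in table.children[branch]
                ]
                kids = [k for k in kids if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]  # unifurcation suppressed
                node = _Node(lid, t_end, "speciation")
                node.children = kids
                return node
            u = rng.uniform(0.0, total_rate)
            if u < mu:
                finalise(lid, parent_id, branch, t, t_event, birth, "loss")
                log.events.append(("loss", t_event, branch, lid, None))
                return None
            if u < mu + lam:
                finalise(lid, parent_id, branch, t, t_event, birth, "duplication")
                log.events.append(("duplication", t_event, branch, lid, None))
                left = simulate_lineage(branch, t_event, lid, "duplication")
                right = simulate_lineage(branch, t_event, lid, "duplication")
                kids = [k for k in [left, right] if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                node = _Node(lid, t_event, "duplication")
                node.children = kids
                return node
            # transfer
            recipients = table.contemporaries(branch, t_event)
            if not recipients:
                t_now = t_event  # nowhere to go; lineage just continues
                continue
            finalise(lid, parent_id, branch, t, t_event, birth, "transfer")
            recipient = recipients[int(rng.integers(len(recipients)))]
            log.events.append(("transfer", t_event, branch, lid, recipient))
            stay = simulate_lineage(branch, t_event, lid, "continuation")
            moved = simulate_lineage(recipient, t_event, lid, "transfer")
            kids = [k for k in [stay, moved] if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = _Node(lid, t_event, "transfer")
            node.children = kids
            return node

    roots = [
        simulate_lineage(cb, table.t1[table.root], None, "root")
        for cb in table.children[table.root]
    ]
    roots = [r for r in roots if r is not None]
    if not roots:
        return None, log

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    def build(node: _Node, dnode: dendropy.Node, t_parent: float) -> None:
        dnode.edge.length = node.t - t_parent
        if not node.children:
            gene = log.by_id(node.lineage_id).gene_id
            dnode.taxon = taxa.require_taxon(label=gene)
            return
        dnode.label = node.kind
        for child in node.children:
            c = dendropy.Node()
            dnode.add_child(c)
            build(child, c, node.t)

    t_root = table.t1[table.root]
    if len(roots) == 1:
        build(roots[0], tree.seed_node, t_root)
    else:
        tree.seed_node.label = "speciation"
        for r in roots:
            c = dendropy.Node()
            tree.seed_node.add_child(c)
            build(r, c, t_root)
    tree.seed_node.edge.length = None  # roots carry no stem
    return tree, log


def ground_truth_ogs(
    log: EventLog, reference_node: str | None = None
) -> tuple[list[frozenset[str]], frozenset[str]]:
    """Derive true orthologous groups and xenologs from an event log.

    Extant ingroup genes are grouped by the gene copy present at the
    reference node they descend from vertically; genes whose ancestry
    entered the ingroup via a transfer from outside are returned as
    xenologs instead.  (The reference node is fixed by the log; the
    argument is accepted for interface symmetry and ignored.)
    """
    groups: dict[int, set[str]] = {}
    xenologs: set[str] = set()
    for leaf in log.extant():
        if not log.in_ingroup.get(leaf.branch, False):
            continue  # outgroup gene: in no group by definition
        cur = leaf
        founder: int | None = None
        is_xeno = False
        while cur is not None:
            if cur.branch == log.ref_branch and cur.fate == "speciation":
                founder = cur.lineage_id
                break
            if cur.birth == "transfer":
                parent = log.by_id(cur.parent_id)
                inside = log.in_ingroup.get(cur.branch, False)
                donor_inside = (
                    log.in_ingroup.get(parent.branch, False)
                    or parent.branch == log.ref_branch
                )
                if inside and not donor_inside:
                    is_xeno = True
                    break
            cur = log.by_id(cur.parent_id) if cur.parent_id is not None else None
        if is_xeno or founder is None:
            xenologs.add(leaf.gene_id)
        else:
            groups.setdefault(founder, set()).add(leaf.gene_id)
    ogs = [frozenset(g) for _, g in sorted(groups.items())]
    return ogs, frozenset(xenologs)


# ---------------------------------------------------------------------------
# the assembled world
# ---------------------------------------------------------------------------

@dataclass
class SimWorld:
    """Everything one simulation produced, with ground truth attached."""

    config: SimConfig
    clades: dict[str, str]
    trees: dict[str, dendropy.Tree]
    logs: dict[str, EventLog]
    refogs: list[RefOG] = field(default_factory=list)
    #: gene -> family id, for every extant xenolog
    xenologs: dict[str, str] = field(default_factory=dict)
    #: refog_id -> family id
    refog_family: dict[str, str] = field(default_factory=dict)
    genomes: dict[str, Genome] = field(default_factory=dict)
    domains: FeatureMap | None = None
    ec: FeatureMap | None = None
    hits: list[HomologyHit] = field(default_factory=list)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    predictions: PredictedOGSet | None = None
    #: refog_id -> expected (n_TA, n_FA, n_MA) after perturbation
    expected_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    perturbation_log: list[tuple[str, str]] = field(default_factory=list)

    def family_genes(self, family_id: str) -> list[str]:
        return sorted(l.gene_id for l in self.logs[family_id].extant())

    def family_xenologs(self, family_id: str) -> frozenset[str]:
        return frozenset(
            g for g, f in self.xenologs.items() if f == family_id
        )


def simulate_genomes(
    world: SimWorld, p_syn: float = 0.95, seed: int = 0
) -> dict[str, Genome]:
    """Fabricate one circular replicon per species with operon-like order.

    An ancestral order over families is drawn once; every genome lists its
    genes in that order (in-paralogs adjacent at their family's slot).  Each
    non-xenolog gene then keeps its ancestral position with probability
    ``p_syn`` and is otherwise relocated uniformly at random; xenologs are
    *always* randomly relocated, reflecting that horizontally acquired genes
    land anywhere in the genome.
    """
    rng = np.random.default_rng(seed)
    families = sorted(world.logs)
    order = list(families)
    rng.shuffle(order)
    slot = {f: i for i, f in enumerate(order)}

    by_species: dict[str, list[tuple[int, str]]] = {}
    xeno_by_species: dict[str, list[str]] = {}
    for fam in families:
        for lin in world.logs[fam].extant():
            gene = lin.gene_id
            species = gene.split(".", 1)[0]
            if gene in world.xenologs:
                xeno_by_species.setdefault(species, []).append(gene)
            else:
                by_species.setdefault(species, []).append((slot[fam], gene))

    genomes: dict[str, Genome] = {}
    for species in sorted(set(by_species) | set(xeno_by_species)):
        ordered = [g for _, g in sorted(by_species.get(species, []))]
        # per-gene relocation, violating synteny with probability 1 - p_syn
        if p_syn < 1.0 and len(ordered) > 1:
            keep_mask = rng.random(len(ordered)) < p_syn
            movers = [g for g, k in zip(ordered, keep_mask) if not k]
            ordered = [g for g, k in zip(ordered, keep_mask) if k]
            for gene in movers:
                pos = int(rng.integers(len(ordered) + 1))
                ordered.insert(pos, gene)
        for gene in sorted(xeno_by_species.get(species, [])):
            pos = int(rng.integers(len(ordered) + 1))
            ordered.insert(pos, gene)
        genomes[species] = Genome(
            species=species, replicons={"chr": ordered}, circular={"chr": True}
        )
    return genomes


def simulate_annotations(
    world: SimWorld,
    q_dom: float = 0.95,
    ec_fraction: float = 0.6,
    q_ec: float = 0.9,
    seed: int = 0,
) -> tuple[FeatureMap, FeatureMap]:
    """Fabricate per-gene domain and EC annotations.

    Every family carries 1–4 domain tokens and, with probability
    ``ec_fraction``, one four-digit EC number.  Each extant member —
    xenologs included, since a transferred gene keeps its architecture —
    inherits each family domain with probability ``q_dom`` and the family
    EC with probability ``q_ec``.
    """
    rng = np.random.default_rng(seed)
    domains: dict[str, frozenset[str]] = {}
    ecs: dict[str, frozenset[str]] = {}
    for fam in sorted(world.logs):
        n_dom = int(rng.integers(1, 5))
        fam_domains = [f"PF_{fam}_{k}" for k in range(n_dom)]
        fam_ec = None
        if rng.random() < ec_fraction:
            a, b, c = rng.integers(1, 7), rng.integers(1, 10), rng.integers(1, 10)
            d = rng.integers(1, 100)
            fam_ec = f"EC:{a}.{b}.{c}.{d}"
        for gene in world.family_genes(fam):
            kept = frozenset(t for t in fam_domains if rng.random() < q_dom)
            domains[gene] = kept
            if fam_ec is not None and rng.random() < q_ec:
                ecs[gene] = frozenset([fam_ec])
    return (
        FeatureMap(feature_kind="domain", assignments=domains),
        FeatureMap(feature_kind="ec", assignments=ecs),
    )


def simulate_hits(
    world: SimWorld,
    within_e: float = 1e-30,
    between_e: float = 1.0,
    n_decoys_per_family: int = 2,
    seed: int = 0,
) -> tuple[list[HomologyHit], dict[str, int]]:
    """Fabricate pairwise homology hits.

    All within-family pairs receive hits at or below ``within_e`` with >=95%
    coverage of the shorter gene, so single-linkage clustering recovers the
    family partition exactly; a few cross-family decoy pairs receive
    e-values between 1e-4 and ``between_e`` (above any sensible threshold).
    Gene lengths are drawn per family with small per-gene jitter and
    returned alongside the hits.
    """
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    lengths: dict[str, int] = {}
    fam_genes: dict[str, list[str]] = {}
    for fam in sorted(world.logs):
        base = int(rng.integers(200, 801))
        genes = world.family_genes(fam)
        fam_genes[fam] = genes
        for g in genes:
            lengths[g] = base + int(rng.integers(-base // 20, base // 20 + 1))
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                shorter = min(lengths[a], lengths[b])
                aligned = math.ceil(0.95 * shorter)
                e = within_e * 10.0 ** (-float(rng.uniform(0.0, 20.0)))
                hits.append(HomologyHit(
                    query=a, subject=b, e_value=e, aligned_length=aligned,
                    query_length=lengths[a], subject_length=lengths[b],
                    bit_score=round(1.9 * aligned + float(rng.normal(0, 5)), 1),
                ))
    fams = [f for f in sorted(fam_genes) if fam_genes[f]]
    if len(fams) >= 2:
        for fam in fams:
            for _ in range(n_decoys_per_family):
                other = fams[int(rng.integers(len(fams)))]
                if other == fam:
                    continue
                a = fam_genes[fam][int(rng.integers(len(fam_genes[fam])))]
                b = fam_genes[other][int(rng.integers(len(fam_genes[other])))]
                shorter = min(lengths[a], lengths[b])
                e = float(10.0 ** rng.uniform(-4.0, math.log10(between_e)))
                hits.append(HomologyHit(
                    query=a, subject=b, e_value=e,
                    aligned_length=max(30, int(0.3 * shorter)),
                    query_length=lengths[a], subject_length=lengths[b],
                    bit_score=round(40 + float(rng.normal(0, 5)), 1),
                ))
    return hits, lengths


def perturb_predictions(
    refogs: Sequence[RefOG],
    pconfig: PerturbationConfig,
    xenologs_by_refog: Mapping[str, frozenset[str]] | None = None,
    dataset_name: str = "perturbed",
) -> tuple[PredictedOGSet, dict[str, tuple[int, int, int]], list[tuple[str, str]]]:
    """Inject known errors into the true groups.

    Each group receives at most one structural perturbation (split, merge,
    contaminate with fabricated foreign genes, or drop members); the
    returned expected counts give the exact (TA, FA, MA) the benchmark
    classification must recover for every reference group.  When
    ``xenologs_by_refog`` maps group ids to xenolog genes and
    ``pconfig.include_xenologs`` is set, those genes are additionally placed
    into the group's predicted match and counted as expected false
    assignments.
    """
    rng = np.random.default_rng(pconfig.seed)
    xen = dict(xenologs_by_refog or {})
    ordered = sorted(refogs, key=lambda r: r.refog_id)

    # decide one action per group; merges pair with a following intact group
    actions: dict[str, str] = {}
    thresholds = np.cumsum([
        pconfig.p_split, pconfig.p_merge, pconfig.p_contaminate, pconfig.p_drop
    ])
    names = ["split", "merge", "contaminate", "drop"]
    for r in ordered:
        u = rng.random()
        idx = int(np.searchsorted(thresholds, u, side="left"))
        actions[r.refog_id] = names[idx] if idx < 4 else "intact"
        if actions[r.refog_id] == "split" and len(r.members) < 3:
            actions[r.refog_id] = "intact"

    merge_partner: dict[str, str] = {}
    mergers = [r.refog_id for r in ordered if actions[r.refog_id] == "merge"]
    intact = [r.refog_id for r in ordered if actions[r.refog_id] == "intact"]
    for rid in mergers:
        if not intact:
            actions[rid] = "intact"
            continue
        j = int(rng.integers(len(intact)))
        partner = intact.pop(j)
        actions[partner] = "merged_into"
        merge_partner[rid] = partner

    by_id = {r.refog_id: r for r in ordered}
    groups: dict[str, set[str]] = {}
    expected: dict[str, tuple[int, int, int]] = {}
    plog: list[tuple[str, str]] = []
    matched_group_of: dict[str, str] = {}
    foreign_counter = 0

    for r in ordered:
        act = actions[r.refog_id]
        gid = f"P_{r.refog_id}"
        members = sorted(r.members)
        n = len(members)
        if act == "merged_into":
            continue  # handled by its merging partner
        if act == "intact":
            groups[gid] = set(members)
            expected[r.refog_id] = (n, 0, 0)
            matched_group_of[r.refog_id] = gid
            plog.append((r.refog_id, "intact"))
        elif act == "split":
            k = int(rng.integers(1, (n - 1) // 2 + 1))  # strict minority
            idx = rng.choice(n, size=k, replace=False)
            off = {members[i] for i in idx}
            main = set(members) - off
            groups[gid] = main
            groups[gid + "_split"] = set(off)
            expected[r.refog_id] = (n - k, 0, k)
            matched_group_of[r.refog_id] = gid
            plog.append((r.refog_id, f"split:{k}"))
        elif act == "merge":
            partner = by_id[merge_partner[r.refog_id]]
            merged = set(members) | set(partner.members)
            groups[gid] = merged
            expected[r.refog_id] = (n, len(partner.members), 0)
            expected[partner.refog_id] = (len(partner.members), n, 0)
            matched_group_of[r.refog_id] = gid
            matched_group_of[partner.refog_id] = gid
            plog.append((r.refog_id, f"merge:{partner.refog_id}"))
            plog.append((partner.refog_id, f"merged_into:{r.refog_id}"))
        elif act == "contaminate":
            k = int(rng.integers(1, pconfig.contaminate_max + 1))
            foreign = set()
            for _ in range(k):
                foreign.add(f"999.decoy{foreign_counter}")
                foreign_counter += 1
            groups[gid] = set(members) | foreign
            expected[r.refog_id] = (n, len(foreign), 0)
            matched_group_of[r.refog_id] = gid
            plog.append((r.refog_id, f"contaminate:{len(foreign)}"))
        elif act == "drop":
            k = max(1, int(round(pconfig.drop_fraction * n)))
            k = min(k, n)
            idx = rng.choice(n, size=k, replace=False)
            dropped = {members[i] for i in idx}
            remaining = set(members) - dropped
            if remaining:
                groups[gid] = remaining
                matched_group_of[r.refog_id] = gid
            expected[r.refog_id] = (n - k, 0, k)
            plog.append((r.refog_id, f"drop:{k}"))

    if pconfig.include_xenologs and xen:
        for rid in sorted(xen):
            gid = matched_group_of.get(rid)
            if gid is None or not xen[rid]:
                continue
            new = set(xen[rid]) - groups[gid]
            groups[gid] |= new
            ta, fa, ma = expected[rid]
            expected[rid] = (ta, fa + len(new), ma)
            # a merge partner shares the predicted group: its FA grows too
            for other, g in matched_group_of.items():
                if g == gid and other != rid:
                    ta2, fa2, ma2 = expected[other]
                    expected[other] = (ta2, fa2 + len(new), ma2)
            plog.append((rid, f"xenologs:{len(new)}"))

    predictions = PredictedOGSet(
        dataset_name=dataset_name,
        groups={g: frozenset(m) for g, m in groups.items() if m},
    )
    return predictions, expected, plog


def simulate_world(
    config: SimConfig,
    pconfig: PerturbationConfig | None = None,
    clades: Mapping[str, str] | None = None,
    p_syn: float = 0.95,
    q_dom: float = 0.95,
    ec_fraction: float = 0.6,
    min_og_size: int = 1,
    with_genomes: bool = True,
    with_annotations: bool = True,
    with_hits: bool = True,
) -> SimWorld:
    """Simulate a complete world: families, ground truth, data, predictions.

    ``min_og_size`` filters trivially small true groups out of the reference
    set (singleton groups are kept by default so the bookkeeping invariant
    "every non-xenolog ingroup gene is in exactly one group" stays visible).
    Heavy components (genomes, annotations, hits) can be switched off for
    speed when only classification-level ground truth is needed.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_families + 4)
    if clades is None:
        clades = _infer_clades(config)
    world = SimWorld(config=config, clades=dict(clades), trees={}, logs={})

    refog_idx = 0
    xen_by_refog: dict[str, frozenset[str]] = {}
    for i in range(config.n_families):
        fam = f"F{i + 1:04d}"
        rng = np.random.default_rng(seeds[i])
        tree, log = simulate_family(config, family_id=fam, rng=rng)
        if tree is None:
            continue
        world.trees[fam] = tree
        world.logs[fam] = log
        ogs, xenologs = ground_truth_ogs(log)
        for gene in sorted(xenologs):
            world.xenologs[gene] = fam
        fam_refogs = []
        for og in sorted(ogs, key=min):
            if len(og) < min_og_size:
                continue
            refog_idx += 1
            rid = f"ROG{refog_idx:04d}"
            fam_refogs.append(RefOG(refog_id=rid, members=og, xenologs=xenologs))
            world.refog_family[rid] = fam
        world.refogs.extend(fam_refogs)
        if fam_refogs and xenologs:
            # attach the family's xenologs to its largest group's prediction
            target = max(fam_refogs, key=lambda r: (len(r.members), r.refog_id))
            xen_by_refog[target.refog_id] = xenologs

    if with_genomes:
        world.genomes = simulate_genomes(
            world, p_syn=p_syn, seed=seeds[config.n_families].generate_state(1)[0] % (2**31)
        )
    if with_annotations:
        world.domains, world.ec = simulate_annotations(
            world, q_dom=q_dom, ec_fraction=ec_fraction,
            seed=seeds[config.n_families + 1].generate_state(1)[0] % (2**31),
        )
    if with_hits:
        world.hits, world.gene_lengths = simulate_hits(
            world, seed=seeds[config.n_families + 2].generate_state(1)[0] % (2**31)
        )
    if pconfig is None:
        pconfig = PerturbationConfig(
            seed=int(seeds[config.n_families + 3].generate_state(1)[0] % (2**31))
        )
    world.predictions, world.expected_counts, world.perturbation_log = (
        perturb_predictions(world.refogs, pconfig, xenologs_by_refog=xen_by_refog)
    )
    return world


def _infer_clades(config: SimConfig) -> dict[str, str]:
    """Derive a clade map from the species tree and reference node.

    Species below the reference node are ingroup; the remaining species
    split into close outgroup (sharing the reference node's parent) and
    distant outgroup (everything else).
    """
    table = _BranchTable(config.species_tree, config.reference_node)
    clades: dict[str, str] = {}
    ref_parent = table.parent[table.ref_branch]
    under_parent: set[int] = set()
    if ref_parent is not None:
        stack = [ref_parent]
        while stack:
            b = stack.pop()
            under_parent.add(b)
            stack.extend(table.children[b])
    for b in table.leaves:
        taxon = table.taxon[b]
        if table.in_ingroup[b] or b == table.ref_branch:
            clades[taxon] = INGROUP
        elif b in under_parent:
            clades[taxon] = CLOSE_OUTGROUP
        else:
            clades[taxon] = DISTANT_OUTGROUP
    return clades
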