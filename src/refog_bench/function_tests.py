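"""Function-based validation scores for orthologous groups.

Orthology predictions are often validated by conserved *function* instead of
by evolutionary history.  This module implements the three classical
function-based tests so their discriminative power can be measured against a
phylogeny-based ground truth:

1. **Protein-domain content** — domains present in more than 75% of a
   reference group's members are "family-specific conserved domains"; a
   gene's score is how many of them it carries.
2. **Gene order (synteny)** — neighbour genes (±5 around each member,
   roughly an operon-sized window) are clustered into families by
   single-linkage over pairwise homology hits; families present in at least
   75% of member neighbourhoods are conserved, and a gene's score counts the
   conserved families found in its own window.
3. **Enzymatic activity** — EC numbers, hierarchically expanded
   (``EC:1.2.3.4 → {EC:1.2.3.4, EC:1.2.3.-, EC:1.2.-.-}``), conserved when
   assigned to more than 75% of members.

The per-gene scores feed category summaries (TA vs FA vs MA) and an
"accurately inferred" call per group: a test vindicates a predicted group
when no false assignment scores below the worst true assignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "FeatureMap",
    "HomologyHit",
    "Genome",
    "ConservedFeatureSet",
    "conserved_features",
    "feature_score",
    "extract_neighborhood",
    "build_neighbor_families",
    "gene_order_score",
    "ec_expand",
    "expand_ec_map",
    "ec_score",
    "category_score_distributions",
    "og_accuracy_call",
]

logger = logging.getLogger(__name__)

Comparator = Literal["strict", "inclusive"]


@dataclass
class FeatureMap:
    """Per-gene feature tokens (domains, EC terms, or neighbour-family ids).

    A gene *present* in ``assignments`` with an empty set is "annotated with
    nothing"; a gene absent from the map is unannotated/unknown — both score
    zero but the distinction is preserved for bookkeeping.
    """

    feature_kind: Literal["domain", "ec", "neighbor_family"]
    assignments: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {g: frozenset(v) for g, v in self.assignments.items()}

    def features(self, gene: str) -> frozenset[str]:
        return self.assignments.get(gene, frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene in self.assignments


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise homology hit (BLAST tabular style; lengths as reported)."""

    query: str
    subject: str
    e_value: float
    aligned_length: int
    query_length: int
    subject_length: int
    bit_score: float = 0.0


@dataclass
class Genome:
    """Ordered gene content of one genome, possibly over several replicons."""

    species: str
    replicons: dict[str, list[str]]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[str, int]] = {}
        for rep, genes in self.replicons.items():
            self.circular.setdefault(rep, False)
            for i, g in enumerate(genes):
                if g in self._index:
                    raise ValueError(
                        f"gene {g!r} placed twice in genome {self.species!r}"
                    )
                self._index[g] = (rep, i)

    def locate(self, gene: str) -> tuple[str, int]:
        """Return (replicon, position) of a gene; KeyError if absent."""
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


@dataclass(frozen=True)
class ConservedFeatureSet:
    """Family-specific conserved feature tokens for one reference group."""

    refog_id: str
    feature_kind: str
    conserved: frozenset[str]
    threshold_used: float
    comparator: Comparator


def conserved_features(
    members: Iterable[str],
    fmap: FeatureMap,
    threshold: float = 0.75,
    comparator: Comparator | None = None,
    refog_id: str = "",
) -> ConservedFeatureSet:
    """Identify feature tokens conserved across a group's members.

    A token is conserved when the fraction of members carrying it passes the
    threshold.  The domain and EC analyses use a strict comparator (*more
    than* 75%), the neighbour-family analysis an inclusive one (*at least*
    75%); when ``comparator`` is not given it defaults accordingly from
    ``fmap.feature_kind``.  Members absent from the map count in the
    denominator (they lower every fraction).
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("members must be non-empty")
    if comparator is None:
        comparator = "inclusive" if fmap.feature_kind == "neighbor_family" else "strict"
    counts: dict[str, int] = {}
    for gene in members:
        for token in fmap.features(gene):
            counts[token] = counts.get(token, 0) + 1
    n = len(members)
    if comparator == "strict":
        conserved = {t for t, c in counts.items() if c / n > threshold}
    else:
        conserved = {t for t, c in counts.items() if c / n >= threshold}
    return ConservedFeatureSet(
        refog_id=refog_id,
        feature_kind=fmap.feature_kind,
        conserved=frozenset(conserved),
        threshold_used=threshold,
        comparator=comparator,
    )


def feature_score(gene: str, conserved: ConservedFeatureSet, fmap: FeatureMap) -> int:
    """Number of family-specific conserved tokens the gene carries."""
    return len(fmap.features(gene) & conserved.conserved)


def extract_neighborhood(genome: Genome, gene: str, flank: int = 5) -> list[str]:
    """Genes within ``flank`` positions on either side of ``gene``.

    The focal gene is excluded.  Windows truncate at the ends of linear
    replicons and wrap around circular ones; on a replicon shorter than the
    window every other gene appears exactly once.
    """
    try:
        rep, i = genome.locate(gene)
    except KeyError:
        raise KeyError(f"gene {gene!r} not present in genome {genome.species!r}")
    genes = genome.replicons[rep]
    n = len(genes)
    if genome.circular.get(rep, False):
        span = min(flank, (n - 1) // 2)
        upstream = [genes[(i - k) % n] for k in range(span, 0, -1)]
        extra = min(2 * flank, n - 1) - 2 * span  # odd-length small replicons
        downstream = [genes[(i + k) % n] for k in range(1, span + extra + 1)]
        return upstream + downstream
    lo = max(0, i - flank)
    hi = min(n, i + flank + 1)
    return genes[lo:i] + genes[i + 1 : hi]


def build_neighbor_families(
    hits: Iterable[HomologyHit],
    e_max: float = 1e-5,
    min_len_frac: float = 0.90,
) -> dict[str, str]:
    """Single-linkage gene families from pairwise homology hits.

    An undirected link joins query and subject when ``e_value <= e_max`` and
    the aligned region covers at least ``min_len_frac`` of the shorter gene.
    Families are the connected components; every gene seen in any hit gets a
    family (singletons allowed).  Family tokens are the lexicographically
    smallest member id, so the naming is deterministic.
    """
    graph = nx.Graph()
    for hit in hits:
        graph.add_node(hit.query)
        graph.add_node(hit.subject)
        shorter = min(hit.query_length, hit.subject_length)
        if hit.e_value <= e_max and hit.aligned_length >= min_len_frac * shorter:
            graph.add_edge(hit.query, hit.subject)
    families: dict[str, str] = {}
    for component in nx.connected_components(graph):
        token = min(component)
        for gene in component:
            families[gene] = token
    return families


def gene_order_score(
    gene: str,
    genomes: Mapping[str, Genome],
    neighbor_families: Mapping[str, str],
    conserved: ConservedFeatureSet,
    flank: int = 5,
    sep: str = ".",
) -> int:
    """Conserved neighbour families represented in a gene's genomic window.

    Each conserved family counts once no matter how many neighbourhood genes
    belong to it.  A gene without genomic placement (e.g. a false assignment
    from a genome outside the dataset) scores 0 with a warning rather than
    being excluded, so category summaries stay comparable.
    """
    species = gene.split(sep, 1)[0]
    genome = genomes.get(species)
    if genome is None or gene not in genome:
        logger.warning("gene %s has no genomic placement; gene-order score 0", gene)
        return 0
    window = extract_neighborhood(genome, gene, flank=flank)
    present = {neighbor_families.get(g, g) for g in window}
    return len(present & conserved.conserved)


_EC_RE = re.compile(r"^(?:EC:)?(\d+)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def ec_expand(ec: str) -> frozenset[str]:
    """Hierarchically expand an EC number to its less-specific ancestors.

    ``EC:1.2.3.4`` expands to ``{EC:1.2.3.4, EC:1.2.3.-, EC:1.2.-.-}``: the
    term itself plus every masking down to two retained digits (no
    single-digit term is emitted).  Already-partial terms expand to their
    remaining ancestors only.  The ``EC:`` prefix is optional on input and
    canonical on output.
    """
    m = _EC_RE.match(ec.strip())
    if m is None:
        raise ValueError(f"malformed EC number: {ec!r}")
    fields = list(m.groups())
    # masked fields may only trail: 1.-.3.4 is invalid
    seen_mask = False
    for f in fields[1:]:
        if f == "-":
            seen_mask = True
        elif seen_mask:
            raise ValueError(f"malformed EC number (non-trailing mask): {ec!r}")
    terms = {"EC:" + ".".join(fields)}
    for keep in range(3, 1, -1):
        if all(f != "-" for f in fields[:keep]):
            masked = fields[:keep] + ["-"] * (4 - keep)
            terms.add("EC:" + ".".join(masked))
    return frozenset(terms)


def expand_ec_map(ec_map: FeatureMap) -> FeatureMap:
    """Return a FeatureMap whose EC annotations are hierarchically expanded."""
    expanded = {
        gene: frozenset(t for ec in terms for t in ec_expand(ec))
        for gene, terms in ec_map.assignments.items()
    }
    return FeatureMap(feature_kind="ec", assignments=expanded)


def ec_score(
    gene: str, conserved: ConservedFeatureSet, ec_map: FeatureMap
) -> int:
    """Number of conserved EC terms assigned to the gene, after expansion."""
    terms = frozenset(t for ec in ec_map.features(gene) for t in ec_expand(ec))
    return len(terms & conserved.conserved)


def category_score_distributions(
    classification,
    scores: Mapping[str, float],
) -> dict[str, dict[str, float]]:
    """Summarise per-gene scores for each assignment category.

    Returns ``{category: {n, mean, q1, median, q3}}`` for the non-empty
    categories among TA, MA, FA; empty categories are absent rather than
    reported with a fabricated zero mean.  Genes missing from ``scores``
    count as 0 (consistent with the unplaced/unannotated policy).
    """
    out: dict[str, dict[str, float]] = {}
    for name, genes in (("TA", classification.TA),
                        ("MA", classification.MA),
                        ("FA", classification.FA)):
        if not genes:
            continue
        vals = np.array([scores.get(g, 0) for g in sorted(genes)], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[name] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
        }
    return out


def og_accuracy_call(classification, scores: Mapping[str, float]) -> bool:
    """Would this group be called "accurately inferred" by the score?

    The test *fails to flag* the group — i.e. calls it accurate — when every
    false assignment scores at least as high as the worst-scoring true
    assignment, making the FA genes indistinguishable.  Vacuously accurate
    when there are no false assignments; a group with false assignments but
    no true ones cannot be vindicated and is called inaccurate.
    """
    if not classification.FA:
        return True
    if not classification.TA:
        return False
    min_ta = min(scores.get(g, 0) for g in classification.TA)
    return all(scores.get(g, 0) >= min_ta for g in classification.FA)
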