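"""Benchmarking predicted orthologous groups against curated references.

Each curated reference orthologous group (RefOG) is matched to the predicted
group that covers most of its members; the predicted group's membership is
then partitioned into

* **true assignments (TA)** — reference orthologs grouped correctly,
* **false assignments (FA)** — predicted members that are not reference
  orthologs,
* **missing assignments (MA)** — reference orthologs the prediction left out.

On top of the per-group classification the module aggregates totals, recall,
per-species error tallies, restriction of datasets to a common species
repertoire, and a two-sample Kolmogorov–Smirnov comparison of per-species
error distributions between two datasets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, overload

import pandas as pd
from scipy import stats

from refog_bench.ids import DEFAULT_SEP, species_of

__all__ = [
    "RefOG",
    "PredictedOGSet",
    "AssignmentClassification",
    "BenchmarkReport",
    "best_coverage_match",
    "classify_assignments",
    "benchmark_dataset",
    "recall_percent",
    "per_species_error_counts",
    "restrict_to_species",
    "ks_compare",
]


@dataclass(frozen=True)
class RefOG:
    """A curated reference orthologous group.

    Parameters
    ----------
    refog_id:
        Stable group label, e.g. ``"RefOG075"``.
    members:
        The curated ortholog membership (non-empty).
    xenologs:
        Genes annotated as horizontally acquired relatives of the family.
        Xenologs are *not* members — by definition they are false assignments
        whenever a prediction includes them — so the two sets are disjoint.
    tree_file:
        Optional path to the curated gene tree backing this group.
    """

    refog_id: str
    members: frozenset[str]
    xenologs: frozenset[str] = frozenset()
    tree_file: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "xenologs", frozenset(self.xenologs))
        if not self.members:
            raise ValueError(f"RefOG {self.refog_id!r} has no members")
        overlap = self.members & self.xenologs
        if overlap:
            raise ValueError(
                f"RefOG {self.refog_id!r}: xenologs must be disjoint from "
                f"members (overlap: {sorted(overlap)[:5]})"
            )


@dataclass
class PredictedOGSet:
    """A database's predicted orthologous groups at one phylogenetic level."""

    dataset_name: str
    groups: dict[str, frozenset[str]]
    level_tag: str = ""

    def __post_init__(self) -> None:
        self.groups = {og: frozenset(genes) for og, genes in self.groups.items()}

    def validate(self) -> None:
        """Raise if a gene belongs to more than one group (input error)."""
        seen: dict[str, str] = {}
        for og_id in sorted(self.groups):
            for gene in self.groups[og_id]:
                if gene in seen:
                    raise ValueError(
                        f"gene {gene!r} appears in groups {seen[gene]!r} and "
                        f"{og_id!r}; membership must be unique per level"
                    )
                seen[gene] = og_id

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.groups.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class AssignmentClassification:
    """TA/FA/MA partition of one RefOG against its best-matching prediction."""

    refog_id: str
    matched_og_id: str | None
    TA: frozenset[str]
    FA: frozenset[str]
    MA: frozenset[str]

    @property
    def n_ta(self) -> int:
        return len(self.TA)

    @property
    def n_fa(self) -> int:
        return len(self.FA)

    @property
    def n_ma(self) -> int:
        return len(self.MA)


@dataclass
class BenchmarkReport:
    """All per-RefOG classifications for one dataset comparison."""

    dataset_name: str
    classifications: list[AssignmentClassification] = field(default_factory=list)

    @property
    def totals(self) -> tuple[int, int, int]:
        """Summed (|TA|, |FA|, |MA|) over all reference groups."""
        ta = sum(c.n_ta for c in self.classifications)
        fa = sum(c.n_fa for c in self.classifications)
        ma = sum(c.n_ma for c in self.classifications)
        return ta, fa, ma

    @property
    def n_reference_genes(self) -> int:
        """Number of distinct reference orthologs across all groups.

        When several reference groups map to the same predicted group the
        summed TA+MA basis can exceed this distinct-gene count; both bases
        are therefore reported explicitly.
        """
        genes: set[str] = set()
        for c in self.classifications:
            genes |= c.TA | c.MA
        return len(genes)


def best_coverage_match(refog: RefOG, predictions: PredictedOGSet) -> str | None:
    """Return the predicted group id that covers most RefOG members.

    Coverage is ``|group ∩ members|``.  Ties favour the smaller group
    (precision) and then the lexicographically smaller group id, so the
    result is deterministic.  Returns ``None`` when no predicted group
    intersects the reference members at all.
    """
    best: tuple[int, int, str] | None = None
    for og_id, genes in predictions.groups.items():
        cov = len(genes & refog.members)
        if cov == 0:
            continue
        key = (-cov, len(genes), og_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def classify_assignments(
    refog: RefOG,
    matched_group: Iterable[str],
    matched_og_id: str | None = None,
) -> AssignmentClassification:
    """Partition a matched predicted group into TA/FA/MA by set arithmetic."""
    group = frozenset(matched_group)
    ta = refog.members & group
    fa = group - refog.members
    ma = refog.members - group
    cls = AssignmentClassification(
        refog_id=refog.refog_id,
        matched_og_id=matched_og_id,
        TA=ta,
        FA=fa,
        MA=ma,
    )
    # partition invariants, asserted on every run
    assert cls.TA | cls.MA == refog.members and not cls.TA & cls.MA
    assert cls.TA | cls.FA == group and not cls.TA & cls.FA
    return cls


def benchmark_dataset(
    refogs: Sequence[RefOG], predictions: PredictedOGSet
) -> BenchmarkReport:
    """Classify every reference group against its best-coverage prediction.

    Each RefOG is matched and classified independently; two reference groups
    may legitimately map to the same predicted group.  A RefOG with no
    overlapping prediction gets ``matched_og_id=None`` and all members MA.
    """
    predictions.validate()
    report = BenchmarkReport(dataset_name=predictions.dataset_name)
    for refog in refogs:
        og_id = best_coverage_match(refog, predictions)
        group = predictions.groups[og_id] if og_id is not None else frozenset()
        report.classifications.append(classify_assignments(refog, group, og_id))
    return report


def recall_percent(report: BenchmarkReport, ndigits: int | None = 0) -> float:
    """Recall over reference orthologs, as a percentage: 100·|TA|/(|TA|+|MA|).

    Rounded to the nearest integer by default; pass ``ndigits=None`` for the
    unrounded value.
    """
    ta, _, ma = report.totals
    if ta + ma == 0:
        raise ValueError("empty report: no reference orthologs to recall")
    pct = 100.0 * ta / (ta + ma)
    return pct if ndigits is None else round(pct, ndigits or None)


def per_species_error_counts(
    report: BenchmarkReport, sep: str = DEFAULT_SEP
) -> pd.DataFrame:
    """Tally false and missing assignments per species.

    Every FA/MA gene is counted exactly once under the species token parsed
    from its identifier (accumulating across reference groups).  Returns a
    DataFrame indexed by species with integer columns ``FA`` and ``MA``,
    sorted by species token.
    """
    fa: Counter[str] = Counter()
    ma: Counter[str] = Counter()
    for c in report.classifications:
        for gene in c.FA:
            fa[species_of(gene, sep)] += 1
        for gene in c.MA:
            ma[species_of(gene, sep)] += 1
    species = sorted(set(fa) | set(ma))
    table = pd.DataFrame(
        {
            "FA": [fa.get(s, 0) for s in species],
            "MA": [ma.get(s, 0) for s in species],
        },
        index=pd.Index(species, name="species"),
    )
    return table


@overload
def restrict_to_species(
    ogs: PredictedOGSet, keep: Iterable[str], sep: str = ...
) -> PredictedOGSet: ...


@overload
def restrict_to_species(
    ogs: Sequence[RefOG], keep: Iterable[str], sep: str = ...
) -> list[RefOG]: ...


def restrict_to_species(ogs, keep, sep=DEFAULT_SEP):
    """Drop all members whose species is not in ``keep``.

    Works on a list of RefOGs or on a PredictedOGSet; groups emptied by the
    restriction are dropped entirely.  The input objects are not modified.
    """
    keep = {str(s) for s in keep}
    if not keep:
        raise ValueError("keep must be a non-empty species set")

    def _filter(genes: Iterable[str]) -> frozenset[str]:
        return frozenset(g for g in genes if species_of(g, sep) in keep)

    if isinstance(ogs, PredictedOGSet):
        groups = {}
        for og_id, genes in ogs.groups.items():
            kept = _filter(genes)
            if kept:
                groups[og_id] = kept
        return PredictedOGSet(
            dataset_name=ogs.dataset_name, groups=groups, level_tag=ogs.level_tag
        )
    if isinstance(ogs, RefOG):
        kept = _filter(ogs.members)
        if not kept:
            return None
        return replace(ogs, members=kept, xenologs=_filter(ogs.xenologs))
    out = []
    for refog in ogs:
        kept = restrict_to_species(refog, keep, sep)
        if kept is not None:
            out.append(kept)
    return out


def ks_compare(
    errors_a: Sequence[float] | pd.Series,
    errors_b: Sequence[float] | pd.Series,
    exact: bool = False,
) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov–Smirnov test on per-species errors.

    Returns ``(D, p)``.  The asymptotic p-value is used by default, matching
    common practice for ~100-species samples; ``exact=True`` switches to the
    exact small-sample distribution.
    """
    a = pd.Series(errors_a).to_numpy(dtype=float)
    b = pd.Series(errors_b).to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)
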