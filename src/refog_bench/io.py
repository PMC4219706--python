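"""Readers and writers for the interchange formats.

Tabular formats are plain TSV with ``#`` comments; orthologous-group
membership tables come in two dialects (one gene per row, or eggNOG-style
member lists), OrthoXML is supported read-only, trees travel as Newick, and
reports are written as both TSV (counts) and JSON (full gene lists).  All
writers sort their output so files are diff-stable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
import pandas as pd
import yaml
from lxml import etree

from refog_bench.benchmark_core import (
    AssignmentClassification,
    BenchmarkReport,
    PredictedOGSet,
    RefOG,
)
from refog_bench.function_tests import FeatureMap, Genome, HomologyHit

__all__ = [
    "read_og_table",
    "read_refogs",
    "read_predictions",
    "read_orthoxml",
    "read_newick",
    "write_newick",
    "read_clade_map",
    "write_clade_map",
    "read_feature_map",
    "write_feature_map",
    "read_hits",
    "write_hits",
    "read_genomes",
    "write_genomes",
    "write_og_table",
    "write_report",
    "read_report_json",
    "RunConfig",
]

logger = logging.getLogger(__name__)

Dialect = Literal["auto", "pairwise", "members-list"]

_HITS_COLUMNS = [
    "query", "subject", "e_value", "aligned_length",
    "query_length", "subject_length", "bit_score",
]


def _data_rows(path: str | Path, comment: str = "#"):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


def read_og_table(
    path: str | Path, dialect: Dialect = "auto", sep: str = "\t"
) -> dict[str, frozenset[str]]:
    """Read an orthologous-group membership table.

    ``pairwise`` rows are ``og_id<TAB>gene_id``; ``members-list`` rows are
    ``og_id<TAB>gene1,gene2,...``.  ``auto`` decides per file: if any
    second column contains a comma it is a member list.  Duplicate
    (og, gene) rows collapse with a warning; structurally malformed rows
    raise with their line number.
    """
    rows: list[tuple[int, str, str]] = []
    for lineno, line in _data_rows(path):
        parts = line.split(sep)
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"{path}:{lineno}: expected 'og_id{sep!r}genes', got {line!r}")
        rows.append((lineno, parts[0].strip(), parts[1].strip()))
    if dialect == "auto":
        dialect = (
            "members-list" if any("," in genes for _, _, genes in rows) else "pairwise"
        )
    groups: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, og_id, genes_field in rows:
        genes = (
            [g.strip() for g in genes_field.split(",") if g.strip()]
            if dialect == "members-list"
            else [genes_field]
        )
        bucket = groups.setdefault(og_id, set())
        for gene in genes:
            if (og_id, gene) in seen:
                logger.warning("%s:%d: duplicate membership (%s, %s) collapsed",
                               path, lineno, og_id, gene)
            seen.add((og_id, gene))
            bucket.add(gene)
    if not groups:
        logger.warning("%s: empty orthologous-group table", path)
    return {og: frozenset(genes) for og, genes in groups.items()}


def read_refogs(path: str | Path, dialect: Dialect = "auto") -> list[RefOG]:
    """Read reference groups from a membership table (sorted by id)."""
    groups = read_og_table(path, dialect)
    return [RefOG(refog_id=og, members=genes) for og, genes in sorted(groups.items())]


def read_predictions(
    path: str | Path, dataset_name: str | None = None, dialect: Dialect = "auto"
) -> PredictedOGSet:
    """Read predicted groups from a membership table."""
    groups = read_og_table(path, dialect)
    name = dataset_name or Path(path).stem
    return PredictedOGSet(dataset_name=name, groups=dict(groups))


def _localname(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def read_orthoxml(path: str | Path, dataset_name: str | None = None) -> PredictedOGSet:
    """Read a flat OrthoXML document into a predicted-group set.

    Namespace tolerant.  ``<gene>`` elements map internal ids to protein
    ids; top-level ``<orthologGroup>`` elements become groups, nested
    groups are flattened into their top-level ancestor with a warning.
    Unresolvable ``<geneRef>`` ids raise, listing the offenders.
    """
    doc = etree.parse(str(path))
    root = doc.getroot()
    id_map: dict[str, str] = {}
    for gene in root.iter():
        if _localname(gene) == "gene":
            gid = gene.get("id")
            prot = gene.get("protId") or gene.get("geneId") or gid
            if gid is not None:
                id_map[gid] = prot
    groups: dict[str, frozenset[str]] = {}
    unresolved: list[str] = []
    counter = 0
    for el in root.iter():
        if _localname(el) != "orthologGroup":
            continue
        ancestor = el.getparent()
        nested = False
        while ancestor is not None:
            if _localname(ancestor) == "orthologGroup":
                nested = True
                break
            ancestor = ancestor.getparent()
        if nested:
            logger.warning("%s: nested orthologGroup flattened into its parent", path)
            continue
        counter += 1
        og_id = el.get("id") or f"OG{counter:05d}"
        members: set[str] = set()
        for ref in el.iter():
            if _localname(ref) == "geneRef":
                gid = ref.get("id")
                if gid in id_map:
                    members.add(id_map[gid])
                else:
                    unresolved.append(gid or "<missing id>")
        if members:
            groups[og_id] = frozenset(members)
        else:
            logger.warning("%s: empty orthologGroup %r dropped", path, og_id)
    if unresolved:
        raise ValueError(
            f"{path}: unresolved geneRef ids: {sorted(set(unresolved))[:10]}"
        )
    return PredictedOGSet(dataset_name=dataset_name or Path(path).stem, groups=groups)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal node labels are kept as support labels."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Read ``taxid<TAB>clade`` rows into a clade map."""
    clades: dict[str, str] = {}
    for lineno, line in _data_rows(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'taxid<TAB>clade'")
        clades[parts[0].strip()] = parts[1].strip()
    return clades


def write_clade_map(clades: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# taxid\tclade\n")
        for taxid in sorted(clades):
            fh.write(f"{taxid}\t{clades[taxid]}\n")


def read_feature_map(
    path: str | Path, feature_kind: Literal["domain", "ec", "neighbor_family"]
) -> FeatureMap:
    """Read ``gene_id<TAB>feature_token`` rows (one per assignment).

    A row with an empty second column records a gene annotated with
    nothing, which is distinct from a gene absent from the file.
    """
    assignments: dict[str, set[str]] = {}
    for lineno, line in _data_rows(path):
        parts = line.split("\t")
        if len(parts) < 1 or not parts[0].strip():
            raise ValueError(f"{path}:{lineno}: expected 'gene_id<TAB>token'")
        gene = parts[0].strip()
        bucket = assignments.setdefault(gene, set())
        if len(parts) > 1 and parts[1].strip():
            bucket.add(parts[1].strip())
    return FeatureMap(
        feature_kind=feature_kind,
        assignments={g: frozenset(v) for g, v in assignments.items()},
    )


def write_feature_map(fmap: FeatureMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tfeature_token\n")
        for gene in sorted(fmap.assignments):
            tokens = sorted(fmap.assignments[gene])
            if not tokens:
                fh.write(f"{gene}\t\n")
            for token in tokens:
                fh.write(f"{gene}\t{token}\n")


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read a homology-hits table.

    Accepts a named header (columns ``query subject e_value aligned_length
    query_length subject_length bit_score``) or headerless positional
    columns in that order.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    first = [str(v) for v in df.iloc[0].tolist()]
    if "query" in first:
        df.columns = first
        df = df.iloc[1:]
    else:
        if df.shape[1] < len(_HITS_COLUMNS):
            raise ValueError(
                f"{path}: expected {len(_HITS_COLUMNS)} columns {_HITS_COLUMNS}"
            )
        df.columns = _HITS_COLUMNS + [
            f"extra{i}" for i in range(df.shape[1] - len(_HITS_COLUMNS))
        ]
    hits = []
    for row in df.itertuples(index=False):
        hits.append(HomologyHit(
            query=row.query, subject=row.subject, e_value=float(row.e_value),
            aligned_length=int(row.aligned_length),
            query_length=int(row.query_length),
            subject_length=int(row.subject_length),
            bit_score=float(row.bit_score),
        ))
    return hits


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.e_value:.3e}\t{h.aligned_length}"
                f"\t{h.query_length}\t{h.subject_length}\t{h.bit_score}\n"
            )


def read_genomes(path: str | Path) -> dict[str, Genome]:
    """Read gene-order rows ``species<TAB>replicon<TAB>position<TAB>gene_id<TAB>circular``."""
    acc: dict[str, dict[str, list[tuple[int, str]]]] = {}
    circ: dict[str, dict[str, bool]] = {}
    for lineno, line in _data_rows(path):
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 'species\\treplicon\\tposition\\tgene\\tcircular'"
            )
        species, rep, pos, gene, flag = (p.strip() for p in parts)
        acc.setdefault(species, {}).setdefault(rep, []).append((int(pos), gene))
        circ.setdefault(species, {})[rep] = flag.lower() in {"1", "true", "yes"}
    genomes = {}
    for species, reps in acc.items():
        replicons = {
            rep: [g for _, g in sorted(entries)] for rep, entries in reps.items()
        }
        genomes[species] = Genome(
            species=species, replicons=replicons, circular=circ[species]
        )
    return genomes


def write_genomes(genomes: dict[str, Genome], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# species\treplicon\tposition\tgene_id\tcircular\n")
        for species in sorted(genomes):
            genome = genomes[species]
            for rep in sorted(genome.replicons):
                flag = "1" if genome.circular.get(rep, False) else "0"
                for pos, gene in enumerate(genome.replicons[rep]):
                    fh.write(f"{species}\t{rep}\t{pos}\t{gene}\t{flag}\n")


def write_og_table(
    groups: dict[str, frozenset[str]] | PredictedOGSet | Sequence[RefOG],
    path: str | Path,
) -> None:
    """Write groups as a pairwise membership table (sorted, diff-stable)."""
    if isinstance(groups, PredictedOGSet):
        table = groups.groups
    elif isinstance(groups, dict):
        table = groups
    else:
        table = {r.refog_id: r.members for r in groups}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# og_id\tgene_id\n")
        for og_id in sorted(table):
            for gene in sorted(table[og_id]):
                fh.write(f"{og_id}\t{gene}\n")


def write_report(
    report: BenchmarkReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("tsv", "json"),
    stem: str = "benchmark",
) -> list[Path]:
    """Write a benchmark report as TSV (counts + totals row) and/or JSON.

    The TSV has one row per reference group (sorted by id) with the matched
    group id and TA/FA/MA counts, plus a ``TOTAL`` row; the JSON carries
    the full gene lists and both reference-ortholog count bases.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows = sorted(report.classifications, key=lambda c: c.refog_id)
    if "tsv" in formats:
        p = out_dir / f"{stem}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("refog_id\tmatched_og_id\tn_TA\tn_FA\tn_MA\n")
            for c in rows:
                fh.write(
                    f"{c.refog_id}\t{c.matched_og_id or '-'}"
                    f"\t{c.n_ta}\t{c.n_fa}\t{c.n_ma}\n"
                )
            ta, fa, ma = report.totals
            fh.write(f"TOTAL\t-\t{ta}\t{fa}\t{ma}\n")
        written.append(p)
    if "json" in formats:
        p = out_dir / f"{stem}.json"
        ta, fa, ma = report.totals
        payload = {
            "dataset_name": report.dataset_name,
            "totals": {"TA": ta, "FA": fa, "MA": ma},
            "n_reference_genes": report.n_reference_genes,
            "classifications": [
                {
                    "refog_id": c.refog_id,
                    "matched_og_id": c.matched_og_id,
                    "TA": sorted(c.TA),
                    "FA": sorted(c.FA),
                    "MA": sorted(c.MA),
                }
                for c in rows
            ],
        }
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    return written


def read_report_json(path: str | Path) -> BenchmarkReport:
    """Re-read a JSON report into a BenchmarkReport object."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    report = BenchmarkReport(dataset_name=payload["dataset_name"])
    for c in payload["classifications"]:
        report.classifications.append(AssignmentClassification(
            refog_id=c["refog_id"], matched_og_id=c["matched_og_id"],
            TA=frozenset(c["TA"]), FA=frozenset(c["FA"]), MA=frozenset(c["MA"]),
        ))
    return report


_CONFIG_DEFAULTS = {
    "conservation_threshold": 0.75,
    "domain_comparator": "strict",
    "ec_comparator": "strict",
    "neighbor_comparator": "inclusive",
    "e_max": 1e-5,
    "min_len_frac": 0.90,
    "flank": 5,
    "min_flank": 3,
    "min_og_size": 2,
    "gene_id_separator": ".",
    "seed": 0,
}


class RunConfig:
    """Validated run configuration with the standard analysis constants.

    Defaults: 75% conservation threshold (strict comparator for domains and
    EC terms, inclusive for neighbour families), homology links at E <= 1e-5
    covering >= 90% of the shorter gene, +-5-gene neighbourhoods.  Unknown
    keys are rejected rather than ignored.
    """

    def __init__(self, **kwargs) -> None:
        unknown = set(kwargs) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key, default in _CONFIG_DEFAULTS.items():
            setattr(self, key, kwargs.get(key, default))
        if not 0.0 < self.conservation_threshold <= 1.0:
            raise ValueError("conservation_threshold must be in (0, 1]")
        if not 0.0 < self.min_len_frac <= 1.0:
            raise ValueError("min_len_frac must be in (0, 1]")
        if self.e_max < 0:
            raise ValueError("e_max must be non-negative")
        if self.flank < 1 or self.min_flank < 1 or self.min_og_size < 1:
            raise ValueError("flank, min_flank and min_og_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _CONFIG_DEFAULTS}
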