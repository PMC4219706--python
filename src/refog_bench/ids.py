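"""Gene identifier helpers.

Genes are identified throughout the package by strings of the form
``"<taxid><sep><accession>"`` (eggNOG convention, separator ``"."``), e.g.
``"83333.b0002"``.  The species token is everything before the *first*
separator; accessions may themselves contain the separator character.
"""

from __future__ import annotations

DEFAULT_SEP = "."


def make_gene_id(species: str | int, accession: str, sep: str = DEFAULT_SEP) -> str:
    """Render a gene identifier from its species token and accession."""
    return f"{species}{sep}{accession}"


def split_gene_id(gene_id: str, sep: str = DEFAULT_SEP) -> tuple[str, str]:
    """Split a gene identifier into (species token, accession).

    Raises
    ------
    ValueError
        If the identifier contains no separator, naming the offending token.
    """
    species, _, accession = gene_id.partition(sep)
    if not _:
        raise ValueError(
            f"gene identifier {gene_id!r} has no species token "
            f"(expected '<taxid>{sep}<accession>')"
        )
    return species, accession


def species_of(gene_id: str, sep: str = DEFAULT_SEP) -> str:
    """Return the species token of a gene identifier."""
    return split_gene_id(gene_id, sep)[0]
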