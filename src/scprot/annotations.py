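"""Protein annotations and contaminant-class rules.

Two contaminant/reference classes matter downstream:

* **Keratins** — abundant skin/dust contaminants in nanolitre sample
  preparation; removed before quantitation.  A gene is a keratin iff it
  matches ``KRT<number>`` (case-insensitive).  Keratin-*associated* proteins
  (``KRTAP*``) are deliberately excluded: they are distinct gene products and
  not typical contaminants.
* **Histones** — used as a per-cell normalization reference (their abundance
  tracks chromatin content rather than cytoplasmic volume).  A gene is a
  histone iff it is in the configured histone list; the default list ships
  with the package and covers the current HGNC cluster symbols plus the
  legacy ``HIST*`` aliases via a pattern fallback.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

KERATIN_RE = re.compile(r"^KRT[0-9]+", re.IGNORECASE)

# Fallback pattern covering histone symbol families when no explicit list is
# configured: H1-*, H2A*, H2B*, H3*, H4* cluster symbols and legacy HIST*.
HISTONE_RE = re.compile(r"^(H1-|H2A|H2B|H3|H4|HIST)", re.IGNORECASE)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinAnnotation:
    """Per-accession annotation parsed from the protein database."""

    accession: str
    gene_symbol: str
    organism: str
    sequence: str
    is_keratin: bool = False
    is_histone: bool = False


def default_histone_genes() -> frozenset[str]:
    """Histone gene symbols shipped with the package."""
    text = resources.files("scprot").joinpath("data/histone_genes.txt").read_text()
    genes = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.upper())
    return frozenset(genes)


def is_keratin_gene(gene_symbol: str) -> bool:
    return bool(KERATIN_RE.match(gene_symbol or ""))


def is_histone_gene(gene_symbol: str, histone_list: frozenset[str] | None = None) -> bool:
    """True when the symbol is in ``histone_list``; with no list configured,
    membership in the shipped default list or a match of the histone symbol
    pattern counts."""
    g = (gene_symbol or "").upper()
    if histone_list is not None:
        return g in {s.upper() for s in histone_list}
    return g in default_histone_genes() or bool(HISTONE_RE.match(g))


def flag_contaminant_classes(
    annotations: dict[str, ProteinAnnotation],
    histone_list: frozenset[str] | None = None,
) -> dict[str, ProteinAnnotation]:
    """Set ``is_keratin`` / ``is_histone`` on every annotation (in place)."""
    for ann in annotations.values():
        ann.is_keratin = is_keratin_gene(ann.gene_symbol)
        ann.is_histone = is_histone_gene(ann.gene_symbol, histone_list)
    return annotations
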