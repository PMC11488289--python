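"""Canonical vocabulary for the 37-gene metazoan mitochondrial gene set.

The canonical labels are the 13 protein-coding genes (``cox1``-``cox3``,
``cob``, ``nad1``-``nad6``, ``nad4L``, ``atp6``, ``atp8``), the two rRNAs
(``rrnS``, ``rrnL``) and the 22 tRNAs by amino-acid single-letter code, with
the two leucine and two serine isoacceptors distinguished as ``L1`` (CUN),
``L2`` (UUR), ``S1`` (AGN) and ``S2`` (UCN).

Annotators spell gene names in many dialects ("COI", "ND4L", "trnL-uur",
"tRNA-Ser(AGN)", "16S ribosomal RNA", ...).  The alias map shipped in
``data/gene_aliases.tsv`` translates those spellings to the canonical labels;
:func:`canonical_label` applies it after aggressive normalisation.  Unmapped
names are never silently dropped — callers receive ``None`` and must flag the
feature as "unmapped".
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

PCGS: tuple[str, ...] = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)
RRNAS: tuple[str, ...] = ("rrnS", "rrnL")
TRNAS: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)

#: All 37 canonical labels; index+1 is the stable internal integer id.
CANONICAL: tuple[str, ...] = PCGS + RRNAS + TRNAS

GENE_ID: dict[str, int] = {g: i + 1 for i, g in enumerate(CANONICAL)}
ID_GENE: dict[int, str] = {i: g for g, i in GENE_ID.items()}

_FTYPE: dict[str, str] = {}
_FTYPE.update({g: "PCG" for g in PCGS})
_FTYPE.update({g: "rRNA" for g in RRNAS})
_FTYPE.update({g: "tRNA" for g in TRNAS})


def feature_type(label: str) -> str:
    """Return ``PCG``/``rRNA``/``tRNA`` for a canonical label."""
    return _FTYPE[label]


def is_trna(label: str) -> bool:
    return _FTYPE.get(label) == "tRNA"


def _normalise(name: str) -> str:
    """Lower-case and strip every non-alphanumeric character."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


@lru_cache(maxsize=1)
def _alias_map() -> dict[str, str]:
    aliases: dict[str, str] = {}
    # every canonical label maps to itself
    for g in CANONICAL:
        aliases[_normalise(g)] = g
    text = resources.files("mitorder.data").joinpath("gene_aliases.tsv").read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"gene_aliases.tsv line {lineno}: expected 2 columns")
        alias, canonical = parts
        if canonical not in GENE_ID:
            raise ValueError(
                f"gene_aliases.tsv line {lineno}: unknown canonical label {canonical!r}"
            )
        aliases[_normalise(alias)] = canonical
    return aliases


def canonical_label(name: str) -> str | None:
    """Map an annotator gene name to its canonical label, or ``None``.

    >>> canonical_label("COI")
    'cox1'
    >>> canonical_label("tRNA-Leu(UUR)")
    'L2'
    """
    if not name:
        return None
    return _alias_map().get(_normalise(name))
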