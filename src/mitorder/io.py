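"""Readers and writers for every external format the pipeline touches.

GenBank flatfiles are read through Biopython; newick trees through dendropy.
Feature tables come in three dialects:

``gff3``
    9-column GFF3; 1-based inclusive coordinates are converted to the
    internal 0-based half-open convention.
``bed``
    6-column BED; already 0-based half-open.
``mitos_tsv``
    a simple annotator TSV: ``name  start  end  strand  [structure]`` with
    1-based inclusive coordinates and an optional dot-bracket string, the
    shape of MITOS/ARWEN-style exports.

Reports are deterministic TSVs: fixed column order, rows sorted by genome id
then coordinate, floats printed with fixed precision (4 decimals for skews,
1 for percentages; round-half-even).
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

from .model import AnnotatedGenome, Feature, make_feature

# ---------------------------------------------------------------------------
# GenBank

_GB_TYPE_HINT = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "NCR"}
_SKIP_GB_TYPES = {"source", "gene", "misc_feature"}


def _feature_name(qualifiers: Mapping) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in qualifiers:
            return str(qualifiers[key][0])
    return ""


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read one GenBank flatfile into an :class:`AnnotatedGenome`.

    Coordinates are converted from GenBank 1-based inclusive to 0-based
    half-open; ``join()`` locations that wrap the origin become a single
    feature with ``end > genome_length``.  A record without an ORIGIN
    sequence is a hard error; an unmappable gene name is kept with an
    ``unmapped`` flag and a warning.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        sequence = str(record.seq)
    except UndefinedSequenceError as exc:
        raise ValueError(f"{path}: GenBank record has no sequence") from exc
    if not sequence:
        raise ValueError(f"{path}: GenBank record has no sequence")
    n = len(sequence)
    circular = record.annotations.get("topology", "circular") == "circular"

    features: list[Feature] = []
    for feat in record.features:
        if feat.type in _SKIP_GB_TYPES:
            continue
        hint = _GB_TYPE_HINT.get(feat.type, "other")
        strand = "-" if feat.location.strand == -1 else "+"
        parts = feat.location.parts
        if len(parts) > 1 and int(parts[0].end) == n and int(parts[-1].start) == 0:
            # origin-spanning join: represent with end beyond genome length
            start = int(parts[0].start)
            end = n + int(parts[-1].end)
        else:
            start = int(feat.location.start)
            end = int(feat.location.end)
        name = _feature_name(feat.qualifiers)
        f = make_feature(name, hint, strand, start, end, source="genbank")
        if "unmapped" in f.flags:
            warnings.warn(f"{record.id}: unmappable gene name {name!r}", stacklevel=2)
        features.append(f)

    return AnnotatedGenome(
        id=record.id or record.name, sequence=sequence,
        circular=circular, features=features,
    )


# ---------------------------------------------------------------------------
# Feature tables

_GFF_TYPE_HINT = {
    "CDS": "PCG", "gene": "other", "tRNA": "tRNA", "rRNA": "rRNA",
    "region": "other", "sequence_feature": "other",
}


def _check_strand(symbol: str, lineno: int) -> str:
    if symbol not in {"+", "-", "."}:
        raise ValueError(f"line {lineno}: bad strand symbol {symbol!r}")
    return "+" if symbol == "." else symbol


def _attr_name(attrs: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in ("Name", "gene", "product", "ID"):
        if key in fields:
            return fields[key]
    return ""


def read_feature_table(
    path: str | Path, dialect: str, source: str | None = None
) -> list[Feature]:
    """Read annotator feature calls from a table file.

    ``source`` tags every returned feature (defaults to the dialect name) so
    that call sets from different annotators stay distinguishable downstream.
    Malformed lines raise :class:`ValueError` naming the line number.
    """
    if dialect not in {"gff3", "bed", "mitos_tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    tag = source or dialect
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) != 9:
                        raise ValueError("expected 9 columns")
                    ftype, start, end = cols[2], int(cols[3]) - 1, int(cols[4])
                    strand = _check_strand(cols[6], lineno)
                    name = _attr_name(cols[8])
                    hint = _GFF_TYPE_HINT.get(ftype, "other")
                elif dialect == "bed":
                    if len(cols) < 6:
                        raise ValueError("expected >= 6 columns")
                    start, end, name = int(cols[1]), int(cols[2]), cols[3]
                    strand = _check_strand(cols[5], lineno)
                    hint = None
                else:  # mitos_tsv
                    if len(cols) < 4:
                        raise ValueError("expected >= 4 columns")
                    name, start, end = cols[0], int(cols[1]) - 1, int(cols[2])
                    strand = _check_strand(cols[3], lineno)
                    hint = None
                structure = (
                    cols[4] if dialect == "mitos_tsv" and len(cols) > 4 and cols[4]
                    else None
                )
                feature = make_feature(name, hint, strand, start, end,
                                       source=tag, structure=structure)
            except ValueError as exc:
                if str(exc).startswith("line "):
                    raise
                raise ValueError(f"line {lineno}: {exc}") from exc
            features.append(feature)
    return features


def write_feature_table(
    path: str | Path, features: Sequence[Feature], dialect: str,
    genome_id: str = ".",
) -> None:
    """Write features as GFF3 or BED (inverse of :func:`read_feature_table`)."""
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"cannot write dialect {dialect!r}")
    lines = []
    if dialect == "gff3":
        lines.append("##gff-version 3")
        type_map = {"PCG": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
                    "NCR": "sequence_feature", "other": "sequence_feature"}
    for f in sorted(features, key=lambda f: (f.start, f.end, f.label)):
        if dialect == "gff3":
            attrs = f"Name={f.label}"
            if f.flags:
                attrs += ";note=" + ",".join(f.flags)
            lines.append("\t".join([
                genome_id, f.source or ".", type_map[f.ftype],
                str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
            ]))
        else:
            lines.append("\t".join([
                genome_id, str(f.start), str(f.end), f.label, "0", f.strand,
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick

def read_newick(
    path: str | Path, genome_ids: Iterable[str] | None = None
) -> dendropy.Tree:
    """Read a rooted newick tree; tips must match the supplied genome ids.

    Polytomies are preserved.  If ``genome_ids`` is given, any tip name
    absent from the set raises an error listing the missing names.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip names in tree")
    if genome_ids is not None:
        missing = sorted(set(tips) - set(genome_ids))
        if missing:
            raise ValueError(
                "tree tips missing from genome set: " + ", ".join(missing)
            )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )


# ---------------------------------------------------------------------------
# Reports

#: column-name substring -> decimals
_DEFAULT_PRECISION = (("skew", 4), ("percent", 1), ("pct", 1), ("rscu", 2))


def _fmt(value, column: str, precision: Mapping[str, int] | None) -> str:
    if isinstance(value, bool) or value is None:
        return str(value)
    if isinstance(value, float):
        decimals = None
        if precision and column in precision:
            decimals = precision[column]
        else:
            low = column.lower()
            for key, d in _DEFAULT_PRECISION:
                if key in low:
                    decimals = d
                    break
        if decimals is None:
            decimals = 4
        q = Decimal(1).scaleb(-decimals)
        return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))
    return str(value)


def write_report(
    path: str | Path,
    records: Sequence[Mapping[str, object]],
    columns: Sequence[str] | None = None,
    precision: Mapping[str, int] | None = None,
) -> None:
    """Write statistic records as a byte-deterministic TSV.

    Rows are sorted by genome id then coordinate (``genome``/``id`` and
    ``start`` columns, when present); identical inputs always produce
    byte-identical files.  An empty record list yields a header-only file
    (header requires ``columns``).
    """
    if columns is None:
        if not records:
            raise ValueError("need explicit columns for an empty report")
        columns = list(records[0].keys())

    def sort_key(rec: Mapping[str, object]):
        key = []
        for col in ("genome", "id", "start"):
            if col in rec:
                key.append(rec[col])
        key.append(tuple(str(rec.get(c, "")) for c in columns))
        return tuple(key)

    lines = ["\t".join(columns)]
    for rec in sorted(records, key=sort_key):
        lines.append("\t".join(_fmt(rec.get(c, ""), c, precision) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")
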