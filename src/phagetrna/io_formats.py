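"""Readers and writers for every external file the pipeline touches.

Formats handled here:

* FASTA (via Biopython), normalized to an uppercase DNA alphabet with U→T;
* tRNAscan-SE v2.0 tab-delimited output (the ``-o`` table, optionally with
  its three-line header block);
* the anticodon-nuclease catalog TSV (columns: nuclease_name,
  source_organism, isotype, anticodon, cleavage_bond, motif,
  modification_dependent, citation_note);
* flat TSV reports (one header line, tab-separated, Unix newlines).

Coordinates in tRNAscan-SE tables are 1-based inclusive and ``begin > end``
denotes the minus strand; that convention is preserved here and converted
to explicit strand arithmetic in :mod:`phagetrna.trna_structure`.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Any, Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .nuclease_catalog import NucleaseEntry

# IUPAC one-letter DNA codes accepted on input; ambiguity codes collapse to N
# because every downstream comparison is exact-match on A/C/G/T.
_AMBIGUITY = set("RYSWKMBDHV")
_ALPHABET = set("ACGTN")

AMINO_ACIDS_3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}
#: isotype codes accepted in the nuclease catalog
CATALOG_ISOTYPES = AMINO_ACIDS_3 | {"fMet", "Sup"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (genome, CDS, or tRNA gene)."""

    identifier: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.identifier!r} has an empty sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise FormatError(
                f"record {self.identifier!r} contains non-DNA characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRow:
    """One data row of a tRNAscan-SE table.

    ``begin``/``end`` are 1-based inclusive; ``begin > end`` marks the
    minus strand (tRNAscan-SE convention).
    """

    source_sequence: str
    gene_index: int
    begin: int
    end: int
    isotype: str
    anticodon: str
    score: float | None = None
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.begin == self.end:
            raise ValidationError(
                f"{self.source_sequence}.{self.gene_index}: begin == end"
            )
        if len(self.anticodon) != 3:
            raise ValidationError(
                f"{self.source_sequence}.{self.gene_index}: anticodon "
                f"{self.anticodon!r} is not a 3-mer"
            )

    @property
    def is_reverse(self) -> bool:
        return self.begin > self.end


def normalize_residues(raw: str) -> str:
    """Uppercase, map U→T, collapse IUPAC ambiguity codes to N."""
    out = raw.upper().replace("U", "T")
    if set(out) <= _ALPHABET:
        return out
    return "".join("N" if c in _AMBIGUITY else c for c in out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Raises :class:`FormatError` on an empty file or a record without
    residues; order of records is preserved.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has no residues")
        records.append(
            SequenceRecord(
                identifier=rec.id,
                description=rec.description,
                residues=residues,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> Path:
    """Write records as FASTA with fixed line width; returns the path."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.identifier
            if rec.description and rec.description != rec.identifier:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    return path


def _looks_like_header(fields: Sequence[str]) -> bool:
    first = fields[0].strip()
    return (
        first.startswith("-")
        or first in {"Sequence", "Name"}
        or first.endswith("Name")
        or (len(fields) > 1 and fields[1].strip() in {"tRNA #", "tRNA#"})
    )


def parse_trnascan_table(path: str | Path) -> list[AnnotationRow]:
    """Parse tRNAscan-SE tab-delimited output into :class:`AnnotationRow`.

    The optional three-line header block is skipped. Pseudogene-flagged
    rows (a ``pseudo`` note in the trailing column) are retained with
    ``pseudo=True``. Rows with non-numeric coordinates raise a
    :class:`FormatError` naming the line number.
    """
    path = Path(path)
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if _looks_like_header(fields):
                continue
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected ≥6 columns, "
                                  f"got {len(fields)}")
            try:
                gene_index = int(fields[1])
                begin = int(fields[2])
                end = int(fields[3])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{fields[1:4]!r}"
                ) from None
            score: float | None = None
            if len(fields) > 8 and fields[8].strip():
                try:
                    score = float(fields[8])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric score {fields[8]!r}"
                    ) from None
            note = fields[9] if len(fields) > 9 else ""
            rows.append(
                AnnotationRow(
                    source_sequence=fields[0].strip(),
                    gene_index=gene_index,
                    begin=begin,
                    end=end,
                    isotype=fields[4].strip(),
                    anticodon=normalize_residues(fields[5].strip()),
                    score=score,
                    pseudo="pseudo" in note.lower(),
                )
            )
    return rows


_TRNASCAN_HEADER = (
    "Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tInf\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
    "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\n"
)


def write_trnascan_table(rows: Iterable[AnnotationRow],
                         path: str | Path) -> Path:
    """Write annotation rows in the tRNAscan-SE tab-delimited dialect,
    including the three-line header block."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(_TRNASCAN_HEADER)
        for r in rows:
            score = "" if r.score is None else f"{r.score:.1f}"
            note = "pseudo" if r.pseudo else ""
            fh.write(
                f"{r.source_sequence}\t{r.gene_index}\t{r.begin}\t{r.end}\t"
                f"{r.isotype}\t{r.anticodon}\t0\t0\t{score}\t{note}\n"
            )
    return path


_CATALOG_COLUMNS = [
    "nuclease_name", "source_organism", "isotype", "anticodon",
    "cleavage_bond", "motif", "modification_dependent", "citation_note",
]


def load_catalog(path: str | Path) -> "list[NucleaseEntry]":
    """Load an anticodon-nuclease catalog TSV.

    Rows sharing a ``nuclease_name`` are grouped into one
    :class:`~phagetrna.nuclease_catalog.NucleaseEntry` whose target list
    preserves file order. ``cleavage_bond`` must be an integer 0–5 or the
    sentinel ``anticodon``; the isotype must be a recognised code.
    """
    from .nuclease_catalog import NucleaseEntry, TargetSpec
    from .trna_structure import IsoacceptorKey

    path = Path(path)
    entries: dict[str, dict[str, Any]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty catalog file")
        missing = set(_CATALOG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            isotype = row["isotype"].strip()
            if isotype not in CATALOG_ISOTYPES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown isotype code {isotype!r}"
                )
            raw_bond = row["cleavage_bond"].strip()
            bond: int | str
            if raw_bond == "anticodon":
                bond = "anticodon"
            else:
                try:
                    bond = int(raw_bond)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: cleavage_bond {raw_bond!r} is "
                        "neither an integer nor 'anticodon'"
                    ) from None
                if not 0 <= bond <= 5:
                    raise ValidationError(
                        f"{path}:{lineno}: cleavage_bond {bond} outside 0..5"
                    )
            anticodon = row["anticodon"].strip().lower()
            if anticodon != "*":
                anticodon = normalize_residues(anticodon).lower()
            motif_raw = row["motif"].strip()
            motif = None if motif_raw in {"", "-"} else normalize_residues(motif_raw)
            spec = TargetSpec(
                key=IsoacceptorKey(isotype=isotype, anticodon=anticodon),
                cleavage_bond=bond,
                motif=motif,
                citation_note=row["citation_note"].strip(),
            )
            name = row["nuclease_name"].strip()
            entry = entries.setdefault(
                name,
                {
                    "source_organism": row["source_organism"].strip(),
                    "modification_dependent":
                        row["modification_dependent"].strip() == "1",
                    "targets": [],
                },
            )
            entry["targets"].append(spec)
    return [
        NucleaseEntry(
            name=name,
            source_organism=info["source_organism"],
            modification_dependent=info["modification_dependent"],
            targets=tuple(info["targets"]),
        )
        for name, info in entries.items()
    ]


def _row_to_mapping(row: Any) -> Mapping[str, Any]:
    if dataclasses.is_dataclass(row) and not isinstance(row, type):
        return dataclasses.asdict(row)
    if isinstance(row, Mapping):
        return row
    raise TypeError(f"cannot serialize row of type {type(row).__name__}")


def write_report_tsv(rows: Sequence[Any], path: str | Path,
                     columns: Sequence[str] | None = None) -> Path:
    """Write uniform records (dataclasses or mappings) as a TSV report.

    All rows must share one field set; an empty row list needs explicit
    ``columns`` and yields a header-only file. List/tuple cell values are
    serialized as comma-joined strings.
    """
    path = Path(path)
    mapped = [_row_to_mapping(r) for r in rows]
    if columns is None:
        if not mapped:
            raise ValueError("empty row list requires explicit columns")
        columns = list(mapped[0].keys())
    for m in mapped:
        if list(m.keys()) != list(columns):
            raise ValueError("rows do not share a uniform field set")

    def cell(v: Any) -> str:
        if isinstance(v, Enum):
            return str(v.value)
        if isinstance(v, (list, tuple)):
            return ",".join(cell(x) for x in v)
        if v is None:
            return ""
        if isinstance(v, bool):
            return str(int(v))
        return str(v)

    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for m in mapped:
            fh.write("\t".join(cell(m[c]) for c in columns) + "\n")
    return path


def read_report_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read back a report written by :func:`write_report_tsv` (all cells
    as strings); used for round-trip checks and by downstream scripts."""
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(r) for r in reader]
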