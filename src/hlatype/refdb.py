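"""HLA allele reference database.

Parses IMGT/HLA-style allele FASTA files together with per-allele exon
annotations, assembles the *sub-transcript* reference sequences used for
read mapping, and exposes two-digit group naming.

The sub-transcript covers the peptide-binding exons plus short flanks so
that reads spanning exon boundaries still map:

* class I  (loci A, B, C):        exon 1 + exon 2 + exon 3 + first 75 nt of exon 4
* class II (loci DQA1, DQB1, DRB1): last 75 nt of exon 1 + exon 2 + first 75 nt of exon 3

Typing is performed at two-digit resolution, i.e. at the level of allele
*groups* such as ``A*01`` — the first field of the colon-separated allele
name.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DQA1", "DQB1", "DRB1")

#: accepted locus spellings -> canonical gene name
_LOCUS_ALIASES = {
    "A": "A", "B": "B", "C": "C",
    "DQA": "DQA1", "DQA1": "DQA1",
    "DQB": "DQB1", "DQB1": "DQB1",
    "DRB": "DRB1", "DRB1": "DRB1",
}

FLANK_NT = 75  # retained portion of the flanking exons

_VALID_BASES = frozenset("ACGTN")


class AlleleNameError(ValueError):
    """Raised when an allele name cannot be parsed."""


class FastaFormatError(ValueError):
    """Raised when an allele FASTA file is structurally malformed."""


@dataclass(frozen=True)
class AlleleName:
    """A parsed allele name at two-digit (group) resolution.

    ``group`` is ``locus + "*" + first two-digit field``, e.g. ``A*01`` for
    ``A*01:01:01``.  Legacy four-digit names (``A*0101``) are split 2+2;
    expression-status suffix letters (N, L, Q ...) are kept in ``raw_name``
    but ignored for grouping.
    """

    raw_name: str
    locus: str
    group: str
    hla_class: str  # "I" or "II"


def hla_class_of_locus(locus: str) -> str:
    if locus in CLASS_I_LOCI:
        return "I"
    if locus in CLASS_II_LOCI:
        return "II"
    raise AlleleNameError(f"unrecognized HLA locus: {locus!r}")


def parse_allele_name(raw: str) -> AlleleName:
    """Parse ``"A*01:01:01"`` / legacy ``"DRB1*1501"`` into an :class:`AlleleName`."""
    if "*" not in raw:
        raise AlleleNameError(f"allele name lacks '*': {raw!r}")
    locus_part, _, fields = raw.partition("*")
    locus = _LOCUS_ALIASES.get(locus_part.upper())
    if locus is None:
        raise AlleleNameError(f"unrecognized locus in allele name: {raw!r}")
    first = fields.split(":")[0]
    m = re.match(r"(\d+)", first)
    if not m:
        raise AlleleNameError(f"allele name lacks a numeric first field: {raw!r}")
    digits = m.group(1)
    if ":" not in fields and len(digits) >= 4:
        # legacy concatenated form: first two digits are the group field
        digits = digits[:2]
    group = f"{locus}*{int(digits):02d}"
    return AlleleName(raw_name=raw, locus=locus, group=group,
                      hla_class=hla_class_of_locus(locus))


@dataclass
class AlleleRecord:
    """One allele: its exon sequences and the assembled sub-transcript."""

    name: AlleleName
    exons: list[tuple[int, str]]  # ordered (exon_index, sequence)
    subtranscript: str = ""
    length_nt: int = 0
    short_flank: bool = False

    def exon(self, index: int) -> str | None:
        for i, seq in self.exons:
            if i == index:
                return seq
        return None

    def peptide_binding_region(self) -> str:
        """Exons 2+3 (class I) or exon 2 (class II); falls back to the
        sub-transcript when exon annotations are absent (pre-built references)."""
        if not self.exons:
            return self.subtranscript
        if self.name.hla_class == "I":
            return (self.exon(2) or "") + (self.exon(3) or "")
        return self.exon(2) or ""


def build_subtranscript(record: AlleleRecord, hla_class: str | None = None) -> str:
    """Assemble the mapping reference sequence for one allele.

    Class I concatenates exon 1, exons 2-3 and the first 75 nt of exon 4;
    class II concatenates the last 75 nt of exon 1, exon 2 and the first
    75 nt of exon 3.  A flanking exon shorter than 75 nt (or absent) is used
    in full and flags the record as ``short_flank``.  The record's
    ``subtranscript``/``length_nt``/``short_flank`` fields are updated and
    the sequence returned.
    """
    cls = hla_class or record.name.hla_class
    short = False
    if cls == "I":
        e1, e2, e3 = record.exon(1), record.exon(2), record.exon(3)
        if e1 is None or e2 is None or e3 is None:
            raise ValueError(
                f"{record.name.raw_name}: class I sub-transcript needs exons 1-3")
        e4 = record.exon(4) or ""
        if len(e4) < FLANK_NT:
            short = True
        seq = e1 + e2 + e3 + e4[:FLANK_NT]
    elif cls == "II":
        e2 = record.exon(2)
        if e2 is None:
            raise ValueError(
                f"{record.name.raw_name}: class II sub-transcript needs exon 2")
        e1 = record.exon(1) or ""
        e3 = record.exon(3) or ""
        if len(e1) < FLANK_NT or len(e3) < FLANK_NT:
            short = True
        seq = e1[-FLANK_NT:] if e1 else ""
        seq = seq + e2 + e3[:FLANK_NT]
    else:
        raise ValueError(f"unknown HLA class {cls!r}")
    record.subtranscript = seq
    record.length_nt = len(seq)
    record.short_flank = short
    return seq


# ---------------------------------------------------------------------------
# FASTA + exon-table parsing


def read_exon_table(path: str | Path) -> dict[str, list[tuple[int, int, int]]]:
    """Read a TSV with columns ``name, exon_index, start, end`` (1-based
    inclusive coordinates on the allele's FASTA sequence)."""
    table: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "name":  # header
                continue
            if len(parts) != 4:
                raise FastaFormatError(f"{path}:{lineno}: expected 4 columns")
            name, idx, start, end = parts
            table.setdefault(name, []).append((int(idx), int(start), int(end)))
    return table


def parse_allele_fasta(
    fasta_text: str,
    exon_table: dict[str, list[tuple[int, int, int]]],
) -> tuple[list[AlleleRecord], list[tuple[str, str]]]:
    """Parse an allele FASTA into :class:`AlleleRecord` objects.

    Returns ``(records, rejected)``; ``rejected`` lists ``(header, reason)``
    for entries whose name cannot be parsed, whose exon coordinates are
    invalid, or which lack a required peptide-binding exon.  Rejection is
    always per-record, never a global failure; a structurally broken FASTA
    raises :class:`FastaFormatError`.
    """
    stripped = fasta_text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError("not a FASTA file: no '>' header found")
    records: list[AlleleRecord] = []
    rejected: list[tuple[str, str]] = []
    for entry in SeqIO.parse(io.StringIO(fasta_text), "fasta"):
        header = entry.id
        seq = str(entry.seq).upper()
        try:
            name = parse_allele_name(header)
        except AlleleNameError as exc:
            rejected.append((header, str(exc)))
            continue
        coords = exon_table.get(header) or exon_table.get(name.raw_name)
        if not coords:
            rejected.append((header, "no exon annotation"))
            continue
        coords = sorted(coords)
        exons: list[tuple[int, str]] = []
        bad = None
        prev_end = 0
        for idx, start, end in coords:
            if not (1 <= start <= end <= len(seq)):
                bad = f"exon {idx} coordinates {start}-{end} out of bounds (len {len(seq)})"
                break
            if start <= prev_end:
                bad = f"exon {idx} overlaps or is out of order"
                break
            prev_end = end
            exons.append((idx, seq[start - 1:end]))
        if bad:
            rejected.append((header, bad))
            continue
        rec = AlleleRecord(name=name, exons=exons)
        required = (1, 2, 3) if name.hla_class == "I" else (2,)
        missing = [i for i in required if rec.exon(i) is None]
        if missing:
            rejected.append((header, f"missing required exon(s) {missing}"))
            continue
        build_subtranscript(rec)
        records.append(rec)
    return records, rejected


# ---------------------------------------------------------------------------
# The reference database


@dataclass
class ReferenceDB:
    """A set of allele sub-transcripts indexed by locus.

    Every record is reachable from exactly one ``by_locus`` bucket and all
    record names are unique.
    """

    records: list[AlleleRecord]
    by_locus: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_locus:
            self.by_locus = {}
            for i, rec in enumerate(self.records):
                self.by_locus.setdefault(rec.name.locus, []).append(i)
        names = [r.name.raw_name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate allele names in reference: {dupes}")

    @classmethod
    def from_records(cls, records: Sequence[AlleleRecord]) -> "ReferenceDB":
        return cls(records=list(records))

    @property
    def loci(self) -> list[str]:
        return list(self.by_locus)

    def __len__(self) -> int:
        return len(self.records)

    def locus_records(self, locus: str) -> list[AlleleRecord]:
        return [self.records[i] for i in self.by_locus.get(locus, [])]

    def allele_names(self, locus: str | None = None) -> list[str]:
        idx = range(len(self.records)) if locus is None else self.by_locus.get(locus, [])
        return [self.records[i].name.raw_name for i in idx]

    def groups(self, locus: str) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.locus_records(locus):
            seen.setdefault(rec.name.group, None)
        return list(seen)

    def group_of(self, allele_index: int) -> str:
        return self.records[allele_index].name.group

    @classmethod
    def from_subtranscript_fasta(cls, path: str | Path) -> "ReferenceDB":
        """Load a pre-built sub-transcript FASTA (headers are allele names).

        Records carry no exon annotations; the sequence is taken as the
        sub-transcript verbatim.
        """
        records = []
        for entry in SeqIO.parse(str(path), "fasta"):
            name = parse_allele_name(entry.id)
            seq = str(entry.seq).upper()
            records.append(AlleleRecord(name=name, exons=[], subtranscript=seq,
                                        length_nt=len(seq)))
        return cls.from_records(records)


def write_reference(db: ReferenceDB, path: str | Path) -> None:
    """Write the sub-transcripts as FASTA, one entry per record, header =
    raw allele name, input record order."""
    if not db.records:
        raise ValueError("refusing to write an empty reference database")
    entries = [
        SeqRecord(Seq(rec.subtranscript), id=rec.name.raw_name, description="")
        for rec in db.records
    ]
    SeqIO.write(entries, str(path), "fasta")


def write_manifest(db: ReferenceDB, path: str | Path) -> None:
    """TSV manifest: name, locus, group, class, length_nt (input order)."""
    with open(path, "w") as fh:
        fh.write("name\tlocus\tgroup\tclass\tlength_nt\n")
        for rec in db.records:
            n = rec.name
            fh.write(f"{n.raw_name}\t{n.locus}\t{n.group}\t{n.hla_class}\t{rec.length_nt}\n")


def load_reference(
    fasta_path: str | Path,
    exon_table_path: str | Path,
) -> tuple[ReferenceDB, list[tuple[str, str]]]:
    """Parse an allele FASTA + exon TSV and build the reference database."""
    fasta_text = Path(fasta_path).read_text()
    table = read_exon_table(exon_table_path)
    records, rejected = parse_allele_fasta(fasta_text, table)
    return ReferenceDB.from_records(records), rejected
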