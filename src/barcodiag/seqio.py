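"""Sequence records, sample sheets, FASTA I/O and IUPAC primitives.

All sequences are DNA over the IUPAC alphabet (``ACGT`` plus the ambiguity
codes ``RYSWKMBDHVN``); the gap character ``-`` is legal only inside
alignments.  Records carry a species label and a *group role* that the
downstream diagnostic scanners key on: the declared species of interest
(TARGET), its potential surrogates (NONTARGET), phylogenetic outgroups
(OUTGROUP) and unassigned material such as commercial products (UNKNOWN).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "Group",
    "Source",
    "SequenceRecord",
    "SampleSheet",
    "IUPAC_SETS",
    "iupac_match",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_sample_sheet",
    "write_sample_sheet",
    "merge_bidirectional_reads",
]

# base sets represented by each IUPAC nucleotide code
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)

ALPHABET = frozenset(IUPAC_SETS) | {"-"}


class Group(str, enum.Enum):
    TARGET = "TARGET"
    NONTARGET = "NONTARGET"
    OUTGROUP = "OUTGROUP"
    UNKNOWN = "UNKNOWN"


class Source(str, enum.Enum):
    REFERENCE = "REFERENCE"
    COMMERCIAL = "COMMERCIAL"
    SYNTHETIC = "SYNTHETIC"


class SeqFormatError(ValueError):
    """Malformed sequence input (bad residue, duplicate id, ragged row...)."""


def _validate_residues(res: str, rec_id: str, allow_gaps: bool) -> str:
    res = res.upper()
    if not res:
        raise SeqFormatError(f"record {rec_id!r}: empty sequence")
    legal = ALPHABET if allow_gaps else frozenset(IUPAC_SETS)
    for pos, ch in enumerate(res, start=1):
        if ch not in legal:
            raise SeqFormatError(
                f"record {rec_id!r}: illegal residue {ch!r} at position {pos}"
            )
    return res


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its species label and group role."""

    id: str
    residues: str
    species: str = ""
    group: Group = Group.UNKNOWN
    source: Source = Source.REFERENCE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _validate_residues(self.residues, self.id, allow_gaps=True)
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def degap(self) -> "SequenceRecord":
        return replace(self, residues=self.ungapped)


@dataclass(frozen=True)
class SampleSheet:
    """Mapping record id -> (species, group, source)."""

    entries: Mapping[str, tuple[str, Group, Source]] = field(default_factory=dict)

    def annotate(self, rec: SequenceRecord) -> SequenceRecord:
        if rec.id not in self.entries:
            return rec
        species, group, source = self.entries[rec.id]
        return replace(rec, species=species, group=group, source=source)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self.entries


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet with header columns id/species/group/source."""
    entries: dict[str, tuple[str, Group, Source]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "species", "group", "source"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SeqFormatError(
                f"sample sheet {path}: header must contain {sorted(required)}"
            )
        for row in reader:
            rid = row["id"]
            if rid in entries:
                raise SeqFormatError(f"sample sheet {path}: duplicate id {rid!r}")
            entries[rid] = (
                row["species"],
                Group(row["group"].upper()),
                Source(row["source"].upper()),
            )
    return SampleSheet(entries)


def write_sample_sheet(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "group", "source"])
        for rec in records:
            writer.writerow([rec.id, rec.species, rec.group.value, rec.source.value])


def read_fasta(
    path: str | Path, sheet: SampleSheet | None = None, allow_gaps: bool = False
) -> list[SequenceRecord]:
    """Read FASTA records in file order; annotate species/group from *sheet*.

    Records absent from the sheet keep group UNKNOWN.  Lowercase residues are
    normalised to uppercase; ids must be unique; residues outside the IUPAC
    DNA alphabet raise :class:`SeqFormatError` naming the id and position.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise SeqFormatError(f"duplicate id {bio.id!r} in {path}")
        seen.add(bio.id)
        res = _validate_residues(str(bio.seq), bio.id, allow_gaps=allow_gaps)
        rec = SequenceRecord(id=bio.id, residues=res)
        if sheet is not None:
            rec = sheet.annotate(rec)
        records.append(rec)
    if not records:
        raise SeqFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrapped, in input order."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC ambiguity mapping."""
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise SeqFormatError(f"illegal residue {ch!r} at position {pos}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect; '-' matches nothing."""
    if a == "-" or b == "-":
        return False
    try:
        return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])
    except KeyError as exc:
        raise SeqFormatError(f"not an IUPAC code: {exc.args[0]!r}") from None


def _consensus_symbol(a: str, b: str) -> str:
    """Consensus of two IUPAC codes at a merged-overlap position.

    Identical codes pass through; compatible codes collapse to their
    intersection; disjoint codes become 'N' (no quality information is
    available to arbitrate).
    """
    if a == b:
        return a
    inter = IUPAC_SETS[a] & IUPAC_SETS[b]
    if not inter:
        return "N"
    for sym, bases in IUPAC_SETS.items():
        if bases == inter:
            return sym
    return "N"  # unreachable: every subset of ACGT has a symbol


class MergeError(ValueError):
    """No acceptable overlap between a bidirectional read pair."""


def merge_bidirectional_reads(
    fwd: str,
    rev_read: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.05,
) -> str:
    """Merge a forward read with the reverse-complemented reverse read.

    The two Sanger reads of one amplicon are merged ungapped over their
    best-scoring suffix(fwd)/prefix(revcomp(rev)) overlap of length at least
    ``min_overlap``.  The overlap maximising the number of matching positions
    wins (ties go to the longer overlap); discordant positions in the overlap
    become 'N'.
    """
    if not fwd or not rev_read:
        raise MergeError("both reads must be non-empty")
    f = fwd.upper()
    r = reverse_complement(rev_read)
    max_k = min(len(f), len(r))
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    best: tuple[int, int] | None = None  # (matches, k)
    for k in range(min_overlap, max_k + 1):
        fs, rp = f[-k:], r[:k]
        matches = sum(1 for x, y in zip(fs, rp) if iupac_match(x, y))
        if (k - matches) / k > max_mismatch_frac:
            continue
        if best is None or (matches, k) > best:
            best = (matches, k)
    if best is None:
        raise MergeError(
            f"no overlap >= {min_overlap} with mismatch fraction <= {max_mismatch_frac}"
        )
    _, k = best
    junction = "".join(_consensus_symbol(x, y) for x, y in zip(f[-k:], r[:k]))
    return f[:-k] + junction + r[k:]
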