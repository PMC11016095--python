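"""Multiple sequence alignments and primer-interior trimming.

The toolkit ships a small deterministic progressive aligner (pairwise global
Needleman-Wunsch with affine gaps, profile-profile extension, UPGMA guide
tree over k-mer distances) so that the whole pipeline runs without external
binaries; alignments produced by MUSCLE/MAFFT can be imported verbatim with
:func:`import_alignment` and are the recommended production path.

Columns are 1-based and inclusive throughout, matching the convention used
for diagnostic-site positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import (
    Group,
    SeqFormatError,
    SequenceRecord,
    iupac_match,
    read_fasta,
    reverse_complement,
    write_fasta,
)

__all__ = [
    "Alignment",
    "PrimerSpec",
    "PrimerRole",
    "Strand",
    "PrimerSite",
    "align",
    "import_alignment",
    "export_alignment",
    "locate_primer",
    "trim_to_primer_interior",
    "consensus_sequence",
]


class AlignmentError(ValueError):
    pass


class PrimerNotFoundError(AlignmentError):
    pass


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows over sequence records (1-based columns)."""

    records: tuple[SequenceRecord, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise AlignmentError("alignment needs at least one row")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = sorted(
                r.id for r in self.records if len(r.residues) != len(self.records[0].residues)
            )
            raise AlignmentError(f"ragged rows (ids: {', '.join(bad)})")
        if self.ncol < 1:
            raise AlignmentError("alignment must have >= 1 column")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate row ids")

    @property
    def ncol(self) -> int:
        return len(self.records[0].residues)

    @property
    def nrow(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """Residues of 1-based column *col*, top to bottom."""
        if not 1 <= col <= self.ncol:
            raise IndexError(f"column {col} out of range 1..{self.ncol}")
        return "".join(r.residues[col - 1] for r in self.records)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of 1-based inclusive columns [start, end]."""
        if not (1 <= start <= end <= self.ncol):
            raise IndexError(f"bad column interval [{start}, {end}] for ncol={self.ncol}")
        rows = [
            replace(r, residues=r.residues[start - 1 : end]) for r in self.records
        ]
        return Alignment(tuple(rows))

    def rows_by_group(self, group: Group) -> list[SequenceRecord]:
        return [r for r in self.records if r.group is group]


class PrimerRole:
    UNIVERSAL_FWD = "UNIVERSAL_FWD"
    UNIVERSAL_REV = "UNIVERSAL_REV"
    DIAGNOSTIC = "DIAGNOSTIC"


class Strand:
    PLUS = "PLUS"
    MINUS = "MINUS"


@dataclass(frozen=True)
class PrimerSpec:
    """An oligonucleotide primer, written 5'->3'."""

    name: str
    sequence: str
    role: str = PrimerRole.UNIVERSAL_FWD
    strand: str = Strand.PLUS

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if "-" in seq:
            raise SeqFormatError(f"primer {self.name!r}: gaps not allowed")
        if len(seq) < 15:
            raise SeqFormatError(f"primer {self.name!r}: length must be >= 15")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSite:
    """Located primer occurrence: 1-based inclusive interval on the search string."""

    start: int
    end: int
    strand: str
    mismatches: int


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_columns(rows: list[str]) -> list[np.ndarray]:
    """Per-column frequency vectors over A,C,G,T,other,gap."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ncol = len(rows[0])
    cols = []
    for j in range(ncol):
        v = np.zeros(6)
        for row in rows:
            ch = row[j]
            if ch == "-":
                v[5] += 1
            else:
                v[idx.get(ch, 4)] += 1
        cols.append(v / len(rows))
    return cols


def _col_score(u: np.ndarray, v: np.ndarray, match: float, mismatch: float) -> float:
    # expected pair score between two profile columns; existing gaps neutral
    base_u, base_v = u[:4], v[:4]
    p_match = float(base_u @ base_v)
    p_pair = float(base_u.sum() * base_v.sum())
    # 'other' (ambiguity) residues scored as half-matches
    p_amb = float(u[4] * v[:5].sum() + v[4] * u[:5].sum())
    return match * p_match + mismatch * (p_pair - p_match) + 0.5 * match * p_amb


def _nw_profiles(
    rows_a: list[str],
    rows_b: list[str],
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (Gotoh); deterministic."""
    ca, cb = _profile_columns(rows_a), _profile_columns(rows_b)
    n, m = len(ca), len(cb)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A column)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    S = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = _col_score(ca[i], cb[j], match, mismatch)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback, preferring diagonal, then gap-in-B, then gap-in-A
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])), key=lambda t: t[1]
    )[0]
    path: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            path.append("M")
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = ("M", "X", "Y")[int(np.argmax(prev))]
        elif state == "X":
            path.append("X")
            state = "M" if (i == 1 or M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend) else "X"
            i -= 1
        else:
            path.append("Y")
            state = "M" if (j == 1 or M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_extend) else "Y"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in path:
        if op == "M":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
    return out_a, out_b


def align(
    records: Sequence[SequenceRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -6.0,
    gap_extend: float = -0.5,
) -> Alignment:
    """Progressive multiple alignment (UPGMA guide tree over k-mer distances).

    Deterministic for fixed inputs and parameters.  Intended for the modest
    divergence of intra-genus barcode sets; use :func:`import_alignment` for
    alignments produced by a dedicated aligner.
    """
    if not records:
        raise AlignmentError("no records to align")
    recs = [r.degap() for r in records]
    if len(recs) == 1:
        return Alignment((recs[0],))
    n = len(recs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(recs[i].residues, recs[j].residues)
    if n == 2:
        merge_order = [(0, 1)]
    else:
        Z = linkage(squareform(dm, checks=False), method="average")
        merge_order = [(int(a), int(b)) for a, b, _, _ in Z]
    # clusters indexed like scipy: 0..n-1 leaves, then n, n+1, ... merges
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [recs[i].residues]) for i in range(n)
    }
    nxt = n
    for a, b in merge_order:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _nw_profiles(rows_a, rows_b, match, mismatch, gap_open, gap_extend)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    ids, rows = clusters.popitem()[1]
    # restore input order
    by_input = sorted(zip(ids, rows))
    out = [replace(recs[i], residues=row) for i, row in by_input]
    return Alignment(tuple(out))


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def import_alignment(path: str | Path, sheet=None) -> Alignment:
    """Read an aligned FASTA (equal row lengths) as an :class:`Alignment`."""
    records = read_fasta(path, sheet=sheet, allow_gaps=True)
    return Alignment(tuple(records))


def export_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(aln.records, path)


# ---------------------------------------------------------------------------
# primer location and trimming
# ---------------------------------------------------------------------------

def _count_mismatches(window: str, primer_seq: str) -> int:
    return sum(1 for w, p in zip(window, primer_seq) if not iupac_match(w, p))


def locate_primer(
    sequence: str | SequenceRecord,
    primer: PrimerSpec,
    max_mismatch: int = 2,
) -> PrimerSite:
    """Best ungapped occurrence of a primer in a sequence.

    PLUS-strand primers are searched as written; MINUS-strand primers are
    searched as their reverse complement (i.e. the interval returned is on
    the plus strand of *sequence*).  Ties are broken by the smallest start.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    seq = seq.upper()
    query = (
        primer.sequence if primer.strand == Strand.PLUS else reverse_complement(primer.sequence)
    )
    L = len(query)
    if len(seq) < L:
        raise PrimerNotFoundError(
            f"sequence shorter than primer {primer.name!r} ({len(seq)} < {L})"
        )
    best: PrimerSite | None = None
    for start in range(len(seq) - L + 1):
        mm = _count_mismatches(seq[start : start + L], query)
        if best is None or mm < best.mismatches:
            best = PrimerSite(start + 1, start + L, primer.strand, mm)
    assert best is not None
    if best.mismatches > max_mismatch:
        raise PrimerNotFoundError(
            f"primer {primer.name!r}: best hit has {best.mismatches} mismatches "
            f"(> {max_mismatch})"
        )
    return best


def consensus_sequence(aln: Alignment, rows: Iterable[SequenceRecord] | None = None) -> str:
    """Column-wise majority consensus (ties -> lexicographically smallest).

    A column whose majority symbol is the gap yields '-'; the consensus has
    exactly one character per alignment column.
    """
    use = list(rows) if rows is not None else list(aln.records)
    if not use:
        raise AlignmentError("consensus over zero rows")
    out = []
    for j in range(aln.ncol):
        counts: dict[str, int] = {}
        for r in use:
            ch = r.residues[j]
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def trim_to_primer_interior(
    aln: Alignment,
    fwd: PrimerSpec,
    rev: PrimerSpec,
    max_mismatch: int = 3,
) -> Alignment:
    """Trim an alignment to the first column downstream of the forward primer
    through the last column preceding the reverse primer.

    Primer intervals are located on the column-wise majority consensus so
    that individual rows with sequencing errors cannot shift the trim
    coordinates.  All-gap columns created by trimming are retained and count
    toward the column total; the trim report in ``meta`` gives both the
    gap-inclusive and gap-free column counts.
    """
    cons = consensus_sequence(aln)
    fwd_spec = replace(fwd, strand=Strand.PLUS) if fwd.strand != Strand.PLUS else fwd
    rev_spec = replace(rev, strand=Strand.MINUS) if rev.strand != Strand.MINUS else rev
    site_f = locate_primer(cons, fwd_spec, max_mismatch)
    site_r = locate_primer(cons, rev_spec, max_mismatch)
    if site_r.start <= site_f.end + 1:
        raise AlignmentError(
            f"reverse primer interval [{site_r.start},{site_r.end}] does not lie "
            f"downstream of forward primer interval [{site_f.start},{site_f.end}]"
        )
    start, end = site_f.end + 1, site_r.start - 1
    trimmed = aln.slice_columns(start, end)
    ngapfree = sum(
        1
        for j in range(1, trimmed.ncol + 1)
        if any(ch != "-" for ch in trimmed.column(j))
    )
    trimmed.meta.update(
        {
            "fwd_interval": (site_f.start, site_f.end),
            "rev_interval": (site_r.start, site_r.end),
            "ncol_before": aln.ncol,
            "ncol_after": trimmed.ncol,
            "ncol_after_gapfree": ngapfree,
            "offset": start - 1,  # original column = trimmed column + offset
        }
    )
    return trimmed
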