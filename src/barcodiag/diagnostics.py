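"""Discovery of group-diagnostic variation in barcode alignments.

A *diagnostic site* is an alignment column (or a private indel interval)
where the target group is fixed for an allele that no non-target sequence
carries.  Such fixed private SNPs are the raw material for allele-specific
(ARMS) primer design; private indels and group-level amplicon-length
differences support gel-level discrimination.

Scanners accept the grouping either as the TARGET/NONTARGET roles carried by
the records or as an explicit species name / id set, so the same machinery
answers "declared species vs all surrogates" and "surrogate A vs surrogate B"
questions.  UNKNOWN- and OUTGROUP-role rows never participate in discovery.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment import Alignment
from .seqio import Group, IUPAC_SETS, SequenceRecord

__all__ = [
    "SiteType",
    "AmbiguityPolicy",
    "DiagnosticSite",
    "LengthSummary",
    "scan_diagnostic_snps",
    "scan_diagnostic_indels",
    "group_length_summary",
    "at_content",
    "gc_content",
]


class DiagnosticsError(ValueError):
    pass


class SiteType(str, enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class AmbiguityPolicy(str, enum.Enum):
    STRICT = "STRICT"
    COMPATIBLE = "COMPATIBLE"


@dataclass(frozen=True)
class DiagnosticSite:
    """A fixed, group-private difference at an alignment position."""

    column: int  # 1-based; for INDEL the first column of the interval
    site_type: SiteType
    target_allele: str  # base (SNP) or the private segment (INDEL)
    nontarget_alleles: frozenset[str]
    n_target: int
    n_nontarget: int
    context_gc: float
    window: int = 41
    end_column: int | None = None  # INDEL only (inclusive)
    indel_in_target: bool | None = None  # INDEL: True = segment present in target rows

    @property
    def length(self) -> int:
        if self.site_type is SiteType.SNP:
            return 1
        return self.end_column - self.column + 1


@dataclass(frozen=True)
class LengthSummary:
    """Per-group ungapped length statistics."""

    stats: dict[str, tuple[int, float, int]]  # group -> (min, median, max)


def _resolve_groups(
    aln: Alignment, target
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split reference rows into target vs non-target per the *target* spec.

    ``target`` may be ``Group.TARGET`` (use the annotated roles), a species
    label, or a set of row ids.  OUTGROUP/UNKNOWN rows are excluded either
    way.
    """
    reference = [r for r in aln.records if r.group in (Group.TARGET, Group.NONTARGET)]
    if isinstance(target, Group):
        if target is not Group.TARGET:
            raise DiagnosticsError("group-based scanning keys on Group.TARGET")
        tgt = [r for r in reference if r.group is Group.TARGET]
    elif isinstance(target, str):
        tgt = [r for r in reference if r.species == target]
    else:
        ids = set(target)
        tgt = [r for r in reference if r.id in ids]
    tgt_ids = {r.id for r in tgt}
    non = [r for r in reference if r.id not in tgt_ids]
    if not tgt or not non:
        raise DiagnosticsError(
            f"need >=1 target and >=1 non-target reference row "
            f"(got {len(tgt)} / {len(non)})"
        )
    return tgt, non


def _window_gc(aln: Alignment, col: int, window: int) -> float:
    """GC fraction of the column-majority consensus in a centered window.

    Gap and ambiguous consensus characters are excluded from the tally
    (S counts as GC, W as AT).
    """
    half = window // 2
    lo, hi = max(1, col - half), min(aln.ncol, col + half)
    gc = at = 0
    for j in range(lo, hi + 1):
        column = aln.column(j)
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if best in "GCS":
            gc += 1
        elif best in "ATW":
            at += 1
    total = gc + at
    return gc / total if total else 0.0


def scan_diagnostic_snps(
    aln: Alignment,
    target=Group.TARGET,
    ambiguity_policy: AmbiguityPolicy = AmbiguityPolicy.STRICT,
    window: int = 41,
) -> list[DiagnosticSite]:
    """All columns where the target group is fixed for a private base.

    A column qualifies when every target row shares one unambiguous base,
    every non-target row carries a base from a set disjoint from it, and no
    participating row has a gap there.  STRICT disqualifies any IUPAC
    ambiguity code; COMPATIBLE accepts an ambiguity code when its base set
    intersects the alleles already established by the unambiguous rows of
    its own group (it contributes no new alleles).  Sites are sorted by
    column and carry the GC fraction of a centered consensus window.
    """
    if window < 1 or window % 2 == 0:
        raise DiagnosticsError("window must be a positive odd integer")
    tgt, non = _resolve_groups(aln, target)
    sites: list[DiagnosticSite] = []
    for col in range(1, aln.ncol + 1):
        t_syms = {r.residues[col - 1] for r in tgt}
        n_syms = {r.residues[col - 1] for r in non}
        if "-" in t_syms or "-" in n_syms:
            continue
        t_unamb = {s for s in t_syms if s in "ACGT"}
        n_unamb = {s for s in n_syms if s in "ACGT"}
        if ambiguity_policy is AmbiguityPolicy.STRICT:
            if t_syms != t_unamb or n_syms != n_unamb:
                continue
        if len(t_unamb) != 1:
            continue
        allele = next(iter(t_unamb))
        if not n_unamb or allele in n_unamb:
            continue
        if ambiguity_policy is AmbiguityPolicy.COMPATIBLE:
            t_amb = t_syms - t_unamb
            n_amb = n_syms - n_unamb
            if any(allele not in IUPAC_SETS[s] for s in t_amb):
                continue
            if any(not (IUPAC_SETS[s] & n_unamb) for s in n_amb):
                continue
        sites.append(
            DiagnosticSite(
                column=col,
                site_type=SiteType.SNP,
                target_allele=allele,
                nontarget_alleles=frozenset(n_unamb),
                n_target=len(tgt),
                n_nontarget=len(non),
                context_gc=_window_gc(aln, col, window),
                window=window,
            )
        )
    return sites


def scan_diagnostic_indels(
    aln: Alignment,
    target=Group.TARGET,
    window: int = 41,
) -> list[DiagnosticSite]:
    """Maximal column runs gapped in every row of one group and ungapped in
    every row of the other (private insertions/deletions)."""
    tgt, non = _resolve_groups(aln, target)
    sites: list[DiagnosticSite] = []
    run_start: int | None = None
    run_in_target: bool | None = None

    def close_run(end_col: int) -> None:
        nonlocal run_start, run_in_target
        if run_start is None:
            return
        rows = tgt if run_in_target else non
        segment = rows[0].residues[run_start - 1 : end_col]
        sites.append(
            DiagnosticSite(
                column=run_start,
                site_type=SiteType.INDEL,
                target_allele=segment,
                nontarget_alleles=frozenset({"-" * len(segment)}),
                n_target=len(tgt),
                n_nontarget=len(non),
                context_gc=_window_gc(aln, run_start, window),
                window=window,
                end_column=end_col,
                indel_in_target=run_in_target,
            )
        )
        run_start, run_in_target = None, None

    for col in range(1, aln.ncol + 1):
        t_gap = [r.residues[col - 1] == "-" for r in tgt]
        n_gap = [r.residues[col - 1] == "-" for r in non]
        if all(t_gap) and not any(n_gap):
            state: bool | None = False  # segment present in non-target rows
        elif all(n_gap) and not any(t_gap):
            state = True
        else:
            state = None
        if state is None:
            close_run(col - 1)
        elif run_start is None:
            run_start, run_in_target = col, state
        elif run_in_target != state:
            close_run(col - 1)
            run_start, run_in_target = col, state
    close_run(aln.ncol)
    return sites


def group_length_summary(
    records: Sequence[SequenceRecord],
    groups: dict[str, Iterable[str]] | None = None,
) -> LengthSummary:
    """Min/median/max ungapped length per group.

    ``groups`` maps a group name to the species labels it covers; by default
    every distinct species label forms its own group.
    """
    if groups is None:
        groups = {sp: [sp] for sp in sorted({r.species for r in records})}
    stats: dict[str, tuple[int, float, int]] = {}
    for name, species in groups.items():
        spset = set(species)
        lengths = [len(r.ungapped) for r in records if r.species in spset]
        if not lengths:
            raise DiagnosticsError(f"group {name!r} has no records")
        stats[name] = (min(lengths), statistics.median(lengths), max(lengths))
    return LengthSummary(stats)


def at_content(seq: str) -> float:
    """AT fraction: (A+T+W) over counted A,C,G,T,W,S.

    Gaps and ambiguity codes other than W/S are excluded from numerator and
    denominator.
    """
    seq = seq.upper()
    at = sum(seq.count(c) for c in "ATW")
    gc = sum(seq.count(c) for c in "GCS")
    if at + gc == 0:
        raise DiagnosticsError("no countable bases")
    return at / (at + gc)


def gc_content(seq: str) -> float:
    return 1.0 - at_content(seq)
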