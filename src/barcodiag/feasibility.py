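"""Fingerprinting-feasibility screens for diagnostic SNP sites.

Before committing to an assay, each candidate site is screened for the two
sequencing-free readouts:

* **RFLP / CAPS** — does the SNP create or destroy a restriction site, so a
  digest would distinguish the alleles?  Only gain/loss at the variant
  position is screened, not full digest geometry.
* **ARMS primer context** — can an allele-specific primer anchored with its
  3' end on the SNP have workable composition?  Footprints in AT-rich
  context melt too low and mismatch discrimination collapses, so a site is
  ARMS-feasible only if some candidate footprint passes the AT-fraction and
  melting-temperature thresholds.

The default thresholds (``max_at = 0.75``, ``min_tm = 55``) encode common
primer-design practice: an AT fraction above ~3/4 leaves too little pairing
energy for a discriminating 3' end.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .alignment import Alignment, consensus_sequence
from .diagnostics import DiagnosticSite, SiteType, _resolve_groups, at_content
from .seqio import iupac_match, reverse_complement

__all__ = [
    "Enzyme",
    "RflpEffect",
    "FeasibilityReport",
    "builtin_enzymes",
    "load_enzymes",
    "rflp_screen",
    "arms_context_screen",
]


class FeasibilityError(ValueError):
    pass


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme recognition site (IUPAC, cut offset from 5')."""

    name: str
    site: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise FeasibilityError(f"enzyme {self.name!r}: recognition length must be >= 4")
        object.__setattr__(self, "site", self.site.upper())


class RflpEffect(str, enum.Enum):
    #: recognition present in the target-allele consensus only
    #: (the non-target allele has lost the site)
    SITE_LOST = "SITE_LOST"
    #: recognition present in the non-target-allele consensus only
    SITE_GAINED = "SITE_GAINED"


def load_enzymes(path) -> list[Enzyme]:
    """Load an enzyme table (TSV columns name/site/cut_offset)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(Enzyme(row["name"], row["site"], int(row.get("cut_offset", 0))))
    return out


def builtin_enzymes() -> list[Enzyme]:
    """The shipped table of common 6-cutters (user-extensible via TSV)."""
    ref = resources.files("barcodiag.data").joinpath("enzymes.tsv")
    with resources.as_file(ref) as path:
        return load_enzymes(path)


def _matches_at(seq: str, pos: int, pattern: str) -> bool:
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    return all(iupac_match(seq[pos + k], pattern[k]) for k in range(len(pattern)))


def _recognizes_over(seq: str, col0: int, enzyme: Enzyme) -> bool:
    """Any enzyme occurrence (either strand) overlapping 0-based position col0."""
    for pattern in (enzyme.site, reverse_complement(enzyme.site)):
        L = len(pattern)
        for start in range(col0 - L + 1, col0 + 1):
            if _matches_at(seq, start, pattern):
                return True
    return False


def _allele_consensus(
    aln: Alignment, site: DiagnosticSite, rows, allele: str
) -> tuple[str, int]:
    """Ungapped group consensus with *allele* forced at the site column.

    Returns the sequence and the 0-based index of the site position in it.
    """
    cons = list(consensus_sequence(aln, rows))
    cons[site.column - 1] = allele
    seq = []
    idx = -1
    for j, ch in enumerate(cons):
        if ch == "-":
            continue
        if j == site.column - 1:
            idx = len(seq)
        seq.append(ch)
    return "".join(seq), idx


def rflp_screen(
    aln: Alignment,
    site: DiagnosticSite,
    enzymes: Iterable[Enzyme] | None = None,
    target=None,
) -> list[tuple[Enzyme, RflpEffect]]:
    """Enzymes whose recognition overlaps the SNP in exactly one allele.

    The target-allele consensus is compared against a consensus carrying
    each non-target allele in turn; an enzyme is reported when its site
    (either strand) overlaps the SNP position in exactly one of the two.
    """
    if site.site_type is not SiteType.SNP:
        raise FeasibilityError("rflp_screen requires a SNP site")
    if enzymes is None:
        enzymes = builtin_enzymes()
    from .seqio import Group

    tgt, non = _resolve_groups(aln, target if target is not None else Group.TARGET)
    t_seq, t_idx = _allele_consensus(aln, site, tgt, site.target_allele)
    hits: list[tuple[Enzyme, RflpEffect]] = []
    for enzyme in enzymes:
        t_hit = _recognizes_over(t_seq, t_idx, enzyme)
        n_hit = False
        for allele in sorted(site.nontarget_alleles):
            n_seq, n_idx = _allele_consensus(aln, site, non, allele)
            if _recognizes_over(n_seq, n_idx, enzyme):
                n_hit = True
                break
        if t_hit and not n_hit:
            hits.append((enzyme, RflpEffect.SITE_LOST))
        elif n_hit and not t_hit:
            hits.append((enzyme, RflpEffect.SITE_GAINED))
    return hits


@dataclass(frozen=True)
class FeasibilityReport:
    site: DiagnosticSite
    rflp_hits: tuple[tuple[Enzyme, RflpEffect], ...]
    arms_feasible: bool
    reasons: tuple[str, ...]
    context_gc: float
    best_candidate_tm: float | None


def _candidate_footprints(
    aln: Alignment, site: DiagnosticSite, rows, primer_len_range: tuple[int, int]
):
    """Yield (orientation, length, footprint 5'->3') for every candidate
    allele-specific primer with its 3' end anchored on the site column."""
    cons = consensus_sequence(aln, rows).replace("-", "")
    # map the site column to the ungapped consensus position
    full = consensus_sequence(aln, rows)
    pos = sum(1 for ch in full[: site.column - 1] if ch != "-")  # 0-based
    lo, hi = primer_len_range
    for length in range(lo, hi + 1):
        start = pos - length + 1
        if start >= 0:
            yield "PLUS", length, cons[start : pos + 1]
        end = pos + length
        if end <= len(cons):
            yield "MINUS", length, reverse_complement(cons[pos:end])


def arms_context_screen(
    aln: Alignment,
    site: DiagnosticSite,
    window: int = 41,
    max_at: float = 0.75,
    min_tm: float = 55.0,
    primer_len_range: tuple[int, int] = (18, 28),
    target=None,
) -> tuple[bool, list[str]]:
    """ARMS feasibility of a SNP site.

    Infeasible iff *every* candidate primer footprint (both orientations,
    lengths in range, 3' end anchored on the site) fails the AT-fraction or
    melting-temperature threshold.  Relaxing either threshold can only turn
    an infeasible site feasible (monotone screen).
    """
    from .arms_design import melting_temperature, TmMethod
    from .seqio import Group

    if site.site_type is not SiteType.SNP:
        raise FeasibilityError("arms_context_screen requires a SNP site")
    tgt, _non = _resolve_groups(aln, target if target is not None else Group.TARGET)
    reasons: set[str] = set()
    best_tm: float | None = None
    for _orient, _length, footprint in _candidate_footprints(
        aln, site, tgt, primer_len_range
    ):
        at = at_content(footprint)
        if all(ch in "ACGT" for ch in footprint):
            tm = melting_temperature(footprint, TmMethod.NN_SANTALUCIA)
        else:
            tm = melting_temperature(footprint, TmMethod.WALLACE)
        if best_tm is None or tm > best_tm:
            best_tm = tm
        ok = True
        if at > max_at:
            reasons.add("AT-rich context")
            ok = False
        if tm < min_tm:
            reasons.add(f"melting temperature below {min_tm:g} degC")
            ok = False
        if ok:
            return True, []
    if best_tm is None:
        reasons.add("no candidate footprint fits inside the alignment")
    return False, sorted(reasons)


def screen_site(
    aln: Alignment,
    site: DiagnosticSite,
    enzymes: Iterable[Enzyme] | None = None,
    target=None,
    **arms_kwargs,
) -> FeasibilityReport:
    """Combined RFLP + ARMS screen for one diagnostic SNP site."""
    rflp = tuple(rflp_screen(aln, site, enzymes, target=target))
    feasible, reasons = arms_context_screen(aln, site, target=target, **arms_kwargs)
    from .arms_design import melting_temperature, TmMethod
    from .seqio import Group

    tgt, _ = _resolve_groups(aln, target if target is not None else Group.TARGET)
    best_tm: float | None = None
    for _o, _l, fp in _candidate_footprints(
        aln, site, tgt, arms_kwargs.get("primer_len_range", (18, 28))
    ):
        method = TmMethod.NN_SANTALUCIA if all(c in "ACGT" for c in fp) else TmMethod.WALLACE
        tm = melting_temperature(fp, method)
        if best_tm is None or tm > best_tm:
            best_tm = tm
    return FeasibilityReport(
        site=site,
        rflp_hits=rflp,
        arms_feasible=feasible,
        reasons=tuple(reasons),
        context_gc=site.context_gc,
        best_candidate_tm=best_tm,
    )
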