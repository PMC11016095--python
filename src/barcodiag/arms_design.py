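"""ARMS diagnostic-primer construction and duplex-assay assembly.

The ARMS (Amplification Refractory Mutation System) trick: copy a primer
from the template so that its 3'-terminal base sits exactly on a diagnostic
SNP and base-pairs only with the allele of interest, then *additionally*
exchange the base at the third position from the 3' end for one that
mispairs with every template.  On the intended allele the primer carries a
single internal mismatch and still extends; on the other allele the
3'-terminal mismatch plus the engineered destabiliser abolish extension.

A duplex assay combines the universal barcode primer pair (full-length
control band — the innate control against false negatives) with one such
diagnostic primer (allele-specific side band).  Two complementary assays of
opposite polarity (band means "target present" / band means "non-target
present") make the readout positive in both directions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .alignment import (
    Alignment,
    PrimerRole,
    PrimerSpec,
    Strand,
    consensus_sequence,
    locate_primer,
)
from .diagnostics import DiagnosticSite, SiteType, _resolve_groups
from .seqio import Group, IUPAC_SETS, iupac_match, reverse_complement

__all__ = [
    "TmMethod",
    "TmConditions",
    "Polarity",
    "ArmsPrimer",
    "ArmsAssay",
    "melting_temperature",
    "design_diagnostic_primer",
    "build_duplex_assay",
    "design_complementary_assays",
]


class DesignError(ValueError):
    pass


class TmMethod(str, enum.Enum):
    WALLACE = "WALLACE"
    NN_SANTALUCIA = "NN_SANTALUCIA"


@dataclass(frozen=True)
class TmConditions:
    """Solution conditions for nearest-neighbour Tm.

    Defaults: 50 mM monovalent salt, 250 nM primer.  The primer is assumed
    in large excess over its template (the PCR situation), so the duplex
    concentration term is the primer concentration itself.
    """

    na_mM: float = 50.0
    primer_nM: float = 250.0


# Unified nearest-neighbour parameters (Allawi & SantaLucia 1997):
# dH kcal/mol, dS cal/(mol*K) per 5'->3' dinucleotide step.
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT_GC = (0.1, -2.8)  # per terminal G/C
_NN_INIT_AT = (2.3, 4.1)  # per terminal A/T
_GAS_CONSTANT = 1.987  # cal/(mol*K)


def melting_temperature(
    seq: str,
    method: TmMethod = TmMethod.NN_SANTALUCIA,
    conditions: TmConditions = TmConditions(),
) -> float:
    """Oligo melting temperature in degrees Celsius.

    WALLACE: 2(A+T) + 4(G+C); IUPAC ambiguity codes contribute the midpoint
    of their base set.  NN_SANTALUCIA: unified nearest-neighbour dH/dS with
    the 0.368*(N-1)*ln[Na+] entropy salt correction; requires an unambiguous
    sequence.
    """
    seq = seq.upper()
    if method is TmMethod.WALLACE:
        tm = 0.0
        for ch in seq:
            bases = IUPAC_SETS.get(ch)
            if bases is None:
                raise DesignError(f"not an IUPAC code: {ch!r}")
            tm += sum(4.0 if b in "GC" else 2.0 for b in bases) / len(bases)
        return tm
    if any(ch not in "ACGT" for ch in seq):
        raise DesignError("nearest-neighbour Tm requires an unambiguous sequence")
    if len(seq) < 2:
        raise DesignError("nearest-neighbour Tm requires length >= 2")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        ih, is_ = _NN_INIT_GC if end in "GC" else _NN_INIT_AT
        dh += ih
        ds += is_
    for k in range(len(seq) - 1):
        h, s = _NN_PARAMS[seq[k : k + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(conditions.na_mM / 1000.0)
    ct = conditions.primer_nM * 1e-9
    return dh * 1000.0 / (ds + _GAS_CONSTANT * math.log(ct)) - 273.15


class Polarity(str, enum.Enum):
    PRESENCE_MEANS_TARGET = "PRESENCE_MEANS_TARGET"
    PRESENCE_MEANS_NONTARGET = "PRESENCE_MEANS_NONTARGET"


@dataclass(frozen=True)
class ArmsPrimer:
    """An allele-specific primer with the engineered -3 destabiliser."""

    name: str
    sequence: str  # 5'->3'
    strand: str
    anchored_column: int  # 1-based alignment column under the 3' terminus
    terminal_allele: str  # base the 3' end reads on its own strand
    destabilizer: tuple[int, str, str]  # (offset from 3' end, original, substituted)
    gc_fraction: float
    tm_wallace: float
    tm_nn: float

    def __len__(self) -> int:
        return len(self.sequence)

    def as_primer_spec(self) -> PrimerSpec:
        return PrimerSpec(self.name, self.sequence, PrimerRole.DIAGNOSTIC, self.strand)


@dataclass(frozen=True)
class ArmsAssay:
    """Universal pair + one diagnostic ARMS primer, with expected bands."""

    universal_fwd: PrimerSpec
    universal_rev: PrimerSpec
    diagnostic: ArmsPrimer
    polarity: Polarity
    expected_control_bp: int
    expected_diagnostic_bp: int


# Relative duplex stability of primer-base/template-base mispairs, most
# stable first (G.T wobble) down to C.C; derived from published mismatch
# nearest-neighbour rankings.  Lower score = weaker mispair = stronger
# destabilisation, so candidates are chosen by ascending score.
_MISPAIR_STABILITY: dict[tuple[str, str], int] = {
    ("G", "T"): 8, ("T", "G"): 8,
    ("G", "G"): 7,
    ("G", "A"): 6, ("A", "G"): 6,
    ("A", "A"): 5,
    ("T", "T"): 4,
    ("A", "C"): 3, ("C", "A"): 3,
    ("T", "C"): 2, ("C", "T"): 2,
    ("C", "C"): 1,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _group_rows(aln: Alignment, polarity: Polarity, target):
    tgt, non = _resolve_groups(aln, target if target is not None else Group.TARGET)
    return tgt, non


def design_diagnostic_primer(
    aln: Alignment,
    site: DiagnosticSite,
    polarity: Polarity = Polarity.PRESENCE_MEANS_TARGET,
    strand: str = Strand.MINUS,
    length_range: tuple[int, int] = (18, 30),
    tm_range: tuple[float, float] = (55.0, 68.0),
    target=None,
    name: str | None = None,
    conditions: TmConditions = TmConditions(),
) -> ArmsPrimer:
    """Construct the ARMS primer for one diagnostic SNP site.

    The primer is copied from the consensus of the group it must amplify
    (target group for PRESENCE_MEANS_TARGET, non-target for
    PRESENCE_MEANS_NONTARGET) with its 3' end exactly on the site column,
    reverse-complemented for MINUS-strand primers.  The base at the third
    position from the 3' end is exchanged for the weakest mispair against
    the template that recreates no IUPAC match to either allele group; the
    shortest length whose nearest-neighbour Tm falls in ``tm_range`` wins,
    so the design is deterministic.
    """
    if site.site_type is not SiteType.SNP:
        raise DesignError("ARMS design requires a SNP site")
    tgt, non = _group_rows(aln, polarity, target)
    if polarity is Polarity.PRESENCE_MEANS_TARGET:
        own_rows, other_rows = tgt, non
        own_allele = site.target_allele
        other_alleles = sorted(site.nontarget_alleles)
    else:
        if len(site.nontarget_alleles) != 1:
            raise DesignError(
                "PRESENCE_MEANS_NONTARGET requires a single fixed non-target allele "
                f"(got {sorted(site.nontarget_alleles)})"
            )
        own_rows, other_rows = non, tgt
        own_allele = next(iter(site.nontarget_alleles))
        other_alleles = [site.target_allele]
    if own_allele in other_alleles:
        raise DesignError("site alleles are not distinct")
    cons = consensus_sequence(aln, own_rows)
    other_cons = consensus_sequence(aln, other_rows)
    col0 = site.column - 1

    def template_window(length: int) -> tuple[str, str] | None:
        """(own, other) template consensus under the primer footprint,
        oriented so index -1 is the column under the primer's 3' end."""
        if strand == Strand.PLUS:
            start = col0 - length + 1
            if start < 0:
                return None
            own = cons[start : col0 + 1]
            oth = other_cons[start : col0 + 1]
        else:
            end = col0 + length
            if end > len(cons):
                return None
            own = cons[col0:end][::-1]
            oth = other_cons[col0:end][::-1]
        if "-" in own or "-" in oth:
            return None
        return own, oth

    last_err = "no length in range fits inside the alignment"
    lo, hi = length_range
    for length in range(lo, hi + 1):
        window = template_window(length)
        if window is None:
            continue
        own_tpl, other_tpl = window
        if any(ch not in "ACGT" for ch in own_tpl):
            last_err = "ambiguous consensus under the footprint"
            continue
        # primer read 5'->3': complement of template for MINUS strand,
        # identity for PLUS strand (primer == plus-strand sequence).
        if strand == Strand.PLUS:
            primer = list(own_tpl)
        else:
            primer = [_COMPLEMENT[c] for c in own_tpl]
        # engineered destabiliser at offset 3 from the 3' end (terminal = 1)
        didx = len(primer) - 3
        tpl_own = own_tpl[-3]
        tpl_other = other_tpl[-3]
        original = primer[didx]
        # the base a candidate primer base physically faces: the plus-strand
        # base for MINUS primers, its complement for PLUS primers
        def faced(tpl_base: str) -> str:
            if strand == Strand.MINUS:
                return tpl_base
            return reverse_complement(tpl_base)

        candidates = []
        for base in "ACGT":
            if base == original:
                continue
            # the substituted base must pair with neither group's template
            pairs_own = iupac_match(_COMPLEMENT[base], faced(tpl_own))
            pairs_other = iupac_match(_COMPLEMENT[base], faced(tpl_other))
            if pairs_own or pairs_other:
                continue
            key = (base, faced(tpl_own))
            score = _MISPAIR_STABILITY.get(key, 9)
            candidates.append((score, base))
        if not candidates:
            last_err = "no destabiliser base avoids both allele groups"
            continue
        candidates.sort()
        sub = candidates[0][1]
        primer[didx] = sub
        seq = "".join(primer)
        tm_nn = melting_temperature(seq, TmMethod.NN_SANTALUCIA, conditions)
        if not (tm_range[0] <= tm_nn <= tm_range[1]):
            last_err = (
                f"no length in {length_range} brings Tm into {tm_range} "
                f"(length {length}: {tm_nn:.1f} degC)"
            )
            continue
        terminal = seq[-1]
        gc = sum(seq.count(c) for c in "GC") / len(seq)
        return ArmsPrimer(
            name=name or f"arms_{polarity.value.lower()}_{site.column}",
            sequence=seq,
            strand=strand,
            anchored_column=site.column,
            terminal_allele=terminal,
            destabilizer=(3, original, sub),
            gc_fraction=gc,
            tm_wallace=melting_temperature(seq, TmMethod.WALLACE),
            tm_nn=tm_nn,
        )
    raise DesignError(f"cannot design ARMS primer at column {site.column}: {last_err}")


def _aln_col_to_ungapped(cons: str, col: int) -> int:
    """1-based ungapped position of 1-based alignment column *col*."""
    if cons[col - 1] == "-":
        raise DesignError(f"column {col} is a gap in the consensus")
    return sum(1 for ch in cons[:col] if ch != "-")


def build_duplex_assay(
    aln: Alignment,
    universal_fwd: PrimerSpec,
    universal_rev: PrimerSpec,
    diagnostic: ArmsPrimer,
    polarity: Polarity = Polarity.PRESENCE_MEANS_TARGET,
    min_band_separation: int = 100,
    target=None,
) -> ArmsAssay:
    """Assemble a duplex assay and predict its band sizes on the consensus
    of the group the diagnostic primer amplifies."""
    tgt, non = _group_rows(aln, polarity, target)
    rows = tgt if polarity is Polarity.PRESENCE_MEANS_TARGET else non
    cons_gapped = consensus_sequence(aln, rows)
    cons = cons_gapped.replace("-", "")
    fwd_spec = PrimerSpec(universal_fwd.name, universal_fwd.sequence,
                          PrimerRole.UNIVERSAL_FWD, Strand.PLUS)
    rev_spec = PrimerSpec(universal_rev.name, universal_rev.sequence,
                          PrimerRole.UNIVERSAL_REV, Strand.MINUS)
    site_f = locate_primer(cons, fwd_spec, max_mismatch=3)
    site_r = locate_primer(cons, rev_spec, max_mismatch=3)
    if site_r.end <= site_f.start:
        raise DesignError("universal primer sites are not convergent on the consensus")
    control_bp = site_r.end - site_f.start + 1
    anchor = _aln_col_to_ungapped(cons_gapped, diagnostic.anchored_column)
    if diagnostic.strand == Strand.MINUS:
        diag_bp = (anchor + len(diagnostic) - 1) - site_f.start + 1
    else:
        diag_bp = site_r.end - (anchor - len(diagnostic) + 1) + 1
    if diag_bp <= 0:
        raise DesignError("diagnostic primer does not converge with a universal primer")
    if abs(control_bp - diag_bp) < min_band_separation:
        raise DesignError(
            f"band separation {abs(control_bp - diag_bp)} bp below the resolvable "
            f"minimum {min_band_separation} bp"
        )
    return ArmsAssay(
        universal_fwd=fwd_spec,
        universal_rev=rev_spec,
        diagnostic=diagnostic,
        polarity=polarity,
        expected_control_bp=control_bp,
        expected_diagnostic_bp=diag_bp,
    )


def design_complementary_assays(
    aln: Alignment,
    site: DiagnosticSite,
    universal_fwd: PrimerSpec,
    universal_rev: PrimerSpec,
    site_nontarget: DiagnosticSite | None = None,
    strand: str = Strand.MINUS,
    target=None,
    check_usable: bool = True,
    **design_kwargs,
) -> tuple[ArmsAssay, ArmsAssay]:
    """The complementary assay pair: one primer that lights up on the
    target group and one that lights up on everything else.

    ``site_nontarget`` anchors the second primer at a different diagnostic
    site (distinct band size); by default both polarities anchor the same
    site.  With ``check_usable`` the pair is verified by in-silico PCR:
    every TARGET/NONTARGET reference record must yield a diagnostic band in
    exactly one of the two assays.
    """
    from .insilico_pcr import simulate_duplex

    other = Strand.PLUS if strand == Strand.MINUS else Strand.MINUS

    def design_with_fallback(anchor_site, polarity):
        # if the requested strand cannot reach the Tm range (e.g. a locally
        # AT-poor footprint), fall back to the opposite orientation
        try:
            return design_diagnostic_primer(
                aln, anchor_site, polarity, strand, target=target, **design_kwargs
            )
        except DesignError:
            return design_diagnostic_primer(
                aln, anchor_site, polarity, other, target=target, **design_kwargs
            )

    site_b = site_nontarget or site
    primer_a = design_with_fallback(site, Polarity.PRESENCE_MEANS_TARGET)
    primer_b = design_with_fallback(site_b, Polarity.PRESENCE_MEANS_NONTARGET)
    assay_a = build_duplex_assay(
        aln, universal_fwd, universal_rev, primer_a,
        Polarity.PRESENCE_MEANS_TARGET, target=target,
    )
    assay_b = build_duplex_assay(
        aln, universal_fwd, universal_rev, primer_b,
        Polarity.PRESENCE_MEANS_NONTARGET, target=target,
    )
    if check_usable:
        refs = [
            r.degap()
            for r in aln.records
            if r.group in (Group.TARGET, Group.NONTARGET)
        ]
        pat_a = {p.template_id: p for p in simulate_duplex(refs, assay_a)}
        pat_b = {p.template_id: p for p in simulate_duplex(refs, assay_b)}
        for rec in refs:
            n_diag = sum(
                1
                for pats in (pat_a, pat_b)
                if any(b.identity == "DIAGNOSTIC" for b in pats[rec.id].bands)
            )
            if n_diag != 1:
                raise DesignError(
                    f"complementary pair not usable: record {rec.id!r} yields a "
                    f"diagnostic band in {n_diag} of the two assays"
                )
    return assay_a, assay_b
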