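"""In-silico duplex PCR with ARMS 3'-stringency, virtual gel and verdicts.

Annealing is modelled ungapped with IUPAC-aware mismatch counting and the
ARMS abolition rule: extension is blocked iff the 3'-terminal base
mismatches the template, or at least two mismatches fall within the
3'-terminal three bases.  A designed ARMS primer carries one engineered
mismatch at position -3, so against its intended allele group it anneals
(one internal mismatch) while a single additional SNP — in particular the
diagnostic one under the 3' terminus — abolishes binding.

The verdict logic mirrors duplex-PCR readout on a gel: the universal
full-length band is an innate control (its absence means assay failure, not
species absence), and the complementary assay pair must light up on exactly
one side for a confident call.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .arms_design import ArmsAssay
from .seqio import IUPAC_SETS, SequenceRecord, iupac_match, reverse_complement

__all__ = [
    "AnnealSite",
    "Band",
    "BandIdentity",
    "BandPattern",
    "Call",
    "Verdict",
    "anneal_sites",
    "simulate_duplex",
    "classify",
    "render_gel",
    "render_gel_svg",
]


class PcrError(ValueError):
    pass


@dataclass(frozen=True)
class AnnealSite:
    """One primer annealing site on the plus strand of a template.

    ``extends_right`` is True when the primer sequence matches the plus
    strand (it anneals to the minus strand and extension runs rightward);
    False when its reverse complement matches (3' end at ``start``,
    extension leftward).
    """

    start: int  # 1-based inclusive
    end: int
    extends_right: bool
    mismatches: int
    three_prime_mismatches: int
    terminal_mismatch: bool


# 4-bit base-set encoding for vectorised IUPAC comparison; '-' encodes 0
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE = {
    sym: sum(_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
} | {"-": 0}
_ENCODE = np.zeros(128, dtype=np.uint8)
for _sym, _val in _CODE.items():
    _ENCODE[ord(_sym)] = _val


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr]


def anneal_sites(
    template: str,
    primer: str,
    max_total_mismatch: int = 3,
    three_prime_window: int = 3,
    max_3prime_mismatch: int = 0,
    terminal_must_match: bool = False,
) -> list[AnnealSite]:
    """All ungapped annealing sites of a primer on both template strands.

    A window qualifies when total IUPAC mismatches <= ``max_total_mismatch``
    and mismatches within the 3'-terminal ``three_prime_window`` bases
    <= ``max_3prime_mismatch``; ``terminal_must_match`` additionally vetoes
    any 3'-terminal mismatch (the ARMS rule).
    """
    template = template.upper()
    primer = primer.upper()
    if "-" in template:
        raise PcrError("template must be ungapped")
    L = len(primer)
    out: list[AnnealSite] = []
    if L == 0 or len(template) < L:
        return out
    tpl = _encode(template)
    windows = np.lib.stride_tricks.sliding_window_view(tpl, L)
    for forward, query in ((True, primer), (False, reverse_complement(primer))):
        q = _encode(query)
        mism = (windows & q) == 0  # base sets disjoint -> mismatch
        total = mism.sum(axis=1)
        if forward:
            tp = mism[:, L - three_prime_window :].sum(axis=1)
            term = mism[:, L - 1]
        else:
            tp = mism[:, :three_prime_window].sum(axis=1)
            term = mism[:, 0]
        ok = (total <= max_total_mismatch) & (tp <= max_3prime_mismatch)
        if terminal_must_match:
            ok &= ~term
        for start in np.nonzero(ok)[0]:
            out.append(
                AnnealSite(
                    int(start) + 1,
                    int(start) + L,
                    forward,
                    int(total[start]),
                    int(tp[start]),
                    bool(term[start]),
                )
            )
    out.sort(key=lambda s: (s.start, not s.extends_right))
    return out


class BandIdentity(str, enum.Enum):
    CONTROL = "CONTROL"
    DIAGNOSTIC = "DIAGNOSTIC"
    OFF_TARGET = "OFF_TARGET"


@dataclass(frozen=True)
class Band:
    size: int
    identity: BandIdentity
    fwd_primer: str
    rev_primer: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int


@dataclass(frozen=True)
class BandPattern:
    template_id: str
    bands: tuple[Band, ...]

    def sizes(self, identity: BandIdentity | None = None) -> list[int]:
        return [
            b.size for b in self.bands if identity is None or b.identity is identity
        ]

    def has(self, identity: BandIdentity) -> bool:
        return any(b.identity is identity for b in self.bands)


def simulate_duplex(
    templates: Sequence[SequenceRecord],
    assay: ArmsAssay,
    size_tolerance: float = 0.10,
    max_amplicon: int = 3000,
    max_total_mismatch: int = 3,
    on_short: str = "raise",
) -> list[BandPattern]:
    """Predict the duplex-PCR band pattern for each template.

    Universal primers anneal under the strict terminal rule; the ARMS
    diagnostic primer is budgeted one 3'-window mismatch (its engineered
    destabiliser) but still vetoes any terminal mismatch.  Every convergent
    forward/reverse site pair within ``max_amplicon`` yields an amplicon;
    bands are labelled CONTROL/DIAGNOSTIC when they match the assay's
    expected sizes within ``size_tolerance``, OFF_TARGET otherwise.
    """
    shortest = min(
        len(assay.universal_fwd.sequence),
        len(assay.universal_rev.sequence),
        len(assay.diagnostic.sequence),
    )
    primers = {
        assay.universal_fwd.name: (assay.universal_fwd.sequence, 0),
        assay.universal_rev.name: (assay.universal_rev.sequence, 0),
        assay.diagnostic.name: (assay.diagnostic.sequence, 1),
    }
    patterns: list[BandPattern] = []
    for rec in templates:
        template = rec.ungapped
        if len(template) < shortest:
            # degraded fragments cannot prime at all
            if on_short == "empty":
                patterns.append(BandPattern(rec.id, ()))
                continue
            raise PcrError(
                f"template {rec.id!r} is shorter than the shortest primer"
            )
        rights: list[tuple[str, AnnealSite]] = []
        lefts: list[tuple[str, AnnealSite]] = []
        for name, (seq, budget) in primers.items():
            for site in anneal_sites(
                template,
                seq,
                max_total_mismatch=max_total_mismatch,
                max_3prime_mismatch=budget,
                terminal_must_match=True,
            ):
                (rights if site.extends_right else lefts).append((name, site))
        bands: list[Band] = []
        for fname, fsite in rights:
            for rname, rsite in lefts:
                length = rsite.end - fsite.start + 1
                flen = len(primers[fname][0])
                rlen = len(primers[rname][0])
                if length < flen + rlen or length > max_amplicon:
                    continue
                ident = BandIdentity.OFF_TARGET
                if _within(length, assay.expected_control_bp, size_tolerance) and {
                    fname,
                    rname,
                } == {assay.universal_fwd.name, assay.universal_rev.name}:
                    ident = BandIdentity.CONTROL
                elif _within(
                    length, assay.expected_diagnostic_bp, size_tolerance
                ) and assay.diagnostic.name in (fname, rname):
                    ident = BandIdentity.DIAGNOSTIC
                bands.append(
                    Band(
                        size=length,
                        identity=ident,
                        fwd_primer=fname,
                        rev_primer=rname,
                        start=fsite.start,
                        end=rsite.end,
                        fwd_mismatches=fsite.mismatches,
                        rev_mismatches=rsite.mismatches,
                    )
                )
        bands.sort(key=lambda b: (-b.size, b.fwd_primer, b.rev_primer))
        patterns.append(BandPattern(rec.id, tuple(bands)))
    return patterns


def _within(size: int, expected: int, tol: float) -> bool:
    return abs(size - expected) <= tol * expected


class Call(str, enum.Enum):
    TARGET_POSITIVE = "TARGET_POSITIVE"
    TARGET_NEGATIVE = "TARGET_NEGATIVE"
    ASSAY_FAILURE = "ASSAY_FAILURE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class Verdict:
    template_id: str
    call: Call
    evidence: tuple[BandPattern, BandPattern]


def classify(
    patterns_target_assay: Sequence[BandPattern],
    patterns_nontarget_assay: Sequence[BandPattern],
) -> list[Verdict]:
    """Authentication verdict per template from the complementary assay pair.

    No control band in either assay -> ASSAY_FAILURE; a diagnostic band only
    in the PRESENCE_MEANS_TARGET assay -> TARGET_POSITIVE; only in the
    PRESENCE_MEANS_NONTARGET assay -> TARGET_NEGATIVE; in both or neither
    (with controls present) -> AMBIGUOUS.
    """
    by_a = {p.template_id: p for p in patterns_target_assay}
    by_b = {p.template_id: p for p in patterns_nontarget_assay}
    if set(by_a) != set(by_b):
        raise PcrError("the two assays cover different template sets")
    verdicts = []
    for tid in by_a:
        a, b = by_a[tid], by_b[tid]
        if not a.has(BandIdentity.CONTROL) and not b.has(BandIdentity.CONTROL):
            call = Call.ASSAY_FAILURE
        else:
            da, db = a.has(BandIdentity.DIAGNOSTIC), b.has(BandIdentity.DIAGNOSTIC)
            if da and not db:
                call = Call.TARGET_POSITIVE
            elif db and not da:
                call = Call.TARGET_NEGATIVE
            else:
                call = Call.AMBIGUOUS
        verdicts.append(Verdict(tid, call, (a, b)))
    verdicts.sort(key=lambda v: v.template_id)
    return verdicts


# ---------------------------------------------------------------------------
# virtual gel
# ---------------------------------------------------------------------------

def _default_ladder() -> list[int]:
    return list(range(100, 1100, 100))


def render_gel(
    patterns: Sequence[BandPattern],
    ladder: Sequence[int] | None = None,
    n_rows: int = 20,
) -> str:
    """Deterministic text rendering of the gel: one lane per template plus a
    size-standard lane, migration log-scaled (large fragments on top)."""
    if not patterns:
        raise PcrError("no patterns to render")
    ladder = list(ladder) if ladder is not None else _default_ladder()
    sizes = [s for p in patterns for s in p.sizes()] + ladder
    smin, smax = min(sizes), max(sizes)
    lo, hi = math.log(max(smin, 1)), math.log(max(smax, 2))
    span = hi - lo or 1.0

    def row_of(size: int) -> int:
        return round((hi - math.log(max(size, 1))) / span * (n_rows - 1))

    lane_names = ["ladder"] + [p.template_id for p in patterns]
    width = max(6, max(len(n) for n in lane_names))
    lanes: list[set[int]] = [{row_of(s) for s in ladder}] + [
        {row_of(s) for s in p.sizes()} for p in patterns
    ]
    lines = ["  ".join(n.rjust(width) for n in lane_names)]
    for row in range(n_rows):
        cells = []
        for lane in lanes:
            cells.append(("=" * width) if row in lane else (" " * width))
        lines.append("  ".join(cells))
    return "\n".join(lines)


def render_gel_svg(
    patterns: Sequence[BandPattern],
    path,
    ladder: Sequence[int] | None = None,
) -> None:
    """Render the virtual gel as an SVG image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ladder = list(ladder) if ladder is not None else _default_ladder()
    fig, ax = plt.subplots(figsize=(1 + 0.8 * (len(patterns) + 1), 4))
    lanes = [("ladder", ladder)] + [(p.template_id, p.sizes()) for p in patterns]
    for x, (name, sizes) in enumerate(lanes):
        for s in sizes:
            ax.plot([x - 0.3, x + 0.3], [s, s], lw=3, color="k")
    ax.set_yscale("log")
    ax.set_xticks(range(len(lanes)))
    ax.set_xticklabels([n for n, _ in lanes], rotation=90, fontsize=7)
    ax.set_ylabel("fragment size (bp)")
    ax.set_title("virtual gel")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
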