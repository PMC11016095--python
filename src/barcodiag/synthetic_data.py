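"""Synthetic genus-like barcode datasets with exact ground truth.

The generator emulates the data geometry of a plant-genus authentication
study: one target species plus several surrogate species evolved under
Jukes-Cantor substitutions down a small species tree, with

* conserved universal primer flanks at both ends of every record,
* planted group-private SNPs in GC-favourable and AT-rich contexts, each
  inside a *guard window* frozen to the ancestral sequence so that primer
  footprints are conserved across species,
* lineage-private insertions (e.g. a 9-bp insertion in one surrogate, or a
  ~100-bp segment distinguishing regional clades by amplicon length),
* "commercial product" samples copied from target accessions, optionally
  fragmented to emulate processed DNA.

Planted features are overwritten after the stochastic background is drawn,
and an explicit repair pass reverts any *accidental* fixed target/non-target
difference created by the background substitutions, so the planted ledger
is the exact set of diagnostic features, by construction.  Everything is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alignment import Alignment
from .seqio import Group, SequenceRecord, Source, reverse_complement

__all__ = [
    "PlantedSnp",
    "PlantedIndel",
    "SpeciesDef",
    "GenusConfig",
    "GroundTruth",
    "simulate_genus",
    "fragment_templates",
    "default_genus_config",
    "at_rich_genus_config",
    "load_genus_config",
]

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSnp:
    """A fixed private SNP: carriers get ``target_allele``, all other
    species ``other_allele`` (ancestral-sequence coordinates, 1-based)."""

    position: int
    carriers: frozenset[str]
    target_allele: str
    other_allele: str
    label: str = ""


@dataclass(frozen=True)
class PlantedIndel:
    """A segment present only in ``carriers``, inserted before
    ``position`` of the ancestral coordinate system."""

    position: int
    length: int
    carriers: frozenset[str]
    label: str = ""


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    role: Group
    n_accessions: int


# species tree: (branch_length, species_name) leaf or (branch_length, [subtrees])
TreeSpec = tuple


@dataclass(frozen=True)
class GenusConfig:
    seed: int
    barcode_length: int
    species: tuple[SpeciesDef, ...]
    tree: TreeSpec
    fwd_flank: str  # universal forward primer, as template prefix
    rev_primer: str  # universal reverse primer 5'->3' (template suffix = its revcomp)
    planted_snps: tuple[PlantedSnp, ...] = ()
    planted_indels: tuple[PlantedIndel, ...] = ()
    gc_default: float = 0.45
    gc_segments: tuple[tuple[int, int, float], ...] = ()  # (start, end, gc), 1-based
    accession_divergence: float = 0.002
    guard_radius: int = 34
    commercial_n: int = 2
    commercial_species: str | None = None
    fragmentation_mean: float | None = None

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate species names")
        flank_f, flank_r = len(self.fwd_flank), len(self.rev_primer)
        interior = range(flank_f + 1, self.barcode_length - flank_r + 1)
        used_cols: set[int] = set()
        for snp in self.planted_snps:
            if snp.position not in interior:
                raise ConfigError(f"planted SNP at {snp.position} outside the interior")
            if snp.position in used_cols:
                raise ConfigError(f"overlapping planted SNPs at {snp.position}")
            used_cols.add(snp.position)
            if not snp.carriers <= set(names):
                raise ConfigError(f"unknown species in SNP carriers {snp.carriers}")
            if snp.target_allele == snp.other_allele:
                raise ConfigError("planted SNP alleles must differ")
        for ind in self.planted_indels:
            if ind.position not in interior:
                raise ConfigError(f"planted indel at {ind.position} outside the interior")
            if ind.length < 1:
                raise ConfigError("indel length must be >= 1")
            for snp in self.planted_snps:
                if abs(snp.position - ind.position) <= self.guard_radius:
                    raise ConfigError(
                        "planted indel overlaps a planted SNP guard window"
                    )
            if not ind.carriers <= set(names):
                raise ConfigError(f"unknown species in indel carriers {ind.carriers}")

    def _gc_at(self, pos: int) -> float:
        for start, end, gc in self.gc_segments:
            if start <= pos <= end:
                return gc
        return self.gc_default


@dataclass(frozen=True)
class GroundTruth:
    """Planted features in alignment coordinates, plus the true alignment."""

    alignment: Alignment
    snps: tuple[dict, ...]  # column, carriers, target_allele, other_allele, label
    indels: tuple[dict, ...]  # start, end, length, carriers, label
    config: GenusConfig


def _jc_evolve(seq: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitution along one branch (expected subs/site)."""
    if branch_length <= 0:
        return seq.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    hit = rng.random(seq.size) < p_diff
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _evolve_tree(
    node: TreeSpec, seq: np.ndarray, rng: np.random.Generator, out: dict[str, np.ndarray]
) -> None:
    length, payload = node
    evolved = _jc_evolve(seq, float(length), rng)
    if isinstance(payload, str):
        out[payload] = evolved
    else:
        for child in payload:
            _evolve_tree(child, evolved, rng, out)


def simulate_genus(config: GenusConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate a genus dataset; returns ungapped records and the truth ledger.

    Fully deterministic for a fixed config (byte-identical across runs).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.barcode_length
    # ancestor drawn per-position from the GC profile
    gc = np.array([config._gc_at(p) for p in range(1, L + 1)])
    u = rng.random(L)
    # P(A)=P(T)=(1-gc)/2, P(C)=P(G)=gc/2
    at_half = (1 - gc) / 2
    anc = np.empty(L, dtype=int)
    anc[u < at_half] = 0  # A
    anc[(at_half <= u) & (u < 2 * at_half)] = 3  # T
    anc[(2 * at_half <= u) & (u < 2 * at_half + gc / 2)] = 1  # C
    anc[u >= 2 * at_half + gc / 2] = 2  # G
    # species-level sequences down the tree, then per-accession noise
    species_seqs: dict[str, np.ndarray] = {}
    _evolve_tree(config.tree, anc, rng, species_seqs)
    missing = {s.name for s in config.species} - set(species_seqs)
    if missing:
        raise ConfigError(f"species missing from the tree: {sorted(missing)}")

    roles = {s.name: s.role for s in config.species}
    rows: list[tuple[str, str, Group, Source, np.ndarray]] = []  # id, species, ...
    for sp in config.species:
        for k in range(1, sp.n_accessions + 1):
            acc = _jc_evolve(species_seqs[sp.name], config.accession_divergence, rng)
            rows.append((f"{sp.name}_{k:02d}", sp.name, sp.role, Source.SYNTHETIC, acc))

    # --- deterministic overwrites -------------------------------------------------
    flank_f = np.array([_BASES.tolist().index(c) for c in config.fwd_flank.upper()])
    rev_suffix = reverse_complement(config.rev_primer)
    flank_r = np.array([_BASES.tolist().index(c) for c in rev_suffix])
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for _id, _sp, _role, _src, arr in rows:
        arr[: len(flank_f)] = flank_f
        arr[L - len(flank_r) :] = flank_r
    # guard windows frozen to the ancestor; planted alleles on top
    guarded: set[int] = set()
    for snp in config.planted_snps:
        lo = max(1, snp.position - config.guard_radius)
        hi = min(L, snp.position + config.guard_radius)
        guarded.update(range(lo, hi + 1))
        for _id, sp, _role, _src, arr in rows:
            arr[lo - 1 : hi] = anc[lo - 1 : hi]
            arr[snp.position - 1] = base_idx[
                snp.target_allele if sp in snp.carriers else snp.other_allele
            ]
    # repair accidental fixed target/non-target differences in the background
    tgt_rows = [arr for _i, _s, role, _src, arr in rows if role is Group.TARGET]
    non_rows = [arr for _i, _s, role, _src, arr in rows if role is Group.NONTARGET]
    protected = guarded | set(range(1, len(flank_f) + 1)) | set(
        range(L - len(flank_r) + 1, L + 1)
    )
    if tgt_rows and non_rows:
        T = np.stack(tgt_rows)
        N = np.stack(non_rows)
        for pos in range(1, L + 1):
            if pos in protected:
                continue
            tvals = np.unique(T[:, pos - 1])
            if tvals.size != 1:
                continue
            if tvals[0] not in N[:, pos - 1]:
                non_rows[0][pos - 1] = tvals[0]

    # --- build the true alignment (insertions as private segments) ---------------
    indels = sorted(config.planted_indels, key=lambda d: d.position)
    segments: dict[int, str] = {}
    for ind in indels:
        # the inserted segment follows the local GC profile
        seg_gc = config._gc_at(min(ind.position, L))
        probs = [(1 - seg_gc) / 2, seg_gc / 2, seg_gc / 2, (1 - seg_gc) / 2]
        seg = "".join(rng.choice(_BASES, size=ind.length, p=probs))
        segments[id(ind)] = seg

    def to_row(arr: np.ndarray, sp: str) -> str:
        s = "".join(_BASES[arr])
        # insert segments right-to-left so ancestral coordinates stay valid
        for ind in reversed(indels):
            piece = segments[id(ind)] if sp in ind.carriers else "-" * ind.length
            s = s[: ind.position - 1] + piece + s[ind.position - 1 :]
        return s

    aln_records: list[SequenceRecord] = []
    records: list[SequenceRecord] = []
    for rid, sp, role, src, arr in rows:
        gapped = to_row(arr, sp)
        rec = SequenceRecord(rid, gapped, species=sp, group=role, source=src)
        aln_records.append(rec)
        records.append(rec.degap())

    # commercial products: copies of accessions of the declared species
    com_species = config.commercial_species or next(
        (s.name for s in config.species if s.role is Group.TARGET), None
    )
    if com_species and config.commercial_n:
        pool = [r for r in aln_records if r.species == com_species]
        for k in range(1, config.commercial_n + 1):
            src_rec = pool[int(rng.integers(0, len(pool)))]
            com = SequenceRecord(
                f"product_{k:02d}",
                src_rec.residues,
                species="",
                group=Group.UNKNOWN,
                source=Source.COMMERCIAL,
            )
            aln_records.append(com)
            records.append(com.degap())

    alignment = Alignment(tuple(aln_records))

    def aln_col(pos: int) -> int:
        shift = sum(ind.length for ind in indels if ind.position <= pos)
        return pos + shift

    truth_snps = tuple(
        {
            "column": aln_col(s.position),
            "carriers": s.carriers,
            "target_allele": s.target_allele,
            "other_allele": s.other_allele,
            "label": s.label,
        }
        for s in config.planted_snps
    )
    truth_indels = []
    for ind in indels:
        start = ind.position + sum(
            d.length for d in indels if d.position < ind.position
        )
        truth_indels.append(
            {
                "start": start,
                "end": start + ind.length - 1,
                "length": ind.length,
                "carriers": ind.carriers,
                "segment": segments[id(ind)],
                "label": ind.label,
            }
        )
    truth = GroundTruth(alignment, truth_snps, tuple(truth_indels), config)
    return records, truth


def fragment_templates(
    records: Sequence[SequenceRecord], mean_fragment_bp: float, seed: int
) -> list[SequenceRecord]:
    """Cut each record at uniform-random breakpoints into fragments with the
    requested mean length; fragment ids record parent and 1-based offsets."""
    if mean_fragment_bp < 50:
        raise ConfigError("mean_fragment_bp must be >= 50")
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    for rec in records:
        seq = rec.ungapped
        n_frag = max(1, round(len(seq) / mean_fragment_bp))
        if n_frag == 1:
            out.append(rec)
            continue
        cuts = sorted(rng.choice(np.arange(1, len(seq)), size=n_frag - 1, replace=False))
        bounds = [0, *map(int, cuts), len(seq)]
        for i in range(n_frag):
            lo, hi = bounds[i], bounds[i + 1]
            out.append(
                replace(
                    rec,
                    id=f"{rec.id}|frag{i + 1}|{lo + 1}-{hi}",
                    residues=seq[lo:hi],
                )
            )
    return out


def load_genus_config(path) -> GenusConfig:
    """Load a :class:`GenusConfig` from a YAML or JSON file.

    The file mirrors the dataclass fields; the species tree is written as
    nested ``[branch_length, payload]`` pairs where the payload is either a
    species name or a list of subtrees.
    """
    import json

    import yaml

    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)

    def tree_of(node):
        length, payload = node
        if isinstance(payload, str):
            return (float(length), payload)
        return (float(length), [tree_of(c) for c in payload])

    return GenusConfig(
        seed=int(data["seed"]),
        barcode_length=int(data["barcode_length"]),
        species=tuple(
            SpeciesDef(s["name"], Group(s["role"].upper()), int(s["n_accessions"]))
            for s in data["species"]
        ),
        tree=tree_of(data["tree"]),
        fwd_flank=data["fwd_flank"],
        rev_primer=data["rev_primer"],
        planted_snps=tuple(
            PlantedSnp(
                int(s["position"]), frozenset(s["carriers"]),
                s["target_allele"], s["other_allele"], s.get("label", ""),
            )
            for s in data.get("planted_snps", [])
        ),
        planted_indels=tuple(
            PlantedIndel(
                int(d["position"]), int(d["length"]), frozenset(d["carriers"]),
                d.get("label", ""),
            )
            for d in data.get("planted_indels", [])
        ),
        gc_default=float(data.get("gc_default", 0.45)),
        gc_segments=tuple(
            (int(a), int(b), float(g)) for a, b, g in data.get("gc_segments", [])
        ),
        accession_divergence=float(data.get("accession_divergence", 0.002)),
        guard_radius=int(data.get("guard_radius", 34)),
        commercial_n=int(data.get("commercial_n", 2)),
        commercial_species=data.get("commercial_species"),
        fragmentation_mean=data.get("fragmentation_mean"),
    )


# ---------------------------------------------------------------------------
# default study geometries
# ---------------------------------------------------------------------------

_DEFAULT_TREE: TreeSpec = (
    0.0,
    [
        (0.02, [(0.0, "tgt"), (0.04, "pere")]),
        (0.03, [(0.03, "afr1"), (0.03, "afr2")]),
        (0.25, "out"),
    ],
)

_DEFAULT_SPECIES = (
    SpeciesDef("tgt", Group.TARGET, 4),
    SpeciesDef("pere", Group.NONTARGET, 2),
    SpeciesDef("afr1", Group.NONTARGET, 3),
    SpeciesDef("afr2", Group.NONTARGET, 3),
    SpeciesDef("out", Group.OUTGROUP, 2),
)


def default_genus_config(seed: int = 0, **overrides) -> GenusConfig:
    """A ~950-bp coding-marker geometry: GC-favourable private SNPs placed so
    the target-diagnostic amplicon lands near 650 bp and the complementary
    (non-target) amplicon near 800 bp, an AT-rich decoy SNP that must fail
    the ARMS context screen, and a 9-bp insertion private to one surrogate."""
    cfg = GenusConfig(
        seed=seed,
        barcode_length=950,
        species=_DEFAULT_SPECIES,
        tree=_DEFAULT_TREE,
        fwd_flank="TCTCGACGAAAATCAGATTGTTG",
        rev_primer="ATACATGTCCAAAGTGATGGAAA",
        planted_snps=(
            PlantedSnp(628, frozenset({"tgt"}), "G", "T", label="gc_target"),
            PlantedSnp(778, frozenset({"tgt"}), "C", "A", label="gc_second"),
            PlantedSnp(420, frozenset({"tgt"}), "A", "T", label="at_decoy"),
        ),
        planted_indels=(
            PlantedIndel(300, 9, frozenset({"pere"}), label="pere_9bp"),
        ),
        gc_segments=((380, 460, 0.10),),
    )
    return replace(cfg, **overrides) if overrides else cfg


def at_rich_genus_config(seed: int = 0, **overrides) -> GenusConfig:
    """A ~550-bp AT-rich spacer-marker geometry (~75% AT): target-private
    substitutions at positions 320 and 381 in AT-rich context (ARMS-
    infeasible), a ~100-bp segment private to the regional surrogate clade
    (amplicon-length polymorphism, ~550 vs ~450 bp) and a 9-bp insertion
    private to one surrogate."""
    cfg = GenusConfig(
        seed=seed,
        barcode_length=450,
        species=_DEFAULT_SPECIES,
        tree=_DEFAULT_TREE,
        fwd_flank="GTTATGCATGAACGTAATGCTC",
        rev_primer="CGCGCATGGTGGATTCACAATCC",
        planted_snps=(
            PlantedSnp(320, frozenset({"tgt"}), "C", "T", label="at_320"),
            PlantedSnp(381, frozenset({"tgt"}), "A", "G", label="at_381"),
        ),
        planted_indels=(
            PlantedIndel(416, 100, frozenset({"afr1", "afr2"}), label="african_100bp"),
            PlantedIndel(421, 9, frozenset({"pere"}), label="pere_9bp"),
        ),
        gc_default=0.27,
        gc_segments=((286, 415, 0.12),),
    )
    return replace(cfg, **overrides) if overrides else cfg
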