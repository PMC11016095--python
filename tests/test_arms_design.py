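"""ARMS primer construction, melting temperatures and duplex assemblies."""

import numpy as np
import pytest

import barcodiag as bd
from barcodiag.alignment import PrimerRole, PrimerSpec, Strand
from barcodiag.arms_design import (
    DesignError,
    Polarity,
    TmConditions,
    TmMethod,
    design_diagnostic_primer,
    melting_temperature,
)
from barcodiag.seqio import Group, iupac_match, reverse_complement
from conftest import make_alignment

T, N = Group.TARGET, Group.NONTARGET


def _site_alignment(target_allele="G", other_allele="T", col=101):
    rng = np.random.default_rng(17)
    context = "".join(rng.choice(list("ACGT"), size=201))
    t = context[: col - 1] + target_allele + context[col:]
    n = context[: col - 1] + other_allele + context[col:]
    aln = make_alignment(
        {"t0": t, "t1": t, "n0": n, "n1": n},
        groups={"t0": T, "t1": T, "n0": N, "n1": N},
    )
    (site,) = [s for s in bd.scan_diagnostic_snps(aln) if s.column == col]
    return aln, site


class TestMeltingTemperature:
    @pytest.mark.parametrize("seq,expected", [("AAAA", 8.0), ("GGGG", 16.0)])
    def test_wallace_rule(self, seq, expected):
        assert melting_temperature(seq, TmMethod.WALLACE) == expected

    def test_wallace_ambiguity_midpoint(self):
        # R = {A,G} -> (2+4)/2 = 3
        assert melting_temperature("R", TmMethod.WALLACE) == 3.0

    def test_nn_matches_independent_dh_ds_evaluation(self):
        # hand evaluation with the unified dinucleotide table for ATGCAA
        # steps: AT, TG, GC, CA, AA; ends: A/T + A/T
        dh = 2.3 + 2.3 + (-7.2) + (-8.5) + (-9.8) + (-8.5) + (-7.9)
        ds = 4.1 + 4.1 + (-20.4) + (-22.7) + (-24.4) + (-22.7) + (-22.2)
        import math

        ds_salt = ds + 0.368 * 5 * math.log(0.05)
        expected = dh * 1000 / (ds_salt + 1.987 * math.log(250e-9)) - 273.15
        got = melting_temperature("ATGCAA", TmMethod.NN_SANTALUCIA)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_nn_agrees_with_biopython_reference(self):
        from Bio.SeqUtils import MeltingTemp as mt

        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 31))))
            mine = melting_temperature(seq, TmMethod.NN_SANTALUCIA)
            ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=250, dnac2=0,
                           saltcorr=5)
            assert mine == pytest.approx(ref, abs=0.1)

    def test_ambiguous_sequence_rejected_for_nn(self):
        with pytest.raises(DesignError):
            melting_temperature("ACGTN", TmMethod.NN_SANTALUCIA)

    def test_both_methods_monotone_in_gc_at_fixed_length(self):
        seqs = ["ATATATATATATATATATAT", "ATATGCATATATGCATATAT",
                "GCGCGCATATATGCGCGCAT", "GCGCGCGCGCGCGCGCGCGC"]
        for method in (TmMethod.WALLACE, TmMethod.NN_SANTALUCIA):
            tms = [melting_temperature(s, method) for s in seqs]
            assert tms == sorted(tms)


def _mismatches_vs_template(primer, template_window, strand):
    """Mismatch count of a primer against a plus-strand template window whose
    last/first position sits under the primer's 3' terminus."""
    if strand == Strand.MINUS:
        aligned = reverse_complement(primer)  # plus-strand sense, 3' at idx 0
        return [
            i for i in range(len(aligned)) if not iupac_match(aligned[i], template_window[i])
        ]
    return [
        i for i in range(len(primer)) if not iupac_match(primer[i], template_window[i])
    ]


class TestDesignDiagnosticPrimer:
    def test_minus_strand_terminal_base_pairs_target_allele(self):
        aln, site = _site_alignment("G", "T")
        primer = design_diagnostic_primer(aln, site, strand=Strand.MINUS)
        assert primer.sequence[-1] == "C"  # pairs template G
        assert primer.destabilizer[0] == 3
        assert primer.destabilizer[1] != primer.destabilizer[2]

    def test_discriminating_architecture_mismatch_counts(self):
        """One engineered mismatch vs the intended template; >=2 of the
        3'-terminal three bases mismatch the other group's template."""
        aln, site = _site_alignment("G", "T")
        primer = design_diagnostic_primer(aln, site, strand=Strand.MINUS)
        L = len(primer.sequence)
        t_cons = bd.consensus_sequence(
            aln, [r for r in aln.records if r.group is T]
        )
        n_cons = bd.consensus_sequence(
            aln, [r for r in aln.records if r.group is N]
        )
        col0 = site.column - 1
        own_window = t_cons[col0 : col0 + L]
        other_window = n_cons[col0 : col0 + L]
        mm_own = _mismatches_vs_template(primer.sequence, own_window, Strand.MINUS)
        mm_other = _mismatches_vs_template(primer.sequence, other_window, Strand.MINUS)
        assert len(mm_own) == 1 and mm_own[0] == 2  # only the -3 destabiliser
        assert sum(1 for i in mm_other if i < 3) >= 2  # terminal + destabiliser

    def test_plus_strand_design(self):
        aln, site = _site_alignment("G", "T")
        primer = design_diagnostic_primer(aln, site, strand=Strand.PLUS)
        assert primer.sequence[-1] == "G"  # reads the target allele directly
        t_cons = bd.consensus_sequence(aln, [r for r in aln.records if r.group is T])
        window = t_cons[site.column - len(primer) : site.column]
        mm = _mismatches_vs_template(primer.sequence, window, Strand.PLUS)
        assert mm == [len(primer) - 3]

    def test_nontarget_polarity_reads_other_allele(self):
        aln, site = _site_alignment("G", "T")
        primer = design_diagnostic_primer(
            aln, site, Polarity.PRESENCE_MEANS_NONTARGET, strand=Strand.MINUS
        )
        assert primer.sequence[-1] == "A"  # pairs template T

    def test_design_is_deterministic(self):
        aln, site = _site_alignment("G", "T")
        p1 = design_diagnostic_primer(aln, site)
        p2 = design_diagnostic_primer(aln, site)
        assert p1 == p2

    def test_unreachable_tm_range_errors(self):
        aln, site = _site_alignment("G", "T")
        with pytest.raises(DesignError, match="Tm|length"):
            design_diagnostic_primer(aln, site, tm_range=(95.0, 99.0))

    def test_polymorphic_nontarget_rejected_for_nontarget_polarity(self):
        rng = np.random.default_rng(23)
        context = "".join(rng.choice(list("ACGT"), size=121))
        col = 61
        t = context[: col - 1] + "G" + context[col:]
        n1 = context[: col - 1] + "T" + context[col:]
        n2 = context[: col - 1] + "C" + context[col:]
        aln = make_alignment(
            {"t0": t, "n0": n1, "n1": n2},
            groups={"t0": T, "n0": N, "n1": N},
        )
        (site,) = [s for s in bd.scan_diagnostic_snps(aln) if s.column == col]
        with pytest.raises(DesignError, match="non-target"):
            design_diagnostic_primer(aln, site, Polarity.PRESENCE_MEANS_NONTARGET)


class TestBuildDuplexAssay:
    def test_expected_band_sizes_from_planted_geometry(self, genus, genus_assays):
        assay_a, assay_b = genus_assays
        assert assay_a.expected_control_bp == 950
        assert assay_a.expected_diagnostic_bp == pytest.approx(650, abs=30)
        assert assay_b.expected_diagnostic_bp == pytest.approx(800, abs=30)

    def test_unresolvable_bands_rejected(self, genus):
        cfg, _, truth = genus
        aln = truth.alignment
        # anchor a diagnostic primer right next to the universal site: the
        # amplicon would nearly coincide with the control band
        sites = bd.scan_diagnostic_snps(aln)
        site = sites[-1]
        fwd = PrimerSpec("f", cfg.fwd_flank, PrimerRole.UNIVERSAL_FWD, Strand.PLUS)
        rev = PrimerSpec("r", cfg.rev_primer, PrimerRole.UNIVERSAL_REV, Strand.MINUS)
        primer = design_diagnostic_primer(aln, site, strand=Strand.MINUS)
        with pytest.raises(DesignError, match="separation"):
            bd.build_duplex_assay(
                aln, fwd, rev, primer, min_band_separation=500
            )

    def test_complementary_pair_polarity_and_usability(self, genus_assays):
        assay_a, assay_b = genus_assays
        assert assay_a.polarity is Polarity.PRESENCE_MEANS_TARGET
        assert assay_b.polarity is Polarity.PRESENCE_MEANS_NONTARGET
        assert assay_a.diagnostic.sequence != assay_b.diagnostic.sequence
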