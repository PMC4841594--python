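"""Bisulfite conversion, enzyme classification, digestion and calling."""

import warnings

import numpy as np
import pytest

from ecrfoot.cobra import (DEFAULT_ENZYME_LIBRARY, CobraDesignError, BandTable,
                           EnzymeSpec, METHYLATION_INDICATING,
                           UNMETHYLATION_INDICATING, UNINFORMATIVE,
                           bisulfite_convert, call_delta, classify_enzyme,
                           digest, expected_fragments, in_silico_pcr,
                           quantify_methylation)
from ecrfoot.seqs import cpg_positions
from ecrfoot.synthetic import generate_cobra_gel

from conftest import random_dna
from oracles import brute_digest

ENZYMES = {e.name: e for e in DEFAULT_ENZYME_LIBRARY}


class TestBisulfiteConvert:
    def test_all_cs_convert_without_methylation(self):
        assert bisulfite_convert("ACCGT") == "ATTGT"

    def test_methylated_cpg_c_is_retained(self):
        assert bisulfite_convert("ACCGT", {2}) == "ATCGT"

    def test_sequence_without_c_unchanged(self):
        assert bisulfite_convert("AGTGA") == "AGTGA"

    def test_conversion_is_idempotent(self, rng):
        seq = random_dna(rng, 100)
        once = bisulfite_convert(seq)
        assert bisulfite_convert(once) == once

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValueError, match="not a CpG"):
            bisulfite_convert("ACCGT", {1})

    def test_bottom_strand_converts_its_own_sense(self):
        # bottom strand of ACG(top) is CGT; its CpG C maps through the
        # palindromic CpG
        assert bisulfite_convert("TACGA", set(), strand="bottom") == "TTGTA"
        assert bisulfite_convert("TACGA", {2}, strand="bottom") == "TCGTA"


class TestInSilicoPCR:
    def _template(self, rng):
        left = random_dna(rng, 40).replace("CG", "CA")
        right = random_dna(rng, 40).replace("CG", "CA")
        return bisulfite_convert(left + "TTACGTT" + right, {len(left) + 3})

    def test_amplicon_spans_primers_inclusive(self, rng):
        tmpl = self._template(rng)
        amp, start, end = in_silico_pcr(tmpl, tmpl[5:25], tmpl[-25:-5][::-1].translate(
            str.maketrans("ACGT", "TGCA")))
        assert amp == tmpl[5:len(tmpl) - 5]
        assert (start, end) == (5, len(tmpl) - 5)

    def test_primer_overlapping_cpg_rejected(self, rng):
        left = random_dna(rng, 40).replace("CG", "CA")
        right = random_dna(rng, 40).replace("CG", "CA")
        seq = left + "TTACGTT" + right
        cpg = cpg_positions(seq)
        tmpl = bisulfite_convert(seq, set(cpg))
        fwd = tmpl[40:60]  # covers the CpG
        rev = tmpl[-20:][::-1].translate(str.maketrans("ACGT", "TGCA"))
        with pytest.raises(CobraDesignError, match="CpG in primer"):
            in_silico_pcr(tmpl, fwd, rev, cpg_positions_template=cpg)

    def test_nonunique_primer_rejected(self):
        tmpl = ("ATTAGGTTAGGATTTA" * 2) + "TTTTAAAT"
        with pytest.raises(CobraDesignError, match="non-unique"):
            in_silico_pcr(tmpl, "ATTAGGTTAGG", "ATTTAAAA")

    def test_absent_primer_rejected(self):
        with pytest.raises(CobraDesignError, match="not found"):
            in_silico_pcr("ATTAGGTTAGGATTTA", "GGGGGG", "AAAT")


class TestClassifyEnzyme:
    def test_fok1_site_completed_by_conversion_indicates_unmethylation(self):
        # unmethylated conversion turns GGACG -> GGATG (FokI site)
        amp = "TTAAT" + "GGACG" + "ATTATTAAGGATTTAATT"
        cls, assayed = classify_enzyme(ENZYMES["FokI"], amp)
        assert cls == UNMETHYLATION_INDICATING
        assert assayed == [8]

    def test_taq1_site_requires_retained_cpg_indicates_methylation(self):
        amp = "TTAAT" + "TCGA" + "ATTATTAAGGATTTAATT"
        cls, assayed = classify_enzyme(ENZYMES["TaqI"], amp)
        assert cls == METHYLATION_INDICATING
        assert assayed == [6]

    def test_cpg_free_amplicon_is_uninformative(self):
        amp = "TTAATGTATTATTAAGGATTTAATT"
        cls, assayed = classify_enzyme(ENZYMES["TaqI"], amp)
        assert cls == UNINFORMATIVE and assayed == []

    def test_class_is_derived_not_taken_from_label(self):
        # HphI (nominally TG-class) on an amplicon where its site GGTGA
        # exists regardless of methylation: uninformative here
        amp = "TTAAT" + "GGTGA" + "TTATTAAGGATTTAATT"
        cls, _ = classify_enzyme(ENZYMES["HphI"], amp)
        assert cls == UNINFORMATIVE


class TestDigest:
    def test_single_cut_splits_amplicon(self):
        amp = ("T" * 117 + "TCGA" + "T" * 179)  # TaqI cuts after T at 118
        frags = digest(amp, ENZYMES["TaqI"], {118})
        assert sorted(frags) == [118, 182]

    def test_no_sites_returns_full_length(self):
        amp = "TA" * 150
        assert digest(amp, ENZYMES["TaqI"]) == [300]

    def test_cut_outside_amplicon_skipped_with_warning(self):
        amp = "GGATG" + "AAA"  # FokI cut lands 9 bp past the site end
        with pytest.warns(UserWarning, match="outside amplicon"):
            assert digest(amp, ENZYMES["FokI"]) == [8]

    def test_fragments_match_position_scan_oracle(self, rng):
        for _ in range(100):
            amp = random_dna(rng, int(rng.integers(60, 200)))
            enz = DEFAULT_ENZYME_LIBRARY[int(rng.integers(len(DEFAULT_ENZYME_LIBRARY)))]
            cpgs = cpg_positions(amp)
            meth = {p for p in cpgs if rng.random() < 0.5}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = digest(amp, enz, meth)
                expected = brute_digest(amp, enz.recognition, enz.cut_offset, meth)
            assert got == expected
            assert sum(got) == len(amp)


class TestQuantify:
    AMP = "T" * 117 + "TCGA" + "T" * 179  # one TaqI-assayed CpG at 118

    def _uf(self):
        return expected_fragments(self.AMP, ENZYMES["TaqI"])

    def test_equal_band_intensities_give_50_percent(self):
        u, m = self._uf()
        bands = BandTable((118, 182, 300), (50.0, 50.0, 50.0), enzyme="TaqI")
        pct = quantify_methylation(bands, METHYLATION_INDICATING, m, u)
        assert pct == pytest.approx(50.0)

    def test_fully_digested_tg_class_is_zero_methylation(self):
        bands = BandTable((118, 182), (80.0, 80.0))
        pct = quantify_methylation(bands, UNMETHYLATION_INDICATING, [118, 182], [300])
        assert pct == 0.0

    def test_boundary_fractions_recover_exactly_at_zero_noise(self):
        u, m = self._uf()
        for frac, expect in ((0.0, 0.0), (1.0, 100.0)):
            bands, _ = generate_cobra_gel(self.AMP, frac, ENZYMES["TaqI"],
                                          n_molecules=500, noise_sd=0.0, seed=1)
            pct = quantify_methylation(bands, METHYLATION_INDICATING, m, u)
            assert pct == pytest.approx(expect)

    def test_simulated_gel_recovers_true_fraction(self):
        """At 10,000 molecules and 2% densitometry noise the estimate is
        within Monte-Carlo tolerance (+/-3 points) of the truth."""
        u, m = self._uf()
        bands, _ = generate_cobra_gel(self.AMP, 0.3, ENZYMES["TaqI"],
                                      n_molecules=10_000, noise_sd=0.02, seed=4)
        pct = quantify_methylation(bands, METHYLATION_INDICATING, m, u)
        assert abs(pct - 30.0) < 3.0

    def test_opposite_class_enzymes_agree(self):
        """A methylation-indicating and an unmethylation-indicating
        enzyme estimate the same fraction from the same molecules."""
        amp = ("TTAAT" + "GGACG" + "TTATTAAGGATT" + "TAT" + "T" * 60
               + "TTCGAA" + "T" * 30)
        fok_cls, _ = classify_enzyme(ENZYMES["FokI"], amp)
        taq_cls, _ = classify_enzyme(ENZYMES["TaqI"], amp)
        assert {fok_cls, taq_cls} == {UNMETHYLATION_INDICATING,
                                      METHYLATION_INDICATING}
        results = {}
        for name, cls in (("FokI", fok_cls), ("TaqI", taq_cls)):
            u, m = expected_fragments(amp, ENZYMES[name])
            dig, undig = (m, u) if cls == METHYLATION_INDICATING else (u, m)
            bands, _ = generate_cobra_gel(amp, 0.4, ENZYMES[name],
                                          n_molecules=20_000, noise_sd=0.0, seed=9)
            results[name] = quantify_methylation(bands, cls, dig, undig)
        assert results["FokI"] == pytest.approx(results["TaqI"], abs=2.0)

    def test_unassignable_band_rejected(self):
        u, m = self._uf()
        bands = BandTable((50,), (10.0,))
        with pytest.raises(ValueError, match="no expected fragment"):
            quantify_methylation(bands, METHYLATION_INDICATING, m, u)


class TestCallDelta:
    def test_clear_increase_called_hypermethylation(self):
        call = call_delta([58, 62, 60], [4, 6, 5])
        assert call.verdict == "hypermethylation"
        assert call.delta == pytest.approx(55.0)

    def test_clear_decrease_called_hypomethylation(self):
        assert call_delta([4, 6, 5], [58, 62, 60]).verdict == "hypomethylation"

    def test_identical_groups_unchanged(self):
        assert call_delta([50, 50, 50], [50, 50, 50]).verdict == "unchanged"

    def test_small_difference_blocked_by_min_delta(self):
        call = call_delta([55, 56, 54], [50, 51, 49], min_delta=10)
        assert call.verdict == "unchanged"

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            call_delta([50], [40, 41])

    def test_noise_only_false_positive_rate_near_alpha(self):
        """With equal true means and min_delta disabled, the call rate
        approaches the test's alpha (within 3 binomial SD)."""
        rng = np.random.default_rng(11)
        alpha, n_trials = 0.05, 1000
        fp = sum(
            call_delta(list(rng.normal(50, 5, 3)), list(rng.normal(50, 5, 3)),
                       alpha=alpha, min_delta=0.0).verdict != "unchanged"
            for _ in range(n_trials))
        sd = np.sqrt(alpha * (1 - alpha) / n_trials)
        assert abs(fp / n_trials - alpha) < 3 * sd
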