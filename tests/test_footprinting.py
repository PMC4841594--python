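"""Reference-anchored alignment, invariant regions and motif scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecrfoot.footprinting import (DEFAULT_MOTIF_LIBRARY, Motif, MultipleAlignment,
                                  align_ortholog_set, find_invariant_regions,
                                  motif_frequency_matrix, scan_motifs)
from ecrfoot.seqs import reverse_complement
from ecrfoot.synthetic import SimulationConfig, generate_ortholog_set

from conftest import random_dna
from oracles import brute_motif_scan, column_scan_footprints


def _msa(rows, species=None, reference=None):
    species = species or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(species=species, rows=rows,
                             reference=reference or species[0],
                             ref_gap_columns=np.zeros(len(rows[0]), dtype=bool))


class TestAlignOrthologSet:
    def test_identical_sequences_have_no_variant_columns(self, rng):
        seq = random_dna(rng, 80)
        msa = align_ortholog_set({f"s{i}": seq for i in range(5)}, "s0")
        mat = msa.column_matrix()
        assert (mat == mat[0]).all()

    def test_single_substitution_gives_one_variant_column(self, rng):
        seq = random_dna(rng, 60)
        mutated = seq[:30] + ("A" if seq[30] != "A" else "C") + seq[31:]
        msa = align_ortholog_set({"ref": seq, "x": seq, "y": mutated}, "ref")
        mat = msa.column_matrix()
        variant = (~(mat == mat[0]).all(axis=0)).sum()
        assert variant == 1

    def test_rows_ungap_to_inputs(self, rng):
        seqs, _ = generate_ortholog_set(SimulationConfig(
            seed=3, n_species=4, substitution_rate=0.05, indel_rate=0.01,
            ancestral_length=150))
        msa = align_ortholog_set(seqs, "species1")
        for sp in msa.species:
            assert msa.row(sp).replace("-", "") == seqs[sp]

    def test_variant_fraction_matches_binomial_expectation(self):
        """Under independent lineages at rate r, a column is invariant
        with probability ((1-r)^k + sum over bases of P(all k mutate to
        same base)); for small r the variant fraction is within 3
        binomial SD of 1-(1-r)^k."""
        rate, k, length = 0.05, 6, 2000
        seqs, _ = generate_ortholog_set(SimulationConfig(
            seed=9, n_species=k, substitution_rate=rate,
            ancestral_length=length))
        msa = align_ortholog_set(seqs, "species1")
        mat = msa.column_matrix()
        variant = float((~(mat == mat[0]).all(axis=0)).mean())
        # P(column unchanged in every lineage); same-target convergence
        # contributes < 1e-3 at this rate
        p_expected = 1 - (1 - rate) ** k
        sd = np.sqrt(p_expected * (1 - p_expected) / length)
        assert abs(variant - p_expected) < 3 * sd + 3e-3

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            align_ortholog_set({"a": "ACGT", "b": "ACGT"}, "zz")


class TestInvariantRegions:
    def test_all_identical_alignment_is_one_region(self):
        msa = _msa(["ACGTACGTACGTACGTACGTACGTACGTAC"] * 4)
        (region,) = find_invariant_regions(msa, 6)
        assert (region.col_start, region.col_end) == (0, 30)

    def test_single_variant_splits_region(self):
        row = "ACGTACGTACGTACGTACGTACGTACGTAC"
        variant = row[:10] + "T" + row[11:]
        regions = find_invariant_regions(_msa([row, row, variant]), 6)
        assert [(r.col_start, r.col_end) for r in regions] == [(0, 10), (11, 30)]

    def test_matches_column_scan_oracle_on_random_alignments(self, rng):
        for _ in range(100):
            ncol = int(rng.integers(10, 51))
            nrow = int(rng.integers(2, 6))
            base = list(random_dna(rng, ncol))
            rows = []
            for _r in range(nrow):
                row = base.copy()
                for c in range(ncol):
                    u = rng.random()
                    if u < 0.1:
                        row[c] = "-"
                    elif u < 0.25:
                        row[c] = random_dna(rng, 1)
                rows.append("".join(row))
            min_len = int(rng.integers(1, 8))
            got = [(r.col_start, r.col_end)
                   for r in find_invariant_regions(_msa(rows), min_len)]
            assert got == column_scan_footprints(rows, min_len)

    def test_planted_motif_lies_inside_a_footprint(self):
        """A motif copied unmutated into every species is always inside
        an invariant region when flanks diverge."""
        for seed in range(10):
            seqs, truth = generate_ortholog_set(SimulationConfig(
                seed=seed, n_species=10, substitution_rate=0.1,
                ancestral_length=200, planted_motifs=[("CAGCTG", 80)]))
            msa = align_ortholog_set(seqs, "species1")
            regions = find_invariant_regions(msa, 6)
            assert any(r.ref_start <= 80 and r.ref_end >= 86 for r in regions)


class TestScanMotifs:
    def test_palindromic_ebox_counted_once(self):
        hits = scan_motifs("TTCAGCTGTT")
        ebox = [h for h in hits if h.motif == "E_box"]
        assert len(ebox) == 1
        assert (ebox[0].offset, ebox[0].strand) == (2, "+")

    def test_pitx2_reverse_spelling_is_minus_strand_hit(self):
        hits = [h for h in scan_motifs("AATAATCCCAA") if h.motif == "PITX2"]
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_n_in_sequence_never_matches(self):
        assert [h for h in scan_motifs("TTCAGNTGTT") if h.motif == "E_box"] == []

    def test_invalid_iupac_pattern_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motifs("ACGT", [Motif("bad", "CAGX")])

    def test_inconsistent_revcomp_spelling_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Motif("PITX2", "GGGATTA", "TAATCCG")

    def test_matches_bruteforce_scan_on_random_sequences(self, rng):
        for _ in range(50):
            seq = random_dna(rng, 200)
            got = {(h.motif, h.offset, h.strand) for h in scan_motifs(seq)}
            expected = set()
            for m in DEFAULT_MOTIF_LIBRARY:
                for off, strand in brute_motif_scan(seq, m.pattern):
                    expected.add((m.name, off, strand))
            assert got == expected

    def test_strand_consistency_under_reverse_complement(self, rng):
        """Scanning the reverse complement swaps strands and reflects
        offsets; counts are unchanged."""
        for _ in range(20):
            seq = random_dna(rng, 150)
            fwd = scan_motifs(seq)
            rev = scan_motifs(reverse_complement(seq))
            assert len(fwd) == len(rev)
            lib = {m.name: m for m in DEFAULT_MOTIF_LIBRARY}
            mapped = {(h.motif,
                       len(seq) - h.offset - len(lib[h.motif].pattern),
                       h.strand if lib[h.motif].is_palindromic
                       else {"+": "-", "-": "+"}[h.strand])
                      for h in rev}
            assert mapped == {(h.motif, h.offset, h.strand) for h in fwd}


class TestMotifFrequencyMatrix:
    def _hits(self, n):
        from ecrfoot.footprinting import MotifHit
        return [MotifHit("E_box", 0, "+")] * n

    def test_printed_survey_example_34_hits_20_species(self):
        """34 occurrences over 20 available orthologs average 1.7 per
        species and flag as enriched."""
        per_species = {f"s{i}": self._hits(2) for i in range(14)}
        per_species |= {f"s{i}": self._hits(1) for i in range(14, 20)}
        df = motif_frequency_matrix({"ECR18": per_species})
        row = df[(df.element == "ECR18") & (df.motif == "E_box")].iloc[0]
        assert row.total_hits == 34
        assert row.n_species_with_sequence == 20
        assert row.ratio == pytest.approx(1.7)
        assert bool(row.enriched)

    def test_zero_hits_not_enriched(self):
        df = motif_frequency_matrix({"e": {"s1": [], "s2": []}})
        assert not df.enriched.any()
        assert (df.ratio == 0).all()

    def test_ratio_exactly_half_not_enriched(self):
        """The enrichment rule is strict: ratio 0.5 does not qualify."""
        per_species = {f"s{i}": self._hits(1) for i in range(10)}
        per_species |= {f"s{i}": [] for i in range(10, 20)}
        df = motif_frequency_matrix({"e": per_species})
        row = df[df.motif == "E_box"].iloc[0]
        assert row.ratio == pytest.approx(0.5)
        assert not bool(row.enriched)

    def test_totals_are_sums_over_species(self, rng):
        counts = {f"s{i}": self._hits(int(rng.integers(0, 4))) for i in range(8)}
        df = motif_frequency_matrix({"e": counts})
        row = df[df.motif == "E_box"].iloc[0]
        assert row.total_hits == sum(len(v) for v in counts.values())

    def test_empty_species_set_rejected(self):
        with pytest.raises(ValueError, match="no scanned species"):
            motif_frequency_matrix({"e": {}})
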