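"""Pairwise alignment, conserved-element calling and ortholog search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecrfoot.conservation import (ConservationParams, build_presence_matrix,
                                  call_conserved_elements, find_conserved_elements,
                                  ortholog_search, pairwise_align)
from ecrfoot.synthetic import SimulationConfig, generate_genome_pair

from conftest import random_dna
from oracles import gotoh_score

DNA = st.text(alphabet="ACGT", min_size=1, max_size=15)
DNA_N = st.text(alphabet="ACGTN", min_size=1, max_size=15)


class TestPairwiseAlign:
    def test_identical_40mers_gapless_full_score(self):
        seq = "ACGTACGTAC" * 4
        aln = pairwise_align(seq, seq, mode="local")
        assert aln.score == 40  # 40 x match(+1)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_ref + aln.aligned_query

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_align("", "ACGT")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            pairwise_align("ACGT", "ACXT")

    def test_n_never_scores_as_match(self):
        aln = pairwise_align("ANNNA", "ANNNA", mode="global")
        assert aln.match_flags.sum() == 2  # only the two A columns

    @given(a=DNA_N, b=DNA_N, mode=st.sampled_from(["local", "global"]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_score_matches_bruteforce_dp(self, a, b, mode):
        """Optimality: identical score to an independent Gotoh DP on
        all short inputs."""
        assert pairwise_align(a, b, mode=mode).score == pytest.approx(
            gotoh_score(a, b, mode=mode))

    def test_seeded_random_cases_match_oracle(self, rng):
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(1, 16)), with_n=True)
            b = random_dna(rng, int(rng.integers(1, 16)), with_n=True)
            aln = pairwise_align(a, b, mode="local")
            assert aln.score == pytest.approx(gotoh_score(a, b, mode="local"))


class TestCallConservedElements:
    def test_identical_pair_is_single_full_length_element(self):
        seq = random_dna(np.random.default_rng(0), 100)
        aln = pairwise_align(seq, seq, mode="global")
        (elem,) = call_conserved_elements(aln)
        assert (elem.interval_ref.start, elem.interval_ref.end) == (0, 100)
        assert elem.identity == 1.0

    def test_exactly_50bp_not_called_strict_inequality(self):
        """A fully identical block of exactly the threshold length must
        NOT be called: the rule is strictly 'longer than'."""
        seq = random_dna(np.random.default_rng(1), 50)
        aln = pairwise_align(seq, seq, mode="global")
        assert call_conserved_elements(aln) == []

    def test_51bp_called(self):
        seq = random_dna(np.random.default_rng(2), 51)
        aln = pairwise_align(seq, seq, mode="global")
        assert len(call_conserved_elements(aln)) == 1

    def test_planted_blocks_recovered_with_reciprocal_overlap(self):
        cfg = SimulationConfig(seed=11, n_elements=3, element_identity=0.85)
        a, b, truth = generate_genome_pair(cfg)
        elements = find_conserved_elements(a, b, ref_name="genomeA",
                                           query_name="genomeB")
        assert len(elements) == 3
        for t in truth.elements_ref:
            assert any(e.interval_ref.reciprocal_overlap(t) >= 0.8
                       for e in elements)

    def test_symmetry_under_sequence_swap(self):
        cfg = SimulationConfig(seed=5, n_elements=2, element_identity=0.9)
        a, b, _ = generate_genome_pair(cfg)
        fwd = find_conserved_elements(a, b)
        rev = find_conserved_elements(b, a)
        assert len(fwd) == len(rev)
        for ef, er in zip(fwd, rev):
            # swapped roles: intervals agree within alignment tie-break slack
            assert abs(ef.interval_ref.start - er.interval_query.start) <= 5
            assert abs(ef.interval_query.start - er.interval_ref.start) <= 5

    def test_threshold_relaxation_never_loses_coverage(self):
        """Lowering min_identity or min_length keeps every stricter
        element covered by some looser element."""
        cfg = SimulationConfig(seed=7, n_elements=3, element_identity=0.9)
        a, b, _ = generate_genome_pair(cfg)
        strict = find_conserved_elements(
            a, b, ConservationParams(min_length=60, min_identity=0.8))
        loose = find_conserved_elements(
            a, b, ConservationParams(min_length=50, min_identity=0.75))
        for e in strict:
            assert any(l.interval_ref.overlap_length(e.interval_ref)
                       >= 0.9 * e.interval_ref.length for l in loose)


class TestOrthologSearch:
    def test_exact_substring_found_at_offset(self, rng):
        target = random_dna(rng, 400)
        probe = target[100:160]
        (hit,) = ortholog_search(probe, target)
        assert (hit.interval.start, hit.interval.end) == (100, 160)
        assert hit.identity == 1.0 and hit.strand == "+"

    def test_reverse_strand_hit_found(self, rng):
        from ecrfoot.seqs import reverse_complement
        target = random_dna(rng, 400)
        probe = reverse_complement(target[100:160])
        (hit,) = ortholog_search(probe, target)
        assert hit.strand == "-"
        assert (hit.interval.start, hit.interval.end) == (100, 160)

    def test_mismatched_copy_scores_like_smith_waterman(self, rng):
        target = random_dna(rng, 300)
        probe = list(target[80:180])
        for pos in rng.choice(100, size=10, replace=False):  # 10% mismatches
            probe[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[probe[pos]]
        probe = "".join(probe)
        hits = ortholog_search(probe, target)
        assert hits[0].score == pytest.approx(gotoh_score(probe, target))

    def test_no_hit_between_unrelated_homopolymers(self):
        # note poly-A vs poly-T is NOT unrelated: the minus strand of
        # poly-T is poly-A, and both strands are searched
        assert ortholog_search("A" * 50, "G" * 500) == []
        assert ortholog_search("A" * 50, "T" * 500)[0].strand == "-"

    def test_probe_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="seed word"):
            ortholog_search("ACGTACGT", "ACGT" * 100)

    def test_planted_copies_found_across_species(self, rng):
        """Any planted copy at >=0.9 identity and >=100 bp is found at
        default parameters."""
        found = 0
        n_trials = 50
        for t in range(n_trials):
            r = np.random.default_rng(t)
            target = random_dna(r, 600)
            probe = random_dna(r, 120)
            copy = list(probe)
            for pos in r.choice(120, size=12, replace=False):
                copy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[pos]]
            target = target[:250] + "".join(copy) + target[250:]
            hits = ortholog_search(probe, target)
            if hits and hits[0].interval.overlaps(
                    type(hits[0].interval)("target", 250, 370)):
                found += 1
        assert found >= 0.95 * n_trials


class TestPresenceMatrix:
    def test_empty_hits_give_all_absent_matrix(self):
        m = build_presence_matrix([], species=["a", "b"], probes=["p1"])
        assert m.isna().all().all()
        assert m.attrs["mean_species_count"] == 0.0

    def test_cell_records_maximum_score(self, rng):
        target = random_dna(rng, 400)
        probe = target[50:150]
        hits = ortholog_search(probe, target, probe_id="p", species="s")
        hits = hits + [h for h in hits]  # duplicates cannot inflate the max
        m = build_presence_matrix(hits)
        assert m.at["s", "p"] == max(h.score for h in hits)

    def test_species_counts_follow_hit_structure(self, rng):
        target = random_dna(rng, 300)
        probe = target[10:110]
        base = ortholog_search(probe, target, probe_id="p1", species="s1")[0]
        hits = [base,
                type(base)(probe_id="p1", species="s2", interval=base.interval,
                           strand="+", score=40.0, identity=0.9)]
        m = build_presence_matrix(hits, species=["s1", "s2", "s3"], probes=["p1"])
        assert m.attrs["species_count"]["p1"] == 2
        assert m.attrs["mean_species_count"] == 2.0
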