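"""Subtractive screen, genome filter and candidate selection."""

import numpy as np
import pytest

from radsub import (
    CandidateMarker,
    ConfigurationError,
    TagCatalog,
    clean_reads,
    cross_sex_screen,
    demultiplex,
    final_markers,
    genome_filter,
    select_candidates,
    stack_tags,
)
from radsub.dna import canonical, random_dna, revcomp
from radsub.errors import ValidationError
from radsub.preprocess import MidTable

from oracles import maps_oracle


def cat(ind, seqs):
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return TagCatalog(ind, counts, len(seqs))


class TestCrossSexScreen:
    def test_set_subtraction(self):
        t1, t2 = "A" * 10, "C" * 10
        out = cross_sex_screen({"f": cat("f", [t1, t2])}, {"m": [t1]},
                               canonicalize=False)
        assert [c.sequence for c in out] == [t2]
        assert out[0].screen_status == "unmatched"
        assert out[0].genome_status == "not_tested"

    def test_empty_opposite_set_keeps_everything(self):
        out = cross_sex_screen({"f": cat("f", ["AAAA", "CCCC"])}, {},
                               canonicalize=False)
        assert [c.sequence for c in out] == ["AAAA", "CCCC"]

    def test_canonical_matching_catches_reverse_complement(self):
        tag = "AACCGGTTAA"
        out = cross_sex_screen({"f": cat("f", [tag])}, {"m": [revcomp(tag)]})
        assert out == []

    def test_mixed_tag_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cross_sex_screen({"f": cat("f", ["AAAA"])}, {"m": ["AAA"]})

    def test_min_source_individuals_filter(self):
        shared, private = "A" * 10, "C" * 10
        source = {"f1": cat("f1", [shared, private]), "f2": cat("f2", [shared])}
        strict = cross_sex_screen(source, {}, canonicalize=False)
        assert [c.sequence for c in strict] == [shared]
        loose = cross_sex_screen(source, {}, min_source_individuals=1,
                                 canonicalize=False)
        assert [c.sequence for c in loose] == [shared, private]
        assert loose[1].n_source_individuals_present == 1

    def test_monotonicity_in_opposite_reads(self, rng):
        tags = [random_dna(rng, 30) for _ in range(40)]
        source = {"f": cat("f", tags)}
        opp_small = {"m": tags[:5]}
        opp_large = {"m": tags[:15]}
        small = {c.sequence for c in cross_sex_screen(source, opp_small)}
        large = {c.sequence for c in cross_sex_screen(source, opp_large)}
        assert large <= small

    def test_planted_population_equals_set_difference_oracle(self, population):
        """On the simulated ZW population the candidate set must equal the
        brute-force canonical 110-mer set difference, and every planted
        size-selected W tag must be recovered."""
        mids = MidTable(tuple((i.individual_id, i.sex, i.mid)
                              for i in population.individuals))
        from radsub.preprocess import ReadRecord
        reads = [ReadRecord(r.read_id, r.bases1, tuple(int(q) for q in r.quals1))
                 for r in population.reads]
        assigned, _ = demultiplex(reads, mids)
        cats = {i: stack_tags(clean_reads(assigned[i]), individual_id=i,
                              canonicalize=True) for i in assigned}
        females = [i.individual_id for i in population.individuals if i.sex == "female"]
        males = [i.individual_id for i in population.individuals if i.sex == "male"]
        out = cross_sex_screen({i: cats[i] for i in females},
                               {i: cats[i] for i in males})
        got = {c.sequence for c in out}

        # oracle: tags in every female catalog and in no male catalog
        female_sets = [set(cats[i].counts) for i in females]
        male_union = set().union(*(set(cats[i].counts) for i in males))
        oracle = set.intersection(*female_sets) - male_union
        assert got == oracle

        planted = {canonical(w.cassette_fragment[:110])
                   for w in population.genomes.truth}
        assert planted <= got  # 100% recall of planted W tags


class TestGenomeFilter:
    def _cands(self, seqs):
        return [CandidateMarker(f"m{i}", s, "female", 4, "unmatched")
                for i, s in enumerate(seqs)]

    def test_exact_substring_is_mapped(self, rng):
        genome = random_dna(rng, 5000)
        (out,) = genome_filter(self._cands([genome[1000:1110]]), genome)
        assert out.genome_status == "mapped"

    def test_random_tag_is_unmapped_and_oracle_agrees(self, rng):
        genome = random_dna(rng, 100_000)
        tag = random_dna(rng, 110)
        (out,) = genome_filter(self._cands([tag]), genome)
        assert out.genome_status == "unmapped"
        assert not maps_oracle(genome, tag, 11)

    def test_mismatch_threshold_boundary(self, rng):
        """11 substitutions in 110 nt (10%) still maps; 12 does not."""
        genome = random_dna(rng, 20_000)
        window = genome[7000:7110]

        def mutate(seq, k):
            pos = rng.choice(len(seq), size=k, replace=False)
            out = list(seq)
            for p in pos:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        eleven, twelve = mutate(window, 11), mutate(window, 12)
        a, b = genome_filter(self._cands([eleven, twelve]), genome)
        assert a.genome_status == "mapped"
        assert b.genome_status == ("mapped" if maps_oracle(genome, twelve, 11)
                                   else "unmapped")
        assert maps_oracle(genome, eleven, 11)

    def test_reverse_complement_hits_are_found(self, rng):
        genome = random_dna(rng, 5000)
        (out,) = genome_filter(self._cands([revcomp(genome[2000:2110])]), genome)
        assert out.genome_status == "mapped"

    def test_seed_longer_than_tag_rejected(self):
        with pytest.raises(ConfigurationError):
            genome_filter(self._cands(["ACGT" * 5]), "ACGT" * 100, seed_length=30)

    def test_final_markers_are_the_unmapped_ones(self, rng):
        genome = random_dna(rng, 5000)
        cands = self._cands([genome[100:210], random_dna(rng, 110)])
        out = genome_filter(cands, genome)
        assert [m.sequence for m in final_markers(out)] == [cands[1].sequence]


class TestSelectCandidates:
    def _markers(self, n):
        return [CandidateMarker(f"m{i}", f"{i:04d}", "female", 4, "unmatched",
                                "unmapped") for i in range(n)]

    def test_sample_size_and_distinctness(self):
        sel = select_candidates(self._markers(308), 100, rng_seed=1)
        assert len(sel) == 100
        assert len({m.marker_id for m in sel}) == 100

    def test_n_at_least_population_returns_all_in_order(self):
        markers = self._markers(5)
        assert select_candidates(markers, 10, rng_seed=1) == markers

    def test_deterministic_for_fixed_seed(self):
        a = select_candidates(self._markers(308), 100, rng_seed=42)
        b = select_candidates(self._markers(308), 100, rng_seed=42)
        assert a == b

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ConfigurationError):
            select_candidates(self._markers(3), 0, rng_seed=1)
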