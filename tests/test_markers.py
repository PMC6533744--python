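"""In-silico PCR, genotyping, sex calls and reversal detection."""

import numpy as np
import pytest

from radsub import (
    ConfigurationError,
    PrimerPair,
    call_genetic_sex,
    detect_reversals,
    genotype_panel,
    insilico_pcr,
    markers_to_primers,
)
from radsub.dna import random_dna, revcomp
from radsub.errors import ValidationError
from radsub.subtract import CandidateMarker
from radsub import study

from oracles import pcr_oracle


def pair(fwd, rev, product):
    return PrimerPair("p", fwd, rev, product)


class TestInsilicoPcr:
    def test_constructed_template_yields_single_expected_product(self, rng):
        panel = study.primer_panel()
        p = panel["adf225"]
        core = random_dna(rng, 162 - len(p.forward_seq) - len(p.reverse_seq))
        template = p.forward_seq + core + revcomp(p.reverse_seq)
        (prod,) = insilico_pcr(p, template)
        assert prod.product_length == 162

    def test_absent_primers_give_no_product(self, rng):
        p = study.primer_panel()["adf340"]
        for _ in range(5):
            assert insilico_pcr(p, random_dna(rng, 500)) == []

    def test_minus_strand_products_are_reported(self, rng):
        p = study.primer_panel()["adf431"]
        core = random_dna(rng, 178 - len(p.forward_seq) - len(p.reverse_seq))
        template = revcomp(p.forward_seq + core + revcomp(p.reverse_seq))
        (prod,) = insilico_pcr(p, template)
        assert prod.product_length == 178 and prod.strand == "-"

    def test_short_primer_rejected(self):
        with pytest.raises(ValidationError):
            PrimerPair("x", "ACGTACGTACGTAC", "ACGTACGTACGTACG", 100)

    @pytest.mark.parametrize("seed,mm", [(s, m) for s in range(5) for m in (0, 1, 2)])
    def test_matches_sliding_window_oracle_with_planted_sites(self, seed, mm):
        rng = np.random.default_rng(seed)
        fwd, rev = random_dna(rng, 20), random_dna(rng, 20)
        template = list(random_dna(rng, 300))

        def plant(site, pos):
            template[pos:pos + len(site)] = site

        # plant a clean amplicon plus a mutated forward site
        plant(fwd, 30)
        plant(revcomp(rev), 170)
        mutated = list(fwd)
        for p_ in rng.choice(len(fwd) - 1, size=mm, replace=False):
            mutated[p_] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p_]]
        plant("".join(mutated), 220)
        tpl = "".join(template)
        got = {(x.start, x.end) for x in
               insilico_pcr(pair(fwd, rev, 40), tpl, max_product_bp=300,
                            max_primer_mismatches=mm)}
        assert got == pcr_oracle(fwd, rev, tpl, max_product_bp=300, max_mm=mm)

    def test_three_prime_terminal_mismatch_blocks_extension(self, rng):
        fwd, rev = random_dna(rng, 20), random_dna(rng, 20)
        bad_fwd = fwd[:-1] + {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd[-1]]
        template = fwd + random_dna(rng, 60) + revcomp(rev)
        assert insilico_pcr(pair(bad_fwd, rev, 100), template,
                            max_primer_mismatches=1) == []


class TestGenotypePanel:
    def test_validation_cohort_24_females_24_males(self, rng):
        """A true W marker bands in all 24 females and no male."""
        p = study.primer_panel()["adf340"]
        bands = {f"F{i}": True for i in range(24)} | {f"M{i}": False for i in range(24)}
        templates = study.synthetic_group_templates(bands, p, rng)
        geno = genotype_panel(templates, [p])
        assert geno.matrix["adf340"].sum() == 24
        assert not geno.matrix.loc[[f"M{i}" for i in range(24)], "adf340"].any()

    def test_empty_panel_gives_zero_column_matrix(self):
        geno = genotype_panel({"a": "ACGT" * 50}, [])
        assert geno.matrix.shape == (1, 0)

    def test_missing_template_recorded_and_run_continues(self, rng):
        p = study.primer_panel()["adf225"]
        templates = study.synthetic_group_templates({"ok": True}, p, rng)
        geno = genotype_panel({"ok": templates["ok"], "broken": None}, [p])
        assert geno.band("ok", "adf225")
        assert not geno.band("broken", "adf225")
        assert "broken" in geno.errors

    def test_tag_set_templates_are_each_tried(self, rng):
        p = study.primer_panel()["adf225"]
        amplicon = (p.forward_seq + random_dna(rng, 122) + revcomp(p.reverse_seq))
        tags = [random_dna(rng, 162), amplicon]
        geno = genotype_panel({"a": tags}, [p])
        assert geno.band("a", "adf225")


class TestSexCallsAndReversals:
    def test_single_marker_band_is_female_under_zw(self):
        import pandas as pd
        m = pd.DataFrame({"adf340": [True, False]}, index=["a", "b"])
        assert call_genetic_sex(m) == {"a": "female", "b": "male"}
        assert call_genetic_sex(m, "XY_male_marker") == {"a": "male", "b": "female"}

    def test_tied_markers_are_indeterminate(self):
        import pandas as pd
        m = pd.DataFrame({"x": [True], "y": [False]}, index=["a"])
        assert call_genetic_sex(m) == {"a": "indeterminate"}

    def test_unknown_system_rejected(self):
        import pandas as pd
        with pytest.raises(ConfigurationError):
            call_genetic_sex(pd.DataFrame(), system="UV_system")

    def test_concordant_calls_give_empty_report(self):
        rep = detect_reversals({"a": "female", "b": "male"},
                               {"a": "female", "b": "male"})
        assert rep.reversals == []
        assert int(rep.crosstab.values.sum()) == 2

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            detect_reversals({"a": "female"}, {"b": "female"})

    def test_order_invariance_and_marginals(self, rng):
        ids = [f"i{k}" for k in range(30)]
        genetic = {i: ("female" if rng.random() < 0.5 else "male") for i in ids}
        phenotypic = {i: ("female" if rng.random() < 0.5 else "male") for i in ids}
        fwd = detect_reversals(genetic, phenotypic)
        shuffled = dict(reversed(list(genetic.items())))
        rev = detect_reversals(shuffled, phenotypic)
        assert fwd.n_female_to_male == rev.n_female_to_male
        assert fwd.n_male_to_female == rev.n_male_to_female
        assert int(fwd.crosstab.values.sum()) == 30


class TestRoundTrip:
    def test_discovered_markers_genotype_their_own_population(self, population):
        """Markers from the subtractive screen, converted to naive primer
        pairs, must genotype the simulated population with zero
        genetic/phenotypic discordance at error_rate=0."""
        from radsub import clean_reads, cross_sex_screen, demultiplex, \
            genome_filter, stack_tags, final_markers
        from radsub.preprocess import MidTable, ReadRecord

        mids = MidTable(tuple((i.individual_id, i.sex, i.mid)
                              for i in population.individuals))
        reads = [ReadRecord(r.read_id, r.bases1, tuple(int(q) for q in r.quals1))
                 for r in population.reads]
        assigned, _ = demultiplex(reads, mids)
        cats = {i: stack_tags(clean_reads(assigned[i]), individual_id=i,
                              canonicalize=True) for i in assigned}
        females = {i: cats[i] for i in cats if mids.sex_of[i] == "female"}
        males = {i: cats[i] for i in cats if mids.sex_of[i] == "male"}
        cands = cross_sex_screen(females, males)
        markers = final_markers(
            genome_filter(cands, population.genomes.male_genome))
        assert markers
        panel = markers_to_primers(markers)
        geno = genotype_panel({i: list(cats[i].counts) for i in cats}, panel,
                              max_product_bp=115)
        calls = call_genetic_sex(geno)
        rep = detect_reversals(calls, mids.sex_of)
        assert rep.reversals == []
        assert all(calls[i] == mids.sex_of[i] for i in calls)


class TestMarkersToPrimers:
    def test_primer_geometry(self):
        seq = random_dna(np.random.default_rng(0), 110)
        (p,) = markers_to_primers(
            [CandidateMarker("m1", seq, "female", 4, "unmatched", "unmapped")])
        assert p.forward_seq == seq[:20]
        assert p.reverse_seq == revcomp(seq[-20:])
        assert p.expected_product_bp == 110

    def test_too_short_marker_rejected(self):
        with pytest.raises(ConfigurationError):
            markers_to_primers(
                [CandidateMarker("m1", "ACGT" * 8, "female", 4, "unmatched",
                                 "unmapped")])
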