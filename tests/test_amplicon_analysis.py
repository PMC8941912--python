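import numpy as np
import pytest

from mockqc.amplicon_analysis import (
    PrimerPair,
    annotate_reads,
    classify_primer_regions,
    copy_number_correct,
    expected_errors,
    extract_amplicons,
    resolve_primer,
    revcomp,
)
from mockqc.synthetic_data import make_genome
from tests.conftest import FW_SITE, RV_SITE


class TestPrimerPair:
    def test_defaults_are_v4_primers(self, primers):
        assert primers.forward == "GTGYCAGCMGCCGCGGTAA"
        assert primers.reverse == "GGACTACNVGGGTWTCTAAT"

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair(forward="GTGYCAG", reverse="GGACTACNVGGGTWTCTAAT")


class TestExtractAmplicons:
    def test_known_insert_recovered(self, amplicon_fixture):
        for s in amplicon_fixture["strains"]:
            assert amplicon_fixture["refs"][s].variants == (amplicon_fixture["inserts"][s],)

    def test_strand_symmetry(self, amplicon_fixture, primers, cell_ref):
        rc_genes = {s: [revcomp(g[0])] for s, g in amplicon_fixture["genes"].items()}
        refs = extract_amplicons(rc_genes, primers, ref=cell_ref)
        for s in amplicon_fixture["strains"]:
            assert refs[s].variants == (amplicon_fixture["inserts"][s],)

    def test_copy_number_pulled_from_registry(self, amplicon_fixture, cell_ref):
        for s in amplicon_fixture["strains"]:
            assert amplicon_fixture["refs"][s].n_16s == cell_ref.get(s).n_16s

    def test_shared_insert_flagged_for_both_strains(self, primers):
        insert = make_genome(250, 0.5, seed=7)
        gene = "T" * 30 + FW_SITE + insert + revcomp(RV_SITE) + "A" * 30
        refs = extract_amplicons({"S1": [gene], "S2": [gene]}, primers)
        assert refs["S1"].variants == refs["S2"].variants == (insert,)
        assert refs["S1"].shared_with == ("S2",)
        assert refs["S2"].shared_with == ("S1",)

    def test_missing_primer_site_skipped_with_warning(self, primers):
        with pytest.warns(UserWarning, match="primer sites not found"):
            refs = extract_amplicons({"S1": [make_genome(400, 0.5, seed=8)]}, primers)
        assert "S1" not in refs

    def test_mismatch_tolerance(self, primers):
        insert = make_genome(250, 0.5, seed=9)
        site = "A" + FW_SITE[1:]  # one substitution in a 19-mer: within 20%
        gene = "T" * 30 + site + insert + revcomp(RV_SITE) + "A" * 30
        refs = extract_amplicons({"S1": [gene]}, primers)
        assert refs["S1"].variants == (insert,)


class TestExpectedErrors:
    def test_closed_form(self):
        assert expected_errors([20] * 10) == pytest.approx(0.1)
        assert expected_errors([]) == 0.0

    def test_monotone_in_quality(self):
        base = expected_errors([30, 30, 30])
        assert expected_errors([30, 20, 30]) > base

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            expected_errors([10, -1])


class TestAnnotateReads:
    def test_exact_read_assigned(self, amplicon_fixture):
        s = amplicon_fixture["strains"][0]
        res = annotate_reads([("r1", amplicon_fixture["inserts"][s])], amplicon_fixture["refs"])
        assert res.counts[s] == 1 and res.n_unassigned == 0

    def test_identity_threshold_excludes_8_of_250(self, amplicon_fixture):
        s = amplicon_fixture["strains"][0]
        seq = list(amplicon_fixture["inserts"][s])
        for i in range(0, 80, 10):  # 8 substitutions -> identity 242/250 = 96.8%
            seq[i] = "A" if seq[i] != "A" else "C"
        res = annotate_reads([("r1", "".join(seq))], amplicon_fixture["refs"])
        assert res.n_unassigned == 1 and sum(res.counts.values()) == 0

    def test_7_of_250_substitutions_still_assigned(self, amplicon_fixture):
        s = amplicon_fixture["strains"][0]
        seq = list(amplicon_fixture["inserts"][s])
        for i in range(0, 70, 10):  # identity 243/250 = 97.2%
            seq[i] = "A" if seq[i] != "A" else "C"
        res = annotate_reads([("r1", "".join(seq))], amplicon_fixture["refs"])
        assert res.counts[s] == 1

    def test_tie_counted_ambiguous(self, primers):
        insert = make_genome(250, 0.5, seed=7)
        gene = "T" * 30 + FW_SITE + insert + revcomp(RV_SITE) + "A" * 30
        refs = extract_amplicons({"S1": [gene], "S2": [gene]}, primers)
        res = annotate_reads([("r1", insert)], refs)
        assert res.n_ambiguous == 1
        assert sum(res.counts.values()) == 0

    def test_partition_invariant(self, amplicon_fixture):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(30):
            s = amplicon_fixture["strains"][i % 4]
            seq = list(amplicon_fixture["inserts"][s])
            n_mut = rng.integers(0, 12)
            for pos in rng.choice(len(seq), size=n_mut, replace=False):
                seq[pos] = "ACGT"[rng.integers(4)]
            reads.append((f"r{i}", "".join(seq)))
        res = annotate_reads(reads, amplicon_fixture["refs"])
        assert sum(res.counts.values()) + res.n_ambiguous + res.n_unassigned == res.n_total

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            annotate_reads([("r1", "ACGT")], {})


class TestCopyNumberCorrect:
    def test_two_to_one_ratio(self, cell_ref):
        # equal read counts, 4 vs 8 copies -> 2:1 after correction
        counts = {"NBRC 113350": 100, "NBRC 3202": 100}  # 4 and 8 copies
        comp = copy_number_correct(counts, cell_ref)
        assert comp["NBRC 113350"] == pytest.approx(200 / 3)
        assert comp["NBRC 3202"] == pytest.approx(100 / 3)

    def test_equal_counts_equal_copies_uniform(self, cell_ref):
        counts = {"NBRC 113351": 50, "NBRC 113352": 50}  # both 5 copies
        comp = copy_number_correct(counts, cell_ref)
        np.testing.assert_allclose(comp.values, 50.0)

    def test_unknown_strain_rejected(self, cell_ref):
        with pytest.raises(ValueError, match="not in registry"):
            copy_number_correct({"NBRC 99999": 10}, cell_ref)


class TestResolvePrimer:
    def test_degenerate_positions_follow_template(self, primers):
        template = FW_SITE
        assert resolve_primer(primers.forward, template) == template

    def test_fixed_positions_keep_primer_base(self, primers):
        template = list(FW_SITE)
        template[0] = "A"  # primer position 0 is a fixed G
        resolved = resolve_primer(primers.forward, "".join(template))
        assert resolved[0] == "G"


class TestClassifyPrimerRegions:
    @pytest.fixture()
    def mismatch_template(self):
        # two fixed mismatches to the primer at non-degenerate positions
        t = list(FW_SITE)
        t[5] = "T"  # primer has A
        t[10] = "A"  # primer has C
        return "".join(t)

    def test_template_matching_prefix_is_edited(self, primers, mismatch_template):
        read = mismatch_template + "ACGT" * 10
        calls, _ = classify_primer_regions(
            [("r1", "S", read)], primers, {"S": mismatch_template}
        )
        c = calls[0]
        assert c.klass == "edited_perfect"
        assert c.hamming_d_edited == 0 and c.hamming_d_unedited == 2

    def test_primer_matching_prefix_is_unedited(self, primers, mismatch_template):
        unedited = resolve_primer(primers.forward, mismatch_template)
        calls, _ = classify_primer_regions(
            [("r1", "S", unedited + "ACGT" * 10)], primers, {"S": mismatch_template}
        )
        assert calls[0].klass == "unedited_perfect"

    def test_n_base_forces_mismatch(self, primers, mismatch_template):
        read = "N" + mismatch_template[1:] + "ACGT" * 10
        calls, _ = classify_primer_regions(
            [("r1", "S", read)], primers, {"S": mismatch_template}
        )
        assert calls[0].klass == "mismatch"

    def test_degenerate_template_reported_unedited_with_flag(self, primers):
        calls, _ = classify_primer_regions(
            [("r1", "S", FW_SITE + "ACGT" * 10)], primers, {"S": FW_SITE}
        )
        assert calls[0].klass == "unedited_perfect"
        assert calls[0].degenerate_indistinguishable

    def test_partition_and_summary(self, primers, mismatch_template):
        unedited = resolve_primer(primers.forward, mismatch_template)
        reads = [
            ("e1", "S", mismatch_template + "A" * 30),
            ("e2", "S", mismatch_template + "A" * 30),
            ("u1", "S", unedited + "A" * 30),
            ("m1", "S", ("N" + unedited[1:]) + "A" * 30),
        ]
        calls, summary = classify_primer_regions(reads, primers, {"S": mismatch_template})
        s = summary["S"]
        assert s["n_edited_perfect"] + s["n_unedited_perfect"] + s["n_mismatch"] == s["n_reads"]
        assert s["pct_edited_of_perfect"] == pytest.approx(100 * 2 / 3)

    def test_short_read_rejected(self, primers, mismatch_template):
        with pytest.raises(ValueError, match="shorter"):
            classify_primer_regions([("r1", "S", "ACGT")], primers, {"S": mismatch_template})
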