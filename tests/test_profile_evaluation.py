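import numpy as np
import pandas as pd
import pytest

from mockqc.compositional_stats import Composition, ProfileSet, closure
from mockqc.profile_evaluation import (
    counts_to_abundance,
    evaluate_profile,
    gram_bias_summary,
    match_expected,
    parse_mpa,
    protocol_dispersion,
    species_count_curve,
)


def assigned_observed(ref):
    """Observed table equal to the assigned composition, using the names
    profilers report (each strain's first search term)."""
    from mockqc.profile_evaluation import search_terms

    terms = search_terms(ref)
    out = {}
    for s in ref:
        name = terms[s.strain_id][0]
        out[name] = out.get(name, 0.0) + s.abundance(ref.community)
    return out


class TestCountsToAbundance:
    def test_equal_coverage_gives_even_split(self):
        table = pd.DataFrame(
            {
                "unit_id": ["c1", "c2"],
                "strain_id": ["A", "B"],
                "est_count": [1000.0, 500.0],
                "effective_length": [1e6, 5e5],
            }
        )
        comp = counts_to_abundance(table)
        assert comp.as_dict() == pytest.approx({"A": 50.0, "B": 50.0})

    def test_replicon_coverages_add(self):
        table = pd.DataFrame(
            {
                "unit_id": ["chr", "plasmid", "chr"],
                "strain_id": ["A", "A", "B"],
                "est_count": [900.0, 100.0, 1000.0],
                "effective_length": [1e6, 1e5, 2e6],
            }
        )
        comp = counts_to_abundance(table)
        # A: 0.0009 + 0.001 = 0.0019; B: 0.0005
        assert comp["A"] == pytest.approx(100 * 0.0019 / 0.0024)

    def test_scale_invariance(self):
        table = pd.DataFrame(
            {
                "unit_id": ["c1", "c2"],
                "strain_id": ["A", "B"],
                "est_count": [300.0, 100.0],
                "effective_length": [1e6, 1e6],
            }
        )
        doubled = table.assign(est_count=table.est_count * 2)
        np.testing.assert_allclose(
            counts_to_abundance(table).values, counts_to_abundance(doubled).values
        )

    def test_zero_total_coverage_rejected(self):
        table = pd.DataFrame(
            {"unit_id": ["c"], "strain_id": ["A"], "est_count": [0.0], "effective_length": [1e6]}
        )
        with pytest.raises(ValueError, match="zero total"):
            counts_to_abundance(table)


class TestMatchExpected:
    @pytest.mark.parametrize(
        "name,strain",
        [
            ("Clostridium clostridioforme", "NBRC 113352"),
            ("Enterocloster clostridioformis", "NBRC 113352"),
            ("Blautia producta", "NBRC 113351"),
            ("Bacteroides rodentium/uniformis", "NBRC 113350"),
            ("Bacteroides uniformis", "NBRC 113350"),
            ("Escherichia coli", "NBRC 3301"),
        ],
    )
    def test_search_terms(self, dna_ref, name, strain):
        (a,) = match_expected([name], dna_ref)
        assert a.matched_strains == (strain,)

    def test_subspecies_names_match_via_species(self, dna_ref):
        (a,) = match_expected(["Bacillus subtilis"], dna_ref)
        assert a.matched_strains == ("NBRC 13719",)

    def test_false_positive_unmatched(self, dna_ref):
        (a,) = match_expected(["Bacillus intestinalis"], dna_ref)
        assert not a.matched
        # congeneric false positives do not inherit a match
        (b,) = match_expected(["Megasphaera elsdenii"], dna_ref)
        assert not b.matched

    def test_longum_pair_collapses_not_errors(self, dna_ref):
        (a,) = match_expected(["Bifidobacterium longum"], dna_ref)
        assert set(a.matched_strains) == {"NBRC 114370", "NBRC 114494"}


class TestParseMpa:
    def test_species_level_lines_only(self, tmp_path):
        report = tmp_path / "profile.mpa"
        report.write_text(
            "#mpa_v30\n"
            "k__Bacteria\t100.0\n"
            "k__Bacteria|p__Proteobacteria\t40.0\n"
            "k__Bacteria|p__Proteobacteria|g__Escherichia|s__Escherichia_coli\t40.0\n"
            "k__Bacteria|p__Firmicutes|g__Bacillus|s__Bacillus_intestinalis\t60.0\n"
        )
        got = parse_mpa(report)
        assert got == {"Escherichia coli": 40.0, "Bacillus intestinalis": 60.0}


class TestSpeciesCountCurve:
    def test_expected_species_at_low_threshold(self, dna_ref):
        obs = {s.species_name: s.abundance_dna_pct for s in dna_ref}
        curve = species_count_curve(obs, [3.6, 1.0, 0.1])
        assert (curve["n_species"] == 20).all()

    def test_threshold_filtering(self):
        curve = species_count_curve({"A": 50.0, "B": 49.5, "C": 0.5}, [1.0, 60.0])
        assert list(curve["n_species"]) == [2, 0]

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        obs = {f"sp{i}": v for i, v in enumerate(closure(rng.uniform(0.01, 5, 30)))}
        thresholds = sorted(np.geomspace(0.01, 10, 12))
        counts = species_count_curve(obs, thresholds)["n_species"]
        assert (counts.diff().dropna() <= 0).all()


class TestEvaluateProfile:
    def test_perfect_profile(self, dna_ref):
        ev = evaluate_profile(assigned_observed(dna_ref), dna_ref, collapse_longum=True)
        assert ev.expected_fraction_pct == pytest.approx(100.0)
        assert not ev.false_positives and not ev.missing
        assert ev.bray_curtis_similarity_pct == pytest.approx(100.0)
        assert ev.gmafd_vs_expected == pytest.approx(1.0)

    def test_renamed_species_becomes_miss_and_false_positive(self, dna_ref):
        obs = assigned_observed(dna_ref)
        val = obs.pop("Bacillus subtilis")
        obs["Bacillus intestinalis"] = val
        ev = evaluate_profile(obs, dna_ref)
        assert "NBRC 13719" in ev.missing
        assert ("Bacillus intestinalis", pytest.approx(val)) in [
            (n, v) for n, v in ev.false_positives
        ]

    def test_abundance_conservation(self, dna_ref):
        obs = assigned_observed(dna_ref)
        obs["Pseudomonas sp."] = 5.0
        obs["unclassified"] = 3.0
        ev = evaluate_profile(obs, dna_ref)
        total = (
            ev.expected_fraction_pct
            + ev.false_positive_fraction_pct
            + ev.unassigned_fraction_pct
        )
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_collapse_longum_merges_buckets(self, dna_ref):
        obs = assigned_observed(dna_ref)
        ev = evaluate_profile(obs, dna_ref, collapse_longum=True)
        assert "NBRC 114370+NBRC 114494" in ev.per_strain_pct
        assert ev.per_strain_pct["NBRC 114370+NBRC 114494"] == pytest.approx(5.7 + 4.7)


class TestProtocolDispersion:
    def _profiles(self, bias=None, n=3, seed=0, labs=("LabA", "LabA", "LabB")):
        rng = np.random.default_rng(seed)
        base = closure(np.array([5.0, 15.0, 30.0, 50.0]))
        rows, meta = [], []
        for i in range(n):
            vals = base * np.exp(rng.normal(0, 0.02, 4))
            if bias is not None and i >= n - 2:
                vals = vals * bias
            rows.append(closure(vals))
            meta.append(
                {
                    "lab": labs[i % len(labs)],
                    "extraction_protocol": "non_sop" if (bias is not None and i >= n - 2) else "sop",
                }
            )
        idx = [f"s{i}" for i in range(n)]
        return ProfileSet(
            pd.DataFrame(rows, index=idx, columns=list("abcd")),
            pd.DataFrame(meta, index=idx),
        )

    def test_pair_count(self):
        ps = self._profiles(n=5, labs=("L1", "L2", "L3", "L4", "L5"))
        assert len(protocol_dispersion(ps)) == 10

    def test_identical_profiles_zero_distance(self):
        vals = np.tile(closure(np.array([1.0, 2.0, 3.0, 4.0])), (3, 1))
        ps = ProfileSet(pd.DataFrame(vals, index=["a", "b", "c"], columns=list("wxyz")))
        d = protocol_dispersion(ps)
        np.testing.assert_allclose(d["aitchison"], 0, atol=1e-9)

    def test_biased_group_increases_between_group_distance(self):
        bias = np.array([0.3, 0.3, 1.0, 1.0])
        ps = self._profiles(bias=bias, n=6, seed=1, labs=("L1",) * 6)
        d = protocol_dispersion(ps, grouping="extraction_protocol")
        within = d[d["within_group"]]["aitchison"].median()
        between = d[~d["within_group"]]["aitchison"].median()
        assert between > within

    def test_singleton_group_warns(self):
        ps = self._profiles(bias=np.array([0.5, 1, 1, 1]), n=3, seed=2)
        with pytest.warns(UserWarning, match="fewer than 2"):
            protocol_dispersion(ps, grouping="extraction_protocol")


class TestGramBiasSummary:
    def _assigned_profiles(self, cell_ref, scale_positive=None, n=2):
        labels = list(cell_ref.strain_ids)
        vals = np.array([s.abundance_cell_pct for s in cell_ref])
        rows = []
        for _ in range(n):
            v = vals.copy()
            if scale_positive is not None:
                from mockqc.reference_data import gram_subset

                pos = gram_subset(cell_ref, "+")
                mask = np.array([l in pos for l in labels])
                v = np.where(mask, v * scale_positive, v)
            rows.append(closure(v))
        return ProfileSet(pd.DataFrame(rows, index=[f"s{i}" for i in range(n)], columns=labels))

    def test_assigned_gram_positive_total(self, cell_ref):
        ps = self._assigned_profiles(cell_ref)
        rep = gram_bias_summary(ps, cell_ref)
        # 12 of 18 even strains; the registry prints 12 x 5.6 = 67.2 on a
        # 100.8 total, i.e. 66.67% once the profile is closed to exactly 100
        np.testing.assert_allclose(
            rep["gram_positive_totals"]["gram_positive_pct"], 100 * 12 / 18, rtol=1e-9
        )

    def test_subcompositional_coherence_under_gram_scaling(self, cell_ref):
        ps_scaled = self._assigned_profiles(cell_ref, scale_positive=0.5)
        ps_plain = self._assigned_profiles(cell_ref)
        both = ProfileSet(
            pd.concat(
                [
                    ps_plain.abundances.rename(index={"s0": "plain"}).iloc[[0]],
                    ps_scaled.abundances.rename(index={"s0": "scaled"}).iloc[[0]],
                ]
            )
        )
        rep = gram_bias_summary(both, cell_ref)
        # scaling all Gram-positives uniformly leaves their subcomposition intact
        np.testing.assert_allclose(rep["gram_positive_pairdist"]["aitchison"], 0, atol=1e-9)
        np.testing.assert_allclose(rep["gram_negative_pairdist"]["aitchison"], 0, atol=1e-9)
        # but the scaled profile's Gram-positive total drops below the assigned 67.2
        totals = rep["gram_positive_totals"]["gram_positive_pct"]
        assert totals.loc["scaled"] < totals.loc["plain"]
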