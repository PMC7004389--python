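import math
import random

import pytest

from phenoscore import (
    ConciseProfile,
    DataError,
    Measurement,
    OntologyGraph,
    ScoringConfig,
    build_complete,
    build_model_profiles,
    build_reference_set,
    estimate_priors,
    fill_background,
    frequency_to_penetrance,
    translate_profile,
)


@pytest.fixture()
def two_child_graph():
    return OntologyGraph({"R": set(), "A": {"R"}, "B": {"R"}})


class TestEstimatePriors:
    def test_two_gene_corpus_hand_counts(self, two_child_graph):
        priors = estimate_priors(
            two_child_graph, {"g1": {"A"}, "g2": {"B"}}, dark_count=2
        )
        assert priors["A"] == pytest.approx(3 / 6)
        assert priors["B"] == pytest.approx(3 / 6)
        assert priors["R"] == pytest.approx(4 / 6)

    def test_gene_annotating_term_and_ancestor_counts_once(self, two_child_graph):
        priors = estimate_priors(two_child_graph, {"g1": {"A", "R"}}, dark_count=2)
        # n(R) = 1, not 2
        assert priors["R"] == pytest.approx((2 + 1) / (4 + 1))

    def test_universal_annotation_stays_below_one(self, two_child_graph):
        genes = {f"g{i}": {"A"} for i in range(10)}
        priors = estimate_priors(two_child_graph, genes, dark_count=2)
        assert priors["A"] == pytest.approx((2 + 10) / (4 + 10))
        assert priors["A"] < 1.0

    def test_empty_corpus_rejected(self, two_child_graph):
        with pytest.raises(DataError):
            estimate_priors(two_child_graph, {})

    def test_unknown_term_listed(self, two_child_graph):
        with pytest.raises(DataError, match="NOPE"):
            estimate_priors(two_child_graph, {"g1": {"NOPE"}})

    def test_hierarchy_monotone_on_random_corpora(self):
        rng = random.Random(7)
        for _ in range(10):
            n = rng.randint(3, 30)
            names = [f"N:{i}" for i in range(n)]
            parents = {names[0]: set()}
            for i in range(1, n):
                parents[names[i]] = {names[rng.randrange(i)]}
            g = OntologyGraph(parents)
            genes = {
                f"g{j}": set(rng.sample(names, rng.randint(1, min(3, n))))
                for j in range(rng.randint(1, 20))
            }
            priors = estimate_priors(g, genes)
            for child, ps in parents.items():
                for p in ps:
                    assert priors[p] >= priors[child]

    def test_unannotated_leaf_leaves_other_priors_invariant(self, two_child_graph):
        genes = {"g1": {"A"}, "g2": {"B"}}
        before = estimate_priors(two_child_graph, genes)
        extended = OntologyGraph(
            {"R": set(), "A": {"R"}, "B": {"R"}, "C": {"B"}}
        )
        after = estimate_priors(extended, genes)
        for t in ("R", "A", "B"):
            assert after[t] == before[t]


class TestFrequencyToPenetrance:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("obligate", 1.0),
            ("very frequent", 0.895),
            ("frequent", 0.545),
            ("occasional", 0.17),
            ("very rare", 0.025),
            ("excluded", 0.0),
            ("3/10", 0.3),
            ("45%", 0.45),
            ("Very Frequent", 0.895),
        ],
    )
    def test_decision_table_and_literals(self, code, expected):
        assert frequency_to_penetrance(code) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", ["sometimes", "5/0", "7/3", "120%"])
    def test_unknown_codes_raise(self, bad):
        with pytest.raises(DataError):
            frequency_to_penetrance(bad)


class TestTranslateProfile:
    def test_saturating_score_preserves_penetrance(self):
        hp = ConciseProfile("d", {"HP:1": 0.9})
        out = translate_profile(hp, [("HP:1", "MP:1", 1e6)])
        assert out.values["MP:1"] == pytest.approx(0.9)

    def test_zero_score_discards_translation(self):
        hp = ConciseProfile("d", {"HP:1": 0.9})
        out = translate_profile(hp, [("HP:1", "MP:1", 0.0)])
        assert out.values["MP:1"] == 0.0

    def test_unit_score_scaling(self):
        hp = ConciseProfile("d", {"HP:1": 0.8})
        out = translate_profile(hp, [("HP:1", "MP:1", 1.0)])
        assert out.values["MP:1"] == pytest.approx(0.8 * math.tanh(1), abs=1e-6)

    def test_ties_populate_every_target_and_collisions_keep_max(self):
        hp = ConciseProfile("d", {"HP:1": 0.8, "HP:2": 0.4})
        table = [("HP:1", "MP:1", 100.0), ("HP:1", "MP:2", 100.0),
                 ("HP:2", "MP:2", 100.0)]
        out = translate_profile(hp, table)
        assert out.values["MP:1"] == pytest.approx(0.8)
        assert out.values["MP:2"] == pytest.approx(0.8)  # max, not OR

    def test_missing_terms_warn_and_skip(self):
        hp = ConciseProfile("d", {"HP:1": 0.8, "HP:9": 0.5})
        with pytest.warns(UserWarning, match="HP:9"):
            out = translate_profile(hp, [("HP:1", "MP:1", 100.0)])
        assert "HP:9" not in out.values

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            translate_profile(ConciseProfile("d", {"HP:1": 0.8}), [])


class TestBuildComplete:
    def test_sibling_or_example(self, two_child_graph):
        complete = build_complete(
            two_child_graph, ConciseProfile("d", {"A": 0.25, "B": 0.5})
        )
        assert complete.values["R"] == pytest.approx(1 - (1 - 0.25) * (1 - 0.5))
        assert complete.provenance["R"] == "propagated"

    def test_single_leaf_propagates_unchanged(self, seven_term_graph):
        complete = build_complete(
            seven_term_graph, ConciseProfile("d", {"T:0000004": 0.4})
        )
        for anc in ("T:0000002", "T:0000001"):
            assert complete.values[anc] == pytest.approx(0.4)
        assert "T:0000003" not in complete.values  # no annotated descendant

    def test_diamond_counts_one_source_once(self, diamond_graph):
        complete = build_complete(diamond_graph, ConciseProfile("d", {"D": 0.3}))
        # one observation reaching A along two paths is not OR-ed with itself
        assert complete.values["A"] == pytest.approx(0.3)

    def test_parent_own_value_joins_or(self, two_child_graph):
        complete = build_complete(
            two_child_graph, ConciseProfile("d", {"A": 0.5, "R": 0.5})
        )
        assert complete.values["R"] == pytest.approx(0.75)

    def test_propagated_values_monotone_up_edges(self, seven_term_graph):
        complete = build_complete(
            seven_term_graph,
            ConciseProfile("d", {"T:0000004": 0.3, "T:0000006": 0.9,
                                 "T:0000007": 0.2}),
        )
        for child, parents in seven_term_graph.parents.items():
            if child not in complete.values:
                continue
            for p in parents:
                assert complete.values[p] >= complete.values[child] - 1e-12


class TestReferenceSet:
    def make_diseases(self, graph, k=6):
        leaves = sorted(t for t in graph.terms if not graph.children[t])
        return {
            f"D{i}": ConciseProfile(f"D{i}", {leaves[i % len(leaves)]: 0.8})
            for i in range(k)
        }

    def test_requires_k_plus_one_diseases(self, seven_term_graph):
        priors = estimate_priors(seven_term_graph, {"g": {"T:0000004"}})
        cfg = ScoringConfig(k_neighbors=5)
        with pytest.raises(DataError, match="k_neighbors"):
            build_reference_set(
                seven_term_graph, self.make_diseases(seven_term_graph, 3),
                priors, cfg,
            )

    def test_bg_multiplier_one_fills_with_priors(self, seven_term_graph):
        priors = estimate_priors(seven_term_graph, {"g": {"T:0000004"}})
        cfg = ScoringConfig(k_neighbors=2, bg_multiplier=1.0)
        refs = build_reference_set(
            seven_term_graph, self.make_diseases(seven_term_graph), priors, cfg
        )
        g0 = refs.general["D0"]
        for term, prov in g0.provenance.items():
            if prov == "background":
                assert g0.values[term] == pytest.approx(priors[term])

    def test_identical_corpus_lifts_specific_to_background(self, seven_term_graph):
        priors = estimate_priors(seven_term_graph, {"g": {"T:0000004"}})
        cfg = ScoringConfig(k_neighbors=2)
        leaves = ["T:0000004"]
        diseases = {
            f"D{i}": ConciseProfile(f"D{i}", {t: 0.8 for t in leaves})
            for i in range(3)
        }
        refs = build_reference_set(seven_term_graph, diseases, priors, cfg)
        # raw residual is 0 everywhere; annotated terms are lifted to b(t)
        for term in ("T:0000004", "T:0000002", "T:0000001"):
            if refs.general["D0"].values[term] > priors[term] + cfg.tol:
                assert refs.specific["D0"].values[term] == pytest.approx(priors[term])

    def test_unique_phenotypes_survive_in_specific(self, bundle):
        refs = bundle.references
        for disease, profile in list(bundle.diseases.items())[:5]:
            for term in profile.values:
                g = refs.general[disease].values[term]
                s = refs.specific[disease].values[term]
                # disjoint corpus: neighbor average is near the filled level
                assert s >= bundle.priors[term] - 1e-12
                assert s <= g + 1e-12

    def test_specific_bounded_by_general_everywhere(self, bundle):
        refs = bundle.references
        for d in refs.disease_ids():
            for t, s in refs.specific[d].values.items():
                assert -1e-12 <= s <= refs.general[d].values[t] + 1e-12


class TestModelProfiles:
    def test_empty_measurements_empty_profiles(self, bundle):
        assert build_model_profiles([], bundle.graph, bundle.priors) == {}

    def test_single_positive_record_odds(self, two_child_graph):
        priors = estimate_priors(two_child_graph, {f"g{i}": {"B"} for i in range(500)})
        # force b(A) = (2+0)/(4+500) ~ 0.00397; use explicit prior instead
        from phenoscore import PriorVector

        priors = PriorVector({"R": 0.5, "A": 0.01, "B": 0.01}, n_genes=1)
        m = Measurement("mod", "A", "positive", tau=0.8, phi=0.05)
        profiles = build_model_profiles([m], two_child_graph, priors)
        assert profiles["mod"].values["A"] == pytest.approx(0.139130, abs=1e-6)

    def test_multi_record_effective_power(self, two_child_graph):
        from phenoscore import PriorVector, UpdateFactor, update_positive

        priors = PriorVector({"R": 0.5, "A": 0.1, "B": 0.1}, n_genes=1)
        records = [
            Measurement("mod", "A", "positive", source_id="impc"),
            Measurement("mod", "A", "positive", source_id="impc"),
            Measurement("mod", "A", "negative", source_id="impc"),
        ]
        profiles = build_model_profiles(records, two_child_graph, priors)
        tau_eff = 0.05 + 0.75 * (2 / 3)
        assert tau_eff == pytest.approx(0.55)
        expected = update_positive(0.1, UpdateFactor(tau_eff, 0.05))
        assert profiles["mod"].values["A"] == pytest.approx(expected, abs=1e-12)

    def test_minority_positive_fraction_updates_negative(self, two_child_graph):
        from phenoscore import PriorVector

        priors = PriorVector({"R": 0.5, "A": 0.1, "B": 0.1}, n_genes=1)
        records = [
            Measurement("mod", "A", "negative", source_id="impc"),
            Measurement("mod", "A", "negative", source_id="impc"),
            Measurement("mod", "A", "positive", source_id="impc"),
        ]
        profiles = build_model_profiles(records, two_child_graph, priors)
        assert profiles["mod"].values["A"] < 0.1

    def test_distinct_sources_update_separately(self, two_child_graph):
        from phenoscore import PriorVector, UpdateFactor, update_positive

        priors = PriorVector({"R": 0.5, "A": 0.1, "B": 0.1}, n_genes=1)
        records = [
            Measurement("mod", "A", "positive", source_id="pub1"),
            Measurement("mod", "A", "positive", source_id="pub2"),
        ]
        profiles = build_model_profiles(records, two_child_graph, priors)
        f = UpdateFactor(0.8, 0.05)
        expected = update_positive(update_positive(0.1, f), f)
        assert profiles["mod"].values["A"] == pytest.approx(expected, abs=1e-12)

    def test_order_invariance_of_measurement_list(self, bundle):
        rng = random.Random(3)
        shuffled = list(bundle.measurements)
        rng.shuffle(shuffled)
        again = build_model_profiles(
            shuffled, bundle.graph, bundle.priors, bundle.config
        )
        for mid, profile in bundle.models.items():
            for t, v in profile.values.items():
                assert again[mid].values[t] == pytest.approx(v, abs=1e-12)

    def test_uninformative_assay_rejected(self, two_child_graph):
        from phenoscore import PriorVector

        priors = PriorVector({"R": 0.5, "A": 0.1, "B": 0.1}, n_genes=1)
        bad = Measurement("mod", "A", "positive", tau=0.05, phi=0.8)
        with pytest.raises(DataError, match="uninformative"):
            build_model_profiles([bad], two_child_graph, priors)

    def test_sex_stratification_partitions_records(self, two_child_graph):
        from phenoscore import PriorVector

        priors = PriorVector({"R": 0.5, "A": 0.1, "B": 0.1}, n_genes=1)
        records = [
            Measurement("mod", "A", "positive", sex="F"),
            Measurement("mod", "B", "positive", sex="M"),
            Measurement("mod", "A", "positive", sex="U"),
        ]
        profiles = build_model_profiles(
            records, two_child_graph, priors, stratify_by_sex=True
        )
        assert set(profiles) == {"mod|F", "mod|M", "mod|U"}
        assert set(profiles["mod|F"].values) == {"A"}
        assert set(profiles["mod|M"].values) == {"B"}


def test_fill_background_covers_every_term(seven_term_graph):
    priors = estimate_priors(seven_term_graph, {"g": {"T:0000004"}})
    complete = build_complete(seven_term_graph, ConciseProfile("d", {"T:0000004": 0.4}))
    filled = fill_background(seven_term_graph, complete, priors, multiplier=0.5)
    assert set(filled.values) == set(seven_term_graph.terms)
    assert filled.provenance["T:0000007"] == "background"
    assert filled.values["T:0000007"] == pytest.approx(0.5 * priors["T:0000007"])
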