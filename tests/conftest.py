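import pytest

from phenoscore import (
    ConciseProfile,
    ScoringConfig,
    build_model_profiles,
    build_reference_set,
    estimate_priors,
    frequency_to_penetrance,
    score_all,
)
from phenoscore.io import frame_to_measurements
from phenoscore.simulate import CohortSpec, make_synthetic_cohort, make_toy_ontology

SEVEN_TERM_OBO = """format-version: 1.2
ontology: test

[Term]
id: T:0000001
name: root

[Term]
id: T:0000002
name: left
is_a: T:0000001

[Term]
id: T:0000003
name: right
alt_id: T:0000099
is_a: T:0000001

[Term]
id: T:0000004
name: left-left
is_a: T:0000002

[Term]
id: T:0000005
name: left-right
is_a: T:0000002

[Term]
id: T:0000006
name: right-left
is_a: T:0000003

[Term]
id: T:0000007
name: right-right
is_a: T:0000003
"""


@pytest.fixture(scope="session")
def seven_term_graph(tmp_path_factory):
    from phenoscore import parse_obo

    path = tmp_path_factory.mktemp("obo") / "seven.obo"
    path.write_text(SEVEN_TERM_OBO)
    return parse_obo(str(path))


@pytest.fixture(scope="session")
def diamond_graph():
    """D is_a B, D is_a C; B, C is_a A."""
    from phenoscore import OntologyGraph

    return OntologyGraph({"A": set(), "B": {"A"}, "C": {"A"}, "D": {"B", "C"}})


class CohortBundle:
    """The default synthetic study: ontology, corpus, priors, references,
    model profiles and the full score table, all derived from one seed."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.config = ScoringConfig()
        self.graph = make_toy_ontology(spec)
        self.cohort = make_synthetic_cohort(spec, self.graph)
        genes: dict[str, set[str]] = {}
        for r in self.cohort.gene_annotations.itertuples():
            genes.setdefault(r.gene_id, set()).add(r.term_id)
        self.gene_annotations = genes
        self.priors = estimate_priors(self.graph, genes, self.config.dark_count)
        d: dict[str, dict[str, float]] = {}
        for r in self.cohort.diseases.itertuples():
            d.setdefault(r.disease_id, {})[r.hp_term] = frequency_to_penetrance(
                r.frequency_code
            )
        self.diseases = {k: ConciseProfile(k, v) for k, v in d.items()}
        self.references = build_reference_set(
            self.graph, self.diseases, self.priors, self.config
        )
        self.measurements = frame_to_measurements(self.cohort.measurements)
        self.models = build_model_profiles(
            self.measurements, self.graph, self.priors, self.config
        )
        self.truth = list(zip(self.cohort.truth.disease_id,
                              self.cohort.truth.model_id))

    def score_table(self):
        if not hasattr(self, "_table"):
            self._table = score_all(
                self.graph, self.models, self.references, self.priors, self.config
            )
        return self._table


@pytest.fixture(scope="session")
def bundle():
    return CohortBundle(CohortSpec())
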