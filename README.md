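# phenoscore

Incremental Bayesian scoring of phenotype-annotated models (e.g. mouse
knockouts) against phenotype-annotated references (e.g. rare diseases).

## The problem

Animal models accumulate phenotype observations over years, across assays,
laboratories and publications. Deciding whether a mouse line phenocopies a
human disease usually means recomputing a similarity score over the full
annotation sets every time new data arrive, with normalisation steps that
make old and new scores incomparable. `phenoscore` instead treats every
single observation as a Bayes-style probability update: an observation with
true-positive rate τ and false-positive rate ϕ updates any probability p via

    p' = τ·p / ((τ − ϕ)·p + ϕ)

which is exactly multiplication of the odds p/(1−p) by ω = τ/ϕ. These
updates form a commutative group — τ=ϕ is the identity, swapping τ and ϕ
inverts, order never matters — so association scores can be accumulated
incrementally, measurement by measurement, and replayed in any order.

Phenotypes are terms of an ontology (the Mammalian Phenotype ontology for
mouse data; Human Phenotype annotations are carried over through a
precomputed translation table). The package builds:

- **priors** b(t): the background probability of each phenotype, estimated
  from a gene-annotation corpus with dark-count smoothing,
  b(t) = (dark + n(t)) / (2·dark + N);
- **reference profiles** per disease: penetrances OR-propagated up the
  hierarchy (a parent of children with values vᵢ gets 1 − Π(1 − vᵢ)),
  unannotated terms filled at b(t)·bg; plus a **specific** profile — the
  residual after subtracting the mean of the k nearest phenotypic
  neighbors — which emphasises disease-distinguishing phenotypes;
- **model profiles**: each measured term starts at b(t) and is updated per
  record (positive or negative), with optional sex stratification and
  per-source pooling.

Scoring a model against a reference compares, per phenotype, the model
value m, the reference value r, and the background b. Each comparison falls
into one of nine scenarios; the four corners (TP/FP/TN/FN) update the
association score with (τ, ϕ) from the comparison values, interpolated by
α = (r−b)/(Θ(r−b)−b). False positives get a composition of a contradiction
penalty and a confirmatory component credited through the nearest ancestor
annotated above background, balanced by β = tanh(fp·ln(b_a/b)).

On top of the scoring engine, the package audits disease annotation quality
with *technical controls* (synthetic models that positively report every
disease phenotype), classifying diseases as diagnostic / informative /
unspecific / suggestive / unscored; calibrates the two free parameters
(background multiplier, FP penalty) against known pairs vs count-matched
random pairs; and maintains a persistent workspace with an append-only
measurement log and incremental score refresh.

## Worked example

```python
from phenoscore import (
    OntologyGraph, ConciseProfile, Measurement, ScoringConfig,
    build_model_profiles, build_complete, fill_background,
    estimate_priors, score_association,
)

graph = OntologyGraph({
    "MP:0000001": set(),
    "MP:0003631": {"MP:0000001"},   # nervous system phenotype
    "MP:0005266": {"MP:0000001"},   # abnormal metabolism
    "MP:0002066": {"MP:0003631"},   # abnormal motor capabilities
    "MP:0001262": {"MP:0005266"},   # decreased body weight
    "MP:0001260": {"MP:0005266"},   # increased body weight
})

corpus = {f"gene{i}": {"MP:0001262"} for i in range(10)}
corpus |= {f"geneX{i}": {"MP:0002066"} for i in range(3)}
corpus |= {f"geneY{i}": {"MP:0001260"} for i in range(37)}
priors = estimate_priors(graph, corpus)

disease = ConciseProfile("ORPHA:toy", {"MP:0001262": 0.895, "MP:0002066": 0.545})
reference = fill_background(graph, build_complete(graph, disease), priors, 0.5)

measurements = [
    Measurement("Lep-ko", "MP:0001262", "positive"),
    Measurement("Lep-ko", "MP:0001260", "positive"),
    Measurement("Lep-ko", "MP:0002066", "negative"),
]
model = build_model_profiles(measurements, graph, priors)["Lep-ko"]
traj = score_association(graph, model, reference, priors, ScoringConfig())
for u in traj.updates:
    print(u.term, u.scenario.value, round(u.factor.tau, 4),
          round(u.factor.phi, 4), f"{u.score_after:.3e}")
print(f"final score {traj.final_score:.3e}  enrichment {traj.enrichment:.1f}x")
```

prints

```
MP:0001260 FP 0.1506 0.2778 5.423e-08
MP:0001262 TP 0.7397 0.2222 1.805e-07
MP:0002066 FN 0.9433 0.979 1.739e-07
final score 1.739e-07  enrichment 1.7x
```

Reading the trajectory: the model's spurious weight-gain call contradicts
the disease (FP, ω < 1, score drops below the 1e-7 prior), the concordant
weight-loss call is a strong confirmation (TP, ω ≈ 3.3), and the negative
motor result mildly penalises the association (FN) because the disease
expects that phenotype about half the time. The final 1.7× enrichment says
the evidence weakly favours the association — exactly the kind of
"suggestive but objectively weak" link the incremental breakdown makes
visible.

## Command line

`phenoscore` exposes the pipeline over a workspace directory:

```sh
phenoscore simulate sim/ --seed 1          # toy ontology + synthetic cohort
phenoscore init ws/ --ontology sim/ontology.obo
phenoscore priors ws/ --gene-annotations sim/gene_annotations.tsv
phenoscore references ws/ --disease-annotations sim/diseases.tsv
phenoscore update ws/ --measurements sim/measurements.tsv
phenoscore score ws/ --out scores.tsv
phenoscore classify ws/
phenoscore calibrate ws/ --known-pairs sim/truth.tsv --seed 1
```

Exit codes: 0 ok, 1 usage error, 2 data error.

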