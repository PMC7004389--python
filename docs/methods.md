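# Methods

## The update transformation

The framework's primitive is the probability update

    p' = τ·p / ((τ − ϕ)·p + ϕ),

the posterior of Bayes' rule when an assay with true-positive rate τ and
false-positive rate ϕ reports a positive outcome. Negative outcomes use the
replacements τ → 1−τ, ϕ → 1−ϕ. The update multiplies the odds p/(1−p) by
ω = τ/ϕ, so although two parameters are tracked for interpretability, each
update has a single degree of freedom. The set of updates under composition
is a commutative group: ω=1 (τ=ϕ) is the identity, (ϕ, τ) inverts (τ, ϕ),
and results are independent of order.

**Numerics.** Accumulated evidence is stored as a log-odds sum and converted
to a probability only at read-out. This makes order invariance hold to
≲1e-15 even across thousands of updates and keeps values near 0 and 1
well-conditioned. p = 0 and p = 1 are absorbing fixed points of the formula;
all probabilities entering odds computations are therefore clamped to
[ε, 1−ε] with ε = 1e-12, and a single update of an interior probability is
clamped back into the interior so rounding can never absorb a score. A
trajectory to which no factor has been applied reads out as exactly its
prior.

## Priors

Background phenotype probabilities are estimated from a gene-annotation
corpus: every gene contributes one unit count to each term it annotates and
to every ontology ancestor of those terms, at most once per gene and term.
With dark count d (default 2) and corpus size N,

    b(t) = (d + n(t)) / (2·d + N).

The symmetric normaliser (rather than (d + n)/N) keeps b strictly inside
(0, 1) even when every gene annotates a term, and preserves the two
properties the estimate must have: hierarchy monotonicity
b(parent) ≥ b(child), and invariance under adding unannotated terms to the
ontology (only the new term acquires a value, d/(2d+N)). The corpus-based
estimate inherits publication bias; it is a pragmatic stand-in for the
phenotype rates of a background population of mutants.

## Disease references

Frequency annotation codes decode to the midpoint of their declared range
(obligate 1.0; very frequent 0.895; frequent 0.545; occasional 0.17; very
rare 0.025; excluded 0.0); literal "m/n" and "x%" values pass through;
unknown codes are an error, never a silent default. Profiles annotated in a
foreign ontology are carried over through a precomputed translation table:
value v maps to v·tanh(score/tanh_scale), preserving penetrance for strong
translations and damping weak ones; several targets per source term all
receive the value, and collisions onto one target keep the maximum — a
translation is a renaming, not independent evidence. The tanh scale
defaults to 1.0, i.e. table scores are read on a unit scale where a score
of ~2 already transfers >96% of the penetrance.

**OR-propagation.** The complete profile assigns each term
1 − Π(1 − vᵢ) over the annotated values at or below it, reading the join of
children into a parent as an OR of independent phenotype events. On DAGs,
each annotated source term contributes exactly once to any ancestor no
matter how many paths connect them, so diamond topologies never
double-count one observation. A parent's own annotation joins the product
as one more source. Terms with no annotated descendant stay unvalued until
the background fill assigns b(t)·bg_multiplier. The multiplier (default
0.5, a free parameter) encodes a compromise between two readings of a
missing annotation — phenotype absent (0) vs status unknown (b).

**Specific profiles.** For each disease, the k = 5 nearest neighbors by
cosine similarity over general-profile vectors are averaged; the specific
profile is the residual general − mean(neighbors), clamped at 0 (a negative
probability is meaningless), with one repair: where a term sits above
background in the disease but the residual fell below background, the
specific value is restored to b(t), so genuinely annotated phenotypes are
never erased below the background by popular neighbors.

## Model profiles

Each measured term starts at b(t) and receives one update per
(term, source) group. A single record applies the plain positive/negative
update with its declared (τ, ϕ), defaulting to (0.8, 0.05) — the power and
significance criteria of common experiment design. Multiple records for one
term *within one source* are treated as mixed evidence from a screening
pipeline and collapse into a single update: ϕ is kept, and the effective
power is interpolated linearly in the positive fraction f̄,
τ_eff = ϕ + (τ−ϕ)·f̄, applied in the direction of the majority call (with
f̄ → 1−f̄ for a negative majority). This keeps each phenotype's direction
consistent between positive-only and positive+negative builds of the same
model. Records from distinct sources update separately, which is what lets
trajectories be replayed publication by publication. Records may be
partitioned by sex label (F/M/U) into stratified profiles before updating.
Assays with τ ≤ ϕ are rejected as uninformative.

## Scoring

For each model phenotype the engine compares the model value m and
reference value r to the background b (absolute tolerance 1e-9 for
equality, a float-safe reading of "exactly equal"). The four corner
scenarios update the association score; the five cells with an equality are
neutral by construction, since the α-interpolation

    α = (r − b) / (Θ(r − b) − b),   τ → α·τ + (1 − α)·ϕ

drives τ to ϕ (the identity) as r approaches b. Base parameters: TP (m, b);
TN (1−m, 1−b); FN (1−b, 1−m); FP (τ_a·(1−m), ϕ_a·(1−b)).

**False positives.** The FP update composes a contradiction penalty with a
confirmatory component earned through the hierarchy: the nearest ancestor
(breadth-first by hop distance, lexicographic tie-break — the ontology walk
must be deterministic) whose reference value exceeds its own background.
The model's evidence at the seed is expressed as the odds factor

    ω̃ = (m / (1 − m)) · ((1 − b) / b)

and projected onto the ancestor: m_a = ω̃·b_a / ((ω̃−1)·b_a + 1). This form
of ω̃ is pinned by two consistency requirements: when the ancestor's
background equals the seed's (b_a = b) the projection must be the identity
(m_a = m), and a model at background (m = b) must project to the ancestor's
background (m_a = b_a). The balance

    β = tanh(fp_penalty · ln(b_a / b)),  τ_a = (1−β)·m_a + β·b_a,  ϕ_a = b_a

approaches pure contradiction (τ_a → ϕ_a, net base ratio (1−m)/(1−b) < 1)
when the qualifying ancestor is far more general than the seed. α for FP
updates uses the ancestor's reference value r_a in the numerator with the
seed background in the denominator (a config switch selects b_a instead;
the defining sentence of the procedure is ambiguous between the two and the
seed reading is the literal one). When no ancestor qualifies there is no
fuzzy similarity to credit and the update is the bare contradiction
(1−m, 1−b) with α from r.

Association scores start at P0 = 1e-7 — not a calibrated probability of
incidence, but a baseline from which enrichment (score/P0) is tracked.
Scores for a (model, disease) pair depend only on that model, that
disease's profiles and the priors; there is no cross-normalisation, so
adding data for one model can never move another model's scores.

## Technical controls and disease classification

A technical control for a disease carries one positive default-(τ,ϕ)
measurement per concise disease phenotype. Scored against all diseases,
controls measure whether annotations are recoverable and discriminating.
Classification (enrichment thresholds, all configurable): below θ_min = 10
→ unscored; general and specific both ≥ θ_g = θ_s = 100 → diagnostic if the
control strictly beats its score against every other disease (ties are
never diagnostic), else informative; general only ≥ θ_g → unspecific;
otherwise suggestive. The class boundaries are acknowledged to be somewhat
arbitrary, which is why they are explicit config fields with declared
defaults rather than constants.

## Calibration

The two free parameters — background multiplier and FP penalty — are swept
over a grid. At each point the references are rebuilt and known
disease-model pairs are scored alongside matched random pairs: for each
known model, a seeded random other model with the same number of concise
phenotypes (nearest count as a recorded fallback; draws without replacement
while candidates remain). Matches are drawn once per sweep so grid points
differ only through the parameters. Summaries are log10-enrichment
quantiles; the recommended operating point is the grid point whose
random-pair median enrichment is closest to 1, i.e. where random pairings
show no evidence either way.

## Workspace

The workspace persists the measurement log, score table and run log in a
single-file SQLite store next to TSV exports; the storage engine is
incidental, the contract is not: batches append atomically (a single
malformed row rejects the whole batch with the offenders listed), only
models touched by a batch are re-profiled and re-scored, and a full rebuild
reproduces the incremental table exactly. Timestamps are caller-supplied
metadata and never enter score arithmetic — group commutativity makes
ordering cosmetic. Trajectory replay orders a model's phenotypes by the
lowest source identifier among their records, breaking ties
lexicographically, which reconstructs how an association would have
appeared to evolve as sources accrued.

## Synthetic cohort

The generator emulates the statistical structure of a phenomics study, not
the marginal distributions of any real resource. Defaults: a 3-ary
depth-4 tree (121 terms, 81 leaves; optional seeded "diamond" second
parents exercise DAG handling); 20 diseases × 4 leaf phenotypes, disjoint
at overlap 0; penetrance drawn uniformly from {0.25, 0.5, 0.895, 1.0} and
emitted through all four frequency-code encodings (literal percent,
fraction, class midpoint, obligate); 40 models — 5 planted causal pairs
whose positive calls are their disease's phenotypes flipped at the
false-call rate (default 0), the rest drawing phenotypes from diseases
without a planted pair; one negative record per four positives on
unrelated leaves; 10% of records carry a sex label; 200 background genes ×
3 leaf annotations for prior estimation. Leaf backgrounds land around
0.02–0.05, so a single positive call lifts a model phenotype to ~0.3–0.5,
comfortably above background — the regime the scoring grid distinguishes
well.

What passing tests on this cohort do **not** show: robustness to the deep,
unbalanced topology of real phenotype ontologies, to heavily shared
annotations between disease subtypes (which is precisely what drives real
diseases out of the diagnostic class), to translation noise between
ontologies, or to the annotation-count heterogeneity of curated corpora.
The cohort is a correctness instrument, not a realism claim.

## Problem sizes and determinism

Default test and acceptance runs use the cohort above (20 diseases, 40
models plus 20 technical controls, 121-term ontology) — sizes chosen so a
full pipeline pass, including property suites, completes in seconds while
still exercising every code path (DAGs, mixed frequency codes, negative
records, sex labels, multi-source pooling). All stochastic components
(cohort generation, random matching in calibration) are driven by explicit
seeds; the same seed reproduces outputs bit-identically.

## Known limitations

- Directional phenotype pairs (increased vs decreased body weight) receive
  no special treatment; a model can be rewarded through a shared ancestor
  of a phenotype pointing the "wrong" way.
- Saturated scores (≈1) convey that more data of the same kind will not
  change the picture, not that the association is certain.
- Priors inherit the publication and recency biases of the annotation
  corpus they are estimated from.
- The OR-propagation independence assumption is wrong for correlated
  phenotype pairs; it is accepted as a reasonable approximation.
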