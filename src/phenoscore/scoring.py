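"""Scoring a model against a reference profile.

Each model phenotype contributes one incremental update to the association
score. The update is derived in three steps: (1) compare the model value m
and the reference value r against the background b, yielding one of nine
scenarios; (2) pick base (τ, ϕ) for the four informative corners —
true/false positives and negatives; (3) interpolate τ toward ϕ according to
how far the reference prevalence sits from the background,
τ → α·τ + (1−α)·ϕ with α = (r−b)/(Θ(r−b)−b).

False positives are a composition of a contradiction penalty and a
confirmatory component credited through the nearest ancestor whose reference
value exceeds its own background: the model's evidence is projected onto the
ancestor as an odds factor ω̃ = (m/(1−m))·((1−b)/b), giving
m_a = ω̃·b_a/((ω̃−1)·b_a + 1), and the two components are balanced by
β = tanh(fp_penalty · ln(b_a/b)), which approaches 1 (pure contradiction)
when the qualifying ancestor is far more general than the seed phenotype.

Because every update multiplies the association odds by a fixed factor, the
final score is independent of the order in which phenotypes are processed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import bayes
from .bayes import UpdateFactor
from .config import ScoringConfig
from .errors import DataError
from .ontology import OntologyGraph
from .profiles import CompleteProfile, ConciseProfile, PriorVector, ReferenceSet

__all__ = [
    "Scenario",
    "ComparisonTriple",
    "AncestralContext",
    "ScoreUpdate",
    "ScoreTrajectory",
    "classify_comparison",
    "interpolation_alpha",
    "fp_ancestral",
    "update_parameters",
    "score_association",
    "score_all",
    "sum_scores",
]


class Scenario(enum.Enum):
    """The nine cells of the (m vs b) × (r vs b) comparison grid.

    Only the four corners update the score; the five cells with at least one
    equality are neutral.
    """

    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"
    EXPECTED_POSITIVE = "expected_positive"      # m = b, r > b
    EXPECTED_NEGATIVE = "expected_negative"      # m = b, r < b
    ANTICIPATED_POSITIVE = "anticipated_positive"  # m > b, r = b
    ANTICIPATED_NEGATIVE = "anticipated_negative"  # m < b, r = b
    UNDETERMINED = "undetermined"                # m = b, r = b

    @property
    def updates_score(self) -> bool:
        return self in (Scenario.TP, Scenario.FP, Scenario.TN, Scenario.FN)


@dataclass(frozen=True)
class ComparisonTriple:
    """Model value m, reference value r and background b for one term."""

    term: str
    m: float
    r: float
    b: float

    def __post_init__(self) -> None:
        for name in ("m", "r", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0,1], got {v} for {self.term}")
        if not (0.0 < self.b < 1.0):
            raise DataError(f"background must be interior, got {self.b}")


@dataclass(frozen=True)
class AncestralContext:
    """Confirmatory parameters derived from the nearest qualifying ancestor."""

    ancestor: str
    b_a: float
    r_a: float
    omega_tilde: float
    m_a: float
    tau_a: float
    phi_a: float
    beta: float


@dataclass(frozen=True)
class ScoreUpdate:
    term: str
    scenario: Scenario
    alpha: float
    factor: UpdateFactor | None
    score_before: float
    score_after: float
    ancestral: AncestralContext | None = None


@dataclass
class ScoreTrajectory:
    """Ordered per-phenotype score updates from prior to final association."""

    model_id: str
    reference_id: str
    kind: str  # "general" | "specific"
    prior: float
    updates: list[ScoreUpdate] = field(default_factory=list)
    final_score: float = 0.0

    @property
    def enrichment(self) -> float:
        return self.final_score / self.prior

    def n_scoring_updates(self) -> int:
        return sum(1 for u in self.updates if u.factor is not None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.updates):
            rows.append(
                {
                    "step": i,
                    "term": u.term,
                    "scenario": u.scenario.value,
                    "tau": u.factor.tau if u.factor else float("nan"),
                    "phi": u.factor.phi if u.factor else float("nan"),
                    "alpha": u.alpha,
                    "score_after": u.score_after,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["step", "term", "scenario", "tau", "phi", "alpha", "score_after"],
        )


# ---------------------------------------------------------------------------
# the three-step update derivation
# ---------------------------------------------------------------------------

def classify_comparison(c: ComparisonTriple, tol: float = 1e-9) -> Scenario:
    """Place a (m, r, b) triple into one of the nine comparison scenarios."""
    dm = 0 if abs(c.m - c.b) <= tol else (1 if c.m > c.b else -1)
    dr = 0 if abs(c.r - c.b) <= tol else (1 if c.r > c.b else -1)
    grid = {
        (1, 1): Scenario.TP,
        (1, -1): Scenario.FP,
        (-1, -1): Scenario.TN,
        (-1, 1): Scenario.FN,
        (0, 1): Scenario.EXPECTED_POSITIVE,
        (0, -1): Scenario.EXPECTED_NEGATIVE,
        (1, 0): Scenario.ANTICIPATED_POSITIVE,
        (-1, 0): Scenario.ANTICIPATED_NEGATIVE,
        (0, 0): Scenario.UNDETERMINED,
    }
    return grid[(dm, dr)]


def interpolation_alpha(r: float, b: float) -> float:
    """α = (r−b)/(Θ(r−b)−b): how far the reference sits from the background.

    Θ(r−b) is 1 when r > b and 0 otherwise, so α = (r−b)/(1−b) above
    background and (b−r)/b below; α = 0 at r = b and 1 at the extremes.
    """
    if r > b:
        return min((r - b) / (1.0 - b), 1.0)
    if r < b:
        return min((b - r) / b, 1.0)
    return 0.0


def fp_ancestral(
    graph: OntologyGraph,
    reference: CompleteProfile,
    c: ComparisonTriple,
    priors: PriorVector,
    config: ScoringConfig | None = None,
) -> AncestralContext | None:
    """Find the nearest ancestor justifying a confirmatory FP component.

    Walks the seed term's ancestors in breadth-first order (lexicographic
    tie-break) and stops at the first whose reference value exceeds its own
    background. Returns ``None`` when no ancestor qualifies — the FP update
    then degrades to the pure contradiction penalty.
    """
    config = config or ScoringConfig()
    seed = graph.resolve(c.term)
    chosen = None
    for anc in graph.ancestors(seed):
        if reference.values[anc] > priors[anc] + config.tol:
            chosen = anc
            break
    if chosen is None:
        return None
    b = bayes.clamp(c.b, config.epsilon)
    m = bayes.clamp(c.m, config.epsilon)
    b_a = bayes.clamp(priors[chosen], config.epsilon)
    omega_tilde = (m / (1.0 - m)) * ((1.0 - b) / b)
    m_a = omega_tilde * b_a / ((omega_tilde - 1.0) * b_a + 1.0)
    beta = math.tanh(config.fp_penalty * math.log(b_a / b)) if b_a > b else 0.0
    beta = max(beta, 0.0)
    tau_a = (1.0 - beta) * m_a + beta * b_a
    return AncestralContext(
        ancestor=chosen,
        b_a=b_a,
        r_a=reference.values[chosen],
        omega_tilde=omega_tilde,
        m_a=m_a,
        tau_a=tau_a,
        phi_a=b_a,
        beta=beta,
    )


def update_parameters(
    scenario: Scenario,
    c: ComparisonTriple,
    ctx: AncestralContext | None = None,
    config: ScoringConfig | None = None,
) -> tuple[UpdateFactor, float] | None:
    """Derive the (τ, ϕ) update factor and α for one comparison.

    Base parameters per corner scenario: TP (m, b); TN (1−m, 1−b);
    FN (1−b, 1−m); FP (τ_a·(1−m), ϕ_a·(1−b)) with the ancestral context, or
    the pure contradiction (1−m, 1−b) when no ancestor qualifies. τ is then
    interpolated toward ϕ by α, computed from r for the corner scenarios and
    from r_a for ancestral FPs. Neutral scenarios return ``None``.
    """
    config = config or ScoringConfig()
    if not scenario.updates_score:
        return None
    eps = config.epsilon
    m = bayes.clamp(c.m, eps)
    b = bayes.clamp(c.b, eps)
    if scenario is Scenario.TP:
        tau, phi = m, b
        alpha = interpolation_alpha(c.r, c.b)
    elif scenario is Scenario.TN:
        tau, phi = 1.0 - m, 1.0 - b
        alpha = interpolation_alpha(c.r, c.b)
    elif scenario is Scenario.FN:
        tau, phi = 1.0 - b, 1.0 - m
        alpha = interpolation_alpha(c.r, c.b)
    else:  # FP
        if ctx is None:
            tau, phi = 1.0 - m, 1.0 - b
            alpha = interpolation_alpha(c.r, c.b)
        else:
            tau = ctx.tau_a * (1.0 - m)
            phi = ctx.phi_a * (1.0 - b)
            denom_b = b if config.fp_alpha_denominator == "seed" else ctx.b_a
            alpha = interpolation_alpha(ctx.r_a, denom_b)
    tau = bayes.clamp(alpha * tau + (1.0 - alpha) * phi, eps)
    phi = bayes.clamp(phi, eps)
    return UpdateFactor(tau, phi), alpha


# ---------------------------------------------------------------------------
# trajectories and tables
# ---------------------------------------------------------------------------

def score_association(
    graph: OntologyGraph,
    model: ConciseProfile,
    reference: CompleteProfile,
    priors: PriorVector,
    config: ScoringConfig | None = None,
    kind: str = "general",
    order: Sequence[str] | None = None,
) -> ScoreTrajectory:
    """Score one model against one reference, phenotype by phenotype.

    The score starts at the association prior P0 and is multiplied, in odds
    space, by one update factor per model phenotype. ``order`` overrides the
    default lexicographic iteration order; the final score is order-invariant
    by construction (only the recorded trajectory changes).
    """
    config = config or ScoringConfig()
    p0 = config.prior_association
    traj = ScoreTrajectory(
        model_id=model.owner, reference_id=reference.owner, kind=kind, prior=p0
    )
    terms = list(order) if order is not None else sorted(model.values)
    if order is not None and sorted(terms) != sorted(model.values):
        raise DataError("order must be a permutation of the model's terms")
    log_odds0 = bayes.logit(bayes.clamp(p0, config.epsilon))
    delta = 0.0  # accumulated log-odds; zero delta reads out as exactly P0
    score = p0
    for term in terms:
        canonical = graph.resolve(term)
        c = ComparisonTriple(
            term=canonical,
            m=model.values[term],
            r=reference.values[canonical],
            b=priors[canonical],
        )
        scenario = classify_comparison(c, config.tol)
        ctx = None
        if scenario is Scenario.FP:
            ctx = fp_ancestral(graph, reference, c, priors, config)
        derived = update_parameters(scenario, c, ctx, config)
        before = score
        if derived is None:
            traj.updates.append(
                ScoreUpdate(canonical, scenario, 0.0, None, before, before, None)
            )
            continue
        factor, alpha = derived
        delta += factor.log_omega
        score = p0 if delta == 0.0 else bayes.expit(log_odds0 + delta)
        traj.updates.append(
            ScoreUpdate(canonical, scenario, alpha, factor, before, score, ctx)
        )
    traj.final_score = score
    return traj


def score_all(
    graph: OntologyGraph,
    models: Mapping[str, ConciseProfile],
    reference_set: ReferenceSet,
    priors: PriorVector,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Score every model against every disease's general and specific profile.

    Returns a deterministic table with one row per (model, disease) pair.
    There is no cross-normalisation: each row depends only on that model,
    that disease's profiles and the priors.
    """
    if not models or not reference_set.general:
        raise DataError("score_all needs at least one model and one reference")
    config = config or ScoringConfig()
    rows = []
    for model_id in sorted(models):
        for disease_id in reference_set.disease_ids():
            g = score_association(
                graph, models[model_id], reference_set.general[disease_id],
                priors, config, kind="general",
            )
            s = score_association(
                graph, models[model_id], reference_set.specific[disease_id],
                priors, config, kind="specific",
            )
            rows.append(
                {
                    "model_id": model_id,
                    "disease_id": disease_id,
                    "general_score": g.final_score,
                    "specific_score": s.final_score,
                    "n_updates": g.n_scoring_updates(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["model_id", "disease_id", "general_score", "specific_score", "n_updates"],
    )


def sum_scores(
    table: pd.DataFrame,
    axis: str = "disease",
    model_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Sum general and specific scores per disease or per gene.

    The sums estimate how many models (or genes) phenocopy each disease —
    or, by gene, how many diseases a gene's models resemble. ``axis`` is
    "disease", "model" or "gene"; summing by gene requires a model -> gene
    map.
    """
    if axis == "disease":
        key = table["disease_id"]
    elif axis == "model":
        key = table["model_id"]
    elif axis == "gene":
        if model_to_gene is None:
            raise DataError("summing by gene requires a model_to_gene map")
        key = table["model_id"].map(dict(model_to_gene))
        if key.isna().any():
            missing = sorted(table.loc[key.isna(), "model_id"].unique())
            raise DataError(f"model(s) without gene mapping: {missing}")
    else:
        raise DataError(f"unknown axis {axis!r}")
    out = (
        table.assign(_key=key)
        .groupby("_key")[["general_score", "specific_score"]]
        .sum()
        .rename_axis(axis)
        .reset_index()
    )
    return out
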