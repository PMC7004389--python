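"""Phenotype priors and concise/complete/specific profile construction.

A *concise* profile maps only measured or annotated terms to probabilities;
a *complete* profile carries a value for every ontology term, obtained by
OR-propagation up the hierarchy plus background fill. Disease references get
an additional *specific* profile: the residual after subtracting the mean of
the disease's nearest phenotypic neighbors, which emphasises the phenotypes
that distinguish the disease from look-alikes.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from . import bayes
from .bayes import UpdateFactor
from .config import ScoringConfig
from .errors import DataError, UnknownTermError
from .ontology import OntologyGraph

__all__ = [
    "PriorVector",
    "ConciseProfile",
    "CompleteProfile",
    "ReferenceSet",
    "Measurement",
    "estimate_priors",
    "frequency_to_penetrance",
    "translate_profile",
    "build_complete",
    "fill_background",
    "build_reference_set",
    "build_model_profiles",
]

Provenance = Literal["annotated", "propagated", "background"]


@dataclass(frozen=True)
class PriorVector:
    """Background probability b(t) for every ontology term.

    b(t) = (dark + n(t)) / (2·dark + N) where n(t) counts the corpus genes
    annotating t or any of its descendants (each gene at most once) and N is
    the corpus size. The symmetric dark-count smoothing keeps every value
    strictly inside (0, 1) and preserves hierarchy monotonicity
    b(parent) >= b(child).
    """

    b: dict[str, float]
    n_genes: int
    dark_count: int = 2

    def __getitem__(self, term: str) -> float:
        return self.b[term]

    def __contains__(self, term: str) -> bool:
        return term in self.b

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.b.get(term, default)


@dataclass
class ConciseProfile:
    """Phenotype -> probability map restricted to measured/annotated terms."""

    owner: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.values.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise DataError(f"profile {self.owner!r} has values outside [0,1]: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.values))


@dataclass
class CompleteProfile:
    """Phenotype -> probability map over *all* ontology terms.

    ``provenance`` records, per term, whether the value was directly
    annotated, OR-propagated from descendants, or filled from the background.
    """

    owner: str
    values: dict[str, float]
    provenance: dict[str, Provenance]

    def __getitem__(self, term: str) -> float:
        return self.values[term]


@dataclass
class ReferenceSet:
    """Per-disease general and specific complete profiles."""

    general: dict[str, CompleteProfile]
    specific: dict[str, CompleteProfile]
    neighbors: dict[str, tuple[str, ...]]

    def disease_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.general))


@dataclass(frozen=True)
class Measurement:
    """One experimental phenotype call for a model.

    ``outcome`` is "positive" when the assay supported the phenotype and
    "negative" when the measurement was performed but the phenotype was not
    called. Defaults τ=0.8, ϕ=0.05 correspond to common experiment-design
    criteria (power 0.8, significance 0.05).
    """

    model_id: str
    term: str
    outcome: str
    tau: float = 0.8
    phi: float = 0.05
    source_id: str = "default"
    sex: str = "U"
    gene: str = ""
    allele: str = ""
    zygosity: str = ""
    strain: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in ("positive", "negative"):
            raise DataError(
                f"outcome must be 'positive' or 'negative', got {self.outcome!r}"
            )
        if not (0.0 < self.tau < 1.0 and 0.0 < self.phi < 1.0):
            raise DataError(
                f"tau/phi must be in (0,1), got ({self.tau}, {self.phi})"
            )
        if self.sex not in ("F", "M", "U"):
            raise DataError(f"sex must be F, M or U, got {self.sex!r}")


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def estimate_priors(
    graph: OntologyGraph,
    gene_annotations: Mapping[str, Iterable[str]],
    dark_count: int = 2,
) -> PriorVector:
    """Estimate background phenotype probabilities from an annotation corpus.

    Each gene contributes one unit count to every term it annotates and to
    all ontology-inferred ancestors of those terms (at most once per gene and
    term). Counts start from ``dark_count`` and are normalised so that every
    value stays strictly inside (0, 1).
    """
    if not gene_annotations:
        raise DataError("cannot estimate priors from an empty gene corpus")
    counts = {t: 0 for t in graph.terms}
    unknown: set[str] = set()
    for gene, terms in gene_annotations.items():
        closure: set[str] = set()
        for term in terms:
            try:
                canonical = graph.resolve(term)
            except UnknownTermError:
                unknown.add(term)
                continue
            closure.add(canonical)
            closure.update(graph.ancestors(canonical))
        for t in closure:
            counts[t] += 1
    if unknown:
        raise DataError(f"gene annotations reference unknown term(s): {sorted(unknown)}")
    n = len(gene_annotations)
    denom = 2 * dark_count + n
    b = {t: (dark_count + c) / denom for t, c in counts.items()}
    return PriorVector(b=b, n_genes=n, dark_count=dark_count)


# ---------------------------------------------------------------------------
# disease annotations
# ---------------------------------------------------------------------------

#: Midpoints of the standard 'Frequency' annotation class ranges.
_FREQUENCY_CLASSES = {
    "obligate": 1.0,
    "very frequent": (0.80 + 0.99) / 2,
    "frequent": (0.30 + 0.79) / 2,
    "occasional": (0.05 + 0.29) / 2,
    "very rare": (0.01 + 0.04) / 2,
    "excluded": 0.0,
}

_FRACTION_RE = re.compile(r"^(\d+)\s*/\s*(\d+)$")
_PERCENT_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*%$")


def frequency_to_penetrance(code: str) -> float:
    """Convert a frequency annotation code to a penetrance probability.

    Standard class labels map to the midpoint of their declared range
    (e.g. "very frequent" = [80, 99]% -> 0.895); literal "m/n" fractions and
    "x%" percentages pass through. Unknown codes raise — there is no silent
    default.
    """
    key = str(code).strip().lower().replace("_", " ")
    if key in _FREQUENCY_CLASSES:
        return _FREQUENCY_CLASSES[key]
    m = _FRACTION_RE.match(key)
    if m:
        num, den = int(m.group(1)), int(m.group(2))
        if den == 0 or num > den:
            raise DataError(f"invalid fraction frequency code {code!r}")
        return num / den
    m = _PERCENT_RE.match(key)
    if m:
        v = float(m.group(1)) / 100.0
        if v > 1.0:
            raise DataError(f"percentage frequency code {code!r} exceeds 100%")
        return v
    try:
        v = float(key)
    except ValueError:
        raise DataError(f"unknown frequency code {code!r}") from None
    if not (0.0 <= v <= 1.0):
        raise DataError(f"literal frequency {code!r} outside [0,1]")
    return v


def translate_profile(
    concise_hp: ConciseProfile,
    table: Iterable[tuple[str, str, float]],
    config: ScoringConfig | None = None,
) -> ConciseProfile:
    """Carry a profile across ontologies using a precomputed translation table.

    Each table row (hp_term, mp_term, score) maps value v to
    v · tanh(score / tanh_scale): strong translations preserve penetrance,
    weak ones are down-weighted. A source term with several equally good
    targets populates each of them; when several source terms land on the
    same target, the maximum is kept (a translation is a renaming, not
    independent evidence). Source terms absent from the table are skipped
    with a warning.
    """
    config = config or ScoringConfig()
    mapping: dict[str, list[tuple[str, float]]] = {}
    n_rows = 0
    for hp, mp, score in table:
        n_rows += 1
        mapping.setdefault(hp, []).append((mp, float(score)))
    if n_rows == 0:
        raise DataError("translation table is empty")
    out: dict[str, float] = {}
    missing: list[str] = []
    for hp, v in concise_hp.values.items():
        rows = mapping.get(hp)
        if not rows:
            missing.append(hp)
            continue
        for mp, score in rows:
            scaled = v * math.tanh(score / config.tanh_scale)
            if mp not in out or scaled > out[mp]:
                out[mp] = scaled
    if missing:
        warnings.warn(
            f"{len(missing)} term(s) of {concise_hp.owner!r} missing from the "
            f"translation table were skipped: {sorted(missing)}",
            stacklevel=2,
        )
    return ConciseProfile(owner=concise_hp.owner, values=out)


# ---------------------------------------------------------------------------
# complete profiles
# ---------------------------------------------------------------------------

def build_complete(graph: OntologyGraph, concise: ConciseProfile) -> CompleteProfile:
    """OR-propagate a concise profile up the hierarchy (no background fill).

    A parent whose children carry values v_i gets 1 − Π(1 − v_i), reading the
    join of children into a parent as an OR of independent events; the
    parent's own annotated value, if any, joins the product as one more
    source. On DAGs each annotated source term contributes at most once to
    any ancestor, so one observation is never double-counted through diamond
    topologies. Terms with no annotated descendant and no own value stay
    unvalued (their provenance is unset).
    """
    annotated: dict[str, float] = {}
    for term, v in concise.values.items():
        annotated[graph.resolve(term)] = v
    sources: dict[str, set[str]] = {}
    for term in graph.topological_order():  # children before parents
        s: set[str] = set()
        if term in annotated:
            s.add(term)
        for child in graph.children[term]:
            s |= sources.get(child, frozenset())
        if s:
            sources[term] = s
    values: dict[str, float] = {}
    provenance: dict[str, Provenance] = {}
    for term, s in sources.items():
        log_none = math.fsum(math.log1p(-annotated[src]) for src in s
                             if annotated[src] < 1.0)
        values[term] = 1.0 if any(annotated[src] >= 1.0 for src in s) \
            else -math.expm1(log_none)
        provenance[term] = "annotated" if term in annotated else "propagated"
    return CompleteProfile(owner=concise.owner, values=values, provenance=provenance)


def fill_background(
    graph: OntologyGraph,
    profile: CompleteProfile,
    priors: PriorVector,
    multiplier: float = 1.0,
) -> CompleteProfile:
    """Give every still-unvalued term the value b(t) · multiplier."""
    values = dict(profile.values)
    provenance = dict(profile.provenance)
    for term in graph.terms:
        if term not in values:
            values[term] = min(priors[term] * multiplier, 1.0)
            provenance[term] = "background"
    return CompleteProfile(owner=profile.owner, values=values, provenance=provenance)


# ---------------------------------------------------------------------------
# reference set
# ---------------------------------------------------------------------------

def build_reference_set(
    graph: OntologyGraph,
    diseases: Mapping[str, ConciseProfile],
    priors: PriorVector,
    config: ScoringConfig | None = None,
) -> ReferenceSet:
    """Build general and specific complete profiles for a disease corpus.

    General profile: OR-propagation of the annotated penetrances followed by
    background fill at b(t) · bg_multiplier. Specific profile: the general
    profile minus the mean of its k nearest neighbors (cosine similarity over
    general-profile vectors), clamped at zero; where a term is annotated
    above background in the disease but the residual fell below background,
    the specific value is restored to the background.
    """
    config = config or ScoringConfig()
    k = config.k_neighbors
    ids = sorted(diseases)
    if len(ids) < k + 1:
        raise DataError(
            f"need at least k_neighbors+1 = {k + 1} diseases for specific "
            f"profiles, got {len(ids)}"
        )
    general = {
        d: fill_background(
            graph, build_complete(graph, diseases[d]), priors, config.bg_multiplier
        )
        for d in ids
    }
    terms = sorted(graph.terms)
    mat = np.array([[general[d].values[t] for t in terms] for d in ids])
    norms = np.linalg.norm(mat, axis=1)
    zero = [ids[i] for i in np.nonzero(norms == 0)[0]]
    if zero:
        raise DataError(f"cosine similarity undefined for all-zero profile(s): {zero}")
    unit = mat / norms[:, None]
    sim = unit @ unit.T

    b_vec = np.array([priors[t] for t in terms])
    specific: dict[str, CompleteProfile] = {}
    neighbors: dict[str, tuple[str, ...]] = {}
    for i, d in enumerate(ids):
        order = sorted(
            (j for j in range(len(ids)) if j != i),
            key=lambda j: (-sim[i, j], ids[j]),
        )
        nn = order[:k]
        neighbors[d] = tuple(ids[j] for j in nn)
        residual = np.clip(mat[i] - mat[nn].mean(axis=0), 0.0, None)
        lift = (mat[i] > b_vec + config.tol) & (residual < b_vec)
        residual[lift] = b_vec[lift]
        specific[d] = CompleteProfile(
            owner=d,
            values=dict(zip(terms, residual.tolist())),
            provenance=dict(general[d].provenance),
        )
    return ReferenceSet(general=general, specific=specific, neighbors=neighbors)


# ---------------------------------------------------------------------------
# model profiles
# ---------------------------------------------------------------------------

def _apply_group(b: float, group: list[Measurement], eps: float) -> float:
    """Update one term's probability from all records of one source.

    A single record applies the plain positive/negative update. Multiple
    records for the same term within one source are mixed evidence from a
    screening pipeline; they collapse into a single update whose
    false-positive rate is unchanged and whose effective power is
    interpolated linearly in the positive fraction f̄:
    τ_eff = ϕ + (τ − ϕ)·f̄, applied in the direction of the majority call.
    """
    p = bayes.clamp(b, eps)
    if len(group) == 1:
        m = group[0]
        f = UpdateFactor(m.tau, m.phi)
        return bayes.update_positive(p, f) if m.outcome == "positive" \
            else bayes.update_negative(p, f)
    tau = float(np.mean([m.tau for m in group]))
    phi = float(np.mean([m.phi for m in group]))
    f_pos = sum(1 for m in group if m.outcome == "positive") / len(group)
    if f_pos >= 0.5:
        return bayes.update_positive(p, UpdateFactor(phi + (tau - phi) * f_pos, phi))
    return bayes.update_negative(p, UpdateFactor(phi + (tau - phi) * (1 - f_pos), phi))


def build_model_profiles(
    measurements: Iterable[Measurement],
    graph: OntologyGraph,
    priors: PriorVector,
    config: ScoringConfig | None = None,
    stratify_by_sex: bool = False,
) -> dict[str, ConciseProfile]:
    """Turn measurement records into concise model profiles.

    Each measured term starts at its background b(t) and receives one update
    per (term, source) group; see :func:`_apply_group` for the multi-record
    rule. With ``stratify_by_sex`` the records are partitioned into separate
    F/M/U profiles (keyed ``"<model>|<sex>"``) before updating. Unmeasured
    terms are absent from the result. An empty measurement list yields an
    empty dict — downstream scoring then leaves associations at their prior.
    """
    config = config or ScoringConfig()
    measurements = list(measurements)
    for m in measurements:
        if m.tau <= m.phi:
            raise DataError(
                f"uninformative assay for {m.model_id}/{m.term}: "
                f"tau={m.tau} <= phi={m.phi}"
            )
    grouped: dict[str, dict[str, dict[str, list[Measurement]]]] = {}
    for m in measurements:
        term = graph.resolve(m.term)
        key = f"{m.model_id}|{m.sex}" if stratify_by_sex else m.model_id
        grouped.setdefault(key, {}).setdefault(term, {}).setdefault(
            m.source_id, []
        ).append(m)
    profiles: dict[str, ConciseProfile] = {}
    for key in sorted(grouped):
        values: dict[str, float] = {}
        for term in sorted(grouped[key]):
            p = bayes.clamp(priors[term], config.epsilon)
            log_odds = bayes.logit(p)
            base = p
            for source in sorted(grouped[key][term]):
                p_next = _apply_group(base, grouped[key][term][source], config.epsilon)
                log_odds += bayes.logit(p_next) - bayes.logit(base)
            values[term] = bayes.expit(log_odds)
        profiles[key] = ConciseProfile(owner=key, values=values)
    return profiles
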