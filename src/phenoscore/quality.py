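"""Annotation-quality audit via technical controls.

A technical control is a synthetic model carrying one positive measurement
per concise phenotype of a disease. Scoring every control against every
disease reveals whether the disease's annotations are recoverable
(high score against its own disease) and discriminating (best recovered by
its own control rather than another disease's). Diseases are then assigned
one of five classes:

- diagnostic:  own control scores high on both profiles and strictly beats
               its score against every other disease (general profile);
- informative: high on both profiles but not uniquely best;
- unspecific:  high on the general profile only;
- suggestive:  scored, but below the high thresholds;
- unscored:    the control never achieved a minimal improvement over the
               prior.

Thresholds are enrichment-based (score / P0) and configurable; the
boundaries are acknowledged to be somewhat arbitrary, so they are explicit
parameters rather than constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .config import ScoringConfig
from .errors import DataError
from .ontology import OntologyGraph
from .profiles import (
    ConciseProfile,
    Measurement,
    PriorVector,
    ReferenceSet,
    build_model_profiles,
)
from .scoring import score_all

__all__ = [
    "TechnicalControl",
    "DISEASE_CLASSES",
    "make_technical_control",
    "classify_diseases",
    "audit_annotations",
]

DISEASE_CLASSES = ("diagnostic", "informative", "unspecific", "suggestive", "unscored")

CONTROL_PREFIX = "control:"


@dataclass(frozen=True)
class TechnicalControl:
    """Synthetic confirmatory measurements for one disease's phenotypes."""

    disease_id: str
    measurements: tuple[Measurement, ...]

    @property
    def model_id(self) -> str:
        return CONTROL_PREFIX + self.disease_id


def make_technical_control(
    disease: ConciseProfile, config: ScoringConfig | None = None
) -> TechnicalControl:
    """One positive measurement per concise disease phenotype, default (τ,ϕ)."""
    config = config or ScoringConfig()
    if not disease.values:
        raise DataError(
            f"disease {disease.owner!r} has no phenotypes; its control is "
            "unscorable by construction"
        )
    measurements = tuple(
        Measurement(
            model_id=CONTROL_PREFIX + disease.owner,
            term=term,
            outcome="positive",
            tau=config.default_tau,
            phi=config.default_phi,
            source_id="technical-control",
        )
        for term in disease.terms()
    )
    return TechnicalControl(disease_id=disease.owner, measurements=measurements)


def classify_diseases(
    control_scores: pd.DataFrame,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Assign the five annotation-quality classes from a control score table.

    ``control_scores`` must hold one row per (control, disease) pair with
    columns model_id (``control:<disease>``), disease_id, general_score and
    specific_score, covering every control against every disease.
    """
    config = config or ScoringConfig()
    p0 = config.prior_association
    table = control_scores.copy()
    table["source_disease"] = table["model_id"].str.removeprefix(CONTROL_PREFIX)
    rows = []
    for disease, sub in table.groupby("source_disease", sort=True):
        own = sub[sub["disease_id"] == disease]
        if own.empty:
            raise DataError(f"missing own-control row for disease {disease!r}")
        own_general = float(own["general_score"].iloc[0])
        own_specific = float(own["specific_score"].iloc[0])
        others = sub[sub["disease_id"] != disease]
        if others.empty:
            best_other, best_other_score = "", float("nan")
        else:
            idx = others["general_score"].idxmax()
            best_other = str(others.loc[idx, "disease_id"])
            best_other_score = float(others.loc[idx, "general_score"])
        gen_enrich = own_general / p0
        spec_enrich = own_specific / p0
        if gen_enrich < config.theta_min:
            cls = "unscored"
        elif gen_enrich >= config.theta_general and spec_enrich >= config.theta_specific:
            beats_all = others.empty or own_general > best_other_score
            cls = "diagnostic" if beats_all else "informative"
        elif gen_enrich >= config.theta_general:
            cls = "unspecific"
        else:
            cls = "suggestive"
        rows.append(
            {
                "disease_id": disease,
                "disease_class": cls,
                "own_general": own_general,
                "own_specific": own_specific,
                "best_other_disease": best_other,
                "best_other_score": best_other_score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "disease_id",
            "disease_class",
            "own_general",
            "own_specific",
            "best_other_disease",
            "best_other_score",
        ],
    )


def audit_annotations(
    graph: OntologyGraph,
    diseases: Mapping[str, ConciseProfile],
    reference_set: ReferenceSet,
    priors: PriorVector,
    config: ScoringConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build all controls, score them against all diseases, and classify.

    Returns (classification table, full control score table).
    """
    config = config or ScoringConfig()
    measurements = [
        m
        for d in sorted(diseases)
        for m in make_technical_control(diseases[d], config).measurements
    ]
    profiles = build_model_profiles(measurements, graph, priors, config)
    scores = score_all(graph, profiles, reference_set, priors, config)
    return classify_diseases(scores, config), scores
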