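"""Scoring configuration shared across the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import DataError

__all__ = ["ScoringConfig"]


@dataclass
class ScoringConfig:
    """All tunable parameters of the scoring framework.

    Attributes
    ----------
    dark_count
        Smoothing count added to every term when estimating phenotype priors.
    bg_multiplier
        Multiplier applied to the background prior when filling reference
        terms that carry no annotation — a compromise between reading a
        missing annotation as "phenotype absent" (0) and "status unknown"
        (the background itself). Free parameter, calibrated against known
        associations.
    fp_penalty
        Strength of the contradiction penalty for false-positive comparisons;
        enters β = tanh(fp_penalty · ln(b_a/b)). Free parameter.
    k_neighbors
        Number of nearest phenotypic neighbors averaged when building
        specific disease profiles.
    prior_association
        P0, the association score every model-reference pair starts from.
    default_tau, default_phi
        Assay power and false-positive rate assumed for measurements that do
        not declare their own.
    tanh_scale
        Scale of the hyperbolic-tangent weighting of cross-ontology
        translation scores: a translation of score s multiplies the carried
        penetrance by tanh(s / tanh_scale).
    theta_min, theta_general, theta_specific
        Enrichment (score / P0) thresholds for the five-class annotation
        quality classification of diseases.
    tol
        Absolute tolerance for "equal to background" comparisons.
    fp_alpha_denominator
        Which background enters the denominator of the interpolation factor α
        for false-positive updates: "seed" uses the seed phenotype's b
        (default), "ancestor" uses the ancestral b_a.
    epsilon
        Clamp width keeping probabilities away from the absorbing 0/1.
    """

    dark_count: int = 2
    bg_multiplier: float = 0.5
    fp_penalty: float = 1.0
    k_neighbors: int = 5
    prior_association: float = 1e-7
    default_tau: float = 0.8
    default_phi: float = 0.05
    tanh_scale: float = 1.0
    theta_min: float = 10.0
    theta_general: float = 100.0
    theta_specific: float = 100.0
    tol: float = 1e-9
    fp_alpha_denominator: str = "seed"
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("bg_multiplier", "prior_association", "default_tau", "default_phi"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and name != "bg_multiplier":
                raise DataError(f"{name} must be in (0,1), got {v}")
        if self.bg_multiplier <= 0:
            raise DataError(f"bg_multiplier must be > 0, got {self.bg_multiplier}")
        if self.fp_penalty < 0:
            raise DataError(f"fp_penalty must be >= 0, got {self.fp_penalty}")
        if self.k_neighbors < 1:
            raise DataError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if self.dark_count < 1:
            raise DataError(f"dark_count must be >= 1, got {self.dark_count}")
        if self.default_tau <= self.default_phi:
            raise DataError("default_tau must exceed default_phi")
        if self.fp_alpha_denominator not in ("seed", "ancestor"):
            raise DataError(
                "fp_alpha_denominator must be 'seed' or 'ancestor', "
                f"got {self.fp_alpha_denominator!r}"
            )

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise DataError(f"config file {path!r} must hold a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
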