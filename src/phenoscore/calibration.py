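"""Calibration of the free parameters against known associations.

The background multiplier (bg) and the false-positive penalty (fp) cannot be
fixed from first principles. They are swept over a grid: at each grid point
the references are rebuilt with that bg, and known (curated) disease-model
pairs are scored alongside matched random pairs — for each known model, a
randomly chosen other model with the same number of concise phenotypes
(nearest count as a recorded fallback). A well-calibrated operating point
leaves random pairs, on average, with no enrichment over the prior.

Enrichment is final score / P0, summarised as log10 quantiles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ScoringConfig
from .errors import DataError
from .ontology import OntologyGraph
from .profiles import ConciseProfile, PriorVector, build_reference_set
from .scoring import score_association

__all__ = [
    "CalibrationResult",
    "calibrate",
    "recommend_operating_point",
    "results_to_frame",
]

_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)
_CELLS = tuple(
    (kind, cohort)
    for kind in ("general", "specific")
    for cohort in ("known", "random")
)


@dataclass(frozen=True)
class CalibrationResult:
    """Enrichment summaries at one (bg_multiplier, fp_penalty) grid point.

    ``quantiles`` maps (profile kind, cohort) — e.g. ("general", "random") —
    to the (5%, 25%, 50%, 75%, 95%) quantiles of log10 enrichment.
    """

    bg_multiplier: float
    fp_penalty: float
    quantiles: dict[tuple[str, str], tuple[float, float, float, float, float]]
    n_pairs: int
    exact_match_fraction: float

    def median(self, kind: str, cohort: str) -> float:
        return self.quantiles[(kind, cohort)][2]


def _match_random_models(
    known_pairs: Sequence[tuple[str, str]],
    models: Mapping[str, ConciseProfile],
    rng: np.random.Generator,
) -> tuple[list[str], float]:
    """Pick, per known pair, a random other model with matching term count.

    Matching is on the number of concise phenotypes; when no other model has
    the exact count, the nearest count is used and counted as a fallback.
    Draws are without replacement across known pairs while candidates remain.
    """
    counts = {mid: len(p.values) for mid, p in models.items()}
    used: set[str] = set()
    matched: list[str] = []
    exact = 0
    for disease_id, model_id in known_pairs:
        target = counts[model_id]
        candidates = [m for m in sorted(models) if m != model_id and m not in used]
        if not candidates:
            candidates = [m for m in sorted(models) if m != model_id]
        if not candidates:
            raise DataError("need at least two models for random matching")
        best_gap = min(abs(counts[m] - target) for m in candidates)
        pool = [m for m in candidates if abs(counts[m] - target) == best_gap]
        choice = pool[int(rng.integers(len(pool)))]
        if counts[choice] == target:
            exact += 1
        used.add(choice)
        matched.append(choice)
    return matched, exact / len(known_pairs)


def calibrate(
    known_pairs: Sequence[tuple[str, str]],
    models: Mapping[str, ConciseProfile],
    diseases: Mapping[str, ConciseProfile],
    graph: OntologyGraph,
    priors: PriorVector,
    grid: Iterable[tuple[float, float]],
    seed: int,
    config: ScoringConfig | None = None,
) -> list[CalibrationResult]:
    """Sweep (bg_multiplier, fp_penalty) over known vs matched random pairs.

    ``known_pairs`` are (disease_id, model_id) tuples. References are rebuilt
    from the disease concise profiles at every bg value. The random matches
    are drawn once from ``seed``, so grid points differ only through the
    parameters; the whole sweep is reproducible from the seed.
    """
    config = config or ScoringConfig()
    known_pairs = list(known_pairs)
    grid = list(grid)
    if not known_pairs:
        raise DataError("calibration needs at least one known pair")
    if not grid:
        raise DataError("calibration needs at least one grid point")
    for disease_id, model_id in known_pairs:
        if disease_id not in diseases:
            raise DataError(f"unknown disease in known pairs: {disease_id!r}")
        if model_id not in models:
            raise DataError(f"unknown model in known pairs: {model_id!r}")
    for bg, fp in grid:
        if bg <= 0:
            raise DataError(f"degenerate bg_multiplier {bg} in grid")
        if fp < 0:
            raise DataError(f"negative fp_penalty {fp} in grid")

    rng = np.random.default_rng(seed)
    matched, exact_fraction = _match_random_models(known_pairs, models, rng)

    results: list[CalibrationResult] = []
    for bg, fp in grid:
        cfg = dataclasses.replace(config, bg_multiplier=bg, fp_penalty=fp)
        refs = build_reference_set(graph, diseases, priors, cfg)
        enrich: dict[tuple[str, str], list[float]] = {cell: [] for cell in _CELLS}
        for (disease_id, model_id), random_model in zip(known_pairs, matched):
            for kind, profiles in (
                ("general", refs.general),
                ("specific", refs.specific),
            ):
                for cohort, mid in (("known", model_id), ("random", random_model)):
                    traj = score_association(
                        graph, models[mid], profiles[disease_id], priors, cfg,
                        kind=kind,
                    )
                    enrich[(kind, cohort)].append(np.log10(traj.enrichment))
        quantiles = {
            cell: tuple(np.quantile(values, _QUANTILES))
            for cell, values in enrich.items()
        }
        results.append(
            CalibrationResult(
                bg_multiplier=bg,
                fp_penalty=fp,
                quantiles=quantiles,
                n_pairs=len(known_pairs),
                exact_match_fraction=exact_fraction,
            )
        )
    return results


def recommend_operating_point(
    results: Sequence[CalibrationResult],
) -> tuple[float, float]:
    """Grid point whose random-pair median enrichment is closest to 1.

    Measured on the general profile (median log10 enrichment closest to 0);
    ties break toward the smaller parameter values.
    """
    if not results:
        raise DataError("no calibration results to recommend from")
    best = min(
        results,
        key=lambda r: (abs(r.median("general", "random")),
                       r.bg_multiplier, r.fp_penalty),
    )
    return best.bg_multiplier, best.fp_penalty


def results_to_frame(results: Sequence[CalibrationResult]) -> pd.DataFrame:
    """Flatten to the TSV layout (bg, fp, kind, cohort, q05..q95)."""
    rows = []
    for r in results:
        for (kind, cohort), q in sorted(r.quantiles.items()):
            rows.append(
                {
                    "bg": r.bg_multiplier,
                    "fp": r.fp_penalty,
                    "kind": kind,
                    "cohort": cohort,
                    "q05": q[0], "q25": q[1], "q50": q[2],
                    "q75": q[3], "q95": q[4],
                    "n_pairs": r.n_pairs,
                    "exact_match_fraction": r.exact_match_fraction,
                }
            )
    return pd.DataFrame(rows)
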