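"""Synthetic ontologies and cohorts with planted causal structure.

The generator emulates the statistical structure of a phenomics study:
diseases annotated with penetrant phenotype sets, models measuring those
phenotypes with assay power 0.8 and false-positive rate 0.05, negative
records for measured-but-not-called terms, sex-specific phenotype labels,
and a background gene-annotation corpus for prior estimation. Planted
causal (disease, model) pairs provide ground truth for end-to-end tests.

The same spec and seed always produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .ontology import OntologyGraph, parse_obo

__all__ = ["CohortSpec", "SyntheticCohort", "make_toy_ontology", "make_synthetic_cohort",
           "write_obo"]

TERM_PREFIX = "TOY"


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults describe a well-separated corpus: a 3-ary depth-4 tree
    (121 terms, 81 leaves), 20 diseases with 4 disjoint leaf phenotypes
    each, 40 models of which 5 are planted causal pairs, noise-free positive
    calls, one negative record per four positives, a light sprinkling of
    sex-specific labels, and 200 background genes annotating 3 leaves each.
    """

    n_terms: int = 121
    branching: int = 3
    depth: int = 4
    diamond_fraction: float = 0.0
    n_diseases: int = 20
    phenotypes_per_disease: int = 4
    overlap_fraction: float = 0.0
    n_models: int = 40
    n_planted: int = 5
    noise: float = 0.0
    negative_fraction: float = 0.25
    sex_effect_fraction: float = 0.1
    n_background_genes: int = 200
    terms_per_gene: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_terms < 3:
            raise DataError("need at least 3 ontology terms")
        if self.branching < 2 or self.depth < 1:
            raise DataError("branching must be >= 2 and depth >= 1")
        for name in ("diamond_fraction", "overlap_fraction", "noise",
                     "negative_fraction", "sex_effect_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0,1], got {v}")
        if self.n_planted > self.n_models:
            raise DataError("more planted pairs than models")
        if min(self.n_diseases, self.n_models, self.phenotypes_per_disease,
               self.n_background_genes, self.terms_per_gene) < 1:
            raise DataError("all cohort counts must be >= 1")


@dataclass
class SyntheticCohort:
    diseases: pd.DataFrame       # disease_id, hp_term, frequency_code
    measurements: pd.DataFrame   # model_id, gene, ..., term_id, outcome, tau, phi, source_id
    truth: pd.DataFrame          # disease_id, model_id, gene
    gene_annotations: pd.DataFrame  # gene_id, term_id, publication_id

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("diseases", self.diseases),
            ("measurements", self.measurements),
            ("truth", self.truth),
            ("gene_annotations", self.gene_annotations),
        ):
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def _term_id(i: int) -> str:
    return f"{TERM_PREFIX}:{i:07d}"


def make_toy_ontology(spec: CohortSpec, path=None) -> OntologyGraph:
    """Build a rooted DAG: a truncated b-ary tree plus optional diamond edges.

    Terms are numbered breadth-first from the root. With a positive
    ``diamond_fraction``, that share of non-root terms gains a second parent
    drawn (seeded) from strictly shallower levels, which keeps the graph
    acyclic. When ``path`` is given, the graph is also written as an OBO
    file that re-parses to an identical hierarchy.
    """
    max_terms = sum(spec.branching ** d for d in range(spec.depth + 1))
    if spec.n_terms > max_terms:
        raise DataError(
            f"cannot fit {spec.n_terms} terms into a branching-{spec.branching} "
            f"tree of depth {spec.depth} (max {max_terms})"
        )
    rng = np.random.default_rng(spec.seed)
    parents: dict[str, set[str]] = {_term_id(1): set()}
    depths = {_term_id(1): 0}
    next_id = 2
    frontier = [_term_id(1)]
    while next_id <= spec.n_terms and frontier:
        new_frontier = []
        for parent in frontier:
            if depths[parent] >= spec.depth:
                continue
            for _ in range(spec.branching):
                if next_id > spec.n_terms:
                    break
                t = _term_id(next_id)
                parents[t] = {parent}
                depths[t] = depths[parent] + 1
                new_frontier.append(t)
                next_id += 1
        frontier = new_frontier
    if spec.diamond_fraction > 0:
        eligible = sorted(t for t, d in depths.items() if d >= 2)
        n_extra = int(round(spec.diamond_fraction * len(eligible)))
        chosen = rng.choice(len(eligible), size=n_extra, replace=False)
        for idx in sorted(chosen):
            t = eligible[idx]
            shallower = sorted(
                u for u, d in depths.items()
                if d < depths[t] and u not in parents[t]
            )
            if shallower:
                extra = shallower[int(rng.integers(len(shallower)))]
                parents[t].add(extra)
    graph = OntologyGraph(parents, names={t: f"toy term {t}" for t in parents})
    if path is not None:
        write_obo(graph, path)
        graph = parse_obo(str(path))
    return graph


def write_obo(graph: OntologyGraph, path) -> None:
    """Write the hierarchy as a minimal OBO flat file."""
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for term in sorted(graph.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {graph.names.get(term, term)}")
        for parent in sorted(graph.parents[term]):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


#: Penetrance levels spanning the frequency-code decision paths: two literal
#: encodings, one class midpoint, and the obligate class.
_PENETRANCE_CODES = [(0.25, "25%"), (0.5, "1/2"), (0.895, "very frequent"),
                     (1.0, "obligate")]


def make_synthetic_cohort(spec: CohortSpec, graph: OntologyGraph) -> SyntheticCohort:
    """Generate disease annotations, model measurements and ground truth.

    Diseases draw phenotype sets from the ontology leaves; at overlap 0 the
    sets are disjoint. Planted causal models positively call their disease's
    phenotypes (flipped to negative at the false-call rate); other models
    draw their positives from a different disease. Negative records cover
    measured-but-not-called leaf terms outside the source disease's set at
    the configured fraction. Sex labels mark a fraction of records F or M.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = sorted(t for t in graph.terms if not graph.children[t])
    needed = spec.n_diseases * spec.phenotypes_per_disease
    if spec.overlap_fraction == 0.0 and needed > len(leaves):
        raise DataError(
            f"{spec.n_diseases} disjoint diseases x {spec.phenotypes_per_disease} "
            f"phenotypes need {needed} leaves, ontology has {len(leaves)}"
        )
    perm = rng.permutation(len(leaves))
    n_shared = int(round(spec.overlap_fraction * spec.phenotypes_per_disease))
    shared_pool = [leaves[i] for i in perm[:n_shared]] if n_shared else []
    exclusive = [leaves[i] for i in perm[n_shared:]]

    disease_terms: dict[str, list[str]] = {}
    disease_rows = []
    cursor = 0
    for d in range(spec.n_diseases):
        disease_id = f"DIS:{d:04d}"
        own = list(shared_pool)
        n_own = spec.phenotypes_per_disease - len(own)
        if cursor + n_own > len(exclusive):
            raise DataError("not enough leaves for the requested disease corpus")
        own += exclusive[cursor:cursor + n_own]
        cursor += n_own
        disease_terms[disease_id] = sorted(own)
        for term in disease_terms[disease_id]:
            _, code = _PENETRANCE_CODES[int(rng.integers(len(_PENETRANCE_CODES)))]
            disease_rows.append(
                {"disease_id": disease_id, "hp_term": term, "frequency_code": code}
            )

    disease_ids = sorted(disease_terms)
    planted_diseases = {disease_ids[m % spec.n_diseases]
                        for m in range(spec.n_planted)}
    unrelated = [d for d in disease_ids if d not in planted_diseases] or disease_ids
    truth_rows = []
    meas_rows = []
    for m in range(spec.n_models):
        model_id = f"model_{m:03d}"
        gene = f"gene_{m:03d}"
        if m < spec.n_planted:
            source = disease_ids[m % spec.n_diseases]
            truth_rows.append(
                {"disease_id": source, "model_id": model_id, "gene": gene}
            )
        else:
            # non-causal models mimic diseases without a planted pair, so
            # their resemblance to planted diseases is incidental
            source = unrelated[int(rng.integers(len(unrelated)))]
        pos_terms = list(disease_terms[source])
        flips = rng.random(len(pos_terms)) < spec.noise
        n_neg = int(round(spec.negative_fraction * len(pos_terms)))
        off_terms = sorted(set(leaves) - set(pos_terms))
        neg_extra = [off_terms[i] for i in
                     rng.choice(len(off_terms), size=n_neg, replace=False)]
        records = [(t, "negative" if flip else "positive")
                   for t, flip in zip(pos_terms, flips)]
        records += [(t, "negative") for t in neg_extra]
        for term, outcome in records:
            if rng.random() < spec.sex_effect_fraction:
                sex = "F" if rng.random() < 0.5 else "M"
            else:
                sex = "U"
            meas_rows.append(
                {
                    "model_id": model_id,
                    "gene": gene,
                    "allele": f"{gene}<tm1>",
                    "zygosity": "hom",
                    "strain": "B6",
                    "sex": sex,
                    "term_id": term,
                    "outcome": outcome,
                    "tau": 0.8,
                    "phi": 0.05,
                    "source_id": "synthetic",
                }
            )

    genes = []
    for g in range(spec.n_background_genes):
        gene_id = f"bg_gene_{g:04d}"
        picks = rng.choice(len(leaves), size=min(spec.terms_per_gene, len(leaves)),
                           replace=False)
        for i in sorted(picks):
            genes.append(
                {"gene_id": gene_id, "term_id": leaves[i], "publication_id": "PUB:1"}
            )

    return SyntheticCohort(
        diseases=pd.DataFrame(disease_rows),
        measurements=pd.DataFrame(meas_rows),
        truth=pd.DataFrame(truth_rows, columns=["disease_id", "model_id", "gene"]),
        gene_annotations=pd.DataFrame(genes),
    )
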