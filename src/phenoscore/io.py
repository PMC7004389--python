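"""Readers and writers for the flat-file TSV dialects of the pipeline.

Schemas (tab-separated, header row required):

- gene annotations: gene_id, term_id[, publication_id]
- disease annotations: disease_id, hp_term, frequency_code
- translation table: hp_term, mp_term, score
- measurements: model_id, gene, allele, zygosity, strain, sex, term_id,
  outcome, tau, phi, source_id
- priors: term_id, prior
- references: disease_id, term_id, general, specific
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DataError
from .profiles import (
    ConciseProfile,
    Measurement,
    PriorVector,
    ReferenceSet,
    CompleteProfile,
    frequency_to_penetrance,
)

__all__ = [
    "read_gene_annotations",
    "read_disease_annotations",
    "read_translation_table",
    "read_measurements",
    "measurements_to_frame",
    "write_priors",
    "read_priors",
    "write_reference_set",
    "read_reference_set",
]


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    return df


def read_gene_annotations(path) -> dict[str, set[str]]:
    """Gene -> set of annotated terms (publication column, if any, ignored)."""
    df = _read_tsv(path, ("gene_id", "term_id"))
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    if not out:
        raise DataError(f"{path}: no gene annotations")
    return out


def read_disease_annotations(path) -> dict[str, ConciseProfile]:
    """Disease -> concise profile with frequency codes decoded to penetrance.

    Duplicate (disease, term) rows keep the highest penetrance.
    """
    df = _read_tsv(path, ("disease_id", "hp_term", "frequency_code"))
    out: dict[str, dict[str, float]] = {}
    for disease, term, code in zip(
        df["disease_id"], df["hp_term"], df["frequency_code"]
    ):
        v = frequency_to_penetrance(code)
        d = out.setdefault(disease, {})
        if term not in d or v > d[term]:
            d[term] = v
    return {d: ConciseProfile(owner=d, values=vals) for d, vals in sorted(out.items())}


def read_translation_table(path) -> list[tuple[str, str, float]]:
    df = _read_tsv(path, ("hp_term", "mp_term", "score"))
    rows = [
        (hp, mp, float(score))
        for hp, mp, score in zip(df["hp_term"], df["mp_term"], df["score"])
    ]
    if not rows:
        raise DataError(f"{path}: translation table is empty")
    return rows


_MEASUREMENT_COLUMNS = (
    "model_id", "gene", "allele", "zygosity", "strain", "sex",
    "term_id", "outcome", "tau", "phi", "source_id",
)


def read_measurements(path) -> list[Measurement]:
    df = _read_tsv(path, ("model_id", "term_id", "outcome"))
    return frame_to_measurements(df)


def frame_to_measurements(df: pd.DataFrame) -> list[Measurement]:
    out = []
    for row in df.to_dict("records"):
        try:
            out.append(
                Measurement(
                    model_id=str(row["model_id"]),
                    term=str(row["term_id"]),
                    outcome=str(row["outcome"]),
                    tau=float(row.get("tau", 0.8) or 0.8),
                    phi=float(row.get("phi", 0.05) or 0.05),
                    source_id=str(row.get("source_id", "default") or "default"),
                    sex=str(row.get("sex", "U") or "U"),
                    gene=str(row.get("gene", "") or ""),
                    allele=str(row.get("allele", "") or ""),
                    zygosity=str(row.get("zygosity", "") or ""),
                    strain=str(row.get("strain", "") or ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataError(f"malformed measurement row {row}: {exc}") from exc
    return out


def measurements_to_frame(measurements) -> pd.DataFrame:
    rows = [
        {
            "model_id": m.model_id,
            "gene": m.gene,
            "allele": m.allele,
            "zygosity": m.zygosity,
            "strain": m.strain,
            "sex": m.sex,
            "term_id": m.term,
            "outcome": m.outcome,
            "tau": m.tau,
            "phi": m.phi,
            "source_id": m.source_id,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS)


def write_priors(priors: PriorVector, path) -> None:
    df = pd.DataFrame(
        sorted(priors.b.items()), columns=["term_id", "prior"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_priors(path, n_genes: int = 0, dark_count: int = 2) -> PriorVector:
    df = _read_tsv(path, ("term_id", "prior"))
    b = {t: float(p) for t, p in zip(df["term_id"], df["prior"])}
    return PriorVector(b=b, n_genes=n_genes, dark_count=dark_count)


def write_reference_set(refs: ReferenceSet, path) -> None:
    rows = []
    for disease in refs.disease_ids():
        g = refs.general[disease]
        s = refs.specific[disease]
        for term in sorted(g.values):
            rows.append(
                {
                    "disease_id": disease,
                    "term_id": term,
                    "general": g.values[term],
                    "specific": s.values[term],
                    "provenance": g.provenance.get(term, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_set(path, neighbors: Mapping[str, tuple[str, ...]] | None = None
                       ) -> ReferenceSet:
    df = _read_tsv(path, ("disease_id", "term_id", "general", "specific"))
    general: dict[str, CompleteProfile] = {}
    specific: dict[str, CompleteProfile] = {}
    for disease, sub in df.groupby("disease_id", sort=True):
        values_g = dict(zip(sub["term_id"], sub["general"].astype(float)))
        values_s = dict(zip(sub["term_id"], sub["specific"].astype(float)))
        prov = dict(zip(sub["term_id"], sub.get("provenance", "")))
        general[disease] = CompleteProfile(disease, values_g, dict(prov))
        specific[disease] = CompleteProfile(disease, values_s, dict(prov))
    return ReferenceSet(
        general=general, specific=specific, neighbors=dict(neighbors or {})
    )
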