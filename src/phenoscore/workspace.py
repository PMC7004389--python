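"""Persistent workspace: append-only measurement log + incremental scores.

A workspace directory holds the ontology, the config snapshot, derived
priors and references as TSV, and a single-file SQLite store with the
measurement log, the score table and a run log. The score store is always
reproducible from (ontology, annotations, measurement log, config): a full
rebuild and an incremental refresh yield identical scores, because scoring
one model never depends on any other model's data.
"""

from __future__ import annotations

import datetime as _dt
import shutil
import sqlite3
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import ScoringConfig
from .errors import DataError, UnknownTermError
from .io import (
    frame_to_measurements,
    measurements_to_frame,
    read_disease_annotations,
    read_gene_annotations,
    read_priors,
    read_reference_set,
    read_translation_table,
    write_priors,
    write_reference_set,
)
from .ontology import OntologyGraph, parse_obo
from .profiles import (
    ConciseProfile,
    Measurement,
    build_model_profiles,
    build_reference_set,
    estimate_priors,
    translate_profile,
)
from .quality import audit_annotations
from .scoring import ScoreTrajectory, score_all, score_association

__all__ = ["Workspace"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS measurements (
    id INTEGER PRIMARY KEY,
    model_id TEXT NOT NULL,
    gene TEXT, allele TEXT, zygosity TEXT, strain TEXT,
    sex TEXT NOT NULL,
    term_id TEXT NOT NULL,
    outcome TEXT NOT NULL,
    tau REAL NOT NULL,
    phi REAL NOT NULL,
    source_id TEXT NOT NULL,
    batch INTEGER NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_meas_model ON measurements(model_id);
CREATE TABLE IF NOT EXISTS scores (
    model_id TEXT NOT NULL,
    disease_id TEXT NOT NULL,
    general_score REAL NOT NULL,
    specific_score REAL NOT NULL,
    n_updates INTEGER NOT NULL,
    PRIMARY KEY (model_id, disease_id)
);
CREATE TABLE IF NOT EXISTS runlog (
    ts TEXT NOT NULL,
    action TEXT NOT NULL,
    config_hash TEXT NOT NULL,
    detail TEXT
);
"""


class Workspace:
    """A directory-backed scoring workspace."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        if not (self.root / "config.yaml").exists():
            raise DataError(f"{self.root} is not an initialised workspace")
        self.config = ScoringConfig.from_yaml(self.root / "config.yaml")
        self._graph: OntologyGraph | None = None
        self._conn = sqlite3.connect(self.root / "workspace.db")
        self._conn.executescript(_SCHEMA)

    # -- lifecycle ------------------------------------------------------------

    @classmethod
    def create(cls, root, ontology_path, config: ScoringConfig | None = None
               ) -> "Workspace":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        ontology_path = Path(ontology_path)
        if not ontology_path.exists():
            raise DataError(f"ontology file not found: {ontology_path}")
        parse_obo(str(ontology_path))  # validate before committing
        shutil.copy(ontology_path, root / "ontology.obo")
        (config or ScoringConfig()).to_yaml(root / "config.yaml")
        ws = cls(root)
        ws._log("init", detail=str(ontology_path))
        return ws

    def close(self) -> None:
        self._conn.close()

    @property
    def graph(self) -> OntologyGraph:
        if self._graph is None:
            self._graph = parse_obo(str(self.root / "ontology.obo"))
        return self._graph

    def _log(self, action: str, detail: str = "") -> None:
        self._conn.execute(
            "INSERT INTO runlog VALUES (?, ?, ?, ?)",
            (_dt.datetime.now(_dt.timezone.utc).isoformat(), action,
             self.config.digest(), detail),
        )
        self._conn.commit()

    # -- derived inputs -------------------------------------------------------

    def compute_priors(self, gene_annotations_path) -> None:
        genes = read_gene_annotations(gene_annotations_path)
        priors = estimate_priors(self.graph, genes, self.config.dark_count)
        write_priors(priors, self.root / "priors.tsv")
        self._n_genes = priors.n_genes
        (self.root / "n_genes.txt").write_text(str(priors.n_genes))
        self._log("priors", detail=f"{priors.n_genes} genes")

    @property
    def priors(self):
        path = self.root / "priors.tsv"
        if not path.exists():
            raise DataError("priors not computed yet; run compute_priors first")
        n = int((self.root / "n_genes.txt").read_text()) \
            if (self.root / "n_genes.txt").exists() else 0
        return read_priors(path, n_genes=n, dark_count=self.config.dark_count)

    def build_references(self, disease_annotations_path,
                         translation_path=None) -> None:
        diseases = read_disease_annotations(disease_annotations_path)
        if translation_path is not None:
            table = read_translation_table(translation_path)
            diseases = {
                d: translate_profile(p, table, self.config)
                for d, p in diseases.items()
            }
        refs = build_reference_set(self.graph, diseases, self.priors, self.config)
        write_reference_set(refs, self.root / "references.tsv")
        rows = [
            {"disease_id": d, "term_id": t, "penetrance": v}
            for d in sorted(diseases)
            for t, v in sorted(diseases[d].values.items())
        ]
        pd.DataFrame(rows).to_csv(self.root / "disease_concise.tsv",
                                  sep="\t", index=False)
        self._log("references", detail=f"{len(diseases)} diseases")

    @property
    def references(self):
        path = self.root / "references.tsv"
        if not path.exists():
            raise DataError("references not built yet; run build_references first")
        return read_reference_set(path)

    def disease_profiles(self) -> dict[str, ConciseProfile]:
        path = self.root / "disease_concise.tsv"
        if not path.exists():
            raise DataError("references not built yet; run build_references first")
        df = pd.read_csv(path, sep="\t", dtype={"disease_id": str, "term_id": str})
        out: dict[str, ConciseProfile] = {}
        for d, sub in df.groupby("disease_id", sort=True):
            out[d] = ConciseProfile(
                owner=d, values=dict(zip(sub["term_id"], sub["penetrance"]))
            )
        return out

    # -- measurement log ------------------------------------------------------

    def measurements(self, model_ids: Sequence[str] | None = None
                     ) -> list[Measurement]:
        q = ("SELECT model_id, gene, allele, zygosity, strain, sex, term_id, "
             "outcome, tau, phi, source_id FROM measurements")
        params: tuple = ()
        if model_ids is not None:
            q += f" WHERE model_id IN ({','.join('?' * len(model_ids))})"
            params = tuple(model_ids)
        q += " ORDER BY id"
        df = pd.read_sql_query(q, self._conn, params=params)
        return frame_to_measurements(df)

    def _validate_batch(self, measurements: list[Measurement]) -> None:
        offenders = []
        for i, m in enumerate(measurements):
            try:
                self.graph.resolve(m.term)
            except UnknownTermError:
                offenders.append(f"row {i}: unknown term {m.term!r}")
            if m.tau <= m.phi:
                offenders.append(f"row {i}: tau {m.tau} <= phi {m.phi}")
        if offenders:
            raise DataError(
                "batch rejected (no rows were appended): " + "; ".join(offenders)
            )

    def append_and_refresh(self, new_measurements: Iterable[Measurement]
                           ) -> pd.DataFrame:
        """Append a batch atomically and refresh only the touched models.

        Returns the refreshed score rows; all other rows are untouched
        (scoring one pair never reads another model's data). Appending an
        empty batch changes nothing.
        """
        batch = list(new_measurements)
        if not batch:
            self._log("update", detail="empty batch")
            return pd.DataFrame(
                columns=["model_id", "disease_id", "general_score",
                         "specific_score", "n_updates"]
            )
        self._validate_batch(batch)
        cur = self._conn.execute("SELECT COALESCE(MAX(batch), 0) FROM measurements")
        batch_no = cur.fetchone()[0] + 1
        frame = measurements_to_frame(batch)
        frame["batch"] = batch_no
        frame.to_sql("measurements", self._conn, if_exists="append", index=False)
        self._conn.commit()
        touched = sorted({m.model_id for m in batch})
        refreshed = self._score_models(touched)
        self._log("update", detail=f"batch {batch_no}: {len(batch)} rows, "
                                   f"{len(touched)} models")
        return refreshed

    def _score_models(self, model_ids: Sequence[str]) -> pd.DataFrame:
        measurements = self.measurements(model_ids)
        profiles = build_model_profiles(
            measurements, self.graph, self.priors, self.config
        )
        table = score_all(self.graph, profiles, self.references, self.priors,
                          self.config)
        rows = [
            (r.model_id, r.disease_id, r.general_score, r.specific_score,
             int(r.n_updates))
            for r in table.itertuples(index=False)
        ]
        self._conn.executemany(
            "INSERT OR REPLACE INTO scores VALUES (?, ?, ?, ?, ?)", rows
        )
        self._conn.commit()
        return table

    def rebuild_scores(self) -> pd.DataFrame:
        """Recompute the whole score table from the measurement log."""
        self._conn.execute("DELETE FROM scores")
        self._conn.commit()
        model_ids = [
            r[0] for r in self._conn.execute(
                "SELECT DISTINCT model_id FROM measurements ORDER BY model_id"
            )
        ]
        if model_ids:
            self._score_models(model_ids)
        self._log("rebuild", detail=f"{len(model_ids)} models")
        return self.scores()

    def scores(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM scores ORDER BY model_id, disease_id", self._conn
        )

    # -- analyses -------------------------------------------------------------

    def trajectory(self, model_id: str, disease_id: str, kind: str = "general"
                   ) -> ScoreTrajectory:
        """Replay one pair's updates with terms grouped by source.

        Terms are ordered by the lowest source identifier among their records
        (publication with the lowest id wins on ambiguity), then
        lexicographically, mirroring how the association would have evolved
        as sources accrued. The final score is order-invariant.
        """
        measurements = self.measurements([model_id])
        if not measurements:
            raise DataError(f"no measurements for model {model_id!r}")
        profiles = build_model_profiles(
            measurements, self.graph, self.priors, self.config
        )
        profile = profiles[model_id]
        first_source: dict[str, str] = {}
        for m in measurements:
            t = self.graph.resolve(m.term)
            if t not in first_source or m.source_id < first_source[t]:
                first_source[t] = m.source_id
        order = sorted(profile.values, key=lambda t: (first_source[t], t))
        refs = self.references
        reference = (refs.general if kind == "general" else refs.specific)
        if disease_id not in reference:
            raise DataError(f"unknown disease {disease_id!r}")
        return score_association(
            self.graph, profile, reference[disease_id], self.priors, self.config,
            kind=kind, order=order,
        )

    def classify(self) -> pd.DataFrame:
        classification, _ = audit_annotations(
            self.graph, self.disease_profiles(), self.references, self.priors,
            self.config,
        )
        self._log("classify", detail=f"{len(classification)} diseases")
        return classification

    def runlog(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM runlog ORDER BY ts", self._conn)
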