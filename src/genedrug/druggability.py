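"""Druggability scoring of disease genes from database provenance.

Each of the eight source databases carries a quality point value derived
from how often its genetics-implicated drug activities are clinically
supported: the highest-quality source (ClinVar) is worth 8 points, the
lowest (DisGeNET) 1 point. A (gene, disease) pair's druggability score is
the sum of points over the *distinct* databases recording it, so the same
gene may score differently for different diseases, and the maximum for a
single gene recorded everywhere is 8+7+...+1 = 36.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from genedrug.data_model import Dataset, FormatError, SourceDB, ValidationError

#: Default quality points, ranked by empirical clinically-active ratio.
DEFAULT_POINTS: dict[SourceDB, int] = {
    SourceDB.CLINVAR: 8,
    SourceDB.OMIM: 7,
    SourceDB.HGMD: 6,
    SourceDB.ORPHANET: 5,
    SourceDB.GWASDB: 4,
    SourceDB.INTREPID: 3,
    SourceDB.GAD: 2,
    SourceDB.DISGENET: 1,
}


@dataclass(frozen=True)
class DbPointTable:
    """Mapping from source database to integer quality points (1..8).

    User-supplied tables may cover a subset of sources for corpora drawing
    on fewer databases; scoring a record from an unlisted source is an error.
    """

    points: Mapping[SourceDB, int] = field(default_factory=lambda: dict(DEFAULT_POINTS))

    def __post_init__(self) -> None:
        for db, pts in self.points.items():
            if not isinstance(db, SourceDB):
                raise ValidationError(f"unknown source database in point table: {db!r}")
            if not 1 <= int(pts) <= 8:
                raise ValidationError(f"points for {db.value} must be in 1..8, got {pts}")

    def __getitem__(self, db: SourceDB) -> int:
        return int(self.points[db])

    @property
    def max_single_gene_score(self) -> int:
        """Highest score attainable by one gene recorded in every configured source."""
        return sum(int(v) for v in self.points.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DbPointTable":
        df = pd.read_csv(path, sep="\t", dtype={"source_db": str, "points": int})
        missing = [c for c in ("source_db", "points") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        table = {}
        for row in df.itertuples(index=False):
            try:
                db = SourceDB(row.source_db)
            except ValueError:
                raise ValidationError(f"{path}: unknown source_db {row.source_db!r}") from None
            table[db] = int(row.points)
        return cls(points=table)


@dataclass(frozen=True)
class DruggabilityScore:
    gene_id: str
    disease_id: str
    score: int


def score_gene_disease(
    ds: Dataset, table: DbPointTable, gene_id: str, disease_id: str
) -> DruggabilityScore:
    """Druggability score for one (gene, disease) pair.

    Each database counts at most once per pair regardless of duplicate
    records. A pair with no association in the corpus is a lookup error —
    never a score of 0, which the scoring scheme cannot produce.
    """
    dbs = {
        a.source_db
        for a in ds.associations
        if a.gene_id == gene_id and a.disease_id == disease_id
    }
    if not dbs:
        raise KeyError(f"no association recorded for gene {gene_id!r}, disease {disease_id!r}")
    return DruggabilityScore(gene_id, disease_id, sum(table[db] for db in dbs))


def score_all(ds: Dataset, table: DbPointTable | None = None) -> dict[tuple[str, str], int]:
    """Druggability scores for every distinct (gene, disease) pair in the corpus."""
    if table is None:
        table = DbPointTable()
    seen: dict[tuple[str, str], set[SourceDB]] = {}
    for a in ds.associations:
        seen.setdefault((a.gene_id, a.disease_id), set()).add(a.source_db)
    return {pair: sum(table[db] for db in dbs) for pair, dbs in seen.items()}
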