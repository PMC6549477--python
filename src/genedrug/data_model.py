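"""Domain types and tabular I/O.

The corpus is a tripartite structure: gene-disease associations carrying a
source-database provenance tag, drug-target pairs, drug-indication pairs
with a clinical status, and a registry of ohnolog gene pairs (paralogs
retained from whole-genome duplication, used as a proxy for high-confidence
disease genes). Identifiers are opaque strings; no external-vocabulary
validation is performed, which keeps the tool corpus-agnostic.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A required column or structural element of an input table is missing."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


class SourceDB(enum.Enum):
    """The eight recognized disease-gene source databases."""

    CLINVAR = "CLINVAR"
    OMIM = "OMIM"
    HGMD = "HGMD"
    ORPHANET = "ORPHANET"
    GWASDB = "GWASDB"
    INTREPID = "INTREPID"
    GAD = "GAD"
    DISGENET = "DISGENET"


class IndicationStatus(enum.Enum):
    CLINICAL = "CLINICAL"
    APPROVED = "APPROVED"


@dataclass(frozen=True, order=True)
class GeneDiseaseAssociation:
    """One (gene, disease, source database) record — the atom of druggability scoring."""

    gene_id: str
    disease_id: str
    source_db: SourceDB = field(compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.source_db, SourceDB):
            raise ValidationError(f"unknown source database: {self.source_db!r}")


@dataclass(frozen=True)
class DrugProfile:
    """A drug and its target-gene set."""

    drug_id: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"drug {self.drug_id!r} has an empty target set")


@dataclass(frozen=True)
class IndicationRecord:
    """A drug-disease pair with clinical status.

    APPROVED implies the pair also counts as clinically supported wherever
    clinically-active ratios are computed.
    """

    drug_id: str
    disease_id: str
    status: IndicationStatus


@dataclass(frozen=True)
class OhnologRegistry:
    """Symmetric registry of ohnolog gene pairs."""

    pairs: frozenset[frozenset[str]]

    @property
    def members(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.update(p)
        return frozenset(out)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OhnologRegistry":
        return cls(pairs=frozenset(frozenset(p) for p in pairs))


@dataclass
class Dataset:
    """A complete corpus with deterministic (lexicographic) orderings.

    ``diseases`` indexes the label space l = 1..q and ``drug_order`` the
    instance space i = 1..n; every derived matrix is aligned to these, so
    two loads of the same files produce identical matrices.
    """

    associations: list[GeneDiseaseAssociation]
    drugs: list[DrugProfile]
    indications: list[IndicationRecord]
    ohnologs: OhnologRegistry
    diseases: list[str] = field(default_factory=list)
    drug_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.diseases:
            names = {a.disease_id for a in self.associations}
            names |= {r.disease_id for r in self.indications}
            self.diseases = sorted(names)
        if not self.drug_order:
            self.drug_order = sorted(d.drug_id for d in self.drugs)
        missing = {r.disease_id for r in self.indications} - set(self.diseases)
        if missing:
            raise ValidationError(
                f"indications reference diseases absent from the disease index: {sorted(missing)}"
            )
        self._drug_map = {d.drug_id: d for d in self.drugs}
        if len(self._drug_map) != len(self.drugs):
            raise ValidationError("duplicate drug_id in drug profiles")

    @property
    def n(self) -> int:
        return len(self.drugs)

    @property
    def q(self) -> int:
        return len(self.diseases)

    def drug(self, drug_id: str) -> DrugProfile:
        try:
            return self._drug_map[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug: {drug_id!r}") from None

    def disease_genes(self, disease_id: str) -> frozenset[str]:
        """All genes associated with a disease, irrespective of source database."""
        return self._gene_index().get(disease_id, frozenset())

    def _gene_index(self) -> Mapping[str, frozenset[str]]:
        if not hasattr(self, "_disease_to_genes"):
            idx: dict[str, set[str]] = {}
            for a in self.associations:
                idx.setdefault(a.disease_id, set()).add(a.gene_id)
            self._disease_to_genes = {d: frozenset(g) for d, g in idx.items()}
        return self._disease_to_genes

    def indication_map(self) -> dict[tuple[str, str], IndicationStatus]:
        """(drug, disease) -> strongest status (APPROVED dominates CLINICAL)."""
        out: dict[tuple[str, str], IndicationStatus] = {}
        for r in self.indications:
            key = (r.drug_id, r.disease_id)
            if key not in out or r.status is IndicationStatus.APPROVED:
                out[key] = r.status
        return out

    def unscorable_indications(self) -> list[IndicationRecord]:
        """Indications whose drug targets no gene of the indicated disease.

        Retained in the corpus but excluded from training and evaluation;
        callers report the count.
        """
        elig = eligible_pairs(self)
        return [
            r
            for r in self.indications
            if (r.drug_id, r.disease_id) not in elig
        ]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path: str | Path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, cols, path)
    return df


def load_dataset(
    assoc_path: str | Path,
    drugs_path: str | Path,
    indications_path: str | Path,
    ohnolog_path: str | Path,
) -> Dataset:
    """Load and validate the four corpus tables.

    Duplicate rows are silently deduplicated with a logged count; an unknown
    source_db or status token, or a drug with no targets, is a validation
    error naming the offending line.
    """
    adf = _read_tsv(assoc_path, ["gene_id", "disease_id", "source_db"])
    n_before = len(adf)
    adf = adf.drop_duplicates()
    if len(adf) < n_before:
        logger.info("%s: dropped %d duplicate association row(s)", assoc_path, n_before - len(adf))
    associations = []
    for row in adf.itertuples(index=True):
        try:
            db = SourceDB(row.source_db)
        except ValueError:
            raise ValidationError(
                f"{assoc_path} line {row.Index + 2}: unknown source_db {row.source_db!r}"
            ) from None
        associations.append(GeneDiseaseAssociation(row.gene_id, row.disease_id, db))

    ddf = _read_tsv(drugs_path, ["drug_id", "gene_id"])
    n_before = len(ddf)
    ddf = ddf.drop_duplicates()
    if len(ddf) < n_before:
        logger.info("%s: dropped %d duplicate drug-target row(s)", drugs_path, n_before - len(ddf))
    drugs = []
    for drug_id, grp in ddf.groupby("drug_id", sort=True):
        genes = frozenset(g for g in grp["gene_id"] if g != "")
        if not genes:
            raise ValidationError(f"{drugs_path}: drug {drug_id!r} has no target genes")
        drugs.append(DrugProfile(drug_id=str(drug_id), targets=genes))

    idf = _read_tsv(indications_path, ["drug_id", "disease_id", "status"])
    n_before = len(idf)
    idf = idf.drop_duplicates()
    if len(idf) < n_before:
        logger.info(
            "%s: dropped %d duplicate indication row(s)", indications_path, n_before - len(idf)
        )
    indications = []
    for row in idf.itertuples(index=True):
        try:
            status = IndicationStatus(row.status)
        except ValueError:
            raise ValidationError(
                f"{indications_path} line {row.Index + 2}: unknown status {row.status!r}"
            ) from None
        indications.append(IndicationRecord(row.drug_id, row.disease_id, status))

    odf = _read_tsv(ohnolog_path, ["gene_a", "gene_b"])
    pairs = [(row.gene_a, row.gene_b) for row in odf.itertuples(index=False)]
    ohnologs = OhnologRegistry.from_pairs(pairs)

    return Dataset(
        associations=associations, drugs=drugs, indications=indications, ohnologs=ohnologs
    )


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical TSV form (sorted rows, fixed columns).

    Round-trips: loading the written files reproduces byte-identical output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": out / "associations.tsv",
        "drug_targets": out / "drug_targets.tsv",
        "indications": out / "indications.tsv",
        "ohnologs": out / "ohnologs.tsv",
    }
    arows = sorted((a.gene_id, a.disease_id, a.source_db.value) for a in ds.associations)
    pd.DataFrame(arows, columns=["gene_id", "disease_id", "source_db"]).to_csv(
        paths["associations"], sep="\t", index=False
    )
    drows = sorted((d.drug_id, g) for d in ds.drugs for g in d.targets)
    pd.DataFrame(drows, columns=["drug_id", "gene_id"]).to_csv(
        paths["drug_targets"], sep="\t", index=False
    )
    irows = sorted((r.drug_id, r.disease_id, r.status.value) for r in ds.indications)
    pd.DataFrame(irows, columns=["drug_id", "disease_id", "status"]).to_csv(
        paths["indications"], sep="\t", index=False
    )
    orows = sorted(tuple(sorted(p)) for p in ds.ohnologs.pairs)
    pd.DataFrame(orows, columns=["gene_a", "gene_b"]).to_csv(
        paths["ohnologs"], sep="\t", index=False
    )
    return paths


def eligible_pairs(ds: Dataset) -> set[tuple[str, str]]:
    """All (drug, disease) pairs where the drug targets >=1 disease-associated gene.

    This is the sample universe: positives are eligible pairs carrying an
    indication, negatives are the rest. Pairs where the drug targets no gene
    of the disease are outside the universe entirely.
    """
    out: set[tuple[str, str]] = set()
    for drug in ds.drugs:
        for disease in ds.diseases:
            if drug.targets & ds.disease_genes(disease):
                out.add((drug.drug_id, disease))
    return out
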