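"""Synthetic corpora with planted ground truth.

The generator emulates the statistical structure the pipeline is meant to
detect: a drug's probability of being truly indicated for a disease rises
monotonically with how strongly it targets that disease's genes. For each
eligible (drug, disease) pair the planted model is

    P(indicated) = logistic(base_logit + beta1 * f1/36 + beta3 * f3)

where f1 is the summed druggability score of the targeted disease genes
and f3 the number of those genes with ohnolog support. Only f1 and f3
drive the link (f2/f4 are deterministic transforms of them and would
confound recovery checks). Gene-disease associations are drawn per source
database independently, with inclusion probabilities increasing as the
database's quality points decrease — the highest-quality source is the
most selective, mirroring real provenance.

Defaults give a baseline clinically-active ratio of a few percent rising
past 15% across druggability strata, the magnitude regime of real
genetics-implicated activity data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from genedrug.data_model import (
    Dataset,
    DrugProfile,
    GeneDiseaseAssociation,
    IndicationRecord,
    IndicationStatus,
    OhnologRegistry,
    SourceDB,
    write_dataset,
)
from genedrug.druggability import score_all
from genedrug.features import NORMALIZATION_CONSTANT


class GenerationError(RuntimeError):
    """The configuration produced a corpus with no eligible pair."""


#: per-database inclusion probability, ordered CLINVAR..DISGENET:
#: rarer, curated sources first; prolific text-mined sources last
DEFAULT_DB_PROBS = (0.005, 0.007, 0.010, 0.012, 0.015, 0.020, 0.030, 0.050)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 300
    n_diseases: int = 20
    n_drugs: int = 200
    db_inclusion_probs: tuple[float, ...] = DEFAULT_DB_PROBS
    ohnolog_fraction: float = 0.3
    targets_per_drug: tuple[int, int] = (2, 10)
    effect_beta1: float = 6.0
    effect_beta3: float = 1.0
    base_logit: float = -3.5
    approved_given_clinical: float = 0.3
    #: draw indications for every (drug, disease) pair at the base rate,
    #: independent of target structure — a true null for the drug-target
    #: permutation test (the default planted model puts indications only on
    #: eligible pairs, which by itself couples activity to real targets)
    random_indications: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_diseases, self.n_drugs) <= 0:
            raise ValueError("counts must be positive")
        if len(self.db_inclusion_probs) != len(SourceDB):
            raise ValueError("one inclusion probability per source database is required")
        probs = (*self.db_inclusion_probs, self.ohnolog_fraction, self.approved_given_clinical)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.targets_per_drug
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("targets_per_drug must satisfy 1 <= min <= max <= n_genes")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: SimulationConfig) -> tuple[Dataset, pd.DataFrame]:
    """Draw a corpus from the planted model; reproducible given the seed.

    Returns the Dataset and a ground-truth table with one row per eligible
    pair: drug_id, disease_id, f1, f3, p_indicated, indicated.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    diseases = [f"d{l + 1:03d}" for l in range(config.n_diseases)]
    drug_ids = [f"agent{i + 1:04d}" for i in range(config.n_drugs)]

    associations = []
    for db, p in zip(SourceDB, config.db_inclusion_probs):
        hits = rng.random((config.n_genes, config.n_diseases)) < p
        for gi, li in zip(*np.nonzero(hits)):
            associations.append(GeneDiseaseAssociation(genes[gi], diseases[li], db))

    n_ohno = int(round(config.ohnolog_fraction * config.n_genes)) // 2 * 2
    chosen = rng.choice(config.n_genes, size=n_ohno, replace=False)
    pairs = [(genes[chosen[2 * i]], genes[chosen[2 * i + 1]]) for i in range(n_ohno // 2)]
    ohnologs = OhnologRegistry.from_pairs(pairs)

    lo, hi = config.targets_per_drug
    drugs = []
    for did in drug_ids:
        size = int(rng.integers(lo, hi + 1))
        targets = frozenset(genes[i] for i in rng.choice(config.n_genes, size=size, replace=False))
        drugs.append(DrugProfile(did, targets))

    skeleton = Dataset(
        associations=associations,
        drugs=drugs,
        indications=[],
        ohnologs=ohnologs,
        diseases=diseases,
    )
    scores = score_all(skeleton)
    members = ohnologs.members

    base_rate = float(_logistic(np.array(config.base_logit)))
    rows = []
    indications = []
    for drug in sorted(drugs, key=lambda d: d.drug_id):
        for disease in diseases:
            hit = drug.targets & skeleton.disease_genes(disease)
            if not hit and not config.random_indications:
                continue
            f1 = sum(scores[(g, disease)] for g in hit)
            f3 = len(hit & members)
            if config.random_indications:
                p_ind = base_rate
            else:
                p_ind = float(
                    _logistic(
                        np.array(
                            config.base_logit
                            + config.effect_beta1 * f1 / NORMALIZATION_CONSTANT
                            + config.effect_beta3 * f3
                        )
                    )
                )
            indicated = bool(rng.random() < p_ind)
            if indicated:
                status = (
                    IndicationStatus.APPROVED
                    if rng.random() < config.approved_given_clinical
                    else IndicationStatus.CLINICAL
                )
                indications.append(IndicationRecord(drug.drug_id, disease, status))
            if hit:
                rows.append((drug.drug_id, disease, f1, f3, p_ind, indicated))

    if not rows:
        raise GenerationError("configuration produced zero eligible (drug, disease) pairs")

    truth = pd.DataFrame(
        rows, columns=["drug_id", "disease_id", "f1", "f3", "p_indicated", "indicated"]
    )
    ds = Dataset(
        associations=associations,
        drugs=drugs,
        indications=indications,
        ohnologs=ohnologs,
        diseases=diseases,
    )
    return ds, truth


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a corpus and write the four canonical TSVs plus truth.tsv."""
    ds, truth = generate(config)
    paths = write_dataset(ds, out_dir)
    truth_path = Path(out_dir) / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def fixture_minimal() -> Dataset:
    """A hand-written 6-drug corpus embedding the canonical worked example.

    ``agent01`` targets exactly two genes associated with disease ``d1``,
    one recorded only in ClinVar and one only in DisGeNET, so its first
    feature for d1 is 8 + 1 = 9 and its second 9 / (2 x 36) = 0.125.
    """
    associations = [
        GeneDiseaseAssociation("g1", "d1", SourceDB.CLINVAR),
        GeneDiseaseAssociation("g2", "d1", SourceDB.DISGENET),
        GeneDiseaseAssociation("g3", "d1", SourceDB.OMIM),
        GeneDiseaseAssociation("g3", "d2", SourceDB.GWASDB),
        GeneDiseaseAssociation("g4", "d2", SourceDB.HGMD),
        GeneDiseaseAssociation("g4", "d2", SourceDB.GAD),
        GeneDiseaseAssociation("g5", "d2", SourceDB.ORPHANET),
        GeneDiseaseAssociation("g6", "d3", SourceDB.INTREPID),
        GeneDiseaseAssociation("g6", "d1", SourceDB.DISGENET),
        GeneDiseaseAssociation("g7", "d3", SourceDB.CLINVAR),
        GeneDiseaseAssociation("g7", "d3", SourceDB.DISGENET),
    ]
    drugs = [
        DrugProfile("agent01", frozenset({"g1", "g2"})),
        DrugProfile("agent02", frozenset({"g3", "g8"})),
        DrugProfile("agent03", frozenset({"g4", "g5"})),
        DrugProfile("agent04", frozenset({"g6"})),
        DrugProfile("agent05", frozenset({"g7", "g2"})),
        DrugProfile("agent06", frozenset({"g1", "g3", "g7"})),
    ]
    indications = [
        IndicationRecord("agent01", "d1", IndicationStatus.APPROVED),
        IndicationRecord("agent02", "d2", IndicationStatus.CLINICAL),
        IndicationRecord("agent03", "d2", IndicationStatus.APPROVED),
        IndicationRecord("agent06", "d3", IndicationStatus.CLINICAL),
        IndicationRecord("agent06", "d1", IndicationStatus.CLINICAL),
    ]
    ohnologs = OhnologRegistry.from_pairs([("g2", "g5"), ("g3", "g7")])
    return Dataset(
        associations=associations, drugs=drugs, indications=indications, ohnologs=ohnologs
    )
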