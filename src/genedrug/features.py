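"""The four disease-indexed genetics features of a drug.

For a drug and a disease, with T the drug's targets that are associated
with the disease:

* **F1** — sum of druggability scores over T ("overall druggability score
  of the pathogenic genes within drug targets").
* **F2** — F1 normalized by |T| x 36, i.e. the per-gene average relative
  to the maximum single-gene score; lies in [0, 1].
* **F3** — number of genes in T that are ohnolog members (the proxy for
  high-confidence disease genes).
* **F4** — F3 / |T|, the ohnolog fraction of the targeted disease genes.

A drug targeting two disease genes, one known only to ClinVar (8 points)
and one only to DisGeNET (1 point), has F1 = 9 and F2 = 9/(2x36) = 0.125.

Feature vectors are disease-indexed: each drug's instance vector has one
entry per disease, zero wherever the drug targets no gene of that disease.
F4's denominator is the number of targeted *disease* genes, paralleling
F2; a variant using all targets is available via ``f4_denominator``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import numpy.typing as npt

from genedrug.data_model import Dataset


class FeatureKind(enum.Enum):
    F1_SCORE_SUM = "f1"
    F2_NORM_AVG = "f2"
    F3_OHNOLOG_COUNT = "f3"
    F4_OHNOLOG_RATIO = "f4"


#: Maximum attainable druggability score of a single gene (8+7+...+1).
NORMALIZATION_CONSTANT = 36


@dataclass(frozen=True)
class FeatureMatrix:
    """One n x q feature matrix aligned to Dataset.drug_order x Dataset.diseases."""

    feature_kind: FeatureKind
    values: npt.NDArray[np.float64]

    def row(self, ds: Dataset, drug_id: str) -> npt.NDArray[np.float64]:
        return self.values[ds.drug_order.index(drug_id)]


def _targeted_disease_genes(ds: Dataset, drug_id: str, disease_id: str) -> frozenset[str]:
    return ds.drug(drug_id).targets & ds.disease_genes(disease_id)


def f1_score_sum(
    ds: Dataset,
    scores: Mapping[tuple[str, str], int],
    drug_id: str,
    disease_id: str,
) -> int:
    """Sum of druggability scores over the drug's disease-associated targets; 0 if none."""
    genes = _targeted_disease_genes(ds, drug_id, disease_id)
    return sum(scores[(g, disease_id)] for g in genes)


def f2_norm_avg(f1: float, n_disease_genes_targeted: int) -> float:
    """F1 normalized by (count of targeted disease genes x 36); 0 when the count is 0."""
    if n_disease_genes_targeted == 0:
        return 0.0
    return f1 / (n_disease_genes_targeted * NORMALIZATION_CONSTANT)


def f3_f4_ohnolog(
    ds: Dataset,
    drug_id: str,
    disease_id: str,
    denominator: Literal["disease_targets", "all_targets"] = "disease_targets",
) -> tuple[int, float]:
    """Count and fraction of ohnolog members among the drug's targeted disease genes."""
    genes = _targeted_disease_genes(ds, drug_id, disease_id)
    members = ds.ohnologs.members
    f3 = len(genes & members)
    if denominator == "all_targets":
        denom = len(ds.drug(drug_id).targets)
    else:
        denom = len(genes)
    f4 = f3 / denom if denom else 0.0
    return f3, f4


def build_feature_matrices(
    ds: Dataset,
    scores: Mapping[tuple[str, str], int],
    denominator: Literal["disease_targets", "all_targets"] = "disease_targets",
) -> list[FeatureMatrix]:
    """Build all four n x q feature matrices, consistent with the scalar operations."""
    n, q = ds.n, ds.q
    f1 = np.zeros((n, q))
    f2 = np.zeros((n, q))
    f3 = np.zeros((n, q))
    f4 = np.zeros((n, q))
    members = ds.ohnologs.members
    for i, drug_id in enumerate(ds.drug_order):
        targets = ds.drug(drug_id).targets
        for l, disease_id in enumerate(ds.diseases):
            genes = targets & ds.disease_genes(disease_id)
            if not genes:
                continue
            f1[i, l] = sum(scores[(g, disease_id)] for g in genes)
            f2[i, l] = f1[i, l] / (len(genes) * NORMALIZATION_CONSTANT)
            f3[i, l] = len(genes & members)
            denom = len(targets) if denominator == "all_targets" else len(genes)
            f4[i, l] = f3[i, l] / denom if denom else 0.0
    return [
        FeatureMatrix(FeatureKind.F1_SCORE_SUM, f1),
        FeatureMatrix(FeatureKind.F2_NORM_AVG, f2),
        FeatureMatrix(FeatureKind.F3_OHNOLOG_COUNT, f3),
        FeatureMatrix(FeatureKind.F4_OHNOLOG_RATIO, f4),
    ]


def export_features_tsv(ds: Dataset, matrices: list[FeatureMatrix], path) -> None:
    """Long-format export: drug_id, disease_id, f1, f2, f3, f4."""
    import pandas as pd

    by_kind = {m.feature_kind: m.values for m in matrices}
    rows = []
    for i, drug_id in enumerate(ds.drug_order):
        for l, disease_id in enumerate(ds.diseases):
            rows.append(
                (
                    drug_id,
                    disease_id,
                    by_kind[FeatureKind.F1_SCORE_SUM][i, l],
                    by_kind[FeatureKind.F2_NORM_AVG][i, l],
                    by_kind[FeatureKind.F3_OHNOLOG_COUNT][i, l],
                    by_kind[FeatureKind.F4_OHNOLOG_RATIO][i, l],
                )
            )
    pd.DataFrame(rows, columns=["drug_id", "disease_id", "f1", "f2", "f3", "f4"]).to_csv(
        path, sep="\t", index=False
    )
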