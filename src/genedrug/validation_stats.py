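"""Data-validation and stratification statistics.

Covers the set-similarity measures used to vet the corpus (Tanimoto
coefficient between disease gene or drug sets, Lin information-content
similarity between ontology concepts, Czekanowski-Dice distance between
GO-term sets), the degree-preserving permutation null for drug-target
pairs, the clinically-active/approved-ratio stratifications, and the
Spearman comparison of disease druggability profiles.

The clinically-active ratio of a pair set is the fraction of its pairs
whose indication status is at least CLINICAL (approved pairs count as
clinically supported too); the approved ratio counts APPROVED only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from genedrug.data_model import Dataset, IndicationStatus, ValidationError, eligible_pairs
from genedrug.druggability import score_all


# ---------------------------------------------------------------------------
# set-similarity statistics

def tanimoto(n_a: int, n_b: int, n_ab: int) -> float:
    """Tanimoto coefficient |A n B| / |A u B| from set and intersection sizes."""
    if n_ab > min(n_a, n_b):
        raise ValidationError("intersection cannot exceed either set size")
    denom = n_a + n_b - n_ab
    if denom <= 0:
        raise ValidationError("Tanimoto is undefined for two empty sets")
    return n_ab / denom


@dataclass(frozen=True)
class OntologyConcept:
    """A concept in a probability-annotated DAG.

    ``probability`` is the corpus occurrence probability of the concept
    *including its descendants*, so it is non-decreasing from child to
    ancestor and the information content IC = -log(probability) decreases
    toward the root (IC(root) = 0).
    """

    concept_id: str
    parents: frozenset[str]
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValidationError(
                f"concept {self.concept_id!r}: probability must be in (0, 1]"
            )

    @property
    def ic(self) -> float:
        return -math.log(self.probability)


def _ancestors(concept_id: str, ontology: Mapping[str, OntologyConcept]) -> set[str]:
    """The concept itself plus all transitive parents."""
    out: set[str] = set()
    stack = [concept_id]
    while stack:
        cid = stack.pop()
        if cid in out:
            continue
        out.add(cid)
        stack.extend(ontology[cid].parents)
    return out


def lin_similarity(
    c1: OntologyConcept,
    c2: OntologyConcept,
    ontology: Mapping[str, OntologyConcept],
    canonical: bool = False,
) -> float:
    """Lin concept similarity IC(lcs) / (IC(c1) + IC(c2)).

    ``lcs`` is the common subsumer with maximal information content. The
    default follows the as-printed formula, under which a concept's
    similarity with itself is 0.5; ``canonical=True`` enables the usual
    2 * IC(lcs) numerator so self-similarity is 1. Returns NaN when the
    concepts share no ancestor.
    """
    common = _ancestors(c1.concept_id, ontology) & _ancestors(c2.concept_id, ontology)
    if not common:
        return math.nan
    lcs_ic = max(ontology[c].ic for c in common)
    denom = c1.ic + c2.ic
    if denom == 0.0:
        return math.nan
    numerator = 2.0 * lcs_ic if canonical else lcs_ic
    return numerator / denom


def load_ontology(path: str | Path) -> dict[str, OntologyConcept]:
    """Read ontology.tsv: concept_id, parent_ids (comma-joined, may be empty), probability."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        parents = frozenset(p for p in row.parent_ids.split(",") if p)
        out[row.concept_id] = OntologyConcept(row.concept_id, parents, float(row.probability))
    return out


def czekanowski_dice(go_a: Iterable[str], go_b: Iterable[str]) -> float:
    """GO-based Czekanowski-Dice distance: |A xor B| / (|A u B| + |A n B|)."""
    a, b = set(go_a), set(go_b)
    if not a and not b:
        return math.nan
    return len(a ^ b) / (len(a | b) + len(a & b))


def load_go_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read go_annotations.tsv: gene_id, term_id -> gene -> term set."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, set()).add(row.term_id)
    return {g: frozenset(t) for g, t in out.items()}


# ---------------------------------------------------------------------------
# clinically-active ratios and stratifications

def clinically_active_ratio(
    ds: Dataset, pair_subset: Iterable[tuple[str, str]]
) -> tuple[float, float]:
    """(clinically supported fraction, approved fraction) of a pair subset.

    Returns (NaN, NaN) for an empty subset.
    """
    pairs = list(pair_subset)
    if not pairs:
        return math.nan, math.nan
    status = ds.indication_map()
    n_clin = sum(1 for p in pairs if p in status)
    n_appr = sum(1 for p in pairs if status.get(p) is IndicationStatus.APPROVED)
    return n_clin / len(pairs), n_appr / len(pairs)


class Stratifier(enum.Enum):
    TARGET_COUNT = "target_count"
    DRUGGABILITY_SCORE_BIN = "druggability_score"
    OHNOLOG_COVERAGE = "ohnolog_coverage"
    TOPGENE_COVERAGE = "topgene_coverage"


@dataclass(frozen=True)
class RatioCurvePoint:
    stratum: str
    n_pairs: int
    clinically_active_ratio: float
    approved_ratio: float


def _pair_statistic(ds: Dataset, stratifier: Stratifier) -> dict[tuple[str, str], float]:
    """Per eligible pair: the quantity the curve stratifies on."""
    from genedrug.features import f1_score_sum, f3_f4_ohnolog

    scores = score_all(ds)
    out = {}
    for drug_id, disease_id in eligible_pairs(ds):
        if stratifier is Stratifier.TARGET_COUNT:
            v = float(len(ds.drug(drug_id).targets & ds.disease_genes(disease_id)))
        elif stratifier is Stratifier.DRUGGABILITY_SCORE_BIN:
            v = float(f1_score_sum(ds, scores, drug_id, disease_id))
        else:
            # ohnolog membership doubles as the high-confidence ("top gene") proxy
            v = float(f3_f4_ohnolog(ds, drug_id, disease_id)[0])
        out[(drug_id, disease_id)] = v
    return out


def stratified_ratio_curve(
    ds: Dataset,
    stratifier: Stratifier,
    bins: Sequence[float] | int = 5,
) -> tuple[list[RatioCurvePoint], float]:
    """Clinically-active/approved ratios per stratum, plus the monotone-trend statistic.

    ``bins`` is either a bin count (equal-width over the stratifier's range)
    or an explicit ascending edge sequence covering it. Empty bins yield a
    point with n_pairs = 0 and NaN ratios. The trend statistic is the
    Spearman correlation of bin index against clinically-active ratio over
    the non-empty bins (NaN when fewer than 2 non-empty bins exist).
    """
    values = _pair_statistic(ds, stratifier)
    if not values:
        raise ValidationError("no eligible pairs to stratify")
    vals = np.array(list(values.values()))
    if isinstance(bins, int):
        lo, hi = vals.min(), vals.max()
        edges = np.linspace(lo, hi, bins + 1) if hi > lo else np.array([lo, lo + 1.0])
    else:
        edges = np.asarray(bins, dtype=float)
        if edges[0] > vals.min() or edges[-1] < vals.max():
            raise ValidationError("bins must cover the stratifier's range")
    n_bins = len(edges) - 1
    assignment = np.clip(np.digitize(vals, edges[1:-1]), 0, n_bins - 1)

    pairs = list(values.keys())
    points = []
    ratios = []
    for b in range(n_bins):
        subset = [pairs[i] for i in np.flatnonzero(assignment == b)]
        clin, appr = clinically_active_ratio(ds, subset)
        points.append(
            RatioCurvePoint(
                stratum=f"[{edges[b]:g}, {edges[b + 1]:g}{']' if b == n_bins - 1 else ')'}",
                n_pairs=len(subset),
                clinically_active_ratio=clin,
                approved_ratio=appr,
            )
        )
        if subset:
            ratios.append((b, clin))
    if len(ratios) >= 2 and len({r for _, r in ratios}) > 1:
        trend = float(stats.spearmanr([b for b, _ in ratios], [r for _, r in ratios]).statistic)
    else:
        trend = math.nan
    return points, trend


# ---------------------------------------------------------------------------
# permutation null for drug-target pairs

def permutation_test(
    ds: Dataset, n_perm: int = 10000, seed: int = 0
) -> tuple[float, np.ndarray, float]:
    """Degree-preserving permutation null for the clinically-active ratio.

    The gene column of the drug-target table is randomly permuted, which
    preserves both each drug's number of target slots and the global target
    multiset. The clinically-active ratio over eligible pairs is recomputed
    per permutation, and the empirical p-value uses the +1 correction

        p = (1 + #{null >= observed}) / (1 + n_perm)

    so it can never be exactly zero (with 10,000 permutations the smallest
    attainable p is 1/10,001).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    genes = sorted({g for d in ds.drugs for g in d.targets} | {a.gene_id for a in ds.associations})
    gi = {g: i for i, g in enumerate(genes)}
    q = ds.q
    dli = {d: l for l, d in enumerate(ds.diseases)}
    assoc = np.zeros((len(genes), q), dtype=bool)
    for a in ds.associations:
        assoc[gi[a.gene_id], dli[a.disease_id]] = True

    drugs = sorted(ds.drugs, key=lambda d: d.drug_id)
    flat = np.array([gi[g] for d in drugs for g in sorted(d.targets)])
    sizes = np.array([len(d.targets) for d in drugs])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    indicated = np.zeros((len(drugs), q), dtype=bool)
    dii = {d.drug_id: i for i, d in enumerate(drugs)}
    for r in ds.indications:
        if r.drug_id in dii:
            indicated[dii[r.drug_id], dli[r.disease_id]] = True

    def _ratio(flat_genes: np.ndarray) -> float:
        hit = np.add.reduceat(assoc[flat_genes].astype(np.int32), offsets, axis=0) > 0
        n_elig = int(hit.sum())
        if n_elig == 0:
            return 0.0
        return float((hit & indicated).sum()) / n_elig

    observed = _ratio(flat)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _ratio(rng.permutation(flat))
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    return observed, null, p


# ---------------------------------------------------------------------------
# disease druggability-profile comparison

def disease_profile_correlation(
    scores: Mapping[tuple[str, str], int], disease_a: str, disease_b: str
) -> float:
    """Spearman correlation of two diseases' gene druggability profiles.

    Profiles are compared over the union of genes scored for either
    disease, with absent genes scored 0. Returns NaN when the union holds
    fewer than 3 genes.
    """
    genes = sorted(
        {g for g, d in scores if d == disease_a} | {g for g, d in scores if d == disease_b}
    )
    if len(genes) < 3:
        return math.nan
    a = [scores.get((g, disease_a), 0) for g in genes]
    b = [scores.get((g, disease_b), 0) for g in genes]
    return float(stats.spearmanr(a, b).statistic)
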