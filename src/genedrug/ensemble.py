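"""Weighted-scoring ensemble of per-feature MLKNN predictors.

One MLKNN model is built per feature kind; because features contribute
unevenly, their score matrices S_i are combined by a linear weighted sum
with non-negative weights on the unit simplex:

    ensemble score = sum_i w_i S_i,   w_i >= 0,  sum_i w_i = 1.

Weights are tuned by exhaustive search over a simplex grid, with the
internal 5-fold cross-validated AUPR on the training data — pooled over
all eligible (drug, disease) cells — as the fitness score. For each
feature kind the five per-fold models are kept and averaged at prediction
time; the cell-wise standard deviation across folds is reported alongside
the mean as an uncertainty indicator but never affects calls.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import numpy.typing as npt

from genedrug import mlknn
from genedrug.data_model import Dataset, ValidationError, eligible_pairs
from genedrug.features import FeatureMatrix, build_feature_matrices
from genedrug.metrics import pr_curve_aupr
from genedrug.mlknn import ConfigurationError, MLKNNModel

logger = logging.getLogger(__name__)

FORMAT_TAG = "genedrug-ensemble/1"
N_INTERNAL_FOLDS = 5


def label_matrix(ds: Dataset) -> npt.NDArray[np.int_]:
    """Binary n x q indication matrix aligned to drug_order x diseases."""
    Y = np.zeros((ds.n, ds.q), dtype=int)
    dii = {d: i for i, d in enumerate(ds.drug_order)}
    dli = {d: l for l, d in enumerate(ds.diseases)}
    for r in ds.indications:
        if r.drug_id in dii:
            Y[dii[r.drug_id], dli[r.disease_id]] = 1
    return Y


def eligible_mask(ds: Dataset) -> npt.NDArray[np.bool_]:
    """Boolean n x q mask of eligible (drug targets >=1 disease gene) cells."""
    M = np.zeros((ds.n, ds.q), dtype=bool)
    dii = {d: i for i, d in enumerate(ds.drug_order)}
    dli = {d: l for l, d in enumerate(ds.diseases)}
    for drug_id, disease_id in eligible_pairs(ds):
        M[dii[drug_id], dli[disease_id]] = True
    return M


def simplex_grid(m: int, step: float) -> list[tuple[float, ...]]:
    """All weight vectors on the m-simplex with the given grid resolution."""
    t = round(1.0 / step)
    if abs(t * step - 1.0) > 1e-9:
        raise ValidationError(f"grid step {step} does not evenly divide 1")
    grid = []
    for parts in itertools.product(range(t + 1), repeat=m - 1):
        rest = t - sum(parts)
        if rest >= 0:
            grid.append(tuple(p / t for p in parts) + (rest / t,))
    return grid


def _check_simplex(weights: npt.NDArray[np.float64], tol: float = 1e-9) -> None:
    w = np.asarray(weights, dtype=float)
    if (w < -tol).any() or abs(w.sum() - 1.0) > tol:
        raise ValidationError(f"weights must be non-negative and sum to 1, got {w}")


def combine(
    score_matrices: list[npt.NDArray[np.float64]], weights: npt.NDArray[np.float64]
) -> npt.NDArray[np.float64]:
    """Cell-wise weighted sum sum_i w_i S_i of base-predictor score matrices."""
    w = np.asarray(weights, dtype=float)
    if len(score_matrices) != w.size:
        raise ValidationError("one weight per score matrix is required")
    _check_simplex(w)
    stack = np.stack(score_matrices, axis=0)
    return np.tensordot(w, stack, axes=1)


def feature_group_score(
    group: list[MLKNNModel], test_features: npt.NDArray[np.float64]
) -> tuple[npt.NDArray[np.float64], npt.NDArray[np.float64]]:
    """Cell-wise mean and population SD across the five fold models of one feature."""
    if len(group) != N_INTERNAL_FOLDS:
        raise ConfigurationError(
            f"a feature group holds exactly {N_INTERNAL_FOLDS} fold models, got {len(group)}"
        )
    preds = np.stack([m.predict_scores(test_features) for m in group], axis=0)
    return preds.mean(axis=0), preds.std(axis=0)


def _cardinality_bands(Y: npt.NDArray[np.int_]) -> npt.NDArray[np.int_]:
    # stratification bands on per-drug positive count: 0, 1-2, >=3
    card = Y.sum(axis=1)
    return np.digitize(card, [1, 3])


def _stratified_folds(
    Y: npt.NDArray[np.int_], n_folds: int, rng: np.random.Generator
) -> npt.NDArray[np.int_]:
    n = Y.shape[0]
    bands = _cardinality_bands(Y)
    fold = np.empty(n, dtype=int)
    for b in np.unique(bands):
        idx = np.flatnonzero(bands == b)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


@dataclass
class EnsembleModel:
    """Per-feature fold-averaged MLKNN predictors plus tuned simplex weights."""

    base_predictors: list[list[MLKNNModel]]  # [feature][fold]
    weights: npt.NDArray[np.float64]
    fitness: float
    k: int
    s: float

    def __post_init__(self) -> None:
        _check_simplex(self.weights)
        for group in self.base_predictors:
            if len(group) != N_INTERNAL_FOLDS:
                raise ConfigurationError("each feature group must hold 5 fold models")

    def score_matrices(
        self, feature_matrices: list[FeatureMatrix]
    ) -> tuple[npt.NDArray[np.float64], npt.NDArray[np.float64]]:
        """Ensemble mean score and cross-fold SD for every (drug, disease) cell."""
        per_fold = []
        for j in range(N_INTERNAL_FOLDS):
            fold_scores = [
                self.base_predictors[f][j].predict_scores(fm.values)
                for f, fm in enumerate(feature_matrices)
            ]
            per_fold.append(combine(fold_scores, self.weights))
        stack = np.stack(per_fold, axis=0)
        return stack.mean(axis=0), stack.std(axis=0)

    def save(self, path: str | Path) -> None:
        def _model_payload(m: MLKNNModel) -> dict:
            return {
                "k": m.k,
                "s": m.s,
                "prior_h1": m.prior_h1.tolist(),
                "posterior_h1": m.posterior_h1.tolist(),
                "posterior_h0": m.posterior_h0.tolist(),
                "c_pos": m.c_pos.tolist(),
                "c_neg": m.c_neg.tolist(),
                "train_features": m.train_features.tolist(),
                "train_labels": m.train_labels.tolist(),
            }

        payload = {
            "format": FORMAT_TAG,
            "weights": self.weights.tolist(),
            "fitness": self.fitness,
            "k": self.k,
            "s": self.s,
            "base_predictors": [
                [_model_payload(m) for m in group] for group in self.base_predictors
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != FORMAT_TAG:
            raise ValidationError(f"unrecognized model format tag: {payload.get('format')!r}")

        def _model(p: dict) -> MLKNNModel:
            return MLKNNModel(
                k=int(p["k"]),
                s=float(p["s"]),
                train_features=np.asarray(p["train_features"], dtype=float),
                train_labels=np.asarray(p["train_labels"], dtype=int),
                prior_h1=np.asarray(p["prior_h1"], dtype=float),
                posterior_h1=np.asarray(p["posterior_h1"], dtype=float),
                posterior_h0=np.asarray(p["posterior_h0"], dtype=float),
                c_pos=np.asarray(p["c_pos"], dtype=int),
                c_neg=np.asarray(p["c_neg"], dtype=int),
            )

        return cls(
            base_predictors=[
                [_model(p) for p in group] for group in payload["base_predictors"]
            ],
            weights=np.asarray(payload["weights"], dtype=float),
            fitness=float(payload["fitness"]),
            k=int(payload["k"]),
            s=float(payload["s"]),
        )


def out_of_fold_scores(
    feature_matrices: list[FeatureMatrix],
    Y: npt.NDArray[np.int_],
    folds: npt.NDArray[np.int_],
    k: int,
    s: float,
) -> tuple[list[npt.NDArray[np.float64]], list[list[MLKNNModel]]]:
    """Per-feature out-of-fold score matrices and the fitted fold models."""
    oof = []
    groups = []
    for fm in feature_matrices:
        X = fm.values
        S = np.zeros_like(X, dtype=float)
        group = []
        for j in range(N_INTERNAL_FOLDS):
            train = folds != j
            model = mlknn.fit(X[train], Y[train], k=k, s=s)
            S[~train] = model.predict_scores(X[~train])
            group.append(model)
        oof.append(S)
        groups.append(group)
    return oof, groups


def tune_weights(
    feature_matrices: list[FeatureMatrix],
    Y: npt.NDArray[np.int_],
    mask: npt.NDArray[np.bool_],
    k: int = 10,
    s: float = 1.0,
    grid_step: float = 0.1,
    seed: int = 0,
) -> EnsembleModel:
    """Tune simplex weights by internal 5-fold CV AUPR over eligible cells.

    The search is an exhaustive simplex grid (step 0.1 over 4 weights gives
    286 candidates), which is deterministic and exactly reproducible. Ties
    are broken toward the uniform vector, then lexicographically. A fold
    whose held-out eligible cells contain no positive is re-drawn once;
    a second failure raises.
    """
    n = Y.shape[0]
    if n < 10:
        raise ValidationError("weight tuning requires at least 10 drugs")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(Y, N_INTERNAL_FOLDS, rng)
    for attempt in range(2):
        bad = [
            j
            for j in range(N_INTERNAL_FOLDS)
            if Y[(folds == j)][mask[folds == j]].sum() == 0
        ]
        if not bad:
            break
        if attempt == 1:
            raise ValidationError(f"fold(s) {bad} hold no positive eligible cell after re-draw")
        logger.info("re-drawing internal folds: fold(s) %s had no positives", bad)
        folds = _stratified_folds(Y, N_INTERNAL_FOLDS, rng)

    oof, groups = out_of_fold_scores(feature_matrices, Y, folds, k=k, s=s)
    y_flat = Y[mask]
    s_flat = [S[mask] for S in oof]

    m = len(feature_matrices)
    uniform = np.full(m, 1.0 / m)
    best: tuple[float, float, tuple[float, ...]] | None = None
    best_w = None
    for w in simplex_grid(m, grid_step):
        wv = np.asarray(w)
        combined = sum(wi * sf for wi, sf in zip(w, s_flat))
        aupr = pr_curve_aupr(combined, y_flat)
        # sort key: maximize AUPR, then minimize distance to uniform, then lexicographic
        key = (-aupr, float(np.sum((wv - uniform) ** 2)), w)
        if best is None or key < best:
            best = key
            best_w = wv
    assert best is not None and best_w is not None
    return EnsembleModel(
        base_predictors=groups, weights=best_w, fitness=-best[0], k=k, s=s
    )


def train_on_dataset(
    ds: Dataset,
    k: int = 10,
    s: float = 1.0,
    grid_step: float = 0.1,
    seed: int = 0,
) -> tuple[EnsembleModel, list[FeatureMatrix]]:
    """Score genes, build the four feature matrices and tune the ensemble."""
    from genedrug.druggability import score_all

    scores = score_all(ds)
    mats = build_feature_matrices(ds, scores)
    model = tune_weights(mats, label_matrix(ds), eligible_mask(ds), k=k, s=s,
                         grid_step=grid_step, seed=seed)
    return model, mats


def predict(
    model: EnsembleModel,
    ds: Dataset,
    threshold: float = 0.5,
    feature_matrices: list[FeatureMatrix] | None = None,
) -> list[tuple[str, str, float, float, bool]]:
    """Score all eligible pairs; call = score >= threshold; sorted by descending score.

    Returns (drug_id, disease_id, score, sd, call) tuples.
    """
    if feature_matrices is None:
        from genedrug.druggability import score_all

        feature_matrices = build_feature_matrices(ds, score_all(ds))
    mean, sd = model.score_matrices(feature_matrices)
    mask = eligible_mask(ds)
    rows = []
    for i, drug_id in enumerate(ds.drug_order):
        for l, disease_id in enumerate(ds.diseases):
            if mask[i, l]:
                sc = float(mean[i, l])
                rows.append((drug_id, disease_id, sc, float(sd[i, l]), sc >= threshold))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows
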