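"""Multi-label k-nearest-neighbor (MLKNN) classifier.

For each label l the classifier makes a MAP decision between H1 ("the
instance carries label l") and H0, conditioned on the event E_j that
exactly j of the instance's k nearest training neighbors carry l:

    prior      P(H1) = (s + n_pos(l)) / (2s + n)
    posterior  P(E_j | H1) = (s + c_l[j]) / (s(k+1) + sum_i c_l[i])
               P(E_j | H0) = (s + c'_l[j]) / (s(k+1) + sum_i c'_l[i])

where c_l[j] counts training instances *carrying* l with exactly j
positive neighbors and c'_l[j] those *not carrying* l with exactly j
positive neighbors, and s is the Laplace smoothing factor. The reported
score is the normalized two-hypothesis posterior

    score = P(H1) P(E_C|H1) / (P(H1) P(E_C|H1) + P(H0) P(E_C|H0)),

which lies in [0, 1] and reproduces the MAP decision at a 0.5 cutoff.

During fitting each instance is excluded from its own neighborhood
(leave-one-out), preventing label leakage. Distance ties at the k-th
neighbor are broken by ascending training-instance index, making fits
and predictions fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import numpy.typing as npt

from genedrug.data_model import ValidationError

FORMAT_TAG = "genedrug-mlknn/1"


class ConfigurationError(ValueError):
    """k exceeds the number of available neighbors, or a group is malformed."""


def _pairwise_sq_dists(
    X: npt.NDArray[np.float64], Y: npt.NDArray[np.float64]
) -> npt.NDArray[np.float64]:
    # broadcast form keeps per-cell summation order identical to a plain loop,
    # so neighbor orderings are reproducible against a loop-based reference
    return ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)


def _k_nearest(
    dists: npt.NDArray[np.float64], k: int, exclude_diagonal: bool
) -> npt.NDArray[np.intp]:
    """Indices of the k nearest columns per row; ties broken by ascending index."""
    m, n = dists.shape
    if exclude_diagonal:
        dists = dists.copy()
        np.fill_diagonal(dists, np.inf)
    avail = n - 1 if exclude_diagonal else n
    if k > avail:
        raise ConfigurationError(f"k={k} exceeds the {avail} available neighbors")
    order = np.lexsort((np.broadcast_to(np.arange(n), (m, n)), dists), axis=1)
    return order[:, :k]


@dataclass
class MLKNNModel:
    """A fitted MLKNN model for one feature matrix.

    Attributes hold the smoothed prior per label, the (q, k+1) posterior
    tables for each hypothesis, and the raw neighbor-count tables they
    were built from.
    """

    k: int
    s: float
    train_features: npt.NDArray[np.float64]
    train_labels: npt.NDArray[np.int_]
    prior_h1: npt.NDArray[np.float64]
    posterior_h1: npt.NDArray[np.float64]
    posterior_h0: npt.NDArray[np.float64]
    c_pos: npt.NDArray[np.int_]
    c_neg: npt.NDArray[np.int_]

    @property
    def n(self) -> int:
        return self.train_features.shape[0]

    @property
    def q(self) -> int:
        return self.train_labels.shape[1]

    def membership_counts(self, instance_features: npt.NDArray[np.float64]) -> npt.NDArray[np.int_]:
        """C(l): how many of the k nearest training drugs carry each label."""
        x = np.asarray(instance_features, dtype=float).reshape(1, -1)
        if x.shape[1] != self.train_features.shape[1]:
            raise ValidationError(
                f"feature dimension mismatch: got {x.shape[1]}, expected "
                f"{self.train_features.shape[1]}"
            )
        nn = _k_nearest(_pairwise_sq_dists(x, self.train_features), self.k, False)
        return self.train_labels[nn[0]].sum(axis=0)

    def predict_scores(self, test_features: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        """Normalized two-hypothesis posterior scores, shape (m, q), in [0, 1]."""
        X = np.asarray(test_features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.train_features.shape[1]:
            raise ValidationError(
                f"test feature matrix must be (m, {self.train_features.shape[1]})"
            )
        nn = _k_nearest(_pairwise_sq_dists(X, self.train_features), self.k, False)
        counts = self.train_labels[nn].sum(axis=1)  # (m, q)
        m = X.shape[0]
        scores = np.empty((m, self.q))
        for l in range(self.q):
            c = counts[:, l]
            num = self.prior_h1[l] * self.posterior_h1[l, c]
            den = num + (1.0 - self.prior_h1[l]) * self.posterior_h0[l, c]
            scores[:, l] = num / den
        return scores

    def save(self, path: str | Path) -> None:
        payload = {
            "format": FORMAT_TAG,
            "k": self.k,
            "s": self.s,
            "prior_h1": self.prior_h1.tolist(),
            "posterior_h1": self.posterior_h1.tolist(),
            "posterior_h0": self.posterior_h0.tolist(),
            "c_pos": self.c_pos.tolist(),
            "c_neg": self.c_neg.tolist(),
            "train_features": self.train_features.tolist(),
            "train_labels": self.train_labels.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MLKNNModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != FORMAT_TAG:
            raise ValidationError(f"unrecognized model format tag: {payload.get('format')!r}")
        return cls(
            k=int(payload["k"]),
            s=float(payload["s"]),
            train_features=np.asarray(payload["train_features"], dtype=float),
            train_labels=np.asarray(payload["train_labels"], dtype=int),
            prior_h1=np.asarray(payload["prior_h1"], dtype=float),
            posterior_h1=np.asarray(payload["posterior_h1"], dtype=float),
            posterior_h0=np.asarray(payload["posterior_h0"], dtype=float),
            c_pos=np.asarray(payload["c_pos"], dtype=int),
            c_neg=np.asarray(payload["c_neg"], dtype=int),
        )


def fit(
    train_features: npt.NDArray[np.float64],
    train_labels: npt.NDArray[np.int_],
    k: int = 10,
    s: float = 1.0,
) -> MLKNNModel:
    """Fit priors, neighbor-count tables and posteriors from a training matrix.

    ``train_labels`` must be binary, one column per label. Raises
    ConfigurationError when k exceeds n - 1 (each instance's own row is
    excluded from its neighborhood).
    """
    X = np.asarray(train_features, dtype=float)
    Y = np.asarray(train_labels)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("feature and label matrices disagree on instance count")
    if not np.isin(Y, (0, 1)).all():
        raise ValidationError("labels must be binary (0/1)")
    Y = Y.astype(int)
    n, q = Y.shape

    nn = _k_nearest(_pairwise_sq_dists(X, X), k, exclude_diagonal=True)
    counts = Y[nn].sum(axis=1)  # (n, q): positive neighbors per instance/label

    prior_h1 = (s + Y.sum(axis=0)) / (s * 2 + n)
    c_pos = np.zeros((q, k + 1), dtype=int)
    c_neg = np.zeros((q, k + 1), dtype=int)
    for l in range(q):
        for i in range(n):
            j = counts[i, l]
            if Y[i, l] == 1:
                c_pos[l, j] += 1
            else:
                c_neg[l, j] += 1
    posterior_h1 = (s + c_pos) / (s * (k + 1) + c_pos.sum(axis=1, keepdims=True))
    posterior_h0 = (s + c_neg) / (s * (k + 1) + c_neg.sum(axis=1, keepdims=True))

    return MLKNNModel(
        k=k,
        s=s,
        train_features=X,
        train_labels=Y,
        prior_h1=prior_h1,
        posterior_h1=posterior_h1,
        posterior_h0=posterior_h0,
        c_pos=c_pos,
        c_neg=c_neg,
    )
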