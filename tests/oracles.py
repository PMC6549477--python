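"""Independent, loop-based reference implementations used as test oracles.

Everything here is written as literal transcriptions of the defining
formulas — plain Python loops, no shared code with the package — so that
agreement between the package and these functions is evidence, not
tautology.
"""

from __future__ import annotations

import math


def mlknn_oracle(X, Y, X_test, k, s):
    """Literal MLKNN: returns (prior, post1, post0, scores) as nested lists.

    Training neighborhoods exclude the instance itself; distance ties are
    broken by ascending training index.
    """
    n = len(Y)
    q = len(Y[0])

    def sqdist(a, b):
        t = 0.0
        for u, v in zip(a, b):
            t += (u - v) ** 2
        return t

    def knn(x, exclude):
        cand = []
        for j in range(n):
            if j == exclude:
                continue
            cand.append((sqdist(x, X[j]), j))
        cand.sort()
        return [j for _, j in cand[:k]]

    counts = []
    for i in range(n):
        nbrs = knn(X[i], i)
        counts.append([sum(Y[a][l] for a in nbrs) for l in range(q)])

    prior = []
    for l in range(q):
        prior.append((s + sum(Y[i][l] for i in range(n))) / (s * 2 + n))

    post1 = []
    post0 = []
    for l in range(q):
        c_pos = [0] * (k + 1)
        c_neg = [0] * (k + 1)
        for i in range(n):
            if Y[i][l] == 1:
                c_pos[counts[i][l]] += 1
            else:
                c_neg[counts[i][l]] += 1
        post1.append(
            [(s + c_pos[j]) / (s * (k + 1) + sum(c_pos)) for j in range(k + 1)]
        )
        post0.append(
            [(s + c_neg[j]) / (s * (k + 1) + sum(c_neg)) for j in range(k + 1)]
        )

    scores = []
    for x in X_test:
        cand = sorted((sqdist(x, X[j]), j) for j in range(n))
        nbrs = [j for _, j in cand[:k]]
        row = []
        for l in range(q):
            c = sum(Y[a][l] for a in nbrs)
            num = prior[l] * post1[l][c]
            den = num + (1.0 - prior[l]) * post0[l][c]
            row.append(num / den)
        scores.append(row)
    return prior, post1, post0, scores


def aupr_sweep_oracle(scores, labels):
    """AUPR as the precision-recall step integral over distinct thresholds."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def multilabel_rank_oracle(S, Y):
    """Brute-force pairwise-rank enumeration of the five multi-label metrics."""
    n = len(S)
    q = len(S[0])
    hamming = sum(
        1 for i in range(n) for l in range(q) if (S[i][l] >= 0.5) != (Y[i][l] == 1)
    ) / (n * q)

    one_err, cover, rloss, ap = [], [], [], []
    for i in range(n):
        rel = [l for l in range(q) if Y[i][l] == 1]
        irr = [l for l in range(q) if Y[i][l] == 0]
        if not rel:
            continue
        s = S[i]
        one_err.append(0.0 if max(s[l] for l in rel) == max(s) else 1.0)
        cover.append(max(sum(1 for j in range(q) if s[j] >= s[l]) for l in rel) - 1)
        if irr:
            bad = 0.0
            for a in rel:
                for b in irr:
                    if s[a] < s[b]:
                        bad += 1.0
                    elif s[a] == s[b]:
                        bad += 0.5
            rloss.append(bad / (len(rel) * len(irr)))
        precs = []
        for l in rel:
            rank = 1 + sum(1 for j in range(q) if s[j] > s[l]) + 0.5 * sum(
                1 for j in range(q) if j != l and s[j] == s[l]
            )
            rel_above = 1 + sum(1 for j in rel if s[j] > s[l]) + 0.5 * sum(
                1 for j in rel if j != l and s[j] == s[l]
            )
            precs.append(rel_above / rank)
        ap.append(sum(precs) / len(precs))

    def mean(xs):
        return sum(xs) / len(xs) if xs else math.nan

    return {
        "hamming_loss": hamming,
        "one_error": mean(one_err),
        "coverage": mean(cover),
        "ranking_loss": mean(rloss),
        "average_precision": mean(ap),
    }
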