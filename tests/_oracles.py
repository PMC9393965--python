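"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the package: plain-Python counting
and exhaustive search only.
"""

import math
from collections import Counter

import numpy as np


def gorodkin_rk(y_true, y_pred, classes):
    """K-category correlation coefficient from the confusion matrix."""
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    C = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        C[pos[t], pos[p]] += 1
    s = C.sum()
    c = np.trace(C)
    t_k = C.sum(axis=1)
    p_k = C.sum(axis=0)
    num = c * s - float(t_k @ p_k)
    den = math.sqrt(s**2 - float(p_k @ p_k)) * math.sqrt(s**2 - float(t_k @ t_k))
    return 0.0 if den == 0 else num / den


def binary_mcc_closed_form(y_true, y_pred, positive):
    """TP/FP/TN/FN closed form of the binary Matthews correlation."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else (tp * tn - fp * fn) / den


def brute_mi(x, y):
    """Mutual information in bits by direct summation over observed cells."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        total += p_ab * math.log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return total


def brute_mrmr_order(states, y, criterion):
    """Exhaustive per-step argmax of the greedy max-relevance/min-redundancy
    rule; ties broken by column index."""
    n, d = states.shape
    eps = np.finfo(float).eps
    relevance = [brute_mi(states[:, j].tolist(), list(y)) for j in range(d)]
    selected = []
    remaining = list(range(d))
    while remaining:
        best, best_score = None, None
        for j in remaining:
            if not selected:
                score = relevance[j]
            else:
                red = sum(
                    brute_mi(states[:, j].tolist(), states[:, s].tolist())
                    for s in selected
                ) / len(selected)
                if criterion == "difference":
                    score = relevance[j] - red
                else:
                    score = relevance[j] / max(red, eps)
            if best_score is None or score > best_score + 1e-9:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return selected
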