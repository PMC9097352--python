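"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np


def brute_force_matches(surfaces: list[str], words: tuple[str, ...], max_gap: int):
    """All-subsequence gap-rule matcher: enumerate, then select greedily.

    Enumerates every increasing token-index subsequence whose lowercased
    surfaces equal ``words`` with at most ``max_gap`` intervening tokens
    between consecutive picks; then repeatedly selects the leftmost-starting,
    shortest candidate that does not overlap previous selections, resuming
    after each selection.
    """
    low = [s.lower() for s in surfaces]
    words = tuple(w.lower() for w in words)
    candidates: set[tuple[int, int]] = set()

    def rec(wi: int, prev: int, first: int) -> None:
        if wi == len(words):
            candidates.add((first, prev))
            return
        lo = 0 if prev < 0 else prev + 1
        hi = len(low) if prev < 0 else min(len(low), prev + 2 + max_gap)
        for j in range(lo, hi):
            if low[j] == words[wi]:
                rec(wi + 1, j, j if prev < 0 else first)

    rec(0, -1, -1)
    selected = []
    cursor = 0
    remaining = sorted(candidates)
    while True:
        avail = [c for c in remaining if c[0] >= cursor]
        if not avail:
            break
        best = min(avail, key=lambda c: (c[0], c[1]))
        selected.append(best)
        cursor = best[1] + 1
    return selected


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 200) -> np.ndarray:
    """Unpenalized logistic regression by Newton / iteratively reweighted LS.

    Returns [intercept, b1, ..., bp].
    """
    X1 = np.column_stack([np.ones(len(y)), X])
    b = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X1 @ b)))
        w = p * (1 - p)
        step = np.linalg.solve((X1.T * w) @ X1, X1.T @ (y - p))
        b += step
        if np.max(np.abs(step)) < tol:
            break
    return b


def confusion_by_counting(probs, labels, cutoff):
    """Explicit per-row counting of the 2x2 table."""
    tp = fp = tn = fn = 0
    for p, y in zip(probs, labels):
        pred = p >= cutoff
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def auc_by_pair_enumeration(probs, labels) -> float:
    """Mann-Whitney AUC by enumerating every (positive, negative) pair."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    wins = sum((1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def random_toy_setup(rng: np.random.Generator):
    """A random sentence corpus plus a random toy pattern set for oracle checks.

    The vocabulary deliberately overlaps the pattern words heavily so that
    matches, near-misses and overlapping candidates are all common.
    """
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]
    patterns = []
    for _ in range(int(rng.integers(1, 6))):
        k = int(rng.integers(1, 4))
        words = tuple(vocab[int(i)] for i in rng.integers(0, len(vocab), size=k))
        patterns.append((words, int(rng.integers(0, 3))))
    sentences = []
    for _ in range(int(rng.integers(1, 50))):
        n = int(rng.integers(3, 13))
        sentences.append([vocab[int(i)] for i in rng.integers(0, len(vocab), size=n)])
    return sentences, patterns
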