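"""Independent brute-force oracles used to cross-check the implementations.

These are deliberately naive: the DTW oracle enumerates every reference
window and runs a plain closed dynamic program on it; the matching oracle
enumerates every one-to-one assignment. They share no code with the
package's implementations.
"""

import numpy as np


def closed_dtw_cost(query: np.ndarray, window: np.ndarray) -> float:
    """Classic DTW accumulated cost, closed at both ends, squared local cost."""
    q = np.atleast_2d(query.T).T if query.ndim == 1 else query
    w = np.atleast_2d(window.T).T if window.ndim == 1 else window
    n, m = len(q), len(w)
    acc = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            c = float(((q[i] - w[j]) ** 2).sum())
            if i == 0 and j == 0:
                acc[i, j] = c
            else:
                best = np.inf
                if i > 0:
                    best = min(best, acc[i - 1, j])
                if j > 0:
                    best = min(best, acc[i, j - 1])
                if i > 0 and j > 0:
                    best = min(best, acc[i - 1, j - 1])
                acc[i, j] = c + best
    return float(acc[n - 1, m - 1])


def subsequence_dtw_oracle(query: np.ndarray, reference: np.ndarray) -> float:
    """Minimum closed-DTW distance over all reference windows [s, e]."""
    m = len(reference)
    best = np.inf
    for s in range(m):
        for e in range(s, m):
            best = min(best, closed_dtw_cost(query, reference[s : e + 1]))
    return float(np.sqrt(best))


def best_matching_oracle(iou: np.ndarray, threshold: float) -> int:
    """Maximum number of one-to-one matches with IoU >= threshold.

    Kuhn's augmenting-path algorithm on the thresholded bipartite graph —
    maximizes the match *count* directly, independently of the weighted
    assignment used by the implementation.
    """
    n_gt, n_pred = iou.shape
    adj = [[p for p in range(n_pred) if iou[g, p] >= threshold] for g in range(n_gt)]
    match_of_pred = [-1] * n_pred

    def try_augment(g: int, visited: list[bool]) -> bool:
        for p in adj[g]:
            if not visited[p]:
                visited[p] = True
                if match_of_pred[p] == -1 or try_augment(match_of_pred[p], visited):
                    match_of_pred[p] = g
                    return True
        return False

    count = 0
    for g in range(n_gt):
        if try_augment(g, [False] * n_pred):
            count += 1
    return count
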