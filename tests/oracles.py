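"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: textbook full-matrix DTW
with path backtracking, and a plain-numpy LSTM cell.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np


def dtw_full(s1, s2, gamma: float = 1.0) -> Tuple[float, List[Tuple[int, int]]]:
    """Unconstrained textbook DTW: full (n+1)x(m+1) DP plus path backtrack.

    Returns (distance, path) with the path as 1-based (i, j) pairs from
    (1, 1) to (n, m).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n, m = len(s1), len(s2)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(s1[i - 1] - s2[j - 1]) ** gamma
            D[i, j] = c + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    # backtrack (prefer diagonal on ties)
    path = [(n, m)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = []
        if i > 1 and j > 1:
            moves.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            moves.append((D[i - 1, j], (i - 1, j)))
        if j > 1:
            moves.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(moves, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return float(D[n, m]), path


def dtw_brute_force(s1, s2, gamma: float = 1.0) -> float:
    """Exhaustive enumeration of all monotone warping paths (tiny inputs only)."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n, m = len(s1), len(s2)
    best = [math.inf]

    def cost(i, j):
        return abs(s1[i - 1] - s2[j - 1]) ** gamma

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if (i, j) == (n, m):
            best[0] = acc
            return
        if i < n:
            walk(i + 1, j, acc + cost(i + 1, j))
        if j < m:
            walk(i, j + 1, acc + cost(i, j + 1))
        if i < n and j < m:
            walk(i + 1, j + 1, acc + cost(i + 1, j + 1))

    walk(1, 1, cost(1, 1))
    return best[0]


def path_within_band(path, n: int, m: int, w: int) -> bool:
    """True if every (i, j) on the path satisfies |i - j| <= w."""
    return all(abs(i - j) <= w for i, j in path)


def lstm_reference(x, wx, wh) -> np.ndarray:
    """Plain-numpy LSTM cell: gates (input, forget, candidate, output),
    zero biases, h_0 = c_0 = 0; returns the final hidden state."""
    def sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    units = wx.shape[1]
    h = np.zeros(units)
    c = np.zeros(units)
    for xt in np.asarray(x, dtype=float):
        i = sigmoid(wx[0] * xt + wh[0] @ h)
        f = sigmoid(wx[1] * xt + wh[1] @ h)
        g = np.tanh(wx[2] * xt + wh[2] @ h)
        o = sigmoid(wx[3] * xt + wh[3] @ h)
        c = f * c + i * g
        h = o * np.tanh(c)
    return h
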