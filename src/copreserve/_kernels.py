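"""Numba inner loops for banded DTW and the fixed-weight LSTM cell."""

import numpy as np
from numba import njit


@njit(cache=True)
def dtw_banded(s1, s2, gamma, w):
    """Cumulative cost D(n, m) of banded DTW with pointwise cost |a-b|**gamma.

    Two-row dynamic program; cells outside the band j in [i-w, i+w] stay +inf.
    D(0,0) = 0 so the first matched pair contributes its own cost.
    """
    n = s1.shape[0]
    m = s2.shape[0]
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, np.inf)
        lo = i - w
        if lo < 1:
            lo = 1
        hi = i + w
        if hi > m:
            hi = m
        for j in range(lo, hi + 1):
            c = abs(s1[i - 1] - s2[j - 1]) ** gamma
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev = cur
    return prev[m]


@njit(cache=True)
def lstm_forward(x, wx, wh):
    """Final hidden state of a single-layer LSTM over a scalar sequence.

    Gate order in the weight stacks is (input, forget, candidate, output):
    wx has shape (4, units), wh has shape (4, units, units); biases are zero
    and h_0 = c_0 = 0.
    """
    units = wx.shape[1]
    h = np.zeros(units)
    c = np.zeros(units)
    for t in range(x.shape[0]):
        xt = x[t]
        zi = wx[0] * xt + wh[0] @ h
        zf = wx[1] * xt + wh[1] @ h
        zg = wx[2] * xt + wh[2] @ h
        zo = wx[3] * xt + wh[3] @ h
        gi = 1.0 / (1.0 + np.exp(-zi))
        gf = 1.0 / (1.0 + np.exp(-zf))
        gg = np.tanh(zg)
        go = 1.0 / (1.0 + np.exp(-zo))
        c = gf * c + gi * gg
        h = go * np.tanh(c)
    return h
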