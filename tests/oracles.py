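"""Independent brute-force oracles used to validate the implementation.

These are deliberately plain (nested-loop dynamic programming, direct
formula evaluation) and share no code with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np

from cemag.homology import encode_protein


def brute_force_smith_waterman(query: str, subject: str, sub: np.ndarray,
                               gap_open: int = 11, gap_extend: int = 1) -> int:
    """Affine-gap local alignment optimum by the textbook Gotoh recurrences
    (score only).  A gap of length L costs gap_open + L*gap_extend."""
    q = encode_protein(query)
    s = encode_protein(subject)
    nq, ns = len(q), len(s)
    neg = -(10**9)
    go = gap_open + gap_extend
    ge = gap_extend
    h_prev = [0] * (ns + 1)
    e_prev = [neg] * (ns + 1)
    f_prev = [neg] * (ns + 1)
    best = 0
    for i in range(1, nq + 1):
        h_cur = [0] * (ns + 1)
        e_cur = [neg] * (ns + 1)
        f_cur = [neg] * (ns + 1)
        row = sub[q[i - 1]]
        for j in range(1, ns + 1):
            e = max(h_cur[j - 1] - go, e_cur[j - 1] - ge)
            f = max(h_prev[j] - go, f_prev[j] - ge)
            h = max(0, h_prev[j - 1] + int(row[s[j - 1]]), e, f)
            e_cur[j] = e
            f_cur[j] = f
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev, f_prev = h_cur, e_cur, f_cur
    return best


def brute_force_bray_curtis(x, y) -> float:
    num = sum(min(a, b) for a, b in zip(x, y))
    den = sum(x) + sum(y)
    return 1.0 - 2.0 * num / den
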