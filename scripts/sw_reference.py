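"""Reference full-matrix local Smith-Waterman (Gotoh, affine gaps) used by
the acceptance script as an independent check on the seed-and-extend engine.
Fills the complete DP matrices (no seeding, no pruning) and tracebacks one
optimal alignment to measure its longest exact-match run."""
from __future__ import annotations

import numpy as np

NEG = -(10**9)


def sw_local_align(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """(optimal local score, longest exact-match run in one optimal alignment)."""
    n, m = len(a), len(b)
    au, bu = a.upper(), b.upper()
    ac = np.frombuffer(au.encode(), dtype=np.uint8)
    bc = np.frombuffer(bu.encode(), dtype=np.uint8)
    go, ge = gap_open, gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    j_arr = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(bc == ac[i - 1], match, mismatch)
        F[i] = np.maximum(H[i - 1] + go + ge, F[i - 1] + ge)
        H0 = np.zeros(m + 1, dtype=np.int64)
        H0[1:] = np.maximum(H[i - 1, :-1] + sub, 0)
        H0 = np.maximum(H0, F[i])
        H0[0] = 0
        C = H0 - ge * j_arr
        E[i, 1:] = go + ge * j_arr[1:] + np.maximum.accumulate(C)[:-1]
        H[i] = np.maximum(H0, E[i])
    best = int(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    run = longest = 0
    state = "H"
    while H[i, j] != 0 or state != "H":
        if state == "H":
            if E[i, j] == H[i, j]:
                state = "E"
                continue
            if F[i, j] == H[i, j]:
                state = "F"
                continue
            if au[i - 1] == bu[j - 1]:
                run += 1
                longest = max(longest, run)
            else:
                run = 0
            i, j = i - 1, j - 1
        elif state == "E":
            run = 0
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            run = 0
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    return best, longest
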