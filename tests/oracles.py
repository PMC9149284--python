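"""Independent brute-force reference implementations used by the tests.

Everything here is written with plain loops and textbook formulas,
deliberately sharing no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# ---------------------------------------------------------------------------
# Benjamini-Hochberg: sort, cumulative minimum from the top, unsort.
# ---------------------------------------------------------------------------


def bh_oracle(p):
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return adj


# ---------------------------------------------------------------------------
# Pearson r with the two-sided p from the t transform.
# ---------------------------------------------------------------------------


def pearson_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    dx = x - x.mean()
    dy = y - y.mean()
    r = float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# miRNA target scoring: exhaustive enumeration of all admissible
# <=1-contiguous-bulge antiparallel alignments with the penalty scheme
# (WC 0, G:U 0.5, mismatch 1, 2.0 per indel base, positions 2-13 doubled;
# a bulged target base takes the weight of the miRNA position immediately
# 3' of the insertion point, clamped to the last position).
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pen(m_base: str, t_base: str) -> float:
    if _COMP[m_base] == t_base:
        return 0.0
    if (m_base, t_base) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def _w(pos_1based: int) -> float:
    return 2.0 if 2 <= pos_1based <= 13 else 1.0


def score_oracle(mirna: str, window: str, max_bulge: int = 1) -> float:
    m = mirna.upper().replace("U", "T")
    t = window.upper().replace("U", "T")[::-1]
    Lm, Lt = len(m), len(t)
    d = Lt - Lm
    if abs(d) > max_bulge:
        raise ValueError("length difference exceeds allowed bulge")
    scores = []
    if d == 0:
        scores.append(sum(_pen(m[i], t[i]) * _w(i + 1) for i in range(Lm)))
    elif d < 0:
        dd = -d
        for k in range(Lm - dd + 1):
            s = sum(_pen(m[i], t[i]) * _w(i + 1) for i in range(k))
            s += sum(2.0 * _w(i + 1) for i in range(k, k + dd))
            s += sum(_pen(m[i], t[i - dd]) * _w(i + 1) for i in range(k + dd, Lm))
            scores.append(s)
    else:
        for k in range(Lm + 1):
            s = sum(_pen(m[i], t[i]) * _w(i + 1) for i in range(k))
            s += 2.0 * d * _w(min(k + 1, Lm))
            s += sum(_pen(m[i], t[i + d]) * _w(i + 1) for i in range(k, Lm))
            scores.append(s)
    return min(scores)


def best_site_oracle(mirna: str, transcript: str, max_bulge: int = 1):
    """Exhaustive window scan; returns (score, start, length) or None."""
    m = mirna.upper().replace("U", "T")
    tx = transcript.upper().replace("U", "T")
    best = None
    for Lw in range(len(m) - max_bulge, len(m) + max_bulge + 1):
        if Lw <= 0:
            continue
        for s in range(0, len(tx) - Lw + 1):
            sc = score_oracle(m, tx[s : s + Lw], max_bulge)
            cand = (sc, s, Lw)
            if best is None or cand < best:
                best = cand
    return best


# ---------------------------------------------------------------------------
# Longest forward-frame ORF, counted in codons (stop excluded; open ORFs
# running off the 3' end count).
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_oracle(seq: str) -> int:
    s = seq.upper().replace("U", "T")
    best = 0
    for start in range(len(s) - 2):
        if s[start : start + 3] != "ATG":
            continue
        aa = 0
        i = start
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if codon in _STOPS and i > start:
                break
            aa += 1
            i += 3
        best = max(best, aa)
    return best
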