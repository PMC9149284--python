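"""Plant-style miRNA target prediction and expression-coherence pairing.

Plant miRNAs recognize near-perfect complementary sites on their target
transcripts, so target prediction reduces to a penalty-scored antiparallel
alignment of the miRNA against every transcript window:

* Watson-Crick pair: 0, G:U wobble: 0.5, mismatch: 1.0, each inserted or
  deleted base: 2.0;
* penalties at miRNA positions 2-13 (1-based from the 5' end, the region
  that directs cleavage) are doubled;
* the site score is the minimum penalty sum over all alignments with at
  most one contiguous bulge (default length 1).

A site is reported when its score is at or below the cutoff (default 4.0).
Bulge bookkeeping: a bulged miRNA base is penalized at its own position
weight; a bulged target base takes the weight of the miRNA position
immediately 3' of the insertion point (clamped to the final position).

Coherence pairing: among pairs where both the miRNA and its target are
differentially expressed in a contrast, opposite call signs are "coherent"
(consistent with cleavage/repression) and equal signs "noncoherent".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import DECalls

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEC = "ACGT"

#: penalty[miRNA base, target base] for an antiparallel pairing
_PAIR = np.full((4, 4), 1.0)
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # Watson-Crick
    _PAIR[_m, _t] = 0.0
for _m, _t in ((2, 3), (3, 2)):  # G:U wobble (T stands for U)
    _PAIR[_m, _t] = 0.5

_PAIR_SYM = np.full((4, 4), ".", dtype="U1")
for _m in range(4):
    for _t in range(4):
        if _PAIR[_m, _t] == 0.0:
            _PAIR_SYM[_m, _t] = "|"
        elif _PAIR[_m, _t] == 0.5:
            _PAIR_SYM[_m, _t] = "o"


@dataclass(frozen=True)
class ScoringConfig:
    """Penalty weights for the target scorer; defaults follow the classic
    plant-rule family."""

    wobble: float = 0.5
    mismatch: float = 1.0
    gap_per_base: float = 2.0
    seed_start: int = 2  # 1-based, inclusive
    seed_end: int = 13  # 1-based, inclusive
    seed_multiplier: float = 2.0
    max_bulge_len: int = 1
    cutoff: float = 4.0


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based on the transcript
    site_length: int
    penalty_score: float
    paired_string: str


def _encode(seq: str, what: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"{what}: non-ACGTU character {exc.args[0]!r}") from exc


def _weights(n: int, cfg: ScoringConfig) -> np.ndarray:
    w = np.ones(n)
    lo, hi = cfg.seed_start - 1, cfg.seed_end  # to 0-based half-open
    w[max(lo, 0) : hi] = cfg.seed_multiplier
    return w


def _pair_table(cfg: ScoringConfig) -> np.ndarray:
    tab = np.where(_PAIR == 1.0, cfg.mismatch, _PAIR)
    tab = np.where(_PAIR == 0.5, cfg.wobble, tab)
    return tab


def _score_windows(
    m: np.ndarray, wins: np.ndarray, cfg: ScoringConfig
) -> np.ndarray:
    """Minimal penalty for each reversed-window row against miRNA ``m``.

    ``wins`` has shape (n_windows, Lw) where each row is a target window
    already reversed so that column i faces miRNA position i.  Lw may be
    Lm - d, Lm, or Lm + d with d <= max_bulge_len.
    """
    Lm, Lw = len(m), wins.shape[1]
    d = Lw - Lm
    if abs(d) > cfg.max_bulge_len:
        raise ValueError(
            f"window length {Lw} vs miRNA length {Lm}: difference exceeds the "
            f"allowed bulge ({cfg.max_bulge_len})"
        )
    pair = _pair_table(cfg)
    w = _weights(Lm, cfg)
    if d == 0:
        pen = pair[m[None, :], wins] * w[None, :]
        return pen.sum(axis=1)
    if d < 0:
        # bulge of |d| unpaired miRNA bases at positions k..k+|d|-1
        d = -d
        a = pair[m[None, : Lm - d], wins] * w[None, : Lm - d]
        e = pair[m[None, d:], wins] * w[None, d:]
        cum_a = np.concatenate(
            [np.zeros((wins.shape[0], 1)), np.cumsum(a, axis=1)], axis=1
        )
        suf_e = np.concatenate(
            [np.cumsum(e[:, ::-1], axis=1)[:, ::-1], np.zeros((wins.shape[0], 1))],
            axis=1,
        )
        gap = np.array(
            [cfg.gap_per_base * w[k : k + d].sum() for k in range(Lm - d + 1)]
        )
        scores = cum_a + suf_e + gap[None, :]
        return scores.min(axis=1)
    # d > 0: bulge of d unpaired target bases inserted before miRNA position k
    a = pair[m[None, :], wins[:, :Lm]] * w[None, :]
    b = pair[m[None, :], wins[:, d:]] * w[None, :]
    cum_a = np.concatenate(
        [np.zeros((wins.shape[0], 1)), np.cumsum(a, axis=1)], axis=1
    )
    suf_b = np.concatenate(
        [np.cumsum(b[:, ::-1], axis=1)[:, ::-1], np.zeros((wins.shape[0], 1))], axis=1
    )
    gap = np.array(
        [cfg.gap_per_base * d * w[min(k, Lm - 1)] for k in range(Lm + 1)]
    )
    scores = cum_a[:, : Lm + 1] + suf_b + gap[None, :]
    return scores.min(axis=1)


def score_mirna_target(
    mirna_seq: str, window_seq: str, config: ScoringConfig = DEFAULT_SCORING
) -> float:
    """Penalty score of one miRNA against one candidate site.

    The window is given in transcript orientation (5'->3'); the miRNA is
    aligned antiparallel, so miRNA position 1 faces the window's 3' end.
    Case and U/T representation are normalized away.
    """
    m = _encode(mirna_seq, "miRNA")
    t = _encode(window_seq, "window")
    if len(m) == 0 or len(t) == 0:
        raise ValueError("empty sequence")
    wins = t[::-1][None, :]
    return float(_score_windows(m, wins, config)[0])


def render_alignment(
    mirna_seq: str, window_seq: str, config: ScoringConfig = DEFAULT_SCORING
) -> str:
    """Human-readable pairing string for the best alignment of one window.

    '|' Watson-Crick, 'o' G:U wobble, '.' mismatch, '-' bulged base.  Shown
    with the miRNA 5'->3' on top against the reversed target window.
    """
    m = _encode(mirna_seq, "miRNA")
    t = _encode(window_seq, "window")[::-1]
    cfg = config
    pair = _pair_table(cfg)
    w = _weights(len(m), cfg)
    Lm, Lt = len(m), len(t)
    d = Lt - Lm

    best: tuple[float, str, str, str] | None = None

    def consider(score: float, top: str, mid: str, bot: str) -> None:
        nonlocal best
        if best is None or score < best[0]:
            best = (score, top, mid, bot)

    if d == 0:
        score = float((pair[m, t] * w).sum())
        consider(
            score,
            "".join(_DEC[c] for c in m),
            "".join(_PAIR_SYM[a, b] for a, b in zip(m, t)),
            "".join(_DEC[c] for c in t),
        )
    elif d < 0:
        dd = -d
        for k in range(Lm - dd + 1):
            score = float(
                (pair[m[:k], t[:k]] * w[:k]).sum()
                + cfg.gap_per_base * w[k : k + dd].sum()
                + (pair[m[k + dd :], t[k:]] * w[k + dd :]).sum()
            )
            top = "".join(_DEC[c] for c in m)
            mid = (
                "".join(_PAIR_SYM[a, b] for a, b in zip(m[:k], t[:k]))
                + "-" * dd
                + "".join(_PAIR_SYM[a, b] for a, b in zip(m[k + dd :], t[k:]))
            )
            bot = (
                "".join(_DEC[c] for c in t[:k])
                + "-" * dd
                + "".join(_DEC[c] for c in t[k:])
            )
            consider(score, top, mid, bot)
    else:
        for k in range(Lm + 1):
            score = float(
                (pair[m[:k], t[:k]] * w[:k]).sum()
                + cfg.gap_per_base * d * w[min(k, Lm - 1)]
                + (pair[m[k:], t[k + d :]] * w[k:]).sum()
            )
            top = (
                "".join(_DEC[c] for c in m[:k]) + "-" * d + "".join(_DEC[c] for c in m[k:])
            )
            mid = (
                "".join(_PAIR_SYM[a, b] for a, b in zip(m[:k], t[:k]))
                + "-" * d
                + "".join(_PAIR_SYM[a, b] for a, b in zip(m[k:], t[k + d :]))
            )
            bot = "".join(_DEC[c] for c in t)
            consider(score, top, mid, bot)
    assert best is not None
    return f"5' {best[1]} 3' / {best[2]} / 3' {best[3]} 5'"


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float | None = None,
    config: ScoringConfig = DEFAULT_SCORING,
) -> list[TargetSite]:
    """Best site per miRNA x transcript pair with penalty <= cutoff.

    All windows of length Lm and Lm +/- b (b <= max_bulge_len) are scored;
    ties are broken toward the leftmost site, then the shortest window.
    """
    if cutoff is None:
        cutoff = config.cutoff
    sites: list[TargetSite] = []
    enc_tx = {
        tid: _encode(seq, f"transcript {tid}")[::-1] for tid, seq in transcripts.items()
    }
    for mid in sorted(mirnas):
        m = _encode(mirnas[mid], f"miRNA {mid}")
        Lm = len(m)
        lengths = sorted(
            {
                Lm + delta
                for delta in range(-config.max_bulge_len, config.max_bulge_len + 1)
                if Lm + delta > 0
            }
        )
        for tid in sorted(transcripts):
            rt = enc_tx[tid]
            n = len(rt)
            best: tuple[float, int, int] | None = None  # (score, start, length)
            for Lw in lengths:
                if n < Lw:
                    continue
                wins = np.lib.stride_tricks.sliding_window_view(rt, Lw)
                scores = _score_windows(m, wins, config)
                # row r of wins is the reversed window whose transcript
                # start is n - r - Lw
                starts = n - np.arange(len(scores)) - Lw
                for r in np.flatnonzero(scores <= cutoff):
                    cand = (float(scores[r]), int(starts[r]), Lw)
                    if (
                        best is None
                        or cand[0] < best[0]
                        or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
                    ):
                        best = cand
            if best is not None:
                score, start, Lw = best
                window = transcripts[tid].upper().replace("U", "T")[start : start + Lw]
                sites.append(
                    TargetSite(
                        mirna_id=mid,
                        transcript_id=tid,
                        site_start=start,
                        site_length=Lw,
                        penalty_score=score,
                        paired_string=render_alignment(mirnas[mid], window, config),
                    )
                )
    return sites


def sites_to_frame(sites: Sequence[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in sites],
            "transcript_id": [s.transcript_id for s in sites],
            "site_start": [s.site_start for s in sites],
            "site_length": [s.site_length for s in sites],
            "score": [s.penalty_score for s in sites],
            "alignment": [s.paired_string for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# Small-RNA length filter and coherence
# ---------------------------------------------------------------------------


def filter_small_rna(
    sequences: Mapping[str, str], min_nt: int = 18, max_nt: int = 30
) -> dict[str, str]:
    """Keep sequences with min_nt <= length <= max_nt (inclusive bounds)."""
    if not sequences:
        raise ValueError("no sequences supplied")
    return {k: v for k, v in sequences.items() if min_nt <= len(v) <= max_nt}


@dataclass(frozen=True)
class PairCoherence:
    mirna_id: str
    target_id: str
    contrast: str
    coherence: str  # "coherent" | "noncoherent"


def coherence_of_calls(call_mirna: str, call_target: str) -> str | None:
    """Opposite DE signs -> coherent, equal -> noncoherent, any ns -> None."""
    if call_mirna == "ns" or call_target == "ns":
        return None
    return "coherent" if call_mirna != call_target else "noncoherent"


def classify_pair_coherence(
    mirna_id: str,
    target_id: str,
    mirna_calls: DECalls,
    target_calls: DECalls,
    contrast: str,
) -> PairCoherence | None:
    coh = coherence_of_calls(
        mirna_calls.call(mirna_id, contrast), target_calls.call(target_id, contrast)
    )
    if coh is None:
        return None
    return PairCoherence(mirna_id, target_id, contrast, coh)
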