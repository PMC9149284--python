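"""TF -> gene regulatory pairs from coexpression plus promoter-motif evidence.

A TF-gene pair is accepted when |PCC| > pcc_threshold (strict), the
correlation p-value is < p_threshold (strict), and — when motif gating is
on — the TF's binding element has at least one hit in the gene's promoter.
The sign of the correlation is deliberately not restricted, so repressive
TFs remain representable; the sign travels with the edge evidence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DECalls
from .io import ExpressionMatrix, FeatureModel, reverse_complement

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


@dataclass
class MotifModel:
    """A binding element as an IUPAC consensus and/or weight matrix.

    In weight-matrix mode a window is a hit when its summed per-position
    score reaches ``score_fraction_threshold`` times the maximal attainable
    score.
    """

    name: str
    iupac_consensus: str
    weight_matrix: np.ndarray | None = None  # shape (len, 4), ACGT columns
    score_fraction_threshold: float = 0.85

    def __post_init__(self) -> None:
        if not self.iupac_consensus:
            raise ValueError("empty motif consensus")
        bad = set(self.iupac_consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC codes {sorted(bad)}")
        if self.weight_matrix is not None:
            wm = np.asarray(self.weight_matrix, dtype=float)
            if wm.shape != (len(self.iupac_consensus), 4):
                raise ValueError(
                    f"motif {self.name}: weight matrix shape {wm.shape} does not "
                    f"match consensus length {len(self.iupac_consensus)}"
                )
            self.weight_matrix = wm
        if not 0 < self.score_fraction_threshold <= 1:
            raise ValueError("score_fraction_threshold must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.iupac_consensus)


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    score: float


@dataclass
class TFPair:
    tf_id: str
    gene_id: str
    pcc: float
    pcc_p: float
    motif_hits: int
    accepted: bool
    contrasts: tuple[str, ...] = field(default_factory=tuple)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t transform
    t = r sqrt(n-2) / sqrt(1 - r^2) on n-2 degrees of freedom; |r| = 1 -> p = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    p = 0.0 if abs(r) >= 1.0 else float(res.pvalue)
    return r, p


def extract_promoter(
    gene: FeatureModel, genome_seq: str, length: int = 2000
) -> str:
    """Strand-aware promoter: the ``length`` bases immediately upstream of
    the TSS, returned 5'->3' relative to the gene (minus-strand promoters
    are reverse-complemented).  Truncated at the chromosome boundary with a
    warning."""
    n = len(genome_seq)
    if gene.strand == "+":
        lo = gene.start - length
        if lo < 0:
            log.warning(
                "promoter of %s truncated to %d bp at chromosome start",
                gene.id,
                gene.start,
            )
            lo = 0
        return genome_seq[lo : gene.start].upper()
    hi = gene.end + length
    if hi > n:
        log.warning(
            "promoter of %s truncated to %d bp at chromosome end", gene.id, n - gene.end
        )
        hi = n
    return reverse_complement(genome_seq[gene.end : hi].upper())


def iupac_to_regex(consensus: str) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]"
        for c in consensus.upper()
    )


def scan_motif(promoter_seq: str, motif: MotifModel) -> list[MotifHit]:
    """All hits of the motif on either strand of the promoter.

    Consensus mode matches the IUPAC pattern exactly (overlaps included);
    weight-matrix mode thresholds the window score against the maximal
    attainable score.  Offsets are on the promoter coordinate frame; a '-'
    strand hit means the reverse complement of the motif matched the
    promoter at that offset.
    """
    seq = promoter_seq.upper().replace("U", "T")
    hits: list[MotifHit] = []
    if motif.weight_matrix is None:
        fwd = re.compile("(?=" + iupac_to_regex(motif.iupac_consensus) + ")")
        rev = re.compile(
            "(?=" + iupac_to_regex(reverse_complement(motif.iupac_consensus)) + ")"
        )
        for m in fwd.finditer(seq):
            hits.append(MotifHit(m.start(), "+", 1.0))
        for m in rev.finditer(seq):
            hits.append(MotifHit(m.start(), "-", 1.0))
    else:
        wm = motif.weight_matrix
        L = len(motif)
        max_score = wm.max(axis=1).sum()
        threshold = motif.score_fraction_threshold * max_score
        enc = np.array(
            [{"A": 0, "C": 1, "G": 2, "T": 3}.get(c, -1) for c in seq], dtype=int
        )
        if len(enc) >= L:
            wins = np.lib.stride_tricks.sliding_window_view(enc, L)
            valid = (wins >= 0).all(axis=1)
            pos = np.arange(L)
            fwd_scores = np.where(valid, wm[pos, np.clip(wins, 0, 3)].sum(axis=1), -np.inf)
            # reverse strand: complement and reverse the window
            comp = np.array([3, 2, 1, 0])
            rc_wins = comp[np.clip(wins, 0, 3)][:, ::-1]
            rev_scores = np.where(valid, wm[pos, rc_wins].sum(axis=1), -np.inf)
            for off in np.flatnonzero(fwd_scores >= threshold):
                hits.append(MotifHit(int(off), "+", float(fwd_scores[off])))
            for off in np.flatnonzero(rev_scores >= threshold):
                hits.append(MotifHit(int(off), "-", float(rev_scores[off])))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def tf_gene_pairs(
    tf_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    de_calls: DECalls,
    promoters: Mapping[str, str],
    motifs: Mapping[str, MotifModel],
    pcc_threshold: float = 0.8,
    p_threshold: float = 0.05,
    require_motif: bool = True,
) -> list[TFPair]:
    """Evaluate every DE TF x DE gene combination and record its evidence.

    Correlation is computed on log2(value + 1) across shared samples.  A
    pair is accepted iff |PCC| > pcc_threshold, p < p_threshold and (when
    ``require_motif``) the TF's motif hits the gene's promoter at least
    once.  A TF without an assigned motif is an error when gating is on.
    """
    samples = [s for s in tf_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if len(samples) < 3:
        raise ValueError("need >= 3 shared samples")
    tf_ids = [f for f in tf_expr.feature_ids if de_calls.is_de(f)]
    gene_ids = [f for f in gene_expr.feature_ids if de_calls.is_de(f)]
    if require_motif:
        missing = [t for t in tf_ids if t not in motifs]
        if missing:
            raise ValueError(f"no motif assigned for TF(s): {missing}")

    pairs: list[TFPair] = []
    if not tf_ids or not gene_ids:
        return pairs
    tv = np.log2(tf_expr.data.loc[tf_ids, samples].to_numpy(dtype=float) + 1.0)
    gv = np.log2(gene_expr.data.loc[gene_ids, samples].to_numpy(dtype=float) + 1.0)
    hit_cache: dict[tuple[str, str], int] = {}
    for i, tf_id in enumerate(tf_ids):
        for j, gene_id in enumerate(gene_ids):
            if tf_id == gene_id:
                continue
            shared = de_calls.shared_de_contrasts(tf_id, gene_id)
            if not shared:
                continue
            if np.ptp(tv[i]) == 0 or np.ptp(gv[j]) == 0:
                log.warning("skipping constant profile in pair %s-%s", tf_id, gene_id)
                continue
            r, p = pearson_with_p(tv[i], gv[j])
            n_hits = 0
            if tf_id in motifs and gene_id in promoters:
                key = (tf_id, gene_id)
                if key not in hit_cache:
                    hit_cache[key] = len(scan_motif(promoters[gene_id], motifs[tf_id]))
                n_hits = hit_cache[key]
            accepted = (
                abs(r) > pcc_threshold
                and p < p_threshold
                and (not require_motif or n_hits >= 1)
            )
            pairs.append(
                TFPair(
                    tf_id=tf_id,
                    gene_id=gene_id,
                    pcc=r,
                    pcc_p=p,
                    motif_hits=n_hits,
                    accepted=accepted,
                    contrasts=tuple(shared),
                )
            )
    return pairs


def pairs_to_frame(pairs: Sequence[TFPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf_id": [p.tf_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "pcc": [p.pcc for p in pairs],
            "pcc_p": [p.pcc_p for p in pairs],
            "motif_hits": [p.motif_hits for p in pairs],
            "accepted": [p.accepted for p in pairs],
        }
    )


def read_motif_table(path) -> dict[str, MotifModel]:
    """TF -> motif assignment table (TSV with columns tf_id, motif)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tf_id", "motif"} <= set(df.columns):
        raise ValueError(f"{path}: motif table needs columns tf_id, motif")
    return {
        row.tf_id: MotifModel(name=f"{row.tf_id}_motif", iupac_consensus=row.motif)
        for row in df.itertuples()
    }
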