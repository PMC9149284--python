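"""lncRNA candidate filtering, positional classification, cis/trans targets.

Positional classes follow the usual lincRNA / intronic / antisense / sense
partition relative to protein-coding gene models.  Because a locus can
satisfy several definitions at once, a fixed precedence makes the label
single-valued: same-strand exonic overlap (sense) > any opposite-strand
overlap (antisense) > fully intronic on the same strand (intronic) >
no genic overlap (lincRNA).

cis targets are genes whose span lies within ``window_bp`` (default 10 kb)
of the lncRNA span on either side, strand-agnostic, with overlap counting
as distance 0.  trans targets are expression-based: differentially
expressed lncRNA-gene pairs whose Pearson correlation across samples is
<= -r_threshold (default mode; ``absolute`` accepts either sign) with
opposite differential calls in at least one shared contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DECalls
from .io import ExpressionMatrix, FeatureModel, GenomeAnnotation

log = logging.getLogger(__name__)

LNC_CLASSES = ("lincRNA", "intronic", "antisense", "sense")


@dataclass(frozen=True)
class LncClassification:
    lnc_id: str
    lnc_class: str
    supporting_gene_id: str = ""


@dataclass(frozen=True)
class CisWindow:
    window_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp strictly between two half-open intervals; 0 when they overlap."""
    if _overlap(a_start, a_end, b_start, b_end):
        return 0
    return max(a_start, b_start) - min(a_end, b_end)


def classify_lncrna(
    lnc: FeatureModel, annotation: GenomeAnnotation
) -> LncClassification:
    """Assign exactly one positional class by the stated precedence."""
    genes = [
        g
        for g in annotation.genes(roles=("mRNA", "TF"))
        if g.chrom == lnc.chrom and _overlap(lnc.start, lnc.end, g.start, g.end)
    ]
    # 1. exonic overlap, same strand -> sense
    for g in genes:
        if g.strand == lnc.strand:
            if any(
                _overlap(lnc.start, lnc.end, s, e)
                for s, e in annotation.model_exons(g.id)
            ):
                return LncClassification(lnc.id, "sense", g.id)
    # 2. any overlap, opposite strand -> antisense
    for g in genes:
        if g.strand != lnc.strand:
            return LncClassification(lnc.id, "antisense", g.id)
    # 3. fully inside an intron of a same-strand gene -> intronic
    for g in genes:
        if g.strand == lnc.strand:
            for s, e in annotation.model_introns(g.id):
                if s <= lnc.start and lnc.end <= e:
                    return LncClassification(lnc.id, "intronic", g.id)
    # 4. no genic overlap (or precedence exhausted) -> lincRNA
    return LncClassification(lnc.id, "lincRNA", "")


def classify_all(
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    rows = [
        classify_lncrna(t, annotation)
        for t in annotation.transcripts(roles=("lncRNA",))
    ]
    return pd.DataFrame(
        {
            "lnc_id": [r.lnc_id for r in rows],
            "class": [r.lnc_class for r in rows],
            "supporting_gene_id": [r.supporting_gene_id for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Candidate filter
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_aa(seq: str) -> int:
    """Longest ATG-initiated ORF over the three forward frames, in codons.

    The stop codon is not counted; an ORF running off the 3' end without a
    stop still counts (it retains coding potential).
    """
    seq = seq.upper().replace("U", "T")
    best = 0
    n = len(seq)
    for frame in range(3):
        i = frame
        open_starts: list[int] = []
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon == "ATG" and not open_starts:
                open_starts.append(i)
            if codon in _STOPS and open_starts:
                best = max(best, (i - open_starts[0]) // 3)
                open_starts.clear()
            i += 3
        if open_starts:  # ran off the end while open
            tail = (n - open_starts[0]) // 3
            best = max(best, tail)
    return best


def filter_lncrna_candidates(
    candidate_ids: list[str],
    sequences: dict[str, str],
    min_length: int = 200,
    max_orf_aa: int = 100,
) -> list[str]:
    """Retain candidates with length >= min_length and longest ORF < max_orf_aa."""
    missing = [c for c in candidate_ids if c not in sequences]
    if missing:
        raise ValueError(f"missing sequence for candidates: {missing[:5]}")
    retained = []
    for cid in candidate_ids:
        seq = sequences[cid]
        if len(seq) >= min_length and longest_orf_aa(seq) < max_orf_aa:
            retained.append(cid)
    return retained


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


def cis_targets(
    lnc: FeatureModel,
    annotation: GenomeAnnotation,
    window: CisWindow = CisWindow(),
) -> list[str]:
    """Genes on the same chromosome within window_bp of the lncRNA span.

    The gap is measured between spans (overlap = 0); a gap of exactly
    window_bp is included. Both sides of the lncRNA are covered because the
    gap is symmetric.
    """
    out = []
    for g in annotation.genes(roles=("mRNA", "TF")):
        if g.chrom != lnc.chrom:
            continue
        if interval_gap(lnc.start, lnc.end, g.start, g.end) <= window.window_bp:
            out.append(g.id)
    return out


def trans_targets(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    de_calls: DECalls,
    r_threshold: float = 0.9,
    mode: str = "anticorrelated",
) -> pd.DataFrame:
    """Expression-based lncRNA targets among DE lncRNA x DE gene pairs.

    Correlations are computed on log2(value + 1) across the shared samples.
    ``anticorrelated`` (default) reports PCC <= -r_threshold with opposite
    differential calls in >= 1 shared contrast; ``absolute`` reports
    |PCC| >= r_threshold for pairs differentially expressed in >= 1 shared
    contrast regardless of sign.  Zero-variance features are skipped with a
    warning, never emitted as NaN.
    """
    if mode not in ("anticorrelated", "absolute"):
        raise ValueError(f"unknown trans_correlation_mode {mode!r}")
    samples = [s for s in lnc_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(samples) < 3:
        raise ValueError("need >= 3 shared samples")

    lnc_ids = [f for f in lnc_expr.feature_ids if de_calls.is_de(f)]
    gene_ids = [f for f in mrna_expr.feature_ids if de_calls.is_de(f)]
    rows: list[tuple[str, str, float]] = []
    if lnc_ids and gene_ids:
        lv = np.log2(lnc_expr.data.loc[lnc_ids, samples].to_numpy(dtype=float) + 1.0)
        gv = np.log2(mrna_expr.data.loc[gene_ids, samples].to_numpy(dtype=float) + 1.0)
        l_sd = lv.std(axis=1)
        g_sd = gv.std(axis=1)
        for name, sd, ids in (("lncRNA", l_sd, lnc_ids), ("gene", g_sd, gene_ids)):
            flat = [i for i, s in zip(ids, sd) if s == 0]
            if flat:
                log.warning("trans_targets: skipping zero-variance %s %s", name, flat)
        lz = (lv - lv.mean(axis=1, keepdims=True))
        gz = (gv - gv.mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (lz @ gz.T) / np.outer(
                np.linalg.norm(lz, axis=1), np.linalg.norm(gz, axis=1)
            )
        for i, lid in enumerate(lnc_ids):
            if l_sd[i] == 0:
                continue
            for j, gid in enumerate(gene_ids):
                if g_sd[j] == 0 or lid == gid:
                    continue
                r = float(corr[i, j])
                if mode == "anticorrelated":
                    if r <= -r_threshold and de_calls.opposite_sign_contrasts(lid, gid):
                        rows.append((lid, gid, r))
                else:
                    if abs(r) >= r_threshold and de_calls.shared_de_contrasts(lid, gid):
                        rows.append((lid, gid, r))
    return pd.DataFrame(rows, columns=["lnc_id", "gene_id", "pcc"])
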