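"""Abundance normalization, differential-expression calling and enrichment.

Normalization follows the two conventions used for the two sequencing
assays: FPKM (length- and depth-normalized) for mRNA/lncRNA libraries and
TPM (depth only; a small-RNA read is the molecule) for miRNA libraries.
Differential features are called per pairwise condition contrast at
|FC| >= fc_threshold and BH FDR < fdr_threshold; the location test is a
Welch unequal-variance t-test on log2(normalized + 1), which is
assumption-light and adequate at bench scale (see docs/methods.md for why a
negative-binomial GLM is deliberately not re-implemented here).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

DE_COLUMNS = [
    "feature_id",
    "contrast",
    "mean_a",
    "mean_b",
    "log2fc",
    "p_value",
    "fdr",
    "call",
]


def fpkm(matrix: ExpressionMatrix, feature_lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    value = count * 1e9 / (length_bp * sample_total).
    """
    if matrix.unit != "raw_count":
        raise ValueError(f"fpkm expects raw counts, got {matrix.unit}")
    missing = [f for f in matrix.feature_ids if f not in feature_lengths]
    if missing:
        raise ValueError(f"no length for features: {missing[:5]}")
    lengths = np.array([feature_lengths[f] for f in matrix.feature_ids], dtype=float)
    if (lengths <= 0).any():
        bad = [f for f in matrix.feature_ids if feature_lengths[f] <= 0]
        raise ValueError(f"non-positive feature length: {bad[:5]}")
    totals = matrix.data.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = [s for s, t in zip(matrix.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    values = matrix.data.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return matrix.with_values(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        unit="FPKM",
    )


def tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts per million without length normalization (small-RNA sense).

    Each sample column sums to 1e6 up to floating error.
    """
    if matrix.unit != "raw_count":
        raise ValueError(f"tpm expects raw counts, got {matrix.unit}")
    totals = matrix.data.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = [s for s, t in zip(matrix.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    values = matrix.data.to_numpy(dtype=float) * 1e6 / totals[None, :]
    return matrix.with_values(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        unit="TPM",
    )


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 1.0) -> float:
    """log2((mean_b + pc) / (mean_a + pc)); antisymmetric in (a, b)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def welch_p_values(
    matrix: ExpressionMatrix, condition_a: str, condition_b: str
) -> pd.Series:
    """Two-sided Welch t-test per feature on log2(value + 1).

    Features constant in both groups get p = 1 (no-signal convention).
    Groups need >= 2 replicates.
    """
    sa = matrix.samples_of(condition_a)
    sb = matrix.samples_of(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"contrast ({condition_a}, {condition_b}): need >=2 replicates per group"
        )
    a = np.log2(matrix.data[sa].to_numpy(dtype=float) + 1.0)
    b = np.log2(matrix.data[sb].to_numpy(dtype=float) + 1.0)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    constant = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    # Constant-everywhere features (and the zero-variance NaNs scipy emits
    # for them) carry no evidence either way.
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    return pd.Series(p, index=matrix.data.index, name="p_value")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: float,
    fdr: float,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> str:
    """Direction call at |FC| >= fc_threshold (inclusive) and FDR < fdr_threshold
    (strict)."""
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc_cut = np.log2(fc_threshold)
    if fdr < fdr_threshold:
        if log2fc >= lfc_cut:
            return "up"
        if log2fc <= -lfc_cut:
            return "down"
    return "ns"


def de_table(
    norm_matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full differential result for one contrast.

    ``log2fc`` is computed from group means of the normalized values with a
    pseudocount; ``call`` is 'up' when condition_b exceeds condition_a.
    """
    sa = norm_matrix.samples_of(condition_a)
    sb = norm_matrix.samples_of(condition_b)
    mean_a = norm_matrix.data[sa].mean(axis=1)
    mean_b = norm_matrix.data[sb].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    p = welch_p_values(norm_matrix, condition_a, condition_b)
    fdr = benjamini_hochberg(p.to_numpy())
    calls = [
        call_de(l, q, fc_threshold, fdr_threshold) for l, q in zip(lfc, fdr)
    ]
    return pd.DataFrame(
        {
            "feature_id": norm_matrix.feature_ids,
            "contrast": f"{condition_a}_vs_{condition_b}",
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "p_value": p.to_numpy(),
            "fdr": fdr,
            "call": calls,
        }
    )


def de_all_contrasts(
    norm_matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Stacked DE tables over all pairwise contrasts in condition order."""
    conds = norm_matrix.condition_order()
    tables = [
        de_table(norm_matrix, a, b, fc_threshold, fdr_threshold, pseudocount)
        for i, a in enumerate(conds)
        for b in conds[i + 1 :]
    ]
    return pd.concat(tables, ignore_index=True)


class DECalls:
    """Indexed view of a stacked DE table: (feature, contrast) -> call."""

    def __init__(self, table: pd.DataFrame):
        self.table = table
        self.contrasts = list(dict.fromkeys(table["contrast"]))
        self._calls: dict[tuple[str, str], str] = {
            (f, c): call
            for f, c, call in zip(table["feature_id"], table["contrast"], table["call"])
        }

    def call(self, feature: str, contrast: str) -> str:
        return self._calls.get((feature, contrast), "ns")

    def is_de(self, feature: str) -> bool:
        return any(self.call(feature, c) != "ns" for c in self.contrasts)

    def de_features(self) -> set[str]:
        return {f for (f, _c), call in self._calls.items() if call != "ns"}

    def shared_de_contrasts(self, f1: str, f2: str) -> list[str]:
        return [
            c
            for c in self.contrasts
            if self.call(f1, c) != "ns" and self.call(f2, c) != "ns"
        ]

    def opposite_sign_contrasts(self, f1: str, f2: str) -> list[str]:
        return [
            c
            for c in self.shared_de_contrasts(f1, f2)
            if self.call(f1, c) != self.call(f2, c)
        ]


def hypergeometric_enrichment(
    de_set: set[str],
    background_set: set[str],
    term_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided over-representation test per term, BH-corrected across terms.

    p = P(X >= k) with X ~ Hypergeom(N, K, n): N background size, K term
    size, n DE set size, k overlap.  k = 0 gives p = 1 under the upper-tail
    convention.
    """
    stray = de_set - background_set
    if stray:
        raise ValueError(f"DE features absent from background: {sorted(stray)[:5]}")
    N, n = len(background_set), len(de_set)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background_set
        K = len(members)
        k = len(members & de_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy()) if len(df) else []
    return df


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-delta_delta))
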