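import re

import numpy as np
import pandas as pd
import pytest

from lmrnet.de import DECalls
from lmrnet.io import ExpressionMatrix, FeatureModel, reverse_complement
from lmrnet.tf import (
    MotifModel,
    extract_promoter,
    iupac_to_regex,
    pearson_with_p,
    scan_motif,
    tf_gene_pairs,
)

from .oracles import pearson_oracle


class TestPearson:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.array([1.0, 2, 3, 5, 8])
        r, p = pearson_with_p(x, 2 * x + 3)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12
        r2, _ = pearson_with_p(x, -x)
        assert r2 == pytest.approx(-1.0, abs=1e-12)

    def test_hand_case_exact(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-15)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(200):
            n = int(rng.choice([6, 9, 12]))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = pearson_with_p(x, y)
            ro, po = pearson_oracle(x, y)
            assert abs(r - ro) < 1e-10
            assert abs(p - po) < 1e-10

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestPromoter:
    def _gene(self, strand, start, end):
        return FeatureModel(
            id="g", type="gene", chrom="chr1", strand=strand, start=start,
            end=end, role="mRNA",
        )

    def test_plus_strand_upstream_slice(self):
        genome = "".join("ACGT"[i % 4] for i in range(8000))
        g = self._gene("+", 5000, 6000)
        assert extract_promoter(g, genome, 2000) == genome[3000:5000]

    def test_minus_strand_reverse_complemented(self):
        genome = "".join("ACGT"[(i * 7) % 4] for i in range(8000))
        g = self._gene("-", 1000, 2000)
        assert extract_promoter(g, genome, 2000) == reverse_complement(
            genome[2000:4000]
        )

    def test_truncation_at_chromosome_start(self, caplog):
        genome = "A" * 3000
        g = self._gene("+", 100, 500)
        with caplog.at_level("WARNING"):
            prom = extract_promoter(g, genome, 2000)
        assert len(prom) == 100
        assert "truncated" in caplog.text


class TestMotifScan:
    def test_exact_forward_hit(self):
        prom = "AAAA" + "TGACGT" + "CCCC"
        hits = scan_motif(prom, MotifModel("m", "TGACGT"))
        assert [(h.offset, h.strand) for h in hits] == [(4, "+")]

    def test_reverse_strand_hit(self):
        prom = "AAAA" + "ACGTCA" + "CCCC"  # revcomp of TGACGT
        hits = scan_motif(prom, MotifModel("m", "TGACGT"))
        assert [(h.offset, h.strand) for h in hits] == [(4, "-")]

    def test_iupac_degeneracy(self):
        hits = scan_motif("ATGACGTA", MotifModel("m", "TGACNT"))
        assert any(h.strand == "+" and h.offset == 1 for h in hits)

    def test_matches_naive_regex_oracle(self, rng):
        motif = MotifModel("m", "TGASNTW")
        pattern = iupac_to_regex("TGASNTW")
        rc_pattern = iupac_to_regex(reverse_complement("TGASNTW"))
        for _ in range(20):
            prom = "".join(rng.choice(list("ACGT"), size=300))
            expect = {(m.start(), "+") for m in re.finditer("(?=" + pattern + ")", prom)}
            expect |= {(m.start(), "-") for m in re.finditer("(?=" + rc_pattern + ")", prom)}
            got = {(h.offset, h.strand) for h in scan_motif(prom, motif)}
            assert got == expect

    def test_weight_matrix_mode(self):
        wm = np.array(
            [[5, 0, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]],
            dtype=float,
        )  # consensus ACGT
        motif = MotifModel("m", "ACGT", weight_matrix=wm, score_fraction_threshold=1.0)
        hits = scan_motif("TTACGTTT", motif)
        assert any(h.offset == 2 and h.strand == "+" for h in hits)
        # reverse strand: ACGT is its own reverse complement
        assert any(h.offset == 2 and h.strand == "-" for h in hits)


class TestTfGenePairs:
    def _setup(self, tf_vals, gene_vals, motif_in_promoter=True):
        samples = [f"s{i}" for i in range(len(tf_vals))]
        half = len(samples) // 2
        conds = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
        tf_m = ExpressionMatrix(
            pd.DataFrame([tf_vals], index=["tf1"], columns=samples),
            {"tf1": "TF"}, conds, unit="FPKM",
        )
        g_m = ExpressionMatrix(
            pd.DataFrame([gene_vals], index=["g1"], columns=samples),
            {"g1": "mRNA"}, conds, unit="FPKM",
        )
        calls = DECalls(pd.DataFrame({
            "feature_id": ["tf1", "g1"],
            "contrast": ["A_vs_B"] * 2,
            "call": ["up", "up"],
        }))
        prom = ("AAAA" + "TGACGT" + "C" * 20) if motif_in_promoter else "C" * 30
        motifs = {"tf1": MotifModel("m", "TGACGT")}
        return tf_m, g_m, calls, {"g1": prom}, motifs

    def test_correlated_pair_with_motif_accepted(self):
        x = [1, 2, 3, 60, 70, 80]
        tf_m, g_m, calls, proms, motifs = self._setup(x, [2, 3, 4, 65, 72, 85])
        pairs = tf_gene_pairs(tf_m, g_m, calls, proms, motifs)
        assert len(pairs) == 1 and pairs[0].accepted
        assert pairs[0].motif_hits >= 1

    def test_motif_gate_rejects_without_hit(self):
        x = [1, 2, 3, 60, 70, 80]
        tf_m, g_m, calls, proms, motifs = self._setup(
            x, [2, 3, 4, 65, 72, 85], motif_in_promoter=False
        )
        pairs = tf_gene_pairs(tf_m, g_m, calls, proms, motifs)
        assert len(pairs) == 1 and not pairs[0].accepted
        pairs2 = tf_gene_pairs(
            tf_m, g_m, calls, proms, motifs, require_motif=False
        )
        assert pairs2[0].accepted

    def test_pcc_exactly_at_threshold_rejected(self):
        # log2(v+1) = (1,2,3,4) vs (1,3,2,4) gives r = 0.8 exactly
        tf_vals = [2**k - 1 for k in (1, 2, 3, 4)]
        g_vals = [2**k - 1 for k in (1, 3, 2, 4)]
        tf_m, g_m, calls, proms, motifs = self._setup(tf_vals, g_vals)
        pairs = tf_gene_pairs(
            tf_m, g_m, calls, proms, motifs, pcc_threshold=0.8, p_threshold=1.0
        )
        assert pairs[0].pcc == pytest.approx(0.8, abs=1e-12)
        assert not pairs[0].accepted

    def test_missing_motif_assignment_is_an_error(self):
        x = [1, 2, 3, 60, 70, 80]
        tf_m, g_m, calls, proms, _ = self._setup(x, [2, 3, 4, 65, 72, 85])
        with pytest.raises(ValueError, match="tf1"):
            tf_gene_pairs(tf_m, g_m, calls, proms, {})


def test_motif_model_validation():
    with pytest.raises(ValueError):
        MotifModel("m", "")
    with pytest.raises(ValueError):
        MotifModel("m", "ACGX")
    with pytest.raises(ValueError):
        MotifModel("m", "ACG", weight_matrix=np.zeros((2, 4)))
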