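import numpy as np
import pandas as pd
import pytest

from lmrnet.de import DECalls
from lmrnet.io import ExpressionMatrix, FeatureModel, GenomeAnnotation
from lmrnet.lncrna import (
    CisWindow,
    cis_targets,
    classify_lncrna,
    filter_lncrna_candidates,
    longest_orf_aa,
    trans_targets,
)

from .oracles import longest_orf_oracle


def _gene(gid, start, end, strand="+", exons=None, role="mRNA"):
    return FeatureModel(
        id=gid, type="gene", chrom="chr1", strand=strand, start=start, end=end,
        role=role, exons=exons or [],
    )


def _lnc(lid, start, end, strand="+"):
    return FeatureModel(
        id=lid, type="transcript", chrom="chr1", strand=strand, start=start,
        end=end, role="lncRNA", exons=[(start, end)],
    )


@pytest.fixture()
def annotation():
    host = _gene("host", 1000, 3000, "+", exons=[(1000, 1500), (2500, 3000)])
    return GenomeAnnotation([host])


class TestClassification:
    def test_intronic_same_strand_inside_intron(self, annotation):
        lnc = _lnc("l1", 1600, 2000, "+")
        assert classify_lncrna(lnc, annotation).lnc_class == "intronic"

    def test_antisense_any_opposite_strand_overlap(self, annotation):
        lnc = _lnc("l2", 1200, 1800, "-")
        assert classify_lncrna(lnc, annotation).lnc_class == "antisense"

    def test_sense_same_strand_exonic_overlap(self, annotation):
        lnc = _lnc("l3", 1200, 1800, "+")
        res = classify_lncrna(lnc, annotation)
        assert res.lnc_class == "sense"
        assert res.supporting_gene_id == "host"

    def test_distant_locus_is_lincRNA(self, annotation):
        lnc = _lnc("l4", 53_000, 53_400, "+")
        res = classify_lncrna(lnc, annotation)
        assert res.lnc_class == "lincRNA"
        assert res.supporting_gene_id == ""

    def test_every_simulated_lncrna_gets_exactly_one_class(self, small_dataset):
        ann = small_dataset.annotation
        for t in ann.transcripts(roles=("lncRNA",)):
            cls = classify_lncrna(t, ann).lnc_class
            assert cls in ("lincRNA", "intronic", "antisense", "sense")


class TestOrfFilter:
    def test_longest_orf_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(30, 400))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert longest_orf_aa(seq) == longest_orf_oracle(seq)

    def test_short_transcript_removed(self):
        with_seq = {"a": "A" * 150}
        assert filter_lncrna_candidates(["a"], with_seq) == []

    def test_long_noncoding_transcript_retained(self):
        # 40-codon ORF inside a 500-nt transcript passes both rules
        orf = "ATG" + "GCA" * 39 + "TAA"
        seq = ("C" * 180 + orf + "C" * (500 - 180 - len(orf)))
        assert filter_lncrna_candidates(["a"], {"a": seq}) == ["a"]
        assert longest_orf_aa(seq) == 40

    def test_coding_transcript_removed(self):
        orf = "ATG" + "GCA" * 149 + "TAA"
        seq = "C" * 70 + orf + "C" * (600 - 70 - len(orf))
        assert len(seq) == 600
        assert longest_orf_aa(seq) == 150
        assert filter_lncrna_candidates(["a"], {"a": seq}) == []

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            filter_lncrna_candidates(["a"], {})


class TestCisTargets:
    def _setup(self, gene_start, gene_end, lnc_start, lnc_end):
        ann = GenomeAnnotation([_gene("g", gene_start, gene_end)])
        return _lnc("l", lnc_start, lnc_end), ann

    def test_gap_exactly_window_included(self):
        lnc, ann = self._setup(0, 1000, 11_000, 11_500)  # gap = 10_000
        assert cis_targets(lnc, ann) == ["g"]

    def test_gap_one_over_excluded(self):
        lnc, ann = self._setup(0, 1000, 11_001, 11_500)
        assert cis_targets(lnc, ann) == []

    def test_overlap_counts_as_zero_gap(self):
        lnc, ann = self._setup(0, 1000, 500, 1500)
        assert cis_targets(lnc, ann) == ["g"]

    def test_reflection_symmetry(self, rng):
        """Mirroring all coordinates about a point preserves the target set."""
        pivot = 1_000_000
        for _ in range(20):
            gs = int(rng.integers(0, 50_000))
            ge = gs + int(rng.integers(100, 3000))
            ls = int(rng.integers(0, 50_000))
            le = ls + 400
            lnc, ann = self._setup(gs, ge, ls, le)
            fwd = cis_targets(lnc, ann)
            lnc_m, ann_m = self._setup(pivot - ge, pivot - gs, pivot - le, pivot - ls)
            assert (fwd == ["g"]) == (cis_targets(lnc_m, ann_m) == ["g"])


class TestTransTargets:
    def _exprs(self, lnc_vals, gene_vals):
        samples = [f"s{i}" for i in range(len(lnc_vals))]
        conds = {s: ["A", "A", "A", "B", "B", "B"][i] for i, s in enumerate(samples)}
        lnc = ExpressionMatrix(
            pd.DataFrame([lnc_vals], index=["l1"], columns=samples),
            {"l1": "lncRNA"}, conds, unit="FPKM",
        )
        gene = ExpressionMatrix(
            pd.DataFrame([gene_vals], index=["g1"], columns=samples),
            {"g1": "mRNA"}, conds, unit="FPKM",
        )
        return lnc, gene

    def _calls(self, lnc_call, gene_call):
        return DECalls(pd.DataFrame({
            "feature_id": ["l1", "g1"],
            "contrast": ["A_vs_B", "A_vs_B"],
            "call": [lnc_call, gene_call],
        }))

    def test_strong_anticorrelation_with_opposite_calls_reported(self):
        lnc, gene = self._exprs([1, 2, 1, 60, 70, 65], [60, 70, 62, 1, 2, 1])
        out = trans_targets(lnc, gene, self._calls("up", "down"))
        assert len(out) == 1
        assert out.loc[0, "pcc"] < -0.9

    def test_positive_correlation_excluded_by_default(self):
        lnc, gene = self._exprs([1, 2, 1, 60, 70, 65], [2, 3, 1, 55, 80, 70])
        out = trans_targets(lnc, gene, self._calls("up", "up"))
        assert out.empty

    def test_positive_correlation_reported_in_absolute_mode(self):
        lnc, gene = self._exprs([1, 2, 1, 60, 70, 65], [2, 3, 1, 55, 80, 70])
        out = trans_targets(lnc, gene, self._calls("up", "up"), mode="absolute")
        assert len(out) == 1

    def test_weak_anticorrelation_excluded(self):
        lnc, gene = self._exprs([1, 5, 2, 50, 80, 20], [60, 20, 70, 10, 2, 40])
        calls = self._calls("up", "down")
        out = trans_targets(lnc, gene, calls)
        # the magnitude rule: only |pcc| >= 0.9 survives
        for row in out.itertuples():
            assert row.pcc <= -0.9

    def test_non_de_pairs_never_reported(self):
        lnc, gene = self._exprs([1, 2, 1, 60, 70, 65], [60, 70, 62, 1, 2, 1])
        out = trans_targets(lnc, gene, self._calls("up", "ns"))
        assert out.empty

    def test_zero_variance_feature_skipped_without_nan(self):
        lnc, gene = self._exprs([5, 5, 5, 5, 5, 5], [60, 70, 62, 1, 2, 1])
        out = trans_targets(lnc, gene, self._calls("up", "down"))
        assert out.empty
        assert not out.isna().any().any()

    def test_invalid_mode_rejected(self):
        lnc, gene = self._exprs([1, 2, 1, 6, 7, 6], [6, 7, 6, 1, 2, 1])
        with pytest.raises(ValueError, match="mode"):
            trans_targets(lnc, gene, self._calls("up", "down"), mode="both")


def test_cis_window_validation():
    with pytest.raises(ValueError):
        CisWindow(0)
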