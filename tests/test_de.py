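import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lmrnet.de import (
    benjamini_hochberg,
    call_de,
    ddct,
    fpkm,
    hypergeometric_enrichment,
    log2_fold_change,
    tpm,
    welch_p_values,
)
from lmrnet.io import ExpressionMatrix

from .oracles import bh_oracle


def _matrix(values, feature_ids=None, conditions=None, unit="raw_count"):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    conditions = conditions or {s: ("A" if i < n // 2 else "B") for i, s in enumerate(samples)}
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=feature_ids, columns=samples),
        roles={f: "mRNA" for f in feature_ids},
        conditions=conditions,
        unit=unit,
    )


class TestNormalization:
    def test_fpkm_hand_value(self):
        # 10 fragments on a 2-kb transcript in a 1e6-fragment library -> 5.0
        m = _matrix([[10.0], [999_990.0]], conditions={"s0": "A"})
        out = fpkm(m, {"f0": 2000, "f1": 1000})
        assert out.data.loc["f0", "s0"] == pytest.approx(5.0)

    def test_fpkm_zero_count_is_zero_and_symmetry(self):
        m = _matrix([[0, 4], [8, 4]], conditions={"s0": "A", "s1": "B"})
        out = fpkm(m, {"f0": 500, "f1": 500})
        assert out.data.loc["f0", "s0"] == 0.0
        # equal counts & lengths within a sample -> equal FPKM
        assert out.data.loc["f0", "s1"] == out.data.loc["f1", "s1"]

    def test_fpkm_errors(self):
        m = _matrix([[1, 0], [1, 0]], conditions={"s0": "A", "s1": "B"})
        with pytest.raises(ValueError, match="zero-total"):
            fpkm(m, {"f0": 100, "f1": 100})
        m2 = _matrix([[1], [1]], conditions={"s0": "A"})
        with pytest.raises(ValueError, match="length"):
            fpkm(m2, {"f0": 0, "f1": 100})

    def test_tpm_hand_values_and_conservation(self):
        m = _matrix([[1.0], [3.0]], conditions={"s0": "A"})
        out = tpm(m)
        assert out.data["s0"].tolist() == pytest.approx([250_000.0, 750_000.0])
        assert out.data["s0"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_tpm_single_feature_forced_to_million(self):
        m = _matrix([[17.0]], conditions={"s0": "A"})
        assert tpm(m).data.iloc[0, 0] == pytest.approx(1e6)

    def test_scale_equivariance(self, rng):
        counts = rng.integers(1, 1000, size=(20, 4)).astype(float)
        m = _matrix(counts)
        doubled = _matrix(counts * np.array([2.0, 1, 1, 1]))
        lengths = {f"f{i}": int(l) for i, l in enumerate(rng.integers(200, 5000, 20))}
        assert np.allclose(fpkm(m, lengths).data, fpkm(doubled, lengths).data)
        assert np.allclose(tpm(m).data, tpm(doubled).data)


class TestFoldChangeAndCalls:
    def test_hand_values(self):
        assert log2_fold_change(7.0, 7.0, 1.0) == 0.0
        assert log2_fold_change(10.0, 40.0, 1e-12) == pytest.approx(2.0, abs=1e-9)

    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))

    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.0, 0.049, "up"),  # |FC| exactly 2 qualifies
            (0.9, 0.001, "ns"),  # below the FC threshold
            (-3.0, 0.05, "ns"),  # FDR exactly 0.05 excluded
            (-1.0, 0.049, "down"),
        ],
    )
    def test_boundary_semantics(self, lfc, fdr, expected):
        assert call_de(lfc, fdr) == expected

    @given(
        lfc=st.floats(-10, 10),
        fdr=st.floats(0, 1),
        dl=st.floats(0, 5),
        df=st.floats(0, 1),
    )
    def test_monotonicity(self, lfc, fdr, dl, df):
        """Strengthening the evidence never turns a call into ns."""
        base = call_de(lfc, fdr)
        if base == "ns":
            return
        stronger = call_de(lfc + np.sign(lfc) * dl, max(fdr - df, 0.0))
        assert stronger == base


class TestWelch:
    def test_identical_groups_p_is_one(self):
        m = _matrix([[5, 5, 5, 5, 5, 5]], conditions=None)
        p = welch_p_values(m, "A", "B")
        assert p.iloc[0] == 1.0

    def test_strong_separation_detected(self, rng):
        vals = np.array([[1, 1, 1, 100, 100, 100]]) + rng.normal(0, 0.01, (1, 6))
        m = _matrix(np.abs(vals))
        assert welch_p_values(m, "A", "B").iloc[0] < 0.01

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(1234)
        vals = rng.lognormal(3, 1, size=(1000, 6))
        m = _matrix(vals)
        p = welch_p_values(m, "A", "B")
        assert 0.02 <= (p < 0.05).mean() <= 0.09

    def test_too_few_replicates_rejected(self):
        m = _matrix([[1, 2]], conditions={"s0": "A", "s1": "B"})
        with pytest.raises(ValueError, match="replicates"):
            welch_p_values(m, "A", "B")


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_hand_step_up(self, p, expected):
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 200)))
            assert np.max(np.abs(benjamini_hochberg(p) - bh_oracle(p))) < 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])


class TestEnrichment:
    def test_whole_background_term_not_enriched(self):
        bg = {f"g{i}" for i in range(20)}
        de = {f"g{i}" for i in range(5)}
        res = hypergeometric_enrichment(de, bg, {"all": set(bg)})
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_tail_value(self):
        # drawing all 5 term members in 5 draws from 20: p = 1/C(20,5)
        bg = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        res = hypergeometric_enrichment(term, bg, {"t": term})
        assert res.loc[0, "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_is_one(self):
        bg = {f"g{i}" for i in range(10)}
        res = hypergeometric_enrichment({"g0"}, bg, {"t": {"g9"}})
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_stray_de_feature_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            hypergeometric_enrichment({"x"}, {"a"}, {})


class TestDdct:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((20, 15, 22, 17), 1.0),  # ddCt = 0
            ((21, 15, 22, 17), 0.5),  # ddCt = 1
            ((18, 15, 22, 17), 4.0),  # ddCt = -2
        ],
    )
    def test_hand_values(self, args, expected):
        assert ddct(*args) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct(np.nan, 1, 1, 1)
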