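import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedcoex.association import (compare_groups, ddct_fold_change,
                                  fold_change_frame,
                                  signature_correlation_summary)
from seedcoex.errors import (InsufficientDataError, UnknownGeneError,
                             ValidationError)
from seedcoex.io import ExpressionMatrix, GeneSet
from seedcoex.synthetic import SyntheticConfig, generate_dataset


def _matrix_from_rows(rows: dict, symbols: dict) -> ExpressionMatrix:
    values = pd.DataFrame(rows).T
    values.columns = [f"S{i:02d}" for i in range(values.shape[1])]
    return ExpressionMatrix(values=values,
                            gene_symbols=pd.Series(symbols).loc[values.index])


class TestSignatureCorrelation:
    def test_candidate_against_itself_is_positive(self):
        rng = np.random.default_rng(0)
        m = _matrix_from_rows({"p1": rng.normal(size=30)}, {"p1": "CAND"})
        summ = signature_correlation_summary(m, "CAND", ("CAND",))
        assert summ.fraction("positive") == 1.0
        assert summ.table.loc[0, "r"] == pytest.approx(1.0)

    def test_unknown_candidate_raises(self):
        rng = np.random.default_rng(0)
        m = _matrix_from_rows({"p1": rng.normal(size=30)}, {"p1": "A"})
        with pytest.raises(UnknownGeneError):
            signature_correlation_summary(m, "NOSUCH", ("A",))

    def test_unmatched_genes_excluded_from_denominator(self):
        rng = np.random.default_rng(1)
        m = _matrix_from_rows({"p1": rng.normal(size=40),
                               "p2": rng.normal(size=40)},
                              {"p1": "CAND", "p2": "G1"})
        summ = signature_correlation_summary(m, "CAND", ("G1", "MISSING1", "MISSING2"))
        assert summ.n_matched == 1
        assert summ.unmatched == ("MISSING1", "MISSING2")
        assert sum(summ.fractions.values()) == pytest.approx(1.0)

    def test_independent_signature_mostly_unclassified(self):
        # 61 genes generated independently of the candidate: ~95% should
        # land in the "none" class at alpha = 0.05
        rng = np.random.default_rng(2)
        n = 200
        rows = {"pc": rng.normal(size=n)}
        symbols = {"pc": "CAND"}
        members = []
        for i in range(61):
            rows[f"p{i}"] = rng.normal(size=n)
            symbols[f"p{i}"] = f"SIG{i:02d}"
            members.append(f"SIG{i:02d}")
        m = _matrix_from_rows(rows, symbols)
        summ = signature_correlation_summary(m, "CAND", members)
        assert summ.fraction("none") == pytest.approx(0.95, abs=0.08)

    def test_planted_split_recovered(self):
        # mirrors a 44 positive / 4 negative / 13 uncorrelated signature
        cfg = SyntheticConfig(seed=21, n_samples=150, subgroup_effects={})
        b = generate_dataset(cfg)
        summ = signature_correlation_summary(b.matrix, cfg.candidate, b.signature)
        assert summ.n_matched == 61
        assert summ.fraction("positive") == pytest.approx(44 / 61, abs=0.08)
        assert summ.fraction("negative") == pytest.approx(4 / 61, abs=0.08)
        assert summ.fraction("none") == pytest.approx(13 / 61, abs=0.08)


class TestCompareGroups:
    def test_identical_groups(self):
        stat, p = compare_groups([1, 2, 3, 1, 2, 3], list("aaabbb"), test="t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_clear_separation(self):
        vals = [0, 0.01, -0.01, 0, 10, 10.01, 9.99, 10]
        stat, p = compare_groups(vals, list("aaaabbbb"), test="t")
        assert p < 1e-3

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=20)
        labels = np.array(["x"] * 10 + ["y"] * 10)
        s1, p1 = compare_groups(vals, labels, test="t")
        swapped = np.where(labels == "x", "y", "x")
        s2, p2 = compare_groups(vals, swapped, test="t")
        assert s2 == pytest.approx(-s1)
        assert p2 == pytest.approx(p1)

    def test_anova_three_groups(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                               rng.normal(3, 1, 20)])
        labels = np.repeat(["a", "b", "c"], 20)
        stat, p = compare_groups(vals, labels, test="anova")
        assert p < 1e-6

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1, 2, 3], ["a", "a", "b"], test="t")

    def test_empirical_power_matches_closed_form(self):
        # N(0,1) vs N(1,1), n = 50 each: power of the two-sample t-test at
        # alpha = 0.05 from the noncentral t distribution
        from scipy import stats
        n, delta, alpha = 50, 1.0, 0.05
        nc = delta / np.sqrt(2 / n)
        df = 2 * n - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 500
        labels = np.repeat(["a", "b"], n)
        for _ in range(reps):
            vals = np.concatenate([rng.normal(0, 1, n), rng.normal(delta, 1, n)])
            _, p = compare_groups(vals, labels, test="t")
            rejections += p < alpha
        assert rejections / reps == pytest.approx(power, abs=0.05)


def _qpcr(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "target",
                                       "ct_target", "ct_actb", "ct_gapdh"])


class TestDdctFoldChange:
    def test_calibrator_identity(self):
        q = _qpcr([("S1", "ctrl", "G", 24.0, 18.0, 20.0),
                   ("S2", "ctrl", "G", 25.0, 19.0, 21.0)])
        res = ddct_fold_change(q, "ctrl")
        # both ctrl samples share dCt = 5 -> ddCt = 0, fold = 1
        assert all(r.ddct == pytest.approx(0.0) for r in res)
        assert all(r.fold_change == pytest.approx(1.0) for r in res)

    def test_one_cycle_doubling(self):
        q = _qpcr([("S1", "ctrl", "G", 24.0, 18.0, 20.0),
                   ("S2", "tum", "G", 23.0, 18.0, 20.0)])
        res = {r.sample_id: r for r in ddct_fold_change(q, "ctrl")}
        assert res["S2"].ddct == pytest.approx(-1.0)
        assert res["S2"].fold_change == pytest.approx(2.0)

    def test_worked_example(self):
        # target 25, ACTB 20, GAPDH 22 -> dCt = 25 - 21 = 4; with
        # calibrator mean dCt 3: ddCt = 1, fold = 0.5
        q = _qpcr([("C1", "ctrl", "G", 24.0, 20.0, 22.0),  # dCt = 3
                   ("S1", "tum", "G", 25.0, 20.0, 22.0)])
        res = {r.sample_id: r for r in ddct_fold_change(q, "ctrl")}
        assert res["S1"].dct == pytest.approx(4.0)
        assert res["S1"].ddct == pytest.approx(1.0)
        assert res["S1"].fold_change == pytest.approx(0.5)

    def test_calibrator_geometric_mean_fold_is_one(self):
        rng = np.random.default_rng(7)
        rows = [(f"S{i}", "ctrl" if i < 6 else "tum", "G",
                 float(rng.uniform(22, 28)), float(rng.uniform(17, 19)),
                 float(rng.uniform(18, 20))) for i in range(12)]
        res = fold_change_frame(ddct_fold_change(_qpcr(rows), "ctrl"))
        calib = res[res["group"] == "ctrl"]["fold_change"]
        geo_mean = np.exp(np.log(calib).mean())
        assert geo_mean == pytest.approx(1.0, abs=1e-12)
        assert (res["fold_change"] > 0).all()

    @settings(max_examples=30)
    @given(st.floats(-5, 5), st.integers(0, 2 ** 31 - 1))
    def test_shifting_all_three_cts_preserves_dct(self, c, seed):
        # adding c to target and both housekeepers cancels: two housekeepers
        # are averaged, the target is single, so dCt shifts by c - c = 0
        rng = np.random.default_rng(seed)
        base = [("C1", "ctrl", "G", 24.0, 18.0, 20.0),
                ("S1", "tum", "G", float(rng.uniform(20, 30)),
                 float(rng.uniform(16, 20)), float(rng.uniform(17, 21)))]
        shifted = [base[0],
                   ("S1", "tum", "G", base[1][3] + c, base[1][4] + c, base[1][5] + c)]
        r0 = ddct_fold_change(_qpcr(base), "ctrl")[1]
        r1 = ddct_fold_change(_qpcr(shifted), "ctrl")[1]
        assert r1.dct == pytest.approx(r0.dct, abs=1e-9)
        assert r1.fold_change == pytest.approx(r0.fold_change, rel=1e-9)

    def test_missing_calibrator_group_rejected(self):
        q = _qpcr([("S1", "tum", "G", 24.0, 18.0, 20.0)])
        with pytest.raises(ValidationError, match="calibrator"):
            ddct_fold_change(q, "ctrl")
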