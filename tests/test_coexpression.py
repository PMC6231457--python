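import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedcoex.coexpression import (SeedCorrelationTable, deduplicate_probes,
                                   filter_module, intersect_modules,
                                   pearson_with_p, seed_correlation_table)
from seedcoex.errors import (InsufficientDataError, UndefinedCorrelationError,
                             UnknownGeneError, ValidationError)
from seedcoex.synthetic import PlantedBlock, SyntheticConfig, generate_dataset


def _pearson_from_sums(x, y):
    """Independent from-definition oracle: raw sum formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    return (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))


class TestPearsonWithP:
    def test_perfect_collinearity(self):
        r, p, n = pearson_with_p([1, 2, 3], [2, 4, 6], min_samples=3)
        assert (r, p, n) == (1.0, 0.0, 3)

    def test_perfect_anticollinearity(self):
        r, p, n = pearson_with_p([1, 2, 3], [6, 4, 2], min_samples=3)
        assert (r, p, n) == (-1.0, 0.0, 3)

    def test_hand_computed_r_and_t_distribution_p(self):
        # deviations give covariance sum 4.0 and squared sums 5.0 -> r = 0.8;
        # t = 0.8*sqrt(2/0.36) with 2 df gives the frozen two-sided p
        r, p, n = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4], min_samples=4)
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=1e-9)

    def test_pairwise_complete_drops_missing_pairs(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        r, p, n = pearson_with_p(x, y, min_samples=3)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4], min_samples=3)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            pearson_with_p([1, 2], [3, 4], min_samples=10)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(5, 30))
    def test_matches_from_definition_sums(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, _, _ = pearson_with_p(x, y, min_samples=5)
        assert r == pytest.approx(_pearson_from_sums(x, y), abs=1e-12)


class TestSeedCorrelationTable:
    def test_one_row_per_non_seed_probe(self, small_matrix):
        tab = seed_correlation_table(small_matrix, "SEED", min_samples=10)
        assert len(tab.table) == 5
        assert "p_seed" not in set(tab.table["probe_id"])

    def test_probe_identical_to_seed_has_r_one(self, small_matrix):
        m = small_matrix
        m.values.loc["p_null1"] = m.values.loc["p_seed"]
        tab = seed_correlation_table(m, "SEED", min_samples=10)
        row = tab.table.set_index("probe_id").loc["p_null1"]
        assert row["r"] == pytest.approx(1.0)

    def test_unknown_seed_raises(self, small_matrix):
        with pytest.raises(UnknownGeneError):
            seed_correlation_table(small_matrix, "NOSUCH")

    def test_planted_block_mean_r_near_target(self):
        cfg = SyntheticConfig(
            seed=7, n_samples=200, n_background=100,
            blocks=(PlantedBlock("SNAI1", 30, 0, rho=0.6),),
            overlap_size=0, subgroup_effects={}, duplication_rate=0.0)
        b = generate_dataset(cfg)
        tab = seed_correlation_table(b.matrix, "SNAI1").table.set_index("symbol")
        block = sorted(b.truth.planted["SNAI1"])
        assert tab.loc[block, "r"].mean() == pytest.approx(0.6, abs=0.1)


def _table(rows):
    df = pd.DataFrame(rows, columns=["probe_id", "symbol", "r", "p"])
    df["n_used"] = 50
    df["skipped"] = False
    return SeedCorrelationTable(seed="SEED", seed_probe="p0", table=df,
                                min_samples=10)


class TestDeduplicateProbes:
    def test_most_significant_probe_retained(self):
        tab = _table([("A_1", "G", 0.5, 0.010), ("A_2", "G", 0.4, 0.001)])
        out = deduplicate_probes(tab).table
        assert list(out["probe_id"]) == ["A_2"]

    def test_p_tie_breaks_to_larger_abs_r(self):
        tab = _table([("A_1", "G", 0.35, 0.02), ("A_2", "G", -0.40, 0.02)])
        out = deduplicate_probes(tab).table
        assert list(out["probe_id"]) == ["A_2"]

    def test_full_tie_breaks_to_smallest_probe_id(self):
        tab = _table([("A_2", "G", 0.4, 0.02), ("A_1", "G", 0.4, 0.02)])
        out = deduplicate_probes(tab).table
        assert list(out["probe_id"]) == ["A_1"]

    def test_unique_symbols_pass_through(self):
        tab = _table([("A_1", "G1", 0.5, 0.01), ("A_2", "G2", 0.4, 0.02)])
        out = deduplicate_probes(tab).table
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      tab.table.reset_index(drop=True))

    def test_unannotated_probes_untouched(self):
        tab = _table([("A_1", "", 0.5, 0.01), ("A_2", "", 0.4, 0.02),
                      ("A_3", "G", 0.3, 0.03), ("A_4", "G", 0.2, 0.01)])
        out = deduplicate_probes(tab).table
        assert set(out["probe_id"]) == {"A_1", "A_2", "A_4"}

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 40))
    def test_idempotent_and_one_row_per_symbol(self, seed, n_rows):
        rng = np.random.default_rng(seed)
        rows = [(f"pr{i:02d}", f"G{rng.integers(0, 8)}",
                 float(rng.uniform(-1, 1)), float(rng.uniform(0, 1)))
                for i in range(n_rows)]
        tab = _table(rows)
        once = deduplicate_probes(tab)
        twice = deduplicate_probes(once)
        pd.testing.assert_frame_equal(once.table, twice.table)
        syms = once.table.loc[once.table["symbol"] != "", "symbol"]
        assert not syms.duplicated().any()


class TestFilterModule:
    def test_threshold_edges(self):
        tab = _table([("p1", "IN", 0.31, 0.01),     # passes both strict filters
                      ("p2", "OUTR", 0.29, 0.0001),  # fails |r| > 0.3
                      ("p3", "OUTP", -0.50, 0.20),   # fails p < 0.05
                      ("p4", "NEG", -0.45, 0.01)])
        m = filter_module(tab, r_cutoff=0.3, alpha=0.05)
        assert m.positive == {"IN"}
        assert m.negative == {"NEG"}

    def test_partition_matches_sign(self, default_bundle):
        tab = deduplicate_probes(
            seed_correlation_table(default_bundle.matrix, "SNAI1"))
        m = filter_module(tab)
        assert m.positive.isdisjoint(m.negative)
        assert m.size == len(m.positive) + len(m.negative)
        assert all(m.r[g] > 0 for g in m.positive)
        assert all(m.r[g] < 0 for g in m.negative)
        assert "SNAI1" not in m.members

    def test_relaxing_thresholds_is_monotone(self, default_bundle):
        tab = deduplicate_probes(
            seed_correlation_table(default_bundle.matrix, "SNAI2"))
        strict = filter_module(tab, r_cutoff=0.3, alpha=0.05)
        loose = filter_module(tab, r_cutoff=0.2, alpha=0.10)
        assert strict.members <= loose.members

    def test_parameter_validation(self):
        tab = _table([("p1", "G", 0.5, 0.01)])
        with pytest.raises(ValidationError):
            filter_module(tab, r_cutoff=1.5)
        with pytest.raises(ValidationError):
            filter_module(tab, alpha=0.0)


class TestIntersectModules:
    def _module(self, seed, pos, neg):
        from seedcoex.coexpression import CoexpressionModule
        r = {g: 0.5 for g in pos} | {g: -0.5 for g in neg}
        return CoexpressionModule(seed=seed, positive=set(pos), negative=set(neg),
                                  r_cutoff=0.3, alpha=0.05, r=r,
                                  p={g: 0.01 for g in r})

    def test_set_arithmetic(self):
        a = self._module("A", {"X", "Y"}, {"Z"})
        b = self._module("B", {"Y"}, {"Z", "W"})
        inter = intersect_modules(a, b)
        assert inter.common == {"Y", "Z"}
        assert inter.exclusive_a == {"X"}
        assert inter.exclusive_b == {"W"}
        assert inter.sign_concordant == {"Y", "Z"}
        assert inter.n_common + len(inter.exclusive_a) == a.size

    def test_disjoint_modules(self):
        inter = intersect_modules(self._module("A", {"X"}, set()),
                                  self._module("B", {"Y"}, set()))
        assert inter.common == set()

    def test_symmetry(self):
        a = self._module("A", {"X", "Y"}, {"Z"})
        b = self._module("B", {"Y", "Z"}, {"Q"})
        assert intersect_modules(a, b).common == intersect_modules(b, a).common

    def test_discordant_sign_reported_not_dropped(self):
        a = self._module("A", {"Y"}, set())
        b = self._module("B", set(), {"Y"})
        inter = intersect_modules(a, b)
        assert inter.common == {"Y"}
        assert inter.sign_concordant == set()
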