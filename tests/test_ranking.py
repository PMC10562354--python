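"""Additive-benefit greedy ranking against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forestprio as fp

Z = 0.25


def oracle_greedy_order(values, z=Z):
    """Independent greedy: recompute total benefit from scratch around every
    candidate removal; lexicographic (smallest index) tie-break."""
    values = np.asarray(values, dtype=float)
    totals = values.sum(axis=0)
    keep = totals > 0
    values = values[:, keep] / totals[keep]
    remaining = list(range(len(values)))
    order, losses = [], []

    def total_benefit(cells):
        r = values[cells].sum(axis=0) if cells else np.zeros(values.shape[1])
        r = np.clip(r, 0, 1)
        r[r < 1e-12] = 0.0  # an exhausted feature's true remaining share is exactly 0
        return float(np.sum(r**z))

    while remaining:
        before = total_benefit(remaining)
        best_i, best_loss = None, None
        for i in remaining:
            loss = before - total_benefit([c for c in remaining if c != i])
            if best_loss is None or loss < best_loss - 1e-15:
                best_i, best_loss = i, loss
            elif abs(loss - best_loss) <= 1e-15 and i < best_i:
                best_i = i
        order.append(best_i)
        losses.append(best_loss)
        remaining.remove(best_i)
    return np.asarray(order), np.asarray(losses)


def random_stack(rng, n_cells, n_features, zero_frac=0.4):
    vals = rng.random((n_cells, n_features))
    vals[rng.random((n_cells, n_features)) < zero_frac] = 0.0
    if not (vals.sum(axis=0) > 0).any():
        vals[0, 0] = 1.0
    return vals


class TestBenefit:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.0), (0.0625, 0.5)])
    def test_power_law_values(self, r, expected):
        assert fp.benefit(r, 0.25) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fp.benefit(1.5)
        with pytest.raises(ValueError):
            fp.benefit(0.5, z=0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_concave(self, a, b):
        lo, hi = sorted((a, b))
        assert fp.benefit(lo) <= fp.benefit(hi)
        mid = 0.5 * (lo + hi)
        assert fp.benefit(mid) >= 0.5 * (fp.benefit(lo) + fp.benefit(hi)) - 1e-12


class TestMarginalLoss:
    def test_empty_cell_loses_nothing(self):
        assert fp.marginal_loss(np.zeros(3), np.ones(3)) == 0.0

    def test_whole_feature_in_one_cell(self):
        assert fp.marginal_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(1.0)

    def test_two_cell_toy_losses(self):
        # feature X all in cell A; feature Y split 0.1/0.9
        qa, qb = np.array([1.0, 0.1]), np.array([0.0, 0.9])
        r = np.ones(2)
        assert fp.marginal_loss(qa, r) == pytest.approx(1.0 + 1 - 0.9**Z, abs=1e-3)
        assert fp.marginal_loss(qa, r) == pytest.approx(1.026, abs=1e-3)
        assert fp.marginal_loss(qb, r) == pytest.approx(1 - 0.1**Z, abs=1e-3)
        assert fp.marginal_loss(qb, r) == pytest.approx(0.438, abs=1e-3)

    def test_inconsistent_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fp.marginal_loss(np.array([0.5]), np.array([0.2]))


class TestRankCells:
    def test_rare_feature_cell_outranks_common_one(self):
        # concavity at z=0.25 protects the cell holding 100% of feature X
        vals = np.array([[1.0, 0.1], [0.0, 0.9]])
        ranking = fp.rank_cells(vals)
        np.testing.assert_array_equal(ranking.order, [1, 0])
        assert ranking.ranks[0] == 1.0  # cell A top-ranked

    def test_uniform_feature_any_top_fraction_holds_its_share(self):
        vals = np.ones((20, 1))
        ranking = fp.rank_cells(vals)
        curve = fp.performance_curve(ranking, vals)
        for p in (0.2, 0.5, 1.0):
            assert curve.loc[p].iloc[0] == pytest.approx(p, abs=1 / 20 + 1e-12)

    def test_ranks_are_nested_permutation(self, small_stack):
        ranking = fp.rank_cells(small_stack)
        n = ranking.n_cells
        np.testing.assert_allclose(np.sort(ranking.ranks), np.arange(1, n + 1) / n)
        prev = np.zeros(ranking.shape, dtype=bool)
        for p in (0.02, 0.1, 0.5, 1.0):
            mask = fp.top_fraction(ranking, p)
            assert (mask | prev).sum() == mask.sum()  # nested
            prev = mask

    def test_matches_full_recomputation_oracle_on_small_stacks(self):
        rng = np.random.default_rng(2024)
        for trial in range(60):
            vals = random_stack(rng, int(rng.integers(2, 13)), int(rng.integers(1, 5)))
            expected, _ = oracle_greedy_order(vals)
            got = fp.rank_cells(vals, fp.BenefitConfig(z=Z))
            np.testing.assert_array_equal(got.order, expected, err_msg=f"trial {trial}")

    def test_incremental_and_naive_engines_agree(self):
        rng = np.random.default_rng(7)
        vals = random_stack(rng, 120, 8)
        a = fp.rank_cells(vals, method="incremental")
        b = fp.rank_cells(vals, method="naive")
        np.testing.assert_array_equal(a.order, b.order)

    def test_warp_one_equals_default_and_warp_batches_run(self):
        rng = np.random.default_rng(8)
        vals = random_stack(rng, 60, 5)
        base = fp.rank_cells(vals)
        w1 = fp.rank_cells(vals, fp.BenefitConfig(warp=1))
        np.testing.assert_array_equal(base.order, w1.order)
        w4 = fp.rank_cells(vals, fp.BenefitConfig(warp=4))
        assert sorted(w4.order) == list(range(60))

    def test_empty_cells_removed_first(self):
        vals = np.array([[0.0], [2.0], [0.0], [1.0]])
        ranking = fp.rank_cells(vals)
        assert set(ranking.order[:2]) == {0, 2}
        assert list(ranking.order[:2]) == [0, 2]  # lexicographic among ties

    def test_random_tie_rule_is_seeded(self):
        vals = np.ones((10, 1))
        a = fp.rank_cells(vals, tie_rule="random", seed=3)
        b = fp.rank_cells(vals, tie_rule="random", seed=3)
        c = fp.rank_cells(vals, tie_rule="random", seed=4)
        np.testing.assert_array_equal(a.order, b.order)
        assert (a.order != c.order).any()

    def test_all_zero_stack_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fp.rank_cells(np.zeros((4, 2)))

    def test_zero_total_features_dropped(self, caplog):
        vals = np.array([[1.0, 0.0], [2.0, 0.0]])
        ranking = fp.rank_cells(vals)
        assert ranking.feature_names == ("feature_0",)


class TestPerformanceCurve:
    def test_endpoints(self, small_stack):
        ranking = fp.rank_cells(small_stack)
        curve = fp.performance_curve(ranking, small_stack)
        assert (curve.loc[0.0] == 0).all()
        assert np.allclose(curve.loc[1.0], 1.0)
        assert (curve.diff().dropna() >= -1e-12).all().all()  # non-decreasing

    def test_matches_cumulative_sum_oracle(self):
        rng = np.random.default_rng(11)
        vals = random_stack(rng, 6, 3, zero_frac=0.2)
        ranking = fp.rank_cells(vals)
        curve = fp.performance_curve(ranking, vals)
        q = vals / vals.sum(axis=0)
        rev = ranking.order[::-1]
        for k in range(7):
            expected = q[rev[:k]].sum(axis=0)
            np.testing.assert_allclose(curve.iloc[k].to_numpy(), expected, atol=1e-12)


class TestTopFraction:
    @pytest.mark.parametrize("n,p,m", [(100, 0.02, 2), (50, 0.10, 5), (7, 1.0, 7)])
    def test_ceil_cell_counts(self, n, p, m):
        ranking = fp.rank_cells(np.linspace(1, 2, n)[:, None])
        assert fp.top_fraction(ranking, p).sum() == m

    def test_rejects_out_of_range(self, small_stack):
        ranking = fp.rank_cells(small_stack)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                fp.top_fraction(ranking, bad)
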