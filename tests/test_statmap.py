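import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainnetsim.landscape import build_grid
from brainnetsim.statmap import (
    BehavioralFit,
    MaskSet,
    NoFitError,
    bh_adjust,
    correlation_map,
    edgewise_correlation_fdr,
    rosenthal_effect_map,
    select_optimum,
    significance_mask,
    variability_mask,
)


GRID1 = build_grid(1, (0, 0), 1, (0, 0))


def as_stack(values):
    """subjects x 1 x 1 stack from a 1D sample."""
    return np.asarray(values, dtype=float)[:, None, None]


def exact_ranksum_p(x, y):
    """Two-tailed rank-sum p by total enumeration of group assignments."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(combined)
    mu = n1 * (len(combined) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    stat = [
        abs(sum(ranks[list(idx)]) - mu)
        for idx in itertools.combinations(range(len(combined)), n1)
    ]
    return sum(s >= obs - 1e-9 for s in stat) / len(stat)


class TestRosenthalEffectMap:
    def test_matches_exact_enumeration_oracle(self):
        hc = np.array([1.0, 2.0, 3.0])
        pd_ = np.array([10.0, 11.0, 12.0])
        smap = rosenthal_effect_map(as_stack(hc), as_stack(pd_), GRID1)
        p_exact = exact_ranksum_p(hc, pd_)
        assert smap.p_values[0, 0] == pytest.approx(p_exact, abs=1e-12)
        z_expected = stats.norm.isf(p_exact / 2) * -1  # PD ranks higher -> negative
        assert smap.z_values[0, 0] == pytest.approx(z_expected, abs=1e-12)
        assert smap.values[0, 0] == pytest.approx(z_expected / np.sqrt(6), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_on_random_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 7, 2)
        x, y = rng.normal(size=n1), rng.normal(size=n2) + rng.normal()
        smap = rosenthal_effect_map(as_stack(x), as_stack(y), GRID1)
        assert smap.p_values[0, 0] == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12) + 0.8
        a = rosenthal_effect_map(as_stack(x), as_stack(y), GRID1)
        b = rosenthal_effect_map(as_stack(y), as_stack(x), GRID1)
        assert a.values[0, 0] == pytest.approx(-b.values[0, 0])
        assert a.p_values[0, 0] == pytest.approx(b.p_values[0, 0])

    def test_identical_distributions(self):
        x = np.arange(12.0)
        smap = rosenthal_effect_map(as_stack(x), as_stack(x), GRID1)
        assert smap.values[0, 0] == pytest.approx(0.0)
        assert smap.p_values[0, 0] == pytest.approx(1.0)

    def test_large_groups_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = np.round(rng.normal(size=30), 1)  # rounding creates ties
        y = np.round(rng.normal(size=30) + 0.5, 1)
        smap = rosenthal_effect_map(as_stack(x), as_stack(y), GRID1)
        ref = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert smap.p_values[0, 0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            rosenthal_effect_map(as_stack([1.0]), as_stack([1.0, 2.0]), GRID1)


class TestCorrelationMap:
    def test_five_point_formula_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        y = np.array([2.0, 0.5, 3.5, 1.0, 7.0])
        smap = correlation_map(as_stack(x), y, GRID1)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(3 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df=3)
        assert smap.values[0, 0] == pytest.approx(r, abs=1e-12)
        assert smap.p_values[0, 0] == pytest.approx(p, abs=1e-12)

    def test_perfect_linear_relation(self):
        y = np.arange(8.0)
        smap = correlation_map(as_stack(2 * y + 1), y, GRID1)
        assert smap.values[0, 0] == pytest.approx(1.0)
        assert smap.p_values[0, 0] < 1e-10
        assert smap.z_values[0, 0] > 6

    def test_constant_clinical_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_map(as_stack(np.arange(5.0)), np.ones(5), GRID1)

    def test_zero_variance_point_becomes_nan(self):
        grid = build_grid(2, (0, 1), 1, (0, 0))
        stack = np.zeros((5, 2, 1))
        stack[:, 0, 0] = np.arange(5.0)  # point 1 constant
        smap = correlation_map(stack, np.arange(5.0), grid)
        assert np.isfinite(smap.values[0, 0])
        assert np.isnan(smap.values[1, 0])
        assert not significance_mask(smap, 0.0)[1, 0]

    def test_misaligned_stack_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            correlation_map(np.zeros((4, 1, 1)), np.arange(5.0), GRID1)


class TestMasks:
    def test_significance_mask_basics(self):
        grid = build_grid(2, (0, 1), 2, (0, 0.1))
        z = np.array([[0.0, 4.0], [-4.0, 2.0]])
        smap = type("S", (), {"z_values": z})()
        assert significance_mask(smap, 3.82).sum() == 2
        assert significance_mask(smap, 3.82, sign="+").sum() == 1
        assert significance_mask(smap, 3.82, sign="-")[1, 0]
        assert significance_mask(smap, 0.0).sum() == 3  # strictly greater
        with pytest.raises(ValueError):
            significance_mask(smap, 1.0, sign="x")

    def test_variability_mask_top_quartile_exact(self):
        """Grid of 100 points whose across-subject SDs are 1..100: exactly
        the 25 largest must be masked."""
        rng = np.random.default_rng(0)
        sds = np.arange(1.0, 101.0)
        rng.shuffle(sds)
        base = rng.normal(size=(40, 100))
        base = (base - base.mean(0)) / base.std(0)
        stack = (base * sds).reshape(40, 10, 10)
        mask = variability_mask(stack)
        assert mask.sum() == 25
        assert set(sds.reshape(10, 10)[mask]) == set(range(76, 101))

    def test_constant_sd_masks_nothing(self):
        stack = np.random.default_rng(1).normal(size=(6, 1, 4))
        stack = (stack - stack.mean(0)) / stack.std(0)  # all SDs equal 1
        assert variability_mask(stack).sum() == 0

    def test_mask_fraction_bounded(self):
        stack = np.random.default_rng(2).normal(size=(8, 6, 7))
        # at most a quarter of the cells, up to percentile interpolation
        assert variability_mask(stack).mean() <= 0.25 + 1.5 / 42


class TestSelectOptimum:
    def test_single_masked_point(self):
        grid = build_grid(3, (0, 2), 3, (0, 0.2))
        smap = type("S", (), {"values": np.zeros((3, 3)), "grid": grid})()
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        opt = select_optimum(smap, mask, "max")
        assert (opt.coupling_index, opt.delay_index) == (1, 2)

    def test_tie_broken_by_lower_delay(self):
        grid = build_grid(2, (0, 1), 3, (0, 0.2))
        vals = np.array([[0.0, 5.0, 5.0], [0.0, 0.0, 0.0]])
        smap = type("S", (), {"values": vals, "grid": grid})()
        opt = select_optimum(smap, np.ones_like(vals, dtype=bool), "max")
        assert opt.delay_index == 1 and opt.coupling_index == 0

    @pytest.mark.parametrize("mode", ["max", "min"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, mode, seed):
        rng = np.random.default_rng(seed)
        grid = build_grid(20, (0, 19), 15, (0, 0.14))
        vals = rng.normal(size=(20, 15))
        mask = rng.random((20, 15)) < 0.3
        if not mask.any():
            mask[0, 0] = True
        smap = type("S", (), {"values": vals, "grid": grid})()
        opt = select_optimum(smap, mask, mode)
        masked_vals = np.where(mask, vals, np.nan)
        target = np.nanmax(masked_vals) if mode == "max" else np.nanmin(masked_vals)
        assert opt.value == target

    def test_empty_mask_raises(self):
        grid = build_grid(2, (0, 1), 2, (0, 0.1))
        smap = type("S", (), {"values": np.zeros((2, 2)), "grid": grid})()
        with pytest.raises(NoFitError):
            select_optimum(smap, np.zeros((2, 2), dtype=bool), "max")

    def test_delay_window_restriction(self):
        grid = build_grid(1, (0, 0), 5, (0, 0.4))
        vals = np.array([[5.0, 1.0, 2.0, 3.0, 9.0]])
        smap = type("S", (), {"values": vals, "grid": grid})()
        opt = select_optimum(smap, np.ones_like(vals, bool), "max", delay_window=(0.06, 0.25))
        assert opt.value == 2.0  # only delays 0.1 and 0.2 fall inside the window


class TestBenjaminiHochberg:
    def bh_oracle(self, p):
        """Independent step-up oracle: adjusted p = cummin of m p(k) / k."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_hand_step_up_example(self):
        rej, _ = bh_adjust([0.01, 0.02, 0.04, 0.05], alpha=0.05)
        assert rej.all()  # largest k with p(k) <= k alpha / m is k = 4

    def test_all_ones_no_rejections(self):
        rej, adj = bh_adjust(np.ones(10))
        assert not rej.any() and np.all(adj == 1.0)

    def test_single_test_equals_uncorrected(self):
        rej, adj = bh_adjust([0.03])
        assert rej[0] and adj[0] == pytest.approx(0.03)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_cummin_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(3, 40))
        rej, adj = bh_adjust(p, alpha=0.05)
        oracle = self.bh_oracle(p)
        assert np.allclose(adj, oracle, atol=1e-12)
        assert np.array_equal(rej, oracle <= 0.05)

    def test_rejection_set_monotone_in_alpha(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(size=25)
        prev = np.zeros(25, dtype=bool)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            rej, _ = bh_adjust(p, alpha=alpha)
            assert np.all(prev <= rej)
            prev = rej


class TestEdgewiseFDR:
    def test_planted_edge_detected_and_degenerate_excluded(self):
        rng = np.random.default_rng(4)
        n_subj, n_reg = 30, 5
        y = np.linspace(0, 1, n_subj)
        fc = rng.normal(0, 0.05, size=(n_subj, n_reg, n_reg))
        fc = (fc + fc.transpose(0, 2, 1)) / 2
        fc[:, 3, 1] = fc[:, 1, 3] = y + rng.normal(0, 0.01, n_subj)  # planted edge
        fc[:, 4, 0] = fc[:, 0, 4] = 0.5  # degenerate edge
        with pytest.warns(UserWarning, match="constant edge"):
            table = edgewise_correlation_fdr(fc, y, alpha=0.05)
        hit = table[(table.region_i == 3) & (table.region_j == 1)].iloc[0]
        assert hit.significant and hit.r > 0.9
        degenerate = table[(table.region_i == 4) & (table.region_j == 0)].iloc[0]
        assert np.isnan(degenerate.r) and not degenerate.significant
        assert len(table) == 10  # lower-triangle edges of a 5-node graph


class TestBehavioralFitModel:
    def make_inputs(self, n_hc=6, n_pd=8, seed=0):
        rng = np.random.default_rng(seed)
        grid = build_grid(4, (0, 3), 3, (0, 0.2))
        clinical = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n_hc + n_pd)],
                "group": ["HC"] * n_hc + ["PD"] * n_pd,
                "updrs3_on": [np.nan] * n_hc + list(rng.uniform(5, 40, n_pd)),
            }
        )
        stack = rng.normal(size=(n_hc + n_pd, 4, 3))
        # plant a strong group separation and severity correlation at (2, 1)
        stack[n_hc:, 2, 1] += 10.0 + 0.5 * clinical.updrs3_on[n_hc:].to_numpy()
        return stack, grid, clinical

    def test_group_fit_finds_planted_point(self):
        stack, grid, clinical = self.make_inputs()
        res = BehavioralFit(stack, grid, clinical, "group").fit(
            mode="min", sign="-", z_threshold=1.96
        )
        assert (res.optimum.coupling_index, res.optimum.delay_index) == (2, 1)
        assert res.optimum.value < 0  # PD above HC
        assert "rosenthal_r" in res.summary()

    def test_correlation_fit_finds_planted_point(self):
        stack, grid, clinical = self.make_inputs()
        res = BehavioralFit(stack, grid, clinical, "updrs3_on").fit(
            mode="max", sign="+", z_threshold=1.96
        )
        assert (res.optimum.coupling_index, res.optimum.delay_index) == (2, 1)
        assert res.optimum.value > 0.9
        assert len(res.values_at_optimum()) == 8

    def test_empty_mask_reported_not_relaxed(self):
        stack, grid, clinical = self.make_inputs()
        with pytest.raises(NoFitError):
            BehavioralFit(stack, grid, clinical, "group").fit(z_threshold=50.0)

    def test_mask_set_intersection(self):
        sig = np.array([[True, False], [True, True]])
        var = np.array([[True, True], [False, True]])
        ms = MaskSet(significance=sig, variability=var)
        assert np.array_equal(ms.intersection, sig & var)
        ms2 = MaskSet(sig, var, plausible_delay=np.array([[True, False], [True, False]]))
        assert ms2.intersection.sum() == 1
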