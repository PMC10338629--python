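"""Differential expression: OLS contrasts, variance moderation, BH, phases."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tolnet.de import (
    DesignInfo,
    adjust_bh,
    call_de,
    estimate_prior,
    fit_timepoint_model,
    moderate_variance,
    phase_partition,
    run_de,
)


def _design(weeks_per_sample, controls):
    return DesignInfo(sample_weeks=weeks_per_sample, control_samples=controls)


def _toy_matrix(values, samples):
    return pd.DataFrame([values], index=["f0"], columns=samples)


class TestFitTimepointModel:
    def test_noiseless_mean_difference(self):
        samples = [f"c{i}" for i in range(6)] + [f"t{i}" for i in range(3)]
        design = _design({**{f"c{i}": 0 for i in range(6)}, **{f"t{i}": 6 for i in range(3)}},
                         controls=[f"c{i}" for i in range(6)])
        mat = _toy_matrix([1.0] * 6 + [3.0] * 3, samples)
        fits = fit_timepoint_model(mat, design)
        assert fits.weeks == [6]
        assert fits.coef[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-24)

    def test_permutation_invariance(self, rng):
        samples = [f"s{i}" for i in range(12)]
        weeks = {s: w for s, w in zip(samples, [0] * 4 + [2] * 4 + [6] * 4)}
        design = _design(weeks, controls=samples[:4])
        mat = pd.DataFrame(rng.normal(size=(5, 12)), columns=samples,
                           index=[f"f{i}" for i in range(5)])
        f1 = fit_timepoint_model(mat, design)
        perm = list(rng.permutation(samples))
        f2 = fit_timepoint_model(mat[perm], design)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-12)
        np.testing.assert_allclose(f1.s2, f2.s2, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        samples = [f"s{i}" for i in range(15)]
        week_of = dict(zip(samples, [0] * 5 + [2] * 5 + [4] * 5))
        design = _design(week_of, controls=samples[:5])
        mat = pd.DataFrame(rng.normal(size=(8, 15)), columns=samples,
                           index=[f"f{i}" for i in range(8)])
        fits = fit_timepoint_model(mat, design)
        X, weeks = design.design_matrix(samples)
        for i in range(8):
            b = np.linalg.solve(X.T @ X, X.T @ mat.iloc[i].to_numpy())
            np.testing.assert_allclose(fits.coef[i], b[1:], atol=1e-10)

    def test_week_with_one_sample_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            _design({"a": 0, "b": 0, "c": 2}, controls=["a", "b"])

    def test_empty_control_group_rejected(self):
        with pytest.raises(ValueError, match="control group"):
            _design({"a": 2, "b": 2}, controls=[])


class TestModeration:
    def _fits(self, rng, n_features=200, df=6):
        samples = [f"s{i}" for i in range(df + 3)]
        week_of = {s: (0 if i < df else 4) for i, s in enumerate(samples)}
        design = _design(week_of, controls=samples[:df])
        mat = pd.DataFrame(rng.normal(size=(n_features, len(samples))), columns=samples)
        return fit_timepoint_model(mat, design)

    def test_shrinkage_between_extremes(self, rng):
        fits = self._fits(rng)
        res = moderate_variance(fits)
        lo = np.minimum(fits.s2, res.s0_sq)
        hi = np.maximum(fits.s2, res.s0_sq)
        assert np.all(res.s2_mod.to_numpy() >= lo - 1e-12)
        assert np.all(res.s2_mod.to_numpy() <= hi + 1e-12)

    def test_infinite_prior_df_forces_s0(self, rng):
        fits = self._fits(rng)
        res = moderate_variance(fits, d0=np.inf, s0_sq=0.7)
        np.testing.assert_allclose(res.s2_mod.to_numpy(), 0.7)

    def test_zero_prior_df_is_ordinary_t(self, rng):
        fits = self._fits(rng)
        res = moderate_variance(fits, d0=0.0, s0_sq=1.0)
        ordinary = fits.coef[:, 0] / fits.se[:, 0]
        np.testing.assert_allclose(
            res.table["t"].to_numpy(), ordinary, atol=1e-10
        )

    def test_method_of_moments_recovers_prior(self):
        """s0^2 estimated within 10% on variances drawn from the assumed prior."""
        d0_true, s0_true, d = 8.0, 1.3, 6.0
        ests = []
        rng = np.random.default_rng(42)
        for _ in range(100):
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=500)
            s2 = sigma2 * rng.chisquare(d, size=500) / d
            _, s0_hat = estimate_prior(s2, d)
            ests.append(s0_hat)
        assert abs(np.mean(ests) - s0_true) / s0_true < 0.10


class TestAdjustBH:
    def test_hand_applied_step_up(self):
        # m=4: sorted p * m/rank, cummin from the largest
        adj = adjust_bh([0.005, 0.011, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.022, 0.0266667, 0.04], atol=1e-6)

    def test_degenerate_cases(self):
        np.testing.assert_array_equal(adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(adjust_bh([0.3]), [0.3])

    def test_nan_excluded_from_m(self):
        adj = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_naive_step_up(self, ps):
        """Agreement with a direct implementation of the step-up definition."""
        adj = adjust_bh(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        naive = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, ps[idx] * m / rank)
            naive[idx] = running
        np.testing.assert_allclose(adj, naive, atol=1e-12)


class TestCallDE:
    def _result(self, rows):
        from tolnet.de import DEResult

        table = pd.DataFrame(rows, columns=["feature", "week", "log2fc", "se", "t", "p", "fdr"])
        return DEResult(table, 6.0, 1.0, 0.5,
                        pd.Series(dtype=float), pd.Series(dtype=float))

    def test_threshold_rules(self):
        res = self._result([
            ("a", 2, 1.0, 0.1, 5.0, 0.001, 0.04),
            ("b", 2, 0.3, 0.1, 3.0, 0.002, 0.04),
            ("c", 2, 2.0, 0.1, 6.0, 0.001, 0.20),
        ])
        transcript = call_de(res, fdr=0.05, fc=1.5, mode="transcript")
        assert transcript[2] == {"a"}  # b fails fold cutoff, c fails FDR
        protein = call_de(res, fdr=0.05, mode="protein")
        assert protein[2] == {"a", "b"}

    def test_log2_scale_cutoff(self):
        res = self._result([("a", 2, 1.2, 0.1, 5.0, 0.001, 0.01)])
        assert call_de(res, fc=1.5, fc_scale="log2")[2] == set()
        assert call_de(res, fc=1.0, fc_scale="log2")[2] == {"a"}

    def test_invalid_fc_rejected(self):
        res = self._result([("a", 2, 1.0, 0.1, 5.0, 0.001, 0.01)])
        with pytest.raises(ValueError):
            call_de(res, fc=0.9, fc_scale="natural")
        with pytest.raises(ValueError):
            call_de(res, fc=-1.0, fc_scale="log2")

    def test_monotone_in_thresholds(self, rng):
        rows = [(f"f{i}", 2, float(rng.normal(0, 2)), 0.1, 0.0,
                 float(rng.uniform(0, 1)), float(rng.uniform(0, 1))) for i in range(100)]
        res = self._result(rows)
        loose = call_de(res, fdr=0.2, fc=1.2)[2]
        tight_fdr = call_de(res, fdr=0.05, fc=1.2)[2]
        tight_fc = call_de(res, fdr=0.2, fc=2.0)[2]
        assert tight_fdr <= loose and tight_fc <= loose


class TestPhasePartition:
    PHASE_MAP = {1: "initiation", 2: "progression", 3: "tolerance", 4: "tolerance"}

    def test_set_algebra_example(self):
        sets = {1: {"a", "b", "c"}, 2: {"b", "c"}, 3: {"c", "d"}}
        ph = phase_partition(sets, {1: "A", 2: "B", 3: "C"})
        assert ph.unique["C"] == {"d"}
        assert ph.shared == {"c"}

    def test_identical_sets(self):
        s = {"x", "y"}
        ph = phase_partition({1: set(s), 2: set(s), 3: set(s)},
                             {1: "A", 2: "B", 3: "C"})
        assert all(not u for u in ph.unique.values())
        assert ph.shared == s

    def test_unmapped_week_rejected(self):
        with pytest.raises(ValueError, match="week 9"):
            phase_partition({9: {"a"}}, {1: "A"})

    def test_matches_bitmask_enumeration(self, rng):
        feats = [f"f{i}" for i in range(500)]
        sets = {w: {f for f in feats if rng.random() < 0.3} for w in (1, 2, 3)}
        ph = phase_partition(sets, {1: "A", 2: "B", 3: "C"})
        # oracle: per-feature membership bitmask over the three phases
        masks = {}
        for f in feats:
            m = sum(1 << i for i, w in enumerate((1, 2, 3)) if f in sets[w])
            masks[f] = m
        for i, phase in enumerate("ABC"):
            only = {f for f, m in masks.items() if m == 1 << i}
            assert ph.unique[phase] == only
        assert ph.shared == {f for f, m in masks.items() if m == 0b111}
        venn = ph.venn_counts()
        for combo_mask in range(1, 8):
            name = "&".join(p for i, p in enumerate("ABC") if combo_mask >> i & 1)
            assert venn[name] == sum(1 for m in masks.values() if m == combo_mask)

    def test_venn_identity(self, rng):
        sets = {w: {f"f{i}" for i in rng.integers(0, 200, size=80)} for w in (1, 2, 3)}
        ph = phase_partition(sets, {1: "A", 2: "B", 3: "C"})
        union = set().union(*ph.phase_sets.values())
        assert sum(ph.venn_counts().values()) == len(union)


def test_planted_de_recovery(small_config):
    """Planted effects are called with high sensitivity and controlled FDR."""
    from tolnet.simulate import simulate_timecourse

    dataset, truth = simulate_timecourse(small_config)
    _, sets = run_de(dataset.transcript, dataset.sample_meta, mode="transcript")
    phases = phase_partition(sets, small_config.phase_map)
    called = set().union(*phases.phase_sets.values())
    planted = set().union(*truth.de_sets_by_phase.values())
    sens = len(called & planted) / len(planted)
    fdr = len(called - planted) / max(len(called), 1)
    assert sens >= 0.9
    assert fdr <= 0.1
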