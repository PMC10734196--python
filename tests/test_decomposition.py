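"""Threefold decomposition: algebraic identities, hand values, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import healthgap as hg
from conftest import cell_dataset


def two_group_binary_dataset(p1_hi=0.6, p2_hi=0.4,
                             means1=(0.1, 0.6), means2=(0.1, 0.5)):
    """Weighted cells giving exact level shares and exact within-cell outcome means.

    With a saturated binary covariate the group-specific linear-probability
    fit reproduces the cell means, so the decomposition components are exact
    hand-computable quantities: slope_g = means_g[1] - means_g[0].
    """
    def cells_for(group, p_hi, means):
        out = []
        for lvl, share, m in (("lo", 1 - p_hi, means[0]), ("hi", p_hi, means[1])):
            out.append((group, (lvl,), 1, share * m))
            out.append((group, (lvl,), 0, share * (1 - m)))
        return out

    cells = cells_for("urban", p1_hi, means1) + cells_for("rural", p2_hi, means2)
    return cell_dataset(cells, ("x",))


class TestLinearMode:
    def test_hand_computed_components_on_binary_toy(self):
        # xbar1=0.6, xbar2=0.4; slopes b1=0.5, b2=0.4; intercepts 0.1, 0.1
        ds = two_group_binary_dataset()
        res = hg.threefold_decompose(ds, mode="linear")
        assert res.E == pytest.approx(0.4 * 0.2, abs=1e-10)   # b2*(dx)
        assert res.C == pytest.approx(0.4 * 0.1, abs=1e-10)   # x2*(db)
        assert res.I == pytest.approx(0.2 * 0.1, abs=1e-10)
        assert res.B == pytest.approx(0.0, abs=1e-10)
        assert res.D == pytest.approx(res.E + res.C + res.I, abs=1e-10)

    def test_equal_coefficients_collapse_C_and_I(self):
        ds = two_group_binary_dataset(means1=(0.2, 0.7), means2=(0.2, 0.7))
        res = hg.threefold_decompose(ds, mode="linear")
        assert res.C == pytest.approx(0.0, abs=1e-12)
        assert res.I == pytest.approx(0.0, abs=1e-12)
        assert res.D == pytest.approx(res.E, abs=1e-12)

    def test_exchangeable_groups_have_null_decomposition(self):
        cfg = hg.default_config(n=30_000, seed=17)
        cfg = cfg.replace(mix_group2=dict(cfg.mix_group1),
                          beta_group2=dict(cfg.beta_group1))
        raw = hg.generate_sample(cfg)
        ds = hg.apply_exclusions(raw.drop(columns=["outcome"]), cfg.schema())
        for mode in ("linear", "logit_counterfactual"):
            res = hg.threefold_decompose(ds, mode=mode)
            for v in (res.D, res.E, res.C, res.I):
                assert v == pytest.approx(0.0, abs=0.03)


class TestIdentities:
    @pytest.mark.parametrize("viewpoint", ["group1", "group2"])
    def test_additivity(self, small_sample, viewpoint):
        _, _, ds = small_sample
        lin = hg.threefold_decompose(ds, mode="linear", viewpoint=viewpoint)
        assert lin.E + lin.C + lin.I == pytest.approx(lin.D, abs=1e-10)
        cf = hg.threefold_decompose(ds, mode="logit_counterfactual",
                                    viewpoint=viewpoint)
        assert cf.E + cf.C + cf.I == cf.D  # residual-defined, exact

    def test_gap_equals_mean_prediction_difference(self, small_sample):
        _, _, ds = small_sample
        res = hg.threefold_decompose(ds)
        assert res.D == res.mean_pred_group1 - res.mean_pred_group2

    @pytest.mark.parametrize("mode", ["linear", "logit_counterfactual"])
    def test_mean_predictions_equal_weighted_observed_prevalence(
            self, small_sample, mode):
        _, _, ds = small_sample
        res = hg.threefold_decompose(ds, mode=mode)
        w, y = ds.weights, ds.outcome
        for group, pred in (("urban", res.mean_pred_group1),
                            ("rural", res.mean_pred_group2)):
            m = ds.group_mask(group)
            observed = np.sum(w[m] * y[m]) / np.sum(w[m])
            assert pred == pytest.approx(observed, abs=1e-8)

    def test_label_swap_antisymmetry(self, small_sample):
        _, _, ds = small_sample
        swapped_schema = hg.CovariateSchema(
            covariates=ds.schema.covariates,
            group_variable=ds.schema.group_variable,
            group_levels=ds.schema.group_levels[::-1],
        )
        ds_sw = hg.AnalysisDataset(ds.data.copy(), swapped_schema)
        for mode in ("linear", "logit_counterfactual"):
            orig = hg.threefold_decompose(ds, mode=mode, viewpoint="group1")
            mirr = hg.threefold_decompose(ds_sw, mode=mode, viewpoint="group2")
            tol = 1e-9 if mode == "linear" else 1e-7
            assert mirr.D == pytest.approx(-orig.D, abs=tol)
            assert mirr.E == pytest.approx(-orig.E, abs=tol)
            assert mirr.C == pytest.approx(-orig.C, abs=tol)
            assert mirr.I == pytest.approx(-orig.I, abs=tol)


class TestDetailedContributions:
    @pytest.mark.parametrize("mode", ["linear", "logit_counterfactual"])
    @pytest.mark.parametrize("normalization", ["as_encoded", "deviation"])
    def test_parts_sum_to_aggregates(self, small_sample, mode, normalization):
        _, _, ds = small_sample
        res = hg.threefold_decompose(ds, mode=mode, normalization=normalization)
        t = res.detailed.table
        assert t.E_part.sum() == pytest.approx(res.E, abs=1e-8)
        assert t.C_part.sum() + res.detailed.constant_C == pytest.approx(
            res.C, abs=1e-8)

    def test_identical_group_means_zero_E_part(self):
        ds = two_group_binary_dataset(p1_hi=0.5, p2_hi=0.5,
                                      means1=(0.1, 0.6), means2=(0.2, 0.4))
        res = hg.threefold_decompose(ds, mode="linear")
        assert res.detailed.table.E_part.abs().max() == pytest.approx(0, abs=1e-12)

    def test_deviation_contrast_splits_binary_covariate_evenly(self, small_sample):
        _, _, ds = small_sample
        res = hg.threefold_decompose(ds, mode="linear", normalization="deviation")
        t = res.detailed.table
        media = t[t.covariate == "media_exposure"]
        assert len(media) == 2
        assert media.E_part.iloc[0] == pytest.approx(media.E_part.iloc[1],
                                                     abs=1e-12)

    def test_percent_columns_are_parts_over_gap(self, small_sample):
        _, _, ds = small_sample
        res = hg.threefold_decompose(ds)
        t = res.detailed.table
        np.testing.assert_allclose(t.E_pct, 100 * t.E_part / res.D, atol=1e-9)


class TestPercentContribution:
    @pytest.mark.parametrize(
        "part, D, expected",
        [(0.123, 0.144, 85.4), (0.018, 0.144, 12.5), (0.003, 0.144, 2.1),
         (0.035, 0.144, 24.3), (0.007, 0.144, 4.9)],
    )
    def test_published_component_shares(self, part, D, expected):
        from healthgap.descriptives import _round_half_up
        assert _round_half_up(hg.percent_contribution(part, D), 1) == expected

    def test_full_share_and_sign_preservation(self):
        assert hg.percent_contribution(0.37, 0.37) == pytest.approx(100.0)
        assert hg.percent_contribution(-0.0003, 0.144) < 0

    def test_zero_gap_is_an_error(self):
        with pytest.raises(hg.DataError):
            hg.percent_contribution(0.1, 0.0)

    def test_near_zero_gap_flags_percents_undefined(self):
        ds = two_group_binary_dataset(p1_hi=0.5, p2_hi=0.5,
                                      means1=(0.2, 0.6), means2=(0.2, 0.6))
        res = hg.threefold_decompose(ds, mode="linear")
        assert not res.percents_defined
        assert res.pct_E is None and res.detailed.constant_pct is None


class TestBootstrap:
    def test_fixed_seed_reproduces_intervals(self, small_sample):
        _, _, ds = small_sample
        kw = dict(mode="linear", B=100, detailed=False)
        a = hg.bootstrap_cis(ds, seed=5, **kw)
        b = hg.bootstrap_cis(ds, seed=5, **kw)
        assert a.ci == b.ci
        c = hg.bootstrap_cis(ds, seed=6, **kw)
        assert a.ci != c.ci

    def test_no_covariates_gives_zero_width_E_interval(self, small_sample):
        _, _, ds = small_sample
        res = hg.bootstrap_cis(ds, covariates=[], mode="linear", B=100,
                               seed=1, detailed=False)
        assert res.ci["E"] == (0.0, 0.0)
        lo, hi = res.ci["D"]
        assert lo < res.D < hi

    def test_intervals_bracket_point_estimates(self, small_sample):
        _, _, ds = small_sample
        res = hg.bootstrap_cis(ds, B=100, seed=3, detailed=True)
        for k in ("D", "E", "C"):
            lo, hi = res.ci[k]
            assert lo <= res.components()[k] <= hi
        t = res.detailed.table
        assert (t.E_low <= t.E_high).all()
        assert res.n_bootstrap_failures == 0

    def test_minimum_replicates_enforced(self, small_sample):
        _, _, ds = small_sample
        with pytest.raises(hg.DataError, match="B >= 100"):
            hg.bootstrap_cis(ds, B=50)

    def test_unstable_resampling_detected(self):
        # one rural record carries a level; most stratified resamples drop it,
        # leaving an all-zero column and a singular fit
        cells = [
            ("urban", ("a",), 1, 1.0)] * 6 + [("urban", ("b",), 0, 1.0)] * 6 + [
            ("rural", ("a",), 0, 1.0)] * 11 + [("rural", ("b",), 1, 1.0)]
        ds = cell_dataset(cells, ("x",))
        with pytest.raises(hg.UnstableResamplingError):
            hg.bootstrap_cis(ds, mode="linear", B=100, seed=0, detailed=False)
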