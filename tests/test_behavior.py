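"""Psychometric fitting, indifference-curve estimation, choice controls."""

import numpy as np
import pandas as pd
import pytest

import revpref as rp
from revpref.behavior import fit_ic, mrs, trade_off
from revpref.bundles import Bundle

GRID5 = [0.1, 0.2, 0.3, 0.4, 0.5]


def _block_with_choices(model, freqs, grid=GRID5, reps=8):
    """IP block whose per-quantity choice frequencies are forced."""
    blk = rp.make_ip_block(model, Bundle(0.4, 0.0), "A", 0.2, grid,
                           reps=reps, seed=0)
    for q, f in zip(grid, freqs):
        idx = blk.index[blk["qA1"] == q]
        n_choose = int(round(f * len(idx)))
        blk.loc[idx, "chosen"] = 0
        blk.loc[idx[:n_choose], "chosen"] = 1
    blk["chose_variable"] = blk["chosen"] == 1
    return blk


class TestPsychometric:
    def test_symmetric_frequencies_put_ip_at_middle_quantity(self, curved_model):
        blk = _block_with_choices(curved_model, [0.0, 0.0, 0.5, 1.0, 1.0])
        fit = rp.fit_psychometric(blk, n_boot=0)
        assert fit.ip == pytest.approx(0.3, abs=0.02)

    def test_fitted_curve_crosses_half_at_ip(self, curved_model):
        blk = rp.make_ip_block(curved_model, Bundle(0.4, 0.0), "A", 0.2,
                               GRID5, reps=8, seed=3)
        fit = rp.fit_psychometric(blk, n_boot=0)
        assert fit.predict(fit.ip) == pytest.approx(0.5, abs=1e-9)

    def test_ip_within_bootstrap_ci_of_analytic(self, curved_model):
        blk = rp.make_ip_block(curved_model, Bundle(0.4, 0.0), "A", 0.2,
                               GRID5, reps=8, seed=4)
        fit = rp.fit_psychometric(blk, n_boot=200, seed=1)
        lo, hi = fit.ci95
        assert lo <= blk.attrs["analytic_ip"] <= hi

    def test_perfect_separation_returns_flagged_midpoint(self, curved_model):
        blk = _block_with_choices(curved_model, [0.0, 0.0, 1.0, 1.0, 1.0])
        fit = rp.fit_psychometric(blk)
        assert fit.flagged
        assert fit.ip == pytest.approx(0.25)

    def test_all_same_choice_raises(self, curved_model):
        blk = _block_with_choices(curved_model, [1.0] * 5)
        with pytest.raises(ValueError, match="same choice"):
            rp.fit_psychometric(blk)

    def test_bootstrap_ci_covers_analytic_ip_at_nominal_rate(self, curved_model):
        # coverage of the parametric bootstrap over repeated blocks
        covered = 0
        n_runs = 60
        for s in range(n_runs):
            blk = rp.make_ip_block(curved_model, Bundle(0.4, 0.0), "A", 0.2,
                                   GRID5, reps=8, seed=100 + s)
            fit = rp.fit_psychometric(blk, n_boot=100, seed=s)
            lo, hi = fit.ci95
            covered += lo <= blk.attrs["analytic_ip"] <= hi
        assert covered / n_runs >= 0.85


class TestTradeOff:
    @pytest.mark.parametrize(
        "ref,ip,expected",
        [
            (Bundle(0.8, 0.0), Bundle(0.3, 0.3), (0.5, 0.3)),
            (Bundle(0.6, 0.1), Bundle(0.6, 0.1), (0.0, 0.0)),
            (Bundle(0.6, 0.1), Bundle(0.4, 0.3), (0.2, 0.2)),
        ],
    )
    def test_given_up_and_gained(self, ref, ip, expected):
        got = trade_off(ref, ip)
        assert got[0] == pytest.approx(expected[0])
        assert got[1] == pytest.approx(expected[1])


class TestFitIC:
    def test_linear_ips_give_diagonal_curve(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        ips = np.column_stack([x, 0.5 - x])
        ic = fit_ic(ips, n_boot=0)
        assert ic.slope == pytest.approx(-1.0, abs=1e-6)
        assert ic.c == pytest.approx(0.0, abs=1e-6)
        assert ic.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery_within_bootstrap_ci(self):
        # normalized coefficients recovered, with bootstrap CIs covering the
        # truth for the large majority of noisy replicates
        a, b, c, d = 1.0, 1.25, 0.4, 0.6
        truth = np.array([a / d, b / d, c / d])
        x = np.linspace(0.0, 0.45, 8)
        covered = 0
        n_runs = 10
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            y = (d - a * x) / (b + c * x) + rng.normal(0, 0.01, len(x))
            ic = fit_ic(np.column_stack([x, y]), n_boot=300, seed=s)
            # slope-defining coefficients are tightly identified; the
            # interaction term is weakly identified from 8 noisy points and
            # is checked through its CI coverage only
            assert ic.a == pytest.approx(truth[0], rel=0.15)
            assert ic.b == pytest.approx(truth[1], rel=0.15)
            ci = ic.coef_ci()
            covered += all(lo <= t <= hi for t, (lo, hi) in zip(truth, ci))
        assert covered >= 0.7 * n_runs

    def test_gauge_normalization_removes_scale_freedom(self):
        # identical curves written at different overall scales fit identically
        a, b, c, d = 1.0, 1.25, 0.4, 0.6
        x = np.linspace(0.0, 0.45, 8)
        y = (d - a * x) / (b + c * x)
        ic = fit_ic(np.column_stack([x, y]), n_boot=0)
        assert ic.a == pytest.approx(a / d, abs=1e-6)
        assert ic.b == pytest.approx(b / d, abs=1e-6)
        assert ic.c == pytest.approx(c / d, abs=1e-5)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_ic([(0.1, 0.4), (0.2, 0.3)])

    def test_clean_synthetic_ips_fit_tightly(self, curved_model):
        # IPs estimated from simulated psychometric blocks at the study's
        # noise level reproduce a high goodness of fit
        ref = Bundle(0.4, 0.0)
        pts, wts = [], []
        for i, qB in enumerate((0.1, 0.2, 0.3, 0.4)):
            true_ip = curved_model.indifference_qA(ref, qB)
            grid = np.clip(true_ip + np.array([-0.2, -0.1, 0, 0.1, 0.2]), 0, 0.9)
            blk = rp.make_ip_block(curved_model, ref, "A", qB, grid,
                                   reps=8, seed=50 + i)
            fit = rp.fit_psychometric(blk, n_boot=100, seed=i)
            pts.append((qB, fit.ip))
            wts.append(1.0 / max(((fit.ci95[1] - fit.ci95[0]) / 3.92) ** 2, 1e-6))
        pts.append((0.0, ref.qA))
        wts.append(np.median(wts))
        ic = fit_ic(pts, wts, n_boot=0)
        assert ic.adj_r2 > 0.9

    def test_higher_curve_means_higher_utility(self, curved_model):
        # fitted curves preserve the preference order of the generator
        ref_lo, ref_hi = Bundle(0.3, 0.0), Bundle(0.55, 0.0)
        curves = []
        for ref in (ref_lo, ref_hi):
            x = np.linspace(0.0, 0.4, 6)
            y = [curved_model.indifference_qA(ref, q) for q in x]
            curves.append(fit_ic(np.column_stack([x, y]), n_boot=0))
        qb = np.linspace(0.0, 0.4, 9)
        u_lo = curved_model.utility_xy(curves[0].qA(qb), qb)
        u_hi = curved_model.utility_xy(curves[1].qA(qb), qb)
        assert np.all(u_hi > u_lo)


class TestMRS:
    def test_symmetric_linear_curve_trades_one_for_one(self):
        x = np.linspace(0, 0.5, 6)
        ic = fit_ic(np.column_stack([x, 0.5 - x]), n_boot=0)
        for q in (0.0, 0.2, 0.4):
            assert mrs(ic, q) == pytest.approx(1.0, abs=1e-6)

    def test_piecewise_trade_off_ratios(self):
        # steep initial segment: 0.3 ml A per 0.1 ml B; flat final segment:
        # 0.1 per 0.1 -> marginal rates 3 then 1
        ref = Bundle(0.8, 0.0)
        first = Bundle(0.5, 0.1)
        giv, gain = trade_off(ref, first)
        assert giv / gain == pytest.approx(3.0)
        last = Bundle(0.4, 0.2)
        giv2, gain2 = trade_off(first, last)
        assert giv2 / gain2 == pytest.approx(1.0)

    def test_formula_matches_numeric_derivative(self):
        a, b, c, d = 1.0, 1.25, 0.4, 0.6
        x = np.linspace(0.0, 0.45, 8)
        y = (d - a * x) / (b + c * x)
        ic = fit_ic(np.column_stack([x, y]), n_boot=0)
        h = 1e-6
        for q in np.linspace(0.05, 0.4, 7):
            numeric = -(ic.qA(q + h) - ic.qA(q - h)) / (2 * h)
            assert mrs(ic, q) == pytest.approx(float(numeric), abs=1e-6)

    def test_singular_denominator_raises(self):
        ic = rp.BehavioralIC(a=1.0, b=0.2, c=-1.0)
        with pytest.raises(ZeroDivisionError):
            mrs(ic, 0.2)


class TestChoiceControls:
    def test_utility_agent_shows_reward_not_side_effects(self, curved_model):
        rng = np.random.default_rng(1)
        pairs = [(Bundle(round(a, 2), round(b, 2)), Bundle(round(c, 2), round(d, 2)))
                 for a, b, c, d in rng.uniform(0.05, 0.6, size=(12, 4))]
        blk = rp.make_choice_block(curved_model, pairs, reps=20, seed=2)
        res = rp.choice_control_variable(blk)
        assert res.converged and not res.separation
        for term in ("ref_qA", "ref_qB", "var_qA", "var_qB"):
            assert res.pvalues[term] < 0.01
        assert res.pvalues["ref_left"] > 0.01

    def test_spatial_regression_mirror_symmetry(self, curved_model):
        rng = np.random.default_rng(3)
        pairs = [(Bundle(round(a, 2), round(b, 2)), Bundle(round(c, 2), round(d, 2)))
                 for a, b, c, d in rng.uniform(0.05, 0.6, size=(12, 4))]
        blk = rp.make_choice_block(curved_model, pairs, reps=25, seed=4)
        res = rp.choice_control_spatial(blk)
        assert res.converged
        # left and right quantities push choice in opposite directions
        assert np.sign(res.params["left_qA"]) == -np.sign(res.params["right_qA"])
        assert abs(res.params["left_qA"] + res.params["right_qA"]) \
            < 0.5 * abs(res.params["left_qA"])

    def test_planted_perseveration_recovered(self, curved_model):
        rng = np.random.default_rng(5)
        pairs = [(Bundle(round(a, 2), round(b, 2)), Bundle(round(c, 2), round(d, 2)))
                 for a, b, c, d in rng.uniform(0.05, 0.6, size=(8, 4))]
        blk = rp.make_choice_block(curved_model, pairs, reps=25, seed=6)
        # replay choices with a planted tendency to repeat the previous side
        prev_left = False
        for i in blk.index:
            if rng.random() < 0.55:
                go_left = prev_left
                ref_left = blk.at[i, "ref_left"]
                blk.at[i, "chosen"] = 0 if go_left == ref_left else 1
            prev_left = bool(
                (blk.at[i, "chosen"] == 0) == blk.at[i, "ref_left"])
        blk["chose_variable"] = blk["chosen"] == 1
        blk["chose_left"] = (blk["chosen"] == 0) == blk["ref_left"]
        res = rp.choice_control_spatial(blk)
        assert res.params["prev_chose_left"] > 0
        assert res.pvalues["prev_chose_left"] < 0.01

    def test_constant_regressor_dropped(self, curved_model):
        blk = rp.make_choice_block(
            curved_model,
            [(Bundle(0.0, 0.0), Bundle(0.3, 0.2)), (Bundle(0.0, 0.0), Bundle(0.1, 0.5))],
            reps=20, seed=7)
        res = rp.choice_control_variable(blk)
        assert "ref_qA" in res.dropped and "ref_qB" in res.dropped

    def test_all_left_chooser_flags_separation(self, curved_model):
        blk = rp.make_choice_block(
            curved_model, [(Bundle(0.2, 0.1), Bundle(0.3, 0.2))], reps=30, seed=8)
        blk["chosen"] = np.where(blk["ref_left"], 0, 1)
        blk["chose_variable"] = blk["chosen"] == 1
        blk["chose_left"] = True
        res = rp.choice_control_spatial(blk)
        assert res.separation


class TestSatiety:
    def _early(self, model, seed=0):
        blk = rp.make_ip_block(model, Bundle(0.4, 0.0), "A", 0.2, GRID5,
                               reps=8, seed=seed)
        return rp.fit_psychometric(blk, n_boot=150, seed=seed)

    def test_identical_block_not_flagged(self, curved_model):
        blk = rp.make_ip_block(curved_model, Bundle(0.4, 0.0), "A", 0.2,
                               GRID5, reps=8, seed=1)
        early = rp.fit_psychometric(blk, n_boot=150, seed=1)
        assert not rp.detect_satiety(early, blk)

    def test_planted_preference_shift_flagged(self, curved_model):
        early = self._early(curved_model, seed=2)
        # late block from an agent whose currency drifted (reward B devalued)
        drifted = rp.make_utility(0.45, 1.25, 0.4, 0.05)
        late = rp.make_ip_block(drifted, Bundle(0.4, 0.0), "A", 0.2, GRID5,
                                reps=8, seed=3)
        assert rp.detect_satiety(early, late)

    def test_null_flag_rate_is_small(self, curved_model):
        early = self._early(curved_model, seed=4)
        flags = [
            rp.detect_satiety(
                early,
                rp.make_ip_block(curved_model, Bundle(0.4, 0.0), "A", 0.2,
                                 GRID5, reps=8, seed=200 + s))
            for s in range(20)
        ]
        assert np.mean(flags) <= 0.25

    def test_mismatched_design_rejected(self, curved_model):
        early = self._early(curved_model, seed=5)
        other = rp.make_ip_block(curved_model, Bundle(0.4, 0.0), "A", 0.2,
                                 [0.15, 0.25, 0.35, 0.45, 0.55], reps=8, seed=6)
        with pytest.raises(ValueError, match="match"):
            rp.detect_satiety(early, other)
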