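"""Response normalization, task-relatedness screens, and the three-test
classification."""

import numpy as np
import pandas as pd
import pytest

import revpref as rp
from revpref.bundles import Bundle
from revpref.classify import (
    EpochResponse,
    anova_two_factor,
    assign_ic_ranks,
    classify,
    epoch_response,
    model_comparison,
    regress_both,
    regress_extended,
    regress_interaction,
    regress_quadratic,
    regress_single,
    screening_pass,
    spearman_across_ics,
    task_related_sliding_anova,
    task_related_wilcoxon,
    zscore,
)
from revpref.simulate import simulate_binned_counts, simulate_neuron


def _response(z, qA, qB, value_fn=None, levels=None):
    qA = np.asarray(qA, float)
    qB = np.asarray(qB, float)
    if value_fn is None:
        value_fn = lambda a, b: a + b
    ic, within = assign_ic_ranks(qA, qB, value_fn, levels=levels)
    return EpochResponse("n", "stimulus", np.asarray(z, float), qA, qB, ic, within)


def _grid_design(n_rep=12, qs=(0.1, 0.3, 0.5, 0.7)):
    qA, qB = np.meshgrid(qs, qs)
    qA = np.tile(qA.ravel(), n_rep)
    qB = np.tile(qB.ravel(), n_rep)
    return qA, qB


class TestZscore:
    def test_matches_two_pass_oracle(self, grid_block):
        blk, _ = grid_block
        z = zscore(blk, "n0", "stimulus")
        # independent recomputation
        pre = blk["n0_pretrial"].to_numpy(float) / 1.0
        rate = blk["n0_stimulus"].to_numpy(float) / 2.0
        oracle = (rate - pre.mean()) / pre.std()
        np.testing.assert_allclose(z, oracle, atol=1e-12)

    def test_shift_by_two_sd_gives_z_two(self):
        df = pd.DataFrame({
            "n_pretrial": np.tile([8, 12], 10),  # mean 10, sd 2
            "n_go": np.full(20, 14),             # 1 s epoch at +2 sd
        })
        z = zscore(df, "n", "go")
        np.testing.assert_allclose(z, 2.0)

    def test_zero_pretrial_variance_raises(self):
        df = pd.DataFrame({"n_pretrial": np.full(10, 5), "n_go": np.arange(10)})
        with pytest.raises(ValueError, match="variance"):
            zscore(df, "n", "go")


class TestTaskRelated:
    def test_planted_gain_flags_responsive_epoch(self, grid_block):
        blk, labels = grid_block
        name = [n for n, l in labels.items() if l == "rp_positive"][0]
        flags = task_related_wilcoxon(blk, name)
        assert flags["stimulus"]

    def test_unmodulated_rarely_flagged(self, curved_model):
        blk = rp.make_choice_block(
            curved_model, [(Bundle(0, 0), Bundle(0.3, 0.2))], reps=30, seed=0)
        n_flags = 0
        for s in range(25):
            simulate_neuron(rp.NeuronSpec("unmodulated", 10, 0), blk,
                            curved_model, seed=s, name="u")
            n_flags += sum(task_related_wilcoxon(blk, "u").values())
        # 100 epoch tests at the 1% screening level
        assert n_flags <= 4

    def test_identical_counts_not_flagged(self, curved_model):
        blk = rp.make_choice_block(
            curved_model, [(Bundle(0, 0), Bundle(0.3, 0.2))], reps=10, seed=0)
        blk["c_pretrial"] = 10
        for ep in ("stimulus", "reward"):
            blk[f"c_{ep}"] = 10 * rp.EPOCH_DURATIONS[ep]
        blk["c_go"] = 10
        blk["c_choice"] = 10
        flags = task_related_wilcoxon(blk, "c")
        assert not any(flags.values())

    def test_sustained_step_flagged_transient_not(self, curved_model):
        blk = rp.make_choice_block(
            curved_model, [(Bundle(0, 0), Bundle(0.6, 0.5))], reps=15, seed=1)
        spec = rp.NeuronSpec("rp_positive", 10, 40)
        sustained = simulate_binned_counts(spec, blk, curved_model, seed=2,
                                           active_window=(0.0, 0.7))
        assert task_related_sliding_anova(sustained)
        transient = simulate_binned_counts(spec, blk, curved_model, seed=3,
                                           active_window=(0.0, 0.1))
        assert not task_related_sliding_anova(transient)

    def test_flat_neuron_rarely_flagged(self, curved_model):
        blk = rp.make_choice_block(
            curved_model, [(Bundle(0, 0), Bundle(0.3, 0.2))], reps=15, seed=4)
        spec = rp.NeuronSpec("unmodulated", 10, 0)
        flags = [
            task_related_sliding_anova(
                simulate_binned_counts(spec, blk, curved_model, seed=s))
            for s in range(20)
        ]
        assert sum(flags) <= 1


class TestScreeningRegression:
    def test_noiseless_linear_law_recovers_exact_coefficients(self):
        qA, qB = _grid_design(2)
        fit = regress_both(_response(qA + qB, qA, qB))
        assert fit.params["qA"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["qB"] == pytest.approx(1.0, abs=1e-10)
        assert screening_pass(fit)

    def test_opposite_signs_fail_screening(self):
        qA, qB = _grid_design(2)
        rng = np.random.default_rng(0)
        fit = regress_both(_response(qA - qB + rng.normal(0, 0.01, len(qA)),
                                     qA, qB))
        assert fit.pvalues["qA"] < 0.05 and fit.pvalues["qB"] < 0.05
        assert not screening_pass(fit)

    def test_degenerate_design_rejected(self):
        qA = np.tile([0.1, 0.3, 0.5], 10)
        qB = np.full(30, 0.2)
        with pytest.raises(ValueError, match="reward B"):
            regress_both(_response(qA, qA, qB))

    def test_single_reward_verdicts(self):
        qA, qB = _grid_design(6)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.3, len(qA))
        assert regress_single(_response(2 * qA + noise, qA, qB))["verdict"] \
            == "single_A_pos"
        assert regress_single(_response(-2 * qB + noise, qA, qB))["verdict"] \
            == "single_B_neg"
        # a joint coder earns no single-reward verdict
        assert regress_single(_response(qA + qB + noise, qA, qB))["verdict"] is None
        assert regress_single(_response(noise, qA, qB))["verdict"] is None


class TestSpearmanAndAnova:
    def test_strict_order_gives_rho_one(self):
        qA = np.repeat([0.1, 0.2, 0.3], 4)
        qB = np.zeros(12)
        z = np.repeat([1.0, 2.0, 3.0], 4) + np.tile([0, .01, .02, .03], 3)
        rho, p = spearman_across_ics(_response(z, qA, qB))
        assert rho > 0.9 and p < 0.01

    def test_inverse_coder_gives_negative_rho(self, ic_block, curved_model):
        blk, labels = ic_block
        name = [n for n, l in labels.items() if l == "rp_inverse"][0]
        resp = epoch_response(blk, name, "stimulus", curved_model.utility_xy,
                              levels=(0.3, 0.5, 0.7, 0.9))
        rho, p = spearman_across_ics(resp)
        assert rho < -0.3 and p < 1e-4

    def test_constant_response_fails_gracefully(self):
        qA = np.repeat([0.1, 0.2], 4)
        rho, p = spearman_across_ics(_response(np.ones(8), qA, np.zeros(8)))
        assert p == 1.0

    def test_anova_patterns(self, curved_model):
        # preference coder: significant across curves, not along them;
        # a response varying along curves breaks the pattern
        levels = (0.4, 0.8)
        on = rp.design_bundles_on_ics(curved_model, levels, (0.0, 0.2, 0.4))
        qA = np.repeat([b.qA for pts in on.values() for b in pts], 10)
        qB = np.repeat([b.qB for pts in on.values() for b in pts], 10)
        u = curved_model.utility_xy(qA, qB)
        rng = np.random.default_rng(2)
        rp_resp = _response(u + rng.normal(0, 0.05, len(u)), qA, qB,
                            curved_model.utility_xy, levels)
        p_across, p_within, p_inter = anova_two_factor(rp_resp)
        assert p_across < 0.05 and p_within > 0.05
        mixed = _response(u + qB + rng.normal(0, 0.05, len(u)), qA, qB,
                          curved_model.utility_xy, levels)
        assert anova_two_factor(mixed)[1] < 0.05

    def test_anova_null_calibration(self):
        qA, qB = _grid_design(4, qs=(0.1, 0.4))
        rng = np.random.default_rng(3)
        fp = 0
        for _ in range(30):
            resp = _response(rng.normal(size=len(qA)), qA, qB)
            p_across, p_within, _ = anova_two_factor(resp)
            fp += (p_across < 0.05)
        assert fp <= 5


class TestClassify:
    @pytest.mark.parametrize("label,expected", [
        ("rp_positive", "rp_positive"),
        ("rp_inverse", "rp_inverse"),
        ("single_A", "single_A_pos"),
        ("single_B", "single_B_pos"),
    ])
    def test_planted_class_recovery_on_grid(self, grid_block, curved_model,
                                            label, expected):
        blk, labels = grid_block
        name = [n for n, l in labels.items() if l == label][0]
        resp = epoch_response(blk, name, "stimulus", curved_model.utility_xy)
        assert classify(resp).label == expected

    def test_unmodulated_specificity(self, curved_model):
        qs = [0.1, 0.3, 0.5, 0.7]
        bundles = [Bundle(a, b) for a in qs for b in qs]
        zero = Bundle(0.0, 0.0)
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            blk = rp.make_choice_block(curved_model, [(zero, b) for b in bundles],
                                       reps=8, seed=300 + s)
            simulate_neuron(rp.NeuronSpec("unmodulated", 10, 0), blk,
                            curved_model, seed=s, name="u")
            resp = epoch_response(blk, "u", "stimulus", curved_model.utility_xy)
            hits += classify(resp).label == "unmodulated"
        assert hits / n_runs >= 0.9

    def test_rp_single_confusion_low(self, curved_model):
        # planted preference coders are almost never read as single-reward
        # coders and vice versa
        qs = [0.1, 0.3, 0.5, 0.7]
        bundles = [Bundle(a, b) for a in qs for b in qs]
        zero = Bundle(0.0, 0.0)
        confusions, total = 0, 0
        for s in range(12):
            blk = rp.make_choice_block(curved_model, [(zero, b) for b in bundles],
                                       reps=8, seed=400 + s)
            blk = rp.simulate_population(
                [rp.NeuronSpec("rp_positive", 10, 25),
                 rp.NeuronSpec("single_A", 10, 30)],
                blk, curved_model, seed=500 + s)
            for name, planted in (("n0", "rp"), ("n1", "single")):
                lab = classify(epoch_response(blk, name, "stimulus",
                                              curved_model.utility_xy)).label
                total += 1
                if planted == "rp" and lab.startswith("single"):
                    confusions += 1
                if planted == "single" and lab.startswith("rp"):
                    confusions += 1
        assert confusions / total < 0.1

    def test_label_shuffling_destroys_preference_verdicts(self, ic_block,
                                                          curved_model):
        blk, labels = ic_block
        rng = np.random.default_rng(9)
        name = [n for n, l in labels.items() if l == "rp_positive"][0]
        hits = 0
        for _ in range(10):
            resp = epoch_response(blk, name, "stimulus",
                                  curved_model.utility_xy,
                                  levels=(0.3, 0.5, 0.7, 0.9))
            perm = rng.permutation(len(resp.z))
            shuffled = EpochResponse(resp.neuron, resp.epoch, resp.z[perm],
                                     resp.qA, resp.qB, resp.ic_rank,
                                     resp.within_rank)
            hits += classify(shuffled).label in ("rp_positive", "rp_inverse")
        assert hits == 0


class TestCompanionModels:
    def test_curved_generator_rewards_interaction_model(self, curved_model):
        qA, qB = _grid_design(10)
        u = curved_model.utility_xy(qA, qB)
        rng = np.random.default_rng(4)
        resp = _response(u + rng.normal(0, 0.03, len(u)), qA, qB)
        tab = model_comparison(resp)
        assert tab.loc["interaction", "improves"]
        fit = regress_interaction(resp)
        assert np.sign(fit.params["qA_qB"]) == np.sign(0.4)

    def test_linear_generator_interaction_adds_nothing(self):
        qA, qB = _grid_design(6)
        rng = np.random.default_rng(5)
        improves = sum(
            model_comparison(
                _response(qA + qB + rng.normal(0, 0.3, len(qA)), qA, qB)
            ).loc["interaction", "improves"]
            for _ in range(15)
        )
        assert improves <= 3

    def test_exact_quadratic_law_fits_perfectly(self):
        qA, qB = _grid_design(2)
        resp = _response(qA + qB + 0.5 * qA**2 - 0.3 * qB**2, qA, qB)
        fit = regress_quadratic(resp)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_extended_regression_drops_degenerate_terms(self, ic_block):
        blk, labels = ic_block
        name = [n for n, l in labels.items() if l == "rp_positive"][0]
        fit = regress_extended(blk, name, "stimulus")
        # zero-reward reference: its quantities are constant and dropped
        assert "ref_qA" in fit.dropped and "ref_qB" in fit.dropped

    def test_extended_regression_no_spurious_history(self, curved_model):
        rng = np.random.default_rng(6)
        pairs = [(Bundle(round(a, 2), round(b, 2)), Bundle(round(c, 2), round(d, 2)))
                 for a, b, c, d in rng.uniform(0.05, 0.6, size=(8, 4))]
        blk = rp.make_choice_block(curved_model, pairs, reps=10, seed=7)
        simulate_neuron(rp.NeuronSpec("rp_positive", 10, 25), blk,
                        curved_model, seed=8, name="r")
        fit = regress_extended(blk, "r", "stimulus")
        assert fit.pvalues["prev_chose_variable"] > 0.01
        assert fit.pvalues["chose_left"] > 0.01
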