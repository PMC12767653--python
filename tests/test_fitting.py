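"""Tests of likelihood evaluation, ML fitting, BIC/R2 and calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from flashbci import (
    DegenerateDataError,
    IntegrationSpec,
    ModelParams,
    calibrate_sigma_a,
    compare_models,
    compute_bic,
    compute_r2,
    fit_model,
    negative_log_likelihood,
    response_distribution,
)
from flashbci.pipeline import _simulate_design_scale, child_seed
from flashbci.simulate import build_task_design, simulate_participant
from flashbci.types import VARIANTS, ObserverSpec

from conftest import fast_fit_config


def make_trials(responses_by_cond, task="double_flash"):
    rows = []
    for cond, responses in responses_by_cond.items():
        for r in responses:
            rows.append(
                {
                    "participant_id": "P0",
                    "group": "sighted",
                    "eye": "left",
                    "location_id": 0,
                    "task": task,
                    "condition": cond,
                    "response": r,
                }
            )
    return pd.DataFrame(rows)


class TestNegativeLogLikelihood:
    def test_single_trial_is_minus_log_prob(self, table3_params, default_spec):
        d = response_distribution("F1B2", table3_params, "averaging", default_spec)
        trials = make_trials({"F1B2": [1]})
        nll = negative_log_likelihood(
            trials, "bci", "averaging", table3_params, default_spec
        )
        assert nll == pytest.approx(-math.log(d[1]), rel=1e-9)

    def test_floor_caps_impossible_responses(self, default_spec):
        # near-noiseless segregated observer: response 3 has probability ~0
        p = ModelParams(0.0, sigma_v=0.01, sigma_a=0.2, sigma_p=4000.0, mu_p=1.5)
        trials = make_trials({"F1B0": [3]})
        nll = negative_log_likelihood(trials, "full_segregation", "averaging", p,
                                      default_spec, floor=1e-6)
        assert nll == pytest.approx(math.log(1e6), rel=1e-9)

    def test_additive_over_disjoint_trial_sets(self, table3_params, default_spec):
        a = make_trials({"F1B2": [1, 2, 2]})
        b = make_trials({"F1B1": [1, 1], "F1B2": [0]})
        both = pd.concat([a, b], ignore_index=True)
        nll = lambda t: negative_log_likelihood(
            t, "bci", "averaging", table3_params, default_spec
        )
        assert nll(both) == pytest.approx(nll(a) + nll(b), rel=1e-12)

    def test_detection_trials_use_yes_no_split(self, table3_params, default_spec):
        d = response_distribution("F1B0", table3_params, "averaging", default_spec)
        trials = make_trials({"F1B0": [0, 1, 1]}, task="detection")
        nll = negative_log_likelihood(
            trials, "bci", "averaging", table3_params, default_spec
        )
        expected = -(math.log(d[0]) + 2 * math.log(1 - d[0]))
        assert nll == pytest.approx(expected, rel=1e-9)

    def test_empty_trials_error(self, table3_params):
        with pytest.raises(ValueError):
            negative_log_likelihood(pd.DataFrame(), "bci", "averaging", table3_params)

    def test_violating_fixed_params_error(self, table3_params):
        trials = make_trials({"F1B2": [1]})
        with pytest.raises(ValueError):
            # forced fusion requires p_common = 1
            negative_log_likelihood(trials, "forced_fusion", "averaging", table3_params)


class TestBic:
    def test_zero_params_zero_loglik(self):
        assert compute_bic(0.0, 0, 10) == 0.0

    def test_arithmetic(self):
        assert compute_bic(-100.0, 3, 480) == pytest.approx(200 + 3 * math.log(480))

    def test_extra_parameter_costs_log_n(self):
        assert compute_bic(-50.0, 3, 816) - compute_bic(-50.0, 2, 816) == pytest.approx(
            math.log(816)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_bic(0.0, 1, 0)
        with pytest.raises(ValueError):
            compute_bic(0.0, -1, 10)


class TestR2:
    def _oracle_r2(self, trials, params, strategy, spec):
        """From-scratch recomputation: cell proportions vs model probabilities."""
        obs, pred = [], []
        for (eye, loc, task, cond), sub in trials.groupby(
            ["eye", "location_id", "task", "condition"]
        ):
            r = sub["response"].to_numpy()
            d = response_distribution(cond, params, strategy, spec)
            if task == "detection":
                obs += [(r == 0).mean(), (r >= 1).mean()]
                pred += [d[0], 1 - d[0]]
            else:
                obs += list(np.bincount(r, minlength=4) / len(r))
                pred += list(d)
        obs, pred = np.array(obs), np.array(pred)
        return 1 - ((obs - pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum()

    def test_matches_independent_oracle(self, table3_params, fit_spec):
        trials = _simulate_design_scale(
            table3_params, "averaging", ("detection", "double_flash"), 11
        )
        r2 = compute_r2(trials, table3_params, fit_spec, "averaging")
        assert r2 == pytest.approx(
            self._oracle_r2(trials, table3_params, "averaging", fit_spec), abs=1e-12
        )

    def test_degenerate_cells_signalled(self, table3_params, fast_spec):
        # a single 50/50 detection cell: every observed proportion equals 0.5
        trials = make_trials({"F1B0": [0, 1]}, task="detection")
        with pytest.raises(DegenerateDataError):
            compute_r2(trials, table3_params, fast_spec, "averaging")

    def test_self_consistency_high_r2(self, table3_params, fit_spec):
        """Data simulated from the model at >=50 trials/cell explains itself."""
        rng = np.random.default_rng(21)
        passes = 0
        for rep in range(5):
            rows = []
            from flashbci import simulate_responses

            for cond in ("F1B1", "F1B2"):
                for loc in range(4):
                    r = simulate_responses(cond, table3_params, "averaging", 60, rng)
                    rows += [
                        {
                            "eye": "left",
                            "location_id": loc,
                            "task": "double_flash",
                            "condition": cond,
                            "response": int(x),
                        }
                        for x in r
                    ]
            r2 = compute_r2(pd.DataFrame(rows), table3_params, fit_spec, "averaging")
            passes += r2 >= 0.8
        assert passes >= 4


class TestFitModel:
    def test_deterministic_given_seed(self, table3_params):
        trials = _simulate_design_scale(
            table3_params, "averaging", ("double_flash",), 5
        )
        cfg = fast_fit_config(seed=3, n_restarts=2, n_nodes=31)
        f1 = fit_model(trials, "bci", "averaging", cfg)
        f2 = fit_model(trials, "bci", "averaging", cfg)
        assert f1.params == f2.params
        assert f1.log_likelihood == f2.log_likelihood

    def test_bic_identity(self, table3_params):
        trials = _simulate_design_scale(table3_params, "averaging", ("double_flash",), 5)
        f = fit_model(trials, "mle", "averaging", fast_fit_config(n_restarts=2, n_nodes=31))
        assert f.bic == pytest.approx(
            compute_bic(f.log_likelihood, f.k_free, f.n_trials), rel=1e-12
        )
        assert f.k_free == VARIANTS["mle"].k_free

    def test_empty_trials_error(self):
        with pytest.raises(ValueError):
            fit_model(pd.DataFrame(), "bci", "averaging", fast_fit_config())

    def test_recovers_generating_parameters(self):
        """Median recovery error across seeded replicates stays tight."""
        true = ModelParams(0.7, sigma_v=0.35, sigma_a=0.2, sigma_p=1.5, mu_p=1.5)
        errs_p, errs_v = [], []
        for rep in range(6):
            trials = _simulate_design_scale(
                true, "averaging", ("detection", "double_flash"),
                child_seed(5, "rec", rep),
            )
            f = fit_model(trials, "bci", "averaging",
                          fast_fit_config(seed=rep, n_restarts=3))
            errs_p.append(f.params.p_common - true.p_common)
            errs_v.append(f.params.sigma_v / true.sigma_v - 1)
            # optimiser sanity: the fit is at least as likely as the truth
            nll_true = negative_log_likelihood(
                trials, "bci", "averaging", true,
                IntegrationSpec(n_nodes_per_axis=61),
            )
            assert -f.log_likelihood <= nll_true + 1e-6
        assert abs(np.median(errs_p)) <= 0.15
        assert abs(np.median(errs_v)) <= 0.25

    def test_boundary_truth_recovered(self):
        """Data generated at p_common=1 is fitted near the fusion boundary."""
        true = ModelParams(1.0, sigma_v=0.35, sigma_a=0.2, sigma_p=1.5, mu_p=1.5)
        ps = []
        for rep in range(5):
            trials = _simulate_design_scale(
                true, "averaging", ("detection", "double_flash"),
                child_seed(6, "b", rep),
            )
            f = fit_model(trials, "bci", "averaging", fast_fit_config(seed=rep))
            ps.append(f.params.p_common)
        assert np.median(ps) >= 0.9

    def test_pinned_bci_reproduces_reduced_fits(self, table3_params):
        """BCI evaluated at the reduced models' optima matches their logL."""
        trials = _simulate_design_scale(
            table3_params, "averaging", ("double_flash",), 9
        )
        cfg = fast_fit_config(n_restarts=2)
        for reduced in ("forced_fusion", "full_segregation"):
            f = fit_model(trials, reduced, "averaging", cfg)
            nll = negative_log_likelihood(
                trials, "bci", "averaging", f.params, cfg.integration
            )
            assert -nll == pytest.approx(f.log_likelihood, abs=1e-6)


class TestCompareModels:
    def test_report_structure(self, table3_params):
        trials = _simulate_design_scale(table3_params, "averaging", ("double_flash",), 4)
        report = compare_models(trials, fast_fit_config(n_restarts=1, n_nodes=31))
        assert len(report.variant_best) == 4
        bci_entries = [k for k in report.fits if k[0] == "bci"]
        assert len(bci_entries) == 3
        assert report.best_variant in report.variant_best
        assert report.best.bic == min(f.bic for f in report.variant_best.values())

    def test_bci_wins_on_intermediate_p_common(self):
        true = ModelParams(0.6, sigma_v=0.35, sigma_a=0.2, sigma_p=1.5, mu_p=1.5)
        wins = 0
        for rep in range(4):
            trials = _simulate_design_scale(
                true, "averaging", ("detection", "double_flash"),
                child_seed(7, "mr", rep),
            )
            report = compare_models(trials, fast_fit_config(seed=rep))
            wins += report.best_variant == "bci"
        assert wins >= 3

    def test_fusion_data_penalises_bci_complexity(self):
        true = ModelParams(1.0, sigma_v=0.35, sigma_a=0.2, sigma_p=1.5, mu_p=1.5)
        fusion_le_bci = 0
        for rep in range(4):
            trials = _simulate_design_scale(
                true, "averaging", ("detection", "double_flash"),
                child_seed(8, "fu", rep),
            )
            report = compare_models(trials, fast_fit_config(seed=rep))
            fusion_le_bci += (
                report.variant_best["forced_fusion"].bic
                <= report.variant_best["bci"].bic
            )
        assert fusion_le_bci >= 3


class TestCalibrateSigmaA:
    def _beep_trials(self, sigma_a, seed, responses=None):
        params = ModelParams(0.0, sigma_v=0.4, sigma_a=sigma_a, sigma_p=4000.0, mu_p=0.0)
        spec = ObserverSpec(
            participant_id="B0", group="sighted", true_params=params,
            strategy="selection",
        )
        design = build_task_design("beep_detection", seed=seed)
        trials = simulate_participant(spec, design, seed=seed + 1)
        if responses is not None:
            trials = trials.assign(response=responses(trials))
        return trials

    def test_recovers_auditory_noise(self):
        ests = [
            calibrate_sigma_a(self._beep_trials(0.2, 100 + rep), fast_fit_config())
            for rep in range(8)
        ]
        assert abs(np.median(ests) - 0.2) <= 0.05

    def test_perfect_responses_hit_lower_bound(self):
        trials = self._beep_trials(
            0.2, 7, responses=lambda t: [
                int(c[3]) for c in t["condition"]
            ],
        )
        est = calibrate_sigma_a(trials, fast_fit_config())
        assert est <= 0.011

    def test_uniform_responses_imply_high_noise(self):
        rng = np.random.default_rng(13)
        trials = self._beep_trials(
            0.2, 8, responses=lambda t: rng.integers(0, 4, size=len(t))
        )
        assert calibrate_sigma_a(trials, fast_fit_config()) >= 1.0

    def test_no_auditory_variation_error(self):
        trials = self._beep_trials(0.2, 9)
        only_b1 = trials[trials["condition"].str.endswith("B1")]
        with pytest.raises(ValueError):
            calibrate_sigma_a(only_b1, fast_fit_config())
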