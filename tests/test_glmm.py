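"""Choice GLMM: observation building, Laplace fit, likelihood-ratio tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sceneaffect import (
    ALL_BINS,
    EFFECTS,
    MalformedTrialError,
    ObserverSpec,
    RandomInterceptLogit,
    build_choice_observations,
    condition_summaries,
    design_matrix,
    fit_logistic_glmm,
    likelihood_ratio_tests,
    synth_choice_session,
)


def bernoulli_observer(sd=0.5, **kwargs):
    return ObserverSpec(decision_rule="bernoulli", intercept_sd=sd, **kwargs)


class TestBuildChoiceObservations:
    @staticmethod
    def trial_frame(high="A", low="C"):
        return pd.DataFrame(
            [
                {
                    "participant_id": "p1", "task": "valence", "trial_index": 1,
                    "img1": "A", "img2": "B", "img3": "C", "img4": "D",
                    "choice_high": high, "choice_low": low,
                }
            ]
        )

    @staticmethod
    def manifest():
        return pd.DataFrame(
            {
                "image_id": list("ABCD"),
                "length_class": ["short"] * 4,
                "angularity_class": ["low"] * 4,
                "orientation_class": ["horizontal", "vertical", "both", "diagonal"],
            }
        )

    def test_two_rows_per_trial_neutral_excluded(self):
        obs = build_choice_observations(self.trial_frame(), self.manifest())
        assert len(obs) == 2
        assert obs.loc[obs["outcome"] == 1, "image_id"].item() == "A"
        assert obs.loc[obs["outcome"] == 0, "image_id"].item() == "C"

    def test_same_high_and_low_rejected(self):
        with pytest.raises(MalformedTrialError):
            build_choice_observations(self.trial_frame(high="A", low="A"), self.manifest())

    def test_choice_outside_shown_images_rejected(self):
        with pytest.raises(MalformedTrialError):
            build_choice_observations(self.trial_frame(high="Z"), self.manifest())

    def test_unknown_image_id_rejected(self):
        man = self.manifest().iloc[:2]
        with pytest.raises(ValueError, match="absent"):
            build_choice_observations(self.trial_frame(), man)

    def test_observation_count_from_session(self, cell_manifest, small_gumbel_trials):
        obs = build_choice_observations(small_gumbel_trials, cell_manifest)
        assert len(obs) == 2 * len(small_gumbel_trials)
        assert len(small_gumbel_trials) == 12 * 120


def test_design_matrix_structure(cell_manifest):
    X, names, effect_cols = design_matrix(cell_manifest)
    assert X.shape == (480, 24)
    assert names[0] == "(Intercept)"
    # sum-to-zero: each factor's columns sum to zero over a balanced set
    np.testing.assert_allclose(X[:, 1:].sum(axis=0), 0.0, atol=1e-9)
    assert {e: len(c) for e, c in effect_cols.items()} == {
        "Orientation": 3, "Angularity": 2, "Length": 1,
        "Orientation:Angularity": 6, "Orientation:Length": 3,
        "Angularity:Length": 2, "Orientation:Angularity:Length": 6,
    }


class TestFit:
    def test_zero_variance_matches_plain_logistic(self, cell_manifest):
        obs = synth_choice_session(
            cell_manifest, bernoulli_observer(sd=0.0), n_participants=40, seed=20
        )
        fit = fit_logistic_glmm(obs)
        assert fit.sd_participant < 0.05
        X, _, _ = design_matrix(obs)
        oracle = sm.Logit(obs["outcome"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.fixed_effects, oracle.params, atol=1e-3)
        assert fit.loglik >= oracle.llf - 1e-6  # the GLMM nests the GLM

    def test_balanced_null_gives_zero_effects(self):
        # every cell 50/50 within participant: all fixed effects vanish
        rows = []
        for p in range(4):
            for b in ALL_BINS:
                for outcome in (0, 1):
                    rows.append(
                        {
                            "participant_id": f"p{p}",
                            "length_class": b.length_class,
                            "angularity_class": b.angularity_class,
                            "orientation_class": b.orientation_class,
                            "outcome": outcome,
                        }
                    )
        obs = pd.DataFrame(rows)
        fit = fit_logistic_glmm(obs)
        np.testing.assert_allclose(fit.fixed_effects, 0.0, atol=1e-6)

    def test_bernoulli_direct_recovery(self, cell_manifest):
        """Known utilities and intercept SD recovered from simulated data."""
        observer = bernoulli_observer(sd=0.5)
        names, beta_true = observer.true_fixed_effects()
        obs = synth_choice_session(cell_manifest, observer, n_participants=157, seed=21)
        fit = fit_logistic_glmm(obs)
        est = dict(zip(fit.fixed_names, fit.fixed_effects))
        truth = dict(zip(names, beta_true))
        for name in names:
            assert est[name] == pytest.approx(truth[name], abs=0.1)
        assert fit.sd_participant == pytest.approx(0.5, abs=0.15)

    def test_missing_cell_warns(self, cell_manifest):
        obs = synth_choice_session(
            cell_manifest, bernoulli_observer(), n_participants=4, seed=2
        )
        obs = obs[obs["orientation_class"] != "both"]
        with pytest.warns(UserWarning, match="design cells"):
            RandomInterceptLogit().fit(
                obs, obs["outcome"], groups=obs["participant_id"]
            )

    def test_requires_two_participants(self, cell_manifest):
        obs = synth_choice_session(
            cell_manifest, bernoulli_observer(), n_participants=1, seed=2
        )
        with pytest.raises(ValueError, match="participants"):
            fit_logistic_glmm(obs)

    def test_nested_trial_structure_runs(self, cell_manifest):
        obs = synth_choice_session(
            cell_manifest, bernoulli_observer(sd=0.4), n_participants=12, seed=22
        )
        fit = fit_logistic_glmm(obs, random_structure="participant+trial")
        assert fit.converged
        assert fit.sd_trial is not None and fit.sd_trial >= 0.0
        assert fit.sd_participant == pytest.approx(0.4, abs=0.2)
        base = fit_logistic_glmm(obs)
        # the richer model cannot have a lower maximized likelihood
        assert fit.loglik >= base.loglik - 1e-4


class TestLrt:
    def test_full_vs_itself_is_zero(self, cell_manifest):
        obs = synth_choice_session(
            cell_manifest, bernoulli_observer(), n_participants=8, seed=23
        )
        fit_a = fit_logistic_glmm(obs)
        fit_b = fit_logistic_glmm(obs, drop_effects=())
        chisq = 2.0 * (fit_a.loglik - fit_b.loglik)
        assert chisq == pytest.approx(0.0, abs=1e-6)

    def test_chisq_matches_independent_loglik_oracle(self, cell_manifest):
        """chi-square equals twice the deviance difference, with both
        log-likelihoods recomputed by numerical integration."""
        obs = synth_choice_session(
            cell_manifest, bernoulli_observer(sd=0.5), n_participants=10, seed=24
        )
        full = fit_logistic_glmm(obs)
        reduced = fit_logistic_glmm(obs, drop_effects=("Length",))
        lrt = likelihood_ratio_tests(obs, effects=("Length",), full_fit=full)
        assert lrt["chisq"].iloc[0] == pytest.approx(
            2.0 * (full.loglik - reduced.loglik), abs=1e-8
        )

        # independent oracle: Gauss-Hermite marginal likelihood at the fitted
        # parameters must be close to the Laplace value used in the test
        def gh_loglik(fit, drop):
            X, _, _ = design_matrix(obs, drop_effects=drop)
            eta0 = X @ fit.fixed_effects
            y = obs["outcome"].to_numpy()
            nodes, weights = np.polynomial.hermite_e.hermegauss(40)
            total = 0.0
            for pid in obs["participant_id"].unique():
                m = (obs["participant_id"] == pid).to_numpy()
                eta = eta0[m][:, None] + fit.sd_participant * nodes[None, :]
                ll = y[m][:, None] * eta - np.logaddexp(0.0, eta)
                lik = np.exp(ll.sum(axis=0))
                total += np.log((weights * lik).sum() / np.sqrt(2 * np.pi))
            return total

        ll_full = gh_loglik(full, ())
        ll_red = gh_loglik(reduced, ("Length",))
        assert ll_full == pytest.approx(full.loglik, abs=0.5)
        oracle_chisq = 2.0 * (ll_full - ll_red)
        assert lrt["chisq"].iloc[0] == pytest.approx(oracle_chisq, abs=1.0)

    def test_effect_table_structure(self, cell_manifest, small_gumbel_trials):
        obs = build_choice_observations(small_gumbel_trials, cell_manifest)
        lrt = likelihood_ratio_tests(obs)
        assert list(lrt["effect"]) == list(EFFECTS)
        assert list(lrt["df"]) == [3, 2, 1, 6, 3, 2, 6]
        assert (lrt["chisq"] >= 0).all()
        assert lrt["tested"].all()


class TestConditionSummaries:
    def test_proportions_and_shape(self, cell_manifest, small_gumbel_trials):
        obs = build_choice_observations(small_gumbel_trials, cell_manifest)
        cells, per_participant = condition_summaries(obs)
        assert len(cells) <= 24
        assert cells["prop_positive"].between(0, 1).all()
        assert set(per_participant["participant_id"]) == set(obs["participant_id"])

    def test_pure_cell_proportion_is_one(self):
        obs = pd.DataFrame(
            {
                "participant_id": ["p1", "p2"],
                "length_class": ["short"] * 2,
                "angularity_class": ["low"] * 2,
                "orientation_class": ["horizontal"] * 2,
                "outcome": [1, 1],
            }
        )
        cells, _ = condition_summaries(obs)
        assert cells["prop_positive"].item() == 1.0

    def test_preferred_cells_win_under_known_utilities(self, cell_manifest):
        """With the default utilities the best cell (long, low,
        horizontal) is chosen-high more often than the worst."""
        trials = synth_choice_session(
            cell_manifest, ObserverSpec(), n_participants=25, seed=25
        )
        obs = build_choice_observations(trials, cell_manifest)
        cells, _ = condition_summaries(obs)
        idx = cells.set_index(
            ["length_class", "angularity_class", "orientation_class"]
        )["prop_positive"]
        assert idx[("long", "low", "horizontal")] > 0.8
        assert idx[("short", "high", "vertical")] < 0.2
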