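"""Compound covariate classifier: centering, Gaussian posterior, LOOCV."""

import math

import numpy as np
import pandas as pd
import pytest

from arid1a_hcc.bccp import (BCCPModel, center_cohort, classify_cohort,
                             compound_covariate, fit_bccp,
                             loocv_misclassification, posterior_low)
from arid1a_hcc.errors import InsufficientOverlapError, InvalidArgumentError
from arid1a_hcc.signature import GeneSignature


def two_density_posterior(c, mu_low, mu_high, sigma, prior_low=0.5):
    """Direct evaluation of the two Gaussian densities (oracle form)."""
    from scipy.stats import norm

    f_low = prior_low * norm.pdf(c, mu_low, sigma)
    f_high = (1 - prior_low) * norm.pdf(c, mu_high, sigma)
    return f_low / (f_low + f_high)


class TestCentering:
    def test_constant_row_goes_to_zero(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc"))
        assert (center_cohort(expr).loc["g"] == 0).all()

    def test_median_arithmetic(self):
        expr = pd.DataFrame([[1.0, 2.0, 4.0]], index=["g"], columns=list("abc"))
        assert center_cohort(expr).loc["g"].tolist() == [-1.0, 0.0, 2.0]

    def test_idempotent(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (20, 9)))
        once = center_cohort(expr)
        pd.testing.assert_frame_equal(center_cohort(once), once)


def _one_gene_model():
    expr = pd.DataFrame([[-1.0, -1.2, 1.0, 1.2, -1.1, 1.1]], index=["g"],
                        columns=list("abcdef"))
    labels = pd.Series(["low", "low", "high", "high", "low", "high"],
                       index=list("abcdef"))
    sig = GeneSignature(entries=pd.DataFrame(
        {"weight": [1.0], "direction": ["up"]}, index=pd.Index(["g"], name="gene_id")))
    return expr, labels, sig


class TestFit:
    def test_separated_classes_recover_means(self):
        expr, labels, sig = _one_gene_model()
        model = fit_bccp(expr, labels, sig, low_class="low")
        assert model.mu_low == pytest.approx(-1.1)
        assert model.mu_high == pytest.approx(1.1)
        post = posterior_low(np.array([-1.1, 1.1]), model.mu_low, model.mu_high,
                             model.sigma)
        assert post[0] > 0.99 and post[1] < 0.01

    def test_posterior_closed_form_value(self):
        """mu_low 2, mu_high 0, sigma 1, c 1.5 -> logistic(1) = 0.7311."""
        p = posterior_low(1.5, 2.0, 0.0, 1.0)
        assert p == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_midpoint_posterior_is_half_and_ties_go_high(self):
        expr, labels, sig = _one_gene_model()
        model = fit_bccp(expr, labels, sig, low_class="low")
        mid = (model.mu_low + model.mu_high) / 2
        assert posterior_low(mid, model.mu_low, model.mu_high, model.sigma) \
            == pytest.approx(0.5, abs=1e-12)
        cohort = pd.DataFrame([[mid]], index=["g"], columns=["s"])
        # a sample sitting exactly at the midpoint is called signature-high
        cls = classify_cohort(model, cohort.join(
            pd.DataFrame([[mid]], index=["g"], columns=["s2"])))
        assert (cls.labels == "signature-high").all()

    def test_posteriors_sum_to_one_and_logspace_matches_densities(self, rng):
        """Log-sum-exp evaluation equals the direct two-density form wherever
        the direct form is representable, and stays finite far in the tails
        where the direct form underflows."""
        for _ in range(1000):
            mu_l, mu_h = rng.normal(0, 5, 2)
            sigma = rng.uniform(0.1, 4)
            c = rng.normal(0, 10)
            p = float(posterior_low(c, mu_l, mu_h, sigma))
            assert 0.0 <= p <= 1.0
            # log-odds closed form holds everywhere
            from scipy.special import expit

            log_odds = ((c - mu_h) ** 2 - (c - mu_l) ** 2) / (2 * sigma ** 2)
            assert p == pytest.approx(float(expit(log_odds)), abs=1e-12)
            # direct density ratio wherever it is representable
            direct = two_density_posterior(c, mu_l, mu_h, sigma)
            if np.isfinite(direct):
                assert p == pytest.approx(direct, abs=1e-12)

    def test_posterior_monotone_in_covariate(self):
        c = np.linspace(-10, 10, 201)
        p = posterior_low(c, 2.0, -1.0, 1.5)
        assert (np.diff(p) > 0).all()

    def test_scale_invariance_of_labels(self, mouse_experiment, mouse_signature):
        expr, labels, _ = mouse_experiment
        m1 = fit_bccp(expr, labels, mouse_signature, low_class="KO")
        m2 = fit_bccp(expr * 3.0, labels, mouse_signature, low_class="KO")
        l1 = classify_cohort(m1, expr).labels
        l2 = classify_cohort(m2, expr * 3.0).labels
        assert (l1 == l2).all()

    def test_missing_overlap_raises(self, toy_signature):
        expr = pd.DataFrame(np.zeros((2, 4)), index=["x", "SIGA"],
                            columns=list("abcd"))
        labels = pd.Series(["l", "l", "h", "h"], index=list("abcd"))
        with pytest.raises(InsufficientOverlapError):
            fit_bccp(expr, labels, toy_signature, low_class="l")


class TestClassify:
    def test_resubstitution_on_separable_data(self, mouse_experiment, mouse_signature):
        expr, labels, _ = mouse_experiment
        model = fit_bccp(expr, labels, mouse_signature, low_class="KO")
        cls = classify_cohort(model, expr)
        predicted = cls.labels.map({"signature-low": "KO", "signature-high": "WT"})
        assert (predicted == labels).all()
        assert cls.genes_used == len(mouse_signature)

    def test_gene_subset_recomputes_training_parameters(self, mouse_experiment,
                                                        mouse_signature):
        """Dropping genes from the cohort must reproduce a model fit on the
        reduced signature, not a rescaled full model."""
        expr, labels, _ = mouse_experiment
        model = fit_bccp(expr, labels, mouse_signature, low_class="KO")
        keep = mouse_signature.genes[: len(mouse_signature) // 2]
        reduced_sig = GeneSignature(entries=mouse_signature.entries.loc[keep])
        direct = fit_bccp(expr, labels, reduced_sig, low_class="KO")
        cls = classify_cohort(model, expr.loc[keep])
        direct_cls = classify_cohort(direct, expr.loc[keep])
        assert cls.genes_used == len(keep)
        assert np.allclose(cls.table["posterior_low"],
                           direct_cls.table["posterior_low"], atol=1e-10)

    def test_model_text_roundtrip(self, tmp_path, mouse_experiment, mouse_signature):
        expr, labels, _ = mouse_experiment
        model = fit_bccp(expr, labels, mouse_signature, low_class="KO")
        path = tmp_path / "model.txt"
        model.to_text(path)
        back = BCCPModel.from_text(path)
        assert back.mu_low == pytest.approx(model.mu_low)
        assert back.sigma == pytest.approx(model.sigma)
        cls_a = classify_cohort(model, expr)
        cls_b = classify_cohort(back, expr)
        assert np.allclose(cls_a.table["posterior_low"],
                           cls_b.table["posterior_low"], atol=1e-9)
        # the cached training data must survive the round trip too
        keep = mouse_signature.genes[:10]
        assert np.allclose(
            classify_cohort(back, expr.loc[keep]).table["posterior_low"],
            classify_cohort(model, expr.loc[keep]).table["posterior_low"],
            atol=1e-9)


class TestLOOCV:
    def test_zero_rate_on_separable_classes(self, mouse_experiment):
        expr, labels, _ = mouse_experiment
        rate, folds = loocv_misclassification(expr, labels, low_class="KO",
                                              classes=("WT", "KO"))
        assert rate == 0.0
        assert len(folds) == expr.shape[1]

    def test_matches_hand_enumerated_folds(self, rng):
        """6-sample toy set: LOOCV equals manually running each of the 6 folds."""
        expr = pd.DataFrame(rng.normal(0, 1, (40, 6)) +
                            np.concatenate([np.zeros((40, 3)),
                                            np.tile(rng.choice([-2.0, 2.0], 40)[:, None], 3)],
                                           axis=1),
                            index=[f"g{i}" for i in range(40)],
                            columns=list("abcdef"))
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=list("abcdef"))
        rate, folds = loocv_misclassification(expr, labels, low_class="B")
        from arid1a_hcc.signature import compute_gene_stats, derive_signature

        manual_errors = 0
        for held in labels.index:
            rest = labels.drop(held)
            stats = compute_gene_stats(expr[rest.index], rest)
            sig = derive_signature(stats)
            model = fit_bccp(expr[rest.index], rest, sig, low_class="B")
            c = compound_covariate(expr.loc[model.weights.index, [held]],
                                   model.weights)
            post = float(posterior_low(c.to_numpy(), model.mu_low, model.mu_high,
                                       model.sigma)[0])
            pred = "B" if post > 0.5 else "A"
            manual_errors += int(pred != labels[held])
        assert rate == pytest.approx(manual_errors / 6)

    def test_permuted_labels_give_chance_rate(self, rng):
        """Label permutation destroys the signal: mean LOOCV error near 0.5.

        Monte-Carlo error uses the empirical SD of the per-permutation rates
        (fold decisions share data and are not independent Bernoullis).
        """
        n_per = 10
        expr = pd.DataFrame(rng.normal(0, 1, (200, 2 * n_per)),
                            index=[f"g{i}" for i in range(200)],
                            columns=[f"s{i}" for i in range(2 * n_per)])
        rates = []
        for _ in range(100):
            labels = pd.Series(rng.permutation(["A"] * n_per + ["B"] * n_per),
                               index=expr.columns)
            rate, _ = loocv_misclassification(expr, labels, low_class="B")
            rates.append(rate)
        mean_rate = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
        assert abs(mean_rate - 0.5) < 3 * se

    def test_requires_three_samples(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        labels = pd.Series(["A", "B"], index=["a", "b"])
        with pytest.raises(InvalidArgumentError):
            loocv_misclassification(expr, labels, low_class="B")
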