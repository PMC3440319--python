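import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sarcsig import (
    CVConfig,
    ExpressionMatrix,
    ExpressionSimConfig,
    compare_accuracy_distributions,
    cross_cohort_evaluate,
    pca_projection,
    repeated_stratified_cv,
    simulate_expression_cohort,
)
from sarcsig.evaluate import EvaluationReport
from tests.conftest import binary_cs_hc


def make_report(acc, sens=None, spec=None):
    acc = np.asarray(acc, float)
    return EvaluationReport(
        accuracy_samples=acc,
        sensitivity_samples=np.asarray(sens if sens is not None else acc),
        specificity_samples=np.asarray(spec if spec is not None else acc),
        n_repetitions=len(acc),
        n_folds=5,
        confusion_total=(0, 0, 0, 0),
        mode="fixed_signature",
    )


class TestMetricArithmetic:
    def test_confusion_ratios(self):
        tp, fn, tn, fp = 15, 2, 10, 2
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        acc = (tp + tn) / (tp + fn + tn + fp)
        assert sens == pytest.approx(15 / 17)
        assert spec == pytest.approx(10 / 12)
        assert acc == pytest.approx(25 / 29)

    def test_report_accuracy_identity(self, planted_cohort):
        """Pooled confusion totals reproduce the mean accuracy identity."""
        m, ph, truth = planted_cohort
        sub, y = binary_cs_hc(m, ph)
        rep = repeated_stratified_cv(
            sub, y, truth.signature_genes, CVConfig(n_repetitions=20, seed=5)
        )
        tp, fp, tn, fn = rep.confusion_total
        assert tp + fp + tn + fn == rep.n_repetitions * sub.n_samples
        assert (tp + tn) / (tp + fp + tn + fn) == pytest.approx(
            rep.accuracy_samples.mean()
        )


class TestRepeatedStratifiedCV:
    def test_reproducible_bit_for_bit(self, planted_cohort):
        m, ph, truth = planted_cohort
        sub, y = binary_cs_hc(m, ph)
        cfg = CVConfig(n_repetitions=10, seed=11)
        a = repeated_stratified_cv(sub, y, truth.signature_genes, cfg)
        b = repeated_stratified_cv(sub, y, truth.signature_genes, cfg)
        np.testing.assert_array_equal(a.accuracy_samples, b.accuracy_samples)
        np.testing.assert_array_equal(a.sensitivity_samples, b.sensitivity_samples)

    def test_strongly_separable_signature_near_perfect(self):
        cfg = ExpressionSimConfig(
            n_genes=100,
            n_signature=10,
            n_per_class={"HC": 20, "US": 0, "CS": 20},
            delta=1.0,
            additive_factor=2.0,
            noise_sd=0.3,
            seed=8,
        )
        with pytest.warns(UserWarning):
            m, ph, truth = simulate_expression_cohort(cfg)
        sub, y = binary_cs_hc(m, ph)
        rep = repeated_stratified_cv(
            sub, y, truth.signature_genes, CVConfig(n_repetitions=50, seed=2)
        )
        assert rep.accuracy_samples.mean() >= 0.99

    def test_permuted_labels_chance_level_balanced(self):
        """Permutation null on balanced classes: mean accuracy ~= 0.5."""
        cfg = ExpressionSimConfig(
            n_genes=60,
            n_signature=10,
            n_per_class={"HC": 20, "US": 0, "CS": 20},
            delta=1.0,
            seed=13,
        )
        with pytest.warns(UserWarning):
            m, ph, truth = simulate_expression_cohort(cfg)
        sub, y = binary_cs_hc(m, ph)
        rep = repeated_stratified_cv(
            sub,
            y,
            truth.signature_genes,
            CVConfig(n_repetitions=200, seed=3, permute_labels=True),
        )
        assert abs(rep.accuracy_samples.mean() - 0.5) < 0.05

    def test_class_smaller_than_k_errors(self, planted_cohort):
        m, ph, truth = planted_cohort
        sub, y = binary_cs_hc(m, ph)
        with pytest.raises(ValueError, match="k <="):
            repeated_stratified_cv(
                sub, y, truth.signature_genes, CVConfig(n_folds=30, n_repetitions=2)
            )


class TestCompareAccuracyDistributions:
    def test_identical_reports(self):
        a = make_report([0.8, 0.82, 0.84, 0.81, 0.79])
        t, p, diff = compare_accuracy_distributions(a, make_report(a.accuracy_samples))
        assert diff == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_matches_hand_formula(self):
        xa = np.array([0.70, 0.72, 0.71, 0.69, 0.73])
        xb = np.array([0.60, 0.58, 0.63, 0.61, 0.59])
        t, p, diff = compare_accuracy_distributions(make_report(xa), make_report(xb))
        va, vb = xa.var(ddof=1) / 5, xb.var(ddof=1) / 5
        t_hand = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)
        assert diff == pytest.approx(xa.mean() - xb.mean())

    def test_degenerate_zero_variance(self):
        a = make_report([1.0, 1.0, 1.0])
        b = make_report([0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="degenerate"):
            _, p, diff = compare_accuracy_distributions(a, b)
        assert p == 0.0 and diff == pytest.approx(0.5)

    def test_informative_vs_random_geneset_separates(self, planted_cohort):
        m, ph, truth = planted_cohort
        sub, y = binary_cs_hc(m, ph)
        rng = np.random.default_rng(0)
        noise_genes = [g for g in m.gene_ids if g not in truth.signature_genes]
        random_set = list(rng.choice(noise_genes, size=20, replace=False))
        cfg = CVConfig(n_repetitions=50, seed=21)
        good = repeated_stratified_cv(sub, y, truth.signature_genes, cfg)
        rand = repeated_stratified_cv(sub, y, random_set, cfg)
        _, p, diff = compare_accuracy_distributions(good, rand)
        assert diff > 0
        assert p < 1e-10


class TestPCAProjection:
    def test_eigenvalue_ordering_and_bound(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(10, 15)),
                index=[f"G{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(15)],
            )
        )
        proj = pca_projection(m)
        e1, e2 = proj.eigenvalues
        assert e1 >= e2 >= 0
        assert e1 + e2 <= proj.total_variance + 1e-9

    def test_two_gene_variance_equality(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(2, 12)),
                index=["G0", "G1"],
                columns=[f"s{j}" for j in range(12)],
            )
        )
        proj = pca_projection(m)
        assert sum(proj.eigenvalues) == pytest.approx(proj.total_variance)

    def test_duplicated_sample_same_coordinates(self, rng):
        X = rng.normal(size=(6, 8))
        X[:, 7] = X[:, 6]
        m = ExpressionMatrix(
            pd.DataFrame(
                X, index=[f"G{i}" for i in range(6)], columns=[f"s{j}" for j in range(8)]
            )
        )
        proj = pca_projection(m)
        np.testing.assert_allclose(
            proj.coordinates.loc["s6"], proj.coordinates.loc["s7"], atol=1e-9
        )

    def test_three_class_separation_along_pc1(self):
        """Severity classes separate on PC1 of the signature submatrix."""
        cfg = ExpressionSimConfig(
            n_genes=100, n_signature=20, delta=1.5, noise_sd=0.5, seed=17
        )
        m, ph, truth = simulate_expression_cohort(cfg)
        proj = pca_projection(m, truth.signature_genes)
        pc1 = proj.coordinates["PC1"]
        groups = {
            c: pc1[ph.select_samples(classes=[c])] for c in ("HC", "US", "CS")
        }
        pooled_sd = np.sqrt(
            np.mean([groups[c].var(ddof=1) for c in ("HC", "CS")])
        )
        assert abs(groups["CS"].mean() - groups["HC"].mean()) > 2 * pooled_sd

    def test_too_few_genes_errors(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 5)), index=["G"], columns=list("abcde"))
        )
        with pytest.raises(ValueError):
            pca_projection(m)


class TestCrossCohort:
    def _cohort(self, seed):
        cfg = ExpressionSimConfig(
            n_genes=80,
            n_signature=10,
            n_per_class={"HC": 20, "US": 0, "CS": 20},
            delta=1.0,
            seed=seed,
        )
        with pytest.warns(UserWarning):
            m, ph, truth = simulate_expression_cohort(cfg)
        sub, y = binary_cs_hc(m, ph)
        return sub, y, truth

    def test_missing_gene_logged_and_dropped(self):
        train, y, truth = self._cohort(1)
        test_m = ExpressionMatrix(train.values.drop(index=truth.signature_genes[0]))
        with pytest.warns(UserWarning, match=truth.signature_genes[0]):
            rep = cross_cohort_evaluate(
                truth.signature_genes,
                (train, y),
                (test_m, y),
                CVConfig(n_repetitions=5, seed=0),
            )
        assert rep.transfer_accuracy is not None

    def test_too_few_shared_genes_errors(self):
        train, y, truth = self._cohort(2)
        keep = [g for g in train.gene_ids if g not in truth.signature_genes[:7]]
        test_m = ExpressionMatrix(train.values.loc[keep])
        with pytest.raises(ValueError, match="shares only"):
            cross_cohort_evaluate(
                truth.signature_genes, (train, y), (test_m, y), CVConfig(n_repetitions=2)
            )

    def test_random_test_labels_chance(self):
        train, y, truth = self._cohort(3)
        rng = np.random.default_rng(0)
        y_rand = rng.permutation(y)
        rep = cross_cohort_evaluate(
            truth.signature_genes,
            (train, y),
            (train, y_rand),
            CVConfig(n_repetitions=100, seed=4, permute_labels=True),
        )
        assert abs(rep.accuracy_samples.mean() - 0.5) < 0.06
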