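"""Model search: grid contract, LOOCV against a manual loop, omission and
tie-break rules, risk-score definition, and the odds-ratio meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import cafsig as cs
from cafsig.algorithms import (
    AlgorithmRegistry,
    ClassifierSpec,
    ComboSpec,
    ModelAdapter,
    SelectorSpec,
    default_manifest,
)
from cafsig.modelsearch import FittedCombo, gene_or_meta, loocv_auc, rank_models


def _logistic_factory():
    return ModelAdapter(LogisticRegression(C=1e3, max_iter=500), linear=True)


def test_default_manifest_has_113_combinations():
    assert len(cs.build_grid()) == 113
    assert len({c.combo_id for c in default_manifest()}) == 113


def test_custom_manifest_products():
    reg = cs.default_registry()
    one = AlgorithmRegistry(manifest=[ComboSpec("lasso+rf", "lasso", "rf")])
    assert len(cs.build_grid(one)) == 1
    six = AlgorithmRegistry(
        manifest=[ComboSpec(f"{s}+{c}", s, c)
                  for s in ("lasso", "enet") for c in ("rf", "lda", "svm")]
    )
    assert len(cs.build_grid(six)) == 6
    assert reg.manifest[0].combo_id == cs.build_grid()[0].combo_id  # deterministic


def test_manifest_with_unregistered_algorithm_errors():
    with pytest.raises(ValueError, match="unregistered"):
        AlgorithmRegistry(manifest=[ComboSpec("bogus+rf", "bogus", "rf")])


def test_loocv_matches_manual_leave_one_out_loop(rng):
    X = rng.normal(size=(12, 4))
    y = np.array([0, 1] * 6)
    auc, held = loocv_auc(_logistic_factory, X, y)
    # independent manual loop
    manual = np.empty(12)
    for i in range(12):
        mask = np.arange(12) != i
        m = LogisticRegression(C=1e3, max_iter=500).fit(X[mask], y[mask])
        manual[i] = m.decision_function(X[i:i + 1])[0]
    from sklearn.metrics import roc_auc_score

    np.testing.assert_allclose(held, manual, atol=1e-10)
    assert auc == pytest.approx(roc_auc_score(y, manual))


def test_loocv_null_auc_near_half():
    """Labels independent of features: mean LOOCV AUC over 50 seeds ~ 0.5.

    Pooled held-out scores are slightly pessimistic at very small n (the
    held-out sample's class is underrepresented in its training fold), so
    the null check uses a moderate n where that bias is negligible.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    aucs = []
    for seed in range(50):
        r = np.random.default_rng(seed)
        X = r.normal(size=(100, 5))
        y = np.array([0, 1] * 50)
        auc, _ = loocv_auc(
            lambda: ModelAdapter(LinearDiscriminantAnalysis(), linear=True), X, y
        )
        aucs.append(auc)
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_loocv_rejects_degenerate_inputs(rng):
    X = rng.normal(size=(12, 3))
    with pytest.raises(ValueError, match="both classes"):
        loocv_auc(_logistic_factory, X, np.zeros(12, dtype=int))
    with pytest.raises(ValueError, match="n >= 6"):
        loocv_auc(_logistic_factory, X[:4], np.array([0, 1, 0, 1]))
    with pytest.raises(ValueError, match="single sample"):
        loocv_auc(_logistic_factory, X, np.array([1] + [0] * 11))


def test_run_combo_omits_below_min_genes(small_cohorts, small_split):
    cohorts, truth = small_cohorts
    reg = cs.default_registry()
    reg.feature_selectors["tiny"] = SelectorSpec(
        "tiny", lambda X, y, genes, k, seed: list(genes[:4])
    )
    combo = ComboSpec("tiny+lda", "tiny", "lda")
    fitted = cs.run_combo(combo, cohorts, small_split, reg, min_genes=5, seed=0)
    assert fitted.omitted
    assert "fewer than 5 model genes" in fitted.omit_reason


def test_separable_training_reaches_loocv_auc_one(small_cohorts, small_split):
    """With a strong planted effect, lasso selection + logistic reaches a
    perfect LOOCV training AUC, confirmed by the explicit manual loop."""
    cohorts, truth = small_cohorts
    combo = ComboSpec("lasso+lasso", "lasso", "lasso")
    fitted = cs.run_combo(combo, cohorts, small_split, seed=0)
    assert not fitted.omitted
    assert fitted.group_auc["training"] == pytest.approx(1.0)


def test_permuted_labels_destroy_cohort_aucs(small_cohorts, small_split):
    """Permuting response labels removes the score-label association."""
    cohorts, truth = small_cohorts
    aucs = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        permuted = {}
        for name, c in cohorts.items():
            labels = pd.Series(r.permutation(c.labels.to_numpy()),
                               index=c.labels.index)
            permuted[name] = cs.ExpressionCohort(name, c.expr, labels)
        fitted = cs.run_combo(
            ComboSpec("ridge_rank+lda", "ridge_rank", "lda"),
            permuted, small_split, seed=seed,
        )
        aucs.extend([fitted.cohort_auc["C02"], fitted.cohort_auc["C03"]])
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)
    assert min(aucs) > 0.2 and max(aucs) < 0.8


def _combo_stub(combo_id, n_genes, tr, inte, ext):
    f = FittedCombo(combo_id, "sel", "clf")
    f.selected_genes = [f"G{i}" for i in range(n_genes)]
    f.group_auc = {"training": tr, "internal": inte, "external": ext}
    f.mean_auc = float(np.mean([tr, inte, ext]))
    return f


def test_rank_models_overall_mean_and_tiebreak():
    """Three combos with identical overall mean 0.80 rank by fewer genes,
    then combo id."""
    a = _combo_stub("a", 10, 0.9, 0.8, 0.7)
    b = _combo_stub("b", 8, 0.8, 0.8, 0.8)
    c = _combo_stub("c", 8, 0.6, 0.9, 0.9)
    lb = rank_models([a, b, c])
    assert np.allclose(lb.table["mean_auc"], 0.8)
    assert list(lb.table["combo_id"]) == ["b", "c", "a"]


def test_rank_models_excludes_omitted_and_errors_when_all_omitted():
    f = FittedCombo("x", "sel", "clf", omitted=True, omit_reason="too few")
    with pytest.raises(ValueError, match="omitted"):
        rank_models([f])
    ok = _combo_stub("ok", 6, 0.7, 0.7, 0.7)
    lb = rank_models([f, ok])
    assert list(lb.table["combo_id"]) == ["ok"]


def test_risk_score_equals_hand_computed_linear_predictor(small_cohorts, small_split):
    cohorts, truth = small_cohorts
    fitted = cs.run_combo(ComboSpec("lasso+ridge", "lasso", "ridge"),
                          cohorts, small_split, seed=0)
    std, genes = cs.standardize_cohorts(cohorts)
    X = std["C03"]
    scores = cs.risk_score(fitted, X)
    coef = fitted.model.coefficients
    manual = X[fitted.feature_space].to_numpy() @ coef + fitted.model.intercept
    np.testing.assert_allclose(scores.to_numpy(), manual, atol=1e-10)
    with pytest.raises(ValueError, match="missing model genes"):
        cs.risk_score(fitted, X.drop(columns=fitted.selected_genes[:1]))


def test_risk_score_orientation_on_planted_signal(small_cohorts, small_split):
    cohorts, truth = small_cohorts
    fitted = cs.run_combo(ComboSpec("lasso+lasso", "lasso", "lasso"),
                          cohorts, small_split, seed=0)
    std, _ = cs.standardize_cohorts(cohorts)
    scores = cs.risk_score(fitted, std["C03"])
    y = cohorts["C03"].y
    assert np.median(scores[y == 1]) > np.median(scores[y == 0])


def _binary_cohort(name, x, y):
    expr = pd.DataFrame({f"S{i}": [v] for i, v in enumerate(x)}, index=["G1"])
    labels = pd.Series(np.where(np.asarray(y) == 1, "NR", "R"), index=expr.columns)
    return cs.ExpressionCohort(name, expr, labels)


def test_meta_or_matches_cross_product_ratio():
    """Binary exposure with counts (exposed: 10 NR / 5 R; unexposed:
    2 NR / 8 R) has logistic OR equal to (10*8)/(5*2) = 8."""
    x = [1] * 15 + [0] * 10
    y = [1] * 10 + [0] * 5 + [1] * 2 + [0] * 8
    row = gene_or_meta("G1", {"A": _binary_cohort("A", x, y)}, standardize=False)
    assert row.pooled_or == pytest.approx(8.0, abs=1e-6)


def test_meta_or_single_cohort_identity_and_duplicate_shrinkage():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
    one = gene_or_meta("G1", {"A": _binary_cohort("A", x, y)})
    lo, hi = one.ci
    assert lo < one.pooled_or < hi
    two = gene_or_meta("G1", {"A": _binary_cohort("A", x, y),
                              "B": _binary_cohort("B", x, y)})
    assert two.pooled_or == pytest.approx(one.pooled_or, rel=1e-9)
    assert two.pooled_se == pytest.approx(one.pooled_se / np.sqrt(2), rel=1e-9)


def test_meta_or_flags_perfect_separation():
    x = [0.0] * 10 + [1.0] * 10
    y = [0] * 10 + [1] * 10
    good_x = np.concatenate([np.random.default_rng(1).normal(size=20)])
    good_y = (np.random.default_rng(2).random(20) > 0.5).astype(int)
    row = gene_or_meta("G1", {
        "sep": _binary_cohort("sep", x, y),
        "ok": _binary_cohort("ok", good_x, good_y),
    })
    per = row.per_cohort.set_index("cohort")
    assert bool(per.loc["sep", "excluded"])
    assert not bool(per.loc["ok", "excluded"])
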