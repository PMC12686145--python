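"""Scoring: the running-sum enrichment score against a brute-force oracle,
its invariances, the Caf.Sig identities, and the QC rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

import cafsig as cs
from cafsig.scoring import qc_filter

from .conftest import random_expression


def ssgsea_oracle(values: pd.Series, set_genes, alpha: float) -> float:
    """Independent position-by-position running-sum enumeration."""
    genes = list(values.index)
    ranks = dict(zip(genes, rankdata(values.to_numpy())))
    ordering = sorted(genes, key=lambda g: (-values[g], g))
    in_set = [g in set_genes for g in ordering]
    n_out = sum(1 for f in in_set if not f)
    w_total = sum(ranks[g] ** alpha for g, f in zip(ordering, in_set) if f)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for g, f in zip(ordering, in_set):
        if f:
            cum_in += ranks[g] ** alpha / w_total
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def test_five_gene_example_matches_term_by_term_oracle():
    expr = pd.DataFrame({"S1": [5.0, 3.0, 9.0, 1.0, 7.0]},
                        index=["G1", "G2", "G3", "G4", "G5"])
    gs = cs.GeneSet("pair", ["G3", "G2"])
    got = cs.ssgsea_score(expr, gs, alpha=0.25)["S1"]
    want = ssgsea_oracle(expr["S1"], {"G3", "G2"}, 0.25)
    assert got == pytest.approx(want, abs=1e-12)


@pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
def test_ssgsea_matches_oracle_on_random_instances(rng, alpha):
    for _ in range(30):
        n_genes = int(rng.integers(5, 100))
        n_samples = int(rng.integers(1, 10))
        expr = random_expression(rng, n_genes, n_samples)
        size = int(rng.integers(1, n_genes))
        set_genes = set(rng.choice(expr.index, size=size, replace=False))
        got = cs.ssgsea_score(expr, cs.GeneSet("s", set_genes), alpha=alpha)
        for col in expr.columns:
            assert got[col] == pytest.approx(
                ssgsea_oracle(expr[col], set_genes, alpha), abs=1e-9
            )


@pytest.mark.parametrize("transform", [lambda x: 3 * x + 2, np.exp, lambda x: x ** 3])
def test_rank_invariance_under_monotone_transform(rng, transform):
    expr = random_expression(rng, 40, 3)
    gs = cs.GeneSet("s", list(expr.index[:8]))
    base = cs.ssgsea_score(expr, gs)
    warped = expr.copy()
    warped["S001"] = transform(warped["S001"].to_numpy())
    assert cs.ssgsea_score(warped, gs)["S001"] == pytest.approx(base["S001"])


def test_top_ranked_set_scores_higher_than_bottom_ranked():
    vals = np.arange(20, 0, -1, dtype=float)
    expr = pd.DataFrame({"S1": vals}, index=[f"G{i:02d}" for i in range(20)])
    top = cs.GeneSet("top", list(expr.index[:4]))
    bottom = cs.GeneSet("bottom", list(expr.index[-4:]))
    assert (cs.ssgsea_score(expr, top)["S1"]
            > cs.ssgsea_score(expr, bottom)["S1"])


def test_scores_invariant_to_row_and_column_order(rng):
    expr = random_expression(rng, 30, 4)
    gs = cs.GeneSet("s", list(expr.index[:6]))
    base = cs.ssgsea_score(expr, gs)
    shuffled = expr.sample(frac=1, axis=0, random_state=1).sample(
        frac=1, axis=1, random_state=2
    )
    got = cs.ssgsea_score(shuffled, gs)
    pd.testing.assert_series_equal(got.sort_index(), base.sort_index())


def test_empty_intersection_raises(rng):
    expr = random_expression(rng, 10, 2)
    with pytest.raises(ValueError, match="absent"):
        cs.ssgsea_score(expr, cs.GeneSet("absent", ["X1", "X2"]))


@pytest.mark.parametrize("scorer", ["ssgsea", "mean_module"])
def test_caf_sig_antisymmetry_and_self_cancellation(rng, scorer):
    expr = random_expression(rng, 50, 5)
    up = cs.GeneSet("up", list(expr.index[:8]))
    down = cs.GeneSet("down", list(expr.index[10:18]))
    fwd = cs.caf_sig_score(expr, cs.SignaturePair(up, down), scorer=scorer)
    rev = cs.caf_sig_score(expr, cs.SignaturePair(down, up), scorer=scorer)
    np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)
    same = cs.SignaturePair(up, up, validate=False)
    zero = cs.caf_sig_score(expr, same, scorer=scorer)
    np.testing.assert_allclose(zero.to_numpy(), 0.0, atol=1e-12)


def test_caf_sig_separates_planted_signature():
    """On synthetic cohorts the planted-truth signature yields AUC >= 0.85
    for non-response at effect 1.5, n = 100."""
    cohorts, truth = cs.simulate_cohorts(
        cs.CohortSimSpec(n_cohorts=1, samples_per_cohort=100, n_genes=150,
                         n_up=15, n_down=15, effect_size=1.5, seed=21)
    )
    c = cohorts["C01"]
    sig = cs.SignaturePair(cs.GeneSet("up", truth["up_genes"]),
                           cs.GeneSet("down", truth["down_genes"]))
    score = cs.caf_sig_score(c.expr, sig)
    assert roc_auc_score(c.y, score) >= 0.85


def test_mean_module_location_invariance(rng):
    expr = random_expression(rng, 60, 4)
    gs = cs.GeneSet("s", list(expr.index[:10]))
    base = cs.mean_module_score(expr, gs, seed=5)
    shifted = expr.copy()
    shifted["S001"] = shifted["S001"] + 7.5
    got = cs.mean_module_score(shifted, gs, seed=5)
    assert got["S001"] == pytest.approx(base["S001"], abs=1e-9)


def test_mean_module_zero_when_set_covers_matrix(rng):
    expr = random_expression(rng, 30, 3)
    gs = cs.GeneSet("all", list(expr.index))
    score = cs.mean_module_score(expr, gs, n_control=30, seed=0)
    np.testing.assert_allclose(score.to_numpy(), 0.0, atol=1e-9)


def test_partition_signature_direction_and_ties():
    expr = pd.DataFrame(
        {"S1": [8.0, 6.0, 5.0], "S2": [8.0, 6.0, 5.0],
         "S3": [6.0, 8.0, 5.0], "S4": [6.0, 8.0, 5.0]},
        index=["Gup", "Gdown", "Gtie"],
    )
    labels = pd.Series(["NR", "NR", "R", "R"], index=expr.columns)
    sig = cs.partition_signature(expr, labels, ["Gup", "Gdown", "Gtie", "Gmissing"])
    assert sig.up.genes == frozenset({"Gup"})
    assert sig.down.genes == frozenset({"Gdown"})


def test_partition_recovers_planted_truth():
    cohorts, truth = cs.simulate_cohorts(
        cs.CohortSimSpec(n_cohorts=1, samples_per_cohort=200, n_genes=100,
                         n_up=20, n_down=20, effect_size=1.5, seed=17)
    )
    c = cohorts["C01"]
    candidates = truth["up_genes"] + truth["down_genes"]
    sig = cs.partition_signature(c.expr, c.labels, candidates)
    correct = len(sig.up.genes & set(truth["up_genes"])) + len(
        sig.down.genes & set(truth["down_genes"])
    )
    assert correct >= 0.95 * len(candidates)


def test_qc_filter_boundary_and_rule_attribution():
    cells = pd.DataFrame(
        {
            "cell_id": ["umi", "glow", "ghigh", "mito", "edge", "clean"],
            "umi_count": [40001, 10000, 10000, 10000, 10000, 9000],
            "n_genes": [2000, 499, 5001, 2000, 500, 2500],
            "pct_mito": [5.0, 5.0, 5.0, 20.5, 20.0, 3.0],
        }
    )
    retained, log = qc_filter(cells)
    assert sorted(retained["cell_id"]) == ["clean", "edge"]
    rules = dict(zip(log["cell_id"], log["rules"]))
    assert rules == {"umi": "umi_high", "glow": "gene_low",
                     "ghigh": "gene_high", "mito": "mito_high"}
    # retained and removed partition the input
    assert set(retained["cell_id"]) | set(log["cell_id"]) == set(cells["cell_id"])
    assert set(retained["cell_id"]) & set(log["cell_id"]) == set()


def test_qc_filter_negative_values_raise():
    cells = pd.DataFrame({"cell_id": ["a"], "umi_count": [-1],
                          "n_genes": [100], "pct_mito": [1.0]})
    with pytest.raises(ValueError, match="negative"):
        qc_filter(cells)
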