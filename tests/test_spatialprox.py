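"""Spatial proximity: k-distance geometry, per-section ranking, robust rank
aggregation against closed forms and a Monte-Carlo oracle, and the
responder/non-responder contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import cafsig as cs
from cafsig.spatialprox import (
    build_kdistance_table,
    compare_groups,
    k_distance,
    rank_by_proximity,
    rank_matrix,
    rra_aggregate,
)


def _table(points):
    """points: list of (x, y, cell_type); single section 'S', group 'R'."""
    return pd.DataFrame(
        [(f"c{i}", x, y, t, "S", "R") for i, (x, y, t) in enumerate(points)],
        columns=["cell_id", "x", "y", "cell_type", "section_id", "group"],
    )


def test_hand_computed_k_distance():
    t = _table([(0, 0, "ref"), (1, 0, "tgt"), (2, 0, "tgt"), (3, 0, "tgt")])
    d = k_distance(t, "S", "ref", "tgt", k=2)
    assert d.iloc[0] == pytest.approx(1.5)


def test_coincident_targets_give_zero():
    t = _table([(5, 5, "ref"), (5, 5, "tgt"), (5, 5, "tgt")])
    assert k_distance(t, "S", "ref", "tgt", k=2).iloc[0] == 0.0


def test_translation_rotation_invariance_and_homogeneity(rng):
    pts = rng.uniform(0, 10, size=(30, 2))
    types = ["ref"] * 10 + ["tgt"] * 20
    base = k_distance(
        _table([(x, y, t) for (x, y), t in zip(pts, types)]), "S", "ref", "tgt", k=4
    )
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([100.0, -40.0])
    got = k_distance(
        _table([(x, y, t) for (x, y), t in zip(moved, types)]), "S", "ref", "tgt", k=4
    )
    np.testing.assert_allclose(got.to_numpy(), base.to_numpy(), rtol=1e-9)
    doubled = k_distance(
        _table([(2 * x, 2 * y, t) for (x, y), t in zip(pts, types)]),
        "S", "ref", "tgt", k=4,
    )
    np.testing.assert_allclose(doubled.to_numpy(), 2 * base.to_numpy(), rtol=1e-9)


def test_self_type_excludes_own_cell():
    t = _table([(0, 0, "ref"), (1, 0, "ref"), (3, 0, "ref")])
    d = k_distance(t, "S", "ref", "ref", k=1)
    np.testing.assert_allclose(d.to_numpy(), [1.0, 1.0, 2.0])


def test_too_few_targets_returns_missing():
    t = _table([(0, 0, "ref"), (1, 0, "tgt")])
    assert k_distance(t, "S", "ref", "tgt", k=5) is None


def test_rank_by_proximity_orders_medians_and_averages_ties():
    rows = []
    for tt, dists in [("A", [1.0, 1.0]), ("B", [5.0, 5.0]), ("C", [2.0, 2.0])]:
        for d in dists:
            rows.append(("S", "R", "c", tt, d, 2))
    kt = pd.DataFrame(rows, columns=["section_id", "group", "ref_cell",
                                     "target_type", "k_distance", "k"])
    ranks = rank_by_proximity(kt, "S")
    assert ranks.to_dict() == {"A": 1.0, "C": 2.0, "B": 3.0}
    kt.loc[kt["target_type"] == "C", "k_distance"] = 1.0  # tie with A
    ranks = rank_by_proximity(kt, "S")
    assert ranks["A"] == ranks["C"] == 1.5


def test_rra_single_section_preserves_ordering():
    ranks = pd.DataFrame({"A": [1.0], "B": [2.0], "C": [3.0]}, index=["S1"])
    out = rra_aggregate(ranks)
    assert list(out["target_type"]) == ["A", "B", "C"]


def test_rra_closed_form_binomial_tail():
    """A type ranked in the top decile of all 5 sections: rho is the k=5
    binomial tail 0.1^5; the correction multiplies by the number of types."""
    n_types = 10
    ranks = pd.DataFrame({f"T{i}": [float(i)] * 5 for i in range(1, n_types + 1)},
                         index=[f"S{j}" for j in range(5)])
    out = rra_aggregate(ranks).set_index("target_type")
    assert out.loc["T1", "rho"] == pytest.approx(0.1 ** 5, rel=1e-12)
    assert out.loc["T1", "rho_corrected"] == pytest.approx(n_types * 0.1 ** 5, rel=1e-12)


def rra_rho_mc_oracle(norm_ranks_sorted, n_draws, rng):
    """Monte-Carlo rho: for each k, the share of simulated uniform vectors
    whose k-th order statistic is at or below the observed one."""
    m = len(norm_ranks_sorted)
    sims = np.sort(rng.random((n_draws, m)), axis=1)
    fracs = (sims <= np.asarray(norm_ranks_sorted)[None, :]).mean(axis=0)
    return float(fracs.min())


def test_rra_rho_matches_monte_carlo_oracle(rng):
    for _ in range(5):
        m, n_types = int(rng.integers(3, 8)), int(rng.integers(3, 9))
        mat = np.column_stack([rng.permuted(np.arange(1, n_types + 1.0))
                               for _ in range(m)]).T
        ranks = pd.DataFrame(mat, columns=[f"T{t}" for t in range(n_types)])
        out = rra_aggregate(ranks).set_index("target_type")
        for t in out.index:
            r_sorted = np.sort(ranks[t].to_numpy()) / n_types
            mc = rra_rho_mc_oracle(r_sorted, 100_000, rng)
            se = max(np.sqrt(mc * (1 - mc) / 100_000), 1e-6)
            assert abs(out.loc[t, "rho"] - mc) <= 3 * se + 1e-3


def test_rra_invariant_to_section_order(rng):
    mat = np.column_stack([rng.permuted(np.arange(1, 6.0)) for _ in range(4)]).T
    ranks = pd.DataFrame(mat, columns=list("ABCDE"), index=list("wxyz"))
    out1 = rra_aggregate(ranks)
    out2 = rra_aggregate(ranks.sample(frac=1, random_state=9))
    pd.testing.assert_frame_equal(out1, out2)


def test_missing_type_gets_worst_rank(caplog):
    rows = [("S1", "R", "c", "A", 1.0, 2), ("S1", "R", "c", "B", 2.0, 2),
            ("S2", "R", "c", "A", 1.0, 2), ("S2", "R", "c", "B", 2.0, 2),
            ("S1", "R", "c", "C", 3.0, 2)]  # C missing in S2
    kt = pd.DataFrame(rows, columns=["section_id", "group", "ref_cell",
                                     "target_type", "k_distance", "k"])
    rm = rank_matrix(kt)
    assert rm.loc["S2", "C"] == 3.0


def test_compare_groups_detects_planted_contrast():
    spec = cs.SpatialSimSpec(
        n_sections_responder=3, n_sections_nonresponder=3,
        n_reference_cells=10, cells_per_type=80,
        target_types=[cs.TargetTypeSpec("near_nr", 150.0, 30.0),
                      cs.TargetTypeSpec("ctrl", 90.0, 90.0)],
        seed=5,
    )
    table, _ = cs.simulate_sections(spec)
    kt = build_kdistance_table(table, "iCAF", k=10)
    res = compare_groups(kt, "near_nr")
    assert res["median_nonresponder"] < res["median_responder"]
    assert res["p_value"] < 0.05


def test_compare_groups_null_is_calm():
    """With identical dispersions in both groups the rank-sum test rejects
    at roughly its nominal rate."""
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        spec = cs.SpatialSimSpec(
            n_sections_responder=2, n_sections_nonresponder=2,
            n_reference_cells=8, cells_per_type=40,
            target_types=[cs.TargetTypeSpec("T", 60.0, 60.0),
                          cs.TargetTypeSpec("U", 60.0, 60.0)],
            seed=100 + seed,
        )
        table, _ = cs.simulate_sections(spec)
        kt = build_kdistance_table(table, "iCAF", k=5)
        if compare_groups(kt, "T")["p_value"] < 0.05:
            hits += 1
    assert hits / n_rep <= 0.2  # sections share parents, mild correlation allowed
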