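"""Spatial proximity of cell types to a reference type.

For every reference cell in a tissue section, the k-distance to a target
type is the mean Euclidean distance to its k nearest target-type cells
within the same section (cross-section geometry does not exist).  Target
types are ranked per section by their median k-distance (1 = nearest), and
the per-section rankings are integrated with robust rank aggregation (RRA):
for each type, ranks are normalized to (0, 1], sorted, and the rho score is
the minimum over k of the binomial tail probability that at least k of m
uniform draws fall at or below the k-th smallest normalized rank; a small
rho flags a type consistently ranked nearer than chance.  The minimum-p
statistic is Bonferroni-corrected by the number of types compared.

:func:`compare_groups` contrasts pooled per-cell k-distances between
responder and non-responder sections with a two-sided rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import binom, mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "k_distance",
    "build_kdistance_table",
    "rank_by_proximity",
    "rank_matrix",
    "rra_aggregate",
    "compare_groups",
]

_SPATIAL_COLS = ("cell_id", "x", "y", "cell_type", "section_id", "group")


def _check_table(table: pd.DataFrame) -> None:
    missing = set(_SPATIAL_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"spatial table missing columns: {sorted(missing)}")


def k_distance(
    table: pd.DataFrame,
    section: str,
    reference_type: str,
    target_type: str,
    k: int = 10,
) -> pd.Series | None:
    """Per-reference-cell mean distance to the k nearest target-type cells.

    Returns a Series indexed by reference cell id, or ``None`` (with a
    warning) when the section holds fewer than k target cells.  When the
    reference and target types coincide, each cell is excluded from its own
    neighbour set.
    """
    _check_table(table)
    sec = table[table["section_id"] == section]
    ref = sec[sec["cell_type"] == reference_type]
    tgt = sec[sec["cell_type"] == target_type]
    if ref.empty:
        raise ValueError(
            f"section {section!r} has no cells of reference type {reference_type!r}"
        )
    same = reference_type == target_type
    n_avail = len(tgt) - (1 if same else 0)
    if n_avail < k:
        logger.warning(
            "section %s: only %d %s cells available (k=%d); k-distance missing",
            section, n_avail, target_type, k,
        )
        return None
    tree = cKDTree(tgt[["x", "y"]].to_numpy(dtype=float))
    q = k + 1 if same else k
    dist, _ = tree.query(ref[["x", "y"]].to_numpy(dtype=float), k=q)
    dist = np.atleast_2d(dist)
    if same:
        dist = dist[:, 1:]  # drop the self-match (distance 0)
    return pd.Series(dist.mean(axis=1), index=ref["cell_id"].to_numpy(), name=target_type)


def build_kdistance_table(
    table: pd.DataFrame,
    reference_type: str,
    target_types: list[str] | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Long-format k-distance table over all sections and target types.

    Columns: section_id, group, ref_cell, target_type, k_distance, k.
    (section, type) pairs with fewer than k target cells are absent (logged).
    """
    _check_table(table)
    if target_types is None:
        target_types = sorted(set(table["cell_type"]) - {reference_type})
    if not target_types:
        raise ValueError("no target types to measure")
    rows = []
    for section, sec in table.groupby("section_id", sort=True):
        group = sec["group"].iloc[0]
        if (sec["cell_type"] == reference_type).sum() == 0:
            logger.warning("section %s has no reference cells; skipped", section)
            continue
        for tt in target_types:
            d = k_distance(table, section, reference_type, tt, k=k)
            if d is None:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "section_id": section,
                        "group": group,
                        "ref_cell": d.index,
                        "target_type": tt,
                        "k_distance": d.to_numpy(),
                        "k": k,
                    }
                )
            )
    if not rows:
        raise ValueError("no (section, target type) pair had enough cells")
    return pd.concat(rows, ignore_index=True)


def rank_by_proximity(ktable: pd.DataFrame, section: str) -> pd.Series:
    """Rank target types in one section by median k-distance (1 = nearest).

    Ties receive average ranks.
    """
    sec = ktable[ktable["section_id"] == section]
    if sec.empty:
        raise ValueError(f"no k-distance entries for section {section!r}")
    med = sec.groupby("target_type")["k_distance"].median().sort_index()
    if len(med) < 2:
        raise ValueError(f"section {section!r} has fewer than 2 target types")
    ranks = pd.Series(rankdata(med.to_numpy()), index=med.index, name=section)
    return ranks


def rank_matrix(ktable: pd.DataFrame) -> pd.DataFrame:
    """Sections × types matrix of proximity ranks.

    Types missing from a section (too few cells) are assigned that
    section's worst rank (the number of types), a conservative choice that
    keeps the number of rank lists constant for RRA.
    """
    all_types = sorted(ktable["target_type"].unique())
    rows = {}
    for section in sorted(ktable["section_id"].unique()):
        try:
            r = rank_by_proximity(ktable, section)
        except ValueError as exc:
            logger.warning("section %s skipped in rank matrix: %s", section, exc)
            continue
        row = r.reindex(all_types)
        n_missing = row.isna().sum()
        if n_missing:
            logger.warning(
                "section %s: %d missing type(s) assigned worst rank %d",
                section, n_missing, len(all_types),
            )
            row = row.fillna(float(len(all_types)))
        rows[section] = row
    if not rows:
        raise ValueError("no section produced a usable ranking")
    return pd.DataFrame(rows).T[all_types]


def rra_aggregate(ranks: pd.DataFrame) -> pd.DataFrame:
    """Robust rank aggregation over per-section rankings.

    ``ranks``: rows = sections, columns = types, entries = within-section
    rank (1 = nearest).  Per type, normalized ranks r = rank / n_types are
    sorted ascending and rho = min over k of
    P(at least k of m uniforms <= r_(k)) = sum_{j>=k} C(m,j) r_(k)^j (1-r_(k))^(m-j);
    the Bonferroni-corrected score is min(1, n_types * rho).  The result is
    ordered ascending by rho (position 1 = consistently nearest).
    """
    if ranks.empty:
        raise ValueError("rank matrix is empty")
    n_types = ranks.shape[1]
    m = ranks.shape[0]
    if n_types == 1:
        logger.warning("single type: RRA result is trivial")
    rows = []
    for t in ranks.columns:
        r = np.sort(ranks[t].to_numpy(dtype=float)) / n_types
        ks = np.arange(1, m + 1)
        # P(Binomial(m, r_(k)) >= k) for each order statistic
        p = binom.sf(ks - 1, m, r)
        rho = float(p.min())
        rows.append({"target_type": t, "rho": rho,
                     "rho_corrected": float(min(1.0, n_types * rho))})
    out = pd.DataFrame(rows).sort_values(
        by=["rho", "target_type"], kind="mergesort"
    ).reset_index(drop=True)
    out["position"] = np.arange(1, len(out) + 1)
    return out


def compare_groups(
    ktable: pd.DataFrame,
    target_type: str,
) -> dict:
    """Responder vs non-responder contrast of pooled per-cell k-distances.

    Returns medians per group, their difference (non-responder −
    responder), the two-sided rank-sum (Mann–Whitney) statistic and p-value.
    """
    sub = ktable[ktable["target_type"] == target_type]
    d_r = sub.loc[sub["group"] == "R", "k_distance"].to_numpy()
    d_nr = sub.loc[sub["group"] == "NR", "k_distance"].to_numpy()
    if len(d_r) == 0 or len(d_nr) == 0:
        raise ValueError(
            f"both groups need k-distances for type {target_type!r} "
            f"(R: {len(d_r)}, NR: {len(d_nr)})"
        )
    stat, p = mannwhitneyu(d_nr, d_r, alternative="two-sided")
    med_r, med_nr = float(np.median(d_r)), float(np.median(d_nr))
    return {
        "target_type": target_type,
        "median_responder": med_r,
        "median_nonresponder": med_nr,
        "median_difference": med_nr - med_r,
        "statistic": float(stat),
        "p_value": float(p),
        "n_responder": int(len(d_r)),
        "n_nonresponder": int(len(d_nr)),
    }
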