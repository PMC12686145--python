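"""Single-sample gene-set scoring, the Caf.Sig score, and single-cell QC.

The central statistic is a rank-weighted running-sum enrichment score
computed per sample (the ssGSEA statistic): genes are ordered by expression,
and the score is the summed difference between the weighted in-set ECDF and
the uniform out-of-set ECDF along that ordering.  The Caf.Sig score of a
signature pair is the enrichment of the up-regulated set minus that of the
down-regulated set, oriented so that higher values mark predicted
non-response to immune checkpoint inhibition.

A mean-module scorer (average of set genes minus average of
expression-matched controls) is provided as an independent, simpler scorer
for concordance checks, and :func:`qc_filter` applies the single-cell QC
rules (UMI > 40000, genes < 500, genes > 5000, mito% > 20 ⇒ remove).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "SignaturePair",
    "QC_UMI_MAX",
    "QC_GENES_MIN",
    "QC_GENES_MAX",
    "QC_MITO_MAX",
    "ssgsea_score",
    "mean_module_score",
    "caf_sig_score",
    "partition_signature",
    "qc_filter",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes) -> None:
        genes = frozenset(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SignaturePair:
    """Up- and down-regulated gene sets defining a two-sided signature."""

    up: GeneSet
    down: GeneSet
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            overlap = self.up.genes & self.down.genes
            if overlap:
                raise ValueError(
                    f"up and down sets overlap: {sorted(overlap)[:5]}"
                    + ("..." if len(overlap) > 5 else "")
                )


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Per-sample rank-weighted running-sum enrichment score.

    For each sample, genes are ordered by expression descending (ties broken
    deterministically by gene id; rank *values* use average ranks).  Walking
    down the ordering, the in-set ECDF steps by rank^alpha normalized over
    in-set genes and the out-of-set ECDF steps uniformly; the score is the
    sum of (in-set ECDF − out-of-set ECDF) over all positions.

    With ``normalize=True`` all scores are divided by the global max − min
    across samples (the cross-sample range normalization of the original
    implementation).

    Parameters
    ----------
    expr : DataFrame, genes × samples (log2 scale assumed but not required —
        the statistic is rank-based).
    gene_set : the set to score; must intersect the matrix genes and leave
        at least one gene outside the set.
    alpha : rank-weighting exponent (0 = unweighted Kolmogorov–Smirnov walk).
    """
    if expr.shape[0] < 2:
        raise ValueError("expression matrix must contain at least 2 genes")
    genes = expr.index.to_numpy(dtype=str)
    mask = expr.index.isin(gene_set.genes).astype(bool)
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no genes with the expression matrix"
        )
    n_out = len(genes) - n_in
    if n_out == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} covers every gene in the matrix; "
            "the out-of-set ECDF is undefined"
        )

    scores = np.empty(expr.shape[1])
    values = expr.to_numpy(dtype=float)
    for j in range(expr.shape[1]):
        x = values[:, j]
        if np.ptp(x) == 0:
            logger.warning(
                "sample %r is constant; ssGSEA resolved by the tie rule",
                str(expr.columns[j]),
            )
        r = rankdata(x)  # ascending, average ranks on ties
        order = np.lexsort((genes, -x))  # expression desc, then gene id
        in_ord = mask[order]
        w = np.where(in_ord, r[order] ** alpha, 0.0)
        cdf_in = np.cumsum(w) / w.sum()
        cdf_out = np.cumsum(~in_ord) / n_out
        scores[j] = float(np.sum(cdf_in - cdf_out))

    out = pd.Series(scores, index=expr.columns, name=gene_set.name)
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    out.attrs.update({"scorer": "ssgsea", "alpha": alpha, "normalize": normalize})
    return out


def mean_module_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    n_control: int = 100,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.Series:
    """Mean set expression minus mean of expression-matched control genes.

    Genes are binned into ``n_bins`` equal-count bins of average expression;
    for each set gene, ``n_control`` control genes are sampled (seeded,
    without replacement, clamped to the bin size with a warning) from its
    bin.  The score is mean(set genes) − mean(sampled controls), per sample.
    """
    present = [g for g in expr.index if g in gene_set.genes]
    if not present:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no genes with the expression matrix"
        )
    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=1)
    n_bins = min(n_bins, len(avg))
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    controls: list[str] = []
    for g in present:
        pool = bins.index[bins == bins[g]].to_numpy(dtype=str)
        take = min(n_control, len(pool))
        if take < n_control:
            logger.warning(
                "control pool for gene %s has only %d genes (requested %d); clamped",
                g, len(pool), n_control,
            )
        controls.extend(rng.choice(np.sort(pool), size=take, replace=False))
    control_genes = sorted(set(controls))
    score = expr.loc[present].mean(axis=0) - expr.loc[control_genes].mean(axis=0)
    score.name = gene_set.name
    score.attrs.update(
        {"scorer": "mean_module", "n_control": n_control, "n_bins": n_bins, "seed": seed}
    )
    return score


_SCORERS = {"ssgsea": ssgsea_score, "mean_module": mean_module_score}


def caf_sig_score(
    expr: pd.DataFrame,
    signature: SignaturePair,
    scorer: str = "ssgsea",
    **scorer_params,
) -> pd.Series:
    """Caf.Sig score: scorer(up-regulated set) − scorer(down-regulated set).

    Both sets are scored with the same scorer and parameters; higher values
    indicate predicted non-response.
    """
    if callable(scorer):
        fn = scorer
        name = getattr(scorer, "__name__", "custom")
    else:
        try:
            fn = _SCORERS[scorer]
        except KeyError:
            raise ValueError(
                f"unknown scorer {scorer!r}; available: {sorted(_SCORERS)}"
            ) from None
        name = scorer
    score = fn(expr, signature.up, **scorer_params) - fn(expr, signature.down, **scorer_params)
    score.name = "caf_sig"
    score.attrs.update({"scorer": name, "orientation": "higher = non-responder"})
    return score


def partition_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    genes,
    up_name: str = "up_in_nonresponders",
    down_name: str = "down_in_nonresponders",
) -> SignaturePair:
    """Split candidate genes into up/down sets by non-responder mean contrast.

    A gene goes to the up set when its mean expression in non-responders
    exceeds that in responders, to the down set when lower; exact ties are
    excluded (logged), and candidates absent from the matrix are skipped
    with a warning.
    """
    labels = labels.reindex(expr.columns)
    nr = labels == "NR"
    r = labels == "R"
    if not nr.any() or not r.any():
        raise ValueError("both label groups (R and NR) must be non-empty")
    up: list[str] = []
    down: list[str] = []
    for g in genes:
        if g not in expr.index:
            logger.warning("candidate gene %s absent from matrix; skipped", g)
            continue
        diff = expr.loc[g, nr.to_numpy()].mean() - expr.loc[g, r.to_numpy()].mean()
        if diff > 0:
            up.append(g)
        elif diff < 0:
            down.append(g)
        else:
            logger.info("gene %s has zero group difference; excluded", g)
    if not up or not down:
        raise ValueError(
            f"signature partition degenerate: {len(up)} up / {len(down)} down genes"
        )
    return SignaturePair(GeneSet(up_name, up), GeneSet(down_name, down))


# Single-cell QC thresholds; all removal comparisons are strict.
QC_UMI_MAX = 40_000
QC_GENES_MIN = 500
QC_GENES_MAX = 5_000
QC_MITO_MAX = 20.0

_QC_CHECKS = (
    ("umi_high", lambda c: c["umi_count"] > QC_UMI_MAX),
    ("gene_low", lambda c: c["n_genes"] < QC_GENES_MIN),
    ("gene_high", lambda c: c["n_genes"] > QC_GENES_MAX),
    ("mito_high", lambda c: c["pct_mito"] > QC_MITO_MAX),
)


def qc_filter(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the single-cell QC rules; return (retained, removal_log).

    A cell is removed iff UMI > 40000 OR genes < 500 OR genes > 5000 OR
    mito% > 20 (all strict).  The removal log has one row per removed cell
    with the triggering rule name(s), semicolon-joined.
    """
    required = {"cell_id", "umi_count", "n_genes", "pct_mito"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    for col in ("umi_count", "n_genes", "pct_mito"):
        if (cells[col] < 0).any():
            bad = cells.loc[cells[col] < 0, "cell_id"].iloc[0]
            raise ValueError(f"negative {col} for cell {bad!r}")

    rule_hits = {name: fn(cells).to_numpy() for name, fn in _QC_CHECKS}
    any_hit = np.logical_or.reduce(list(rule_hits.values()))
    log_rows = []
    for i in np.flatnonzero(any_hit):
        rules = [name for name in rule_hits if rule_hits[name][i]]
        log_rows.append((cells["cell_id"].iloc[i], ";".join(rules)))
    removal_log = pd.DataFrame(log_rows, columns=["cell_id", "rules"])
    retained = cells.loc[~any_hit].reset_index(drop=True)
    logger.info("qc_filter: retained %d / %d cells", len(retained), len(cells))
    return retained, removal_log
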