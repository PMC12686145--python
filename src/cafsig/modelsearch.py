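"""Ensemble model search: selector × classifier combinations evaluated by
leave-one-out cross-validation and cross-cohort AUC.

Workflow: cohorts are reduced to their common gene space and standardized
gene-wise within each cohort (mean 0, SD 1 — the stand-in for a dedicated
batch-correction step).  For each combination in the manifest, the feature
selector is fit once on the pooled training cohorts; combinations selecting
fewer than ``min_genes`` model genes are omitted.  The classifier's
hyperparameters are then tuned by LOOCV on the pooled training data
(maximizing held-out AUC), the model is refit on the full training pool,
and AUC is recorded for every cohort — training cohorts are scored with
their LOOCV held-out predictions, validation cohorts with the refit model.
The leaderboard orders combinations by the mean of the three group means
(training / internal / external), ties broken by fewer genes then combo id.

The positive class is the non-responder throughout, so every score is
oriented as higher = more likely not to respond.

:func:`gene_or_meta` provides the per-gene odds-ratio meta-analysis:
univariate logistic regression of non-response on standardized expression
per cohort, pooled by inverse variance (fixed effect) or
DerSimonian–Laird (random effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .algorithms import (
    AlgorithmRegistry,
    ClassifierSpec,
    ComboSpec,
    ModelAdapter,
    default_registry,
)
from .synthdata import ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "CohortGroupSplit",
    "FittedCombo",
    "Leaderboard",
    "MetaORRow",
    "build_grid",
    "standardize_cohorts",
    "loocv_auc",
    "run_combo",
    "run_search",
    "rank_models",
    "risk_score",
    "gene_or_meta",
]

GROUPS = ("training", "internal", "external")


@dataclass(frozen=True)
class CohortGroupSplit:
    """Assignment of cohort ids to training / internal / external groups."""

    training: tuple[str, ...]
    internal: tuple[str, ...]
    external: tuple[str, ...]

    def __init__(self, training, internal, external):
        object.__setattr__(self, "training", tuple(training))
        object.__setattr__(self, "internal", tuple(internal))
        object.__setattr__(self, "external", tuple(external))
        groups = [self.training, self.internal, self.external]
        if any(not g for g in groups):
            raise ValueError("every split group must be non-empty")
        flat = [c for g in groups for c in g]
        if len(set(flat)) != len(flat):
            raise ValueError("split groups must be disjoint")

    def group_of(self, cohort: str) -> str:
        for name, members in zip(GROUPS, (self.training, self.internal, self.external)):
            if cohort in members:
                return name
        raise KeyError(f"cohort {cohort!r} not assigned to any group")

    @property
    def all_cohorts(self) -> list[str]:
        return list(self.training) + list(self.internal) + list(self.external)


@dataclass
class FittedCombo:
    """Result of evaluating one selector × classifier combination."""

    combo_id: str
    selector: str | None
    classifier: str
    selected_genes: list[str] = field(default_factory=list)
    feature_space: list[str] = field(default_factory=list)  # columns the model was fit on
    model: ModelAdapter | None = None
    best_params: dict = field(default_factory=dict)
    cohort_auc: dict[str, float] = field(default_factory=dict)
    group_auc: dict[str, float] = field(default_factory=dict)
    mean_auc: float = float("nan")
    omitted: bool = False
    omit_reason: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.selected_genes)


@dataclass
class Leaderboard:
    """Ranked table of non-omitted combinations (best first)."""

    table: pd.DataFrame
    fitted: dict[str, FittedCombo]

    @property
    def top(self) -> FittedCombo:
        return self.fitted[self.table.iloc[0]["combo_id"]]


def build_grid(registry: AlgorithmRegistry | None = None) -> list[ComboSpec]:
    """Return the registry's combination manifest in deterministic order."""
    registry = registry or default_registry()
    return list(registry.manifest)


def standardize_cohorts(
    cohorts: dict[str, ExpressionCohort]
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Intersect gene spaces and z-score each gene within each cohort.

    Returns ``(matrices, genes)`` where each matrix is samples × genes.
    Genes constant within a cohort standardize to 0 there.
    """
    gene_sets = [set(c.expr.index) for c in cohorts.values()]
    genes = sorted(set.intersection(*gene_sets))
    if not genes:
        raise ValueError("cohorts share no genes")
    out = {}
    for name, cohort in cohorts.items():
        mat = cohort.expr.loc[genes].T  # samples × genes
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        sd = sd.replace(0.0, 1.0)
        out[name] = (mat - mu) / sd
    return out, genes


def loocv_auc(
    estimator_factory,
    X: np.ndarray,
    y: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validated AUC.

    For each sample, a fresh model from ``estimator_factory()`` is fit on
    the remaining samples and scores the held-out one; the AUC of the n
    held-out scores against the labels is returned together with the score
    vector.  The training side of every fold must contain both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 6:
        raise ValueError(f"LOOCV requires n >= 6 samples, got {n}")
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present for LOOCV")
    if counts.min() < 2:
        raise ValueError(
            "minority class has a single sample; every LOOCV training fold "
            "must contain both classes"
        )
    held_out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = estimator_factory()
        model.fit(X[mask], y[mask])
        held_out[i] = model.decision_scores(X[i : i + 1])[0]
    return float(roc_auc_score(y, held_out)), held_out


def _safe_auc(y: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, scores))


def run_combo(
    combo: ComboSpec,
    cohorts: dict[str, ExpressionCohort],
    split: CohortGroupSplit,
    registry: AlgorithmRegistry | None = None,
    min_genes: int = 5,
    top_k: int = 20,
    seed: int = 0,
    _standardized: tuple[dict[str, pd.DataFrame], list[str]] | None = None,
    _preselected: list[str] | None = None,
) -> FittedCombo:
    """Fit and evaluate one combination against all cohorts.

    See the module docstring for the procedure.  ``top_k`` is the selected-
    set size for rank-only selectors.
    """
    registry = registry or default_registry()
    std, genes = _standardized if _standardized is not None else standardize_cohorts(
        {k: cohorts[k] for k in split.all_cohorts}
    )
    gene_arr = np.asarray(genes, dtype=str)

    X_train = pd.concat([std[c] for c in split.training], axis=0)
    y_train = np.concatenate([cohorts[c].y for c in split.training])
    if len(np.unique(y_train)) < 2:
        raise ValueError("training cohorts contain a single response class")

    result = FittedCombo(combo.combo_id, combo.selector, combo.classifier)

    if combo.selector is not None:
        if _preselected is not None:
            selected = list(_preselected)
        else:
            sel = registry.feature_selectors[combo.selector]
            selected = sel.select(X_train.to_numpy(), y_train, gene_arr, top_k, seed)
        if len(selected) < min_genes:
            result.selected_genes = selected
            result.omitted = True
            result.omit_reason = (
                f"selector chose {len(selected)} model genes; models with "
                f"fewer than {min_genes} model genes are omitted"
            )
            return result
        feature_genes = selected
    else:
        feature_genes = genes  # standalone embedded model: all genes in

    clf: ClassifierSpec = registry.classifiers[combo.classifier]
    Xt = X_train[feature_genes].to_numpy()

    best = None
    for params in clf.grid:
        auc, held = loocv_auc(lambda: clf.build(params, seed), Xt, y_train)
        if best is None or auc > best[0] + 1e-12:
            best = (auc, params, held)
    loo_auc, best_params, held_scores = best

    model = clf.build(best_params, seed).fit(Xt, y_train)

    if combo.selector is None:
        support = model.embedded_support()
        result.selected_genes = (
            sorted(gene_arr[support]) if support is not None else list(genes)
        )
        if len(result.selected_genes) < min_genes:
            result.omitted = True
            result.omit_reason = (
                f"embedded model kept {len(result.selected_genes)} genes; "
                f"models with fewer than {min_genes} model genes are omitted"
            )
            return result
    else:
        result.selected_genes = list(feature_genes)

    result.model = model
    result.feature_space = list(feature_genes)
    result.best_params = dict(best_params)

    # Training cohorts: LOOCV held-out scores; validation cohorts: refit model.
    offsets = np.cumsum([0] + [std[c].shape[0] for c in split.training])
    for c, lo, hi in zip(split.training, offsets[:-1], offsets[1:]):
        auc = _safe_auc(cohorts[c].y, held_scores[lo:hi])
        if np.isnan(auc):
            logger.warning("cohort %s has a single class; AUC excluded", c)
        result.cohort_auc[c] = auc
    for c in list(split.internal) + list(split.external):
        scores = model.decision_scores(std[c][feature_genes].to_numpy())
        auc = _safe_auc(cohorts[c].y, scores)
        if np.isnan(auc):
            logger.warning("cohort %s has a single class; AUC excluded", c)
        result.cohort_auc[c] = auc

    for group, members in zip(GROUPS, (split.training, split.internal, split.external)):
        vals = [result.cohort_auc[c] for c in members if not np.isnan(result.cohort_auc[c])]
        result.group_auc[group] = float(np.mean(vals)) if vals else float("nan")
    group_vals = [v for v in result.group_auc.values() if not np.isnan(v)]
    result.mean_auc = float(np.mean(group_vals))
    return result


def run_search(
    cohorts: dict[str, ExpressionCohort],
    split: CohortGroupSplit,
    registry: AlgorithmRegistry | None = None,
    manifest: list[ComboSpec] | None = None,
    min_genes: int = 5,
    top_k: int = 20,
    seed: int = 0,
) -> tuple[Leaderboard, list[FittedCombo]]:
    """Evaluate every manifest combination and rank the survivors.

    Selector results are cached per selector name (selection depends only
    on the pooled training data), and each combination receives a stable
    seed derived from the base seed and its manifest position.
    """
    registry = registry or default_registry()
    manifest = list(manifest) if manifest is not None else build_grid(registry)
    std = standardize_cohorts({k: cohorts[k] for k in split.all_cohorts})
    X_train = pd.concat([std[0][c] for c in split.training], axis=0)
    y_train = np.concatenate([cohorts[c].y for c in split.training])
    gene_arr = np.asarray(std[1], dtype=str)

    sel_cache: dict[str, list[str]] = {}
    fitted: list[FittedCombo] = []
    for i, combo in enumerate(manifest):
        combo_seed = (seed * 1009 + i) % (2**31 - 1)
        pre = None
        if combo.selector is not None:
            if combo.selector not in sel_cache:
                sel = registry.feature_selectors[combo.selector]
                sel_cache[combo.selector] = sel.select(
                    X_train.to_numpy(), y_train, gene_arr, top_k, combo_seed
                )
            pre = sel_cache[combo.selector]
        fitted.append(
            run_combo(
                combo, cohorts, split, registry,
                min_genes=min_genes, top_k=top_k, seed=combo_seed,
                _standardized=std, _preselected=pre,
            )
        )
    return rank_models(fitted), fitted


def rank_models(fitted: list[FittedCombo]) -> Leaderboard:
    """Rank non-omitted combinations by overall mean AUC (descending).

    The overall mean is the mean of the three group means; exact ties are
    broken by fewer model genes, then lexicographic combo id.
    """
    keep = [f for f in fitted if not f.omitted]
    if not keep:
        raise ValueError("all combinations were omitted; nothing to rank")
    rows = [
        {
            "combo_id": f.combo_id,
            "selector": f.selector if f.selector is not None else "(embedded)",
            "classifier": f.classifier,
            "n_genes": f.n_genes,
            "auc_training": f.group_auc.get("training", float("nan")),
            "auc_internal": f.group_auc.get("internal", float("nan")),
            "auc_external": f.group_auc.get("external", float("nan")),
            "mean_auc": f.mean_auc,
        }
        for f in keep
    ]
    table = pd.DataFrame(rows)
    # round the sort key so a genuine three-way tie of group means is not
    # broken by floating-point dust before the parsimony tie-break applies
    table["_key"] = table["mean_auc"].round(10)
    table = table.sort_values(
        by=["_key", "n_genes", "combo_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_key").reset_index(drop=True)
    return Leaderboard(table, {f.combo_id: f for f in keep})


def risk_score(fitted: FittedCombo, X: pd.DataFrame) -> pd.Series:
    """Per-sample risk score of a fitted combination (higher = non-response).

    ``X`` is samples × genes on the same (standardized) scale the model was
    fit on.  Linear models emit the linear predictor; non-linear models the
    predicted non-response probability.
    """
    if fitted.omitted or fitted.model is None:
        raise ValueError(f"combination {fitted.combo_id!r} was omitted; no model")
    cols = fitted.feature_space or fitted.selected_genes
    missing = [g for g in cols if g not in X.columns]
    if missing:
        raise ValueError(f"matrix is missing model genes: {missing[:10]}")
    scores = fitted.model.risk(X[cols].to_numpy())
    out = pd.Series(scores, index=X.index, name="risk_score")
    out.attrs["orientation"] = "higher = more likely non-responder"
    out.attrs["kind"] = "linear_predictor" if fitted.model.linear else "probability"
    return out


@dataclass
class MetaORRow:
    """Per-gene odds-ratio meta-analysis result."""

    gene: str
    per_cohort: pd.DataFrame  # cohort, log_or, se, excluded, reason
    pooled_log_or: float
    pooled_se: float
    method: str
    q_statistic: float
    tau2: float

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_log_or))

    @property
    def ci(self) -> tuple[float, float]:
        lo = self.pooled_log_or - 1.96 * self.pooled_se
        hi = self.pooled_log_or + 1.96 * self.pooled_se
        return float(np.exp(lo)), float(np.exp(hi))

    @property
    def p_value(self) -> float:
        z = self.pooled_log_or / self.pooled_se
        return float(2 * norm.sf(abs(z)))


def _cohort_log_or(
    cohort: ExpressionCohort, gene: str, standardize: bool = True
) -> tuple[float, float, str]:
    """Univariate logistic log-OR of non-response on (standardized) expression."""
    x = cohort.expr.loc[gene].to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.nan, np.nan, "constant expression"
    if standardize:
        x = (x - x.mean()) / sd
    y = cohort.y
    if len(np.unique(y)) < 2:
        return np.nan, np.nan, "single response class"
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation or non-convergence
        return np.nan, np.nan, f"fit failed: {exc.__class__.__name__}"
    b, se = float(res.params[1]), float(res.bse[1])
    if not (np.isfinite(b) and np.isfinite(se)) or se > 50:
        return np.nan, np.nan, "perfect separation"
    return b, se, ""


def gene_or_meta(
    gene: str,
    cohorts: dict[str, ExpressionCohort],
    method: str = "fixed",
    standardize: bool = True,
) -> MetaORRow:
    """Pool per-cohort univariate logistic odds ratios for one gene.

    Fixed effect = inverse-variance weighting; random effects =
    DerSimonian–Laird.  Expression is z-scored per cohort by default
    (``standardize=False`` keeps the native scale, e.g. for binary
    covariates).  Cohorts with perfect separation, a single class, or
    constant expression are excluded and flagged.
    """
    if method not in {"fixed", "random"}:
        raise ValueError(f"method must be 'fixed' or 'random', got {method!r}")
    rows = []
    for name, cohort in cohorts.items():
        if gene not in cohort.expr.index:
            rows.append((name, np.nan, np.nan, True, "gene absent"))
            continue
        b, se, reason = _cohort_log_or(cohort, gene, standardize=standardize)
        rows.append((name, b, se, bool(reason), reason))
        if reason:
            logger.warning("gene %s cohort %s excluded from meta-analysis: %s",
                           gene, name, reason)
    per = pd.DataFrame(rows, columns=["cohort", "log_or", "se", "excluded", "reason"])
    ok = per[~per["excluded"]]
    if ok.empty:
        raise ValueError(f"no cohort usable for gene {gene!r}")

    b = ok["log_or"].to_numpy()
    se = ok["se"].to_numpy()
    w = 1.0 / se**2
    fixed = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - fixed) ** 2))
    df = len(b) - 1
    if method == "fixed" or df == 0:
        tau2 = 0.0
        pooled, pooled_se = fixed, float(np.sqrt(1.0 / np.sum(w)))
        used = "fixed" if method == "fixed" else method
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w_star * b) / np.sum(w_star))
        pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
        used = "random"
    return MetaORRow(gene, per, pooled, pooled_se, used, q, tau2)
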