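"""Synthetic data generators with known ground truth.

Three generators emulate the study designs that the downstream stages
operate on:

* :func:`simulate_cohorts` — multi-cohort bulk expression (log2 scale) with
  planted responder-associated up/down genes and additive per-cohort batch
  shifts, the substrate for signature scoring and the ensemble model search.
* :func:`simulate_sections` — tissue sections where target cell types are
  scattered around reference cells (a parent–offspring process) with a
  group-specific dispersion sigma, so the planted proximity ordering is the
  ground truth the k-distance + rank-aggregation stage must recover.
* :func:`simulate_cell_qc_table` — per-cell QC tables with planted violators
  of each single-cell QC rule.

Every generator takes an explicit spec dataclass, draws all randomness from
one seeded :class:`numpy.random.Generator`, and returns the data together
with a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSimSpec",
    "TargetTypeSpec",
    "SpatialSimSpec",
    "CellQCSimSpec",
    "ExpressionCohort",
    "simulate_cohorts",
    "simulate_sections",
    "simulate_cell_qc_table",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid spec field {name!r}: {msg}")


@dataclass
class ExpressionCohort:
    """One cohort: genes × samples log2 expression plus R/NR labels."""

    name: str
    expr: pd.DataFrame          # rows = genes, columns = samples
    labels: pd.Series           # index = samples, values in {"R", "NR"}

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.labels.index):
            self.labels = self.labels.reindex(self.expr.columns)
        if self.labels.isna().any():
            raise ValueError(f"cohort {self.name!r}: labels missing for some samples")
        bad = set(self.labels.unique()) - {"R", "NR"}
        if bad:
            raise ValueError(f"cohort {self.name!r}: unknown labels {sorted(bad)}")

    @property
    def y(self) -> np.ndarray:
        """Binary outcome, 1 = non-responder (the positive class throughout)."""
        return (self.labels == "NR").to_numpy(dtype=int)


@dataclass
class CohortSimSpec:
    """Design of the multi-cohort expression simulation.

    ``effect_size`` is the mean shift of planted genes in non-responders, in
    within-gene SD units (``noise_sd``); up genes shift +, down genes −.
    Batch shifts are additive, drawn once per (cohort, gene) from
    N(0, ``batch_sd``).
    """

    n_cohorts: int = 5
    samples_per_cohort: int = 100
    n_genes: int = 200
    n_up: int = 20
    n_down: int = 20
    effect_size: float = 1.5
    nonresponder_fraction: float = 0.5
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cohorts >= 1, "n_cohorts", "must be >= 1")
        _require(self.samples_per_cohort >= 2, "samples_per_cohort", "must be >= 2")
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(self.n_up >= 0, "n_up", "must be >= 0")
        _require(self.n_down >= 0, "n_down", "must be >= 0")
        _require(
            self.n_up + self.n_down <= self.n_genes,
            "n_up",
            "n_up + n_down must not exceed n_genes",
        )
        _require(self.effect_size >= 0, "effect_size", "must be >= 0")
        _require(
            0 < self.nonresponder_fraction < 1,
            "nonresponder_fraction",
            "must lie in (0, 1)",
        )
        _require(self.batch_sd >= 0, "batch_sd", "must be >= 0")
        _require(self.noise_sd > 0, "noise_sd", "must be > 0")


def simulate_cohorts(spec: CohortSimSpec) -> tuple[dict[str, ExpressionCohort], dict]:
    """Generate cohorts of log2 expression with planted response signal.

    Per-gene baseline means are drawn once (N(6, 1)) and shared across
    cohorts; each (cohort, gene) pair receives an additive batch shift
    N(0, batch_sd); residual noise is N(0, noise_sd).  The first ``n_up``
    genes are elevated and the next ``n_down`` reduced in non-responders by
    ``effect_size * noise_sd``.

    Returns ``(cohorts, truth)`` where truth records the planted up/down
    gene ids and every sample's label.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    baseline = rng.normal(6.0, 1.0, size=spec.n_genes)

    up_genes = genes[: spec.n_up]
    down_genes = genes[spec.n_up : spec.n_up + spec.n_down]
    shift = np.zeros(spec.n_genes)
    shift[: spec.n_up] = spec.effect_size * spec.noise_sd
    shift[spec.n_up : spec.n_up + spec.n_down] = -spec.effect_size * spec.noise_sd

    n_nr = int(round(spec.samples_per_cohort * spec.nonresponder_fraction))
    n_nr = min(max(n_nr, 1), spec.samples_per_cohort - 1)

    cohorts: dict[str, ExpressionCohort] = {}
    truth_labels: dict[str, str] = {}
    for c in range(1, spec.n_cohorts + 1):
        cname = f"C{c:02d}"
        samples = [f"{cname}_S{i:03d}" for i in range(1, spec.samples_per_cohort + 1)]
        is_nr = np.zeros(spec.samples_per_cohort, dtype=bool)
        is_nr[rng.permutation(spec.samples_per_cohort)[:n_nr]] = True
        batch = rng.normal(0.0, spec.batch_sd, size=spec.n_genes)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.samples_per_cohort))
        mat = baseline[:, None] + batch[:, None] + noise
        mat = mat + np.outer(shift, is_nr.astype(float))
        expr = pd.DataFrame(mat, index=genes, columns=samples)
        labels = pd.Series(np.where(is_nr, "NR", "R"), index=samples, name="response")
        cohorts[cname] = ExpressionCohort(cname, expr, labels)
        truth_labels.update(labels.to_dict())

    truth = {
        "up_genes": list(up_genes),
        "down_genes": list(down_genes),
        "labels": truth_labels,
        "effect_size": spec.effect_size,
    }
    return cohorts, truth


@dataclass
class TargetTypeSpec:
    """A target cell type with per-response-group placement dispersion."""

    name: str
    sigma_responder: float
    sigma_nonresponder: float

    def __post_init__(self) -> None:
        _require(self.sigma_responder > 0, "sigma_responder", "must be > 0")
        _require(self.sigma_nonresponder > 0, "sigma_nonresponder", "must be > 0")


def _default_targets() -> list[TargetTypeSpec]:
    # Emulates the study contrast: effector T cells near the reference type
    # in responders, exhausted T cells near it in non-responders.
    return [
        TargetTypeSpec("Tem_Teff", 30.0, 150.0),
        TargetTypeSpec("CD8_Tex", 150.0, 30.0),
        TargetTypeSpec("mCAF", 90.0, 90.0),
        TargetTypeSpec("apCAF", 90.0, 90.0),
    ]


@dataclass
class SpatialSimSpec:
    """Design of the synthetic tissue sections.

    Reference cells are uniform in a ``section_extent`` × ``section_extent``
    box; each target-type cell sits at a uniformly chosen reference cell
    plus an isotropic Gaussian displacement with that type's group-specific
    sigma, clipped to the box.  Smaller sigma means genuinely nearer.

    ``cells_per_type`` should comfortably exceed ``n_reference_cells`` so
    that each reference cell owns a real offspring cluster; otherwise the
    k-distance is dominated by the spacing between reference cells rather
    than by the dispersion knob that defines the planted ordering.
    """

    n_sections_responder: int = 5
    n_sections_nonresponder: int = 5
    section_extent: float = 1000.0
    reference_type: str = "iCAF"
    target_types: list[TargetTypeSpec] = field(default_factory=_default_targets)
    n_reference_cells: int = 25
    cells_per_type: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_sections_responder >= 1, "n_sections_responder", "must be >= 1")
        _require(self.n_sections_nonresponder >= 1, "n_sections_nonresponder", "must be >= 1")
        _require(self.section_extent > 0, "section_extent", "must be > 0")
        _require(self.n_reference_cells >= 1, "n_reference_cells", "must be >= 1")
        _require(self.cells_per_type >= 1, "cells_per_type", "must be >= 1")
        if not self.target_types:
            raise ValueError("invalid spec field 'target_types': must be non-empty")
        names = [t.name for t in self.target_types]
        _require(len(set(names)) == len(names), "target_types", "type names must be distinct")
        _require(
            self.reference_type not in names,
            "reference_type",
            "must differ from every target type name",
        )


def simulate_sections(spec: SpatialSimSpec) -> tuple[pd.DataFrame, dict]:
    """Generate spatial cell tables for responder and non-responder sections.

    Returns ``(table, truth)``; the table has columns
    ``cell_id, x, y, cell_type, section_id, group`` and truth holds, per
    group, the target types ordered from nearest (smallest sigma) out.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    ext = spec.section_extent
    plan = [("R", spec.n_sections_responder), ("NR", spec.n_sections_nonresponder)]
    cell_counter = 0
    for group, n_sections in plan:
        for s in range(1, n_sections + 1):
            section = f"{group}{s:02d}"
            ref_xy = rng.uniform(0.0, ext, size=(spec.n_reference_cells, 2))
            for x, y in ref_xy:
                cell_counter += 1
                rows.append((f"cell{cell_counter:06d}", x, y, spec.reference_type, section, group))
            for tt in spec.target_types:
                sigma = tt.sigma_responder if group == "R" else tt.sigma_nonresponder
                parents = ref_xy[rng.integers(0, spec.n_reference_cells, size=spec.cells_per_type)]
                xy = parents + rng.normal(0.0, sigma, size=(spec.cells_per_type, 2))
                xy = np.clip(xy, 0.0, ext)
                for x, y in xy:
                    cell_counter += 1
                    rows.append((f"cell{cell_counter:06d}", x, y, tt.name, section, group))
    table = pd.DataFrame(rows, columns=["cell_id", "x", "y", "cell_type", "section_id", "group"])

    def ordering(group: str) -> list[str]:
        key = "sigma_responder" if group == "R" else "sigma_nonresponder"
        return [t.name for t in sorted(spec.target_types, key=lambda t: (getattr(t, key), t.name))]

    truth = {
        "ordering_responder": ordering("R"),
        "ordering_nonresponder": ordering("NR"),
        "sigmas": {
            t.name: {"R": t.sigma_responder, "NR": t.sigma_nonresponder}
            for t in spec.target_types
        },
        "reference_type": spec.reference_type,
    }
    return table, truth


_QC_RULES = ("umi_high", "gene_low", "gene_high", "mito_high")


@dataclass
class CellQCSimSpec:
    """Per-cell QC table with planted single-rule violators.

    ``fail_fractions`` maps rule name (umi_high, gene_low, gene_high,
    mito_high) to the fraction of cells violating exactly that rule; the
    remaining cells pass every rule.
    """

    n_cells: int = 1000
    fail_fractions: dict[str, float] = field(
        default_factory=lambda: {r: 0.02 for r in _QC_RULES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        unknown = set(self.fail_fractions) - set(_QC_RULES)
        if unknown:
            raise ValueError(
                f"invalid spec field 'fail_fractions': unknown rules {sorted(unknown)}"
            )
        for rule, frac in self.fail_fractions.items():
            _require(0 <= frac <= 1, "fail_fractions", f"{rule} fraction must be in [0, 1]")
        _require(
            sum(self.fail_fractions.values()) <= 1,
            "fail_fractions",
            "fractions must sum to at most 1",
        )


def simulate_cell_qc_table(spec: CellQCSimSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Generate a per-cell QC table (umi_count, n_genes, pct_mito).

    Planted violators exceed exactly their designated rule's threshold
    (UMI > 40000, genes < 500, genes > 5000, mito% > 20); all other fields
    and all non-violators lie safely inside the pass region.  Returns the
    table and a truth map rule → violating cell ids.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    ids = [f"cell{i:05d}" for i in range(1, n + 1)]
    umi = rng.integers(5000, 30000, size=n).astype(float)
    genes = rng.integers(800, 4500, size=n).astype(float)
    mito = rng.uniform(0.0, 15.0, size=n)

    order = rng.permutation(n)
    counts = {r: int(round(spec.fail_fractions.get(r, 0.0) * n)) for r in _QC_RULES}
    while sum(counts.values()) > n:  # rounding overflow guard
        busiest = max(counts, key=counts.get)
        counts[busiest] -= 1
    truth: dict[str, list[str]] = {}
    pos = 0
    for rule in _QC_RULES:
        idx = order[pos : pos + counts[rule]]
        pos += counts[rule]
        if rule == "umi_high":
            umi[idx] = rng.integers(40001, 80000, size=len(idx))
        elif rule == "gene_low":
            genes[idx] = rng.integers(0, 500, size=len(idx))
        elif rule == "gene_high":
            genes[idx] = rng.integers(5001, 9000, size=len(idx))
        else:
            mito[idx] = 20.0 + rng.uniform(0.5, 70.0, size=len(idx))
        truth[rule] = sorted(ids[i] for i in idx)

    table = pd.DataFrame(
        {
            "cell_id": ids,
            "umi_count": umi.astype(int),
            "n_genes": genes.astype(int),
            "pct_mito": mito,
        }
    )
    return table, truth
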