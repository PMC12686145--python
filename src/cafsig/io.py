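"""Readers and writers for the standard interchange formats.

Expression matrices travel as TSV/CSV (genes in rows, sample-id header) or
as a MatrixMarket triplet with row/column id files; gene sets as GMT;
response labels as a two-column CSV; spatial cell tables as CSV.  Readers
validate and log every dropped/collapsed event.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from .scoring import GeneSet
from .synthdata import ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_expression_mtx",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_cohort",
    "read_gmt",
    "write_gmt",
    "read_spatial_table",
    "write_spatial_table",
    "load_config",
    "write_json",
]

# How clinical response categories map onto the binary R/NR encoding
# (partial/complete response = responder; stable/progressive disease =
# non-responder).  Extendable at ingestion.
DEFAULT_RESPONSE_MAP = {
    "R": "R", "NR": "NR",
    "CR": "R", "PR": "R", "SD": "NR", "PD": "NR",
}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples matrix from TSV/CSV.

    First column = gene ids, header = sample ids.  Duplicate gene rows are
    collapsed by mean (warning); non-numeric cells raise with row/column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy()][0]
                raise ValueError(
                    f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
                ) from None
        df = df.apply(pd.to_numeric)
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene id rows collapsed by mean", path, n_dup)
        df = df.groupby(level=0, sort=False).mean()
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in header")
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def read_expression_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    """Read a genes × samples matrix from a MatrixMarket triplet.

    ``genes_path`` / ``samples_path`` are one-id-per-line text files for
    the rows and columns of the matrix.
    """
    mat = scipy.io.mmread(str(mtx_path))
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    if dense.shape != (len(genes), len(samples)):
        raise ValueError(
            f"{mtx_path}: matrix is {dense.shape}, ids give "
            f"({len(genes)}, {len(samples)})"
        )
    df = pd.DataFrame(dense, index=genes, columns=samples)
    if df.index.has_duplicates:
        logger.warning("%s: duplicate gene ids collapsed by mean", mtx_path)
        df = df.groupby(level=0, sort=False).mean()
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_labels(path, response_map: dict | None = None) -> pd.Series:
    """Read sample response labels (CSV: sample_id,response) as R/NR."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id,response")
    df.columns = ["sample_id", "response"] + list(df.columns[2:])
    mapping = response_map or DEFAULT_RESPONSE_MAP
    mapped = df["response"].astype(str).map(mapping)
    if mapped.isna().any():
        bad = sorted(df.loc[mapped.isna(), "response"].astype(str).unique())
        raise ValueError(
            f"{path}: unmapped response values {bad}; allowed: {sorted(set(mapping))}"
        )
    return pd.Series(mapped.to_numpy(), index=df["sample_id"].astype(str), name="response")


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "response": labels.to_numpy()}).to_csv(
        Path(path), index=False
    )


def read_cohort(name: str, expr_path, labels_path) -> ExpressionCohort:
    expr = read_expression(expr_path)
    labels = read_labels(labels_path)
    missing = set(expr.columns) - set(labels.index)
    if missing:
        raise ValueError(f"cohort {name!r}: labels missing for {sorted(missing)[:5]}")
    return ExpressionCohort(name, expr, labels.reindex(expr.columns))


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) < len(genes):
            logger.warning(
                "%s: line %d set %r contains %d duplicate gene id(s); dropped",
                path, lineno, name, len(genes) - len(unique),
            )
        sets.append(GeneSet(name, unique))
    return sets


def write_gmt(sets: list[GeneSet], path, descriptions: dict | None = None) -> None:
    lines = []
    for s in sets:
        desc = (descriptions or {}).get(s.name, "na")
        lines.append("\t".join([s.name, desc] + sorted(s.genes)))
    Path(path).write_text("\n".join(lines) + "\n")


_SPATIAL_COLS = ["cell_id", "x", "y", "cell_type", "section_id", "group"]


def read_spatial_table(path) -> pd.DataFrame:
    """Read and validate a spatial cell table CSV.

    Required columns: cell_id,x,y,cell_type,section_id,group; coordinates
    must be finite and group values in {R, NR}.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_SPATIAL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-finite {col} at row {row + 1} "
                f"(cell {df['cell_id'].iloc[row]!r})"
            )
        df[col] = vals
    bad_groups = set(df["group"].astype(str)) - {"R", "NR"}
    if bad_groups:
        raise ValueError(
            f"{path}: unknown group value(s) {sorted(bad_groups)}; allowed: ['NR', 'R']"
        )
    return df[_SPATIAL_COLS].copy()


def write_spatial_table(df: pd.DataFrame, path) -> None:
    df[_SPATIAL_COLS].to_csv(Path(path), index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
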