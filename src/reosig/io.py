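"""Readers, writers and cohort utilities for expression and clinical tables.

Expression matrices are plain :class:`pandas.DataFrame` objects: one row per
gene, one column per sample, values are log2-scale intensities.  Clinical
tables are DataFrames indexed by sample id.  All file formats are
tab-separated text so fixtures stay small and diff-able.

Missing expression values are rejected at read time: the relative ordering of
a gene pair is undefined if either member is missing, so imputation would
silently fabricate votes.  Missing survival annotations are permitted in the
clinical table and excluded (with a logged count) at cohort selection.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")

#: required clinical columns besides the sample id
CLINICAL_REQUIRED = ("stage", "ctx", "rfs_time", "rfs_event")

#: recognised optional covariates; "unknown" is an explicit token
CLINICAL_OPTIONAL = (
    "age",
    "sex",
    "msi",
    "localization",
    "braf_mut",
    "kras_mut",
    "tp53_mut",
)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the frame unchanged.

    Raises
    ------
    ValueError
        on duplicate gene or sample identifiers, or non-finite values.
    """
    if expr.index.duplicated().any():
        dups = sorted(expr.index[expr.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene identifiers: {dups}")
    if expr.columns.duplicated().any():
        dups = sorted(expr.columns[expr.columns.duplicated()].unique().tolist())
        raise ValueError(f"duplicate sample identifiers: {dups}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(expr.columns):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = coerced.isna() & expr[col].notna()
            if bad.any():
                gene = expr.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric expression value at gene {gene!r}, sample {col!r}"
                )
        raise ValueError("expression matrix is not numeric")
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"missing/non-finite expression value at gene "
            f"{expr.index[i]!r}, sample {expr.columns[j]!r}"
        )
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV (first column gene id, header sample ids)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.columns.size == 0:
        raise ValueError(f"{path}: no sample columns found in header")
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path: str | Path, digits: int = 6) -> None:
    """Write an expression matrix as TSV with fixed decimal precision."""
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format=f"%.{digits}f")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe_id → gene_id TSV into a dict (many-to-one)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"], dtype=str)
    if table["probe_id"].duplicated().any():
        dups = sorted(table["probe_id"][table["probe_id"].duplicated()].unique())
        raise ValueError(f"probes mapped to more than one gene: {dups}")
    return dict(zip(table["probe_id"], table["gene_id"]))


def collapse_probes(probe_expr: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    A gene's row is the unweighted arithmetic mean (on the log2 scale) of the
    rows of all probes mapping to it.  Probes absent from the map are dropped
    with a logged count.
    """
    mapped = probe_expr.index[probe_expr.index.isin(probe_map.keys())]
    n_dropped = probe_expr.shape[0] - mapped.size
    if mapped.size == 0:
        raise ValueError("no probe in the matrix is present in the probe map")
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = probe_expr.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="gene_id")
    collapsed = sub.groupby(genes, sort=True).mean()
    return validate_expression(collapsed)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV indexed by sample_id.

    Required columns: stage (I/II/III/IV), ctx (0/1), rfs_time (months),
    rfs_event (0 censored / 1 relapse).  rfs_time and rfs_event may be empty
    for samples lacking follow-up; such samples are excluded later by
    :func:`select_cohort`.
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: clinical table must have a 'sample_id' column")
    missing = [c for c in CLINICAL_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns: {missing}")
    table = table.set_index("sample_id")
    if table.index.duplicated().any():
        dups = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate sample identifiers: {dups}")
    return validate_clinical(table)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    bad_stage = set(clinical["stage"].astype(str)) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unrecognised tumor stages: {sorted(bad_stage)}")
    ctx = pd.to_numeric(clinical["ctx"], errors="raise")
    if not ctx.isin([0, 1]).all():
        raise ValueError("ctx must be coded 0/1")
    clinical = clinical.copy()
    clinical["ctx"] = ctx.astype(bool)
    times = pd.to_numeric(clinical["rfs_time"], errors="coerce")
    events = pd.to_numeric(clinical["rfs_event"], errors="coerce")
    if ((times <= 0) & times.notna()).any():
        bad = clinical.index[(times <= 0) & times.notna()][0]
        raise ValueError(f"rfs_time must be positive (sample {bad!r})")
    if (~events.isin([0, 1]) & events.notna()).any():
        bad = clinical.index[~events.isin([0, 1]) & events.notna()][0]
        raise ValueError(f"rfs_event must be 0 or 1 (sample {bad!r})")
    clinical["rfs_time"] = times
    clinical["rfs_event"] = events
    return clinical


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out["ctx"] = out["ctx"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.4f")


def select_cohort(
    clinical: pd.DataFrame,
    stages: Iterable[str],
    ctx: bool | str = "any",
) -> list[str]:
    """Select sample ids by tumor stage and adjuvant-chemotherapy status.

    Parameters
    ----------
    stages : iterable of {"I","II","III","IV"}
    ctx : True, False or "any"

    Samples with missing relapse-free-survival annotations are excluded with
    a logged count; downstream survival analysis cannot use them and the
    screening cohorts must be comparable to the survival cohorts.
    """
    stages = set(stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unrecognised stages: {sorted(unknown)}")
    mask = clinical["stage"].astype(str).isin(stages)
    if ctx != "any":
        mask &= clinical["ctx"] == bool(ctx)
    has_rfs = clinical["rfs_time"].notna() & clinical["rfs_event"].notna()
    n_missing = int((mask & ~has_rfs).sum())
    if n_missing:
        log.info("select_cohort: excluded %d samples with missing RFS annotation", n_missing)
    return clinical.index[mask & has_rfs].tolist()
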