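"""Quantile normalization, probe-to-gene collapsing, and sample filtering.

These are the first steps applied to every cohort: force all samples of a
series onto a common intensity distribution, average multi-probe genes, and
(optionally) drop controls below an age cutoff so groups are age-matched.
Normalization is always per cohort — each disease series with its own
controls — never pooled across series.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import ExpressionMatrix

log = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank-mean distribution.

    Each column is replaced by the means, across samples, of the sorted
    columns ("sort / average / unsort"). Tied values within a column receive
    the mean of the rank-means their span covers (the "average ties" rule),
    which makes the transform deterministic and idempotent.
    """
    values = m.data.to_numpy(dtype=float)
    n_rows, n_cols = values.shape
    if n_cols < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("NaN or infinite values present")

    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_rows)
        assigned[order] = rank_means
        # average the rank-means across each tied run
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_rows]))
        tied_out = np.empty(n_rows)
        for s, e in zip(starts, ends):
            tied_out[s:e] = rank_means[s:e].mean()
        assigned[order] = tied_out
        out[:, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), m.row_kind
    )


def collapse_probes(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Average the probes of each gene; drop unannotated probes.

    ``annotation`` maps probe_id -> gene_symbol (empty symbol = unannotated).
    Output rows are gene symbols, sorted; values are per-sample arithmetic
    means over that gene's probes.
    """
    if m.row_kind != "probe":
        raise ValueError("collapse_probes expects a probe-level matrix")
    mapping = annotation.set_index("probe_id")["gene_symbol"]
    symbols = m.data.index.map(mapping)
    keep = symbols.notna() & (symbols != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d unannotated probes at collapse", n_dropped)
    if not keep.any():
        raise ValueError("no annotated probes; cannot collapse to genes")
    collapsed = m.data.loc[keep].groupby(symbols[keep].to_numpy()).mean()
    collapsed.index.name = "gene"
    return ExpressionMatrix(collapsed.sort_index(), row_kind="gene")


def filter_samples(
    meta: pd.DataFrame, min_age: float | None = None, group: str | None = None
) -> pd.DataFrame:
    """Retain samples with age >= min_age (and matching group, if given).

    The cutoff excludes strictly-under ages, so a sample aged exactly
    ``min_age`` is kept. With ``min_age`` set, every candidate sample must
    have a recorded age.
    """
    out = meta
    if group is not None:
        out = out[out["group"] == group]
    if min_age is not None:
        missing = out.loc[out["age"].isna(), "sample_id"].tolist()
        if missing:
            raise ValueError(f"age missing for samples: {missing}")
        out = out[out["age"] >= min_age]
    return out.reset_index(drop=True)


def filter_cohort(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    min_age_control: float | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply an age floor to the control group only and subset the matrix.

    This mirrors age-matching a control series to an older disease group:
    disease samples are untouched, controls under the floor are removed.
    Filtering happens before normalization.
    """
    if min_age_control is None:
        return matrix, meta
    controls = filter_samples(meta, min_age=min_age_control, group="control")
    disease = filter_samples(meta, group="disease")
    kept = pd.concat([disease, controls], ignore_index=True)
    kept = kept.set_index("sample_id").loc[
        [s for s in meta["sample_id"] if s in set(kept["sample_id"])]
    ].reset_index()
    return matrix.subset_samples(kept["sample_id"].tolist()), kept
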