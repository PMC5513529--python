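"""Per-gene log2 disease/control ratios and their projection onto panels.

The unit of downstream inference is the marker panel, not the gene: each
cell type's panel of enriched genes reads that cell type's signal out of
whole-tissue ratios. A gene's ratio is log2 of the ratio of group
arithmetic means on the linear scale — a single number per gene even for
unpaired, unequal-size groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CellTypePanel, ExpressionMatrix

log = logging.getLogger(__name__)


def log2_ratio(m: ExpressionMatrix, meta: pd.DataFrame, cohort: str = "") -> pd.DataFrame:
    """Per-gene log2(mean disease / mean control) on the linear scale.

    Returns a DataFrame with columns gene, ratio, cohort. Genes whose
    disease or control mean is nonpositive cannot be placed on the log
    scale; they are excluded and the count logged.
    """
    if m.row_kind != "gene":
        raise ValueError("log2_ratio expects a gene-level matrix")
    ids = {g: meta.loc[meta["group"] == g, "sample_id"].tolist() for g in ("disease", "control")}
    for g, samples in ids.items():
        if not samples:
            raise ValueError(f"no {g} samples in metadata")
    dis = m.data.loc[:, ids["disease"]].mean(axis=1)
    ctl = m.data.loc[:, ids["control"]].mean(axis=1)
    ok = (dis > 0) & (ctl > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("%s: excluded %d genes with nonpositive group mean", cohort or "?", n_excluded)
    if not ok.any():
        raise ValueError("every gene excluded (nonpositive group means)")
    ratio = np.log2(dis[ok] / ctl[ok])
    out = pd.DataFrame({"gene": ratio.index, "ratio": ratio.to_numpy(), "cohort": cohort})
    out.attrs["n_excluded"] = n_excluded
    return out.reset_index(drop=True)


@dataclass
class PanelRatioVector:
    """A cohort's log2 ratios restricted to one cell type's markers."""

    cell_type: str
    cohort: str
    ratios: pd.DataFrame  # columns gene, ratio
    n_matched: int


def project_panel(ratio_table: pd.DataFrame, panel: CellTypePanel) -> PanelRatioVector:
    """Subset a ratio table to the panel's genes (case-normalized match).

    Panel genes absent from the measured data are dropped silently;
    ``n_matched`` records how many were present. Zero overlap is an error —
    it almost always means a symbol-vintage or annotation mismatch.
    """
    genes = ratio_table["gene"].str.upper()
    mask = genes.isin(set(panel.genes))
    matched = ratio_table.loc[mask, ["gene", "ratio"]].reset_index(drop=True)
    if matched.empty:
        raise ValueError(
            f"panel {panel.cell_type!r} shares no genes with the measured data"
        )
    cohort = ratio_table["cohort"].iloc[0] if "cohort" in ratio_table else ""
    return PanelRatioVector(panel.cell_type, cohort, matched, len(matched))
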