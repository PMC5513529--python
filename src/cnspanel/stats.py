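"""Statistical kernel: panel shift tests, winsorized correlation, shared genes.

Three instruments, all operating on vectors of per-gene log2 disease/control
ratios restricted to a cell-type panel:

* a one-sample t-test of the panel's mean ratio against 0 — is this cell
  type's program up- or down-regulated overall;
* a winsorized Pearson correlation between two diseases' panel ratios —
  do the same genes move the same way in both diseases, with outlier genes
  clipped at a robust boundary first;
* a fixed-threshold shared-gene table — which individual panel genes exceed
  a log2 ratio cutoff in every disease of a required set.

The t-test treats panel genes as independent replicates; genes are in fact
co-regulated, so its p-values are anti-conservative. This is deliberate —
the panel-level summary is a descriptive effect size with a conventional
significance annotation — and is documented as a limitation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CellTypePanel

log = logging.getLogger(__name__)

DEFAULT_WINSOR_C = 2.0
DEFAULT_THRESHOLD = 0.5
DEFAULT_TIER_CUTPOINTS = (0.01, 0.001, 0.0001)
TIER_LABELS = ("ns", "*", "**", "***")

#: scale factor making the MAD consistent with the SD under normality
MAD_TO_SD = 1.4826022185056018


def one_sample_t(values) -> tuple[float, float, float, int]:
    """Classical one-sample t of the mean against 0.

    Returns ``(t_stat, p_value, mean, n)`` with a two-sided p from the t
    distribution on n-1 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t needs n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate sample: zero variance")
    t_stat = mean / (sd / sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t_stat), n - 1))
    return t_stat, p, mean, n


def winsorize(values, c: float = DEFAULT_WINSOR_C):
    """Clip values to ±c robust-SD units around the median.

    Values are centered at the median and scaled by the normal-consistent
    MAD, clipped to [-c, +c] in that scale, and returned on the original
    scale. Robust (not mean/SD) centering is essential: the clipping
    boundary must itself be insensitive to the outliers being clipped.
    A zero MAD (more than half the values tied) makes the scale undefined;
    the data are returned unclipped with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("winsorize needs n >= 2")
    if not c > 0:
        raise ValueError("clipping constant must be positive")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * MAD_TO_SD
    if mad == 0.0:
        warnings.warn("MAD is zero; winsorization skipped (no robust scale)")
        return x.copy()
    return med + np.clip((x - med) / mad, -c, c) * mad


def winsorized_correlation(x, y, c: float = DEFAULT_WINSOR_C) -> tuple[float, float, int]:
    """Pearson correlation of marginally winsorized vectors, with p-value.

    Each margin is winsorized independently at ``c`` robust-SD units, then
    the textbook Pearson r is computed; the two-sided p-value comes from
    the transform t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    ``c = inf`` reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    xw = winsorize(x, c) if np.isfinite(c) else x
    yw = winsorize(y, c) if np.isfinite(c) else y
    if np.ptp(xw) == 0 or np.ptp(yw) == 0:
        raise ValueError("constant vector after winsorization")
    xc = xw - xw.mean()
    yc = yw - yw.mean()
    r = float(np.dot(xc, yc) / sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t_stat = r * sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t_stat), n - 2))
    return r, p, n


def assign_tier(p: float, cutpoints=DEFAULT_TIER_CUTPOINTS) -> str:
    """Map a p-value to a significance annotation (ns/*/**/***).

    ``cutpoints`` are strictly descending thresholds; the tier is the number
    of them the p-value falls below.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    cp = tuple(cutpoints)
    if any(not 0 < c < 1 for c in cp) or any(later >= earlier for later, earlier in zip(cp[1:], cp)):
        raise ValueError("cutpoints must be strictly descending within (0, 1)")
    k = sum(p < c for c in cp)
    return TIER_LABELS[k]


@dataclass
class PanelShiftResult:
    """Location-test summary for one (cell type, cohort) panel."""

    cell_type: str
    cohort: str
    mean_ratio: float
    t_stat: float
    p_value: float
    n: int
    tier: str


def panel_shift(
    panel_vector, cutpoints=DEFAULT_TIER_CUTPOINTS
) -> PanelShiftResult:
    """One-sample t of a projected panel's ratios against 0, with tier."""
    t_stat, p, mean, n = one_sample_t(panel_vector.ratios["ratio"].to_numpy())
    return PanelShiftResult(
        panel_vector.cell_type, panel_vector.cohort, mean, t_stat, p, n,
        assign_tier(p, cutpoints),
    )


@dataclass
class PairCorrelationResult:
    """Winsorized cross-disease correlation for one cell type."""

    cell_type: str
    cohort_a: str
    cohort_b: str
    r: float
    p_value: float
    n: int


def pair_correlation(
    vec_a, vec_b, c: float = DEFAULT_WINSOR_C
) -> PairCorrelationResult:
    """Correlate two cohorts' panel ratios over their shared measured genes."""
    if vec_a.cell_type != vec_b.cell_type:
        raise ValueError("panel vectors belong to different cell types")
    merged = vec_a.ratios.merge(vec_b.ratios, on="gene", suffixes=("_a", "_b"))
    r, p, n = winsorized_correlation(
        merged["ratio_a"].to_numpy(), merged["ratio_b"].to_numpy(), c
    )
    return PairCorrelationResult(vec_a.cell_type, vec_a.cohort, vec_b.cohort, r, p, n)


def shared_genes(
    ratio_tables: dict[str, pd.DataFrame],
    panel: CellTypePanel,
    threshold: float = DEFAULT_THRESHOLD,
    required: set[str] | None = None,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Panel genes whose ratio exceeds a threshold in every required cohort.

    ``ratio_tables`` maps cohort label -> ratio table. Per-cohort ratios are
    reported for all supplied cohorts, including non-required ones, so a
    gene shared by a subset still shows its (sub-threshold) values
    elsewhere. Rows are sorted alphabetically by gene. An empty result is
    valid, not an error.

    The boundary is inclusive by default (ratio >= threshold): published
    ratio tables are rounded to two decimals and treat boundary entries as
    selected, so a strict comparison would drop genes whose unrounded value
    cleared the cutoff. Pass ``inclusive=False`` for a strict reading.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    cohorts = list(ratio_tables)
    required = set(cohorts) if required is None else set(required)
    if not required <= set(cohorts):
        raise ValueError(f"required cohorts {sorted(required - set(cohorts))} not supplied")
    panel_set = set(panel.genes)
    wide = None
    for cohort, rt in ratio_tables.items():
        sub = rt.loc[rt["gene"].str.upper().isin(panel_set), ["gene", "ratio"]].copy()
        sub["gene"] = sub["gene"].str.upper()
        sub = sub.rename(columns={"ratio": cohort}).set_index("gene")
        wide = sub if wide is None else wide.join(sub, how="outer")
    log.debug("shared_genes threshold %.3g (%s boundary)",
              threshold, "inclusive" if inclusive else "strict")
    keep = pd.Series(True, index=wide.index)
    for cohort in required:
        above = wide[cohort] >= threshold if inclusive else wide[cohort] > threshold
        keep &= wide[cohort].notna() & above
    out = wide.loc[keep].sort_index().reset_index()
    out.insert(0, "cell_type", panel.cell_type)
    out["membership"] = "+".join(sorted(required))
    return out
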