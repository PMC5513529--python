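"""End-to-end orchestration over two or more disease cohorts.

For each cohort: read matrix + metadata, apply the control age floor,
quantile-normalize, collapse probes to genes, compute log2 disease/control
ratios. Then per (cohort, panel) a one-sample shift test, per (cohort pair,
panel) a winsorized correlation, and per panel a shared-gene table for each
required cohort set. Every configurable decision lands in the summary JSON.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .differential import log2_ratio, project_panel
from .model import CellTypePanel
from .preprocess import collapse_probes, filter_cohort, quantile_normalize
from .stats import (
    DEFAULT_THRESHOLD,
    DEFAULT_TIER_CUTPOINTS,
    DEFAULT_WINSOR_C,
    pair_correlation,
    panel_shift,
    shared_genes,
)

log = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    label: str
    matrix: str
    annotation: str
    metadata: str | None = None      # falls back to series-matrix characteristics
    min_age_control: float | None = None
    log_scale: bool | None = None    # None = auto-detect


@dataclass
class RunConfig:
    cohorts: list
    panels: str = ""
    out_dir: str = "results"
    top_n: int = 500
    threshold: float = DEFAULT_THRESHOLD
    winsor_c: float = DEFAULT_WINSOR_C
    tier_cutpoints: tuple = DEFAULT_TIER_CUTPOINTS
    required_sets: list = field(default_factory=list)  # lists of cohort labels

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["cohorts"] = [CohortSpec(**c) for c in raw["cohorts"]]
        return cls(**raw)


def _sniff_and_read(spec: CohortSpec):
    """Read a cohort matrix: series-matrix dialect if '!' lines, else TSV."""
    with open(spec.matrix, encoding="utf-8") as fh:
        head = fh.readline()
    if head.startswith("!"):
        matrix, meta = cio.read_series_matrix(spec.matrix, spec.log_scale, spec.label)
    else:
        matrix = cio.read_matrix_tsv(spec.matrix, spec.log_scale)
        meta = None
    if spec.metadata:
        meta = cio.read_metadata(spec.metadata, cohort=spec.label)
    if meta is None:
        raise ValueError(f"{spec.label}: no metadata in matrix file and none supplied")
    meta = meta[meta["sample_id"].isin(matrix.sample_ids)].reset_index(drop=True)
    return matrix.subset_samples(meta["sample_id"].tolist()), meta


def prepare_cohort(spec: CohortSpec):
    """Filter, normalize, collapse, and ratio one cohort."""
    try:
        matrix, meta = _sniff_and_read(spec)
        matrix, meta = filter_cohort(matrix, meta, spec.min_age_control)
        normalized = quantile_normalize(matrix)
        annotation = cio.read_annotation(spec.annotation)
        genes = collapse_probes(normalized, annotation)
        ratios = log2_ratio(genes, meta, cohort=spec.label)
    except Exception as exc:
        raise RuntimeError(f"cohort {spec.label}: {exc}") from exc
    return genes, meta, ratios


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; write TSVs + summary JSON under out_dir.

    Returns the result bundle: per-cohort ratio tables, panel shift and
    pair correlation frames, and the shared-gene table(s).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels = cio.read_panels(config.panels)
    panels = [CellTypePanel(p.cell_type, p.genes[: config.top_n]) for p in panels]

    ratio_tables: dict[str, pd.DataFrame] = {}
    projections: dict[tuple[str, str], object] = {}
    for spec in config.cohorts:
        _, _, ratios = prepare_cohort(spec)
        ratio_tables[spec.label] = ratios
        for panel in panels:
            projections[(spec.label, panel.cell_type)] = project_panel(ratios, panel)

    shift_rows = [
        vars(panel_shift(vec, config.tier_cutpoints)) for vec in projections.values()
    ]
    shifts = pd.DataFrame(shift_rows)

    corr_rows = []
    for a, b in itertools.combinations(ratio_tables, 2):
        for panel in panels:
            res = pair_correlation(
                projections[(a, panel.cell_type)], projections[(b, panel.cell_type)],
                config.winsor_c,
            )
            corr_rows.append(vars(res))
    correlations = pd.DataFrame(corr_rows)

    required_sets = config.required_sets or (
        [sorted(ratio_tables)] if len(ratio_tables) >= 2 else []
    )
    shared_frames = []
    for req in required_sets:
        for panel in panels:
            shared_frames.append(
                shared_genes(ratio_tables, panel, config.threshold, set(req))
            )
    shared = (
        pd.concat(shared_frames, ignore_index=True) if shared_frames
        else pd.DataFrame(columns=["cell_type", "gene", "membership"])
    )

    for label, rt in ratio_tables.items():
        cio.write_table(rt, out_dir / f"ratios_{label}.tsv", key="gene")
    cio.write_table(shifts, out_dir / "panel_shift.tsv", key=["cohort", "cell_type"])
    if not correlations.empty:
        cio.write_table(correlations, out_dir / "pair_correlation.tsv",
                        key=["cohort_a", "cohort_b", "cell_type"])
    else:
        cio.write_table(pd.DataFrame(
            columns=["cell_type", "cohort_a", "cohort_b", "r", "p_value", "n"]),
            out_dir / "pair_correlation.tsv", allow_empty=True)
    cio.write_table(shared, out_dir / "shared_genes.tsv",
                    key=["membership", "cell_type", "gene"], allow_empty=True)

    summary = {
        "cohorts": [vars(s) for s in config.cohorts],
        "top_n": config.top_n,
        "threshold": config.threshold,
        "threshold_rule": "strictly greater than",
        "winsor_c": config.winsor_c,
        "tier_cutpoints": list(config.tier_cutpoints),
        "required_sets": [sorted(r) for r in required_sets],
        "order_of_operations": ["filter_samples", "quantile_normalize",
                                "collapse_probes", "log2_ratio"],
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=1))

    return {
        "ratio_tables": ratio_tables,
        "projections": projections,
        "panel_shift": shifts,
        "pair_correlation": correlations,
        "shared_genes": shared,
        "panels": panels,
        "out_dir": str(out_dir),
    }


def export_figure_data(bundle: dict, out_dir=None) -> dict:
    """Export the plotted quantities: box summaries, scatter tables, fits.

    Box summaries give median/quartiles/mean/tier per (cohort, panel);
    scatter tables give per-gene (x, y) ratios per cohort pair and panel,
    with the least-squares regression slope and intercept per scatter.
    """
    out_dir = Path(out_dir or bundle["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    shifts = bundle["panel_shift"]
    box_rows = []
    for (label, ct), vec in bundle["projections"].items():
        vals = vec.ratios["ratio"].to_numpy()
        row = shifts[(shifts["cohort"] == label) & (shifts["cell_type"] == ct)].iloc[0]
        box_rows.append({
            "cohort": label, "cell_type": ct,
            "median": float(np.median(vals)),
            "q1": float(np.quantile(vals, 0.25)),
            "q3": float(np.quantile(vals, 0.75)),
            "mean": float(vals.mean()), "n": len(vals), "tier": row["tier"],
        })
    box = pd.DataFrame(box_rows)
    cio.write_table(box, out_dir / "figure_box_summary.tsv", key=["cohort", "cell_type"])

    scatter_frames, fit_rows = [], []
    labels = list(bundle["ratio_tables"])
    for a, b in itertools.combinations(labels, 2):
        for panel in bundle["panels"]:
            ct = panel.cell_type
            merged = bundle["projections"][(a, ct)].ratios.merge(
                bundle["projections"][(b, ct)].ratios, on="gene", suffixes=("_x", "_y"))
            merged.insert(0, "cell_type", ct)
            merged.insert(0, "pair", f"{a}-{b}")
            scatter_frames.append(merged)
            x = merged["ratio_x"].to_numpy()
            y = merged["ratio_y"].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            fit_rows.append({"pair": f"{a}-{b}", "cell_type": ct,
                             "slope": float(slope), "intercept": float(intercept),
                             "n": len(merged)})
    if scatter_frames:
        scatter = pd.concat(scatter_frames, ignore_index=True)
        cio.write_table(scatter, out_dir / "figure_scatter.tsv",
                        key=["pair", "cell_type", "gene"])
        fits = pd.DataFrame(fit_rows)
        cio.write_table(fits, out_dir / "figure_regression.tsv", key=["pair", "cell_type"])
    else:
        scatter, fits = pd.DataFrame(), pd.DataFrame()
    return {"box": box, "scatter": scatter, "regression": fits}
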