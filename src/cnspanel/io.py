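"""Readers and writers for every external file the pipeline touches.

Formats
-------
* GEO Series Matrix text dialect: "!"-prefixed metadata lines around a
  tab-delimited table bracketed by ``!series_matrix_table_begin`` /
  ``!series_matrix_table_end``.
* Plain TSV expression matrices (first column = row id, header = sample ids).
* Two-column TSV marker-panel files (cell_type, gene_symbol).
* TSV probe annotation (probe_id, gene_symbol) and CSV sample metadata.

All downstream modules consume only the in-memory model; nothing below this
module opens a file.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CellTypePanel, ExpressionMatrix, FormatError, make_metadata

log = logging.getLogger(__name__)

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"

#: intensities never exceed this on a log2 scale; used to auto-detect
#: log-submitted series (GEO mixes linear and log uploads)
LOG_SCALE_MAX = 30.0


def _strip_quotes(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def _parse_characteristic(field_map: dict, text: str) -> None:
    """Fill age/sex/group from one 'key: value' characteristics token."""
    if ":" not in text:
        return
    key, _, value = text.partition(":")
    key = key.strip().lower()
    value = value.strip()
    if key == "age":
        try:
            field_map["age"] = float(value)
        except ValueError:
            pass
    elif key == "sex" and value:
        v = value.upper()[0]
        field_map["sex"] = v if v in ("M", "F") else "unknown"
    elif key in ("group", "disease state", "diagnosis") and value:
        v = value.strip().lower()
        if v in ("control", "normal", "healthy", "nl"):
            field_map["group"] = "control"
        else:
            field_map["group"] = "disease"


def read_series_matrix(
    path,
    log_scale: bool | None = None,
    cohort: str = "",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a series-matrix file into an expression matrix plus metadata.

    Parameters
    ----------
    path:
        Series-matrix text file.
    log_scale:
        ``True`` forces the table to be treated as log2 (exponentiated to
        linear), ``False`` as linear. ``None`` auto-detects: a maximum below
        ``LOG_SCALE_MAX`` is taken as a log2 submission. The decision is
        logged either way.
    cohort:
        Disease label stamped into the metadata.

    Returns
    -------
    (ExpressionMatrix with row_kind="probe", metadata DataFrame)
    """
    path = Path(path)
    meta_lines: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(TABLE_BEGIN):
                saw_begin, in_table = True, True
                continue
            if line.startswith(TABLE_END):
                saw_end, in_table = True, False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                meta_lines.append([_strip_quotes(t) for t in line.split("\t")])
    if not (saw_begin and saw_end):
        raise FormatError(f"{path}: missing series-matrix table sentinels")
    if not table_lines:
        raise FormatError(f"{path}: table section is empty")

    header = [_strip_quotes(t) for t in table_lines[0].split("\t")]
    sample_ids = header[1:]
    n_cols = len(header)
    probes: list[str] = []
    rows: list[list[float]] = []
    for line in table_lines[1:]:
        toks = [_strip_quotes(t) for t in line.split("\t")]
        if len(toks) != n_cols:
            raise FormatError(
                f"{path}: ragged row {toks[0]!r} ({len(toks)} fields, expected {n_cols})"
            )
        vals = []
        for sample, tok in zip(sample_ids, toks[1:]):
            try:
                vals.append(float(tok))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {toks[0]!r}, column {sample!r}: {tok!r}"
                ) from None
        probes.append(toks[0])
        rows.append(vals)

    values = np.asarray(rows, dtype=float)
    if log_scale is None:
        log_scale = bool(values.size) and float(np.nanmax(values)) < LOG_SCALE_MAX
        log.info(
            "%s: auto-detected %s-scale values (max=%.3g, threshold=%g)",
            path.name, "log2" if log_scale else "linear",
            float(np.nanmax(values)) if values.size else float("nan"), LOG_SCALE_MAX,
        )
    if log_scale:
        log.info("%s: exponentiating log2 table to linear scale", path.name)
        values = np.exp2(values)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=sample_ids),
        row_kind="probe",
    )

    # sample metadata from the "!" header: geo accessions, characteristics
    per_sample = [{"sample_id": s, "group": "control", "age": np.nan, "sex": "unknown"}
                  for s in sample_ids]
    group_seen = False
    for toks in meta_lines:
        tag = toks[0].lower()
        if tag.startswith("!sample_characteristics"):
            for fields, tok in zip(per_sample, toks[1:]):
                before = fields.get("group")
                _parse_characteristic(fields, tok)
                if fields.get("group") != before or "group" in tok.lower() \
                        or "disease state" in tok.lower() or "diagnosis" in tok.lower():
                    group_seen = True
    if not group_seen:
        log.warning("%s: no group/disease-state characteristics found; "
                    "all samples marked control — supply metadata separately", path.name)
    meta = make_metadata(per_sample)
    meta["cohort"] = cohort
    return matrix, meta


def write_series_matrix(path, matrix: ExpressionMatrix, meta: pd.DataFrame | None = None) -> None:
    """Emit a matrix (and optional metadata) in the series-matrix dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("!Series_title\t\"synthetic cohort\"\n")
        if meta is not None:
            meta = meta.set_index("sample_id").loc[matrix.sample_ids].reset_index()
            for key in ("age", "sex", "group"):
                toks = "\t".join(
                    f'"{key}: {row[key]}"' for _, row in meta.iterrows()
                    if not (key == "age" and pd.isna(row[key]))
                ) or "\t".join(f'"{key}: "' for _ in matrix.sample_ids)
                fh.write(f"!Sample_characteristics_ch1\t{toks}\n")
        fh.write(TABLE_BEGIN + "\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{s}"' for s in matrix.sample_ids) + "\n")
        for probe, row in matrix.data.iterrows():
            fh.write(f'"{probe}"\t' + "\t".join(format(v, ".10g") for v in row) + "\n")
        fh.write(TABLE_END + "\n")


def read_matrix_tsv(path, log_scale: bool | None = None) -> ExpressionMatrix:
    """Read a plain TSV matrix: first column row id, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if log_scale is None:
        log_scale = bool(values.size) and float(np.nanmax(values)) < LOG_SCALE_MAX
        log.info("%s: auto-detected %s scale", path, "log2" if log_scale else "linear")
    if log_scale:
        values = np.exp2(values)
        df = pd.DataFrame(values, index=df.index, columns=df.columns)
    return ExpressionMatrix(df, row_kind="probe")


def read_panels(path) -> list[CellTypePanel]:
    """Read a two-column TSV (cell_type, gene_symbol) into ordered panels.

    A header row is detected and skipped; duplicate (cell_type, gene) pairs
    are dropped with a warning; panel insertion order is preserved.
    """
    path = Path(path)
    seen: dict[str, list[str]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    n_dup = 0
    with path.open(encoding="utf-8") as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) < 2:
                raise FormatError(f"{path}: line {i + 1} has fewer than 2 columns")
            ct, gene = toks[0].strip(), toks[1].strip().upper()
            if i == 0 and ct.lower() in ("cell_type", "celltype", "cell type"):
                continue
            key = (ct, gene)
            if key in seen_pairs:
                n_dup += 1
                continue
            seen_pairs.add(key)
            seen.setdefault(ct, []).append(gene)
    if not seen:
        raise FormatError(f"{path}: empty panel file")
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate (cell_type, gene) pairs")
    return [CellTypePanel(ct, genes) for ct, genes in seen.items()]


def write_panels(path, panels: list[CellTypePanel]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("cell_type\tgene_symbol\n")
        for panel in panels:
            for gene in panel.genes:
                fh.write(f"{panel.cell_type}\t{gene}\n")


def read_annotation(path) -> pd.DataFrame:
    """Probe annotation TSV -> DataFrame(probe_id, gene_symbol).

    Symbols are upper-cased; empty symbols (unannotated probes) are kept as
    empty strings so the caller can drop them at collapse time.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in ann.columns}
    if "probe_id" not in cols or "gene_symbol" not in cols:
        raise FormatError(f"{path}: annotation needs probe_id and gene_symbol columns")
    ann = ann.rename(columns={cols["probe_id"]: "probe_id", cols["gene_symbol"]: "gene_symbol"})
    ann = ann.loc[:, ["probe_id", "gene_symbol"]]
    if ann["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe_id in annotation")
    ann["gene_symbol"] = ann["gene_symbol"].str.strip().str.upper()
    return ann.reset_index(drop=True)


def write_annotation(path, ann: pd.DataFrame) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_metadata(path, cohort: str = "") -> pd.DataFrame:
    """CSV metadata (sample_id, group, age, sex[, cohort]) -> validated frame."""
    with Path(path).open(encoding="utf-8", newline="") as fh:
        records = list(csv.DictReader(fh))
    if not records:
        raise FormatError(f"{path}: empty metadata file")
    meta = make_metadata(records)
    if cohort:
        meta["cohort"] = cohort
    return meta


def write_metadata(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, index=False)


def write_table(rows, path, key=None, allow_empty: bool = False) -> None:
    """Write a result table as deterministic TSV.

    Floats are rendered at 6 significant digits; rows are sorted by ``key``
    (a column name or list of names) when given, so reruns are byte-stable.
    """
    df = pd.DataFrame(rows)
    if df.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path}; pass allow_empty=True")
    if key is not None and not df.empty:
        df = df.sort_values(key, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_wide_ratio_table(path) -> tuple[dict[str, pd.DataFrame], list[CellTypePanel]]:
    """Read a wide published ratio table (cell_type, gene, one column per cohort).

    Returns per-cohort long-format ratio tables plus the per-cell-type gene
    panels implied by the table — the shape needed to replay a published
    shared-gene selection from its printed values.
    """
    wide = pd.read_csv(path, sep="\t")
    cohorts = [c for c in wide.columns if c not in ("cell_type", "gene")]
    tables = {
        c: pd.DataFrame({"gene": wide["gene"].str.upper(), "ratio": wide[c], "cohort": c})
        for c in cohorts
    }
    panels = [
        CellTypePanel(ct, sub["gene"].tolist())
        for ct, sub in wide.groupby("cell_type", sort=False)
    ]
    return tables, panels
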