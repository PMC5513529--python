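"""Synthetic whole-tissue expression cohorts with known cell-type structure.

Real brain expression series are mixtures: each sample's value for a gene is
a proportion-weighted sum of that gene's expression across cell types, so a
disease signal confined to one cell type is diluted by all the others. The
generator reproduces exactly that structure with a known ground truth:

* a signature matrix in which each marker gene is ``enrichment_factor``-fold
  higher in its home cell type than anywhere else;
* per-sample tissue values formed by mixing the signatures with fixed group
  proportions, with disease samples applying a log2 fold change to affected
  cell types' intrinsic expression (and optionally shifting composition —
  the two mechanisms a marker-panel readout confounds);
* multi-probe genes with deterministic per-probe offsets, multiplicative
  log-normal noise, and ages drawn per group.

Everything is reproducible from the seed, and every cohort can be written
out in the same file formats the readers consume, so the whole pipeline is
testable end to end with no external data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .model import CellTypePanel, ExpressionMatrix, make_metadata

CNS_CELL_TYPES = (
    "neuron",
    "microglia",
    "astrocyte",
    "endothelia",
    "newly formed oligodendrocyte",
    "myelinating oligodendrocyte",
)

DEFAULT_PROPORTIONS = {
    "neuron": 0.40,
    "microglia": 0.10,
    "astrocyte": 0.20,
    "endothelia": 0.10,
    "newly formed oligodendrocyte": 0.05,
    "myelinating oligodendrocyte": 0.15,
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    noise_sd is the SD of multiplicative log-normal noise in log2 units;
    enrichment_factor is the fold by which a marker exceeds its level in
    every other cell type; disease_effects maps cell type -> log2 fold
    change applied to that type's intrinsic expression in disease samples;
    effect_gene_sd adds per-gene heterogeneity around those means.
    """

    n_genes: int = 4000
    cell_types: tuple = CNS_CELL_TYPES
    markers_per_type: int = 500
    enrichment_factor: float = 10.0
    baseline_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    disease_effects: dict = field(default_factory=dict)
    proportion_shift: dict = field(default_factory=dict)
    n_disease: int = 10
    n_control: int = 10
    probes_per_gene: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    noise_sd: float = 0.3
    age_ranges: dict = field(default_factory=lambda: {"disease": (70, 95), "control": (70, 99)})
    effect_gene_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        if self.n_genes < len(self.cell_types) * self.markers_per_type:
            raise ValueError("n_genes must cover cell_types x markers_per_type markers")
        if not self.enrichment_factor > 1:
            raise ValueError("enrichment_factor must exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_disease < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        for label, props in (("baseline", self.baseline_proportions),
                             ("disease", self.group_proportions("disease"))):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} proportions sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"negative {label} proportion after shift")
        if set(self.baseline_proportions) != set(self.cell_types):
            raise ValueError("baseline_proportions must cover exactly the cell types")

    def group_proportions(self, group: str) -> dict:
        """Mixing fractions for a group; disease applies proportion_shift."""
        props = dict(self.baseline_proportions)
        if group == "disease":
            for ct, delta in self.proportion_shift.items():
                props[ct] = props.get(ct, 0.0) + delta
        return props


@dataclass
class GroundTruthLedger:
    """What the generator injected, for recovery checks."""

    home_cell_type: dict            # gene -> its home type ("" for non-markers)
    panels: dict                    # cell type -> marker gene list
    disease_effects: dict           # cell type -> mean log2 effect
    proportion_shift: dict
    proportions: dict               # group -> {cell type: fraction} (fixed per group)
    gene_effects: dict              # cell type -> {gene: realized log2 effect}
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def make_signatures(cfg: SyntheticConfig) -> tuple[pd.DataFrame, list[CellTypePanel]]:
    """Cell-type signature matrix (cell types x genes) plus true marker panels.

    Gene base levels are log-normal; each marker's home-type expression is
    ``enrichment_factor`` times its level in every other type, non-marker
    genes are uniform across types. Panels are disjoint by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base = np.exp2(rng.normal(7.0, 1.0, size=cfg.n_genes))
    sig = pd.DataFrame(
        np.tile(base, (len(cfg.cell_types), 1)),
        index=list(cfg.cell_types), columns=genes,
    )
    panels = []
    for k, ct in enumerate(cfg.cell_types):
        start = k * cfg.markers_per_type
        markers = genes[start:start + cfg.markers_per_type]
        sig.loc[ct, markers] *= cfg.enrichment_factor
        panels.append(CellTypePanel(ct, markers))
    return sig, panels


def draw_gene_effects(cfg: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Realized per-gene log2 effects (genes x cell types).

    Each affected cell type's column is its mean effect plus N(0,
    effect_gene_sd) per-gene deviation; unaffected types are 0. Drawing
    these once and passing the frame to several cohorts gives "shared
    effect" diseases; drawing with different seeds gives independent ones.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    eff = pd.DataFrame(0.0, index=genes, columns=list(cfg.cell_types))
    for ct, mean in cfg.disease_effects.items():
        eff[ct] = mean + rng.normal(0.0, cfg.effect_gene_sd, size=cfg.n_genes)
    return eff


def _probe_offset(seed: int, gene: str, j: int) -> float:
    """Deterministic multiplicative probe offset in [2^-0.5, 2^0.5].

    The first probe of a gene reports the tissue value itself (offset 1);
    additional probes get fixed offsets hashed from (seed, gene, index).
    Offsets are shared by disease and control, so they cancel in ratios.
    """
    if j == 0:
        return 1.0
    u = zlib.crc32(f"{seed}|{gene}|{j}".encode()) / 0xFFFFFFFF
    return float(np.exp2(u - 0.5))


def simulate_cohort(
    cfg: SyntheticConfig,
    signatures: pd.DataFrame,
    seed: int | None = None,
    cohort: str = "SYN",
    gene_effects: pd.DataFrame | None = None,
):
    """Simulate one disease-vs-control cohort at probe level.

    Returns ``(ExpressionMatrix(probe), annotation, metadata, ledger)``.
    Tissue value of gene g in a sample is the proportion-weighted sum over
    cell types of the type's expression of g, with disease samples applying
    2**effect to affected types' intrinsic expression and any composition
    shift; genes are then expanded to probes with fixed per-probe offsets
    and multiplied by log-normal noise. Bit-reproducible from the seed.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genes = list(signatures.columns)
    if gene_effects is None:
        gene_effects = draw_gene_effects(cfg, seed)
    gene_effects = gene_effects.loc[genes, list(cfg.cell_types)]

    props = {g: cfg.group_proportions(g) for g in ("disease", "control")}
    p_ctl = np.array([props["control"][ct] for ct in cfg.cell_types])
    p_dis = np.array([props["disease"][ct] for ct in cfg.cell_types])
    sig = signatures.loc[list(cfg.cell_types)].to_numpy()        # types x genes

    tissue_ctl = p_ctl @ sig
    tissue_dis = p_dis @ (sig * np.exp2(gene_effects.to_numpy().T))

    # expand genes to probes
    counts = np.array(sorted(cfg.probes_per_gene))
    weights = np.array([cfg.probes_per_gene[c] for c in counts], dtype=float)
    weights /= weights.sum()
    n_probes = rng.choice(counts, size=len(genes), p=weights)
    probe_ids, probe_gene_idx, offsets = [], [], []
    for gi, (gene, k) in enumerate(zip(genes, n_probes)):
        for j in range(k):
            probe_ids.append(f"{gene}_p{j + 1}")
            probe_gene_idx.append(gi)
            offsets.append(_probe_offset(cfg.seed, gene, j))
    probe_gene_idx = np.array(probe_gene_idx)
    offsets = np.array(offsets)

    sample_ids = [f"{cohort}_D{i + 1:02d}" for i in range(cfg.n_disease)] + \
                 [f"{cohort}_C{i + 1:02d}" for i in range(cfg.n_control)]
    groups = ["disease"] * cfg.n_disease + ["control"] * cfg.n_control

    clean = np.empty((len(probe_ids), len(sample_ids)))
    for s, grp in enumerate(groups):
        tissue = tissue_dis if grp == "disease" else tissue_ctl
        clean[:, s] = tissue[probe_gene_idx] * offsets
    if cfg.noise_sd > 0:
        clean = clean * np.exp2(rng.normal(0.0, cfg.noise_sd, size=clean.shape))

    matrix = ExpressionMatrix(
        pd.DataFrame(clean, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        row_kind="probe",
    )
    annotation = pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": [genes[i] for i in probe_gene_idx],
    })
    ages = {
        grp: rng.uniform(*cfg.age_ranges[grp], size=n)
        for grp, n in (("disease", cfg.n_disease), ("control", cfg.n_control))
    }
    meta = make_metadata({
        "sample_id": sample_ids,
        "group": groups,
        "age": np.round(np.concatenate([ages["disease"], ages["control"]]), 1),
        "sex": [("M", "F")[i] for i in rng.integers(0, 2, size=len(sample_ids))],
        "cohort": cohort,
    })

    n_marker_genes = len(cfg.cell_types) * cfg.markers_per_type
    home = {g: (cfg.cell_types[i // cfg.markers_per_type] if i < n_marker_genes else "")
            for i, g in enumerate(genes)}
    ledger = GroundTruthLedger(
        home_cell_type=home,
        panels={ct: [g for g, h in home.items() if h == ct] for ct in cfg.cell_types},
        disease_effects=dict(cfg.disease_effects),
        proportion_shift=dict(cfg.proportion_shift),
        proportions=props,
        gene_effects={ct: dict(zip(genes, np.round(gene_effects[ct].to_numpy(), 6)))
                      for ct in cfg.disease_effects},
        seed=seed,
    )
    return matrix, annotation, meta, ledger


def expected_panel_ratio(cfg: SyntheticConfig, cell_type: str) -> float:
    """Closed-form expected log2 tissue ratio for a marker of ``cell_type``.

    With enrichment E, control proportions p, disease proportions p', and
    mean log2 effects d, a marker of type T has relative expression E in T
    and 1 elsewhere (the gene's base level cancels), so

        ratio = log2( sum_ct p'_ct * e_ct * 2^d_ct  /  sum_ct p_ct * e_ct )

    with e_T = E and e_ct = 1 otherwise. Exact for a noise-free cohort with
    homogeneous effects; the dilution by other cell types is explicit.
    """
    if cell_type not in cfg.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    e = {ct: (cfg.enrichment_factor if ct == cell_type else 1.0) for ct in cfg.cell_types}
    p_ctl = cfg.group_proportions("control")
    p_dis = cfg.group_proportions("disease")
    den = sum(p_ctl[ct] * e[ct] for ct in cfg.cell_types)
    num = sum(p_dis[ct] * e[ct] * 2.0 ** cfg.disease_effects.get(ct, 0.0)
              for ct in cfg.cell_types)
    return float(np.log2(num / den))


def write_cohort(out_dir, cohort: str, matrix, annotation, meta, ledger) -> dict:
    """Write one cohort in the formats the readers consume; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{cohort}_series_matrix.txt",
        "annotation": out_dir / f"{cohort}_annotation.tsv",
        "metadata": out_dir / f"{cohort}_metadata.csv",
        "ledger": out_dir / f"{cohort}_ground_truth.json",
    }
    cio.write_series_matrix(paths["matrix"], matrix, meta)
    cio.write_annotation(paths["annotation"], annotation)
    cio.write_metadata(paths["metadata"], meta)
    ledger.to_json(paths["ledger"])
    return {k: str(v) for k, v in paths.items()}


def simulate_study(
    cfg: SyntheticConfig,
    cohorts: list[str],
    shared_effects: bool = True,
    seed: int | None = None,
):
    """Simulate several diseases over one signature matrix.

    With ``shared_effects`` the per-gene effect deviations are drawn once
    and reused in every cohort (diseases hit the same genes — this is what
    produces positive cross-disease panel correlations); otherwise each
    cohort draws its own.
    Returns ``(signatures, panels, {cohort: (matrix, annotation, meta, ledger)})``.
    """
    seed = cfg.seed if seed is None else seed
    signatures, panels = make_signatures(cfg)
    shared = draw_gene_effects(cfg, seed) if shared_effects else None
    out = {}
    for k, label in enumerate(cohorts):
        eff = shared if shared_effects else draw_gene_effects(cfg, seed + 1000 + k)
        out[label] = simulate_cohort(
            cfg, signatures, seed=seed + 1 + k, cohort=label, gene_effects=eff
        )
    return signatures, panels, out
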