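"""Simulation studies that validate the statistical kernel and the generator.

These are the package's own calibration experiments: type-I error of the
panel tests under simulated nulls, recovery of the closed-form expected
panel ratio from synthetic mixtures, and cross-cohort correlation recovery
under shared versus independent disease effects. The analysis drivers, the
test suite, and the acceptance script all run these same routines.

Recovery runs the un-normalized route (simulate -> collapse -> ratio ->
project): the generator emits arrays already on a common scale, and
quantile normalization — a between-array correction — would bias ratios
when a sizeable fraction of genes truly shifts (see methods note).
"""

from __future__ import annotations

import numpy as np

from .differential import log2_ratio, project_panel
from .preprocess import collapse_probes
from .simulate import (
    SyntheticConfig,
    draw_gene_effects,
    expected_panel_ratio,
    make_signatures,
    simulate_cohort,
)
from .stats import one_sample_t, pair_correlation, winsorized_correlation


def type_one_error_one_sample_t(
    n_genes: int = 500, n_reps: int = 2000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the panel one-sample t under an i.i.d. normal null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        _, p, _, _ = one_sample_t(rng.standard_normal(n_genes))
        hits += p < alpha
    return hits / n_reps


def type_one_error_winsorized_correlation(
    n_genes: int = 500, n_reps: int = 2000, alpha: float = 0.05,
    c: float = 2.0, seed: int = 0,
) -> float:
    """Rejection rate of the winsorized correlation test under independence."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n_genes)
        y = rng.standard_normal(n_genes)
        _, p, _ = winsorized_correlation(x, y, c)
        hits += p < alpha
    return hits / n_reps


def _cohort_panel_vector(cfg, signatures, panels, cell_type, seed, cohort="SYN",
                         gene_effects=None):
    matrix, ann, meta, _ = simulate_cohort(cfg, signatures, seed=seed,
                                           cohort=cohort, gene_effects=gene_effects)
    rt = log2_ratio(collapse_probes(matrix, ann), meta, cohort)
    panel = next(p for p in panels if p.cell_type == cell_type)
    return project_panel(rt, panel)


def default_recovery_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The standard recovery study: default mixture, +1 log2 microglia effect."""
    kwargs = dict(disease_effects={"microglia": 1.0}, seed=seed)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def recovery_noise_free(seed: int = 0) -> float:
    """Max |panel ratio - closed form| for a noise-free default cohort."""
    cfg = default_recovery_config(seed=seed, noise_sd=0.0)
    signatures, panels = make_signatures(cfg)
    vec = _cohort_panel_vector(cfg, signatures, panels, "microglia", seed)
    expected = expected_panel_ratio(cfg, "microglia")
    return float(np.max(np.abs(vec.ratios["ratio"].to_numpy() - expected)))


def recovery_noisy(n_seeds: int = 20, base_seed: int = 0) -> np.ndarray:
    """Per-seed deviation of the noisy panel mean from the closed form."""
    devs = []
    for k in range(n_seeds):
        seed = base_seed + k
        cfg = default_recovery_config(seed=seed)
        signatures, panels = make_signatures(cfg)
        vec = _cohort_panel_vector(cfg, signatures, panels, "microglia", seed)
        devs.append(vec.ratios["ratio"].mean()
                    - expected_panel_ratio(cfg, "microglia"))
    return np.asarray(devs)


def correlation_recovery(
    shared_effects: bool, n_seeds: int = 20, base_seed: int = 0,
    effect_gene_sd: float = 0.5,
) -> np.ndarray:
    """Microglia cross-cohort r for simulated disease pairs, one per seed.

    With shared effects the two diseases reuse the same per-gene effect
    draws (gene-level SD ``effect_gene_sd``); otherwise each draws its own.
    """
    rs = []
    for k in range(n_seeds):
        seed = base_seed + 7919 * k
        cfg = default_recovery_config(seed=seed, effect_gene_sd=effect_gene_sd)
        signatures, panels = make_signatures(cfg)
        eff_a = draw_gene_effects(cfg, seed)
        eff_b = eff_a if shared_effects else draw_gene_effects(cfg, seed + 1)
        vec_a = _cohort_panel_vector(cfg, signatures, panels, "microglia",
                                     seed + 2, "A", eff_a)
        vec_b = _cohort_panel_vector(cfg, signatures, panels, "microglia",
                                     seed + 3, "B", eff_b)
        rs.append(pair_correlation(vec_a, vec_b).r)
    return np.asarray(rs)
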