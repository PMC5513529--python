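"""Replay the published shared-gene selection from its printed ratios.

data/published_marker_ratios.tsv transcribes the published per-gene log2
disease/control ratios for microglia, astrocyte, and endothelia markers in
three neurodegenerative cohorts (AD, MS, PD). Applying the threshold-0.5
selection should reproduce the printed memberships: nine microglia genes
common to all three diseases; astrocyte and endothelia genes common to MS
and PD only, with AD below threshold.

    python analysis/05_shared_gene_replay.py
"""

from pathlib import Path

from cnspanel import shared_genes
from cnspanel import io as cio

PUBLISHED = Path(__file__).resolve().parent.parent / "data" / "published_marker_ratios.tsv"


def main() -> None:
    tables, panels = cio.read_wide_ratio_table(PUBLISHED)
    by_ct = {p.cell_type: p for p in panels}

    common3 = shared_genes(tables, by_ct["microglia"], 0.5, required={"AD", "MS", "PD"})
    print(f"microglia genes above 0.5 in AD, MS and PD ({len(common3)}):")
    print("  " + ", ".join(common3["gene"]))

    for ct in ("astrocyte", "endothelia"):
        ms_pd = shared_genes(tables, by_ct[ct], 0.5, required={"MS", "PD"})
        n_ad = int((ms_pd["AD"] >= 0.5).sum())
        print(f"{ct} genes above 0.5 in MS and PD ({len(ms_pd)}), "
              f"of which {n_ad} also pass in AD:")
        print("  " + ", ".join(ms_pd["gene"]))


if __name__ == "__main__":
    main()
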