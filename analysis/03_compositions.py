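#!/usr/bin/env python
"""Build per-sample and pooled cell-type compositions.

Counts phenotypes per sample and per subtype (cell-weighted pooling),
merges the two antibody panels into one composition per stratum, derives
the aggregate rows (Total T cells, Total macrophages), and writes a
grouped summary rounded to 3 significant figures alongside the raw
composition matrices.
"""

import argparse
from pathlib import Path

import pandas as pd

from plexcompo import phenotyping as ph
from plexcompo.panels import DEFAULT_PANELS


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--compartment", choices=["all", "dermis", "epidermis"],
                    default="all")
    args = ap.parse_args()

    by_sample, pooled = {}, {}
    for name, panel in DEFAULT_PANELS.items():
        gated = pd.read_csv(args.results / f"gated_{name}.tsv", sep="\t")
        by_sample[name] = ph.composition(
            gated, by="sample_id", compartment=args.compartment,
            categories=panel.phenotypes,
        )
        pooled[name] = ph.pool_compositions(
            gated, compartment=args.compartment, categories=panel.phenotypes
        )
        by_sample[name].to_csv(args.results / f"composition_{name}_by_sample.csv")

    merged_samples = ph.merge_panel_matrices(
        by_sample["tcell"], by_sample["macrophage"]
    )
    merged_samples.to_csv(args.results / "composition_merged_by_sample.csv")
    merged_pooled = ph.merge_panel_matrices(pooled["tcell"], pooled["macrophage"])
    summary = ph.table1_style_summary(merged_pooled)
    summary.to_csv(args.results / "composition_summary.tsv", sep="\t")
    print(f"pooled merged composition ({args.compartment}), "
          "3 significant figures:")
    print(summary.drop(columns=["n_cells"], errors="ignore").T.to_string())


if __name__ == "__main__":
    main()
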