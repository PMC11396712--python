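#!/usr/bin/env python
"""Simulate the synthetic study inputs.

Generates (a) two-panel per-cell intensity tables for a cohort of four
lichen-planus-like subtypes plus non-diseased controls, with per-sample
compositions drawn around the published subtype compositions, and (b) a
NanoString-style negative-binomial count matrix with planted fold changes.
Writes the tables plus the ground truth under the results directory.
"""

import argparse
from pathlib import Path

from plexcompo import synthetic


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--samples-per-subtype", type=int, default=5)
    ap.add_argument("--cells-per-sample", type=int, default=2000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    cfg = synthetic.default_cohort_config(
        samples_per_subtype=args.samples_per_subtype,
        cells_per_sample=args.cells_per_sample,
        seed=args.seed,
    )
    cohort = synthetic.simulate_two_panel_cohort(cfg)
    for name, table in cohort.tables.items():
        synthetic.write_cell_table(table, args.results / f"cells_{name}.tsv")
        synthetic.write_truth(
            cohort.truths[name],
            args.results / f"truth_cells_{name}.tsv",
            args.results / "truth_compositions.tsv",
        )
        print(f"panel {name}: {len(table)} cells, "
              f"{table['sample_id'].nunique()} samples")

    groups = ["ctrl"] * 10 + ["case"] * 10
    counts, lfc = synthetic.simulate_count_matrix(
        400, 20, groups,
        planted_log2fc={"G050": 2.0, "G060": -1.5, "G070": 1.0},
        nb_dispersion=0.05, seed=args.seed,
    )
    synthetic.write_count_matrix(counts, args.results / "counts.csv")
    lfc.to_csv(args.results / "truth_log2fc.csv")
    print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1] - 1} samples "
          f"({int(counts['housekeeping'].sum())} housekeeping)")


if __name__ == "__main__":
    main()
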