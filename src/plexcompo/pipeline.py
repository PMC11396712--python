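"""End-to-end cohort pipeline: simulate -> gate -> compose -> test.

Glues the stage modules together the way the analysis scripts and the
reproduction script use them, and computes the truth-vs-estimate summaries
used to validate the whole chain on synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compstats, gating, phenotyping, synthetic
from .panels import MACROPHAGE_PANEL, T_CELL_PANEL


@dataclass
class CohortPipelineResult:
    cohort: synthetic.SimulatedCohort
    gated: dict[str, pd.DataFrame]
    fits: dict[str, dict]
    comp_by_sample: dict[str, pd.DataFrame]  # per panel
    comp_pooled: dict[str, pd.DataFrame]  # per panel, by subtype
    merged_by_sample: pd.DataFrame
    merged_pooled: pd.DataFrame
    truth_pooled: pd.DataFrame  # realized truth labels, both panels combined
    gating_accuracy: dict[str, float]  # per marker, across panels
    extras: dict = field(default_factory=dict)


def pooled_truth_composition(
    cohort: synthetic.SimulatedCohort, compartment: str = "all"
) -> pd.DataFrame:
    """Cell-weighted pooled composition of the realized truth labels
    (both panels' cells combined), as percentages per subtype."""
    frames = []
    for name, table in cohort.tables.items():
        truth = cohort.truths[name].cells
        frame = table[["sample_id", "subtype", "compartment", "cell_id"]].copy()
        frame["phenotype"] = truth.loc[frame["cell_id"], "true_type"].to_numpy()
        frames.append(frame)
    cells = pd.concat(frames, ignore_index=True)
    return phenotyping.pool_compositions(cells, compartment=compartment)


def run_cohort_pipeline(
    config: synthetic.CohortConfig,
    families=("normal", "lognormal"),
    seed: int = 0,
    compartment: str = "all",
) -> CohortPipelineResult:
    """Simulate a two-panel cohort, gate it, and build all compositions."""
    cohort = synthetic.simulate_two_panel_cohort(config)
    gated, fits, comp_by_sample, comp_pooled, accuracy = {}, {}, {}, {}, {}
    for panel in (T_CELL_PANEL, MACROPHAGE_PANEL):
        g, f = gating.gate_cells(
            cohort.tables[panel.name], panel, mode="pooled",
            families=families, seed=seed,
        )
        gated[panel.name] = g
        fits[panel.name] = f
        comp_by_sample[panel.name] = phenotyping.composition(
            g, by="sample_id", compartment=compartment,
            categories=panel.phenotypes,
        )
        comp_pooled[panel.name] = phenotyping.pool_compositions(
            g, compartment=compartment, categories=panel.phenotypes
        )
        truth = cohort.truths[panel.name].cells
        for m in panel.markers:
            tp = truth.loc[g["cell_id"], f"true_pos_{m}"].to_numpy()
            accuracy[m] = float((g[f"{m}_call"].to_numpy() == tp).mean())

    merged_by_sample = phenotyping.merge_panel_matrices(
        comp_by_sample["tcell"], comp_by_sample["macrophage"]
    )
    merged_pooled = phenotyping.merge_panel_matrices(
        comp_pooled["tcell"], comp_pooled["macrophage"]
    )
    truth_pooled = pooled_truth_composition(cohort, compartment=compartment)
    return CohortPipelineResult(
        cohort=cohort, gated=gated, fits=fits,
        comp_by_sample=comp_by_sample, comp_pooled=comp_pooled,
        merged_by_sample=merged_by_sample, merged_pooled=merged_pooled,
        truth_pooled=truth_pooled, gating_accuracy=accuracy,
    )


def composition_error(result: CohortPipelineResult) -> pd.DataFrame:
    """|estimated - truth| in percentage points, per subtype x category."""
    truth = result.truth_pooled
    est = result.merged_pooled
    cats = [c for c in phenotyping.category_columns(truth) if c in est.columns]
    err = (est.loc[truth.index, cats].astype(float) - truth[cats].astype(float)).abs()
    return err


def ordination_summary(
    result: CohortPipelineResult, n_perm: int = 999, seed: int = 0
) -> dict:
    """Bray-Curtis / NMDS / PERMANOVA / SIMPER / CLR-ANOVA on the merged
    per-sample compositions."""
    comp = result.merged_by_sample
    groups = comp["subtype"].to_numpy()
    D = compstats.bc_distance_matrix(comp)
    overall = compstats.permanova(D, groups, n_perm=n_perm, seed=seed)
    pairwise = compstats.permanova_pairwise(D, groups, n_perm=n_perm, seed=seed)
    ordination = compstats.nmds(D, k=2, n_restarts=20, seed=seed)
    anova = compstats.clr_anova(comp, groups)
    simper_ab = None
    if {"classical", "NDC"} <= set(groups):
        simper_ab = compstats.simper(
            comp, groups, "classical", "NDC", n_perm=n_perm, seed=seed
        )
    return {
        "distance": D,
        "permanova": overall,
        "pairwise": pairwise,
        "nmds": ordination,
        "clr_anova": anova,
        "simper_classical_vs_ndc": simper_ab,
    }


def pooled_fisher_tests(
    result: CohortPipelineResult,
    panel_name: str = "tcell",
    compartment: str = "all",
    n_mc: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fisher exact tests between subtype pairs on pooled phenotype counts
    of one panel (cells of a subtype combined into one composition)."""
    gated = result.gated[panel_name]
    sub = gated if compartment == "all" else gated[gated["compartment"] == compartment]
    counts = (
        sub.groupby(["subtype", "phenotype"], observed=True).size().unstack(fill_value=0)
    )
    rows = []
    labels = list(counts.index)
    seeds = iter(np.random.SeedSequence(seed).generate_state(
        len(labels) * (len(labels) - 1) // 2))
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            table = counts.loc[[a, b]].to_numpy()
            table = table[:, table.sum(axis=0) > 0]
            p = compstats.fisher_exact(table, n_mc=n_mc, seed=int(next(seeds) % 2**31))
            rows.append({"group_a": a, "group_b": b, "p_value": p, "n_mc": n_mc})
    return pd.DataFrame(rows)
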