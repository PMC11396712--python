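"""Cell-type compositions: per-sample and pooled percentages, derived totals,
and merging of the two antibody panels into one composition.

A composition is a row of percentages over mutually exclusive cell-type
categories (including "other"), summing to 100.  Pooling across samples of
a subtype is cell-weighted: all cells are concatenated first and then
counted, which is not the same as averaging per-sample percentages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

T_LINEAGES = ("CD4_T", "CD8_T", "Treg", "GranzymeB", "IL17A")
MACROPHAGE_PARTS = ("macrophage", "M1", "M2")

log = logging.getLogger(__name__)


def round_sig(x, digits: int = 3):
    """Round to ``digits`` significant figures (vectorized, 0 stays 0)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    factor = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(x[nz] * factor) / factor
    return out if out.ndim else float(out)


def composition(
    cells: pd.DataFrame,
    by: str = "sample_id",
    compartment: str = "all",
    categories=None,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Percentage composition of each stratum of ``by``.

    ``compartment`` restricts to "dermis" or "epidermis" ("all" keeps both).
    Returns a DataFrame indexed by the stratum label with one percentage
    column per category plus ``n_cells`` (and ``subtype`` when available).
    Rows sum to 100; empty strata are omitted with a logged warning.
    """
    if phenotype_col not in cells.columns:
        raise ValueError(f"cells lack a {phenotype_col!r} column")
    sub = cells
    if compartment != "all":
        sub = cells[cells["compartment"] == compartment]
    counts = sub.groupby([by, phenotype_col], observed=True).size().unstack(fill_value=0)
    if categories is not None:
        counts = counts.reindex(columns=list(categories), fill_value=0)
    empty = set(cells[by].unique()) - set(counts.index)
    for stratum in sorted(empty):
        log.warning("stratum %r has no cells in compartment %r", stratum, compartment)
    n_cells = counts.sum(axis=1)
    if (n_cells == 0).any():
        counts = counts[n_cells > 0]
        n_cells = n_cells[n_cells > 0]
    comp = 100.0 * counts.div(n_cells, axis=0)
    comp["n_cells"] = n_cells.astype(int)
    if by != "subtype" and "subtype" in cells.columns:
        comp.insert(0, "subtype", sub.groupby(by)["subtype"].first())
    return comp


def category_columns(comp: pd.DataFrame) -> list[str]:
    """Category columns of a composition frame (excludes metadata)."""
    return [c for c in comp.columns if c not in ("subtype", "n_cells")]


def pool_compositions(
    cells: pd.DataFrame,
    group_col: str = "subtype",
    compartment: str = "all",
    categories=None,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Cell-weighted pooled composition per group (concatenate, then count)."""
    return composition(
        cells, by=group_col, compartment=compartment,
        categories=categories, phenotype_col=phenotype_col,
    )


def derive_totals(comp: pd.DataFrame) -> pd.DataFrame:
    """Add aggregate columns: Total T cells and Total macrophages.

    Total T cells is the sum of the five T lineages (CD4+, CD8+, Treg,
    Granzyme B+, IL17A+).  Total macrophages sums the mutually exclusive
    CD68+ categories (CD68-only, M1, M2); M1/M2 remain as sub-fractions.
    """
    missing = [c for c in T_LINEAGES if c not in comp.columns]
    if missing:
        raise ValueError(f"missing T-lineage categories: {missing}")
    out = comp.copy()
    out["Total T cells"] = comp[list(T_LINEAGES)].sum(axis=1)
    mac = [c for c in MACROPHAGE_PARTS if c in comp.columns]
    if mac:
        out["Total macrophages"] = comp[mac].sum(axis=1)
    return out


def merge_panels(
    comp_tcell: pd.Series,
    comp_mac: pd.Series,
    n_tcell: int | None = None,
    n_mac: int | None = None,
) -> pd.Series:
    """Merge one stratum's T-cell-panel and macrophage-panel compositions.

    Each panel only names the cell types its markers can see; everything
    else lands in its "other" bin (e.g. macrophages are "other" on the
    T-cell panel).  Named categories are therefore taken from their home
    panel (T lineages from the T-cell panel; macrophage/M1/M2/neutrophil
    from the macrophage panel), keratinocyte — visible on both — is a
    cell-count-weighted average, and "other" is the remainder
    100 - sum(named) - keratinocyte, clipped at 0; the result is
    renormalized to 100.  Raises if a category other than keratinocyte or
    "other" is claimed by both panels.
    """
    t = comp_tcell.drop(labels=["subtype", "n_cells"], errors="ignore").astype(float)
    m = comp_mac.drop(labels=["subtype", "n_cells"], errors="ignore").astype(float)
    if "keratinocyte" not in t.index or "keratinocyte" not in m.index:
        raise ValueError("both panels must report keratinocyte")
    if "other" not in t.index or "other" not in m.index:
        raise ValueError("both panels must report 'other'")
    shared = {"keratinocyte", "other"}
    t_named = [c for c in t.index if c not in shared]
    m_named = [c for c in m.index if c not in shared]
    overlap = set(t_named) & set(m_named)
    if overlap:
        raise ValueError(f"category claimed by both panels: {sorted(overlap)}")

    if n_tcell is None:
        n_tcell = int(comp_tcell.get("n_cells", 1))
    if n_mac is None:
        n_mac = int(comp_mac.get("n_cells", 1))
    w_t = n_tcell / (n_tcell + n_mac)
    ker = w_t * t["keratinocyte"] + (1.0 - w_t) * m["keratinocyte"]

    merged = {c: t[c] for c in t_named}
    merged.update({c: m[c] for c in m_named})
    merged["keratinocyte"] = ker
    merged["other"] = max(100.0 - sum(merged.values()), 0.0)
    out = pd.Series(merged)
    return 100.0 * out / out.sum()


def merge_panel_matrices(
    comp_tcell: pd.DataFrame, comp_mac: pd.DataFrame
) -> pd.DataFrame:
    """Row-wise :func:`merge_panels` over strata shared by both panels."""
    common = comp_tcell.index.intersection(comp_mac.index)
    rows = {
        s: merge_panels(comp_tcell.loc[s], comp_mac.loc[s]) for s in common
    }
    merged = pd.DataFrame.from_dict(rows, orient="index")
    merged.index.name = comp_tcell.index.name
    if "subtype" in comp_tcell.columns:
        merged.insert(0, "subtype", comp_tcell.loc[common, "subtype"])
    return merged


def table1_style_summary(
    comp_by_group: pd.DataFrame, digits: int = 3
) -> pd.DataFrame:
    """Grouped summary with derived totals, rounded to significant figures."""
    out = derive_totals(comp_by_group)
    cats = [c for c in out.columns if c not in ("subtype", "n_cells")]
    out[cats] = round_sig(out[cats].to_numpy(), digits)
    return out
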