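"""Synthetic multiplex-IHC cell tables and NanoString-style count matrices.

Real segmented-cell exports for this kind of study are rarely deposited, so
every downstream stage is exercised on simulated data with known ground
truth.  The generator emulates:

* per-marker bimodal intensity distributions (a negative and a positive
  stained component, by default log-normal, ~5.5 pooled SDs apart);
* per-subtype cell-type mixing proportions centered on published dermal
  compositions of lichen planus subtypes (classical, genital, oral,
  lichen planopilaris) and non-diseased control skin;
* sample-to-sample compositional variability via a Dirichlet distribution
  around each subtype's target composition;
* a two-panel design on serial sections (T-cell and macrophage panels)
  sharing each sample's true composition;
* a dermis/epidermis compartment label with keratinocytes enriched in the
  epidermis;
* negative-binomial gene counts with housekeeping genes and planted
  log2 fold changes for the differential-expression screen.

All randomness flows through explicit integer seeds; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._families import FAMILIES, dist_mean, sample
from .panels import GLOBAL_SIGNATURES, MACROPHAGE_PANEL, T_CELL_PANEL, PanelSpec

# Published dermal cell-type percentages per subtype ("macrophage" is the
# total macrophage pool; M1/M2 are sub-fractions of it, listed separately
# so the simulated cell types are mutually exclusive).
TABLE1_PERCENT: dict[str, dict[str, float]] = {
    "classical": {
        "CD4_T": 8.5, "CD8_T": 6.44, "Treg": 30.3, "GranzymeB": 1.15,
        "IL17A": 2.39, "keratinocyte": 24.9, "macrophage": 12.3,
        "M1": 0.0397, "M2": 0.176, "neutrophil": 0.301, "other": 13.8,
    },
    "genital": {
        "CD4_T": 3.14, "CD8_T": 4.87, "Treg": 14.6, "GranzymeB": 0.619,
        "IL17A": 1.54, "keratinocyte": 25.4, "macrophage": 9.26,
        "M1": 0.243, "M2": 0.191, "neutrophil": 2.51, "other": 38.1,
    },
    "oral": {
        "CD4_T": 0.108, "CD8_T": 5.27, "Treg": 39.2, "GranzymeB": 0.434,
        "IL17A": 8.02, "keratinocyte": 24.6, "macrophage": 11.2,
        "M1": 0.266, "M2": 0.124, "neutrophil": 0.730, "other": 10.5,
    },
    "planopilaris": {
        "CD4_T": 0.069, "CD8_T": 2.17, "Treg": 3.51, "GranzymeB": 0.110,
        "IL17A": 1.18, "keratinocyte": 54.0, "macrophage": 3.96,
        "M1": 0.0092, "M2": 0.212, "neutrophil": 0.446, "other": 34.6,
    },
    "NDC": {
        "CD4_T": 0.0, "CD8_T": 0.373, "Treg": 2.29, "GranzymeB": 0.117,
        "IL17A": 0.831, "keratinocyte": 62.1, "macrophage": 0.193,
        "M1": 0.0, "M2": 0.0126, "neutrophil": 0.0084, "other": 34.1,
    },
}

T_LINEAGES = ("CD4_T", "CD8_T", "Treg", "GranzymeB", "IL17A")


def table1_targets() -> dict[str, dict[str, float]]:
    """Mutually-exclusive cell-type fractions per subtype, renormalized to 1.

    The total-macrophage pool is split into M1, M2 and a CD68-only
    remainder so that every cell carries exactly one true type.
    """
    out: dict[str, dict[str, float]] = {}
    for subtype, row in TABLE1_PERCENT.items():
        frac = dict(row)
        frac["macrophage"] = max(frac["macrophage"] - frac["M1"] - frac["M2"], 0.0)
        total = sum(frac.values())
        out[subtype] = {k: v / total for k, v in frac.items()}
    return out


@dataclass(frozen=True)
class MarkerModel:
    """Two-component intensity model for one marker.

    ``(neg_mean, neg_sd)`` and ``(pos_mean, pos_sd)`` are family-specific
    parameter pairs: (mean, sd) for ``normal``, (meanlog, sdlog) for
    ``lognormal``, (shape, scale) for ``weibull``.  The positive component
    must have the larger distribution mean.
    """

    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float
    family: str = "lognormal"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (dist_mean(self.family, self.pos)) > dist_mean(self.family, self.neg):
            raise ValueError("positive component must have larger mean")

    @property
    def neg(self) -> tuple[float, float]:
        return (self.neg_mean, self.neg_sd)

    @property
    def pos(self) -> tuple[float, float]:
        return (self.pos_mean, self.pos_sd)


def default_marker_models(markers) -> dict[str, MarkerModel]:
    """Log-normal components ~5.5 pooled SDs apart, typical of clean stains."""
    return {m: MarkerModel(0.0, 0.4, 2.2, 0.4, "lognormal") for m in markers}


@dataclass
class CohortConfig:
    """Everything needed to simulate one cohort.

    ``composition_targets`` maps subtype -> cell type -> fraction; each row
    must sum to 1.  ``dirichlet_concentration`` controls sample-to-sample
    scatter around the subtype target (``inf`` = no scatter).  Cell types
    with a target of exactly 0 stay 0 in every sample.
    """

    subtypes: tuple[str, ...]
    samples_per_subtype: int
    cells_per_sample: int
    composition_targets: dict[str, dict[str, float]]
    marker_models: dict[str, MarkerModel]
    dirichlet_concentration: float = 200.0
    epidermis_frac_keratinocyte: float = 0.8
    epidermis_frac_other: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def cell_types(self) -> tuple[str, ...]:
        first = self.composition_targets[self.subtypes[0]]
        return tuple(first.keys())

    def validate(self) -> None:
        if self.samples_per_subtype < 1 or self.cells_per_sample < 1:
            raise ValueError("samples_per_subtype and cells_per_sample must be >= 1")
        if not self.dirichlet_concentration > 0:
            raise ValueError("dirichlet_concentration must be positive")
        types = None
        for subtype in self.subtypes:
            row = self.composition_targets.get(subtype)
            if row is None:
                raise ValueError(f"no composition target for subtype {subtype!r}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"composition target for {subtype!r} must sum to 1")
            if any(v < 0 for v in row.values()):
                raise ValueError("composition targets must be nonnegative")
            if types is None:
                types = set(row)
            elif set(row) != types:
                raise ValueError("all subtypes must share one cell-type set")


def default_cohort_config(
    samples_per_subtype: int = 5,
    cells_per_sample: int = 2000,
    seed: int = 1,
    dirichlet_concentration: float = 200.0,
) -> CohortConfig:
    """Cohort centered on the published subtype compositions."""
    markers = sorted(set(T_CELL_PANEL.markers) | set(MACROPHAGE_PANEL.markers))
    return CohortConfig(
        subtypes=tuple(TABLE1_PERCENT),
        samples_per_subtype=samples_per_subtype,
        cells_per_sample=cells_per_sample,
        composition_targets=table1_targets(),
        marker_models=default_marker_models(markers),
        dirichlet_concentration=dirichlet_concentration,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Per-cell and per-sample truth for one simulated table."""

    cells: pd.DataFrame  # cell_id-indexed: true_type + true_pos_<marker> columns
    sample_compositions: pd.DataFrame  # sample x cell-type true fractions


def draw_sample_compositions(config: CohortConfig, rng=None) -> pd.DataFrame:
    """Per-sample true compositions: Dirichlet around each subtype target.

    Returns a DataFrame indexed by sample_id with a ``subtype`` column and
    one fraction column per cell type (rows sum to 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    types = list(config.cell_types)
    rows, index = [], []
    for subtype in config.subtypes:
        target = np.array([config.composition_targets[subtype][t] for t in types])
        nonzero = target > 0
        for i in range(config.samples_per_subtype):
            p = np.zeros(len(types))
            if math.isinf(config.dirichlet_concentration):
                p = target.copy()
            else:
                alpha = config.dirichlet_concentration * target[nonzero]
                p[nonzero] = rng.dirichlet(alpha)
            rows.append(p)
            index.append(f"{subtype}-s{i + 1}")
    comp = pd.DataFrame(rows, index=pd.Index(index, name="sample_id"), columns=types)
    comp.insert(0, "subtype", [s.rsplit("-s", 1)[0] for s in index])
    return comp


def simulate_cell_table(
    config: CohortConfig,
    panel: PanelSpec = T_CELL_PANEL,
    compositions: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a segmented-cell intensity table for one antibody panel.

    Each cell gets a true type drawn from its sample's true composition, a
    marker-positivity pattern implied by the panel's signatures, intensities
    drawn from the corresponding component of each marker's model, and a
    dermis/epidermis compartment label.  Passing the same ``compositions``
    to several panels emulates serial sections sharing one ground truth.
    """
    for subtype in config.subtypes:
        for cell_type in config.composition_targets[subtype]:
            panel.signature(cell_type)  # raises KeyError if unknown
    missing = [m for m in panel.markers if m not in config.marker_models]
    if missing:
        raise ValueError(f"no marker model for {missing}")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    if compositions is None:
        compositions = draw_sample_compositions(config, rng)
    types = [t for t in config.cell_types]

    frames, truth_frames = [], []
    for sample_id, row in compositions.iterrows():
        p = row[types].to_numpy(dtype=float)
        counts = rng.multinomial(config.cells_per_sample, p)
        true_type = np.repeat(types, counts)
        rng.shuffle(true_type)
        n = len(true_type)
        is_ker = true_type == "keratinocyte"
        p_epi = np.where(
            is_ker, config.epidermis_frac_keratinocyte, config.epidermis_frac_other
        )
        compartment = np.where(rng.random(n) < p_epi, "epidermis", "dermis")
        cell_ids = [f"{sample_id}-c{i:05d}" for i in range(n)]
        cells = pd.DataFrame(
            {
                "sample_id": sample_id,
                "subtype": row["subtype"],
                "panel": panel.name,
                "compartment": compartment,
                "cell_id": cell_ids,
            }
        )
        truth = pd.DataFrame({"cell_id": cell_ids, "true_type": true_type})
        for marker in panel.markers:
            model = config.marker_models[marker]
            positive = np.array(
                [marker in panel.signature(t) for t in types], dtype=bool
            )[[types.index(t) for t in true_type]]
            x = np.empty(n)
            x[~positive] = sample(rng, model.family, model.neg, int((~positive).sum()))
            x[positive] = sample(rng, model.family, model.pos, int(positive.sum()))
            cells[marker] = x
            truth[f"true_pos_{marker}"] = positive
        frames.append(cells)
        truth_frames.append(truth)

    table = pd.concat(frames, ignore_index=True)
    truth_cells = pd.concat(truth_frames, ignore_index=True).set_index("cell_id")
    return table, GroundTruth(cells=truth_cells, sample_compositions=compositions)


@dataclass
class SimulatedCohort:
    config: CohortConfig
    compositions: pd.DataFrame  # shared per-sample truth (fractions)
    tables: dict[str, pd.DataFrame]  # panel name -> cell table
    truths: dict[str, GroundTruth]


def simulate_two_panel_cohort(
    config: CohortConfig,
    panels: tuple[PanelSpec, ...] = (T_CELL_PANEL, MACROPHAGE_PANEL),
) -> SimulatedCohort:
    """Simulate both antibody panels from one shared per-sample truth."""
    seeds = np.random.SeedSequence(config.seed).generate_state(len(panels) + 1)
    seeds = [int(s % (2**31)) for s in seeds]
    comps = draw_sample_compositions(config, np.random.default_rng(seeds[0]))
    tables, truths = {}, {}
    for panel, s in zip(panels, seeds[1:]):
        table, truth = simulate_cell_table(config, panel, compositions=comps, seed=s)
        tables[panel.name] = table
        truths[panel.name] = truth
    return SimulatedCohort(config=config, compositions=comps, tables=tables, truths=truths)


def simulate_count_matrix(
    n_genes: int,
    n_housekeeping: int,
    groups,
    planted_log2fc: dict[str, float] | None = None,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    base_mean: float = 200.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial genes x samples counts with planted fold changes.

    ``groups`` is one label per sample; the first label encountered is the
    reference, and ``planted_log2fc`` (gene name -> log2 fold change) is
    applied to all non-reference samples.  Housekeeping genes are named
    ``HK...``, are flagged in a ``housekeeping`` column, and must have no
    planted effect.  Variance model: var = mu + nb_dispersion * mu^2.

    Returns the count table and the per-gene true log2 fold change.
    """
    if not 0 <= n_housekeeping < n_genes:
        raise ValueError("need 0 <= n_housekeeping < n_genes")
    if not nb_dispersion > 0:
        raise ValueError("nb_dispersion must be positive")
    planted_log2fc = dict(planted_log2fc or {})
    groups = list(groups)
    n_target = n_genes - n_housekeeping
    width = len(str(n_target))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_target)]
    hk = [f"HK{i + 1:02d}" for i in range(n_housekeeping)]
    for g in planted_log2fc:
        if g in hk or g.startswith("HK"):
            raise ValueError(f"planted fold change on housekeeping gene {g!r}")
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not among target genes")

    rng = np.random.default_rng(seed)
    all_genes = genes + hk
    mu0 = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_target)
    mu_hk = rng.lognormal(mean=np.log(4 * base_mean), sigma=0.3, size=n_housekeeping)
    baseline = np.concatenate([mu0, mu_hk])
    lfc = pd.Series(0.0, index=all_genes, name="true_log2fc")
    for g, v in planted_log2fc.items():
        lfc[g] = float(v)

    reference = groups[0]
    size = 1.0 / nb_dispersion
    counts = np.empty((n_genes, len(groups)), dtype=np.int64)
    for j, grp in enumerate(groups):
        mu = baseline if grp == reference else baseline * 2.0 ** lfc.to_numpy()
        counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    samples = [f"{g}_{j + 1}" for j, g in enumerate(groups)]
    df = pd.DataFrame(counts, index=pd.Index(all_genes, name="gene"), columns=samples)
    df.insert(0, "housekeeping", [g in hk for g in all_genes])
    return df, lfc


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """TSV with header sample_id, subtype, panel, compartment, cell_id, markers."""
    cells.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_truth(truth: GroundTruth, cells_path, compositions_path) -> None:
    truth.cells.to_csv(cells_path, sep="\t", float_format="%.6g")
    truth.sample_compositions.to_csv(compositions_path, sep="\t", float_format="%.6g")


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path)
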