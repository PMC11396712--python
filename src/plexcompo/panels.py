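"""Antibody panel definitions: markers, phenotype rules, and cell-type signatures.

A panel couples two views of the same biology:

* **rules** — how a gated cell (a set of per-marker positive/negative calls)
  is mapped to a composite phenotype label.  Rules are ordered by priority;
  the first rule whose required markers are all positive wins.  Rules may
  share a priority (e.g. M1/M2 macrophages), in which case the tie is broken
  by the posterior probability of each rule's distinguishing marker.
* **signatures** — which markers each true cell type expresses, used by the
  synthetic-data generator to paint ground-truth positivity onto cells.

Two panels mirror a dual-panel Opal multiplex IHC design on serial sections:
a T-cell panel (CD8, FoxP3, IL17A, GranzymeB, PanCK, CD4) and a macrophage
panel (pSTAT1, MPO, cMaf, PanCK, CD68).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

OTHER = "other"

# Cohort-wide cell types and the markers they express (across both panels).
# Within one panel, a type's signature is the intersection with that panel's
# markers; types invisible to a panel (no marker overlap) gate as "other".
GLOBAL_SIGNATURES: dict[str, tuple[str, ...]] = {
    "CD4_T": ("CD4",),
    "CD8_T": ("CD8",),
    "Treg": ("CD4", "FoxP3"),
    "GranzymeB": ("CD8", "GranzymeB"),
    "IL17A": ("CD8", "IL17A"),  # Tc17-like: CD8+ IL-17A producers
    "keratinocyte": ("PanCK",),
    "macrophage": ("CD68",),
    "M1": ("CD68", "pSTAT1"),
    "M2": ("CD68", "cMaf"),
    "neutrophil": ("MPO",),
    OTHER: (),
}


@dataclass(frozen=True)
class PhenotypeRule:
    """One line of a panel's gating hierarchy."""

    name: str
    requires: tuple[str, ...]
    priority: int


@dataclass(frozen=True)
class PanelSpec:
    name: str
    markers: tuple[str, ...]
    rules: tuple[PhenotypeRule, ...]
    signatures: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for rule in self.rules:
            missing = set(rule.requires) - set(self.markers)
            if missing:
                raise ValueError(
                    f"rule {rule.name!r} requires markers not on panel "
                    f"{self.name!r}: {sorted(missing)}"
                )

    @property
    def phenotypes(self) -> tuple[str, ...]:
        """Phenotype labels this panel can emit, 'other' last."""
        return tuple(r.name for r in self.rules) + (OTHER,)

    def signature(self, cell_type: str) -> tuple[str, ...]:
        """Markers of `cell_type` visible on this panel."""
        sig = self.signatures.get(cell_type)
        if sig is None:
            sig = GLOBAL_SIGNATURES.get(cell_type)
        if sig is None:
            raise KeyError(f"unknown cell type {cell_type!r}")
        return tuple(m for m in sig if m in self.markers)

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "markers": list(self.markers),
            "rules": [
                {"name": r.name, "requires": list(r.requires), "priority": r.priority}
                for r in self.rules
            ],
            "signatures": {k: list(v) for k, v in self.signatures.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            markers=tuple(doc["markers"]),
            rules=tuple(
                PhenotypeRule(r["name"], tuple(r["requires"]), int(r["priority"]))
                for r in doc["rules"]
            ),
            signatures={k: tuple(v) for k, v in doc.get("signatures", {}).items()},
        )


def _restrict_signatures(markers: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    return {
        t: tuple(m for m in sig if m in markers)
        for t, sig in GLOBAL_SIGNATURES.items()
    }


_T_MARKERS = ("CD8", "FoxP3", "IL17A", "GranzymeB", "PanCK", "CD4")
_M_MARKERS = ("pSTAT1", "MPO", "cMaf", "PanCK", "CD68")

# FoxP3 outranks everything (Tregs may co-express CD4); IL17A and GranzymeB
# outrank the bare lineage markers so Tc17/cytotoxic cells are not swallowed
# by CD8; PanCK last among positives.  Treg is FoxP3-only by default (CD4
# co-requirement configurable by editing the rule).
T_CELL_PANEL = PanelSpec(
    name="tcell",
    markers=_T_MARKERS,
    rules=(
        PhenotypeRule("Treg", ("FoxP3",), 0),
        PhenotypeRule("IL17A", ("IL17A",), 1),
        PhenotypeRule("GranzymeB", ("GranzymeB",), 2),
        PhenotypeRule("CD8_T", ("CD8",), 3),
        PhenotypeRule("CD4_T", ("CD4",), 4),
        PhenotypeRule("keratinocyte", ("PanCK",), 5),
    ),
    signatures=_restrict_signatures(_T_MARKERS),
)

# M1 and M2 share priority 0: a CD68+ pSTAT1+ cMaf+ cell is assigned to the
# polarization whose defining marker has the higher posterior.
MACROPHAGE_PANEL = PanelSpec(
    name="macrophage",
    markers=_M_MARKERS,
    rules=(
        PhenotypeRule("M1", ("CD68", "pSTAT1"), 0),
        PhenotypeRule("M2", ("CD68", "cMaf"), 0),
        PhenotypeRule("macrophage", ("CD68",), 1),
        PhenotypeRule("neutrophil", ("MPO",), 2),
        PhenotypeRule("keratinocyte", ("PanCK",), 3),
    ),
    signatures=_restrict_signatures(_M_MARKERS),
)

DEFAULT_PANELS = {"tcell": T_CELL_PANEL, "macrophage": MACROPHAGE_PANEL}
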