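"""Definition of the quantitative microbial element cycling (QMEC) qPCR panel.

The bundled panel mirrors the high-throughput SmartChip assay set used for
soil CNPS-cycle profiling: 71 functional-gene primer sets — 35 carbon-cycle
(degradation, fixation, methane metabolism), 22 nitrogen-cycle, 9
phosphorus-cycle and 5 sulfur-cycle genes — plus a single 16S rRNA reference
assay used for absolute quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

CATEGORIES = (
    "C_degradation",
    "C_fixation",
    "C_methane",
    "N",
    "P",
    "S",
    "reference_16S",
)

FUNCTIONAL_CATEGORIES = CATEGORIES[:-1]

# assay -> category; efficiencies default to 2.0 (perfect doubling per cycle)
_BUNDLED_ASSAYS = {
    "C_degradation": [
        "amyA", "apu", "sga", "pulA", "cex", "cbhI", "xylA", "abfA",
        "manB", "naglu", "chiA", "lig", "mnp", "glx", "pox", "pgu",
    ],
    "C_fixation": [
        "cbbL", "rbcL_II", "aclB", "accA", "acsA", "acsB", "mct",
        "smtA", "korA", "frdA", "fhs", "pccA", "mcl",
    ],
    "C_methane": ["mcrA", "pmoA", "mmoX", "mxaF", "mtbA", "fae"],
    "N": [
        "amoA_AOA", "amoA_AOB", "hao", "nxrA", "narG", "napA", "napB",
        "nirK", "nirS", "norB", "nosZ", "nosZ_II", "nifH", "nrfA",
        "nasA", "nirA", "nirB", "gdh", "ureC", "hzsB", "hzo", "amtB",
    ],
    "P": ["phoD", "phoX", "phoN", "pqqC", "ppx", "ppk", "phnK", "phnX", "pitA"],
    "S": ["dsrA", "dsrB", "soxB", "aprA", "sqr"],
    "reference_16S": ["16S"],
}


class PanelError(ValueError):
    """Raised when a panel definition violates its invariants."""


@dataclass
class PanelDefinition:
    """Per-assay metadata for a qPCR chip: cycling category and amplification
    efficiency (fold amplification per cycle, nominally 2)."""

    table: pd.DataFrame = field(repr=False)  # index assay_id; category, efficiency

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].tolist()
            raise PanelError(f"duplicate assay ids in panel: {dups}")
        bad = set(t["category"]) - set(CATEGORIES)
        if bad:
            raise PanelError(f"unknown panel categories: {sorted(bad)}")
        n_ref = int((t["category"] == "reference_16S").sum())
        if n_ref != 1:
            raise PanelError(f"panel must contain exactly one reference_16S assay, found {n_ref}")
        if (t["efficiency"] <= 1).any():
            raise PanelError("amplification efficiencies must exceed 1")

    @property
    def assay_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def reference_assay(self) -> str:
        return self.table.index[self.table["category"] == "reference_16S"][0]

    @property
    def functional_assays(self) -> list[str]:
        return list(self.table.index[self.table["category"] != "reference_16S"])

    def category_of(self, assay_id: str) -> str:
        return self.table.loc[assay_id, "category"]

    def efficiency_of(self, assay_id: str) -> float:
        return float(self.table.loc[assay_id, "efficiency"])

    def category_counts(self) -> dict[str, int]:
        """Number of functional assays per category (reference excluded)."""
        counts = self.table.loc[
            self.table["category"] != "reference_16S", "category"
        ].value_counts()
        return {c: int(counts.get(c, 0)) for c in FUNCTIONAL_CATEGORIES}

    def to_yaml(self, path) -> None:
        payload = {
            aid: {"category": row["category"], "efficiency": float(row["efficiency"])}
            for aid, row in self.table.iterrows()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelDefinition":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        table = pd.DataFrame.from_dict(payload, orient="index")
        table.index.name = "assay_id"
        return cls(table)


def default_panel(efficiency: float = 2.0) -> PanelDefinition:
    """The bundled 71-functional-assay + 16S-reference CNPS panel."""
    rows = []
    for category, assays in _BUNDLED_ASSAYS.items():
        for aid in assays:
            rows.append((aid, category, efficiency))
    table = pd.DataFrame(rows, columns=["assay_id", "category", "efficiency"])
    table = table.set_index("assay_id")
    return PanelDefinition(table)
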