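"""Tabular input/output and validation.

All primary tables are tab-separated with a header row of feature ids and the
sample id in the first column. Sample and feature order is preserved on load;
downstream operations are order-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .panel import PanelDefinition, default_panel

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
EDAPHIC_VARS = ("pH", "TC", "TN", "TP", "AN", "NN", "AP")
GROUPS = ("AP", "N")  # invaded (A. palmeri) vs native vegetation


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class DuplicateIdError(ValidationError):
    """A sample or feature id occurs more than once."""


class MissingMetadataError(ValidationError):
    """A sample present in a data table has no metadata row."""


class UnknownAssayError(ValidationError):
    """A CT-table assay is absent from the panel definition."""


@dataclass
class FeatureTable:
    """Samples × features matrix of non-negative values.

    ``kind`` tags what the features are (``otu`` or ``gene``); ``units``
    records the measurement scale (``reads``, ``relative`` or
    ``copies_per_gram``).
    """

    data: pd.DataFrame = field(repr=False)
    kind: str = "otu"
    units: str = "reads"

    def __post_init__(self) -> None:
        if self.kind not in ("otu", "gene"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.units not in ("reads", "relative", "copies_per_gram"):
            raise ValidationError(f"unknown units {self.units!r}")
        self.validate()

    def validate(self) -> None:
        self.data.index.name = "sample_id"
        self.data.columns.name = None
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("feature table must be numeric")
        if np.isnan(values).any():
            raise ValidationError("feature table contains missing values")
        if (values < 0).any():
            raise ValidationError("feature table contains negative entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def relative_abundance(self) -> "FeatureTable":
        """Row-normalise to proportions (samples with zero total stay zero)."""
        totals = self.data.sum(axis=1)
        rel = self.data.div(totals.where(totals > 0, 1.0), axis=0)
        return FeatureTable(rel, kind=self.kind, units="relative")

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], kind=self.kind, units=self.units)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, kind: str = "otu", units: str = "reads") -> "FeatureTable":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        return cls(data, kind=kind, units=units)


@dataclass
class TaxonomyTable:
    """OTU → 7-rank lineage (domain…species); missing ranks are "unclassified"."""

    data: pd.DataFrame = field(repr=False)  # index otu_id; columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy missing ranks: {missing}")
        if self.data.index.duplicated().any():
            raise DuplicateIdError("duplicate otu ids in taxonomy")
        self.data = self.data[list(RANKS)].fillna("unclassified")
        self.data.index.name = "otu_id"
        empty = (self.data == "").any(axis=None)
        if empty:
            raise ValidationError('empty rank strings; use "unclassified"')

    def lineage(self, otu_id: str) -> dict[str, str]:
        return self.data.loc[otu_id].to_dict()

    def collapse(self, table: FeatureTable, rank: str) -> pd.DataFrame:
        """Sum a feature table's OTU columns by taxon at ``rank``."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        labels = self.data[rank].reindex(table.feature_ids).fillna("unclassified")
        return table.data.T.groupby(labels.values).sum().T

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        data = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(data)


@dataclass
class SampleMetadata:
    """Per-sample site, group, coordinates and edaphic variables."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["site_id", "group", "lon", "lat", *EDAPHIC_VARS]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        self.data.index.name = "sample_id"
        if self.data.index.duplicated().any():
            raise DuplicateIdError("duplicate sample ids in metadata")
        bad_groups = set(self.data["group"]) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown groups {sorted(bad_groups)}; expected {GROUPS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def check_paired_design(self) -> None:
        """Each site must appear exactly once per group."""
        counts = self.data.groupby(["site_id", "group"]).size()
        if (counts != 1).any():
            bad = counts[counts != 1].index.tolist()
            raise ValidationError(f"design not paired at (site, group): {bad}")

    def edaphic(self) -> pd.DataFrame:
        return self.data[list(EDAPHIC_VARS)].astype(float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        return cls(data)


@dataclass
class CtTable:
    """Samples × assays qPCR cycle-threshold values; blank cells (NaN) encode
    non-detects, per the chip software's export convention."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data.index.name = "sample_id"
        self.data.columns.name = None
        if self.data.index.duplicated().any():
            raise DuplicateIdError("duplicate sample ids in CT table")
        if self.data.columns.duplicated().any():
            raise DuplicateIdError("duplicate assay ids in CT table")
        values = self.data.to_numpy(dtype=float)
        present = values[~np.isnan(values)]
        if (present <= 0).any() or np.isinf(present).any():
            raise ValidationError("CT values must be finite and positive where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.data.columns)

    def check_panel(self, panel: PanelDefinition) -> None:
        unknown = set(self.data.columns) - set(panel.assay_ids)
        if unknown:
            raise UnknownAssayError(f"assays absent from panel: {sorted(unknown)}")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "CtTable":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        return cls(data)


@dataclass
class Dataset:
    """Cross-validated bundle of all study inputs."""

    otus: FeatureTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    ct: CtTable
    panel: PanelDefinition
    abs_16s: pd.Series = field(repr=False)  # per-sample absolute 16S copies/g

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        meta_samples = set(self.metadata.sample_ids)
        for name, ids in (
            ("feature table", self.otus.sample_ids),
            ("CT table", self.ct.sample_ids),
            ("16S reference", self.abs_16s.index),
        ):
            orphans = set(ids) - meta_samples
            if orphans:
                raise MissingMetadataError(
                    f"samples in {name} without metadata: {sorted(orphans)}"
                )
        self.ct.check_panel(self.panel)
        missing_tax = set(self.otus.feature_ids) - set(self.taxonomy.data.index)
        if missing_tax:
            raise ValidationError(f"OTUs without taxonomy: {sorted(missing_tax)[:5]}...")
        if (self.abs_16s <= 0).any():
            raise ValidationError("absolute 16S copy numbers must be positive")


_FILES = {
    "otus": "otus.tsv",
    "taxonomy": "taxonomy.tsv",
    "metadata": "metadata.tsv",
    "ct": "ct.tsv",
    "abs_16s": "abs16s.tsv",
    "panel": "panel.yaml",
}


def load_dataset(directory, panel: PanelDefinition | None = None) -> Dataset:
    """Load a full dataset from a directory laid out by :func:`write_dataset`.

    A ``panel.yaml`` in the directory overrides the bundled default panel.
    """
    d = Path(directory)
    for key in ("otus", "taxonomy", "metadata", "ct", "abs_16s"):
        if not (d / _FILES[key]).exists():
            raise FileNotFoundError(f"missing input file: {d / _FILES[key]}")
    if panel is None:
        panel_path = d / _FILES["panel"]
        panel = PanelDefinition.from_yaml(panel_path) if panel_path.exists() else default_panel()
    abs_16s = pd.read_csv(d / _FILES["abs_16s"], sep="\t", index_col=0).iloc[:, 0]
    abs_16s.index = abs_16s.index.astype(str)
    return Dataset(
        otus=FeatureTable.from_tsv(d / _FILES["otus"], kind="otu", units="reads"),
        taxonomy=TaxonomyTable.from_tsv(d / _FILES["taxonomy"]),
        metadata=SampleMetadata.from_tsv(d / _FILES["metadata"]),
        ct=CtTable.from_tsv(d / _FILES["ct"]),
        panel=panel,
        abs_16s=abs_16s,
    )


def write_dataset(ds: Dataset, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ds.otus.to_tsv(d / _FILES["otus"])
    ds.taxonomy.to_tsv(d / _FILES["taxonomy"])
    ds.metadata.to_tsv(d / _FILES["metadata"])
    ds.ct.to_tsv(d / _FILES["ct"])
    ds.abs_16s.rename("abs_16s_copies").to_csv(d / _FILES["abs_16s"], sep="\t", index_label="sample_id")
    ds.panel.to_yaml(d / _FILES["panel"])


def write_network(net: nx.Graph, path) -> None:
    """Export a co-occurrence network to GraphML; round-trips all node and
    edge attributes (kind, abundance, rho, p, q, sign)."""
    nx.write_graphml(net, path)


def read_network(path) -> nx.Graph:
    g = nx.read_graphml(path)
    # GraphML node ids round-trip as strings, which is what we use throughout
    return g
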