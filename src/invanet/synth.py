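"""Synthetic paired-design soil microbiome datasets with planted structure.

The generator emulates a field survey of invaded/native vegetation pairs:
``n_sites`` sites, each contributing one rhizosphere sample under the invader
(group AP) and one under native plants (group N). Planted structure, recorded
in :class:`SyntheticTruth`, drives every downstream analysis stage:

* a per-sample latent factor loads (weight ``keystone_loading``) onto the k
  planted keystone OTUs of that sample's group and onto all functional-gene
  abundances, creating the keystone–gene co-occurrence the network stage
  should recover;
* a group shift ``group_effect`` (log units) raises designated responder
  phyla (Bacteroidetes, Nitrospirae) and lowers Actinobacteria in group AP,
  and shifts ammonium nitrogen (AN) between groups, with AN negatively
  coupled to the latent factor in AP samples;
* a north–south gradient ``spatial_gradient`` tilts the configured gene
  categories along latitude.

OTU counts are Dirichlet-multinomial draws around a log-scale mean with
site-by-feature random effects, so paired samples are compositionally
correlated as in real field designs. CT values are produced by inverting the
qPCR quantification chain, making absolute-abundance recovery exact by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CtTable,
    Dataset,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    RANKS,
)
from .panel import PanelDefinition, default_panel
from .qmec import CT_DETECTION_THRESHOLD

# study-region bounding box (south, north, west, east), decimal degrees
BBOX = (38.74, 40.04, 116.36, 117.85)

_PHYLA = {
    "Proteobacteria": 0.30,
    "Actinobacteria": 0.15,
    "Acidobacteria": 0.12,
    "Chloroflexi": 0.10,
    "Bacteroidetes": 0.08,
    "Gemmatimonadetes": 0.06,
    "Planctomycetes": 0.05,
    "Verrucomicrobia": 0.05,
    "Firmicutes": 0.04,
    "Nitrospirae": 0.03,
    "Armatimonadetes": 0.01,
    "Myxococcota": 0.01,
}

RESPONDERS_UP = ("Bacteroidetes", "Nitrospirae")
RESPONDERS_DOWN = ("Actinobacteria",)


@dataclass
class SynthConfig:
    """Generator parameters. ``seed`` is mandatory; all effect sizes are on
    the natural-log scale unless noted."""

    seed: int
    n_sites: int = 22
    n_otus: int = 300
    k_planted: int = 5
    keystone_loading: float = 0.9   # λ: latent-factor loading on keystones & genes
    group_effect: float = 0.8       # δ: responder-phylum shift and AN shift (in AN sd units)
    spatial_gradient: float = 0.8   # γ: latitude trend on gradient_categories
    site_sd: float = 0.3            # site-by-feature random-effect sd
    otu_noise_sd: float = 0.25
    gene_noise_sd: float = 0.2
    otu_log_sd: float = 1.5         # spread of base OTU log abundances
    overdispersion: float = 500.0   # Dirichlet concentration
    depth_log_mean: float = float(np.log(15000))
    depth_log_sd: float = 0.3
    gene_log_mean: float = float(np.log(1e7))
    gene_log_sd: float = 1.0
    abs16s_log_mean: float = float(np.log(1e9))
    abs16s_log_sd: float = 0.3
    an_coupling: float = 1.0        # mg/kg AN decrease per latent-factor sd, AP only
    gradient_categories: tuple[str, ...] = ("C_degradation", "C_fixation", "C_methane", "P")
    panel: PanelDefinition = field(default_factory=default_panel)
    bbox: tuple[float, float, float, float] = BBOX

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.k_planted > self.n_otus:
            raise ValueError("k_planted cannot exceed n_otus")
        for name in ("site_sd", "otu_noise_sd", "gene_noise_sd", "otu_log_sd",
                     "overdispersion", "depth_log_sd", "gene_log_sd", "abs16s_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.keystone_loading <= 1:
            raise ValueError("keystone_loading must lie in [0, 1]")

    def null(self) -> "SynthConfig":
        """Truth-free copy: no keystone loading, no group effect, no gradient,
        and no site random effects.

        Site effects correlate the paired samples; under them, group-label
        permutation tests (ANOSIM) are conservative rather than exact because
        samples are not exchangeable. The calibration null therefore removes
        every source of structure, leaving i.i.d. samples.
        """
        return replace(
            self,
            keystone_loading=0.0,
            group_effect=0.0,
            spatial_gradient=0.0,
            site_sd=0.0,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: what a correct pipeline should recover."""

    keystones: dict[str, list[str]]          # group -> planted keystone OTU ids
    keystone_loading: float
    group_effect: float
    spatial_gradient: float
    latent: pd.Series = field(repr=False)    # per-sample latent factor values
    responders_up: tuple[str, ...] = RESPONDERS_UP
    responders_down: tuple[str, ...] = RESPONDERS_DOWN
    gradient_categories: tuple[str, ...] = ()

    def to_json(self, path) -> None:
        payload = {
            "keystones": self.keystones,
            "keystone_loading": self.keystone_loading,
            "group_effect": self.group_effect,
            "spatial_gradient": self.spatial_gradient,
            "latent": {k: float(v) for k, v in self.latent.items()},
            "responders_up": list(self.responders_up),
            "responders_down": list(self.responders_down),
            "gradient_categories": list(self.gradient_categories),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            keystones=payload["keystones"],
            keystone_loading=payload["keystone_loading"],
            group_effect=payload["group_effect"],
            spatial_gradient=payload["spatial_gradient"],
            latent=pd.Series(payload["latent"]),
            responders_up=tuple(payload["responders_up"]),
            responders_down=tuple(payload["responders_down"]),
            gradient_categories=tuple(payload["gradient_categories"]),
        )


def _make_taxonomy(otu_ids, rng) -> TaxonomyTable:
    phyla = list(_PHYLA)
    probs = np.array(list(_PHYLA.values()))
    assigned = rng.choice(phyla, size=len(otu_ids), p=probs / probs.sum())
    rows = []
    for otu, phy in zip(otu_ids, assigned):
        lineage = {"domain": "Bacteria", "phylum": phy}
        prev = phy
        for rank, tag in zip(RANKS[2:], ("c", "o", "f", "g", "s")):
            # deeper ranks increasingly unclassified, as in real 16S annotation
            if rng.random() < {"c": 0.05, "o": 0.15, "f": 0.3, "g": 0.5, "s": 0.8}[tag]:
                lineage[rank] = "unclassified"
                prev = None
            elif prev is None:
                lineage[rank] = "unclassified"
            else:
                prev = f"{prev}_{tag}{rng.integers(1, 4)}"
                lineage[rank] = prev
        rows.append(lineage)
    data = pd.DataFrame(rows, index=pd.Index(otu_ids, name="otu_id"))
    return TaxonomyTable(data)


def generate_dataset(cfg: SynthConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw one synthetic dataset plus its ground truth. Deterministic in
    (config, seed): identical inputs give bit-identical outputs."""
    rng = np.random.default_rng(cfg.seed)
    n_sites, n_otus = cfg.n_sites, cfg.n_otus
    site_ids = [f"S{i + 1:02d}" for i in range(n_sites)]
    sample_ids = [f"{s}_{g}" for s in site_ids for g in ("AP", "N")]
    n_samples = len(sample_ids)
    sample_site = np.repeat(np.arange(n_sites), 2)
    is_ap = np.tile([True, False], n_sites)

    lat_s, lat_n, lon_w, lon_e = cfg.bbox
    lat = rng.uniform(lat_s, lat_n, size=n_sites)
    lon = rng.uniform(lon_w, lon_e, size=n_sites)

    otu_ids = [f"OTU_{i + 1}" for i in range(n_otus)]
    taxonomy = _make_taxonomy(otu_ids, rng)
    phylum = taxonomy.data["phylum"].to_numpy()

    # base log abundances; keystones are planted in the upper abundance tail
    # (~1-2% relative abundance) so they pass the 80% prevalence screen and,
    # more importantly, so multinomial/Dirichlet counting noise does not
    # attenuate the latent-factor correlation the loading is meant to set
    base = rng.normal(0.0, cfg.otu_log_sd, size=n_otus)
    keystone_idx = rng.choice(n_otus, size=2 * cfg.k_planted, replace=False)
    ks_ap = keystone_idx[: cfg.k_planted]
    ks_n = keystone_idx[cfg.k_planted:]
    ks_floor = np.quantile(base, 0.95)
    base[keystone_idx] = ks_floor + rng.uniform(0.0, 0.4, size=2 * cfg.k_planted)

    latent = rng.normal(0.0, 1.0, size=n_samples)
    site_otu = rng.normal(0.0, cfg.site_sd, size=(n_sites, n_otus))

    direction = np.zeros(n_otus)
    direction[np.isin(phylum, RESPONDERS_UP)] = 1.0
    direction[np.isin(phylum, RESPONDERS_DOWN)] = -1.0

    logmean = (
        base[None, :]
        + site_otu[sample_site]
        + rng.normal(0.0, cfg.otu_noise_sd, size=(n_samples, n_otus))
    )
    logmean[is_ap] += cfg.group_effect * direction[None, :]
    load = np.zeros((n_samples, n_otus))
    load[np.ix_(is_ap, ks_ap)] = 1.0
    load[np.ix_(~is_ap, ks_n)] = 1.0
    logmean += cfg.keystone_loading * latent[:, None] * load

    depth = np.maximum(
        rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=n_samples), 1000
    ).astype(int)
    counts = np.empty((n_samples, n_otus), dtype=int)
    for s in range(n_samples):
        w = np.exp(logmean[s] - logmean[s].max())
        alpha = cfg.overdispersion * w / w.sum()
        p = rng.dirichlet(alpha)
        counts[s] = rng.multinomial(depth[s], p)

    otus = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids), kind="otu", units="reads"
    )

    # functional genes: log-normal absolute copies with latent-factor loading
    # and a latitude gradient on the configured categories
    assays = cfg.panel.functional_assays
    cats = cfg.panel.table["category"].reindex(assays).to_numpy()
    n_genes = len(assays)
    gene_base = rng.normal(cfg.gene_log_mean, cfg.gene_log_sd, size=n_genes)
    site_gene = rng.normal(0.0, cfg.site_sd, size=(n_sites, n_genes))
    z_lat = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)
    on_gradient = np.isin(cats, cfg.gradient_categories).astype(float)
    gene_log = (
        gene_base[None, :]
        + site_gene[sample_site]
        + cfg.keystone_loading * latent[:, None]
        + cfg.spatial_gradient * z_lat[sample_site][:, None] * on_gradient[None, :]
        + rng.normal(0.0, cfg.gene_noise_sd, size=(n_samples, n_genes))
    )
    gene_abs = pd.DataFrame(np.exp(gene_log), index=sample_ids, columns=assays)

    abs_16s = pd.Series(
        rng.lognormal(cfg.abs16s_log_mean, cfg.abs16s_log_sd, size=n_samples),
        index=sample_ids,
        name="abs_16s_copies",
    )
    ct = invert_quantification(gene_abs, cfg.panel, abs_16s)

    an_sd = 2.0
    edaphic = pd.DataFrame(
        {
            "pH": rng.normal(7.9, 0.35, n_samples),
            "TC": np.abs(rng.normal(15.0, 3.0, n_samples)),
            "TN": np.abs(rng.normal(1.2, 0.25, n_samples)),
            "TP": np.abs(rng.normal(0.7, 0.15, n_samples)),
            "AN": np.abs(
                rng.normal(8.0, an_sd, n_samples)
                + cfg.group_effect * an_sd * is_ap
                - cfg.an_coupling * latent * is_ap
            ),
            "NN": np.abs(rng.normal(12.0, 3.0, n_samples)),
            "AP": np.abs(rng.normal(10.0, 2.5, n_samples)),
        },
        index=sample_ids,
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "site_id": [site_ids[i] for i in sample_site],
                "group": ["AP" if a else "N" for a in is_ap],
                "lon": lon[sample_site],
                "lat": lat[sample_site],
                **{c: edaphic[c] for c in edaphic.columns},
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    dataset = Dataset(
        otus=otus, taxonomy=taxonomy, metadata=metadata, ct=ct,
        panel=cfg.panel, abs_16s=abs_16s,
    )
    truth = SyntheticTruth(
        keystones={
            "AP": [otu_ids[i] for i in sorted(ks_ap)],
            "N": [otu_ids[i] for i in sorted(ks_n)],
        },
        keystone_loading=cfg.keystone_loading,
        group_effect=cfg.group_effect,
        spatial_gradient=cfg.spatial_gradient,
        latent=pd.Series(latent, index=sample_ids),
        gradient_categories=cfg.gradient_categories,
    )
    return dataset, truth


def invert_quantification(
    abs_abundance: pd.DataFrame,
    panel: PanelDefinition,
    abs_16s: pd.Series,
    threshold: float = CT_DETECTION_THRESHOLD,
    ct_reference: float = 12.0,
    nondetect_ct: float = 40.0,
) -> CtTable:
    """Back out the CT table that quantifies to the given absolute abundances.

    Zero abundances map to a sentinel CT above the detection threshold;
    everything else round-trips through :func:`invanet.qmec.quantify` to
    1e-9 relative error.
    """
    if (abs_abundance.to_numpy() < 0).any():
        raise ValueError("absolute abundances must be non-negative")
    if (abs_16s <= 0).any():
        raise ValueError("absolute 16S copies must be positive")
    ref = panel.reference_assay
    eff = panel.table["efficiency"].reindex(abs_abundance.columns).to_numpy()
    ref_eff = panel.efficiency_of(ref)
    rel_ref = ref_eff ** (threshold - ct_reference)
    rel = abs_abundance.mul(rel_ref / abs_16s.reindex(abs_abundance.index), axis=0)
    with np.errstate(divide="ignore"):
        ct = threshold - np.log(rel.to_numpy()) / np.log(eff)[None, :]
    ct[rel.to_numpy() <= 0] = nondetect_ct
    ct = np.minimum(ct, nondetect_ct)
    out = pd.DataFrame(ct, index=abs_abundance.index, columns=abs_abundance.columns)
    out[ref] = ct_reference
    return CtTable(out)
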