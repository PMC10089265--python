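"""Co-occurrence / functional molecular ecological network construction.

Features (OTU relative abundances and/or absolute gene copies) are screened
by prevalence (present in strictly more than a fraction π of samples), all
pairwise Spearman correlations are computed, p-values are BH-FDR adjusted
over the whole network's pair family, and an edge is kept iff |rho| exceeds
the correlation threshold and the adjusted p-value is below alpha. Keystone
taxa are the top-k OTU nodes by degree.

Two presets mirror common practice: ``fmen`` (OTUs + genes, |rho| > 0.6)
and ``genenet`` (genes only, |rho| > 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, ValidationError


@dataclass
class NetworkConfig:
    prevalence_min: float = 0.8
    r_min: float = 0.6
    alpha: float = 0.05
    p_adjust: str = "bh_fdr"          # or "none"
    pair_types: str = "all"           # or "otu_gene" to restrict cross-type pairs

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_min <= 1:
            raise ValidationError("prevalence_min must lie in [0, 1]")
        if not 0 < self.r_min < 1:
            raise ValidationError("r_min must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.p_adjust not in ("bh_fdr", "none"):
            raise ValidationError(f"unknown p_adjust {self.p_adjust!r}")


FMEN = NetworkConfig(r_min=0.6)          # OTU–gene functional network preset
GENENET = NetworkConfig(r_min=0.8)       # gene–gene co-occurrence preset


def prevalence_filter(table: FeatureTable, prevalence_min: float = 0.8) -> FeatureTable:
    """Keep features detected (value > 0) in strictly more than
    ``prevalence_min``·n_samples samples."""
    present = (table.data > 0).sum(axis=0)
    n = table.shape[0]
    keep = present > prevalence_min * n
    if not keep.any():
        raise ValidationError(
            f"no feature present in more than {prevalence_min:.0%} of samples; lower the threshold"
        )
    return FeatureTable(table.data.loc[:, keep], kind=table.kind, units=table.units)


def correlation_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho (mid-rank ties) and two-sided p from the
    t approximation. Zero-variance features are excluded with a warning."""
    n = features.shape[0]
    if n < 5:
        raise ValidationError("need at least 5 samples for rank correlations")
    variances = features.to_numpy().std(axis=0)
    degenerate = features.columns[variances == 0].tolist()
    if degenerate:
        warnings.warn(f"excluding zero-variance features: {degenerate}", stacklevel=2)
        features = features.drop(columns=degenerate)
    ranks = scipy.stats.rankdata(features.to_numpy(), axis=0)
    rho = np.atleast_2d(np.corrcoef(ranks, rowvar=False))
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t) | np.isinf(t)] = 0.0  # |rho| == 1 exactly
    np.fill_diagonal(p, 0.0)
    cols = features.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    otus: FeatureTable | None,
    genes: FeatureTable | None = None,
    cfg: NetworkConfig = FMEN,
) -> nx.Graph:
    """Build the correlation network from one or two feature tables.

    OTU tables in read counts are converted to relative abundance; gene
    tables are used on their given (absolute-copy) scale. The prevalence
    screen runs per table, then BH adjustment is applied once over every
    pair tested in this network.
    """
    blocks = []
    kinds = {}
    abund = {}
    sample_index = None
    for table in (otus, genes):
        if table is None:
            continue
        if sample_index is None:
            sample_index = table.data.index
        elif not sample_index.sort_values().equals(table.data.index.sort_values()):
            raise ValidationError("feature tables must share an identical sample set")
        filtered = prevalence_filter(table, cfg.prevalence_min)
        if table.kind == "otu" and table.units == "reads":
            rel_full = table.relative_abundance().data
            values = rel_full[filtered.feature_ids]
        else:
            values = filtered.data
        values = values.loc[sample_index] if sample_index is not None else values
        blocks.append(values)
        for f in values.columns:
            kinds[f] = table.kind
        mean_rel = (
            table.relative_abundance().data.mean(axis=0)
            if table.kind == "otu"
            else table.data.div(table.data.sum(axis=1), axis=0).mean(axis=0)
        )
        for f in values.columns:
            abund[f] = float(mean_rel[f])
    if not blocks:
        raise ValidationError("at least one feature table is required")
    features = pd.concat(blocks, axis=1)
    if features.columns.duplicated().any():
        raise ValidationError("feature ids collide between tables")

    rho, p = correlation_matrix(features)
    ids = list(rho.columns)
    iu, ju = np.triu_indices(len(ids), k=1)
    rho_flat = rho.to_numpy()[iu, ju]
    p_flat = p.to_numpy()[iu, ju]

    if cfg.pair_types == "otu_gene":
        cross = np.array([kinds[ids[a]] != kinds[ids[b]] for a, b in zip(iu, ju)])
    else:
        cross = np.ones(len(iu), dtype=bool)

    q_flat = np.full_like(p_flat, np.nan)
    if cross.any():
        if cfg.p_adjust == "bh_fdr":
            q_flat[cross] = multipletests(p_flat[cross], method="fdr_bh")[1]
        else:
            q_flat[cross] = p_flat[cross]

    g = nx.Graph()
    for f in ids:
        g.add_node(f, kind=kinds[f], mean_abundance=abund[f])
    edge_mask = cross & (np.abs(rho_flat) > cfg.r_min) & (q_flat < cfg.alpha)
    for a, b, r, praw, q in zip(
        iu[edge_mask], ju[edge_mask], rho_flat[edge_mask], p_flat[edge_mask], q_flat[edge_mask]
    ):
        g.add_edge(
            ids[a], ids[b],
            rho=float(r), p_raw=float(praw), q=float(q),
            sign="positive" if r > 0 else "negative",
        )
    return g


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree: float
    average_clustering: float
    transitivity: float
    modularity: float | None
    average_distance: float | None
    diameter: int | None
    component_count: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def topology(net: nx.Graph) -> TopologySummary:
    """Topological attributes of a co-occurrence network.

    Clustering of degree<2 nodes counts as 0 in the average; distance and
    diameter are computed on the largest connected component; modularity is
    from greedy agglomerative maximization on the unweighted graph.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    n_edges = net.number_of_edges()
    signs = [d.get("sign", "positive") for _, _, d in net.edges(data=True)]
    n_pos = sum(s == "positive" for s in signs)
    components = list(nx.connected_components(net))
    if n_edges > 0:
        giant = net.subgraph(max(components, key=len))
        avg_dist = (
            nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else None
        )
        diam = nx.diameter(giant) if giant.number_of_nodes() > 1 else None
        communities = nx.algorithms.community.greedy_modularity_communities(net)
        q = nx.algorithms.community.modularity(net, communities)
    else:
        avg_dist = diam = q = None
    return TopologySummary(
        n_nodes=net.number_of_nodes(),
        n_edges=n_edges,
        n_positive=n_pos,
        n_negative=n_edges - n_pos,
        average_degree=2.0 * n_edges / net.number_of_nodes(),
        average_clustering=nx.average_clustering(net) if net.number_of_nodes() else 0.0,
        transitivity=nx.transitivity(net),
        modularity=None if q is None else float(q),
        average_distance=None if avg_dist is None else float(avg_dist),
        diameter=None if diam is None else int(diam),
        component_count=len(components),
    )


def keystone_taxa(net: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Top-k OTU nodes by degree; ties broken by higher mean relative
    abundance, then lexicographic id. Fewer than k OTU nodes returns them
    all with a warning."""
    otu_nodes = [n for n, d in net.nodes(data=True) if d.get("kind") == "otu"]
    if not otu_nodes:
        raise ValidationError("network has no OTU nodes")
    rows = [
        {
            "otu_id": n,
            "degree": net.degree(n),
            "mean_abundance": net.nodes[n].get("mean_abundance", np.nan),
        }
        for n in otu_nodes
    ]
    ranked = sorted(rows, key=lambda r: (-r["degree"], -r["mean_abundance"], r["otu_id"]))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} OTU nodes available for {k} keystones", stacklevel=2
        )
    return pd.DataFrame(ranked[:k]).set_index("otu_id")


def keystone_table(net: nx.Graph, taxonomy, k: int = 5) -> pd.DataFrame:
    """Keystone listing with full lineages, shaped like a results table."""
    ks = keystone_taxa(net, k=k)
    lineages = taxonomy.data.reindex(ks.index)
    return pd.concat([ks, lineages], axis=1)
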