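"""Community diversity and composition statistics.

Alpha diversity (richness, Chao1, ACE, Shannon with natural log,
Gini–Simpson), Bray–Curtis dissimilarity, principal coordinate analysis,
ANOSIM with seeded permutations, and a Kruskal–Wallis differential-abundance
screen at a chosen taxonomic rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.ordination import pcoa as _skbio_pcoa
import skbio

from .io import FeatureTable, TaxonomyTable, ValidationError

logger = logging.getLogger(__name__)


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample each sample to ``depth`` reads without replacement
    (multivariate hypergeometric). Samples with fewer reads than ``depth``
    are dropped with a warning. Default depth is the minimum sample total.
    """
    data = table.data
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValidationError("rarefaction needs integer counts")
        values = values.astype(np.int64)
    totals = values.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    keep = totals >= depth
    if not keep.all():
        dropped = data.index[~keep].tolist()
        warnings.warn(
            f"dropping {len(dropped)} samples below depth {depth}: {dropped}", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), values.shape[1]), dtype=np.int64)
    for row, s in enumerate(np.flatnonzero(keep)):
        if totals[s] == depth:
            out[row] = values[s]
        else:
            out[row] = rng.multivariate_hypergeometric(values[s], depth)
    return FeatureTable(
        pd.DataFrame(out, index=data.index[keep], columns=data.columns),
        kind=table.kind,
        units=table.units,
    )


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample richness, Chao1 (bias-corrected), ACE (rare cutoff 10),
    Shannon H (natural log) and Gini–Simpson (1 − Σp²).

    All-zero samples are returned as NaN rows with a warning, never silent
    zeros.
    """
    rows = {}
    empty = []
    for sid, counts in table.data.iterrows():
        c = counts.to_numpy()
        c = np.round(c).astype(np.int64)
        total = c.sum()
        if total == 0:
            empty.append(sid)
            rows[sid] = dict.fromkeys(
                ("richness", "chao1", "ace", "shannon", "simpson"), np.nan
            )
            continue
        p = c[c > 0] / total
        chao1 = float(_skbio_chao1(c, bias_corrected=True))
        try:
            ace = float(_skbio_ace(c, rare_threshold=10))
        except ValueError:
            # all rare taxa are singletons: ACE undefined; EstimateS
            # recommends bias-corrected Chao1 in that case
            ace = chao1
        rows[sid] = {
            "richness": int((c > 0).sum()),
            "chao1": chao1,
            "ace": ace,
            "shannon": float(-(p * np.log(p)).sum()),
            "simpson": float(1.0 - (p**2).sum()),
        }
    if empty:
        warnings.warn(f"diversity undefined for all-zero samples: {empty}", stacklevel=2)
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]


def bray_curtis(table: FeatureTable) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity d(x,y) = Σ|x−y| / Σ(x+y)."""
    x = table.data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least two samples")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        bad = [table.sample_ids[i] for i in zero_rows]
        raise ValidationError(f"Bray–Curtis undefined between all-zero samples: {bad}")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame = field(repr=False)   # samples × positive axes, scaled by √λ
    eigenvalues: np.ndarray = field(repr=False)     # all eigenvalues, descending
    proportion_explained: np.ndarray = field(repr=False)  # over positive eigenvalues


def pcoa(dm: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates: Gower-center −½d², eigendecompose, scale axes
    by √λ. Negative eigenvalues are reported but excluded from coordinates
    and explained proportions (Bray–Curtis is only a semi-metric)."""
    d = dm.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.index, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int

    def __repr__(self) -> str:  # compact, figure-legend style
        return f"ANOSIM R = {self.R:.3f}, p = {self.p_value:.4g} ({self.n_permutations} permutations)"


def anosim(
    dm: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    All M = n(n−1)/2 distances are ranked with mid-ranks for ties;
    R = (mean between-group rank − mean within-group rank) / (M/2). The
    p-value counts label permutations with R at least as large, with the
    +1 convention so p ≥ 1/(n_permutations+1).
    """
    labels = groups.reindex(dm.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    codes = pd.factorize(labels)[0]
    counts = np.bincount(codes)
    if len(counts) < 2 or (counts < 2).any():
        raise ValidationError("ANOSIM needs >= 2 groups with >= 2 samples each")
    d = dm.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(codes), k=1)
    ranks = scipy.stats.rankdata(d[iu, ju])
    m = len(ranks)

    def _r(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = _r(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _r(rng.permutation(codes)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(R=float(r_obs), p_value=float(p), n_permutations=n_permutations, seed=seed)


@dataclass
class KWResult:
    taxon: str
    H: float
    p_value: float
    medians: dict[str, float]
    mean_abundance: float


def kruskal_wallis_screen(
    table: FeatureTable,
    groups: pd.Series,
    taxonomy: TaxonomyTable | None = None,
    rank: str | None = None,
    top_n: int | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Tie-corrected Kruskal–Wallis test per taxon between groups.

    With ``taxonomy`` and ``rank`` the table is first collapsed (summed) to
    that rank; ``top_n`` keeps the most-abundant taxa (mean relative
    abundance), matching the common practice of screening the top phyla or
    families. Raw p-values are reported by default; ``bh_correct`` adds a
    Benjamini–Hochberg column.
    """
    if (taxonomy is None) != (rank is None):
        raise ValidationError("taxonomy and rank must be given together")
    if taxonomy is not None:
        data = taxonomy.collapse(table, rank)
    else:
        data = table.data
    rel = data.div(data.sum(axis=1).where(lambda s: s > 0, 1.0), axis=0)
    mean_abund = rel.mean(axis=0)
    if top_n is not None:
        data = data[mean_abund.sort_values(ascending=False).index[:top_n]]
    labels = groups.reindex(data.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    level_names = list(pd.unique(labels))
    results = []
    for taxon in data.columns:
        per_group = [data.loc[labels == g, taxon].to_numpy() for g in level_names]
        if np.ptp(np.concatenate(per_group)) == 0:
            h, p = 0.0, 1.0  # identical values in every group
        else:
            h, p = scipy.stats.kruskal(*per_group)
        results.append(
            {
                "taxon": taxon,
                "H": float(h),
                "p_value": float(p),
                **{f"median_{g}": float(np.median(v)) for g, v in zip(level_names, per_group)},
                "mean_abundance": float(mean_abund.get(taxon, np.nan)),
            }
        )
    out = pd.DataFrame(results).set_index("taxon")
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def anosim_reference(dm: pd.DataFrame, groups: pd.Series, n_permutations: int = 999):
    """Independent ANOSIM via scikit-bio, for cross-checking."""
    sk_dm = skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index))
    return skbio.stats.distance.anosim(
        sk_dm, groups.reindex(dm.index).to_numpy(), permutations=n_permutations
    )


def pcoa_reference(dm: pd.DataFrame):
    """Independent PCoA via scikit-bio, for cross-checking."""
    return _skbio_pcoa(skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
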