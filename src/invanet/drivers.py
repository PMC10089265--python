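"""Driver-importance analysis: how keystone abundances and edaphic variables
predict functional-gene profiles.

Two importance methods share one interface:

* ``rf_permutation`` — a bagged regression forest; importance is the
  percentage increase in out-of-bag mean squared error when a predictor's
  out-of-bag values are permuted (the classic %IncMSE of regression forests).
* ``lmg`` — the averaged-over-orderings R² decomposition of a linear model
  (the LMG / "relative importance" metric), whose contributions sum to the
  full-model R².

Significance for both comes from a response-permutation null: each observed
importance is compared against the permutation distribution of the *maximum*
importance across predictors, which controls the family-wise false-positive
rate at the nominal level.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.tree import DecisionTreeRegressor

from .io import FeatureTable, ValidationError


# ---------------------------------------------------------------------------
# bagged forest with out-of-bag permutation importance
# ---------------------------------------------------------------------------

def _forest_oob_importance(
    x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """%IncMSE per predictor: 100 × (OOB MSE after permuting the predictor −
    OOB MSE) / OOB MSE, with OOB predictions aggregated over trees."""
    n, p = x.shape
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    perm_sum = np.zeros((p, n))
    perm_cnt = np.zeros((p, n))
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if len(oob) == 0:
            continue
        tree = DecisionTreeRegressor(random_state=int(rng.integers(2**31)))
        tree.fit(x[boot], y[boot])
        pred = tree.predict(x[oob])
        pred_sum[oob] += pred
        pred_cnt[oob] += 1
        # one shared OOB shuffle per tree keeps importances exactly
        # invariant to predictor column order
        shuffle = rng.permutation(len(oob))
        for j in range(p):
            xp = x[oob].copy()
            xp[:, j] = xp[shuffle, j]
            perm_sum[j, oob] += tree.predict(xp)
            perm_cnt[j, oob] += 1
    seen = pred_cnt > 0
    mse0 = np.mean((y[seen] - pred_sum[seen] / pred_cnt[seen]) ** 2)
    imps = np.empty(p)
    for j in range(p):
        seen_j = perm_cnt[j] > 0
        mse_j = np.mean((y[seen_j] - perm_sum[j, seen_j] / perm_cnt[j, seen_j]) ** 2)
        imps[j] = 100.0 * (mse_j - mse0) / mse0 if mse0 > 0 else 0.0
    return imps


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

def _subset_r2(cov: np.ndarray, subset: tuple[int, ...]) -> float:
    """R² of the OLS regression of y on the predictor subset, from the joint
    covariance matrix (y last)."""
    if not subset:
        return 0.0
    idx = np.array(subset)
    sxx = cov[np.ix_(idx, idx)]
    sxy = cov[idx, -1]
    syy = cov[-1, -1]
    try:
        beta = np.linalg.solve(sxx, sxy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(sxx, sxy, rcond=None)[0]
    return float(sxy @ beta / syy) if syy > 0 else 0.0


def lmg_decomposition(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LMG contributions: each predictor's R² increment averaged over all
    orderings. Contributions sum to the full-model R². Zero-variance
    predictors contribute exactly 0."""
    n, p = x.shape
    if p > 15:
        raise ValidationError("LMG enumerates 2^p subsets; use <= 15 predictors")
    live = np.flatnonzero(x.std(axis=0) > 0)
    q = len(live)
    cov = np.cov(np.column_stack([x[:, live], y]), rowvar=False)
    cache = {(): 0.0}
    for size in range(1, q + 1):
        for subset in itertools.combinations(range(q), size):
            cache[subset] = _subset_r2(cov, subset)
    contrib = np.zeros(p)
    fact = math.factorial
    for jj, j in enumerate(live):
        total = 0.0
        others = [k for k in range(q) if k != jj]
        for size in range(q):
            w = fact(size) * fact(q - size - 1) / fact(q)
            for subset in itertools.combinations(others, size):
                with_j = tuple(sorted(subset + (jj,)))
                total += w * (cache[with_j] - cache[subset])
        contrib[j] = total
    return contrib


# ---------------------------------------------------------------------------
# shared interface
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    importances: pd.Series = field(repr=False)  # %IncMSE or LMG share of R²
    p_values: pd.Series = field(repr=False)     # max-null permutation p
    method: str = "rf_permutation"
    n_permutations: int = 0

    def summary(self) -> pd.DataFrame:
        stars = self.p_values.map(lambda p: "**" if p <= 0.01 else "*" if p <= 0.05 else "")
        return pd.DataFrame(
            {"importance": self.importances, "p_value": self.p_values, "signif": stars}
        ).sort_values("importance", ascending=False)


def importance(
    predictors: pd.DataFrame,
    response: pd.Series,
    method: str = "rf_permutation",
    n_trees: int = 500,
    n_perm: int = 99,
    seed: int = 0,
) -> ImportanceResult:
    """Predictor importance for a single response, with permutation p-values.

    ``n_perm`` response permutations rebuild the importance vector under the
    null; each predictor's p-value is the fraction of permutations whose
    maximum importance reaches its observed value (+1 convention).
    """
    # canonical column order makes the result exactly invariant to how the
    # caller happened to arrange the predictor matrix
    original_columns = list(predictors.columns)
    predictors = predictors[sorted(predictors.columns)]
    x = predictors.to_numpy(dtype=float)
    y = response.reindex(predictors.index).to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    if np.ptp(y) == 0:
        raise ValidationError("constant response")
    if method == "lmg" and x.shape[0] <= x.shape[1]:
        warnings.warn("fewer samples than predictors: LMG estimates unstable", stacklevel=2)
    rng = np.random.default_rng(seed)

    def _imps(yy: np.ndarray, r: np.random.Generator) -> np.ndarray:
        if method == "rf_permutation":
            return _forest_oob_importance(x, yy, n_trees, r)
        if method == "lmg":
            return lmg_decomposition(x, yy)
        raise ValidationError(f"unknown importance method {method!r}")

    obs = _imps(y, rng)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        null_max[b] = _imps(rng.permutation(y), rng).max()
    pvals = (1.0 + (null_max[:, None] >= obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    cols = list(predictors.columns)
    return ImportanceResult(
        importances=pd.Series(obs, index=cols, name="importance").reindex(original_columns),
        p_values=pd.Series(pvals, index=cols, name="p_value").reindex(original_columns),
        method=method,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# keystone–gene regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __repr__(self) -> str:
        return (f"ln-ln regression: slope = {self.slope:.3f}, "
                f"R² = {self.r_squared:.2f}, p = {self.p_value:.3g}, n = {self.n}")


def average_standardized_abundance(keystones: FeatureTable) -> pd.Series:
    """Average standardized keystone abundance per sample: each keystone OTU's
    ln abundance is z-scored across samples, then the z-scores are averaged
    within each sample."""
    values = keystones.data.to_numpy(dtype=float)
    if (values <= 0).any():
        bad = keystones.data.index[(values <= 0).any(axis=1)].tolist()
        raise ValidationError(
            f"keystone abundances must be positive for the ln transform; offending samples: {bad}. "
            "Use a pseudo-count or drop the samples."
        )
    ln = np.log(values)
    z = (ln - ln.mean(axis=0)) / ln.std(axis=0, ddof=1)
    return pd.Series(z.mean(axis=1), index=keystones.data.index, name="keystone_z")


def keystone_gene_regression(
    keystones: FeatureTable,
    genes: pd.Series,
    zero_policy: str = "error",
) -> RegressionResult:
    """OLS of ln gene abundance on the average standardized ln keystone
    abundance.

    ``zero_policy``: 'error' (default) rejects nonpositive gene abundances,
    naming the offending samples; 'pseudocount' substitutes half the smallest
    positive value.
    """
    x = average_standardized_abundance(keystones)
    y = genes.reindex(x.index).astype(float)
    nonpos = y.index[y <= 0].tolist()
    if nonpos:
        if zero_policy == "error":
            raise ValidationError(
                f"nonpositive gene abundances in samples {nonpos}; "
                "set zero_policy='pseudocount' or exclude them"
            )
        if zero_policy == "pseudocount":
            pc = y[y > 0].min() / 2.0
            y = y.where(y > 0, pc)
            warnings.warn(f"substituted pseudo-count {pc:g} in {len(nonpos)} samples", stacklevel=2)
        else:
            raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    fit = scipy.stats.linregress(x.to_numpy(), np.log(y.to_numpy()))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class RdaResult:
    eigenvalues: np.ndarray = field(repr=False)          # constrained axes
    proportion_constrained: float = 0.0
    sample_scores: pd.DataFrame | None = field(default=None, repr=False)
    f_statistic: float = 0.0
    p_value: float = 1.0
    n_permutations: int = 0


def rda(
    response: pd.DataFrame,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    standardize_response: bool = True,
) -> RdaResult:
    """Redundancy analysis: PCA of the fitted values of the multivariate
    regression of (standardized) response on centered predictors, with an
    overall permutation F-test (rows of the predictor matrix permuted)."""
    y = response.to_numpy(dtype=float)
    x = predictors.reindex(response.index).to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    n, q = x.shape
    y = y - y.mean(axis=0)
    if standardize_response:
        sd = y.std(axis=0, ddof=1)
        y = y / np.where(sd > 0, sd, 1.0)
    x = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(x)
    if rank < q:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        a, b = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            "collinear predictors: "
            f"{predictors.columns[a]!r} and {predictors.columns[b]!r} are linearly dependent"
        )

    def _stats(xmat: np.ndarray):
        beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
        fitted = xmat @ beta
        ss_fit = float((fitted**2).sum())
        ss_tot = float((y**2).sum())
        ss_res = ss_tot - ss_fit
        dof_res = n - q - 1
        f = (ss_fit / q) / (ss_res / dof_res) if ss_res > 1e-12 and dof_res > 0 else np.inf
        return fitted, ss_fit, ss_tot, f

    fitted, ss_fit, ss_tot, f_obs = _stats(x)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = (s**2) / (n - 1)
    keep = eig > 1e-12 * max(eig[0], 1.0) if len(eig) else np.array([], bool)
    eig = eig[keep]
    scores = u[:, keep] * s[keep]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, _, f_b = _stats(x[rng.permutation(n)])
        if f_b >= f_obs:
            hits += 1
    return RdaResult(
        eigenvalues=eig,
        proportion_constrained=ss_fit / ss_tot if ss_tot > 0 else 0.0,
        sample_scores=pd.DataFrame(
            scores, index=response.index, columns=[f"RDA{i+1}" for i in range(scores.shape[1])]
        ),
        f_statistic=float(f_obs),
        p_value=(1.0 + hits) / (1.0 + n_perm),
        n_permutations=n_perm,
    )
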