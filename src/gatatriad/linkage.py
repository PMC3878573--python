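"""Linking gene expression to TF binding.

Time-course k-means clustering (on per-gene z-scored profiles, so clusters
capture shape rather than level), correspondence analysis of bound-gene
counts against expression clusters, hypergeometric cluster enrichment with
BH FDR, centroid-reference correlation, fold-change stratification by
binding profile, the differential-expression fraction versus peak count with
a size-matched random null, concordance scoring of two fold-change
responses, and bound-versus-unbound expression comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("gatatriad")


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    sd = sd.replace(0.0, 1.0)  # flat genes stay flat (all-zero profile)
    return values.sub(mu, axis=0).div(sd, axis=0)


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # gene -> cluster id
    centroids: pd.DataFrame  # k x timepoints, mean of members (z-space)
    sse: float
    zvalues: pd.DataFrame


def cluster_timecourse(
    matrix: ExpressionMatrix, k: int = 30, n_init: int = 25, seed: int = 0
) -> ClusterResult:
    """Best-of-n_init k-means on per-gene z-scored time courses."""
    z = zscore_rows(matrix.values)
    if k > len(z):
        raise ValueError(f"k = {k} exceeds number of genes ({len(z)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    labels = pd.Series(labels, index=z.index, name="cluster")
    centroids = z.groupby(labels).mean()
    centroids.index.name = "cluster"
    sse = float(((z.to_numpy() - centroids.to_numpy()[labels.to_numpy()]) ** 2).sum())
    return ClusterResult(k=k, labels=labels, centroids=centroids, sse=sse, zvalues=z)


@dataclass
class CAResult:
    """Correspondence analysis of a two-way contingency table.

    ``row_coords``/``col_coords`` are principal coordinates; the origin is
    the point of inertia, and a point's distance from it reflects how
    strongly that row/column departs from independence. Total inertia equals
    the table's chi-square statistic divided by the grand total, and also
    the sum of squared singular values.
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    total_inertia: float
    row_masses: pd.Series
    col_masses: pd.Series

    @property
    def row_distance(self) -> pd.Series:
        return np.sqrt((self.row_coords**2).sum(axis=1))

    @property
    def col_distance(self) -> pd.Series:
        return np.sqrt((self.col_coords**2).sum(axis=1))


def correspondence(table: pd.DataFrame) -> CAResult:
    """Standard CA via SVD of the standardized residual matrix."""
    X = table.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("contingency table must be nonnegative")
    zero_rows = np.where(X.sum(axis=1) == 0)[0]
    if len(zero_rows):
        raise ValueError(f"all-zero row: {table.index[zero_rows[0]]!r}")
    zero_cols = np.where(X.sum(axis=0) == 0)[0]
    if len(zero_cols):
        raise ValueError(f"all-zero column: {table.columns[zero_cols[0]]!r}")
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    ndim = min(X.shape[0] - 1, X.shape[1] - 1)
    U, sv, Vt = U[:, :ndim], sv[:ndim], Vt[:ndim]
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    dims = [f"dim{i + 1}" for i in range(len(sv))]
    return CAResult(
        row_coords=pd.DataFrame(row_coords, index=table.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=table.columns, columns=dims),
        singular_values=sv,
        total_inertia=float(np.sum(sv**2)),
        row_masses=pd.Series(r, index=table.index),
        col_masses=pd.Series(c, index=table.columns),
    )


def cluster_enrichment(
    bound_genes, clusters: ClusterResult | pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cluster two-sided hypergeometric (Fisher exact) test of bound-gene
    membership, BH-corrected across clusters."""
    labels = clusters.labels if isinstance(clusters, ClusterResult) else clusters
    genes = set(labels.index)
    bound = set(bound_genes)
    if not bound <= genes:
        raise ValueError("bound_genes must be a subset of clustered genes")
    n_total = len(genes)
    n_bound = len(bound)
    rows = []
    for cid, members in labels.groupby(labels).groups.items():
        n_c = len(members)
        obs = len(bound.intersection(members))
        expected = n_bound * n_c / n_total
        if n_bound == 0 or n_bound == n_total:
            p = 1.0  # no contrast
        else:
            tab = [[obs, n_bound - obs], [n_c - obs, n_total - n_bound - (n_c - obs)]]
            p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
        fold = obs / expected if expected > 0 else np.nan
        rows.append((cid, n_c, obs, expected, fold, p))
    df = pd.DataFrame(rows, columns=["cluster", "n_genes", "observed", "expected", "fold", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["call"] = np.where(
        (df["q"] < alpha) & (df["observed"] > df["expected"]), "enriched",
        np.where((df["q"] < alpha) & (df["observed"] < df["expected"]), "depleted", "ns"),
    )
    return df


def centroid_correlation(centroids: pd.DataFrame, reference) -> pd.Series:
    """Pearson r between each cluster centroid and a reference time course.

    Constant centroids (or reference) give NaN (undefined correlation)."""
    ref = np.asarray(reference, dtype=float)
    if len(ref) != centroids.shape[1]:
        raise ValueError("reference profile must share the centroid time grid")
    out = {}
    ref_sd = ref.std()
    for cid, row in centroids.iterrows():
        vals = row.to_numpy()
        if vals.std() == 0 or ref_sd == 0:
            out[cid] = np.nan
        else:
            out[cid] = float(np.corrcoef(vals, ref)[0, 1])
    return pd.Series(out, name="pearson_r")


def foldchange_by_binding(
    matrix: ExpressionMatrix,
    groups: dict,
    t0: float,
    t1: float,
    pseudocount: float | None = None,
    thresholds=(1.5, 2.0),
):
    """Per-group log2 fold-change distributions between two timepoints.

    The pseudocount defaults to the 1st percentile of positive expression
    values at the two timepoints. Returns ({label: log2fc Series}, summary
    DataFrame with medians and fractions beyond each fold threshold).
    """
    tps = list(matrix.values.columns)
    for t in (t0, t1):
        if float(t) not in tps:
            raise ValueError(f"timepoint {t} not in matrix")
    x0 = matrix.values[float(t0)]
    x1 = matrix.values[float(t1)]
    if pseudocount is None:
        if (x0 <= 0).any() or (x1 <= 0).any():
            pos = np.concatenate([x0[x0 > 0].to_numpy(), x1[x1 > 0].to_numpy()])
            pseudocount = float(np.percentile(pos, 1)) if len(pos) else 1.0
            logger.info("applying pseudocount %.4g to fold changes", pseudocount)
        else:
            pseudocount = 0.0
    distributions = {}
    rows = []
    for label, genes in groups.items():
        genes = [g for g in genes if g in matrix.values.index]
        fc = np.log2((x1.loc[genes] + pseudocount) / (x0.loc[genes] + pseudocount))
        distributions[label] = fc
        row = {"group": label, "n": len(fc), "median_log2fc": float(fc.median())}
        for thr in thresholds:
            row[f"frac_beyond_{thr}x"] = float((fc.abs() >= np.log2(thr)).mean())
        rows.append(row)
    return distributions, pd.DataFrame(rows)


def de_fraction_vs_peakcount(
    peak_counts: pd.Series,
    de_labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
    band=(2.5, 97.5),
) -> pd.DataFrame:
    """Observed DE fraction per peak-count bin versus a random-bin null.

    Bins are integer peak counts. The null draws size-matched random gene
    sets (with the same number of genes as the bin) and records their DE
    fraction; bins whose observed fraction falls outside the null band are
    flagged. Empty bins are skipped.
    """
    rng = np.random.default_rng(seed)
    de = de_labels.astype(bool)
    all_de = de.to_numpy()
    rows = []
    for count, members in peak_counts.groupby(peak_counts).groups.items():
        n = len(members)
        if n == 0:
            continue
        obs = float(de.loc[members].mean())
        idx = rng.integers(0, len(all_de), size=(n_boot, n))
        null = all_de[idx].mean(axis=1)
        lo, hi = np.percentile(null, band)
        rows.append((int(count), n, obs, float(lo), float(hi), bool(obs < lo or obs > hi)))
    return pd.DataFrame(
        rows, columns=["peak_count", "n_genes", "de_fraction", "null_lo", "null_hi", "outside_band"]
    )


def concordance(responses_a: pd.Series, responses_b: pd.Series, threshold: float = 2.0) -> pd.DataFrame:
    """Concordant/discordant counts for genes modulated in A.

    Genes with fold change >= threshold (up) or <= 1/threshold (down) in A
    are concordant when B passes the same threshold in the same direction,
    discordant otherwise.
    """
    common = responses_a.index.intersection(responses_b.index)
    a, b = responses_a.loc[common], responses_b.loc[common]
    rows = []
    for direction, sel in (("up", a >= threshold), ("down", a <= 1.0 / threshold)):
        genes = common[sel]
        if direction == "up":
            conc = int((b.loc[genes] >= threshold).sum())
        else:
            conc = int((b.loc[genes] <= 1.0 / threshold).sum())
        rows.append((direction, conc, len(genes) - conc))
    return pd.DataFrame(rows, columns=["direction", "concordant", "discordant"])


def bound_vs_unbound_expression(expression: pd.Series, bound_sets: dict) -> pd.DataFrame:
    """Median expression of bound versus unbound genes per TF with a
    two-sided Wilcoxon rank-sum test."""
    genes = set(expression.index)
    rows = []
    for tf, bound in bound_sets.items():
        bound = set(bound) & genes
        unbound = genes - bound
        if not bound or not unbound:
            logger.info("no contrast for %s (empty bound or unbound side)", tf)
            rows.append((tf, len(bound), np.nan, np.nan, np.nan, "no contrast"))
            continue
        xb = expression.loc[sorted(bound)].to_numpy()
        xu = expression.loc[sorted(unbound)].to_numpy()
        p = float(stats.mannwhitneyu(xb, xu, alternative="two-sided").pvalue)
        rows.append((tf, len(bound), float(np.median(xb)), float(np.median(xu)), p, ""))
    return pd.DataFrame(
        rows, columns=["tf", "n_bound", "median_bound", "median_unbound", "p", "note"]
    )
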