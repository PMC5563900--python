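"""Element-stratified comparisons, clustering and enrichment.

Genes are split into with/without groups by the presence of a 5'UTR
regulatory element (uORF, IRES or 5'TOP) and their r5'LR or TE
fold-change distributions are compared with the Wilcoxon rank-sum
(Mann-Whitney U) test. For small samples the p-value is computed by
exact enumeration of the permutation null — a dynamic program over the
midrank multiset, so ties are handled exactly — and for larger samples
by the normal approximation with tie-corrected variance and continuity
correction.

Dynamic fold-change profiles are clustered with k-means on per-gene
z-scores, and clusters are annotated against user-supplied gene sets
with an upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ElementTable

ELEMENTS = ("uORF", "IRES", "5TOP")

#: largest pooled sample size for which the exact permutation null is used
EXACT_LIMIT = 14


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_ranksum_p(ranks2: np.ndarray, n_a: int, w2_obs: int, alternative: str) -> float:
    """Exact permutation p-value for the rank-sum statistic.

    ``ranks2`` holds doubled midranks (integers even with ties); the DP
    table ``ways[j, s]`` counts subsets of size j summing to s, built item
    by item, giving the full null distribution of the doubled rank sum of
    group a. Two-sided p is the probability of a rank sum at least as far
    from its null mean as observed.
    """
    total2 = int(ranks2.sum())
    max_s = total2
    ways = np.zeros((n_a + 1, max_s + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(n_a, 0, -1):
            ways[j, r:] += ways[j - 1, : max_s + 1 - r]
    dist = ways[n_a]  # counts over doubled rank sums
    n_total = dist.sum()
    support = np.nonzero(dist)[0]
    if alternative == "greater":
        mass = dist[support[support >= w2_obs]].sum()
    elif alternative == "less":
        mass = dist[support[support <= w2_obs]].sum()
    elif alternative == "two-sided":
        n = len(ranks2)
        mu2 = n_a * (n + 1)  # doubled null mean of the rank sum
        dev = abs(w2_obs - mu2)
        mass = dist[support[np.abs(support - mu2) >= dev]].sum()
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float(mass / n_total)


def wilcoxon_rank_sum(
    a,
    b,
    alternative: str = "two-sided",
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of two independent samples.

    Returns (U, p) where U is the Mann-Whitney statistic of sample ``a``.
    With ``n_a + n_b <= exact_limit`` the p-value enumerates the
    permutation null exactly (ties included, via midranks); otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used. Two identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 values")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN values are not allowed")
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w_a = float(ranks[:n_a].sum())
    u_a = w_a - n_a * (n_a + 1) / 2.0

    if n <= exact_limit:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        w2_obs = int(round(2 * w_a))
        p = _exact_ranksum_p(ranks2, n_a, w2_obs, alternative)
        return u_a, p

    mu_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all values identical
        return u_a, 1.0
    sd = np.sqrt(var_u)
    if alternative == "two-sided":
        z = (abs(u_a - mu_u) - 0.5) / sd
        p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    elif alternative == "greater":
        z = (u_a - mu_u - 0.5) / sd
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        z = (u_a - mu_u + 0.5) / sd
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return u_a, float(p)


# ---------------------------------------------------------------------------
# element stratification


@dataclass
class GroupComparison:
    """Rank-sum comparison of a metric between genes with and without a
    5'UTR element."""

    element: str
    metric: str
    timepoint: str
    n_with: int
    n_without: int
    median_with: float
    median_without: float
    u_statistic: float
    p_value: float
    alternative: str


def compare_by_element(
    values: pd.Series,
    elements: ElementTable,
    element: str,
    metric: str = "",
    timepoint: str = "",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Split a per-gene metric by element presence and rank-sum test it.

    ``values`` is indexed by gene_id; NaNs (genes excluded upstream) are
    dropped before grouping. Raises when either group has fewer than two
    usable genes.
    """
    if element not in ELEMENTS:
        raise ValueError(f"unknown element: {element!r}")
    vals = values.dropna()
    flagged = elements.genes_with(element)
    with_el = vals[vals.index.isin(flagged)]
    without_el = vals[~vals.index.isin(flagged)]
    if len(with_el) < 2 or len(without_el) < 2:
        raise ValueError(
            f"empty group: {element} split has {len(with_el)} with / "
            f"{len(without_el)} without usable values"
        )
    u, p = wilcoxon_rank_sum(with_el.to_numpy(), without_el.to_numpy(), alternative)
    return GroupComparison(
        element=element,
        metric=metric,
        timepoint=timepoint,
        n_with=len(with_el),
        n_without=len(without_el),
        median_with=float(np.median(with_el)),
        median_without=float(np.median(without_el)),
        u_statistic=u,
        p_value=p,
        alternative=alternative,
    )


def permutation_null_pvalues(
    values: pd.Series,
    n_flagged: int,
    n_permutations: int,
    seed: int,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Rank-sum p-values under random relabelling of element flags.

    Used for null calibration: with no real group difference, the
    fraction of p < 0.05 should sit near 0.05.
    """
    vals = values.dropna().to_numpy()
    rng = np.random.default_rng(seed)
    ps = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(vals))
        a = vals[perm[:n_flagged]]
        b = vals[perm[n_flagged:]]
        _, ps[i] = wilcoxon_rank_sum(a, b, alternative)
    return ps


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


# ---------------------------------------------------------------------------
# clustering + enrichment


@dataclass
class ClusterResult:
    labels: pd.Series  # gene_id -> cluster label (0..k-1)
    centroids: pd.DataFrame  # cluster x time point (z-score space)
    enrichment: pd.DataFrame | None = None


def cluster_profiles(fc_matrix: pd.DataFrame, k: int = 5, seed: int = 0) -> ClusterResult:
    """k-means clustering of per-gene z-scored fold-change profiles.

    Genes with a flat profile (zero variance across time points) z-score
    to the zero vector and cluster together. Deterministic given ``seed``.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    if len(fc_matrix) < k:
        raise ValueError("fewer genes than clusters")
    X = fc_matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    labels = km.fit_predict(Z)
    return ClusterResult(
        labels=pd.Series(labels, index=fc_matrix.index, name="cluster"),
        centroids=pd.DataFrame(
            km.cluster_centers_, columns=fc_matrix.columns
        ).rename_axis("cluster"),
    )


def hypergeometric_test(k_overlap: int, set_size: int, cluster_size: int, universe: int) -> float:
    """Upper-tail enrichment p-value P(X >= k) for overlap k between a gene
    set of size K and a cluster of size n drawn from a universe of N genes."""
    k, K, n, N = int(k_overlap), int(set_size), int(cluster_size), int(universe)
    if K > N or n > N:
        raise ValueError("set and cluster sizes cannot exceed the universe")
    if k > min(K, n):
        raise ValueError("overlap cannot exceed min(set size, cluster size)")
    if k < 0:
        raise ValueError("overlap must be non-negative")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_clusters(
    labels: pd.Series,
    gene_sets: dict[str, set],
    universe: set | None = None,
) -> pd.DataFrame:
    """Hypergeometric annotation of each cluster against each gene set.

    The universe defaults to the clustered genes; supplied gene sets are
    intersected with it so the sampling model is consistent.
    """
    uni = set(labels.index) if universe is None else set(universe)
    N = len(uni)
    rows = []
    for cluster in sorted(labels.unique()):
        members = set(labels.index[labels == cluster]) & uni
        for name in sorted(gene_sets):
            gs = set(gene_sets[name]) & uni
            k = len(members & gs)
            p = hypergeometric_test(k, len(gs), len(members), N)
            rows.append(
                {
                    "cluster": cluster,
                    "set_name": name,
                    "overlap_k": k,
                    "set_size_K": len(gs),
                    "cluster_size_n": len(members),
                    "universe_N": N,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def read_gmt(path: str) -> dict[str, set]:
    """Read gene sets from GMT (set name, description, then gene ids)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


# ---------------------------------------------------------------------------
# summaries


def ecdf_and_median(values) -> tuple[pd.DataFrame, float]:
    """Empirical CDF table (x, F) and the sample median.

    The median of an even-sized sample is the mean of the central pair.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values")
    table = pd.DataFrame(
        {"x": v, "F": np.arange(1, len(v) + 1) / len(v)}
    )
    return table, float(np.median(v))
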