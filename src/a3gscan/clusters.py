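"""Mutation clustering and negative-binomial cluster scores.

A cluster is a maximal chain of >= ``min_size`` mutations on one
chromosome in which every consecutive pair lies within ``max_spacing`` bp
(default 50; 100/300/1000 supported for sensitivity analyses).  Clusters
containing a consecutive pair <= 10 bp apart are excluded as potential
complex mutations.  Clusters are typed by their shared ancestral base
(A/C/G/T) or N when mixed; N clusters are kept for audit but excluded from
coordinated-cluster statistics.

The cluster score is the probability of observing k-1 further mutations
within x-1 bp of the first, where x is the cluster span and pi the
genome-wide per-bp mutation probability (mutation count / callable
length): the lower CDF at x-k failures of a negative binomial with k-1
successes and success probability pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError

CLUSTER_COLUMNS = ["cluster_id", "chrom", "start", "end", "k", "span", "type",
                   "min_gap", "p_value"]


def detect_clusters(
    muts: pd.DataFrame, max_spacing: int = 50, min_size: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chain sorted mutations into clusters.

    Returns ``(muts_with_cluster_id, clusters)``; unclustered mutations get
    cluster_id -1.  Input must be sorted by (chrom, pos0) with unique
    positions per chromosome.
    """
    if max_spacing < 1:
        raise ArgumentError("max_spacing must be >= 1")
    pos = muts["pos0"].to_numpy()
    chrom = muts["chrom"].to_numpy()
    if len(muts) == 0:
        out = muts.copy()
        out["cluster_id"] = np.array([], dtype=np.int64)
        return out, pd.DataFrame(columns=CLUSTER_COLUMNS[:-1])
    same = chrom[1:] == chrom[:-1]
    gaps = np.diff(pos)
    if np.any(same & (gaps <= 0)):
        raise ArgumentError("mutations must be sorted with unique positions per chromosome")

    new_chain = np.ones(len(muts), dtype=bool)
    new_chain[1:] = ~same | (gaps > max_spacing)
    chain_id = np.cumsum(new_chain) - 1
    sizes = np.bincount(chain_id)
    keep = sizes >= min_size

    cluster_of_chain = np.full(sizes.size, -1, dtype=np.int64)
    cluster_of_chain[keep] = np.arange(int(keep.sum()))
    out = muts.copy()
    out["cluster_id"] = cluster_of_chain[chain_id]

    cl = (out[out["cluster_id"] >= 0]
          .groupby("cluster_id")
          .agg(chrom=("chrom", "first"), start=("pos0", "min"),
               end=("pos0", "max"), k=("pos0", "size")))
    cl["span"] = cl["end"] - cl["start"] + 1
    # smallest consecutive gap, for the complex-mutation exclusion
    min_gaps = []
    for cid, grp in out[out["cluster_id"] >= 0].groupby("cluster_id"):
        min_gaps.append(int(np.diff(grp["pos0"].to_numpy()).min()))
    cl["min_gap"] = min_gaps
    cl = cl.reset_index()
    return out, cl


def exclude_complex(
    muts: pd.DataFrame, clusters: pd.DataFrame, min_spacing: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop whole clusters containing a consecutive pair <= min_spacing bp
    apart.  Returns (muts, kept_clusters, removed_clusters); mutations of
    removed clusters revert to cluster_id -1."""
    bad = clusters["min_gap"] <= min_spacing
    removed = clusters[bad].copy()
    kept = clusters[~bad].copy()
    out = muts.copy()
    out.loc[out["cluster_id"].isin(set(removed["cluster_id"])), "cluster_id"] = -1
    return out, kept, removed


def classify_clusters(muts: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Assign cluster type: the shared ancestral base, or N when mixed."""
    cl = clusters.copy()
    if len(cl) == 0:
        cl["type"] = pd.Series(dtype=object)
        return cl
    anc = muts[muts["cluster_id"] >= 0].groupby("cluster_id")["anc"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else "N")
    cl["type"] = cl["cluster_id"].map(anc)
    return cl


def cluster_pvalue(k, x, pi):
    """P(k-1 further mutations within x-1 bp | per-bp probability pi).

    Vectorised; equals ``sum_{j=0}^{x-k} C(k-2+j, j) (1-pi)^j pi^(k-1)``.
    """
    k = np.asarray(k)
    x = np.asarray(x)
    if np.any(k < 2):
        raise ArgumentError("cluster size k must be >= 2")
    if np.any(x < k):
        raise ArgumentError("cluster span x must be >= k")
    if not 0 < pi < 1:
        raise ArgumentError(f"pi must lie in (0, 1), got {pi}")
    p = stats.nbinom.cdf(x - k, k - 1, pi)
    return float(p) if p.ndim == 0 else p


@dataclass
class ClusterSet:
    """Clusters plus the mutation table they were built from.

    ``mutations`` covers *all* mutations of the lineage (clustered or not;
    cluster_id -1 marks unclustered), which is what the genome-wide
    per-bp probability ``pi`` is computed from.
    """

    mutations: pd.DataFrame
    clusters: pd.DataFrame
    callable_length: int
    pi: float
    max_spacing: int = 50
    min_spacing_complex: int = 10
    p_threshold: float | None = None
    removed_complex: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_n: pd.DataFrame = field(default_factory=pd.DataFrame)

    def coordinated(self, types=("C", "G")) -> pd.DataFrame:
        return self.clusters[self.clusters["type"].isin(types)]

    def clustered_mutations(self, types=("C", "G")) -> pd.DataFrame:
        ids = set(self.coordinated(types)["cluster_id"])
        m = self.mutations
        return m[m["cluster_id"].isin(ids)]

    def cluster_types(self, muts_or_ids) -> pd.Series:
        return self.clusters.set_index("cluster_id")["type"]

    def size_histogram(self, types=("C", "G")) -> dict[int, int]:
        """N_i: number of clusters of the given types with i mutations."""
        counts = self.coordinated(types)["k"].value_counts()
        return {int(i): int(n) for i, n in counts.sort_index().items()}

    def subset(self, cluster_ids) -> "ClusterSet":
        ids = set(cluster_ids)
        cl = self.clusters[self.clusters["cluster_id"].isin(ids)]
        m = self.mutations.copy()
        m.loc[~m["cluster_id"].isin(ids), "cluster_id"] = -1
        return ClusterSet(m, cl, self.callable_length, self.pi, self.max_spacing,
                          self.min_spacing_complex, self.p_threshold)


def build_cluster_set(
    muts: pd.DataFrame,
    callable_length: int,
    max_spacing: int = 50,
    min_spacing_complex: int = 10,
    min_size: int = 2,
    p_threshold: float | None = None,
) -> ClusterSet:
    """Full clustering stage: chain, exclude complex, classify, score.

    ``pi`` is the per-lineage mutation probability: total mutations of the
    lineage divided by the callable length.
    """
    if callable_length <= 0:
        raise ArgumentError("callable_length must be positive")
    pi = len(muts) / callable_length
    mm, clusters = detect_clusters(muts, max_spacing, min_size)
    mm, clusters, removed_complex = exclude_complex(mm, clusters, min_spacing_complex)
    clusters = classify_clusters(mm, clusters)
    if len(clusters) and 0 < pi < 1:
        clusters["p_value"] = cluster_pvalue(
            clusters["k"].to_numpy(), clusters["span"].to_numpy(), pi)
    else:
        clusters["p_value"] = np.nan
    removed_n = clusters[clusters["type"] == "N"].copy()
    cs = ClusterSet(mm, clusters, callable_length, pi, max_spacing,
                    min_spacing_complex, None, removed_complex, removed_n)
    if p_threshold is not None:
        cs = filter_by_pvalue(cs, p_threshold)
    return cs


def filter_by_pvalue(cluster_set: ClusterSet, threshold: float) -> ClusterSet:
    """Keep clusters with p <= threshold (threshold in (0, 1])."""
    if not 0 < threshold <= 1:
        raise ArgumentError(f"p-value threshold must lie in (0, 1], got {threshold}")
    cl = cluster_set.clusters
    keep = cl[cl["p_value"] <= threshold]
    out = cluster_set.subset(keep["cluster_id"])
    out.p_threshold = threshold
    out.removed_complex = cluster_set.removed_complex
    out.removed_n = out.clusters[out.clusters["type"] == "N"].copy()
    return out


def expected_same_ancestor_clusters(n_i: dict[int, int], p: float) -> float:
    """Expected count of clusters whose mutations all share one ancestral
    state: sum_i N_i * p**i, with p the prevalence of that state among all
    mutations."""
    if not 0 <= p <= 1:
        raise ArgumentError("prevalence p must lie in [0, 1]")
    return float(sum(n * p ** i for i, n in n_i.items()))


def expected_a3g_clusters(n_i: dict[int, int], p_motif: float) -> float:
    """Expected count of clusters with at least one motif mutation:
    sum_i N_i * (1 - (1-p)**i), the closed form of the binomial sum."""
    if not 0 <= p_motif <= 1:
        raise ArgumentError("p_motif must lie in [0, 1]")
    return float(sum(n * (1 - (1 - p_motif) ** i) for i, n in n_i.items()))


def define_a3g_clusters(cluster_set: ClusterSet, motif=None) -> ClusterSet:
    """C-coordinated clusters with >= 1 mutation matching the stringent
    deaminase motif (CCC, 3' C) on the plus strand, plus G-coordinated
    clusters with a reverse-complement (GGG) match.  The union of their
    mutations is the putative enzyme-induced set."""
    from .motifs import A3G_CCC, window_matches

    motif = A3G_CCC if motif is None else motif
    m = cluster_set.mutations
    types = cluster_set.clusters.set_index("cluster_id")["type"]
    clustered = m[m["cluster_id"] >= 0].copy()
    if len(clustered) == 0:
        return cluster_set.subset([])
    ctype = clustered["cluster_id"].map(types)
    match = np.zeros(len(clustered), dtype=bool)
    for t, strand in (("C", "+"), ("G", "-")):
        sel = (ctype == t).to_numpy()
        if sel.any():
            match[sel] = window_matches(clustered.loc[sel, "window"], motif, strand)
    clustered["motif_match"] = match
    ids = clustered.loc[match, "cluster_id"].unique()
    return cluster_set.subset(ids)
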