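"""Cluster distinctness by total variation distance (TVD).

The TVD of two clusters is half the L1 distance between their normalized
copying vectors — the distance between the clusters in terms of haplotype
sharing with *all* clusters.  Significance comes from a permutation test
that reassigns the pooled members of the two clusters to pseudo-clusters
of the original sizes (enumerated exhaustively when feasible); cluster
relations are summarized by a tree built in k-1 successive lowest-TVD
merges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .coancestry import ClusterAssignment, CoancestryMatrix, CopyingVectors, \
    copying_vectors


def tvd_pair(v: CopyingVectors, a: str, b: str, raw: bool = False) -> float:
    """TVD between the copying vectors of clusters a and b.

    Returns half the L1 distance (a metric in [0, 1] on probability
    vectors); ``raw=True`` returns the unhalved sum of absolute
    differences.
    """
    if not v.normalized:
        raise ValueError("copying vectors must be normalized; build them with "
                         "copying_vectors(..., normalize=True)")
    diff = np.abs(v.vector(a).to_numpy() - v.vector(b).to_numpy()).sum()
    return float(diff if raw else 0.5 * diff)


@dataclass(frozen=True)
class TVDResult:
    """TVD of a cluster pair with its permutation p-value."""

    cluster_a: str
    cluster_b: str
    tvd: float
    n_permutations: int
    n_at_least_as_extreme: int
    p_value: float
    exhaustive: bool
    p_is_upper_bound: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.tvd <= 1 + 1e-12:
            raise ValueError("tvd must be in [0, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        if self.n_at_least_as_extreme > self.n_permutations:
            raise ValueError("count cannot exceed number of permutations")

    @property
    def p_label(self) -> str:
        if self.p_is_upper_bound:
            return f"<{1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


def _pair_tvd_engine(m: CoancestryMatrix, c: ClusterAssignment,
                     a: str, b: str, raw: bool = False):
    """Precompute the pieces needed to evaluate the pseudo-cluster TVD of any
    split of the pooled members of clusters a and b.

    Only the vectors of the two pseudo-clusters matter for the statistic, so
    unrelated clusters' memberships stay fixed: their aggregated donor
    columns are precomputed once; the a/b donor columns are recomputed per
    split from the pool submatrix.
    """
    c.check_covers(m.ids)
    labels = c.labels.loc[m.ids]
    members_a = list(labels.index[labels == a])
    members_b = list(labels.index[labels == b])
    if not members_a or not members_b:
        raise ValueError(f"clusters {a!r} and {b!r} must both be non-empty")
    pool = members_a + members_b
    pool_idx = pd.Index(pool)
    other_clusters = [k for k in sorted(labels.unique()) if k not in (a, b)]
    # donor columns of unrelated clusters, for pool recipients only
    M_pool = m.df.loc[pool]
    S_other = np.column_stack([
        M_pool[labels.index[labels == k].intersection(m.df.columns)].to_numpy().sum(axis=1)
        for k in other_clusters]) if other_clusters else np.zeros((len(pool), 0))
    M_pp = m.df.loc[pool, pool].to_numpy()
    n_a = len(members_a)

    def split_tvd(idx_a: np.ndarray) -> float:
        """TVD of the pseudo-clusters defined by pool positions idx_a vs rest."""
        mask = np.zeros(len(pool), dtype=bool)
        mask[idx_a] = True
        col_a = M_pp[:, mask].sum(axis=1)   # donation from pseudo-a to each pool member
        col_b = M_pp[:, ~mask].sum(axis=1)
        # copying vectors of the two pseudo-clusters over (others..., a, b)
        va = np.concatenate([S_other[mask].mean(axis=0),
                             [col_a[mask].mean(), col_b[mask].mean()]])
        vb = np.concatenate([S_other[~mask].mean(axis=0),
                             [col_a[~mask].mean(), col_b[~mask].mean()]])
        sa, sb = va.sum(), vb.sum()
        if sa <= 0 or sb <= 0:
            raise ValueError("zero-mass pseudo-cluster copying vector")
        diff = np.abs(va / sa - vb / sb).sum()
        return float(diff if raw else 0.5 * diff)

    observed = split_tvd(np.arange(n_a))
    return split_tvd, observed, n_a, len(pool), members_a, members_b


def tvd_permutation_test(m: CoancestryMatrix, c: ClusterAssignment,
                         a: str, b: str, n_perm: int = 1000,
                         seed: int | None = None, raw: bool = False,
                         add_one_smoothing: bool = False,
                         force_monte_carlo: bool = False) -> TVDResult:
    """Permutation test of the TVD between clusters a and b.

    Pooled members of a and b are reassigned to pseudo-clusters of the
    original sizes and the TVD recomputed (unrelated clusters held fixed;
    the restricted recomputation equals a full one since their memberships
    do not change).  When the number of distinct splits C(|a|+|b|, |a|) is
    at most ``n_perm`` all splits are enumerated exactly and the result is
    flagged exhaustive.  p is the plain ratio of permutations with TVD at
    least the observed; with zero exceedances (possible only in Monte
    Carlo mode) it is reported as an upper bound 1/n_perm.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    split_tvd, observed, n_a, n_pool, *_ = _pair_tvd_engine(m, c, a, b, raw)
    n_splits = comb(n_pool, n_a)
    tol = 1e-12
    if n_splits <= n_perm and not force_monte_carlo:
        count = 0
        for combo in itertools.combinations(range(n_pool), n_a):
            if split_tvd(np.array(combo)) >= observed - tol:
                count += 1
        total, exhaustive = n_splits, True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n_pool)[:n_a]
            if split_tvd(idx) >= observed - tol:
                count += 1
        total, exhaustive = n_perm, False
    if add_one_smoothing:
        p, upper = (count + 1) / (total + 1), False
    elif count > 0:
        p, upper = count / total, False
    else:
        p, upper = 1.0 / total, True
    return TVDResult(a, b, observed, total, count, p, exhaustive, upper)


def tvd_matrix(m: CoancestryMatrix, c: ClusterAssignment, n_perm: int = 1000,
               seed: int | None = None, raw: bool = False) -> list[TVDResult]:
    """Permutation-tested TVD for all unordered cluster pairs (raw p-values,
    no multiplicity correction)."""
    clusters = sorted(c.labels.loc[m.ids].unique())
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(comb(len(clusters), 2))
    results = []
    for (a, b), child in zip(itertools.combinations(clusters, 2), children):
        results.append(tvd_permutation_test(
            m, c, a, b, n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2 ** 31)), raw=raw))
    return results


def tvd_results_frame(results: list[TVDResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "clusterA": r.cluster_a, "clusterB": r.cluster_b, "tvd": r.tvd,
        "p": r.p_value, "p_label": r.p_label, "n_perm": r.n_permutations,
        "exhaustive": r.exhaustive} for r in results])


# ---------------------------------------------------------------------------
# TVD tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TVDTree:
    """Binary merge tree over clusters; each merge records its TVD height."""

    leaves: list[str]
    merges: list[tuple[str, str, float]]  # (label_a, label_b, tvd) in merge order

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a tree over k clusters needs exactly k-1 merges")

    def newick(self) -> str:
        """Newick string; a child's branch length is the difference between its
        parent's merge height and its own (leaves sit at height 0), floored
        at 0 when merge heights are non-monotone."""
        node_repr = {leaf: leaf for leaf in self.leaves}
        node_height = {leaf: 0.0 for leaf in self.leaves}
        merged_label = {leaf: leaf for leaf in self.leaves}
        for a, b, h in self.merges:
            bl_a = max(h - node_height[a], 0.0)
            bl_b = max(h - node_height[b], 0.0)
            rep = f"({node_repr[a]}:{bl_a:.6g},{node_repr[b]}:{bl_b:.6g})"
            new = _merge_label(a, b)
            node_repr[new] = rep
            node_height[new] = h
            for old in (a, b):
                del node_repr[old], node_height[old]
        (root_rep,) = node_repr.values()
        return root_rep + ";"


def _merge_label(a: str, b: str) -> str:
    return f"({a}+{b})"


def tvd_tree(m: CoancestryMatrix, c: ClusterAssignment,
             raw: bool = False) -> TVDTree:
    """Build the k-1-step TVD merge tree.

    At each step the pair of clusters with lowest TVD (copying vectors and
    TVD recomputed over the current, reduced cluster set) is merged into
    the union of its members; ties break on the lexicographically smallest
    (a, b) label pair.  Merge heights are the TVD values of the merged
    pairs.
    """
    c.check_covers(m.ids)
    labels = c.labels.loc[m.ids].copy()
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    leaves = list(clusters)
    merges: list[tuple[str, str, float]] = []
    while len(set(labels)) > 1:
        assignment = ClusterAssignment(labels)
        vectors = copying_vectors(m, assignment, normalize=True)
        current = sorted(labels.unique())
        best: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(current, 2):
            t = tvd_pair(vectors, a, b, raw=raw)
            if best is None or t < best[0] - 1e-15 or \
                    (abs(t - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])):
                best = (t, a, b)
        t, a, b = best
        merges.append((a, b, t))
        labels[labels.isin([a, b])] = _merge_label(a, b)
    return TVDTree(leaves, merges)
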