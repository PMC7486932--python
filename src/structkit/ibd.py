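"""Time-stratified IBD-sharing analysis.

IBD (identity-by-descent) segment length carries time information: a
segment of length l cM shared by two individuals coalesces, in a large
population, at an expected depth of 75(1/L1 + 1/L2) generations for
segments binned in [L1, L2] cM.  This module turns segment lists into
length-binned pairwise sharing matrices, dates bins with that closed form,
clusters individuals per bin (PCA + Gaussian mixture with BIC model
selection), and computes within/between-group mean sharing with exact
pair-count denominators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .coancestry import ClusterAssignment, CoancestryPCA, ParseError

SEGMENT_COLUMNS = ["id1", "hap1", "id2", "hap2", "chromosome",
                   "start_bp", "end_bp", "lod", "length_cM"]


@dataclass(frozen=True)
class IBDSegmentSet:
    """Pairwise IBD segments with cM lengths; pairs canonical (id1 < id2)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = set(SEGMENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing segment columns: {sorted(missing)}")
        if (df["id1"] == df["id2"]).any():
            raise ValueError("self-pairs are not allowed")
        if len(df) and ((df["length_cM"] <= 0).any()
                        or (df["start_bp"] >= df["end_bp"]).any()):
            raise ValueError("segments must have length_cM > 0 and start_bp < end_bp")
        swap = df["id1"] > df["id2"]
        if swap.any():
            df = df.copy()
            df.loc[swap, ["id1", "id2"]] = df.loc[swap, ["id2", "id1"]].values
            df.loc[swap, ["hap1", "hap2"]] = df.loc[swap, ["hap2", "hap1"]].values
            object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return sorted(set(self.df["id1"]) | set(self.df["id2"]))

    @classmethod
    def empty(cls) -> "IBDSegmentSet":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            SEGMENT_COLUMNS,
            [str, int, str, int, str, int, int, float, float])}))


@dataclass(frozen=True)
class SegmentBin:
    """Half-open cM length bin [L1, L2)."""

    L1: float
    L2: float

    def __post_init__(self) -> None:
        if not 0 < self.L1 < self.L2:
            raise ValueError(f"need 0 < L1 < L2, got [{self.L1}, {self.L2})")

    def mask(self, lengths) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        return (lengths >= self.L1) & (lengths < self.L2)


@dataclass(frozen=True)
class BinnedSharingMatrix:
    """Symmetric per-pair sharing within one length bin (total cM or count)."""

    df: pd.DataFrame
    bin: SegmentBin
    statistic: str

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)


# ---------------------------------------------------------------------------
# RefinedIBD file dialect
# ---------------------------------------------------------------------------

def read_ibd(path) -> IBDSegmentSet:
    """Read a RefinedIBD-format segment file.

    Tab-delimited, nine columns: sample1, hap1, sample2, hap2, chromosome,
    start_bp, end_bp, LOD, length_cM.  Malformed rows are rejected with
    their line numbers; pairs are canonicalized to id1 < id2.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-delimited "
                                 f"columns, got {len(fields)}")
            s1, h1, s2, h2, chrom, start, end, lod, length = fields
            if s1 == s2:
                raise ParseError(f"{path}:{lineno}: self-pair {s1!r}")
            try:
                records.append((s1, int(h1), s2, int(h2), chrom,
                                int(start), int(end), float(lod), float(length)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    if not records:
        return IBDSegmentSet.empty()
    df = pd.DataFrame.from_records(records, columns=SEGMENT_COLUMNS)
    return IBDSegmentSet(df)


def write_ibd(s: IBDSegmentSet, path) -> None:
    """Write the 9-column tab-delimited RefinedIBD dialect."""
    with open(path, "w") as fh:
        for row in s.df.itertuples(index=False):
            fh.write("\t".join([
                str(row.id1), str(int(row.hap1)), str(row.id2), str(int(row.hap2)),
                str(row.chromosome), str(int(row.start_bp)), str(int(row.end_bp)),
                f"{row.lod:.1f}", repr(float(row.length_cM))]) + "\n")


# ---------------------------------------------------------------------------
# binned sharing matrices
# ---------------------------------------------------------------------------

def binned_sharing_matrix(s: IBDSegmentSet, bin: SegmentBin,
                          statistic: str = "total_cM",
                          roster: list[str] | None = None) -> BinnedSharingMatrix:
    """Pairwise sharing matrix restricted to segments with L1 <= length < L2.

    ``statistic`` is ``total_cM`` (sum of segment lengths) or ``count``.
    ``roster`` fixes the id order and admits individuals with no segments;
    it defaults to the ids present in the full segment set.
    """
    if statistic not in ("total_cM", "count"):
        raise ValueError("statistic must be 'total_cM' or 'count'")
    if roster is None:
        roster = s.ids
    roster = list(roster)
    if not roster:
        raise ValueError("empty roster")
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate ids in roster")
    pos = {ident: k for k, ident in enumerate(roster)}
    out = np.zeros((len(roster), len(roster)))
    if len(s):
        sel = s.df[bin.mask(s.df["length_cM"])]
        unknown = (set(sel["id1"]) | set(sel["id2"])) - set(roster)
        if unknown:
            raise ValueError(f"segment ids missing from roster: {sorted(unknown)[:5]}")
        if len(sel):
            grouped = (sel.groupby(["id1", "id2"])["length_cM"].sum()
                       if statistic == "total_cM"
                       else sel.groupby(["id1", "id2"]).size())
            for (a, b), v in grouped.items():
                i, j = pos[a], pos[b]
                out[i, j] += v
                out[j, i] += v
    df = pd.DataFrame(out, index=roster, columns=roster)
    return BinnedSharingMatrix(df, bin, statistic)


# ---------------------------------------------------------------------------
# closed-form segment dating
# ---------------------------------------------------------------------------

def expected_tmrca(bin: SegmentBin,
                   generation_time_years: float = 28.0) -> tuple[float, float]:
    """Expected coalescence time of segments in a length bin.

    In the large-population limit, segments of length between L1 and L2 cM
    coalesce at ``75 * (1/L1 + 1/L2)`` generations on average; years are
    generations times the human generation time (default 28).  Returns
    ``(generations, years)``.
    """
    if bin.L1 <= 0:
        raise ValueError("L1 must be positive")
    generations = 75.0 * (1.0 / bin.L1 + 1.0 / bin.L2)
    return generations, generations * generation_time_years


# ---------------------------------------------------------------------------
# PCA + Gaussian-mixture clustering of sharing matrices
# ---------------------------------------------------------------------------

class IBDMixtureClusterer(BaseEstimator):
    """Cluster individuals from a binned sharing matrix.

    PCA (column-centred, unscaled, deterministic component signs) reduces
    the symmetric sharing matrix to ``n_pcs`` scores; Gaussian mixtures are
    then fit for k = 1..k_max over diagonal and full covariance families
    with multi-start EM, and the model with lowest BIC is kept.

    Attributes
    ----------
    labels_ : pd.Series of cluster labels ("C1"..), indexed by id
    n_clusters_ : selected component count
    bic_table_ : DataFrame (k, covariance, bic) for every candidate
    scores_ : PC score DataFrame used for clustering
    """

    def __init__(self, n_pcs: int = 10, k_max: int = 9,
                 covariance_types: tuple[str, ...] = ("diag", "full"),
                 n_init: int = 10, random_state: int = 0):
        self.n_pcs = n_pcs
        self.k_max = k_max
        self.covariance_types = covariance_types
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        df = X.df if isinstance(X, BinnedSharingMatrix) else pd.DataFrame(X)
        n = df.shape[0]
        if n < self.k_max + 1:
            raise ValueError("need at least k_max + 1 individuals")
        if not np.any(df.to_numpy() != 0) or np.allclose(df.to_numpy().std(axis=0), 0):
            raise ValueError("degenerate sharing matrix: no variation to cluster")
        n_pcs = min(self.n_pcs, n - 1)
        self.scores_ = CoancestryPCA(n_components=n_pcs).fit_transform(df)
        Z = self.scores_.to_numpy()
        rows = []
        best = None
        for cov, k in itertools.product(self.covariance_types,
                                        range(1, self.k_max + 1)):
            gmm = GaussianMixture(n_components=k, covariance_type=cov,
                                  n_init=self.n_init, reg_covar=1e-6,
                                  random_state=self.random_state)
            gmm.fit(Z)
            bic = gmm.bic(Z)
            rows.append({"k": k, "covariance": cov, "bic": bic})
            if best is None or bic < best[0]:
                best = (bic, gmm)
        self.bic_table_ = pd.DataFrame(rows)
        self.gmm_ = best[1]
        self.n_clusters_ = self.gmm_.n_components
        raw = self.gmm_.predict(Z)
        # stable label names by order of first appearance
        remap: dict[int, str] = {}
        for lab in raw:
            if lab not in remap:
                remap[lab] = f"C{len(remap) + 1}"
        self.labels_ = pd.Series([remap[v] for v in raw], index=df.index)
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_

    def assignment_(self) -> ClusterAssignment:
        return ClusterAssignment(self.labels_)


def pca_gmm_cluster(m: BinnedSharingMatrix, n_pcs: int = 10, k_max: int = 9,
                    seed: int = 0) -> tuple[ClusterAssignment, pd.DataFrame, int]:
    """PCA + BIC-selected Gaussian-mixture clustering of a sharing matrix.

    Returns ``(assignment, bic_table, chosen_k)``.
    """
    est = IBDMixtureClusterer(n_pcs=n_pcs, k_max=k_max, random_state=seed).fit(m)
    return est.assignment_(), est.bic_table_, est.n_clusters_


# ---------------------------------------------------------------------------
# mean pairwise sharing with exact denominators
# ---------------------------------------------------------------------------

def mean_pairwise_sharing(s: IBDSegmentSet, groups: ClusterAssignment,
                          bin: SegmentBin,
                          statistic: str = "count") -> pd.DataFrame:
    """Group-by-group mean pairwise sharing within a length bin.

    The numerator totals the qualifying statistic over the relevant pair
    set; the denominator is the exact pair count: (N^2 - N)/2 for a group
    of size N with itself, N*M for two distinct groups.  Requesting the
    within-group mean of a singleton group is an error.
    """
    if statistic not in ("total_cM", "count"):
        raise ValueError("statistic must be 'total_cM' or 'count'")
    groups.check_covers(s.ids)
    sizes = groups.sizes()
    labels = groups.labels
    names = list(sizes.index)
    for g, n in sizes.items():
        if n < 2:
            raise ValueError(f"within-group mean undefined for singleton group {g!r}")
    totals = pd.DataFrame(0.0, index=names, columns=names)
    if len(s):
        sel = s.df[bin.mask(s.df["length_cM"])]
        if len(sel):
            g1 = labels.loc[sel["id1"]].to_numpy()
            g2 = labels.loc[sel["id2"]].to_numpy()
            weight = (sel["length_cM"].to_numpy() if statistic == "total_cM"
                      else np.ones(len(sel)))
            for a, b, w in zip(g1, g2, weight):
                totals.loc[a, b] += w
                if a != b:
                    totals.loc[b, a] += w
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            na, nb = sizes[a], sizes[b]
            denom = (na * na - na) / 2 if a == b else na * nb
            out.loc[a, b] = totals.loc[a, b] / denom
    return out
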