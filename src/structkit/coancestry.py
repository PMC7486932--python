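"""Coancestry (chunklength) matrices, copying vectors and coancestry PCA.

The substrate of all cluster-validation work is the recipient-by-donor
matrix of total genetic map length (cM) each donor contributes to each
recipient under a haplotype-copying model.  A cluster's *copying vector*
is its average donation profile over clusters; normalized copying vectors
are probability vectors and support total-variation-distance comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; message carries line numbers."""


@dataclass(frozen=True)
class CoancestryMatrix:
    """Square donated-cM matrix; entry (i, j) is what donor j donates to recipient i.

    ``df`` is indexed by recipient id with identical column order.  The
    diagonal is zero: an individual never copies from itself.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.shape[0] != self.df.shape[1]:
            raise ValueError("coancestry matrix must be square")
        if not self.df.index.equals(self.df.columns):
            raise ValueError("row and column ids must be identical and in the same order")
        if self.df.index.has_duplicates:
            dupes = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ids: {dupes}")
        values = self.df.to_numpy()
        if (values < 0).any():
            raise ValueError("coancestry entries must be non-negative")
        diag = np.diag(values)
        if (diag != 0).any():
            warnings.warn("nonzero diagonal in coancestry matrix forced to 0",
                          stacklevel=2)
            fixed = self.df.copy()
            np.fill_diagonal(fixed.values, 0.0)
            object.__setattr__(self, "df", fixed)

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __len__(self) -> int:
        return self.df.shape[0]


@dataclass(frozen=True)
class ClusterAssignment:
    """Map individual id -> cluster label, with optional cluster-group labels."""

    labels: pd.Series  # index: individual id, values: cluster label
    groups: dict[str, str] | None = None  # cluster label -> cluster-group label

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("individuals assigned more than once")
        object.__setattr__(self, "labels", self.labels.astype(str))

    @classmethod
    def from_dict(cls, mapping: dict, groups: dict | None = None) -> "ClusterAssignment":
        return cls(pd.Series(mapping, dtype=str), groups)

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())

    def members(self, cluster: str) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def check_covers(self, ids) -> None:
        missing = set(ids) - set(self.labels.index)
        if missing:
            raise ValueError(f"ids without cluster assignment: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class CopyingVectors:
    """Per-cluster donation profiles over clusters (rows: cluster, cols: donor cluster)."""

    df: pd.DataFrame
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.normalized:
            sums = self.df.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized copying vectors must sum to 1 within 1e-9")

    def vector(self, cluster: str) -> pd.Series:
        return self.df.loc[cluster]


# ---------------------------------------------------------------------------
# chunklengths file dialect
# ---------------------------------------------------------------------------

def read_chunklengths(path) -> CoancestryMatrix:
    """Read a whitespace-delimited chunklengths file.

    The header row begins with ``Recipient`` followed by donor ids; each
    subsequent row is a recipient id followed by donated cM per donor.
    The header and first-column id sets must agree; a nonzero diagonal is
    forced to zero with a warning.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split()
    if header[0] != "Recipient":
        raise ParseError(f"{path}:1: header must begin with 'Recipient'")
    donor_ids = header[1:]
    if len(set(donor_ids)) != len(donor_ids):
        raise ParseError(f"{path}:1: duplicate donor ids in header")
    rows: dict[str, list[float]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) != len(donor_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(donor_ids) + 1} fields, got {len(fields)}")
        rid = fields[0]
        if rid in rows:
            raise ParseError(f"{path}:{lineno}: duplicate recipient id {rid!r}")
        try:
            rows[rid] = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if set(rows) != set(donor_ids):
        odd = sorted(set(rows) ^ set(donor_ids))
        raise ParseError(
            f"{path}: header and first-column ids disagree on {odd[:5]}")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=donor_ids)
    df = df.loc[donor_ids]  # row order follows the header
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CoancestryMatrix(df)


def write_chunklengths(m: CoancestryMatrix, path) -> None:
    """Write the chunklengths dialect read by :func:`read_chunklengths`."""
    with open(path, "w") as fh:
        fh.write("Recipient " + " ".join(m.ids) + "\n")
        for rid, row in m.df.iterrows():
            fh.write(rid + " " + " ".join(repr(float(v)) for v in row) + "\n")


def read_clusters(path) -> ClusterAssignment:
    """Read a cluster TSV (id, cluster[, cluster_group])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "cluster" not in df.columns:
        raise ParseError(f"{path}: need 'id' and 'cluster' columns")
    labels = pd.Series(df["cluster"].values, index=df["id"].values)
    groups = None
    if "cluster_group" in df.columns:
        groups = dict(zip(df["cluster"], df["cluster_group"]))
    return ClusterAssignment(labels, groups)


# ---------------------------------------------------------------------------
# copying vectors
# ---------------------------------------------------------------------------

def copying_vectors(m: CoancestryMatrix, c: ClusterAssignment,
                    normalize: bool = True) -> CopyingVectors:
    """Average donation profile of each cluster over donor clusters.

    Component k of the vector for cluster A is the mean over recipients
    i in A of the total cM donated to i by members of cluster k.  The
    recipient's own cluster column includes donations from its other
    members (self-donation is excluded only by the zero diagonal).
    """
    c.check_covers(m.ids)
    labels = c.labels.loc[m.ids]
    empty = [cl for cl in c.clusters if (labels == cl).sum() == 0]
    if empty:
        raise ValueError(f"empty clusters: {empty}")
    # aggregate donor columns by cluster, then average recipient rows by cluster
    by_donor = m.df.T.groupby(labels).sum().T  # individuals x clusters
    vectors = by_donor.groupby(labels).mean()  # clusters x clusters
    vectors = vectors.loc[sorted(vectors.index), sorted(vectors.columns)]
    if normalize:
        sums = vectors.sum(axis=1)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValueError(f"cannot normalize zero-mass copying vectors: {bad}")
        vectors = vectors.div(sums, axis=0)
    return CopyingVectors(vectors, normalized=normalize)


# ---------------------------------------------------------------------------
# PCA of coancestry
# ---------------------------------------------------------------------------

class CoancestryPCA(BaseEstimator, TransformerMixin):
    """Principal components of a coancestry matrix.

    Columns are centred but not variance-scaled, matching the default
    convention of the R ``prcomp``-based tooling this mirrors.  Component
    signs are fixed deterministically: the loading of largest magnitude on
    each component is made positive, so scores are reproducible across runs.

    Attributes
    ----------
    components_ : ndarray (n_components, n_features)
    explained_variance_ : ndarray
    explained_variance_ratio_ : ndarray
    feature_ids_ : list of donor ids seen at fit
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, CoancestryMatrix):
            X = X.df
        if isinstance(X, pd.DataFrame):
            self._index = list(X.index)
            self.feature_ids_ = list(X.columns)
            X = X.to_numpy()
        else:
            X = np.asarray(X, dtype=float)
            self._index = list(range(X.shape[0]))
            self.feature_ids_ = list(range(X.shape[1]))
        if not np.isfinite(X).all():
            raise ValueError("coancestry matrix contains non-finite values")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        if self.n_components <= 0:
            raise ValueError("n_components must be positive")
        if self.n_components >= X.shape[0]:
            raise ValueError("n_components must be smaller than the number of individuals")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(X)
        comp = self._pca.components_
        # deterministic sign: largest-|loading| entry of each component positive
        flip = np.sign(comp[np.arange(comp.shape[0]),
                            np.abs(comp).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self._flip = flip
        self.components_ = comp * flip[:, None]
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.mean_ = self._pca.mean_
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, CoancestryMatrix):
            X = X.df
        index = list(X.index) if isinstance(X, pd.DataFrame) else None
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        scores = self._pca.transform(arr) * self._flip[None, :]
        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=index if index is not None else self._index,
                            columns=cols)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def pca_coancestry(m: CoancestryMatrix, n_components: int) -> pd.DataFrame:
    """PC scores per individual (columns PC1..PCn, decreasing explained variance)."""
    return CoancestryPCA(n_components=n_components).fit_transform(m)
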