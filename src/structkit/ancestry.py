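"""Ancestry profiles: non-negative mixture deconvolution of copying vectors.

Each target individual's normalized copying vector Y over G donor groups
is modelled as a non-negative mixture of the donor groups' own copying
profiles X_1..X_G:

    Y = beta_1 X_1 + ... + beta_G X_G,   beta_g >= 0,  sum(beta) = 1.

The betas are the "cleaned" genome proportions most closely shared with
each donor group.  Groups contributing less than a threshold (5% by
default) are pruned and the model refit to suppress noise from donor-group
similarity; shares can then be aggregated by the donor groups' countries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .coancestry import ClusterAssignment, CoancestryMatrix


@dataclass(frozen=True)
class DonorCopyMatrix:
    """G x G matrix; row g is the average normalized profile donor group g copies
    from every donor group (its own included).  Rows sum to 1."""

    df: pd.DataFrame
    countries: pd.Series | None = None  # group label -> country

    def __post_init__(self) -> None:
        if self.df.shape[0] != self.df.shape[1]:
            raise ValueError("donor copy matrix must be square (groups x groups)")
        if not self.df.index.equals(self.df.columns):
            raise ValueError("row and column group labels must match")
        vals = self.df.to_numpy()
        if (vals < 0).any():
            raise ValueError("donor copy matrix must be non-negative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("donor copy matrix rows must sum to 1 within 1e-9")

    @property
    def groups(self) -> list[str]:
        return list(self.df.index)

    def country_of(self, group: str) -> str:
        if self.countries is None or group not in self.countries.index \
                or pd.isna(self.countries.loc[group]):
            raise ValueError(f"donor group {group!r} has no country label")
        return str(self.countries.loc[group])


@dataclass(frozen=True)
class AncestryProfile:
    """Mixture coefficients beta over donor groups for one individual."""

    id: str
    beta: pd.Series  # index: donor groups, non-negative, sums to 1

    def __post_init__(self) -> None:
        b = self.beta.to_numpy(dtype=float)
        if (b < 0).any() or not np.isclose(b.sum(), 1.0, atol=1e-9):
            raise ValueError("beta must be non-negative and sum to 1 within 1e-9")

    @property
    def retained(self) -> list[str]:
        return list(self.beta.index[self.beta > 0])


def donor_copy_matrix(reference_painting: CoancestryMatrix,
                      donor_groups: ClusterAssignment) -> DonorCopyMatrix:
    """Build X from a donors-vs-donors painting.

    Each donor row is normalized to 1, columns are aggregated by donor
    group and rows averaged within group.
    """
    donor_groups.check_covers(reference_painting.ids)
    labels = donor_groups.labels.loc[reference_painting.ids]
    for g in donor_groups.clusters:
        if (labels == g).sum() == 0:
            raise ValueError(f"empty donor group {g!r}")
    df = reference_painting.df
    sums = df.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("donor rows with zero total donation cannot be normalized")
    norm = df.div(sums, axis=0)
    by_group = norm.T.groupby(labels).sum().T
    X = by_group.groupby(labels).mean()
    X = X.loc[sorted(X.index), sorted(X.columns)]
    return DonorCopyMatrix(X)


def _solve_nnls(y: np.ndarray, X: np.ndarray, method: str,
                penalty_weight: float = 1e3) -> np.ndarray:
    """NNLS for y ~ beta @ X; sum-to-one by renormalization or a penalty row."""
    A = X.T  # columns are donor-group profiles
    if method == "renormalize":
        beta, _ = nnls(A, y)
    elif method == "penalty":
        A_aug = np.vstack([A, penalty_weight * np.ones(A.shape[1])])
        y_aug = np.concatenate([y, [penalty_weight]])
        beta, _ = nnls(A_aug, y_aug)
    else:
        raise ValueError("method must be 'renormalize' or 'penalty'")
    total = beta.sum()
    if total <= 0:
        raise ValueError("NNLS returned an all-zero solution; target is "
                         "orthogonal to every donor profile")
    return beta / total


def nnls_profile(y: pd.Series, x: DonorCopyMatrix,
                 method: str = "renormalize") -> AncestryProfile:
    """Solve min ||y - sum beta_g x_g|| s.t. beta >= 0, then rescale to sum 1."""
    y = y.reindex(x.groups)
    if y.isna().any():
        raise ValueError("target vector missing donor-group components")
    yv = y.to_numpy(dtype=float)
    if not np.isclose(yv.sum(), 1.0, atol=1e-6):
        raise ValueError("target copying vector must be normalized to sum 1")
    beta = _solve_nnls(yv, x.df.to_numpy(), method)
    return AncestryProfile(str(y.name) if y.name is not None else "",
                           pd.Series(beta, index=x.groups))


def prune_and_refit(p: AncestryProfile, x: DonorCopyMatrix, y: pd.Series,
                    threshold: float = 0.05,
                    method: str = "renormalize") -> AncestryProfile:
    """Iteratively drop donor groups with beta below threshold and refit.

    Groups are pruned per individual; NNLS is refit on the survivors and the
    loop repeats until every retained beta meets the threshold or a single
    group remains.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if threshold == 0:
        return p
    y = y.reindex(x.groups)
    beta = p.beta.copy()
    retained = list(beta.index[beta > 0]) or list(beta.index)
    while True:
        sub = beta.loc[retained]
        low = list(sub.index[sub < threshold])
        if not low or len(retained) <= 1:
            break
        keep = [g for g in retained if g not in low]
        if not keep:  # everything below threshold: keep the largest share
            keep = [sub.idxmax()]
        retained = keep
        if len(retained) == 1:
            beta = pd.Series(0.0, index=x.groups)
            beta.loc[retained[0]] = 1.0
            break
        sub_beta = _solve_nnls(y.to_numpy(dtype=float),
                               x.df.loc[retained].to_numpy(), method)
        beta = pd.Series(0.0, index=x.groups)
        beta.loc[retained] = sub_beta
    return AncestryProfile(p.id, beta)


def aggregate_by_country(p: AncestryProfile, x: DonorCopyMatrix) -> pd.Series:
    """Sum beta over donor groups of the same country; shares sum to 1."""
    countries = pd.Series({g: x.country_of(g) for g in x.groups})
    return p.beta.groupby(countries).sum()


class AncestryNNLS(BaseEstimator, TransformerMixin):
    """Batch estimator: fit on a donor copy matrix, transform target vectors.

    Parameters
    ----------
    prune_threshold : float
        Per-individual prune-and-refit threshold (0 disables pruning).
    method : {"renormalize", "penalty"}
        How the sum-to-one constraint is enforced: rescale the
        unconstrained NNLS solution, or append a heavily weighted
        sum-to-one penalty row to the design.

    Attributes
    ----------
    donor_matrix_ : DonorCopyMatrix
    groups_ : donor group labels
    """

    def __init__(self, prune_threshold: float = 0.05,
                 method: str = "renormalize"):
        self.prune_threshold = prune_threshold
        self.method = method

    def fit(self, X: DonorCopyMatrix, y=None):
        if not isinstance(X, DonorCopyMatrix):
            X = DonorCopyMatrix(pd.DataFrame(X))
        rank = np.linalg.matrix_rank(X.df.to_numpy())
        if rank < len(X.groups):
            raise ValueError("donor copy matrix is rank-deficient; profiles "
                             "are not identifiable")
        self.donor_matrix_ = X
        self.groups_ = X.groups
        return self

    def transform(self, Y: pd.DataFrame) -> pd.DataFrame:
        """Profiles for each row of Y (individuals x donor groups)."""
        out = []
        for ident, row in Y.iterrows():
            row = row.rename(ident)
            prof = nnls_profile(row, self.donor_matrix_, method=self.method)
            if self.prune_threshold > 0:
                prof = prune_and_refit(prof, self.donor_matrix_, row,
                                       threshold=self.prune_threshold,
                                       method=self.method)
            out.append(prof.beta.rename(ident))
        return pd.DataFrame(out)

    def fit_transform(self, X, y=None, Y: pd.DataFrame | None = None):
        if Y is None:
            raise ValueError("pass targets via Y=")
        return self.fit(X).transform(Y)
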