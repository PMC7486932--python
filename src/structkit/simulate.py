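"""Synthetic structured cohorts with known truth.

The generator emulates the statistical structure the downstream analyses
assume, without simulating genealogies or sequence:

* a block-structured coancestry (chunklength) matrix over demes — expected
  donation decays as ``exp(-d/rho)`` with distance and is boosted by
  ``1 + kappa`` within a deme; realized rows are scaled Dirichlet draws;
* IBD segment sets — per pair, a Poisson number of segment events, each
  with a gamma-distributed coalescence time t (generations) and an
  Erlang(2, rate t/50 per cM) length, truncated at the detection floor.
  The Erlang law is the unique choice under which the closed-form bin
  dating E[T] = 75(1/L1 + 1/L2) is exact with an improper uniform time
  prior (see docs/methods.md for the derivation);
* linear spatial ancestry gradients with optional noise on the target
  copying vectors;
* case/control labels with per-deme log-odds offsets.

A single master seed expands into per-component substreams (geography,
coancestry, IBD, ancestry, phenotype) so toggling one component never
shifts another's draws.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ancestry import DonorCopyMatrix
from .coancestry import CoancestryMatrix, write_chunklengths
from .config import ConfigError, ScenarioConfig
from .ibd import IBDSegmentSet, SEGMENT_COLUMNS, write_ibd

_SUBSTREAMS = ("geography", "coancestry", "ibd", "ancestry", "phenotype")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)}


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    config: ScenarioConfig
    individuals: pd.DataFrame      # id, deme, longitude, latitude
    coancestry: CoancestryMatrix
    ibd: IBDSegmentSet
    true_ancestry: pd.DataFrame    # individuals x sources, rows sum to 1
    ancestry_targets: pd.DataFrame  # individuals x donor groups (observed Y)
    donor_matrix: DonorCopyMatrix
    phenotype: pd.Series           # 0/1 per individual

    @property
    def ids(self) -> list[str]:
        return list(self.individuals["id"])

    def deme_labels(self) -> pd.Series:
        return pd.Series(self.individuals["deme"].values,
                         index=self.individuals["id"].values)


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def simulate_geography(config: ScenarioConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Individuals scattered around their deme centres (planar degrees)."""
    rng = rng if rng is not None else _substreams(config.seed)["geography"]
    rows = []
    for d in range(config.n_demes):
        cx, cy = config.deme_centers[d]
        jitter = rng.normal(0.0, config.coord_jitter_sd, size=(config.n_per_deme, 2))
        for i in range(config.n_per_deme):
            rows.append({"id": f"D{d}_{i:03d}", "deme": f"deme{d}",
                         "longitude": cx + jitter[i, 0],
                         "latitude": cy + jitter[i, 1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coancestry
# ---------------------------------------------------------------------------

def simulate_coancestry(config: ScenarioConfig, individuals: pd.DataFrame,
                        rng: np.random.Generator | None = None) -> CoancestryMatrix:
    """Block-structured chunklength matrix with spatial decay.

    Expected donation from j to i is proportional to
    ``exp(-d_ij/rho) * (1 + kappa * [same deme])``; each row is drawn as
    genome_length x Dirichlet(alpha * expectation) so rows sum exactly to
    the genome length and the diagonal is exactly zero.
    """
    rng = rng if rng is not None else _substreams(config.seed)["coancestry"]
    ids = list(individuals["id"])
    coords = individuals[["longitude", "latitude"]].to_numpy()
    demes = individuals["deme"].to_numpy()
    d = squareform(pdist(coords))
    same = demes[:, None] == demes[None, :]
    w = np.exp(-d / config.spatial_decay) * (1.0 + config.within_deme_boost * same)
    np.fill_diagonal(w, 0.0)
    p = w / w.sum(axis=1, keepdims=True)
    n = len(ids)
    values = np.zeros((n, n))
    alpha = config.dirichlet_concentration
    for i in range(n):
        conc = alpha * np.delete(p[i], i)
        row = rng.dirichlet(conc)
        values[i, np.arange(n) != i] = row * config.genome_length_cM
    return CoancestryMatrix(pd.DataFrame(values, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

# Synthetic chromosome map: 22 autosomes with linearly decreasing map length
# summing to genome_length_cM; 1 cM = 1 Mb for bp coordinates.
_N_CHROM = 22


def _chromosome_lengths(genome_length_cM: float) -> np.ndarray:
    weights = np.arange(_N_CHROM, 0, -1, dtype=float)
    return genome_length_cM * weights / weights.sum()


def _draw_segments(rng: np.random.Generator, pair_ids: np.ndarray,
                   lam: float, tmrca: tuple[float, float] | None,
                   config: ScenarioConfig,
                   t_max: float | None = None) -> pd.DataFrame:
    """Segments for a batch of pairs; ``pair_ids`` is (n_pairs, 2) of ids."""
    n_pairs = len(pair_ids)
    counts = rng.poisson(lam, size=n_pairs)
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    owner = np.repeat(np.arange(n_pairs), counts)
    if t_max is not None:  # validation mode: improper-uniform time prior, truncated
        t = rng.uniform(0.0, t_max, size=total)
    else:
        shape, scale = tmrca
        t = rng.gamma(shape, scale, size=total)
    lengths = rng.gamma(2.0, 50.0 / t)  # Erlang(2, rate t/50) in cM
    keep = lengths >= config.min_length_cM
    if not keep.any():
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    owner, lengths = owner[keep], lengths[keep]
    m = len(lengths)
    chrom_len = _chromosome_lengths(config.genome_length_cM)
    chrom = rng.choice(_N_CHROM, size=m, p=chrom_len / chrom_len.sum())
    span = np.maximum(chrom_len[chrom] - lengths, 0.0)
    start_cM = rng.uniform(0.0, 1.0, size=m) * span
    start_bp = np.round(start_cM * 1e6).astype(np.int64)
    end_bp = start_bp + np.round(lengths * 1e6).astype(np.int64)
    return pd.DataFrame({
        "id1": pair_ids[owner, 0], "hap1": 1,
        "id2": pair_ids[owner, 1], "hap2": 1,
        "chromosome": (chrom + 1).astype(str),
        "start_bp": start_bp, "end_bp": end_bp,
        "lod": 10.0, "length_cM": lengths})


def simulate_ibd_pairs(config: ScenarioConfig, pair_class: str, n_pairs: int,
                       rng: np.random.Generator | None = None,
                       validation_mode: bool = False,
                       t_max: float | None = None) -> IBDSegmentSet:
    """IBD segments for ``n_pairs`` synthetic pairs of one class.

    Per pair the event count is Poisson with the class rate; per event the
    coalescence time t is gamma-distributed for the class (or, in
    validation mode, uniform on (0, t_max]) and the segment length is
    Erlang(2, rate t/50 per cM).  Segments below the detection floor are
    discarded.  Pairs are labelled ``P{k}_a`` / ``P{k}_b``.
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    if pair_class not in ("within", "between"):
        raise ConfigError("pair_class must be 'within' or 'between'")
    if validation_mode and (t_max is None or t_max <= 0):
        raise ConfigError("validation mode requires a positive t_max")
    rng = rng if rng is not None else _substreams(config.seed)["ibd"]
    lam = config.ibd_rate_within if pair_class == "within" else config.ibd_rate_between
    tmrca = config.tmrca_within if pair_class == "within" else config.tmrca_between
    pair_ids = np.array([[f"P{k}_a", f"P{k}_b"] for k in range(n_pairs)])
    df = _draw_segments(rng, pair_ids, lam, None if validation_mode else tmrca,
                        config, t_max=t_max if validation_mode else None)
    if df.empty:
        return IBDSegmentSet.empty()
    return IBDSegmentSet(df)


def simulate_cohort_ibd(config: ScenarioConfig, individuals: pd.DataFrame,
                        rng: np.random.Generator | None = None) -> IBDSegmentSet:
    """IBD segments for every pair in the cohort, by within/between class."""
    rng = rng if rng is not None else _substreams(config.seed)["ibd"]
    ids = individuals["id"].to_numpy()
    demes = individuals["deme"].to_numpy()
    pairs = np.array(list(itertools.combinations(range(len(ids)), 2)))
    same = demes[pairs[:, 0]] == demes[pairs[:, 1]]
    frames = []
    for mask, lam, tmrca in ((same, config.ibd_rate_within, config.tmrca_within),
                             (~same, config.ibd_rate_between, config.tmrca_between)):
        if mask.any() and lam > 0:
            pair_ids = np.column_stack([ids[pairs[mask, 0]], ids[pairs[mask, 1]]])
            frames.append(_draw_segments(rng, pair_ids, lam, tmrca, config))
    frames = [f for f in frames if not f.empty]
    if not frames:
        return IBDSegmentSet.empty()
    return IBDSegmentSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# ancestry targets
# ---------------------------------------------------------------------------

def make_donor_matrix(source_names: list[str],
                      self_copy: float = 0.8) -> DonorCopyMatrix:
    """Synthetic donor copy matrix: each group copies ``self_copy`` of its
    genome from itself and the rest evenly from the other groups."""
    g = len(source_names)
    if g < 2:
        raise ValueError("need at least 2 donor groups")
    if not 0 < self_copy < 1:
        raise ValueError("self_copy must be in (0, 1)")
    off = (1.0 - self_copy) / (g - 1)
    X = np.full((g, g), off)
    np.fill_diagonal(X, self_copy)
    return DonorCopyMatrix(pd.DataFrame(X, index=source_names, columns=source_names))


def simulate_ancestry_targets(config: ScenarioConfig,
                              donor_matrix: DonorCopyMatrix,
                              coords: pd.DataFrame | None = None,
                              rng: np.random.Generator | None = None
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target copying vectors and true mixture coefficients.

    Per individual, the true share of each source follows
    ``intercept + slope * projection(coords, bearing)``, clipped at 0 and
    renormalized; the observed target is ``Y = beta @ X`` plus optional
    zero-mean Gaussian noise (clipped at 0, renormalized).  Coordinates
    are centred on the centroid of the deme centres before projection, so
    intercepts are the share at the centre of the study region and slopes
    are per degree of displacement.  Returns ``(targets, truth)`` as
    individuals-x-groups DataFrames.
    """
    groups = donor_matrix.groups
    names = config.source_names
    if sorted(names) != sorted(groups):
        raise ConfigError("gradient_specs sources must match donor matrix groups")
    X = donor_matrix.df.loc[names, names].to_numpy()
    if np.linalg.matrix_rank(X) < len(names):
        raise ValueError("degenerate donor matrix (rank < G)")
    rng = rng if rng is not None else _substreams(config.seed)["ancestry"]
    if coords is None:
        coords = simulate_geography(config)
    centre = np.asarray(config.deme_centers, dtype=float).mean(axis=0)
    lon = coords["longitude"].to_numpy() - centre[0]
    lat = coords["latitude"].to_numpy() - centre[1]
    ids = list(coords["id"]) if "id" in coords else list(coords.index)
    raw = np.zeros((len(lon), len(names)))
    noise_sd = np.zeros(len(names))
    for g, spec in enumerate(config.gradient_specs):
        theta = np.deg2rad(spec.bearing_deg)
        proj = lon * np.sin(theta) + lat * np.cos(theta)
        raw[:, g] = spec.intercept + spec.slope_per_deg * proj
        noise_sd[g] = spec.noise_sd
    raw = np.clip(raw, 0.0, None)
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        raise ConfigError("gradient_specs give all-zero ancestry for some "
                          "individuals; raise the intercepts")
    truth = raw / sums[:, None]
    targets = truth @ X
    if (noise_sd > 0).any():
        targets = targets + rng.normal(0.0, 1.0, targets.shape) * noise_sd[None, :]
        targets = np.clip(targets, 0.0, None)
    targets = targets / targets.sum(axis=1, keepdims=True)
    return (pd.DataFrame(targets, index=ids, columns=names),
            pd.DataFrame(truth, index=ids, columns=names))


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(config: ScenarioConfig, individuals: pd.DataFrame,
                       rng: np.random.Generator | None = None) -> pd.Series:
    """Binary labels with P(case | deme d) = logistic(b0 + s_d)."""
    intercepts = config.intercepts()
    rng = rng if rng is not None else _substreams(config.seed)["phenotype"]
    deme_idx = individuals["deme"].str.removeprefix("deme").astype(int).to_numpy()
    logit = config.phenotype_base + np.asarray(intercepts)[deme_idx]
    p = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.uniform(size=len(p)) < p).astype(int)
    return pd.Series(labels, index=individuals["id"].values, name="phenotype")


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: ScenarioConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort, deterministic in the seed."""
    streams = _substreams(config.seed)
    individuals = simulate_geography(config, streams["geography"])
    coancestry = simulate_coancestry(config, individuals, streams["coancestry"])
    ibd = simulate_cohort_ibd(config, individuals, streams["ibd"])
    donor_matrix = make_donor_matrix(config.source_names)
    targets, truth = simulate_ancestry_targets(config, donor_matrix,
                                               coords=individuals,
                                               rng=streams["ancestry"])
    phenotype = simulate_phenotype(config, individuals, streams["phenotype"])
    return SyntheticCohort(config=config, individuals=individuals,
                           coancestry=coancestry, ibd=ibd,
                           true_ancestry=truth, ancestry_targets=targets,
                           donor_matrix=donor_matrix, phenotype=phenotype)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the cohort in the on-disk dialects the readers consume.

    chunklengths (whitespace, header ``Recipient``), RefinedIBD segments
    (9-column TSV), geography TSV (id, longitude, latitude, town,
    province) and a truth TSV (id, deme, one beta column per source,
    phenotype).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chunklengths": outdir / "chunklengths.txt",
        "ibd": outdir / "ibd_segments.ibd",
        "geography": outdir / "geography.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_chunklengths(cohort.coancestry, paths["chunklengths"])
    write_ibd(cohort.ibd, paths["ibd"])
    geo = cohort.individuals.copy()
    geo["town"] = geo["deme"].str.replace("deme", "town", regex=False)
    geo["province"] = geo["deme"]
    geo[["id", "longitude", "latitude", "town", "province"]].to_csv(
        paths["geography"], sep="\t", index=False)
    truth = cohort.individuals[["id", "deme"]].merge(
        cohort.true_ancestry, left_on="id", right_index=True)
    truth["phenotype"] = cohort.phenotype.loc[truth["id"]].values
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Monte-Carlo oracle for the closed-form bin dating
# ---------------------------------------------------------------------------

def eq2_oracle(L1: float, L2: float, n_draws: int = 10 ** 6,
               T_max: float | None = None,
               seed: int | None = None) -> float:
    """Monte-Carlo mean coalescence time of segments retained in [L1, L2).

    Draws t ~ Uniform(0, T_max) and l | t ~ Erlang(2, rate t/50 per cM)
    and returns the mean t of draws with L1 <= l < L2.  As n_draws grows
    this approaches the closed form 75(1/L1 + 1/L2).  T_max (default
    100 * 50/L1) must be at least that; smaller values truncate the time
    integral and bias the mean.
    """
    if not 0 < L1 < L2:
        raise ValueError("need 0 < L1 < L2")
    min_t_max = 100.0 * 50.0 / L1
    if T_max is None:
        T_max = min_t_max
    if T_max < min_t_max:
        raise ValueError(f"T_max={T_max} too small (truncation bias); "
                         f"need at least 100*50/L1 = {min_t_max}")
    rng = np.random.default_rng(seed)
    mean_sum = 0.0
    kept = 0
    chunk = 10 ** 6
    remaining = n_draws
    while remaining > 0:
        m = min(chunk, remaining)
        t = rng.uniform(0.0, T_max, size=m)
        l = rng.gamma(2.0, 50.0 / t)
        mask = (l >= L1) & (l < L2)
        mean_sum += t[mask].sum()
        kept += int(mask.sum())
        remaining -= m
    if kept == 0:
        raise ValueError("no draws retained in the bin; increase n_draws")
    return mean_sum / kept
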