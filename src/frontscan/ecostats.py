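"""Catch standardization, diversity, rank correlation, and community tests.

Trawl catches are standardized to densities per m³ of water filtered
before any comparison. Diversity uses natural-log Shannon-Wiener H′ and
Simpson's 1 − Σp². Abundance–environment relationships use Kendall's
tau-b with Benjamini–Hochberg false-discovery control across the
correlation table. Community structure across seasons and water masses is
tested with ANOSIM on square-root-transformed relative-abundance
Bray–Curtis distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class TrawlCatch:
    """One trawl station's catch with the metadata needed to standardize it."""

    station: str
    season: str
    water_mass: str
    mouth_area_m2: float
    tow_distance_m: float
    counts: dict[str, float]  # taxon -> individuals
    dry_weights_g: dict[str, float] = field(default_factory=dict)

    @property
    def volume_m3(self) -> float:
        return self.mouth_area_m2 * self.tow_distance_m


@dataclass
class CommunityMatrix:
    """Station × taxon abundances (standardized) with grouping factors."""

    abundance: pd.DataFrame  # index station, columns taxa
    groups: pd.DataFrame  # index station, columns e.g. season, water_mass


def standardize_catch(catch: TrawlCatch) -> tuple[dict[str, float],
                                                  dict[str, float]]:
    """Counts and dry weights per m³ of water filtered (area × distance)."""
    vol = catch.volume_m3
    if vol <= 0:
        raise ValueError("trawled volume must be positive")
    dens = {t: c / vol for t, c in catch.counts.items()}
    biom = {t: w / vol for t, w in catch.dry_weights_g.items()}
    return dens, biom


def community_matrix(catches: list[TrawlCatch],
                     exclude_taxa: tuple[str, ...] = ()) -> CommunityMatrix:
    """Assemble standardized counts into a station × taxon matrix.

    ``exclude_taxa`` drops pooled groups that were never enumerated (e.g. a
    mixed-mesozooplankton biomass fraction) from count-based analyses while
    the caller can still use their weights elsewhere.
    """
    rows, meta = {}, {}
    for c in catches:
        dens, _ = standardize_catch(c)
        rows[c.station] = {t: v for t, v in dens.items()
                           if t not in exclude_taxa}
        meta[c.station] = {"season": c.season, "water_mass": c.water_mass}
    ab = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return CommunityMatrix(abundance=ab,
                           groups=pd.DataFrame.from_dict(meta, orient="index"))


# ---------------------------------------------------------------------------
# diversity


def shannon(counts) -> float:
    """Shannon-Wiener H′ = −Σ p·ln p (natural log); zero-count taxa drop out."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict)
                   else counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson's diversity as 1 − Σp² (probability two draws differ)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict)
                   else counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c / total
    return float(1.0 - (p**2).sum())


# ---------------------------------------------------------------------------
# correlation and multiple testing


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction.

    The p-value is exact (permutation enumeration) for small untied
    samples and switches to the normal approximation for larger or tied
    data — the same policy as R's cor.test, which keeps small-n survey
    tables honest.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau undefined for a constant vector")
    tau, p = stats.kendalltau(x, y, variant="b", method="auto")
    return float(tau), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_table(table: pd.DataFrame, response_cols: list[str],
                      covariate_cols: list[str],
                      alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Kendall correlations with BH-adjusted significance.

    One row per (response, covariate) pair with τ, raw p, adjusted p and a
    significance flag; adjustment is across the whole table, controlling
    the false-discovery rate over every test reported together.
    """
    rows = []
    for r in response_cols:
        for c in covariate_cols:
            sub = table[[r, c]].dropna()
            try:
                tau, p = kendall_tau(sub[r].to_numpy(), sub[c].to_numpy())
            except ValueError:
                tau, p = np.nan, np.nan
            rows.append({"response": r, "covariate": c, "tau": tau,
                         "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["p_adj"] = adj
    out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# community structure


def bray_curtis(matrix: CommunityMatrix | pd.DataFrame,
                sqrt_transform: bool = True) -> np.ndarray:
    """Bray–Curtis distances on (square-rooted) relative abundance.

    Rows are converted to relative abundance, square-root transformed to
    damp dominance by a few very abundant taxa, then
    BC_ij = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ). Returns the square distance matrix.
    """
    ab = matrix.abundance if isinstance(matrix, CommunityMatrix) else matrix
    x = ab.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two stations")
    row_sums = x.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("zero-sum station row")
    x = x / row_sums[:, None]
    if sqrt_transform:
        x = np.sqrt(x)
    return squareform(pdist(x, metric="braycurtis"))


def anosim(dist: np.ndarray, groups, n_perm: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    All n(n−1)/2 pairwise distances are ranked (average ranks for ties) and
    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M the number of pairs; R near 1 means groups are well separated, near 0
    means no structure. p is the seeded-permutation tail probability
    (1 + #{R_perm ≥ R}) / (1 + n_perm) under random relabelling.
    """
    dist = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    n = dist.shape[0]
    if dist.shape != (n, n) or groups.size != n:
        raise ValueError("distance matrix and groups are inconsistent")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2 or np.any(counts < 2):
        raise ValueError("need at least two groups of at least two members")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist[iu])
    m = ranks.size

    codes = np.searchsorted(labels, groups)

    def r_stat(c: np.ndarray) -> float:
        within = c[iu[0]] == c[iu[1]]
        rb = ranks[~within].mean()
        rw = ranks[within].mean()
        return (rb - rw) / (m / 2.0)

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(codes)) >= r_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return float(r_obs), float(p)


def anosim_exact(dist: np.ndarray, groups) -> tuple[float, float]:
    """ANOSIM with p from full enumeration of distinct label permutations.

    Feasible only for a handful of samples; used to validate the seeded
    permutation test on tiny instances.
    """
    from itertools import permutations

    dist = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist[iu])
    m = ranks.size
    labels = np.unique(groups)
    codes = np.searchsorted(labels, groups)

    def r_stat(c) -> float:
        c = np.asarray(c)
        within = c[iu[0]] == c[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_stat(codes)
    perms = list(permutations(codes))
    vals = np.array([r_stat(p) for p in perms])
    p = float((vals >= r_obs - 1e-12).mean())
    return float(r_obs), p
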