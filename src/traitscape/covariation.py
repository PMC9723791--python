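"""Trait covariation, orthogonal trait groups, reduced-trait recovery and
genotype-vs-phenotype regression.

The central statistic here is the variance-weighted centroid distance
between two strains in the trait-scape,

    distance = sqrt((dPC1 * a)^2 + (dPC2 * b)^2)

where a and b are the percent variance explained by the first two axes.
Pairwise centroid distances from two scapes (e.g. a full 9-trait scape and
a reduced 4-trait scape) are compared by ordinary least squares; because
R^2 is scale invariant, it does not matter whether the weights are entered
as percentages or proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .scape import TraitScape, build_traitscape, trait_columns


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values and an
    alpha-level significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n: int

    @property
    def traits(self) -> list[str]:
        return list(self.r.index)


def correlation_matrix(
    table: pd.DataFrame, alpha: float = 0.05, holm: bool = False
) -> CorrelationMatrix:
    """Pearson correlation matrix of the trait columns.

    p-values come from t = r sqrt((n-2)/(1-r^2)) on n-2 df.  No
    multiple-testing correction is applied by default; ``holm=True``
    applies a Holm step-down correction over the upper-triangle tests.
    Constant traits give NaN correlations for their pairs.
    """
    traits = trait_columns(table)
    x = table[traits].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.ix_(sd == 0, range(len(traits)))] = np.nan
    r[np.ix_(range(len(traits)), np.flatnonzero(sd == 0))] = np.nan
    np.fill_diagonal(r, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)

    if holm:
        iu = np.triu_indices(len(traits), k=1)
        raw = p[iu]
        order = np.argsort(raw)
        m = np.sum(~np.isnan(raw))
        adj = np.full_like(raw, np.nan)
        running = 0.0
        for rank, idx in enumerate(order):
            if np.isnan(raw[idx]):
                continue
            running = max(running, min(1.0, (m - rank) * raw[idx]))
            adj[idx] = running
        p[iu] = adj
        p[(iu[1], iu[0])] = adj

    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    sig = (pdf < alpha) & pdf.notna()
    return CorrelationMatrix(r=rdf, p=pdf, significant=sig, alpha=alpha, n=n)


@dataclass
class TraitGroups:
    """A partition of traits into orthogonal groups with representatives."""

    groups: dict[str, list[str]]          # label -> member traits
    representatives: dict[str, str]       # label -> representative trait

    def labels_by_trait(self) -> dict[str, str]:
        return {t: lab for lab, members in self.groups.items() for t in members}

    def representative_subset(self) -> list[str]:
        return sorted(self.representatives.values())


def identify_trait_groups(
    corr: CorrelationMatrix, scape: TraitScape, threshold: float = 0.7
) -> TraitGroups:
    """Partition traits into groups by strong, significant correlation.

    Traits are nodes; an edge joins two traits when |r| >= threshold and the
    correlation is significant at the matrix's alpha.  Connected components
    are the groups (singletons form their own group).  Each group's
    representative is the member contributing most to the group's dominant
    axis among the first two scape axes, ties broken alphabetically.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    traits = corr.traits
    if set(traits) != set(scape.trait_names):
        raise ValueError("correlation matrix and scape cover different traits")

    # connected components via union-find
    parent = {t: t for t in traits}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for a, b in combinations(traits, 2):
        r = corr.r.loc[a, b]
        if np.isfinite(r) and abs(r) >= threshold and bool(corr.significant.loc[a, b]):
            parent[find(a)] = find(b)

    comps: dict[str, list[str]] = {}
    for t in traits:
        comps.setdefault(find(t), []).append(t)

    contrib = pd.DataFrame(
        scape.contributions[:, :2], index=scape.trait_names, columns=["PC1", "PC2"]
    )
    groups, reps = {}, {}
    for members in comps.values():
        members = sorted(members)
        sub = contrib.loc[members]
        dominant = sub.sum(axis=0).idxmax()
        best = sub[dominant].max()
        rep = sorted(t for t in members if sub.loc[t, dominant] == best)[0]
        groups[rep] = members
        reps[rep] = rep
    return TraitGroups(groups=groups, representatives=reps)


def centroid_distance(
    c1: np.ndarray, c2: np.ndarray, a: float, b: float
) -> float:
    """Variance-weighted distance between two trait-scape centroids:
    sqrt((dPC1 * a)^2 + (dPC2 * b)^2), a and b the percent variance of the
    two axes."""
    if not (a > 0 and b > 0):
        raise ValueError("axis weights must be positive")
    d1 = float(c1[0]) - float(c2[0])
    d2 = float(c1[1]) - float(c2[1])
    return float(np.hypot(d1 * a, d2 * b))


def strain_centroids(
    scores: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Mean PC1/PC2 position per strain (or per strain x environment)."""
    by = by or ["strain_id"]
    return scores.groupby(by, sort=True)[["PC1", "PC2"]].mean()


def pairwise_centroid_distances(
    centroids: pd.DataFrame, a: float, b: float
) -> pd.Series:
    """Condensed pairwise centroid distances, indexed by (id1, id2) with
    id1 < id2 in the centroid index order."""
    idx = list(centroids.index)
    vals = {}
    for i, j in combinations(range(len(idx)), 2):
        vals[(idx[i], idx[j])] = centroid_distance(
            centroids.iloc[i].to_numpy(), centroids.iloc[j].to_numpy(), a, b
        )
    return pd.Series(vals, name="distance")


@dataclass
class RegressionResult:
    r2: float
    adj_r2: float
    p: float
    slope: float
    intercept: float
    n_pairs: int
    mantel_p: float | None = None


def distance_regression(
    d_ref: pd.Series | np.ndarray,
    d_alt: pd.Series | np.ndarray,
    mantel_permutations: int = 0,
    seed: int = 0,
) -> RegressionResult:
    """OLS of one pairwise-distance set on another.

    Adjusted R^2 = 1 - (1 - R^2)(m - 1)/(m - 2) for m pairs (one
    predictor).  Pair non-independence is ignored, as in standard
    centroid-distance comparisons; ``mantel_permutations > 0`` additionally
    reports a Mantel-style permutation p-value for the correlation (a
    non-standard diagnostic, clearly separate from the OLS p).
    """
    if isinstance(d_ref, pd.Series) and isinstance(d_alt, pd.Series):
        if not d_ref.index.equals(d_alt.index):
            d_alt = d_alt.reindex(d_ref.index)
            if d_alt.isna().any():
                raise ValueError("distance sets cover different pairs")
    x = np.asarray(d_ref, dtype=float)
    y = np.asarray(d_alt, dtype=float)
    m = x.size
    if m < 3:
        raise ValueError("need at least 3 pairs")
    if y.size != m:
        raise ValueError("distance sets have different lengths")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    mantel_p = None
    if mantel_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = abs(fit.rvalue)
        count = 0
        for _ in range(mantel_permutations):
            perm = rng.permutation(m)
            r = np.corrcoef(x, y[perm])[0, 1]
            if abs(r) >= obs:
                count += 1
        mantel_p = (count + 1) / (mantel_permutations + 1)
    return RegressionResult(
        r2=float(r2),
        adj_r2=float(adj),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=m,
        mantel_p=mantel_p,
    )


def reduced_traitscape_recovery(
    table: pd.DataFrame,
    subset: list[str],
    full_scape: TraitScape | None = None,
) -> tuple[TraitScape, RegressionResult]:
    """Score how well a reduced trait set recovers the full trait-scape.

    Builds a scape from ``subset`` traits only, computes strain centroids in
    both the full and the reduced scape, and regresses the reduced pairwise
    centroid distances on the full ones.  High adjusted R^2 means the
    strains sit in the same relative positions with fewer traits.
    """
    traits = trait_columns(table)
    unknown = [t for t in subset if t not in traits]
    if unknown:
        raise ValueError(f"subset traits not in table: {unknown}")
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 traits")
    if full_scape is None:
        full_scape = build_traitscape(table)
    meta = [c for c in table.columns if c not in traits]
    reduced_scape = build_traitscape(table[meta + list(subset)])

    def dists(scape: TraitScape) -> pd.Series:
        cents = strain_centroids(scape.scores)
        return pairwise_centroid_distances(
            cents, a=scape.variance_pct(1), b=scape.variance_pct(2)
        )

    reg = distance_regression(dists(full_scape), dists(reduced_scape))
    return reduced_scape, reg


def genotype_phenotype_regression(
    identity: pd.DataFrame,
    centroids: pd.DataFrame,
    a: float,
    b: float,
) -> RegressionResult:
    """Regress pairwise trait-scape centroid distance on percent sequence
    identity.  A small R^2 with p > alpha means phenotypic proximity cannot
    be predicted from genetic relatedness."""
    strains = list(centroids.index)
    missing = [s for s in strains if s not in identity.index or s not in identity.columns]
    if missing:
        raise ValueError(f"strains missing from identity matrix: {missing}")
    ident_vals, dist_vals = [], []
    for s1, s2 in combinations(strains, 2):
        ident_vals.append(float(identity.loc[s1, s2]))
        dist_vals.append(
            centroid_distance(
                centroids.loc[s1].to_numpy(), centroids.loc[s2].to_numpy(), a, b
            )
        )
    ident = np.asarray(ident_vals)
    if np.ptp(ident) == 0:
        raise ValueError("identity values are constant; regression slope undefined")
    return distance_regression(ident, np.asarray(dist_vals))
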