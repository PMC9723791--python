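"""Multi-trait phenotypic plasticity: relative trait changes and the
"strategy" PCA.

For a strain grown in a new environment, each trait's plastic response is
expressed as a dimensionless relative change against that strain's
standard-environment mean:

    relative change = (value_new - mean_standard) / mean_standard

A PCA of the relative-change table asks whether whole-phenotype responses
are conserved across strains: if every strain shifts its nine traits in a
similar direction for a given environment, treatment cultures cluster by
environment in the change space — a shared "strategy".  The clustering is
quantified by the ratio of between-environment to within-environment mean
score distances, with a permutation null obtained by shuffling environment
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .scape import METADATA_COLUMNS, TraitScape, build_traitscape, trait_columns


@dataclass
class RelativeChangeTable:
    """Per-culture relative trait changes plus the baselines used."""

    changes: pd.DataFrame        # treatment cultures x relative changes
    baselines: pd.DataFrame      # strain x trait standard-environment means
    baseline_environment: str


def relative_changes(
    table: pd.DataFrame,
    baseline_env: str = "standard",
    tol: float = 1e-9,
) -> RelativeChangeTable:
    """Relative trait changes of every non-baseline culture.

    The baseline for a (strain, trait) is the strain's mean trait value
    across its baseline-environment replicates.  Baselines with
    |mean| <= tol raise (the relative change would divide by ~zero),
    naming the strain and trait.
    """
    traits = trait_columns(table)
    base = table[table["environment"] == baseline_env]
    trt = table[table["environment"] != baseline_env]
    if len(trt) == 0:
        raise ValueError("no non-baseline rows in table")
    strains = sorted(trt["strain_id"].unique())
    missing = [s for s in strains if s not in set(base["strain_id"])]
    if missing:
        raise ValueError(f"strains lack baseline-environment rows: {missing}")

    baselines = base.groupby("strain_id")[traits].mean()
    small = (baselines.loc[strains].abs() <= tol).stack()
    if small.any():
        strain, trait = small[small].index[0]
        raise ValueError(
            f"baseline mean of trait {trait!r} for strain {strain!r} is below "
            f"tolerance ({tol:g}); relative change undefined"
        )

    meta = [c for c in METADATA_COLUMNS if c in trt.columns]
    out = trt[meta].copy()
    for t in traits:
        b = trt["strain_id"].map(baselines[t])
        out[t] = (trt[t] - b) / b
    return RelativeChangeTable(
        changes=out.reset_index(drop=True),
        baselines=baselines.loc[strains],
        baseline_environment=baseline_env,
    )


@dataclass
class StrategyResult:
    """Strategy PCA over relative changes with clustering diagnostics."""

    scape: TraitScape
    environment_centroids: pd.DataFrame
    within_mean_distance: float
    between_mean_distance: float
    separation_ratio: float          # between / within
    permutation_p: float | None
    applicable: bool                 # False when only one environment present


def _mean_pair_distances(scores: np.ndarray, envs: np.ndarray) -> tuple[float, float]:
    within, between = [], []
    for i, j in combinations(range(len(envs)), 2):
        d = float(np.linalg.norm(scores[i] - scores[j]))
        (within if envs[i] == envs[j] else between).append(d)
    w = float(np.mean(within)) if within else float("nan")
    b = float(np.mean(between)) if between else float("nan")
    return w, b


def strategy_pca(
    change_table: RelativeChangeTable,
    standardize_changes: bool = True,
    include_standard_zero_rows: bool = False,
    standard_strains: list[str] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> StrategyResult:
    """PCA of the relative-change table with environment-clustering
    diagnostics.

    ``include_standard_zero_rows`` optionally appends zero-change rows for
    strains measured only in the baseline environment (for plots that show
    them at the origin of the change space); they are excluded from the
    clustering diagnostic either way.  ``standardize_changes=False`` runs
    the PCA on the raw (covariance-scale) changes instead.
    """
    changes = change_table.changes.copy()
    diag_n = len(changes)
    if include_standard_zero_rows and standard_strains:
        traits = trait_columns(changes)
        zero_rows = pd.DataFrame(
            [
                {
                    "strain_id": s,
                    "species": "",
                    "replicate": 0,
                    "environment": change_table.baseline_environment,
                    **{t: 0.0 for t in traits},
                }
                for s in standard_strains
            ]
        )
        changes = pd.concat([changes, zero_rows], ignore_index=True)

    if standardize_changes:
        scape = build_traitscape(changes)
    else:
        scape = _covariance_scape(changes)

    scores = scape.scores.iloc[:diag_n]
    envs = scores["environment"].to_numpy()
    xy = scores[["PC1", "PC2"]].to_numpy()
    applicable = len(np.unique(envs)) >= 2
    centroids = scores.groupby("environment")[["PC1", "PC2"]].mean()

    if applicable:
        within, between = _mean_pair_distances(xy, envs)
        ratio = between / within if within > 0 else float("inf")
        perm_p = None
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                w, b = _mean_pair_distances(xy, rng.permutation(envs))
                r = b / w if w > 0 else float("inf")
                if r >= ratio:
                    count += 1
            perm_p = (count + 1) / (n_permutations + 1)
    else:
        within = between = ratio = float("nan")
        perm_p = None

    return StrategyResult(
        scape=scape,
        environment_centroids=centroids,
        within_mean_distance=within,
        between_mean_distance=between,
        separation_ratio=ratio,
        permutation_p=perm_p,
        applicable=applicable,
    )


def _covariance_scape(changes: pd.DataFrame) -> TraitScape:
    """PCA of the raw relative changes (centering only, no rescaling).

    Relative changes are already dimensionless, so a covariance-scale PCA is
    a defensible alternative to the default correlation-scale one; axes then
    weight traits by the magnitude of their plastic response.
    """
    traits = trait_columns(changes)
    x = changes[traits].to_numpy(dtype=float)
    n, t = x.shape
    mean = x.mean(axis=0)
    xc = x - mean
    _, svals, vt = np.linalg.svd(xc, full_matrices=True)
    eig = np.zeros(t)
    eig[: len(svals)] = svals**2 / (n - 1)
    eig[eig < 1e-10] = 0.0
    loadings = vt.T.copy()
    for k in range(t):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    contributions = 100.0 * loadings**2
    contributions[:, eig == 0.0] = 0.0
    scores_mat = xc @ loadings
    meta = [c for c in METADATA_COLUMNS if c in changes.columns]
    scores = changes[meta].copy()
    for k in range(t):
        scores[f"PC{k + 1}"] = scores_mat[:, k]
    total = eig.sum() if eig.sum() > 0 else 1.0
    return TraitScape(
        trait_names=traits,
        mean=mean,
        sd=np.ones(t),
        loadings=loadings,
        eigenvalues=eig,
        proportion_of_variance=eig / total,
        contributions=contributions,
        scores=scores,
        n_samples=n,
    )


@dataclass
class TradeoffContrast:
    """Across-strain vs within-strain contrast for a trait pair."""

    trait_x: str
    trait_y: str
    across_strain_r: float
    per_strain_signs: pd.DataFrame   # strain x (delta_x, delta_y, environment)
    consistent_direction: bool       # all strains share the same sign pattern


def tradeoff_contrast(
    table: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    baseline_env: str = "standard",
    treatment_env: str | None = None,
) -> TradeoffContrast:
    """Contrast the across-strain correlation of two traits with their
    within-strain plastic responses.

    Across strains (standard environment), a positive correlation of e.g.
    chlorophyll and lipid content reflects a shared size-related axis;
    within a strain moved to low nutrients, the two traits can respond in
    opposite directions — a short-term physiological trade-off invisible in
    the across-strain view.
    """
    for t in (trait_x, trait_y):
        if t not in table.columns:
            raise ValueError(f"trait {t!r} not in table")
    envs = sorted(set(table["environment"]) - {baseline_env})
    if not envs:
        raise ValueError("table has no treatment environments")
    if treatment_env is not None:
        if treatment_env not in envs:
            raise ValueError(f"environment {treatment_env!r} not in table")
        envs = [treatment_env]

    cols = [trait_x] if trait_x == trait_y else [trait_x, trait_y]
    base = table[table["environment"] == baseline_env]
    base_means = base.groupby("strain_id")[cols].mean()
    if trait_x == trait_y:
        across_r = 1.0
    else:
        across_r = float(np.corrcoef(base_means[trait_x], base_means[trait_y])[0, 1])

    rows = []
    for env in envs:
        trt = table[table["environment"] == env]
        trt_means = trt.groupby("strain_id")[cols].mean()
        for sid in trt_means.index:
            if sid not in base_means.index:
                continue
            dx = float(trt_means.loc[sid, trait_x] - base_means.loc[sid, trait_x])
            dy = float(trt_means.loc[sid, trait_y] - base_means.loc[sid, trait_y])
            rows.append(
                {
                    "strain_id": sid,
                    "environment": env,
                    "delta_x": dx,
                    "delta_y": dy,
                    "sign_x": int(np.sign(dx)),
                    "sign_y": int(np.sign(dy)),
                }
            )
    signs = pd.DataFrame(rows)
    consistent = bool(
        len(signs)
        and all(
            signs[signs["environment"] == env]["sign_x"].nunique() == 1
            and signs[signs["environment"] == env]["sign_y"].nunique() == 1
            for env in signs["environment"].unique()
        )
    )
    return TradeoffContrast(
        trait_x=trait_x,
        trait_y=trait_y,
        across_strain_r=across_r,
        per_strain_signs=signs,
        consistent_direction=consistent,
    )
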