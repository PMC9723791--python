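"""Trait-scape construction: standardization, PCA, projection.

The trait-scape is a PCA of a cultures x traits table, computed on the
correlation matrix (each trait standardized to mean 0, sample SD 1 before
decomposition).  Axes are ordered by decreasing eigenvalue; the scape proper
is the first two axes, but all axes are retained.  Per-axis "trait
contributions" follow the factoextra convention: 100 x squared element of
the unit eigenvector, so every axis column sums to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical trait order used throughout the package.
TRAIT_NAMES: tuple[str, ...] = (
    "growth_rate",
    "cell_size",
    "chl_a",
    "granularity",
    "lipids",
    "ros",
    "alpha",
    "etrmax",
    "ik",
)

#: Metadata columns of a trait table; everything else is a trait column.
METADATA_COLUMNS: tuple[str, ...] = ("strain_id", "species", "replicate", "environment")


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Trait columns of a table = all columns not in METADATA_COLUMNS."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_trait_table(table: pd.DataFrame) -> None:
    """Check trait-table invariants: >= 2 rows, no duplicate culture keys,
    complete trait values."""
    if len(table) < 2:
        raise ValueError("trait table needs at least 2 rows")
    keys = [c for c in ("strain_id", "replicate", "environment") if c in table.columns]
    if keys and table.duplicated(subset=keys).any():
        dup = table[table.duplicated(subset=keys)].iloc[0]
        raise ValueError(f"duplicate culture key: {tuple(dup[k] for k in keys)}")
    traits = trait_columns(table)
    if not traits:
        raise ValueError("trait table has no trait columns")
    bad = [t for t in traits if table[t].isna().any()]
    if bad:
        raise ValueError(f"missing trait values in columns: {bad}")


def standardize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each trait column to mean 0 and sample SD 1 (ddof=1).

    Returns
    -------
    z : DataFrame
        Standardized trait values (metadata columns preserved).
    params : DataFrame
        Per-trait ``mean`` and ``sd`` used, indexed by trait name; needed to
        project new samples into the same scape.

    Raises
    ------
    ValueError
        If any trait column is constant (SD = 0), naming the trait.
    """
    traits = trait_columns(table)
    values = table[traits].to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    const = [t for t, s in zip(traits, sd) if not s > 0]
    if const:
        raise ValueError(f"constant trait column(s), cannot standardize: {const}")
    z = table.copy()
    z[traits] = (values - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd}, index=pd.Index(traits, name="trait"))
    return z, params


@dataclass
class TraitScape:
    """A fitted trait-scape.

    Attributes
    ----------
    trait_names : list of str
        Traits in loading-row order.
    mean, sd : ndarray
        Standardization parameters (per trait).
    loadings : ndarray, traits x axes
        Unit eigenvectors of the trait correlation matrix, columns ordered by
        decreasing eigenvalue.  Sign convention: each column is flipped so
        its largest-magnitude element is positive.
    eigenvalues : ndarray
        Variance of scores along each axis (ddof=1); zero beyond the rank.
    proportion_of_variance : ndarray
        eigenvalue / number of traits; sums to 1.
    contributions : ndarray, traits x axes, percent
        100 x loading^2; columns sum to 100 on non-degenerate axes, and are
        zeroed on axes beyond the rank.
    scores : DataFrame
        Training-sample scores (metadata + PC1..PCk columns).
    """

    trait_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    proportion_of_variance: np.ndarray
    contributions: np.ndarray
    scores: pd.DataFrame = field(repr=False)
    n_samples: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def axis_names(self) -> list[str]:
        return [f"PC{k + 1}" for k in range(self.loadings.shape[1])]

    def variance_pct(self, axis: int) -> float:
        """Percent variance explained by a 1-based axis index."""
        return 100.0 * float(self.proportion_of_variance[axis - 1])

    def two_axis_variance_pct(self) -> float:
        """Percent of total trait variance captured by the first two axes."""
        return 100.0 * float(self.proportion_of_variance[:2].sum())

    def to_dict(self) -> dict:
        return {
            "trait_names": list(self.trait_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "proportion_of_variance": self.proportion_of_variance.tolist(),
            "contributions": self.contributions.tolist(),
            "n_samples": self.n_samples,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict, scores: pd.DataFrame | None = None) -> "TraitScape":
        return cls(
            trait_names=list(d["trait_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            proportion_of_variance=np.asarray(d["proportion_of_variance"], dtype=float),
            contributions=np.asarray(d["contributions"], dtype=float),
            scores=scores if scores is not None else pd.DataFrame(),
            n_samples=int(d.get("n_samples", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TraitScape":
        return cls.from_dict(json.loads(Path(path).read_text()))


_RANK_TOL = 1e-10


def build_traitscape(table: pd.DataFrame) -> TraitScape:
    """Build the trait-scape of a trait table.

    Equivalent to an eigendecomposition of the trait correlation matrix,
    computed via SVD of the standardized data for numerical stability.
    Rank-deficient tables are allowed: axes beyond the rank get eigenvalue 0
    and zero contributions (never NaN).
    """
    validate_trait_table(table)
    z, params = standardize(table)
    traits = list(params.index)
    zmat = z[traits].to_numpy(dtype=float)
    n, t = zmat.shape

    # full_matrices=True keeps V square (t x t) so loadings stay orthonormal
    # even when n - 1 < t.
    _, svals, vt = np.linalg.svd(zmat, full_matrices=True)
    eig = np.zeros(t)
    eig[: len(svals)] = svals**2 / (n - 1)
    eig[eig < _RANK_TOL] = 0.0
    loadings = vt.T.copy()

    # sign convention: largest-|element| of each column made positive
    for k in range(t):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0

    contributions = 100.0 * loadings**2
    contributions[:, eig == 0.0] = 0.0

    scores_mat = zmat @ loadings
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    scores = table[meta].copy() if meta else pd.DataFrame(index=table.index)
    for k in range(t):
        scores[f"PC{k + 1}"] = scores_mat[:, k]

    return TraitScape(
        trait_names=traits,
        mean=params["mean"].to_numpy(),
        sd=params["sd"].to_numpy(),
        loadings=loadings,
        eigenvalues=eig,
        proportion_of_variance=eig / t,
        contributions=contributions,
        scores=scores,
        n_samples=n,
    )


def project(samples: pd.DataFrame, scape: TraitScape) -> pd.DataFrame:
    """Place new samples in an existing trait-scape.

    Uses the scape's stored standardization parameters and loadings;
    projecting the training table reproduces the stored scores.
    """
    missing = [t for t in scape.trait_names if t not in samples.columns]
    if missing:
        raise ValueError(f"samples are missing trait column(s): {missing}")
    x = samples[list(scape.trait_names)].to_numpy(dtype=float)
    scores_mat = ((x - scape.mean) / scape.sd) @ scape.loadings
    meta = [c for c in METADATA_COLUMNS if c in samples.columns]
    out = samples[meta].copy() if meta else pd.DataFrame(index=samples.index)
    for k in range(scores_mat.shape[1]):
        out[f"PC{k + 1}"] = scores_mat[:, k]
    return out


def expanded_traitscape(
    standard: pd.DataFrame, treatments: pd.DataFrame
) -> TraitScape:
    """Trait-scape over standard-environment plus treatment rows combined.

    The combined table is re-standardized before decomposition (the scaling
    of the standard-only scape is *not* reused), so adding environments can
    legitimately change both the axes and the variance split.
    """
    if len(treatments) == 0:
        return build_traitscape(standard)
    std_traits = set(trait_columns(standard))
    trt_traits = set(trait_columns(treatments))
    if std_traits != trt_traits:
        raise ValueError(
            "trait columns differ between tables: "
            f"{sorted(std_traits ^ trt_traits)}"
        )
    combined = pd.concat([standard, treatments], ignore_index=True)
    return build_traitscape(combined)
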