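"""Hierarchical clustering of replicate phenotypes with multiscale-bootstrap
approximately-unbiased (AU) support.

Cultures are clustered by UPGMA (average linkage) on Euclidean distances
between their standardized trait vectors.  Support for each internal node
is assessed by resampling the *traits* (features) with replacement at a
range of resample sizes round(r * n_traits) for scales r in
{0.5, 0.6, ..., 1.4}: at each scale, B bootstrap dendrograms are built and
the bootstrap probability BP_r of a node is the fraction containing exactly
the same member set.  The AU p-value is then obtained from the scaling law
of BP: with s_r = resample size / n_traits and z_r = Phi^-1(1 - BP_r), a
weighted least-squares fit of

    z_r = v * sqrt(s_r) + c / sqrt(s_r)

estimates a signed distance v and curvature c per node, giving

    AU  = 1 - Phi(v - c)       (approximately unbiased support)
    BP0 = 1 - Phi(v + c)       (model-smoothed ordinary BP at s = 1)

BP values of exactly 0 or 1 are clamped to 1/(2B) and 1 - 1/(2B) before
the probit transform; nodes whose BP sits at a bound on every scale are
flagged degenerate and reported with AU 0 or 1 directly.  With only nine
traits the resample sizes span roughly 5-13 features, so BP estimates are
coarse; clamping and the binomial-variance weights make the fit behave in
this small-sample regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

DEFAULT_SCALES: np.ndarray = np.round(np.arange(0.5, 1.41, 0.1), 10)


@dataclass
class ClusterNode:
    """One internal node of the dendrogram."""

    node_id: int
    members: frozenset[str]
    height: float
    bp: float = float("nan")       # BP at scale closest to 1
    au: float = float("nan")
    v: float = float("nan")
    c: float = float("nan")
    degenerate: bool = False


@dataclass
class Dendrogram:
    """UPGMA merge tree with per-node support statistics."""

    labels: list[str]
    linkage_matrix: np.ndarray = field(repr=False)
    nodes: list[ClusterNode] = field(default_factory=list)

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": [n.node_id for n in self.nodes],
                "size": [len(n.members) for n in self.nodes],
                "height": [n.height for n in self.nodes],
                "bp": [n.bp for n in self.nodes],
                "au": [n.au for n in self.nodes],
                "v": [n.v for n in self.nodes],
                "c": [n.c for n in self.nodes],
                "degenerate": [n.degenerate for n in self.nodes],
                "members": ["|".join(sorted(n.members)) for n in self.nodes],
            }
        )

    def to_newick(self, with_support: bool = True) -> str:
        """Newick string; internal nodes carry AU/BP as comments."""
        n = len(self.labels)
        z = self.linkage_matrix
        stats = {n + i: self.nodes[i] for i in range(len(self.nodes))}

        def render(idx: int) -> str:
            if idx < n:
                return self.labels[idx].replace(" ", "_")
            row = z[idx - n]
            left, right = render(int(row[0])), render(int(row[1]))
            comment = ""
            node = stats.get(idx)
            if with_support and node is not None and np.isfinite(node.au):
                comment = f"[&&au={node.au:.3f},bp={node.bp:.3f}]"
            return f"({left},{right}){comment}:{row[2]:.6g}"

        return render(2 * n - 2) + ";"


def _member_sets(z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Member leaf-index sets for every internal node of a linkage matrix."""
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, row in enumerate(z):
        merged = sets[int(row[0])] | sets[int(row[1])]
        sets[n + i] = merged
        out.append(merged)
    return out


def upgma(distances: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram from a distance matrix.

    ``distances`` may be square-symmetric or condensed.  Agglomeration is
    deterministic (scipy's nearest-neighbor-chain algorithm).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be square and symmetric")
        n = d.shape[0]
        condensed = squareform(d, checks=False)
    elif d.ndim == 1:
        condensed = d
        n = int(round((1 + np.sqrt(1 + 8 * d.size)) / 2))
    else:
        raise ValueError("distances must be 1-D condensed or 2-D square")
    labels = labels or [f"obs{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match distance matrix")
    z = linkage(condensed, method="average")
    nodes = [
        ClusterNode(
            node_id=n + i,
            members=frozenset(labels[j] for j in mem),
            height=float(z[i, 2]),
        )
        for i, mem in enumerate(_member_sets(z, n))
    ]
    return Dendrogram(labels=list(labels), linkage_matrix=z, nodes=nodes)


def cophenetic_matrix(dend: Dendrogram) -> pd.DataFrame:
    from scipy.cluster.hierarchy import cophenet

    coph = squareform(cophenet(dend.linkage_matrix))
    return pd.DataFrame(coph, index=dend.labels, columns=dend.labels)


@dataclass
class BootstrapResult:
    """Per-node bootstrap probabilities across resample scales."""

    bp: pd.DataFrame          # nodes x scales, values in [0, 1]
    scales: np.ndarray        # requested relative scales r
    sizes: np.ndarray         # actual resample sizes round(r * n_features)
    n_features: int
    n_boot: int


def multiscale_bootstrap(
    z_matrix: np.ndarray,
    labels: list[str],
    scales: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[Dendrogram, BootstrapResult]:
    """Feature-resampling multiscale bootstrap of a UPGMA dendrogram.

    ``z_matrix`` is the observations x features (cultures x standardized
    traits) matrix the dendrogram is built from.  For each scale r, features
    are resampled with replacement to size round(r * n_features) (half-up),
    the full distance + UPGMA construction is repeated, and each original
    internal node's BP_r is the fraction of the ``n_boot`` bootstrap trees
    containing its exact member set.  Per-scale RNG substreams are derived
    from ``seed``, so results are reproducible and each scale's stream is
    independent of the others.
    """
    x = np.asarray(z_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("z_matrix must be 2-D (observations x features)")
    n_obs, n_feat = x.shape
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scales = DEFAULT_SCALES if scales is None else np.asarray(scales, dtype=float)
    sizes = np.floor(scales * n_feat + 0.5).astype(int)
    if np.any(sizes < 1):
        bad = scales[sizes < 1]
        raise ValueError(f"scale(s) {bad} give a resample size of 0")

    dend = upgma(pdist(x), labels=labels)
    orig_sets = [frozenset(dend.labels.index(l) for l in node.members) for node in dend.nodes]
    bp = np.zeros((len(orig_sets), len(scales)))

    for si, size in enumerate(sizes):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), si]))
        counts = {s: 0 for s in orig_sets}
        for _ in range(n_boot):
            cols = rng.integers(0, n_feat, size=size)
            zb = linkage(pdist(x[:, cols]), method="average")
            for mem in _member_sets(zb, n_obs):
                if mem in counts:
                    counts[mem] += 1
        bp[:, si] = [counts[s] / n_boot for s in orig_sets]

    result = BootstrapResult(
        bp=pd.DataFrame(
            bp,
            index=pd.Index([n.node_id for n in dend.nodes], name="node_id"),
            columns=[f"r={r:g}" for r in scales],
        ),
        scales=scales,
        sizes=sizes,
        n_features=n_feat,
        n_boot=n_boot,
    )
    return dend, result


@dataclass
class AuFit:
    au: float
    bp0: float
    v: float
    c: float
    degenerate: bool


def au_fit_single(
    bp_values: np.ndarray, sizes: np.ndarray, n_features: int, n_boot: int
) -> AuFit:
    """Fit (v, c) for one node from its BP-versus-scale curve (WLS on the
    probit scale with binomial-variance weights)."""
    bp_raw = np.asarray(bp_values, dtype=float)
    lo, hi = 1.0 / (2 * n_boot), 1.0 - 1.0 / (2 * n_boot)
    at_bound = (bp_raw <= 0.0) | (bp_raw >= 1.0)
    if np.all(at_bound):
        au = 1.0 if bp_raw.mean() > 0.5 else 0.0
        return AuFit(au=au, bp0=au, v=float("nan"), c=float("nan"), degenerate=True)
    bp = np.clip(bp_raw, lo, hi)
    s = sizes / n_features
    z = norm.isf(bp)  # Phi^-1(1 - BP)
    # delta method: var(z) = BP(1-BP) / (B * phi(z)^2)
    w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    design = np.column_stack([np.sqrt(s), 1.0 / np.sqrt(s)])
    wsqrt = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * wsqrt[:, None], z * wsqrt, rcond=None)
    v, c = map(float, coef)
    return AuFit(
        au=float(norm.sf(v - c)),
        bp0=float(norm.sf(v + c)),
        v=v,
        c=c,
        degenerate=False,
    )


def au_from_multiscale(result: BootstrapResult) -> pd.DataFrame:
    """AU and smoothed BP for every node of a multiscale bootstrap run."""
    rows = []
    for node_id, row in result.bp.iterrows():
        fit = au_fit_single(row.to_numpy(), result.sizes, result.n_features, result.n_boot)
        rows.append(
            {
                "node_id": node_id,
                "au": fit.au,
                "bp0": fit.bp0,
                "v": fit.v,
                "c": fit.c,
                "degenerate": fit.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("node_id")


def cluster_with_support(
    z_matrix: np.ndarray,
    labels: list[str],
    scales: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[Dendrogram, BootstrapResult, pd.DataFrame]:
    """UPGMA + multiscale bootstrap + AU fit in one call; the returned
    dendrogram's nodes are annotated with BP (at the scale nearest 1) and AU."""
    dend, boot = multiscale_bootstrap(z_matrix, labels, scales=scales, n_boot=n_boot, seed=seed)
    au = au_from_multiscale(boot)
    near_one = int(np.argmin(np.abs(boot.scales - 1.0)))
    for node in dend.nodes:
        node.bp = float(boot.bp.loc[node.node_id].iloc[near_one])
        node.au = float(au.loc[node.node_id, "au"])
        node.v = float(au.loc[node.node_id, "v"])
        node.c = float(au.loc[node.node_id, "c"])
        node.degenerate = bool(au.loc[node.node_id, "degenerate"])
    return dend, boot, au
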