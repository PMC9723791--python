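"""End-to-end pipeline: simulate -> derive -> scape -> reduce -> cluster ->
plasticity -> genotype, with a content-hashed run manifest.

A single master seed drives the simulation and the bootstrap; identical
configurations therefore produce byte-identical outputs and an identical
manifest.  All tables are written as UTF-8 CSV with a header row, model
objects as JSON, and the dendrogram additionally as Newick with AU/BP node
comments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariation, plasticity as plasticity_mod, synthetic
from .cluster import cluster_with_support
from .scape import TraitScape, build_traitscape, expanded_traitscape, standardize, trait_columns

logger = logging.getLogger("traitscape")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "traitscape_run"
    traits_csv: str | None = None       # use an existing table instead of simulating
    n_strains: int = 13
    n_replicates: int = 3
    alpha: float = 0.05
    group_threshold: float = 0.7
    bootstrap_n: int = 1000
    bootstrap_scales: list[float] = field(
        default_factory=lambda: [round(0.5 + 0.1 * i, 1) for i in range(10)]
    )
    subset: list[str] | None = None     # None -> group representatives
    baseline_environment: str = "standard"
    permutations: int = 500
    identity_mode: str = "independent"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.traits_csv is not None and not Path(self.traits_csv).exists():
            raise FileNotFoundError(f"traits table not found: {self.traits_csv}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def diagnostics_report(scape: TraitScape) -> dict:
    """Consistency diagnostics of a fitted trait-scape.

    Reports the cumulative two-axis variance, both null expectations for the
    two-axis capture under randomly distributed trait values — 2/(T-1),
    the rank-based null for T fully standardized traits, and 2/T, the naive
    trait-count null — and a recomputation of each axis's proportion of
    variance from its score standard deviation (sd^2 / T), which must agree
    with the eigenvalue route.
    """
    t = scape.n_traits
    sds = np.sqrt(scape.eigenvalues)
    recomputed = sds**2 / t
    return {
        "n_traits": t,
        "two_axis_variance_pct": scape.two_axis_variance_pct(),
        "null_two_axis_pct_rank": 100.0 * 2.0 / (t - 1),
        "null_two_axis_pct_traits": 100.0 * 2.0 / t,
        "axis_sd": sds.tolist(),
        "proportion_recomputed_from_sd": recomputed.tolist(),
        "proportion_of_variance": scape.proportion_of_variance.tolist(),
        "proportions_consistent": bool(
            np.allclose(recomputed, scape.proportion_of_variance, atol=1e-10)
        ),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Any stage failure raises with the stage name; outputs written before the
    failure are retained on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        p = outdir / name
        df.to_csv(p, index=index)
        written.append(p)
        return p

    def save_json(obj, name: str) -> Path:
        p = outdir / name
        p.write_text(json.dumps(obj, indent=2, default=_jsonify))
        written.append(p)
        return p

    stage = "simulate"
    try:
        sim_config = synthetic.default_config(
            n_strains=config.n_strains,
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        if config.traits_csv is not None:
            table = pd.read_csv(config.traits_csv)
            full_table = table
        else:
            table, _truth = synthetic.simulate_trait_table(sim_config)
            full_table = synthetic.simulate_plasticity_shift(sim_config, table)
            instruments = synthetic.emit_instrument_data(table, sim_config)
            for name, df in instruments.items():
                save_df(df, f"{name}.csv")
        standard = full_table[full_table["environment"] == config.baseline_environment]
        treatments = full_table[full_table["environment"] != config.baseline_environment]
        save_df(full_table, "traits.csv")
        logger.info("simulate: %d cultures (%d treatment rows)", len(full_table), len(treatments))

        stage = "scape"
        scape = build_traitscape(standard)
        save_json(scape.to_dict(), "scape.json")
        save_df(scape.scores, "scores.csv")
        save_json(diagnostics_report(scape), "diagnostics.json")

        stage = "covariation"
        corr = covariation.correlation_matrix(standard, alpha=config.alpha)
        save_df(corr.r, "correlation_r.csv", index=True)
        save_df(corr.p, "correlation_p.csv", index=True)
        groups = covariation.identify_trait_groups(corr, scape, threshold=config.group_threshold)
        save_json({"groups": groups.groups, "representatives": groups.representatives}, "trait_groups.json")

        stage = "reduce"
        subset = config.subset or groups.representative_subset()
        reduced, recovery = covariation.reduced_traitscape_recovery(
            standard, subset, full_scape=scape
        )
        save_json(
            {
                "subset": subset,
                "two_axis_variance_pct": reduced.two_axis_variance_pct(),
                "r2": recovery.r2,
                "adj_r2": recovery.adj_r2,
                "p": recovery.p,
                "n_pairs": recovery.n_pairs,
            },
            "recovery.json",
        )

        stage = "cluster"
        z, _ = standardize(standard)
        labels = [synthetic.culture_id_of(r) for _, r in standard.iterrows()]
        dend, boot, au = cluster_with_support(
            z[trait_columns(standard)].to_numpy(),
            labels,
            scales=np.asarray(config.bootstrap_scales),
            n_boot=config.bootstrap_n,
            seed=config.seed,
        )
        save_df(dend.node_table(), "dendrogram_nodes.csv")
        p = outdir / "dendrogram.nwk"
        p.write_text(dend.to_newick())
        written.append(p)

        stage = "plasticity"
        if len(treatments):
            changes = plasticity_mod.relative_changes(
                full_table, baseline_env=config.baseline_environment
            )
            save_df(changes.changes, "relative_changes.csv")
            strat = plasticity_mod.strategy_pca(
                changes, n_permutations=config.permutations, seed=config.seed
            )
            save_json(
                {
                    "separation_ratio": strat.separation_ratio,
                    "permutation_p": strat.permutation_p,
                    "within_mean_distance": strat.within_mean_distance,
                    "between_mean_distance": strat.between_mean_distance,
                    "environment_centroids": strat.environment_centroids.to_dict(),
                },
                "strategy.json",
            )
            exp_scape = expanded_traitscape(standard, treatments)
            save_json(exp_scape.to_dict(), "expanded_scape.json")

        stage = "genotype"
        identity = synthetic.simulate_identity_matrix(sim_config, mode=config.identity_mode)
        save_df(identity, "identity.csv", index=True)
        cents = covariation.strain_centroids(scape.scores)
        geno = covariation.genotype_phenotype_regression(
            identity, cents, a=scape.variance_pct(1), b=scape.variance_pct(2)
        )
        save_json({"r2": geno.r2, "p": geno.p, "n_pairs": geno.n_pairs}, "genotype.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
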