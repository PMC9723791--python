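"""Synthetic trait data with known latent structure.

Every input the pipeline consumes can be generated here with ground truth
attached, emulating a culturing experiment in which a panel of diatom
strains is grown in triplicate in a nutrient-replete "standard" environment,
and a subset is additionally grown under a high-temperature/high-light (HT)
and a low-nutrient (LN) treatment.

Generative model
----------------
Trait values live on a standardized latent scale and are mapped to natural
units at the end.  For culture ``c`` (strain ``s``, environment ``e``) and
trait ``j``:

    z_cj = Lambda_j . f_s  +  shift_j(e) + delta_sj(e)  +  eps_cj
    value_cj = trait_mean_j + trait_scale_j * z_cj

with ``f_s`` the strain's latent factor vector (fixed across replicates),
``Lambda`` a traits x factors loading matrix with orthogonal columns,
``shift(e)`` an environment mean-shift vector shared across strains,
``delta`` a small strain-specific deviation of that shift
(``env_shift_noise_sd``), and ``eps`` replicate noise.  The default loading
matrix has two latent factors — a cell-size factor carrying cell size,
chlorophyll, granularity and lipids, and a photophysiology factor carrying
alpha, ETRmax and Ik — with weak cross-loadings for growth rate and ROS, so
the generated tables show four near-orthogonal trait groups and a two-axis
PCA captures most of the variance.

The default LN shift has a negative chlorophyll and a positive lipid
component while both traits load positively on the size factor, so the
across-strain chlorophyll-lipid correlation is positive but the
within-strain response to low nutrients moves the two traits in opposite
directions (a short-term physiological trade-off).

All randomness flows from ``config.seed`` through documented substreams
(one integer label per consumer), so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .scape import TRAIT_NAMES
from .traits import PAPER_CALIBRATION, GrowthSeries, LightCurve

# substream labels for the master-seed splitting scheme
_STREAM_FACTORS = 0
_STREAM_TABLE = 1
_STREAM_PLASTICITY = 2
_STREAM_IDENTITY = 3
_STREAM_GROWTH = 4
_STREAM_LIGHT = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


#: Trait -> group partition implied by the default loadings.
DEFAULT_GROUP_ASSIGNMENT: dict[str, str] = {
    "growth_rate": "growth",
    "cell_size": "size",
    "chl_a": "size",
    "granularity": "size",
    "lipids": "size",
    "ros": "ros",
    "alpha": "photophysiology",
    "etrmax": "photophysiology",
    "ik": "photophysiology",
}

# hand-set loadings (traits x 2 factors, TRAIT_NAMES order); the second
# column is Gram-Schmidt-orthogonalised against the first at config build
_RAW_LOADINGS = np.array(
    [
        [0.15, 0.10],   # growth_rate: weak on both factors
        [0.95, 0.00],   # cell_size
        [0.90, 0.12],   # chl_a
        [0.92, 0.05],   # granularity
        [0.88, -0.10],  # lipids
        [0.10, 0.30],   # ros: weak photophysiology cross-loading
        [0.00, 0.80],   # alpha
        [0.08, 0.88],   # etrmax
        [0.00, 0.85],   # ik
    ]
)

# environment mean shifts, standardized trait units, TRAIT_NAMES order
_DEFAULT_ENV_SHIFTS: dict[str, np.ndarray] = {
    # high temperature / high light: photophysiology and ROS up
    "HT": np.array([0.5, -0.5, -0.6, -0.2, 0.2, 1.2, -0.8, 1.5, 1.8]),
    # low nutrients: chlorophyll down, lipids up, growth and photochemistry down
    "LN": np.array([-1.2, -0.3, -1.5, 0.3, 1.6, 0.8, -0.6, -1.0, -0.8]),
}

# natural-unit trait means and scales (per standardized unit)
_DEFAULT_TRAIT_MEANS = np.array([0.8, 9.0, 50.0, 40.0, 30.0, 5.0, 0.30, 60.0, 200.0])
_DEFAULT_TRAIT_SCALES = np.array([0.12, 1.8, 10.0, 8.0, 7.0, 1.2, 0.05, 10.0, 35.0])


def _orthogonalize(loadings: np.ndarray) -> np.ndarray:
    """Project each later column out of the span of earlier ones."""
    out = loadings.astype(float).copy()
    for k in range(1, out.shape[1]):
        for j in range(k):
            cj = out[:, j]
            out[:, k] -= (out[:, k] @ cj) / (cj @ cj) * cj
    return out


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment.

    ``strain_factor_means`` may be left ``None``, in which case strain
    factor vectors are drawn N(0, diag(strain_factor_sd^2)) from the seed's
    factor substream.
    """

    n_strains: int = 13
    n_replicates: int = 3
    trait_names: tuple[str, ...] = TRAIT_NAMES
    factor_loadings: np.ndarray = field(default_factory=lambda: _orthogonalize(_RAW_LOADINGS))
    group_assignment: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_ASSIGNMENT)
    )
    strain_factor_sd: np.ndarray = field(default_factory=lambda: np.array([1.4, 0.8]))
    strain_factor_means: np.ndarray | None = None
    replicate_noise_sd: np.ndarray = field(default_factory=lambda: np.full(9, 0.35))
    env_shift_vectors: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_ENV_SHIFTS.items()}
    )
    env_shift_noise_sd: float = 0.15
    standard_environment: str = "standard"
    trait_means: np.ndarray = field(default_factory=lambda: _DEFAULT_TRAIT_MEANS.copy())
    trait_scales: np.ndarray = field(default_factory=lambda: _DEFAULT_TRAIT_SCALES.copy())
    # instrument-level generation
    growth_days: int = 6
    growth_f0: float = 100.0
    growth_noise_sd: float = 0.05
    light_irradiances: np.ndarray = field(
        default_factory=lambda: np.array([20.0, 40.0, 80.0, 120.0, 180.0, 260.0, 380.0, 550.0])
    )
    light_noise_sd: float = 1.0
    bead_diameters: np.ndarray = field(default_factory=lambda: np.array([2.0, 4.0, 6.0, 10.0, 15.0]))
    identity_range: tuple[float, float] = (85.0, 99.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        self.replicate_noise_sd = np.broadcast_to(
            np.asarray(self.replicate_noise_sd, dtype=float), (len(self.trait_names),)
        ).copy()
        self.validate()

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_factors(self) -> int:
        return self.factor_loadings.shape[1]

    @property
    def strain_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_strains)]

    def species_of(self, strain_id: str) -> str:
        # strains are grouped into synthetic "species" of up to three strains
        i = self.strain_ids.index(strain_id)
        return f"Synthosira sp. {chr(ord('A') + i // 3)}"

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.factor_loadings.shape[0] != self.n_traits:
            raise ValueError("factor_loadings rows must match trait count")
        if np.any(self.replicate_noise_sd < 0):
            raise ValueError("replicate_noise_sd must be non-negative")
        if self.env_shift_noise_sd < 0:
            raise ValueError("env_shift_noise_sd must be non-negative")
        gram = self.factor_loadings.T @ self.factor_loadings
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(off)) > 1e-8:
            raise ValueError("factor_loadings columns must be orthogonal")
        missing = set(self.trait_names) - set(self.group_assignment)
        if missing:
            raise ValueError(f"traits without a group assignment: {sorted(missing)}")
        for env, vec in self.env_shift_vectors.items():
            if len(np.asarray(vec)) != self.n_traits:
                raise ValueError(f"env shift vector for {env!r} has wrong length")
        lo, hi = self.identity_range
        if not (0 <= lo < hi <= 100):
            raise ValueError("identity_range must satisfy 0 <= lo < hi <= 100")

    # -- population-level (implied) quantities, for recovery tests ---------
    def implied_correlation(self) -> np.ndarray:
        """Trait correlation matrix implied by the factor model (strains
        drawn from the factor population, replicate noise included)."""
        lam = self.factor_loadings * self.strain_factor_sd  # scale columns
        cov = lam @ lam.T + np.diag(self.replicate_noise_sd**2)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def implied_two_axis_fraction(self) -> float:
        """Fraction of total variance on the first two population PCA axes."""
        eig = np.sort(np.linalg.eigvalsh(self.implied_correlation()))[::-1]
        return float(eig[:2].sum() / self.n_traits)


def default_config(**overrides) -> SimulationConfig:
    """The default simulated experiment: 13 strains x 3 replicates x 9
    traits, two latent factors, HT and LN treatments for a 5-strain subset."""
    return SimulationConfig(**overrides)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated table, for recovery tests."""

    strain_factor_means: pd.DataFrame  # strains x factors
    culture_means: pd.DataFrame        # per-culture noiseless natural-unit traits
    group_assignment: dict[str, str]
    env_shift_vectors: dict[str, np.ndarray]
    factor_loadings: np.ndarray


def _strain_factors(config: SimulationConfig) -> pd.DataFrame:
    """Strain latent-factor vectors (deterministic from config.seed)."""
    if config.strain_factor_means is not None:
        f = np.asarray(config.strain_factor_means, dtype=float)
        if f.shape != (config.n_strains, config.n_factors):
            raise ValueError("strain_factor_means has wrong shape")
    else:
        rng = _rng(config.seed, _STREAM_FACTORS)
        f = rng.normal(size=(config.n_strains, config.n_factors)) * config.strain_factor_sd
    return pd.DataFrame(
        f,
        index=pd.Index(config.strain_ids, name="strain_id"),
        columns=[f"f{k + 1}" for k in range(config.n_factors)],
    )


def _assemble_rows(
    config: SimulationConfig,
    factors: pd.DataFrame,
    strain_ids: list[str],
    environment: str,
    shift: np.ndarray,
    delta_by_strain: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate rows for one environment; returns (table rows, noiseless means)."""
    rows, mean_rows = [], []
    for sid in strain_ids:
        f = factors.loc[sid].to_numpy()
        signal = config.factor_loadings @ f + shift + delta_by_strain[sid]
        mean_nat = config.trait_means + config.trait_scales * signal
        for rep in range(1, config.n_replicates + 1):
            eps = rng.normal(size=config.n_traits) * config.replicate_noise_sd
            z = signal + eps
            values = config.trait_means + config.trait_scales * z
            meta = {
                "strain_id": sid,
                "species": config.species_of(sid),
                "replicate": rep,
                "environment": environment,
            }
            rows.append({**meta, **dict(zip(config.trait_names, values))})
            mean_rows.append({**meta, **dict(zip(config.trait_names, mean_nat))})
    return pd.DataFrame(rows), pd.DataFrame(mean_rows)


def simulate_trait_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate the standard-environment trait table (all strains).

    Returns the cultures x traits table and the generative ground truth.
    Deterministic given ``config`` (including its seed).
    """
    factors = _strain_factors(config)
    rng = _rng(config.seed, _STREAM_TABLE)
    zero = np.zeros(config.n_traits)
    delta = {sid: zero for sid in config.strain_ids}
    table, means = _assemble_rows(
        config, factors, config.strain_ids, config.standard_environment, zero, delta, rng
    )
    truth = SimulationTruth(
        strain_factor_means=factors,
        culture_means=means,
        group_assignment=dict(config.group_assignment),
        env_shift_vectors={k: np.asarray(v).copy() for k, v in config.env_shift_vectors.items()},
        factor_loadings=config.factor_loadings.copy(),
    )
    return table, truth


def simulate_plasticity_shift(
    config: SimulationConfig,
    base: pd.DataFrame,
    strain_ids: list[str] | None = None,
    environments: list[str] | None = None,
) -> pd.DataFrame:
    """Append treatment-environment rows for a strain subset to ``base``.

    The environment shift vector is shared across strains up to a per-strain
    N(0, env_shift_noise_sd) deviation drawn once per (strain, environment)
    and shared by its replicates.  Default subset: the first five strains,
    grown in every configured treatment environment.
    """
    if strain_ids is None:
        strain_ids = config.strain_ids[: min(5, config.n_strains)]
    if environments is None:
        environments = list(config.env_shift_vectors)
    present = set(base.loc[base["environment"] == config.standard_environment, "strain_id"])
    absent = [s for s in strain_ids if s not in present]
    if absent:
        raise ValueError(f"strains lack standard-environment rows in base: {absent}")
    for env in environments:
        if env not in config.env_shift_vectors:
            raise ValueError(f"unknown environment {env!r}; configured: {list(config.env_shift_vectors)}")

    factors = _strain_factors(config)
    rng = _rng(config.seed, _STREAM_PLASTICITY)
    parts = [base]
    for env in environments:
        shift = np.asarray(config.env_shift_vectors[env], dtype=float)
        delta = {
            sid: rng.normal(size=config.n_traits) * config.env_shift_noise_sd
            for sid in strain_ids
        }
        rows, _ = _assemble_rows(config, factors, strain_ids, env, shift, delta, rng)
        parts.append(rows)
    return pd.concat(parts, ignore_index=True)


def simulate_growth_series(
    mu: float,
    f0: float = 100.0,
    days: int = 6,
    noise_sd: float = 0.0,
    lag_days: float = 0.0,
    plateau: float | None = None,
    seed: int | np.random.Generator = 0,
    culture_id: str = "culture",
) -> GrowthSeries:
    """Daily in-vivo fluorescence series F(t) = F0 exp(mu t), optionally with
    a lag phase, a plateau (stationary phase cap) and multiplicative
    log-normal noise exp(noise_sd * z).  Noiseless series are exactly
    exponential."""
    if not np.isfinite(mu):
        raise ValueError("mu must be finite")
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    if days < 2:
        raise ValueError("need at least 2 daily steps (3 points)")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_GROWTH)
    t = np.arange(days + 1, dtype=float)
    te = np.clip(t - lag_days, 0.0, None)
    f = f0 * np.exp(mu * te)
    if plateau is not None:
        f = np.minimum(f, plateau)
    if noise_sd > 0:
        f = f * np.exp(noise_sd * rng.normal(size=f.size))
    return GrowthSeries(culture_id=culture_id, time=t, fluorescence=f)


def simulate_light_curves(
    alpha: float,
    etrmax: float,
    irradiances: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    culture_id: str = "culture",
) -> LightCurve:
    """Rapid light curve over 8 increasing irradiance steps,
    ETR(E) = ETRmax tanh(alpha E / ETRmax) + noise."""
    if alpha <= 0 or etrmax <= 0:
        raise ValueError("alpha and ETRmax must be positive")
    if irradiances is None:
        irradiances = np.array([20.0, 40.0, 80.0, 120.0, 180.0, 260.0, 380.0, 550.0])
    e = np.asarray(irradiances, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_LIGHT)
    etr = etrmax * np.tanh(alpha * e / etrmax)
    if noise_sd > 0:
        etr = etr + noise_sd * rng.normal(size=e.size)
    return LightCurve(culture_id=culture_id, irradiance=e, etr=etr)


def simulate_identity_matrix(
    config: SimulationConfig,
    seed: int | None = None,
    mode: str = "independent",
    coupled_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Strain x strain percent sequence-identity matrix.

    ``independent`` mode draws off-diagonals uniformly in
    ``config.identity_range``, independent of the phenotype factors (the
    null structure: genetic relatedness unrelated to trait-scape position).
    ``coupled`` mode makes identity a decreasing function of the strains'
    latent-factor distance (plus optional noise), for power tests.
    """
    if config.n_strains < 3:
        raise ValueError("need at least 3 strains for an identity matrix")
    if mode not in ("independent", "coupled"):
        raise ValueError(f"unknown mode {mode!r}")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STREAM_IDENTITY)
    ids = config.strain_ids
    n = len(ids)
    lo, hi = config.identity_range
    m = np.full((n, n), 100.0)
    if mode == "independent":
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = rng.uniform(lo, hi)
    else:
        f = _strain_factors(config).to_numpy()
        d = np.linalg.norm(f[:, None, :] - f[None, :, :], axis=2)
        dmax = d.max()
        if dmax <= 0:
            raise ValueError("degenerate factor configuration: all strains identical")
        for i in range(n):
            for j in range(i + 1, n):
                val = hi - (hi - lo) * d[i, j] / dmax
                if coupled_noise_sd > 0:
                    val += coupled_noise_sd * rng.normal()
                m[i, j] = m[j, i] = float(np.clip(val, 0.0, 100.0))
    return pd.DataFrame(m, index=pd.Index(ids, name="strain_id"), columns=ids)


# ---------------------------------------------------------------------------
# instrument-level emission (summary-level, per-sample medians)
# ---------------------------------------------------------------------------

def culture_id_of(row: pd.Series) -> str:
    return f"{row['strain_id']}-{row['environment']}-r{row['replicate']}"


def emit_instrument_data(
    table: pd.DataFrame, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Generate instrument-level inputs consistent with a trait table.

    Returns DataFrames ``growth``, ``light_curves``, ``beads`` and ``fcm``
    such that the trait-derivation module reproduces the table's traits:
    growth series use each culture's growth-rate trait, light curves its
    alpha and ETRmax traits (so the derived Ik is ETRmax/alpha), and
    flow-cytometry medians invert the per-ESD normalizations.  Bead FSC
    medians lie exactly on the built-in calibration line.
    """
    cal = PAPER_CALIBRATION
    growth_rows, light_rows, fcm_rows = [], [], []
    grow_rng = _rng(config.seed, _STREAM_GROWTH)
    light_rng = _rng(config.seed, _STREAM_LIGHT)
    for _, row in table.iterrows():
        cid = culture_id_of(row)
        series = simulate_growth_series(
            mu=float(row["growth_rate"]),
            f0=config.growth_f0,
            days=config.growth_days,
            noise_sd=config.growth_noise_sd,
            seed=grow_rng,
            culture_id=cid,
        )
        for t, f in zip(series.time, series.fluorescence):
            growth_rows.append({"culture_id": cid, "day": t, "fluorescence": f})
        curve = simulate_light_curves(
            alpha=float(row["alpha"]),
            etrmax=float(row["etrmax"]),
            irradiances=config.light_irradiances,
            noise_sd=config.light_noise_sd,
            seed=light_rng,
            culture_id=cid,
        )
        for step, (e, y) in enumerate(zip(curve.irradiance, curve.etr), start=1):
            light_rows.append({"culture_id": cid, "step": step, "irradiance": e, "etr": y})
        esd = float(row["cell_size"])
        cell_count = 5000.0
        prestain = 1000.0
        ros_blank = 500.0
        fcm_rows.append(
            {
                "culture_id": cid,
                "strain_id": row["strain_id"],
                "species": row["species"],
                "replicate": row["replicate"],
                "environment": row["environment"],
                "fsc_median": cal.slope * esd + cal.intercept,
                "chl_median": float(row["chl_a"]) * esd,
                "ssc_median": float(row["granularity"]) * esd,
                "prestain_median": prestain,
                "poststain_median": prestain + float(row["lipids"]) * esd,
                "ros_stained": ros_blank + float(row["ros"]) * esd * cell_count,
                "ros_blank": ros_blank,
                "cell_count": cell_count,
            }
        )
    beads = pd.DataFrame(
        {
            "diameter_um": config.bead_diameters,
            "fsc_median": cal.slope * config.bead_diameters + cal.intercept,
        }
    )
    return {
        "growth": pd.DataFrame(growth_rows),
        "light_curves": pd.DataFrame(light_rows),
        "beads": beads,
        "fcm": pd.DataFrame(fcm_rows),
    }


def write_instrument_csvs(
    data: dict[str, pd.DataFrame], outdir: str | Path
) -> dict[str, Path]:
    """Write the instrument DataFrames to their fixed-schema CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in data.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
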