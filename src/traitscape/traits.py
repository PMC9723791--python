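"""Derive the nine phenotypic traits from instrument-level measurements.

Traits and their instruments:

* growth rate (d^-1) — daily in-vivo chlorophyll fluorescence series;
  per-step rates mu = (ln F2 - ln F1)/(t2 - t1), with the maximum taken as
  the best mean over 2-4 consecutive steps.
* cell size (ESD, um) — flow-cytometry forward scatter calibrated against
  beads of known diameter.
* chlorophyll-a, granularity, neutral lipids, ROS — flow-cytometry /
  plate-reader medians, each normalized by ESD; lipids and ROS are
  stained-minus-unstained differences (negative differences preserved).
* alpha, ETRmax, Ik — rapid-light-curve fit of a saturating
  photosynthesis-irradiance model, Ik = ETRmax/alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class GrowthSeries:
    """Daily fluorescence time series for one culture."""

    culture_id: str
    time: np.ndarray  # days, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.fluorescence.size:
            raise ValueError("time and fluorescence must be 1-D and equally long")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")


@dataclass
class LightCurve:
    """Rapid light curve: relative ETR at increasing irradiance steps."""

    culture_id: str
    irradiance: np.ndarray  # umol photons m^-2 s^-1
    etr: np.ndarray

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        self.etr = np.asarray(self.etr, dtype=float)
        if np.any(np.diff(self.irradiance) <= 0):
            raise ValueError("irradiance steps must be strictly increasing")


@dataclass(frozen=True)
class BeadCalibration:
    """Linear FSC -> ESD map fitted on calibration beads.

    The fit is FSC = slope * diameter + intercept, so
    ESD = (FSC - intercept)/slope.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")

    @classmethod
    def fit(cls, diameters_um: np.ndarray, fsc_medians: np.ndarray) -> "BeadCalibration":
        d = np.asarray(diameters_um, dtype=float)
        f = np.asarray(fsc_medians, dtype=float)
        if d.size < 2:
            raise ValueError("need at least 2 beads to fit a calibration")
        slope, intercept = np.polyfit(d, f, 1)
        return cls(slope=float(slope), intercept=float(intercept))


#: The published instrument calibration, ESD = (FSC + 194636)/75775.
PAPER_CALIBRATION = BeadCalibration(slope=75775.0, intercept=-194636.0)


def step_growth_rates(series: GrowthSeries) -> np.ndarray:
    """Per-step exponential growth rates from consecutive fluorescence pairs.

    mu_i = (ln F_{i+1} - ln F_i) / (t_{i+1} - t_i)
    """
    bad = np.flatnonzero(series.fluorescence <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive fluorescence in {series.culture_id!r} at "
            f"t = {series.time[bad[0]]:g}"
        )
    return np.diff(np.log(series.fluorescence)) / np.diff(series.time)


def max_growth_rate(
    series: GrowthSeries, window_lengths: tuple[int, ...] = (2, 3, 4)
) -> float:
    """Maximum growth rate: the best mean over 2-4 consecutive step rates.

    All contiguous windows of the given step lengths are scanned (windows
    longer than the series are skipped); ties go to the earliest window.
    """
    rates = step_growth_rates(series)
    if rates.size < 2:
        raise ValueError(
            f"{series.culture_id!r}: need at least 2 step rates "
            f"(3 time points), got {rates.size}"
        )
    best = -np.inf
    for start in range(rates.size):
        for w in sorted(window_lengths):
            if start + w > rates.size:
                continue
            m = float(rates[start : start + w].mean())
            if m > best:
                best = m
    return best


def fsc_to_esd(fsc: np.ndarray | float, calibration: BeadCalibration = PAPER_CALIBRATION):
    """Convert forward scatter to equivalent spherical diameter (um).

    With the built-in published calibration this is
    ESD = (FSC + 194636)/75775.  Values at or below zero ESD are outside
    the calibration range and raise.
    """
    esd = (np.asarray(fsc, dtype=float) - calibration.intercept) / calibration.slope
    if np.any(esd <= 0):
        raise ValueError("FSC below calibration range (ESD <= 0)")
    return esd if np.ndim(fsc) else float(esd)


@dataclass
class CytometrySummary:
    """Per-culture flow-cytometry / plate-reader medians."""

    culture_id: str
    fsc_median: float
    chl_median: float
    ssc_median: float
    prestain_median: float
    poststain_median: float
    ros_stained: float
    ros_blank: float
    cell_count: float

    def __post_init__(self) -> None:
        if not self.cell_count > 0:
            raise ValueError(f"{self.culture_id!r}: cell_count must be positive")


def derive_fcm_traits(summary: CytometrySummary, esd: float) -> dict[str, float]:
    """Size-normalized cytometry traits for one culture.

    chlorophyll = chl median / ESD; granularity = side scatter / ESD;
    lipids = (post-stain - pre-stain) / ESD;
    ROS = ((stained - blank)/cell count) / ESD.
    Negative stain differences are preserved, not clipped.
    """
    if not esd > 0:
        raise ValueError("esd must be positive")
    return {
        "cell_size": float(esd),
        "chl_a": summary.chl_median / esd,
        "granularity": summary.ssc_median / esd,
        "lipids": (summary.poststain_median - summary.prestain_median) / esd,
        "ros": ((summary.ros_stained - summary.ros_blank) / summary.cell_count) / esd,
    }


@dataclass
class LightCurveFit:
    """Result of a photosynthesis-irradiance curve fit."""

    alpha: float
    etrmax: float
    ik: float
    model: str
    converged: bool
    message: str = ""
    residual_rms: float = float("nan")


def _tanh_model(e, alpha, etrmax):
    return etrmax * np.tanh(alpha * e / etrmax)


def _exp_model(e, alpha, etrmax):
    return etrmax * (1.0 - np.exp(-alpha * e / etrmax))


_PI_MODELS = {"tanh": _tanh_model, "exp": _exp_model}


def fit_light_curve(curve: LightCurve, model: str = "tanh") -> LightCurveFit:
    """Least-squares fit of a saturating P-I model to a rapid light curve.

    The default is the Jassby-Platt hyperbolic tangent,
    ETR = ETRmax tanh(alpha E / ETRmax); its parameters are exactly the
    three reported photophysiological traits, with Ik = ETRmax/alpha.  An
    exponential (Webb) saturating model is available via ``model="exp"``.
    Non-convergence or a degenerate curve returns ``converged=False`` with
    NaN traits rather than raising, so failed cultures propagate as missing.
    """
    if model not in _PI_MODELS:
        raise ValueError(f"unknown P-I model {model!r}; options: {sorted(_PI_MODELS)}")
    e, y = curve.irradiance, curve.etr
    if np.sum(e > 0) < 4:
        raise ValueError("need at least 4 positive-irradiance points")
    if np.allclose(y, 0.0):
        raise ValueError(f"{curve.culture_id!r}: ETR identically zero (degenerate curve)")
    fn = _PI_MODELS[model]
    alpha0 = max((y[1] - y[0]) / (e[1] - e[0]), 1e-6)
    etrmax0 = max(float(np.max(y)), 1e-6)
    try:
        popt, _ = curve_fit(
            fn,
            e,
            y,
            p0=[alpha0, etrmax0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # no convergence
        return LightCurveFit(
            alpha=float("nan"), etrmax=float("nan"), ik=float("nan"),
            model=model, converged=False, message=str(exc),
        )
    alpha, etrmax = map(float, popt)
    resid = y - fn(e, alpha, etrmax)
    return LightCurveFit(
        alpha=alpha,
        etrmax=etrmax,
        ik=etrmax / alpha,
        model=model,
        converged=True,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# table-level derivation from the fixed CSV schemas
# ---------------------------------------------------------------------------

def derive_trait_table(
    growth: pd.DataFrame,
    light_curves: pd.DataFrame,
    beads: pd.DataFrame,
    fcm: pd.DataFrame,
    pi_model: str = "tanh",
) -> pd.DataFrame:
    """Assemble the cultures x 9 traits table from instrument CSVs.

    ``fcm`` carries the culture metadata (strain_id, species, replicate,
    environment).  Cultures with a failed light-curve fit get NaN
    photophysiology traits (they are excluded from PCA downstream, with a
    warning from the table validator).
    """
    cal = BeadCalibration.fit(
        beads["diameter_um"].to_numpy(), beads["fsc_median"].to_numpy()
    )
    rows = []
    for _, s in fcm.iterrows():
        cid = s["culture_id"]
        g = growth[growth["culture_id"] == cid].sort_values("day")
        series = GrowthSeries(cid, g["day"].to_numpy(), g["fluorescence"].to_numpy())
        mu_max = max_growth_rate(series)

        lc = light_curves[light_curves["culture_id"] == cid].sort_values("irradiance")
        curve = LightCurve(cid, lc["irradiance"].to_numpy(), lc["etr"].to_numpy())
        fit = fit_light_curve(curve, model=pi_model)

        esd = fsc_to_esd(float(s["fsc_median"]), cal)
        summary = CytometrySummary(
            culture_id=cid,
            fsc_median=float(s["fsc_median"]),
            chl_median=float(s["chl_median"]),
            ssc_median=float(s["ssc_median"]),
            prestain_median=float(s["prestain_median"]),
            poststain_median=float(s["poststain_median"]),
            ros_stained=float(s["ros_stained"]),
            ros_blank=float(s["ros_blank"]),
            cell_count=float(s["cell_count"]),
        )
        fcm_traits = derive_fcm_traits(summary, esd)
        rows.append(
            {
                "strain_id": s["strain_id"],
                "species": s["species"],
                "replicate": s["replicate"],
                "environment": s["environment"],
                "growth_rate": mu_max,
                **fcm_traits,
                "alpha": fit.alpha,
                "etrmax": fit.etrmax,
                "ik": fit.ik,
            }
        )
    return pd.DataFrame(rows)


def derive_trait_table_from_csvs(indir: str | Path, pi_model: str = "tanh") -> pd.DataFrame:
    """Convenience: read growth.csv, light_curves.csv, beads.csv and fcm.csv
    from a directory and derive the trait table."""
    indir = Path(indir)
    return derive_trait_table(
        growth=pd.read_csv(indir / "growth.csv"),
        light_curves=pd.read_csv(indir / "light_curves.csv"),
        beads=pd.read_csv(indir / "beads.csv"),
        fcm=pd.read_csv(indir / "fcm.csv"),
        pi_model=pi_model,
    )
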