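"""One-step growth parameter estimation from qPCR genome-copy time series.

Converts qPCR plates into copies/ml via a standard curve, then estimates the
parameters of the one-step growth experiment: latent period (fold-threshold
crossing of the extracellular signal, log-interpolated), burst size
(extracellular plateau minus baseline per infected cell), intracellular DNA
synthesis rate, and between-condition comparisons.

Replicates are aggregated by geometric mean (lognormal error model);
bootstrap confidence intervals resample replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import QpcrPlate, TimeSeriesTable

__all__ = [
    "StandardCurve",
    "GrowthParams",
    "LatentEstimate",
    "NoBurstError",
    "poisson_infected",
    "fit_standard_curve",
    "quantify",
    "estimate_latent_period",
    "estimate_burst_size",
    "dna_synthesis_rate",
    "estimate_growth_params",
    "compare_conditions",
]


class NoBurstError(RuntimeError):
    """No burst detected: the series never crosses the rise threshold."""


def poisson_infected(cells_per_ml: float, moi: float) -> float:
    """Infected-cell density under Poisson adsorption: cells*(1-exp(-moi))."""
    return cells_per_ml * (1.0 - np.exp(-moi))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares CT vs log10(copies) calibration line.

    efficiency E = 10^(-1/slope); a usable assay has E in (1, 2.1] and
    values outside (1.8, 2.05) trigger a warning.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not 1.0 < self.efficiency <= 2.1:
            raise ValueError(
                f"amplification efficiency {self.efficiency:.3f} outside (1, 2.1]"
            )
        if not 1.8 < self.efficiency < 2.05:
            warnings.warn(
                f"amplification efficiency {self.efficiency:.3f} outside (1.8, 2.05)",
                stacklevel=3,
            )


def fit_standard_curve(standards) -> StandardCurve:
    """Fit the dilution series: CT regressed on log10(known copies).

    ``standards`` is an iterable of (known_copies, ct) pairs or a QpcrPlate
    (its standard wells are used). Replicate CTs enter individually, not
    pre-averaged. Requires >= 3 distinct dilution levels.
    """
    if isinstance(standards, QpcrPlate):
        std = standards.standards().dropna(subset=["ct"])
        pairs = list(zip(std["known_copies"], std["ct"]))
    else:
        pairs = list(standards)
    copies = np.array([p[0] for p in pairs], dtype=float)
    cts = np.array([p[1] for p in pairs], dtype=float)
    if (copies <= 0).any():
        raise ValueError("standard copies must be > 0")
    if np.unique(copies).size < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.log10(copies)
    fit = stats.linregress(x, cts)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        r_squared=float(fit.rvalue**2),
    )


def quantify(plate: QpcrPlate, curve: StandardCurve, dilution_factor: float = 1.0) -> pd.DataFrame:
    """Copies/ml for every unknown well: dilution * 10^((ct - intercept)/slope).

    Missing CT propagates to missing copies (NaN), never zero.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    unknowns = plate.unknowns().copy()
    ct = unknowns["ct"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        copies = dilution_factor * 10.0 ** ((ct - curve.intercept) / curve.slope)
    unknowns["copies_per_ml"] = copies
    return unknowns.reset_index(drop=True)


def _geomean_by_time(df: pd.DataFrame) -> pd.Series:
    """Geometric mean of copies across replicates, indexed by time."""
    positive = df[df["copies_per_ml"] > 0]
    if positive.empty:
        raise ValueError("no positive copy values")
    return (
        positive.groupby("time_h")["copies_per_ml"]
        .apply(lambda v: float(np.exp(np.mean(np.log(v)))))
        .sort_index()
    )


@dataclass(frozen=True)
class LatentEstimate:
    hours: float
    ci_low: float
    ci_high: float
    baseline: float
    threshold: float


def _crossing_time(series: pd.Series, threshold: float) -> float | None:
    """First crossing of the threshold, log10-interpolated between samples."""
    times = series.index.to_numpy(dtype=float)
    values = series.to_numpy(dtype=float)
    above = values >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    v0, v1 = values[k - 1], values[k]
    frac = (np.log10(threshold) - np.log10(v0)) / (np.log10(v1) - np.log10(v0))
    return float(t0 + (t1 - t0) * frac)


def estimate_latent_period(
    extracellular: TimeSeriesTable,
    condition: str,
    rise_threshold_fold: float = 2.0,
    baseline_points: int = 3,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> LatentEstimate:
    """Latent period as the first fold-threshold crossing of free phage.

    The baseline is the geometric mean over the first ``baseline_points``
    sampling times; the latent period is the first time the
    replicate-aggregated series reaches baseline * rise_threshold_fold,
    linearly interpolated in log10 space between bracketing samples. The CI
    is a seeded percentile bootstrap over replicates.
    """
    df = extracellular.select(condition=condition, compartment="extracellular")
    if df.empty:
        raise ValueError(f"no extracellular data for condition {condition!r}")
    times = np.sort(df["time_h"].unique())
    if times.size < 5:
        raise ValueError("need >= 5 time points")
    if baseline_points >= times.size:
        raise ValueError("baseline_points must be < number of time points")

    def estimate(frame: pd.DataFrame) -> float | None:
        series = _geomean_by_time(frame)
        base = float(np.exp(np.mean(np.log(series.iloc[:baseline_points]))))
        return _crossing_time(series, base * rise_threshold_fold)

    series = _geomean_by_time(df)
    baseline = float(np.exp(np.mean(np.log(series.iloc[:baseline_points]))))
    point = _crossing_time(series, baseline * rise_threshold_fold)
    if point is None:
        raise NoBurstError(f"no burst detected for condition {condition!r}")

    reps = df["replicate"].unique()
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_bootstrap):
        chosen = rng.choice(reps, size=reps.size, replace=True)
        parts = [
            df[df["replicate"] == r].assign(replicate=i) for i, r in enumerate(chosen)
        ]
        est = estimate(pd.concat(parts, ignore_index=True))
        if est is not None:
            boot.append(est)
    if boot:
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:
        lo = hi = point
    return LatentEstimate(
        hours=point,
        ci_low=float(lo),
        ci_high=float(hi),
        baseline=baseline,
        threshold=baseline * rise_threshold_fold,
    )


def estimate_burst_size(
    extracellular: TimeSeriesTable,
    condition: str,
    n_infected: float,
    plateau_points: int = 2,
    baseline_points: int = 3,
) -> float:
    """Burst size = (plateau - baseline) free phage per infected cell.

    Plateau is the arithmetic mean of the replicate-aggregated values at the
    last ``plateau_points`` sampling times. A negative difference clips to 0
    with a warning.
    """
    if n_infected <= 0:
        raise ValueError("n_infected must be > 0")
    df = extracellular.select(condition=condition, compartment="extracellular")
    series = _geomean_by_time(df)
    baseline = float(np.exp(np.mean(np.log(series.iloc[:baseline_points]))))
    plateau = float(series.iloc[-plateau_points:].mean())
    diff = plateau - baseline
    if diff < 0:
        warnings.warn("plateau below baseline; burst size clipped to 0", stacklevel=2)
        return 0.0
    return diff / n_infected


def dna_synthesis_rate(
    intracellular: TimeSeriesTable,
    condition: str,
    n_infected: float,
    rise_fold: float = 1.5,
) -> float:
    """Intracellular DNA synthesis rate in genome copies per infected cell per hour.

    The rise window runs from the first sample exceeding ``rise_fold`` times
    the t0 value to the sample of maximum signal; the rate is the
    least-squares slope of per-cell copies against time over that window.
    """
    if n_infected <= 0:
        raise ValueError("n_infected must be > 0")
    df = intracellular.select(condition=condition, compartment="intracellular")
    series = _geomean_by_time(df)
    values = series.to_numpy(dtype=float)
    times = series.index.to_numpy(dtype=float)
    start_candidates = np.flatnonzero(values > rise_fold * values[0])
    if start_candidates.size == 0:
        raise NoBurstError("no rise in intracellular signal")
    start = int(start_candidates[0])
    end = int(np.argmax(values))
    if end - start + 1 < 2:
        raise NoBurstError("rise window too short to fit a slope")
    window_t = times[start : end + 1]
    window_v = values[start : end + 1] / n_infected
    fit = stats.linregress(window_t, window_v)
    return float(fit.slope)


@dataclass(frozen=True)
class GrowthParams:
    """One-step growth parameters for one condition."""

    condition: str
    latent_period_h: float
    burst_size: float
    dna_rate: float
    baseline_extracellular: float
    plateau_extracellular: float
    n_infected: float


def estimate_growth_params(
    timeseries: TimeSeriesTable,
    condition: str,
    n_infected: float,
    rise_threshold_fold: float = 2.0,
    seed: int = 0,
) -> GrowthParams:
    """Run all three estimators for one condition and bundle the results."""
    latent = estimate_latent_period(
        timeseries, condition, rise_threshold_fold=rise_threshold_fold, seed=seed
    )
    burst = estimate_burst_size(timeseries, condition, n_infected=n_infected)
    try:
        rate = dna_synthesis_rate(timeseries, condition, n_infected=n_infected)
    except NoBurstError:
        rate = float("nan")
    ext = timeseries.select(condition=condition, compartment="extracellular")
    series = _geomean_by_time(ext)
    return GrowthParams(
        condition=condition,
        latent_period_h=latent.hours,
        burst_size=burst,
        dna_rate=rate,
        baseline_extracellular=latent.baseline,
        plateau_extracellular=float(series.iloc[-2:].mean()),
        n_infected=n_infected,
    )


def compare_conditions(a: GrowthParams, b: GrowthParams) -> dict[str, float]:
    """Changes of ``a`` relative to the reference condition ``b``.

    latent_change_pct = 100*(a.latent - b.latent)/b.latent, so a shortened
    latent period under ``a`` is negative (e.g. -40% for 7.5 h vs 12.5 h).
    """
    if b.latent_period_h == 0:
        raise ValueError("reference latent period is 0")
    return {
        "latent_change_h": a.latent_period_h - b.latent_period_h,
        "latent_change_pct": 100.0 * (a.latent_period_h - b.latent_period_h) / b.latent_period_h,
        "burst_ratio": a.burst_size / b.burst_size if b.burst_size else float("nan"),
        "rate_ratio": a.dna_rate / b.dna_rate if b.dna_rate else float("nan"),
    }
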