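"""PSII maximum quantum yield (Fv/Fm) and photoinhibition kinetics.

Fv/Fm = (Fm - F0)/Fm from dark-adapted pulse-amplitude-modulated
fluorescence: F0 is the basal fluorescence with all reaction centres open,
Fm the maximum with the primary acceptor fully reduced. Values live in
[0, 1); photoinhibition under high light is fitted as a single-exponential
decay to a plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_formats import FluorescenceTable

__all__ = [
    "compute_fvfm",
    "fvfm_series",
    "normalise_to_t0",
    "PhotoinhibitionFit",
    "fit_photoinhibition",
]


def compute_fvfm(f0, fm):
    """(Fm - F0)/Fm. Scalar or array; F0 > Fm is an instrument artefact."""
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if (fm <= 0).any():
        raise ValueError("Fm must be > 0")
    if (f0 < 0).any():
        raise ValueError("F0 must be >= 0")
    if (f0 > fm).any():
        raise ValueError("F0 > Fm: instrument artefact")
    out = (fm - f0) / fm
    return float(out) if out.ndim == 0 else out


def fvfm_series(table: FluorescenceTable) -> pd.DataFrame:
    """Row-wise Fv/Fm for a fluorescence table."""
    df = table.df.copy()
    df["fvfm"] = compute_fvfm(df["f0"].to_numpy(), df["fm"].to_numpy())
    return df


def normalise_to_t0(series: pd.DataFrame) -> pd.DataFrame:
    """Divide each replicate's Fv/Fm by its own t = 0 value.

    Replicate identity is (condition, replicate, infected). Idempotent up to
    floating point: after one application every t = 0 value is 1.
    """
    required = {"time_h", "condition", "replicate", "infected", "fvfm"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns {sorted(missing)}")
    out = series.copy()
    for key, group in out.groupby(["condition", "replicate", "infected"]):
        t0 = group[group["time_h"] == 0]
        if t0.empty or not (t0["fvfm"] > 0).all():
            raise ValueError(f"replicate {key}: no t=0 row with fvfm > 0")
        out.loc[group.index, "fvfm"] = group["fvfm"] / float(t0["fvfm"].iloc[0])
    return out


@dataclass(frozen=True)
class PhotoinhibitionFit:
    """y(t) = y_inf + (y0 - y_inf) * exp(-k t), nonlinear least squares."""

    k: float
    y0: float
    y_inf: float
    rss: float


def fit_photoinhibition(times, values, max_iterations: int = 500) -> PhotoinhibitionFit:
    """Fit the exponential photoinhibition decay to an Fv/Fm trajectory.

    Initialisation: y0 from the first value, y_inf from the last, k from a
    log-linear pre-fit of the decay amplitude. Parameters are bounded
    (k >= 0, 0 <= y_inf <= y0); non-convergence raises RuntimeError.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 time points")
    order = np.argsort(t)
    t, y = t[order], y[order]

    y0_init = float(y[0])
    yinf_init = float(y[-1])
    amplitude = y[: max(2, t.size // 2)] - yinf_init
    positive = amplitude > 0
    if positive.sum() >= 2 and y0_init > yinf_init:
        pre = np.polyfit(t[: len(amplitude)][positive], np.log(amplitude[positive]), 1)
        k_init = max(1e-6, float(-pre[0]))
    else:
        k_init = 1e-3  # flat or non-decaying series

    def model(tt, k, y0, y_inf):
        return y_inf + (y0 - y_inf) * np.exp(-k * tt)

    params, _ = curve_fit(
        model,
        t,
        y,
        p0=[k_init, y0_init, max(yinf_init, 1e-9)],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=max_iterations * 10,
        xtol=1e-8,
        ftol=1e-12,
    )
    k, y0, y_inf = (float(p) for p in params)
    rss = float(np.sum((y - model(t, k, y0, y_inf)) ** 2))
    return PhotoinhibitionFit(k=k, y0=y0, y_inf=y_inf, rss=rss)
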