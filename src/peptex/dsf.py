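"""Differential scanning fluorimetry: thermal melts and T_m extraction.

Melt curves follow a two-state Boltzmann sigmoid
``f(T) = f_min + (f_max - f_min) / (1 + exp((tm - T) / slope))`` scanned
1 degC per step between 25 and 95 degC; the melting temperature is the
inflection point.  A helper correlates melting temperatures with
competition IC50 values (log10 scale) across a peptide series, the
package's stand-in for the stability-versus-loading comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "TmIc50Correlation",
    "simulate_melt",
    "fit_tm",
    "correlate_tm_ic50",
]

SCAN_MIN_C = 25.0
SCAN_MAX_C = 95.0


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence versus temperature for one melt."""

    temperature_C: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperature_C, float)
        s = np.asarray(self.signal, float)
        if t.shape != s.shape:
            raise ValueError("temperature and signal must match")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if t.min() < SCAN_MIN_C - 1e-9 or t.max() > SCAN_MAX_C + 1e-9:
            raise ValueError(f"temperatures must lie within [{SCAN_MIN_C}, {SCAN_MAX_C}] degC")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "signal", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature_C": self.temperature_C, "signal": self.signal})

    def to_csv(self, path, replicate: int = 1) -> None:
        df = self.to_frame()
        df["replicate"] = replicate
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeltCurve":
        df = pd.read_csv(path)
        if "replicate" in df:
            df = df.groupby("temperature_C", as_index=False)["signal"].mean()
        return cls(df["temperature_C"].to_numpy(float), df["signal"].to_numpy(float))


@dataclass(frozen=True)
class BoltzmannFit:
    tm: float
    slope: float
    f_min: float
    f_max: float
    tm_stderr: float
    slope_stderr: float
    rss: float
    unidentifiable: bool = False


def boltzmann(t: np.ndarray, tm: float, slope: float, f_min: float, f_max: float) -> np.ndarray:
    with np.errstate(over="ignore"):  # saturates cleanly for sharp transitions
        return f_min + (f_max - f_min) / (1 + np.exp((tm - np.asarray(t, float)) / slope))


def simulate_melt(
    tm: float,
    slope: float = 2.0,
    f_min: float = 0.0,
    f_max: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    temperatures: np.ndarray | None = None,
) -> MeltCurve:
    """Simulate one melt curve; ``noise_sd`` is additive Gaussian per reading.

    ``slope`` is the transition width in degC (must be positive); a midpoint
    outside the scan range is simulated anyway with a warning since the
    transition will be truncated.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if not (SCAN_MIN_C <= tm <= SCAN_MAX_C):
        warnings.warn(f"tm {tm} degC lies outside the {SCAN_MIN_C}-{SCAN_MAX_C} scan range", stacklevel=2)
    t = np.arange(SCAN_MIN_C, SCAN_MAX_C + 0.5, 1.0) if temperatures is None else np.asarray(temperatures, float)
    signal = boltzmann(t, tm, slope, f_min, f_max)
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return MeltCurve(t, signal)


def fit_tm(curve: MeltCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit; T_m is the sigmoid inflection."""
    if len(curve.signal) < 10:
        raise ValueError("need at least 10 points spanning the transition")
    t, y = curve.temperature_C, curve.signal
    span = float(np.ptp(y))
    noise_guess = float(np.std(np.diff(y))) / np.sqrt(2)
    if span == 0 or span < 3 * noise_guess:
        return BoltzmannFit(np.nan, np.nan, float(np.min(y)), float(np.max(y)), np.nan, np.nan, 0.0, True)

    params = lmfit.Parameters()
    half = (np.min(y) + np.max(y)) / 2
    tm0 = float(t[np.argmin(np.abs(y - half))])
    params.add("tm", value=tm0, min=t.min() - 20, max=t.max() + 20)
    params.add("slope", value=2.0, min=1e-3, max=50)
    params.add("f_min", value=float(np.min(y)))
    params.add("span", value=span, min=0)

    def residuals(p):
        return boltzmann(t, p["tm"], p["slope"], p["f_min"], p["f_min"] + p["span"]) - y

    result = lmfit.minimize(residuals, params, method="leastsq")
    p = result.params

    def err(name):
        s = p[name].stderr
        return float(s) if s is not None else np.nan

    # transition amplitude indistinguishable from residual noise -> no T_m
    resid_sd = np.sqrt(result.chisqr / max(result.nfree, 1))
    unident = float(p["span"].value) < 3 * resid_sd
    return BoltzmannFit(
        tm=float(p["tm"].value),
        slope=float(p["slope"].value),
        f_min=float(p["f_min"].value),
        f_max=float(p["f_min"].value + p["span"].value),
        tm_stderr=err("tm"),
        slope_stderr=err("slope"),
        rss=float(result.chisqr),
        unidentifiable=bool(unident),
    )


@dataclass(frozen=True)
class TmIc50Correlation:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def correlate_tm_ic50(tm_list, ic50_list) -> TmIc50Correlation:
    """Linear regression of log10(IC50) on T_m across a peptide series."""
    tm = np.asarray(tm_list, float)
    ic50 = np.asarray(ic50_list, float)
    if tm.shape != ic50.shape or tm.size < 3:
        raise ValueError("need matched lists of at least 3 values")
    if np.ptp(tm) == 0:
        raise ValueError("degenerate T_m variance")
    res = stats.linregress(tm, np.log10(ic50))
    return TmIc50Correlation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
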