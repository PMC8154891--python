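"""Fluorescence-polarization competition and titration assays.

A TAMRA-labelled tracer peptide reports on its own binding state: free
tracer tumbles fast (low polarization), tracer inside any MHC-I-containing
complex — binary pMHC-I or the ternary pMHC-I/chaperone complex, both
~50-100 kDa — tumbles slowly (high polarization).  Polarization mixes
linearly in the bound fraction, and readings are background-subtracted
against tracer alone, so the reported signal is
``(mp_bound - mp_free) * bound_fraction``.

Two competition regimes isolate different cycle steps:

* substoichiometric — MHC-I/chaperone complex diluted below the kd of the
  chaperone interaction and no free chaperone added, so incoming peptide
  strips the chaperone off and the IC50 tracks peptide binding to empty
  MHC-I (cycle step 2);
* stoichiometric — 1 uM excess free chaperone keeps the MHC-I chaperoned,
  so the IC50 tracks peptide capture by the chaperoned groove (step 4).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .cycle import PeptideAffinities, SolverError, SpeciesTotals, solve_equilibrium

__all__ = [
    "CompetitionAssay",
    "PolarizationCurve",
    "FourPLFit",
    "SaturationFit",
    "SUBSTOICH_GRID",
    "STOICH_GRID",
    "KD3_TAPBPR_GRID",
    "simulate_competition",
    "fit_ic50",
    "simulate_kd3_titration",
    "fit_saturation",
]

NM = 1e-9
UM = 1e-6

#: competitor grids of the two competition designs (molar)
SUBSTOICH_GRID = tuple(c * NM for c in (0, 2.5, 5, 10, 25, 50, 100, 500, 1000, 2000, 3000, 4000, 5000))
STOICH_GRID = tuple(
    c * NM for c in (0, 10, 50, 250, 500, 1000, 2000, 3000, 4000, 6000, 8000, 10000, 50000, 100000)
)
#: chaperone titration grid of the saturation design (molar)
KD3_TAPBPR_GRID = tuple(c * UM for c in (0, 0.1, 2, 4, 10, 30, 50, 80))


@dataclass(frozen=True)
class CompetitionAssay:
    """Composition of one FP competition plate."""

    competitor_id: str
    competitor_grid: Sequence[float]
    tracer_id: str = "tracer"
    tracer_total: float = 1 * NM
    complex_total: float = 50 * NM
    excess_tapbpr: float = 0.0

    def __post_init__(self):
        grid = tuple(float(c) for c in self.competitor_grid)
        object.__setattr__(self, "competitor_grid", grid)
        if self.tracer_total <= 0:
            raise ValueError("tracer_total must be positive")
        if any(c < 0 for c in grid):
            raise ValueError("competitor grid must be non-negative")
        if any(b < a for a, b in zip(grid, grid[1:])):
            raise ValueError("competitor grid must be sorted ascending")

    @classmethod
    def substoichiometric(cls, competitor_id: str, **kw) -> "CompetitionAssay":
        kw.setdefault("competitor_grid", SUBSTOICH_GRID)
        return cls(competitor_id=competitor_id, excess_tapbpr=0.0, **kw)

    @classmethod
    def stoichiometric(cls, competitor_id: str, **kw) -> "CompetitionAssay":
        kw.setdefault("competitor_grid", STOICH_GRID)
        return cls(competitor_id=competitor_id, excess_tapbpr=1 * UM, **kw)


@dataclass(frozen=True)
class PolarizationCurve:
    """Background-subtracted polarization (mP) versus competitor concentration."""

    concentration_M: np.ndarray
    mp: np.ndarray

    def __post_init__(self):
        conc = np.asarray(self.concentration_M, float)
        mp = np.asarray(self.mp, float)
        if conc.shape != mp.shape:
            raise ValueError("concentration and mP arrays must match")
        if not np.all(np.isfinite(mp)):
            raise ValueError("mP values must be finite")
        order = np.argsort(conc, kind="stable")
        object.__setattr__(self, "concentration_M", conc[order])
        object.__setattr__(self, "mp", mp[order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"competitor_nM": self.concentration_M / NM, "mp": self.mp})

    def to_csv(self, path, replicate: int = 1) -> None:
        df = self.to_frame()
        df["replicate"] = replicate
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PolarizationCurve":
        df = pd.read_csv(path)
        if "replicate" in df:
            df = df.groupby("competitor_nM", as_index=False)["mp"].mean()
        return cls(df["competitor_nM"].to_numpy(float) * NM, df["mp"].to_numpy(float))


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit of a competition curve."""

    top: float
    bottom: float
    hill: float
    ic50: float
    top_stderr: float
    bottom_stderr: float
    hill_stderr: float
    ic50_stderr: float
    rss: float
    unidentifiable: bool = False


@dataclass(frozen=True)
class SaturationFit:
    """One-site saturation fit (mP versus titrant) yielding an apparent kd."""

    kd: float
    amplitude: float
    baseline: float
    kd_stderr: float
    rss: float


def _tracer_bound_fraction(
    totals: SpeciesTotals, kd1: float, affinities, tracer_id: str
) -> float:
    state = solve_equilibrium(totals, kd1, affinities)
    total = totals.peptide_totals[tracer_id]
    return (state.mp[tracer_id] + state.mpt[tracer_id]) / total


def simulate_competition(
    assay: CompetitionAssay,
    kd1: float,
    tracer_aff: PeptideAffinities,
    competitor_aff: PeptideAffinities,
    mp_free: float = 20.0,
    mp_bound: float = 200.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PolarizationCurve:
    """Solve the two-peptide equilibrium at every grid point and read out mP.

    Returned values are background-subtracted (tracer alone reads 0), so the
    noiseless signal is ``(mp_bound - mp_free) * fraction of tracer bound``.
    """
    if assay.tracer_total > 0.1 * assay.complex_total and assay.complex_total > 0:
        warnings.warn(
            "tracer is not much below the complex concentration; IC50 values will "
            "be depletion-shifted",
            stacklevel=2,
        )
    tracer_aff = _as_tracer(tracer_aff, assay.tracer_id)
    rng = np.random.default_rng(seed)
    mps = []
    for conc in assay.competitor_grid:
        peptides = {assay.tracer_id: assay.tracer_total}
        if conc > 0:
            peptides[assay.competitor_id] = conc
        totals = SpeciesTotals(
            mhc_total=assay.complex_total,
            tapbpr_total=assay.complex_total + assay.excess_tapbpr,
            peptide_totals=peptides,
        )
        try:
            frac = _tracer_bound_fraction(totals, kd1, [tracer_aff, competitor_aff], assay.tracer_id)
        except SolverError as exc:
            raise SolverError(
                f"equilibrium failed at competitor {conc:g} M of {assay.competitor_id!r}",
                exc.residual,
            ) from exc
        mp = (mp_bound - mp_free) * frac
        if noise_sd > 0:
            mp += rng.normal(0.0, noise_sd)
        mps.append(mp)
    return PolarizationCurve(np.array(assay.competitor_grid), np.array(mps))


def _as_tracer(aff: PeptideAffinities, tracer_id: str) -> PeptideAffinities:
    if aff.peptide_id == tracer_id:
        return aff
    return PeptideAffinities(tracer_id, aff.kd2, aff.kd3, aff.kd4, aff.dh2, aff.dh3, aff.dh4)


def _log_floor(conc: np.ndarray) -> np.ndarray:
    """Place zero concentrations at one tenth of the smallest nonzero point."""
    conc = np.asarray(conc, float)
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError("curve has no nonzero concentrations")
    return np.where(conc > 0, conc, nonzero.min() / 10)


def fit_ic50(curve: PolarizationCurve, hill_bounds: tuple[float, float] = (0.5, 3.0)) -> FourPLFit:
    """Least-squares 4-parameter logistic fit in log10 concentration.

    ``y = bottom + (top - bottom) / (1 + (x / ic50)^hill)`` for a descending
    competition curve; the Hill slope is free within ``hill_bounds``.
    """
    if len(curve.mp) < 6:
        raise ValueError("need at least 6 grid points to fit an IC50")
    x = _log_floor(curve.concentration_M)
    logx = np.log10(x)
    y = curve.mp

    span = float(np.ptp(y))
    noise_guess = float(np.std(np.diff(y))) / math.sqrt(2) if len(y) > 3 else 0.0
    if span == 0 or (noise_guess > 0 and span < 3 * noise_guess):
        return FourPLFit(
            float(np.max(y)), float(np.min(y)), np.nan, np.nan,
            np.nan, np.nan, np.nan, np.nan, 0.0, unidentifiable=True,
        )

    params = lmfit.Parameters()
    params.add("top", value=float(np.max(y)))
    params.add("bottom", value=float(np.min(y)))
    params.add("hill", value=1.0, min=hill_bounds[0], max=hill_bounds[1])
    params.add("logic50", value=float(np.median(logx)), min=logx.min() - 2, max=logx.max() + 2)

    def residuals(p):
        model = p["bottom"] + (p["top"] - p["bottom"]) / (
            1 + 10 ** ((logx - p["logic50"]) * p["hill"])
        )
        return model - y

    # multistart over the midpoint: the 4PL surface has local minima when the
    # transition amplitude is close to the noise floor
    result = None
    for start in np.linspace(logx.min(), logx.max(), 7):
        params["logic50"].value = start
        try:
            candidate = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:
            continue
        if result is None or candidate.chisqr < result.chisqr:
            result = candidate
    if result is None:
        raise RuntimeError("4PL fit did not converge from any start")
    p = result.params

    def err(name, transform=lambda v: v):
        s = p[name].stderr
        return float(s) if s is not None else np.nan

    ic50 = float(10 ** p["logic50"].value)
    lse = err("logic50")
    ic50_stderr = ic50 * math.log(10) * lse if np.isfinite(lse) else np.nan
    return FourPLFit(
        top=float(p["top"].value),
        bottom=float(p["bottom"].value),
        hill=float(p["hill"].value),
        ic50=ic50,
        top_stderr=err("top"),
        bottom_stderr=err("bottom"),
        hill_stderr=err("hill"),
        ic50_stderr=ic50_stderr,
        rss=float(result.chisqr),
    )


def simulate_kd3_titration(
    kd1: float,
    loaded_aff: PeptideAffinities,
    tracer_aff: PeptideAffinities,
    tapbpr_grid: Sequence[float] = KD3_TAPBPR_GRID,
    tracer_total: float = 1 * NM,
    pmhc_total: float = 50 * NM,
    mp_free: float = 20.0,
    mp_bound: float = 200.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PolarizationCurve:
    """Titrate chaperone into a loaded pMHC-I plus tracer mixture.

    The chaperone bridges tracer into slow-tumbling ternary complexes, so mP
    rises and saturates with an apparent kd reporting chaperone binding to
    pMHC-I (cycle step 3).
    """
    tracer_aff = _as_tracer(tracer_aff, "tracer")
    rng = np.random.default_rng(seed)
    mps = []
    for t_tot in tapbpr_grid:
        totals = SpeciesTotals(
            mhc_total=pmhc_total,
            tapbpr_total=t_tot,
            peptide_totals={"tracer": tracer_total, loaded_aff.peptide_id: pmhc_total},
        )
        frac = _tracer_bound_fraction(totals, kd1, [tracer_aff, loaded_aff], "tracer")
        mp = (mp_bound - mp_free) * frac
        if noise_sd > 0:
            mp += rng.normal(0.0, noise_sd)
        mps.append(mp)
    return PolarizationCurve(np.array(list(tapbpr_grid)), np.array(mps))


def fit_saturation(curve: PolarizationCurve) -> SaturationFit:
    """One-site saturation fit ``mp = baseline + amplitude * x / (kd + x)``."""
    x = curve.concentration_M
    y = curve.mp
    params = lmfit.Parameters()
    params.add("baseline", value=float(y[0]))
    params.add("amplitude", value=float(y[-1] - y[0]))
    nonzero = x[x > 0]
    params.add("kd", value=float(np.median(nonzero)), min=1e-12, max=1.0)

    def residuals(p):
        return p["baseline"] + p["amplitude"] * x / (p["kd"] + x) - y

    result = lmfit.minimize(residuals, params, method="leastsq")
    p = result.params
    stderr = p["kd"].stderr
    return SaturationFit(
        kd=float(p["kd"].value),
        amplitude=float(p["amplitude"].value),
        baseline=float(p["baseline"].value),
        kd_stderr=float(stderr) if stderr is not None else np.nan,
        rss=float(result.chisqr),
    )
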