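"""Isothermal titration calorimetry: forward simulation and one-site fitting.

Three titration designs isolate different steps of the exchange cycle:

* ``KD2`` — peptide titrated into the peptide-deficient MHC-I/chaperone
  complex with no excess chaperone, so incoming peptide displaces the
  chaperone and the heats report (apparent) peptide binding to empty MHC-I.
* ``KD3`` — peptide-loaded MHC-I titrated into chaperone with a large excess
  of free peptide in both cell and syringe, so the only net reaction is
  ternary-complex formation.
* ``KD4`` — peptide titrated into the MHC-I/chaperone complex with excess
  free chaperone, keeping the MHC-I chaperone-bound so the heats report
  peptide binding to the chaperoned groove.

Heats are referenced against a pure-dilution baseline (the standard control
subtraction of a titration into buffer): the cumulative heat after injection
``i`` is ``V0 * sum_s dH_s * ([complex_s]_i - [complex_s]_i^dilution)``, where
the dilution trajectory mixes cell and syringe without re-equilibration.
Injection displacement follows the continuous-perfusion model (totals decay
by ``exp(-dV/V0)`` per injection), which makes simulated heats exactly
additive when an injection is split in two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .cycle import (
    CycleError,
    PeptideAffinities,
    SpeciesTotals,
    solve_equilibrium,
)

__all__ = [
    "TitrationProtocol",
    "Isotherm",
    "OneSiteFit",
    "preset_protocol",
    "simulate_titration",
    "fit_one_site",
    "wiseman_heats",
]

KCAL_TO_UCAL = 1e9

#: nominal VP-ITC cell volume (L)
DEFAULT_CELL_VOLUME = 1.4e-3
DEFAULT_INJECTION_VOLUME = 10e-6
DEFAULT_N_INJECTIONS = 28


@dataclass(frozen=True)
class TitrationProtocol:
    """Geometry and composition of one titration experiment."""

    cell: SpeciesTotals
    syringe: SpeciesTotals
    cell_volume: float = DEFAULT_CELL_VOLUME
    injection_volume: float = DEFAULT_INJECTION_VOLUME
    n_injections: int = DEFAULT_N_INJECTIONS
    temperature: float = 25.0
    #: component whose cumulative concentration defines the molar-ratio axis
    titrant: str = "peptide"
    #: cell component the ratio is normalised against
    macromolecule: str = "mhc"
    #: peptide id used when titrant/macromolecule refer to a peptide
    peptide_id: str | None = None

    def __post_init__(self):
        if self.cell_volume <= 0 or self.injection_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.n_injections < 2:
            raise ValueError("need at least two injections")
        if self.n_injections * self.injection_volume >= self.cell_volume:
            raise ValueError("total injected volume must stay below the cell volume")

    def component_conc(self, totals: SpeciesTotals, component: str) -> float:
        if component == "mhc":
            return totals.mhc_total
        if component == "tapbpr":
            return totals.tapbpr_total
        if component == "peptide":
            return totals.peptide_totals.get(self.peptide_id, 0.0)
        raise ValueError(f"unknown component {component!r}")


@dataclass(frozen=True)
class Isotherm:
    """Per-injection heats with the metadata needed for refitting.

    ``macromolecule_M``/``titrant_M`` are the running in-cell concentrations
    after each injection (perfusion-diluted), which the one-site fit model
    consumes directly.
    """

    molar_ratio: np.ndarray
    heat_ucal: np.ndarray
    ndh_kcal_per_mol: np.ndarray
    macromolecule_M: np.ndarray
    titrant_M: np.ndarray
    cell_volume: float = DEFAULT_CELL_VOLUME

    def __post_init__(self):
        n = len(self.heat_ucal)
        for name in ("molar_ratio", "ndh_kcal_per_mol", "macromolecule_M", "titrant_M"):
            if len(getattr(self, name)) != n:
                raise ValueError("isotherm columns must share one length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar ratio must be strictly increasing")

    def __len__(self) -> int:
        return len(self.heat_ucal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_index": np.arange(1, len(self) + 1),
                "molar_ratio": self.molar_ratio,
                "heat_ucal": self.heat_ucal,
                "ndh_kcal_per_mol": self.ndh_kcal_per_mol,
                "macromolecule_M": self.macromolecule_M,
                "titrant_M": self.titrant_M,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell_volume: float = DEFAULT_CELL_VOLUME) -> "Isotherm":
        df = pd.read_csv(path)
        return cls(
            molar_ratio=df["molar_ratio"].to_numpy(float),
            heat_ucal=df["heat_ucal"].to_numpy(float),
            ndh_kcal_per_mol=df["ndh_kcal_per_mol"].to_numpy(float),
            macromolecule_M=df["macromolecule_M"].to_numpy(float),
            titrant_M=df["titrant_M"].to_numpy(float),
            cell_volume=cell_volume,
        )


@dataclass(frozen=True)
class OneSiteFit:
    """Result of a one-site binding fit: stoichiometry, kd, enthalpy."""

    n: float
    kd: float
    dh: float
    n_stderr: float
    kd_stderr: float
    dh_stderr: float
    rss: float
    n_points: int
    unidentifiable: bool = False


def preset_protocol(step: str, peptide_id: str = "TAX9") -> TitrationProtocol:
    """Titration compositions for the three cycle-step designs.

    Concentration ranges quoted as intervals in the experimental design are
    taken at their midpoints (peptide syringe 75 uM for the KD2 design,
    150-200 uM ranges at 175 uM).
    """
    step = step.upper()
    uM = 1e-6
    if step == "KD2":
        # 15 uM 1:1 peptide-deficient MHC-I/chaperone complex; peptide syringe
        cell = SpeciesTotals(mhc_total=15 * uM, tapbpr_total=15 * uM)
        syringe = SpeciesTotals(peptide_totals={peptide_id: 75 * uM})
        return TitrationProtocol(cell, syringe, titrant="peptide", macromolecule="mhc", peptide_id=peptide_id)
    if step == "KD3":
        # pMHC-I titrated into chaperone; 1 mM free peptide on both sides
        cell = SpeciesTotals(tapbpr_total=15 * uM, peptide_totals={peptide_id: 1e-3})
        syringe = SpeciesTotals(mhc_total=175 * uM, peptide_totals={peptide_id: 1e-3 + 175 * uM})
        return TitrationProtocol(cell, syringe, titrant="mhc", macromolecule="tapbpr", peptide_id=peptide_id)
    if step == "KD4":
        # complex plus 50 uM excess chaperone; peptide syringe
        cell = SpeciesTotals(mhc_total=15 * uM, tapbpr_total=65 * uM)
        syringe = SpeciesTotals(peptide_totals={peptide_id: 175 * uM})
        return TitrationProtocol(cell, syringe, titrant="peptide", macromolecule="mhc", peptide_id=peptide_id)
    raise ValueError(f"unknown titration step {step!r}; expected KD2, KD3 or KD4")


def _enthalpy_density(state, affinities, dh1) -> float:
    """kcal per litre of reaction enthalpy stored in complexes."""
    aff = {a.peptide_id: a for a in affinities}
    h = dh1 * state.mt
    for pid, a in aff.items():
        if pid not in state.mp:
            continue
        if a.dh2 is None or a.dh3 is None:
            raise CycleError(f"enthalpies dh2/dh3 required for peptide {pid!r}")
        h += a.dh2 * state.mp[pid] + (a.dh2 + a.dh3) * state.mpt[pid]
    return h


def _dilution_enthalpy_density(totals_like: dict, affinities, dh1) -> float:
    h = dh1 * totals_like["mt"]
    aff = {a.peptide_id: a for a in affinities}
    for pid, a in aff.items():
        h += a.dh2 * totals_like["mp"].get(pid, 0.0) + (a.dh2 + a.dh3) * totals_like["mpt"].get(pid, 0.0)
    return h


def simulate_titration(
    protocol: TitrationProtocol,
    kd1: float,
    affinities: Sequence[PeptideAffinities],
    dh1: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dilution_heat_ucal: float = 0.0,
) -> Isotherm:
    """Forward-simulate an isotherm from the full cycle model.

    ``noise_sd`` is the per-injection Gaussian heat noise in ucal;
    ``dilution_heat_ucal`` models any residual constant heat per injection
    left after control subtraction (default 0).
    """
    needs_dh = any(a.dh2 is None or a.dh3 is None for a in affinities)
    if needs_dh:
        raise CycleError("every peptide needs dh2 and dh3 set for titration simulation")

    v0 = protocol.cell_volume
    f = protocol.injection_volume / v0
    decay = math.exp(-f)

    syr_state = solve_equilibrium(protocol.syringe, kd1, affinities) if (
        protocol.syringe.mhc_total > 0 and (protocol.syringe.tapbpr_total > 0 or protocol.syringe.peptide_totals)
    ) else None
    syr_complexes = {
        "mt": syr_state.mt if syr_state else 0.0,
        "mp": dict(syr_state.mp) if syr_state else {},
        "mpt": dict(syr_state.mpt) if syr_state else {},
    }

    totals = protocol.cell
    state = solve_equilibrium(totals, kd1, affinities)
    h_prev = _enthalpy_density(state, affinities, dh1)
    # dilution baseline: same mixing, no re-equilibration
    base = {"mt": state.mt, "mp": dict(state.mp), "mpt": dict(state.mpt)}
    h_base_prev = _dilution_enthalpy_density(base, affinities, dh1)

    rng = np.random.default_rng(seed)
    heats, ratios, ndh, mac_conc, tit_conc = [], [], [], [], []
    for inj in range(1, protocol.n_injections + 1):
        old = totals.diluted(decay)
        add = protocol.syringe.diluted(1 - decay)
        totals = SpeciesTotals(
            old.mhc_total + add.mhc_total,
            old.tapbpr_total + add.tapbpr_total,
            {
                k: old.peptide_totals.get(k, 0.0) + add.peptide_totals.get(k, 0.0)
                for k in set(old.peptide_totals) | set(add.peptide_totals)
            },
        )
        state = solve_equilibrium(totals, kd1, affinities)
        h = _enthalpy_density(state, affinities, dh1)

        for key in ("mt",):
            base[key] = base[key] * decay + syr_complexes[key] * (1 - decay)
        for key in ("mp", "mpt"):
            pids = set(base[key]) | set(syr_complexes[key])
            base[key] = {
                pid: base[key].get(pid, 0.0) * decay + syr_complexes[key].get(pid, 0.0) * (1 - decay)
                for pid in pids
            }
        h_base = _dilution_enthalpy_density(base, affinities, dh1)

        q = v0 * ((h - h_base) - (h_prev - h_base_prev)) * KCAL_TO_UCAL + dilution_heat_ucal
        if noise_sd > 0:
            q += rng.normal(0.0, noise_sd)
        h_prev, h_base_prev = h, h_base

        injected_moles = protocol.component_conc(protocol.syringe, protocol.titrant) * v0 * (1 - decay)
        mac = protocol.component_conc(totals, protocol.macromolecule)
        tit = protocol.component_conc(totals, protocol.titrant)
        # ratio axis counts only syringe-delivered titrant (the designs with
        # background peptide in the cell would otherwise start off-scale)
        tit_titrated = tit - protocol.component_conc(protocol.cell, protocol.titrant) * decay**inj
        heats.append(q)
        ratios.append(tit_titrated / mac if mac > 0 else np.nan)
        ndh.append(q / KCAL_TO_UCAL / injected_moles)
        mac_conc.append(mac)
        tit_conc.append(tit)

    return Isotherm(
        molar_ratio=np.array(ratios),
        heat_ucal=np.array(heats),
        ndh_kcal_per_mol=np.array(ndh),
        macromolecule_M=np.array(mac_conc),
        titrant_M=np.array(tit_conc),
        cell_volume=v0,
    )


def _binary_bound(m_tot, x_tot, kd):
    """Closed-form bound concentration for one-site binding (vectorised)."""
    b = m_tot + x_tot + kd
    return (b - np.sqrt(b * b - 4 * m_tot * x_tot)) / 2


def wiseman_heats(
    mac0: float,
    titrant_syringe: float,
    kd: float,
    dh: float,
    n_injections: int,
    cell_volume: float = DEFAULT_CELL_VOLUME,
    injection_volume: float = DEFAULT_INJECTION_VOLUME,
    n_sites: float = 1.0,
) -> np.ndarray:
    """Closed-form one-site (Wiseman) heats under the perfusion dilution model.

    Serves both as the fit model and as an independent oracle for binary
    titrations simulated through the full equilibrium solver.
    """
    f = injection_volume / cell_volume
    i = np.arange(1, n_injections + 1)
    mac = n_sites * mac0 * np.exp(-f * i)
    tit = titrant_syringe * (1 - np.exp(-f * i))
    bound = _binary_bound(mac, tit, kd)
    bound = np.concatenate(([0.0], bound))
    return cell_volume * dh * np.diff(bound) * KCAL_TO_UCAL


def _one_site_model_heats(params, iso: Isotherm):
    n = params["n"].value
    kd = params["kd"].value
    dh = params["dh"].value
    mac = n * iso.macromolecule_M
    bound = _binary_bound(mac, iso.titrant_M, kd)
    bound = np.concatenate(([0.0], bound))
    return iso.cell_volume * dh * np.diff(bound) * KCAL_TO_UCAL


def _auto_window(heats: np.ndarray) -> int:
    """Start index for fitting a biphasic isotherm's second transition.

    The first (tight) phase saturates where the running heat slope changes
    sign; returns 0 when the curve is monophasic.
    """
    dq = np.diff(heats)
    signs = np.sign(dq)
    flips = np.where(signs[1:] * signs[:-1] < 0)[0]
    if flips.size == 0:
        return 0
    first = int(flips[0]) + 1
    # a flip in the last third is noise on a monophasic tail, not a phase break
    if first > len(heats) * 2 // 3:
        return 0
    return first


def fit_one_site(
    isotherm: Isotherm,
    cell_macromolecule: float | None = None,
    exclude_first: bool = True,
    window: slice | str | None = None,
) -> OneSiteFit:
    """Nonlinear least-squares one-site fit of an isotherm.

    ``exclude_first`` drops injection 1 (diffusion across the syringe tip
    corrupts it in real experiments).  ``window`` restricts the fitted
    injections: a slice, or ``"auto"`` to start after the first heat-slope
    sign change (for biphasic curves where a tight first phase precedes the
    transition of interest).
    """
    heats = isotherm.heat_ucal
    idx = np.arange(len(heats))
    if window == "auto":
        start = _auto_window(heats)
        keep = idx >= start
    elif isinstance(window, slice):
        keep = np.zeros(len(heats), bool)
        keep[window] = True
    else:
        keep = np.ones(len(heats), bool)
    if exclude_first:
        keep[0] = False
    if keep.sum() < 5:
        raise ValueError("need at least 5 usable injections to fit")

    span = float(np.max(heats) - np.min(heats))
    scale = float(np.max(np.abs(heats)))
    if scale == 0 or span < 1e-12 * max(scale, 1.0):
        return OneSiteFit(1.0, np.nan, 0.0, np.nan, np.nan, np.nan, 0.0, int(keep.sum()), unidentifiable=True)

    mac0 = cell_macromolecule if cell_macromolecule is not None else float(isotherm.macromolecule_M[0])
    dh0 = float(np.sum(heats[keep]) / KCAL_TO_UCAL / (mac0 * isotherm.cell_volume))
    if dh0 == 0:
        dh0 = -1.0

    params = lmfit.Parameters()
    params.add("n", value=1.0, min=1e-3, max=10)
    params.add("kd", value=1e-6, min=1e-13, max=1.0)
    params.add("dh", value=dh0)

    # heats are cumulative differences, so the model is always evaluated on
    # the full injection series and subset afterwards
    def residuals(p):
        return (_one_site_model_heats(p, isotherm) - heats)[keep]

    best, best_res = None, np.inf
    for kd0 in (1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        params["kd"].value = kd0
        try:
            res = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:
            continue
        if res.chisqr < best_res:
            best, best_res = res, res.chisqr
    if best is None:
        raise RuntimeError("one-site fit did not converge")

    p = best.params

    def err(name):
        s = p[name].stderr
        return float(s) if s is not None else np.nan

    # a flat-within-noise curve cannot pin kd down
    model_span = float(np.ptp(_one_site_model_heats(p, isotherm)[keep]))
    unident = model_span < 3 * math.sqrt(best_res / max(best.nfree, 1))
    return OneSiteFit(
        n=float(p["n"].value),
        kd=float(p["kd"].value),
        dh=float(p["dh"].value),
        n_stderr=err("n"),
        kd_stderr=err("kd"),
        dh_stderr=err("dh"),
        rss=float(best_res),
        n_points=int(keep.sum()),
        unidentifiable=bool(unident),
    )
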