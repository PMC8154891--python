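"""Four-state thermodynamic cycle of chaperone-mediated MHC-I peptide exchange.

The cycle couples four reversible binding steps between the MHC-I
heavy-chain/beta-2-microglobulin heterodimer (M), the chaperone TAPBPR (T),
and a peptide (P):

    step 1:  M  + T ⇌ MT     dissociation constant kd1
    step 2:  M  + P ⇌ MP     kd2
    step 3:  MP + T ⇌ MPT    kd3
    step 4:  MT + P ⇌ MPT    kd4

Because the two routes into the ternary complex MPT must agree at
equilibrium, detailed balance forces ``kd1 * kd4 == kd2 * kd3``.  The
chaperone-free MHC-I is too unstable for kd1 to be measured directly, so
the package infers it from the other three constants via this closure
("thermodynamic balance").

This module also solves the coupled mass-action equilibria for arbitrary
mixtures of M, T and one or more peptide species, which is the forward
model behind every assay simulator in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CycleParameters",
    "PeptideAffinities",
    "SpeciesTotals",
    "EquilibriumState",
    "CycleError",
    "SolverError",
    "make_cycle",
    "cycle_from_config",
    "balance_residual",
    "solve_equilibrium",
    "free_peptide_fraction",
]

#: largest |kd1*kd4/(kd2*kd3) - 1| accepted (with a warning) for a fully
#: specified constant set; printed tables are rounded and rarely close exactly
BALANCE_WARN_TOL = 0.1
#: closure considered exact below this relative residual
BALANCE_STRICT_TOL = 1e-6


class CycleError(ValueError):
    """Invalid or inconsistent cycle parameters."""


class SolverError(RuntimeError):
    """Equilibrium solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final residual {residual:.3e})")
        self.residual = residual


def _check_positive(**kds: float) -> None:
    for name, value in kds.items():
        if value is None:
            continue
        if not np.isfinite(value) or value <= 0:
            raise CycleError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CycleParameters:
    """The four dissociation constants of the exchange cycle, in molar.

    Optional per-step binding enthalpies (kcal/mol of complex formed) enable
    forward simulation of calorimetric titrations.  Enthalpies obey their own
    Hess-cycle closure ``dh1 + dh4 == dh2 + dh3``.
    """

    kd1: float
    kd2: float
    kd3: float
    kd4: float
    dh1: float | None = None
    dh2: float | None = None
    dh3: float | None = None
    dh4: float | None = None

    def __post_init__(self):
        _check_positive(kd1=self.kd1, kd2=self.kd2, kd3=self.kd3, kd4=self.kd4)
        resid = self.kd1 * self.kd4 / (self.kd2 * self.kd3) - 1.0
        if abs(resid) > BALANCE_WARN_TOL:
            raise CycleError(
                f"detailed-balance residual {resid:+.3g} exceeds {BALANCE_WARN_TOL}; "
                "the four constants are thermodynamically inconsistent"
            )
        if abs(resid) > BALANCE_STRICT_TOL:
            warnings.warn(
                f"cycle constants do not close exactly (residual {resid:+.3g}); "
                "accepted because the discrepancy is within printed-rounding range",
                stacklevel=3,
            )

    @property
    def enthalpies(self) -> tuple[float | None, float | None, float | None, float | None]:
        return (self.dh1, self.dh2, self.dh3, self.dh4)


def make_cycle(
    kd2: float,
    kd3: float,
    kd4: float,
    kd1: float | None = None,
    dh: Mapping[str, float] | None = None,
) -> CycleParameters:
    """Build cycle parameters, inferring ``kd1`` by closure when not given.

    ``kd1 = kd2 * kd3 / kd4`` so detailed balance holds exactly by
    construction.  A user-supplied ``kd1`` is accepted (with a warning) only
    when the closure residual stays within ``BALANCE_WARN_TOL``.

    ``dh`` maps step names ``dh1..dh4`` to binding enthalpies in kcal/mol;
    any single missing step is filled in from the Hess closure
    ``dh1 + dh4 = dh2 + dh3``.
    """
    _check_positive(kd2=kd2, kd3=kd3, kd4=kd4)
    if kd1 is None:
        kd1 = kd2 * kd3 / kd4
    dh = dict(dh) if dh else {}
    unknown = set(dh) - {"dh1", "dh2", "dh3", "dh4"}
    if unknown:
        raise CycleError(f"unknown enthalpy keys {sorted(unknown)}")
    missing = [k for k in ("dh1", "dh2", "dh3", "dh4") if k not in dh]
    if dh and len(missing) == 1:
        m = missing[0]
        if m == "dh1":
            dh["dh1"] = dh["dh2"] + dh["dh3"] - dh["dh4"]
        elif m == "dh2":
            dh["dh2"] = dh["dh1"] + dh["dh4"] - dh["dh3"]
        elif m == "dh3":
            dh["dh3"] = dh["dh1"] + dh["dh4"] - dh["dh2"]
        else:
            dh["dh4"] = dh["dh2"] + dh["dh3"] - dh["dh1"]
    if len(dh) == 4:
        hess = (dh["dh1"] + dh["dh4"]) - (dh["dh2"] + dh["dh3"])
        if abs(hess) > 1e-9 * max(1.0, *(abs(v) for v in dh.values())):
            raise CycleError(f"enthalpies violate Hess closure by {hess:g} kcal/mol")
    return CycleParameters(kd1=kd1, kd2=kd2, kd3=kd3, kd4=kd4, **dh)


def cycle_from_config(config: Mapping) -> CycleParameters:
    """Build cycle parameters from a key-value config.

    Keys ``kd2``/``kd3``/``kd4`` (required), ``kd1`` (optional; inferred by
    closure when absent) and ``dh1``..``dh4`` (optional, kcal/mol); constants
    may be units-suffixed strings like ``"40.2 nM"``.
    """
    from .units import parse_concentration

    known = {"kd1", "kd2", "kd3", "kd4", "dh1", "dh2", "dh3", "dh4"}
    unknown = set(config) - known
    if unknown:
        raise CycleError(f"unknown config keys {sorted(unknown)}")
    missing = {"kd2", "kd3", "kd4"} - set(config)
    if missing:
        raise CycleError(f"config must set kd2, kd3 and kd4; missing {sorted(missing)}")
    dh = {k: float(config[k]) for k in ("dh1", "dh2", "dh3", "dh4") if k in config}
    return make_cycle(
        parse_concentration(config["kd2"]),
        parse_concentration(config["kd3"]),
        parse_concentration(config["kd4"]),
        kd1=parse_concentration(config["kd1"]) if "kd1" in config else None,
        dh=dh or None,
    )


def balance_residual(params) -> float:
    """Detailed-balance residual ``kd1*kd4/(kd2*kd3) - 1`` (dimensionless).

    Accepts :class:`CycleParameters`, a ``(kd1, kd2, kd3, kd4)`` sequence or a
    mapping with those keys, so user-supplied four-constant sets can be
    validated before construction (which rejects badly inconsistent sets).
    """
    if isinstance(params, CycleParameters):
        kds = (params.kd1, params.kd2, params.kd3, params.kd4)
    elif isinstance(params, Mapping):
        try:
            kds = tuple(params[k] for k in ("kd1", "kd2", "kd3", "kd4"))
        except KeyError as exc:
            raise CycleError(f"balance_residual requires all four constants; {exc} missing") from None
    else:
        kds = tuple(params)
        if len(kds) != 4:
            raise CycleError("balance_residual requires exactly four constants")
    if any(k is None for k in kds):
        missing = [n for n, k in zip(("kd1", "kd2", "kd3", "kd4"), kds) if k is None]
        raise CycleError(f"balance_residual requires all four constants; {missing} missing")
    _check_positive(**dict(zip(("kd1", "kd2", "kd3", "kd4"), kds)))
    kd1, kd2, kd3, kd4 = kds
    return kd1 * kd4 / (kd2 * kd3) - 1.0


@dataclass(frozen=True)
class PeptideAffinities:
    """Per-peptide dissociation constants (molar) for cycle steps 2-4.

    ``kd1`` (chaperone binding to empty MHC-I) is peptide-independent and
    lives outside this record; each peptide's own closure ``kd1*kd4 = kd2*kd3``
    is available through :attr:`closure_kd1`.  Optional per-step enthalpies
    (kcal/mol) follow the same convention as :class:`CycleParameters`.
    """

    peptide_id: str
    kd2: float
    kd3: float
    kd4: float
    dh2: float | None = None
    dh3: float | None = None
    dh4: float | None = None

    def __post_init__(self):
        _check_positive(kd2=self.kd2, kd3=self.kd3, kd4=self.kd4)

    @property
    def closure_kd1(self) -> float:
        """kd1 implied by this peptide's constants via detailed balance."""
        return self.kd2 * self.kd3 / self.kd4

    def as_cycle(self, dh1: float | None = None) -> CycleParameters:
        dh = {}
        if None not in (self.dh2, self.dh3, self.dh4):
            dh = {"dh2": self.dh2, "dh3": self.dh3, "dh4": self.dh4}
            if dh1 is not None:
                dh["dh1"] = dh1
        return make_cycle(self.kd2, self.kd3, self.kd4, dh=dh or None)


@dataclass(frozen=True)
class SpeciesTotals:
    """Total (analytic) concentrations of each component, molar."""

    mhc_total: float = 0.0
    tapbpr_total: float = 0.0
    peptide_totals: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "peptide_totals", dict(self.peptide_totals))
        for name, value in [
            ("mhc_total", self.mhc_total),
            ("tapbpr_total", self.tapbpr_total),
            *[(f"peptide_totals[{k}]", v) for k, v in self.peptide_totals.items()],
        ]:
            if not np.isfinite(value) or value < 0:
                raise CycleError(f"{name} must be finite and >= 0, got {value!r}")

    @classmethod
    def from_config(cls, config: Mapping) -> "SpeciesTotals":
        """Build totals from a key-value config with units-suffixed strings.

        Keys: ``mhc``, ``tapbpr``, and ``peptides`` (a peptide_id -> value
        map); values like ``"15 uM"`` or plain molar numbers.
        """
        from .units import parse_concentration

        known = {"mhc", "tapbpr", "peptides"}
        unknown = set(config) - known
        if unknown:
            raise CycleError(f"unknown config keys {sorted(unknown)}; expected {sorted(known)}")
        return cls(
            mhc_total=parse_concentration(config.get("mhc", 0.0)),
            tapbpr_total=parse_concentration(config.get("tapbpr", 0.0)),
            peptide_totals={
                k: parse_concentration(v) for k, v in (config.get("peptides") or {}).items()
            },
        )

    def diluted(self, factor: float) -> "SpeciesTotals":
        return SpeciesTotals(
            self.mhc_total * factor,
            self.tapbpr_total * factor,
            {k: v * factor for k, v in self.peptide_totals.items()},
        )

    def mixed_with(self, other: "SpeciesTotals", other_fraction: float) -> "SpeciesTotals":
        """Linear mixture ``self*(1-f) + other*f`` over the union of peptides."""
        f = other_fraction
        peptides = set(self.peptide_totals) | set(other.peptide_totals)
        return SpeciesTotals(
            self.mhc_total * (1 - f) + other.mhc_total * f,
            self.tapbpr_total * (1 - f) + other.tapbpr_total * f,
            {
                k: self.peptide_totals.get(k, 0.0) * (1 - f) + other.peptide_totals.get(k, 0.0) * f
                for k in peptides
            },
        )


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (molar) of every species in the mixture.

    ``mp``/``mpt`` map peptide id to the binary pMHC-I and ternary
    pMHC-I/chaperone complex concentrations; ``mt`` is the peptide-deficient
    MHC-I/chaperone complex.
    """

    free_mhc: float
    free_tapbpr: float
    free_peptide: Mapping[str, float]
    mp: Mapping[str, float]
    mt: float
    mpt: Mapping[str, float]
    totals: SpeciesTotals

    def peptide_total(self, peptide_id: str) -> float:
        return self.totals.peptide_totals[peptide_id]

    def bound_mhc(self) -> float:
        return self.mt + sum(self.mp.values()) + sum(self.mpt.values())

    def mass_balance_residuals(self) -> dict[str, float]:
        """Relative mass-balance residual per component (0 for absent ones)."""
        out = {}
        m = self.free_mhc + self.mt + sum(self.mp.values()) + sum(self.mpt.values())
        t = self.free_tapbpr + self.mt + sum(self.mpt.values())
        out["mhc"] = _rel(m, self.totals.mhc_total)
        out["tapbpr"] = _rel(t, self.totals.tapbpr_total)
        for pid, ptot in self.totals.peptide_totals.items():
            p = self.free_peptide[pid] + self.mp[pid] + self.mpt[pid]
            out[f"peptide:{pid}"] = _rel(p, ptot)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per species, columns species/concentration_M."""
        rows = [("M", self.free_mhc), ("T", self.free_tapbpr), ("MT", self.mt)]
        for pid in self.totals.peptide_totals:
            rows.append((f"P:{pid}", self.free_peptide[pid]))
            rows.append((f"MP:{pid}", self.mp[pid]))
            rows.append((f"MPT:{pid}", self.mpt[pid]))
        return pd.DataFrame(rows, columns=["species", "concentration_M"])


def _rel(value: float, total: float) -> float:
    if total == 0:
        return abs(value)
    return (value - total) / total


def _complexes(m, t, p, kd1, kd2, kd3, kd4):
    """Complex concentrations from free concentrations (vectorised over p)."""
    mt = m * t / kd1
    mp = m * p / kd2
    mpt = m * t * p / (kd1 * kd4)  # equals mp*t/kd3 under closure
    return mt, mp, mpt


def solve_equilibrium(
    totals: SpeciesTotals,
    kd1: float,
    affinities: Sequence[PeptideAffinities],
    rtol: float = 1e-12,
    max_iter: int = 10000,
) -> EquilibriumState:
    """Solve the coupled mass-action equilibria for one mixture.

    Deterministic damped fixed-point iteration on the free concentrations
    (each update divides a component's total by its binding polynomial, which
    preserves positivity), polished/backed up by multivariate root finding on
    log-free-concentrations for stiff constant sets.  Raises
    :class:`SolverError` if the relative residual never falls below ``1e-10``.
    """
    _check_positive(kd1=kd1)
    aff = {a.peptide_id: a for a in affinities}
    pep_ids = [pid for pid in totals.peptide_totals]
    missing = [pid for pid in pep_ids if totals.peptide_totals[pid] > 0 and pid not in aff]
    if missing:
        raise CycleError(f"no affinities supplied for peptide(s) {missing}")

    m_tot = totals.mhc_total
    t_tot = totals.tapbpr_total
    active = [pid for pid in pep_ids if totals.peptide_totals[pid] > 0]
    p_tot = np.array([totals.peptide_totals[pid] for pid in active])
    kd2 = np.array([aff[pid].kd2 for pid in active])
    kd3 = np.array([aff[pid].kd3 for pid in active])
    kd4 = np.array([aff[pid].kd4 for pid in active])

    # Degenerate mixtures short-circuit (nothing to iterate on).
    if m_tot == 0:
        free_p = dict(zip(active, p_tot))
        return _assemble(totals, active, 0.0, t_tot, free_p, kd1, kd2, kd3, kd4)

    m, t, p = _fixed_point(m_tot, t_tot, p_tot, kd1, kd2, kd4, rtol, max_iter)
    resid = _max_residual(m, t, p, m_tot, t_tot, p_tot, kd1, kd2, kd4)
    if resid > 1e-10:
        m, t, p, resid = _root_polish(m, t, p, m_tot, t_tot, p_tot, kd1, kd2, kd4)
    if resid > 1e-10:
        raise SolverError("equilibrium solver did not converge", resid)

    free_p = dict(zip(active, p))
    return _assemble(totals, active, m, t, free_p, kd1, kd2, kd3, kd4)


def _fixed_point(m_tot, t_tot, p_tot, kd1, kd2, kd4, rtol, max_iter):
    # Each update divides a component's total by its binding polynomial
    # evaluated at the current free concentrations; geometric damping keeps
    # the iteration stable when the constants span nM-mM.
    m, t, p = m_tot, t_tot, p_tot.copy()
    damp = 0.5
    for _ in range(max_iter):
        m_new = m_tot / (1 + t / kd1 + np.sum(p / kd2) + np.sum(t * p / (kd1 * kd4)))
        t_new = t_tot / (1 + m / kd1 + np.sum(m * p / (kd1 * kd4))) if t_tot > 0 else 0.0
        p_new = p_tot / (1 + m / kd2 + m * t / (kd1 * kd4))
        m_next = m * (m_new / m) ** damp
        t_next = t * (t_new / t) ** damp if t > 0 else 0.0
        p_next = p * (p_new / p) ** damp if p.size else p
        change = max(
            abs(m_next - m) / m,
            abs(t_next - t) / t if t > 0 else 0.0,
            float(np.max(np.abs(p_next - p) / p, initial=0.0)),
        )
        m, t, p = m_next, t_next, p_next
        if change < rtol:
            break
    return m, t, p


def _max_residual(m, t, p, m_tot, t_tot, p_tot, kd1, kd2, kd4):
    mt = m * t / kd1
    mp = m * p / kd2
    mpt = m * t * p / (kd1 * kd4)
    res = [abs(m + mt + np.sum(mp) + np.sum(mpt) - m_tot) / m_tot if m_tot else 0.0]
    if t_tot:
        res.append(abs(t + mt + np.sum(mpt) - t_tot) / t_tot)
    if p_tot.size:
        res.append(float(np.max(np.abs(p + mp + mpt - p_tot) / np.maximum(p_tot, 1e-300))))
    return max(res)


def _root_polish(m, t, p, m_tot, t_tot, p_tot, kd1, kd2, kd4):
    """Root-finding on log free concentrations of the active components."""
    has_t = t_tot > 0
    x0 = np.log(np.concatenate(([max(m, 1e-300)], [max(t, 1e-300)] if has_t else [], np.maximum(p, 1e-300))))

    def unpack(x):
        xm = np.exp(x[0])
        idx = 1
        xt = np.exp(x[idx]) if has_t else 0.0
        idx += 1 if has_t else 0
        xp = np.exp(x[idx:])
        return xm, xt, xp

    def residuals(x):
        xm, xt, xp = unpack(x)
        mt = xm * xt / kd1
        mp = xm * xp / kd2
        mpt = xm * xt * xp / (kd1 * kd4)
        out = [(xm + mt + np.sum(mp) + np.sum(mpt)) / m_tot - 1.0]
        if has_t:
            out.append((xt + mt + np.sum(mpt)) / t_tot - 1.0)
        out.extend((xp + mp + mpt) / p_tot - 1.0)
        return np.array(out)

    sol = optimize.root(residuals, x0, method="hybr", options={"xtol": 1e-14})
    xm, xt, xp = unpack(sol.x)
    resid = _max_residual(xm, xt, xp, m_tot, t_tot, p_tot, kd1, kd2, kd4)
    return xm, xt, xp, resid


def _assemble(totals, active, m, t, free_p, kd1, kd2, kd3, kd4):
    mp, mpt, fp = {}, {}, {}
    for i, pid in enumerate(active):
        p = free_p[pid]
        _, mp_i, mpt_i = _complexes(m, t, p, kd1, kd2[i], kd3[i], kd4[i])
        mp[pid], mpt[pid], fp[pid] = float(mp_i), float(mpt_i), float(p)
    for pid in totals.peptide_totals:
        mp.setdefault(pid, 0.0)
        mpt.setdefault(pid, 0.0)
        fp.setdefault(pid, 0.0)
    mt = m * t / kd1
    return EquilibriumState(
        free_mhc=float(m),
        free_tapbpr=float(t),
        free_peptide=fp,
        mp=mp,
        mt=float(mt),
        mpt=mpt,
        totals=totals,
    )


def free_peptide_fraction(state: EquilibriumState, peptide_id: str) -> float:
    """Fraction of a peptide's total pool that is free in solution.

    This is the quantity read out by the NMR unloading assay: signal of
    free-peptide methyl resonances relative to the total labelled peptide.
    """
    if peptide_id not in state.totals.peptide_totals:
        raise KeyError(f"unknown peptide {peptide_id!r}")
    total = state.peptide_total(peptide_id)
    if total == 0:
        raise CycleError(f"peptide {peptide_id!r} has zero total concentration")
    return min(1.0, state.free_peptide[peptide_id] / total)
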