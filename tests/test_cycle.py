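"""Cycle parameters, detailed balance, and the coupled equilibrium solver."""

import numpy as np
import pytest

from peptex.cycle import (
    CycleError,
    PeptideAffinities,
    SpeciesTotals,
    balance_residual,
    cycle_from_config,
    free_peptide_fraction,
    make_cycle,
    solve_equilibrium,
)
from peptex.units import format_concentration, parse_concentration

NM = 1e-9
UM = 1e-6


def binary_bound(a_tot, b_tot, kd):
    """Closed-form bound concentration for a single A + B <-> AB equilibrium."""
    s = a_tot + b_tot + kd
    return (s - np.sqrt(s * s - 4 * a_tot * b_tot)) / 2


def grid_oracle(m_tot, t_tot, p_tot, kd1, kd2, kd3, kd4):
    """Brute-force oracle: global minimisation of the summed squared
    mass-balance residuals over log free concentrations, independent of the
    package solver's iteration scheme."""
    from scipy.optimize import differential_evolution

    def sq_residual(x):
        m, t, p = 10.0 ** x
        mt = m * t / kd1
        mp = m * p / kd2
        mpt = m * t * p / (kd1 * kd4)
        r1 = (m + mt + mp + mpt) / m_tot - 1
        r2 = (t + mt + mpt) / t_tot - 1
        r3 = (p + mp + mpt) / p_tot - 1
        return r1 * r1 + r2 * r2 + r3 * r3

    bounds = [
        (np.log10(m_tot) - 12, np.log10(m_tot)),
        (np.log10(t_tot) - 12, np.log10(t_tot)),
        (np.log10(p_tot) - 12, np.log10(p_tot)),
    ]
    result = differential_evolution(sq_residual, bounds, seed=7, tol=1e-14, maxiter=400)
    return 10.0 ** result.x


class TestClosure:
    @pytest.mark.parametrize(
        "kd2, kd3, kd4, expected_kd1",
        [
            (40.2 * NM, 1.9 * UM, 2.5 * UM, 30.552 * NM),
            (326 * NM, 2.6 * UM, 22.7 * UM, 37.339 * NM),
        ],
    )
    def test_kd1_inferred_from_measured_steps(self, kd2, kd3, kd4, expected_kd1):
        params = make_cycle(kd2, kd3, kd4)
        assert params.kd1 == pytest.approx(expected_kd1, rel=1e-3)
        assert balance_residual(params) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1e-9, 3.7e-7, 2e-3])
    def test_symmetric_constants_close_to_themselves(self, k):
        assert make_cycle(k, k, k).kd1 == pytest.approx(k, rel=1e-12)

    def test_residual_of_printed_rounded_set(self):
        with pytest.warns(UserWarning):
            params = make_cycle(40.2 * NM, 1.9 * UM, 2.5 * UM, kd1=30.6 * NM)
        assert balance_residual(params) == pytest.approx(0.00157, abs=2e-4)

    def test_residual_direct_arithmetic(self):
        assert balance_residual((1.0, 1.0, 1.0, 2.0)) == pytest.approx(1.0)

    def test_residual_requires_all_constants(self):
        with pytest.raises(CycleError):
            balance_residual({"kd1": 1.0, "kd2": 1.0, "kd3": 1.0})

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(CycleError):
            make_cycle(-1e-9, 1e-6, 1e-6)
        with pytest.raises(CycleError):
            make_cycle(0.0, 1e-6, 1e-6)

    def test_grossly_inconsistent_set_rejected(self):
        with pytest.raises(CycleError):
            make_cycle(1e-6, 1e-6, 1e-6, kd1=2e-6)

    def test_enthalpy_hess_closure_completion(self):
        params = make_cycle(1e-6, 1e-6, 1e-6, dh={"dh1": -2.0, "dh2": -10.0, "dh3": -8.0})
        assert params.dh4 == pytest.approx(-16.0)
        with pytest.raises(CycleError):
            make_cycle(1e-6, 1e-6, 1e-6, dh={"dh1": -2.0, "dh2": -10.0, "dh3": -8.0, "dh4": 0.0})


class TestUnits:
    @pytest.mark.parametrize(
        "text, molar",
        [("40.2 nM", 40.2e-9), ("1.9 uM", 1.9e-6), ("1.9 µM", 1.9e-6), ("1 mM", 1e-3), ("2e-6", 2e-6)],
    )
    def test_parse(self, text, molar):
        assert parse_concentration(text) == pytest.approx(molar)

    def test_parse_rejects_unknown_unit(self):
        with pytest.raises(ValueError):
            parse_concentration("5 furlongs")

    def test_format_round_trip(self):
        assert parse_concentration(format_concentration(2.5e-6)) == pytest.approx(2.5e-6)

    def test_cycle_from_units_suffixed_config(self):
        params = cycle_from_config({"kd2": "40.2 nM", "kd3": "1.9 uM", "kd4": "2.5 uM"})
        assert params.kd1 == pytest.approx(30.552e-9, rel=1e-6)
        with pytest.raises(CycleError):
            cycle_from_config({"kd2": "40.2 nM"})

    def test_totals_from_config(self):
        totals = SpeciesTotals.from_config(
            {"mhc": "15 uM", "tapbpr": "65 uM", "peptides": {"TAX9": "175 uM"}}
        )
        assert totals.mhc_total == pytest.approx(15e-6)
        assert totals.peptide_totals["TAX9"] == pytest.approx(175e-6)
        with pytest.raises(CycleError):
            SpeciesTotals.from_config({"mhc": "1 uM", "typo": 1})


class TestSolver:
    def test_nothing_to_bind(self):
        state = solve_equilibrium(SpeciesTotals(mhc_total=1 * UM), 30 * NM, [])
        assert state.free_mhc == pytest.approx(1 * UM)
        assert state.mt == 0.0

    def test_binary_peptide_quadratic(self):
        aff = PeptideAffinities("p", kd2=1 * UM, kd3=1 * UM, kd4=1 * UM)
        state = solve_equilibrium(
            SpeciesTotals(mhc_total=1 * UM, peptide_totals={"p": 1 * UM}), 1.0, [aff]
        )
        assert state.mp["p"] == pytest.approx((3 - np.sqrt(5)) / 2 * UM, rel=1e-8)

    def test_binary_chaperone_quadratic(self):
        kd1 = 30.6 * NM
        state = solve_equilibrium(SpeciesTotals(mhc_total=15 * UM, tapbpr_total=15 * UM), kd1, [])
        assert state.mt == pytest.approx(binary_bound(15 * UM, 15 * UM, kd1), rel=1e-8)

    def test_missing_affinity_rejected(self):
        with pytest.raises(CycleError):
            solve_equilibrium(SpeciesTotals(1 * UM, 0.0, {"p": 1 * UM}), 1e-6, [])

    def test_three_component_vs_grid_oracle(self, rng):
        for _ in range(20):
            kd2, kd3 = 10.0 ** rng.uniform(-9, -4, size=2)
            kd4 = 10.0 ** rng.uniform(-9, -4)
            kd1 = kd2 * kd3 / kd4
            m_tot, t_tot, p_tot = 10.0 ** rng.uniform(-8, -4, size=3)
            aff = PeptideAffinities("p", kd2, kd3, kd4)
            state = solve_equilibrium(
                SpeciesTotals(m_tot, t_tot, {"p": p_tot}), kd1, [aff]
            )
            m, t, p = grid_oracle(m_tot, t_tot, p_tot, kd1, kd2, kd3, kd4)
            assert state.free_mhc == pytest.approx(m, rel=1e-3)
            assert state.free_tapbpr == pytest.approx(t, rel=1e-3)
            assert state.free_peptide["p"] == pytest.approx(p, rel=1e-3)

    def test_mass_conservation_and_equilibrium_relations_random_draws(self, rng):
        for _ in range(1000):
            kd2, kd3 = 10.0 ** rng.uniform(-12, -3, size=2)
            kd4 = 10.0 ** rng.uniform(-12, -3)
            kd1 = kd2 * kd3 / kd4
            totals = SpeciesTotals(
                10.0 ** rng.uniform(-12, -3),
                10.0 ** rng.uniform(-12, -3),
                {"p": 10.0 ** rng.uniform(-12, -3)},
            )
            aff = PeptideAffinities("p", kd2, kd3, kd4)
            state = solve_equilibrium(totals, kd1, [aff])
            for r in state.mass_balance_residuals().values():
                assert abs(r) <= 1e-9
            # every concentration non-negative
            assert state.free_mhc >= 0 and state.free_tapbpr >= 0 and state.mt >= 0
            # equilibrium relations hold to 1e-6 relative
            if state.mt > 0:
                assert state.free_mhc * state.free_tapbpr / state.mt == pytest.approx(kd1, rel=1e-6)
            if state.mp["p"] > 0:
                assert state.free_mhc * state.free_peptide["p"] / state.mp["p"] == pytest.approx(
                    kd2, rel=1e-6
                )
            if state.mpt["p"] > 0 and state.mp["p"] > 0:
                assert state.mp["p"] * state.free_tapbpr / state.mpt["p"] == pytest.approx(
                    kd3, rel=1e-6
                )

    def test_solution_invariant_under_peptide_relabeling(self, tax9_wt):
        other = PeptideAffinities("other", 300 * NM, 2.0 * UM, 20 * UM)
        totals_a = SpeciesTotals(10 * UM, 20 * UM, {"TAX9": 5 * UM, "other": 8 * UM})
        kd1 = tax9_wt.closure_kd1
        state_a = solve_equilibrium(totals_a, kd1, [tax9_wt, other])

        renamed_tax9 = PeptideAffinities("zz", tax9_wt.kd2, tax9_wt.kd3, tax9_wt.kd4)
        totals_b = SpeciesTotals(10 * UM, 20 * UM, {"zz": 5 * UM, "other": 8 * UM})
        state_b = solve_equilibrium(totals_b, kd1, [renamed_tax9, other])

        assert state_b.mp["zz"] == pytest.approx(state_a.mp["TAX9"], rel=1e-9)
        assert state_b.mpt["other"] == pytest.approx(state_a.mpt["other"], rel=1e-9)
        assert state_b.free_mhc == pytest.approx(state_a.free_mhc, rel=1e-9)

    def test_state_export_is_tidy(self, tax9_wt):
        state = solve_equilibrium(
            SpeciesTotals(1 * UM, 1 * UM, {"TAX9": 1 * UM}), tax9_wt.closure_kd1, [tax9_wt]
        )
        df = state.to_frame()
        assert list(df.columns) == ["species", "concentration_M"]
        assert set(df.species) == {"M", "T", "MT", "P:TAX9", "MP:TAX9", "MPT:TAX9"}


class TestFreePeptideFraction:
    def test_unbound_when_alone(self):
        aff = PeptideAffinities("p", 1 * UM, 1 * UM, 1 * UM)
        state = solve_equilibrium(SpeciesTotals(0.0, 0.0, {"p": 1 * UM}), 1e-6, [aff])
        assert free_peptide_fraction(state, "p") == pytest.approx(1.0)

    def test_unknown_peptide_rejected(self, tax9_wt):
        state = solve_equilibrium(
            SpeciesTotals(1 * UM, 0.0, {"TAX9": 1 * UM}), tax9_wt.closure_kd1, [tax9_wt]
        )
        with pytest.raises(KeyError):
            free_peptide_fraction(state, "nope")

    def test_loop_deletion_releases_more_peptide(self, tax9_wt, tax9_loopless):
        """Eightfold chaperone excess over loaded MHC frees more peptide when
        the trap loop is deleted (weaker peptide capture by the complex)."""
        totals = SpeciesTotals(100 * UM, 800 * UM, {"TAX9": 100 * UM})
        frac_wt = free_peptide_fraction(
            solve_equilibrium(totals, tax9_wt.closure_kd1, [tax9_wt]), "TAX9"
        )
        frac_loopless = free_peptide_fraction(
            solve_equilibrium(totals, tax9_loopless.closure_kd1, [tax9_loopless]), "TAX9"
        )
        assert frac_loopless > frac_wt

    def test_weak_capture_limit_sequesters_mhc(self, tax9_wt):
        """As kd4 -> infinity (kd3 fixed, kd1 from closure) the ternary complex
        vanishes and the chaperone sequesters MHC as MT, leaving the peptide
        governed by binary binding to the residual free MHC."""
        totals = SpeciesTotals(100 * UM, 800 * UM, {"TAX9": 100 * UM})
        kd4 = tax9_wt.kd4 * 1e9
        kd1 = tax9_wt.kd2 * tax9_wt.kd3 / kd4
        aff = PeptideAffinities("TAX9", tax9_wt.kd2, tax9_wt.kd3, kd4)
        state = solve_equilibrium(totals, kd1, [aff])
        frac = free_peptide_fraction(state, "TAX9")

        # independent closed-form limit: M/T binary equilibrium, then the free
        # MHC left over buffers the peptide at kd2
        mt = binary_bound(100 * UM, 800 * UM, kd1)
        m_free = 100 * UM - mt
        expected = 1 / (1 + m_free / tax9_wt.kd2)
        assert frac == pytest.approx(expected, rel=1e-3)

    def test_monotone_in_kd4(self, tax9_wt):
        """Weakening peptide capture by the chaperoned groove monotonically
        increases the free-peptide fraction (the peptide-trap direction)."""
        totals = SpeciesTotals(100 * UM, 800 * UM, {"TAX9": 100 * UM})
        fracs = []
        for scale in [0.25, 0.5, 1, 2, 4, 8, 16]:
            kd4 = tax9_wt.kd4 * scale
            kd1 = tax9_wt.kd2 * tax9_wt.kd3 / kd4
            aff = PeptideAffinities("TAX9", tax9_wt.kd2, tax9_wt.kd3, kd4)
            fracs.append(
                free_peptide_fraction(solve_equilibrium(totals, kd1, [aff]), "TAX9")
            )
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))
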