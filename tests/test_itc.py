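"""Titration forward model and one-site fitting."""

import numpy as np
import pytest

from peptex import itc
from peptex.cycle import CycleError, PeptideAffinities, SpeciesTotals
from peptex.synth import DEFAULT_DH1, preset

UM = 1e-6


@pytest.fixture(scope="module")
def binary_protocol():
    """Peptide into MHC alone: a pure one-site system."""
    return itc.TitrationProtocol(
        cell=SpeciesTotals(mhc_total=15 * UM),
        syringe=SpeciesTotals(peptide_totals={"p": 150 * UM}),
        titrant="peptide",
        macromolecule="mhc",
        peptide_id="p",
    )


def binary_affinity(kd=2 * UM, dh=-10.0):
    return PeptideAffinities("p", kd2=kd, kd3=1 * UM, kd4=1 * UM, dh2=dh, dh3=-8.0)


class TestProtocols:
    def test_kd2_preset_composition(self):
        p = itc.preset_protocol("KD2", "TAX9")
        assert p.cell.mhc_total == pytest.approx(15 * UM)
        assert p.cell.tapbpr_total == pytest.approx(15 * UM)
        assert p.syringe.peptide_totals["TAX9"] == pytest.approx(75 * UM)

    def test_kd3_preset_has_excess_peptide_both_sides(self):
        p = itc.preset_protocol("KD3", "TAX9")
        assert p.cell.tapbpr_total == pytest.approx(15 * UM)
        assert p.cell.peptide_totals["TAX9"] == pytest.approx(1e-3)
        assert p.syringe.mhc_total == pytest.approx(175 * UM)
        assert p.syringe.peptide_totals["TAX9"] >= 1e-3

    def test_kd4_preset_has_excess_chaperone(self):
        p = itc.preset_protocol("KD4", "TAX9")
        assert p.cell.mhc_total == pytest.approx(15 * UM)
        assert p.cell.tapbpr_total == pytest.approx(65 * UM)  # 15 complexed + 50 excess
        assert p.syringe.peptide_totals["TAX9"] == pytest.approx(175 * UM)

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError):
            itc.preset_protocol("KD9")

    def test_protocol_volume_validation(self):
        with pytest.raises(ValueError):
            itc.TitrationProtocol(
                cell=SpeciesTotals(mhc_total=1 * UM),
                syringe=SpeciesTotals(),
                cell_volume=1e-4,
                injection_volume=1e-5,
                n_injections=20,
            )


class TestSimulate:
    def test_zero_enthalpies_give_zero_heats(self, binary_protocol):
        aff = PeptideAffinities("p", 2 * UM, 1 * UM, 1 * UM, dh2=0.0, dh3=0.0)
        iso = itc.simulate_titration(binary_protocol, kd1=1.0, affinities=[aff], dh1=0.0)
        assert np.allclose(iso.heat_ucal, 0.0)

    def test_missing_enthalpy_rejected(self, binary_protocol):
        aff = PeptideAffinities("p", 2 * UM, 1 * UM, 1 * UM)
        with pytest.raises(CycleError):
            itc.simulate_titration(binary_protocol, kd1=1.0, affinities=[aff])

    def test_binary_matches_wiseman_oracle(self, binary_protocol):
        iso = itc.simulate_titration(binary_protocol, kd1=1.0, affinities=[binary_affinity()], dh1=0.0)
        oracle = itc.wiseman_heats(15 * UM, 150 * UM, 2 * UM, -10.0, 28)
        assert np.max(np.abs(iso.heat_ucal - oracle) / np.abs(oracle)) < 1e-6

    def test_saturating_titration_conserves_total_heat(self):
        """Cumulative heat approaches dH x (moles of macromolecule in cell)."""
        protocol = itc.TitrationProtocol(
            cell=SpeciesTotals(mhc_total=5 * UM),
            syringe=SpeciesTotals(peptide_totals={"p": 500 * UM}),
            titrant="peptide",
            macromolecule="mhc",
            peptide_id="p",
        )
        aff = binary_affinity(kd=1e-9)
        iso = itc.simulate_titration(protocol, kd1=1.0, affinities=[aff], dh1=0.0)
        expected = -10.0 * iso.macromolecule_M[-1] * protocol.cell_volume * itc.KCAL_TO_UCAL
        assert np.sum(iso.heat_ucal) == pytest.approx(expected, rel=1e-3)

    def test_injection_splitting_invariance(self, tax9_wt):
        """Summed heats are unchanged when each injection is split in two."""
        protocol = itc.preset_protocol("KD4", "TAX9")
        iso = itc.simulate_titration(protocol, tax9_wt.closure_kd1, [tax9_wt], dh1=DEFAULT_DH1)
        halved = itc.TitrationProtocol(
            cell=protocol.cell,
            syringe=protocol.syringe,
            injection_volume=protocol.injection_volume / 2,
            n_injections=protocol.n_injections * 2,
            titrant=protocol.titrant,
            macromolecule=protocol.macromolecule,
            peptide_id=protocol.peptide_id,
        )
        iso2 = itc.simulate_titration(halved, tax9_wt.closure_kd1, [tax9_wt], dh1=DEFAULT_DH1)
        paired = iso2.heat_ucal.reshape(-1, 2).sum(axis=1)
        assert np.max(np.abs(paired - iso.heat_ucal) / np.abs(iso.heat_ucal)) < 1e-6

    def test_noise_is_seeded(self, binary_protocol):
        kw = dict(kd1=1.0, affinities=[binary_affinity()], dh1=0.0, noise_sd=0.5)
        a = itc.simulate_titration(binary_protocol, seed=11, **kw)
        b = itc.simulate_titration(binary_protocol, seed=11, **kw)
        c = itc.simulate_titration(binary_protocol, seed=12, **kw)
        assert np.array_equal(a.heat_ucal, b.heat_ucal)
        assert not np.array_equal(a.heat_ucal, c.heat_ucal)

    def test_csv_round_trip(self, binary_protocol, tmp_path):
        iso = itc.simulate_titration(binary_protocol, kd1=1.0, affinities=[binary_affinity()], dh1=0.0)
        path = tmp_path / "iso.csv"
        iso.to_csv(path)
        back = itc.Isotherm.from_csv(path)
        assert np.allclose(back.heat_ucal, iso.heat_ucal)
        assert np.allclose(back.molar_ratio, iso.molar_ratio)


class TestFit:
    def test_noiseless_binary_recovery(self, binary_protocol):
        iso = itc.simulate_titration(binary_protocol, kd1=1.0, affinities=[binary_affinity()], dh1=0.0)
        fit = itc.fit_one_site(iso, cell_macromolecule=15 * UM)
        assert fit.n == pytest.approx(1.0, rel=1e-3)
        assert fit.kd == pytest.approx(2 * UM, rel=1e-3)
        assert fit.dh == pytest.approx(-10.0, rel=1e-3)
        assert not fit.unidentifiable

    def test_kd3_and_kd4_designs_fit_with_unit_stoichiometry(self, tax9_wt):
        for step, truth, tol in [("KD3", tax9_wt.kd3, 0.05), ("KD4", tax9_wt.kd4, 0.15)]:
            protocol = itc.preset_protocol(step, "TAX9")
            iso = itc.simulate_titration(protocol, tax9_wt.closure_kd1, [tax9_wt], dh1=DEFAULT_DH1)
            fit = itc.fit_one_site(
                iso, cell_macromolecule=15 * UM, window="auto" if step == "KD4" else None
            )
            assert fit.n == pytest.approx(1.0, abs=0.1)
            assert fit.kd == pytest.approx(truth, rel=tol)

    def test_kd2_design_reports_composite_displacement_constant(self, tax9_wt):
        """Peptide must displace the chaperone in this design; at equilibrium
        the displacement constant is kd3/kd4 < 1, so the one-site fit returns
        a composite apparent kd well above the true peptide constant."""
        protocol = itc.preset_protocol("KD2", "TAX9")
        iso = itc.simulate_titration(protocol, tax9_wt.closure_kd1, [tax9_wt], dh1=DEFAULT_DH1)
        fit = itc.fit_one_site(iso, cell_macromolecule=15 * UM)
        assert fit.kd > tax9_wt.kd2  # displacement weakens the apparent affinity
        assert fit.kd < 100 * UM
        assert np.all(iso.heat_ucal < 0)  # net exothermic displacement

    def test_noisy_recovery_kd3(self, tax9_wt, rng):
        """Median fitted constant across noisy replicates stays within 10%."""
        protocol = itc.preset_protocol("KD3", "TAX9")
        clean = itc.simulate_titration(protocol, tax9_wt.closure_kd1, [tax9_wt], dh1=DEFAULT_DH1)
        kds = []
        for _ in range(20):
            noisy = itc.Isotherm(
                molar_ratio=clean.molar_ratio,
                heat_ucal=clean.heat_ucal + rng.normal(0, 0.1, size=len(clean)),
                ndh_kcal_per_mol=clean.ndh_kcal_per_mol,
                macromolecule_M=clean.macromolecule_M,
                titrant_M=clean.titrant_M,
            )
            kds.append(itc.fit_one_site(noisy, cell_macromolecule=15 * UM).kd)
        assert np.median(kds) == pytest.approx(tax9_wt.kd3, rel=0.10)

    def test_kd4_apparent_kd_converges_with_chaperone_excess(self, tax9_wt):
        """More excess chaperone pins the MHC in its chaperoned form, so the
        apparent constant approaches the true peptide-capture constant."""
        errors = []
        for excess in [20 * UM, 50 * UM, 200 * UM, 800 * UM]:
            protocol = itc.TitrationProtocol(
                cell=SpeciesTotals(mhc_total=15 * UM, tapbpr_total=15 * UM + excess),
                syringe=SpeciesTotals(peptide_totals={"TAX9": 175 * UM}),
                titrant="peptide",
                macromolecule="mhc",
                peptide_id="TAX9",
            )
            iso = itc.simulate_titration(protocol, tax9_wt.closure_kd1, [tax9_wt], dh1=DEFAULT_DH1)
            fit = itc.fit_one_site(iso, cell_macromolecule=15 * UM, window="auto")
            errors.append(abs(fit.kd - tax9_wt.kd4) / tax9_wt.kd4)
        assert all(b <= a + 1e-9 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 0.02

    def test_flat_isotherm_flagged_unidentifiable(self):
        n = 20
        iso = itc.Isotherm(
            molar_ratio=np.linspace(0.1, 2.0, n),
            heat_ucal=np.zeros(n),
            ndh_kcal_per_mol=np.zeros(n),
            macromolecule_M=np.full(n, 15 * UM),
            titrant_M=np.linspace(1 * UM, 30 * UM, n),
        )
        fit = itc.fit_one_site(iso, cell_macromolecule=15 * UM)
        assert fit.unidentifiable

    def test_too_few_points_rejected(self, binary_protocol):
        iso = itc.simulate_titration(binary_protocol, kd1=1.0, affinities=[binary_affinity()], dh1=0.0)
        with pytest.raises(ValueError):
            itc.fit_one_site(iso, cell_macromolecule=15 * UM, window=slice(0, 4))
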