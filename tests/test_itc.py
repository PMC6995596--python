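import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetra.itc import (
    BindingModel,
    ITCError,
    Isotherm,
    R_GAS,
    TitrationScheme,
    default_injection_volumes,
    free_ligand,
    simulate_isotherm,
    species,
    thermo_decompose,
)

SEQ2 = BindingModel.sequential(((1.5e-9, -226.25), (4.3e-6, -360.0)))


def assembly_scheme(**over):
    kw = dict(cell_conc_M=2.5e-6, syringe_conc_M=25e-6, temperature_K=298.15)
    kw.update(over)
    return TitrationScheme(**kw)


class TestSchemeAndModel:
    def test_default_schedule(self):
        v = default_injection_volumes()
        assert len(v) == 20 and v[0] == 0.4 and set(v[1:]) == {2.0}

    def test_invalid_scheme(self):
        with pytest.raises(ITCError):
            TitrationScheme(cell_conc_M=0.0, syringe_conc_M=1e-6)
        with pytest.raises(ITCError):
            TitrationScheme(cell_conc_M=1e-6, syringe_conc_M=1e-6,
                            injection_volumes_ul=(2.0,))

    def test_invalid_model(self):
        with pytest.raises(ITCError):
            BindingModel.sequential(((0.0, -10.0),))
        with pytest.raises(ITCError):
            BindingModel.sequential(((1e-9, -1.0),) * 4)


class TestFreeLigand:
    def test_zero_ligand(self):
        assert free_ligand(0.0, 1e-6, SEQ2) == 0.0

    def test_zero_macromolecule(self):
        assert free_ligand(5e-6, 0.0, SEQ2) == 5e-6

    def test_matches_grid_scan_oracle(self):
        """Dense scan of the mass balance agrees to 6 significant digits."""
        a_tot, m_tot = 10e-6, 2.5e-6
        betas = np.cumprod(1.0 / np.array(SEQ2.kd))

        def balance(a):
            t1 = betas[0] * a
            t2 = betas[1] * a**2
            phi = 1.0 + t1 + t2
            return a + m_tot * (t1 + 2 * t2) / phi - a_tot

        grid = np.linspace(0.0, a_tot, 1_000_001)
        vals = balance(grid)
        i = np.searchsorted(vals > 0, True)
        fine = np.linspace(grid[i - 1], grid[i], 1_000_001)
        j = np.searchsorted(balance(fine) > 0, True)
        oracle = 0.5 * (fine[j - 1] + fine[j])
        assert free_ligand(a_tot, m_tot, SEQ2) == pytest.approx(oracle, rel=1e-6)

    def test_negative_totals_rejected(self):
        with pytest.raises(ITCError):
            free_ligand(-1.0, 1.0, SEQ2)


class TestSpecies:
    def test_no_ligand_no_complexes(self):
        sp = species(0.0, 1e-6, SEQ2)
        assert sp[0] == pytest.approx(1e-6) and np.all(sp[1:] == 0.0)

    def test_kd_definition_one_step(self):
        model = BindingModel.sequential(((2e-6, -5.0),))
        sp = species(2e-6, 1e-6, model)  # A_free = Kd => [MA] = [M]
        assert sp[1] == pytest.approx(sp[0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1e-2),
        m=st.floats(1e-9, 1e-2),
        logk=st.tuples(st.floats(-9, -2), st.floats(-9, -2), st.floats(-9, -2)),
    )
    def test_mass_conservation_over_states(self, a, m, logk):
        model = BindingModel.sequential(tuple((10.0**k, -1.0) for k in logk))
        sp = species(a, m, model)
        assert sp.sum() == pytest.approx(m, rel=1e-12)

    def test_one_set_binomial_states(self):
        sp = species(1e-6, 1e-6, BindingModel.one_set(2, 1e-6, -1.0))
        # at A_free = Kd the three states follow 1 : 2 : 1
        assert sp[1] == pytest.approx(2 * sp[0]) and sp[2] == pytest.approx(sp[0])


class TestSimulate:
    def test_zero_enthalpy_gives_zero_heat(self):
        model = BindingModel.sequential(((1e-8, 0.0), (1e-6, 0.0)))
        iso = simulate_isotherm(assembly_scheme(), model)
        np.testing.assert_array_equal(iso.q_norm, 0.0)

    def test_tight_binding_cumulative_heat(self):
        """Saturated total heat approaches V0 * M0 * sum(dH)."""
        model = BindingModel.sequential(((1e-15, -100.0), (1e-15, -50.0)))
        # schedule long enough to pass full saturation (ratio > 2)
        scheme = assembly_scheme(injection_volumes_ul=(0.4,) + (2.0,) * 29)
        iso = simulate_isotherm(scheme, model, dilution="none")
        raw = iso.q_norm * scheme.syringe_conc_M * np.array(iso.injection_volumes_ul) * 1e-6
        expected = scheme.cell_volume_ul * 1e-6 * scheme.cell_conc_M * (-150.0)
        assert raw.sum() == pytest.approx(expected, rel=0.01)

    @staticmethod
    def _wiseman_slope(xr: float, r: float) -> float:
        """Closed-form Wiseman isotherm: dQ/dXr per dH at molar ratio Xr."""
        return 0.5 + (1.0 - xr - r) / (2.0 * np.sqrt((1.0 + xr + r) ** 2 - 4.0 * xr))

    def test_wiseman_midpoint_matches_closed_form(self):
        """At c = 10 the simulated heat at molar ratio 1 equals the
        closed-form Wiseman inflection value, 0.42 dH (dH/2 is the steep
        c -> infinity limit, not yet reached at c = 10)."""
        m0, c = 2.5e-6, 10.0
        model = BindingModel.one_set(1, m0 / c, -100.0)
        scheme = assembly_scheme(
            injection_volumes_ul=(0.4,) + (1.0,) * 39, syringe_conc_M=25e-6
        )
        iso = simulate_isotherm(scheme, model, dilution="none")
        i = int(np.argmin(np.abs(iso.molar_ratio - 1.0)))
        expected = -100.0 * self._wiseman_slope(iso.molar_ratio[i], 1.0 / c)
        assert iso.q_norm[i] == pytest.approx(expected, rel=0.05)

    def test_deterministic(self):
        a = simulate_isotherm(assembly_scheme(), SEQ2)
        b = simulate_isotherm(assembly_scheme(), SEQ2)
        assert np.array_equal(a.q_norm, b.q_norm)
        assert np.array_equal(a.molar_ratio, b.molar_ratio)

    def test_weaker_binding_releases_less_heat(self):
        """Exothermic steps: total |heat| is non-increasing in each Kd."""
        scheme = assembly_scheme()
        for step in (0, 1):
            totals = []
            for kd in (1e-9, 1e-7, 1e-5, 1e-3):
                kds = [1.5e-9, 4.3e-6]
                kds[step] = kd
                model = BindingModel.sequential(tuple(zip(kds, (-200.0, -300.0))))
                totals.append(simulate_isotherm(scheme, model).q_norm.sum())
            assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_one_step_sequential_equals_one_set_single_site(self):
        seq = BindingModel.sequential(((5e-7, -80.0),))
        one = BindingModel.one_set(1, 5e-7, -80.0)
        qa = simulate_isotherm(assembly_scheme(), seq).q_norm
        qb = simulate_isotherm(assembly_scheme(), one).q_norm
        np.testing.assert_allclose(qa, qb, rtol=1e-12, atol=1e-12)

    def test_ligand_mass_conserved_across_injections(self):
        scheme = assembly_scheme()
        model = SEQ2
        v0 = scheme.cell_volume_ul
        a_tot, m_tot = 0.0, scheme.cell_conc_M
        for v in scheme.injection_volumes_ul:
            f = 1.0 - v / v0
            m_tot *= f
            a_tot = a_tot * f + scheme.syringe_conc_M * v / v0
            a_free = free_ligand(a_tot, m_tot, model)
            sp = species(a_free, m_tot, model)
            bound = sp[1] + 2 * sp[2]
            assert bound + a_free == pytest.approx(a_tot, rel=1e-9)

    def test_dilution_heat_offset(self):
        iso = simulate_isotherm(assembly_scheme(), SEQ2, dilution_heat=1.5)
        base = simulate_isotherm(assembly_scheme(), SEQ2)
        np.testing.assert_allclose(iso.q_norm - base.q_norm, 1.5)


class TestThermo:
    def test_unit_kd_zero_free_energy(self):
        assert thermo_decompose(1.0, -10.0, 298.15).dG == 0.0

    def test_one_set_affinity_from_report(self):
        # Kd 66.7 nM at 30 C: direct evaluation of R T ln Kd
        step = thermo_decompose(66.7e-9, -50.0, 303.15)
        expected = R_GAS * 303.15 * np.log(66.7e-9) / 1000.0
        assert step.dG == pytest.approx(expected)
        assert step.dG == pytest.approx(-41.6, abs=0.1)

    def test_entropy_term_closes_the_cycle(self):
        step = thermo_decompose(1e-6, -30.0, 298.15)
        assert step.dG == pytest.approx(step.dH + step.mTdS, abs=1e-9)
        assert thermo_decompose(1e-6, thermo_decompose(1e-6, 0, 298.15).dG, 298.15).mTdS == pytest.approx(0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ITCError):
            thermo_decompose(0.0, 1.0, 298.15)


class TestIsothermIO:
    def test_csv_round_trip(self, tmp_path):
        iso = simulate_isotherm(assembly_scheme(), SEQ2)
        p = tmp_path / "iso.csv"
        iso.to_csv(str(p))
        back = Isotherm.from_csv(str(p))
        np.testing.assert_allclose(back.q_norm, iso.q_norm, rtol=1e-12)
        np.testing.assert_allclose(back.molar_ratio, iso.molar_ratio, rtol=1e-12)

    def test_row_order_is_rederived_from_injection_index(self, tmp_path):
        import pandas as pd

        iso = simulate_isotherm(assembly_scheme(), SEQ2)
        p = tmp_path / "iso.csv"
        iso.to_csv(str(p))
        df = pd.read_csv(p).sample(frac=1.0, random_state=0)
        df.to_csv(p, index=False)
        back = Isotherm.from_csv(str(p))
        np.testing.assert_allclose(back.q_norm, iso.q_norm, rtol=1e-12)

    def test_non_monotone_ratio_rejected(self):
        with pytest.raises(ITCError):
            Isotherm(np.array([1.0, 0.5]), np.array([0.0, 0.0]), (1.0, 1.0))
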