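"""Activity coefficients, water capacity, LLE flash, and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microaqua.errors import CalibrationError, DomainError, RegistryError
from microaqua.thermo import (ActivityModel, MixtureComposition,
                              activity_coefficients, calibrate_water_cpme,
                              default_model, lle_split, water_activity,
                              water_capacity)

from microaqua.species import DEFAULT_SPECIES

# saturation mole fraction implied by 0.7 wt% water in CPME
_MW = DEFAULT_SPECIES["H2O"].molar_mass
_MC = DEFAULT_SPECIES["CPME"].molar_mass
X_SAT_CPME = (0.7 / _MW) / (0.7 / _MW + 99.3 / _MC)        # ≈ 0.03772
A_WC = np.log(1.0 / X_SAT_CPME) / (1.0 - X_SAT_CPME) ** 2  # ≈ 3.5397


def margules_binary(a):
    return ActivityModel.margules({("A", "B"): a})


def numeric_ln_gamma(names, moles, model, h=1e-6):
    """Central-difference oracle: ln γ_k = ∂(n·G^E/RT)/∂n_k."""

    def n_ge(n):
        n = np.asarray(n, dtype=float)
        x = n / n.sum()
        A = model.matrix(names)
        return n.sum() * (x @ A @ x) / 2.0

    out = []
    for k in range(len(names)):
        up = np.array(moles, dtype=float)
        dn = np.array(moles, dtype=float)
        up[k] += h
        dn[k] -= h
        out.append((n_ge(up) - n_ge(dn)) / (2.0 * h))
    return np.array(out)


class TestActivityCoefficients:
    def test_ideal_returns_unity_for_any_composition(self):
        comp = MixtureComposition({"A": 0.2, "B": 1.3, "C": 0.01})
        gam = activity_coefficients(comp, ActivityModel.ideal())
        assert all(g == 1.0 for g in gam.values())

    def test_binary_margules_closed_form(self):
        comp = MixtureComposition({"A": 0.5, "B": 0.5})
        gam = activity_coefficients(comp, margules_binary(2.0))
        expected = np.exp(2.0 * 0.25)  # ln γ1 = A x2²
        assert gam["A"] == pytest.approx(expected, abs=1e-12)
        assert gam["B"] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("moles", [(0.2, 0.3, 0.5), (1.0, 0.05, 0.4), (0.01, 0.9, 0.09)])
    def test_ternary_matches_numeric_differentiation(self, moles):
        names = ["A", "B", "C"]
        model = ActivityModel.margules({("A", "B"): 1.3, ("A", "C"): -0.7, ("B", "C"): 2.1})
        comp = MixtureComposition(dict(zip(names, moles)))
        gam = activity_coefficients(comp, model)
        oracle = numeric_ln_gamma(names, moles, model)
        assert np.log([gam[n] for n in names]) == pytest.approx(oracle, abs=1e-5)

    @given(st.floats(min_value=0.5, max_value=4.0))
    @settings(deadline=None, max_examples=25)
    def test_normalization_gamma_to_one_in_pure_limit(self, a):
        comp = MixtureComposition({"A": 1.0 - 1e-5, "B": 1e-5})
        gam = activity_coefficients(comp, margules_binary(a))
        assert abs(gam["A"] - 1.0) < 1e-9

    def test_unknown_species_rejected(self, model):
        with pytest.raises(RegistryError):
            activity_coefficients(MixtureComposition({"ethanol": 1.0}), model)

    def test_empty_and_negative_compositions_rejected(self):
        with pytest.raises(DomainError):
            MixtureComposition({})
        with pytest.raises(DomainError):
            MixtureComposition({"A": -0.1, "B": 1.0})

    def test_mole_fractions_sum_to_one(self):
        comp = MixtureComposition({"A": 0.123, "B": 4.56, "C": 7.8e-4})
        assert sum(comp.mole_fractions().values()) == pytest.approx(1.0, abs=1e-12)


class TestGibbsDuhem:
    def test_sum_x_dlngamma_vanishes_along_path(self):
        """Σ_i x_i Δln γ_i ≈ 0 for each 1e-4 step of a composition path."""
        names = ["A", "B", "C"]
        model = ActivityModel.margules({("A", "B"): 2.0, ("A", "C"): 0.8, ("B", "C"): -1.1})
        start = np.array([0.6, 0.3, 0.1])
        end = np.array([0.2, 0.3, 0.5])
        ts = np.arange(0.0, 1.0 + 1e-12, 1e-2)
        for t0, t1 in zip(ts[:-1], ts[1:]):
            for s0, s1 in [(t0, t0 + 1e-4), (t1 - 1e-4, t1)]:
                x0 = (1 - s0) * start + s0 * end
                x1 = (1 - s1) * start + s1 * end
                d_ln = model.ln_gamma(names, x1) - model.ln_gamma(names, x0)
                xm = 0.5 * (x0 + x1)
                assert abs(float(xm @ d_ln)) <= 1e-6


class TestWaterActivity:
    def test_pure_water_is_unity(self, model):
        assert water_activity(MixtureComposition({"H2O": 1.0}), model) == pytest.approx(1.0)

    def test_ideal_half_water(self):
        comp = MixtureComposition({"H2O": 1.0, "CPME": 1.0})
        assert water_activity(comp, ActivityModel.ideal()) == pytest.approx(0.5)

    def test_saturated_binary_water_cpme_is_unity(self):
        m = ActivityModel.margules({("H2O", "CPME"): A_WC})
        comp = MixtureComposition({"H2O": X_SAT_CPME, "CPME": 1.0 - X_SAT_CPME})
        assert water_activity(comp, m) == pytest.approx(1.0, abs=1e-9)

    def test_zero_water_gives_zero(self, model):
        assert water_activity(MixtureComposition({"CPME": 1.0}), model) == 0.0


def brute_force_capacity(z_names, z, model, step=1e-6):
    """Smallest 1e-6-grid root of x·γ_w(x) = 1 (independent of the solver)."""
    xs = np.arange(step, 1.0, step)
    names = ["H2O"] + list(z_names)
    X = np.empty((len(names), len(xs)))
    X[0] = xs
    X[1:] = (1.0 - xs) * np.asarray(z)[:, None]
    g = np.log(xs) + model.ln_gamma(names, X)[0]
    idx = np.flatnonzero(g >= 0)
    return float(xs[idx[0]]) if idx.size else 1.0


class TestWaterCapacity:
    def test_pure_cpme_reproduces_printed_saturation(self):
        m = ActivityModel.margules({("H2O", "CPME"): 3.540})
        cap = water_capacity(MixtureComposition({"CPME": 1.0}), m)
        assert cap.x_sat == pytest.approx(0.0377, abs=5e-4)
        assert not cap.miscible

    def test_ideal_model_fully_miscible(self):
        cap = water_capacity(MixtureComposition({"CPME": 1.0}), ActivityModel.ideal())
        assert cap.x_sat == 1.0
        assert cap.miscible

    def test_capacity_strictly_decreasing_in_interaction_strength(self):
        caps = [water_capacity(MixtureComposition({"CPME": 1.0}),
                               ActivityModel.margules({("H2O", "CPME"): a})).x_sat
                for a in np.linspace(2.5, 5.0, 8)]
        assert all(b < a for a, b in zip(caps, caps[1:]))

    @pytest.mark.parametrize("solutes", [
        {"CPME": 1.0},
        {"CPME": 0.95, "FA": 0.05},
        {"CPME": 0.8, "FA": 0.1, "4VG": 0.1},
    ])
    def test_matches_brute_force_grid_root(self, model, solutes):
        cap = water_capacity(MixtureComposition(solutes), model)
        names = list(solutes)
        z = np.array(list(solutes.values())) / sum(solutes.values())
        bf = brute_force_capacity(names, z, model)
        assert abs(cap.x_sat - bf) <= 1e-6

    def test_water_in_solute_mix_rejected(self, model):
        with pytest.raises(DomainError):
            water_capacity(MixtureComposition({"CPME": 1.0, "H2O": 0.1}), model)

    def test_hydrophilic_solute_raises_capacity_ordering(self, model):
        """FA (more hydrophilic) raises capacity more than 4VG at equal loading."""
        base = water_capacity(MixtureComposition({"CPME": 1.0}), model).x_sat
        with_fa = water_capacity(MixtureComposition({"CPME": 0.95, "FA": 0.05}), model).x_sat
        with_vg = water_capacity(MixtureComposition({"CPME": 0.95, "4VG": 0.05}), model).x_sat
        assert with_fa > with_vg > base


class TestLLESplit:
    def test_symmetric_binary_splits_mirror_compositions(self):
        res = lle_split(MixtureComposition({"A": 0.5, "B": 0.5}), margules_binary(3.0))
        assert res.split
        xi = res.phase_i.mole_fractions()
        xii = res.phase_ii.mole_fractions()
        assert xi["A"] == pytest.approx(1.0 - xii["A"], abs=1e-8)
        assert res.residual <= 1e-8

    def test_symmetric_binary_matches_grid_scan_binodal(self):
        a = 3.0
        xs = np.arange(1e-6, 0.5, 1e-6)
        diff = xs * np.exp(a * (1 - xs) ** 2) - (1 - xs) * np.exp(a * xs ** 2)
        x_binodal = xs[np.flatnonzero(np.diff(np.sign(diff)))[0]]
        res = lle_split(MixtureComposition({"A": 0.5, "B": 0.5}), margules_binary(a))
        x_lean = min(res.phase_i.mole_fractions()["A"], res.phase_ii.mole_fractions()["A"])
        assert x_lean == pytest.approx(x_binodal, abs=2e-6)

    def test_critical_point_reports_no_split(self):
        res = lle_split(MixtureComposition({"A": 0.5, "B": 0.5}), margules_binary(2.0))
        assert not res.split

    def test_moles_conserved_exactly(self):
        comp = MixtureComposition({"A": 0.7, "B": 1.1})
        res = lle_split(comp, margules_binary(3.5))
        assert res.split
        for s in comp.species:
            total = res.phase_i.amounts[s] + res.phase_ii.amounts[s]
            assert total == pytest.approx(comp.amounts[s], abs=1e-12)

    def test_ternary_split_satisfies_isoactivity(self):
        model = ActivityModel.margules({("A", "B"): 3.2, ("A", "C"): 0.5, ("B", "C"): 0.4})
        res = lle_split(MixtureComposition({"A": 0.45, "B": 0.45, "C": 0.1}), model)
        assert res.split
        assert res.residual <= 1e-8

    def test_outside_binodal_is_single_phase(self):
        res = lle_split(MixtureComposition({"A": 0.01, "B": 0.99}), margules_binary(3.0))
        assert not res.split


class TestCalibration:
    def test_anchor_value(self):
        assert calibrate_water_cpme(0.007) == pytest.approx(A_WC, abs=1e-9)
        assert A_WC == pytest.approx(3.540, abs=1e-3)

    @pytest.mark.parametrize("w", [0.003, 0.007, 0.015])
    def test_round_trip_reproduces_target(self, w):
        a = calibrate_water_cpme(w)
        m = ActivityModel.margules({("H2O", "CPME"): a})
        cap = water_capacity(MixtureComposition({"CPME": 1.0}), m)
        x_target = (w / _MW) / (w / _MW + (1 - w) / _MC)
        assert abs(cap.x_sat - x_target) <= 1e-6

    def test_miscible_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_water_cpme(0.999)

    def test_out_of_range_mass_fraction_raises(self):
        with pytest.raises(DomainError):
            calibrate_water_cpme(1.5)
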