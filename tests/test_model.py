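"""Closed-form concentration equations against the numeric ODE oracle."""

import dataclasses
import math

import numpy as np
import pytest

from dendripk import (
    DoseSpec,
    LinkerKinetics,
    closed_form_constants,
    conjugated_plasma_conc,
    conjugated_tumour_conc,
    ode_reference_solution,
    released_plasma_conc_approx,
    released_tumour_conc,
    total_tumour_conc,
)
from dendripk.errors import SingularParameterError
from dendripk.model import ApproximationDomainWarning, exp_divided_difference

T_GRID = np.linspace(0.0, 72.0, 289)


def _rel_to_peak(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.max(np.abs(a - b)) / np.max(np.abs(b)))


class TestConjugatedPlasma:
    def test_bolus_initial_concentration(self, table2, dose):
        disp, _, linkers = table2
        c = conjugated_plasma_conc(linkers["SPL-8932"], disp, dose, [0.0])
        # 10 mg/kg over 59.2 mL/kg of plasma
        assert c.values[0] == pytest.approx(10.0 / 59.2 * 1e3, rel=1e-12)

    def test_strictly_decreasing(self, table2, dose):
        disp, _, linkers = table2
        c = conjugated_plasma_conc(linkers["SPL-8932"], disp, dose, T_GRID)
        assert np.all(np.diff(c.values) < 0)

    def test_no_elimination_limit_is_constant(self, table2, dose):
        disp, _, _ = table2
        slow = dataclasses.replace(disp, k_res=1e-12)
        inert = LinkerKinetics.from_rate("inert", 1e-12)
        c = conjugated_plasma_conc(inert, slow, dose, np.linspace(0, 24, 50))
        assert np.allclose(c.values, c.values[0], rtol=1e-9)


class TestConjugatedTumour:
    def test_zero_at_time_zero(self, table2, dose):
        disp, _, linkers = table2
        c = conjugated_tumour_conc(linkers["SPL-8977"], disp, dose, [0.0])
        assert c.values[0] == 0.0

    def test_no_release_plateau(self, table2, dose):
        """With negligible hydrolysis the tumour pool saturates at D k_ext/(V_tu k_res)."""
        disp, _, _ = table2
        inert = LinkerKinetics.from_rate("inert", 1e-12)
        c = conjugated_tumour_conc(inert, disp, dose, [1e4])
        plateau = dose.dose_abs(disp.body_mass) / disp.V_tu * disp.k_ext / disp.k_res * 1e3
        assert c.values[0] == pytest.approx(plateau, rel=1e-6)

    def test_unimodal(self, table2, dose):
        disp, _, linkers = table2
        c = conjugated_tumour_conc(linkers["SPL-8977"], disp, dose, np.linspace(0, 400, 2000))
        signs = np.sign(np.diff(c.values))
        changes = np.sum(np.diff(signs[signs != 0]) != 0)
        assert changes == 1


class TestAgainstOdeOracle:
    @pytest.mark.parametrize("label", ["SPL-8931", "SPL-8932", "SPL-8933",
                                       "SPL-8974", "SPL-8976", "SPL-8977"])
    def test_closed_forms_agree(self, table2, dose, label):
        disp, rel, linkers = table2
        linker = linkers[label]
        ode = ode_reference_solution(linker, disp, rel, dose, T_GRID)
        pairs = [
            (conjugated_plasma_conc(linker, disp, dose, T_GRID), "plasma_conjugated"),
            (conjugated_tumour_conc(linker, disp, dose, T_GRID), "tumour_conjugated"),
            (released_tumour_conc(linker, disp, rel, dose, T_GRID), "tumour_released"),
            (total_tumour_conc(linker, disp, rel, dose, T_GRID), "tumour_total"),
        ]
        for closed, key in pairs:
            assert _rel_to_peak(closed.values, ode.series[key].values) < 1e-6

    def test_mass_conservation(self, table2, dose):
        disp, rel, linkers = table2
        ode = ode_reference_solution(linkers["SPL-8977"], disp, rel, dose, T_GRID)
        assert np.max(np.abs(ode.mass_balance)) < 1e-6

    def test_zero_dose_all_zero(self, table2):
        disp, rel, linkers = table2
        ode = ode_reference_solution(linkers["SPL-8977"], disp, rel, DoseSpec(0.0), T_GRID)
        assert all(np.all(s.values == 0) for s in ode.series.values())

    def test_removable_singularity_k_h_equals_k_tu(self, table2, dose):
        """k_h = k_tu exactly (half-life ~13.1 h) must evaluate cleanly."""
        disp, rel, linkers = table2
        linker = LinkerKinetics.from_rate("critical", rel.k_tu)
        c = released_tumour_conc(linker, disp, rel, dose, T_GRID)
        ode = ode_reference_solution(linker, disp, rel, dose, T_GRID)
        assert np.all(np.isfinite(c.values))
        assert _rel_to_peak(c.values, ode.series["tumour_released"].values) < 1e-6


class TestReleasedTumour:
    def test_zero_at_time_zero_and_nonnegative(self, table2, dose):
        disp, rel, linkers = table2
        c = released_tumour_conc(linkers["SPL-8932"], disp, rel, dose, T_GRID)
        assert c.values[0] == 0.0
        assert np.all(c.values >= 0)

    def test_dose_linearity(self, table2):
        disp, rel, linkers = table2
        c1 = released_tumour_conc(linkers["SPL-8977"], disp, rel, DoseSpec(10.0), T_GRID)
        c2 = released_tumour_conc(linkers["SPL-8977"], disp, rel, DoseSpec(20.0), T_GRID)
        np.testing.assert_allclose(c2.values, 2.0 * c1.values, rtol=1e-12)

    def test_unimodal(self, table2, dose):
        disp, rel, linkers = table2
        c = released_tumour_conc(linkers["SPL-8932"], disp, rel, dose,
                                 np.linspace(0, 300, 3000))
        signs = np.sign(np.diff(c.values))
        changes = np.sum(np.diff(signs[signs != 0]) != 0)
        assert changes == 1


class TestReleasedPlasmaApprox:
    def test_zero_at_time_zero(self, table2, dose):
        disp, rel, linkers = table2
        c = released_plasma_conc_approx(linkers["SPL-8977"], disp, rel, dose, [0.0])
        assert c.values[0] == 0.0

    def test_peak_time_closed_form(self, table2, dose):
        disp, rel, linkers = table2
        linker = linkers["SPL-8977"]
        a = rel.k_el + rel.k12 + rel.k13
        b = linker.k_h + disp.k_res
        t_star = math.log(a / b) / (a - b)
        fine = np.linspace(1e-4, 2.0, 20001)
        c = released_plasma_conc_approx(linker, disp, rel, dose, fine)
        assert fine[np.argmax(c.values)] == pytest.approx(t_star, abs=2e-4)

    def test_warns_beyond_two_hours(self, table2, dose):
        disp, rel, linkers = table2
        with pytest.warns(ApproximationDomainWarning):
            released_plasma_conc_approx(linkers["SPL-8977"], disp, rel, dose, [3.0])

    def test_never_exceeds_full_ode_solution(self, table2, dose):
        """Neglecting peripheral backflow makes the short-time form an underestimate."""
        disp, rel, linkers = table2
        t = np.linspace(1e-3, 2.0, 200)
        for label in ("SPL-8931", "SPL-8977", "SPL-8933"):
            approx = released_plasma_conc_approx(linkers[label], disp, rel, dose, t)
            ode = ode_reference_solution(linkers[label], disp, rel, dose, t)
            full = ode.series["plasma_released"].values
            assert np.all(approx.values <= full * (1 + 1e-9))


class TestClosedFormConstants:
    def test_identity_and_k_el(self, table2):
        disp, rel, linkers = table2
        consts = closed_form_constants(linkers["SPL-8932"], disp, rel)
        assert consts.beta + consts.gamma - consts.delta == pytest.approx(0.0, abs=1e-12)
        assert consts.k_el == pytest.approx(0.0296 / 0.0042, rel=1e-12)

    def test_alpha_linear_in_k_ext(self, table2):
        disp, rel, linkers = table2
        doubled = dataclasses.replace(disp, k_ext=2 * disp.k_ext)
        a1 = closed_form_constants(linkers["SPL-8932"], disp, rel).alpha
        a2 = closed_form_constants(linkers["SPL-8932"], doubled, rel).alpha
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_singular_configuration_rejected_with_named_denominator(self, table2):
        disp, rel, _ = table2
        critical = LinkerKinetics.from_rate("critical", rel.k_tu)
        with pytest.raises(SingularParameterError, match="k_h - k_tu"):
            closed_form_constants(critical, disp, rel)


class TestTotalTumour:
    def test_total_dominates_components(self, table2, dose):
        disp, rel, linkers = table2
        linker = linkers["SPL-8977"]
        total = total_tumour_conc(linker, disp, rel, dose, T_GRID)
        conj = conjugated_tumour_conc(linker, disp, dose, T_GRID)
        free = released_tumour_conc(linker, disp, rel, dose, T_GRID)
        assert np.all(total.values >= conj.values)
        assert np.all(total.values >= free.values)
        assert total.species == "total"


def test_exp_divided_difference_matches_naive_form():
    t = np.linspace(0.0, 50.0, 101)
    p, q = 0.3, 0.07
    naive = (np.exp(-p * t) - np.exp(-q * t)) / (q - p)
    np.testing.assert_allclose(exp_divided_difference(p, q, t), naive, rtol=1e-12)
    # removable limit p == q
    np.testing.assert_allclose(exp_divided_difference(p, p, t), t * np.exp(-p * t),
                               rtol=1e-12)
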