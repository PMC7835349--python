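"""Recovery of k_res, k_ext and k_tu from concentration-time data."""

import dataclasses

import numpy as np
import pytest

from dendripk import (
    ConcentrationSeries,
    ConjugateObservations,
    DoseSpec,
    LinkerKinetics,
    MultiConjugateDataset,
    NoiseModel,
    StudyDesign,
    conjugated_plasma_conc,
    fit_kres,
    fit_tumour_params,
    generate_in_vivo_dataset,
    released_tumour_conc,
)
from dendripk.errors import UnidentifiableError

TRIO = ("SPL-8931", "SPL-8932", "SPL-8933")


def _trio_design(table2, **kwargs):
    _, _, linkers = table2
    return StudyDesign(conjugates=tuple(linkers[l] for l in TRIO), **kwargs)


class TestFitKres:
    def test_noiseless_self_consistency(self, table2, dose):
        disp, _, linkers = table2
        linker = linkers["SPL-8932"]
        t = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
        plasma = conjugated_plasma_conc(linker, disp, dose, t)
        observed = ConcentrationSeries(t, plasma.values, "plasma", "total", linker.label)
        fit = fit_kres(observed, linker, dose, disp.V_pl)
        assert fit.estimates["k_res"] == pytest.approx(0.21, rel=1e-6)

    def test_non_releasing_conjugate_returns_total_decay(self, table2, dose):
        """With k_h ~ 0 the whole plasma decay is attributed to RES uptake."""
        disp, _, _ = table2
        inert = LinkerKinetics.from_rate("inert", 1e-12)
        t = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        c0 = dose.dose_per_kg / disp.V_pl * 1e3
        observed = ConcentrationSeries(t, c0 * np.exp(-0.37 * t), "plasma", "total")
        fit = fit_kres(observed, inert, dose, disp.V_pl)
        assert fit.estimates["k_res"] == pytest.approx(0.37, rel=1e-6)

    def test_flat_profile_unidentifiable(self, table2, dose):
        disp, _, linkers = table2
        t = np.array([1.0, 2.0, 5.0])
        c0 = dose.dose_per_kg / disp.V_pl * 1e3
        flat = ConcentrationSeries(t, np.full(3, c0), "plasma", "total")
        with pytest.raises(UnidentifiableError):
            fit_kres(flat, linkers["SPL-8932"], dose, disp.V_pl)

    def test_noisy_median_within_ten_percent(self, table2):
        disp, rel, linkers = table2
        design = _trio_design(table2)
        estimates = []
        for seed in range(20):
            ds = generate_in_vivo_dataset(design, disp, rel,
                                          NoiseModel(cv_or_sd=0.15, seed=seed))
            fit = fit_kres(ds.plasma_total["SPL-8932"], linkers["SPL-8932"],
                           design.dose, disp.V_pl)
            estimates.append(fit.estimates["k_res"])
        assert abs(np.median(estimates) / 0.21 - 1) < 0.10


class TestFitTumourParams:
    def test_noiseless_exact_recovery(self, table2):
        disp, rel, _ = table2
        design = _trio_design(table2)
        ds = generate_in_vivo_dataset(design, disp, rel, NoiseModel(cv_or_sd=0.0, seed=0))
        fit = fit_tumour_params(ds.tumour, disp, rel)
        assert fit.estimates["k_ext"] == pytest.approx(3.8e-4, rel=1e-5)
        assert fit.estimates["k_tu"] == pytest.approx(0.053, rel=1e-5)
        assert fit.converged

    def test_objective_at_estimate_not_worse_than_truth(self, table2, dose):
        disp, rel, linkers = table2
        rng_t = np.repeat([0.5, 2.0, 8.0, 24.0], 2)
        entries = []
        for label in TRIO:
            truth = released_tumour_conc(linkers[label], disp, rel, dose, rng_t)
            obs = ConcentrationSeries(rng_t, truth.values, "tumour", "released", label)
            entries.append(ConjugateObservations(linkers[label], obs, dose))
        fit = fit_tumour_params(MultiConjugateDataset(tuple(entries)), disp, rel)
        # truth is the global minimum (zero residual) for noiseless data
        assert fit.residual_ss <= 1e-12

    def test_concentration_scaling_moves_kext_only(self, table2, dose):
        disp, rel, linkers = table2
        t = np.array([0.5, 1.0, 2.0, 5.0, 24.0, 48.0])
        def dataset(scale):
            entries = []
            for label in TRIO:
                truth = released_tumour_conc(linkers[label], disp, rel, dose, t)
                obs = ConcentrationSeries(t, scale * truth.values, "tumour",
                                          "released", label)
                entries.append(ConjugateObservations(linkers[label], obs, dose))
            return MultiConjugateDataset(tuple(entries))
        base = fit_tumour_params(dataset(1.0), disp, rel)
        scaled = fit_tumour_params(dataset(10.0), disp, rel)
        assert scaled.estimates["k_ext"] == pytest.approx(10 * base.estimates["k_ext"], rel=1e-4)
        assert scaled.estimates["k_tu"] == pytest.approx(base.estimates["k_tu"], rel=1e-4)

    def test_noisy_recovery_within_quarter(self, table2):
        disp, rel, _ = table2
        design = _trio_design(table2, animals_per_timepoint=2)
        ds = generate_in_vivo_dataset(design, disp, rel, NoiseModel(cv_or_sd=0.20, seed=11))
        fit = fit_tumour_params(ds.tumour, disp, rel)
        assert fit.estimates["k_ext"] == pytest.approx(3.8e-4, rel=0.25)
        assert fit.estimates["k_tu"] == pytest.approx(0.053, rel=0.25)

    def test_standard_errors_reported_positive(self, table2):
        disp, rel, _ = table2
        design = _trio_design(table2)
        ds = generate_in_vivo_dataset(design, disp, rel, NoiseModel(cv_or_sd=0.10, seed=5))
        fit = fit_tumour_params(ds.tumour, disp, rel)
        assert fit.stderr["k_ext"] > 0
        assert fit.stderr["k_tu"] > 0
        assert fit.n_obs == ds.tumour.n_obs


class TestEstimatorCalibration:
    def test_coverage_of_two_sigma_intervals(self, table2):
        """±2·stderr intervals should cover the truth in most replicates."""
        disp, rel, _ = table2
        design = _trio_design(table2, animals_per_timepoint=2)
        hits = {"k_ext": 0, "k_tu": 0}
        truth = {"k_ext": 3.8e-4, "k_tu": 0.053}
        n_rep = 25
        for seed in range(n_rep):
            ds = generate_in_vivo_dataset(design, disp, rel,
                                          NoiseModel(cv_or_sd=0.20, seed=1000 + seed))
            fit = fit_tumour_params(ds.tumour, disp, rel)
            for name in hits:
                k, s = fit.estimates[name], fit.stderr[name]
                if k - 2 * s <= truth[name] <= k + 2 * s:
                    hits[name] += 1
        assert hits["k_ext"] / n_rep >= 0.80
        assert hits["k_tu"] / n_rep >= 0.80
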