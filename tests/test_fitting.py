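"""Staged rate-constant estimation, uncertainties, and pathway comparison."""

import json

import numpy as np
import pandas as pd
import pytest

from oxcascade import (
    RateParameters,
    TimeCourse,
    Variant,
    build_cascade,
    compare_pathways,
    estimate_parameter_sd,
    fit_direct_start,
    fit_staged,
    fit_step1,
    fit_step2,
    rmsd_tot,
    simulate,
)
from oxcascade.synthdata import ExperimentDesign, NoiseLossModel, generate_timecourse

K_TM = 1.75e-5
OX0 = 1.0e-3


def noiseless(model, start="5hm"):
    tc, _ = generate_timecourse(model, ExperimentDesign(start_species=start))
    return tc


class TestStagedProtocol:
    def test_recovers_uracil_cascade_constants(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        f1, f2 = fit_staged(tc, "direct", K_TM, oxidant_init=OX0)
        assert f1.value("k_hm") == pytest.approx(0.66, abs=1e-3)
        assert f2.value("k_f") == pytest.approx(0.43, abs=1e-3)
        assert f1.fitted_init == pytest.approx(2.0e-4, rel=1e-3)
        assert f1.converged and f2.converged

    def test_recovers_hydrate_route_constant(self, aza_hydrate_model):
        tc = noiseless(aza_hydrate_model)
        f1, f2 = fit_staged(tc, "hydrate_route", K_TM, 0.09, oxidant_init=OX0)
        assert f1.value("k_hm") == pytest.approx(1.87, abs=2e-3)
        assert f2.value("k_dhm") == pytest.approx(0.24, abs=1e-3)

    def test_zero_rate_data_recovers_zero(self):
        m = build_cascade("direct", RateParameters(k_TM=K_TM))
        tc = noiseless(m)
        f1 = fit_step1(tc, "direct", K_TM, oxidant_init=OX0)
        assert f1.value("k_hm") == pytest.approx(0.0, abs=1e-6)

    def test_step1_excludes_final_time_point(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        f1 = fit_step1(tc, "direct", K_TM, oxidant_init=OX0)
        assert f1.excluded_times == [86_400.0]
        assert f1.n_points == 11

    def test_step2_objective_excludes_acid_by_default(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        f2 = fit_step2(tc, "direct", 0.66, K_TM, oxidant_init=OX0)
        assert "5ca" not in f2.included_species
        assert set(f2.included_species) == {"5hm", "5f"}

    def test_step2_unidentifiable_without_intermediate(self):
        """No substrate conversion -> second-step constant leaves no signature."""
        m = build_cascade("direct", RateParameters(k_TM=K_TM, k_hm=0.0, k_f=0.4))
        tc = noiseless(m)
        f2 = fit_step2(tc, "direct", 0.0, K_TM, oxidant_init=OX0)
        assert not f2.converged

    def test_noisy_replicates_unbiased(self):
        """Mean recovery over 2%-noise replicates is within 2 SE of truth."""
        m = build_cascade("direct", RateParameters(k_TM=K_TM, k_hm=0.51, k_f=0.53))
        design = ExperimentDesign()
        noise = NoiseLossModel(integral_cv=0.02, loss_rate=0.0)
        values = []
        for seed in range(20):
            tc, _ = generate_timecourse(m, design, noise, seed=7000 + seed)
            f1 = fit_step1(tc, "direct", K_TM, downstream_k=0.53, oxidant_init=OX0)
            values.append(f1.value("k_hm"))
        values = np.array(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 0.51) < 2 * se + 1e-12


class TestDirectStart:
    def test_formyl_start_direct_route(self):
        m = build_cascade("direct", RateParameters(k_TM=K_TM, k_f=0.48))
        tc = noiseless(m, start="5f")
        fit = fit_direct_start(tc, "direct", K_TM, oxidant_init=OX0)
        assert fit.value("k_f") == pytest.approx(0.48, abs=1e-3)
        assert fit.measurement == "direct"

    def test_stiff_low_hydration_regime(self):
        m = build_cascade(
            "hydrate_route", RateParameters(k_TM=K_TM, k_dhm=364.2, k_for=1000.0), 2.64e-5
        )
        tc = noiseless(m, start="5f")
        fit = fit_direct_start(tc, "hydrate_route", K_TM, 2.64e-5, oxidant_init=OX0)
        assert fit.value("k_dhm") == pytest.approx(364.2, rel=0.01)

    def test_constant_concentration_gives_zero_rate(self):
        m = build_cascade("direct", RateParameters(k_TM=K_TM))
        tc = noiseless(m, start="5f")
        fit = fit_direct_start(tc, "direct", K_TM, oxidant_init=OX0)
        assert fit.value("k_f") == pytest.approx(0.0, abs=1e-6)

    def test_direct_and_indirect_measurements_agree(self, uracil_direct_model):
        """One truth, two protocols: formyl-start vs second-step estimates."""
        tc_cascade = noiseless(uracil_direct_model)
        _, f2 = fit_staged(tc_cascade, "direct", K_TM, oxidant_init=OX0)
        m_f = build_cascade("direct", RateParameters(k_TM=K_TM, k_f=0.43))
        tc_f = noiseless(m_f, start="5f")
        fd = fit_direct_start(tc_f, "direct", K_TM, oxidant_init=OX0)
        assert fd.value("k_f") == pytest.approx(f2.value("k_f"), rel=0.02)


class TestRmsdTot:
    def test_zero_for_model_fitted_to_own_noiseless_data(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        r = rmsd_tot(
            uracil_direct_model, tc, ["5hm", "5f"], {"5hm": 2e-4, "TM1": OX0}
        )
        assert r < 1e-10

    def test_constant_residual_equals_its_magnitude(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        shift = 3.0e-6
        frame = tc.frame.copy()
        for s in ("5hm", "5f"):
            frame[s] = frame[s] + shift
        shifted = TimeCourse(frame, meta=tc.meta)
        r = rmsd_tot(
            uracil_direct_model, shifted, ["5hm", "5f"], {"5hm": 2e-4, "TM1": OX0}
        )
        assert r == pytest.approx(shift, rel=1e-6)

    def test_empty_species_set_rejected(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        with pytest.raises(ValueError, match="included_species"):
            rmsd_tot(uracil_direct_model, tc, [], {"5hm": 2e-4, "TM1": OX0})


class TestParameterSd:
    def test_noiseless_fit_has_negligible_sd(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        f1 = fit_step1(tc, "direct", K_TM, downstream_k=0.43, oxidant_init=OX0)
        assert f1.fitted["k_hm"].sd < 1e-6 * f1.value("k_hm")

    def test_singular_jacobian_flagged(self):
        sd = estimate_parameter_sd(np.zeros((10, 2)), np.ones(10))
        assert np.all(np.isnan(sd))

    def test_matches_closed_form_for_exponential_decay(self):
        """Pseudo-first-order decay: Gauss-Newton sd vs the analytic SE."""
        k_true, c0, sigma = 0.51, 1.0e-5, 2.0e-7
        times = np.linspace(60.0, 8000.0, 9)
        decay = c0 * np.exp(-k_true * OX0 * times)
        # closed form: SE = sigma / sqrt(sum (dy/dk)^2), dy/dk = -c0*[TM1]*t*exp(-k*[TM1]*t)
        dydk = -c0 * OX0 * times * np.exp(-k_true * OX0 * times)
        se_oracle = sigma / np.sqrt(np.sum(dydk**2))
        rng = np.random.default_rng(42)
        sds = []
        for _ in range(50):
            obs = decay + rng.normal(0.0, sigma, size=times.size)
            frame = pd.DataFrame({"time_s": times, "5hm": np.clip(obs, 0, None)})
            tc = TimeCourse(frame, meta={"init": {"TM1": OX0}})
            f1 = fit_step1(
                tc, "direct", 0.0, fit_init=False, t_cut=None, oxidant_init=OX0,
                n_starts=1,
            )
            sds.append(f1.fitted["k_hm"].sd)
        assert np.mean(sds) == pytest.approx(se_oracle, rel=0.2)

    def test_sd_magnitude_consistent_with_reported_uncertainty(self, uracil_direct_model):
        """2%-noise replicates give dk within a factor of 3 of 0.02."""
        design = ExperimentDesign()
        noise = NoiseLossModel(integral_cv=0.02, loss_rate=0.0)
        sds = []
        for seed in range(8):
            tc, _ = generate_timecourse(uracil_direct_model, design, noise, seed=500 + seed)
            f1 = fit_step1(tc, "direct", K_TM, downstream_k=0.43, oxidant_init=OX0)
            sds.append(f1.fitted["k_hm"].sd)
        median_sd = float(np.median(sds))
        assert 0.02 / 3 < median_sd < 0.02 * 3


class TestComparePathways:
    def test_hydrate_truth_ranks_hydrate_first(self, aza_hydrate_model):
        tc = noiseless(aza_hydrate_model)
        ranked = compare_pathways(
            tc, 1.87, K_TM, 0.09, init_substrate=2e-4, oxidant_init=OX0
        )
        assert ranked[0].variant is Variant.HYDRATE_ROUTE
        assert ranked[0].rmsd_tot < ranked[1].rmsd_tot

    def test_low_hydration_routes_indistinguishable(self):
        m = build_cascade("direct", RateParameters(k_TM=K_TM, k_hm=0.66, k_f=0.46))
        tc = noiseless(m)
        ranked = compare_pathways(
            tc, 0.66, K_TM, 2.94e-4, init_substrate=2e-4, oxidant_init=OX0
        )
        r = {x.variant: x.rmsd_tot for x in ranked}
        scale = 2e-4
        gap = abs(r[Variant.DIRECT] - r[Variant.HYDRATE_ROUTE])
        assert gap / scale < 1e-6  # equivalent families on pooled-formyl data

    def test_dual_reported_with_warning_when_requested(self, aza_hydrate_model):
        tc = noiseless(aza_hydrate_model)
        ranked = compare_pathways(
            tc, 1.87, K_TM, 0.09, init_substrate=2e-4, oxidant_init=OX0,
            include_dual=True,
        )
        dual = [r for r in ranked if r.variant is Variant.DUAL]
        assert len(dual) == 1
        assert "ill-conditioned" in dual[0].message

    def test_species_free_time_course_rejected(self):
        frame = pd.DataFrame({"time_s": [0.0, 60.0, 120.0, 240.0], "other": [1.0] * 4})
        tc = TimeCourse(frame)
        with pytest.raises(ValueError, match="no nucleobase"):
            compare_pathways(tc, 0.66, K_TM, 0.09, init_substrate=2e-4, oxidant_init=OX0)


class TestObjectiveChoices:
    def test_including_lossy_acid_degrades_recovery(self):
        """Acid-specific signal loss biases the fit only if 5ca enters the objective."""
        m = build_cascade("direct", RateParameters(k_TM=K_TM, k_hm=0.66, k_f=0.43))
        noise = NoiseLossModel(
            integral_cv=0.0, loss_rate=0.0, acid_extra_loss_rate=3.0e-5
        )
        tc, _ = generate_timecourse(m, ExperimentDesign(), noise, seed=1)
        excl = fit_step2(tc, "direct", 0.66, K_TM, oxidant_init=OX0, exclude_acid=True)
        incl = fit_step2(tc, "direct", 0.66, K_TM, oxidant_init=OX0, exclude_acid=False)
        err_excl = abs(excl.value("k_f") - 0.43)
        err_incl = abs(incl.value("k_f") - 0.43)
        assert err_excl < err_incl

    def test_deterministic_serialization(self, uracil_direct_model):
        tc = noiseless(uracil_direct_model)
        runs = [
            fit_staged(tc, "direct", K_TM, oxidant_init=OX0) for _ in range(2)
        ]
        dumps = [
            json.dumps([f1.to_dict(), f2.to_dict()], sort_keys=True)
            for f1, f2 in runs
        ]
        assert dumps[0] == dumps[1]
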