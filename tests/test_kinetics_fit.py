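"""Trace averaging, exponential fitting, model selection, regression and
affinity-table derivation."""

import numpy as np
import pandas as pd
import pytest

from brr2allo.kinetics.fit import (
    AmbiguousPhaseWarning,
    ExponentialFit,
    RateConstantSet,
    TitrationSeries,
    assign_phases,
    derive_affinity_table,
    fit_exponentials,
    fold_ratios,
    normalize_and_average,
    regress_kapp,
    select_phase_count,
)
from brr2allo.kinetics.model import (
    BindingScheme,
    BindingSite,
    ExperimentSpec,
    KineticTrace,
    model_association,
)
from brr2allo.synthetic import KineticsDesign, generate_kinetics_dataset


def _trace(k=2.0, amp=-1.0, f_inf=2.0, t_max=5.0, n=500):
    t = np.geomspace(1e-3, t_max, n)
    return KineticTrace(t, f_inf + amp * np.exp(-k * t))


class TestNormalizeAndAverage:
    def test_identical_traces_average_to_normalized_input(self):
        tr = _trace()
        out = normalize_and_average([tr] * 7)
        np.testing.assert_allclose(out.signal, tr.signal / tr.signal[0])
        assert out.meta["n_averaged"] == 7

    def test_single_trace_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_average([_trace()])

    def test_nonpositive_initial_signal_rejected(self):
        t = np.linspace(0.0, 1.0, 50)
        bad = KineticTrace(t, np.linspace(-1.0, 1.0, 50))
        with pytest.raises(ValueError, match="F_0"):
            normalize_and_average([bad, bad])

    def test_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0.0, 1.0, 4000)
        sigma, n = 0.05, 7
        traces = [
            KineticTrace(t, 1.0 + rng.normal(0, sigma, t.size)) for _ in range(n)
        ]
        out = normalize_and_average(traces)
        assert np.std(out.signal) == pytest.approx(sigma / np.sqrt(n), rel=0.1)

    def test_differing_grids_resampled(self):
        a = _trace(n=400)
        b = KineticTrace(np.geomspace(1e-3, 5.0, 700), _trace(n=700).signal)
        out = normalize_and_average([a, b])
        assert out.time.shape == a.time.shape


class TestFitExponentials:
    def test_noiseless_single_exponential_exact_recovery(self):
        fit = fit_exponentials(_trace(k=6.9, amp=-0.8, f_inf=1.5), 1)
        assert fit.converged
        assert fit.k_app[0] == pytest.approx(6.9, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(-0.8, rel=1e-6)
        assert fit.f_inf == pytest.approx(1.5, rel=1e-6)

    def test_two_phase_recovery_with_noise(self):
        """Rates 13.8 and 0.55 1/s, 1% noise on a log grid, many seeds."""
        t = np.geomspace(1e-4, 15.0, 1000)
        clean = 2.0 - 0.45 * np.exp(-13.8 * t) - 0.55 * np.exp(-0.55 * t)
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            fit = fit_exponentials(
                KineticTrace(t, clean + rng.normal(0, 0.01, t.size)), 2
            )
            ok = abs(fit.k_app[0] - 13.8) <= 3 * fit.k_app_se[0] and abs(
                fit.k_app[1] - 0.55
            ) <= 3 * fit.k_app_se[1]
            hits += ok
        assert hits >= 0.9 * n_seeds

    def test_widely_separated_rates_recovered(self):
        # chase-like: three orders of magnitude between phases
        t = np.geomspace(1e-3, 7000.0, 1000)
        clean = 1.0 + 0.45 * np.exp(-1.3 * t) + 0.55 * np.exp(-1e-3 * t)
        fit = fit_exponentials(KineticTrace(t, clean), 2)
        # slow phase and baseline are strongly correlated, limiting the
        # attainable precision even on noiseless data
        assert fit.k_app[0] == pytest.approx(1.3, rel=1e-3)
        assert fit.k_app[1] == pytest.approx(1e-3, rel=1e-3)

    def test_constant_trace_flagged_non_identifiable(self):
        t = np.geomspace(1e-3, 5.0, 100)
        fit = fit_exponentials(KineticTrace(t, np.ones_like(t)), 1)
        assert not fit.converged
        assert any("non-identifiable" in f for f in fit.flags)

    def test_phases_reported_fast_to_slow(self):
        t = np.geomspace(1e-4, 50.0, 800)
        clean = 2.0 - 0.5 * np.exp(-8.0 * t) - 0.5 * np.exp(-0.3 * t)
        fit = fit_exponentials(KineticTrace(t, clean), 2)
        assert fit.k_app[0] > fit.k_app[1]

    def test_too_few_points_rejected(self):
        t = np.geomspace(1e-3, 1.0, 5)
        with pytest.raises(ValueError):
            fit_exponentials(KineticTrace(t, np.exp(-t)), 1)

    def test_residuals_uncorrelated_on_well_specified_data(self):
        rng = np.random.default_rng(5)
        t = np.geomspace(1e-3, 5.0, 1000)
        y = 2.0 - np.exp(-2.0 * t) + rng.normal(0, 0.01, t.size)
        fit = fit_exponentials(KineticTrace(t, y), 1)
        assert 1.5 <= fit.durbin_watson <= 2.5


class TestSelectPhaseCount:
    def test_single_site_trace_selects_one_phase(self):
        scheme = BindingScheme((BindingSite("NC", 1.0, 1.9),), 0.4, 2.0)
        tr = model_association(scheme, ExperimentSpec("association", 5.0, (1e-3, 3.0)))
        rng = np.random.default_rng(0)
        noisy = KineticTrace(tr.time, tr.signal + rng.normal(0, 0.004, tr.time.size))
        assert select_phase_count(noisy).n_phases == 1

    def test_two_site_trace_selects_two_phases(self):
        scheme = BindingScheme(
            (BindingSite("NC", 2.5, 1.3, 0.45), BindingSite("CC", 0.4, 0.001, 0.55)),
            0.2,
            2.0,
        )
        tr = model_association(scheme, ExperimentSpec("association", 5.0, (1e-4, 30.0)))
        rng = np.random.default_rng(0)
        noisy = KineticTrace(tr.time, tr.signal + rng.normal(0, 0.004, tr.time.size))
        sel = select_phase_count(noisy)
        assert sel.n_phases == 2
        assert sel.rate_ratio > 3

    def test_pure_noise_rarely_rejects_one_phase(self):
        t = np.geomspace(1e-3, 10.0, 200)
        picks = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tr = KineticTrace(t, 1.0 + 0.3 * np.exp(-t) + rng.normal(0, 0.02, t.size))
            picks.append(select_phase_count(tr).n_phases)
        assert np.mean(np.array(picks) == 1) >= 0.95


class TestRegressKapp:
    def test_exact_points_recovered_exactly(self):
        pts = [(c, 2.5 * c + 1.3, 0.0, 1) for c in (1.0, 2.5, 5.0, 10.0, 20.0)]
        reg = regress_kapp(TitrationSeries(pts, "NC"))
        assert reg.k1 == pytest.approx(2.5, rel=1e-12)
        assert reg.k_minus1 == pytest.approx(1.3, rel=1e-12)

    def test_constant_kapp_gives_zero_slope(self):
        pts = [(c, 4.2, 0.0, 1) for c in (1.0, 5.0, 20.0)]
        reg = regress_kapp(TitrationSeries(pts, "NC"))
        assert reg.k1 == pytest.approx(0.0, abs=1e-12)
        assert reg.k_minus1 == pytest.approx(4.2, rel=1e-12)

    def test_negative_intercept_flagged_not_raised(self):
        pts = [(c, 2.0 * c - 0.5, 0.0, 1) for c in (1.0, 5.0, 20.0)]
        reg = regress_kapp(TitrationSeries(pts, "NC"))
        assert reg.k_minus1 < 0
        assert reg.flags

    def test_fewer_than_three_concentrations_rejected(self):
        with pytest.raises(ValueError):
            TitrationSeries([(1.0, 3.0, 0.0, 1), (2.0, 5.0, 0.0, 1)], "NC")

    def test_weighted_regression_downweights_noisy_points(self):
        pts = [
            (1.0, 3.8, 0.01, 3),
            (2.5, 7.55, 0.01, 3),
            (5.0, 13.8, 0.01, 3),
            (10.0, 40.0, 5.0, 3),  # outlier with huge SD
        ]
        w = regress_kapp(TitrationSeries(pts, "NC"), weighted=True)
        u = regress_kapp(TitrationSeries(pts, "NC"), weighted=False)
        assert abs(w.k1 - 2.5) < abs(u.k1 - 2.5)


def _fit_with_rates(k_fast, k_slow):
    return ExponentialFit(
        n_phases=2,
        k_app=[max(k_fast, k_slow), min(k_fast, k_slow)],
        amplitudes=[-0.5, -0.5],
        f_inf=2.0,
        k_app_se=[0.01, 0.01],
        amplitude_se=[0.01, 0.01],
        f_inf_se=0.01,
        residual_ss=0.0,
        n_points=100,
        converged=True,
    )


class TestAssignPhases:
    def test_fast_phase_is_nc(self):
        assignment = assign_phases(_fit_with_rates(13.8, 0.55))
        assert assignment == {"NC": 0, "CC": 1}

    def test_close_rates_warn(self):
        with pytest.warns(AmbiguousPhaseWarning):
            assign_phases(_fit_with_rates(1.0, 0.5))

    def test_input_order_invariance(self):
        a = assign_phases(_fit_with_rates(13.8, 0.55))
        b = assign_phases(_fit_with_rates(0.55, 13.8))
        assert a == b

    def test_calibration_overlap_check_warns_on_mismatch(self):
        calib = RateConstantSet.from_reference(["hBrr2-NC", "hBrr2-CC"])
        # fabricated fast rate far above any calibrated NC k_app at 5 uM
        with pytest.warns(AmbiguousPhaseWarning):
            assign_phases(
                _fit_with_rates(500.0, 0.01),
                calibration=calib,
                nucleotide="mant-ADP",
                nucleotide_conc=5.0,
            )


class TestAffinityTable:
    def test_kd_identity_on_published_rates(self):
        rates = RateConstantSet.from_reference(["hBrr2-CC"])
        aff = derive_affinity_table(rates)
        row = aff[(aff.nucleotide == "mant-ADP")].iloc[0]
        assert row.kd_uM == pytest.approx(0.004, rel=1e-12)  # 4 nM

    def test_isolated_cassette_adp_affinity_fold(self):
        rates = RateConstantSet.from_reference(["hBrr2-NC", "hBrr2-CC"])
        aff = derive_affinity_table(rates)
        folds = fold_ratios(aff, isolated_pairs=[("hBrr2-NC", "hBrr2-CC")])
        adp = folds[
            (folds.ratio == "cc_vs_nc_affinity_fold") & (folds.nucleotide == "mant-ADP")
        ]
        # Kd 1.9/1.0 uM vs 0.002/0.5 uM -> 475, matching the ~500-fold claim
        assert adp.iloc[0].fold == pytest.approx(475.0, rel=1e-9)

    def test_atpgs_dissociation_fold_is_800(self):
        rates = RateConstantSet.from_reference(["hBrr2-NC", "hBrr2-CC"])
        aff = derive_affinity_table(rates)
        folds = fold_ratios(aff, isolated_pairs=[("hBrr2-NC", "hBrr2-CC")])
        atpgs = folds[
            (folds.ratio == "nc_vs_cc_dissociation_fold")
            & (folds.nucleotide == "mant-ATPgS")
        ]
        assert atpgs.iloc[0].fold == pytest.approx(800.0, rel=1e-12)

    def test_identical_kds_give_unit_fold(self):
        records = [
            dict(construct="X", nucleotide="mant-ADP", cassette=cas, k1=1.0,
                 k1_se=0.1, k_minus1=0.5, k_minus1_se=0.05, provenance="test")
            for cas in ("NC", "CC")
        ]
        aff = derive_affinity_table(RateConstantSet.from_records(records))
        folds = fold_ratios(aff)
        assert folds[folds.ratio == "cc_vs_nc_affinity_fold"].iloc[0].fold == 1.0

    def test_fold_ratios_scale_invariant(self):
        rates = RateConstantSet.from_reference(["hBrr2-FL"]).to_frame()
        scaled = rates.copy()
        for col in ("k1", "k1_se", "k_minus1", "k_minus1_se"):
            scaled[col] *= 3.7
        f1 = fold_ratios(derive_affinity_table(RateConstantSet(rates)))
        f2 = fold_ratios(derive_affinity_table(RateConstantSet(scaled)))
        pd.testing.assert_frame_equal(f1, f2, check_exact=False)

    def test_missing_pair_member_skipped(self):
        rates = RateConstantSet.from_reference(["GK1355-6QE"])  # NC-only mutant
        aff = derive_affinity_table(rates)
        folds = fold_ratios(aff)
        assert (folds.ratio != "cc_vs_nc_affinity_fold").all()

    def test_nonpositive_k1_skipped(self):
        records = [
            dict(construct="X", nucleotide="mant-ADP", cassette="NC", k1=0.0,
                 k1_se=0.0, k_minus1=0.5, k_minus1_se=0.05, provenance="test")
        ]
        aff = derive_affinity_table(RateConstantSet.from_records(records))
        assert aff.empty


def test_chase_koff_and_titration_intercept_agree():
    """The two k_minus1 routes agree within a joint confidence band."""
    from brr2allo.kinetics.fit import normalize_and_average

    design = KineticsDesign(construct="hBrr2-NC", nucleotide="mant-ADP", seed=21)
    ds = generate_kinetics_dataset(design)
    chase_fit = fit_exponentials(normalize_and_average(ds.chase), 1)
    pts = []
    for conc in design.association_concs:
        fit = fit_exponentials(normalize_and_average(ds.association[conc]), 1)
        pts.append((conc, fit.k_app[0], 0.0, 1))
    reg = regress_kapp(TitrationSeries(pts, "NC"))
    joint = 3 * np.hypot(chase_fit.k_app_se[0], reg.k_minus1_se)
    assert abs(chase_fit.k_app[0] - reg.k_minus1) <= joint
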