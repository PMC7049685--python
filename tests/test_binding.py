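"""Ensemble binding/kinetics fits and gel quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scrunchfret as sf


class TestQuadraticBinding:
    def test_noiseless_recovery_of_tight_kd(self):
        d = sf.generate_titration(
            "quadratic_binding",
            dict(K_d=0.12, D_t=5.0, r_f=0.15, r_b=0.30),
            np.geomspace(0.01, 50, 12),
            x_unit="nM",
        )
        fit = sf.fit_quadratic_binding(d, D_t=5.0, x_unit="nM")
        assert fit["K_d"] == pytest.approx(0.12, rel=1e-6)
        assert fit["r_f"] == pytest.approx(0.15, rel=1e-6)
        assert fit["r_b"] == pytest.approx(0.30, rel=1e-6)

    def test_saturation_limit_is_rb(self):
        y = sf.quadratic_binding_model(1e9, K_d=0.5, D_t=5.0, r_f=0.1, r_b=0.3)
        assert y == pytest.approx(0.3, abs=1e-6)

    def test_weak_binding_limit_agrees_with_hyperbola(self):
        # D_t << K_d: ligand depletion negligible, quadratic -> hyperbola
        kd = 100.0
        x = np.geomspace(1.0, 2000.0, 12)
        d = sf.generate_titration(
            "quadratic_binding",
            dict(K_d=kd, D_t=kd / 200.0, r_f=0.0, r_b=1.0),
            x,
        )
        hyp = sf.fit_hyperbola(d)
        assert hyp["K_d"] == pytest.approx(kd, rel=0.01)

    def test_unsaturated_titration_warns(self):
        d = sf.generate_titration(
            "quadratic_binding",
            dict(K_d=500.0, D_t=5.0, r_f=0.15, r_b=0.30),
            np.linspace(0.1, 20, 8),
        )
        fit = sf.fit_quadratic_binding(d, D_t=5.0)
        assert any("saturation" in w for w in fit.warnings)

    def test_unit_mismatch_is_an_error(self):
        d = sf.generate_titration(
            "quadratic_binding",
            dict(K_d=0.12, D_t=5.0, r_f=0.15, r_b=0.30),
            np.geomspace(0.01, 50, 12),
            x_unit="nM",
        )
        with pytest.raises(sf.UnitsError):
            sf.fit_quadratic_binding(d, D_t=5.0, x_unit="uM")

    def test_printed_db_variant_available(self):
        # the literal printed closed form with an independent D_b value
        y_dt = sf.quadratic_binding_model(2.0, 1.0, 5.0, 0.0, 1.0)
        y_db = sf.quadratic_binding_model(2.0, 1.0, 5.0, 0.0, 1.0, D_b=3.0)
        assert y_db != y_dt


class TestHyperbola:
    @pytest.mark.parametrize("kd,xmax", [(65.0, 2000.0), (500.0, 4000.0)])
    def test_noiseless_kd_recovery(self, kd, xmax):
        d = sf.generate_titration(
            "hyperbola", dict(F0=1.0, dF=3.0, K_d=kd), np.linspace(0, xmax, 10)
        )
        fit = sf.fit_hyperbola(d)
        assert fit["K_d"] == pytest.approx(kd, rel=1e-6)

    def test_half_saturation_value(self):
        y = sf.hyperbola_model(65.0, F0=2.0, dF=4.0, K_d=65.0)
        assert y == pytest.approx(4.0, abs=1e-12)

    def test_decreasing_data_handled_by_negative_df(self):
        d = sf.generate_titration(
            "hyperbola", dict(F0=5.0, dF=-2.0, K_d=50.0), np.linspace(0, 500, 10)
        )
        fit = sf.fit_hyperbola(d)
        assert fit["dF"] == pytest.approx(-2.0, rel=1e-6)
        assert fit["K_d"] == pytest.approx(50.0, rel=1e-6)

    def test_underranged_titration_warns(self):
        d = sf.generate_titration(
            "hyperbola", dict(F0=0.0, dF=1.0, K_d=1000.0), np.linspace(0, 100, 10)
        )
        fit = sf.fit_hyperbola(d)
        assert any("poorly constrained" in w for w in fit.warnings)


class TestMichaelisMenten:
    def test_noiseless_recovery(self):
        d = sf.generate_titration(
            "michaelis_menten", dict(k_cat=0.4, K_m=165.0), np.linspace(0, 4000, 10)
        )
        fit = sf.fit_michaelis_menten(d)
        assert fit["k_cat"] == pytest.approx(0.4, rel=1e-6)
        assert fit["K_m"] == pytest.approx(165.0, rel=1e-6)

    def test_efficiency_equals_kcat_over_km(self):
        d = sf.generate_titration(
            "michaelis_menten", dict(k_cat=0.4, K_m=165.0), np.linspace(0, 4000, 10)
        )
        fit = sf.fit_michaelis_menten(d)
        assert fit.extras["efficiency"] == pytest.approx(
            fit["k_cat"] / fit["K_m"], rel=1e-12
        )
        assert fit.extras["efficiency"] == pytest.approx(0.4 / 165.0, rel=1e-6)

    def test_raw_velocities_normalised_by_enzyme(self):
        x = np.linspace(0, 4000, 10)
        raw = sf.TitrationDataset(
            x=x, y=2.0 * sf.michaelis_menten_model(x, 0.4, 165.0), y_kind="rate"
        )
        fit = sf.fit_michaelis_menten(raw, limiting_enzyme=2.0, rates_normalized=False)
        assert fit["k_cat"] == pytest.approx(0.4, rel=1e-6)


class TestFoldChange:
    def test_equal_intensities_give_unity(self):
        assert sf.fold_change(100.0, 100.0) == pytest.approx(1.0)

    def test_forty_fold_melting_scenario(self):
        # free DNA at 50 a.u.; polymerase+factor complex melts the -4 base
        # and enhances 2AP emission 40-fold
        assert sf.fold_change(50.0 * 40, 50.0) == pytest.approx(40.0)

    def test_computed_on_background_subtracted_values(self):
        fold = sf.fold_change(3.0 - 0.1, 0.5 - 0.1)
        assert fold == pytest.approx(2.9 / 0.4)

    def test_error_propagation(self):
        fold, err = sf.fold_change(200.0, 100.0, err_complex=10.0, err_free=5.0)
        assert fold == pytest.approx(2.0)
        assert err == pytest.approx(2.0 * np.sqrt(0.05**2 + 0.05**2))

    def test_nonpositive_free_dna_rejected(self):
        with pytest.raises(sf.InvalidParameterError):
            sf.fold_change(10.0, 0.0)


class TestQuantifyRNA:
    def test_equal_bands_half_atp(self):
        assert sf.quantify_rna(1.0, 1.0, 100.0) == pytest.approx(50.0)

    def test_zero_product(self):
        assert sf.quantify_rna(0.0, 3.0, 400.0) == 0.0

    def test_direct_evaluation(self):
        assert sf.quantify_rna(1.0, 3.0, 400.0) == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(sf.InvalidParameterError):
            sf.quantify_rna(0.0, 0.0, 100.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        r=st.floats(0.01, 1e6),
        a=st.floats(0.01, 1e6),
        scale=st.floats(0.01, 1e3),
        atp=st.floats(0.1, 1e4),
    )
    def test_scale_invariance_and_linearity(self, r, a, scale, atp):
        base = sf.quantify_rna(r, a, atp)
        assert sf.quantify_rna(r * scale, a * scale, atp) == pytest.approx(base)
        assert sf.quantify_rna(r, a, 2 * atp) == pytest.approx(2 * base)


class TestAbortiveRunoff:
    def test_single_3mer_band_runoff_undefined(self):
        lanes = [sf.GelLane("free_ATP", 10.0), sf.GelLane("3mer", 10.0)]
        out = sf.abortive_runoff_ratio(lanes, atp_total=100.0)
        assert out["abortive_3to7_uM"] == pytest.approx(50.0)
        assert not out["ratio_defined"]
        assert np.isnan(out["ratio"])

    def test_shared_denominator_convention_additive(self):
        # five equal 3-7mer bands under the shared-denominator convention
        lanes = [sf.GelLane(f"{n}mer", 2.0) for n in range(3, 8)]
        lanes.append(sf.GelLane("free_ATP", 10.0))
        out = sf.abortive_runoff_ratio(lanes, atp_total=100.0)
        assert out["abortive_3to7_uM"] == pytest.approx(5 * 2.0 / (10.0 + 10.0) * 100)

    def test_2mer_excluded_from_abortive_sum(self):
        lanes = [
            sf.GelLane("free_ATP", 10.0),
            sf.GelLane("2mer", 5.0),
            sf.GelLane("3mer", 5.0),
            sf.GelLane("runoff", 10.0),
        ]
        out = sf.abortive_runoff_ratio(lanes, atp_total=100.0)
        # abortive counts only the 3mer
        assert out["abortive_3to7_uM"] == pytest.approx(5.0 / 30.0 * 100)
        assert out["ratio"] == pytest.approx(5.0 / 10.0)

    def test_per_band_denominator_option(self):
        lanes = [sf.GelLane("free_ATP", 10.0), sf.GelLane("3mer", 10.0)]
        out = sf.abortive_runoff_ratio(lanes, 100.0, per_band_denominator=True)
        assert out["abortive_3to7_uM"] == pytest.approx(50.0)

    def test_missing_free_atp_rejected(self):
        with pytest.raises(sf.InvalidParameterError):
            sf.abortive_runoff_ratio([sf.GelLane("3mer", 1.0)], 100.0)


class TestExponentialCollapse:
    def test_flat_trace_no_collapse_verdict(self):
        d = sf.TitrationDataset(
            x=np.linspace(0, 100, 20), y=np.full(20, 3.0), x_unit="s"
        )
        fit = sf.fit_exponential_collapse(d)
        assert fit.extras["verdict"] == "no_collapse"

    def test_noiseless_rate_recovery(self):
        d = sf.generate_titration(
            "exponential_decay",
            dict(amplitude=1.0, k=0.01, baseline=0.2),
            np.linspace(0, 600, 30),
            x_unit="s",
        )
        fit = sf.fit_exponential_collapse(d)
        assert fit["k"] == pytest.approx(0.01, rel=1e-6)
        assert fit.extras["verdict"] == "collapse"

    def test_rate_ordering_preserved(self):
        t = np.linspace(0, 300, 40)
        fits = []
        for k in (0.005, 0.05):
            d = sf.generate_titration(
                "exponential_decay",
                dict(amplitude=1.0, k=k, baseline=0.0),
                t,
                x_unit="s",
            )
            fits.append(sf.fit_exponential_collapse(d)["k"])
        assert fits[0] < fits[1]

    def test_too_few_points_rejected(self):
        d = sf.TitrationDataset(x=np.arange(5.0), y=np.zeros(5), x_unit="s")
        with pytest.raises(sf.InvalidParameterError):
            sf.fit_exponential_collapse(d)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    kd=st.floats(1.0, 100.0),
    kcat=st.floats(0.01, 10.0),
    km=st.floats(10.0, 1000.0),
)
def test_noiseless_recovery_across_magnitudes(kd, kcat, km):
    """All noiseless fits return their truths to <= 1e-6 relative."""
    x = np.geomspace(kd / 20, kd * 50, 12)
    d = sf.generate_titration("hyperbola", dict(F0=0.5, dF=2.0, K_d=kd), x)
    assert sf.fit_hyperbola(d)["K_d"] == pytest.approx(kd, rel=1e-6)
    s = np.geomspace(km / 20, km * 50, 12)
    d = sf.generate_titration("michaelis_menten", dict(k_cat=kcat, K_m=km), s)
    fit = sf.fit_michaelis_menten(d)
    assert fit["k_cat"] == pytest.approx(kcat, rel=1e-6)
    assert fit["K_m"] == pytest.approx(km, rel=1e-6)
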