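"""Feature extraction: CY fitting, yield peaks, amplitude features, table."""

import numpy as np
import pytest

from conftest import score_cohort
from rheoprint.features import (
    FEATURE_SCHEMA,
    KEY_FEATURES,
    PRIMARY_FEATURES,
    RATIOED_FEATURES,
    amplitude_features,
    build_feature_table,
    build_feature_table_from_parts,
    detect_yield_peak,
    extract_features,
    fit_carreau_yasuda,
    flow_proportionality_index,
    frequency_features,
)
from rheoprint.synthetic import FLOW_GRID, PrintRecord, STRESS_GRID, carreau_yasuda


class TestCarreauYasuda:
    def test_noiseless_round_trip(self):
        eta = carreau_yasuda(FLOW_GRID, 100.0, 0.001, 1.0, 2.0, 0.3)
        fit = fit_carreau_yasuda(FLOW_GRID, eta)
        assert fit.eta0 == pytest.approx(100.0, rel=1e-3)
        assert fit.lambda_cy == pytest.approx(1.0, rel=1e-3)
        assert fit.a_cy == pytest.approx(2.0, rel=1e-3)
        assert fit.n_cy == pytest.approx(0.3, rel=1e-3)
        assert abs(fit.eta_inf - 0.001) / 100.0 < 1e-3  # vs the viscosity scale
        assert fit.rel_residual < 1e-8

    def test_constant_viscosity_boundary_flag(self):
        eta = np.full_like(FLOW_GRID, 5.0)
        fit = fit_carreau_yasuda(FLOW_GRID, eta)
        assert fit.eta0 == pytest.approx(5.0)
        assert fit.eta_inf == pytest.approx(5.0)
        assert fit.at_boundary
        assert fit.rel_residual < 1e-9

    @pytest.mark.parametrize(
        "gdot,eta,msg",
        [
            (FLOW_GRID[:5], np.ones(5), "at least 8"),
            (FLOW_GRID[::-1], np.ones(31), "increasing"),
            (FLOW_GRID, -np.ones(31), "positive"),
        ],
    )
    def test_invalid_inputs(self, gdot, eta, msg):
        with pytest.raises(ValueError, match=msg):
            fit_carreau_yasuda(gdot, eta)


class TestYieldPeak:
    def test_constructed_peak_recovered_exactly(self):
        sigma = STRESS_GRID
        u = sigma / 20.0
        eta = 50.0 * (u**2 / (1 + u**4)) / 0.5
        out = detect_yield_peak(sigma, eta)
        assert out.has_peak
        assert out.sigma_peak == 20.0
        assert out.eta_peak == eta[np.argmax(eta)]

    def test_monotone_ramp_has_no_peak(self):
        eta = 30.0 * (1 + STRESS_GRID / 10.0) ** -0.7
        out = detect_yield_peak(STRESS_GRID, eta)
        assert not out.has_peak
        assert out.sigma_peak is None and out.eta_peak is None

    def test_flat_ramp_fails_prominence(self):
        out = detect_yield_peak(STRESS_GRID, np.full_like(STRESS_GRID, 3.0))
        assert not out.has_peak

    def test_single_sample_spike_smoothed_away(self):
        eta = 30.0 * (1 + STRESS_GRID / 10.0) ** -0.7
        eta[60] *= 3.0  # isolated spike, not a physical resistance buildup
        assert not detect_yield_peak(STRESS_GRID, eta).has_peak

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            detect_yield_peak([1.0, 2.0], [1.0, 2.0])


class TestAmplitudeFeatures:
    gamma = np.geomspace(0.01, 500.0, 60)

    def test_pure_lve_gel_in_window(self):
        """Constant moduli with G'' < G': LVE limit pinned at the clip edge,
        no flow point."""
        gp = np.full_like(self.gamma, 100.0)
        gpp = np.full_like(self.gamma, 10.0)
        amp = amplitude_features(self.gamma, gp, gpp)
        assert amp.lve_limit == pytest.approx(100.0)
        assert amp.flow_strain is None and amp.g_flow is None

    def test_analytic_crossover_located(self):
        """tan d = (gamma/35)^0.8 crosses 1 exactly at 35% strain."""
        gp = np.full_like(self.gamma, 200.0)
        gpp = gp * (self.gamma / 35.0) ** 0.8
        amp = amplitude_features(self.gamma, gp, gpp)
        assert amp.flow_strain == pytest.approx(35.0, rel=0.01)
        assert amp.g_flow == pytest.approx(200.0, rel=0.01)

    def test_tan_delta_exact_at_sample_point(self):
        """Interpolation identity: a target lying on the grid returns the
        raw sample ratio (100% is an exact grid point)."""
        from rheoprint.synthetic import AMP_GRID

        rng = np.random.default_rng(3)
        gp = 100.0 * np.exp(0.05 * rng.standard_normal(AMP_GRID.shape))
        gpp = gp * 0.5
        gpp[AMP_GRID == 100.0] = gp[AMP_GRID == 100.0] * 0.77
        amp = amplitude_features(AMP_GRID, gp, gpp)
        assert amp.tan_delta[100.0] == pytest.approx(0.77, rel=1e-12)

    def test_clip_window_not_covered_rejected(self):
        g = np.geomspace(0.2, 50.0, 3)
        with pytest.raises(ValueError):
            amplitude_features(g, np.ones(3), np.ones(3))


class TestFlowProportionality:
    def test_division(self):
        rec = PrintRecord(pressure=50.0, mass_rate=10.0, filament_formed=True,
                          mask=np.zeros((2, 2), bool))
        assert flow_proportionality_index(rec) == pytest.approx(0.2)

    def test_homogeneity(self):
        a = PrintRecord(pressure=50.0, mass_rate=10.0, filament_formed=True,
                        mask=np.zeros((2, 2), bool))
        b = PrintRecord(pressure=100.0, mass_rate=10.0, filament_formed=True,
                        mask=np.zeros((2, 2), bool))
        assert flow_proportionality_index(b) == pytest.approx(
            flow_proportionality_index(a) / 2.0
        )

    def test_zero_pressure_rejected(self):
        rec = PrintRecord(pressure=0.0, mass_rate=10.0, filament_formed=True,
                          mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            flow_proportionality_index(rec)


class TestFeatureTable:
    def test_schema_is_frozen(self):
        """Golden schema: 65 canonical names in a fixed order, with the 13
        key features present."""
        assert len(FEATURE_SCHEMA) == 65
        assert len(set(FEATURE_SCHEMA)) == 65
        assert len(PRIMARY_FEATURES) == 37
        assert len(RATIOED_FEATURES) == 28
        assert FEATURE_SCHEMA[:37] == PRIMARY_FEATURES
        assert FEATURE_SCHEMA[37:] == [f + "_rel" for f in RATIOED_FEATURES]
        assert set(KEY_FEATURES) <= set(FEATURE_SCHEMA)
        assert len(KEY_FEATURES) == 13

    def test_table_shape_and_columns(self, default_table):
        assert default_table.shape == (180, 67)
        assert list(default_table.columns) == FEATURE_SCHEMA + ["score", "printable"]
        assert not default_table.isna().any().any()
        assert not any(c.startswith("truth_") for c in default_table.columns)

    def test_self_ratio_is_one(self, default_cohort):
        """A formulation identical to its base has all ratio features 1."""
        f = default_cohort.formulations[0]
        bundle = default_cohort.bundles[f.id]
        feats = extract_features(bundle, bundle, default_cohort.records[f.id])
        for name in RATIOED_FEATURES:
            if feats[name] == 0.0:
                assert feats[name + "_rel"] == 0.0
            else:
                assert feats[name + "_rel"] == pytest.approx(1.0, rel=1e-12), name

    def test_missing_yield_imputation_count(self):
        """Raising the yield threshold makes weak samples non-yielding; the
        indicator column counts exactly those rows."""
        from rheoprint.synthetic import GeneratorConfig, sample_cohort

        cfg = GeneratorConfig(yield_threshold=1.0)
        coh = sample_cohort(40, seed=3, config=cfg)
        table = build_feature_table(coh, score_cohort(coh), seed=None)
        n_latent = sum(1 for f in coh.formulations if f.sigma_y is None)
        assert n_latent > 0
        assert int(table["yield_missing"].sum()) == n_latent
        imputed = table[table["yield_missing"] == 1.0]
        assert (imputed["yield_eta_peak"] == 0.0).all()
        assert (imputed["yield_sigma_peak"] == 0.0).all()

    def test_missing_base_reference_raises(self, default_cohort):
        scores = score_cohort(default_cohort)
        pairs = [(f.id, "nonexistent") for f in default_cohort.formulations[:2]]
        with pytest.raises(KeyError, match="base reference"):
            build_feature_table_from_parts(
                pairs, default_cohort.bundles, default_cohort.base_bundles,
                default_cohort.records, scores,
            )

    def test_row_shuffle_is_seeded(self, default_cohort):
        scores = score_cohort(default_cohort)
        a = build_feature_table(default_cohort, scores, seed=1)
        b = build_feature_table(default_cohort, scores, seed=1)
        c = build_feature_table(default_cohort, scores, seed=2)
        assert list(a.index) == list(b.index)
        assert list(a.index) != list(c.index)

    def test_clipping_excluded_samples_do_not_matter(self, default_cohort):
        """Perturbing sweep samples outside the 1-10 rad/s and 0.1-100%
        windows leaves the extracted features bit-identical."""
        import copy

        f = default_cohort.formulations[0]
        bundle = default_cohort.bundles[f.id]
        base = default_cohort.base_bundles[f.base_id]
        rec = default_cohort.records[f.id]
        ref = extract_features(bundle, base, rec)
        mod = copy.deepcopy(bundle)
        out_f = (mod.freq_omega < 1.0) | (mod.freq_omega > 10.0)
        out_a = (mod.amp_gamma < 0.1) | (mod.amp_gamma > 100.0)
        mod.freq_gp[out_f] *= 7.3
        mod.freq_gpp[out_f] *= 0.2
        mod.amp_gp[out_a] *= 4.1
        mod.amp_gpp[out_a] *= 2.9
        pert = extract_features(mod, base, rec)
        for name in FEATURE_SCHEMA:
            if name.startswith(("cy_", "yield_")):  # flow/stress steps untouched
                continue
            assert pert[name] == ref[name], name


class TestFrequencyFeatures:
    def test_ratio_identity_at_grid_points(self):
        from rheoprint.synthetic import FREQ_GRID

        gp = 100.0 * (FREQ_GRID / 3.0) ** 0.1
        gpp = gp * 0.5 * (FREQ_GRID / 3.0) ** -0.2
        out = frequency_features(FREQ_GRID, gp, gpp)
        t1 = gpp[FREQ_GRID == 1.0][0] / gp[FREQ_GRID == 1.0][0]
        t10 = gpp[FREQ_GRID == 10.0][0] / gp[FREQ_GRID == 10.0][0]
        assert out["freq_tand_1rad"] == pytest.approx(t1, rel=1e-12)
        assert out["freq_tand_ratio_1_10"] == pytest.approx(t1 / t10, rel=1e-12)
        assert out["freq_gprime_slope"] == pytest.approx(0.1, abs=1e-9)
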