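"""Domain measurement, nurse correction and polarity metrics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oopolar.errors import (
    DegenerateGeometryError,
    InvalidInputError,
)
from oopolar.membrane_geometry import partition_domains, snap_anchors, \
    trace_perimeter
from oopolar.quantification import (
    CytoplasmMeasurement,
    DomainMeasurement,
    QuantConfig,
    compute_metrics,
    correct_anterior,
    estimate_nurse_background,
    measure_cytoplasm,
    measure_domain,
    quantify_oocyte,
)
from oopolar.synthetic import NoiseSpec, OocyteSpec, make_oocyte


@pytest.fixture(scope="module")
def traced_oocyte(oocyte_noisy):
    image, truth = oocyte_noisy
    sn = snap_anchors(image, truth.anchors, 5)
    trace = trace_perimeter(image, sn)
    part = partition_domains(trace, sn, truth.matched_posterior_fraction)
    return image, truth, trace, part


class TestMeasureDomain:
    def test_uniform_field_recovers_constant(self, traced_oocyte):
        _, _, _, part = traced_oocyte
        img = np.full((200, 300), 7.0)
        m = measure_domain(img, part, "posterior", band_width=3)
        assert m.mean_intensity == pytest.approx(7.0)
        assert m.quantity == pytest.approx(7.0 * part.lengths["posterior"])

    def test_zero_image_gives_zero_quantity(self, traced_oocyte):
        _, _, _, part = traced_oocyte
        m = measure_domain(np.zeros((200, 300)), part, "anterior")
        assert m.mean_intensity == 0.0
        assert m.quantity == 0.0

    def test_band_mean_matches_painted_truth(self):
        """Band measurement versus the pixel-sum oracle over the painted
        membrane mask.  The painted band (5 px) is wider than the
        measurement band (3 px) so every sample lies on the membrane."""
        spec = OocyteSpec(seed=4, membrane_width=5.0)
        image, truth = make_oocyte(spec)
        sn = snap_anchors(image, truth.anchors, 5)
        trace = trace_perimeter(image, sn)
        part = partition_domains(trace, sn, truth.matched_posterior_fraction)
        m = measure_domain(image, part, "posterior", band_width=3)
        oracle = image[truth.domain_masks["PPM"]].mean()
        assert m.mean_intensity == pytest.approx(oracle, rel=0.03)

    def test_even_band_width_rejected(self, traced_oocyte):
        image, _, _, part = traced_oocyte
        with pytest.raises(InvalidInputError):
            measure_domain(image, part, "anterior", band_width=4)

    def test_profile_has_one_value_per_trace_point(self, traced_oocyte):
        image, _, _, part = traced_oocyte
        m = measure_domain(image, part, "lateral1")
        assert len(m.profile) == len(part.indices("lateral1"))


class TestMeasureCytoplasm:
    def test_uniform_interior(self, traced_oocyte):
        _, _, trace, _ = traced_oocyte
        img = np.full((200, 300), 3.0)
        c = measure_cytoplasm(img, trace, margin=6)
        assert c.mean_intensity == pytest.approx(3.0)
        assert c.quantity == pytest.approx(3.0 * c.area)

    def test_programmed_cytoplasm_mean_recovered(self, traced_oocyte):
        image, truth, trace, _ = traced_oocyte
        c = measure_cytoplasm(image, trace, margin=6)
        assert c.mean_intensity == pytest.approx(truth.cytoplasm_mean,
                                                 rel=0.02)

    def test_oversized_margin_raises(self, traced_oocyte):
        image, _, trace, _ = traced_oocyte
        with pytest.raises(DegenerateGeometryError):
            measure_cytoplasm(image, trace, margin=120)

    def test_nucleus_mask_excluded(self, traced_oocyte):
        image, _, trace, _ = traced_oocyte
        nucleus = np.zeros(image.shape, dtype=bool)
        nucleus[80:120, 140:200] = True
        whole = measure_cytoplasm(image, trace, 6)
        partial = measure_cytoplasm(image, trace, 6, nucleus_mask=nucleus)
        assert partial.area < whole.area


class TestNurseCorrection:
    def test_equal_membranes_mean_no_contribution(self):
        nb = estimate_nurse_background(40.0, 40.0)
        assert nb.contribution == 0.0 and not nb.clamped

    def test_difference_estimator_cancels_background(self):
        # background 30 + one membrane 60 -> simple 90; two membranes -> 150
        nb = estimate_nurse_background(90.0, 150.0)
        assert nb.contribution == pytest.approx(60.0)

    def test_inverted_means_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            nb = estimate_nurse_background(100.0, 80.0)
        assert nb.contribution == 0.0 and nb.clamped

    def test_simple_mode_subtracts_raw_mean(self):
        nb = estimate_nurse_background(90.0, 150.0, mode="simple")
        assert nb.contribution == 90.0

    def test_zero_contribution_is_identity(self):
        m = DomainMeasurement("anterior", 120.0, 50.0)
        nb = estimate_nurse_background(40.0, 40.0)
        out = correct_anterior(m, nb)
        assert out.mean_intensity == m.mean_intensity
        assert out.quantity == m.quantity

    def test_overcorrection_clamps_to_zero(self):
        m = DomainMeasurement("anterior", 50.0, 10.0)
        nb = estimate_nurse_background(20.0, 100.0)
        with pytest.warns(UserWarning):
            out = correct_anterior(m, nb)
        assert out.mean_intensity == 0.0 and out.quantity == 0.0

    def test_generator_anterior_corrected_to_oocyte_mean(self, oocyte_noisy):
        """Uncorrected anterior = APM + nurse membrane; the difference
        estimator recovers the oocyte-only mean within 10%."""
        image, truth = oocyte_noisy
        cfg = QuantConfig(
            posterior_fraction=truth.matched_posterior_fraction)
        res_u = quantify_oocyte(image, truth.anchors, cfg)
        res_c = quantify_oocyte(image, truth.anchors, cfg,
                                simple_mean=truth.nurse_simple_mean,
                                double_mean=truth.nurse_double_mean)
        apm_true = truth.membrane_means["APM"]
        corrected = res_c.measurements["anterior"].mean_intensity
        uncorrected = res_u.measurements["anterior"].mean_intensity
        assert corrected == pytest.approx(apm_true, rel=0.10)
        assert uncorrected - corrected == pytest.approx(
            truth.nurse_contribution, rel=0.15)
        assert uncorrected > corrected  # correction is strictly monotone


def _measurements(q_apm=2.0, q_lat=1.5, q_ppm=1.0, q_cyto=4.0,
                  lengths=(1.0, 1.0, 1.0, 1.0)):
    apm = DomainMeasurement("anterior", q_apm / lengths[0], lengths[0])
    lat1 = DomainMeasurement("lateral1", q_lat / lengths[1], lengths[1])
    lat2 = DomainMeasurement("lateral2", q_lat / lengths[2], lengths[2])
    ppm = DomainMeasurement("posterior", q_ppm / lengths[3], lengths[3])
    cyto = CytoplasmMeasurement(q_cyto, 1.0)
    return apm, lat1, lat2, ppm, cyto


class TestComputeMetrics:
    def test_forced_arithmetic(self):
        # quantities APM 2, LPM 1.5+1.5, PPM 1, cyto 4 -> total 10
        m = compute_metrics(*_measurements())
        assert m.fractions == pytest.approx(
            {"APM": 0.2, "LPM": 0.3, "PPM": 0.1, "cytoplasm": 0.4})
        assert m.densities["APM"] == pytest.approx(0.2)
        assert m.densities["LPM"] == pytest.approx(0.15)  # length pooled to 2
        assert m.asymmetry_ratio == pytest.approx(2.0)
        assert m.exclusion_ratio == pytest.approx(1.5)
        assert m.cytoplasm_fraction == pytest.approx(0.4)

    def test_equal_densities_give_unit_ratios(self):
        m = compute_metrics(*_measurements(q_apm=5, q_lat=5, q_ppm=5,
                                           lengths=(1, 1, 1, 1)))
        # laterals pool to length 2 with quantity 10: same density as others
        assert m.exclusion_ratio == pytest.approx(1.0)
        assert m.asymmetry_ratio == pytest.approx(1.0)

    def test_posterior_accumulation_reads_below_one(self):
        """LPM density below PPM density means posterior accumulation."""
        m = compute_metrics(*_measurements(q_lat=0.25, q_ppm=1.0))
        assert m.exclusion_ratio < 1.0

    def test_fractions_sum_to_one(self):
        m = compute_metrics(*_measurements(q_apm=0.123, q_lat=7.7,
                                           q_ppm=3.14, q_cyto=0.01))
        assert sum(m.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_posterior_density_flagged_infinite(self):
        m = compute_metrics(*_measurements(q_ppm=0.0))
        assert m.ppm_zero
        assert np.isinf(m.exclusion_ratio) and np.isinf(m.asymmetry_ratio)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_metrics(*_measurements(q_apm=0, q_lat=0, q_ppm=0,
                                           q_cyto=0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_metrics_invariant_under_intensity_scaling(self, scale):
        base = compute_metrics(*_measurements(q_apm=2.2, q_lat=1.1,
                                              q_ppm=0.7, q_cyto=3.3))
        scaled = compute_metrics(*_measurements(q_apm=2.2 * scale,
                                                q_lat=1.1 * scale,
                                                q_ppm=0.7 * scale,
                                                q_cyto=3.3 * scale))
        assert scaled.asymmetry_ratio == pytest.approx(base.asymmetry_ratio)
        assert scaled.fractions == pytest.approx(base.fractions)


class TestPipeline:
    def test_ratio_recovery_on_programmed_oocyte(self):
        """Programmed density ratios (asymmetry 5, exclusion 2) recovered
        within 15% (median of 5 seeds; the wider sweep runs in acceptance)."""
        asyms, excls = [], []
        for seed in range(5):
            spec = OocyteSpec(seed=seed, membrane_means={"APM": 500.0,
                                                         "LPM": 200.0,
                                                         "PPM": 100.0})
            image, truth = make_oocyte(spec)
            cfg = QuantConfig(
                posterior_fraction=truth.matched_posterior_fraction)
            res = quantify_oocyte(image, truth.anchors, cfg,
                                  simple_mean=truth.nurse_simple_mean,
                                  double_mean=truth.nurse_double_mean)
            asyms.append(res.metrics.asymmetry_ratio)
            excls.append(res.metrics.exclusion_ratio)
        assert np.median(asyms) == pytest.approx(5.0, rel=0.15)
        assert np.median(excls) == pytest.approx(2.0, rel=0.15)

    def test_isotropic_oocyte_gives_unit_ratios(self):
        spec = OocyteSpec(seed=7, membrane_means={"APM": 100.0, "LPM": 100.0,
                                                  "PPM": 100.0})
        image, truth = make_oocyte(spec)
        cfg = QuantConfig(posterior_fraction=truth.matched_posterior_fraction)
        res = quantify_oocyte(image, truth.anchors, cfg,
                              simple_mean=truth.nurse_simple_mean,
                              double_mean=truth.nurse_double_mean)
        assert res.metrics.asymmetry_ratio == pytest.approx(1.0, rel=0.05)
        assert res.metrics.exclusion_ratio == pytest.approx(1.0, rel=0.05)

    def test_profile_table_covers_whole_trace(self, oocyte_noisy):
        image, truth = oocyte_noisy
        cfg = QuantConfig(posterior_fraction=truth.matched_posterior_fraction)
        res = quantify_oocyte(image, truth.anchors, cfg)
        table = res.profile_table()
        assert len(table) == res.trace.n_points
        assert set(table["domain"]) == {"anterior", "lateral1", "lateral2",
                                        "posterior"}
        assert table["arc_position"].is_monotonic_increasing

    def test_margin_must_clear_measurement_band(self):
        with pytest.raises(InvalidInputError):
            QuantConfig(band_width=7, margin=2)

    def test_noiseless_isotropic_end_to_end(self):
        """With noise off and equal means everywhere the pipeline is exact
        up to boundary digitization."""
        spec = OocyteSpec(seed=0, membrane_means={"APM": 100.0, "LPM": 100.0,
                                                  "PPM": 100.0},
                          noise=NoiseSpec(gaussian_sd=0.0),
                          nurse=dataclasses.replace(OocyteSpec().nurse,
                                                    present=False))
        image, truth = make_oocyte(spec)
        cfg = QuantConfig(posterior_fraction=truth.matched_posterior_fraction)
        res = quantify_oocyte(image, truth.anchors, cfg)
        assert res.metrics.asymmetry_ratio == pytest.approx(1.0, abs=0.02)
        assert res.metrics.exclusion_ratio == pytest.approx(1.0, abs=0.02)
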