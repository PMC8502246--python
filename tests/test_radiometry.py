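import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavpheno.errors import (
    CalibrationError,
    ContractError,
    DegeneratePanelError,
    GeometryError,
    InvalidMetadataError,
)
from uavpheno.radiometry import (
    BANDS,
    CaptureMeta,
    PanelReference,
    RadianceImage,
    dn_to_radiance,
    panel_factor,
    radiance_to_dn,
    radiance_to_reflectance,
    vignette_factor,
)

from .conftest import make_meta


class TestCaptureMeta:
    def test_rejects_nonpositive_exposure(self):
        with pytest.raises(InvalidMetadataError):
            make_meta(exposure_s=0.0)

    def test_rejects_bad_bit_depth(self):
        with pytest.raises(InvalidMetadataError):
            make_meta(bit_depth=14)

    def test_rejects_unknown_band(self):
        with pytest.raises(InvalidMetadataError):
            make_meta(band="thermal")

    def test_rejects_wrong_coefficient_count(self):
        with pytest.raises(InvalidMetadataError):
            make_meta(vignette_coeffs=(0.0, 0.0))

    def test_rejects_nonfinite_coefficients(self):
        with pytest.raises(InvalidMetadataError):
            make_meta(vignette_coeffs=(np.nan, 0, 0, 0, 0, 0))


class TestVignetteFactor:
    def test_zero_coefficients_identity(self):
        v = vignette_factor(make_meta(vignette_center=(3.0, 7.0)), (10, 12))
        np.testing.assert_array_equal(v, np.ones((10, 12)))

    def test_hand_evaluated_single_term(self):
        # k1 = 0.01, centre (0, 0): pixel (x=3, y=4) has r = 5 -> 1/1.05
        meta = make_meta(vignette_coeffs=(0.01, 0, 0, 0, 0, 0))
        v = vignette_factor(meta, (6, 6))
        assert v[4, 3] == pytest.approx(1.0 / 1.05)

    def test_unity_at_centre_any_coefficients(self):
        meta = make_meta(vignette_center=(5.0, 5.0),
                         vignette_coeffs=(0.3, 0.01, 1e-4, 1e-6, 1e-8, 1e-10))
        v = vignette_factor(meta, (11, 11))
        assert v[5, 5] == pytest.approx(1.0)

    def test_all_positive(self):
        meta = make_meta(vignette_coeffs=(2e-4, 1e-7, 0, 0, 0, 0),
                         vignette_center=(400.0, 300.0))
        assert (vignette_factor(meta, (600, 800)) > 0).all()

    def test_bad_shape_rejected(self):
        with pytest.raises(ContractError):
            vignette_factor(make_meta(), (0, 5))


class TestDnToRadiance:
    def test_identity_configuration(self):
        # V=1, a1=1, g=1, a2=a3=0, BL=0, t_e=0.01, DN=32768 -> p=0.5 -> L=50
        meta = make_meta()
        raw = np.full((4, 5), 32768.0)
        out = dn_to_radiance(raw, meta)
        np.testing.assert_allclose(out.values, 50.0)
        assert out.band_id == meta.band_id
        assert out.values.shape == raw.shape

    def test_hand_evaluated_gain_black_level(self):
        # a1=2, g=2, p=0.5, p_BL=0.1, t_e=0.001 -> L = (2/2)*0.4/0.001 = 400
        meta = make_meta(a1=2.0, gain=2.0, black_level=0.1 * 2**16, exposure_s=0.001)
        out = dn_to_radiance(np.full((3, 3), 0.5 * 2**16), meta)
        np.testing.assert_allclose(out.values, 400.0)

    def test_black_level_maps_to_zero(self):
        meta = make_meta(black_level=5000.0)
        out = dn_to_radiance(np.full((3, 3), 5000.0), meta)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_nonpositive_denominator_names_row(self):
        meta = make_meta(a2=-0.001, exposure_s=0.01)  # denominator hits 0 at row 10
        with pytest.raises(CalibrationError, match="row 10"):
            dn_to_radiance(np.ones((30, 4)), meta)

    def test_row_terms_affect_rows_differently(self):
        meta = make_meta(a2=1e-4)
        out = dn_to_radiance(np.full((10, 4), 32768.0), meta)
        assert out.values[0, 0] > out.values[9, 0]

    def test_flip_row_axis(self):
        meta = make_meta(a2=1e-4, flip_row_axis=True)
        out = dn_to_radiance(np.full((10, 4), 32768.0), meta)
        assert out.values[0, 0] < out.values[9, 0]

    @given(c=st.floats(0.1, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_in_dn_above_black(self, c):
        # scaling (p - p_BL) by c scales L by c exactly
        meta = make_meta(black_level=1000.0, vignette_coeffs=(1e-4, 0, 0, 0, 0, 0),
                         a2=1e-6)
        base = np.full((8, 8), 9000.0)
        l1 = dn_to_radiance(base, meta).values
        l2 = dn_to_radiance(1000.0 + (base - 1000.0) * c, meta).values
        np.testing.assert_allclose(l2, c * l1, rtol=1e-12)

    def test_round_trip_inverse(self, rng):
        meta = make_meta(a1=2.2, a2=1e-6, a3=1e-5, black_level=4800.0,
                         exposure_s=0.004, gain=2.0,
                         vignette_coeffs=(2e-4, 1e-7, 0, 0, 0, 0),
                         vignette_center=(10.0, 10.0))
        radiance = rng.uniform(10, 150, size=(20, 20))
        dn = radiance_to_dn(radiance, meta, quantize=False)
        back = dn_to_radiance(dn, meta)
        np.testing.assert_allclose(back.values, radiance, rtol=1e-9)

    def test_round_trip_quantized_within_half_dn(self, rng):
        meta = make_meta(a1=2.2, black_level=4800.0, exposure_s=0.004, gain=2.0)
        radiance = rng.uniform(10, 150, size=(20, 20))
        dn = radiance_to_dn(radiance, meta)  # quantized
        back = dn_to_radiance(dn.astype(np.float64), meta)
        # worst-case error of 0.5 DN propagated through the linear model
        step = dn_to_radiance(np.full((1, 1), meta.black_level + 1), meta).values[0, 0]
        assert np.abs(back.values - radiance).max() <= 0.5 * step + 1e-9


def _panel(rho=0.49, polygon=None):
    return PanelReference(known_reflectance={b: rho for b in BANDS},
                         panel_polygon=polygon or [(2.0, 2.0), (17.0, 2.0),
                                                   (17.0, 17.0), (2.0, 17.0)])


class TestPanelFactor:
    def test_direct_ratio(self):
        rad = RadianceImage(np.full((20, 20), 98.0), "green", "PANEL")
        assert panel_factor(rad, _panel(0.49)) == pytest.approx(0.005)

    def test_uniform_unit_radiance(self):
        rad = RadianceImage(np.ones((20, 20)), "green", "PANEL")
        assert panel_factor(rad, _panel(0.5)) == pytest.approx(0.5)

    def test_mean_over_polygon_interior(self):
        # half the panel pixels at 90, half at 110 -> mean 100 -> F = 0.0049
        values = np.full((20, 20), 90.0)
        values[:, 10:] = 110.0
        # symmetric polygon spanning equally many centres on both sides
        panel = _panel(0.49, polygon=[(3.5, 4.5), (15.5, 4.5), (15.5, 15.5), (3.5, 15.5)])
        rad = RadianceImage(values, "green", "PANEL")
        assert panel_factor(rad, panel) == pytest.approx(0.0049)

    def test_degenerate_panel(self):
        rad = RadianceImage(np.zeros((20, 20)), "green", "PANEL")
        with pytest.raises(DegeneratePanelError):
            panel_factor(rad, _panel())

    def test_empty_polygon_interior(self):
        rad = RadianceImage(np.ones((20, 20)), "green", "PANEL")
        panel = _panel(polygon=[(2.1, 2.1), (2.4, 2.1), (2.4, 2.4), (2.1, 2.4)])
        with pytest.raises(GeometryError):
            panel_factor(rad, panel)

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(GeometryError):
            _panel(polygon=[(0.0, 0.0), (1.0, 1.0)])

    def test_rho_must_be_in_unit_interval(self):
        with pytest.raises(InvalidMetadataError):
            PanelReference(known_reflectance={"green": 1.5},
                           panel_polygon=[(0, 0), (4, 0), (4, 4)])


class TestRadianceToReflectance:
    def test_scaling(self):
        rad = RadianceImage(np.full((5, 5), 100.0), "red", "C")
        np.testing.assert_allclose(radiance_to_reflectance(rad, 0.005), 0.5)

    def test_panel_round_trip(self):
        values = np.random.default_rng(0).uniform(95, 105, (20, 20))
        rad = RadianceImage(values, "green", "PANEL")
        panel = _panel(0.49)
        f = panel_factor(rad, panel)
        refl = radiance_to_reflectance(rad, f)
        from uavpheno.radiometry import panel_pixel_mask
        mask = panel_pixel_mask(panel.panel_polygon, values.shape)
        assert refl[mask].mean() == pytest.approx(0.49, abs=1e-9)

    def test_no_clipping_but_warns_above_threshold(self):
        rad = RadianceImage(np.full((10, 10), 300.0), "nir", "C")
        with pytest.warns(UserWarning, match="exceed reflectance"):
            out = radiance_to_reflectance(rad, 0.005)
        assert out.max() == pytest.approx(1.5)

    def test_nonpositive_factor_rejected(self):
        rad = RadianceImage(np.ones((2, 2)), "nir", "C")
        with pytest.raises(ContractError):
            radiance_to_reflectance(rad, 0.0)

    def test_full_synthetic_round_trip(self, rng):
        """Reflectance -> DN (inverted model) -> radiance -> reflectance."""
        meta = make_meta(a1=2.2, a2=1e-6, a3=1e-5, black_level=4800.0,
                         exposure_s=0.004, gain=2.0,
                         vignette_coeffs=(2e-4, 0, 0, 0, 0, 0),
                         vignette_center=(25.0, 25.0))
        field = rng.uniform(0.05, 0.9, size=(50, 50))
        factor = 0.005
        dn = radiance_to_dn(field / factor, meta, quantize=False)
        recovered = radiance_to_reflectance(dn_to_radiance(dn, meta), factor)
        np.testing.assert_allclose(recovered, field, rtol=1e-6)
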