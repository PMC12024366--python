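"""Band integration, peak measures, and the 11-variable feature vector."""

import math

import numpy as np
import pytest

from coprofir import Spectrum, compute_features, integrate_band, load_band_library
from coprofir.bands import (
    AREA_WINDOWS,
    BandCoverageError,
    BandDefinition,
    FEATURE_NAMES,
    peak_height,
    peak_position,
    resolved_doublet,
)
from coprofir.simulate import (
    COMPONENTS,
    STANDARD_WEIGHTS,
    analytic_features,
    component_spectrum,
    default_grid,
    synthesize_spectrum,
)
from tests.conftest import gaussian_spectrum


class TestIntegrateBand:
    BAND = BandDefinition("CO3", 860, 880, "area")

    def test_zero_spectrum_zero_area(self):
        w = default_grid(4.0)
        assert integrate_band(Spectrum(w, np.zeros_like(w)), self.BAND) == 0.0

    def test_gaussian_area_matches_fine_grid_oracle(self):
        """4 cm-1 sampling reproduces the 0.01 cm-1 quadrature value of the
        same chord-subtracted surface within 0.5%."""
        coarse = gaussian_spectrum(870.0, 5.0, step=4.0)
        fine = gaussian_spectrum(870.0, 5.0, step=0.01, lo=700.0, hi=1100.0)
        got = integrate_band(coarse, self.BAND)
        oracle = integrate_band(fine, self.BAND)
        assert got == pytest.approx(oracle, rel=0.005)

    def test_disjoint_support_gives_zero(self):
        s = gaussian_spectrum(2900.0, 5.0, step=4.0)
        assert integrate_band(s, self.BAND) == 0.0

    def test_window_outside_range_names_band(self):
        s = gaussian_spectrum(1000.0, 5.0, lo=700.0, hi=1500.0)
        band = BandDefinition("cholesterol", 2850, 2935, "area")
        with pytest.raises(BandCoverageError, match="cholesterol"):
            integrate_band(s, band)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="lo"):
            BandDefinition("bad", 900, 700, "area")


class TestPeakMeasures:
    def test_unit_gaussian_height(self):
        s = gaussian_spectrum(871.0, 5.0)
        assert peak_height(s, 871.0) == pytest.approx(1.0)

    def test_flat_zero_height(self):
        w = default_grid(4.0)
        assert peak_height(Spectrum(w, np.zeros_like(w)), 871.0) == 0.0

    def test_overlapping_gaussians_match_dense_maximum(self):
        def mix(w):
            return (np.exp(-0.5 * ((w - 868.0) / 6.0) ** 2)
                    + 0.7 * np.exp(-0.5 * ((w - 880.0) / 6.0) ** 2))

        wf = np.arange(900.0, 840.0, -0.01)
        dense = float(np.max(mix(wf)[(wf >= 863) & (wf <= 879)]))
        # reference-grid spectra reach the dense-grid maximum to 1e-3 ...
        w1 = default_grid(1.0)
        assert peak_height(Spectrum(w1, mix(w1)), 871.0) == pytest.approx(dense, abs=1e-3)
        # ... and instrument-resolution spectra to interpolation accuracy
        w4 = default_grid(4.0)
        assert peak_height(Spectrum(w4, mix(w4)), 871.0) == pytest.approx(dense, abs=2e-3)

    def test_grid_aligned_narrow_band_position(self):
        s = gaussian_spectrum(1000.0, 1.2, step=1.0)
        assert peak_position(s, 990.0, 1010.0) == pytest.approx(1000.0, abs=1e-6)

    def test_parabolic_refinement_off_grid(self):
        s = gaussian_spectrum(1429.6, 6.0, step=4.0)
        assert peak_position(s, 1400.0, 1460.0) == pytest.approx(1429.6, abs=0.2)

    def test_window_too_short_rejected(self):
        s = gaussian_spectrum(1000.0, 5.0, step=4.0)
        with pytest.raises(ValueError, match="3 grid points"):
            peak_position(s, 1000.0, 1006.0)


class TestReferencePositions:
    """Detected maxima of the pure-component references sit at the
    literature band positions."""

    @pytest.mark.parametrize("component,window,expected", [
        ("calcite", (1350, 1500), 1429.0),
        ("aragonite", (1400, 1550), 1471.0),
        ("bioapatite_PO4", (930, 990), 961.0),
        ("protein", (1600, 1700), 1650.0),
    ])
    def test_component_peak(self, component, window, expected):
        s = component_spectrum(component)
        assert peak_position(s, *window) == pytest.approx(expected, abs=1.0)

    def test_fresh_bone_nu4_doublet(self):
        """The bone reference resolves the phosphate nu4 doublet with the
        stronger peak at 559 cm-1 and the weaker at 600 cm-1."""
        bone, _ = synthesize_spectrum(STANDARD_WEIGHTS["Sus_bone"])
        peaks = resolved_doublet(bone, 500.0, 650.0)
        assert len(peaks) == 2
        assert peaks[0][0] == pytest.approx(559.0, abs=1.0)
        assert peaks[1][0] == pytest.approx(600.0, abs=1.0)
        assert peaks[0][1] > peaks[1][1]


class TestComputeFeatures:
    def test_equal_heights_give_unit_ratio(self):
        w = default_grid(1.0)
        a = (np.exp(-0.5 * ((w - 871.0) / 5.0) ** 2)
             + np.exp(-0.5 * ((w - 1017.0) / 5.0) ** 2))
        fv = compute_features(Spectrum(w, a, sample_id="sym"))
        assert fv["CO3PO4"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_phosphate_flags_ratio_undefined(self):
        weights = {"chitin": 1.0, "protein": 0.5, "cholesterol": 0.15}
        spec, _ = synthesize_spectrum(weights)
        fv = compute_features(spec)
        assert "CO3PO4b" in fv.undefined
        assert math.isnan(fv["CO3PO4b"])

    def test_mixture_areas_match_analytic_ground_truth(self):
        """Apatite+protein mixture sampled at 4 cm-1 reproduces each
        fine-grid analytic band area within 5%."""
        weights = {"bioapatite_PO4": 1.0, "bioapatite_CO3": 0.4, "protein": 0.5}
        truth = analytic_features(weights)
        spec, _ = synthesize_spectrum(weights, default_grid(4.0))
        fv = compute_features(spec)
        for name in AREA_WINDOWS:
            if truth[name] > 1e-6:
                assert fv[name] == pytest.approx(truth[name], rel=0.05), name

    def test_missing_coverage_lists_variables(self):
        w = np.arange(1800.0, 699.0, -4.0)
        s = Spectrum(w, np.ones_like(w))
        with pytest.raises(BandCoverageError) as err:
            compute_features(s)
        assert "cholesterol" in str(err.value)
        assert "PO4" in str(err.value)

    def test_feature_order_and_names(self):
        spec, _ = synthesize_spectrum({"bioapatite_PO4": 1.0, "protein": 0.2})
        fv = compute_features(spec)
        assert list(fv.values) == FEATURE_NAMES


class TestFeatureProperties:
    def test_area_linearity_of_mixtures(self):
        """Areas of a summed noise-free spectrum equal the sum of the
        component areas within 1% (ratios excluded: not additive; the
        zero floor makes surfaces with negative chords non-additive, so
        the components are chosen with non-floored surfaces)."""
        wa = {"bioapatite_PO4": 0.8, "bioapatite_CO3": 0.3}
        wb = {"protein": 0.6}
        grid = default_grid(1.0)
        sa, _ = synthesize_spectrum(wa, grid)
        sb, _ = synthesize_spectrum(wb, grid)
        ssum = Spectrum(grid, sa.absorbance + sb.absorbance, sample_id="sum")
        fa, fb = compute_features(sa), compute_features(sb)
        fsum = compute_features(ssum)
        for name in AREA_WINDOWS:
            expect = fa[name] + fb[name]
            if expect > 1e-6:
                assert fsum[name] == pytest.approx(expect, rel=0.01), name

    def test_po4_monotone_in_apatite_weight(self):
        """More apatite (carbonate held fixed) raises PO4 and lowers the
        carbonate-to-phosphate ratio."""
        po4, ratio = [], []
        for wt in (0.5, 1.0, 2.0):
            spec, _ = synthesize_spectrum(
                {"bioapatite_PO4": wt, "bioapatite_CO3": 0.4}, default_grid(4.0))
            fv = compute_features(spec)
            po4.append(fv["PO4"])
            ratio.append(fv["CO3PO4"])
        assert po4[0] < po4[1] < po4[2]
        assert ratio[0] > ratio[1] > ratio[2]

    def test_ratio_scale_invariance_exact(self):
        spec, _ = synthesize_spectrum(STANDARD_WEIGHTS["Sus_bone"], default_grid(4.0))
        f1 = compute_features(spec)
        f2 = compute_features(spec.with_absorbance(spec.absorbance * 13.7))
        assert f2["CO3PO4"] == pytest.approx(f1["CO3PO4"], rel=1e-12)
        assert f2["CO3PO4b"] == pytest.approx(f1["CO3PO4b"], rel=1e-12)


def test_band_library_contents(band_library):
    names = {b.name for b in band_library}
    for required in ("PO4", "CO3", "CO3b", "CI", "chitin", "cholesterol",
                     "amideII", "amideI", "collagen"):
        assert required in names
    for b in band_library:
        assert 400.0 <= b.lo < b.hi <= 4000.0
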