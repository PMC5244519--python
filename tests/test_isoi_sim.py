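import numpy as np
import pytest
from scipy.integrate import quad

from retinomapper.fourier_mapping import extract_response
from retinomapper.isoi_sim import (AREA_NAMES, AreaSpec, CohortDesign, NoiseModel,
                                   build_default_sheet, first_harmonic_factor,
                                   raised_cosine, simulate_cohort_responses,
                                   simulate_movie)
from retinomapper.movie_io import bin_movie
from retinomapper.segmentation import field_sign
from retinomapper.fourier_mapping import RetinotopyPair
from retinomapper.stimulus_model import (azimuth_bar_spec, grating_patch_spec,
                                         phase_to_stimulus_time)


def quad_first_harmonic(duty, period=8.0):
    """Independent quadrature oracle for the waveform's fundamental."""
    def integrand(tau):
        return raised_cosine(np.array([tau]), period, duty)[0] * np.cos(
            2 * np.pi * tau / period)
    val, _ = quad(integrand, -period / 2, period / 2, limit=200)
    return 2.0 / period * val


class TestWaveform:
    def test_unit_peak_and_support(self):
        w = raised_cosine(np.array([0.0, 1.9, 2.1, 4.0]), 8.0, duty=0.5)
        assert w[0] == pytest.approx(1.0)
        assert w[1] > 0 and w[2] == 0.0 and w[3] == 0.0

    def test_periodic(self):
        tau = np.linspace(0, 8, 33)
        np.testing.assert_allclose(raised_cosine(tau, 8.0), raised_cosine(tau + 8, 8.0),
                                   atol=1e-12)

    @pytest.mark.parametrize("duty", [0.25, 0.5, 0.75, 1.0])
    def test_first_harmonic_matches_quadrature_oracle(self, duty):
        assert first_harmonic_factor(duty) == pytest.approx(
            quad_first_harmonic(duty), rel=1e-6)


class TestDefaultSheet:
    def test_six_areas_v1_largest(self, default_sheet):
        labels = default_sheet.label_image()
        names = default_sheet.label_names()
        assert sorted(n for n in names.values() if n != "background") == \
            sorted(AREA_NAMES)
        sizes = {names[i]: (labels == i).sum() for i in range(1, 7)}
        assert all(sizes["V1"] > s for n, s in sizes.items() if n != "V1")

    def test_label_image_matches_polygons(self, default_sheet):
        # ground-truth invariant: label image is exactly the rasterized polygons
        from skimage.draw import polygon as draw_polygon

        labels = default_sheet.label_image()
        for i, area in enumerate(default_sheet.areas):
            rr, cc = draw_polygon(area.polygon_px[:, 1], area.polygon_px[:, 0],
                                  shape=default_sheet.field_px)
            expected = np.zeros(default_sheet.field_px, dtype=bool)
            expected[rr, cc] = True
            np.testing.assert_array_equal(labels == i + 1, expected)

    def test_um_per_px_scaling(self):
        a1 = build_default_sheet(um_per_px=40.0).label_image()
        a2 = build_default_sheet(um_per_px=80.0).label_image()
        for lbl in range(1, 7):
            ratio = (a2 == lbl).sum() / (a1 == lbl).sum()
            assert ratio == pytest.approx(0.25, rel=0.1)

    def test_mirror_flags_alternate_relative_to_v1(self, default_sheet):
        flags = {a.name: a.mirror for a in default_sheet.areas}
        assert flags["V1"] is False
        assert flags["LM"] is True  # V1's immediate mirror neighbour

    def test_true_field_sign_alternates_v1_lm(self, default_sheet):
        azi, elev = default_sheet.retinotopy_images()
        labels = default_sheet.label_image()
        names = {v: k for k, v in default_sheet.label_names().items()}
        fs = field_sign(RetinotopyPair(np.nan_to_num(azi), np.nan_to_num(elev), 0.0),
                        smooth_sigma_px=0.5)
        v1_sign = np.sign(fs.sign[labels == names["V1"]].sum())
        lm_sign = np.sign(fs.sign[labels == names["LM"]].sum())
        assert v1_sign == 1 and lm_sign == -1

    def test_overlapping_layout_rejected(self):
        layout = {"V1": (0, 3000, 0, 3000), "LM": (2000, 4000, 2000, 4000),
                  "LI": (40, 1040, 4300, 5000), "AL": (4300, 5000, 4300, 5000),
                  "RL": (4300, 5000, 0, 700), "AMPM": (0, 700, 4300, 5000)}
        with pytest.raises(ValueError, match="overlap"):
            build_default_sheet(layout_um=layout)

    def test_amplitude_range_enforced(self):
        with pytest.raises(ValueError, match="response_amplitude"):
            AreaSpec(name="V1", polygon_px=np.array([[0, 0], [4, 0], [4, 4], [0, 4]]),
                     mirror=False, response_amplitude=0.2)


def tiny_sheet(amplitude=0.01, baseline=3000, **kw):
    """One 8x8 area in a 16x16 field, for fast single-area checks."""
    layout = {"V1": (160.0, 480.0, 160.0, 480.0)}
    return build_default_sheet(field_px=(16, 16), layout_um=layout,
                               mirror_flags={"V1": False},
                               amplitudes={"V1": amplitude},
                               baseline_counts=baseline, **kw)


class TestSimulateMovie:
    def test_zero_amplitude_constant_baseline(self):
        sheet = tiny_sheet(amplitude=0.0)
        movie, _ = simulate_movie(sheet, azimuth_bar_spec(n_cycles=2))
        np.testing.assert_array_equal(movie.data, sheet.baseline_counts)

    def test_twelve_bit_contract(self, default_sheet):
        movie, _ = simulate_movie(default_sheet, azimuth_bar_spec(n_cycles=2),
                                  noise=NoiseModel(white_sigma=200.0), seed=0)
        assert movie.data.min() >= 0 and movie.data.max() <= 4095

    def test_fourier_magnitude_matches_first_harmonic(self):
        # interior pixel of a noise-free area: fractional magnitude at
        # f_stim = amplitude x waveform fundamental (quadrature oracle)
        sheet = tiny_sheet(amplitude=0.01)
        spec = grating_patch_spec(n_cycles=10)
        movie, truth = simulate_movie(sheet, spec)
        cmap = extract_response(bin_movie(movie), spec.f_stim_hz)
        expected = 0.01 * quad_first_harmonic(0.5)
        interior = truth.label_image[::2, ::2] > 0
        # shrink to fully-interior binned pixels
        from scipy.ndimage import binary_erosion
        interior = binary_erosion(interior, iterations=2)
        got = cmap.magnitude[interior]
        np.testing.assert_allclose(got, expected, rtol=2e-2)

    def test_phase_recovers_preferred_time(self, silent_animal, bar_specs):
        # spec invariant: noise-free phase -> time within one binned frame
        from retinomapper.fourier_mapping import response_phase
        from tests.conftest import binned_truth_map

        cmap = silent_animal.analysis.cmaps["azimuth"]
        ph = response_phase(cmap, signal_sign=-1)
        t = phase_to_stimulus_time(ph, bar_specs.azimuth, delay_s=0.0)
        t_true = binned_truth_map(silent_animal.truth.t_pref_s)
        inside = np.isfinite(t_true)
        err = np.abs(t - t_true)[inside]
        err = np.minimum(err, 8.0 - err)  # circular distance
        binned_frame = 4.0 / 30.0
        assert np.percentile(err, 99) < binned_frame

    def test_ground_truth_consistency(self, silent_animal, default_sheet):
        np.testing.assert_array_equal(silent_animal.truth.label_image,
                                      default_sheet.label_image())

    def test_seed_contract(self):
        sheet = tiny_sheet()
        noise = NoiseModel(white_sigma=10.0)
        spec = azimuth_bar_spec(n_cycles=2)
        m1, _ = simulate_movie(sheet, spec, noise=noise, seed=7)
        m2, _ = simulate_movie(sheet, spec, noise=noise, seed=7)
        m3, _ = simulate_movie(sheet, spec, noise=noise, seed=8)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert not np.array_equal(m1.data, m3.data)

    def test_amplitude_overflow_rejected(self):
        sheet = tiny_sheet(amplitude=0.09, baseline=4000)
        with pytest.raises(ValueError, match="12-bit"):
            simulate_movie(sheet, azimuth_bar_spec(n_cycles=2))

    def test_harmonic_physio_rejected(self):
        sheet = tiny_sheet()
        bad = NoiseModel(physio_freq_hz=0.25)  # 2 x f_stim
        with pytest.raises(ValueError, match="harmonic"):
            simulate_movie(sheet, azimuth_bar_spec(n_cycles=2), noise=bad)


class TestCohortDesign:
    def test_validation(self):
        with pytest.raises(ValueError, match="n >= 2"):
            CohortDesign.one_way_genotype(
                {"WT": {"AMPM": 1.0}, "KO": {"AMPM": 1.0}}, n=1)
        with pytest.raises(ValueError, match="unknown level"):
            CohortDesign.one_way_genotype({"XX": {"AMPM": 1.0},
                                           "KO": {"AMPM": 1.0}})
        with pytest.raises(ValueError, match="must be > 0"):
            CohortDesign.one_way_genotype({"WT": {"AMPM": 0.0},
                                           "KO": {"AMPM": 1.0}})

    def test_zero_sd_reproduces_cell_means(self):
        design = CohortDesign.one_way_genotype(
            {"WT": {"AMPM": 0.8}, "Het": {"AMPM": 0.7}, "KO": {"AMPM": 0.5}},
            n=3, animal_sd=0.0)
        table = simulate_cohort_responses(design, seed=0)
        assert len(table) == 9
        for g, mean in [("WT", 0.8), ("Het", 0.7), ("KO", 0.5)]:
            np.testing.assert_allclose(
                table.loc[table.genotype == g, "norm_AMPM"], mean)

    def test_seed_reproducibility(self):
        design = CohortDesign.one_way_genotype(
            {"WT": {"AMPM": 1.0}, "KO": {"AMPM": 1.0}}, n=4, animal_sd=0.2)
        t1 = simulate_cohort_responses(design, seed=5)
        t2 = simulate_cohort_responses(design, seed=5)
        t3 = simulate_cohort_responses(design, seed=6)
        assert t1.equals(t2)
        assert not t1.equals(t3)

    def test_truncation_at_zero(self):
        design = CohortDesign.one_way_genotype(
            {"WT": {"AMPM": 0.01}, "KO": {"AMPM": 0.01}}, n=5, animal_sd=5.0)
        table = simulate_cohort_responses(design, seed=1)
        assert (table.norm_AMPM >= 0).all()

    def test_two_factor_design_cells(self):
        design = CohortDesign(
            factors=("age_group", "genotype"),
            levels={"age_group": ("P17", "P30", "P100"), "genotype": ("WT", "KO"),
                    "sex": ("M",)},
            n_per_cell={("P17", "WT"): 7, ("P17", "KO"): 5, ("P30", "WT"): 6,
                        ("P30", "KO"): 6, ("P100", "WT"): 7, ("P100", "KO"): 7},
            cell_means={c: {"AMPM": 1.0} for c in
                        [("P17", "WT"), ("P17", "KO"), ("P30", "WT"),
                         ("P30", "KO"), ("P100", "WT"), ("P100", "KO")]},
            animal_sd=0.1)
        table = simulate_cohort_responses(design, seed=0)
        assert len(table) == 38
        assert set(table.age_group) == {"P17", "P30", "P100"}
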