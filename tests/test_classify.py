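"""Fluorescence screening, peak detection, band matching and phenotype calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import racescrs as rs
from racescrs.classify import (
    BandConfigError, BandDefinition, ClassifierConfig, Peak, carotenoid_bands,
    call_phenotype, classify_cohort, detect_peaks, fluorescence_index,
    match_bands, phb_bands,
)
from racescrs.spectral_io import SpectralValidationError
from tests.conftest import make_processed, oracle_peaks


class TestFluorescenceIndex:
    def test_background_free_spectrum_stays_below_threshold(self):
        # The baseline estimate absorbs some Lorentzian tail mass even with
        # no background, so F is not near zero — but it stays well clear of
        # the 0.85 screening threshold.
        s = rs.render_archetype(
            rs.make_archetype("carotenoid", pinned_triplet=(1003, 1155, 1515)))
        p = rs.preprocess_spectrum(s)
        f = fluorescence_index(s.intensities, p.baseline)
        assert f < 0.5
        assert not call_phenotype(p).is_fluorescent

    def test_fluorescent_archetype_exceeds_threshold(self):
        rng = np.random.default_rng(12)
        s = rs.render_archetype(rs.make_archetype("fluorescent", rng))
        p = rs.preprocess_spectrum(s)
        f = fluorescence_index(s.intensities, p.baseline)
        assert f > 0.85
        assert call_phenotype(p).is_fluorescent

    def test_no_signal_gives_nan(self):
        assert np.isnan(fluorescence_index(np.zeros(10), np.zeros(10)))

    def test_emulation_fluorescent_fraction_near_one_third(self, emulation_report):
        """The screen recovers the preset's 33% fluorescence-dominated cells
        within 3-sigma binomial bounds plus the classifier error budget."""
        frac = emulation_report.fractions["fluorescent"]
        sigma = np.sqrt(0.33 * 0.67 / emulation_report.n_cells)
        assert abs(frac - 0.33) <= 3 * sigma + 0.01


class TestDetectPeaks:
    def test_pinned_carotenoid_bands_detected(self):
        s = rs.render_archetype(
            rs.make_archetype("carotenoid", pinned_triplet=(1003, 1155, 1515)))
        p = rs.preprocess_spectrum(s)
        positions = {pk.position for pk in detect_peaks(p, 5.0)}
        assert {1003.0, 1155.0, 1515.0} <= positions

    def test_monotone_ramp_has_no_peaks(self):
        p = make_processed(np.linspace(0, 1, 50))
        assert detect_peaks(p, 0.0) == []

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=0, max_value=100,
                                  allow_nan=False, width=32),
                        min_size=3, max_size=64),
        thr_sigma=st.floats(min_value=0, max_value=5),
    )
    def test_matches_brute_force_oracle(self, values, thr_sigma):
        """detect_peaks equals an exhaustive interior-point scan with full
        basin prominence computation, for every random spectrum n <= 64."""
        y = np.array(values)
        p = make_processed(y, noise_sigma=1.0)
        got = detect_peaks(p, thr_sigma)
        expected = oracle_peaks(y, thr_sigma * 1.0)
        assert [pk.position for pk in got] == [float(i) for i, _ in expected]
        for pk, (_, prom) in zip(got, expected):
            assert pk.prominence == pytest.approx(prom, abs=1e-9)


class TestMatchBands:
    def mk(self, *pos_prom):
        return [Peak(position=p, height=h, prominence=h) for p, h in pos_prom]

    def test_full_triplet_matches_all_windows(self):
        peaks = self.mk((1003, 1.5), (1155, 3.0), (1515, 5.0))
        m = match_bands(peaks, carotenoid_bands())
        assert all(m[k] is not None for k in ("v1", "v2", "v3"))

    def test_missing_v3_fails_carotenoid_criterion(self):
        peaks = self.mk((1003, 1.5), (1155, 3.0))
        m = match_bands(peaks, carotenoid_bands())
        assert m["v3"] is None

    def test_equal_prominence_tie_breaks_to_lower_wavenumber(self):
        # v2 window [1145, 1161] is centred at 1153: 1150 and 1156 are
        # equidistant, so the lower wavenumber wins.
        peaks = self.mk((1150, 2.0), (1156, 2.0))
        m = match_bands(peaks, carotenoid_bands())
        assert m["v2"].position == 1150

    def test_one_peak_serves_only_one_band(self):
        bands = [BandDefinition("a", (990, 1000), "base_cell"),
                 BandDefinition("b", (1001, 1010), "base_cell")]
        peaks = self.mk((1000, 5.0))
        m = match_bands(peaks, bands)
        assert m["a"] is not None and m["b"] is None

    def test_overlapping_windows_rejected(self):
        bands = [BandDefinition("a", (990, 1005), "base_cell"),
                 BandDefinition("b", (1000, 1010), "base_cell")]
        with pytest.raises(BandConfigError, match="overlap"):
            match_bands([], bands)


class TestCallPhenotype:
    def test_noiseless_carotenoid_called_with_triplet(self):
        s = rs.render_archetype(
            rs.make_archetype("carotenoid", pinned_triplet=(1003, 1155, 1515)))
        call = call_phenotype(rs.preprocess_spectrum(s))
        assert call.label == "carotenoid"
        assert call.triplet == (1003.0, 1155.0, 1515.0)
        assert call.carotenoid_score > 0

    def test_noiseless_phb_called_with_all_four_markers(self):
        s = rs.render_archetype(rs.make_archetype("phb"))
        call = call_phenotype(rs.preprocess_spectrum(s))
        assert call.label == "phb"
        matched = {name: pk for name, pk in call.band_matches.items()
                   if name.startswith("phb_") and pk is not None}
        assert len(matched) == 4

    def test_carotenoid_priority_over_phb(self):
        arch = rs.make_archetype("carotenoid",
                                 pinned_triplet=(1003, 1155, 1515))
        phb_arch = rs.make_archetype("phb")
        both = rs.synthetic.Archetype(
            name="carotenoid",
            peaks=arch.peaks + [p for p in phb_arch.peaks
                                if p not in arch.peaks],
            triplet=arch.triplet)
        call = call_phenotype(rs.preprocess_spectrum(rs.render_archetype(both)))
        assert call.label == "carotenoid"

    def test_fluorescent_call_has_no_band_matches(self):
        rng = np.random.default_rng(13)
        s = rs.render_archetype(rs.make_archetype("fluorescent", rng))
        call = call_phenotype(rs.preprocess_spectrum(s))
        assert call.is_fluorescent
        assert call.label == "fluorescent"
        assert call.band_matches == {}

    @pytest.mark.parametrize("k", [7.3, 0.01, 1e4])
    def test_scale_invariance(self, k):
        """Classification is unchanged under raw-intensity scaling k > 0."""
        rng = np.random.default_rng(14)
        cohort = rs.simulate_cohort(rs.red_sea_default(40), rs.NoiseModel(),
                                    seed=21)
        for s in cohort.spectra[:10]:
            scaled = rs.Spectrum(grid=s.grid, intensities=k * s.intensities,
                                 cell_id=s.cell_id, label=s.label)
            a = call_phenotype(rs.preprocess_spectrum(s))
            b = call_phenotype(rs.preprocess_spectrum(scaled))
            assert a.label == b.label
            assert a.is_fluorescent == b.is_fluorescent


class TestClassifyCohort:
    def test_empty_cohort(self):
        rep = classify_cohort([])
        assert rep.n_cells == 0
        assert all(v == 0 for v in rep.counts.values())

    def test_noiseless_cohort_fully_recovers_ground_truth(self):
        cohort = rs.simulate_cohort(rs.red_sea_default(200),
                                    rs.NoiseModel.noiseless(), seed=5)
        rep = classify_cohort(rs.preprocess_set(cohort))
        assert rep.accuracy == 1.0
        offdiag = rep.confusion.to_numpy().sum() - np.trace(
            rep.confusion.to_numpy())
        assert offdiag == 0

    def test_fluorescent_plus_distinguishable_partition(self, emulation_report):
        rep = emulation_report
        assert rep.n_fluorescent + rep.n_distinguishable == rep.n_cells

    def test_emulation_carotenoid_prevalence(self, emulation_report):
        """The seeded 5321-cell emulation recovers ~23% (1223 cells)
        carotenoid prevalence within 3-sigma binomial + error budget."""
        n = emulation_report.n_cells
        count = emulation_report.counts["carotenoid"]
        sigma = np.sqrt(n * 0.23 * 0.77)
        assert abs(count - 1223.8) <= 3 * sigma + 0.01 * n

    def test_mixed_grids_rejected(self):
        a = rs.render_archetype(rs.make_archetype("typical"))
        g = rs.WavenumberGrid.uniform(700, 1.0, 1100)
        b = rs.render_archetype(rs.make_archetype("typical"), grid=g,
                                cell_id="b")
        with pytest.raises(SpectralValidationError, match="mixed"):
            classify_cohort([rs.preprocess_spectrum(a),
                             rs.preprocess_spectrum(b)])
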