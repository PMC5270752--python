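"""Spectral containers, text/CSV round trips, and resampling."""

import numpy as np
import pytest

from racescrs.spectral_io import (
    SpectralFormatError, SpectralValidationError, Spectrum, SpectrumSet,
    WavenumberGrid, read_cohort_csv, read_spectrum_txt, resample_to_grid,
    write_cohort_csv, write_spectrum_txt,
)


def random_spectrum(seed=0, n=1019, start=700.0, step=1.0, cell_id="c0"):
    rng = np.random.default_rng(seed)
    grid = WavenumberGrid.uniform(start, step, n)
    return Spectrum(grid=grid, intensities=rng.uniform(0, 50, n),
                    cell_id=cell_id, position=(1.5, 2.5), label="typical")


class TestWavenumberGrid:
    def test_default_grid_is_1019_points_at_unit_step(self):
        grid = WavenumberGrid.default()
        assert grid.n_points == 1019
        assert grid.step == pytest.approx(1.0)
        assert grid.start == pytest.approx(700.0)
        assert grid.stop == pytest.approx(1718.0)
        assert grid.is_uniform

    @pytest.mark.parametrize("kwargs", [
        dict(step=0.0), dict(step=-1.0), dict(n_points=1),
    ])
    def test_invalid_uniform_grids_rejected(self, kwargs):
        with pytest.raises(SpectralValidationError):
            WavenumberGrid.uniform(**{**dict(start=0, step=1, n_points=8),
                                      **kwargs})

    def test_non_increasing_values_rejected(self):
        with pytest.raises(SpectralValidationError):
            WavenumberGrid([1.0, 2.0, 2.0, 3.0])


class TestSpectrumInvariants:
    def test_length_mismatch_rejected(self):
        grid = WavenumberGrid.uniform(0, 1, 10)
        with pytest.raises(SpectralValidationError):
            Spectrum(grid=grid, intensities=np.ones(9))

    def test_negative_raw_intensities_rejected(self):
        grid = WavenumberGrid.uniform(0, 1, 5)
        with pytest.raises(SpectralValidationError):
            Spectrum(grid=grid, intensities=np.array([1, -1, 1, 1, 1.0]))

    def test_negative_allowed_when_baseline_subtracted(self):
        grid = WavenumberGrid.uniform(0, 1, 5)
        s = Spectrum(grid=grid, intensities=np.array([1, -1, 1, 1, 1.0]),
                     flags={"baseline_subtracted"})
        assert s.intensities[1] == -1

    def test_mixed_grids_rejected_uniformly(self):
        a = random_spectrum(1, cell_id="a")
        grid_b = WavenumberGrid.uniform(700.0, 1.0, 512)
        b = Spectrum(grid=grid_b, intensities=np.ones(512), cell_id="b")
        with pytest.raises(SpectralValidationError, match="mixed"):
            SpectrumSet([a, b])

    def test_duplicate_cell_ids_rejected(self):
        with pytest.raises(SpectralValidationError, match="a"):
            SpectrumSet([random_spectrum(1, cell_id="a"),
                         random_spectrum(2, cell_id="a")])


class TestSpectrumTxt:
    def test_round_trip_preserves_values_within_print_precision(self, tmp_path):
        s = random_spectrum(42)
        path = tmp_path / "s.txt"
        write_spectrum_txt(s, path)
        back = read_spectrum_txt(path)
        assert back.cell_id == s.cell_id
        assert back.grid == s.grid
        assert back.position == s.position
        np.testing.assert_allclose(back.intensities, s.intensities, atol=1e-6)

    def test_descending_input_equals_ascending(self, tmp_path):
        s = random_spectrum(3, n=64)
        asc = tmp_path / "asc.txt"
        desc = tmp_path / "desc.txt"
        write_spectrum_txt(s, asc)
        lines = asc.read_text().splitlines()
        header = [l for l in lines if l.startswith("#")]
        data = [l for l in lines if not l.startswith("#")]
        desc.write_text("\n".join(header + data[::-1]) + "\n")
        a, d = read_spectrum_txt(asc), read_spectrum_txt(desc)
        assert a.grid == d.grid
        np.testing.assert_array_equal(a.intensities, d.intensities)

    def test_comma_delimited_accepted(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("700,1.0\n701,2.0\n702,3.0\n")
        s = read_spectrum_txt(path)
        assert s.grid.n_points == 3
        np.testing.assert_array_equal(s.intensities, [1.0, 2.0, 3.0])

    def test_non_numeric_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("700 1.0\n701 oops\n702 3.0\n")
        with pytest.raises(SpectralFormatError, match=":2"):
            read_spectrum_txt(path)

    def test_single_point_file_rejected(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("700 1.0\n")
        with pytest.raises(SpectralFormatError, match="fewer than 2"):
            read_spectrum_txt(path)

    def test_non_uniform_grid_flagged(self, tmp_path):
        path = tmp_path / "nu.txt"
        path.write_text("700 1.0\n701 2.0\n703 3.0\n")
        s = read_spectrum_txt(path)
        assert "non_uniform_grid" in s.flags
        assert not s.grid.is_uniform


class TestCohortCsv:
    def test_three_row_csv_shares_one_grid(self, tmp_path):
        spectra = [random_spectrum(i, n=32, cell_id=f"c{i}") for i in range(3)]
        path = tmp_path / "cohort.csv"
        write_cohort_csv(SpectrumSet(spectra), path)
        back = read_cohort_csv(path)
        assert len(back) == 3
        assert back.grid == spectra[0].grid

    def test_duplicate_cell_id_names_offender(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("cell_id,x,y,label,700,701\nA,0,0,,1,2\nA,0,0,,3,4\n")
        with pytest.raises(SpectralValidationError, match="A"):
            read_cohort_csv(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("cell_id,x,y,label,700,701\nA,0,0,,1\n")
        with pytest.raises(SpectralFormatError):
            read_cohort_csv(path)

    def test_seeded_100_spectrum_round_trip(self, tmp_path):
        spectra = [random_spectrum(i, n=128, cell_id=f"c{i:03d}")
                   for i in range(100)]
        original = SpectrumSet(spectra)
        path = tmp_path / "big.csv"
        write_cohort_csv(original, path)
        back = read_cohort_csv(path)
        diff = np.abs(back.intensity_matrix() - original.intensity_matrix())
        assert diff.max() <= 1e-6
        assert back.cell_ids == original.cell_ids


class TestResample:
    def test_identity_on_own_grid(self):
        s = random_spectrum(5, n=64)
        out = resample_to_grid(s, s.grid)
        np.testing.assert_allclose(out.intensities, s.intensities)

    def test_linear_ramp_to_half_step_grid_hits_midpoints(self):
        grid = WavenumberGrid.uniform(0.0, 1.0, 11)
        s = Spectrum(grid=grid, intensities=np.arange(11, dtype=float))
        fine = WavenumberGrid.uniform(0.0, 0.5, 21)
        out = resample_to_grid(s, fine)
        np.testing.assert_allclose(out.intensities, np.arange(21) * 0.5)

    def test_matches_brute_force_two_point_interpolation(self):
        rng = np.random.default_rng(9)
        s = Spectrum(grid=WavenumberGrid.uniform(0.0, 1.0, 50),
                     intensities=rng.uniform(0, 10, 50))
        coarse = WavenumberGrid.uniform(0.3, 2.1, 20)
        out = resample_to_grid(s, coarse)
        w, y = s.wavenumbers, s.intensities
        for target, got in zip(coarse.values, out.intensities):
            i = int(np.searchsorted(w, target, side="right")) - 1
            i = min(max(i, 0), w.size - 2)
            t = (target - w[i]) / (w[i + 1] - w[i])
            expected = (1 - t) * y[i] + t * y[i + 1]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_target_rejected(self):
        s = random_spectrum(2, n=32)
        wide = WavenumberGrid.uniform(600.0, 1.0, 32)
        with pytest.raises(SpectralValidationError, match="beyond"):
            resample_to_grid(s, wide)
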