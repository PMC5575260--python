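"""Reading, validation, cropping, resampling and round-tripping of spectra."""

import numpy as np
import pytest

from evraman.spectra import (
    SpectralDataset,
    SpectralWindowSet,
    Spectrum,
    SpectrumParseError,
    SpectrumValidationError,
    crop_to_windows,
    read_dataset,
    read_spectrum,
    resample_common_axis,
    write_dataset,
)


class TestTwoColumn:
    def test_basic_pairs(self, tmp_path):
        f = tmp_path / "s.txt"
        f.write_text("# comment\n1000 5.0\n1001 6.0\n")
        s = read_spectrum(f)
        assert np.array_equal(s.wavenumbers, [1000.0, 1001.0])
        assert np.array_equal(s.intensities, [5.0, 6.0])

    def test_descending_axis_reordered(self, tmp_path):
        f = tmp_path / "s.txt"
        f.write_text("1001,6.0\n1000,5.0\n")
        s = read_spectrum(f)
        assert np.array_equal(s.wavenumbers, [1000.0, 1001.0])
        assert np.array_equal(s.intensities, [5.0, 6.0])

    def test_malformed_field_names_line(self, tmp_path):
        f = tmp_path / "s.txt"
        f.write_text("1000 5.0\n1001 oops\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(f)

    def test_duplicate_wavenumber_rejected(self, tmp_path):
        f = tmp_path / "s.txt"
        f.write_text("1000 5.0\n1000 6.0\n1001 1.0\n")
        with pytest.raises(SpectrumValidationError, match="duplicate"):
            read_spectrum(f)

    def test_too_few_points_rejected(self, tmp_path):
        f = tmp_path / "s.txt"
        f.write_text("1000 5.0\n")
        with pytest.raises(SpectrumValidationError, match="fewer than 2"):
            read_spectrum(f)


class TestLongFormat:
    def test_grouping_by_sample(self, tmp_path):
        # grouping oracle: 3 sample ids x 4 wavenumbers -> 3 spectra of length 4
        rows = ["sample_id,class_label,donor_id,map_x,map_y,wavenumber,intensity"]
        for sid in ("a", "b", "c"):
            for k, w in enumerate((1000, 1001, 1002, 1003)):
                rows.append(f"{sid},ASC,d1,,,{w},{k}.5")
        f = tmp_path / "long.csv"
        f.write_text("\n".join(rows) + "\n")
        spectra = read_spectrum(f, dialect="long_format")
        assert [s.sample_id for s in spectra] == ["a", "b", "c"]
        assert all(len(s) == 4 for s in spectra)
        assert all(s.class_label == "ASC" for s in spectra)

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "long.csv"
        f.write_text("sample_id,wavenumber,intensity\na,1000,1\na,1001,2\n")
        with pytest.raises(SpectrumParseError, match="missing columns"):
            read_spectrum(f, dialect="long_format")


class TestSpectrumInvariants:
    def test_length_mismatch(self):
        with pytest.raises(SpectrumValidationError):
            Spectrum([1, 2, 3], [1, 2])

    def test_nonfinite_rejected(self):
        with pytest.raises(SpectrumValidationError):
            Spectrum([1, 2], [1, np.nan])

    def test_unknown_label_rejected(self):
        with pytest.raises(SpectrumValidationError):
            Spectrum([1, 2], [1, 2], {"class_label": "EV"})


class TestCrop:
    def test_default_windows_point_count(self):
        # closed intervals: 500..1800 has 1301 integers, 2600..3200 has 601
        axis = np.arange(400.0, 3401.0)
        s = Spectrum(axis, np.zeros(len(axis)))
        c = crop_to_windows(s, SpectralWindowSet())
        assert len(c) == 1301 + 601

    def test_inside_window_is_identity(self):
        s = Spectrum([600.0, 700.0, 800.0], [1.0, 2.0, 3.0])
        c = crop_to_windows(s, SpectralWindowSet())
        assert np.array_equal(c.wavenumbers, s.wavenumbers)
        assert np.array_equal(c.intensities, s.intensities)

    def test_boundaries_inclusive(self):
        s = Spectrum([499.5, 500.0, 1800.0, 1800.5], [1, 2, 3, 4])
        c = crop_to_windows(s, SpectralWindowSet())
        assert np.array_equal(c.wavenumbers, [500.0, 1800.0])
        assert np.array_equal(c.intensities, [2.0, 3.0])

    def test_idempotent(self):
        w = SpectralWindowSet()
        axis = np.linspace(400, 3400, 777)
        s = Spectrum(axis, np.sin(axis))
        once = crop_to_windows(s, w)
        twice = crop_to_windows(once, w)
        assert np.array_equal(once.wavenumbers, twice.wavenumbers)
        assert np.array_equal(once.intensities, twice.intensities)

    def test_empty_result_rejected(self):
        s = Spectrum([100.0, 200.0], [1.0, 2.0])
        with pytest.raises(SpectrumValidationError, match="no points"):
            crop_to_windows(s, SpectralWindowSet())


class TestWindowSet:
    def test_overlap_rejected(self):
        with pytest.raises(SpectrumValidationError, match="overlap"):
            SpectralWindowSet(((500, 1800), (1700, 3200)))

    def test_inverted_rejected(self):
        with pytest.raises(SpectrumValidationError):
            SpectralWindowSet(((1800, 500),))


class TestResample:
    def test_identity_on_grid(self):
        w = SpectralWindowSet(((1000.0, 1010.0),))
        axis = w.grid(1.0)
        vals = np.arange(len(axis), dtype=float)
        s = Spectrum(axis, vals, {"sample_id": "x"})
        d = resample_common_axis([s], step=1.0, w=w)
        assert np.array_equal(d.axis, axis)
        assert np.array_equal(d.matrix[0], vals)

    def test_linear_midpoint(self):
        w = SpectralWindowSet(((1000.0, 1001.0),))
        s = Spectrum([1000.0, 1002.0], [0.0, 4.0])
        d = resample_common_axis([s], step=0.5, w=w)
        # value at 1001 must be the linear midpoint
        j = np.nonzero(d.axis == 1001.0)[0]
        assert d.matrix[0, j] == pytest.approx(2.0, abs=0)

    def test_matches_pointwise_interpolation_oracle(self, rng):
        # independent oracle: two-point linear interpolation at each grid point
        w = SpectralWindowSet(((800.0, 900.0),))
        spectra = []
        for i in range(5):
            base = np.linspace(795, 905, 140)
            ax = np.sort(base + rng.uniform(-0.3, 0.3, size=base.size))
            spectra.append(Spectrum(ax, rng.normal(size=ax.size),
                                    {"sample_id": f"s{i}"}))
        d = resample_common_axis(spectra, step=1.0, w=w)
        for row, s in zip(d.matrix, spectra):
            for j, x in enumerate(d.axis):
                k = np.searchsorted(s.wavenumbers, x)
                if s.wavenumbers[min(k, len(s) - 1)] == x:
                    expected = s.intensities[k]
                elif k == 0:
                    expected = s.intensities[0]
                elif k == len(s):
                    expected = s.intensities[-1]
                else:
                    x0, x1 = s.wavenumbers[k - 1], s.wavenumbers[k]
                    y0, y1 = s.intensities[k - 1], s.intensities[k]
                    expected = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
                assert abs(row[j] - expected) < 1e-12

    def test_insufficient_coverage_names_sample(self):
        w = SpectralWindowSet(((1000.0, 1100.0),))
        s = Spectrum(np.linspace(1000, 1050, 60), np.zeros(60),
                     {"sample_id": "short-one"})
        with pytest.raises(SpectrumValidationError, match="short-one"):
            resample_common_axis([s], step=1.0, w=w)


class TestRoundTrip:
    def test_small_dataset_exact(self, tmp_path):
        d = SpectralDataset(
            axis=[1000.0, 1001.5, 1003.0],
            matrix=[[1.0, 2.0, 1 / 3], [np.pi, 1e-30, 5.0]],
            labels=["ASC", "DF"], donors=["d1", "d2"], ids=["a", "b"],
        )
        write_dataset(d, tmp_path / "d.csv")
        back = read_dataset(tmp_path / "d.csv")
        assert np.array_equal(back.axis, d.axis)
        assert np.array_equal(back.matrix, d.matrix)
        assert list(back.labels) == list(d.labels)
        assert list(back.donors) == list(d.donors)
        assert list(back.ids) == list(d.ids)

    def test_absent_map_coordinates_preserved(self, tmp_path):
        d = SpectralDataset(
            axis=[1.0, 2.0], matrix=[[1.0, 2.0], [3.0, 4.0]],
            labels=["ASC", "ASC"], donors=["d", "d"], ids=["a", "b"],
            map_x=[10.0, np.nan], map_y=[20.0, np.nan],
        )
        write_dataset(d, tmp_path / "d.csv")
        back = read_dataset(tmp_path / "d.csv")
        assert back.map_x[0] == 10.0 and back.map_y[0] == 20.0
        assert np.isnan(back.map_x[1]) and np.isnan(back.map_y[1])

    def test_full_synthetic_cohort_roundtrip(self, tmp_path, default_cohort):
        d, _ = default_cohort
        write_dataset(d, tmp_path / "cohort.csv")
        back = read_dataset(tmp_path / "cohort.csv")
        assert back.matrix.shape == d.matrix.shape
        assert np.max(np.abs(back.matrix - d.matrix)) == 0.0
        assert np.array_equal(back.axis, d.axis)
        assert list(back.labels) == list(d.labels)
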