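"""Cross-acquisition alignment, MS/MS association, recalibration, persistence."""

import numpy as np
import pytest

from lipidquery import masterscan as msc
from lipidquery import synth
from lipidquery.averaging import AveragedSpectrum, ResolutionModel


def _spec(mz, inten, **kw):
    mz = np.asarray(mz, dtype=float)
    inten = np.asarray(inten, dtype=float)
    return AveragedSpectrum(mz, inten, np.ones(mz.size), np.ones(mz.size), **kw)


MODEL = ResolutionModel(100000.0, anchor=400.0)


def _toy_masterscan():
    spectra = [
        _spec([500.0, 600.0], [10.0, 20.0]),
        _spec([500.00001, 600.00001], [11.0, 21.0]),
        _spec([500.00002, 600.00002], [12.0, 22.0]),
    ]
    return msc.build_masterscan(["a1", "a2", "a3"], spectra, MODEL,
                                groups={"sample": ["a1", "a2"], "blank": ["a3"]})


class TestAlign:
    def test_identical_spectra_three_acquisitions(self):
        ms = _toy_masterscan()
        assert len(ms.entries) == 2
        for e in ms.entries:
            assert e.intensities.size == 3
            assert e.occupancy == 1.0

    def test_unweighted_mean_representative_mass(self):
        # one intense and one weak acquisition peak: representative mass must
        # NOT move toward the intense one (alignment is unweighted)
        spectra = [_spec([500.000], [1000.0]), _spec([500.004], [1.0])]
        entries = msc.align_spectra(spectra, MODEL)
        assert len(entries) == 1
        assert entries[0].mz == pytest.approx(500.002, abs=1e-9)

    def test_occupancy_definition(self):
        spectra = [_spec([500.0], [1.0])] * 2 + [_spec([900.0], [1.0])] * 2
        entries = msc.align_spectra(spectra, MODEL)
        assert [e.occupancy for e in entries] == [0.5, 0.5]

    def test_intensity_conservation(self):
        rng = np.random.default_rng(0)
        spectra = []
        for _ in range(5):
            mz = np.sort(rng.uniform(500, 900, 60))
            spectra.append(_spec(mz, rng.uniform(1, 100, 60)))
        entries = msc.align_spectra(spectra, MODEL)
        matrix = np.stack([e.intensities for e in entries])
        for k, spec in enumerate(spectra):
            assert matrix[:, k].sum() == pytest.approx(spec.intensity.sum())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        spectra = []
        for _ in range(4):
            mz = np.sort(rng.uniform(500, 900, 40))
            spectra.append(_spec(mz, rng.uniform(1, 100, 40)))
        entries = msc.align_spectra(spectra, MODEL)
        perm = [2, 0, 3, 1]
        entries_p = msc.align_spectra([spectra[i] for i in perm], MODEL)
        np.testing.assert_allclose(
            [e.mz for e in entries], [e.mz for e in entries_p]
        )
        for e, ep in zip(entries, entries_p):
            np.testing.assert_allclose(e.intensities[perm], ep.intensities)

    def test_mixed_polarity_rejected(self):
        spectra = [_spec([500.0], [1.0]), _spec([500.0], [1.0], polarity="-")]
        with pytest.raises(ValueError):
            msc.align_spectra(spectra, MODEL)


class TestAssociateMsms:
    def _frag_spec(self, prec):
        return _spec([184.0733], [100.0], ms_level=2, precursor_mz=prec)

    def test_within_half_window_attached(self):
        ms = _toy_masterscan()
        ms.resolution_ms2 = MODEL
        msc.associate_msms(ms, {500.3: [(0, self._frag_spec(500.3))]}, 1.0)
        assert len(ms.entries[0].msms) == 1
        assert ms.entries[0].msms[0].mz == pytest.approx(184.0733)
        assert not ms.orphans

    def test_two_entries_share_one_block(self):
        spectra = [_spec([788.3, 788.6], [5.0, 7.0])]
        ms = msc.build_masterscan(["a1"], spectra, MODEL)
        msc.associate_msms(ms, {788.45: [(0, self._frag_spec(788.45))]}, 1.0)
        assert all(len(e.msms) == 1 for e in ms.entries)

    def test_orphan_spectrum_logged_not_fatal(self):
        ms = _toy_masterscan()
        msc.associate_msms(ms, {700.0: [(0, self._frag_spec(700.0))]}, 1.0)
        assert ms.orphans and ms.orphans[0][0] == pytest.approx(700.0)


class TestRecalibrate:
    def test_constant_offset_two_refs(self):
        spectra = [_spec([500.002, 900.002], [1.0, 1.0])]
        ms = msc.build_masterscan(["a"], spectra, MODEL)
        msc.recalibrate(ms, [500.0, 900.0], match_tol="10ppm")
        assert [e.mz for e in ms.entries] == pytest.approx([500.0, 900.0], abs=1e-9)

    def test_proportional_error_removed(self):
        refs = [400.0, 900.0]
        observed = [r * (1 + 5e-6) for r in refs]  # 5 ppm proportional error
        spectra = [_spec(observed, [1.0, 1.0])]
        ms = msc.build_masterscan(["a"], spectra, MODEL)
        msc.recalibrate(ms, refs, match_tol="10ppm")
        for e, r in zip(ms.entries, refs):
            assert abs(e.mz - r) / r * 1e6 < 0.1

    def test_zero_error_is_identity(self):
        spectra = [_spec([500.0, 900.0], [1.0, 1.0])]
        ms = msc.build_masterscan(["a"], spectra, MODEL)
        msc.recalibrate(ms, [500.0, 900.0], match_tol="10ppm")
        assert [e.mz for e in ms.entries] == pytest.approx([500.0, 900.0], abs=1e-12)

    def test_no_match_is_error(self):
        spectra = [_spec([500.0], [1.0])]
        ms = msc.build_masterscan(["a"], spectra, MODEL)
        with pytest.raises(ValueError):
            msc.recalibrate(ms, [620.0], match_tol="5ppm")


class TestFilter:
    def _occupancy_masterscan(self, present_in: int, total: int = 8):
        spectra = [
            _spec([500.0], [1.0]) if i < present_in else _spec([900.0], [1.0])
            for i in range(total)
        ]
        return msc.build_masterscan([f"a{i}" for i in range(total)], spectra, MODEL)

    def test_half_occupancy_retained_at_50pct(self):
        ms = msc.filter_entries(self._occupancy_masterscan(4), min_occupancy=0.5)
        assert any(abs(e.mz - 500.0) < 1e-6 for e in ms.entries)

    def test_three_of_eight_removed_at_50pct(self):
        ms = msc.filter_entries(self._occupancy_masterscan(3), min_occupancy=0.5)
        assert not any(abs(e.mz - 500.0) < 1e-6 for e in ms.entries)

    def test_zero_threshold_is_identity(self):
        base = self._occupancy_masterscan(3)
        ms = msc.filter_entries(base, min_occupancy=0.0)
        assert [e.mz for e in ms.entries] == [e.mz for e in base.entries]

    def test_intensity_threshold_zeroes_before_occupancy(self):
        spectra = [_spec([500.0], [100.0]), _spec([500.0], [1.0])]
        ms = msc.build_masterscan(["a", "b"], spectra, MODEL)
        out = msc.filter_entries(ms, min_occupancy=0.6, min_intensity_ms1=10.0)
        assert not out.entries  # occupancy 0.5 after zeroing the weak slot

    def test_retained_entries_satisfy_threshold(self):
        rng = np.random.default_rng(2)
        spectra = [
            _spec(np.sort(rng.uniform(500, 900, 20)), rng.uniform(1, 10, 20))
            for _ in range(6)
        ]
        ms = msc.build_masterscan([f"a{i}" for i in range(6)], spectra, MODEL)
        out = msc.filter_entries(ms, min_occupancy=0.5)
        assert all(e.occupancy >= 0.5 for e in out.entries)

    def test_unknown_group_rejected(self):
        ms = self._occupancy_masterscan(4)
        with pytest.raises(KeyError):
            msc.filter_entries(ms, min_occupancy=0.5, scope="nonexistent")


class TestPersistence:
    def test_round_trip_equality(self, tmp_path):
        ms = _toy_masterscan()
        ms.resolution_ms2 = MODEL
        msc.associate_msms(ms, {500.3: [(0, _spec([184.0733], [42.0],
                                                  ms_level=2, precursor_mz=500.3))]}, 1.0)
        path = tmp_path / "x.sc"
        msc.save(ms, path)
        back = msc.load(path)
        assert back.acquisition_ids == ms.acquisition_ids
        assert back.groups == ms.groups
        assert [e.mz for e in back.entries] == [e.mz for e in ms.entries]
        for a, b in zip(ms.entries, back.entries):
            np.testing.assert_array_equal(a.intensities, b.intensities)
            assert [f.mz for f in a.msms] == [f.mz for f in b.msms]

    def test_save_is_deterministic(self, tmp_path):
        ms = _toy_masterscan()
        p1, p2 = tmp_path / "a.sc", tmp_path / "b.sc"
        msc.save(ms, p1)
        msc.save(ms, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_file_rejected(self, tmp_path):
        ms = _toy_masterscan()
        path = tmp_path / "x.sc"
        msc.save(ms, path)
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(ValueError):
            msc.load(path)

    def test_foreign_json_rejected(self, tmp_path):
        path = tmp_path / "x.sc"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValueError):
            msc.load(path)

    def test_storage_compaction(self, tmp_path):
        # 8 replicate acquisitions of the same 200-peak spectrum: the
        # MasterScan file must be smaller than the input acquisition files
        from lipidquery.spectra_io import Scan, write_mzxml

        rng = np.random.default_rng(3)
        centers = np.sort(rng.uniform(500, 900, 200))
        raw_bytes = 0
        spectra = []
        for i in range(8):
            mz = np.sort(rng.normal(centers, centers / 2e5))
            inten = rng.uniform(1e3, 1e6, 200)
            fpath = tmp_path / f"a{i}.mzXML"
            write_mzxml(fpath, [Scan(mz, inten, 1, "+")])
            raw_bytes += fpath.stat().st_size
            spectra.append(_spec(mz, inten))
        ms = msc.build_masterscan([f"a{i}" for i in range(8)], spectra, MODEL)
        path = tmp_path / "c.sc"
        msc.save(ms, path)
        assert path.stat().st_size < raw_bytes
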