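"""Loaders, writers and configuration round trips."""

import numpy as np
import pytest

from temposeq.data_io import (
    ImageSeries,
    RunConfig,
    load_config,
    load_profile,
    load_series,
    save_profile,
)
from temposeq.themes import ThematicProfile


def _write_nifti(path, data4d):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data4d, dtype=np.float64), np.eye(4)), str(path))


class TestLoadSeries:
    def test_nifti_shape_bookkeeping(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(4, 4, 4, 10))
        _write_nifti(tmp_path / "vol.nii.gz", vol)
        series = load_series(tmp_path / "vol.nii.gz", tr_seconds=1.0)
        assert (series.n_timepoints, series.n_features) == (10, 64)
        # C-order flattening: feature v is voxel unravel_index(v, (4,4,4))
        assert np.allclose(series.data[3], vol[..., 3].reshape(-1, order="C"))

    def test_all_ones_mask_is_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(4, 4, 4, 5))
        _write_nifti(tmp_path / "vol.nii.gz", vol)
        _write_nifti(tmp_path / "mask.nii.gz", np.ones((4, 4, 4, 1)))
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.ones((4, 4, 4)), np.eye(4)), str(tmp_path / "m.nii.gz"))
        a = load_series(tmp_path / "vol.nii.gz", tr_seconds=1.0)
        b = load_series(tmp_path / "vol.nii.gz", mask=tmp_path / "m.nii.gz", tr_seconds=1.0)
        assert np.array_equal(a.data, b.data)

    def test_half_mask_halves_features(self, tmp_path):
        import nibabel as nib

        rng = np.random.default_rng(2)
        _write_nifti(tmp_path / "vol.nii.gz", rng.normal(size=(4, 4, 4, 6)))
        mask = np.zeros((4, 4, 4))
        mask.reshape(-1)[:32] = 1
        nib.save(nib.Nifti1Image(mask, np.eye(4)), str(tmp_path / "mask.nii.gz"))
        series = load_series(tmp_path / "vol.nii.gz", mask=tmp_path / "mask.nii.gz")
        assert series.n_features == 32

    def test_mask_shape_mismatch_rejected(self, tmp_path):
        import nibabel as nib

        rng = np.random.default_rng(3)
        _write_nifti(tmp_path / "vol.nii.gz", rng.normal(size=(4, 4, 4, 6)))
        nib.save(nib.Nifti1Image(np.ones((3, 3, 3)), np.eye(4)), str(tmp_path / "mask.nii.gz"))
        with pytest.raises(ValueError, match="mask shape"):
            load_series(tmp_path / "vol.nii.gz", mask=tmp_path / "mask.nii.gz")

    def test_delimited_rows_are_timepoints(self, tmp_path):
        data = np.arange(12.0).reshape(4, 3) + np.eye(4, 3)
        np.savetxt(tmp_path / "m.tsv", data, delimiter="\t")
        series = load_series(tmp_path / "m.tsv", tr_seconds=0.72)
        assert (series.n_timepoints, series.n_features) == (4, 3)
        assert series.tr_seconds == 0.72
        np.savetxt(tmp_path / "mt.tsv", data.T, delimiter="\t")
        transposed = load_series(tmp_path / "mt.tsv", tr_seconds=0.72, transpose=True)
        assert np.allclose(transposed.data, series.data)

    def test_nan_cells_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("1\t2\t3\n4\tnan\t6\n")
        with pytest.raises(ValueError, match="NaN"):
            load_series(tmp_path / "m.tsv")

    def test_non_numeric_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("1,2,3\n4,five,6\n")
        with pytest.raises(ValueError):
            load_series(tmp_path / "m.csv")

    def test_too_few_timepoints_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("1\t2\t3\n")
        with pytest.raises(ValueError):
            load_series(tmp_path / "m.tsv")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_series("no-such-file.tsv")

    def test_constant_row_gated_by_flag(self, tmp_path):
        (tmp_path / "m.tsv").write_text("1\t1\t1\n4\t5\t6\n7\t8\t10\n")
        with pytest.raises(ValueError, match="constant"):
            load_series(tmp_path / "m.tsv")
        series = load_series(tmp_path / "m.tsv", allow_degenerate=True)
        assert series.n_timepoints == 3


class TestImageSeries:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ImageSeries(data=np.ones((1, 5)), tr_seconds=1.0)
        with pytest.raises(ValueError):
            ImageSeries(data=np.ones((5, 2)), tr_seconds=1.0)
        with pytest.raises(ValueError):
            ImageSeries(data=np.ones((5, 5)), tr_seconds=0.0)


class TestProfileRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        p = ThematicProfile(labels=[1, 1, 2, 2], q=0.5, tr_seconds=1.0)
        save_profile(p, tmp_path / "p.tsv")
        assert load_profile(tmp_path / "p.tsv") == p

    def test_label_gaps_preserved_verbatim(self, tmp_path):
        p = ThematicProfile(labels=[1, 3, 3, 1], q=0.25, tr_seconds=0.72)
        save_profile(p, tmp_path / "p.tsv")
        out = load_profile(tmp_path / "p.tsv")
        assert np.array_equal(out.labels, [1, 3, 3, 1])
        assert out.q == 0.25 and out.tr_seconds == 0.72

    def test_file_is_one_based(self, tmp_path):
        save_profile(ThematicProfile(labels=[2, 1], q=0.0), tmp_path / "p.tsv")
        body = [l for l in (tmp_path / "p.tsv").read_text().splitlines()
                if not l.startswith(("#", "timepoint"))]
        assert body == ["1\t2", "2\t1"]

    def test_empty_profile_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            ThematicProfile(labels=[], q=0.0)

    def test_malformed_header_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("# garbage\ntimepoint\ttheme\n1\t1\n2\t1\n")
        with pytest.raises(ValueError):
            load_profile(tmp_path / "p.tsv")

    def test_timepoint_gap_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text(
            "# q\t0.1\n# tr_seconds\t1.0\ntimepoint\ttheme\n1\t1\n3\t2\n"
        )
        with pytest.raises(ValueError, match="without gaps"):
            load_profile(tmp_path / "p.tsv")

    def test_non_integer_labels_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text(
            "# q\t0.1\n# tr_seconds\t1.0\ntimepoint\ttheme\n1\t1.5\n"
        )
        with pytest.raises(ValueError):
            load_profile(tmp_path / "p.tsv")


class TestRunConfig:
    def test_reference_defaults(self):
        cfg = RunConfig()
        assert cfg.threshold_fraction == 0.05
        assert cfg.n_surrogates == 100
        assert cfg.motif_lengths == tuple(range(4, 12))
        assert cfg.alpha == 0.05
        assert cfg.louvain_restarts == 100
        assert cfg.gamma == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            RunConfig(threshold_fraction=0.0)
        with pytest.raises(ValueError):
            RunConfig(motif_lengths=(1, 2))
        with pytest.raises(ValueError):
            RunConfig(n_surrogates=0)

    def test_yaml_and_overrides(self, tmp_path):
        (tmp_path / "c.yaml").write_text(
            "threshold_fraction: 0.1\nmotif_lengths: '4:6'\nrng_seed: 9\n"
        )
        cfg = load_config(tmp_path / "c.yaml", n_surrogates=10)
        assert cfg.threshold_fraction == 0.1
        assert cfg.motif_lengths == (4, 5, 6)
        assert cfg.rng_seed == 9 and cfg.n_surrogates == 10

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("frobnicate: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(tmp_path / "c.yaml")
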