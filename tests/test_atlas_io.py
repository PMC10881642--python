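"""Atlas definition, cohort-table IO, image-space extraction and smoothing."""


import numpy as np
import pandas as pd
import pytest

from fdgpattern.atlas import COMPOSITE_NAMES, AtlasDefinition, N_REGIONS
from fdgpattern.images import extract_voi_means, fwhm_to_sigma, gaussian_smooth
from fdgpattern.io import read_cohort_table, read_matrix, write_cohort_table, write_matrix
from fdgpattern.synthetic import SyntheticCohortSpec, simulate_cohort


class TestAtlas:
    def test_default_atlas_invariants(self, atlas):
        assert len(atlas.regions) == N_REGIONS
        assert len(set(atlas.labels)) == N_REGIONS
        assert len(set(atlas.names)) == N_REGIONS
        assert set(atlas.composites) == set(COMPOSITE_NAMES)
        for comp, members in atlas.composites.items():
            assert members, comp
            assert set(members) <= set(atlas.names)
        assert all(v > 0 for v in atlas.volumes)

    def test_invalid_atlases_rejected(self, atlas):
        regions = list(atlas.regions)
        with pytest.raises(ValueError, match="exactly 77"):
            AtlasDefinition(regions=tuple(regions[:-1]))
        dup = regions[:-1] + [(999, regions[0][1])]
        with pytest.raises(ValueError, match="unique"):
            AtlasDefinition(regions=tuple(dup))
        with pytest.raises(ValueError, match="unknown regions"):
            AtlasDefinition(regions=tuple(regions), composites={"frontal": ("not_a_region",)})
        with pytest.raises(ValueError, match="empty"):
            AtlasDefinition(regions=tuple(regions), composites={"frontal": ()})
        with pytest.raises(ValueError, match="positive"):
            AtlasDefinition(regions=tuple(regions), volumes=tuple([1.0] * 76 + [0.0]))


class TestCohortTable:
    @pytest.fixture()
    def table_path(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_table(small_cohort, path)
        return path

    def test_round_trip_identity(self, table_path, atlas, small_cohort):
        back = read_cohort_table(table_path, atlas)
        assert back.subject_ids == small_cohort.subject_ids
        np.testing.assert_allclose(back.matrix(), small_cohort.matrix(), rtol=0, atol=1e-12)

    def test_shuffled_region_columns_reordered(self, table_path, atlas, small_cohort):
        frame = pd.read_csv(table_path)
        region_cols = [c for c in frame.columns if c in atlas.names]
        meta_cols = [c for c in frame.columns if c not in atlas.names]
        shuffled = frame[meta_cols + region_cols[::-1]]
        path2 = table_path.parent / "shuffled.csv"
        shuffled.to_csv(path2, index=False)
        back = read_cohort_table(path2, atlas)
        assert list(back.values.columns) == atlas.names
        np.testing.assert_allclose(back.matrix(), small_cohort.matrix(), atol=1e-12)

    def test_listwise_exclusion(self, table_path, atlas, small_cohort, caplog):
        frame = pd.read_csv(table_path)
        frame.loc[2, atlas.names[10]] = np.nan
        path2 = table_path.parent / "holes.csv"
        frame.to_csv(path2, index=False)
        with caplog.at_level("WARNING"):
            back = read_cohort_table(path2, atlas)
        assert back.n_subjects == small_cohort.n_subjects - 1
        assert "listwise exclusion" in caplog.text

    def test_missing_region_column_named(self, table_path, atlas):
        frame = pd.read_csv(table_path).drop(columns=["hippocampus_L"])
        path2 = table_path.parent / "missing.csv"
        frame.to_csv(path2, index=False)
        with pytest.raises(ValueError, match="hippocampus_L"):
            read_cohort_table(path2, atlas)

    def test_duplicate_subject_and_bad_group(self, table_path, atlas):
        frame = pd.read_csv(table_path)
        dup = pd.concat([frame, frame.iloc[[0]]])
        dup.to_csv(table_path.parent / "dup.csv", index=False)
        with pytest.raises(ValueError, match="duplicate subject"):
            read_cohort_table(table_path.parent / "dup.csv", atlas)
        frame.loc[0, "group"] = "WAT"
        frame.to_csv(table_path.parent / "bad.csv", index=False)
        with pytest.raises(ValueError, match="unknown group"):
            read_cohort_table(table_path.parent / "bad.csv", atlas)

    def test_tsv_autodetect(self, tmp_path, atlas, small_cohort):
        path = tmp_path / "cohort.tsv"
        write_cohort_table(small_cohort, path, sep="\t")
        back = read_cohort_table(path, atlas)
        np.testing.assert_allclose(back.matrix(), small_cohort.matrix(), atol=1e-12)


class TestMatrixIO:
    def test_round_trip(self, tmp_path, atlas):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(77, 77))
        m = (m + m.T) / 2
        path = tmp_path / "m.tsv"
        write_matrix(m, atlas.names, path)
        back, labels = read_matrix(path)
        assert labels == atlas.names
        np.testing.assert_allclose(back, m, atol=1e-12)
        assert "symmetric: True" in path.read_text().splitlines()[0]

    def test_asymmetry_flagged_and_labels_verbatim(self, tmp_path):
        m = np.array([[1.0, 2.0, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        path = tmp_path / "m3.tsv"
        write_matrix(m, ["alpha", "beta", "gamma"], path)
        text = path.read_text()
        assert "symmetric: False" in text
        for label in ("alpha", "beta", "gamma"):
            assert label in text

    def test_shape_label_mismatch(self, tmp_path):
        with pytest.raises(ValueError):
            write_matrix(np.zeros((2, 3)), ["a", "b"], tmp_path / "x.tsv")
        with pytest.raises(ValueError):
            write_matrix(np.zeros((2, 2)), ["a"], tmp_path / "x.tsv")


class TestVoiExtraction:
    def test_constant_field(self, atlas):
        labels = np.zeros((10, 10, 10), dtype=int)
        flat = np.asarray(atlas.labels)
        labels.ravel()[: 77 * 2] = np.repeat(flat, 2)
        image = np.full(labels.shape, 3.0)
        means, counts = extract_voi_means(image, labels, atlas)
        np.testing.assert_allclose(means, 3.0)
        assert (counts >= 2).all()

    def test_direct_mean_and_counts(self, atlas):
        labels = np.zeros((8, 8, 8), dtype=int)
        image = np.zeros(labels.shape)
        pos = 0
        for lab in atlas.labels:
            labels.ravel()[pos] = lab
            labels.ravel()[pos + 1] = lab
            image.ravel()[pos] = 1.0
            image.ravel()[pos + 1] = 3.0
            pos += 2
        # make region with label atlas.labels[1] a singleton of value 2.0
        labels.ravel()[2] = 0
        labels.ravel()[3] = atlas.labels[1]
        image.ravel()[3] = 2.0
        means, counts = extract_voi_means(image, labels, atlas)
        assert means[0] == pytest.approx(2.0)
        assert means[1] == pytest.approx(2.0)
        assert counts[1] == 1

    def test_brute_force_oracle(self, atlas):
        rng = np.random.default_rng(1)
        for _ in range(5):
            labels = rng.choice(atlas.labels, size=(16, 16, 16)).astype(int)
            image = rng.normal(size=labels.shape)
            means, counts = extract_voi_means(image, labels, atlas)
            for i, lab in enumerate(atlas.labels):
                mask = labels == lab
                assert counts[i] == mask.sum()
                assert abs(means[i] - image[mask].mean()) < 1e-12

    def test_missing_label_and_shape_errors(self, atlas):
        labels = np.full((4, 4, 4), atlas.labels[0], dtype=int)
        with pytest.raises(ValueError, match="lacks atlas label"):
            extract_voi_means(np.zeros(labels.shape), labels, atlas)
        with pytest.raises(ValueError, match="shape"):
            extract_voi_means(np.zeros((4, 4, 5)), labels, atlas)


class TestSmoothing:
    def test_constant_image_fixed_point(self):
        img = np.full((12, 12, 12), 2.5)
        out = gaussian_smooth(img, fwhm_mm=8.0, voxel_size_mm=(2, 2, 2))
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_interior_impulse_mass_conserved(self):
        img = np.zeros((31, 31, 31))
        img[15, 15, 15] = 1.0
        out = gaussian_smooth(img, fwhm_mm=4.0, voxel_size_mm=(1, 1, 1))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_fwhm_sigma_closed_form(self):
        assert fwhm_to_sigma(8.0) == pytest.approx(8.0 / 2.3548200450309493, rel=1e-12)
        assert fwhm_to_sigma(8.0) == pytest.approx(3.3973, abs=1e-4)

    def test_commutes_with_scaling(self):
        rng = np.random.default_rng(2)
        img = rng.random((10, 10, 10))
        a = gaussian_smooth(3.0 * img, 6.0, (1.5, 1.5, 1.5))
        b = 3.0 * gaussian_smooth(img, 6.0, (1.5, 1.5, 1.5))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bad_fwhm(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4, 4)), 0.0)


def test_simulated_cohort_survives_strict_container_checks(atlas):
    """The CohortMatrix invariants (positivity, ordering, no NaN) hold for generator output."""
    c = simulate_cohort(SyntheticCohortSpec(seed=9, n_per_group={"HC": 5, "DLB_DATPOS": 5}), atlas)
    assert list(c.values.columns) == atlas.names
    assert (c.matrix() > 0).all()
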