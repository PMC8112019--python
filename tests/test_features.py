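"""Regional extraction, timeseries averaging, connectivity and dropout rules."""

import numpy as np
import pytest

from wassconn import (
    GreyMatterMap,
    RegionAtlas,
    TimeseriesTable,
    average_regional_timeseries,
    extract_regional_samples,
    pearson_connectivity,
    regional_dropout_fraction,
    regional_mean_volumes,
)
from wassconn.features import (
    GridIncompatibilityError,
    InsufficientDataError,
    InvalidAtlasError,
)


def toy_atlas(labels):
    return RegionAtlas(label_volume=np.asarray(labels, dtype=np.int32))


@pytest.fixture(scope="module")
def random_atlas_gm():
    rng = np.random.default_rng(42)
    labels = rng.integers(0, 4, size=(10, 10, 10)).astype(np.int32)
    values = rng.uniform(-0.1, 1.0, size=(10, 10, 10))
    return toy_atlas(labels), GreyMatterMap(values=values)


class TestExtractRegionalSamples:
    def test_all_zero_map_gives_empty_samples(self):
        atlas = toy_atlas(np.tile([[1, 2]], (2, 2, 1)))
        gm = GreyMatterMap(values=np.zeros((2, 2, 2)))
        ss = extract_regional_samples(gm, atlas)
        assert all(v.size == 0 for v in ss.samples.values())

    def test_zero_voxels_excluded(self):
        labels = np.zeros((1, 1, 4), dtype=np.int32)
        labels[0, 0, :3] = 1
        labels[0, 0, 3] = 2
        gm = np.array([[[0.2, 0.0, 0.5, 0.7]]])
        ss = extract_regional_samples(GreyMatterMap(values=gm), toy_atlas(labels))
        assert sorted(ss.samples[1]) == [0.2, 0.5]
        assert list(ss.samples[2]) == [0.7]

    def test_matches_voxel_loop_oracle(self, random_atlas_gm):
        atlas, gm = random_atlas_gm
        ss = extract_regional_samples(gm, atlas)
        for rid in atlas.region_ids:
            expected = []
            for idx in np.ndindex(atlas.shape):
                if atlas.label_volume[idx] == rid and gm.values[idx] > 0:
                    expected.append(gm.values[idx])
            assert np.allclose(sorted(ss.samples[rid]), sorted(expected))

    def test_partition_consistency(self, random_atlas_gm):
        atlas, gm = random_atlas_gm
        ss = extract_regional_samples(gm, atlas)
        total = sum(v.size for v in ss.samples.values())
        labelled_positive = int(
            np.sum((atlas.label_volume > 0) & (gm.values > 0))
        )
        assert total == labelled_positive

    def test_shape_mismatch_raises(self):
        atlas = toy_atlas(np.tile([[1, 2]], (2, 2, 1)))
        with pytest.raises(GridIncompatibilityError):
            extract_regional_samples(GreyMatterMap(values=np.zeros((3, 3, 3))), atlas)

    def test_atlas_without_labels_rejected(self):
        with pytest.raises(InvalidAtlasError):
            toy_atlas(np.zeros((2, 2, 2)))


class TestRegionalMeanVolumes:
    def test_mean_and_missing(self, random_atlas_gm):
        atlas, gm = random_atlas_gm
        ss = extract_regional_samples(gm, atlas)
        vol = regional_mean_volumes(ss)
        for i, rid in enumerate(atlas.region_ids):
            vals = ss.samples[rid]
            if vals.size:
                assert vol.values[i] == pytest.approx(np.mean(vals))
        from wassconn import RegionalSampleSet

        ss2 = RegionalSampleSet(samples={1: [0.2, 0.6], 2: []})
        vol2 = regional_mean_volumes(ss2)
        assert vol2.values[0] == pytest.approx(0.4)
        assert np.isnan(vol2.values[1])


class TestAverageRegionalTimeseries:
    def test_constant_volume(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 2
        fmri = np.full((2, 2, 2, 5), 3.0)
        ts = average_regional_timeseries(fmri, toy_atlas(labels))
        assert np.allclose(ts.series, 3.0)

    def test_mean_then_constant_flag(self):
        # two voxels with series (0,2) and (2,0) average to the constant (1,1)
        labels = np.zeros((1, 1, 3), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[0, 0, 1] = 1
        labels[0, 0, 2] = 2
        fmri = np.zeros((1, 1, 3, 2))
        fmri[0, 0, 0] = [0, 2]
        fmri[0, 0, 1] = [2, 0]
        fmri[0, 0, 2] = [1, 5]
        ts = average_regional_timeseries(fmri, toy_atlas(labels))
        assert np.allclose(ts.series[0], [1, 1])
        assert ts.dropout_rows().tolist() == [True, False]

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, size=(4, 4, 4)).astype(np.int32)
        fmri = rng.normal(size=(4, 4, 4, 6))
        atlas = toy_atlas(labels)
        ts = average_regional_timeseries(fmri, atlas)
        for i, rid in enumerate(atlas.region_ids):
            acc = []
            for idx in np.ndindex(labels.shape):
                if labels[idx] == rid:
                    acc.append(fmri[idx])
            assert np.allclose(ts.series[i], np.mean(acc, axis=0))


class TestPearsonConnectivity:
    def test_affine_and_negated_rows(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        series = np.stack([base, 2 * base + 1, -base])
        fm = pearson_connectivity(TimeseriesTable(series=series, region_ids=(1, 2, 3)))
        assert fm.values[0, 1] == pytest.approx(1.0)
        assert fm.values[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(5, 50))
        fm = pearson_connectivity(TimeseriesTable(series=s, region_ids=tuple(range(1, 6))))
        for i in range(5):
            for j in range(5):
                xi, xj = s[i] - s[i].mean(), s[j] - s[j].mean()
                r = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
                assert fm.values[i, j] == pytest.approx(r, abs=1e-12)

    def test_symmetric_bounded_unit_diagonal(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = rng.normal(size=(6, 30))
            fm = pearson_connectivity(
                TimeseriesTable(series=s, region_ids=tuple(range(1, 7)))
            )
            assert np.array_equal(fm.values, fm.values.T)
            assert np.all(np.abs(fm.values) <= 1.0)
            assert np.allclose(np.diag(fm.values), 1.0)

    def test_constant_row_propagates_missing(self):
        s = np.vstack([np.ones(10), np.random.default_rng(4).normal(size=(2, 10))])
        fm = pearson_connectivity(TimeseriesTable(series=s, region_ids=(1, 2, 3)))
        assert np.all(np.isnan(fm.values[0]))
        assert np.all(np.isnan(fm.values[:, 0]))
        assert not np.isnan(fm.values[1, 2])

    def test_too_few_timepoints(self):
        ts = TimeseriesTable(series=np.zeros((3, 2)), region_ids=(1, 2, 3))
        with pytest.raises(InsufficientDataError):
            pearson_connectivity(ts)

    def test_invariant_to_voxel_order_within_regions(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 4, size=(4, 4, 4)).astype(np.int32)
        fmri = rng.normal(size=(4, 4, 4, 20))
        atlas = toy_atlas(labels)
        fm1 = pearson_connectivity(average_regional_timeseries(fmri, atlas))
        # shuffle voxels jointly (a relabelling of space that keeps labels)
        perm = rng.permutation(64)
        labels2 = labels.ravel()[perm].reshape(labels.shape)
        fmri2 = fmri.reshape(64, 20)[perm].reshape(fmri.shape)
        fm2 = pearson_connectivity(
            average_regional_timeseries(fmri2, toy_atlas(labels2))
        )
        assert np.allclose(fm1.values, fm2.values)


class TestDropoutRule:
    @pytest.mark.parametrize(
        "n_empty, n_regions, excluded",
        [(0, 116, False), (12, 116, True), (11, 116, False)],
    )
    def test_strict_threshold(self, n_empty, n_regions, excluded):
        from wassconn import RegionalSampleSet

        samples = {
            rid: (np.array([]) if rid <= n_empty else np.array([0.5]))
            for rid in range(1, n_regions + 1)
        }
        frac, flag = regional_dropout_fraction(RegionalSampleSet(samples=samples))
        assert frac == pytest.approx(n_empty / n_regions)
        assert flag is excluded

    def test_monotone_in_emptied_regions(self):
        from wassconn import RegionalSampleSet

        rng = np.random.default_rng(6)
        n = 20
        samples = {rid: rng.uniform(0.1, 1, size=5) for rid in range(1, n + 1)}
        previous_excluded = False
        for kill in range(n):
            samples[kill + 1] = np.array([])
            _, flag = regional_dropout_fraction(RegionalSampleSet(samples=dict(samples)))
            assert flag >= previous_excluded  # exclude never flips back to keep
            previous_excluded = flag
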