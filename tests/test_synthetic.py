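"""Synthetic cohort generators: determinism, planted effects, voxel round trip."""

import numpy as np
import pytest

from wassconn import (
    SyntheticConfig,
    extract_regional_samples,
    generate_covariates,
    generate_functional,
    generate_structural,
    pearson_connectivity,
    shuffle_group_labels,
    wasserstein_1d,
)
from wassconn.features import GreyMatterMap
from wassconn.synthetic import emit_voxel_volumes, generate_cohort


def small_cfg(**kw):
    base = dict(n_regions=8, n_cases=30, n_controls=30,
                voxels_per_region=(30, 60), n_timepoints=60,
                age_offset=0.0, fwd_offset=0.0, icv_offset=0.0,
                match_yield_floor=0.0, seed=11)
    base.update(kw)
    return SyntheticConfig(**base)


class TestDeterminism:
    def test_generators_are_pure_functions_of_config(self):
        cfg = small_cfg()
        s1, s2 = generate_structural(cfg), generate_structural(cfg)
        sid = next(iter(s1))
        assert all(
            np.array_equal(s1[k].samples[r], s2[k].samples[r])
            for k in s1 for r in s1[k].samples
        )
        t1, t2 = generate_functional(cfg), generate_functional(cfg)
        assert np.array_equal(t1[sid].series, t2[sid].series)
        r1, r2 = generate_covariates(cfg), generate_covariates(cfg)
        assert r1 == r2

    def test_different_seed_changes_cohort(self):
        s1 = generate_structural(small_cfg(seed=1))
        s2 = generate_structural(small_cfg(seed=2))
        sid = next(iter(s1))
        assert not np.array_equal(s1[sid].samples[1], s2[sid].samples[1])


class TestStructuralEffects:
    def test_values_strictly_positive(self):
        for ss in generate_structural(small_cfg()).values():
            for vals in ss.samples.values():
                assert np.all(vals > 0)

    def test_null_effect_no_group_difference(self):
        cfg = small_cfg(struct_effect=0.0, n_cases=60, n_controls=60)
        sets = generate_structural(cfg)
        # per-subject mean of planted region 1: case vs control effect size
        case_m = [sets[f"case_{i:04d}"].samples[1].mean() for i in range(60)]
        ctrl_m = [sets[f"control_{i:04d}"].samples[1].mean() for i in range(60)]
        pooled = np.sqrt((np.var(case_m, ddof=1) + np.var(ctrl_m, ddof=1)) / 2)
        d = (np.mean(case_m) - np.mean(ctrl_m)) / pooled
        assert abs(d) < 0.5

    def test_planted_shift_separates_wasserstein(self):
        cfg = small_cfg(struct_effect=1.5, planted_regions=(1, 2),
                        n_cases=40, n_controls=40)
        sets = generate_structural(cfg)
        # distance of each subject's region 1 to a reference control's region 1
        ref = sets["control_0000"].samples[1]
        d_case = [wasserstein_1d(sets[f"case_{i:04d}"].samples[1], ref)
                  for i in range(1, 40)]
        d_ctrl = [wasserstein_1d(sets[f"control_{i:04d}"].samples[1], ref)
                  for i in range(1, 40)]
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(d_case, d_ctrl, alternative="greater").pvalue
        assert p < 0.01

    def test_mean_preserving_shape_mode(self):
        cfg_shift = small_cfg(planted_mode="shift", n_cases=80, n_controls=80,
                              voxels_per_region=(100, 150))
        cfg_shape = small_cfg(planted_mode="shape", n_cases=80, n_controls=80,
                              voxels_per_region=(100, 150))
        shift_sets = generate_structural(cfg_shift)
        shape_sets = generate_structural(cfg_shape)

        def group_gap(sets):
            case = np.mean([sets[f"case_{i:04d}"].samples[1].mean()
                            for i in range(80)])
            ctrl = np.mean([sets[f"control_{i:04d}"].samples[1].mean()
                            for i in range(80)])
            return case - ctrl

        assert abs(group_gap(shape_sets)) < abs(group_gap(shift_sets)) / 3


class TestFunctionalEffects:
    def test_zero_loading_near_zero_correlation(self):
        cfg = small_cfg(factor_loading=0.0, n_timepoints=200,
                        n_cases=5, n_controls=5)
        ts = generate_functional(cfg)["case_0000"]
        fm = pearson_connectivity(ts)
        iu = np.triu_indices(cfg.n_regions, k=1)
        assert np.nanmean(np.abs(fm.values[iu])) < 0.1

    def test_block_structure_visible(self):
        cfg = small_cfg(n_cases=5, n_controls=5, n_factors=2, n_timepoints=200)
        fm = pearson_connectivity(generate_functional(cfg)["case_0000"])
        block = np.arange(cfg.n_regions) * 2 // cfg.n_regions
        same = block[:, None] == block[None, :]
        off = ~np.eye(cfg.n_regions, dtype=bool)
        within = fm.values[same & off].mean()
        between = fm.values[~same].mean()
        assert within > between + 0.1

    def test_planted_edge_raises_case_correlation(self):
        cfg = small_cfg(func_effect=0.8, planted_edges=((1, 5),),
                        n_cases=40, n_controls=40, n_timepoints=150)
        tables = generate_functional(cfg)
        r_case = np.mean(
            [np.corrcoef(tables[f"case_{i:04d}"].series[[0, 4]])[0, 1]
             for i in range(40)]
        )
        r_ctrl = np.mean(
            [np.corrcoef(tables[f"control_{i:04d}"].series[[0, 4]])[0, 1]
             for i in range(40)]
        )
        assert r_case > r_ctrl + 0.2


class TestCovariates:
    def test_zero_offsets_balanced_before_matching(self):
        recs = generate_covariates(small_cfg(n_cases=150, n_controls=150))
        for cov in ("age", "mean_fwd", "icv"):
            a = np.array([getattr(r, cov) for r in recs if r.group == "case"])
            b = np.array([getattr(r, cov) for r in recs if r.group == "control"])
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            assert abs(a.mean() - b.mean()) / pooled < 0.25

    def test_age_confound_removed_by_matching(self):
        from wassconn import MatchConfig, balance_report, match_controls

        cfg = SyntheticConfig(n_cases=80, n_controls=240, age_offset=5.0,
                              fwd_offset=0.0, icv_offset=0.0,
                              match_yield_floor=0.3, seed=19)
        recs = generate_covariates(cfg)
        cases = [r for r in recs if r.group == "case"]
        ctrls = [r for r in recs if r.group == "control"]
        a = np.array([r.age for r in cases])
        b = np.array([r.age for r in ctrls])
        pre = (a.mean() - b.mean()) / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert pre > 0.5
        rep = balance_report(match_controls(cases, ctrls, MatchConfig(seed=1)), recs)
        assert abs(rep["smd_age"]) < 0.2

    def test_infeasible_confounds_rejected_with_diagnostics(self):
        with pytest.raises(ValueError, match="eligible"):
            generate_covariates(
                small_cfg(age_offset=40.0, match_yield_floor=0.9)
            )

    def test_label_shuffle_permutes_groups_only(self):
        recs = generate_covariates(small_cfg())
        shuffled = shuffle_group_labels(recs, seed=4)
        assert sorted(r.group for r in recs) == sorted(r.group for r in shuffled)
        assert [r.age for r in recs] == [r.age for r in shuffled]
        assert any(a.group != b.group for a, b in zip(recs, shuffled))


class TestVoxelEmission:
    def test_round_trip_and_background(self, tmp_path):
        cfg = small_cfg(n_regions=6, n_cases=2, n_controls=2,
                        voxels_per_region=(20, 40))
        cohort = generate_cohort(cfg)
        subjects = list(cohort.sample_sets)[:2]
        atlas_path, map_paths = emit_voxel_volumes(
            cohort, tmp_path, grid_size=16, subjects=subjects
        )
        from wassconn.io import read_atlas, read_grey_matter

        atlas = read_atlas(atlas_path)
        assert atlas.n_regions == 6
        for sid in subjects:
            gm = GreyMatterMap(values=read_grey_matter(map_paths[sid]))
            ss = extract_regional_samples(gm, atlas)
            for rid, vals in cohort.sample_sets[sid].samples.items():
                assert np.allclose(sorted(ss.samples[rid]), sorted(vals),
                                   atol=1e-6)
                lo, hi = cfg.voxels_per_region
                assert lo <= vals.size <= hi
            # voxels outside every parcel stay zero (background)
            background = atlas.label_volume == 0
            assert np.all(gm.values[background] == 0)

    def test_grid_too_small_rejected(self):
        cfg = small_cfg(n_regions=8, voxels_per_region=(100, 120))
        cohort = generate_cohort(cfg)
        with pytest.raises(ValueError):
            emit_voxel_volumes(cohort, "unused", grid_size=8)
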