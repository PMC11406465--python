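"""GLM t maps, TFCE enhancement, permutation inference and cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from interofat.errors import InvalidInputError, InvalidParameterError
from interofat.synthetic import CohortParams, EffectFieldSpec, simulate_cohort, simulate_skeleton_maps
from interofat.voxelwise import (
    DesignMatrix,
    SkeletonMap,
    extract_cluster_means,
    glm_tstat_map,
    interaction_design,
    permutation_inference,
    read_skeleton_set,
    tfce_transform,
    write_skeleton_set,
)


def tfce_oracle(stat, mask, E=1.0, H=2.0, dh=None, connectivity=26):
    """Brute-force reference: explicit component labelling at every threshold."""
    stat = np.where(mask, np.asarray(stat, float), 0.0)
    mx = stat.max(initial=0.0)
    if mx <= 0:
        return np.zeros_like(stat)
    step = mx / 100.0 if dh is None else dh
    n_steps = int(np.floor(mx / step))
    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    out = np.zeros_like(stat)
    for i in range(1, n_steps + 1):
        h = i * step
        sup = stat >= h
        lab, n = ndimage.label(sup, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        out[sup] += sizes[lab[sup]] ** E * h**H * step
    return out


def make_maps(Y_flat, mask):
    """Wrap an (n_subjects, n_mask_voxels) array as SkeletonMap objects."""
    maps = []
    for i, row in enumerate(Y_flat):
        vol = np.zeros(mask.shape)
        vol[mask] = row
        maps.append(SkeletonMap(values=vol, mask=mask, subject_id=f"s{i}"))
    return maps


class TestGLM:
    def test_two_group_design_equals_pooled_t(self, rng):
        """Single-voxel two-group contrast reproduces the textbook t statistic."""
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        maps = make_maps(np.r_[a, b][:, None], mask)
        g = np.r_[np.zeros(12), np.ones(12)]
        design = DesignMatrix(
            frame=pd.DataFrame({"intercept": np.ones(24), "group": g}),
            contrasts={"group": np.array([0.0, 1.0])},
        )
        t_map = glm_tstat_map(maps, design, "group")
        expected = stats.ttest_ind(b, a, equal_var=True).statistic
        assert t_map[1, 1, 1] == pytest.approx(expected, rel=1e-10)

    def test_null_t_distribution(self, rng):
        """Pure-noise maps give t values following Student t with n-k df."""
        n, V = 20, 10_000
        mask = np.ones((100, 10, 10), bool)
        Y = rng.normal(size=(n, V))
        x = rng.normal(size=n)
        design = DesignMatrix(
            frame=pd.DataFrame({"intercept": np.ones(n), "x": x}),
            contrasts={"x": np.array([0.0, 1.0])},
        )
        t_map = glm_tstat_map(make_maps(Y, mask), design, "x")
        ks = stats.kstest(t_map[mask], stats.t(df=n - 2).cdf)
        assert ks.pvalue > 0.01

    def test_perfect_fit_flagged_and_capped(self, rng, caplog):
        n = 10
        x = rng.normal(size=n)
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        maps = make_maps(x[:, None], mask)  # maps equal the regressor exactly
        design = DesignMatrix(
            frame=pd.DataFrame({"intercept": np.ones(n), "x": x}),
            contrasts={"x": np.array([0.0, 1.0])},
        )
        with caplog.at_level("WARNING"):
            t_map = glm_tstat_map(maps, design, "x")
        assert t_map[0, 0, 0] == pytest.approx(1e6)
        assert "zero residual" in caplog.text

    def test_design_validation(self):
        with pytest.raises(InvalidInputError):
            DesignMatrix(frame=pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 4.0]}))
        with pytest.raises(InvalidInputError):
            DesignMatrix(
                frame=pd.DataFrame({"a": [1.0, 2.0, 1.5]}),
                contrasts={"bad": np.array([1.0, 0.0])},
            )


class TestTFCE:
    def test_matches_bruteforce_on_random_maps(self, rng):
        for case in range(100):
            stat = rng.normal(size=(8, 8, 8))
            mask = rng.random((8, 8, 8)) < rng.uniform(0.2, 0.9)
            conn = [6, 18, 26][case % 3]
            a = tfce_transform(stat, mask, connectivity=conn)
            b = tfce_oracle(stat, mask, connectivity=conn)
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_single_voxel_discrete_sum(self):
        """Isolated suprathreshold voxel: extent is always 1, so the sum is
        sum(h_i^H) * dh over thresholds below its height."""
        mask = np.ones((5, 5, 5), bool)
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 3.0
        dh = 0.1
        out = tfce_transform(stat, mask, E=1.0, H=2.0, dh=dh)
        hs = dh * np.arange(1, 31)
        assert out[2, 2, 2] == pytest.approx((hs**2).sum() * dh, rel=1e-12)
        assert out.sum() == pytest.approx(out[2, 2, 2])

    def test_all_zero_map(self):
        mask = np.ones((4, 4, 4), bool)
        assert (tfce_transform(np.zeros((4, 4, 4)), mask) == 0).all()

    def test_monotone_in_the_stat_map(self, rng):
        """Pointwise-larger maps yield pointwise-larger enhanced maps."""
        for _ in range(25):
            mask = rng.random((6, 6, 6)) < 0.7
            lo = rng.normal(size=(6, 6, 6))
            hi = lo + rng.uniform(0.0, 1.0, size=(6, 6, 6))
            # common dh so threshold grids align
            dh = max(hi[mask].max(), 1e-9) / 100.0
            a = tfce_transform(lo, mask, dh=dh)
            b = tfce_transform(hi, mask, dh=dh)
            assert (b - a >= -1e-9).all()

    def test_parameter_validation(self):
        mask = np.ones((3, 3, 3), bool)
        with pytest.raises(InvalidParameterError):
            tfce_transform(np.ones((3, 3, 3)), mask, dh=0.0)
        with pytest.raises(InvalidParameterError):
            tfce_transform(np.ones((3, 3, 3)), mask, connectivity=4)


class TestNiftiIO:
    def test_roundtrip_and_validation(self, tmp_path, rng):
        mask = rng.random((6, 6, 4)) < 0.4
        mask[0, 0, 0] = True
        Y = rng.normal(size=(3, int(mask.sum())))
        maps = make_maps(Y, mask)
        paths, mask_path = write_skeleton_set(maps, tmp_path)
        loaded = read_skeleton_set(paths, mask_path)
        assert len(loaded) == 3
        for orig, back in zip(maps, loaded):
            np.testing.assert_allclose(back.values[mask], orig.values[mask], rtol=1e-6)

    def test_mismatched_grid_rejected(self, tmp_path, rng):
        from interofat.voxelwise import write_volume

        mask = np.ones((4, 4, 4), bool)
        maps = make_maps(rng.normal(size=(1, 64)), mask)
        paths, mask_path = write_skeleton_set(maps, tmp_path)
        write_volume(np.zeros((5, 5, 5)), tmp_path / "bad.nii")
        with pytest.raises(InvalidInputError, match="bad"):
            read_skeleton_set([paths[0], tmp_path / "bad.nii"], mask_path)

    def test_empty_mask_rejected(self, tmp_path):
        from interofat.voxelwise import write_volume

        write_volume(np.zeros((4, 4, 4)), tmp_path / "mask.nii")
        with pytest.raises(InvalidInputError, match="no voxels"):
            read_skeleton_set([], tmp_path / "mask.nii")

    def test_nan_inside_mask_rejected(self, tmp_path):
        from interofat.voxelwise import write_volume

        write_volume(np.ones((4, 4, 4)), tmp_path / "mask.nii")
        bad = np.ones((4, 4, 4))
        bad[1, 1, 1] = np.nan
        write_volume(bad, tmp_path / "map.nii")
        with pytest.raises(InvalidInputError, match="NaN"):
            read_skeleton_set([tmp_path / "map.nii"], tmp_path / "mask.nii")


class TestPermutationInference:
    def small_study(self, rng, n=14, effect=0.0):
        mask = np.zeros((8, 8, 4), bool)
        mask[2:6, 2:6, 1:3] = True
        V = int(mask.sum())
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, V))
        Y[:, : V // 2] += effect * x[:, None]
        design = DesignMatrix(
            frame=pd.DataFrame({"intercept": np.ones(n), "x": x}),
            contrasts={"x": np.array([0.0, 1.0])},
        )
        return make_maps(Y, mask), design, mask

    def test_reproducible_given_seed(self, rng):
        maps, design, _ = self.small_study(rng)
        a = permutation_inference(maps, design, "x", n_perm=150, seed=5)
        b = permutation_inference(maps, design, "x", n_perm=150, seed=5)
        np.testing.assert_array_equal(a.fwe_p_map, b.fwe_p_map)
        np.testing.assert_array_equal(a.max_null_distribution, b.max_null_distribution)

    def test_p_values_respect_resolution_floor(self, rng):
        maps, design, mask = self.small_study(rng, effect=3.0)
        res = permutation_inference(maps, design, "x", n_perm=150, seed=6)
        assert res.fwe_p_map[mask].min() >= 1.0 / (res.n_permutations + 1) - 1e-12
        assert (res.fwe_p_map <= 1.0).all()

    def test_strong_effect_detected(self, rng):
        maps, design, mask = self.small_study(rng, effect=3.0)
        res = permutation_inference(maps, design, "x", n_perm=200, seed=7)
        assert res.significance_mask.sum() > 0

    def test_sign_flip_symmetry(self, rng):
        """Negating the contrast with the negative tail reproduces the
        positive-tail analysis of the original contrast."""
        maps, design, _ = self.small_study(rng, effect=2.0)
        pos = permutation_inference(maps, design, [0.0, 1.0], n_perm=150, seed=8, tail="pos")
        neg = permutation_inference(maps, design, [0.0, -1.0], n_perm=150, seed=8, tail="neg")
        np.testing.assert_allclose(pos.tfce_map, neg.tfce_map, rtol=1e-12)
        np.testing.assert_array_equal(pos.fwe_p_map, neg.fwe_p_map)

    def test_tiny_n_enumerates_all_permutations(self, rng):
        maps, design, _ = self.small_study(rng, n=5)
        with pytest.warns(UserWarning, match="enumerating all"):
            res = permutation_inference(maps, design, "x", n_perm=150, seed=9)
        assert res.n_permutations == 120

    def test_invalid_parameters(self, rng):
        maps, design, _ = self.small_study(rng)
        with pytest.raises(InvalidParameterError):
            permutation_inference(maps, design, "x", n_perm=50, seed=0)
        with pytest.raises(InvalidParameterError):
            permutation_inference(maps, design, "x", n_perm=150, seed=0, tail="up")


class TestInteractionDesign:
    def cohort4(self):
        return pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "mfis_cog": [10.0, 20.0, 30.0, 40.0],
                "insight": [0.1, 0.2, 0.4, 0.5],
            }
        )

    def test_hand_built_design(self):
        d = interaction_design(self.cohort4(), "insight")
        X = d.frame
        # median split at 0.3: subjects c, d are high insight
        np.testing.assert_allclose(X["insight_level"], [0, 0, 1, 1])
        np.testing.assert_allclose(X["fatigue"], [-15, -5, 5, 15])
        np.testing.assert_allclose(X["interaction"], [0, 0, 5, 15])
        assert list(d.contrasts) == ["fatigue", "insight", "interaction"]
        assert d.contrasts["interaction"].tolist() == [0, 0, 0, 1]

    def test_constant_split_rejected(self):
        df = self.cohort4().assign(insight=[0.2, 0.2, 0.2, 0.2])
        with pytest.raises(InvalidInputError, match="constant"):
            interaction_design(df, "insight")

    def test_missing_behavioural_values_listed(self):
        df = self.cohort4()
        df.loc[1, "insight"] = np.nan
        with pytest.raises(InvalidInputError, match="b"):
            interaction_design(df, "insight")

    def test_covariates_extend_design(self):
        r = np.random.default_rng(3)
        n = 12
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "mfis_cog": r.integers(0, 36, n).astype(float),
                "insight": r.uniform(0, 1, n),
                "hads_d": r.uniform(0, 10, n),
                "edss": r.uniform(0, 6, n),
                "disease_duration_years": r.uniform(1, 20, n),
            }
        )
        d = interaction_design(df, "insight",
                               covariates=["hads_d", "edss", "disease_duration_years"])
        assert d.frame.shape[1] == 7
        assert abs(d.frame["hads_d"].mean()) < 1e-12


class TestClusterMeans:
    def test_single_voxel_and_uniform_map(self, rng):
        mask = np.ones((4, 4, 2), bool)
        Y = rng.normal(size=(3, 32))
        maps = make_maps(Y, mask)
        sig = np.zeros_like(mask)
        sig[0, 0, 0] = True
        means = extract_cluster_means(maps, sig)
        np.testing.assert_allclose(means["cluster_mean"], Y[:, 0])
        uniform = make_maps(np.full((2, 32), 7.0), mask)
        sig2 = np.zeros_like(mask)
        sig2[1:3, 1:3, :] = True
        means2 = extract_cluster_means(uniform, sig2)
        np.testing.assert_allclose(means2["cluster_mean"], 7.0)

    def test_empty_mask_rejected(self, rng):
        mask = np.ones((2, 2, 2), bool)
        maps = make_maps(rng.normal(size=(2, 8)), mask)
        with pytest.raises(InvalidInputError):
            extract_cluster_means(maps, np.zeros_like(mask))


class TestPlantedEffects:
    def test_null_and_planted_interaction_behaviour(self):
        """Planted negative interaction is recovered inside the effect region
        and extracted cluster means separate the insight groups' slopes."""
        cohort = simulate_cohort(CohortParams(n_subjects=32, seed=42, attach_trials=False))
        # behavioural stand-in cleanly separated by latent insight level
        r = np.random.default_rng(1)
        cohort["tracking_insight"] = np.where(cohort["insight_high"] == 1, 0.7, 0.1) \
            + r.normal(0, 0.02, len(cohort))
        spec = EffectFieldSpec(
            grid_shape=(12, 12, 6), gamma_fatigue=0.03, gamma_interaction=-0.10, noise_sd=0.02
        )
        maps, mask, region = simulate_skeleton_maps(cohort, spec, seed=43)
        design = interaction_design(cohort, "tracking_insight")
        res = permutation_inference(maps, design, "interaction", n_perm=200, seed=44, tail="neg")
        sens = (res.significance_mask & region).sum() / region.sum()
        assert sens >= 0.9
        means = extract_cluster_means(maps, res.significance_mask & region)
        merged = means.merge(cohort, on="subject_id")
        slopes = {
            lvl: np.polyfit(g["mfis_cog"], g["cluster_mean"], 1)[0]
            for lvl, g in merged.groupby("insight_high")
        }
        assert slopes[0] > 0 > slopes[1]
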