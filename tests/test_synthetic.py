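import numpy as np
import pytest

import radstab as rs
from radstab.stability import compute_cov_matrix, motion_magnitude, stability_table


def _spec(**kw):
    defaults = dict(n_patients=5, n_phases=8, feature_names=["a", "b"], seed=4)
    defaults.update(kw)
    return rs.SyntheticSpec(**defaults)


class TestSpecValidation:
    def test_rejects_negative_cov(self):
        with pytest.raises(ValueError):
            _spec(planted_cov={"a": -1.0})

    def test_rejects_single_phase(self):
        with pytest.raises(ValueError):
            _spec(n_phases=1)

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            _spec(feature_names=["a", "a"])

    def test_rejects_unknown_beta_keys(self):
        with pytest.raises(ValueError):
            _spec(hazard_betas={"zzz": 1.0})

    def test_rejects_bad_censor_rate(self):
        with pytest.raises(ValueError):
            _spec(censor_rate=1.0)


class TestPhaseTensor:
    def test_zero_planted_cov_gives_constant_phases(self):
        tensor, _ = rs.gen_phase_feature_tensor(_spec(planted_cov={"a": 0.0, "b": 0.0}))
        assert np.all(tensor.values == tensor.values[:, :1, :])
        assert np.all(compute_cov_matrix(tensor.values) == 0.0)

    def test_deterministic_under_seed(self):
        t1, _ = rs.gen_phase_feature_tensor(_spec(planted_cov={"a": 10.0}))
        t2, _ = rs.gen_phase_feature_tensor(_spec(planted_cov={"a": 10.0}))
        assert np.array_equal(t1.values, t2.values)

    def test_values_positive(self):
        tensor, _ = rs.gen_phase_feature_tensor(_spec(planted_cov={"a": 30.0, "b": 30.0}, n_patients=50))
        assert (tensor.values > 0).all()

    def test_population_cov_recovers_planted(self):
        # Monte-Carlo check of the sample-COV distribution at n_phases=8:
        # E[s/mu] ~ c4(8)*cov with SE ~ cov/sqrt(2*7*20) -> +-2pp band at cov=10
        est = []
        for seed in range(20):
            spec = _spec(n_patients=20, planted_cov={"a": 10.0, "b": 10.0}, seed=100 + seed)
            tensor, _ = rs.gen_phase_feature_tensor(spec)
            est.append(np.nanmean(compute_cov_matrix(tensor.values)))
        assert abs(np.mean(est) - 10.0) < 2.0

    def test_long_frame_round_trip(self):
        tensor, _ = rs.gen_phase_feature_tensor(_spec(planted_cov={"a": 5.0}))
        back = rs.PhaseFeatureTensor.from_long_frame(tensor.to_long_frame())
        assert np.allclose(back.values, tensor.values)


class TestMotion:
    def test_zero_magnitude_identical_centroids(self):
        trajs = rs.gen_motion_trajectories(_spec(motion_magnitudes=[0.0] * 5))
        for tr in trajs:
            assert np.all(tr == tr[0])

    @pytest.mark.parametrize("mag", [1.0, 5.0, 30.0])
    def test_requested_magnitude_exact(self, mag):
        trajs = rs.gen_motion_trajectories(_spec(motion_magnitudes=[mag] * 5))
        assert motion_magnitude(trajs[0]) == pytest.approx(mag, abs=1e-12)

    @pytest.mark.parametrize("n_phases", [2, 3, 8, 10])
    def test_magnitude_exact_for_any_phase_count(self, n_phases):
        trajs = rs.gen_motion_trajectories(_spec(n_phases=n_phases, motion_magnitudes=[5.0] * 5))
        pts = trajs[0]
        brute = max(
            np.linalg.norm(pts[i] - pts[j]) for i in range(n_phases) for j in range(i + 1, n_phases)
        )
        assert brute == pytest.approx(5.0, abs=1e-12)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            rs.gen_motion_trajectories(_spec(motion_magnitudes=[-1.0] * 5))


class TestImages:
    def test_zero_noise_zero_motion_identical_phases(self):
        spec = _spec(motion_magnitudes=[0.0] * 5)
        ps = rs.gen_4d_image(spec, grid_shape=(24, 24, 24))
        for k in range(1, ps.n_phases):
            assert np.array_equal(ps.images[k], ps.images[0])
            assert np.array_equal(ps.masks[k], ps.masks[0])

    def test_tumor_leaving_fov_rejected(self):
        spec = _spec(motion_magnitudes=[200.0] * 5)
        with pytest.raises(ValueError, match="field of view"):
            rs.gen_4d_image(spec, grid_shape=(24, 24, 24))

    def test_mask_centroid_motion_matches_snapped_trajectory(self):
        spec = _spec(motion_magnitudes=[12.0] * 5)
        ps = rs.gen_4d_image(spec)  # 3 mm voxels; 12 mm = 4 voxels, snap-exact
        mags = motion_magnitude(ps.centroids())
        assert mags == pytest.approx(12.0, abs=1e-9)

    def test_image_io_round_trip(self, tmp_path):
        from radstab.roi import read_image

        spec = _spec(motion_magnitudes=[0.0] * 5)
        ps = rs.gen_4d_image(spec, grid_shape=(16, 16, 16))
        paths = ps.write(tmp_path, fmt="nrrd")
        arr, spacing = read_image(paths[0][0])
        assert np.allclose(arr, ps.images[0])
        assert spacing == ps.spacing


class TestSurvivalCohort:
    def test_times_positive_events_binary(self, planted_cohort):
        cohort, _ = planted_cohort
        assert (cohort.time > 0).all()
        assert set(cohort.event.unique()) <= {0, 1}

    def test_deterministic_under_seed(self):
        c1, _ = rs.gen_survival_cohort(rs.planted_survival_spec(seed=9))
        c2, _ = rs.gen_survival_cohort(rs.planted_survival_spec(seed=9))
        assert np.array_equal(c1.features.to_numpy(), c2.features.to_numpy())
        assert np.array_equal(c1.time.to_numpy(), c2.time.to_numpy())

    @pytest.mark.parametrize("target", [0.41, 0.59])
    def test_censor_rate_hit(self, target):
        spec = rs.planted_survival_spec(seed=21)
        spec.censor_rate = target
        _, truth = rs.gen_survival_cohort(spec)
        assert abs(truth.censor_fraction - target) < 0.05

    def test_all_zero_betas_warns(self):
        spec = _spec(hazard_betas={"a": 0.0})
        with pytest.warns(UserWarning, match="hazard betas"):
            rs.gen_survival_cohort(spec)

    def test_planted_beta_recovered_by_cox(self):
        # partial-likelihood consistency: beta=1 on one clean feature
        spec = rs.SyntheticSpec(
            n_patients=500,
            feature_names=["f"],
            hazard_betas={"f": 1.0},
            censor_rate=0.0,
            seed=33,
        )
        cohort, _ = rs.gen_survival_cohort(spec)
        fit = rs.univariate_cox(cohort.features["f"].to_numpy(), cohort.time, cohort.event)
        assert fit.beta[0] == pytest.approx(1.0, abs=0.15)

    def test_null_betas_give_uniform_p(self):
        # fraction of univariate P < 0.05 across nulls stays near 0.05
        ps = []
        for seed in range(10):
            cohort, _ = rs.gen_survival_cohort(rs.planted_survival_spec(seed=200 + seed, null_signal=True))
            ps.append(rs.screen_univariate(cohort)["p"].to_numpy())
        frac = float(np.mean(np.concatenate(ps) < 0.05))
        assert 0.01 < frac < 0.10

    def test_clinical_covariates_present(self, planted_cohort):
        cohort, _ = planted_cohort
        assert set(cohort.clinical.columns) == {"ecog", "gender", "ethnicity", "pack_years", "histology", "location"}
        assert cohort.clinical["pack_years"].ge(0).all()
        assert set(cohort.clinical["ecog"].unique()) <= {0, 1, 2, 3}

    def test_cohort_csv_round_trip(self, planted_cohort, tmp_path):
        cohort, _ = planted_cohort
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = rs.SurvivalCohort.from_csv(path, clinical_columns=list(cohort.clinical.columns))
        assert np.allclose(back.features.to_numpy(), cohort.features.to_numpy())
        assert np.allclose(back.time.to_numpy(), cohort.time.to_numpy())
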