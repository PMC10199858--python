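"""Cohort generator: design contract, determinism, noise model."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from lag3pet.cohort import CohortConfig, add_noise, generate_cohort
from lag3pet.quantify import TimeActivityCurve, Units
from lag3pet.tissue import simulate_tissue_curve


class TestDesignContract:
    def test_default_cohort_matches_study_design(self, default_cohort):
        ds = default_cohort
        assert len(ds.patients) == 6
        arms = [p.arm_dose_mg for p in ds.patients]
        assert arms.count(44.0) == 3 and arms.count(604.0) == 3
        assert 12 <= ds.n_lesions <= 30
        for p in ds.patients:
            assert 2 <= len(p.lesion_ids) <= 5
            assert set(p.injections) == {1, 2}
            assert p.injections[1].mass_dose_mg == 4.0
            assert p.injections[2].mass_dose_mg == p.arm_dose_mg

    def test_lesion_truth_invariants(self, default_cohort):
        for lesion in default_cohort.lesions:
            assert lesion.volume_ml > 0
            assert 0.0 <= lesion.infiltration <= 1.0
            assert 0.0 <= lesion.ihc_lag3_pct <= 100.0
            assert lesion.site_class in ("lymph-node", "other")
            assert lesion.ki_spec_unblocked >= 0

    def test_truth_stored_separately_from_observations(self, default_cohort):
        p = default_cohort.patients[0]
        key = (p.lesion_ids[0], 1)
        assert p.tacs_truth[key].values != p.tacs_observed[key].values
        assert p.tacs_truth[key].decay_corrected
        assert not p.tacs_observed[key].decay_corrected

    @pytest.mark.parametrize("bad", [
        dict(scan_times_c1=(0.0, 90.0)),
        dict(scan_times_c1=(90.0, 90.0, 138.0)),
        dict(arm_doses=(44.0,) * 6),            # fine
        dict(arm_doses=(10.0,) * 6),
        dict(lesions_per_patient=(0, 5)),
        dict(noise_cv=-0.1),
        dict(unknown_key=1),
    ])
    def test_config_validation(self, bad):
        if bad == dict(arm_doses=(44.0,) * 6):
            CohortConfig(**bad)  # a legal unbalanced assignment
        else:
            with pytest.raises(Exception):
                CohortConfig(**bad)


class TestDeterminism:
    def test_same_seed_reproduces_dataset_exactly(self, tumor_model):
        from lag3pet.io import injections_frame, lesions_frame, plasma_frame, \
            tac_frame
        a = generate_cohort(CohortConfig(seed=5), tumor_model=tumor_model)
        b = generate_cohort(CohortConfig(seed=5), tumor_model=tumor_model)
        for frame in (plasma_frame, tac_frame, injections_frame,
                      lesions_frame):
            assert frame(a).equals(frame(b))

    def test_different_seed_differs(self, tumor_model):
        a = generate_cohort(CohortConfig(seed=5), tumor_model=tumor_model)
        b = generate_cohort(CohortConfig(seed=6), tumor_model=tumor_model)
        assert a.patients[0].plasma_observed[1].values \
            != b.patients[0].plasma_observed[1].values


class TestNoiseModel:
    def _point(self):
        return TimeActivityCurve(region_id="x", region_type="organ", cycle=1,
                                 times=(90.0,), values=(100.0,),
                                 units=Units.PCT_IA_PER_L,
                                 decay_corrected=True)

    def test_zero_cv_is_identity(self, rng):
        tac = self._point()
        assert add_noise(tac, 0.0, rng) is tac

    def test_monte_carlo_dispersion_matches_cv(self, rng):
        # 1e4 replicate draws of one sample: SD/mean within [0.095, 0.105]
        tac = self._point()
        draws = np.array([add_noise(tac, 0.1, rng).values[0]
                          for _ in range(10_000)])
        assert 0.095 <= draws.std() / draws.mean() <= 0.105

    def test_truncation_keeps_values_positive(self, rng):
        tac = self._point()
        draws = np.array([add_noise(tac, 0.5, rng).values[0]
                          for _ in range(100_000)])
        assert np.all(draws > 0)

    def test_noise_free_cohort_equals_model_curves(self, noisefree_cohort):
        # with cv = 0 the observed curves are the simulated truth passed
        # through the (exactly invertible) decay/units roundtrip
        ds = noisefree_cohort
        p = ds.patients[0]
        lesion_id = p.lesion_ids[0]
        params = ds.lesion_params[lesion_id]
        occ = float(ds.occupancy.occupancy(4.0))
        expected = simulate_tissue_curve(params, occ, p.plasma_params[1],
                                         ds.config.scan_times_c1)
        truth = np.asarray(p.tacs_truth[(lesion_id, 1)].values)
        assert truth == pytest.approx(expected, rel=1e-12)
        from lag3pet.quantify import percent_injected_activity
        obs = p.tacs_observed[(lesion_id, 1)].decay_corrected_curve()
        back = [percent_injected_activity(v, p.injections[1])
                for v in obs.values]
        assert back == pytest.approx(list(truth), rel=1e-9)


class TestSimulatorScience:
    def test_infiltration_drives_uptake_ratio(self, noisefree_cohort):
        # Spearman between latent lesion infiltration and the noise-free
        # cycle-1 tumor-to-plasma ratio at 138 h must be >= 0.9
        ds = noisefree_cohort
        infil, ratio = [], []
        for p in ds.patients:
            cp138 = float(p.plasma_params[1].conc(138.0))
            for lesion_id in p.lesion_ids:
                truth = p.tacs_truth[(lesion_id, 1)]
                idx = truth.times.index(138.0)
                ratio.append(truth.values[idx] / cp138)
        by_id = {l.lesion_id: l.infiltration for l in ds.lesions}
        infil = [by_id[lid] for p in ds.patients for lid in p.lesion_ids]
        rho = spearmanr(infil, ratio).statistic
        assert rho >= 0.9

    def test_trapped_activity_nondecreasing_in_every_region(
            self, noisefree_cohort):
        # decay-corrected signal of an irreversible region never drops
        # between the two late scans once trapping dominates; verify the
        # weaker, always-true statement on the trapped component via truth
        # curves minus the blood+reversible part being nondecreasing is
        # covered in tissue tests; here: late ratio grows for lesions
        ds = noisefree_cohort
        for p in ds.patients:
            for lesion_id in p.lesion_ids:
                truth = p.tacs_truth[(lesion_id, 1)]
                y90 = truth.values[1] / float(p.plasma_params[1].conc(90.0))
                y138 = truth.values[2] / float(p.plasma_params[1].conc(138.0))
                assert y138 > y90  # uptake ratios increase over time at 4 mg
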