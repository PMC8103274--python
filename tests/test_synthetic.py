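"""Synthetic cohort generator: contracts, determinism, calibration, coupling."""

import numpy as np
import pytest
from scipy import stats as sstats

import vrmotor as vm
from vrmotor import (
    CohortConfig,
    ConfigError,
    generate_cohort,
    simulate_adl_trajectory,
    simulate_slice_log,
    simulate_tremor_trace,
)
from vrmotor.vr_scoring import exceedance_time


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_patients": 0}, "n_patients"),
            ({"frac_male": 1.5}, "frac_male"),
            ({"frac_pd_meds": -0.1}, "frac_pd_meds"),
            ({"vr_noise_sd": -1.0}, "vr_noise_sd"),
            ({"spect_noise_sd": -0.2}, "spect_noise_sd"),
            ({"severity_alpha": 0.0}, "severity_alpha"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            generate_cohort(CohortConfig(**kwargs))

    def test_updrs_link_is_monotone(self):
        link = CohortConfig().updrs_link
        grid = np.linspace(0, 1, 101)
        vals = [link.expected(s) for s in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestCohortContracts:
    def test_patient_count_and_protocol_multiplicities(self):
        patients = generate_cohort(CohortConfig(n_patients=10, rng_seed=1))
        assert len(patients) == 10
        for p in patients:
            assert len(p.traces) == 2 * 2 * 2  # hands x conditions x trials
            for hand in ("left", "right"):
                assert len(p.adl[hand]) == 5
                assert len(p.slicing[hand]) == 2
            assert 0 <= p.latent.severity <= 1
            band = CohortConfig().vr_effect.tremor_band
            assert band[0] <= p.latent.true_tremor_freq <= band[1]
            assert p.latent.true_tremor_amp >= 0

    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_patients=4, rng_seed=33)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for pa, pb in zip(a, b):
            assert pa.record == pb.record
            assert pa.latent == pb.latent
            assert pa.counts == pb.counts
            for key in pa.traces:
                assert np.array_equal(pa.traces[key].pos, pb.traces[key].pos)
            for hand in ("left", "right"):
                for aa, ab in zip(pa.adl[hand], pb.adl[hand]):
                    assert np.array_equal(aa.tilt_deg, ab.tilt_deg)
                assert pa.slicing[hand] == pb.slicing[hand]

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_patients=3, rng_seed=1))
        b = generate_cohort(CohortConfig(n_patients=3, rng_seed=2))
        assert a[0].record != b[0].record or not np.array_equal(
            a[0].traces[("left", "rest", 1)].pos, b[0].traces[("left", "rest", 1)].pos
        )

    def test_cid_prevalence_within_exact_binomial_interval(self):
        patients = generate_cohort(CohortConfig(n_patients=1000, rng_seed=7))
        frac = np.mean([p.record.cid for p in patients])
        # exact binomial 99% interval around the default prevalence 0.57
        lo = sstats.binom.ppf(0.005, 1000, 0.57) / 1000
        hi = sstats.binom.ppf(0.995, 1000, 0.57) / 1000
        assert lo <= frac <= hi


class TestTremorTraceSim:
    def test_sample_count(self):
        trace = simulate_tremor_trace(0.003, 5.0, duration=10, rate=90, seed=0)
        assert trace.t.size == 900

    def test_silent_trace_is_constant(self):
        trace = simulate_tremor_trace(0.0, 5.0, duration=5, rate=90, noise_sd=0.0, seed=0)
        assert np.ptp(trace.pos, axis=0).max() == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            simulate_tremor_trace(0.001, 5.0, duration=0, rate=90)
        with pytest.raises(ConfigError):
            simulate_tremor_trace(0.001, 5.0, duration=10, rate=-1)

    def test_downstream_frequency_recovery(self):
        trace = simulate_tremor_trace(0.01, 4.7, duration=10, rate=90, noise_sd=1e-4, seed=2)
        feats = vm.trace_features(trace)
        assert abs(feats.dominant_frequency - 4.7) <= 90.0 / 256


class TestAdlTrajectorySim:
    def test_zero_instability_stays_upright(self):
        _, tilt = simulate_adl_trajectory(0.0, duration=5, rate=90, seed=0)
        assert np.all(tilt == 0.0)

    def test_seeded_reproducibility(self):
        t1, x1 = simulate_adl_trajectory(0.3, seed=5)
        t2, x2 = simulate_adl_trajectory(0.3, seed=5)
        assert np.array_equal(x1, x2)

    def test_negative_instability_rejected(self):
        with pytest.raises(ConfigError):
            simulate_adl_trajectory(-0.1)

    def test_mean_spill_exposure_monotone_in_instability(self):
        means = []
        for instability in (0.1, 0.4, 0.8):
            totals = [
                exceedance_time(*simulate_adl_trajectory(instability, seed=s), 30.0)
                for s in range(200)
            ]
            means.append(np.mean(totals))
        assert means[0] <= means[1] <= means[2]


class TestCoupling:
    def test_severity_drives_all_modalities_in_the_right_direction(self, coupling_cohort):
        updrs = np.array([p.record.updrs3 for p in coupling_cohort])
        amp = np.array([p.latent.true_tremor_amp for p in coupling_cohort])
        slicing = np.array(
            [
                np.mean(
                    [
                        log.events[-1].t - log.events[0].t
                        for hand in ("left", "right")
                        for log in p.slicing[hand]
                    ]
                )
                for p in coupling_cohort
            ]
        )
        putamen = np.array(
            [
                (p.measures.sbr_putamen_left + p.measures.sbr_putamen_right) / 2
                for p in coupling_cohort
            ]
        )
        assert sstats.spearmanr(updrs, amp).statistic > 0
        assert sstats.spearmanr(updrs, slicing).statistic > 0
        assert sstats.spearmanr(updrs, putamen).statistic < 0

    def test_slice_log_structure(self):
        log = simulate_slice_log(50.0, seed=1)
        kinds = [e.kind for e in log.events]
        assert kinds[0] == "session_start" and kinds[-1] == "session_end"
        assert kinds[1:-1] == ["item_cut"] * 3
        assert log.events[-1].t == 50.0
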