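"""Generator calibration, determinism, and the complex-spike pause rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cerephys import InvalidSpecification, SpikeTrain
from cerephys import synthdata as sd
from cerephys.spike_metrics import firing_rate, isi_cv, isi_cv2


def _spec(rate, cv, dur, seed=0, cv2=None):
    return sd.ProcessSpec(mean_rate=rate, target_cv=cv, duration=dur,
                          seed=seed, target_cv2=cv2)


class TestRenewalTrain:
    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidSpecification):
            _spec(-1.0, 0.5, 10.0)
        with pytest.raises(InvalidSpecification):
            _spec(10.0, 0.5, 0.0)

    def test_degenerate_duration_yields_tiny_train(self):
        train = sd.gen_renewal_train(_spec(1.0, 1.0, 0.01, seed=3))
        assert train.n_spikes <= 1

    def test_regular_limit(self):
        train = sd.gen_renewal_train(_spec(50.0, 0.0, 10.0))
        isis = train.isis()
        assert np.allclose(isis, 0.02)
        assert isi_cv(train) < 0.01

    def test_exponential_cv_is_one(self):
        train = sd.gen_renewal_train(_spec(30.0, 1.0, 10_000.0, seed=42))
        assert 0.98 <= isi_cv(train) <= 1.02

    @pytest.mark.parametrize("rate,cv", [(85.3, 0.55), (30.8, 0.8), (10.0, 0.4)])
    def test_rate_and_cv_calibration(self, rate, cv):
        train = sd.gen_renewal_train(_spec(rate, cv, 5_000.0, seed=7))
        assert abs(firing_rate(train) - rate) / rate < 0.01
        assert abs(isi_cv(train) - cv) < 0.02

    def test_times_strictly_increasing_within_duration(self):
        train = sd.gen_renewal_train(_spec(100.0, 0.8, 50.0, seed=11))
        assert np.all(np.diff(train.times) > 0)
        assert train.times[0] >= 0 and train.times[-1] <= 50.0


class TestCv2Train:
    def test_regular_when_cv2_zero(self):
        train = sd.gen_cv2_train(_spec(40.0, 0.0, 10.0, cv2=0.0))
        assert isi_cv2(train) < 0.01

    def test_exponential_cv2_is_one(self):
        train = sd.gen_cv2_train(_spec(40.0, 1.0, 10_000.0, seed=5, cv2=1.0))
        assert 0.97 <= isi_cv2(train) <= 1.03

    def test_calibrated_low_cv2(self):
        train = sd.gen_cv2_train(_spec(40.0, 0.6, 5_000.0, seed=9, cv2=0.46))
        assert 0.43 <= isi_cv2(train) <= 0.49
        assert abs(isi_cv(train) - 0.6) < 0.1

    def test_calibrated_high_cv2(self):
        train = sd.gen_cv2_train(_spec(40.0, 0.4, 5_000.0, seed=13, cv2=0.7))
        assert 0.67 <= isi_cv2(train) <= 0.73
        assert abs(isi_cv(train) - 0.4) < 0.1

    def test_infeasible_pair_reports_range(self):
        with pytest.raises(sd.InfeasibleTarget, match="achievable"):
            sd.calibrate_two_state(0.3, 1.5)

    def test_requires_cv2(self):
        with pytest.raises(InvalidSpecification):
            sd.gen_cv2_train(_spec(40.0, 0.5, 10.0))


class TestCsPause:
    def test_direct_example(self):
        ss = SpikeTrain(np.array([0.010, 0.025, 0.050]), 1.0)
        cs = SpikeTrain(np.array([0.020]), 1.0)
        out = sd.apply_cs_pause(ss, cs, 20.0)
        assert np.allclose(out.times, [0.010, 0.050])

    def test_empty_cs_is_identity(self):
        ss = SpikeTrain(np.array([0.1, 0.2]), 1.0)
        out = sd.apply_cs_pause(ss, SpikeTrain(np.zeros(0), 1.0), 20.0)
        assert np.array_equal(out.times, ss.times)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_count_conservation_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ss_t = np.unique(rng.uniform(0, 1.0, 40))
        cs_t = np.unique(rng.uniform(0, 1.0, 5))
        pause = 0.02
        out = sd.apply_cs_pause(SpikeTrain(ss_t, 1.0), SpikeTrain(cs_t, 1.0), 20.0)
        removed_brute = sum(
            1 for t in ss_t if any(c <= t <= c + pause for c in cs_t)
        )
        assert out.n_spikes == ss_t.size - removed_brute

    def test_removed_fraction_matches_analytic_rate(self):
        ss = sd.gen_renewal_train(_spec(80.0, 1.0, 1_000.0, seed=21))
        cs = sd.gen_renewal_train(_spec(1.0, 1.0, 1_000.0, seed=22))
        out = sd.apply_cs_pause(ss, cs, 20.0)
        removed = ss.n_spikes - out.n_spikes
        expected = 80.0 * 1.0 * 0.02 * 1_000.0  # rate * cs_rate * pause * T
        assert abs(removed - expected) / expected < 0.15


class TestCohort:
    def test_distinct_seeds_per_cell(self):
        spec = sd.awake_purkinje_cohort(3, n_cells_per_group=1, duration_s=5.0)
        cells = sd.gen_cohort(spec).cells
        assert len(cells) == 2
        assert cells[0].seed != cells[1].seed

    def test_regeneration_is_bit_identical(self):
        spec = sd.awake_purkinje_cohort(17, n_cells_per_group=3, duration_s=10.0)
        a = sd.gen_cohort(spec)
        b = sd.gen_cohort(spec)
        assert a.content_hash() == b.content_hash()

    def test_mdx_multiplier_sets_ground_truth_rate(self):
        spec = sd.awake_purkinje_cohort(0)
        mdx = spec.group_spec("mdx")
        assert mdx.ss.mean_rate == pytest.approx(69.1, abs=0.05)
        assert spec.group_spec("control").ss.mean_rate == pytest.approx(85.3)

    def test_purkinje_cells_respect_pause(self):
        spec = sd.awake_purkinje_cohort(5, n_cells_per_group=2, duration_s=30.0)
        for cell in sd.gen_cohort(spec):
            ss, cs = cell.trains["ss"].times, cell.trains["cs"].times
            for c in cs:
                after = ss[ss > c]
                if after.size:
                    assert after[0] - c > 0.02

    def test_nuclear_cohort_has_single_unit(self):
        spec = sd.awake_nuclear_cohort(2, n_cells_per_group=1, duration_s=5.0)
        cell = sd.gen_cohort(spec).cells[0]
        assert set(cell.trains) == {"cn"}


class TestTraceSynthesis:
    def test_silent_cell_gives_zero_trace(self, templates):
        from cerephys.types import CellRecord

        cell = CellRecord("c0", "control", "awake", "purkinje", 1.0, 3, 1.0, 0,
                          trains={"ss": SpikeTrain(np.zeros(0), 1.0)})
        trace = sd.synth_trace(cell, templates, noise_sd=0.0)
        assert np.allclose(trace.samples, 0.0)

    def test_single_spike_centered_on_ground_truth(self, templates):
        from cerephys.types import CellRecord

        cell = CellRecord("c1", "control", "awake", "purkinje", 1.0, 3, 2.0, 0,
                          trains={"ss": SpikeTrain(np.array([1.0]), 2.0)})
        trace = sd.synth_trace(cell, templates, noise_sd=0.0)
        trough = np.argmin(trace.samples) / trace.fs_hz
        assert abs(trough - 1.0) < 0.2e-3

    def test_sampling_rate_must_cover_band(self, purkinje_cell, templates):
        with pytest.raises(InvalidSpecification):
            sd.synth_trace(purkinje_cell, templates, fs_hz=20_000.0)

    def test_complex_template_longer_than_simple(self, templates):
        assert templates["complex"].duration_ms > templates["simple"].duration_ms

    def test_trace_determinism(self, purkinje_cell, templates):
        a = sd.synth_trace(purkinje_cell, templates, noise_sd=10.0, seed=4)
        b = sd.synth_trace(purkinje_cell, templates, noise_sd=10.0, seed=4)
        assert np.array_equal(a.samples, b.samples)
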