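"""Non-wear detection, time-of-day imputation and inclusion criteria."""

import numpy as np
import pytest

from wristml import simulate as sim, wear
from wristml.signal import CalibrationResult, Recording, epoch_array

SPE = 3000  # samples per 30-s epoch at 100 Hz
GOOD_CAL = CalibrationResult(np.ones(3), np.zeros(3), 0.0, True)


def _active_recording(n_epochs, seed=0, start="2015-01-06"):
    labels = np.array(["walking"] * n_epochs, dtype=object)
    lrec = sim.simulate_recording(
        labels, sim.default_profiles(), seed=seed, start_time=start
    )
    return lrec.recording


def _freeze(rec, start_epoch, n_epochs):
    samples = rec.samples.copy()
    samples[start_epoch * SPE : (start_epoch + n_epochs) * SPE] = [0.1, 0.2, 0.97]
    return Recording(rec.subject_id, rec.rate, rec.start_time, samples)


class TestDetectNonwear:
    def test_61_minute_frozen_block_is_nonwear(self):
        rec = _freeze(_active_recording(240), 50, 122)  # 61 min
        mask = wear.detect_nonwear(rec)
        assert (~mask.worn[50:172]).all()
        assert mask.episodes == [(50, 172, "stationary>=60min")]

    def test_just_under_60_minutes_stays_worn(self):
        rec = _freeze(_active_recording(240), 50, 119)  # 59.5 min
        mask = wear.detect_nonwear(rec)
        assert mask.worn.all()

    def test_active_signal_has_no_nonwear(self):
        mask = wear.detect_nonwear(_active_recording(240))
        assert mask.worn.all() and mask.episodes == []

    def test_idempotent_and_epoch_aligned(self):
        rec = _freeze(_active_recording(300), 10, 150)
        m1 = wear.detect_nonwear(rec)
        m2 = wear.detect_nonwear(rec)
        assert np.array_equal(m1.worn, m2.worn)
        for start, stop, _ in m1.episodes:
            assert 0 <= start < stop <= len(m1.worn)

    def test_injected_episodes_recovered_with_low_false_positive_rate(self):
        cohort = sim.simulate_cohort(2, 12.0, nonwear_rate=2.0, seed=21)
        for lrec in cohort:
            if not lrec.nonwear_truth.any():
                continue
            mask = wear.detect_nonwear(lrec.recording)
            detected = ~mask.worn
            # every injected >= 60-min block is fully detected
            assert detected[lrec.nonwear_truth].mean() == 1.0
            # and active epochs are almost never flagged
            fp = detected[~lrec.nonwear_truth].mean()
            assert fp < 0.01


class TestImputation:
    def test_slot_mean_of_other_days(self):
        # 3 days x 4 slots; slot 1 of day 2 is non-worn
        worn = np.ones(12, dtype=bool)
        worn[5] = False
        values = np.zeros(12)
        values[1] = 0.2  # day 0, slot 1
        values[9] = 0.4  # day 2, slot 1
        slot = np.tile(np.arange(4), 3)
        out, imputed, missing = wear.impute_nonwear(
            values, wear.WearMask(worn=worn), slot
        )
        assert out[5] == pytest.approx(0.3)
        assert imputed[5] and not missing.any()

    def test_single_day_has_no_donor(self):
        worn = np.array([True, False, True])
        out, imputed, missing = wear.impute_nonwear(
            np.array([1.0, 2.0, 3.0]), wear.WearMask(worn=worn), np.arange(3)
        )
        assert out[1] == 2.0 and missing[1] and not imputed.any()

    def test_fully_worn_input_untouched(self):
        values = np.arange(6, dtype=float)
        out, imputed, missing = wear.impute_nonwear(
            values, wear.WearMask(worn=np.ones(6, dtype=bool)), np.arange(6) % 3
        )
        assert np.array_equal(out, values)
        assert not imputed.any() and not missing.any()

    def test_probability_vectors_still_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), 8)
        worn = np.ones(8, dtype=bool)
        worn[6] = False
        slot = np.tile(np.arange(2), 4)
        out, _, _ = wear.impute_nonwear(probs, wear.WearMask(worn=worn), slot)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(out[worn], probs[worn])


class TestInclusion:
    def _recording_and_mask(self, hours, seed=1):
        n_epochs = int(hours * 120)
        rec = _active_recording(n_epochs, seed=seed, start="2015-01-06 00:00:00")
        return rec, wear.detect_nonwear(rec)

    def test_72_hour_boundary_is_inclusive(self):
        rec, mask = self._recording_and_mask(72.0)
        qc = wear.inclusion_check(rec, mask, GOOD_CAL)
        assert qc.wear_hours == pytest.approx(72.0)
        assert qc.included, qc.reasons

    def test_missing_hour_of_day_coverage_excludes(self):
        rec, mask = self._recording_and_mask(100.0)
        # knock out 03:00-04:00 on every day by marking those epochs non-worn
        slot = wear.epoch_slot_index(rec, len(mask.worn))
        hour = slot * 30 // 3600
        mask.worn[hour == 3] = False
        qc = wear.inclusion_check(rec, mask, GOOD_CAL)
        assert not qc.included
        assert any("hour-of-day" in r for r in qc.reasons)

    def test_high_vector_magnitude_excludes(self):
        # implausibly intense signal: mean ENMO of a 0.5 g oscillation is
        # ~159 mg, beyond the 100 mg plausibility bound
        prof = {
            "shake": sim.ActivityProfile(
                "shake", [0.0, 0.0, 1.0], 2.0, 0.5, 0.01, [("shake", 3.0, 1.0)]
            )
        }
        lrec = sim.simulate_recording(
            np.array(["shake"] * (73 * 120), dtype=object), prof, seed=2,
            start_time="2015-01-06 00:00:00",
        )
        rec = lrec.recording
        mask = wear.detect_nonwear(rec)
        qc = wear.inclusion_check(rec, mask, GOOD_CAL)
        assert qc.mean_vm_mg > 100.0
        assert not qc.included
        assert any("vector magnitude" in r for r in qc.reasons)

    def test_failed_calibration_excludes(self):
        rec, mask = self._recording_and_mask(73.0)
        bad = CalibrationResult(np.ones(3), np.zeros(3), np.inf, False)
        qc = wear.inclusion_check(rec, mask, bad)
        assert not qc.included and "calibration failed" in qc.reasons

    def test_clipped_samples_counted(self):
        rec, mask = self._recording_and_mask(73.0)
        samples = rec.samples.copy()
        samples[: len(samples) // 50, 0] = 8.0  # 2% of samples clipped
        clipped_rec = Recording(rec.subject_id, rec.rate, rec.start_time, samples)
        qc = wear.inclusion_check(clipped_rec, wear.detect_nonwear(clipped_rec), GOOD_CAL)
        assert qc.clipped_fraction > 0.01
        assert any("clipped" in r for r in qc.reasons)
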