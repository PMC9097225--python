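"""Synthetic-signal generator: determinism, class structure, displacement."""

import numpy as np
import pytest

import gtcsdetect as g
from gtcsdetect.features import FEATURE_COLUMNS, per_second_features, resultant_force
from gtcsdetect.simulate import (
    DAILY_ACTIVITY_SPECS,
    SEIZURE_SPECS,
    TABLE_DOG_COUNTS,
    MovementSpec,
    apply_displacement,
    load_schedule,
    reference_collection_schedule,
    rotation_about_axis,
    save_schedule,
    simulate_day,
    simulate_gtcs,
    simulate_segment,
)


class TestSimulateSegment:
    def test_same_seed_gives_bit_identical_traces(self):
        spec = DAILY_ACTIVITY_SPECS["walking"]
        a = simulate_segment(spec, seed=5)
        b = simulate_segment(spec, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_static_posture_has_near_zero_cv_and_offset_means(self):
        spec = DAILY_ACTIVITY_SPECS["lying_on_stomach"]
        feats = per_second_features(simulate_segment(spec, seed=1))
        assert np.allclose(feats["mean_z"], 1.0, atol=0.05)
        assert (feats[["cv_x", "cv_y", "cv_z", "cv_r"]].to_numpy() < 0.3).all()

    def test_clonic_axis_variability_exceeds_every_daily_class(self):
        """The clonic phase's per-second axis CVs dominate every daily
        activity, which is what makes the seizure class separable."""
        clonic = per_second_features(
            simulate_segment(SEIZURE_SPECS["gtcs_clonic"], seed=2)
        )
        for name, spec in DAILY_ACTIVITY_SPECS.items():
            daily = per_second_features(
                simulate_segment(MovementSpec(
                    spec.name, spec.base_offset_g, spec.osc_freq_hz,
                    spec.osc_amp_g, spec.noise_sd_g, duration_s=9.0,
                ), seed=3)
            )
            for cv in ("cv_x", "cv_y", "cv_z"):
                assert clonic[cv].mean() > 1.5 * daily[cv].max(), (name, cv)

    def test_supra_nyquist_frequency_rejected(self):
        spec = MovementSpec("bad", (0, 0, 1), 30.0, (0.1, 0.1, 0.1), 0.01)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_segment(spec, rate_hz=50.0)

    def test_clonic_class_separation_at_least_six_pooled_sds(self):
        """In at least one feature dimension the clonic phase sits >= 6
        pooled standard deviations away from every daily-activity class."""
        rows = {
            name: per_second_features(
                simulate_segment(MovementSpec(
                    s.name, s.base_offset_g, s.osc_freq_hz, s.osc_amp_g,
                    s.noise_sd_g, duration_s=30.0), seed=13)
            ).to_numpy()
            for name, s in {**DAILY_ACTIVITY_SPECS,
                            "gtcs_clonic": SEIZURE_SPECS["gtcs_clonic"]}.items()
        }
        clonic = rows.pop("gtcs_clonic")
        for name, daily in rows.items():
            diff = np.abs(clonic.mean(axis=0) - daily.mean(axis=0))
            pooled_sd = np.sqrt((clonic.var(axis=0) + daily.var(axis=0)) / 2)
            standardized = diff / np.maximum(pooled_sd, 1e-12)
            assert standardized.max() >= 6.0, name


class TestSimulateGtcs:
    def test_duration_bookkeeping_and_phase_labels(self):
        trace, labels = simulate_gtcs(tonic_s=5, clonic_s=25, seed=4)
        assert trace.duration_s == 30.0
        assert [iv.label for iv in labels] == ["gtcs_tonic", "gtcs_clonic"]
        assert labels[0].end_s == labels[1].start_s == 5.0

    def test_zero_tonic_gives_pure_clonic(self):
        trace, labels = simulate_gtcs(tonic_s=0, clonic_s=12, seed=4)
        assert [iv.label for iv in labels] == ["gtcs_clonic"]
        assert trace.duration_s == 12.0

    def test_clonic_epochs_classify_seizure_end_to_end(self, rde_model, rdne_model):
        trace, labels = simulate_gtcs(tonic_s=5, clonic_s=25, seed=99)
        feats = per_second_features(trace)
        clonic_start = int(labels[-1].start_s)
        epochs = [
            e for e in g.make_epochs(feats, 9, 1) if e.start_second >= clonic_start
        ]
        assert epochs
        results = g.classify_epochs(epochs, rde_model, rdne_model)
        assert all(r.decision == "seizure" for r in results)


class TestSimulateDay:
    def test_reference_collection_schedule_totals_1215_s(self):
        sched = reference_collection_schedule(seed=0)
        assert len(sched.segments) == sum(TABLE_DOG_COUNTS.values()) == 135
        assert sched.total_duration_s == 9.0 * 135 == 1215.0
        trace, labels = simulate_day(sched)
        assert trace.duration_s == 1215.0
        assert len(labels) == 135

    def test_embedded_seizure_appears_once_in_label_track(self):
        sched = g.day_schedule_with_seizures(
            total_s=600.0, seizure_starts_s=(250.0,), seed=6
        )
        _, labels = simulate_day(sched)
        seizure_ivs = [iv for iv in labels if iv.label.startswith("gtcs")]
        assert len(seizure_ivs) == 2  # tonic + clonic phases
        assert seizure_ivs[0].start_s == 250.0

    def test_same_schedule_and_seed_reproduce_trace(self):
        sched = g.day_schedule_with_seizures(total_s=120.0, seed=7)
        a, _ = simulate_day(sched)
        b, _ = simulate_day(sched)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_gap_in_schedule_rejected(self):
        spec = DAILY_ACTIVITY_SPECS["standing"]
        with pytest.raises(ValueError, match="gap"):
            g.Schedule(segments=((spec, 0.0), (spec, 10.0)), total_duration_s=19.0)

    def test_schedule_json_roundtrip(self, tmp_path):
        sched = g.day_schedule_with_seizures(
            total_s=120.0, seizure_starts_s=(50.0,), seed=8
        )
        path = save_schedule(sched, tmp_path / "s.json")
        back = load_schedule(path)
        assert back.seed == sched.seed
        assert back.total_duration_s == sched.total_duration_s
        a, _ = simulate_day(sched)
        b, _ = simulate_day(back)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestDisplacement:
    def test_identity_rotation_is_noop(self, activity_day):
        trace, _ = activity_day
        out = apply_displacement(trace, np.eye(3), onset_s=100.0)
        np.testing.assert_array_equal(out.samples, trace.samples)

    def test_resultant_force_invariant_under_rotation(self, activity_day):
        trace, _ = activity_day
        rot = rotation_about_axis("x", 37.0)
        out = apply_displacement(trace, rot, onset_s=0.0)
        r_before = resultant_force(*trace.samples.T)
        r_after = resultant_force(*out.samples.T)
        np.testing.assert_allclose(r_after, r_before, rtol=1e-10)

    def test_lateral_quarter_roll_swaps_y_and_z_roles(self):
        spec = DAILY_ACTIVITY_SPECS["standing"]
        trace = simulate_segment(spec, seed=9)
        rolled = apply_displacement(trace, rotation_about_axis("x", 90.0), onset_s=0.0)
        f0 = per_second_features(trace)
        f1 = per_second_features(rolled)
        # gravity moves off Z onto +/-Y; magnitudes swap
        assert np.allclose(np.abs(f1["mean_y"]), np.abs(f0["mean_z"]), atol=0.05)

    def test_samples_before_onset_untouched(self, activity_day):
        trace, _ = activity_day
        rot = rotation_about_axis("z", 45.0)
        out = apply_displacement(trace, rot, onset_s=10.0)
        np.testing.assert_array_equal(out.samples[:500], trace.samples[:500])
        assert not np.allclose(out.samples[500:], trace.samples[500:])

    def test_non_orthonormal_rotation_rejected(self, activity_day):
        trace, _ = activity_day
        with pytest.raises(ValueError, match="orthonormal"):
            apply_displacement(trace, np.eye(3) * 2.0, onset_s=0.0)

    def test_displacement_shifts_distances_on_walking(self, rde_model, rdne_model):
        """A 90-degree harness roll measurably changes epoch distances to
        the upright-built references (the false-positive mechanism seen
        with displaced sensors)."""
        spec = DAILY_ACTIVITY_SPECS["walking"]
        trace = simulate_segment(
            MovementSpec(spec.name, spec.base_offset_g, spec.osc_freq_hz,
                         spec.osc_amp_g, spec.noise_sd_g, duration_s=60.0),
            seed=10,
        )
        rolled = apply_displacement(trace, rotation_about_axis("x", 90.0), onset_s=0.0)
        base = g.classify_epochs(
            g.make_epochs(per_second_features(trace)), rde_model, rdne_model
        )
        disp = g.classify_epochs(
            g.make_epochs(per_second_features(rolled)), rde_model, rdne_model
        )
        d0 = np.mean([r.distance_rdne for r in base])
        d1 = np.mean([r.distance_rdne for r in disp])
        assert d1 > d0  # displaced signal sits farther from the activity reference
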