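import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import saccsync as sc
from saccsync.exceptions import (
    InvalidParameterError,
    InvalidTraceError,
    JoinError,
    NoLabelError,
)
from saccsync.preprocess import (
    REL_CATEGORIES,
    assign_session,
    relative_sequence_index,
)
from saccsync.simulate import SACCADE_DURATION_MS
from conftest import make_event_row


def flat_trace(n=100, x=0.0, y=0.0, rate=1000.0):
    t = np.arange(n) * 1000.0 / rate
    return sc.EyeTrace(rate, t, np.full(n, x), np.full(n, y))


class TestVelocity:
    def test_constant_position_zero_speed(self):
        v = sc.compute_velocity(flat_trace())
        assert np.allclose(v, 0.0)

    def test_linear_ramp_speed(self):
        t = np.arange(200.0)
        x = 0.1 * t  # 100 deg/s, stays on screen for 200 ms
        trace = sc.EyeTrace(1000.0, t, x, np.zeros_like(t))
        v = sc.compute_velocity(trace)
        assert np.allclose(v[5:-5], 100.0, rtol=1e-6)

    def test_rendered_saccade_peak_matches_analytic(self):
        """Raised-cosine ramp peak speed = amplitude*pi/(2*duration)."""
        sched = sc.make_schedule(1, "none", 600, seed=3)
        ev = sc.sample_session(sched, sc.get_phenotype("NULL"), seed=4).iloc[:1]
        trace = sc.render_trace(sched[0], ev)
        start = sc.build_layout().position(sched[0].start_landmark)
        amp = math.hypot(
            ev.iloc[0]["landing_x_deg"] - start[0],
            ev.iloc[0]["landing_y_deg"] - start[1],
        )
        analytic_peak = amp * math.pi / (2.0 * SACCADE_DURATION_MS / 1000.0)
        v = sc.compute_velocity(trace)
        assert v.max() == pytest.approx(analytic_peak, rel=0.05)

    def test_too_short_trace_rejected(self):
        with pytest.raises(InvalidTraceError):
            sc.compute_velocity(flat_trace(n=2))


class TestDetect:
    def test_no_motion_empty(self):
        det = sc.detect_saccades(flat_trace(500))
        assert len(det) == 0

    def test_refractory_merges_nearby_crossings(self):
        # two velocity bursts 10 ms apart -> one event at 50-ms refractory
        t = np.arange(300.0)
        x = np.zeros_like(t)
        x[100:] += 1.0  # instantaneous 1-deg step -> brief supra-threshold burst
        x[110:] += 1.0
        trace = sc.EyeTrace(1000.0, t, x, np.zeros_like(t))
        det = sc.detect_saccades(trace, refractory_ms=50.0, smooth_samples=1)
        assert len(det) == 1
        det2 = sc.detect_saccades(trace, refractory_ms=5.0, smooth_samples=1)
        assert len(det2) == 2

    def test_invalid_threshold(self):
        with pytest.raises(InvalidParameterError):
            sc.detect_saccades(flat_trace(), threshold=0.0)

    def test_session_roundtrip_recovery(self):
        """>=99% of injected onsets recovered within 2 ms; none spurious."""
        sched = sc.make_schedule(5, "all", 600, seed=31)
        events = sc.sample_session(sched, sc.get_phenotype("NULL"), seed=32)
        n_hit, n_total, n_det = 0, 0, 0
        for trial in sched:
            ev = events[events["trial_id"] == trial.trial_id]
            det = sc.detect_saccades(sc.render_trace(trial, ev))
            truth = np.sort(ev["onset_ms"].to_numpy())
            n_total += len(truth)
            n_det += len(det)
            for t_on in truth:
                if np.min(np.abs(det["onset_ms"].to_numpy() - t_on)) <= 2.0:
                    n_hit += 1
        assert n_det == n_total  # no spurious detections on noise-free traces
        assert n_hit / n_total >= 0.99


class TestAssign:
    def test_landing_on_landmark_assigned(self, layout):
        df = pd.DataFrame(
            {
                "landing_x_deg": [layout.positions[2, 0], 0.5],
                "landing_y_deg": [layout.positions[2, 1], 0.5],
            }
        )
        out = sc.assign_landmarks(df, layout)
        assert out["assigned_landmark"].iloc[0] == 2
        # centre of the screen is 7 deg from every landmark -> unassigned
        assert np.isnan(out["assigned_landmark"].iloc[1])

    def test_assign_and_time_latency_and_isi(self, layout):
        sched = sc.make_schedule(1, "all", 600, seed=41)
        trial = sched[0]
        onsets = [trial.target_onset_ms(k) + 10.0 for k in range(1, 6)]
        det = pd.DataFrame(
            {
                "onset_ms": onsets,
                "landing_x_deg": [layout.position(trial.target_landmark(k))[0] for k in range(1, 6)],
                "landing_y_deg": [layout.position(trial.target_landmark(k))[1] for k in range(1, 6)],
            }
        )
        out = sc.assign_and_time(det, trial, layout)
        assert list(out["step"]) == [1, 2, 3, 4, 5]
        np.testing.assert_allclose(out["latency_ms"], 10.0)
        np.testing.assert_allclose(out["isi_ms"].to_numpy()[1:], 600.0)

    def test_assign_session_unknown_trial(self, layout):
        sched = sc.make_schedule(1, "all", 600, seed=41)
        with pytest.raises(JoinError):
            assign_session({99: pd.DataFrame()}, sched, layout)


class TestPredictiveFilter:
    def test_toy_fixture_counts(self, events_frame_factory):
        """10 events; one step-3 and one 200-ms latency violation -> 8 kept."""
        rows = [make_event_row(step=5 + i) for i in range(8)]
        rows.append(make_event_row(step=3))
        rows.append(make_event_row(step=13, latency_ms=200.0))
        out = sc.filter_predictive(events_frame_factory(rows))
        assert len(out) == 8

    def test_direction_violations_removed(self, events_frame_factory):
        # target 1, ccw: two-next target = 2, opposite direction = 5
        rows = [
            make_event_row(step=6, target_landmark=1, assigned=1),
            make_event_row(step=7, target_landmark=1, assigned=2),  # two-next
            make_event_row(step=8, target_landmark=1, assigned=5),  # opposite
            make_event_row(step=9, target_landmark=1, assigned=np.nan),  # unassigned ok
        ]
        out = sc.filter_predictive(events_frame_factory(rows))
        assert list(out["step"]) == [6, 9]

    def test_no_rule_fires_keeps_all(self, events_frame_factory):
        rows = [make_event_row(step=5 + i, latency_ms=(-1) ** i * 60.0) for i in range(6)]
        out = sc.filter_predictive(events_frame_factory(rows))
        assert len(out) == 6

    def test_empty_input(self, events_frame_factory):
        out = sc.filter_predictive(events_frame_factory([make_event_row()]).iloc[0:0])
        assert len(out) == 0

    def test_idempotent(self, events_frame_factory):
        rows = [
            make_event_row(step=s, latency_ms=lat, assigned=a)
            for s, lat, a in itertools.product(
                (3, 5, 8), (-60.0, 0.0, 200.0), (1, 2, np.nan)
            )
        ]
        df = events_frame_factory(rows)
        once = sc.filter_predictive(df)
        twice = sc.filter_predictive(once)
        pd.testing.assert_frame_equal(once, twice)


class TestReactiveFilter:
    def test_toy_fixture_counts(self, events_frame_factory):
        """12 rows with 3 violations -> 9 retained."""
        rows = [make_event_row(step=5 + i, latency_ms=120.0) for i in range(9)]
        rows.append(make_event_row(step=14, latency_ms=-30.0))  # before target onset
        rows.append(make_event_row(step=15, latency_ms=650.0))  # latency > SOA (600)
        rows.append(make_event_row(step=16, latency_ms=120.0, assigned=np.nan))  # off target
        out = sc.filter_reactive(events_frame_factory(rows))
        assert len(out) == 9

    def test_latency_equal_soa_retained(self, events_frame_factory):
        rows = [make_event_row(step=6, latency_ms=600.0, soa_ms=600.0)]
        out = sc.filter_reactive(events_frame_factory(rows))
        assert len(out) == 1

    def test_wrong_landmark_removed(self, events_frame_factory):
        rows = [make_event_row(step=6, target_landmark=1, assigned=4, latency_ms=120.0)]
        out = sc.filter_reactive(events_frame_factory(rows))
        assert len(out) == 0

    def test_idempotent(self, events_frame_factory):
        rows = [
            make_event_row(step=s, latency_ms=lat, assigned=a)
            for s, lat, a in itertools.product(
                (4, 6), (-30.0, 120.0, 700.0), (1, 4, np.nan)
            )
        ]
        once = sc.filter_reactive(events_frame_factory(rows))
        twice = sc.filter_reactive(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRelativeLocation:
    def test_first_covered_landmark_is_in1(self):
        for m in range(6):
            # ccw enters the covered triple at m-1, cw at m+1
            assert sc.relative_location((m - 1) % 6, m, "ccw") == "In1"
            assert sc.relative_location((m + 1) % 6, m, "cw") == "In1"

    def test_exhaustive_enumeration_balanced(self):
        """6 targets x 6 inducers x 2 directions: each label 12 times."""
        from collections import Counter

        counts = Counter(
            sc.relative_location(t, m, d)
            for t, m, d in itertools.product(range(6), range(6), ("ccw", "cw"))
        )
        assert counts == {c: 12 for c in REL_CATEGORIES}

    @given(
        target=st.integers(0, 5),
        inducer=st.integers(0, 5),
        rot=st.integers(0, 5),
        direction=st.sampled_from(["ccw", "cw"]),
    )
    def test_rotation_equivariance(self, target, inducer, rot, direction):
        base = sc.relative_location(target, inducer, direction)
        rotated = sc.relative_location((target + rot) % 6, (inducer + rot) % 6, direction)
        assert base == rotated

    def test_direction_reversal_reflects_cycle(self):
        # reversing direction maps index d -> (6 - d) mod 6 around the inducer
        for t, m in itertools.product(range(6), range(6)):
            d_ccw = relative_sequence_index(t, m, "ccw")
            d_cw = relative_sequence_index(t, m, "cw")
            assert (d_ccw + d_cw) % 6 == (2 * relative_sequence_index(m, m, "ccw")) % 6

    def test_no_inducer_raises(self):
        with pytest.raises(NoLabelError):
            sc.relative_location(2, None, "ccw")


class TestAggregate:
    def test_constant_isis(self):
        lab = pd.DataFrame(
            {
                "isi_ms": 600.0,
                "abs_location": list(range(6)) * 2,
                "direction": "ccw",
                "relative_label": list(REL_CATEGORIES) * 2,
                "soa_ms": 600.0,
            }
        )
        table = sc.aggregate(lab)
        assert np.allclose(table.category_stats["mean_ms"], 600.0)
        assert np.allclose(table.category_stats["sd_ms"], 0.0)

    def test_hand_built_12_rows(self):
        values = [500, 520, 540, 560, 580, 600, 620, 640, 660, 680, 700, 720]
        lab = pd.DataFrame(
            {
                "isi_ms": values,
                "abs_location": 0,
                "direction": "ccw",
                "relative_label": list(REL_CATEGORIES) * 2,
                "soa_ms": 600.0,
            }
        )
        table = sc.aggregate(lab)
        means = table.category_means
        # hand computation: pairs (500,620), (520,640), ...
        for k, cat in enumerate(REL_CATEGORIES):
            assert means[cat] == pytest.approx((values[k] + values[k + 6]) / 2)

    def test_counts_conserved(self, boundary3_labeled):
        table = sc.aggregate(boundary3_labeled)
        assert table.category_stats["n"].sum() == len(boundary3_labeled)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            sc.aggregate(pd.DataFrame(columns=["isi_ms", "relative_label"]))


class TestCounterbalancing:
    def test_absolute_location_effects_average_out(self):
        """With the inducer balanced over six locations and only
        absolute-location effects injected, the six relative-label means
        coincide within 3 SE."""
        sched = sc.make_schedule(120, "all", 600, seed=55, inducer_balance="within")
        phen = sc.PhenotypeParams(
            abs_location_offsets=(0.0, 15.0, -10.0, 20.0, -15.0, 5.0)
        )
        ev = sc.sample_session(sched, phen, seed=56)
        lab = sc.InducerEffectModel.from_events(ev).data
        g = lab.groupby("relative_label")["isi_ms"]
        means, sems = g.mean(), g.sem()
        for a, b in itertools.combinations(REL_CATEGORIES, 2):
            assert abs(means[a] - means[b]) <= 3 * math.hypot(sems[a], sems[b])
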