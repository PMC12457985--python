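"""Stop-and-go segmentation, TAD detection and the full classifier."""

import collections

import numpy as np
import pytest

import granulemotion as gm
from granulemotion import spt, synthetic
from granulemotion.models import ClassifierParams


def make_switching(drift_frames=20, stop_frames=20, cycles=3, v=0.5):
    drift = gm.MotionModel(kind="drifted", v=v, D=1e-3, heading=0.3, sigma_loc=0.02)
    anchor = gm.MotionModel(kind="immobile", sigma_loc=0.02)
    return gm.SwitchingSchedule(segments=tuple([(drift, drift_frames), (anchor, stop_frames)] * cycles))


class TestWindowVelocity:
    def test_immobile_noiseless_zero(self):
        traj = gm.Trajectory(0, np.arange(20), np.ones(20), np.ones(20), 0.204)
        assert np.allclose(spt.window_velocity(traj), 0.0)

    def test_gap_aware_elapsed_time(self):
        # a 2-frame gap doubles the elapsed time across the gap
        frames = np.array([0, 1, 2, 4, 5, 6])
        x = np.array([0.0, 0.1, 0.2, 0.4, 0.5, 0.6])  # constant 0.1 um / frame
        traj = gm.Trajectory(0, frames, x, np.zeros(6), dt=1.0)
        speeds = spt.window_velocity(traj, window=5)
        assert np.allclose(speeds, 0.1)

    def test_too_short_raises(self):
        traj = gm.Trajectory(0, np.arange(2), np.zeros(2), np.zeros(2), 0.2)
        with pytest.raises(ValueError, match="3 spots"):
            spt.window_velocity(traj)

    def test_switch_crossing_near_truth(self):
        sched = gm.SwitchingSchedule(
            segments=(
                (gm.MotionModel(kind="drifted", v=0.5, D=0.0, heading=0.0, sigma_loc=0.005), 20),
                (gm.MotionModel(kind="immobile", sigma_loc=0.005), 20),
            )
        )
        acq = gm.AcquisitionConfig(n_frames=40)
        traj, _ = synthetic.simulate_trajectory(sched, acq, rng=0)
        speeds = spt.window_velocity(traj)
        crossing = np.nonzero(speeds < 0.2)[0][0]
        assert abs(crossing - 20) <= 2


class TestStopAndGo:
    def test_pure_drift_single_segment(self):
        acq = gm.AcquisitionConfig(n_frames=50)
        traj, _ = synthetic.simulate_trajectory(
            gm.MotionModel(kind="drifted", v=0.5, heading=0.2), acq, rng=1
        )
        parts = spt.stop_and_go_segment(traj)
        assert parts == [(0, 50, "drifted_step1")]

    def test_slow_brownian_rarely_drifted(self):
        # at D = 1e-3 um^2/s the windowed speed almost never reaches 0.2 um/s
        acq = gm.AcquisitionConfig(n_frames=50)
        rng = np.random.default_rng(2)
        model = gm.MotionModel(kind="brownian", D=1e-3, sigma_loc=0.02)
        clean = 0
        for _ in range(500):
            traj, _ = synthetic.simulate_trajectory(model, acq, rng)
            parts = spt.stop_and_go_segment(traj)
            if all(kind == "mixed" for _, _, kind in parts):
                clean += 1
        assert clean / 500 >= 0.95

    def test_alternating_boundaries_within_2_frames(self):
        acq = gm.AcquisitionConfig(n_frames=120)
        rng = np.random.default_rng(3)
        sched = make_switching()
        true_bounds = [20, 40, 60, 80, 100]
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            traj, _ = synthetic.simulate_trajectory(sched, acq, rng)
            parts = spt.stop_and_go_segment(traj)
            kinds = [k for _, _, k in parts]
            bounds = [start for start, _, _ in parts[1:]]
            ok = (
                kinds == ["drifted_step1", "mixed"] * 3
                and all(min(abs(b - t) for b in bounds) <= 2 for t in true_bounds)
            )
            hits += ok
        assert hits / n_rep >= 0.8

    def test_every_spot_in_exactly_one_segment(self):
        acq = gm.AcquisitionConfig(n_frames=100)
        rng = np.random.default_rng(4)
        traj, _ = synthetic.simulate_trajectory(make_switching(), gm.AcquisitionConfig(n_frames=120), rng)
        parts = spt.stop_and_go_segment(traj)
        covered = sorted(i for a, b, _ in parts for i in range(a, b))
        assert covered == list(range(traj.n_spots))

    def test_raising_vt_never_increases_drifted_spots(self):
        acq = gm.AcquisitionConfig(n_frames=120)
        rng = np.random.default_rng(5)
        for _ in range(20):
            traj, _ = synthetic.simulate_trajectory(make_switching(), acq, rng)
            counts = []
            for v_t in (0.05, 0.1, 0.2, 0.4, 0.8):
                parts = spt.stop_and_go_segment(traj, ClassifierParams(v_t=v_t))
                counts.append(sum(b - a for a, b, k in parts if k == "drifted_step1"))
            assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


class TestTadDetect:
    def test_homogeneous_brownian_low_false_positive(self):
        acq = gm.AcquisitionConfig(n_frames=100)
        rng = np.random.default_rng(6)
        model = gm.MotionModel(kind="brownian", D=5e-3, sigma_loc=0.02)
        fp = sum(
            bool(spt.tad_detect(synthetic.simulate_trajectory(model, acq, rng)[0]))
            for _ in range(200)
        )
        assert fp / 200 <= 0.10

    def test_planted_arrest_detected_with_overlap(self):
        acq = gm.AcquisitionConfig(n_frames=120)
        rng = np.random.default_rng(7)
        br = gm.MotionModel(kind="brownian", D=5e-3, sigma_loc=0.02)
        anchor = gm.MotionModel(kind="immobile", sigma_loc=0.02)
        sched = gm.SwitchingSchedule(segments=((br, 40), (anchor, 40), (br, 40)))
        good = 0
        for _ in range(200):
            traj, _ = synthetic.simulate_trajectory(sched, acq, rng)
            zones = spt.tad_detect(traj)
            overlap = max(
                (max(0, min(b, 79) - max(a, 40) + 1) for a, b in zones), default=0
            )
            good += len(zones) == 1 and overlap >= 0.8 * 40
        assert good / 200 >= 0.8

    def test_seed_run_shorter_than_tc1_no_zone(self):
        params = ClassifierParams()
        L = np.zeros(30)
        L[10:14] = 2.5  # only 4 spots above Lc1 -> below tc1 = 5
        assert spt._zones_from_likelihood(L, params) == []

    def test_seed_grows_with_lower_threshold(self):
        params = ClassifierParams()
        L = np.zeros(30)
        L[10:15] = 2.5  # seed of 5
        L[8:10] = 1.6  # growable at Lc2 = 1.4
        L[15:18] = 1.6
        assert spt._zones_from_likelihood(L, params) == [(8, 17)]

    def test_degenerate_diffusivity_whole_segment_zone(self):
        traj = gm.Trajectory(0, np.arange(20), np.zeros(20), np.zeros(20), 0.204)
        assert spt.tad_detect(traj) == [(0, 19)]


class TestClassifySegment:
    @pytest.mark.parametrize(
        "D12,gamma,label,sublabel",
        [
            (1e-3, 0.4, "blocked", "immobile"),  # below D_block = 2e-3
            (5e-3, 0.5, "diffusive", "slow"),  # between D_block and D_lim
            (5e-2, 0.5, "diffusive", "fast"),  # above D_lim, still diffusive
            (5e-3, 0.9, "drifted", "drifted_step2"),  # super-diffusive
        ],
    )
    def test_threshold_taxonomy(self, D12, gamma, label, sublabel):
        ms = gm.MomentSpectrum(
            orders=np.arange(1, 7),
            lags=np.arange(1, 6),
            moments=np.ones((6, 5)),
            mss_slopes=np.zeros(6),
            gamma=gamma,
            D12=D12,
            n_spots=20,
            dt=0.204,
        )
        assert spt.classify_segment(ms) == (label, sublabel)


class TestClassifyTrackset:
    def test_single_immobile_track_all_blocked(self):
        traj = gm.Trajectory(0, np.arange(50), np.ones(50), np.ones(50), 0.204)
        segs, summary = spt.classify_trackset(gm.TrackSet([traj], dt=0.204))
        assert summary.pct_blocked == 100.0
        assert summary.pct_diffusive == summary.pct_drifted == 0.0

    def test_three_way_mixture_recovery(self):
        from granulemotion.cli import default_mixture

        acq, tracks, _ = default_mixture(seed=7)
        segs, summary = spt.classify_trackset(gm.TrackSet(tracks, dt=acq.dt))
        for pct in (summary.pct_blocked, summary.pct_diffusive, summary.pct_drifted):
            assert abs(pct - 100 / 3) <= 10
        truth = ["blocked"] * 30 + ["diffusive"] * 30 + ["drifted"] * 30
        votes = collections.defaultdict(collections.Counter)
        for s in segs:
            votes[s.track_id][s.label] += s.n_spots
        per_class = collections.defaultdict(list)
        for tid, counter in votes.items():
            per_class[truth[tid]].append(counter.most_common(1)[0][0] == truth[tid])
        for cls, oks in per_class.items():
            assert np.mean(oks) >= 0.9, cls

    def test_spot_conservation_and_sum_100(self):
        acq = gm.AcquisitionConfig(n_frames=120)
        rng = np.random.default_rng(8)
        tracks = [
            synthetic.simulate_trajectory(make_switching(), acq, rng, track_id=i)[0]
            for i in range(10)
        ]
        segs, summary = spt.classify_trackset(gm.TrackSet(tracks, dt=acq.dt))
        assert sum(s.n_spots for s in segs) == sum(t.n_spots for t in tracks)
        total = summary.pct_blocked + summary.pct_diffusive + summary.pct_drifted
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_lowering_dblock_never_increases_blocked(self):
        acq = gm.AcquisitionConfig(n_frames=100)
        rng = np.random.default_rng(9)
        model = gm.MotionModel(kind="brownian", D=2.5e-3, sigma_loc=0.02)
        tracks = [
            synthetic.simulate_trajectory(model, acq, rng, track_id=i)[0] for i in range(30)
        ]
        ts = gm.TrackSet(tracks, dt=acq.dt)
        counts = []
        for d_block in (4e-3, 2e-3, 1e-3, 5e-4):
            segs, _ = spt.classify_trackset(ts, ClassifierParams(D_block=d_block, D_lim=1e-2))
            counts.append(sum(s.n_spots for s in segs if s.label == "blocked"))
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_empty_trackset_warns(self):
        with pytest.warns(UserWarning, match="no classifiable"):
            _, summary = spt.classify_trackset(gm.TrackSet([], dt=0.204))
        assert summary.n_spots == 0

    def test_deterministic(self):
        from granulemotion.cli import default_mixture

        acq, tracks, _ = default_mixture(seed=11)
        r1 = spt.classify_trackset(gm.TrackSet(tracks, dt=acq.dt))
        r2 = spt.classify_trackset(gm.TrackSet(tracks, dt=acq.dt))
        assert spt.segments_to_dataframe(r1[0]).equals(spt.segments_to_dataframe(r2[0]))


class TestJointDistribution:
    def test_brownian_gamma_mode_near_half(self):
        acq = gm.AcquisitionConfig(n_frames=100)
        rng = np.random.default_rng(10)
        model = gm.MotionModel(kind="brownian", D=5e-3, sigma_loc=0.02)
        spectra = [
            spt.displacement_moments(synthetic.simulate_trajectory(model, acq, rng)[0])
            for _ in range(500)
        ]
        joint = spt.d12_gamma_distribution(spectra)
        assert 0.4 <= joint.gamma_mode <= 0.6

    def test_ballistic_gamma_mode_near_one(self):
        acq = gm.AcquisitionConfig(n_frames=100)
        rng = np.random.default_rng(11)
        spectra = []
        for _ in range(100):
            traj, _ = synthetic.simulate_trajectory(
                gm.MotionModel(kind="drifted", v=0.5, heading=rng.uniform(0, 6.28)), acq, rng
            )
            spectra.append(spt.displacement_moments(traj))
        joint = spt.d12_gamma_distribution(spectra)
        assert 0.9 <= joint.gamma_mode <= 1.1

    def test_empty_input_empty_histogram(self):
        joint = spt.d12_gamma_distribution([])
        assert joint.hist.sum() == 0
        assert joint.n_segments == 0
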