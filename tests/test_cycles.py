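import numpy as np
import pytest

from gaitevents import (
    FeatureSequence,
    GaitCycle,
    TimeSeries,
    label_contact,
    qc_filter,
    segment_cycles,
    split_participants,
    standardise_and_pad,
)
from gaitevents.cycles import FEATURE_CHANNELS, nearest_frame
from gaitevents.events import NoContactError
from gaitevents.synthetic import SyntheticConfig, generate_trial


def _zero_channels(n, rate=200.0):
    return {name: TimeSeries(np.zeros(n), rate, name) for name in FEATURE_CHANNELS}


def _make_cycle(n=100, rate=200.0, vgrf=None, force_rate=200.0, **kw):
    feats = FeatureSequence(np.random.default_rng(0).normal(size=(n, 4)), rate)
    fv = None if vgrf is None else TimeSeries(vgrf, force_rate, "vgrf")
    return GaitCycle(features=feats, vgrf=fv, **kw)


class TestSegmentCycles:
    def test_synthetic_trial_recovers_cycles(self):
        cfg = SyntheticConfig(seed=1)
        from gaitevents import SyntheticCycleTruth

        truth = SyntheticCycleTruth(0.7, 0.2, 0.445, 3.5, "rearfoot", 12.0)
        foot_z, channels, vgrf = generate_trial(cfg, [truth] * 5)
        cycles = segment_cycles(foot_z, channels, vgrf)
        assert len(cycles) == 4
        period = round(0.7 * cfg.mocap_rate)
        for c in cycles:
            assert abs(len(c.features) - period) <= 1

    def test_monotone_height_yields_empty_with_warning(self):
        n = 50
        z = TimeSeries(np.linspace(0, 1, n), 200.0, "z")
        with pytest.warns(UserWarning, match="fewer than two"):
            assert segment_cycles(z, _zero_channels(n)) == []

    def test_plateau_apex_breaks_tie_at_first_index(self):
        z = np.concatenate([[0, 1, 2, 2, 1, 0], [0, 1, 2, 2, 1, 0], [0, 1, 2]])
        ts = TimeSeries(z.astype(float), 200.0, "z")
        cycles = segment_cycles(ts, _zero_channels(len(z)))
        # apices at the first index of each [2, 2] plateau: 2 and 8
        assert len(cycles) == 1
        assert len(cycles[0].features) == 6

    def test_missing_required_channel_raises(self):
        z = TimeSeries(np.zeros(10), 200.0, "z")
        with pytest.raises(ValueError, match="tibia_ap_vel"):
            segment_cycles(z, {})


class TestQCFilter:
    def _descent(self, step_at=None, step=1.0, rate=200.0):
        # clean descent from 300 N to 0 crossing 100 and 50 on the way
        f = np.linspace(300.0, 0.0, 61)
        if step_at is not None:
            f[step_at + 1] = f[step_at] + step
        return TimeSeries(f, rate, "vgrf")

    def test_one_newton_step_per_frame_at_200hz_rejects(self):
        # +1 N between consecutive frames at 200 Hz = 200 N/s, the rejection bound
        idx = int(np.argmax(np.linspace(300, 0, 61) < 95))
        res = qc_filter(self._descent(step_at=idx, step=1.0))
        assert not res.accepted
        assert res.max_rate >= 200.0

    def test_smaller_step_accepts(self):
        # +0.9 N per frame at 200 Hz = 180 N/s < 200 N/s
        idx = int(np.argmax(np.linspace(300, 0, 61) < 95))
        res = qc_filter(self._descent(step_at=idx, step=0.9))
        assert res.accepted
        assert res.max_rate == pytest.approx(180.0)

    def test_strictly_monotone_descent_accepts(self):
        res = qc_filter(self._descent())
        assert res.accepted and res.interval is not None

    def test_never_reaching_100n_is_accepted_as_inapplicable(self):
        res = qc_filter(TimeSeries(np.linspace(80, 0, 40), 200.0, "vgrf"))
        assert res.accepted
        assert res.interval is None and "absent" in res.note

    def test_rise_outside_interval_is_ignored(self):
        # loading-phase rise (before the final 100 N down-crossing) must not reject
        f = np.concatenate([np.linspace(0, 300, 40), np.linspace(300, 0, 61)])
        res = qc_filter(TimeSeries(f, 200.0, "vgrf"))
        assert res.accepted


class TestLabelContact:
    def test_direct_threshold_example(self):
        c = _make_cycle(n=5, vgrf=[0, 60, 120, 60, 0])
        labels, ev = label_contact(c)
        assert labels.labels.tolist() == [0, 1, 1, 1, 0]
        assert (ev.foot_strike_index, ev.toe_off_index) == (1, 3)

    def test_sample_exactly_at_50n_is_contact(self):
        c = _make_cycle(n=5, vgrf=[0, 50.0, 120, 60, 0])
        labels, ev = label_contact(c)
        assert ev.foot_strike_index == 1

    def test_nearest_mocap_frame_mapping(self):
        # force 1000 Hz, mocap 200 Hz: first contact at force frame 103
        # (0.103 s) maps to mocap frame 21 (0.105 s is the closest frame)
        f = np.zeros(1000)
        f[103:500] = 100.0
        c = _make_cycle(n=200, rate=200.0, vgrf=f, force_rate=1000.0)
        _, ev = label_contact(c)
        assert ev.foot_strike_index == 21

    def test_no_contact_raises(self):
        c = _make_cycle(n=5, vgrf=[0, 10, 20, 10, 0])
        with pytest.raises(NoContactError, match="no contact"):
            label_contact(c)

    def test_multiple_runs_keep_longest_with_warning(self):
        c = _make_cycle(n=9, vgrf=[0, 60, 0, 60, 60, 60, 0, 0, 0])
        with pytest.warns(UserWarning, match="contact runs"):
            labels, ev = label_contact(c)
        assert (ev.foot_strike_index, ev.toe_off_index) == (3, 5)

    def test_round_half_up(self):
        assert nearest_frame(0.1025, 200.0) == 21  # 20.5 rounds up
        assert nearest_frame(0.1024, 200.0) == 20


class TestStandardiseAndPad:
    def _cycles(self, n_cycles=4, length=140):
        rng = np.random.default_rng(1)
        out = []
        for i in range(n_cycles):
            feats = FeatureSequence(rng.normal(size=(length, 4)), 200.0)
            out.append(GaitCycle(features=feats, cycle_id=f"c{i}"))
        return out

    def test_training_scaler_gives_zero_mean_unit_sd(self):
        batch = standardise_and_pad(self._cycles())
        real = batch.mask.astype(bool)
        for j in range(4):
            vals = batch.inputs[..., j][real]
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-9

    def test_padding_layout_and_mask_sums(self):
        batch = standardise_and_pad(self._cycles(length=140))
        assert batch.inputs.shape == (4, 200, 4)
        assert np.all(batch.inputs[:, :60] == 0.0)
        assert np.all(batch.mask[:, :60] == 0.0)
        assert np.all(batch.mask[:, 60:] == 1.0)
        assert batch.lengths().tolist() == [140] * 4

    def test_degenerate_channel_raises(self):
        cycles = self._cycles()
        for c in cycles:
            c.features.values[:, 2] = 7.0
        with pytest.raises(ValueError, match="degenerate channel"):
            standardise_and_pad(cycles)

    def test_overlong_cycle_listed_in_error(self):
        cycles = self._cycles(length=250)
        with pytest.raises(ValueError, match="c0"):
            standardise_and_pad(cycles)


class TestSplitParticipants:
    def _cycles(self, n_participants=20, n_datasets=2, per=3):
        out = []
        for p in range(n_participants):
            for k in range(per):
                out.append(
                    GaitCycle(
                        features=FeatureSequence(np.zeros((10, 4)), 200.0),
                        participant_id=f"P{p:02d}",
                        dataset_id=f"D{p % n_datasets}",
                        cycle_id=f"P{p:02d}:{k}",
                    )
                )
        return out

    def test_stratified_test_fraction(self):
        split = split_participants(self._cycles(), test_fraction=0.3, n_folds=5, seed=0)
        per_ds = {}
        for pid in split.test_participants:
            ds = f"D{int(pid[1:]) % 2}"
            per_ds[ds] = per_ds.get(ds, 0) + 1
        assert per_ds == {"D0": 3, "D1": 3}

    def test_partition_property(self):
        cycles = self._cycles()
        split = split_participants(cycles, seed=1)
        groups = [set(split.test_participants)] + [set(fp) for fp in split.fold_participants]
        all_ids = {c.participant_id for c in cycles}
        assert set().union(*groups) == all_ids
        assert sum(len(g) for g in groups) == len(all_ids)

    def test_seventy_participants_give_folds_of_fourteen(self):
        cycles = self._cycles(n_participants=100, n_datasets=1)
        split = split_participants(cycles, test_fraction=0.3, n_folds=5, seed=0)
        assert len(split.test_participants) == 30
        assert [len(fp) for fp in split.fold_participants] == [14] * 5

    def test_deterministic_given_seed(self):
        cycles = self._cycles()
        a = split_participants(cycles, seed=3)
        b = split_participants(cycles, seed=3)
        assert a.test_participants == b.test_participants
        assert a.fold_participants == b.fold_participants

    def test_too_few_participants_raises(self):
        with pytest.raises(ValueError, match="need >="):
            split_participants(self._cycles(n_participants=5, n_datasets=1), n_folds=5)
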