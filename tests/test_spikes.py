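import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from antisync.fixtures import (
    AnticipationProfile,
    BurstModel,
    make_burst_train,
    make_master_slave_pair,
)
from antisync.spikes import (
    SpikeTrain,
    anticipation_vs_isi,
    detect_spikes,
    interspike_intervals,
    isi_histogram,
    match_and_anticipate,
    principal_clusters,
    segment_bursts,
)


def exhaustive_maxima(t, x, threshold):
    """Independent oracle: compare every interior sample to both neighbours."""
    out = []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] > threshold:
            out.append(t[i])
    return np.array(out)


class TestDetectSpikes:
    def test_sine_maxima_found_at_analytic_positions(self):
        t = np.arange(0.0, 20.0, 0.01)
        x = 2 * np.sin(t)
        expected = np.array([np.pi / 2, 5 * np.pi / 2, 9 * np.pi / 2])
        coarse = detect_spikes(t, x, threshold=1.0, refine=False)
        assert np.max(np.abs(coarse.times - expected)) <= 0.01
        fine = detect_spikes(t, x, threshold=1.0, refine=True)
        assert np.max(np.abs(fine.times - expected)) < 1e-4

    def test_constant_series_has_no_spikes(self):
        t = np.arange(0.0, 1.0, 0.01)
        assert len(detect_spikes(t, np.ones_like(t))) == 0

    def test_matches_exhaustive_scan_on_chaotic_series(self):
        # ~1e5-sample series with spike-like structure
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 1000.0, 0.01)
        x = np.sin(t) + 0.5 * np.sin(2.31 * t) + 0.1 * rng.normal(size=len(t))
        for thr in (-0.5, 0.0, 1.0):
            got = detect_spikes(t, x, threshold=thr, refine=False)
            assert np.array_equal(got.times, exhaustive_maxima(t, x, thr))

    @given(data=st.lists(st.integers(-3, 3), min_size=3, max_size=40))
    @settings(max_examples=100)
    def test_matches_exhaustive_scan_on_arbitrary_small_series(self, data):
        x = np.array(data, dtype=float)
        t = 0.01 * np.arange(len(x))
        got = detect_spikes(t, x, threshold=-10.0, refine=False)
        assert np.array_equal(got.times, exhaustive_maxima(t, x, -10.0))

    def test_rejects_non_uniform_grid(self):
        t = np.array([0.0, 0.01, 0.05, 0.06])
        with pytest.raises(ValueError, match="uniform"):
            detect_spikes(t, np.zeros(4))


class TestISIs:
    def test_examples(self):
        train = SpikeTrain("n", np.array([1.0, 2.0, 4.0, 8.0]))
        assert interspike_intervals(train) == pytest.approx([1.0, 2.0, 4.0])
        assert len(interspike_intervals(SpikeTrain("n", np.array([3.0])))) == 0

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=30).map(
            lambda d: np.cumsum(d)
        )
    )
    def test_isis_telescope_to_span(self, times):
        train = SpikeTrain("n", times)
        isis = interspike_intervals(train)
        assert isis.sum() == pytest.approx(times[-1] - times[0])
        assert np.all(isis > 0)


class TestSpikeTrainIO:
    def test_csv_round_trip(self, tmp_path):
        train = SpikeTrain("slave", np.array([1.0, 2.5, 40.25]))
        path = tmp_path / "train.csv"
        train.to_csv(path)
        back = SpikeTrain.from_csv(path)
        assert back.neuron_id == "slave"
        assert np.array_equal(back.times, train.times)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SpikeTrain("n", np.array([2.0, 1.0]))


class TestMatching:
    def test_basic_pairing(self):
        m = SpikeTrain("m", np.array([10.0, 20.0]))
        s = SpikeTrain("s", np.array([9.5, 19.4]))
        tab = match_and_anticipate(m, s)
        assert tab["anticipation"].to_numpy() == pytest.approx([0.5, 0.6])
        assert np.isnan(tab["preceding_isi"].iloc[0])
        assert tab["preceding_isi"].iloc[1] == pytest.approx(9.9)

    def test_identical_trains_have_zero_anticipation(self):
        m = SpikeTrain("m", np.array([1.0, 2.0, 3.5]))
        tab = match_and_anticipate(m, SpikeTrain("s", m.times.copy()))
        assert tab["anticipation"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])

    def test_double_claim_keeps_closer_master(self):
        m = SpikeTrain("m", np.array([10.0, 10.5]))
        s = SpikeTrain("s", np.array([10.4]))
        tab = match_and_anticipate(m, s)
        assert len(tab) == 1
        assert tab["master_time"].iloc[0] == 10.5

    def test_equidistant_tie_prefers_earlier_slave(self):
        m = SpikeTrain("m", np.array([10.0]))
        s = SpikeTrain("s", np.array([9.9, 10.1]))
        tab = match_and_anticipate(m, s)
        assert tab["slave_time"].iloc[0] == 9.9
        assert tab["anticipation"].iloc[0] == pytest.approx(0.1)

    def test_empty_train_rejected(self):
        m = SpikeTrain("m", np.array([1.0]))
        with pytest.raises(ValueError, match="non-empty"):
            match_and_anticipate(m, SpikeTrain("s", np.empty(0)))

    @given(
        deltas=st.lists(st.floats(1.0, 5.0), min_size=2, max_size=20),
        shift=st.floats(-0.4, 0.4),
        extra=st.floats(0.001, 0.1),
    )
    @settings(max_examples=80)
    def test_shift_law(self, deltas, shift, extra):
        # moving the slave train earlier by delta adds delta to every
        # anticipation
        tm = np.cumsum(np.asarray(deltas))
        master = SpikeTrain("m", tm)
        slave = SpikeTrain("s", tm - 0.2)
        base = match_and_anticipate(master, slave)["anticipation"].to_numpy()
        moved = match_and_anticipate(master, slave.shifted(-extra))
        assert moved["anticipation"].to_numpy() == pytest.approx(
            base + extra, abs=1e-9
        )
        del shift  # reserved: symmetric matching holds for any small offset

    def test_unique_nearest_matching_is_a_bijection(self):
        rng = np.random.default_rng(7)
        tm = np.cumsum(rng.uniform(2.0, 4.0, size=50))
        slave = SpikeTrain("s", tm - 0.3)  # well within half the min ISI
        tab = match_and_anticipate(SpikeTrain("m", tm), slave)
        assert len(tab) == 50
        assert len(np.unique(tab["slave_time"])) == 50


class TestHistogram:
    def test_example_counts(self):
        h = isi_histogram(np.array([1.0, 1.0, 3.0]), np.array([0.0, 2.0, 4.0]))
        assert h.counts.tolist() == [2, 1]

    def test_half_open_bins(self):
        h = isi_histogram(np.array([2.0, 4.0]), np.array([0.0, 2.0, 4.0]))
        assert h.counts.tolist() == [0, 1]  # 2.0 falls in [2,4); 4.0 excluded

    def test_empty_isis(self):
        h = isi_histogram(np.empty(0), np.array([0.0, 1.0]))
        assert h.counts.tolist() == [0]

    @given(st.lists(st.floats(0.0, 9.99), min_size=0, max_size=50))
    def test_count_conservation_in_range(self, isis):
        h = isi_histogram(np.array(isis), np.linspace(0, 10, 11))
        assert h.counts.sum() == len(isis)


class TestBursts:
    def test_fixed_threshold_example(self):
        train = SpikeTrain("n", np.array([1.0, 1.5, 2.0, 12.0, 12.5]))
        seg = segment_bursts(train, 5.0)
        assert seg.bursts == ((0, 3), (3, 5))

    def test_all_short_isis_give_one_burst(self):
        train = SpikeTrain("n", np.array([0.0, 1.0, 2.0, 3.0]))
        assert segment_bursts(train, 5.0).bursts == ((0, 4),)

    def test_auto_threshold_recovers_constructed_boundaries(self):
        train, truth = make_burst_train(BurstModel(n_bursts=6, jitter=0.05, seed=3))
        seg = segment_bursts(train, "auto")
        assert seg.bursts == truth.bursts
        assert not seg.degenerate

    def test_unimodal_isis_fall_back_to_single_flagged_burst(self):
        train = SpikeTrain("n", np.cumsum(np.full(30, 2.0)))
        seg = segment_bursts(train, "auto")
        assert seg.degenerate
        assert seg.bursts == ((0, 30),)


class TestAnticipationVsISI:
    def test_step_profile_recovered_as_two_clusters(self, burst_fixture_pair):
        master, _, profile = burst_fixture_pair
        slave = make_master_slave_pair(master, profile)
        tab = match_and_anticipate(master, slave)
        ac = anticipation_vs_isi(tab)
        # records without a preceding ISI are dropped
        assert len(ac.pairs) == len(tab) - 1
        s = ac.summaries
        assert len(s) == 2
        assert s["anticipation_mean"].to_numpy() == pytest.approx([0.7, 0.4])
        # the low-ISI cluster carries the intra-burst spikes
        assert s["isi_max"].iloc[0] < 10 < s["isi_min"].iloc[1]

    def test_principal_clusters_drop_strays(self):
        isi = np.concatenate([np.full(200, 1.0), np.full(200, 50.0), [200.0]])
        ant = np.concatenate([np.full(200, 0.7), np.full(200, 0.4), [0.05]])
        t = np.arange(len(isi), dtype=float)
        tab = pd.DataFrame(
            {
                "master_time": t,
                "slave_time": t,
                "anticipation": ant,
                "preceding_isi": isi,
            }
        )
        ac = anticipation_vs_isi(tab)
        assert len(principal_clusters(ac)) == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            anticipation_vs_isi(pd.DataFrame(columns=["anticipation", "preceding_isi"]))
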