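"""Relative quantification and re-pooling: the data-equalization core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqbalance.balance import (
    DemuxCounts,
    RelativeConcentrations,
    cumulative_totals,
    rebalance_volumes,
    relative_concentration,
    spread_metrics,
)
from seqbalance.errors import EmptyPlanError, InvalidInputError


def run(reads, run_id="r1", volumes=1.0):
    return DemuxCounts.from_reads(run_id, {f"s{i}": r for i, r in enumerate(reads)}, volumes)


class TestRelativeConcentration:
    def test_equal_volume_pool(self):
        conc = relative_concentration(run([80, 120, 100, 100]))
        assert [conc[f"s{i}"] for i in range(4)] == pytest.approx([0.8, 1.2, 1.0, 1.0])

    def test_uniform_reads(self):
        conc = relative_concentration(run([500] * 5))
        assert all(conc[s] == pytest.approx(1.0) for s in conc.values)

    def test_two_sample_ratio(self):
        conc = relative_concentration(run([100, 300]))
        assert conc["s0"] == pytest.approx(0.5)
        assert conc["s1"] == pytest.approx(1.5)

    def test_volume_normalization(self):
        """Same read count at half the volume means twice the concentration."""
        counts = DemuxCounts.from_reads("r", {"a": 100, "b": 100}, {"a": 1.0, "b": 2.0})
        conc = relative_concentration(counts)
        assert conc["a"] / conc["b"] == pytest.approx(2.0)

    def test_zero_read_sample_flagged_failed(self):
        conc = relative_concentration(run([0, 100, 300]))
        assert conc.failed == {"s0"}
        # normalization over the two usable samples only
        assert conc["s1"] + conc["s2"] == pytest.approx(2.0)

    @given(reads=st.lists(st.integers(1, 10**6), min_size=2, max_size=50))
    def test_mean_one_normalization(self, reads):
        conc = relative_concentration(run(reads))
        assert np.mean(list(conc.values.values())) == pytest.approx(1.0)


class TestRebalanceVolumes:
    def test_worked_two_sample_example(self):
        """t=[100,300], c=[0.5,1.5], one 400-read run: volumes [30, 3.333]."""
        counts = run([100, 300])
        conc = RelativeConcentrations({"s0": 0.5, "s1": 1.5})
        plan = rebalance_volumes(counts, conc, remaining_runs=1, per_run_reads=400,
                                 vmax=30, vmin=0)
        assert plan.volumes["s0"] == pytest.approx(30.0)
        assert plan.volumes["s1"] == pytest.approx(10.0 / 3.0)
        finals = [e.expected_final_reads for e in plan.entries]
        assert finals == pytest.approx([400.0, 400.0])

    def test_symmetric_pool(self):
        plan = rebalance_volumes(run([100, 100, 100]), remaining_runs=1,
                                 per_run_reads=300, vmax=30, vmin=0)
        assert all(v == pytest.approx(30.0) for v in plan.volumes.values())
        assert all(e.expected_final_reads == pytest.approx(200.0) for e in plan.entries)

    def test_overshooting_sample_excluded(self):
        """A sample already past the equal-final target is left out of the re-pool."""
        plan = rebalance_volumes(run([900, 100, 100, 100]), remaining_runs=1,
                                 per_run_reads=400, vmax=30, vmin=0)
        assert plan.excluded == {"s0": "deficit-met"}
        assert plan.volumes["s0"] == 0.0

    def test_failed_library_excluded(self):
        plan = rebalance_volumes(run([0, 100, 100]), remaining_runs=1,
                                 per_run_reads=400, vmax=30, vmin=0)
        assert plan.excluded == {"s0": "failed-library"}

    def test_vmin_floor_flagged(self):
        # s1 is enormously overrepresented, so its raw volume scales below vmin
        plan = rebalance_volumes(run([10, 99_000]), remaining_runs=1,
                                 per_run_reads=101_000 * 2 - 99_010,
                                 vmax=30, vmin=1.0)
        entry = {e.sample_id: e for e in plan.entries}["s1"]
        assert entry.volume == 1.0
        assert "below-pipettable" in entry.flags

    def test_all_excluded_raises(self):
        counts = DemuxCounts.from_reads("r", {"a": 0, "b": 0})
        with pytest.raises((EmptyPlanError, InvalidInputError)):
            rebalance_volumes(counts, remaining_runs=1, per_run_reads=100)

    @given(
        reads=st.lists(st.integers(10, 10**5), min_size=3, max_size=40),
        k=st.integers(1, 4),
    )
    @settings(max_examples=60)
    def test_closed_loop_noiseless_equality(self, reads, k):
        """With true concentrations and real-valued allocation, finals are equal.

        Round 1 at equal volumes makes c_i proportional to reads; allocating
        the remaining K runs by c_i v_i share must land every non-excluded
        sample exactly on the common target.
        """
        counts = run(reads)
        n = len(reads)
        total_remaining = k * sum(reads)  # plenty to fill every deficit
        plan = rebalance_volumes(counts, remaining_runs=k,
                                 per_run_reads=total_remaining / k, vmax=30, vmin=0)
        target = (sum(reads) + total_remaining) / n
        if not plan.excluded:
            for e in plan.planned:
                assert e.expected_final_reads == pytest.approx(target, rel=1e-9)
        else:
            # an overshooting sample absorbs part of the budget: planned
            # samples move toward (but cannot pass) the common target
            totals = counts.reads_by_sample()
            for e in plan.planned:
                assert totals[e.sample_id] - 1e-9 <= e.expected_final_reads <= target + 1e-9
        # reads are conserved across the whole batch
        assert sum(e.expected_final_reads for e in plan.entries) == pytest.approx(
            sum(reads) + total_remaining, rel=1e-9
        )

    @given(reads=st.lists(st.integers(10, 10**5), min_size=3, max_size=40, unique=True))
    @settings(max_examples=60)
    def test_volume_monotone_decreasing_in_round1_reads(self, reads):
        """Equal-volume round 1: a richer sample always gets less re-pool volume."""
        plan = rebalance_volumes(run(reads), remaining_runs=2,
                                 per_run_reads=sum(reads), vmax=30, vmin=0)
        vols = plan.volumes
        planned = [(reads[i], vols[f"s{i}"]) for i in range(len(reads))
                   if f"s{i}" not in plan.excluded]
        planned.sort()
        for (r1, v1), (r2, v2) in zip(planned, planned[1:]):
            assert v1 > v2

    @given(
        reads=st.lists(st.integers(10, 10**4), min_size=2, max_size=30),
        factor=st.integers(2, 1000),
    )
    @settings(max_examples=60)
    def test_scale_invariance(self, reads, factor):
        """Scaling round-1 reads and the remaining-run size leaves volumes unchanged."""
        p1 = rebalance_volumes(run(reads), remaining_runs=2,
                               per_run_reads=sum(reads), vmax=30, vmin=0)
        p2 = rebalance_volumes(run([r * factor for r in reads]), remaining_runs=2,
                               per_run_reads=sum(reads) * factor, vmax=30, vmin=0)
        for sid in p1.volumes:
            assert p1.volumes[sid] == pytest.approx(p2.volumes[sid], rel=1e-9)

    @given(reads=st.lists(st.integers(0, 10**4), min_size=2, max_size=30))
    @settings(max_examples=60)
    def test_partition_and_bounds(self, reads):
        """Excluded + planned partition the input; planned volumes are in [vmin, vmax]."""
        if sum(r > 0 for r in reads) < 2:
            return
        counts = run(reads)
        try:
            plan = rebalance_volumes(counts, remaining_runs=1,
                                     per_run_reads=10 * (sum(reads) + 1),
                                     vmax=30, vmin=1)
        except EmptyPlanError:
            return
        ids = {e.sample_id for e in plan.entries}
        assert ids == set(counts.sample_ids)
        assert set(plan.excluded).isdisjoint(e.sample_id for e in plan.planned)
        for e in plan.planned:
            assert 1 <= e.volume <= 30 + 1e-9


class TestCumulativeAndSpread:
    def test_cumulative_two_runs(self):
        total = cumulative_totals([run([300, 100], "r1"), run([100, 300], "r2")])
        assert total == {"s0": 400.0, "s1": 400.0}

    def test_cumulative_single_run_identity(self):
        assert cumulative_totals([run([5, 7])]) == {"s0": 5.0, "s1": 7.0}

    @given(matrix=st.lists(
        st.lists(st.integers(0, 1000), min_size=3, max_size=3),
        min_size=1, max_size=5,
    ))
    def test_cumulative_matches_elementwise_sum(self, matrix):
        runs = [run(row, f"r{i}") for i, row in enumerate(matrix)]
        total = cumulative_totals(runs)
        for j in range(3):
            assert total[f"s{j}"] == sum(row[j] for row in matrix)

    def test_cumulative_union_of_samples(self):
        a = DemuxCounts.from_reads("a", {"x": 10, "y": 20})
        b = DemuxCounts.from_reads("b", {"y": 5, "z": 7})
        assert cumulative_totals([a, b]) == {"x": 10.0, "y": 25.0, "z": 7.0}

    @pytest.mark.parametrize(
        "totals, ratio, max_dev, cv",
        [
            ([100, 200], 2.0, 100 / 3, 100 / 3),
            ([50, 50, 50], 1.0, 0.0, 0.0),
            ([90, 100, 110], 11 / 9, 10.0, None),
        ],
    )
    def test_spread_examples(self, totals, ratio, max_dev, cv):
        m = spread_metrics(totals)
        assert m.maxmin_ratio == pytest.approx(ratio)
        assert m.max_rel_dev == pytest.approx(max_dev)
        if cv is not None:
            assert m.cv == pytest.approx(cv)

    def test_spread_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            spread_metrics([100, 0])
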