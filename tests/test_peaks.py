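"""Peak calling, base-wise merge algebra, and signal counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meripdiff.genome import GenomicInterval, Peak
from meripdiff.peaks import (
    CoverageTrack,
    SampleInfo,
    call_peaks,
    count_signal,
    intersect_within_group,
    union_between_groups,
)


def track(arr, sample_id="s", chrom="chr1"):
    return CoverageTrack(sample_id=sample_id, values={chrom: np.asarray(arr, float)})


def random_peaks(rng, n, chrom_len=1000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(start + 200, chrom_len) + 1))
        out.append(Peak(GenomicInterval("chr1", start, end), name=f"p{i}"))
    return out


def coverage_mask(peaks, chrom_len=1000):
    mask = np.zeros(chrom_len, dtype=bool)
    for p in peaks:
        mask[p.start : p.end] = True
    return mask


def mask_to_spans(mask):
    spans, start = [], None
    for i, b in enumerate(mask):
        if b and start is None:
            start = i
        elif not b and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(mask)))
    return spans


class TestCallPeaks:
    def test_no_enrichment_no_peaks(self):
        flat = np.full(2000, 5.0)
        assert call_peaks(track(flat, "ip"), track(flat.copy(), "in")) == []

    def test_planted_region_yields_one_containing_peak(self):
        inp = np.full(2000, 10.0)
        ip = inp.copy()
        ip[600:750] *= 8  # 150 bp of 8x IP excess
        called = call_peaks(
            track(ip, "ip"), track(inp, "in"),
            window=25, min_enrichment=2.0, min_length=50,
        )
        assert len(called) == 1
        assert called[0].start <= 600 and called[0].end >= 750
        assert called[0].summit is not None

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            call_peaks(track(np.zeros(100), "ip"), track(np.ones(100), "in"))

    def test_recovers_planted_peaks_on_default_scenario(self, default_sim, default_calls):
        from meripdiff.simulate import peak_recovery

        assert peak_recovery(default_sim.truth, default_calls.union) >= 0.95


class TestMerges:
    def test_single_replicate_is_merged_self(self):
        peaks = [
            Peak(GenomicInterval("chr1", 0, 100)),
            Peak(GenomicInterval("chr1", 50, 150)),
        ]
        result = intersect_within_group([peaks])
        assert [(p.start, p.end) for p in result] == [(0, 150)]

    def test_textbook_overlap(self):
        a = [Peak(GenomicInterval("chr1", 0, 100))]
        b = [Peak(GenomicInterval("chr1", 50, 150))]
        result = intersect_within_group([a, b])
        assert [(p.start, p.end) for p in result] == [(50, 100)]
        assert result[0].strand == "."

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            intersect_within_group([])

    def test_union_with_empty_group(self):
        a = [Peak(GenomicInterval("chr1", 0, 100))]
        result = union_between_groups(a, [])
        assert [(p.start, p.end) for p in result] == [(0, 100)]
        assert result[0].name.endswith(".A")

    def test_textbook_union(self):
        a = [Peak(GenomicInterval("chr1", 0, 100))]
        b = [Peak(GenomicInterval("chr1", 50, 150))]
        result = union_between_groups(a, b)
        assert [(p.start, p.end) for p in result] == [(0, 150)]
        assert result[0].name.endswith(".AB")

    def test_random_instances_match_basewise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = random_peaks(rng, int(rng.integers(1, 10)))
            b = random_peaks(rng, int(rng.integers(1, 10)))
            inter = intersect_within_group([a, b])
            union = union_between_groups(a, b)
            and_mask = coverage_mask(a) & coverage_mask(b)
            or_mask = coverage_mask(a) | coverage_mask(b)
            assert [(p.start, p.end) for p in inter] == mask_to_spans(and_mask)
            assert [(p.start, p.end) for p in union] == mask_to_spans(or_mask)
            # intersection is base-wise contained in the union
            assert not np.any(and_mask & ~or_mask)

    def test_merges_idempotent_and_sorted(self):
        rng = np.random.default_rng(8)
        peaks = random_peaks(rng, 20)
        once = intersect_within_group([peaks])
        twice = intersect_within_group([once])
        assert [(p.start, p.end) for p in once] == [(p.start, p.end) for p in twice]
        starts = [p.start for p in once]
        assert starts == sorted(starts)
        assert all(a.end <= b.start for a, b in zip(once, once[1:]))


class TestMergeProperties:
    """Algebraic invariants of the merge operations under arbitrary inputs."""

    intervals = st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 100)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=15,
    )

    @given(a=intervals, b=intervals)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_intersection_contained_in_union(self, a, b):
        pa = [Peak(GenomicInterval("chr1", s, e), name=f"a{i}") for i, (s, e) in enumerate(a)]
        pb = [Peak(GenomicInterval("chr1", s, e), name=f"b{i}") for i, (s, e) in enumerate(b)]
        inter = intersect_within_group([pa, pb])
        union = union_between_groups(pa, pb)
        inter_mask = coverage_mask(inter, 1001)
        union_mask = coverage_mask(union, 1001)
        assert not np.any(inter_mask & ~union_mask)
        # both outputs are sorted and non-overlapping
        for out in (inter, union):
            assert all(x.end <= y.start for x, y in zip(out, out[1:]))

    @given(a=intervals)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_remerge_is_idempotent(self, a):
        pa = [Peak(GenomicInterval("chr1", s, e), name=f"a{i}") for i, (s, e) in enumerate(a)]
        once = intersect_within_group([pa])
        twice = intersect_within_group([once])
        assert [(p.start, p.end) for p in once] == [(p.start, p.end) for p in twice]


class TestCountSignal:
    def test_constant_track_times_length(self):
        peaks = [Peak(GenomicInterval("chr1", 10, 90), name="p")]
        matrix = count_signal(peaks, [track(np.ones(1000))])
        assert matrix.counts[0, 0] == 80.0

    def test_additive_over_peak_splits(self):
        rng = np.random.default_rng(9)
        arr = rng.uniform(0, 5, 1000)
        whole = [Peak(GenomicInterval("chr1", 100, 300), name="w")]
        halves = [
            Peak(GenomicInterval("chr1", 100, 180), name="h1"),
            Peak(GenomicInterval("chr1", 180, 300), name="h2"),
        ]
        m_whole = count_signal(whole, [track(arr)])
        m_halves = count_signal(halves, [track(arr)])
        assert m_whole.counts[0, 0] == pytest.approx(m_halves.counts.sum())

    def test_random_pairs_match_basewise_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            arr = rng.uniform(0, 10, 1000)
            peaks = random_peaks(rng, 5)
            matrix = count_signal(peaks, [track(arr)])
            for i, p in enumerate(peaks):
                assert matrix.counts[i, 0] == pytest.approx(
                    sum(arr[p.start : p.end]), rel=1e-9
                )

    def test_missing_chromosome_reads_zero(self):
        peaks = [Peak(GenomicInterval("chrX", 0, 10), name="p")]
        matrix = count_signal(peaks, [track(np.ones(100), chrom="chr1")])
        assert matrix.counts[0, 0] == 0.0

    def test_matrix_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        peaks = random_peaks(rng, 4)
        infos = [SampleInfo("s1", "A", "IP", 100.0), SampleInfo("s2", "B", "input", 50.0)]
        matrix = count_signal(
            peaks, [track(rng.uniform(0, 3, 1000), "s1"), track(rng.uniform(0, 3, 1000), "s2")],
            infos,
        )
        path = tmp_path / "m.tsv"
        matrix.to_tsv(path)
        back = type(matrix).from_tsv(path)
        assert back.samples == infos
        assert np.allclose(back.counts, matrix.counts, atol=1e-6)
        assert [(p.name, p.start, p.end) for p in back.peaks] == [
            (p.name, p.start, p.end) for p in matrix.peaks
        ]
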