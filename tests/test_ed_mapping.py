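"""ED statistic, SNP filters, windowing and interval calling.

Window sums and interval merging are checked against brute-force oracles
(explicit slice sums; union of spans by base-pair sweep).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulkscan.ed_mapping import (
    ED_MAX,
    CandidateInterval,
    FilterParams,
    NucleotideFrequencies,
    SnpEd,
    call_significant_intervals,
    ed_profile,
    ed_snp,
    filter_snps,
    top_interval,
    window_scan,
)
from bulkscan.variant_io import BulkAlleleObservation


def make_obs(chrom="chr1", pos=100, mut=(10, 10, 0, 0), wt=(10, 10, 0, 0), ref="A"):
    bases = ("A", "C", "G", "T")
    alts = tuple(b for b in bases if b != ref)
    return BulkAlleleObservation(
        chrom, pos, ref, alts,
        dict(zip(bases, mut)), dict(zip(bases, wt)),
    )


# ---------------------------------------------------------------------------
# ed_snp


class TestEdSnp:
    def test_identical_frequencies_give_zero(self):
        assert ed_snp((0.25, 0.25, 0.25, 0.25), (0.25, 0.25, 0.25, 0.25)) == 0.0

    def test_opposite_fixation_gives_sqrt2(self):
        assert ed_snp((1, 0, 0, 0), (0, 1, 0, 0)) == pytest.approx(math.sqrt(2))

    def test_causal_locus_configuration(self):
        # mutant bulk fixed; normal bulk 1/3 +/+ and 2/3 het -> mutant-allele
        # frequency 1/3, ED = (2/3)*sqrt(2)
        got = ed_snp((1, 0, 0, 0), (1 / 3, 2 / 3, 0, 0))
        assert got == pytest.approx(2 / 3 * math.sqrt(2), abs=1e-12)

    def test_accepts_frequency_dataclass(self):
        f = NucleotideFrequencies.from_counts({"A": 5, "C": 5})
        assert f.as_array().sum() == pytest.approx(1.0)
        assert ed_snp(f, f) == 0.0

    def test_zero_depth_frequencies_undefined(self):
        with pytest.raises(ValueError):
            NucleotideFrequencies.from_counts({"A": 0})

    @given(
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_symmetry(self, a, b):
        # normalise to frequency simplices (skip degenerate all-zero draws)
        sa, sb = sum(a), sum(b)
        if sa == 0 or sb == 0:
            return
        fa = [x / sa for x in a]
        fb = [x / sb for x in b]
        d = ed_snp(fa, fb)
        assert 0.0 <= d <= ED_MAX + 1e-12
        assert d == pytest.approx(ed_snp(fb, fa))


def test_ed_profile_matches_scalar_and_rejects_zero_depth():
    obs = [
        make_obs(pos=1, mut=(12, 0, 0, 0), wt=(4, 8, 0, 0)),
        make_obs(pos=2, mut=(5, 5, 0, 0), wt=(5, 5, 0, 0)),
    ]
    eds = ed_profile(obs)
    assert eds[0].ed == pytest.approx(ed_snp((1, 0, 0, 0), (1 / 3, 2 / 3, 0, 0)))
    assert eds[1].ed == 0.0
    with pytest.raises(ValueError, match="zero-depth"):
        ed_profile([make_obs(mut=(0, 0, 0, 0))])


# ---------------------------------------------------------------------------
# filtering


class TestFilterSnps:
    def test_low_coverage_excluded(self):
        obs = [make_obs(mut=(2, 0, 0, 0), wt=(15, 15, 0, 0))]
        assert filter_snps(obs) == []

    def test_low_variant_frequency_excluded(self):
        # 1 non-reference read in 60 pooled reads: frequency ~0.017 < 0.05
        obs = [make_obs(mut=(30, 0, 0, 0), wt=(29, 1, 0, 0))]
        assert filter_snps(obs) == []

    def test_boundaries_are_inclusive(self):
        # depth exactly 3 in both bulks, variant frequency exactly 0.5
        obs = [make_obs(mut=(0, 3, 0, 0), wt=(3, 0, 0, 0))]
        assert filter_snps(obs) == obs

    def test_order_preserved(self):
        obs = [make_obs(pos=p, mut=(10, 10, 0, 0), wt=(10, 10, 0, 0)) for p in (5, 1, 9)]
        assert [o.pos for o in filter_snps(obs)] == [5, 1, 9]

    def test_per_bulk_mode_stricter(self):
        # variant reads all in one bulk: pooled freq 0.25 passes, per-bulk fails
        obs = [make_obs(mut=(0, 10, 0, 0), wt=(10, 0, 0, 0), ref="C")]
        assert filter_snps(obs) == obs
        assert filter_snps(obs, per_bulk_freq=True) == []

    @given(
        st.lists(
            st.tuples(
                st.lists(st.integers(0, 30), min_size=4, max_size=4),
                st.lists(st.integers(0, 30), min_size=4, max_size=4),
            ),
            max_size=30,
        ),
        st.integers(0, 10),
        st.floats(0, 1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_filtering_monotone_in_thresholds(self, counts, min_depth, min_freq):
        obs = [make_obs(pos=i + 1, mut=tuple(m), wt=tuple(w)) for i, (m, w) in enumerate(counts)]
        base = len(filter_snps(obs, FilterParams(min_depth, min_freq)))
        stricter_depth = len(filter_snps(obs, FilterParams(min_depth + 1, min_freq)))
        stricter_freq = len(
            filter_snps(obs, FilterParams(min_depth, min(1.0, min_freq + 0.1)))
        )
        assert stricter_depth <= base
        assert stricter_freq <= base


# ---------------------------------------------------------------------------
# windowing


def brute_force_windows(eds, window, step):
    """Oracle: explicit slice sums per chromosome."""
    out = []
    by_chrom = {}
    for e in eds:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, run in by_chrom.items():
        for first in range(0, len(run) - window + 1, step):
            chunk = run[first : first + window]
            out.append((chrom, first, sum(s.ed for s in chunk)))
    return out


class TestWindowScan:
    def test_single_window_arithmetic(self):
        eds = [SnpEd("chr1", 10 * (i + 1), 0.5) for i in range(100)]
        (w,) = window_scan(eds, window=100)
        assert w.ed_sum == pytest.approx(50.0)
        assert w.ed4 == pytest.approx(50.0**4)
        assert (w.first_snp_index, w.last_snp_index) == (0, 99)
        assert (w.start_bp, w.end_bp) == (10, 1000)

    def test_chromosome_below_window_size_emits_nothing(self):
        eds = [SnpEd("chr1", i + 1, 0.1) for i in range(99)]
        assert window_scan(eds, window=100) == []

    def test_windows_never_span_chromosomes(self):
        eds = [SnpEd("chr1", i + 1, 0.1) for i in range(60)] + [
            SnpEd("chr2", i + 1, 0.1) for i in range(60)
        ]
        assert window_scan(eds, window=50) != []
        assert all(w.n_snps == 50 for w in window_scan(eds, window=50))
        assert len(window_scan(eds, window=100)) == 0

    def test_unsorted_input_is_hard_error(self):
        eds = [SnpEd("chr1", 5, 0.1), SnpEd("chr1", 3, 0.1)]
        with pytest.raises(ValueError, match="sorted"):
            window_scan(eds, window=1)
        interleaved = [SnpEd("chr1", 1, 0.1), SnpEd("chr2", 1, 0.1), SnpEd("chr1", 2, 0.1)]
        with pytest.raises(ValueError, match="chromosome"):
            window_scan(interleaved, window=1)

    @pytest.mark.parametrize("window,step", [(100, 1), (100, 50), (7, 3), (1, 1)])
    def test_matches_brute_force_oracle(self, window, step):
        rng = np.random.default_rng(42)
        eds = [
            SnpEd(chrom, pos, float(rng.uniform(0, ED_MAX)))
            for chrom, n in (("chr1", 120), ("chr2", 333))
            for pos in range(1, n + 1)
        ]
        got = window_scan(eds, window=window, step=step)
        expected = brute_force_windows(eds, window, step)
        assert [(w.chrom, w.first_snp_index) for w in got] == [e[:2] for e in expected]
        for w, (_, _, ed_sum) in zip(got, expected):
            assert w.ed_sum == pytest.approx(ed_sum, abs=1e-9)
            assert w.ed4 == pytest.approx(ed_sum**4, rel=1e-9)

    def test_ed4_ranking_equals_ed_ranking(self):
        rng = np.random.default_rng(7)
        eds = [SnpEd("chr1", i + 1, float(rng.uniform(0, 1.4))) for i in range(300)]
        ws = window_scan(eds, window=100)
        by_sum = sorted(range(len(ws)), key=lambda i: ws[i].ed_sum)
        by_ed4 = sorted(range(len(ws)), key=lambda i: ws[i].ed4)
        assert by_sum == by_ed4


# ---------------------------------------------------------------------------
# interval calling


def brute_force_intervals(windows, threshold, merge_gap_bp):
    """Oracle: base-pair union of padded significant spans per chromosome."""
    sig = [w for w in windows if w.ed4 > threshold]
    out = []
    for chrom in sorted({w.chrom for w in sig}):
        spans = sorted((w.start_bp, w.end_bp) for w in sig if w.chrom == chrom)
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1] + merge_gap_bp:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


class TestCallSignificantIntervals:
    def test_no_window_exceeds_threshold(self):
        w = _window("chr1", 100, 200, ed_sum=1.0)
        assert call_significant_intervals([w], threshold=4.0) == []

    def test_single_significant_window(self):
        w = _window("chr9", 91_910_000, 92_300_000, ed4=9.1)
        (iv,) = call_significant_intervals([w], threshold=4.0)
        assert (iv.chrom, iv.start_bp, iv.end_bp) == ("chr9", 91_910_000, 92_300_000)
        assert iv.peak_ed4 == pytest.approx(9.1)
        assert iv.n_windows == 1

    def test_threshold_is_strict(self):
        w = _window("chr1", 1, 10, ed4=4.0)
        assert call_significant_intervals([w], threshold=4.0) == []

    def test_overlapping_plus_isolated(self):
        windows = [
            _window("chr1", 100, 300, ed4=5.0),
            _window("chr1", 250, 500, ed4=6.0),
            _window("chr1", 450, 700, ed4=5.5),
            _window("chr1", 10_000_000, 10_000_200, ed4=8.0),
            _window("chr1", 400, 600, ed4=0.5),  # not significant
        ]
        ivs = call_significant_intervals(windows, threshold=4.0, merge_gap_bp=1000)
        assert [(iv.chrom, iv.start_bp, iv.end_bp) for iv in ivs] == [
            ("chr1", 100, 700),
            ("chr1", 10_000_000, 10_000_200),
        ]
        assert ivs[0].peak_ed4 == pytest.approx(6.0)
        assert ivs[0].n_windows == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        windows = []
        for chrom in ("chr1", "chr2"):
            for _ in range(rng.integers(0, 60)):
                start = int(rng.integers(1, 5_000_000))
                end = start + int(rng.integers(1, 400_000))
                windows.append(_window(chrom, start, end, ed4=float(rng.uniform(0, 10))))
        gap = int(rng.integers(0, 1_000_000))
        got = call_significant_intervals(windows, threshold=4.0, merge_gap_bp=gap)
        assert [(iv.chrom, iv.start_bp, iv.end_bp) for iv in got] == brute_force_intervals(
            windows, 4.0, gap
        )


def test_top_interval_peak_then_leftmost():
    ivs = [
        CandidateInterval("chr2", 100, 200, peak_ed4=9.0, n_windows=1),
        CandidateInterval("chr1", 500, 600, peak_ed4=9.0, n_windows=1),
        CandidateInterval("chr1", 1, 50, peak_ed4=3.0, n_windows=1),
    ]
    assert top_interval(ivs).chrom == "chr1"
    assert top_interval(ivs).start_bp == 500
    assert top_interval([]) is None


def _window(chrom, start, end, ed4=None, ed_sum=None):
    from bulkscan.ed_mapping import WindowStat

    if ed_sum is None:
        ed_sum = 0.0 if ed4 is None else ed4 ** 0.25
    if ed4 is None:
        ed4 = ed_sum**4
    return WindowStat(
        chrom=chrom, first_snp_index=0, last_snp_index=99,
        start_bp=start, end_bp=end, mid_bp=(start + end) // 2,
        ed_sum=ed_sum, ed4=ed4, n_snps=100,
    )
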