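import numpy as np
import pytest

from epiredist.domains import (
    call_lost_domains,
    domain_correlation,
    select_peaks_in_domains,
    signal_matrix,
    tile,
)
from epiredist.genomic_io import (
    Condition,
    CoverageTrack,
    Factor,
    GenomeLayout,
    GenomicInterval,
    Peak,
    ValidationError,
)


def _peaks(intervals, factor=Factor.SIN3B, cond=Condition.CONTROL):
    return [Peak(iv, factor, cond) for iv in intervals]


def brute_force_lost_domains(control, ko, grid):
    """Reference implementation: per-window scan + merge, all in pure loops."""
    qualifying = []
    for i, w in enumerate(grid.windows):
        has_ctrl = any(w.overlaps(p.interval) for p in control)
        has_ko = any(w.overlaps(p.interval) for p in ko)
        if has_ctrl and not has_ko:
            qualifying.append((i, w))
    merged = []
    for i, w in qualifying:
        if merged and merged[-1][0] == w.chrom and w.start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], w.end)
        else:
            merged.append([w.chrom, w.start, w.end])
    return [(c, s, e) for c, s, e in merged]


class TestTile:
    def test_exact_division(self):
        grid = tile(GenomeLayout((("chr1", 30000),)), 6000, 6000)
        assert len(grid.windows) == 5

    def test_truncated_last_window(self):
        grid = tile(GenomeLayout((("chr1", 31000),)), 6000, 6000)
        assert len(grid.windows) == 6
        last = grid.windows[-1]
        assert (last.start, last.end) == (30000, 31000)

    def test_half_step_sliding(self):
        grid = tile(GenomeLayout((("chr1", 12000),)), 6000, 3000)
        assert len(grid.windows) == 4  # k*3000 < 12000 for k = 0..3

    def test_every_basepair_covered(self):
        layout = GenomeLayout((("chr1", 13001), ("chr2", 7000)))
        grid = tile(layout, 6000, 6000)
        for chrom, length in layout.chroms:
            covered = np.zeros(length, dtype=bool)
            for w in grid.windows:
                if w.chrom == chrom:
                    covered[w.start : w.end] = True
            assert covered.all()

    def test_invalid_step_rejected(self):
        layout = GenomeLayout((("chr1", 10000),))
        with pytest.raises(ValidationError):
            tile(layout, 6000, 0)
        with pytest.raises(ValidationError):
            tile(layout, 6000, 9000)


class TestCallLostDomains:
    layout = GenomeLayout((("chr1", 30000),))

    def test_single_control_peak_yields_its_window(self):
        grid = tile(self.layout, 6000, 6000)
        out = call_lost_domains(
            _peaks([GenomicInterval("chr1", 1000, 1500)]),
            _peaks([], cond=Condition.KO),
            grid,
        )
        assert [(d.chrom, d.start, d.end) for d in out.domains] == [("chr1", 0, 6000)]

    def test_ko_peak_spanning_window_boundary_disqualifies(self):
        grid = tile(self.layout, 6000, 6000)
        out = call_lost_domains(
            _peaks([GenomicInterval("chr1", 1000, 1500)]),
            _peaks([GenomicInterval("chr1", 5900, 6100)], cond=Condition.KO),
            grid,
        )
        assert len(out) == 0

    def test_no_control_peaks_gives_empty_set(self):
        grid = tile(self.layout, 6000, 6000)
        out = call_lost_domains(
            [], _peaks([GenomicInterval("chr1", 0, 100)], cond=Condition.KO), grid
        )
        assert len(out) == 0

    def test_adjacent_qualifying_windows_merge(self):
        grid = tile(self.layout, 6000, 6000)
        out = call_lost_domains(
            _peaks([GenomicInterval("chr1", 5000, 7000)]),
            _peaks([], cond=Condition.KO),
            grid,
        )
        assert [(d.start, d.end) for d in out.domains] == [(0, 12000)]
        assert out.provenance == ((0, 1),)

    def test_mixed_factors_rejected(self):
        grid = tile(self.layout, 6000, 6000)
        with pytest.raises(ValidationError, match="mixed"):
            call_lost_domains(
                _peaks([GenomicInterval("chr1", 0, 10)], factor=Factor.SIN3B),
                _peaks([GenomicInterval("chr1", 0, 10)], factor=Factor.HDAC1, cond=Condition.KO),
                grid,
            )

    def test_matches_brute_force_on_random_genomes(self):
        """Oracle equivalence on random genomes and peak sets."""
        rng = np.random.default_rng(2024)
        for trial in range(30):
            length = int(rng.integers(50_000, 200_000))
            layout = GenomeLayout((("chr1", length),))
            step = 6000 if trial % 2 == 0 else 3000
            grid = tile(layout, 6000, step)
            def random_peaks(cond):
                n = int(rng.integers(0, 25))
                starts = rng.integers(0, length - 1, n)
                widths = rng.integers(1, 8000, n)
                return _peaks(
                    [
                        GenomicInterval("chr1", int(s), int(min(s + w, length)))
                        for s, w in zip(starts, widths)
                    ],
                    cond=cond,
                )
            ctrl, ko = random_peaks(Condition.CONTROL), random_peaks(Condition.KO)
            fast = call_lost_domains(ctrl, ko, grid)
            slow = brute_force_lost_domains(ctrl, ko, grid)
            assert [(d.chrom, d.start, d.end) for d in fast.domains] == slow

    def test_monotone_in_peak_sets(self):
        """More KO peaks never enlarge, more control peaks never shrink."""
        rng = np.random.default_rng(7)
        layout = GenomeLayout((("chr1", 120_000),))
        grid = tile(layout, 6000, 6000)

        def cover(domset):
            return {(d.chrom, s) for d in domset.domains for s in range(d.start, d.end, 6000)}

        ctrl = _peaks(
            [GenomicInterval("chr1", int(s), int(s) + 500) for s in rng.integers(0, 119_000, 10)]
        )
        ko = _peaks(
            [GenomicInterval("chr1", int(s), int(s) + 500) for s in rng.integers(0, 119_000, 5)],
            cond=Condition.KO,
        )
        base = cover(call_lost_domains(ctrl, ko, grid))
        more_ko = ko + _peaks([GenomicInterval("chr1", 30_000, 31_000)], cond=Condition.KO)
        assert cover(call_lost_domains(ctrl, more_ko, grid)) <= base
        more_ctrl = ctrl + _peaks([GenomicInterval("chr1", 90_000, 90_500)])
        assert cover(call_lost_domains(more_ctrl, ko, grid)) >= base


class TestSelectPeaksInDomains:
    def _domains(self, ivs):
        from epiredist.domains import BindingDomainSet

        return BindingDomainSet(tuple(ivs), tuple((i,) for i in range(len(ivs))))

    def test_abutting_peak_excluded_by_half_open_convention(self):
        doms = self._domains([GenomicInterval("chr1", 0, 6000)])
        peaks = _peaks([GenomicInterval("chr1", 6000, 6500)], factor=Factor.H3K27AC)
        assert select_peaks_in_domains(peaks, doms) == []

    def test_contained_peak_included(self):
        doms = self._domains([GenomicInterval("chr1", 0, 6000)])
        peaks = _peaks([GenomicInterval("chr1", 100, 200)], factor=Factor.H3K27AC)
        assert select_peaks_in_domains(peaks, doms) == peaks

    def test_counts_partial_overlaps(self):
        doms = self._domains([GenomicInterval("chr1", 1000, 2000), GenomicInterval("chr1", 5000, 6000)])
        ivs = [
            GenomicInterval("chr1", 0, 1001),     # 1 bp overlap -> in
            GenomicInterval("chr1", 2000, 3000),  # abuts -> out
            GenomicInterval("chr1", 1500, 1600),  # inside -> in
            GenomicInterval("chr1", 4000, 4500),  # disjoint -> out
            GenomicInterval("chr1", 5900, 7000),  # overlap -> in
        ]
        out = select_peaks_in_domains(_peaks(ivs, factor=Factor.H3K27AC), doms)
        assert len(out) == 3


def _track_from_values(layout, values_by_chrom, total=1_000_000):
    data = {
        c: (np.array([0] + list(b)), np.array(v))
        for c, (b, v) in values_by_chrom.items()
    }
    return CoverageTrack(layout, data, total_mapped=total)


class TestDomainCorrelation:
    layout = GenomeLayout((("chr1", 30000),))

    def _domains(self, n=3):
        from epiredist.domains import BindingDomainSet

        ivs = [GenomicInterval("chr1", i * 10000, i * 10000 + 5000) for i in range(n)]
        return BindingDomainSet(tuple(ivs), tuple((i,) for i in range(n)))

    def test_identical_tracks_give_r_one(self):
        track = _track_from_values(
            self.layout,
            {"chr1": ([5000, 10000, 15000, 20000, 25000, 30000], [1, 0, 4, 0, 9, 0])},
        )
        rep = domain_correlation(track, track, self._domains())
        assert rep.r == pytest.approx(1.0)

    def test_reciprocal_signals_give_r_minus_one(self):
        a = _track_from_values(
            self.layout,
            {"chr1": ([5000, 10000, 15000, 20000, 25000, 30000], [0.1, 0, 1.0, 0, 10.0, 0])},
        )
        b = _track_from_values(
            self.layout,
            {"chr1": ([5000, 10000, 15000, 20000, 25000, 30000], [10.0, 0, 1.0, 0, 0.1, 0])},
        )
        rep = domain_correlation(a, b, self._domains(), pseudocount=0.0)
        assert rep.r == pytest.approx(-1.0)

    def test_fewer_than_three_domains_rejected(self):
        track = _track_from_values(self.layout, {"chr1": ([30000], [1.0])})
        with pytest.raises(ValidationError):
            domain_correlation(track, track, self._domains(n=2))

    def test_zero_variance_flagged_undefined(self):
        flat = _track_from_values(self.layout, {"chr1": ([30000], [1.0])})
        other = _track_from_values(
            self.layout,
            {"chr1": ([5000, 10000, 15000, 20000, 25000, 30000], [1, 0, 2, 0, 3, 0])},
        )
        rep = domain_correlation(flat, other, self._domains())
        assert rep.undefined and np.isnan(rep.r)

    def test_invariant_to_library_size_rescaling_without_pseudocount(self):
        vals = {"chr1": ([5000, 10000, 15000, 20000, 25000, 30000], [1, 0, 4, 0, 9, 0])}
        other = {"chr1": ([5000, 10000, 15000, 20000, 25000, 30000], [2, 0, 3, 0, 5, 0])}
        a1 = _track_from_values(self.layout, vals, total=1e6)
        a2 = _track_from_values(self.layout, vals, total=3e6)
        b1 = _track_from_values(self.layout, other, total=1e6)
        b2 = _track_from_values(self.layout, other, total=7e6)
        r1 = domain_correlation(a1, b1, self._domains(), pseudocount=0.0).r
        r2 = domain_correlation(a2, b2, self._domains(), pseudocount=0.0).r
        assert r1 == pytest.approx(r2)


class TestSignalMatrix:
    layout = GenomeLayout((("chr1", 20000),))

    def test_uniform_track_fills_matrix_with_constant(self):
        track = _track_from_values(self.layout, {"chr1": ([20000], [3.0])})
        mat = signal_matrix(track, [("chr1", 10000, "+")], flank=3000, n_bins=10)
        assert np.allclose(mat, 3.0)

    def test_spike_at_anchor_peaks_centrally(self):
        track = _track_from_values(
            self.layout, {"chr1": ([9990, 10010, 20000], [0.0, 50.0, 0.0])}
        )
        mat = signal_matrix(track, [("chr1", 10000, "+")], flank=3000, n_bins=11)
        assert mat[0].argmax() == 5

    def test_minus_strand_row_is_reverse_of_plus(self):
        # asymmetric staircase around position 10000
        track = _track_from_values(
            self.layout,
            {"chr1": ([8000, 10000, 12000, 20000], [1.0, 2.0, 7.0, 0.0])},
        )
        plus = signal_matrix(track, [("chr1", 10000, "+")], flank=2000, n_bins=8)
        minus = signal_matrix(track, [("chr1", 10000, "-")], flank=2000, n_bins=8)
        assert np.allclose(minus[0], plus[0][::-1])

    def test_out_of_bounds_bins_are_zero(self):
        track = _track_from_values(self.layout, {"chr1": ([20000], [1.0])})
        mat = signal_matrix(track, [("chr1", 500, "+")], flank=1000, n_bins=4)
        assert mat[0, 0] == 0.0  # fully upstream of the chromosome start
        assert mat[0, -1] == pytest.approx(1.0)
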