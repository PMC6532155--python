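"""Window placement: the SD² criterion, the three passes, design invariants."""

from itertools import combinations

import numpy as np
import pytest

from snppanel import (
    CandidateSnp,
    DesignConfig,
    GenomeLayout,
    Group,
    Priority,
    SimConfig,
    SnpLocus,
    background_pass,
    best_pair,
    best_single,
    design_panel,
    make_design_fixture,
    priority1_pass,
    priority2_pass,
    sd2,
    write_panel_manifest,
)
from snppanel.panel_design import Window, WindowState
from tests.conftest import make_snp


def brute_best_pair(window, candidates):
    inside = sorted(p for p in candidates if window.start <= p < window.end)
    return min(
        combinations(inside, 2),
        key=lambda pair: (sd2(window.start, window.end, list(pair)), pair),
    )


class TestSd2:
    def test_symmetric_pair(self):
        assert sd2(0, 2, [1, 1]) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        # points {0, 5500, 16500, 22000}, mean 11000:
        # (121 + 30.25 + 30.25 + 121) Mbp² / 4
        assert sd2(0, 22_000, [5_500, 16_500]) == pytest.approx(75_625_000.0)

    def test_degenerate_identity(self):
        assert sd2(7, 7, [7]) == 0.0

    def test_empty_chosen_rejected(self):
        with pytest.raises(ValueError):
            sd2(0, 100, [])

    def test_divisor_is_point_count(self):
        # single candidate -> 3 points
        pts = [0, 22_000, 11_000]
        mean = sum(pts) / 3
        assert sd2(0, 22_000, [11_000]) == pytest.approx(
            sum((p - mean) ** 2 for p in pts) / 3
        )


class TestBestPair:
    def _window(self, start=0, end=22_000):
        return Window(chrom="1", start=start, end=end, index=0)

    def test_three_candidates_tie_broken_low(self):
        w = self._window()
        pair = best_pair(w, [5_500, 11_000, 16_500])
        assert pair == (5_500, 11_000)
        assert sd2(0, 22_000, list(pair)) == pytest.approx(66_171_875.0)

    def test_skewed_candidates_match_exhaustive(self):
        w = self._window()
        cands = [1, 2, 21_999]
        assert best_pair(w, cands) == brute_best_pair(w, cands)

    def test_random_windows_match_exhaustive(self, rng):
        for _ in range(60):
            start = int(rng.integers(0, 1_000_000))
            w = self._window(start, start + 22_000)
            k = int(rng.integers(3, 51))
            cands = sorted(
                {int(p) for p in rng.integers(w.start, w.end, size=k)}
            )
            if len(cands) < 3:
                continue
            assert best_pair(w, cands) == brute_best_pair(w, cands)

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            best_pair(self._window(), [1, 2])


class TestBestSingle:
    def _window(self):
        return Window(chrom="1", start=0, end=22_000, index=0)

    def test_nearest_midpoint_wins(self):
        assert best_single(self._window(), [4_000, 12_000]) == 12_000

    def test_single_candidate(self):
        assert best_single(self._window(), [123]) == 123

    def test_equidistant_tie_broken_low(self):
        assert best_single(self._window(), [10_000, 12_000]) == 10_000

    def test_matches_argmin_over_sd2(self, rng):
        w = self._window()
        for _ in range(50):
            cands = sorted({int(p) for p in rng.integers(0, 22_000, size=20)})
            got = best_single(w, cands)
            expected = min(cands, key=lambda p: (sd2(w.start, w.end, [p]), p))
            assert got == expected


class TestPriority1Pass:
    def test_no_candidates_all_empty_windows(self, design_config):
        sel, ledger = priority1_pass([], "1", 100_000, design_config)
        assert sel == []
        assert len(ledger.windows) == 5
        assert all(w.state is WindowState.EMPTY for w in ledger.windows)
        assert ledger.windows[-1].end == 100_001  # terminal partial window

    def test_one_or_two_snps_reserved(self, design_config):
        cands = [make_snp(pos=5_000), make_snp(pos=9_000)]
        sel, _ = priority1_pass(cands, "1", 22_000, design_config)
        assert {c.locus.pos for c in sel} == {5_000, 9_000}

    def test_crowded_window_keeps_sd2_minimum(self, rng, design_config):
        positions = sorted(int(p) for p in rng.choice(np.arange(1, 22_000), 5, replace=False))
        cands = [make_snp(pos=p) for p in positions]
        _sel, ledger = priority1_pass(cands, "1", 22_000, design_config)
        w = ledger.windows[0]
        assert w.n_selected == 2
        picked = tuple(sorted(c.locus.pos for c, _ in w.selections))
        assert picked == brute_best_pair(w, positions)

    def test_window_restarts_at_probe_position(self, design_config):
        cands = [make_snp(pos=10_000)]
        _sel, ledger = priority1_pass(cands, "1", 60_000, design_config)
        assert ledger.windows[0].state is WindowState.FILLED_1
        assert ledger.windows[1].start == 10_000
        starts = [w.start for w in ledger.windows]
        assert starts == sorted(set(starts))

    def test_indel_forced_beyond_pair(self, design_config):
        plain = [make_snp(pos=p) for p in (2_000, 11_000, 20_000)]
        indel = make_snp(pos=15_000, group=Group.RESEQUENCING, is_indel=True)
        sel, ledger = priority1_pass(plain + [indel], "1", 22_000, design_config)
        assert 15_000 in {c.locus.pos for c in sel}
        assert len(sel) == 3  # best pair + forced indel
        assert ledger.windows[0].n_selected == 3


class TestFillPasses:
    def _ledger(self, candidates, length=110_000, config=None):
        return priority1_pass(candidates, "1", length, config or DesignConfig())[1]

    def test_empty_window_filled_with_p2(self):
        ledger = self._ledger([])
        p2 = [make_snp(pos=5_000, group=Group.RESEQUENCING, priority=Priority.P2)]
        sel = priority2_pass(ledger, p2)
        assert [c.locus.pos for c in sel] == [5_000]
        assert ledger.windows[0].state is WindowState.FILLED_2

    def test_filled_window_skipped(self):
        # the P1 probe sits near the window end, so the P2 candidate at 6 kb
        # lies only inside the filled window, which the fill pass must skip
        ledger = self._ledger([make_snp(pos=21_000)], length=22_000)
        p2 = [make_snp(pos=6_000, group=Group.RESEQUENCING, priority=Priority.P2)]
        assert priority2_pass(ledger, p2) == []
        assert ledger.windows[0].state is WindowState.FILLED_1

    def test_fill_count_matches_intersection_oracle(self, rng):
        ledger = self._ledger([])
        positions = sorted({int(p) for p in rng.integers(1, 110_000, size=8)})
        p2 = [make_snp(pos=p, group=Group.RESEQUENCING, priority=Priority.P2) for p in positions]
        sel = priority2_pass(ledger, p2)
        coverable = sum(
            1
            for w in self._ledger([]).windows
            if any(w.start <= p < w.end for p in positions)
        )
        assert len(sel) == coverable  # non-overlapping windows here

    def test_background_prefers_validated(self):
        ledger = self._ledger([], length=22_000)
        near_mid = make_snp(pos=11_000, group=Group.SNPDB, priority=Priority.BACKGROUND)
        validated_far = CandidateSnp(
            SnpLocus("1", 2_000, "A", "G", "1_2000"),
            Group.SNPDB,
            Priority.BACKGROUND,
            validated=True,
        )
        sel = background_pass(ledger, [near_mid, validated_far])
        assert [c.locus.pos for c in sel] == [2_000]

    def test_background_leaves_uncoverable_window_empty(self):
        ledger = self._ledger([], length=44_000)
        snp = make_snp(pos=5_000, group=Group.SNPDB, priority=Priority.BACKGROUND)
        background_pass(ledger, [snp])
        states = [w.state for w in ledger.windows]
        assert states[0] is WindowState.FILLED_2
        assert states[1] is WindowState.EMPTY

    def test_dense_background_covers_everything(self, rng):
        ledger = self._ledger([], length=110_000)
        snps = [
            make_snp(pos=p, group=Group.SNPDB, priority=Priority.BACKGROUND)
            for p in range(1_000, 110_000, 2_000)
        ]
        background_pass(ledger, snps)
        assert ledger.empty_windows() == []


class TestDesignPanel:
    def test_background_only_panel_fills_every_window(self, design_config):
        genome = GenomeLayout((("1", 110_000),))
        snpdb = [
            make_snp(pos=p, group=Group.SNPDB, priority=Priority.BACKGROUND)
            for p in range(500, 110_000, 1_000)
        ]
        panel, ledgers = design_panel(genome, snpdb, design_config)
        assert len(panel) == len(ledgers["1"].windows) == 5

    def test_occupancy_and_membership(self, fixture_panel):
        panel, ledgers = fixture_panel
        for chrom, ledger in ledgers.items():
            for w in ledger.windows:
                non_indel = [c for c, _ in w.selections if not c.is_indel]
                assert len(non_indel) <= 2
                for snp, _label in w.selections:
                    assert w.start <= snp.locus.pos < w.end

    def test_determinism_byte_identical_manifests(self, tmp_path):
        cfg = SimConfig(seed=77)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            genome, cands, snpdb = make_design_fixture(cfg)
            panel, _ = design_panel(genome, cands + snpdb)
            p = tmp_path / name
            write_panel_manifest(panel, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_spacing_bound_under_dense_background(self, design_config):
        genome = GenomeLayout((("1", 400_000),))
        snpdb = [
            make_snp(pos=p, group=Group.SNPDB, priority=Priority.BACKGROUND)
            for p in range(250, 400_000, 500)
        ]
        panel, _ = design_panel(genome, snpdb, design_config)
        positions = sorted(loc.pos for loc in panel.loci)
        gaps = [b - a for a, b in zip(positions, positions[1:])]
        assert max(gaps) <= 2 * design_config.window_length
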