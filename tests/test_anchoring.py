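"""Region clustering, filtering and scaffold assignment/ordering."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from mapscaff import anchoring as an
from mapscaff import pipeline, simulate
from mapscaff.anchoring import UNANCHORED
from mapscaff.genetic_map import GeneticMarker, MarkerPlacement


def mk(mid, group, cm):
    return GeneticMarker(mid, group, cm, None)


def pl(mid, scaf, pos, identity=100.0):
    return MarkerPlacement(mid, scaf, pos, "+", identity, 100.0, 100.0)


class TestFilterInconsistentMarkers:
    def test_concordant_close_pair_kept(self):
        markers = [mk("a", "chr1", 1.0), mk("b", "chr1", 2.0)]
        placements = [pl("a", "s", 1000), pl("b", "s", 1500)]
        kept, discarded = an.filter_inconsistent_markers(placements, markers)
        assert len(kept) == 2 and discarded == []

    def test_unsupported_member_of_inverted_pair_discarded(self):
        """Hand-traced fixpoint: 'x' inverts against a 4-marker increasing
        run; x has no concordant neighbour and is the one removed."""
        markers = [mk("a", "chr1", 1.0), mk("b", "chr1", 2.0),
                   mk("c", "chr1", 3.0), mk("x", "chr1", 9.0),
                   mk("d", "chr1", 4.0)]
        placements = [pl("a", "s", 10_000), pl("b", "s", 20_000),
                      pl("c", "s", 30_000), pl("x", "s", 30_500),
                      pl("d", "s", 31_000)]
        kept, discarded = an.filter_inconsistent_markers(placements, markers)
        assert [p.marker_id for p in discarded] == ["x"]
        assert [p.marker_id for p in kept] == ["a", "b", "c", "d"]

    def test_distant_inversion_outside_window_kept(self):
        markers = [mk("a", "chr1", 5.0), mk("b", "chr1", 1.0)]
        placements = [pl("a", "s", 1000), pl("b", "s", 6000)]
        kept, discarded = an.filter_inconsistent_markers(placements, markers,
                                                         window=1000)
        assert len(kept) == 2 and discarded == []

    def test_reverse_oriented_scaffold_not_purged(self):
        """Uniformly decreasing cM is orientation, not inconsistency."""
        markers = [mk(f"m{i}", "chr1", 10.0 - i) for i in range(5)]
        placements = [pl(f"m{i}", "s", 200 * i) for i in range(5)]
        kept, discarded = an.filter_inconsistent_markers(placements, markers)
        assert len(kept) == 5 and discarded == []


class TestClusterRegions:
    def test_single_run(self):
        markers = [mk(f"m{i}", "chr1", float(i)) for i in range(5)]
        placements = [pl(f"m{i}", "s", 10_000 * i) for i in range(5)]
        regions = an.cluster_regions(placements, markers)
        assert len(regions) == 1
        assert regions[0].n_markers == 5
        assert (regions[0].start, regions[0].end) == (0, 40_000)

    def test_alternating_groups_break(self):
        markers = [mk("a", "chr1", 1.0), mk("b", "chr2", 1.0),
                   mk("c", "chr1", 1.1), mk("d", "chr2", 1.1)]
        placements = [pl(x, "s", i * 1000) for i, x in enumerate("abcd")]
        regions = an.cluster_regions(placements, markers)
        assert [r.linkage_group for r in regions] == \
            ["chr1", "chr2", "chr1", "chr2"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, seed):
        """Random placements vs an oracle applying the three break rules."""
        rng = np.random.default_rng(seed)
        n = 60
        markers, placements = [], []
        pos = 0
        for i in range(n):
            pos += int(rng.integers(1, 900_000))
            group = f"chr{int(rng.integers(1, 4))}"
            cm = float(np.round(rng.uniform(0, 40), 2))
            markers.append(mk(f"m{i}", group, cm))
            placements.append(pl(f"m{i}", "s", pos))
        regions = an.cluster_regions(placements, markers,
                                     max_phys_gap=500_000, max_cM_jump=5.0)
        # oracle: walk sorted placements, break on any of the three rules
        expected = []
        run = [0]
        for i in range(1, n):
            prev, cur = markers[i - 1], markers[i]
            brk = (cur.linkage_group != prev.linkage_group
                   or placements[i].position - placements[i - 1].position > 500_000
                   or abs(cur.genetic_pos - prev.genetic_pos) > 5.0)
            if brk:
                expected.append(run)
                run = []
            run.append(i)
        expected.append(run)
        assert [[m for m in r.marker_ids] for r in regions] == \
            [[f"m{i}" for i in run] for run in expected]


class TestFilterRegions:
    def _region(self, n_markers, length):
        return an.PhysicalRegion("s", 0, length, "chr1", 1.0, 2.0, 1.5,
                                 tuple(f"m{i}" for i in range(n_markers)))

    def test_single_marker_dropped(self):
        kept, dropped = an.filter_regions([self._region(1, 5000)])
        assert kept == [] and len(dropped) == 1

    def test_small_region_dropped(self):
        kept, dropped = an.filter_regions([self._region(3, 999)])
        assert kept == []

    def test_boundary_kept(self):
        kept, dropped = an.filter_regions([self._region(2, 1000)])
        assert len(kept) == 1 and dropped == []

    def test_idempotent(self):
        regions = [self._region(n, ln) for n, ln in
                   [(1, 5000), (3, 999), (2, 1000), (7, 80_000)]]
        once = an.filter_regions(regions)[0]
        twice = an.filter_regions(once)[0]
        assert once == twice


class TestAssignChromosome:
    def _region(self, group, cm, n, scaf="s", start=0, end=50_000):
        return an.PhysicalRegion(scaf, start, end, group, cm, cm, cm,
                                 tuple(f"{group}_{cm}_{i}" for i in range(n)))

    def test_single_region(self):
        a = an.assign_chromosome("s", [self._region("chr3", 12.0, 10)])
        assert a.chromosome == "chr3"
        assert a.order_key == 12.0
        assert not a.conflict_flag

    def test_majority_wins_with_conflict_flag(self):
        a = an.assign_chromosome("s", [self._region("chr1", 5.0, 8),
                                       self._region("chr2", 30.0, 2)])
        assert a.chromosome == "chr1" and a.conflict_flag

    def test_tie_unanchored(self):
        a = an.assign_chromosome("s", [self._region("chr1", 5.0, 5),
                                       self._region("chr2", 30.0, 5)])
        assert a.chromosome == UNANCHORED and a.conflict_flag

    def test_single_supporting_marker_unanchored(self):
        a = an.assign_chromosome("s", [self._region("chr1", 5.0, 1)])
        assert a.chromosome == UNANCHORED


class TestOrientScaffold:
    def _pair(self, cms):
        markers = [mk(f"m{i}", "chr1", c) for i, c in enumerate(cms)]
        placements = [pl(f"m{i}", "s", 1000 * i) for i in range(len(cms))]
        return placements, markers

    def test_increasing_plus(self):
        assert an.orient_scaffold(*self._pair([1.0, 2.0, 3.0])) == "+"

    def test_decreasing_minus(self):
        assert an.orient_scaffold(*self._pair([3.0, 2.0, 1.0])) == "-"

    def test_cosegregating_unknown(self):
        assert an.orient_scaffold(*self._pair([2.0, 2.0, 2.0])) == "unknown"

    def test_single_placement_unknown(self):
        assert an.orient_scaffold(*self._pair([2.0])) == "unknown"


class TestOrderChromosome:
    def _assign(self, sid, key):
        return an.ScaffoldAssignment(sid, "chr1", key, "+", 5, False)

    def test_sorted_by_key(self):
        out = an.order_chromosome(
            [self._assign("a", 3.2), self._assign("b", 1.1),
             self._assign("c", 7.0)], {"a": 10, "b": 10, "c": 10})
        assert [x.scaffold_id for x in out["chr1"]] == ["b", "a", "c"]

    def test_tie_broken_by_length_then_id(self):
        out = an.order_chromosome(
            [self._assign("a", 2.0), self._assign("b", 2.0)],
            {"a": 5_000, "b": 9_000})
        assert [x.scaffold_id for x in out["chr1"]] == ["b", "a"]

    def test_random_keys_match_sort_oracle(self):
        rng = np.random.default_rng(6)
        keys = rng.uniform(0, 100, size=40)
        assigns = [self._assign(f"s{i:02d}", float(k))
                   for i, k in enumerate(keys)]
        lengths = {a.scaffold_id: 100 for a in assigns}
        out = an.order_chromosome(assigns, lengths)
        assert [a.scaffold_id for a in out["chr1"]] == \
            [a.scaffold_id for a in sorted(assigns, key=lambda x: (x.order_key,
                                                                   x.scaffold_id))]


class TestParameterRecovery:
    def test_noiseless_map_full_recovery(self, small_genome, small_map,
                                         fragmented):
        """Noiseless monotone map: every anchored scaffold lands on its true
        chromosome with correct orientation, and ordering is perfect."""
        markers, _ = small_map
        scaffolds, truth = fragmented
        res = pipeline.anchor_assembly(scaffolds, markers)
        anchored = [a for a in res.assignments if a.chromosome != UNANCHORED]
        assert anchored, "fixture produced no anchored scaffolds"
        for a in anchored:
            assert truth.true_chromosome(a.scaffold_id) == a.chromosome
            true_or = truth.scaffolds[a.scaffold_id]["parts"][0]["orientation"]
            assert a.orientation == true_or
        for chrom, order in res.ordered.items():
            starts = [truth.scaffolds[a.scaffold_id]["parts"][0]["segments"][0][0]
                      for a in order]
            if len(starts) > 1:
                assert kendalltau(range(len(starts)), starts).statistic == \
                    pytest.approx(1.0)

    def test_recovery_under_noise(self, small_genome):
        """cM noise (sd 0.5) plus orphaned tags: scaffolds with >= 5 markers
        still assign to the right chromosome."""
        markers, _ = simulate.simulate_map(small_genome, markers_per_mb=300,
                                           cM_noise_sd=0.5, seed=77)
        rng = np.random.default_rng(77)
        keep = rng.random(len(markers)) > 0.05  # 5% of tags dropped
        markers = [m for m, k in zip(markers, keep) if k]
        scaffolds, truth = simulate.fragment_assembly(
            small_genome, mean_scaffold_len=30_000, seed=77)
        res = pipeline.anchor_assembly(scaffolds, markers)
        strong = [a for a in res.assignments
                  if a.chromosome != UNANCHORED and a.supporting_markers >= 5]
        assert strong
        for a in strong:
            assert truth.true_chromosome(a.scaffold_id) == a.chromosome
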