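"""Segment-calling rules, donor proportion, coverage and library statistics."""

import numpy as np
import pandas as pd
import pytest

from ilqtl.io_core import GenomeSpec, MarkerMap
from ilqtl.segments import (
    ILProfile,
    SegmentSet,
    call_segments,
    donor_proportion,
    library_coverage,
    marker_density,
    polymorphism_summary,
    profile_library,
    round_half_up,
    segment_stats,
    segments_table,
)
from ilqtl.validation import brute_force_interval_weights, segment_caller_agreement

MB = 1_000_000


def _segset(il, pieces, merged=None):
    pc = pd.DataFrame(pieces, columns=["chromosome", "start", "end", "weight"])
    mg = pd.DataFrame(
        merged if merged is not None else [(c, s, e) for c, s, e, _ in pieces],
        columns=["chromosome", "start", "end"],
    )
    return SegmentSet(il, pc, mg)


class TestCallSegments:
    def test_ddr_example_weights_and_length(self, three_marker_map, small_genome):
        segs = call_segments({"RM1": "D", "RM2": "D", "RM3": "R"}, three_marker_map, small_genome)
        got = sorted(map(tuple, segs.pieces[["start", "end", "weight"]].to_numpy()))
        assert got == [
            (0.0, 1 * MB, 0.5),
            (1 * MB, 3 * MB, 1.0),
            (3 * MB, 5 * MB, 0.5),
        ]
        assert segs.weighted_length() == pytest.approx(3.5 * MB)
        assert segs.n_segments == 1  # flanks merge into the donor run
        assert donor_proportion(segs, small_genome) == pytest.approx(0.35)

    def test_all_recurrent_is_empty(self, three_marker_map, small_genome):
        segs = call_segments({"RM1": "R", "RM2": "R", "RM3": "R"}, three_marker_map, small_genome)
        assert segs.pieces.empty and segs.n_segments == 0
        assert donor_proportion(segs, small_genome) == 0.0

    def test_missing_marker_equals_deleted_marker(self, three_marker_map, small_genome):
        """A D,NA,R row must call exactly like D,R on the map without the NA marker."""
        with_na = call_segments({"RM1": "D", "RM2": "NA", "RM3": "R"}, three_marker_map, small_genome)
        reduced_map = MarkerMap(
            three_marker_map.table[three_marker_map.table["marker_id"] != "RM2"].reset_index(drop=True),
            small_genome,
        )
        deleted = call_segments({"RM1": "D", "RM3": "R"}, reduced_map, small_genome)
        pd.testing.assert_frame_equal(
            with_na.pieces.sort_values(["start"]).reset_index(drop=True),
            deleted.pieces.sort_values(["start"]).reset_index(drop=True),
        )
        assert with_na.weighted_length() == pytest.approx(2.5 * MB)

    def test_all_donor_chromosome_matches_brute_force(self, three_marker_map, small_genome):
        calls = {"RM1": "D", "RM2": "D", "RM3": "D"}
        segs = call_segments(calls, three_marker_map, small_genome)
        oracle = brute_force_interval_weights(calls, three_marker_map, small_genome)
        expected = sum(w * (e - s) for _, s, e, w in oracle)
        assert segs.weighted_length() == pytest.approx(expected)
        # outermost span + two half end-flanks
        assert expected == pytest.approx((5 - 1) * MB + 0.5 * (1 * MB) + 0.5 * (1 * MB))

    @pytest.mark.parametrize("het,expected_w", [("donor", 1.0), ("ignore", None)])
    def test_het_policy(self, three_marker_map, small_genome, het, expected_w):
        segs = call_segments({"RM1": "D", "RM2": "H", "RM3": "R"}, three_marker_map, small_genome, het=het)
        if het == "donor":
            core = segs.pieces[segs.pieces["weight"] == 1.0]
            assert len(core) == 1 and core.iloc[0]["end"] == 3 * MB
        else:  # H treated as missing: D..R with the middle marker removed
            assert (segs.pieces["weight"] == 0.5).all()

    def test_matches_brute_force_on_random_matrices(self):
        assert segment_caller_agreement(n_matrices=150, seed=5) == 1.0


class TestProportionInvariants:
    def test_profile_invariants_on_simulated_library(self, sim_library):
        cfg, mm = sim_library["config"], sim_library["marker_map"]
        profiles = profile_library(sim_library["genotypes"], mm, cfg.genome)
        for p in profiles:
            assert 0.0 <= p.donor_proportion <= 1.0
            assert p.donor_proportion + p.background_recovery == 1.0  # exact
            assert p.segments.weighted_length() <= cfg.genome.total_size

    def test_empty_set_full_recovery(self, small_genome):
        empty = _segset("il0", [])
        assert donor_proportion(empty, small_genome) == 0.0
        prof = ILProfile("il0", "d", empty, 0.0)
        assert prof.background_recovery == 1.0


class TestCoverage:
    def test_single_segment_fraction(self, small_genome):
        prof = ILProfile("il1", "d", _segset("il1", [("chr1", 1 * MB, 3 * MB, 1.0)]), 0.1)
        cov = library_coverage([prof], small_genome).set_index("chromosome")["coverage_pct"]
        assert cov["chr1"] == pytest.approx(100 * 2 / 6)
        assert cov["chr2"] == 0.0

    def test_tiling_reaches_100(self, small_genome):
        p1 = ILProfile("a", "d", _segset("a", [("chr1", 0.0, 4 * MB, 1.0)]), 0.1)
        p2 = ILProfile("b", "d", _segset("b", [("chr1", 3 * MB, 6 * MB, 0.5)]), 0.1)
        cov = library_coverage([p1, p2], small_genome).set_index("chromosome")["coverage_pct"]
        assert cov["chr1"] == pytest.approx(100.0)

    def test_monotone_and_order_invariant(self, sim_library):
        cfg, mm = sim_library["config"], sim_library["marker_map"]
        profiles = profile_library(sim_library["genotypes"], mm, cfg.genome)
        prev = np.zeros(len(cfg.genome.chromosomes) + 1)
        for i in range(1, len(profiles) + 1):
            cov = library_coverage(profiles[:i], cfg.genome)["coverage_pct"].to_numpy()
            assert (cov >= prev - 1e-9).all()
            prev = cov
        rng = np.random.default_rng(0)
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        pd.testing.assert_frame_equal(
            library_coverage(profiles, cfg.genome), library_coverage(shuffled, cfg.genome)
        )


class TestStats:
    def test_two_segments_range_and_mean(self, small_genome):
        prof = ILProfile(
            "il1",
            "d",
            _segset("il1", [("chr1", 0.0, 2 * MB, 1.0), ("chr2", 0.0, 4 * MB, 1.0)]),
            0.1,
        )
        st = segment_stats([prof], small_genome)
        assert (st["length_min_mb"], st["length_max_mb"], st["length_mean_mb"]) == (2.0, 4.0, 3.0)

    def test_single_segment_degenerate(self, small_genome):
        prof = ILProfile("il1", "d", _segset("il1", [("chr1", 0.0, 2 * MB, 1.0)]), 0.1)
        st = segment_stats([prof], small_genome)
        assert st["length_min_mb"] == st["length_max_mb"] == st["length_mean_mb"] == 2.0

    def test_empty_library_marker(self, small_genome):
        st = segment_stats([ILProfile("il1", "d", _segset("il1", []), 0.0)], small_genome)
        assert st["empty"] and st["n_segments"] == 0

    def test_stats_equal_flat_recount(self, sim_library):
        """Library stats must equal an independent recount over the flat segment table."""
        cfg, mm = sim_library["config"], sim_library["marker_map"]
        profiles = profile_library(sim_library["genotypes"], mm, cfg.genome)
        st = segment_stats(profiles, cfg.genome)
        merged = pd.concat(
            [p.segments.merged for p in profiles if not p.segments.merged.empty], ignore_index=True
        )
        lengths = (merged["end"] - merged["start"]) / MB
        assert st["n_segments"] == len(merged)
        assert st["length_mean_mb"] == pytest.approx(lengths.mean())
        assert st["length_min_mb"] == pytest.approx(lengths.min())
        assert st["length_max_mb"] == pytest.approx(lengths.max())
        flat = segments_table(profiles)
        assert set(flat["il_id"]) <= set(p.il_id for p in profiles)


class TestPolymorphism:
    def _map_with_flags(self, flags_by_chrom, donor="don"):
        rows, flags = [], []
        lengths = {}
        i = 0
        for chrom, chrom_flags in flags_by_chrom.items():
            lengths[chrom] = (len(chrom_flags) + 1) * MB
            for j, f in enumerate(chrom_flags):
                i += 1
                rows.append((f"m{i}", chrom, (j + 1) * MB))
                flags.append(f)
        t = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
        return MarkerMap(t, GenomeSpec(lengths), {donor: np.array(flags)})

    def test_weighted_vs_simple_modes(self):
        mm = self._map_with_flags({"c1": [True] * 3 + [False], "c2": [True, False]})
        w = polymorphism_summary(mm, "don", "weighted")
        s = polymorphism_summary(mm, "don", "simple")
        assert w["rate_pct"].iloc[-1] == round_half_up(100 * 4 / 6)
        assert s["rate_pct"].iloc[-1] == round_half_up((75.0 + 50.0) / 2)

    def test_all_polymorphic_is_100_in_both_modes(self):
        mm = self._map_with_flags({"c1": [True] * 4, "c2": [True] * 3})
        for mode in ("weighted", "simple"):
            assert polymorphism_summary(mm, "don", mode)["rate_pct"].iloc[-1] == 100.00

    def test_missing_donor_flags_rejected(self):
        mm = self._map_with_flags({"c1": [True, False]})
        with pytest.raises(KeyError):
            polymorphism_summary(mm, "nobody", "weighted")


def test_marker_density_mean(three_marker_map):
    d = marker_density(three_marker_map)
    assert d[d["chromosome"] == "chr1"]["density_mb"].iloc[0] == pytest.approx(2.0)


@pytest.mark.parametrize("x,expected", [(2.225, 2.23), (2.224, 2.22), (89.285, 89.29), (0.005, 0.01)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
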