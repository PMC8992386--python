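"""Breeding-scheme simulator: meiosis model, expectations, determinism."""

import numpy as np
import pytest

from ilqtl.io_core import GenomeSpec
from ilqtl.segments import call_segments, donor_proportion
from ilqtl.simulate import (
    DONOR,
    RECURRENT,
    GenerationEmptied,
    Plant,
    QTLEffect,
    SimConfig,
    apply_phenotype_model,
    build_genetic_map,
    build_marker_map,
    default_test_genome,
    genetic_position,
    genotype_at_markers,
    library_tables,
    run_breeding_scheme,
    simulate_meiosis,
)

MB = 1_000_000


class TestGeneticMap:
    def test_linear_scaling(self):
        assert genetic_position(1 * MB, 4.0) == pytest.approx(4.0)
        assert genetic_position(0, 4.0) == 0.0
        m = build_genetic_map(GenomeSpec({"c": 25 * MB}), 4.0)
        assert m["c"] == pytest.approx(1.0)  # 100 cM = 1 Morgan

    def test_monotone(self, rng):
        pos = np.sort(rng.integers(1, 10**8, 50))
        g = [genetic_position(p, 3.3) for p in pos]
        assert (np.diff(g) >= 0).all()

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            build_genetic_map(GenomeSpec({"c": MB}), 0.0)


class TestMeiosis:
    def test_zero_map_length_returns_parental_haplotype(self, rng):
        a = [(5.0 * MB, DONOR)]
        b = [(5.0 * MB, RECURRENT)]
        for _ in range(20):
            g = simulate_meiosis(a, b, 5.0 * MB, 0.0, rng)
            assert g in (a, b)

    def test_f1_gamete_donor_fraction_half(self):
        rng = np.random.default_rng(8)
        L = 25.0 * MB
        a, b = [(L, DONOR)], [(L, RECURRENT)]
        fractions = []
        for _ in range(10_000):
            g = simulate_meiosis(a, b, L, 1.0, rng)
            d = 0.0
            prev = 0.0
            for end, origin in g:
                if origin == DONOR:
                    d += end - prev
                prev = end
            fractions.append(d / L)
        mean = np.mean(fractions)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(mean - 0.5) <= 3 * se

    def test_crossover_count_poisson_mean(self):
        """On a 100 cM chromosome the mean breakpoint count over F1 meioses
        is 1.0 (every crossover is visible between fully distinct parents)."""
        rng = np.random.default_rng(9)
        L = 25.0 * MB
        a, b = [(L, DONOR)], [(L, RECURRENT)]
        counts = [len(simulate_meiosis(a, b, L, 1.0, rng)) - 1 for _ in range(10_000)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 1.0) <= 3 * se


class TestBreedingScheme:
    def test_backcross_expectation_b2(self):
        cfg = SimConfig(genome=default_test_genome(), n_backcrosses=2, n_selfs=0, n_lines=600, seed=21)
        ils = run_breeding_scheme(cfg, build_marker_map(cfg))
        fr = np.array([il.true_donor_proportion for il in ils])
        se = fr.std(ddof=1) / np.sqrt(len(fr))
        assert abs(fr.mean() - 0.125) <= 3 * se

    def test_selfing_preserves_expectation(self):
        cfg = SimConfig(genome=default_test_genome(), n_backcrosses=2, n_selfs=3, n_lines=600, seed=22)
        ils = run_breeding_scheme(cfg, build_marker_map(cfg))
        fr = np.array([il.true_donor_proportion for il in ils])
        se = fr.std(ddof=1) / np.sqrt(len(fr))
        assert abs(fr.mean() - 0.125) <= 3 * se

    def test_same_seed_identical_output(self):
        cfg = SimConfig(genome=default_test_genome(), n_lines=30, seed=33)
        mm = build_marker_map(cfg)
        a = run_breeding_scheme(cfg, mm)
        b = run_breeding_scheme(cfg, mm)
        assert [il.calls for il in a] == [il.calls for il in b]
        assert [il.plant.haplotypes for il in a] == [il.plant.haplotypes for il in b]

    def test_truth_invariants(self, sim_library):
        for il in sim_library["ils"]:
            assert 0.0 <= il.true_donor_proportion <= 1.0
            for haps in il.plant.haplotypes.values():
                for hap in haps:
                    ends = [e for e, _ in hap]
                    assert all(a < b for a, b in zip(ends, ends[1:]))

    def test_overzealous_selection_raises(self):
        cfg = SimConfig(
            genome=default_test_genome(), n_lines=10, population_size=20,
            selection_threshold_sd=50.0, seed=5,
        )
        with pytest.raises(GenerationEmptied):
            run_breeding_scheme(cfg, build_marker_map(cfg))

    def test_selection_enriches_qtl_carriers(self):
        qtl = QTLEffect("chr1", 15 * MB, "GL", additive=2.0)
        base = SimConfig(genome=default_test_genome(), n_lines=150, qtls=[qtl], seed=6)
        sel = SimConfig(
            genome=default_test_genome(), n_lines=150, population_size=400,
            selection_threshold_sd=2.0, qtls=[qtl], seed=6,
        )
        def carrier_rate(cfg):
            ils = run_breeding_scheme(cfg, build_marker_map(cfg))
            return np.mean([il.plant.dosage_at("chr1", 15 * MB) > 0 for il in ils])
        assert carrier_rate(sel) > carrier_rate(base) + 0.1


class TestPhenotypeModel:
    def _cfg(self, **kw):
        defaults = dict(genome=default_test_genome(), seed=1)
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_no_qtl_no_noise_is_baseline_plus_env(self, rng):
        cfg = self._cfg(residual_sd=0.0)
        vals = apply_phenotype_model(None, cfg, "E2", rng)
        assert np.allclose(vals, cfg.baseline + cfg.environment_effects["E2"])

    def test_homozygous_qtl_adds_full_effect(self, rng):
        cfg = self._cfg(residual_sd=0.0, qtls=[QTLEffect("chr1", 10 * MB, "GL", additive=2.0)])
        L = float(default_test_genome().lengths["chr1"])
        plant = Plant(
            {
                "chr1": ([(L, DONOR)], [(L, DONOR)]),
                "chr2": ([(25.0 * MB, RECURRENT)], [(25.0 * MB, RECURRENT)]),
                "chr3": ([(20.0 * MB, RECURRENT)], [(20.0 * MB, RECURRENT)]),
            }
        )
        vals = apply_phenotype_model(plant, cfg, "E1", rng)
        assert np.allclose(vals, cfg.baseline + 2.0)

    def test_residual_sd_recovered(self, rng):
        cfg = self._cfg(residual_sd=0.5, n_replicates=10_000)
        plant = Plant({c: ([(float(l), RECURRENT)], [(float(l), RECURRENT)])
                       for c, l in default_test_genome().lengths.items()})
        vals = apply_phenotype_model(plant, cfg, "E1", rng)
        assert np.std(vals, ddof=1) == pytest.approx(0.5, rel=0.02)


class TestGenotyping:
    def test_error_free_calls_match_truth(self, sim_library):
        mm = sim_library["marker_map"]
        for il in sim_library["ils"][:5]:
            for marker, call in zip(mm.marker_ids, il.calls):
                chrom, pos = mm.position_of(marker)
                d = il.plant.dosage_at(chrom, float(pos))
                assert call == {0: "R", 2: "D"}.get(d, "H")

    def test_homozygous_donor_region_called_d(self):
        genome = default_test_genome()
        cfg = SimConfig(genome=genome, seed=1)
        mm = build_marker_map(cfg)
        plant = Plant({c: ([(float(l), DONOR)], [(float(l), DONOR)])
                       for c, l in genome.lengths.items()})
        calls = genotype_at_markers(plant, mm, np.random.default_rng(0))
        assert set(calls) == {"D"}

    def test_miscall_rate_calibrated(self):
        genome = default_test_genome()
        cfg = SimConfig(genome=genome, seed=1)
        mm = build_marker_map(cfg)
        plant = Plant({c: ([(float(l), RECURRENT)], [(float(l), RECURRENT)])
                       for c, l in genome.lengths.items()})
        rng = np.random.default_rng(17)
        n_calls, errors = 0, 0
        rate = 0.01
        while n_calls < 100_000:
            calls = genotype_at_markers(plant, mm, rng, error_rate=rate)
            errors += sum(c != "R" for c in calls)
            n_calls += len(calls)
        se = np.sqrt(rate * (1 - rate) / n_calls)
        assert abs(errors / n_calls - rate) <= 3 * se


class TestEndToEndRecovery:
    def test_estimated_tracks_true_proportion(self):
        """Dense-marker (1 Mb) segment estimates track the simulator's truth."""
        cfg = SimConfig(
            genome=default_test_genome(), marker_spacing_bp=MB,
            n_backcrosses=2, n_selfs=4, n_lines=120, seed=12,
        )
        mm = build_marker_map(cfg)
        ils = run_breeding_scheme(cfg, mm)
        est = np.array(
            [
                donor_proportion(
                    call_segments(dict(zip(mm.marker_ids, il.calls)), mm, cfg.genome), cfg.genome
                )
                for il in ils
            ]
        )
        true = np.array([il.true_donor_proportion for il in ils])
        assert np.corrcoef(est, true)[0, 1] >= 0.95

    def test_library_tables_consistent(self, sim_library):
        geno, phen = sim_library["genotypes"], sim_library["phenotypes"]
        cfg = sim_library["config"]
        assert len(geno.il_ids) == cfg.n_lines
        for env in cfg.environment_effects:
            stratum = phen.stratum(cfg.trait, env)
            assert (stratum["il_id"] == phen.control_id).sum() == cfg.n_control_replicates
            assert stratum["il_id"].nunique() == cfg.n_lines + 1
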