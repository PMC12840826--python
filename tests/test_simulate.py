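"""Synthetic-data generator: determinism, validity, recovery of planted truth."""

import numpy as np
import pytest

from vgsckit.errors import ConfigError
from vgsckit.gene_model import assemble_cds, translate
from vgsckit.popstats import frequency
from vgsckit.simulate import (
    HAINAN_POPULATIONS,
    SimulationConfig,
    simulate_dataset,
    simulate_gene,
    simulate_observations,
)
from vgsckit.variants import EffectClass, annotate, annotate_all, partition_effects


class TestSimulateGene:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=11)
        a, b = simulate_gene(cfg), simulate_gene(cfg)
        assert a.genomic_sequence == b.genomic_sequence and a.exons == b.exons

    def test_default_config_matches_study_totals(self):
        model = simulate_gene(SimulationConfig(seed=3))
        assert model.genomic_length == 36774
        assert model.cds_length == 6414
        assert model.intron_length == 30360

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_clean_orf(self, seed):
        model = simulate_gene(SimulationConfig(seed=seed, n_exons=5,
                                               cds_length=900,
                                               genomic_length=3000))
        model.validate()
        prot = translate(assemble_cds(model))
        assert prot.residues.startswith("M")
        assert prot.residues.endswith("*")
        assert prot.internal_stops == ()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigError):
            simulate_gene(SimulationConfig(seed=1, n_exons=100, cds_length=300,
                                           genomic_length=400))


class TestSimulateObservations:
    def test_planted_classes_recovered_by_annotation(self):
        """The annotation pipeline recovers exactly the generator's labels."""
        cfg = SimulationConfig(seed=5, n_variants=50, missing_rate=0.0)
        model, obs, truth = simulate_dataset(cfg)
        effects = annotate_all(model, obs)
        ns, s, other = partition_effects(effects)
        assert not other
        assert len(ns) == truth.n_nonsynonymous
        assert len(s) == truth.n_synonymous
        by_pos = {t.genomic_position: t for t in truth.variants}
        for eff in effects:
            assert eff.effect_class.value == by_pos[eff.genomic_position].effect_class

    def test_degenerate_full_frequency(self):
        cfg = SimulationConfig(seed=2, n_variants=10, missing_rate=0.0,
                               freq_range=(1.0, 1.0))
        _model, obs, _truth = simulate_dataset(cfg)
        for v in obs:
            for f, g in v.counts.values():
                assert f == 0 and g > 0

    def test_estimated_frequency_tracks_truth_within_binomial_error(self):
        """Mean |estimate - truth| over cells stays inside twice the average
        binomial standard error at depth 100 (seeds 1..20, 50 variants)."""
        errors, ses = [], []
        for seed in range(1, 21):
            cfg = SimulationConfig(seed=seed, n_variants=50, missing_rate=0.0,
                                   depth_range=(100, 100))
            _model, obs, truth = simulate_dataset(cfg)
            for v, t in zip(obs, truth.variants):
                for pop, (f, g) in v.counts.items():
                    p = t.true_frequencies[pop]
                    errors.append(abs(frequency(f, g) / 100 - p))
                    ses.append(np.sqrt(p * (1 - p) / 100))
        assert np.mean(errors) < 2 * np.mean(ses)

    def test_interval_coverage_calibrated(self):
        """Wilson 95% intervals on simulated counts cover the planted truth
        at the nominal rate (within 3 points) over 1000 depth-100 cells."""
        from statsmodels.stats.proportion import proportion_confint

        covered = total = 0
        seed = 0
        while total < 1000:
            seed += 1
            cfg = SimulationConfig(seed=seed, n_variants=40, missing_rate=0.0,
                                   depth_range=(100, 100))
            _model, obs, truth = simulate_dataset(cfg)
            for v, t in zip(obs, truth.variants):
                for pop, (f, g) in v.counts.items():
                    lo, hi = proportion_confint(g, f + g, alpha=0.05,
                                                method="wilson")
                    covered += lo <= t.true_frequencies[pop] <= hi
                    total += 1
        assert abs(covered / total - 0.95) < 0.03

    def test_latitude_slope_produces_southward_increase(self):
        cfg = SimulationConfig(seed=9, n_variants=20, missing_rate=0.0,
                               latitude_slope=2.5)
        _model, _obs, truth = simulate_dataset(cfg)
        south, north = HAINAN_POPULATIONS[-1].name, HAINAN_POPULATIONS[0].name
        higher_south = sum(
            t.true_frequencies[south] > t.true_frequencies[north]
            for t in truth.variants
        )
        assert higher_south == len(truth.variants)

    def test_missingness_distinct_from_zero_count(self):
        cfg = SimulationConfig(seed=4, n_variants=30, missing_rate=0.4)
        _model, obs, _truth = simulate_dataset(cfg)
        n_cells = sum(len(v.counts) for v in obs)
        assert 0 < n_cells < 30 * len(HAINAN_POPULATIONS)


class TestPaperFixtureGeneration:
    def test_fixture_deterministic(self, bundle):
        from vgsckit.fixture import paper_fixture

        again = paper_fixture()
        assert again.gene_model.genomic_sequence == bundle.gene_model.genomic_sequence
        assert [v.genomic_position for v in again.observations] == [
            v.genomic_position for v in bundle.observations
        ]

    def test_fixture_populations_north_to_south(self, bundle):
        names = [p.name for p in bundle.populations]
        lats = [p.latitude for p in bundle.populations]
        assert names == ["MY", "TS", "DA", "TY", "JY"]
        assert lats == sorted(lats, reverse=True)

    def test_fixture_q2006_jy_frequency(self, bundle, annotated):
        from vgsckit.popstats import frequency_display

        eff = next(e for e in annotated if e.codon_index == 2006)
        f, g = eff.counts["JY"]
        assert frequency_display(f, g) == "94.31"
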