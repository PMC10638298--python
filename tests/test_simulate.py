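"""Synthetic cohort generator: reference, truth mutations, call sets."""

import numpy as np
import pytest

from dhmut.errors import ConfigError, IntegrityError, SimulationError
from dhmut.io import Genotype, Role
from dhmut.simulate import (
    DEFAULT_SOMACLONAL_SPECTRUM,
    SimulationConfig,
    TruthRecord,
    TruthTable,
    generate_callsets,
    inject_mutations,
    sample_names,
    simulate,
    simulate_reference,
    write_simulation,
)
from dhmut.spectrum import SubstitutionClass


def small_config(**kwargs):
    defaults = dict(
        genome_length=200_000,
        n_chromosomes=2,
        somaclonal_rate=20.0,
        ems_rate=10.0,
        rng_seed=42,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("genome_length", 999),
            ("gc_content", 1.5),
            ("somaclonal_rate", -1.0),
            ("n_chromosomes", 0),
            ("n_treated_samples", -1),
            ("depth_dispersion", 0.0),
            ("genotype_error_rate", 2.0),
        ],
    )
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            small_config(**{field: value})

    def test_spectrum_must_sum_to_one(self):
        bad = dict(DEFAULT_SOMACLONAL_SPECTRUM)
        bad[SubstitutionClass.GC_to_AT] += 0.01
        with pytest.raises(ConfigError, match="somaclonal_spectrum"):
            small_config(somaclonal_spectrum=bad)

    def test_key_value_file_round_trip(self, tmp_path):
        cfg = small_config(gc_content=0.37, mean_depth=11.5)
        path = tmp_path / "sim.cfg"
        cfg.to_file(path)
        assert SimulationConfig.from_file(path) == cfg


class TestReference:
    def test_length_and_gc_within_binomial_3sigma(self):
        cfg = SimulationConfig(genome_length=10_000, n_chromosomes=1,
                               gc_content=0.5, rng_seed=1)
        genome = simulate_reference(cfg)
        assert genome.total_length == 10_000
        sigma = np.sqrt(0.25 / 10_000)
        assert abs(genome.gc_fraction - 0.5) < 3 * sigma

    def test_degenerate_gc_fraction_one(self):
        genome = simulate_reference(small_config(gc_content=1.0))
        assert genome.gc_fraction == 1.0

    def test_same_seed_identical_sequences(self):
        cfg = small_config()
        g1, g2 = simulate_reference(cfg), simulate_reference(cfg)
        for name in g1.chromosomes:
            assert np.array_equal(g1.chromosomes[name], g2.chromosomes[name])
        assert g1.genes == g2.genes

    def test_gene_intervals_disjoint_and_cover_target_fraction(self):
        cfg = small_config(gene_fraction=0.2)
        genome = simulate_reference(cfg)
        by_chrom = {}
        for chrom, start, end in genome.genes:
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2  # non-overlapping
        covered = sum(e - s for _, s, e in genome.genes)
        assert covered / genome.total_length == pytest.approx(0.2, rel=0.05)


class TestInjectMutations:
    def test_zero_rates_empty_truth(self):
        cfg = small_config(somaclonal_rate=0.0, ems_rate=0.0)
        truth = inject_mutations(simulate_reference(cfg), cfg)
        assert truth.records == []

    def test_degenerate_ems_spectrum_all_gc_to_at(self):
        cfg = small_config(ems_gc_to_at_fraction=1.0, somaclonal_rate=0.0, ems_rate=100.0)
        truth = inject_mutations(simulate_reference(cfg), cfg)
        ems = [r for r in truth.records if r.origin == "ems"]
        assert ems
        assert all((r.ref_base, r.mutant_base) in {("G", "A"), ("C", "T")} for r in ems)

    def test_poisson_count_within_3sigma(self):
        # 20 somaclonal/Mb on 0.2 Mb over 3 controls + 3 treated = mean 24 total
        cfg = small_config(ems_rate=0.0, rng_seed=3)
        truth = inject_mutations(simulate_reference(cfg), cfg)
        mean = 20.0 * 0.2 * 6
        assert abs(len(truth.records) - mean) < 3 * np.sqrt(mean)

    def test_roles_receive_correct_components(self):
        cfg = small_config()
        truth = inject_mutations(simulate_reference(cfg), cfg)
        by_sample = truth.by_sample()
        names = sample_names(cfg)
        for sample, role in names.items():
            origins = {r.origin for r in by_sample.get(sample, [])}
            if role is Role.PARENT_SEED:
                assert not origins
            elif role is Role.REGENERATED_CONTROL:
                assert origins <= {"somaclonal"}
        assert any(
            "ems" in {r.origin for r in by_sample.get(s, [])}
            for s, role in names.items()
            if role is Role.REGENERATED_TREATED
        )

    def test_truth_ref_matches_reference(self):
        cfg = small_config()
        genome = simulate_reference(cfg)
        truth = inject_mutations(genome, cfg)
        truth.validate_against(genome)  # raises on mismatch

    def test_infeasible_rates_rejected(self):
        cfg = small_config(somaclonal_rate=1e6, ems_rate=1e6)
        with pytest.raises(SimulationError):
            inject_mutations(simulate_reference(cfg), cfg)

    def test_realized_ems_fraction_converges(self):
        cfg = small_config(somaclonal_rate=0.0, ems_rate=300.0,
                           ems_gc_to_at_fraction=0.8, rng_seed=9)
        truth = inject_mutations(simulate_reference(cfg), cfg)
        ems = [r for r in truth.records if r.origin == "ems"]
        n = len(ems)
        frac = sum(
            1 for r in ems if (r.ref_base, r.mutant_base) in {("G", "A"), ("C", "T")}
        ) / n
        assert abs(frac - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)


class TestCallsets:
    def test_noise_free_limit_equals_truth(self):
        cfg = small_config(
            genotype_error_rate=0.0, mean_depth=50.0, depth_dispersion=1e6,
            min_depth=1, max_depth=10**6,
        )
        genome = simulate_reference(cfg)
        truth = inject_mutations(genome, cfg)
        callsets = generate_callsets(genome, truth, cfg)
        for sample, recs in truth.by_sample().items():
            got = {(c.chromosome, c.position, c.ref_allele, c.alt_alleles[0])
                   for c in callsets[sample].calls.values()}
            want = {(r.chromosome, r.position, r.ref_base, r.mutant_base) for r in recs}
            assert got == want
            assert all(
                c.genotype is Genotype.HOM_ALT for c in callsets[sample].calls.values()
            )

    def test_zero_depth_means_nothing_callable(self):
        cfg = small_config(mean_depth=0.0)
        genome = simulate_reference(cfg)
        callsets = generate_callsets(genome, inject_mutations(genome, cfg), cfg)
        assert all(cs.callable_size == 0 for cs in callsets.values())

    def test_error_site_count_poisson(self):
        cfg = small_config(somaclonal_rate=0.0, ems_rate=0.0,
                           genotype_error_rate=1e-3, rng_seed=5)
        genome = simulate_reference(cfg)
        callsets = generate_callsets(genome, TruthTable(), cfg)
        n_err = sum(len(cs) for cs in callsets.values())
        mean = 1e-3 * 200_000 * len(callsets)
        assert abs(n_err - mean) < 3 * np.sqrt(mean)

    def test_truth_genome_mismatch_is_integrity_error(self):
        cfg = small_config()
        genome = simulate_reference(cfg)
        ref = genome.base("chr1", 10)
        wrong = [b for b in "ACGT" if b != ref][0]
        other = [b for b in "ACGT" if b not in (ref, wrong)][0]
        truth = TruthTable([TruthRecord("control_1", "chr1", 10, wrong, other, "somaclonal")])
        with pytest.raises(IntegrityError):
            generate_callsets(genome, truth, cfg)


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        cfg = small_config(genotype_error_rate=1e-4)
        p1 = write_simulation(simulate(cfg), tmp_path / "a")
        p2 = write_simulation(simulate(cfg), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name
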