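"""Determinism, planted-truth fidelity and capacity limits of the generator."""

import numpy as np
import pytest

from deaminoscan import (
    SimulationConfig,
    apply_filters,
    build_context_index,
    merge_callers,
    place_variants,
    simulate_caller_outputs,
    simulate_cohort,
    simulate_reference,
    write_simulation,
)
from deaminoscan.io_formats import revcomp


class TestSimulateReference:
    def test_same_seed_identical_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=42, contig_length=5000)
        a = simulate_reference(cfg)
        b = simulate_reference(cfg)
        assert a.sequence("chrS") == b.sequence("chrS")

    def test_gc_content_within_band(self):
        cfg = SimulationConfig(seed=1, contig_length=100_000, gc_content=0.5)
        ref = simulate_reference(cfg)
        seq = ref.sequence("chrS")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError, match="contig_length"):
            simulate_reference(SimulationConfig(contig_length=999))

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError, match="gc_content"):
            simulate_reference(SimulationConfig(gc_content=1.5))

    def test_contains_cpg_sites(self, reference):
        assert "CG" in reference.sequence("chrS")


class TestPlacement:
    def test_planted_contexts_match_channels(self, reference, context_index, rng):
        counts = rng.multinomial(300, np.full(96, 1 / 96))
        records = place_variants(reference, counts, rng, "S", context_index=context_index)
        from deaminoscan import CHANNELS, classify_channel

        tally = np.zeros(96, dtype=int)
        for r in records:
            ctx = reference.sequence(r.chrom)[r.pos - 2 : r.pos + 1]
            assert ctx[1] == r.ref_allele
            tally[classify_channel(r.ref_allele, r.alt_allele, ctx)] += 1
        assert np.array_equal(tally, counts)

    def test_no_duplicate_keys_within_sample(self, reference, context_index, rng):
        counts = rng.multinomial(1500, np.full(96, 1 / 96))
        records = place_variants(reference, counts, rng, "S", context_index=context_index)
        assert len({r.key for r in records}) == len(records)

    def test_capacity_error_when_contexts_exhausted(self, rng):
        cfg = SimulationConfig(seed=3, contig_length=1000)
        ref = simulate_reference(cfg)
        counts = np.zeros(96, dtype=int)
        counts[0] = 100_000
        with pytest.raises(ValueError, match="sites with context"):
            place_variants(ref, counts, rng, "S")

    def test_context_index_matches_reference(self, reference, context_index):
        seq = reference.sequence("chrS")
        for ctx, sites in list(context_index.items())[:8]:
            for chrom, pos, strand in sites[:20]:
                tri = seq[pos - 2 : pos + 1]
                assert tri == (ctx if strand == "+" else revcomp(ctx))


class TestSimulateCohort:
    def test_zero_hypermutator_fraction(self, reference):
        cfg = SimulationConfig(seed=5, hypermutator_fraction=0.0, n_samples=8,
                               contig_length=50_000)
        _, truth = simulate_cohort(cfg, reference)
        assert truth.hypermutator_ids() == set()

    def test_truth_covers_every_variant(self, reference, sim_config):
        cohort, truth = simulate_cohort(sim_config, reference)
        for r in cohort:
            assert r.key in truth.samples[r.sample_id].channel_of_variant

    def test_same_seed_identical_output(self, reference, sim_config):
        a, _ = simulate_cohort(sim_config, reference)
        b, _ = simulate_cohort(sim_config, reference)
        assert a == b

    def test_hypermutator_counts_in_configured_range(self, reference, sim_config):
        cohort, truth = simulate_cohort(sim_config, reference)
        lo, hi = sim_config.hypermutator_count_range
        for st in truth.samples.values():
            if st.is_hypermutator:
                assert lo <= st.planted_count <= hi


class TestSimulateCallerOutputs:
    def test_union_of_callers_equals_input(self, reference, sim_config):
        cohort, _ = simulate_cohort(sim_config, reference)
        outputs, _ = simulate_caller_outputs(cohort, sim_config)
        union_keys = {
            (r.sample_id, r.key) for records in outputs.values() for r in records
        }
        assert union_keys == {(r.sample_id, r.key) for r in cohort}

    def test_zero_violation_rates_all_retained(self, reference, sim_config):
        cohort, _ = simulate_cohort(sim_config, reference)
        outputs, truth = simulate_caller_outputs(cohort, sim_config)
        assert truth.violations == {}
        by_sample = {}
        for records in outputs.values():
            for r in records:
                by_sample.setdefault(r.sample_id, {}).setdefault(
                    next(iter(r.callers)), []
                ).append(r)
        for sid, calls in by_sample.items():
            merged = merge_callers(list(calls.values()))
            retained, audit = apply_filters(merged)
            assert audit.n_rejected == 0

    def test_planted_violations_counted_exactly(self, reference):
        cfg = SimulationConfig(
            seed=19, n_samples=10, hypermutator_fraction=0.2, contig_length=50_000,
            violation_rates={"germline_depth": 0.01, "somatic_depth": 0.01,
                             "allele_depth": 0.01, "allele_fraction": 0.01,
                             "pop_freq": 0.01},
        )
        ref = simulate_reference(SimulationConfig(seed=19, contig_length=50_000))
        cohort, _ = simulate_cohort(cfg, ref)
        outputs, truth = simulate_caller_outputs(cohort, cfg)
        by_sample = {}
        for records in outputs.values():
            for r in records:
                by_sample.setdefault(r.sample_id, {}).setdefault(
                    next(iter(r.callers)), []
                ).append(r)
        totals = {}
        for sid, calls in by_sample.items():
            merged = merge_callers(list(calls.values()))
            _, audit = apply_filters(merged)
            for rule, n in audit.rule_counts.items():
                totals[rule.value] = totals.get(rule.value, 0) + n
        planted = {rule: len(v) for rule, v in truth.violations.items()}
        assert planted  # rates were non-zero
        for rule, n in planted.items():
            assert totals.get(rule, 0) == n
        for rule, n in totals.items():
            assert planted.get(rule, 0) == n


def test_write_simulation_emits_all_files(tmp_path):
    cfg = SimulationConfig(seed=13, n_samples=4, contig_length=20_000)
    paths = write_simulation(cfg, tmp_path / "sim")
    for name in ("fasta", "maf", "truth", "haplotypecaller", "mutect2", "mpileup"):
        assert paths[name].exists() and paths[name].stat().st_size > 0
    # byte-level determinism of the emitted MAF
    paths2 = write_simulation(cfg, tmp_path / "sim2")
    assert paths["maf"].read_bytes() == paths2["maf"].read_bytes()
    assert paths["fasta"].read_bytes() == paths2["fasta"].read_bytes()
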