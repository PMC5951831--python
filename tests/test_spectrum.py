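"""96-channel classification, strand collapse and the CpG>TpG statistic."""

import itertools

import numpy as np
import pytest
from scipy import stats

from deaminoscan import (
    CHANNELS,
    CPG_TPG_CHANNELS,
    MutationSpectrum,
    SimulationConfig,
    VariantRecord,
    classify_channel,
    compute_spectrum,
    cpg_tpg_stat,
    is_cpg_tpg,
    place_variants,
    simulate_cohort,
)
from deaminoscan.io_formats import ReferenceSequence, VariantClass

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def oracle_label(ref, alt, context):
    """Independent brute-force collapse: reverse-complement purine refs."""
    if ref in "AG":
        context = oracle_revcomp(context)
        ref, alt = COMP[ref], COMP[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def all_combinations():
    for five, ref, three in itertools.product(BASES, repeat=3):
        for alt in BASES:
            if alt != ref:
                yield ref, alt, five + ref + three


class TestClassifyChannel:
    def test_pyrimidine_centered_passthrough(self):
        assert CHANNELS[classify_channel("C", "T", "ACG")] == "A[C>T]G"

    def test_purine_ref_is_reverse_complemented(self):
        # G>A in CGT collapses onto ACG with C>T
        assert CHANNELS[classify_channel("G", "A", "CGT")] == "A[C>T]G"

    def test_exhaustive_against_bruteforce_oracle(self):
        # 64 contexts x 3 alternate bases = 192 valid combinations,
        # collapsing exactly 2:1 onto the 96 channels
        combos = list(all_combinations())
        assert len(combos) == 192
        for ref, alt, ctx in combos:
            assert CHANNELS[classify_channel(ref, alt, ctx)] == oracle_label(ref, alt, ctx)

    def test_strand_involution_on_all_combinations(self):
        for ref, alt, ctx in all_combinations():
            rc_ctx = oracle_revcomp(ctx)
            assert classify_channel(ref, alt, ctx) == classify_channel(
                COMP[ref], COMP[alt], rc_ctx
            )

    def test_mapping_is_a_bijection_over_collapsed_pairs(self):
        pyr = [
            (ref, alt, ctx)
            for ref, alt, ctx in all_combinations()
            if ref in "CT"
        ]
        assert len(pyr) == 96
        assert sorted(classify_channel(*c) for c in pyr) == list(range(96))

    def test_context_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="centre"):
            classify_channel("C", "T", "AAG")


class TestIsCpgTpg:
    @pytest.mark.parametrize(
        "ref, alt, ctx, expected",
        [
            ("C", "T", "TCG", True),
            ("C", "T", "TCA", False),
            ("G", "A", "CGA", True),  # minus-strand CpG
            ("C", "A", "TCG", False),  # not a transition
            ("T", "C", "ATG", False),
        ],
    )
    def test_definition(self, ref, alt, ctx, expected):
        assert is_cpg_tpg(ref, alt, ctx) is expected

    def test_cpg_channels_are_c_to_t_with_g_flank(self):
        labels = {CHANNELS[i] for i in CPG_TPG_CHANNELS}
        assert labels == {"A[C>T]G", "C[C>T]G", "G[C>T]G", "T[C>T]G"}


class TestComputeSpectrum:
    def test_empty_input_all_zero(self, reference):
        spec = compute_spectrum([], reference)
        assert spec.n_snv == 0 and spec.counts.sum() == 0

    def test_planted_cpg_variants_land_in_cpg_channels(self, reference, rng):
        counts = np.zeros(96, dtype=int)
        np.add.at(counts, rng.choice(list(CPG_TPG_CHANNELS), size=10), 1)
        records = place_variants(reference, counts, rng, "S1")
        spec = compute_spectrum(records, reference)
        assert spec.counts[list(CPG_TPG_CHANNELS)].sum() == 10
        assert spec.n_snv == 10

    def test_mixed_planted_spectrum_recovered_exactly(self, reference, rng):
        counts = rng.multinomial(500, np.full(96, 1 / 96))
        records = place_variants(reference, counts, rng, "S1")
        spec = compute_spectrum(records, reference)
        assert np.array_equal(spec.counts, counts)

    def test_non_snvs_ignored_and_tallied(self, tiny_reference):
        records = [
            VariantRecord("S", "chr1", 2, "C", "T"),
            VariantRecord("S", "chr1", 5, "A", "AT", variant_class=VariantClass.INS),
        ]
        spec = compute_spectrum(records, tiny_reference)
        assert spec.n_snv == 1 and spec.n_non_snv == 1

    def test_edge_contexts_counted_unclassifiable(self, tiny_reference):
        records = [VariantRecord("S", "chr1", 1, "A", "G")]
        spec = compute_spectrum(records, tiny_reference)
        assert spec.n_snv == 0 and spec.n_unclassifiable == 1

    def test_missing_contig_names_the_contig(self, tiny_reference):
        with pytest.raises(KeyError, match="chrX"):
            compute_spectrum([VariantRecord("S", "chrX", 5, "C", "T")], tiny_reference)

    def test_order_invariance_and_additivity(self, reference, rng):
        counts = rng.multinomial(300, np.full(96, 1 / 96))
        records = place_variants(reference, counts, rng, "S1")
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = compute_spectrum(records, reference)
        b = compute_spectrum(shuffled, reference)
        assert np.array_equal(a.counts, b.counts)
        half = len(records) // 2
        left = compute_spectrum(records[:half], reference)
        right = compute_spectrum(records[half:], reference)
        assert np.array_equal((left + right).counts, a.counts)


class TestCpgTpgStat:
    def test_uvm1_like_totals_round_to_97_percent(self, reference, rng):
        """460 of 474 SNVs at CpG -> 97% (the hypermutated TCGA UM case)."""
        counts = np.zeros(96, dtype=int)
        np.add.at(counts, rng.choice(list(CPG_TPG_CHANNELS), size=460), 1)
        non_cpg = [i for i in range(96) if i not in CPG_TPG_CHANNELS]
        np.add.at(counts, rng.choice(non_cpg, size=14), 1)
        stat = cpg_tpg_stat(MutationSpectrum(counts=counts))
        assert (stat.n_cpg_tpg, stat.n_snv) == (460, 474)
        assert round(100 * stat.fraction) == 97

    def test_zero_snvs_flagged_undefined(self):
        stat = cpg_tpg_stat(MutationSpectrum())
        assert not stat.defined and stat.fraction == 0.0

    def test_pure_t_to_a_spectrum_has_zero_fraction(self):
        counts = np.zeros(96, dtype=int)
        counts[CHANNELS.index("A[T>A]A")] = 50
        stat = cpg_tpg_stat(MutationSpectrum(counts=counts))
        assert stat.defined and stat.fraction == 0.0

    def test_simulated_fraction_within_exact_binomial_99_interval(self, reference):
        """Planted weight w: the realised fraction must sit inside the exact
        binomial 99% interval of w at the planted n."""
        w = 0.8
        cfg = SimulationConfig(
            seed=77, n_samples=1, hypermutator_fraction=1.0,
            hypermutator_count_range=(1000, 1000), hypermutator_cpg_weight=w,
        )
        cohort, _ = simulate_cohort(cfg, reference)
        spec = compute_spectrum(cohort, reference)
        stat = cpg_tpg_stat(spec)
        lo, hi = stats.binom.ppf([0.005, 0.995], stat.n_snv, w)
        assert lo <= stat.n_cpg_tpg <= hi
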