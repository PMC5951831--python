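"""Synthetic cohorts with planted CpG>TpG hypermutators, plus truth tables.

The generator emulates the study conditions under which a deamination
hypermutator stands out of a low-burden cohort: most tumors carry a
handful of SNVs (mean 15, a uveal-melanoma-like burden) with a modest
CpG>TpG share (weight 0.25), while planted hypermutators carry hundreds
to thousands of SNVs (300–1500) of which ~95% are CpG>TpG — inside the
91–97% band observed in MBD4-deficient tumors.

Placement is context-aware: each variant's 96-channel is drawn first from
the planted channel weights, then a genomic position whose reference
trinucleotide matches that channel's (strand-collapsed) context is sampled
without replacement within the sample.  CpG>TpG variants therefore sit on
actual CpG sites, on either strand, and planted spectra are exact by
construction.  Every emitted variant is recorded in a machine-readable
truth table.

Reproducibility: every operation derives its own generator from
``config.seed`` combined with a fixed per-operation stream index, so each
call is deterministic under a fixed seed regardless of call order; pass an
explicit ``rng`` to chain operations on one stream instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    FunctionalClass,
    ReferenceSequence,
    VariantClass,
    VariantRecord,
    write_fasta,
    write_json_report,
    write_maf,
    write_vcf,
)
from .lineage import SampleRole
from .spectrum import BASES, CHANNELS, PURINES, classify_channel
from .variant_filtering import FilterRule, FilterThresholds

__all__ = [
    "CountModel",
    "DepthModel",
    "SimulationConfig",
    "SampleTruth",
    "SimulationTruth",
    "CALLER_LABELS",
    "simulate_reference",
    "build_context_index",
    "place_variants",
    "simulate_cohort",
    "simulate_caller_outputs",
    "simulate_patient",
    "write_simulation",
]

CALLER_LABELS = ("haplotypecaller", "mutect2", "mpileup")

# stream indices keeping the per-operation PRNG streams disjoint
_STREAM_REFERENCE = 0
_STREAM_COHORT = 1
_STREAM_CALLERS = 2
_STREAM_PATIENT = 3


@dataclass(frozen=True)
class CountModel:
    """Per-sample background SNV-count distribution.

    ``family`` is "poisson" (dispersion ignored) or "nbinom" (gamma-Poisson
    with the given dispersion = shape parameter).
    """

    family: str = "poisson"
    mean: float = 15.0
    dispersion: float | None = None

    def draw(self, rng: np.random.Generator) -> int:
        if self.family == "poisson":
            return int(rng.poisson(self.mean))
        if self.family == "nbinom":
            if not self.dispersion or self.dispersion <= 0:
                raise ValueError("nbinom count model needs a positive dispersion")
            lam = rng.gamma(self.dispersion, self.mean / self.dispersion)
            return int(rng.poisson(lam))
        raise ValueError(f"unknown count model family {self.family!r}")


@dataclass(frozen=True)
class DepthModel:
    """Sequencing-depth emulation: germline ~30x, somatic ~100x coverage,
    allele fraction ~ Beta(af_alpha, af_beta) (mean 0.4, a clonal-ish VAF)."""

    germline_mean: float = 30.0
    somatic_mean: float = 100.0
    af_alpha: float = 8.0
    af_beta: float = 12.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study-condition defaults."""

    seed: int = 0
    n_samples: int = 20
    hypermutator_fraction: float = 0.1
    background_count_model: CountModel = field(default_factory=CountModel)
    hypermutator_count_range: tuple[int, int] = (300, 1500)
    background_cpg_weight: float = 0.25
    hypermutator_cpg_weight: float = 0.95
    contig_name: str = "chrS"
    contig_length: int = 100_000
    gc_content: float = 0.45
    depth_model: DepthModel = field(default_factory=DepthModel)
    #: fraction of records planted to violate exactly one filter rule each
    violation_rates: dict[str, float] = field(default_factory=dict)
    cohort_id: str = "SYN"
    # multi-sample (lineage) mode
    n_metastases: int = 3
    trunk_count: int = 300
    subclone_count_range: tuple[int, int] = (20, 50)
    private_count_range: tuple[int, int] = (18, 44)
    private_cpg_weight: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.hypermutator_fraction <= 1.0:
            raise ValueError("hypermutator_fraction must be in [0,1]")
        for name in ("background_cpg_weight", "hypermutator_cpg_weight", "private_cpg_weight"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        lo, hi = self.hypermutator_count_range
        if lo <= 0 or hi < lo:
            raise ValueError("hypermutator_count_range must be a positive interval")


@dataclass
class SampleTruth:
    """Planted parameters and per-variant channel labels for one sample."""

    sample_id: str
    is_hypermutator: bool
    planted_count: int
    planted_cpg_weight: float
    channel_of_variant: dict[tuple[str, int, str, str], str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, object]:
        return {
            "sample_id": self.sample_id,
            "is_hypermutator": self.is_hypermutator,
            "planted_count": self.planted_count,
            "planted_cpg_weight": self.planted_cpg_weight,
            "variants": {
                f"{c}:{p}:{r}>{a}": ch for (c, p, r, a), ch in self.channel_of_variant.items()
            },
        }


@dataclass
class SimulationTruth:
    """Machine-readable ground truth covering every emitted variant."""

    samples: dict[str, SampleTruth] = field(default_factory=dict)
    #: filter-rule name -> list of planted violating variant (sample, key)
    violations: dict[str, list[tuple[str, tuple[str, int, str, str]]]] = field(
        default_factory=dict
    )
    #: lineage topology when multi-sample mode is on
    topology: dict[str, object] = field(default_factory=dict)

    def hypermutator_ids(self) -> set[str]:
        return {s.sample_id for s in self.samples.values() if s.is_hypermutator}

    def as_dict(self) -> dict[str, object]:
        return {
            "samples": {sid: s.as_dict() for sid, s in self.samples.items()},
            "violations": {
                rule: [f"{sid}|{c}:{p}:{r}>{a}" for sid, (c, p, r, a) in entries]
                for rule, entries in self.violations.items()
            },
            "topology": self.topology,
        }


# --------------------------------------------------------------------------
# Reference simulation and context indexing
# --------------------------------------------------------------------------


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ReferenceSequence:
    """A seeded random contig with the requested GC content (within 2%)
    and a guaranteed non-zero number of CpG dinucleotides."""
    if not 0.0 < config.gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0,1), got {config.gc_content}")
    if config.contig_length < 1000:
        raise ValueError(f"contig_length must be >= 1000, got {config.contig_length}")
    rng = rng if rng is not None else np.random.default_rng([config.seed, _STREAM_REFERENCE])
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(BASES)[rng.choice(4, size=config.contig_length, p=probs)])
    if "CG" not in seq:  # vanishing probability at >=1 kb, but guaranteed by contract
        seq = seq[:500] + "CG" + seq[502:]
    return ReferenceSequence({config.contig_name: seq})


def build_context_index(reference: ReferenceSequence) -> dict[str, list[tuple[str, int, str]]]:
    """Map each collapsed (pyrimidine-centred) 3-mer to the genomic sites
    presenting it: entries are (chrom, pos, strand) with strand '-' when
    the reference centre base is a purine (context reverse-complemented)."""
    from .io_formats import revcomp

    index: dict[str, list[tuple[str, int, str]]] = {}
    for chrom in reference.contig_names:
        seq = reference.sequence(chrom)
        for pos in range(2, len(seq)):  # 1-based positions 2..len-1
            tri = seq[pos - 2 : pos + 1]
            if "N" in tri:
                continue
            if tri[1] in PURINES:
                index.setdefault(revcomp(tri), []).append((chrom, pos, "-"))
            else:
                index.setdefault(tri, []).append((chrom, pos, "+"))
    return index


_CHANNEL_CONTEXT = [f"{label[0]}{label[2]}{label[-1]}" for label in CHANNELS]  # e.g. "ACG"
_CHANNEL_ALT = [label[4] for label in CHANNELS]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def place_variants(
    reference: ReferenceSequence,
    channel_counts: np.ndarray,
    rng: np.random.Generator,
    sample_id: str,
    context_index: dict[str, list[tuple[str, int, str]]] | None = None,
    patient_id: str | None = None,
) -> list[VariantRecord]:
    """Place exact per-channel SNV counts onto matching reference contexts.

    Positions are drawn without replacement within the sample, so variant
    keys are unique.  Raises a capacity error when the reference lacks
    enough sites of a required context.
    """
    channel_counts = np.asarray(channel_counts, dtype=np.int64)
    if channel_counts.shape != (96,) or (channel_counts < 0).any():
        raise ValueError("channel_counts must be 96 non-negative integers")
    index = context_index if context_index is not None else build_context_index(reference)
    needed: dict[str, list[int]] = {}
    for ch, n in enumerate(channel_counts):
        if n > 0:
            needed.setdefault(_CHANNEL_CONTEXT[ch], []).extend([ch] * int(n))
    records: list[VariantRecord] = []
    for context, channels in sorted(needed.items()):
        pool = index.get(context, [])
        if len(channels) > len(pool):
            raise ValueError(
                f"reference has only {len(pool)} sites with context {context}, "
                f"but {len(channels)} variants were requested"
            )
        picks = rng.choice(len(pool), size=len(channels), replace=False)
        for ch, k in zip(channels, picks):
            chrom, pos, strand = pool[int(k)]
            if strand == "+":
                ref, alt = context[1], _CHANNEL_ALT[ch]
            else:
                ref, alt = _COMP[context[1]], _COMP[_CHANNEL_ALT[ch]]
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    patient_id=patient_id or sample_id,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_class=VariantClass.SNV,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt_allele))
    return records


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------


def _channel_weights(cpg_weight: float) -> np.ndarray:
    """96-channel weights: ``cpg_weight`` split over the four CpG>TpG
    channels, the remainder uniform over the other 92."""
    from .spectrum import CPG_TPG_CHANNELS

    w = np.full(96, (1.0 - cpg_weight) / 92.0)
    w[list(CPG_TPG_CHANNELS)] = cpg_weight / 4.0
    return w


def _draw_passing_depths(
    rng: np.random.Generator, model: DepthModel, thresholds: FilterThresholds
) -> tuple[int, int, int, float | None]:
    """Depths for a clean record: guaranteed to pass every filter rule."""
    gdp = max(thresholds.min_germline_depth, int(rng.poisson(model.germline_mean)))
    dp = max(thresholds.min_somatic_depth, int(rng.poisson(model.somatic_mean)))
    af = float(rng.beta(model.af_alpha, model.af_beta))
    ad = int(round(af * dp))
    floor = max(thresholds.min_allele_depth, int(np.ceil(thresholds.min_allele_fraction * dp)))
    ad = min(dp, max(floor, ad))
    pf = None if rng.random() < 0.9 else float(rng.uniform(0.0, thresholds.max_pop_freq))
    return gdp, dp, ad, pf


_FUNCTIONAL_PROBS = (
    (FunctionalClass.NONSYNONYMOUS, 0.65),
    (FunctionalClass.SYNONYMOUS, 0.25),
    (FunctionalClass.OTHER, 0.10),
)


def _draw_functional(rng: np.random.Generator) -> FunctionalClass:
    u = rng.random()
    acc = 0.0
    for cls, p in _FUNCTIONAL_PROBS:
        acc += p
        if u < acc:
            return cls
    return FunctionalClass.OTHER


def simulate_cohort(
    config: SimulationConfig,
    reference: ReferenceSequence,
    rng: np.random.Generator | None = None,
    context_index: dict[str, list[tuple[str, int, str]]] | None = None,
) -> tuple[list[VariantRecord], SimulationTruth]:
    """A cohort of samples with planted hypermutators.

    ``round(n_samples * hypermutator_fraction)`` samples (chosen at random)
    are hypermutators with counts uniform in ``hypermutator_count_range``
    and CpG>TpG weight ``hypermutator_cpg_weight``; the rest draw counts
    from the background model with weight ``background_cpg_weight``.
    Records carry filter-passing depth annotations.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, _STREAM_COHORT])
    index = context_index if context_index is not None else build_context_index(reference)
    thresholds = FilterThresholds()
    n_hyper = int(round(config.n_samples * config.hypermutator_fraction))
    hyper_idx = set(rng.choice(config.n_samples, size=n_hyper, replace=False).tolist())
    truth = SimulationTruth()
    all_records: list[VariantRecord] = []
    for i in range(config.n_samples):
        sample_id = f"{config.cohort_id}_{i:03d}"
        is_hyper = i in hyper_idx
        if is_hyper:
            lo, hi = config.hypermutator_count_range
            count = int(rng.integers(lo, hi + 1))
            weight = config.hypermutator_cpg_weight
        else:
            count = config.background_count_model.draw(rng)
            weight = config.background_cpg_weight
        channel_counts = rng.multinomial(count, _channel_weights(weight))
        records = place_variants(
            reference, channel_counts, rng, sample_id, context_index=index
        )
        st = SampleTruth(
            sample_id=sample_id,
            is_hypermutator=is_hyper,
            planted_count=count,
            planted_cpg_weight=weight,
        )
        annotated = []
        for r in records:
            gdp, dp, ad, pf = _draw_passing_depths(rng, config.depth_model, thresholds)
            r = dataclasses.replace(
                r,
                germline_depth=gdp,
                somatic_depth=dp,
                allele_depth=ad,
                pop_freq=pf,
                functional_class=_draw_functional(rng),
            )
            annotated.append(r)
            ctx = reference.sequence(r.chrom)[r.pos - 2 : r.pos + 1]
            st.channel_of_variant[r.key] = CHANNELS[
                classify_channel(r.ref_allele, r.alt_allele, ctx)
            ]
        truth.samples[sample_id] = st
        all_records.extend(annotated)
    return all_records, truth


# --------------------------------------------------------------------------
# Per-caller outputs with planted filter violations
# --------------------------------------------------------------------------

_RULE_NAMES = {
    "germline_depth": FilterRule.GERMLINE_DEPTH,
    "somatic_depth": FilterRule.SOMATIC_DEPTH,
    "allele_depth": FilterRule.ALLELE_DEPTH,
    "allele_fraction": FilterRule.ALLELE_FRACTION,
    "pop_freq": FilterRule.POP_FREQ,
}


def _violate(r: VariantRecord, rule: str, rng: np.random.Generator) -> VariantRecord:
    """Rewrite one record's annotations so it fails exactly the given rule."""
    if rule == "germline_depth":
        return dataclasses.replace(r, germline_depth=int(rng.integers(0, 10)))
    if rule == "somatic_depth":
        # DP in [6,9] with AD in [6, DP]: only the somatic-DP rule trips
        dp = int(rng.integers(6, 10))
        return dataclasses.replace(r, somatic_depth=dp, allele_depth=int(rng.integers(6, dp + 1)))
    if rule == "allele_depth":
        # AD in [1,5] with a healthy ratio: DP chosen so AD/DP >= 0.05
        ad = int(rng.integers(1, 6))
        dp = int(rng.integers(10, 20 * ad + 1))
        return dataclasses.replace(r, somatic_depth=dp, allele_depth=ad)
    if rule == "allele_fraction":
        # AD >= 6 but ratio < 0.05
        ad = int(rng.integers(6, 10))
        dp = int(rng.integers(20 * ad + 1, 40 * ad))
        return dataclasses.replace(r, somatic_depth=dp, allele_depth=ad)
    if rule == "pop_freq":
        return dataclasses.replace(r, pop_freq=float(rng.uniform(0.011, 0.5)))
    raise ValueError(f"unknown filter rule {rule!r}")


def simulate_caller_outputs(
    variants: list[VariantRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[VariantRecord]], SimulationTruth]:
    """Split variants across three synthetic callers and plant violations.

    Each variant is detected by a random non-empty subset of the three
    caller labels; all detecting callers report identical annotations, so
    the caller union reconstructs the input set exactly.  For each rule in
    ``config.violation_rates``, ``round(rate * n)`` distinct records are
    rewritten to violate exactly that rule, and recorded in the truth.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, _STREAM_CALLERS])
    truth = SimulationTruth()
    n = len(variants)
    # disjoint violation assignment: rule index per record, -1 = clean
    assignment = np.full(n, -1, dtype=np.int64)
    rules = [r for r in config.violation_rates if config.violation_rates[r] > 0]
    for rule in rules:
        if rule not in _RULE_NAMES:
            raise ValueError(f"unknown filter rule {rule!r} in violation_rates")
    order = rng.permutation(n)
    cursor = 0
    for ri, rule in enumerate(rules):
        k = int(round(config.violation_rates[rule] * n))
        if cursor + k > n:
            raise ValueError("violation rates exceed the number of records")
        assignment[order[cursor : cursor + k]] = ri
        cursor += k
    outputs: dict[str, list[VariantRecord]] = {label: [] for label in CALLER_LABELS}
    for i, r in enumerate(variants):
        if assignment[i] >= 0:
            rule = rules[assignment[i]]
            r = _violate(r, rule, rng)
            truth.violations.setdefault(rule, []).append((r.sample_id, r.key))
        subset_code = int(rng.integers(1, 2 ** len(CALLER_LABELS)))  # non-empty subset
        for b, label in enumerate(CALLER_LABELS):
            if subset_code >> b & 1:
                outputs[label].append(dataclasses.replace(r, callers=frozenset({label})))
    return outputs, truth


# --------------------------------------------------------------------------
# Multi-sample (lineage) simulation
# --------------------------------------------------------------------------


def simulate_patient(
    config: SimulationConfig,
    reference: ReferenceSequence,
    rng: np.random.Generator | None = None,
    patient_id: str = "P1",
) -> tuple[dict[str, list[VariantRecord]], dict[str, SampleRole], SimulationTruth]:
    """One patient with a primary tumor and polyphyletic metastases.

    Star topology: a clonal trunk present in every sample; per metastasis,
    a primary subclone it uniquely shares with the primary, plus private
    SNVs acquired during progression (count in ``private_count_range``,
    CpG>TpG weight ``private_cpg_weight`` — the ongoing deamination
    process).  The primary's set is trunk plus all subclones.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, _STREAM_PATIENT])
    index = build_context_index(reference)
    w_trunk = _channel_weights(config.hypermutator_cpg_weight)
    w_priv = _channel_weights(config.private_cpg_weight)

    def draw(n: int, weights: np.ndarray, sample_id: str) -> list[VariantRecord]:
        return place_variants(
            reference, rng.multinomial(n, weights), rng, sample_id,
            context_index=index, patient_id=patient_id,
        )

    primary_id = f"{patient_id}_primary"
    trunk = draw(config.trunk_count, w_trunk, primary_id)
    lo, hi = config.subclone_count_range
    plo, phi = config.private_count_range
    records: dict[str, list[VariantRecord]] = {}
    roles: dict[str, SampleRole] = {primary_id: SampleRole.PRIMARY}
    truth = SimulationTruth()
    topology: dict[str, object] = {
        "patient_id": patient_id,
        "primary": primary_id,
        "trunk_count": len(trunk),
        "metastases": {},
    }
    subclones: list[list[VariantRecord]] = []
    used_keys = {r.key for r in trunk}

    def draw_disjoint(n: int, weights: np.ndarray, sample_id: str) -> list[VariantRecord]:
        # rejection against already-used keys keeps sample key sets unique
        out: list[VariantRecord] = []
        while len(out) < n:
            for r in draw(n - len(out), weights, sample_id):
                if r.key not in used_keys:
                    used_keys.add(r.key)
                    out.append(r)
        return out

    for m in range(config.n_metastases):
        met_id = f"{patient_id}_met{m + 1}"
        sub = draw_disjoint(int(rng.integers(lo, hi + 1)), w_trunk, primary_id)
        priv = draw_disjoint(int(rng.integers(plo, phi + 1)), w_priv, met_id)
        subclones.append(sub)
        met_records = (
            [dataclasses.replace(r, sample_id=met_id) for r in trunk + sub] + priv
        )
        records[met_id] = sorted(met_records, key=lambda r: (r.chrom, r.pos, r.alt_allele))
        roles[met_id] = SampleRole.METASTASIS
        topology["metastases"][met_id] = {
            "subclone_count": len(sub),
            "private_count": len(priv),
            "private_keys": sorted(f"{c}:{p}:{rf}>{a}" for c, p, rf, a in (r.key for r in priv)),
        }
    primary_records = trunk + [r for sub in subclones for r in sub]
    records[primary_id] = sorted(primary_records, key=lambda r: (r.chrom, r.pos, r.alt_allele))
    records = {primary_id: records[primary_id], **{k: v for k, v in records.items() if k != primary_id}}
    truth.topology = topology
    return records, roles, truth


# --------------------------------------------------------------------------
# File emission
# --------------------------------------------------------------------------


def write_simulation(
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Run the full generator and emit FASTA, cohort MAF, three per-caller
    VCFs and the truth JSON into ``out_dir``.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    cohort, truth = simulate_cohort(config, reference)
    callers, call_truth = simulate_caller_outputs(cohort, config)
    paths: dict[str, Path] = {}
    paths["fasta"] = out / "reference.fa"
    write_fasta(reference, paths["fasta"])
    paths["maf"] = out / "cohort.maf"
    write_maf(cohort, paths["maf"])
    for label, recs in callers.items():
        paths[label] = out / f"calls.{label}.vcf"
        write_vcf(recs, paths[label], reference=reference)
    paths["truth"] = out / "truth.json"
    merged = truth.as_dict()
    merged["violations"] = call_truth.as_dict()["violations"]
    write_json_report(merged, paths["truth"])
    return paths
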