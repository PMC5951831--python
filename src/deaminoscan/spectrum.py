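"""96-channel trinucleotide mutation spectra with pyrimidine strand collapse.

Single-base substitutions are summarised in the standard 96-channel form:
six pyrimidine-centred substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases.  A
substitution observed on a purine reference base is reverse-complemented —
substitution and context together — before lookup, so the spectrum is
strand-agnostic.  That collapse is what makes "CpG>TpG" well defined: a
G>A preceded by C on the reference strand is the same deamination event
as a C>T followed by G, and both land in a C>T channel whose 3' flank is G.

Channel order is fixed: substitution-major in the order above, flanks
alphabetical (5' outer, 3' inner), so serialized spectra are bit-comparable.
Channel 0 is A[C>A]A, channel 95 is T[T>G]T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    ContextUnavailable,
    ReferenceSequence,
    VariantClass,
    VariantRecord,
    extract_context,
    revcomp,
)

__all__ = [
    "CHANNELS",
    "SUBSTITUTIONS",
    "CPG_TPG_CHANNELS",
    "MutationSpectrum",
    "CpGTpGStat",
    "classify_channel",
    "channel_label",
    "is_cpg_tpg",
    "compute_spectrum",
    "cpg_tpg_stat",
]

PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")
BASES = ("A", "C", "G", "T")

#: the six strand-collapsed substitution classes, in canonical order
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)

#: canonical labels for the 96 channels, e.g. "A[C>T]G"
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}

#: the four channels that constitute CpG>TpG: C>T with 3' flank G
CPG_TPG_CHANNELS: tuple[int, ...] = tuple(
    _CHANNEL_INDEX[f"{five}[C>T]G"] for five in BASES
)

#: all C>T channels (used for the screen's scatter coordinates)
C_T_CHANNELS: tuple[int, ...] = tuple(
    i for i, label in enumerate(CHANNELS) if "[C>T]" in label
)


def classify_channel(ref_allele: str, alt_allele: str, context: str) -> int:
    """Map a substitution with its trinucleotide context to a channel index.

    Parameters
    ----------
    ref_allele, alt_allele
        Single bases, ``ref != alt``.
    context
        The reference 3-mer whose centre base equals ``ref_allele``.

    Returns
    -------
    int
        Index into :data:`CHANNELS`.  Purine-reference substitutions are
        reverse-complemented (jointly with the context) before lookup.
    """
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    if context[1] != ref_allele:
        raise ValueError(
            f"context centre {context[1]!r} does not match ref allele {ref_allele!r}"
        )
    if ref_allele == alt_allele:
        raise ValueError(f"ref and alt are both {ref_allele!r}")
    for b in (ref_allele, alt_allele, *context):
        if b not in BASES:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref_allele in PURINES:
        context = revcomp(context)
        ref_allele = context[1]
        alt_allele = revcomp(alt_allele)
    return _CHANNEL_INDEX[f"{context[0]}[{ref_allele}>{alt_allele}]{context[2]}"]


def channel_label(index: int) -> str:
    return CHANNELS[index]


def is_cpg_tpg(ref_allele: str, alt_allele: str, context: str) -> bool:
    """True iff the collapsed channel is C>T at a CpG site (3' flank G).

    Covers both strands: a reference-strand C>T followed by G, and a G>A
    preceded by C (the same deamination seen on the opposite strand).
    """
    return classify_channel(ref_allele, alt_allele, context) in CPG_TPG_CHANNELS


@dataclass
class MutationSpectrum:
    """96 channel counts plus bookkeeping for a single sample.

    ``n_snv`` counts classifiable SNVs (equals ``counts.sum()``);
    ``n_unclassifiable`` counts SNVs whose context was unavailable
    (contig edge or N); ``n_non_snv`` tallies ignored indel/other records.
    """

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    n_unclassifiable: int = 0
    n_non_snv: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum needs 96 channels, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "MutationSpectrum") -> "MutationSpectrum":
        return MutationSpectrum(
            counts=self.counts + other.counts,
            n_unclassifiable=self.n_unclassifiable + other.n_unclassifiable,
            n_non_snv=self.n_non_snv + other.n_non_snv,
            sample_id=self.sample_id or other.sample_id,
        )

    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(96)
        return self.counts / total


@dataclass(frozen=True)
class CpGTpGStat:
    """CpG>TpG count, SNV denominator and their ratio for one spectrum.

    ``defined`` is False when the sample has no classifiable SNVs, in which
    case ``fraction`` is reported as 0.0 but must not be interpreted.
    """

    n_cpg_tpg: int
    n_snv: int
    fraction: float
    defined: bool


def compute_spectrum(
    variants: list[VariantRecord],
    reference: ReferenceSequence,
    sample_id: str = "",
) -> MutationSpectrum:
    """Tally one sample's SNVs into the 96 channels.

    Non-SNV records are ignored (counted in ``n_non_snv``); SNVs with
    unavailable context (edge/N) are counted in ``n_unclassifiable``.
    A variant on a contig absent from the reference is an error.
    """
    spec = MutationSpectrum(sample_id=sample_id)
    for v in variants:
        if v.variant_class is not VariantClass.SNV:
            spec.n_non_snv += 1
            continue
        if v.chrom not in reference:
            raise KeyError(f"contig {v.chrom!r} of variant {v.key} not in reference")
        try:
            context = extract_context(reference, v.chrom, v.pos)
        except ContextUnavailable:
            spec.n_unclassifiable += 1
            continue
        spec.counts[classify_channel(v.ref_allele, v.alt_allele, context)] += 1
    return spec


def cpg_tpg_stat(spectrum: MutationSpectrum) -> CpGTpGStat:
    """The CpG>TpG / SNVs ratio of a spectrum.

    The denominator is classifiable SNVs only; indels and unclassifiable
    SNVs never enter either side of the ratio.
    """
    n_snv = spectrum.n_snv
    n_cpg = int(spectrum.counts[list(CPG_TPG_CHANNELS)].sum())
    if n_snv == 0:
        return CpGTpGStat(n_cpg_tpg=0, n_snv=0, fraction=0.0, defined=False)
    return CpGTpGStat(n_cpg_tpg=n_cpg, n_snv=n_snv, fraction=n_cpg / n_snv, defined=True)
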