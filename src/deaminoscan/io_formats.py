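"""Reading and writing the formats the pipeline touches.

Somatic calls arrive either as MAF tables (TCGA/GDC style, tab-separated,
1-based inclusive coordinates) or as per-caller VCFs; the reference genome
arrives as FASTA.  Everything is normalised into :class:`VariantRecord`,
the single in-memory currency of the pipeline.  Coordinates stay 1-based
inclusive throughout (MAF/VCF native); no half-open coordinates appear
outside export boundaries.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantClass",
    "FunctionalClass",
    "VariantRecord",
    "ReferenceSequence",
    "MafColumnMap",
    "VcfFieldMap",
    "MafFormatError",
    "VcfFormatError",
    "ContextUnavailable",
    "read_maf",
    "write_maf",
    "read_vcf",
    "read_fasta",
    "write_fasta",
    "extract_context",
    "write_spectrum_tsv",
    "write_json_report",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


class VariantClass(enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    OTHER = "other"


class FunctionalClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    OTHER = "other"
    MISSING = "missing"


class MafFormatError(ValueError):
    """Raised when a MAF lacks mandatory columns or a row cannot be parsed."""


class VcfFormatError(ValueError):
    """Raised for malformed VCF input or a missing configured depth key."""


class ContextUnavailable(Exception):
    """Trinucleotide context cannot be formed (contig edge or N base)."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic call.

    ``pos`` is 1-based.  Depth fields are read counts; ``None`` means the
    source table did not annotate the field (never coerced to zero).
    ``pop_freq`` is a population allele frequency in [0, 1], ``None`` when
    the variant is absent from population databases — absent means "not
    filtered on frequency", since the filter only removes common variants.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass = VariantClass.SNV
    patient_id: str = ""
    callers: frozenset[str] = field(default_factory=frozenset)
    germline_depth: int | None = None
    somatic_depth: int | None = None
    allele_depth: int | None = None
    pop_freq: float | None = None
    functional_class: FunctionalClass = FunctionalClass.MISSING

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if (
            self.allele_depth is not None
            and self.somatic_depth is not None
            and self.allele_depth > self.somatic_depth
        ):
            raise ValueError(
                f"allele_depth ({self.allele_depth}) exceeds somatic_depth "
                f"({self.somatic_depth}) at {self.chrom}:{self.pos}"
            )
        if self.variant_class is VariantClass.SNV:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError(
                    f"SNV alleles must be single bases: {self.ref_allele}>{self.alt_allele}"
                )
            if self.ref_allele == self.alt_allele:
                raise ValueError(f"SNV ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity across samples and callers: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def with_caller(self, label: str) -> "VariantRecord":
        return replace(self, callers=self.callers | {label})


# --------------------------------------------------------------------------
# Reference sequences and trinucleotide contexts
# --------------------------------------------------------------------------


class ReferenceSequence:
    """Uppercase DNA contigs with 1-based, bounds-checked lookups.

    Thin wrapper over a plain dict so both in-memory synthetic references
    and pyfaidx-backed FASTA files present the same surface.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: str(seq).upper() for name, seq in contigs.items()}

    @property
    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._contigs[chrom]

    def base(self, chrom: str, pos: int) -> str:
        if chrom not in self._contigs:
            raise KeyError(f"contig {chrom!r} not in reference")
        seq = self._contigs[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside [1, {len(seq)}] on {chrom}")
        return seq[pos - 1]


def read_fasta(path: str | Path) -> ReferenceSequence:
    """Load a FASTA into memory (uses the .fai sidecar when pyfaidx finds one)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return ReferenceSequence({name: str(fa[name][:]) for name in fa.keys()})


def write_fasta(reference: ReferenceSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in reference.contig_names:
            fh.write(f">{name}\n")
            seq = reference.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_context(reference: ReferenceSequence, chrom: str, pos: int) -> str:
    """Uppercase 3-mer centred on ``pos`` (1-based), i.e. bases pos-1..pos+1.

    Raises :class:`ContextUnavailable` at contig edges or when any base of
    the 3-mer is N; callers exclude such records from spectra and tally them.
    """
    if chrom not in reference:
        raise KeyError(f"contig {chrom!r} not in reference")
    length = reference.length(chrom)
    if pos < 2 or pos > length - 1:
        raise ContextUnavailable(f"{chrom}:{pos} at contig edge (length {length})")
    tri = reference.sequence(chrom)[pos - 2 : pos + 1]
    if "N" in tri:
        raise ContextUnavailable(f"{chrom}:{pos} context {tri} contains N")
    return tri


# --------------------------------------------------------------------------
# MAF
# --------------------------------------------------------------------------

# GDC MAF Variant_Classification values that alter the protein sequence.
_NONSYNONYMOUS = {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Translation_Start_Site",
    "Splice_Site",
    "nonsynonymous",
}
_SYNONYMOUS = {"Silent", "synonymous"}


@dataclass(frozen=True)
class MafColumnMap:
    """Column-name policy for MAF dialects.

    Each field lists acceptable header names in priority order; the first
    one present in the file wins.  Defaults accept both the TCGA/GDC header
    and a minimal generic one.  Depth/frequency columns are optional —
    absence yields missing values on the records.
    """

    chrom: tuple[str, ...] = ("Chromosome", "chrom")
    pos: tuple[str, ...] = ("Start_Position", "Start_position", "pos")
    ref: tuple[str, ...] = ("Reference_Allele", "ref")
    alt: tuple[str, ...] = ("Tumor_Seq_Allele2", "Tumor_Seq_Allele1", "alt")
    variant_type: tuple[str, ...] = ("Variant_Type", "variant_type")
    variant_classification: tuple[str, ...] = ("Variant_Classification", "variant_classification")
    sample: tuple[str, ...] = ("Tumor_Sample_Barcode", "sample_id")
    patient: tuple[str, ...] = ("Patient_ID", "patient_id")
    somatic_depth: tuple[str, ...] = ("t_depth", "somatic_depth")
    allele_depth: tuple[str, ...] = ("t_alt_count", "allele_depth")
    germline_depth: tuple[str, ...] = ("n_depth", "germline_depth")
    pop_freq: tuple[str, ...] = ("popfreq_all", "pop_freq")
    callers: tuple[str, ...] = ("callers",)

    def resolve(self, columns: Sequence[str], name: str, required: bool) -> str | None:
        for candidate in getattr(self, name):
            if candidate in columns:
                return candidate
        if required:
            raise MafFormatError(
                f"MAF is missing a mandatory column for {name!r}; "
                f"accepted names: {', '.join(getattr(self, name))}"
            )
        return None


_MAF_TYPE_TO_CLASS = {"SNP": VariantClass.SNV, "SNV": VariantClass.SNV,
                      "INS": VariantClass.INS, "DEL": VariantClass.DEL}


def _functional_class(value: object) -> FunctionalClass:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return FunctionalClass.MISSING
    text = str(value)
    if text in _NONSYNONYMOUS:
        return FunctionalClass.NONSYNONYMOUS
    if text in _SYNONYMOUS:
        return FunctionalClass.SYNONYMOUS
    return FunctionalClass.OTHER


def _opt_int(value: object) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def read_maf(
    path: str | Path,
    column_map: MafColumnMap | None = None,
) -> list[VariantRecord]:
    """Read a MAF (tab-separated, ``#`` comments allowed) into records.

    One record per row, coordinates kept 1-based; ``variant_class`` comes
    from the Variant_Type column (SNP/SNV, INS, DEL, anything else →
    ``other``).  Missing depth/frequency columns yield ``None`` values.
    """
    cmap = column_map or MafColumnMap()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False,
                     na_values=[""])
    cols = list(df.columns)
    c_chrom = cmap.resolve(cols, "chrom", required=True)
    c_pos = cmap.resolve(cols, "pos", required=True)
    c_ref = cmap.resolve(cols, "ref", required=True)
    c_alt = cmap.resolve(cols, "alt", required=True)
    c_type = cmap.resolve(cols, "variant_type", required=True)
    c_class = cmap.resolve(cols, "variant_classification", required=True)
    c_sample = cmap.resolve(cols, "sample", required=True)
    c_patient = cmap.resolve(cols, "patient", required=False)
    c_tdp = cmap.resolve(cols, "somatic_depth", required=False)
    c_ad = cmap.resolve(cols, "allele_depth", required=False)
    c_ndp = cmap.resolve(cols, "germline_depth", required=False)
    c_pf = cmap.resolve(cols, "pop_freq", required=False)
    c_callers = cmap.resolve(cols, "callers", required=False)

    records: list[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False, name=None), start=2):  # header is line 1
        values = dict(zip(cols, row))
        try:
            pos = int(values[c_pos])
        except (TypeError, ValueError) as exc:
            raise MafFormatError(f"unparseable position {values[c_pos]!r} on line {idx}") from exc
        sample = str(values[c_sample])
        callers: frozenset[str] = frozenset()
        if c_callers is not None and not pd.isna(values[c_callers]):
            callers = frozenset(str(values[c_callers]).split(";")) - {""}
        records.append(
            VariantRecord(
                sample_id=sample,
                patient_id=str(values[c_patient]) if c_patient else sample,
                chrom=str(values[c_chrom]),
                pos=pos,
                ref_allele=str(values[c_ref]).upper(),
                alt_allele=str(values[c_alt]).upper(),
                variant_class=_MAF_TYPE_TO_CLASS.get(str(values[c_type]).upper(), VariantClass.OTHER),
                callers=callers,
                germline_depth=_opt_int(values[c_ndp]) if c_ndp else None,
                somatic_depth=_opt_int(values[c_tdp]) if c_tdp else None,
                allele_depth=_opt_int(values[c_ad]) if c_ad else None,
                pop_freq=_opt_float(values[c_pf]) if c_pf else None,
                functional_class=_functional_class(values[c_class]) if c_class else FunctionalClass.MISSING,
            )
        )
    return records


_CLASS_TO_MAF_TYPE = {VariantClass.SNV: "SNP", VariantClass.INS: "INS",
                      VariantClass.DEL: "DEL", VariantClass.OTHER: "Other"}
_FUNC_TO_MAF = {
    FunctionalClass.SYNONYMOUS: "Silent",
    FunctionalClass.NONSYNONYMOUS: "Missense_Mutation",
    FunctionalClass.OTHER: "RNA",
    FunctionalClass.MISSING: "",
}


def write_maf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a GDC-flavoured MAF (1-based inclusive coordinates)."""
    rows = []
    for r in records:
        end = r.pos if r.variant_class is not VariantClass.DEL else r.pos + len(r.ref_allele) - 1
        rows.append(
            {
                "Hugo_Symbol": ".",
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "End_Position": end,
                "Reference_Allele": r.ref_allele,
                "Tumor_Seq_Allele2": r.alt_allele,
                "Variant_Type": _CLASS_TO_MAF_TYPE[r.variant_class],
                "Variant_Classification": _FUNC_TO_MAF[r.functional_class],
                "Tumor_Sample_Barcode": r.sample_id,
                "Patient_ID": r.patient_id,
                "n_depth": "" if r.germline_depth is None else r.germline_depth,
                "t_depth": "" if r.somatic_depth is None else r.somatic_depth,
                "t_alt_count": "" if r.allele_depth is None else r.allele_depth,
                "popfreq_all": "" if r.pop_freq is None else repr(r.pop_freq),
                "callers": ";".join(sorted(r.callers)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# VCF (per-caller somatic call tables)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VcfFieldMap:
    """Where in a VCF the depth/frequency annotations live.

    All keys are INFO keys by default, matching the per-caller tables the
    synthetic generator writes; point them at other keys for real caller
    output.  A configured key absent from the header raises
    :class:`VcfFormatError` up front rather than silently yielding blanks.
    """

    somatic_depth: str = "DP"
    allele_depth: str = "AD"
    germline_depth: str = "GDP"
    pop_freq: str = "PF"


def read_vcf(
    path: str | Path,
    sample_id: str,
    caller_label: str,
    field_map: VcfFieldMap | None = None,
    patient_id: str | None = None,
) -> list[VariantRecord]:
    """Read a VCF v4.x into records, one per alternate allele.

    Biallelic SNVs map to ``variant_class=SNV``; multi-allelic sites are
    split into one record per ALT.  ``caller_label`` is stored in
    ``callers`` so downstream merging can take unions across callers.
    """
    from cyvcf2 import VCF

    fmap = field_map or VcfFieldMap()
    vcf = VCF(str(path))
    header_info = {f["ID"] for f in vcf.header_iter() if f["HeaderType"] == "INFO"}
    for key in (fmap.somatic_depth, fmap.allele_depth, fmap.germline_depth, fmap.pop_freq):
        if key not in header_info:
            raise VcfFormatError(
                f"configured depth key {key!r} not declared in VCF header of {path}"
            )
    records: list[VariantRecord] = []
    for v in vcf:
        dp = v.INFO.get(fmap.somatic_depth)
        ad = v.INFO.get(fmap.allele_depth)
        gdp = v.INFO.get(fmap.germline_depth)
        pf = v.INFO.get(fmap.pop_freq)
        for alt in v.ALT:
            ref, a = v.REF.upper(), alt.upper()
            if len(ref) == 1 and len(a) == 1 and ref != a:
                vclass = VariantClass.SNV
            elif len(ref) < len(a):
                vclass = VariantClass.INS
            elif len(ref) > len(a):
                vclass = VariantClass.DEL
            else:
                vclass = VariantClass.OTHER
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    patient_id=patient_id or sample_id,
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=ref,
                    alt_allele=a,
                    variant_class=vclass,
                    callers=frozenset({caller_label}),
                    germline_depth=None if gdp is None else int(gdp),
                    somatic_depth=None if dp is None else int(dp),
                    allele_depth=None if ad is None else int(ad),
                    pop_freq=None if pf is None else float(pf),
                )
            )
    vcf.close()
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    reference: ReferenceSequence | None = None,
    field_map: VcfFieldMap | None = None,
) -> None:
    """Write records as a plain-text VCF v4.2 with depths in INFO."""
    fmap = field_map or VcfFieldMap()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference is not None:
            for name in reference.contig_names:
                fh.write(f"##contig=<ID={name},length={reference.length(name)}>\n")
        fh.write(f'##INFO=<ID={fmap.somatic_depth},Number=1,Type=Integer,Description="Somatic read depth">\n')
        fh.write(f'##INFO=<ID={fmap.allele_depth},Number=1,Type=Integer,Description="Alternate allele read depth">\n')
        fh.write(f'##INFO=<ID={fmap.germline_depth},Number=1,Type=Integer,Description="Germline read depth">\n')
        fh.write(f'##INFO=<ID={fmap.pop_freq},Number=1,Type=Float,Description="Population allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda x: (x.chrom, x.pos, x.alt_allele)):
            info = []
            if r.somatic_depth is not None:
                info.append(f"{fmap.somatic_depth}={r.somatic_depth}")
            if r.allele_depth is not None:
                info.append(f"{fmap.allele_depth}={r.allele_depth}")
            if r.germline_depth is not None:
                info.append(f"{fmap.germline_depth}={r.germline_depth}")
            if r.pop_freq is not None:
                info.append(f"{fmap.pop_freq}={r.pop_freq:.6g}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t"
                + (";".join(info) or ".")
                + "\n"
            )


# --------------------------------------------------------------------------
# Report writers
# --------------------------------------------------------------------------


def write_spectrum_tsv(channels: Sequence[str], counts: Sequence[int], path: str | Path) -> None:
    total = int(sum(counts))
    with open(path, "w") as fh:
        fh.write("channel\tcount\tproportion\n")
        for ch, n in zip(channels, counts):
            prop = n / total if total else 0.0
            fh.write(f"{ch}\t{int(n)}\t{prop:.6f}\n")


def write_json_report(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
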