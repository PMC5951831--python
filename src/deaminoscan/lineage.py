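"""Multi-sample, per-patient analyses of variant sharing and acquisition.

Given the variant sets of a primary tumor and its metastases, these
routines compute the pairwise shared-variant matrix, check the
polyphyly-consistent sharing pattern (every metastasis shares more with
the primary than with any sibling metastasis), count and characterise
newly acquired SNVs per metastasis, and apply the cluster-retention rule
used when summarising clonal-deconvolution output (keep clusters with at
least five SNVs and a mean cancer-cell fraction of at least 10% in at
least one sample).  Clonal inference itself is out of scope; the primary
sample's variant set stands in for the inferred founding clone unless an
explicit founder set is supplied.

Variant identity is (chrom, pos, ref, alt) throughout — depth or VAF
differences between samples never affect sharing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ReferenceSequence, VariantRecord
from .spectrum import compute_spectrum, cpg_tpg_stat

__all__ = [
    "SampleRole",
    "PatientVariantSets",
    "ClonalCluster",
    "PolyphylyResult",
    "shared_matrix",
    "polyphyly_check",
    "acquired_snvs",
    "filter_clusters",
]

VariantKey = tuple[str, int, str, str]


class SampleRole(enum.Enum):
    PRIMARY = "primary"
    METASTASIS = "metastasis"


@dataclass
class PatientVariantSets:
    """Per-sample variant-key sets for one patient, with sample roles."""

    patient_id: str
    samples: list[str]
    roles: dict[str, SampleRole]
    variant_keys: dict[str, set[VariantKey]]

    def __post_init__(self) -> None:
        primaries = [s for s in self.samples if self.roles.get(s) is SampleRole.PRIMARY]
        if len(primaries) > 1:
            raise ValueError(f"patient {self.patient_id}: more than one primary sample")

    @property
    def primary(self) -> str | None:
        for s in self.samples:
            if self.roles.get(s) is SampleRole.PRIMARY:
                return s
        return None

    @classmethod
    def from_records(
        cls,
        patient_id: str,
        records_by_sample: dict[str, list[VariantRecord]],
        roles: dict[str, SampleRole],
    ) -> "PatientVariantSets":
        return cls(
            patient_id=patient_id,
            samples=list(records_by_sample),
            roles=roles,
            variant_keys={s: {r.key for r in recs} for s, recs in records_by_sample.items()},
        )


@dataclass
class ClonalCluster:
    """One SNV cluster from clonal deconvolution, with per-sample mean CCFs."""

    cluster_id: str
    variant_keys: set[VariantKey]
    mean_ccf: dict[str, float]

    def __post_init__(self) -> None:
        if not self.variant_keys:
            raise ValueError(f"cluster {self.cluster_id} is empty")
        for sample, ccf in self.mean_ccf.items():
            if not 0.0 <= ccf <= 1.0:
                raise ValueError(f"CCF {ccf} for sample {sample!r} outside [0,1]")


@dataclass(frozen=True)
class PolyphylyResult:
    """Per-metastasis outcome: consistent-with-polyphyly flag and tie flag."""

    metastasis: str
    consistent: bool
    tied: bool


def shared_matrix(sets: PatientVariantSets) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of pairwise shared variant counts.

    Entry (i, j) is ``|set_i ∩ set_j|``; the diagonal holds set sizes.
    Returns the matrix together with the sample order of its rows.
    """
    samples = sets.samples
    if len(samples) < 2:
        raise ValueError("shared_matrix needs at least two samples")
    n = len(samples)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(samples):
        mat[i, i] = len(sets.variant_keys[a])
        for j in range(i + 1, n):
            shared = len(sets.variant_keys[a] & sets.variant_keys[samples[j]])
            mat[i, j] = mat[j, i] = shared
    return mat, samples


def polyphyly_check(
    matrix: np.ndarray,
    samples: list[str],
    roles: dict[str, SampleRole],
) -> list[PolyphylyResult]:
    """Flag each metastasis as polyphyly-consistent or not.

    A metastasis is consistent iff it shares strictly more variants with
    the primary than with every other metastasis.  Ties are conservative:
    the flag is False and ``tied`` is set, so no polyphyly claim rests on
    an ambiguous count.
    """
    primaries = [s for s in samples if roles.get(s) is SampleRole.PRIMARY]
    if len(primaries) != 1:
        raise ValueError(f"polyphyly_check needs exactly one primary, got {len(primaries)}")
    p = samples.index(primaries[0])
    mets = [i for i, s in enumerate(samples) if roles.get(s) is SampleRole.METASTASIS]
    results = []
    for m in mets:
        others = [o for o in mets if o != m]
        with_primary = int(matrix[m, p])
        max_other = max((int(matrix[m, o]) for o in others), default=-1)
        tied = bool(others) and with_primary == max_other
        results.append(
            PolyphylyResult(
                metastasis=samples[m],
                consistent=with_primary > max_other,
                tied=tied,
            )
        )
    return results


def acquired_snvs(
    met_records: list[VariantRecord],
    reference_keys: set[VariantKey],
    reference: ReferenceSequence,
) -> tuple[int, float, bool]:
    """New SNVs of a metastasis relative to a reference variant set.

    Acquired variants are those absent from ``reference_keys`` (by default
    the primary sample's keys — a proxy for the inferred founding clone,
    flagged as such in report metadata).  Returns the acquired count, the
    CpG>TpG fraction of the acquired SNVs, and whether that fraction is
    defined (False when nothing was acquired).
    """
    acquired = [r for r in met_records if r.key not in reference_keys]
    spec = compute_spectrum(acquired, reference)
    stat = cpg_tpg_stat(spec)
    return len(acquired), stat.fraction, stat.defined


def filter_clusters(
    clusters: list[ClonalCluster],
    min_snvs: int = 5,
    min_ccf: float = 0.10,
) -> list[ClonalCluster]:
    """Retain clusters with >= min_snvs variants and a mean CCF >= min_ccf
    in at least one sample.  Both boundaries are inclusive ("at least")."""
    retained = []
    for c in clusters:
        if len(c.variant_keys) < min_snvs:
            continue
        if not c.mean_ccf or max(c.mean_ccf.values()) < min_ccf:
            continue
        retained.append(c)
    return retained
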