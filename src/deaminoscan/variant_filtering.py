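"""Multi-caller union merging and the somatic filter cascade.

Calls from several somatic callers are merged by taking the union on
variant identity (chrom, pos, ref, alt), then passed through a cascade of
depth / allele-fraction / population-frequency filters.  All rejection
rules are strict inequalities — a record sitting exactly at a threshold
(allele fraction 0.05, population frequency 0.01, depth 10, allele depth 6)
is retained.  An audit object counts, per rule, how many records failed it;
a record failing several rules is counted once under each.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .io_formats import VariantRecord

__all__ = [
    "FilterThresholds",
    "FilterRule",
    "FilterAudit",
    "merge_callers",
    "apply_filters",
]


class FilterRule(enum.Enum):
    GERMLINE_DEPTH = "germline_depth"
    SOMATIC_DEPTH = "somatic_depth"
    ALLELE_DEPTH = "allele_depth"
    ALLELE_FRACTION = "allele_fraction"
    POP_FREQ = "pop_freq"
    MIN_CALLERS = "min_callers"


@dataclass(frozen=True)
class FilterThresholds:
    """Rejection thresholds for somatic calls.

    A record is rejected iff any of these strict comparisons holds:
    germline depth < ``min_germline_depth``, somatic depth <
    ``min_somatic_depth``, allele depth < ``min_allele_depth``,
    allele-depth/somatic-depth ratio < ``min_allele_fraction``, or
    population frequency > ``max_pop_freq``.  ``min_callers`` defaults to 1
    (plain union of callers); raise it for intersection-style analyses.
    """

    min_germline_depth: int = 10
    min_somatic_depth: int = 10
    min_allele_depth: int = 6
    min_allele_fraction: float = 0.05
    max_pop_freq: float = 0.01
    min_callers: int = 1

    def __post_init__(self) -> None:
        for name in ("min_germline_depth", "min_somatic_depth", "min_allele_depth",
                     "min_callers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_allele_fraction", "max_pop_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterAudit:
    """Per-rule rejection counts; a record can appear under several rules."""

    n_input: int = 0
    n_retained: int = 0
    n_rejected: int = 0
    rule_counts: dict[FilterRule, int] = field(
        default_factory=lambda: {rule: 0 for rule in FilterRule}
    )

    def as_rows(self) -> list[dict[str, object]]:
        return [{"rule": rule.value, "n_failed": n} for rule, n in self.rule_counts.items()]


def merge_callers(call_sets: list[list[VariantRecord]]) -> list[VariantRecord]:
    """Union of per-caller call sets for one sample.

    Records identical on (chrom, pos, ref, alt) collapse into one record
    whose ``callers`` is the union of contributing labels.  Depths are
    resolved permissively: the (somatic_depth, allele_depth) pair of the
    caller reporting the highest somatic depth wins, germline depth and
    population frequency take the maximum and minimum non-missing values
    respectively.  Output is sorted by (chrom, pos, alt).
    """
    sample_ids = {r.sample_id for calls in call_sets for r in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"merge_callers saw multiple sample_ids: {sorted(sample_ids)}")
    merged: dict[tuple[str, int, str, str], VariantRecord] = {}
    for calls in call_sets:
        for r in calls:
            prev = merged.get(r.key)
            if prev is None:
                merged[r.key] = r
                continue
            somatic, allele = prev.somatic_depth, prev.allele_depth
            if (r.somatic_depth or -1) > (somatic if somatic is not None else -1):
                somatic, allele = r.somatic_depth, r.allele_depth
            germline = max(
                (d for d in (prev.germline_depth, r.germline_depth) if d is not None),
                default=None,
            )
            pop = min((p for p in (prev.pop_freq, r.pop_freq) if p is not None), default=None)
            merged[r.key] = replace(
                prev,
                callers=prev.callers | r.callers,
                somatic_depth=somatic,
                allele_depth=allele,
                germline_depth=germline,
                pop_freq=pop,
            )
    return sorted(merged.values(), key=lambda r: (r.chrom, r.pos, r.alt_allele))


def _failed_rules(r: VariantRecord, t: FilterThresholds) -> list[FilterRule]:
    if r.somatic_depth == 0 and (r.allele_depth or 0) > 0:
        raise ValueError(
            f"inconsistent depths at {r.chrom}:{r.pos}: somatic_depth=0 "
            f"with allele_depth={r.allele_depth}"
        )
    failed = []
    if r.germline_depth is not None and r.germline_depth < t.min_germline_depth:
        failed.append(FilterRule.GERMLINE_DEPTH)
    if r.somatic_depth is not None and r.somatic_depth < t.min_somatic_depth:
        failed.append(FilterRule.SOMATIC_DEPTH)
    if r.allele_depth is not None and r.allele_depth < t.min_allele_depth:
        failed.append(FilterRule.ALLELE_DEPTH)
    if (
        r.allele_depth is not None
        and r.somatic_depth is not None
        and r.somatic_depth > 0
        and r.allele_depth / r.somatic_depth < t.min_allele_fraction
    ):
        failed.append(FilterRule.ALLELE_FRACTION)
    if r.pop_freq is not None and r.pop_freq > t.max_pop_freq:
        failed.append(FilterRule.POP_FREQ)
    # an empty caller set means provenance was not annotated (e.g. plain MAF
    # input) — like other missing annotations it cannot fail the rule
    if r.callers and len(r.callers) < t.min_callers:
        failed.append(FilterRule.MIN_CALLERS)
    return failed


def apply_filters(
    variants: list[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], FilterAudit]:
    """Run the filter cascade; return retained records and the audit.

    Missing annotations never reject: a record without a population
    frequency (absent from population databases) or without a depth field
    simply cannot fail the corresponding rule.  ``retained + rejected``
    always equals the input size.
    """
    t = thresholds or FilterThresholds()
    audit = FilterAudit(n_input=len(variants))
    retained: list[VariantRecord] = []
    for r in variants:
        failed = _failed_rules(r, t)
        if failed:
            audit.n_rejected += 1
            for rule in failed:
                audit.rule_counts[rule] += 1
        else:
            retained.append(r)
    audit.n_retained = len(retained)
    return retained, audit
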