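"""Cohort screen for CpG>TpG-dominated hypermutators.

A tumor is a screen hit when it is simultaneously hypermutated (more than
``min_snv`` somatic SNVs, strictly) and CpG>TpG-enriched (CpG>TpG / SNVs
strictly above ``min_fraction``).  The defaults (>200 SNVs, ratio > 0.6)
are the thresholds under which loss of the MBD4 glycosylase — the repair
enzyme for T:G mismatches left by 5-methylcytosine deamination — produces
an unmistakable outlier profile.  Burden is additionally contextualised as
a fold-change of the sample's SNV count over the cohort baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from statistics import mean, median

import numpy as np

from .spectrum import C_T_CHANNELS, CPG_TPG_CHANNELS, MutationSpectrum, cpg_tpg_stat

__all__ = [
    "BaselineStatistic",
    "ScreenConfig",
    "SampleSummary",
    "CohortScreenReport",
    "summarize_sample",
    "fold_change",
    "screen_cohort",
    "carrier_rate",
]


class BaselineStatistic(enum.Enum):
    MEAN = "mean"
    MEDIAN = "median"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and baseline policy for the cohort screen.

    Both cuts are strict: a sample with exactly ``min_snv`` SNVs is not
    hypermutated and a fraction of exactly ``min_fraction`` is not
    enriched.  The fold-change baseline is the mean (or median) SNV count
    of the cohort, by default excluding the index sample so one extreme
    outlier does not inflate its own baseline.
    """

    min_snv: int = 200
    min_fraction: float = 0.6
    baseline_statistic: BaselineStatistic = BaselineStatistic.MEAN
    baseline_excludes_self: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_fraction < 1.0:
            raise ValueError(f"min_fraction must be in (0,1), got {self.min_fraction}")


@dataclass
class SampleSummary:
    """Per-sample screen result.

    ``fold_change`` is None until the cohort-level pass fills it in (it
    needs the other samples' counts).  ``cpg_fraction`` / ``other_ct_fraction``
    are the scatter coordinates used to visualise the screen: proportion of
    C>T at CpG versus proportion of C>T in all other contexts.
    """

    sample_id: str
    n_snv: int
    cpg_tpg_fraction: float
    is_hypermutated: bool
    is_enriched: bool
    is_hit: bool
    cohort_id: str = ""
    n_nonsynonymous: int | None = None
    fold_change: float | None = None
    fraction_defined: bool = True
    other_ct_fraction: float = 0.0

    def as_dict(self) -> dict[str, object]:
        return {
            "sample_id": self.sample_id,
            "cohort_id": self.cohort_id,
            "n_snv": self.n_snv,
            "n_nonsynonymous": self.n_nonsynonymous,
            "cpg_tpg_fraction": self.cpg_tpg_fraction,
            "other_ct_fraction": self.other_ct_fraction,
            "is_hypermutated": self.is_hypermutated,
            "is_enriched": self.is_enriched,
            "is_hit": self.is_hit,
            "fold_change": self.fold_change,
        }


@dataclass
class CohortScreenReport:
    """Ordered hit list plus the full per-sample table for one cohort."""

    hits: list[SampleSummary]
    samples: list[SampleSummary]
    config: ScreenConfig = field(default_factory=ScreenConfig)

    @property
    def hit_ids(self) -> list[str]:
        return [s.sample_id for s in self.hits]

    def as_dict(self) -> dict[str, object]:
        return {
            "n_samples": len(self.samples),
            "n_hits": len(self.hits),
            "hits": [s.as_dict() for s in self.hits],
            "samples": [s.as_dict() for s in self.samples],
        }


def summarize_sample(
    spectrum: MutationSpectrum,
    config: ScreenConfig | None = None,
    cohort_id: str = "",
    n_nonsynonymous: int | None = None,
) -> SampleSummary:
    """Apply the hypermutation and enrichment cuts to one sample's spectrum."""
    cfg = config or ScreenConfig()
    stat = cpg_tpg_stat(spectrum)
    n_ct = int(spectrum.counts[list(C_T_CHANNELS)].sum())
    n_ct_other = n_ct - stat.n_cpg_tpg
    hyper = stat.n_snv > cfg.min_snv
    enriched = stat.defined and stat.fraction > cfg.min_fraction
    return SampleSummary(
        sample_id=spectrum.sample_id,
        cohort_id=cohort_id,
        n_snv=stat.n_snv,
        n_nonsynonymous=n_nonsynonymous,
        cpg_tpg_fraction=stat.fraction,
        other_ct_fraction=(n_ct_other / stat.n_snv) if stat.n_snv else 0.0,
        is_hypermutated=hyper,
        is_enriched=enriched,
        is_hit=hyper and enriched,
        fraction_defined=stat.defined,
    )


def fold_change(
    sample_n_snv: int,
    cohort_counts: list[int],
    config: ScreenConfig | None = None,
) -> float | None:
    """SNV-count fold change of one sample over the cohort baseline.

    Returns None (undefined) when the baseline is zero or the cohort is
    empty; never raises a division error for that case.
    """
    cfg = config or ScreenConfig()
    if not cohort_counts:
        return None
    stat = mean if cfg.baseline_statistic is BaselineStatistic.MEAN else median
    baseline = stat(cohort_counts)
    if baseline == 0:
        return None
    return sample_n_snv / baseline


def screen_cohort(
    summaries: list[SampleSummary],
    config: ScreenConfig | None = None,
) -> CohortScreenReport:
    """Screen a cohort: fill in fold-changes, collect and order the hits.

    Hits are ordered by descending CpG>TpG fraction, ties broken by
    descending SNV count then sample id, so the report is invariant to
    input order.  Duplicate sample ids are a usage error.
    """
    cfg = config or ScreenConfig()
    ids = [s.sample_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s) in cohort: {dupes}")
    counts = {s.sample_id: s.n_snv for s in summaries}
    for s in summaries:
        if cfg.baseline_excludes_self:
            others = [n for sid, n in counts.items() if sid != s.sample_id]
        else:
            others = list(counts.values())
        fc = fold_change(s.n_snv, others, cfg)
        s.fold_change = None if fc is None else round(fc, 1)
    ordered = sorted(summaries, key=lambda s: s.sample_id)
    hits = sorted(
        (s for s in ordered if s.is_hit),
        key=lambda s: (-s.cpg_tpg_fraction, -s.n_snv, s.sample_id),
    )
    return CohortScreenReport(hits=hits, samples=ordered, config=cfg)


def carrier_rate(n_carriers: int, n_total: int) -> float:
    """Cohort carrier frequency as a percentage (e.g. 2 of 102 -> 2.0)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_carriers <= n_total:
        raise ValueError("n_carriers must be between 0 and n_total")
    return round(100.0 * n_carriers / n_total, 10)
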