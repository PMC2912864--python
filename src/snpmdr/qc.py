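"""Genotyping quality control: call rates, missingness filters,
ancestry inclusion, and duplicate-genotyping concordance."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import MISSING, Cohort
from .errors import CohortIntegrityError, NoComparableCellsError

__all__ = [
    "QcReport",
    "snp_call_rate",
    "drop_high_missingness_subjects",
    "ancestry_inclusion_filter",
    "duplicate_concordance",
    "qc_report",
]


@dataclass
class QcReport:
    call_rates: dict[str, float]
    median_call_rate: float
    removed_missingness: list[str] = field(default_factory=list)
    removed_ancestry: list[str] = field(default_factory=list)
    concordance_rate: float | None = None

    @property
    def removed_subject_ids(self) -> list[str]:
        return self.removed_missingness + self.removed_ancestry


def snp_call_rate(cohort: Cohort, rsid: str) -> float:
    """Fraction of subjects with a non-missing genotype at ``rsid``."""
    j = cohort.snp_index(rsid)
    column = cohort.genotypes[:, j]
    if len(column) == 0:
        return float("nan")
    return float((column != MISSING).sum() / len(column))


def drop_high_missingness_subjects(
    cohort: Cohort, min_missing_to_drop: int = 4
) -> tuple[Cohort, list[str]]:
    """Remove subjects missing >= ``min_missing_to_drop`` genotypes.

    Retained subjects keep their order and data unchanged.
    """
    if min_missing_to_drop < 1:
        raise ValueError("threshold must be >= 1")
    n_missing = (cohort.genotypes == MISSING).sum(axis=1)
    keep = n_missing < min_missing_to_drop
    removed = [s.id for s, k in zip(cohort.subjects, keep) if not k]
    return cohort.subset(keep), removed


def ancestry_inclusion_filter(
    cohort: Cohort, min_ancestry: float = 0.25
) -> tuple[Cohort, list[str]]:
    """Keep subjects with ancestry fraction >= ``min_ancestry`` (inclusive)."""
    ancestry = cohort.covariate_array("ancestry")
    if np.isnan(ancestry).any():
        bad = [s.id for s, a in zip(cohort.subjects, ancestry) if math.isnan(a)]
        raise CohortIntegrityError(f"missing ancestry for subjects: {bad}")
    keep = ancestry >= min_ancestry
    removed = [s.id for s, k in zip(cohort.subjects, keep) if not k]
    return cohort.subset(keep), removed


def duplicate_concordance(genotypes_a: Cohort, genotypes_b: Cohort) -> float:
    """Fraction of cells non-missing in both cohorts that carry equal codes."""
    if genotypes_a.rsids != genotypes_b.rsids:
        raise CohortIntegrityError("cohorts have different panels")
    if [s.id for s in genotypes_a.subjects] != [s.id for s in genotypes_b.subjects]:
        raise CohortIntegrityError("cohorts have different subjects")
    a, b = genotypes_a.genotypes, genotypes_b.genotypes
    comparable = (a != MISSING) & (b != MISSING)
    n = int(comparable.sum())
    if n == 0:
        raise NoComparableCellsError("no cell is non-missing in both cohorts")
    return float(((a == b) & comparable).sum() / n)


def qc_report(
    cohort: Cohort,
    min_missing_to_drop: int = 4,
    min_ancestry: float = 0.25,
    duplicate: Cohort | None = None,
) -> tuple[Cohort, QcReport]:
    """Run the full QC stage and return the filtered cohort plus a report.

    Call rates use the pre-filter denominator (all enrolled subjects).
    """
    rates = {rsid: snp_call_rate(cohort, rsid) for rsid in cohort.rsids}
    concordance = None
    if duplicate is not None:
        concordance = duplicate_concordance(cohort, duplicate)
    filtered, removed_miss = drop_high_missingness_subjects(
        cohort, min_missing_to_drop
    )
    filtered, removed_anc = ancestry_inclusion_filter(filtered, min_ancestry)
    report = QcReport(
        call_rates=rates,
        median_call_rate=float(np.median(list(rates.values()))),
        removed_missingness=removed_miss,
        removed_ancestry=removed_anc,
        concordance_rate=concordance,
    )
    return filtered, report
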