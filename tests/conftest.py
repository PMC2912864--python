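import numpy as np
import pytest

from snpmdr import Cohort, SnpDef, Subject
from snpmdr.simulate import (
    DEFAULT_CASE_COUNTS,
    DEFAULT_CONTROL_COUNTS,
    DEFAULT_PANEL,
    default_config,
)


def cohort_from_counts(
    case_counts: dict,
    control_counts: dict,
    panel=DEFAULT_PANEL,
    n_cases: int = 195,
    n_controls: int = 531,
) -> Cohort:
    """Deterministic cohort whose per-SNP genotype tallies exactly equal the
    given counts; subjects beyond a SNP's genotyped total are MISSING there.

    Genotypes are assigned in blocks per SNP independently, which is
    sufficient for all single-locus statistics.
    """
    subjects = []
    for i in range(n_cases):
        subjects.append(
            Subject(f"case_{i:04d}", "case", age=65.0, psa=7.0, ancestry=0.79)
        )
    for i in range(n_controls):
        subjects.append(
            Subject(f"ctrl_{i:04d}", "control", age=53.0, psa=1.1, ancestry=0.73)
        )
    geno = np.full((n_cases + n_controls, len(panel)), -1, dtype=np.int8)
    for j, snp in enumerate(panel):
        for offset, counts, n in (
            (0, case_counts[snp.rsid], n_cases),
            (n_cases, control_counts[snp.rsid], n_controls),
        ):
            column = []
            for code, k in enumerate(counts):
                column.extend([code] * k)
            column.extend([-1] * (n - len(column)))
            geno[offset : offset + n, j] = column
    return Cohort(list(panel), subjects, geno)


@pytest.fixture(scope="session")
def table_cohort() -> Cohort:
    """Cohort exactly reproducing the calibration genotype tallies."""
    return cohort_from_counts(DEFAULT_CASE_COUNTS, DEFAULT_CONTROL_COUNTS)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=0)


@pytest.fixture
def tiny_panel():
    return [SnpDef("rs16901979", "G", "T"), SnpDef("rs6983561", "A", "C")]


def make_cohort(statuses, genotypes, panel, **subject_kwargs):
    """Small hand-built cohort helper: genotypes is a list of per-subject
    code lists (-1 for missing)."""
    defaults = dict(age=60.0, psa=1.0, ancestry=0.8)
    defaults.update(subject_kwargs)
    subjects = [
        Subject(f"s{i}", status, **defaults) for i, status in enumerate(statuses)
    ]
    return Cohort(list(panel), subjects, np.asarray(genotypes, dtype=np.int8))
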