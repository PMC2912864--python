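"""Domain types and I/O for case-control genotype cohorts.

A :class:`Cohort` couples a SNP panel with a subject table and a
subjects x SNPs genotype matrix coded as minor-allele counts
(0 = homozygous major, 1 = heterozygous, 2 = homozygous minor,
``MISSING`` = -1).  Readers exist for a self-describing delimited
format (see :func:`read_cohort_table`) and for bi-allelic VCF
(:func:`read_vcf_cohort`).
"""
from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    CohortFormatError,
    CohortIntegrityError,
    UnknownSnpError,
)

__all__ = [
    "MISSING",
    "Genotype",
    "SnpDef",
    "Subject",
    "Cohort",
    "GenotypeCountTable",
    "count_genotypes",
    "read_cohort_table",
    "write_cohort_table",
    "read_vcf_cohort",
]

MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")
_COVARIATE_COLUMNS = ("subject_id", "status", "age", "psa", "ancestry")


class Genotype(IntEnum):
    """Minor-allele count coding for a bi-allelic genotype."""

    HOM_MAJOR = 0
    HET = 1
    HOM_MINOR = 2
    MISSING = MISSING


@dataclass(frozen=True)
class SnpDef:
    """A bi-allelic SNP: rsid plus its major and minor alleles."""

    rsid: str
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if not self.rsid:
            raise CohortIntegrityError("rsid must be nonempty")
        for allele in (self.major_allele, self.minor_allele):
            if allele not in _NUCLEOTIDES:
                raise CohortIntegrityError(
                    f"{self.rsid}: allele {allele!r} is not a single nucleotide"
                )
        if self.major_allele == self.minor_allele:
            raise CohortIntegrityError(
                f"{self.rsid}: major and minor alleles must differ"
            )

    def code_for_pair(self, pair: str) -> int:
        """Map an unordered two-letter allele pair ('GT', 'TG', ...) to 0/1/2."""
        if len(pair) != 2:
            raise CohortFormatError(
                f"{self.rsid}: genotype cell {pair!r} is not a two-allele pair"
            )
        code = 0
        for allele in pair.upper():
            if allele == self.minor_allele:
                code += 1
            elif allele != self.major_allele:
                raise CohortFormatError(
                    f"{self.rsid}: unknown allele {allele!r} in cell {pair!r} "
                    f"(expected {self.major_allele} or {self.minor_allele})"
                )
        return code

    def pair_for_code(self, code: int) -> str:
        return {
            0: self.major_allele * 2,
            1: self.major_allele + self.minor_allele,
            2: self.minor_allele * 2,
        }[int(code)]


@dataclass
class Subject:
    """One study participant. Missing covariates are NaN."""

    id: str
    status: str  # "case" | "control"
    age: float = math.nan
    psa: float = math.nan
    ancestry: float = math.nan

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise CohortFormatError(
                f"subject {self.id!r}: status {self.status!r} not in {{case, control}}"
            )
        if not math.isnan(self.ancestry) and not 0.0 <= self.ancestry <= 1.0:
            raise CohortIntegrityError(
                f"subject {self.id!r}: ancestry {self.ancestry} outside [0, 1]"
            )

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class Cohort:
    """A SNP panel, a subject list, and the genotype matrix tying them together.

    ``genotypes[i, j]`` is subject i's code at panel SNP j (int8; -1 missing).
    """

    panel: list[SnpDef]
    subjects: list[Subject]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.subjects), len(self.panel)):
            raise CohortIntegrityError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.panel)} SNPs"
            )
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortIntegrityError(f"duplicate subject ids: {dupes}")
        rsids = [s.rsid for s in self.panel]
        if len(set(rsids)) != len(rsids):
            raise CohortIntegrityError("duplicate rsids in panel")
        bad = (self.genotypes < MISSING) | (self.genotypes > 2)
        if bad.any():
            raise CohortIntegrityError("genotype codes must be in {-1, 0, 1, 2}")

    # -- accessors -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.panel]

    def snp_index(self, rsid: str) -> int:
        for j, snp in enumerate(self.panel):
            if snp.rsid == rsid:
                return j
        raise UnknownSnpError(rsid)

    def snp(self, rsid: str) -> SnpDef:
        return self.panel[self.snp_index(rsid)]

    def status_array(self) -> np.ndarray:
        """int8 vector: 1 for cases, 0 for controls."""
        return np.fromiter(
            (1 if s.is_case else 0 for s in self.subjects),
            dtype=np.int8,
            count=self.n_subjects,
        )

    def covariate_array(self, name: str) -> np.ndarray:
        if name not in ("age", "psa", "ancestry"):
            raise KeyError(name)
        return np.array([getattr(s, name) for s in self.subjects], dtype=float)

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "Cohort":
        keep = np.asarray(keep, dtype=bool)
        subjects = [s for s, k in zip(self.subjects, keep) if k]
        return Cohort(list(self.panel), subjects, self.genotypes[keep])

    def validate(self) -> None:
        """Check subject-level invariants that readers should enforce."""
        for s in self.subjects:
            if not s.is_case and not math.isnan(s.psa) and s.psa > 4.0:
                raise CohortIntegrityError(
                    f"control {s.id!r} has PSA {s.psa} > 4.0 ng/ml"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.panel == other.panel
            and len(self.subjects) == len(other.subjects)
            and all(
                a.id == b.id
                and a.status == b.status
                and _float_eq(a.age, b.age)
                and _float_eq(a.psa, b.psa)
                and _float_eq(a.ancestry, b.ancestry)
                for a, b in zip(self.subjects, other.subjects)
            )
            and np.array_equal(self.genotypes, other.genotypes)
        )


def _float_eq(a: float, b: float) -> bool:
    return (math.isnan(a) and math.isnan(b)) or a == b


@dataclass
class GenotypeCountTable:
    """2 x 3 genotype counts for one SNP: row 0 = cases, row 1 = controls."""

    snp: SnpDef
    counts: np.ndarray  # shape (2, 3), nonnegative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 3):
            raise CohortIntegrityError(
                f"count table must be 2x3, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise CohortIntegrityError("negative genotype count")

    @property
    def cases(self) -> np.ndarray:
        return self.counts[0]

    @property
    def controls(self) -> np.ndarray:
        return self.counts[1]

    @property
    def n_cases(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_controls(self) -> int:
        return int(self.counts[1].sum())

    def carrier_counts(self) -> tuple[int, int]:
        """(case carriers, control carriers): subjects with >= 1 minor allele."""
        return int(self.counts[0, 1:].sum()), int(self.counts[1, 1:].sum())


def count_genotypes(
    cohort: Cohort, rsid: str, subset: str | None = None
) -> GenotypeCountTable:
    """Tally non-missing genotypes at ``rsid``, partitioned by status.

    ``subset`` restricts counting to one status ("case" or "control");
    the other row is then all zeros.
    """
    j = cohort.snp_index(rsid)
    column = cohort.genotypes[:, j]
    status = cohort.status_array()
    counts = np.zeros((2, 3), dtype=np.int64)
    for row, is_case in ((0, 1), (1, 0)):
        if subset is not None and subset != ("case" if is_case else "control"):
            continue
        sel = (status == is_case) & (column >= 0)
        counts[row] = np.bincount(column[sel], minlength=3)[:3]
    return GenotypeCountTable(cohort.panel[j], counts)


# ----------------------------------------------------------------------
# Delimited-table I/O
#
# The format is a TSV with optional "##snp=<rsid>:<major>><minor>" header
# lines carrying the panel definition, then a header row
# "subject_id status age psa ancestry <rsid>...".  Genotype cells are
# allele pairs ("GT"), codes (0/1/2), or the missing token.
# ----------------------------------------------------------------------

_SNP_META_PREFIX = "##snp="


def write_cohort_table(
    cohort: Cohort,
    path: str | Path,
    delimiter: str = "\t",
    missing_token: str = "NA",
    genotype_format: str = "code",
) -> None:
    """Write a cohort as delimited text (round-trips via :func:`read_cohort_table`).

    ``genotype_format`` is "code" (0/1/2) or "alleles" (e.g. "GT").
    Floats are written with 17 significant digits so round-trips are exact.
    """
    if genotype_format not in ("code", "alleles"):
        raise ValueError(f"unknown genotype_format {genotype_format!r}")
    path = Path(path)
    with path.open("w", newline="") as fh:
        for snp in cohort.panel:
            fh.write(
                f"{_SNP_META_PREFIX}{snp.rsid}:{snp.major_allele}>{snp.minor_allele}\n"
            )
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(list(_COVARIATE_COLUMNS) + cohort.rsids)
        for i, subj in enumerate(cohort.subjects):
            row = [
                subj.id,
                subj.status,
                _fmt_float(subj.age, missing_token),
                _fmt_float(subj.psa, missing_token),
                _fmt_float(subj.ancestry, missing_token),
            ]
            for j, snp in enumerate(cohort.panel):
                code = int(cohort.genotypes[i, j])
                if code == MISSING:
                    row.append(missing_token)
                elif genotype_format == "code":
                    row.append(str(code))
                else:
                    row.append(snp.pair_for_code(code))
            writer.writerow(row)


def _fmt_float(value: float, missing_token: str) -> str:
    if math.isnan(value):
        return missing_token
    return format(value, ".17g")


def read_cohort_table(
    path: str | Path,
    panel: Sequence[SnpDef] | None = None,
    delimiter: str = "\t",
    missing_token: str = "NA",
) -> Cohort:
    """Parse a delimited cohort table.

    The panel comes from ``##snp=`` metadata lines if present, else from
    the ``panel`` argument.  Allele-pair cells are decoded against the
    panel's major/minor alleles irrespective of within-cell order.
    """
    path = Path(path)
    meta_panel: list[SnpDef] = []
    with path.open(newline="") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("##"):
            if line.startswith(_SNP_META_PREFIX):
                body = line[len(_SNP_META_PREFIX):].strip()
                try:
                    rsid, alleles = body.split(":")
                    major, minor = alleles.split(">")
                except ValueError as exc:
                    raise CohortFormatError(
                        f"{path}: malformed SNP metadata line {line!r}"
                    ) from exc
                meta_panel.append(SnpDef(rsid, major, minor))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file") from None
        rows = list(reader)

    if tuple(header[: len(_COVARIATE_COLUMNS)]) != _COVARIATE_COLUMNS:
        raise CohortFormatError(
            f"{path}: header must start with {' '.join(_COVARIATE_COLUMNS)}"
        )
    rsids = header[len(_COVARIATE_COLUMNS):]
    snp_by_rsid: dict[str, SnpDef] = {}
    if meta_panel:
        snp_by_rsid = {s.rsid: s for s in meta_panel}
    elif panel is not None:
        snp_by_rsid = {s.rsid: s for s in panel}
    resolved_panel: list[SnpDef] = []
    for rsid in rsids:
        if rsid in snp_by_rsid:
            resolved_panel.append(snp_by_rsid[rsid])
        else:
            # Alleles unknown: placeholder definition; allele-pair cells
            # for this SNP will be rejected below.
            resolved_panel.append(SnpDef(rsid, "A", "C"))
            snp_by_rsid[rsid] = resolved_panel[-1]
    have_alleles = {s.rsid for s in meta_panel} | (
        {s.rsid for s in panel} if panel else set()
    )

    subjects: list[Subject] = []
    genotypes = np.full((len(rows), len(resolved_panel)), MISSING, dtype=np.int8)
    for i, row in enumerate(rows, start=1):
        if len(row) != len(header):
            raise CohortFormatError(
                f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
            )
        sid, status = row[0], row[1]
        try:
            subject = Subject(
                id=sid,
                status=status,
                age=_parse_float(row[2], missing_token),
                psa=_parse_float(row[3], missing_token),
                ancestry=_parse_float(row[4], missing_token),
            )
        except CohortFormatError as exc:
            raise CohortFormatError(f"{path}: row {i}: {exc}") from None
        subjects.append(subject)
        for j, rsid in enumerate(rsids):
            cell = row[len(_COVARIATE_COLUMNS) + j].strip()
            if cell == missing_token or cell == "":
                continue
            if cell in ("0", "1", "2"):
                genotypes[i - 1, j] = int(cell)
            else:
                if rsid not in have_alleles:
                    raise CohortFormatError(
                        f"{path}: row {i}, column {rsid}: allele-pair cell "
                        f"{cell!r} but no allele definition for this SNP"
                    )
                try:
                    genotypes[i - 1, j] = snp_by_rsid[rsid].code_for_pair(cell)
                except CohortFormatError as exc:
                    raise CohortFormatError(
                        f"{path}: row {i}, column {rsid}: {exc}"
                    ) from None

    cohort = Cohort(resolved_panel, subjects, genotypes)
    cohort.validate()
    return cohort


def _parse_float(cell: str, missing_token: str) -> float:
    cell = cell.strip()
    if cell == missing_token or cell == "":
        return math.nan
    try:
        return float(cell)
    except ValueError as exc:
        raise CohortFormatError(f"cannot parse number {cell!r}") from exc


# ----------------------------------------------------------------------
# VCF input (read-only, bi-allelic sites, GT subfield only)
# ----------------------------------------------------------------------


def read_vcf_cohort(
    vcf_path: str | Path,
    status_map: Mapping[str, str],
    panel: Sequence[SnpDef],
    covariates: Mapping[str, Mapping[str, float]] | None = None,
) -> Cohort:
    """Build a cohort from a VCF's GT fields.

    Sites are matched to the panel by ID (rsid).  Diploid GT values are
    coded by counting minor alleles; "./." maps to MISSING.  Multi-allelic
    records are rejected.  Panel SNPs absent from the VCF yield a warning
    and an all-MISSING column.  Every VCF sample must appear in
    ``status_map``; ``covariates`` optionally supplies per-subject
    age/psa/ancestry.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in status_map]
    if missing_samples:
        raise CohortIntegrityError(
            f"samples absent from status map: {missing_samples}"
        )

    panel = list(panel)
    index = {snp.rsid: j for j, snp in enumerate(panel)}
    genotypes = np.full((len(samples), len(panel)), MISSING, dtype=np.int8)
    seen: set[str] = set()

    for variant in vcf:
        rsid = variant.ID
        if rsid not in index:
            continue
        if len(variant.ALT) != 1:
            raise CohortFormatError(
                f"{rsid}: multi-allelic records are not supported"
            )
        j = index[rsid]
        snp = panel[j]
        alleles = {variant.REF.upper(), variant.ALT[0].upper()}
        if alleles != {snp.major_allele, snp.minor_allele}:
            raise CohortFormatError(
                f"{rsid}: VCF alleles {sorted(alleles)} do not match panel "
                f"({snp.major_allele}/{snp.minor_allele})"
            )
        minor_is_alt = variant.ALT[0].upper() == snp.minor_allele
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue  # stays MISSING
            alt_count = int(a != 0) + int(b != 0)
            genotypes[i, j] = alt_count if minor_is_alt else 2 - alt_count
        seen.add(rsid)

    for snp in panel:
        if snp.rsid not in seen:
            warnings.warn(
                f"panel SNP {snp.rsid} not found in VCF; column set to MISSING",
                stacklevel=2,
            )

    covariates = covariates or {}
    subjects = []
    for sid in samples:
        cov = covariates.get(sid, {})
        subjects.append(
            Subject(
                id=sid,
                status=status_map[sid],
                age=float(cov.get("age", math.nan)),
                psa=float(cov.get("psa", math.nan)),
                ancestry=float(cov.get("ancestry", math.nan)),
            )
        )
    cohort = Cohort(panel, subjects, genotypes)
    cohort.validate()
    return cohort
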