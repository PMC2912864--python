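"""End-to-end orchestration: simulate/load -> QC -> association -> MDR,
with deterministic TSV report writers."""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats as sps

from . import __version__
from .cohort import Cohort, read_cohort_table, write_cohort_table
from .errors import ConfigError
from .mdr import MDRResult, run_mdr
from .qc import QcReport, qc_report
from .simulate import SimConfig, default_config, simulate_cohort
from .stats import AssociationResult, CovariateSpec, analyze_all_snps

logger = logging.getLogger("snpmdr")

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "StatusSummary",
    "CohortSummary",
    "summarize_cohort",
    "run_full_pipeline",
    "write_association_tsv",
    "write_mdr_tsv",
    "write_summary_tsv",
    "write_qc_tsv",
]


@dataclass
class StatusSummary:
    n: int
    age_median: float
    age_range: tuple[float, float]
    psa_median: float
    psa_range: tuple[float, float]
    psa_strata: tuple[int, int, int]  # < 2.0 | 2.0-4.0 | > 4.0
    ancestry_median: float
    ancestry_range: tuple[float, float]


@dataclass
class CohortSummary:
    case: StatusSummary
    control: StatusSummary
    p_age: float
    p_psa: float
    p_ancestry: float


def _status_summary(cohort: Cohort, status: str) -> StatusSummary:
    keep = np.array([s.status == status for s in cohort.subjects])
    sub = cohort.subset(keep)
    age = sub.covariate_array("age")
    psa = sub.covariate_array("psa")
    ancestry = sub.covariate_array("ancestry")
    psa_ok = psa[~np.isnan(psa)]
    age_ok = age[~np.isnan(age)]
    anc_ok = ancestry[~np.isnan(ancestry)]
    strata = (
        int((psa_ok < 2.0).sum()),
        int(((psa_ok >= 2.0) & (psa_ok <= 4.0)).sum()),
        int((psa_ok > 4.0).sum()),
    )

    def med_range(x: np.ndarray) -> tuple[float, tuple[float, float]]:
        if len(x) == 0:
            return math.nan, (math.nan, math.nan)
        return float(np.median(x)), (float(x.min()), float(x.max()))

    age_m, age_r = med_range(age_ok)
    psa_m, psa_r = med_range(psa_ok)
    anc_m, anc_r = med_range(anc_ok)
    return StatusSummary(
        n=int(keep.sum()),
        age_median=age_m,
        age_range=age_r,
        psa_median=psa_m,
        psa_range=psa_r,
        psa_strata=strata,
        ancestry_median=anc_m,
        ancestry_range=anc_r,
    )


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Per-status medians/ranges, PSA strata, and rank-sum p-values."""
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    case = _status_summary(cohort, "case")
    control = _status_summary(cohort, "control")

    def ranksum_p(name: str) -> float:
        status = cohort.status_array()
        x = cohort.covariate_array(name)
        a = x[(status == 1) & ~np.isnan(x)]
        b = x[(status == 0) & ~np.isnan(x)]
        if len(a) == 0 or len(b) == 0:
            return math.nan
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    return CohortSummary(
        case=case,
        control=control,
        p_age=ranksum_p("age"),
        p_psa=ranksum_p("psa"),
        p_ancestry=ranksum_p("ancestry"),
    )


@dataclass
class PipelineConfig:
    """One input source (file path or simulation config) plus stage knobs."""

    input_path: str | None = None
    sim: SimConfig | None = None
    min_missing_to_drop: int = 4
    min_ancestry: float = 0.25
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    mdr_max_order: int = 1
    mdr_k: int = 10
    mdr_B: int = 1000
    outdir: str = "snpmdr_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ConfigError(
                "exactly one of input_path and sim must be provided"
            )

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "sim": self.sim.to_dict() if self.sim else None,
            "min_missing_to_drop": self.min_missing_to_drop,
            "min_ancestry": self.min_ancestry,
            "covariates": {
                "names": list(self.covariates.names),
                "genotype_coding": self.covariates.genotype_coding,
            },
            "mdr_max_order": self.mdr_max_order,
            "mdr_k": self.mdr_k,
            "mdr_B": self.mdr_B,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.get("sim")
        cov = data.get("covariates") or {}
        kwargs = dict(
            input_path=data.get("input_path"),
            sim=SimConfig.from_dict(sim) if sim else None,
            min_missing_to_drop=int(data.get("min_missing_to_drop", 4)),
            min_ancestry=float(data.get("min_ancestry", 0.25)),
            covariates=CovariateSpec(
                names=tuple(cov.get("names", ("age", "ancestry"))),
                genotype_coding=cov.get("genotype_coding", "indicator"),
            ),
            mdr_max_order=int(data.get("mdr_max_order", 1)),
            mdr_k=int(data.get("mdr_k", 10)),
            mdr_B=int(data.get("mdr_B", 1000)),
            outdir=data.get("outdir", "snpmdr_out"),
            seed=int(data.get("seed", 0)),
            log_level=data.get("log_level", "INFO"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class StudyReport:
    summary: CohortSummary
    qc: QcReport
    association: list[AssociationResult]
    mdr: MDRResult
    provenance: dict


# -- report writers (deterministic formatting) --------------------------


def _fmt(x: float | None, nd: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "---"
    return f"{x:.{nd}f}"


def write_summary_tsv(summary: CohortSummary, path) -> None:
    rows = []
    for label, s in (("case", summary.case), ("control", summary.control)):
        rows.append(
            [
                label,
                str(s.n),
                _fmt(s.age_median, 1),
                f"{_fmt(s.age_range[0], 1)}-{_fmt(s.age_range[1], 1)}",
                _fmt(s.psa_median, 2),
                f"{_fmt(s.psa_range[0], 2)}-{_fmt(s.psa_range[1], 2)}",
                str(s.psa_strata[0]),
                str(s.psa_strata[1]),
                str(s.psa_strata[2]),
                _fmt(s.ancestry_median, 3),
                f"{_fmt(s.ancestry_range[0], 3)}-{_fmt(s.ancestry_range[1], 3)}",
            ]
        )
    with open(path, "w") as fh:
        fh.write(
            "status\tn\tage_median\tage_range\tpsa_median\tpsa_range\t"
            "psa_lt2\tpsa_2to4\tpsa_gt4\tancestry_median\tancestry_range\n"
        )
        for row in rows:
            fh.write("\t".join(row) + "\n")
        fh.write(
            f"# rank-sum p: age={_fmt(summary.p_age, 4)} "
            f"psa={_fmt(summary.p_psa, 4)} ancestry={_fmt(summary.p_ancestry, 4)}\n"
        )


def write_qc_tsv(report: QcReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tcall_rate\n")
        for rsid, rate in report.call_rates.items():
            fh.write(f"{rsid}\t{rate:.6f}\n")
        fh.write(f"# median_call_rate\t{report.median_call_rate:.6f}\n")
        fh.write(f"# removed_missingness\t{','.join(report.removed_missingness) or '-'}\n")
        fh.write(f"# removed_ancestry\t{','.join(report.removed_ancestry) or '-'}\n")
        if report.concordance_rate is not None:
            fh.write(f"# concordance_rate\t{report.concordance_rate:.6f}\n")


_CONTRAST_ORDER = ("het_vs_ref", "hom_vs_ref", "dominant", "collapsed")


def write_association_tsv(results: Sequence[AssociationResult], path) -> None:
    """Association-table analog: one row per contrast, ORs/CIs to 2 dp,
    p-values to 4 dp."""
    with open(path, "w") as fh:
        fh.write(
            "rsid\tcontrast\tcases_exposed\tcases_ref\tcontrols_exposed\t"
            "controls_ref\tor_crude\tci_crude\tp_crude\tor_adj\tci_adj\t"
            "p_homogeneity\tp_trend\n"
        )
        for res in results:
            for name in _CONTRAST_ORDER:
                if name not in res.contrasts:
                    continue
                cres = res.contrasts[name]
                a, b, c, d = cres.counts
                adj_or = _fmt(cres.adjusted.oddsratio, 2) if cres.adjusted else "---"
                adj_ci = (
                    f"{cres.adjusted.ci_low:.2f}-{cres.adjusted.ci_high:.2f}"
                    if cres.adjusted
                    else "---"
                )
                fh.write(
                    f"{res.rsid}\t{name}\t{a}\t{b}\t{c}\t{d}\t"
                    f"{cres.crude.oddsratio:.2f}\t"
                    f"{cres.crude.ci_low:.2f}-{cres.crude.ci_high:.2f}\t"
                    f"{cres.crude.p_value:.4f}\t{adj_or}\t{adj_ci}\t"
                    f"{_fmt(res.p_homogeneity, 4)}\t{_fmt(res.p_trend, 4)}\n"
                )


def write_mdr_tsv(result: MDRResult, path, null_path=None) -> None:
    """MDR-table analog: model, CVC as 'w/k', ATA, permutation p."""
    with open(path, "w") as fh:
        fh.write("model\tcvc\tata\tpermutation_p\tpermutation_p_cvc\tbest\n")
        for cand in result.candidates:
            is_best = cand.loci == result.best.loci
            p = _fmt(result.permutation_p, 4) if is_best else "---"
            p_cvc = _fmt(result.permutation_p_cvc, 4) if is_best else "---"
            fh.write(
                f"{','.join(cand.loci)}\t{cand.cvc}/{result.k}\t"
                f"{cand.ata:.3f}\t{p}\t{p_cvc}\t{int(is_best)}\n"
            )
    if null_path is not None and result.null_ata is not None:
        with open(null_path, "w") as fh:
            fh.write("null_ata\tnull_cvc\n")
            for ata, cvc in zip(result.null_ata, result.null_cvc):
                fh.write(f"{ata:.6f}\t{cvc}\n")


def run_full_pipeline(config: PipelineConfig) -> StudyReport:
    """Run simulate/load -> QC -> association -> MDR and write all artifacts."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim = config.sim
        cohort = simulate_cohort(sim)
        write_cohort_table(cohort, outdir / "cohort.tsv")
        logger.info("simulate: %d subjects generated", cohort.n_subjects)
    else:
        cohort = read_cohort_table(config.input_path)
        logger.info("load: %d subjects read", cohort.n_subjects)

    filtered, qc = qc_report(
        cohort,
        min_missing_to_drop=config.min_missing_to_drop,
        min_ancestry=config.min_ancestry,
    )
    logger.info(
        "qc: %d subjects in, %d removed, %d out",
        cohort.n_subjects,
        len(qc.removed_subject_ids),
        filtered.n_subjects,
    )
    write_qc_tsv(qc, outdir / "qc.tsv")

    summary = summarize_cohort(filtered)
    write_summary_tsv(summary, outdir / "summary.tsv")

    association = analyze_all_snps(filtered, spec=config.covariates)
    write_association_tsv(association, outdir / "association.tsv")
    logger.info("assoc: %d SNPs analyzed", len(association))

    mdr = run_mdr(
        filtered,
        max_order=config.mdr_max_order,
        k=config.mdr_k,
        B=config.mdr_B,
        seed=config.seed,
    )
    write_mdr_tsv(mdr, outdir / "mdr.tsv", null_path=outdir / "mdr_null.tsv")
    logger.info(
        "mdr: best model %s (cvc %d/%d, ata %.3f)",
        ",".join(mdr.best.loci),
        mdr.best.cvc,
        mdr.k,
        mdr.best.ata,
    )

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "subjects_in": cohort.n_subjects,
        "subjects_analyzed": filtered.n_subjects,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return StudyReport(
        summary=summary,
        qc=qc,
        association=association,
        mdr=mdr,
        provenance=provenance,
    )
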