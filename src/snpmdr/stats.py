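"""Single-SNP association statistics.

Implements the contingency-table toolkit for a 2 (status) x 3 (genotype)
table — cross-product odds ratios with Woolf confidence intervals,
Pearson chi-square homogeneity, the Cochran-Armitage trend test — plus
covariate-adjusted logistic regression fitted by IRLS, and a driver that
applies the study's contrast plan across a whole panel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import MISSING, Cohort, GenotypeCountTable, count_genotypes
from .errors import (
    DegenerateTableError,
    SeparationError,
    UndefinedOddsRatioError,
)

__all__ = [
    "Contrast",
    "HET_VS_REF",
    "HOM_VS_REF",
    "DOMINANT",
    "COLLAPSED",
    "OddsRatioResult",
    "ContrastResult",
    "AssociationResult",
    "CovariateSpec",
    "odds_ratio_2x2",
    "chi_square_homogeneity",
    "cochran_armitage_trend",
    "genotype_association",
    "logistic_fit",
    "LogisticFit",
    "analyze_all_snps",
]

_Z95 = sps.norm.ppf(0.975)  # 1.959963984540054


@dataclass(frozen=True)
class Contrast:
    """A 2x2 collapsing of the genotype axis: exposed codes vs code 0."""

    name: str
    exposed_codes: frozenset[int]

    def __post_init__(self) -> None:
        if not self.exposed_codes or not self.exposed_codes <= {1, 2}:
            raise ValueError("exposed_codes must be a nonempty subset of {1, 2}")


HET_VS_REF = Contrast("het_vs_ref", frozenset({1}))
HOM_VS_REF = Contrast("hom_vs_ref", frozenset({2}))
DOMINANT = Contrast("dominant", frozenset({1, 2}))
#: For rare SNPs reported only with carriers pooled: same 2x2 as the
#: dominant model, but the SNP's homogeneity test also runs on the
#: collapsed 2x2 and no trend test is reported.
COLLAPSED = Contrast("collapsed", frozenset({1, 2}))


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float  # two-sided Wald on ln(OR)


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf (log) 95% CI.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.  If any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe).  Two zero cells sharing a row or column leave the
    OR undefined.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise UndefinedOddsRatioError(
            f"table ({a}, {b}, {c}, {d}) has an empty row or column"
        )
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oratio)
    z = log_or / se
    return OddsRatioResult(
        oddsratio=oratio,
        ci_low=math.exp(log_or - _Z95 * se),
        ci_high=math.exp(log_or + _Z95 * se),
        p_value=2.0 * sps.norm.sf(abs(z)),
    )


def chi_square_homogeneity(
    table: GenotypeCountTable | np.ndarray, collapse_exposed: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the genotype table.

    With ``collapse_exposed`` the 2x3 is first pooled into 2x2
    (codes 1+2 vs 0).  Returns (statistic, df, p).
    """
    counts = table.counts if isinstance(table, GenotypeCountTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    if collapse_exposed:
        counts = np.column_stack([counts[:, 0], counts[:, 1:].sum(axis=1)])
    # drop all-zero genotype columns (absent classes carry no information)
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin in contingency table")
    stat, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def cochran_armitage_trend(
    table: GenotypeCountTable | np.ndarray,
    scores: Sequence[float] = (0.0, 1.0, 2.0),
) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    The statistic is the 1-df score test of the ordinal genotype coding in
    a logistic model (no continuity correction); z is signed so positive
    values mean risk rises with the minor-allele count.  Returns (z, p)
    with a two-sided normal p-value.
    """
    counts = table.counts if isinstance(table, GenotypeCountTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 2 or counts.shape[1] != len(scores):
        raise DegenerateTableError("trend test needs a 2 x len(scores) table")
    s = np.asarray(scores, dtype=float)
    cases = counts[0]
    totals = counts.sum(axis=0)
    n = totals.sum()
    r = cases.sum()
    if n <= 0 or r <= 0 or r >= n:
        raise DegenerateTableError("trend test needs both statuses present")
    mean_s = (s * totals).sum() / n
    u = (s * cases).sum() - r * mean_s
    var = (r / n) * (1 - r / n) * ((s**2 * totals).sum() - n * mean_s**2)
    if var <= 0:
        raise DegenerateTableError("degenerate score variance (single genotype class)")
    z = u / math.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


@dataclass
class ContrastResult:
    contrast: Contrast
    counts: tuple[int, int, int, int]  # exposed cases, ref cases, exposed controls, ref controls
    crude: OddsRatioResult
    adjusted: OddsRatioResult | None = None


@dataclass
class AssociationResult:
    rsid: str
    table: GenotypeCountTable
    contrasts: dict[str, ContrastResult]
    p_homogeneity: float
    p_trend: float | None  # None for collapsed-only SNPs


@dataclass(frozen=True)
class CovariateSpec:
    """Covariates and genotype coding for the adjusted logistic models."""

    names: tuple[str, ...] = ("age", "ancestry")
    genotype_coding: str = "indicator"  # "indicator" | "ordinal"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        bad = set(self.names) - {"age", "psa", "ancestry"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")
        if self.genotype_coding not in ("indicator", "ordinal"):
            raise ValueError("genotype_coding must be 'indicator' or 'ordinal'")


def _contrast_cells(
    table: GenotypeCountTable, contrast: Contrast
) -> tuple[int, int, int, int]:
    exposed = sorted(contrast.exposed_codes)
    a = int(table.cases[exposed].sum())
    b = int(table.cases[0])
    c = int(table.controls[exposed].sum())
    d = int(table.controls[0])
    return a, b, c, d


def genotype_association(
    table: GenotypeCountTable,
    contrasts: Iterable[Contrast] = (HET_VS_REF, HOM_VS_REF, DOMINANT),
) -> AssociationResult:
    """Crude association analysis of one SNP from its count table."""
    if table.n_cases == 0 or table.n_controls == 0:
        raise DegenerateTableError("need at least one case and one control")
    contrasts = list(contrasts)
    collapsed_only = all(c.name == "collapsed" for c in contrasts)
    results: dict[str, ContrastResult] = {}
    for contrast in contrasts:
        cells = _contrast_cells(table, contrast)
        results[contrast.name] = ContrastResult(
            contrast=contrast, counts=cells, crude=odds_ratio_2x2(*cells)
        )
    _, _, p_hom = chi_square_homogeneity(table, collapse_exposed=collapsed_only)
    p_trend = None
    if not collapsed_only:
        _, p_trend = cochran_armitage_trend(table)
    return AssociationResult(
        rsid=table.snp.rsid,
        table=table,
        contrasts=results,
        p_homogeneity=p_hom,
        p_trend=p_trend,
    )


# ----------------------------------------------------------------------
# Logistic regression (IRLS)
# ----------------------------------------------------------------------


@dataclass
class LogisticFit:
    terms: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_obs: int
    n_iter: int

    def odds_ratio(self, term: str) -> OddsRatioResult:
        i = self.terms.index(term)
        b = float(self.coef[i])
        se = float(math.sqrt(self.cov[i, i]))
        return OddsRatioResult(
            oddsratio=math.exp(b),
            ci_low=math.exp(b - _Z95 * se),
            ci_high=math.exp(b + _Z95 * se),
            p_value=2.0 * sps.norm.sf(abs(b / se)),
        )


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100):
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares; converges when the relative log-likelihood change
    drops below ``tol``."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -math.inf
    for iteration in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            raise SeparationError("all fitted probabilities degenerate")
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        eta_new = np.clip(X @ beta, -30, 30)
        ll = float(np.sum(y * eta_new - np.log1p(np.exp(eta_new))))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            mu = 1.0 / (1.0 + np.exp(-eta_new))
            w = mu * (1.0 - mu)
            info = X.T @ (X * w[:, None])
            return beta, np.linalg.inv(info), ll, iteration
        ll_old = ll
    raise SeparationError(
        "IRLS did not converge in "
        f"{max_iter} iterations (possible separation; |beta|max={np.abs(beta).max():.2f})"
    )


def logistic_fit(
    cohort: Cohort,
    rsid: str,
    covariates: CovariateSpec = CovariateSpec(),
    contrast: Contrast | None = None,
) -> LogisticFit:
    """Fit case/control status on genotype terms plus covariates.

    Genotype terms follow ``covariates.genotype_coding``: "indicator"
    yields het and hom indicator columns (or, if ``contrast`` is given, a
    single pooled-exposure indicator), "ordinal" a single 0/1/2 column.
    Complete-case analysis on genotype and requested covariates.
    """
    j = cohort.snp_index(rsid)
    geno = cohort.genotypes[:, j].astype(float)
    y = cohort.status_array().astype(float)
    keep = geno != MISSING
    columns: list[np.ndarray] = []
    terms: list[str] = ["intercept"]
    if contrast is not None:
        exposed = np.isin(geno, sorted(contrast.exposed_codes)).astype(float)
        columns.append(exposed)
        terms.append(contrast.name)
    elif covariates.genotype_coding == "ordinal":
        columns.append(geno)
        terms.append("genotype_ordinal")
    else:
        columns.append((geno == 1).astype(float))
        columns.append((geno == 2).astype(float))
        terms.extend(["het_vs_ref", "hom_vs_ref"])
    for name in covariates.names:
        values = cohort.covariate_array(name)
        keep &= ~np.isnan(values)
        columns.append(values)
        terms.append(name)
    X = np.column_stack([np.ones(len(y))] + columns)[keep]
    y = y[keep]
    if len(y) < X.shape[1] + 1:
        raise DegenerateTableError(
            f"{rsid}: {len(y)} complete cases for {X.shape[1]} parameters"
        )
    beta, cov, ll, n_iter = _irls(X, y)
    return LogisticFit(
        terms=tuple(terms), coef=beta, cov=cov, loglik=ll, n_obs=len(y), n_iter=n_iter
    )


# ----------------------------------------------------------------------
# Whole-panel driver
# ----------------------------------------------------------------------

#: SNPs analyzed with carriers pooled because the minor allele is rare.
DEFAULT_COLLAPSE_RSIDS = ("rs11934905",)


def analyze_all_snps(
    cohort: Cohort,
    spec: CovariateSpec = CovariateSpec(),
    collapse_rsids: Sequence[str] = DEFAULT_COLLAPSE_RSIDS,
    adjusted: bool = True,
) -> list[AssociationResult]:
    """Apply the contrast plan to every panel SNP, in panel order.

    Six-of-seven SNPs get codominant (het, hom) plus dominant contrasts
    with a trend test; collapse_rsids get the pooled-carrier contrast only
    and no trend.  Adjusted ORs come from per-contrast logistic fits with
    the requested covariates.
    """
    results = []
    for rsid in cohort.rsids:
        table = count_genotypes(cohort, rsid)
        if rsid in collapse_rsids:
            contrasts: tuple[Contrast, ...] = (COLLAPSED,)
        else:
            contrasts = (HET_VS_REF, HOM_VS_REF, DOMINANT)
        result = genotype_association(table, contrasts)
        if adjusted:
            # het and hom adjusted ORs come from one codominant model with
            # both indicator terms; pooled contrasts get their own fit.
            try:
                codominant = None
                if not all(c.name == "collapsed" for c in contrasts):
                    codominant = logistic_fit(cohort, rsid, covariates=spec)
                for cres in result.contrasts.values():
                    if codominant is not None and cres.contrast.name in (
                        "het_vs_ref",
                        "hom_vs_ref",
                    ):
                        cres.adjusted = codominant.odds_ratio(cres.contrast.name)
                    else:
                        fit = logistic_fit(
                            cohort, rsid, covariates=spec, contrast=cres.contrast
                        )
                        cres.adjusted = fit.odds_ratio(cres.contrast.name)
            except SeparationError:
                pass  # adjusted ORs stay None for this SNP
        results.append(result)
    return results
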