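"""Synthetic case-control cohort generation.

The default configuration targets a cohort of 195 cases / 531
controls over seven 8q24 SNPs, with status-conditional genotype
frequencies, per-SNP call rates, and age / PSA / West African ancestry
distributions taken from the bundled calibration tables below.
Genotypes are drawn independently per SNP (no LD) and missingness is
MCAR at the per-SNP call rate.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import beta as _beta_dist
from scipy.optimize import brentq

from .cohort import MISSING, Cohort, SnpDef, Subject
from .errors import ConfigError

__all__ = [
    "DistSpec",
    "SimConfig",
    "default_config",
    "simulate_cohort",
    "plant_single_locus_effect",
    "DEFAULT_PANEL",
    "DEFAULT_CASE_COUNTS",
    "DEFAULT_CONTROL_COUNTS",
]

# Calibration counts for the default configuration: per-SNP genotype
# tallies (code 0/1/2) by status.  The rare-variant SNP rs11934905 is
# tallied with carriers pooled into the heterozygote class (the expected
# homozygote count at this allele frequency is ~0).
DEFAULT_PANEL: tuple[SnpDef, ...] = (
    SnpDef("rs6983561", "A", "C"),
    SnpDef("rs1447295", "G", "T"),
    SnpDef("rs4242384", "A", "C"),
    SnpDef("rs4242382", "G", "A"),
    SnpDef("rs11934905", "G", "A"),
    SnpDef("rs16901979", "G", "T"),
    SnpDef("rs10090154", "G", "A"),
)

DEFAULT_CASE_COUNTS: dict[str, tuple[int, int, int]] = {
    "rs6983561": (48, 88, 50),
    "rs1447295": (86, 77, 26),
    "rs4242384": (122, 65, 6),
    "rs4242382": (85, 80, 28),
    "rs11934905": (173, 10, 0),
    "rs16901979": (45, 97, 50),
    "rs10090154": (124, 59, 6),
}

DEFAULT_CONTROL_COUNTS: dict[str, tuple[int, int, int]] = {
    "rs6983561": (171, 232, 105),
    "rs1447295": (237, 221, 65),
    "rs4242384": (383, 120, 21),
    "rs4242382": (244, 191, 72),
    "rs11934905": (500, 21, 0),
    "rs16901979": (188, 237, 87),
    "rs10090154": (357, 131, 17),
}

_DEFAULT_N_CASES = 195
_DEFAULT_N_CONTROLS = 531


@dataclass(frozen=True)
class DistSpec:
    """A bounded distribution matched to (min, max, median).

    Values are drawn as ``low + (high - low) * Beta(a, b)`` with the Beta
    shapes solved so the median hits ``median`` at total concentration
    ``concentration``; with ``log10=True`` the Beta acts on the log10
    scale between the bounds (for heavy-tailed supports).
    """

    low: float
    high: float
    median: float
    log10: bool = False
    concentration: float = 6.0

    def __post_init__(self) -> None:
        if not self.low < self.median < self.high:
            raise ConfigError(
                f"median {self.median} must lie strictly inside "
                f"({self.low}, {self.high})"
            )
        if self.log10 and self.low <= 0:
            raise ConfigError("log10 spec requires a positive lower bound")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")

    def _bounds(self) -> tuple[float, float, float]:
        if self.log10:
            return (
                math.log10(self.low),
                math.log10(self.high),
                math.log10(self.median),
            )
        return self.low, self.high, self.median

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi, med = self._bounds()
        m01 = (med - lo) / (hi - lo)
        a, b = _beta_shapes_for_median(m01, self.concentration)
        x = lo + (hi - lo) * rng.beta(a, b, size=n)
        return 10.0 ** x if self.log10 else x


@functools.lru_cache(maxsize=None)
def _beta_shapes_for_median(median01: float, concentration: float) -> tuple[float, float]:
    """Solve Beta(a, c-a) shapes so the median equals ``median01``."""

    def f(a: float) -> float:
        return _beta_dist.ppf(0.5, a, concentration - a) - median01

    eps = 1e-9
    a = brentq(f, eps, concentration - eps, xtol=1e-12)
    return a, concentration - a


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort."""

    n_cases: int
    n_controls: int
    panel: tuple[SnpDef, ...]
    # rsid -> (2, 3) simplex rows; row 0 = cases, row 1 = controls
    genotype_probs: dict[str, np.ndarray]
    call_rates: dict[str, float]
    ancestry: dict[str, DistSpec]  # keyed by status
    age: dict[str, DistSpec]
    psa: dict[str, DistSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("subject counts must be positive")
        self.panel = tuple(self.panel)
        rsids = {s.rsid for s in self.panel}
        for mapping, label in (
            (self.genotype_probs, "genotype_probs"),
            (self.call_rates, "call_rates"),
        ):
            if set(mapping) != rsids:
                raise ConfigError(f"{label} keys must match the panel rsids")
        for rsid, rows in self.genotype_probs.items():
            rows = np.asarray(rows, dtype=float)
            if rows.shape != (2, 3):
                raise ConfigError(f"{rsid}: genotype probabilities must be 2x3")
            if (rows < 0).any():
                raise ConfigError(f"{rsid}: negative genotype probability")
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
                raise ConfigError(f"{rsid}: probability rows must sum to 1")
            self.genotype_probs[rsid] = rows
        for rsid, rate in self.call_rates.items():
            if not 0.0 < rate <= 1.0:
                raise ConfigError(f"{rsid}: call rate {rate} outside (0, 1]")
        for spec in self.ancestry.values():
            if spec.low < 0 or spec.high > 1:
                raise ConfigError("ancestry support must lie within [0, 1]")
        for mapping in (self.ancestry, self.age, self.psa):
            if set(mapping) != {"case", "control"}:
                raise ConfigError("covariate specs must be keyed by status")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def spec_dict(s: DistSpec) -> dict:
            return {
                "low": s.low,
                "high": s.high,
                "median": s.median,
                "log10": s.log10,
                "concentration": s.concentration,
            }

        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "panel": [
                {"rsid": s.rsid, "major": s.major_allele, "minor": s.minor_allele}
                for s in self.panel
            ],
            "genotype_probs": {
                rsid: [[float(p) for p in row] for row in rows]
                for rsid, rows in self.genotype_probs.items()
            },
            "call_rates": {r: float(v) for r, v in self.call_rates.items()},
            "ancestry": {k: spec_dict(v) for k, v in self.ancestry.items()},
            "age": {k: spec_dict(v) for k, v in self.age.items()},
            "psa": {k: spec_dict(v) for k, v in self.psa.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        def spec(d: Mapping) -> DistSpec:
            return DistSpec(
                low=float(d["low"]),
                high=float(d["high"]),
                median=float(d["median"]),
                log10=bool(d.get("log10", False)),
                concentration=float(d.get("concentration", 6.0)),
            )

        panel = tuple(
            SnpDef(p["rsid"], p["major"], p["minor"]) for p in data["panel"]
        )
        return cls(
            n_cases=int(data["n_cases"]),
            n_controls=int(data["n_controls"]),
            panel=panel,
            genotype_probs={
                rsid: np.asarray(rows, dtype=float)
                for rsid, rows in data["genotype_probs"].items()
            },
            call_rates={r: float(v) for r, v in data["call_rates"].items()},
            ancestry={k: spec(v) for k, v in data["ancestry"].items()},
            age={k: spec(v) for k, v in data["age"].items()},
            psa={k: spec(v) for k, v in data["psa"].items()},
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0) -> SimConfig:
    """The study-calibrated configuration.

    Genotype probability rows are the per-genotype counts normalized
    within status; call rates are the per-SNP genotyped totals over the
    number of analyzed subjects (726); covariates match the published
    medians and ranges (controls' PSA support is capped at 3.9 ng/ml;
    case PSA is drawn on the log scale to span 0.01-5000).
    """
    n_total = _DEFAULT_N_CASES + _DEFAULT_N_CONTROLS
    probs: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    for snp in DEFAULT_PANEL:
        case = np.asarray(DEFAULT_CASE_COUNTS[snp.rsid], dtype=float)
        ctrl = np.asarray(DEFAULT_CONTROL_COUNTS[snp.rsid], dtype=float)
        probs[snp.rsid] = np.vstack([case / case.sum(), ctrl / ctrl.sum()])
        rates[snp.rsid] = float((case.sum() + ctrl.sum()) / n_total)
    return SimConfig(
        n_cases=_DEFAULT_N_CASES,
        n_controls=_DEFAULT_N_CONTROLS,
        panel=DEFAULT_PANEL,
        genotype_probs=probs,
        call_rates=rates,
        ancestry={
            "case": DistSpec(0.253, 0.937, 0.788),
            "control": DistSpec(0.255, 0.946, 0.734),
        },
        age={
            "case": DistSpec(41.0, 91.0, 65.0),
            "control": DistSpec(45.0, 89.0, 53.0),
        },
        psa={
            "case": DistSpec(0.01, 5000.0, 7.0, log10=True),
            "control": DistSpec(0.01, 3.9, 1.08),
        },
        seed=seed,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort from ``config``; a pure function of the config (incl. seed).

    Per subject and SNP the genotype is a status-conditional trinomial
    draw; each call then fails independently (MCAR) with probability
    ``1 - call_rate``.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    blocks: list[np.ndarray] = []
    for status, n, tag in (
        ("case", config.n_cases, "case"),
        ("control", config.n_controls, "control"),
    ):
        ages = config.age[status].draw(rng, n)
        psas = config.psa[status].draw(rng, n)
        ancestries = config.ancestry[status].draw(rng, n)
        row_idx = 0 if status == "case" else 1
        geno = np.empty((n, len(config.panel)), dtype=np.int8)
        for j, snp in enumerate(config.panel):
            p = config.genotype_probs[snp.rsid][row_idx]
            cum = np.cumsum(p)
            cum[-1] = 1.0  # guard against fp undershoot
            geno[:, j] = np.searchsorted(cum, rng.random(n), side="right")
            fail = rng.random(n) >= config.call_rates[snp.rsid]
            geno[fail, j] = MISSING
        blocks.append(geno)
        width = len(str(n))
        for i in range(n):
            subjects.append(
                Subject(
                    id=f"{tag}_{i + 1:0{width}d}",
                    status=status,
                    age=float(ages[i]),
                    psa=float(psas[i]),
                    ancestry=float(ancestries[i]),
                )
            )
    return Cohort(list(config.panel), subjects, np.vstack(blocks))


def plant_single_locus_effect(
    config: SimConfig,
    rsid: str,
    genotype_odds_ratios: tuple[float, float],
    baseline_case_fraction: float = 0.25,
) -> SimConfig:
    """Re-derive a SNP's case genotype row from per-genotype odds ratios.

    Under a logistic disease model with odds ratios ``(or_het, or_hom)``
    against code 0 and control genotype frequencies held fixed, the
    case-conditional frequencies are proportional to ``control_freq * OR``
    (the baseline case fraction cancels from the conditional rows).  The
    crude ORs implied by expected counts then equal the requested ORs
    exactly.
    """
    if rsid not in config.genotype_probs:
        raise ConfigError(f"{rsid} not in config panel")
    or_het, or_hom = genotype_odds_ratios
    if not (or_het > 0 and or_hom > 0 and math.isfinite(or_het) and math.isfinite(or_hom)):
        raise ConfigError("genotype odds ratios must be finite and positive")
    if not 0.0 < baseline_case_fraction < 1.0:
        raise ConfigError("baseline case fraction must lie in (0, 1)")
    rows = config.genotype_probs[rsid]
    control = rows[1]
    weights = control * np.array([1.0, or_het, or_hom])
    case = weights / weights.sum()
    new_probs = dict(config.genotype_probs)
    new_probs[rsid] = np.vstack([case, control])
    return replace(config, genotype_probs=new_probs)
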