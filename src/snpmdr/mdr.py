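"""Multifactor dimensionality reduction (MDR).

MDR collapses the multilocus genotype space into one dimension: every
genotype cell whose training case:control ratio reaches a threshold T
(the training set's overall case:control ratio) is labeled high-risk,
the rest low-risk, and the resulting binary classifier is scored by
balanced accuracy under stratified k-fold cross-validation.  The model
search is exhaustive over all locus subsets up to ``max_order``; the best
model maximizes cross-validation consistency (CVC), then average testing
accuracy (ATA).  Significance comes from label-permutation testing in
which the entire search is repeated on each shuffled dataset.

Missing genotypes are handled per candidate: a subject is dropped only
for candidates that involve one of its missing loci, so denominators
match the per-SNP complete-case counts.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import MISSING, Cohort
from .errors import EvaluationError

__all__ = [
    "RiskLabeling",
    "MDRCandidate",
    "MDRResult",
    "assign_risk_labels",
    "balanced_accuracy",
    "cross_validate",
    "select_best_model",
    "permutation_test",
    "run_mdr",
]

HIGH = "high"
LOW = "low"


@dataclass
class RiskLabeling:
    """High/low labels over the genotype cells of a locus subset.

    ``cell_labels`` maps genotype-code tuples to "high"/"low"; cells not
    in the map (never observed when the labeling was built) default to
    low risk.
    """

    loci: tuple[str, ...]
    threshold: float
    cell_labels: dict[tuple[int, ...], str]

    def label(self, cell: tuple[int, ...]) -> str:
        return self.cell_labels.get(cell, LOW)


@dataclass
class MDRCandidate:
    """One locus subset with its cross-validation record."""

    loci: tuple[str, ...]
    training_accuracy: tuple[float, ...]
    testing_accuracy: tuple[float, ...]
    fold_winner: tuple[bool, ...]
    cvc: int
    ata: float


@dataclass
class MDRResult:
    best: MDRCandidate
    candidates: list[MDRCandidate]
    permutation_p: float | None
    null_ata: np.ndarray | None
    permutation_p_cvc: float | None
    null_cvc: np.ndarray | None
    B: int
    k: int
    seed: int


def assign_risk_labels(
    cell_counts: Mapping[tuple[int, ...], tuple[int, int]],
    threshold: float,
    loci: Sequence[str] = (),
) -> RiskLabeling:
    """Label each genotype cell from its (case count, control count).

    A cell is high-risk iff case/control >= threshold (inclusive); a cell
    with zero controls but at least one case is high; empty cells and
    cells with zero cases are low.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels: dict[tuple[int, ...], str] = {}
    for cell, (n_case, n_ctrl) in cell_counts.items():
        if n_case == 0:
            labels[cell] = LOW
        elif n_ctrl == 0:
            labels[cell] = HIGH
        else:
            labels[cell] = HIGH if n_case / n_ctrl >= threshold else LOW
    return RiskLabeling(
        loci=tuple(loci), threshold=float(threshold), cell_labels=labels
    )


def _cells_for(cohort: Cohort, loci: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(cell index per subject, validity mask) for a locus subset.

    Cells are mixed-radix base-3 codes over the loci; subjects missing
    any involved genotype are invalid.
    """
    idx = [cohort.snp_index(r) for r in loci]
    sub = cohort.genotypes[:, idx].astype(np.int64)
    valid = (sub != MISSING).all(axis=1)
    cells = np.zeros(len(sub), dtype=np.int64)
    for col in range(sub.shape[1]):
        cells = cells * 3 + np.where(valid, sub[:, col], 0)
    cells[~valid] = -1
    return cells, valid


def _cell_tuple(cell: int, order: int) -> tuple[int, ...]:
    out = []
    for _ in range(order):
        out.append(cell % 3)
        cell //= 3
    return tuple(reversed(out))


def balanced_accuracy(labeling: RiskLabeling, cohort: Cohort) -> float:
    """(sensitivity + specificity) / 2 of the labeling on a cohort.

    Prediction is high -> case, low -> control; subjects missing any
    involved genotype are excluded.
    """
    cells, valid = _cells_for(cohort, labeling.loci)
    status = cohort.status_array()
    order = len(labeling.loci)
    predicted_high = np.array(
        [
            valid[i] and labeling.label(_cell_tuple(int(cells[i]), order)) == HIGH
            for i in range(len(cells))
        ]
    )
    case_mask = valid & (status == 1)
    ctrl_mask = valid & (status == 0)
    n_case, n_ctrl = int(case_mask.sum()), int(ctrl_mask.sum())
    if n_case == 0 or n_ctrl == 0:
        raise EvaluationError("no evaluable case or control subjects")
    sens = predicted_high[case_mask].sum() / n_case
    spec = (~predicted_high[ctrl_mask]).sum() / n_ctrl
    return float((sens + spec) / 2.0)


# ----------------------------------------------------------------------
# Fast cross-validation core (array-based; reused across permutations)
# ----------------------------------------------------------------------


class _Engine:
    """Precomputed per-candidate cell codes for repeated CV runs."""

    def __init__(self, cohort: Cohort, candidates: Sequence[Sequence[str]]):
        self.loci_sets = [tuple(c) for c in candidates]
        if not self.loci_sets:
            raise ValueError("candidate list is empty")
        self.n = cohort.n_subjects
        self.cells = []
        self.valid = []
        self.n_cells = []
        for loci in self.loci_sets:
            cells, valid = _cells_for(cohort, loci)
            self.cells.append(cells)
            self.valid.append(valid)
            self.n_cells.append(3 ** len(loci))
        # fixed tie-break order: fewest loci, then lexicographic rsids
        self.tie_rank = sorted(
            range(len(self.loci_sets)),
            key=lambda i: (len(self.loci_sets[i]), self.loci_sets[i]),
        )
        self.tie_key = np.empty(len(self.loci_sets), dtype=np.int64)
        self.tie_key[self.tie_rank] = np.arange(len(self.loci_sets))

    def stratified_folds(
        self, status: np.ndarray, k: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Seeded stratified fold assignment: shuffle within status, round-robin."""
        fold = np.empty(self.n, dtype=np.int64)
        for value in (1, 0):
            idx = np.flatnonzero(status == value)
            if len(idx) < k:
                raise EvaluationError(
                    f"only {len(idx)} subjects of one status for {k} folds"
                )
            idx = rng.permutation(idx)
            fold[idx] = np.arange(len(idx)) % k
        return fold

    def run_cv(
        self, status: np.ndarray, k: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One stratified k-fold CV pass over all candidates.

        Returns (train_acc, test_acc, winner): accuracy arrays of shape
        (n_candidates, k) and the per-fold winning candidate index.
        """
        fold = self.stratified_folds(status, k, rng)
        n_cand = len(self.loci_sets)
        train_acc = np.empty((n_cand, k))
        test_acc = np.empty((n_cand, k))
        for ci in range(n_cand):
            cells, valid, n_cells = self.cells[ci], self.valid[ci], self.n_cells[ci]
            case_sel = valid & (status == 1)
            ctrl_sel = valid & (status == 0)
            tot_case = np.bincount(cells[case_sel], minlength=n_cells)
            tot_ctrl = np.bincount(cells[ctrl_sel], minlength=n_cells)
            fold_case = np.zeros((k, n_cells), dtype=np.int64)
            fold_ctrl = np.zeros((k, n_cells), dtype=np.int64)
            np.add.at(fold_case, (fold[case_sel], cells[case_sel]), 1)
            np.add.at(fold_ctrl, (fold[ctrl_sel], cells[ctrl_sel]), 1)
            train_case = tot_case[None, :] - fold_case  # (k, n_cells)
            train_ctrl = tot_ctrl[None, :] - fold_ctrl
            t_num = train_case.sum(axis=1)  # evaluable training cases per fold
            t_den = train_ctrl.sum(axis=1)
            test_case_n = fold_case.sum(axis=1)
            test_ctrl_n = fold_ctrl.sum(axis=1)
            if (
                (t_num == 0).any()
                or (t_den == 0).any()
                or (test_case_n == 0).any()
                or (test_ctrl_n == 0).any()
            ):
                raise EvaluationError(
                    f"candidate {self.loci_sets[ci]}: a fold has no evaluable "
                    "case or control"
                )
            # high-risk iff case/ctrl >= T = t_num/t_den (exact integer compare);
            # zero-control cells are high only when they hold cases.
            high = np.where(
                train_ctrl > 0,
                train_case * t_den[:, None] >= train_ctrl * t_num[:, None],
                train_case > 0,
            )
            sens_tr = (train_case * high).sum(axis=1) / t_num
            spec_tr = (train_ctrl * ~high).sum(axis=1) / t_den
            sens_te = (fold_case * high).sum(axis=1) / test_case_n
            spec_te = (fold_ctrl * ~high).sum(axis=1) / test_ctrl_n
            train_acc[ci] = (sens_tr + spec_tr) / 2.0
            test_acc[ci] = (sens_te + spec_te) / 2.0
        # per-fold winner: max training accuracy, ties by fewest loci then rsids
        winner = np.empty(k, dtype=np.int64)
        for f in range(k):
            best = np.flatnonzero(train_acc[:, f] == train_acc[:, f].max())
            winner[f] = best[np.argmin(self.tie_key[best])]
        return train_acc, test_acc, winner

    def candidates_from_cv(
        self, train_acc: np.ndarray, test_acc: np.ndarray, winner: np.ndarray
    ) -> list[MDRCandidate]:
        k = train_acc.shape[1]
        out = []
        for ci, loci in enumerate(self.loci_sets):
            wins = winner == ci
            out.append(
                MDRCandidate(
                    loci=loci,
                    training_accuracy=tuple(float(x) for x in train_acc[ci]),
                    testing_accuracy=tuple(float(x) for x in test_acc[ci]),
                    fold_winner=tuple(bool(w) for w in wins),
                    cvc=int(wins.sum()),
                    ata=float(test_acc[ci].mean()),
                )
            )
        return out


def cross_validate(
    cohort: Cohort,
    candidates: Sequence[Sequence[str]],
    k: int = 10,
    seed: int = 0,
) -> list[MDRCandidate]:
    """Stratified k-fold CV of every candidate locus set.

    Per fold, each candidate's risk labeling is built on the training
    k-1/k with T equal to the training case:control ratio and evaluated
    on the held-out fold; the fold winner has the highest training
    balanced accuracy (ties: fewest loci, then lexicographic rsids).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    engine = _Engine(cohort, candidates)
    rng = np.random.default_rng(seed)
    return engine.candidates_from_cv(*engine.run_cv(cohort.status_array(), k, rng))


def select_best_model(candidates: Sequence[MDRCandidate]) -> MDRCandidate:
    """Maximal CVC; ties by maximal ATA, then fewest loci, then rsid order."""
    if not candidates:
        raise ValueError("empty candidate list")
    return min(candidates, key=lambda c: (-c.cvc, -c.ata, len(c.loci), c.loci))


def _select_index(
    cvc: np.ndarray, ata: np.ndarray, tie_key: np.ndarray
) -> int:
    order = np.lexsort((tie_key, -ata, -cvc))
    return int(order[0])


def permutation_test(
    cohort: Cohort,
    candidates: Sequence[Sequence[str]],
    k: int = 10,
    B: int = 10000,
    seed: int = 0,
) -> MDRResult:
    """Label-permutation significance for the best cross-validated model.

    For each of B permutations the status vector is shuffled (preserving
    totals) and the entire CV + model-selection procedure re-runs; the
    null statistic is the selected model's ATA.  p = (r + 1) / (B + 1)
    with r = #{null ATA >= observed ATA}.  A parallel p on the selected
    model's CVC is reported alongside.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    engine = _Engine(cohort, candidates)
    status = cohort.status_array()
    master = np.random.default_rng(seed)
    fold_rng = np.random.default_rng(master.integers(2**63))
    train, test, winner = engine.run_cv(status, k, fold_rng)
    observed = engine.candidates_from_cv(train, test, winner)
    best = select_best_model(observed)
    null_ata = np.empty(B)
    null_cvc = np.empty(B, dtype=np.int64)
    for b in range(B):
        perm_status = master.permutation(status)
        fold_rng = np.random.default_rng(master.integers(2**63))
        _, test_b, winner_b = engine.run_cv(perm_status, k, fold_rng)
        cvc_b = np.bincount(winner_b, minlength=len(engine.loci_sets))
        ata_b = test_b.mean(axis=1)
        bi = _select_index(cvc_b, ata_b, engine.tie_key)
        null_ata[b] = ata_b[bi]
        null_cvc[b] = cvc_b[bi]
    p_ata = (int((null_ata >= best.ata).sum()) + 1) / (B + 1)
    p_cvc = (int((null_cvc >= best.cvc).sum()) + 1) / (B + 1)
    return MDRResult(
        best=best,
        candidates=observed,
        permutation_p=p_ata,
        null_ata=null_ata,
        permutation_p_cvc=p_cvc,
        null_cvc=null_cvc,
        B=B,
        k=k,
        seed=seed,
    )


def run_mdr(
    cohort: Cohort,
    max_order: int = 1,
    k: int = 10,
    B: int = 10000,
    seed: int = 0,
) -> MDRResult:
    """Exhaustive MDR over all locus subsets of size 1..max_order."""
    rsids = cohort.rsids
    if not 1 <= max_order <= len(rsids):
        raise ValueError("max_order must be in [1, panel size]")
    candidates = [
        combo
        for order in range(1, max_order + 1)
        for combo in itertools.combinations(rsids, order)
    ]
    if B == 0:
        engine = _Engine(cohort, candidates)
        rng = np.random.default_rng(np.random.default_rng(seed).integers(2**63))
        observed = engine.candidates_from_cv(
            *engine.run_cv(cohort.status_array(), k, rng)
        )
        return MDRResult(
            best=select_best_model(observed),
            candidates=observed,
            permutation_p=None,
            null_ata=None,
            permutation_p_cvc=None,
            null_cvc=None,
            B=0,
            k=k,
            seed=seed,
        )
    return permutation_test(cohort, candidates, k=k, B=B, seed=seed)
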