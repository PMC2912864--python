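import dataclasses
import itertools

import numpy as np
import pytest

from snpmdr import (
    MDRCandidate,
    SnpDef,
    assign_risk_labels,
    balanced_accuracy,
    cross_validate,
    default_config,
    permutation_test,
    plant_single_locus_effect,
    run_mdr,
    select_best_model,
    simulate_cohort,
)
from snpmdr.errors import EvaluationError

from conftest import make_cohort

RS16 = SnpDef("rs16901979", "G", "T")
T_FULL = 192 / 512


def null_config(seed=0, **size):
    cfg = default_config(seed=seed)
    if size:
        cfg = dataclasses.replace(cfg, **size)
    for rsid in [s.rsid for s in cfg.panel]:
        cfg = plant_single_locus_effect(cfg, rsid, (1.0, 1.0))
    return cfg


class TestAssignRiskLabels:
    def test_full_data_labeling(self):
        counts = {(0,): (45, 188), (1,): (97, 237), (2,): (50, 87)}
        labeling = assign_risk_labels(counts, T_FULL, loci=("rs16901979",))
        assert labeling.label((0,)) == "low"  # 0.239 < 0.375
        assert labeling.label((1,)) == "high"  # 0.409
        assert labeling.label((2,)) == "high"  # 0.575

    def test_inclusive_boundary(self):
        counts = {(0,): (10, 20), (1,): (5, 10), (2,): (1, 2)}
        labeling = assign_risk_labels(counts, 0.5)
        assert all(labeling.label(c) == "high" for c in counts)

    def test_empty_cell_low(self):
        labeling = assign_risk_labels({(0,): (0, 0)}, 1.0)
        assert labeling.label((0,)) == "low"
        assert labeling.label((1,)) == "low"  # unseen cell

    def test_zero_controls_with_cases_high(self):
        labeling = assign_risk_labels({(0,): (3, 0)}, 1.0)
        assert labeling.label((0,)) == "high"


class TestBalancedAccuracy:
    def test_full_data_value(self, table_cohort):
        counts = {(0,): (45, 188), (1,): (97, 237), (2,): (50, 87)}
        labeling = assign_risk_labels(counts, T_FULL, loci=("rs16901979",))
        ba = balanced_accuracy(labeling, table_cohort)
        assert ba == pytest.approx((147 / 192 + 188 / 512) / 2, abs=1e-12)
        assert round(ba, 3) == 0.566

    def test_all_high_is_half(self, table_cohort):
        labeling = assign_risk_labels(
            {(c,): (1, 0) for c in range(3)}, 0.1, loci=("rs16901979",)
        )
        assert balanced_accuracy(labeling, table_cohort) == pytest.approx(0.5)

    def test_brute_force_eight_subjects(self):
        statuses = ["case"] * 4 + ["control"] * 4
        geno = [[0], [1], [1], [2], [0], [0], [1], [2]]
        cohort = make_cohort(statuses, geno, [RS16])
        counts = {(0,): (1, 2), (1,): (2, 1), (2,): (1, 1)}
        labeling = assign_risk_labels(counts, 1.0, loci=("rs16901979",))
        # exhaustive confusion matrix
        tp = fn = tn = fp = 0
        for status, (g,) in zip(statuses, geno):
            high = labeling.label((g,)) == "high"
            if status == "case":
                tp, fn = tp + high, fn + (not high)
            else:
                tn, fp = tn + (not high), fp + high
        expected = (tp / (tp + fn) + tn / (tn + fp)) / 2
        assert balanced_accuracy(labeling, cohort) == pytest.approx(expected)

    def test_no_evaluable_subjects(self):
        cohort = make_cohort(["case", "control"], [[-1], [-1]], [RS16])
        labeling = assign_risk_labels({(0,): (1, 1)}, 1.0, loci=("rs16901979",))
        with pytest.raises(EvaluationError):
            balanced_accuracy(labeling, cohort)


class TestCrossValidate:
    def test_single_candidate_wins_all_folds(self):
        cohort = simulate_cohort(default_config(seed=4))
        (cand,) = cross_validate(cohort, [("rs16901979",)], k=10, seed=1)
        assert cand.cvc == 10
        assert all(cand.fold_winner)

    def test_ata_is_mean_testing_accuracy(self):
        cohort = simulate_cohort(default_config(seed=4))
        cands = cross_validate(
            cohort, [("rs16901979",), ("rs1447295",)], k=10, seed=1
        )
        for cand in cands:
            assert cand.ata == pytest.approx(np.mean(cand.testing_accuracy))
            assert all(0.0 <= a <= 1.0 for a in cand.testing_accuracy)

    def test_null_simulation_ata_near_half(self):
        cfg = null_config(seed=8, n_cases=5000, n_controls=5000)
        cohort = simulate_cohort(cfg)
        cands = cross_validate(
            cohort, [(r,) for r in cohort.rsids], k=10, seed=3
        )
        for cand in cands:
            assert abs(cand.ata - 0.5) < 0.03

    def test_reproducible(self):
        cohort = simulate_cohort(default_config(seed=4))
        a = cross_validate(cohort, [("rs16901979",)], k=10, seed=5)
        b = cross_validate(cohort, [("rs16901979",)], k=10, seed=5)
        assert a == b

    def test_engine_matches_public_labeling_path(self, table_cohort):
        # single-locus, k=2: rebuild each fold's labeling with the public
        # API and check the engine's training accuracy agrees
        from snpmdr.cohort import count_genotypes
        from snpmdr.mdr import _Engine

        engine = _Engine(table_cohort, [("rs16901979",)])
        rng = np.random.default_rng(0)
        status = table_cohort.status_array()
        fold = engine.stratified_folds(status, 2, np.random.default_rng(0))
        train_acc, test_acc, _ = engine.run_cv(
            status, 2, np.random.default_rng(0)
        )
        for f in range(2):
            keep = fold != f
            train = table_cohort.subset(keep)
            tab = count_genotypes(train, "rs16901979")
            counts = {
                (c,): (int(tab.cases[c]), int(tab.controls[c])) for c in range(3)
            }
            threshold = tab.n_cases / tab.n_controls
            labeling = assign_risk_labels(
                counts, threshold, loci=("rs16901979",)
            )
            assert balanced_accuracy(labeling, train) == pytest.approx(
                train_acc[0, f], abs=1e-12
            )
            test = table_cohort.subset(~keep)
            assert balanced_accuracy(labeling, test) == pytest.approx(
                test_acc[0, f], abs=1e-12
            )


class TestSelectBestModel:
    def _cand(self, loci, cvc, ata):
        return MDRCandidate(
            loci=loci,
            training_accuracy=(),
            testing_accuracy=(),
            fold_winner=(),
            cvc=cvc,
            ata=ata,
        )

    def test_max_cvc_wins(self):
        cands = [
            self._cand(("a",), 10, 0.5),
            self._cand(("b",), 4, 0.9),
            self._cand(("c",), 3, 0.9),
        ]
        assert select_best_model(cands).loci == ("a",)

    def test_ata_tiebreak(self):
        cands = [
            self._cand(("a",), 5, 0.60),
            self._cand(("b",), 5, 0.55),
        ]
        assert select_best_model(cands).loci == ("a",)

    def test_brute_force_over_orderings(self):
        base = [
            self._cand(("a",), 5, 0.60),
            self._cand(("b",), 5, 0.60),
            self._cand(("a", "b"), 5, 0.60),
            self._cand(("c",), 7, 0.40),
        ]
        expected_key = lambda c: (-c.cvc, -c.ata, len(c.loci), c.loci)
        for perm in itertools.permutations(base):
            best = select_best_model(list(perm))
            brute = sorted(perm, key=expected_key)[0]
            assert best.loci == brute.loci


class TestPermutationTest:
    def test_p_granularity_with_strong_effect(self):
        # a strong planted effect beats every null permutation: p = 1/(B+1)
        cfg = null_config(seed=6, n_cases=1000, n_controls=1000)
        cfg = plant_single_locus_effect(cfg, "rs16901979", (4.0, 8.0))
        cohort = simulate_cohort(cfg)
        res = permutation_test(
            cohort, [(r,) for r in cohort.rsids], k=10, B=99, seed=7
        )
        assert res.best.loci == ("rs16901979",)
        assert res.permutation_p == pytest.approx(1 / 100)

    def test_p_formula_invariant(self):
        cohort = simulate_cohort(default_config(seed=12))
        res = permutation_test(
            cohort, [(r,) for r in cohort.rsids], k=10, B=49, seed=3
        )
        r = int((res.null_ata >= res.best.ata).sum())
        assert res.permutation_p == (r + 1) / 50
        assert 0 < res.permutation_p <= 1

    def test_reproducible(self):
        cohort = simulate_cohort(default_config(seed=12))
        a = permutation_test(cohort, [("rs16901979",)], k=10, B=20, seed=3)
        b = permutation_test(cohort, [("rs16901979",)], k=10, B=20, seed=3)
        assert a.permutation_p == b.permutation_p
        assert np.array_equal(a.null_ata, b.null_ata)


class TestRunMdr:
    def test_candidate_counts(self):
        cohort = simulate_cohort(default_config(seed=1))
        res1 = run_mdr(cohort, max_order=1, B=0, seed=0)
        assert len(res1.candidates) == 7
        res2 = run_mdr(cohort, max_order=2, B=0, seed=0)
        assert len(res2.candidates) == 28

    def test_two_locus_epistasis_recovery(self):
        # XOR-style pure interaction planted on two SNPs: single-locus
        # marginals are null, the pair carries all signal
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 10
        panel = [RS16, SnpDef("rs6983561", "A", "C"), SnpDef("rs1447295", "G", "T")]
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 2000
            statuses = ["case"] * (n // 2) + ["control"] * (n // 2)
            geno = np.empty((n, 3), dtype=np.int8)
            # controls: independent uniform over {0,1,2}
            geno[n // 2 :] = rng.integers(0, 3, size=(n // 2, 3))
            # cases: first two loci correlated XOR-style (both even or both odd
            # parity of "carrier" state), third independent
            g1 = rng.integers(0, 3, size=n // 2)
            parity = (g1 > 0).astype(int)
            flip = rng.random(n // 2) < 0.85
            carrier2 = np.where(flip, parity, 1 - parity)
            g2 = np.where(carrier2 == 1, rng.integers(1, 3, size=n // 2), 0)
            geno[: n // 2, 0] = g1
            geno[: n // 2, 1] = g2
            geno[: n // 2, 2] = rng.integers(0, 3, size=n // 2)
            cohort = make_cohort(statuses, geno, panel)
            res = run_mdr(cohort, max_order=2, B=0, seed=seed)
            pair = tuple(sorted(("rs16901979", "rs6983561")))
            if tuple(sorted(res.best.loci)) == pair and res.best.cvc >= 8:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_monotone_in_effect_size(self):
        medians = []
        for ors in ((1.0, 1.0), (1.8, 1.8), (3.0, 3.0)):
            atas = []
            for seed in range(12):
                cfg = null_config(seed=seed)
                cfg = plant_single_locus_effect(cfg, "rs16901979", ors)
                cohort = simulate_cohort(cfg)
                res = run_mdr(cohort, max_order=1, B=0, seed=seed)
                atas.append(res.best.ata)
            medians.append(np.median(atas))
        assert medians[0] <= medians[1] <= medians[2]
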