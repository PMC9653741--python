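"""balances module: nearest-balance search, clr association, reproducibility,
external evaluation, AUC."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import paircoda as pc
from paircoda.balances import (
    Balance,
    balance_value,
    balance_values,
    clr_association,
    evaluate_balance_external,
    nearest_balance,
    reproducible_balance,
    sample_type_auc,
)
from paircoda.coda import clr, closure, zero_replace
from paircoda.design import AssociationDesign
from paircoda.simulate import balance_recovery, signed_jaccard


def exhaustive_nearest_balance(b: np.ndarray) -> tuple[float, tuple, tuple]:
    """Independent oracle: enumerate every disjoint nonempty (num, den)
    assignment and return the best cosine with its sets."""
    D = len(b)
    norm_b = np.linalg.norm(b)
    best = (-np.inf, (), ())
    for assign in itertools.product((0, 1, 2), repeat=D):  # 0 out, 1 num, 2 den
        num = [i for i, a in enumerate(assign) if a == 1]
        den = [i for i, a in enumerate(assign) if a == 2]
        if not num or not den:
            continue
        kp, km = len(num), len(den)
        contrast = np.zeros(D)
        contrast[num] = np.sqrt(km / (kp * (kp + km)))
        contrast[den] = -np.sqrt(kp / (km * (kp + km)))
        cos = contrast @ b / norm_b
        if cos > best[0]:
            best = (cos, tuple(num), tuple(den))
    return best


class TestBalanceType:
    def test_contrast_unit_norm_zero_sum(self):
        bal = Balance(("a", "b"), ("c",))
        vec = bal.contrast(["a", "b", "c", "d"])
        assert np.linalg.norm(vec) == pytest.approx(1.0)
        assert vec.sum() == pytest.approx(0.0)
        assert vec[3] == 0.0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Balance(("a",), ("a", "b"))

    def test_missing_taxon_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            Balance(("a",), ("b",)).contrast(["a", "c"])


class TestNearestBalance:
    def test_simple_example(self):
        bal = nearest_balance(np.array([1.0, -1.0, 0.0]), ["t1", "t2", "t3"])
        assert bal.numerator == ("t1",)
        assert bal.denominator == ("t2",)
        vec = bal.contrast(["t1", "t2", "t3"])
        b = np.array([1.0, -1.0, 0.0])
        assert vec @ b / np.linalg.norm(b) == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        b = np.array([2.0, 1.0, -3.0])
        bal = nearest_balance(b, ["t1", "t2", "t3"])
        assert set(bal.numerator) == {"t1", "t2"}
        assert bal.denominator == ("t3",)
        cos = bal.contrast(["t1", "t2", "t3"]) @ b / np.linalg.norm(b)
        assert cos == pytest.approx(0.9820, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            b = rng.normal(size=6)
            fwd = nearest_balance(b)
            rev = nearest_balance(-b)
            assert set(fwd.numerator) == set(rev.denominator)
            assert set(fwd.denominator) == set(rev.numerator)

    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(100):
            b = rng.normal(size=6)
            bal = nearest_balance(b, taxa)
            cos = bal.contrast(taxa) @ b / np.linalg.norm(b)
            best_cos, num, den = exhaustive_nearest_balance(b)
            assert cos == pytest.approx(best_cos, abs=1e-10)
            assert set(bal.numerator) == {taxa[i] for i in num}
            assert set(bal.denominator) == {taxa[i] for i in den}

    def test_internal_consistency_vs_sorted_candidates(self):
        rng = np.random.default_rng(8)
        b = rng.normal(size=12)
        taxa = [f"t{i}" for i in range(12)]
        bal = nearest_balance(b, taxa)
        best = bal.contrast(taxa) @ b
        order = np.argsort(-b)
        for kp in range(1, 12):
            for km in range(1, 12 - kp + 1):
                cand = Balance(
                    tuple(taxa[i] for i in order[:kp]),
                    tuple(taxa[i] for i in order[12 - km:]),
                )
                assert cand.contrast(taxa) @ b <= best + 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nearest_balance(np.ones(4))

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 2"):
            nearest_balance(np.array([1.0]))


class TestBalanceValue:
    def test_equal_sides_zero(self):
        bal = Balance(("a", "b"), ("c",))
        assert balance_value(bal, {"a": 2.0, "b": 2.0, "c": 2.0}) == pytest.approx(0.0)

    def test_e_ratio_example(self):
        bal = Balance(("a",), ("b",))
        v = balance_value(bal, {"a": np.e, "b": 1.0})
        assert v == pytest.approx(np.sqrt(0.5), abs=1e-10)
        assert v == pytest.approx(0.7071, abs=1e-4)

    def test_scale_invariance(self):
        bal = Balance(("a",), ("b", "c"))
        s = {"a": 3.0, "b": 1.0, "c": 5.0}
        v1 = balance_value(bal, s)
        v2 = balance_value(bal, {k: 42.0 * v for k, v in s.items()})
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_equals_contrast_dot_clr(self, random_compositions):
        bal = Balance(("t0", "t3"), ("t5",))
        taxa = list(random_compositions.columns)
        contrast = bal.contrast(taxa)
        clr_rows = clr(random_compositions)
        expected = clr_rows.to_numpy() @ contrast
        got = balance_values(bal, random_compositions).to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_missing_taxon_listed(self):
        bal = Balance(("a",), ("zz",))
        with pytest.raises(ValueError, match="zz"):
            balance_value(bal, {"a": 1.0, "b": 1.0})


class TestClrAssociation:
    def _null_frame(self, rng, n=40, d=10):
        comp = pd.DataFrame(
            closure(rng.dirichlet(np.ones(d), n)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"t{i}" for i in range(d)],
        )
        meta = pd.DataFrame(
            {"sample_id": comp.index, "grp": rng.permutation(["a", "b"] * (n // 2))}
        )
        return clr(comp), meta

    def test_coefficients_sum_to_zero(self):
        rng = np.random.default_rng(10)
        clr_table, meta = self._null_frame(rng)
        b, _ = clr_association(clr_table, meta, AssociationDesign(factor="grp"))
        assert abs(b.sum()) < 1e-8

    def test_null_type_one_error(self):
        rng = np.random.default_rng(11)
        hits, total = 0, 0
        for _ in range(30):
            clr_table, meta = self._null_frame(rng)
            _, p = clr_association(clr_table, meta, AssociationDesign(factor="grp"))
            hits += (p < 0.05).sum()
            total += len(p)
        rate = hits / total
        assert 0.01 <= rate <= 0.10

    def test_constant_factor_rejected(self):
        rng = np.random.default_rng(12)
        clr_table, meta = self._null_frame(rng)
        meta["grp"] = "a"
        with pytest.raises(ValueError, match="constant"):
            clr_association(clr_table, meta, AssociationDesign(factor="grp"))

    def test_planted_direction_recovered(self, small_cohort):
        table, meta, truth = small_cohort
        comp = zero_replace(table)
        design = AssociationDesign(
            factor="sample_type", random_group="patient_id"
        )
        b, _ = clr_association(clr(comp), meta, design)
        # sample-type shift was planted along the type balance contrast
        contrast = truth.type_balance.contrast(list(truth.taxa))
        cos = abs(contrast @ b.to_numpy()) / np.linalg.norm(b.to_numpy())
        assert cos > 0.9


class TestReproducibleBalance:
    def test_seed_deterministic(self, small_cohort):
        table, meta, _ = small_cohort
        design = AssociationDesign(factor="sample_type", random_group="patient_id")
        a = reproducible_balance(table, meta, design, n_iter=30, seed=5)
        b = reproducible_balance(table, meta, design, n_iter=30, seed=5)
        assert a.balance == b.balance
        pd.testing.assert_series_equal(a.numerator_freq, b.numerator_freq)

    def test_threshold_excludes(self, small_cohort):
        table, meta, _ = small_cohort
        design = AssociationDesign(factor="sample_type", random_group="patient_id")
        fit = reproducible_balance(table, meta, design, n_iter=50, threshold=0.8, seed=1)
        for taxon in fit.balance.numerator:
            assert fit.numerator_freq[taxon] > 0.8
        below = fit.numerator_freq[(fit.numerator_freq > 0) & (fit.numerator_freq <= 0.8)]
        for taxon in below.index:
            assert taxon not in fit.balance.numerator

    def test_planted_type_balance_recovered(self, small_cohort):
        table, meta, truth = small_cohort
        design = AssociationDesign(factor="sample_type", random_group="patient_id")
        fit = reproducible_balance(table, meta, design, n_iter=100, seed=3)
        j = max(
            signed_jaccard(fit.balance, truth.type_balance),
            signed_jaccard(fit.balance.flip(), truth.type_balance),
        )
        assert j >= 0.8

    def test_export_shapes(self, small_cohort, tmp_path):
        table, meta, _ = small_cohort
        design = AssociationDesign(factor="sample_type", random_group="patient_id")
        fit = reproducible_balance(table, meta, design, n_iter=20, seed=2)
        fit.to_json(tmp_path / "fit.json")
        frame = fit.to_table()
        assert set(frame.columns) == {
            "taxon", "side", "coefficient", "numerator_freq", "denominator_freq"
        }
        assert len(frame) == len(table.taxa)
        assert frame["numerator_freq"].between(0, 1).all()


class TestEvaluateBalanceExternal:
    def test_exact_match_consistency(self, random_compositions):
        bal = Balance(("t1",), ("t4", "t6"))
        lineages = {c: f"d__B;p__P;c__C;o__O;f__F;g__G;s__{c}" for c in random_compositions.columns}
        values, _ = evaluate_balance_external(bal, random_compositions, lineages)
        expected = balance_values(bal, random_compositions)
        np.testing.assert_allclose(values.to_numpy(), expected.to_numpy(), atol=1e-10)

    def test_clade_sum_rule(self):
        relabund = pd.DataFrame(
            {"s__X1": [0.01], "s__X2": [0.02], "s__Y": [0.5]},
            index=["sampleA"],
        )
        lineages = {
            "s__X1": "d__B;p__P;c__C;o__O;f__F;g__GX;s__X1",
            "s__X2": "d__B;p__P;c__C;o__O;f__F;g__GX;s__X2",
            "s__Y": "d__B;p__P;c__C;o__O;f__F;g__GY;s__Y",
        }
        bal = Balance(("unclassified_g__GX",), ("s__Y",))
        member_lineages = {"unclassified_g__GX": "d__B;p__P;c__C;o__O;f__F;g__GX"}
        values, _ = evaluate_balance_external(
            bal, relabund, lineages, member_lineages
        )
        expected = np.sqrt(0.5) * (np.log(0.03) - np.log(0.5))
        assert values.iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_unmatched_member_errors(self, random_compositions):
        bal = Balance(("nope",), ("t1",))
        with pytest.raises(ValueError, match="nope"):
            evaluate_balance_external(bal, random_compositions, {})

    def test_group_comparison_detects_shift(self):
        rng = np.random.default_rng(20)
        n = 200  # 100 per group
        group = np.repeat(["g1", "g2"], n // 2)
        # planted shift of the balance value between groups
        log_a = rng.normal(0.0, 0.3, n) + np.where(group == "g2", 1.0, 0.0)
        a = np.exp(log_a)
        b = np.ones(n)
        relabund = pd.DataFrame(
            {"s__A": a, "s__B": b}, index=[f"s{i}" for i in range(n)]
        )
        relabund = relabund.div(relabund.sum(axis=1), axis=0)
        lineages = {
            "s__A": "d__B;p__P;c__C;o__O;f__F;g__G;s__A",
            "s__B": "d__B;p__P;c__C;o__O;f__F;g__G;s__B",
        }
        bal = Balance(("s__A",), ("s__B",))
        _, comparison = evaluate_balance_external(
            bal, relabund, lineages, group=pd.Series(group, index=relabund.index)
        )
        assert comparison["p"] < 0.001
        assert comparison["slope"] > 0


class TestSampleTypeAuc:
    def test_recovers_strong_shift(self, small_cohort):
        table, meta, _ = small_cohort
        mean, sd, aucs = sample_type_auc(
            table, meta, n_iter=10, inner_iter=15, seed=4
        )
        assert mean >= 0.95
        assert len(aucs) == 10

    def test_shuffled_labels_near_half(self, small_cohort):
        table, meta, _ = small_cohort
        rng = np.random.default_rng(9)
        shuffled = meta.copy()
        for _, idx in shuffled.groupby("patient_id").groups.items():
            if rng.random() < 0.5:
                idx = list(idx)
                vals = shuffled.loc[idx, "sample_type"].to_numpy()
                shuffled.loc[idx, "sample_type"] = vals[::-1]
        mean, _, _ = sample_type_auc(
            table, shuffled, n_iter=15, inner_iter=10, seed=10
        )
        assert 0.25 <= mean <= 0.75

    def test_auc_rank_invariance(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = (scores + rng.normal(size=50)) > 0
        a1 = roc_auc_score(labels, scores)
        a2 = roc_auc_score(labels, np.exp(scores))  # monotone transform
        assert a1 == pytest.approx(a2, abs=1e-12)
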