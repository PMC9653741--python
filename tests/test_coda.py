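"""coda module: simplex machinery, transforms, distance, correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paircoda.coda import (
    aggregate_to_rank,
    aitchison_distance,
    clr,
    clr_inverse,
    closure,
    ilr,
    ilr_basis,
    ilr_inverse,
    perturb,
    random_ilr_basis,
    sample_type_correction,
    zero_replace,
)
from paircoda.io import CountTable


def _table(counts: dict, lineages=None) -> CountTable:
    df = pd.DataFrame(counts)
    df.index = [f"t{i}" for i in range(len(df))]
    df.index.name = "taxon_id"
    lin = pd.Series(lineages if lineages else "d__B", index=df.index)
    return CountTable(df, lin)


class TestZeroReplace:
    def test_zero_ten_example(self):
        comp = zero_replace(_table({"s1": [0, 10]}), pseudocount=0.5)
        np.testing.assert_allclose(comp.loc["s1"], [0.5 / 10.5, 10 / 10.5], atol=1e-4)
        np.testing.assert_allclose(comp.loc["s1"], [0.0476, 0.9524], atol=1e-4)

    def test_all_positive_is_plain_closure(self):
        comp = zero_replace(_table({"s1": [1, 3]}))
        np.testing.assert_allclose(comp.loc["s1"], [0.25, 0.75])

    def test_hand_example_three_parts(self):
        comp = zero_replace(_table({"s1": [0, 0, 1]}), pseudocount=0.5)
        np.testing.assert_allclose(comp.loc["s1"], [0.25, 0.25, 0.5])

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            zero_replace(_table({"s1": [0, 0]}))

    def test_rows_sum_to_one(self, small_cohort):
        table, _, _ = small_cohort
        comp = zero_replace(table)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-10)
        assert (comp.to_numpy() > 0).all()


class TestClr:
    def test_uniform_is_zero(self):
        out = clr(np.array([0.25, 0.25, 0.25, 0.25]))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_example(self):
        out = clr(np.array([0.5, 0.25, 0.25]))
        np.testing.assert_allclose(out, [0.4621, -0.2310, -0.2310], atol=1e-4)

    def test_rows_sum_to_zero(self, random_compositions):
        out = clr(random_compositions)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="zero_replace"):
            clr(np.array([0.5, 0.0, 0.5]))

    def test_clr_inverse_roundtrip(self, random_compositions):
        back = clr_inverse(clr(random_compositions))
        np.testing.assert_allclose(back, random_compositions, atol=1e-12)


class TestIlr:
    def test_basis_orthonormal(self):
        for d in (2, 3, 5, 12):
            basis = ilr_basis(d)
            np.testing.assert_allclose(basis @ basis.T, np.eye(d - 1), atol=1e-12)
            np.testing.assert_allclose(basis.sum(axis=1), 0.0, atol=1e-12)

    def test_roundtrip(self, random_compositions):
        coords = ilr(random_compositions)
        back = ilr_inverse(coords)
        np.testing.assert_allclose(back, random_compositions, atol=1e-10)

    def test_uniform_maps_to_origin(self):
        coords = ilr(np.full(6, 1 / 6))
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)

    def test_isometry_any_basis(self, random_compositions):
        dist = aitchison_distance(random_compositions)
        for seed in (1, 2):
            basis = random_ilr_basis(random_compositions.shape[1], seed)
            coords = ilr(random_compositions, basis)
            from scipy.spatial.distance import pdist, squareform

            euclid = squareform(pdist(coords))
            np.testing.assert_allclose(euclid, dist.to_numpy(), atol=1e-10)

    def test_dimension_mismatch(self, random_compositions):
        with pytest.raises(ValueError, match="basis shape"):
            ilr(random_compositions, ilr_basis(5))


class TestAitchisonDistance:
    def test_self_distance_zero(self, random_compositions):
        dist = aitchison_distance(random_compositions)
        np.testing.assert_allclose(np.diag(dist), 0.0, atol=1e-12)

    def test_hand_example(self):
        comp = pd.DataFrame(
            [[0.5, 0.25, 0.25], [0.25, 0.25, 0.5]], columns=list("abc")
        )
        d = aitchison_distance(comp).iloc[0, 1]
        assert d == pytest.approx(np.log(2) * np.sqrt(2), abs=1e-10)
        assert d == pytest.approx(0.9803, abs=1e-4)

    def test_perturbation_invariance(self, random_compositions):
        rng = np.random.default_rng(4)
        p = closure(rng.dirichlet(np.ones(8)))
        perturbed = perturb(random_compositions, p)
        d0 = aitchison_distance(random_compositions)
        d1 = aitchison_distance(perturbed)
        np.testing.assert_allclose(d0.to_numpy(), d1.to_numpy(), atol=1e-10)

    def test_symmetry_and_triangle(self, random_compositions):
        dist = aitchison_distance(random_compositions).to_numpy()
        np.testing.assert_allclose(dist, dist.T, atol=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j, k = rng.integers(0, len(dist), 3)
            assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-10


class TestPerturb:
    def test_uniform_neutral(self, random_compositions):
        uniform = np.full(8, 1 / 8)
        out = perturb(random_compositions, uniform)
        np.testing.assert_allclose(out, random_compositions, atol=1e-12)

    def test_inverse_element(self, random_compositions):
        rng = np.random.default_rng(5)
        p = closure(rng.dirichlet(np.ones(8)))
        p_inv = closure(1.0 / p)
        out = perturb(perturb(random_compositions, p), p_inv)
        np.testing.assert_allclose(out, random_compositions, atol=1e-10)

    def test_ilr_linearity(self, random_compositions):
        rng = np.random.default_rng(6)
        p = closure(rng.dirichlet(np.ones(8)))
        lhs = ilr(perturb(random_compositions, p))
        rhs = ilr(random_compositions) + ilr(p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestSampleTypeCorrection:
    @pytest.fixture
    def pair(self):
        rng = np.random.default_rng(7)
        cols = [f"t{i}" for i in range(6)]
        stool = pd.DataFrame(
            closure(rng.dirichlet(np.ones(6), 9)),
            columns=cols, index=[f"st{i}" for i in range(9)],
        )
        biopsy = pd.DataFrame(
            closure(rng.dirichlet(np.ones(6), 7)),
            columns=cols, index=[f"bi{i}" for i in range(7)],
        )
        return stool, biopsy

    def test_single_pair_equals_biopsy(self):
        cols = list("abcd")
        stool = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], columns=cols)
        biopsy = pd.DataFrame([[0.4, 0.3, 0.2, 0.1]], columns=cols)
        corrected = sample_type_correction(stool, biopsy)
        np.testing.assert_allclose(corrected.to_numpy(), biopsy.to_numpy(), atol=1e-10)

    def test_mean_ilr_matches_biopsy(self, pair):
        stool, biopsy = pair
        corrected = sample_type_correction(stool, biopsy)
        np.testing.assert_allclose(
            ilr(corrected).mean(axis=0), ilr(biopsy).mean(axis=0), atol=1e-8
        )

    def test_basis_invariance(self, pair):
        stool, biopsy = pair
        c1 = sample_type_correction(stool, biopsy)
        c2 = sample_type_correction(stool, biopsy, basis=random_ilr_basis(6, 3))
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-8)

    def test_closed_form_perturbation_route(self, pair):
        stool, biopsy = pair
        corrected = sample_type_correction(stool, biopsy)
        g_biopsy = np.exp(np.log(biopsy.to_numpy()).mean(axis=0))
        g_stool = np.exp(np.log(stool.to_numpy()).mean(axis=0))
        shift = closure(g_biopsy / g_stool)
        alt = perturb(stool, shift)
        np.testing.assert_allclose(corrected.to_numpy(), alt.to_numpy(), atol=1e-8)

    def test_part_mismatch(self, pair):
        stool, biopsy = pair
        with pytest.raises(ValueError, match="parts"):
            sample_type_correction(stool, biopsy.iloc[:, ::-1])


class TestAggregateToRank:
    @pytest.fixture
    def asv_table(self):
        counts = pd.DataFrame(
            {"s1": [3, 4, 5, 2], "s2": [1, 0, 2, 6]},
            index=pd.Index(["a1", "a2", "a3", "a4"], name="taxon_id"),
        )
        lineages = pd.Series(
            [
                "d__B;p__P1;c__C1;o__O1;f__F1;g__G1;s__Sp1",
                "d__B;p__P1;c__C1;o__O1;f__F1;g__G1;s__Sp1",
                "d__B;p__P1;c__C1;o__O1;f__F1;g__G2;s__Sp2",
                "d__B;p__P2;c__C2;o__O2;f__F2;g__G3",  # unclassified species
            ],
            index=counts.index,
        )
        return CountTable(counts, lineages)

    def test_same_species_summed(self, asv_table):
        out = aggregate_to_rank(asv_table, "species")
        assert out.counts.loc["s__Sp1", "s1"] == 7

    def test_conserves_totals(self, asv_table):
        for rank in ("species", "genus", "family", "phylum"):
            out = aggregate_to_rank(asv_table, rank)
            pd.testing.assert_series_equal(
                out.sample_totals(), asv_table.sample_totals()
            )

    def test_genus_row_count(self, asv_table):
        out = aggregate_to_rank(asv_table, "genus")
        assert len(out.taxa) == 3  # G1, G2, G3

    def test_unclassified_placeholder(self, asv_table):
        out = aggregate_to_rank(asv_table, "species")
        assert "unclassified_g__G3" in out.taxa

    def test_unknown_rank(self, asv_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_to_rank(asv_table, "kingdom")


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=10))
def test_clr_zero_sum_property(values):
    comp = closure(np.asarray(values))
    assert abs(clr(comp).sum()) < 1e-10
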