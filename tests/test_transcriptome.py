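"""Expression thresholds, DE filtering, Venn, transporters, enrichment."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from leafphys.simulate import ExpressionSimSpec, simulate_expression_matrix
from leafphys.transcriptome import (
    ExpressionMatrix,
    classify_transporters,
    differential_expression,
    enrichment,
    expressed_genes,
    read_expression_matrix,
    venn_summary,
    write_expression_matrix,
)


def _matrix(values: dict, types=("BSC", "BSC", "BSC", "MC", "MC", "MC")):
    """Small genes x samples matrix from {gene: [values...]}."""
    samples = [f"{t}_rep{i}" for i, t in enumerate(types)]
    data = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    return ExpressionMatrix(
        data=data, sample_types=pd.Series(list(types), index=samples)
    )


class TestExpressedGenes:
    def test_counts_by_construction(self):
        m = _matrix({
            "g1": [3, 3, 3, 0, 0, 0],
            "g2": [1.9, 2.0, 2.1, 5, 5, 5],   # mean 2.0: inclusive threshold
            "g3": [0, 0, 0, 0, 0, 0],
        })
        assert expressed_genes(m, "BSC", threshold=2.0) == {"g1", "g2"}
        assert expressed_genes(m, "MC", threshold=2.0) == {"g2"}

    def test_all_below_threshold_empty(self):
        m = _matrix({"g1": [1, 1, 1, 1, 1, 1]})
        assert expressed_genes(m, "BSC", threshold=2.0) == set()

    def test_minus_infinity_threshold_returns_all(self):
        m = _matrix({"g1": [0, 0, 0, 0, 0, 0], "g2": [9, 9, 9, 9, 9, 9]})
        assert expressed_genes(m, "MC", threshold=-np.inf) == {"g1", "g2"}

    def test_unknown_cell_type(self):
        with pytest.raises(KeyError):
            expressed_genes(_matrix({"g1": [1] * 6}), "guard-cell")


class TestVenn:
    def test_identical_sets(self):
        v = venn_summary({1, 2, 3}, {1, 2, 3})
        assert v.percent_common == 100 and v.common == 3

    def test_disjoint_sets(self):
        v = venn_summary({1, 2}, {3, 4})
        assert v.percent_common == 0

    def test_percent_of_union(self):
        a = set(range(90))            # overlap 78, union 100
        b = set(range(12, 100))
        v = venn_summary(a, b)
        assert (v.common, v.union, v.percent_common) == (78, 100, 78)

    def test_counts_conserve(self):
        a, b = set(range(0, 50)), set(range(30, 80))
        v = venn_summary(a, b)
        assert v.a_only + v.b_only + v.common == len(a | b)


class TestDifferentialExpression:
    def test_identical_means_unit_fold_change(self):
        m = _matrix({"g1": [2.0, 2.1, 1.9, 2.1, 1.9, 2.0]})
        res = differential_expression(m)
        assert abs(res["signed_fold_change"].iloc[0]) == pytest.approx(1.0)
        assert not res["passed_de"].iloc[0]

    def test_fold_change_boundary_is_inclusive(self):
        """Delta log2 exactly log2(1.5) with zero variance: FC = 1.50
        exactly and passes the >= 1.5 gate (P via the zero-variance
        fallback)."""
        d = math.log2(1.5)
        m = _matrix({"g1": [2 + d, 2 + d, 2 + d, 2.0, 2.0, 2.0]})
        res = differential_expression(m)
        assert res["signed_fold_change"].iloc[0] == pytest.approx(1.5, rel=1e-12)
        assert res["p_fallback"].iloc[0]
        assert res["passed_de"].iloc[0]

    def test_sign_matches_direction(self):
        m = _matrix({
            "up": [4, 4, 4, 2, 2, 2],
            "down": [2, 2, 2, 4, 4, 4],
        })
        res = differential_expression(m)
        assert res.loc["up", "signed_fold_change"] > 0
        assert res.loc["down", "signed_fold_change"] < 0
        assert res.loc["up", "signed_fold_change"] == pytest.approx(4.0)

    def test_spiked_matrix_recovery(self):
        """DE filter recovers the spiked gene set from the generator's
        truth table: sensitivity and specificity >= 0.9 at |log2FC| = 1.5,
        sd 0.2, n = 3."""
        rng = np.random.default_rng(123)
        idx = tuple(int(i) for i in rng.choice(1000, 50, replace=False))
        fcs = tuple(1.5 * s for s in rng.choice([-1.0, 1.0], 50))
        matrix, truth = simulate_expression_matrix(ExpressionSimSpec(
            n_genes=1000, de_gene_indices=idx, de_log2_fold_changes=fcs,
            noise_sd=0.2, seed=123,
        ))
        res = differential_expression(matrix)
        called = res["passed_de"]
        is_de = truth["is_de"]
        sensitivity = (called & is_de).sum() / is_de.sum()
        specificity = (~called & ~is_de).sum() / (~is_de).sum()
        assert sensitivity >= 0.9
        assert specificity >= 0.9

    def test_de_flag_monotone_in_effect_size(self):
        """Increasing a gene's group-mean difference at fixed variance
        never turns the DE flag off."""
        base = np.array([0.1, 0.0, -0.1])
        flags = []
        for delta in (0.3, 0.7, 1.2, 2.0, 3.0):
            m = _matrix({"g": list(base + delta) + list(base)})
            flags.append(bool(differential_expression(m)["passed_de"].iloc[0]))
        # once on, stays on
        assert flags == sorted(flags)

    def test_null_p_only_rate_matches_alpha(self):
        """Without spiked genes the P <= 0.05 flag fires at ~5%."""
        hits, total = 0, 0
        for seed in range(4):
            matrix, _ = simulate_expression_matrix(ExpressionSimSpec(
                n_genes=2500, noise_sd=0.2, seed=seed,
            ))
            res = differential_expression(matrix)
            hits += int(res["passed_p_only"].sum())
            total += len(res)
        rate = hits / total
        assert 0.035 <= rate <= 0.065  # binomial sd ~0.002 at n=10000

    def test_bh_correction_optional(self):
        m = _matrix({"g1": [4, 4.1, 3.9, 2, 2.1, 1.9],
                     "g2": [2, 2.1, 1.9, 2, 2.1, 1.9]})
        res = differential_expression(m, correction="bh")
        assert "p_adjusted" in res
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()


class TestTransporterClassification:
    def _fixture(self):
        # 8 transporter genes engineered into groups: 1 x A, 5 x B, 2 x C
        genes = {}
        types = ("BSC", "BSC", "BSC", "MC", "MC", "MC")
        # group A: high in MC only, differential
        genes["a1"] = [2, 2.1, 1.9, 5, 5.1, 4.9]
        # group B: high in BSC only, differential
        for i in range(5):
            genes[f"b{i}"] = [5, 5.1, 4.9, 2, 2.1, 1.9]
        # group C: high in both, differential
        genes["c1"] = [5, 5.1, 4.9, 4.5, 4.6, 4.4]
        genes["c2"] = [4.5, 4.6, 4.4, 5, 5.1, 4.9]
        # neither high nor differential
        genes["n1"] = [2, 2.1, 1.9, 2, 2.1, 1.9]
        m = _matrix(genes, types)
        flags = pd.Series(1, index=m.data.index)
        return m, flags

    def test_group_counts_recovered(self):
        m, flags = self._fixture()
        de = differential_expression(m)
        cls = classify_transporters(m, flags, de)
        assert len(cls.group_a) == 1
        assert len(cls.group_b) == 5
        assert len(cls.group_c) == 2

    def test_groups_disjoint_and_differential(self):
        m, flags = self._fixture()
        de = differential_expression(m)
        cls = classify_transporters(m, flags, de)
        assert not (cls.group_a & cls.group_b)
        assert not (cls.group_a & cls.group_c)
        assert not (cls.group_b & cls.group_c)
        diff = set(de.index[de["p_value"] <= 0.05])
        for g in cls.group_a | cls.group_b | cls.group_c:
            assert g in diff

    def test_high_in_both_and_differential_is_group_c(self):
        m, flags = self._fixture()
        de = differential_expression(m)
        cls = classify_transporters(m, flags, de)
        assert cls.group_of("c1") == "C"

    def test_high_in_neither_gets_no_group(self):
        m, flags = self._fixture()
        cls = classify_transporters(m, flags, differential_expression(m))
        assert cls.group_of("n1") is None


class TestEnrichment:
    @staticmethod
    def _enumeration_p(background_n, category, de_n, observed):
        """Exhaustive oracle: fraction of size-de_n subsets with category
        overlap >= observed."""
        hits = total = 0
        for subset in combinations(range(background_n), de_n):
            total += 1
            if len(set(subset) & category) >= observed:
                hits += 1
        return hits / total

    @pytest.mark.parametrize("bg_n,cat_n,de_n", [
        (20, 5, 4), (15, 6, 5), (25, 8, 4), (12, 3, 6),
    ])
    def test_matches_exhaustive_enumeration(self, bg_n, cat_n, de_n):
        background = [f"g{i}" for i in range(bg_n)]
        cats = pd.Series(
            ["X" if i < cat_n else "Y" for i in range(bg_n)], index=background
        )
        de = background[:2] + background[cat_n:cat_n + de_n - 2]  # overlap 2
        res = enrichment(de, cats, background)
        expected = self._enumeration_p(bg_n, set(range(cat_n)), de_n, 2)
        assert res.loc["X", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_empty_de_set_nothing_enriched(self):
        background = [f"g{i}" for i in range(10)]
        cats = pd.Series(["X"] * 5 + ["Y"] * 5, index=background)
        res = enrichment([], cats, background)
        assert not res["enriched"].any()

    def test_whole_background_category_p_one(self):
        background = [f"g{i}" for i in range(10)]
        cats = pd.Series(["X"] * 10, index=background)
        res = enrichment(background[:4], cats, background)
        assert res.loc["X", "p_value"] == pytest.approx(1.0)

    def test_direction_split(self):
        background = [f"g{i}" for i in range(10)]
        cats = pd.Series(["X"] * 10, index=background)
        signs = pd.Series([1.8, -2.0, 1.5] + [1.0] * 7, index=background)
        res = enrichment(background[:3], cats, background, de_signs=signs)
        assert res.loc["X", "n_higher"] == 2
        assert res.loc["X", "n_lower"] == 1

    def test_de_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrichment(["z"], pd.Series(["X"], index=["g0"]), ["g0"])


def test_matrix_io_round_trip(tmp_path):
    matrix, _ = simulate_expression_matrix(ExpressionSimSpec(n_genes=20, seed=2))
    write_expression_matrix(matrix, tmp_path / "m.tsv", tmp_path / "a.tsv")
    back = read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv")
    pd.testing.assert_frame_equal(back.data, matrix.data, rtol=1e-12)
    assert list(back.sample_types.loc[list(back.data.columns)]) == \
        list(matrix.sample_types.loc[list(matrix.data.columns)])
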