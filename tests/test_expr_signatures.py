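"""Signature enrichment, three-group classification, DE and cross-dataset intersection."""

import numpy as np
import pandas as pd
import pytest

from iccclust.errors import EmptyOverlapError, ValidationError
from iccclust.expr_signatures import (
    SignatureSet,
    classify_three_group,
    collapse_duplicates,
    differential_expression,
    enrichment_score,
    intersect_signature,
    read_gmt,
    write_gmt,
    zscore_frame,
)


def _expr(rng, genes, samples):
    return pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(genes), samples)),
        index=genes,
        columns=[f"S{i}" for i in range(samples)],
    )


class TestEnrichment:
    def test_constant_matrix_scores_zero(self):
        x = pd.DataFrame(3.0, index=["G1", "G2"], columns=["S1", "S2", "S3"])
        sig = SignatureSet("sig", up=("G1", "G2"))
        assert enrichment_score(x, sig).eq(0.0).all()

    def test_planted_one_sd_shift_scores_near_one(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(100)]
        x = _expr(rng, genes, 200)
        x.loc[:, "S0"] += 1.0  # shift every up gene by +1 SD in one sample
        score = enrichment_score(x, SignatureSet("sig", up=tuple(genes)))
        assert score["S0"] == pytest.approx(1.0, abs=0.35)
        assert abs(score.drop("S0").mean()) < 0.1

    def test_up_down_balance_cancels(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(40)]
        x = _expr(rng, genes, 50)
        x.loc[:, "S0"] += 1.0  # same shift on up and down genes
        sig = SignatureSet("sig", up=tuple(genes[:20]), down=tuple(genes[20:]))
        score = enrichment_score(x, sig)
        assert score["S0"] == pytest.approx(0.0, abs=0.4)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(30)]
        x = _expr(rng, genes, 30)
        sig = SignatureSet("sig", up=tuple(genes[:15]), down=tuple(genes[15:]))
        np.testing.assert_allclose(
            enrichment_score(x, sig).to_numpy(), -enrichment_score(x, sig.swapped()).to_numpy()
        )

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(20)]
        x = _expr(rng, genes, 25)
        sig = SignatureSet("sig", up=tuple(genes))
        shifted = x.add(pd.Series(rng.normal(size=len(genes)), index=genes), axis=0)
        np.testing.assert_allclose(
            enrichment_score(x, sig).to_numpy(), enrichment_score(shifted, sig).to_numpy(), atol=1e-10
        )

    def test_missing_genes_reported_and_empty_overlap_rejected(self):
        x = _expr(np.random.default_rng(5), ["G1", "G2"], 10)
        with pytest.warns(UserWarning, match="absent"):
            score = enrichment_score(x, SignatureSet("sig", up=("G1", "G2", "GX")))
        assert score.attrs["missing_genes"] == ["GX"]
        with pytest.raises(EmptyOverlapError):
            enrichment_score(x, SignatureSet("sig", up=("ZZ",)))

    def test_overlapping_up_down_rejected(self):
        with pytest.raises(ValidationError):
            SignatureSet("bad", up=("G1",), down=("G1",))


class TestThreeGroup:
    @pytest.mark.parametrize(
        "a, b, expected", [(1.0, 0.0, "A"), (0.1, 0.0, "mixed"), (0.0, 1.0, "B")]
    )
    def test_margin_rule(self, a, b, expected):
        out = classify_three_group(
            pd.Series({"s": a}), pd.Series({"s": b}), margin=0.2, label_a="A", label_b="B"
        )
        assert out["s"] == expected

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        a = pd.Series(rng.normal(size=50))
        b = pd.Series(rng.normal(size=50))
        fwd = classify_three_group(a, b, label_a="A", label_b="B")
        rev = classify_three_group(b, a, label_a="B", label_b="A")
        assert (fwd == rev).all()

    def test_planted_two_population_recovery(self):
        rng = np.random.default_rng(7)
        genes_a = [f"A{i}" for i in range(50)]
        genes_b = [f"B{i}" for i in range(50)]
        x = _expr(rng, genes_a + genes_b, 200)
        truth = np.array(["A"] * 100 + ["B"] * 100)
        x.loc[genes_a, truth == "A"] += 1.0
        x.loc[genes_b, truth == "B"] += 1.0
        score_a = enrichment_score(x, SignatureSet("a", up=tuple(genes_a)))
        score_b = enrichment_score(x, SignatureSet("b", up=tuple(genes_b)))
        labels = classify_three_group(score_a, score_b, label_a="A", label_b="B")
        correct = (labels.to_numpy() == truth).mean()
        assert correct >= 0.95


class TestDifferentialExpression:
    def test_exact_fold_change(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        x1 = pd.DataFrame(base + np.log2(3.0), index=["G"], columns=list("abcd"))
        x2 = pd.DataFrame(base, index=["G"], columns=list("wxyz"))
        de = differential_expression(x1, x2)
        assert de.loc["G", "fold_change"] == pytest.approx(3.0)

    def test_identical_groups_null(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G"], columns=list("abc"))
        de = differential_expression(x, x.copy())
        assert de.loc["G", "fold_change"] == pytest.approx(1.0)
        assert de.loc["G", "p_value"] == pytest.approx(1.0)

    def test_constant_gene_p_one_by_convention(self):
        x1 = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G"], columns=list("abc"))
        x2 = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G"], columns=list("xyz"))
        assert differential_expression(x1, x2).loc["G", "p_value"] == 1.0

    def test_small_groups_rejected(self):
        x = pd.DataFrame([[1.0]], index=["G"], columns=["a"])
        with pytest.raises(ValidationError):
            differential_expression(x, x)


class TestIntersect:
    def _datasets(self, seed=8, planted_fc=3.0):
        rng = np.random.default_rng(seed)
        planted = [f"P{i}" for i in range(5)]
        nulls = [f"N{i}" for i in range(50)]
        genes = planted + nulls
        out = []
        for _ in range(3):
            g1 = pd.DataFrame(rng.normal(8, 0.5, size=(len(genes), 30)), index=genes)
            g2 = pd.DataFrame(rng.normal(8, 0.5, size=(len(genes), 30)), index=genes)
            g1.loc[planted] += np.log2(planted_fc)
            out.append(differential_expression(g1, g2))
        return out, planted

    def test_consensus_recovers_planted_genes_exactly(self):
        de, planted = self._datasets()
        consensus = intersect_signature(de)
        assert set(consensus.index) == set(planted)
        assert (consensus["direction"] == "up").all()

    def test_gene_failing_one_dataset_excluded(self):
        de, planted = self._datasets()
        de[2].loc[planted[0], "p_value"] = 0.5  # significant in only 2 of 3
        consensus = intersect_signature(de)
        assert planted[0] not in consensus.index

    def test_boundary_fold_change_fails_strict_filter(self):
        de, planted = self._datasets()
        for d in de:
            d.loc[planted[1], "fold_change"] = 2.0
        assert planted[1] not in intersect_signature(de).index

    def test_top_discriminators_flagged(self):
        de, planted = self._datasets(planted_fc=5.0)
        consensus = intersect_signature(de)
        assert consensus.loc[planted, "is_top"].all()


class TestGmtAndDuplicates:
    def test_gmt_round_trip(self, tmp_path):
        sets = {"sig1": ["G1", "G2"], "sig2": ["G3"]}
        write_gmt(sets, tmp_path / "s.gmt")
        assert read_gmt(tmp_path / "s.gmt") == sets

    def test_duplicate_rows_collapse_to_max_variance(self):
        x = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 5.0, 10.0]], index=["G", "G"], columns=list("abc")
        )
        out = collapse_duplicates(x)
        assert out.shape[0] == 1
        assert out.loc["G", "c"] == 10.0

    def test_zscore_zero_variance_rows(self):
        x = pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], index=["A", "B"], columns=["s1", "s2"])
        z = zscore_frame(x)
        assert (z.loc["A"] == 0).all()
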