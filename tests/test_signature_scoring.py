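import numpy as np
import pandas as pd
import pytest

from liveraging.laasp_core import GeneSignature
from liveraging.signature_scoring import (
    map_homologs,
    score_correlation,
    severity_association,
    signature_score,
    zscore_matrix,
)
from liveraging.synthetic_data import simulate_cohort


def _frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestZscore:
    def test_population_sd_example(self):
        z = zscore_matrix(_frame([[1, 2, 3]]))
        assert np.allclose(z.to_numpy(), [[-1.22474487, 0.0, 1.22474487]])

    def test_constant_gene_maps_to_zero(self):
        z = zscore_matrix(_frame([[5, 5, 5], [1, 2, 3]]))
        assert (z.iloc[0] == 0).all()

    def test_rows_center_to_zero(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(30, 12))))
        assert np.allclose(z.sum(axis=1), 0.0, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_matrix(_frame([[1.0]]))


class TestSignatureScore:
    def test_direct_formula(self):
        z = _frame([[1.2], [-0.5]], genes=["g1", "g2"], samples=["s"])
        sig = GeneSignature("sig", up={"g1"}, down={"g2"})
        vec = signature_score(z, sig)
        assert vec.scores["s"] == pytest.approx(1.7)
        assert vec.n_genes_used == 2

    def test_flip_negates_scores(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(20, 8))))
        sig = GeneSignature("sig", up={"g0", "g1", "g2"}, down={"g10", "g11"})
        fwd = signature_score(z, sig)
        rev = signature_score(z, sig.flipped())
        assert np.allclose(fwd.scores, -rev.scores)

    def test_scores_sum_to_zero_over_cohort(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(25, 10))))
        sig = GeneSignature("sig", up={"g0", "g3"}, down={"g7"})
        assert signature_score(z, sig).scores.sum() == pytest.approx(0.0, abs=1e-9)

    def test_missing_genes_skipped_and_counted(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(5, 4))))
        sig = GeneSignature("sig", up={"g0", "absent1"}, down={"absent2"})
        assert signature_score(z, sig).n_genes_used == 1

    def test_fully_absent_signature_rejected(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(3, 3))))
        with pytest.raises(ValueError, match="ghost"):
            signature_score(z, GeneSignature("ghost", up={"nope"}))

    def test_affine_invariance_of_gene_rows(self, rng):
        raw = _frame(rng.normal(size=(15, 9)))
        sig = GeneSignature("sig", up={"g1", "g2"}, down={"g8"})
        base = signature_score(zscore_matrix(raw), sig)
        transformed = raw.copy()
        transformed.loc["g1"] = 3.5 * transformed.loc["g1"] + 11.0
        transformed.loc["g8"] = 0.2 * transformed.loc["g8"] - 4.0
        after = signature_score(zscore_matrix(transformed), sig)
        assert np.allclose(base.scores, after.scores)


class TestCorrelationAndSeverity:
    def test_self_correlation_is_one(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(20, 10))))
        sig = GeneSignature("sig", up={"g0", "g1"}, down={"g5"})
        vec = signature_score(z, sig)
        assert score_correlation(vec, vec).r == pytest.approx(1.0)

    def test_flipped_signature_anticorrelates_exactly(self, rng):
        z = zscore_matrix(_frame(rng.normal(size=(20, 10))))
        sig = GeneSignature("sig", up={"g0", "g1"}, down={"g5"})
        fwd, rev = signature_score(z, sig), signature_score(z, sig.flipped())
        assert score_correlation(fwd, rev).r == pytest.approx(-1.0)

    def test_zero_variance_returns_degenerate(self):
        from liveraging.signature_scoring import ScoreVector
        a = ScoreVector(pd.Series([1.0, 1.0, 1.0], index=list("xyz")), "a", 1)
        b = ScoreVector(pd.Series([1.0, 2.0, 3.0], index=list("xyz")), "b", 1)
        res = score_correlation(a, b)
        assert res.degenerate and np.isnan(res.r)

    def test_scores_equal_to_encoding_give_r_one(self):
        from liveraging.signature_scoring import ScoreVector
        states = pd.Series(["a", "b", "c", "a", "b", "c"],
                           index=[f"s{i}" for i in range(6)])
        scores = ScoreVector(
            pd.Series([0, 1, 2, 0, 1, 2], index=states.index, dtype=float), "sig", 3
        )
        res = severity_association(scores, states, ["a", "b", "c"])
        assert res.r == pytest.approx(1.0)

    def test_unseen_state_rejected(self):
        from liveraging.signature_scoring import ScoreVector
        states = pd.Series(["a", "weird", "b"], index=["s0", "s1", "s2"])
        scores = ScoreVector(pd.Series([0.0, 1.0, 2.0], index=states.index), "sig", 1)
        with pytest.raises(ValueError, match="weird"):
            severity_association(scores, states, ["a", "b"])

    def test_monotone_reencoding_preserves_sign(self, rng):
        from liveraging.signature_scoring import ScoreVector
        states = pd.Series([["mild", "moderate", "severe"][i % 3] for i in range(30)],
                           index=[f"s{i}" for i in range(30)])
        base = states.map({"mild": 0, "moderate": 1, "severe": 2}).to_numpy(float)
        scores = ScoreVector(
            pd.Series(base + rng.normal(0, 0.5, 30), index=states.index), "sig", 5
        )
        r_unit = severity_association(scores, states, ["mild", "moderate", "severe"]).r
        # unequal-spacing re-encoding via Pearson on a transformed axis
        uneven = states.map({"mild": 0, "moderate": 4, "severe": 5}).to_numpy(float)
        r_uneven = np.corrcoef(scores.scores.to_numpy(), uneven)[0, 1]
        assert np.sign(r_unit) == np.sign(r_uneven) == 1.0

    def test_cohort_recovery_and_null(self):
        sig = GeneSignature("sig", up={f"u{i}" for i in range(40)},
                            down={f"d{i}" for i in range(40)})
        matrix, states = simulate_cohort(sig, 200, ["n", "mild", "severe"],
                                         effect=1.0, seed=31)
        vec = signature_score(zscore_matrix(matrix.values), sig)
        assert severity_association(vec, states, ["n", "mild", "severe"]).r > 0.8
        small = 0
        for seed in range(10):
            m0, s0 = simulate_cohort(sig, 200, ["n", "mild", "severe"],
                                     effect=0.0, seed=100 + seed)
            v0 = signature_score(zscore_matrix(m0.values), sig)
            if abs(severity_association(v0, s0, ["n", "mild", "severe"]).r) < 0.2:
                small += 1
        assert small >= 8  # null correlations should be near zero almost always


class TestHomologs:
    MAP = pd.DataFrame({"mouse": ["Alb", "Trp53", "Cyp1a1", "Gstp1", "Gstp2"],
                        "human": ["ALB", "TP53", "CYP1A1", "GSTP1", "GSTP1"]})

    def test_one_to_one(self):
        sig = GeneSignature("s", up={"Alb"})
        mapped, report = map_homologs(sig, self.MAP)
        assert mapped.up == {"ALB"} and report.n_unmapped == 0

    def test_unmapped_dropped_and_counted(self):
        sig = GeneSignature("s", up={"Alb", "NotAGene"})
        mapped, report = map_homologs(sig, self.MAP)
        assert mapped.up == {"ALB"} and report.n_unmapped == 1

    def test_conflicting_directions_excluded(self):
        # Gstp1 (up) and Gstp2 (down) both map to GSTP1
        sig = GeneSignature("s", up={"Gstp1"}, down={"Gstp2"})
        mapped, report = map_homologs(sig, self.MAP)
        assert report.conflicts == {"GSTP1"}
        assert "GSTP1" not in mapped.genes

    def test_duplicate_pairs_rejected(self):
        bad = pd.DataFrame({"mouse": ["Alb", "Alb"], "human": ["ALB", "ALB"]})
        with pytest.raises(ValueError):
            map_homologs(GeneSignature("s", up={"Alb"}), bad)
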