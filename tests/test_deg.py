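"""Moderated-t DEG calling, BH adjustment and target-overlap rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from teashuttle import deg, simulate
from teashuttle.errors import InsufficientReplicatesError


def tiny_study(rng=None, n_genes=5, n1=4, n0=3):
    rng = rng or np.random.default_rng(0)
    cols = [f"t{i}" for i in range(n1)] + [f"n{i}" for i in range(n0)]
    classes = pd.Series({**{f"t{i}": "LaBC" for i in range(n1)},
                         **{f"n{i}": "normal" for i in range(n0)}})
    mat = pd.DataFrame(rng.normal(7, 1, size=(n_genes, n1 + n0)),
                       index=[f"g{i}" for i in range(n_genes)],
                       columns=cols)
    return deg.ExpressionStudy(mat, classes)


class TestNormalize:
    def test_logged_input_unchanged(self):
        study = tiny_study()
        out = deg.normalize(study)
        pd.testing.assert_frame_equal(out.matrix, study.matrix)

    def test_raw_scale_detected_and_logged(self):
        study = tiny_study()
        raw = deg.ExpressionStudy(2.0 ** study.matrix * 16,
                                  study.sample_classes,
                                  already_logged=False)
        out = deg.normalize(raw)
        assert float(out.matrix.to_numpy().max()) < 50

    def test_quantile_columns_share_sorted_values(self):
        out = deg.normalize(tiny_study(), quantile=True)
        cols = [np.sort(out.matrix[c].to_numpy())
                for c in out.matrix.columns]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0])


class TestModeratedT:
    def test_zero_prior_df_equals_pooled_t_oracle(self):
        """With the prior switched off the statistic is the textbook
        pooled-variance two-sample t."""
        study = tiny_study()
        table = deg.moderated_t(study, "LaBC", prior_df=0)
        x1 = study.matrix[study.samples_of("LaBC")].to_numpy()
        x0 = study.matrix[study.samples_of("normal")].to_numpy()
        for i, row in table.iterrows():
            t, p = stats.ttest_ind(x1[i], x0[i], equal_var=True)
            assert row["t_stat"] == pytest.approx(t, abs=1e-10)
            assert row["p_value"] == pytest.approx(p, abs=1e-10)

    def test_identical_group_means_give_null_result(self):
        study = tiny_study()
        mat = study.matrix.copy()
        mat.iloc[0] = [1, 2, 3, 4, 2, 2.5, 3]   # equal means of 2.5
        study = deg.ExpressionStudy(mat, study.sample_classes)
        row = deg.moderated_t(study, "LaBC").iloc[0]
        assert row["log2fc"] == pytest.approx(0.0)
        assert row["t_stat"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_label_swap_negates_log2fc(self):
        study = tiny_study()
        swapped = deg.ExpressionStudy(
            study.matrix,
            study.sample_classes.map(
                {"LaBC": "normal", "normal": "LaBC"}))
        a = deg.moderated_t(study, "LaBC")["log2fc"].to_numpy()
        b = deg.moderated_t(swapped, "LaBC")["log2fc"].to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_small_class_raises(self):
        study = tiny_study(n0=1)
        with pytest.raises(InsufficientReplicatesError):
            deg.moderated_t(study, "LaBC")

    def test_bh_step_up_hand_example(self):
        """p = (.01,.02,.03,.04) with m=4 all adjust to 0.04."""
        adj = multipletests([0.01, 0.02, 0.03, 0.04],
                            method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04] * 4)

    def test_spiked_recovery_small(self):
        cfg = simulate.small_test_config(11, noise_sd=0.2)
        study, truth = simulate.generate_expression(cfg)
        table = deg.call_degs(deg.moderated_t(study, "LaBC"))
        calls = table.set_index("gene")["call"]
        up = truth.spiked_genes["LaBC"]["up"]
        down = truth.spiked_genes["LaBC"]["down"]
        correct = (sum(calls[g] == "up" for g in up)
                   + sum(calls[g] == "down" for g in down))
        assert correct / (len(up) + len(down)) >= 0.9


class TestCalls:
    def table(self, adj_p, fc):
        lfc = np.log2(abs(fc)) * np.sign(fc)
        return pd.DataFrame({"gene": ["g"], "log2fc": [lfc],
                             "signed_fc": [fc], "t_stat": [0.0],
                             "p_value": [adj_p], "adj_p": [adj_p],
                             "call": ["ns"]})

    @pytest.mark.parametrize("adj_p,fc,expected", [
        (0.04, 2.0, "up"), (0.04, -2.0, "down"),
        (0.05, 2.0, "ns"),          # strict adj-p
        (0.04, 1.5, "ns"),          # strict FC
        (0.04, -1.5, "ns"),
    ])
    def test_strict_thresholds(self, adj_p, fc, expected):
        out = deg.call_degs(self.table(adj_p, fc))
        assert out["call"].iloc[0] == expected

    def test_signed_fc_convention(self):
        np.testing.assert_allclose(
            deg.signed_fold_change(np.array([1.0, 0.0, -1.0])),
            [2.0, 1.0, -2.0])


class TestTargetsAndOverlap:
    def test_qualification_boundaries(self):
        preds = pd.DataFrame({
            "compound_id": ["c"] * 4,
            "gene": ["A", "B", "C", "D"],
            "probability": [0.10, 0.09, 0.60, 0.60],
            "source": ["swiss_like", "swiss_like", "super_like",
                       "super_like"],
            "model_accuracy": [np.nan, np.nan, 0.90, 0.89]})
        per_compound, pooled = deg.qualify_targets(preds)
        assert pooled == {"A", "C"}
        assert per_compound["c"] == {"A", "C"}

    def test_qualification_equals_row_filter_oracle(self):
        rng = np.random.default_rng(5)
        preds = pd.DataFrame({
            "compound_id": rng.choice(["c1", "c2"], 200),
            "gene": [f"G{i}" for i in rng.integers(0, 50, 200)],
            "probability": rng.uniform(0, 1, 200),
            "source": rng.choice(["swiss_like", "super_like"], 200),
            "model_accuracy": rng.uniform(0.5, 1.0, 200)})
        _, pooled = deg.qualify_targets(preds)
        keep = ((preds.source == "swiss_like") & (preds.probability >= .1)
                | (preds.source == "super_like")
                & (preds.probability >= .6)
                & (preds.model_accuracy >= .9))
        assert pooled == set(preds[keep]["gene"])

    def test_overlap_rules(self):
        calls = pd.DataFrame({"gene": ["A", "B", "C"],
                              "call": ["up", "up", "down"]})
        assert deg.overlap(calls, {"B", "C", "Z"}, "up") == ["B"]
        assert deg.overlap(calls, {"X"}, "up") == []
        assert deg.overlap(calls, {"A", "B", "C"}, "up") == ["A", "B"]

    def test_duplicate_probes_collapse_to_min_p(self):
        recs = pd.DataFrame({"gene": ["A", "A", "B"],
                             "p_value": [0.5, 0.01, 0.3],
                             "adj_p": [0.5, 0.02, 0.3]})
        out = deg.collapse_probes(recs)
        assert len(out) == 2
        assert out.loc[out.gene == "A", "p_value"].iloc[0] == 0.01
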