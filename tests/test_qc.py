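"""QC metrics: Spearman matrix, median correlation, gene-level
metrics, flagging semantics and batch-failure propagation."""

import numpy as np
import pandas as pd
import pytest

import ffpeqc
from ffpeqc.matrix import ExpressionMatrix
from ffpeqc.qc import (
    BATCH_CONTROL_FAIL,
    LOW_CORRELATION,
    LOW_GENE_READS,
    LOW_GENE_TPM4,
    QCThresholds,
    flag_samples,
    gene_level_metrics,
    median_cor_expr,
    pairwise_spearman,
    propagate_batch_failure,
)


def expr(arr, layer="logCPM") -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        layer,
    )


def spearman_oracle(values: np.ndarray) -> np.ndarray:
    """Rank (average ties) each column, then Pearson."""

    def avg_rank(col):
        order = np.argsort(col, kind="stable")
        ranks = np.empty(len(col), dtype=float)
        i = 0
        sorted_vals = col[order]
        while i < len(col):
            j = i
            while j + 1 < len(col) and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1
            i = j + 1
        return ranks

    ranked = np.column_stack([avg_rank(values[:, j]) for j in range(values.shape[1])])
    return np.corrcoef(ranked, rowvar=False)


class TestPairwiseSpearman:
    def test_identical_samples(self):
        m = expr([[1, 1], [5, 5], [2, 2]])
        corr = pairwise_spearman(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        a = np.array([1.0, 4.0, 2.0, 9.0, 3.0])
        m = expr(np.column_stack([a, np.exp(a)]))
        assert pairwise_spearman(m).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # ranks (1..5) vs (2,1,3,5,4): sum d^2 = 4,
        # rho = 1 - 6*4/(5*24) = 0.8
        m = expr(np.column_stack([[1, 2, 3, 4, 5], [2, 1, 3, 5, 4]]))
        assert pairwise_spearman(m).iloc[0, 1] == pytest.approx(0.8)

    def test_matches_rank_then_pearson_oracle(self, rng):
        values = rng.gamma(2, 50, size=(30, 6))
        m = expr(values)
        ours = pairwise_spearman(m).to_numpy()
        assert np.allclose(ours, spearman_oracle(values), atol=1e-10)

    def test_constant_sample_is_nan_with_warning(self):
        vals = np.column_stack([[1, 2, 3], [3, 3, 3], [2, 1, 4]])
        with pytest.warns(UserWarning, match="constant"):
            corr = pairwise_spearman(expr(vals))
        assert np.isnan(corr.iloc[0, 1])
        assert corr.iloc[1, 1] == 1.0


class TestMedianCorExpr:
    def test_identical_cohort(self):
        m = expr(np.column_stack([[1, 5, 2]] * 3))
        assert (median_cor_expr(pairwise_spearman(m)) == 1.0).all()

    def test_median_of_three(self):
        corr = pd.DataFrame(
            [
                [1.0, 0.9, 0.8, 0.1],
                [0.9, 1.0, 0.5, 0.2],
                [0.8, 0.5, 1.0, 0.3],
                [0.1, 0.2, 0.3, 1.0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
        )
        assert median_cor_expr(corr)["a"] == pytest.approx(0.8)

    def test_cohort_of_one_rejected(self):
        with pytest.raises(ValueError):
            median_cor_expr(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))

    def test_stable_under_subcohort(self, small_cohort):
        """Value in a 20-sample subcohort stays within 0.05 of the
        full-cohort value."""
        logcpm = ffpeqc.tmm_log2cpm(small_cohort["counts"])
        full = median_cor_expr(pairwise_spearman(logcpm))
        target = full.index[0]
        rng = np.random.default_rng(1)
        others = [s for s in logcpm.sample_ids if s != target]
        sub_ids = [target] + list(rng.choice(others, size=19, replace=False))
        sub = median_cor_expr(pairwise_spearman(logcpm.subset_samples(sub_ids)))
        assert abs(sub[target] - full[target]) < 0.05


class TestGeneLevelMetrics:
    def test_tpm4_strict_inequality(self):
        counts = expr([[10], [20], [30]], layer="counts")
        tpm = ExpressionMatrix(
            pd.DataFrame({"s0": [4.0, 4.01, 1000.0]}, index=["g0", "g1", "g2"]), "TPM"
        )
        out = gene_level_metrics(counts, tpm)
        assert out.loc["s0", "gene_tpm4"] == 2
        assert out.loc["s0", "gene_reads"] == 60

    def test_sample_mismatch_rejected(self):
        counts = expr([[1], [2]], layer="counts")
        tpm = ExpressionMatrix(
            pd.DataFrame({"other": [5e5, 5e5]}, index=["g0", "g1"]), "TPM"
        )
        with pytest.raises(ValueError, match="sample"):
            gene_level_metrics(counts, tpm)


class TestFlagSamples:
    @pytest.mark.parametrize(
        "metrics,expected_status,expected_reasons",
        [
            ((0.74, 30e6, 12000), "FAIL", (LOW_CORRELATION,)),
            ((0.80, 24e6, 11000), "FAIL", (LOW_GENE_READS, LOW_GENE_TPM4)),
            ((0.75, 25e6, 11400), "PASS", ()),
        ],
    )
    def test_criteria_truth_table(self, metrics, expected_status, expected_reasons):
        table = pd.DataFrame(
            [metrics], columns=["median_cor_expr", "gene_reads", "gene_tpm4"], index=["s"]
        )
        out = flag_samples(table, QCThresholds())
        assert out.loc["s", "status"] == expected_status
        assert out.loc["s", "fail_reasons"] == expected_reasons

    def test_missing_metric_names_sample(self):
        table = pd.DataFrame(
            {"median_cor_expr": [0.9], "gene_reads": [np.nan], "gene_tpm4": [12000]},
            index=["sampleX"],
        )
        with pytest.raises(ValueError, match="sampleX"):
            flag_samples(table)

    def test_monotone_in_metrics(self, rng):
        """Improving any metric never flips PASS to FAIL."""
        thr = QCThresholds()
        base = pd.DataFrame(
            {
                "median_cor_expr": rng.uniform(0.5, 1.0, 50),
                "gene_reads": rng.uniform(1e7, 4e7, 50),
                "gene_tpm4": rng.uniform(8000, 15000, 50),
            },
            index=[f"s{i}" for i in range(50)],
        )
        flagged = flag_samples(base, thr)
        better = base.copy()
        better["median_cor_expr"] = np.minimum(base["median_cor_expr"] + 0.1, 1.0)
        better["gene_reads"] += 5e6
        better["gene_tpm4"] += 1000
        improved = flag_samples(better, thr)
        was_pass = flagged["status"] == "PASS"
        assert (improved.loc[was_pass, "status"] == "PASS").all()


class TestBatchPropagation:
    def design(self, controls):
        return pd.DataFrame(
            {
                "batch_id": ["b1"] * 4,
                "is_technical_control": [s in controls for s in "abcd"],
            },
            index=list("abcd"),
        )

    def flagged(self, fails):
        return pd.DataFrame(
            {
                "status": ["FAIL" if s in fails else "PASS" for s in "abcd"],
                "fail_reasons": [
                    (LOW_CORRELATION,) if s in fails else () for s in "abcd"
                ],
            },
            index=list("abcd"),
        )

    def test_failing_control_condemns_batch(self):
        out = propagate_batch_failure(self.flagged("a"), self.design("a"))
        assert (out["status"] == "FAIL").all()
        assert all(BATCH_CONTROL_FAIL in r for r in out["fail_reasons"])
        assert out.loc["b", "fail_reasons"] == (BATCH_CONTROL_FAIL,)

    def test_passing_control_leaves_study_failure_local(self):
        out = propagate_batch_failure(self.flagged("b"), self.design("a"))
        assert out.loc["b", "status"] == "FAIL"
        assert (out.loc[["a", "c", "d"], "status"] == "PASS").all()

    def test_no_controls_is_noop_with_warning(self):
        flagged = self.flagged("b")
        with pytest.warns(UserWarning, match="no technical control"):
            out = propagate_batch_failure(flagged, self.design(""))
        pd.testing.assert_frame_equal(out, flagged)

    def test_fail_rate_decreases_with_quality(self):
        """Synthetic cohorts: FAIL rate non-increasing in latent quality
        (majority over seeds, thresholds scaled to the cohort)."""
        from ffpeqc import simulate as sim

        wins = 0
        for seed in range(3):
            params = sim.SimulationParams(
                n_genes=600, n_samples=20, n_batches=2, n_replicate_groups=1, seed=seed
            )
            bundle = sim.simulate_cohort(params)
            counts = bundle["counts"]
            tpm = ffpeqc.counts_to_tpm(counts, bundle["catalog"]["length_bp"])
            logcpm = ffpeqc.tmm_log2cpm(counts)
            metrics = pd.DataFrame(
                {
                    "median_cor_expr": median_cor_expr(pairwise_spearman(logcpm)),
                    "gene_reads": counts.values.sum(axis=0),
                    "gene_tpm4": (tpm.values > 4).sum(axis=0),
                }
            )
            thr = QCThresholds(cor_min=0.75, reads_min=1_200_000, tpm4_min=320)
            flagged = flag_samples(metrics, thr)
            q = bundle["truth"]["quality"]
            lo = flagged.loc[q.index[q < q.median()], "status"].eq("FAIL").mean()
            hi = flagged.loc[q.index[q >= q.median()], "status"].eq("FAIL").mean()
            if lo >= hi:
                wins += 1
        assert wins >= 2
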