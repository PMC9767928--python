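"""Metabolomics statistics: QC filter, TIC, batch regression, moderated t, BH."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocean.errors import ContrastError, DesignError
from ocean.stats import (
    AbundanceMatrix,
    _moderated_t_arrays,
    bh_adjust,
    differential_pipeline,
    log2_transform,
    moderated_t,
    qc_rsd_filter,
    remove_batch_effect,
    tic_normalize,
)


def _matrix(areas: dict, groups, batches, is_qc):
    idx = pd.Index([f"s{i}" for i in range(len(groups))], name="sample")
    return AbundanceMatrix(
        pd.DataFrame(areas, index=idx),
        pd.DataFrame({"group": groups, "batch": batches, "is_qc": is_qc}, index=idx),
    )


class TestQCFilter:
    def test_stable_and_noisy_metabolites(self):
        mat = _matrix(
            {"stable": [100, 100, 100, 100, 100], "noisy": [50, 50, 10, 20, 30]},
            ["A", "A", "", "", ""],
            ["B0", "B0", "B0", "B0", "B0"],
            [False, False, True, True, True],
        )
        kept, dropped = qc_rsd_filter(mat, 0.30)
        # noisy QC areas [10,20,30]: rsd = 10/20 = 0.5 -> dropped
        assert dropped == ["noisy"]
        assert list(kept.areas.columns) == ["stable"]

    def test_permissive_threshold_drops_nothing(self):
        mat = _matrix(
            {"m": [5, 5, 10, 15, 12]},
            ["A", "A", "", "", ""],
            ["B0"] * 5,
            [False, False, True, True, True],
        )
        _, dropped = qc_rsd_filter(mat, 1.0)
        assert dropped == []

    def test_requires_two_qc_samples(self):
        mat = _matrix({"m": [1, 2]}, ["A", "A"], ["B0", "B0"], [False, False])
        with pytest.raises(DesignError):
            qc_rsd_filter(mat)


class TestTIC:
    def test_rows_sum_to_one(self):
        mat = _matrix(
            {"a": [2.0, 7.0], "b": [3.0, 0.0], "c": [5.0, 0.0]},
            ["A", "A"], ["B0", "B0"], [False, False],
        )
        norm = tic_normalize(mat)
        assert np.allclose(norm.areas.sum(axis=1), 1.0)
        assert list(norm.areas.iloc[0]) == pytest.approx([0.2, 0.3, 0.5])
        assert norm.areas.iloc[1, 0] == 1.0  # single-signal sample

    def test_zero_sample_named(self):
        mat = _matrix({"a": [1.0, 0.0]}, ["A", "A"], ["B0", "B0"], [False, False])
        with pytest.raises(DesignError, match="s1"):
            tic_normalize(mat)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0.1, 1e6), min_size=3, max_size=3),
            min_size=2, max_size=6,
        )
    )
    def test_rows_sum_to_one_property(self, rows):
        mat = _matrix(
            {f"m{j}": [r[j] for r in rows] for j in range(3)},
            ["A"] * len(rows), ["B0"] * len(rows), [False] * len(rows),
        )
        assert np.allclose(tic_normalize(mat).areas.sum(axis=1), 1.0)


class TestBatchCorrection:
    def test_constant_offset_removed_balanced_groups(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(8, 5))
        batch = np.array([0, 1] * 4)
        y = base + 2.5 * batch[:, None]
        mat = _matrix(
            {f"m{j}": y[:, j] for j in range(5)},
            ["A", "A", "A", "A", "B", "B", "B", "B"],
            [f"B{b}" for b in batch],
            [False] * 8,
        )
        mat = AbundanceMatrix(mat.areas, mat.design, log_scale=True)
        corrected = remove_batch_effect(mat)
        means = corrected.areas.groupby(mat.design["batch"]).mean()
        assert np.allclose(means.loc["B0"], means.loc["B1"], atol=1e-10)

    def test_single_batch_identity_with_warning(self):
        mat = _matrix(
            {"m": [1.0, 2, 3, 4]}, ["A", "A", "B", "B"], ["B0"] * 4, [False] * 4
        )
        with pytest.warns(UserWarning):
            out = remove_batch_effect(mat)
        pd.testing.assert_frame_equal(out.areas, mat.areas)

    def test_confounded_design_raises(self):
        mat = _matrix(
            {"m": [1.0, 2, 3, 4]},
            ["A", "A", "B", "B"],
            ["B0", "B0", "B1", "B1"],  # batch == group
            [False] * 4,
        )
        with pytest.raises(DesignError):
            remove_batch_effect(mat)

    def test_recovers_planted_batch_coefficients(self):
        """Known per-metabolite batch shifts are estimated within MC error."""
        rng = np.random.default_rng(42)
        n_per = 30
        beta = rng.normal(0, 1, size=10)  # true batch-1 effect per metabolite
        groups = ["A", "B"] * n_per
        batch = np.array([0] * n_per + [1] * n_per)
        base = rng.normal(12, 1, size=10)
        y = (
            base
            + rng.normal(0, 0.2, size=(2 * n_per, 10))
            + beta * batch[:, None]
        )
        mat = _matrix(
            {f"m{j}": y[:, j] for j in range(10)},
            groups, [f"B{b}" for b in batch], [False] * 2 * n_per,
        )
        mat = AbundanceMatrix(mat.areas, mat.design, log_scale=True)
        corrected = remove_batch_effect(mat)
        shift = (mat.areas - corrected.areas).groupby(pd.Series(batch, mat.areas.index)).mean()
        est = (shift.loc[1] - shift.loc[0]).values
        assert np.allclose(est, beta, atol=5 * 0.2 / np.sqrt(n_per))


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(1)
        y1 = rng.normal(0, 1, size=(5, 30))
        y2 = rng.normal(0.5, 1, size=(6, 30))
        t, p, delta, d0, _ = _moderated_t_arrays(y1, y2, d0=0.0)
        from scipy import stats as sps

        t_ref, p_ref = sps.ttest_ind(y1, y2, axis=0, equal_var=True)
        assert np.allclose(t, t_ref)
        assert np.allclose(p, p_ref)

    def test_identical_variances_concentrate_prior_on_common_value(self):
        """All sample variances equal -> d0 = inf and the shrinkage target
        equals the common variance (up to the finite-df log-scale bias
        exp(log(df/2) - digamma(df/2)), which vanishes as df grows)."""
        rng = np.random.default_rng(2)
        n = 60  # large df so the log-bias factor is ~1.009
        y1 = np.tile(rng.normal(0, 1, size=(n, 1)), (1, 20))
        y2 = np.tile(rng.normal(0, 1, size=(n, 1)), (1, 20))
        _, _, _, d0, s0_sq = _moderated_t_arrays(y1, y2)
        assert np.isinf(d0)
        df = 2 * n - 2
        s2 = (
            ((y1 - y1.mean(0)) ** 2).sum(0) + ((y2 - y2.mean(0)) ** 2).sum(0)
        ) / df
        assert np.allclose(s0_sq, s2, rtol=0.02)

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma lmFit/eBayes via Rscript."""
        rng = np.random.default_rng(5)
        n1, n2, m = 5, 5, 40
        y1 = rng.normal(0, 1, (n1, m))
        y2 = rng.normal(0.3, 1.5 * rng.uniform(0.5, 2, m), (n2, m))
        mat = np.vstack([y1, y2]).T
        df = pd.DataFrame(
            mat,
            index=[f"met{i}" for i in range(m)],
            columns=[f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)],
        )
        df.to_csv(tmp_path / "x.csv")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{tmp_path}/x.csv", row.names=1))
            group <- factor(c(rep("A",{n1}), rep("B",{n2})), levels=c("B","A"))
            fit <- eBayes(lmFit(x, model.matrix(~group)))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.csv(out, "{tmp_path}/limma.csv")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        t, p, _, d0, s0_sq = _moderated_t_arrays(y1, y2)
        assert d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
        assert s0_sq == pytest.approx(ref["s02"].iloc[0], rel=1e-8)
        assert np.allclose(t, ref["t"].values, atol=1e-8)
        assert np.allclose(p, ref["p"].values, atol=1e-10)

    def test_invariant_to_metabolite_and_sample_order(self, abundance6):
        mat = log2_transform(tic_normalize(abundance6))
        table = moderated_t(mat.drop_qc(), ("CASE", "CTRL"))
        shuffled = AbundanceMatrix(
            mat.areas.iloc[::-1, ::-1], mat.design.iloc[::-1], log_scale=True
        )
        table2 = moderated_t(shuffled.drop_qc(), ("CASE", "CTRL"))
        merged = table.set_index("metabolite").join(
            table2.set_index("metabolite"), rsuffix="_2"
        )
        assert np.allclose(merged["t_value"], merged["t_value_2"])

    def test_contrast_errors(self, abundance6):
        with pytest.raises(ContrastError):
            moderated_t(abundance6, ("CASE", "NOPE"))

    def test_null_type_one_error_near_nominal(self):
        """~5% of null p-values under 0.05 (120 reps x 200 metabolites here)."""
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(120):
            y1 = rng.normal(0, 1, size=(6, 200))
            y2 = rng.normal(0, 1, size=(6, 200))
            _, p, *_ = _moderated_t_arrays(y1, y2)
            hits += (p < 0.05).sum()
            total += p.size
        rate = hits / total
        band = 2.807 * np.sqrt(0.05 * 0.95 / total)  # 99.5% two-sided
        assert abs(rate - 0.05) < band + 0.003

    def test_planted_effects_raise_mean_abs_t(self):
        rng = np.random.default_rng(9)
        m, frac = 200, 0.1
        planted = rng.choice(m, size=int(m * frac), replace=False)
        shift = np.zeros(m)
        shift[planted] = 2.0  # 2 sd effect
        y1 = rng.normal(shift, 1, size=(6, m))
        y2 = rng.normal(0, 1, size=(6, m))
        t, *_ = _moderated_t_arrays(y1, y2)
        null_mask = np.ones(m, bool)
        null_mask[planted] = False
        assert np.abs(t[planted]).mean() > np.abs(t[null_mask]).mean()


class TestBH:
    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_trivial_cases(self):
        assert bh_adjust([0.2]).tolist() == [0.2]
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert bh_adjust([]).size == 0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_statsmodels_and_dominates_p(self, p):
        from statsmodels.stats.multitest import multipletests

        mine = bh_adjust(p)
        _, ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(mine, ref)
        assert (mine >= np.asarray(p) - 1e-15).all()

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        permuted = [p[i] for i in perm]
        adjusted_then_unpermuted = np.empty(len(p))
        adj_perm = bh_adjust(permuted)
        for out_pos, in_pos in enumerate(perm):
            adjusted_then_unpermuted[in_pos] = adj_perm[out_pos]
        assert np.allclose(adjusted_then_unpermuted, bh_adjust(p))


def test_full_pipeline_smoke(abundance6):
    table = differential_pipeline(abundance6, ("CASE", "CTRL"))
    assert set(table.columns) == {"metabolite", "t_value", "log2fc", "p", "adj_p"}
    assert (table["adj_p"] >= table["p"] - 1e-15).all()
    assert (table["adj_p"] <= 1).all()
    assert np.isfinite(table["t_value"]).all()
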