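"""Contrast engines: moderated/pooled/Welch t, BH, gates, calibration."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from isomirkit.differential import (
    ContrastConfig,
    ModerationPrior,
    bh_adjust,
    de_filter,
    estimate_prior,
    log2_fold_change,
    moderated_t,
    student_t,
    welch_t,
)


def _frame(y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(y, columns=[f"s{i}" for i in range(y.shape[1])])


def _groups(n_a, n_b):
    return [f"s{i}" for i in range(n_a)], [f"s{i}" for i in range(n_a, n_a + n_b)]


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "a, b, pc, expected", [(40, 10, 0, 2.0), (10, 40, 0, -2.0), (7, 7, 0.5, 0.0)]
    )
    def test_values(self, a, b, pc, expected):
        assert log2_fold_change(a, b, pc) == pytest.approx(expected)


class TestBH:
    def test_hand_oracle(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_all_ones(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @staticmethod
    def _hand_bh(p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        return q

    def test_matches_hand_oracle_on_all_permutations(self, rng):
        base = rng.random(6).tolist()
        for perm in itertools.permutations(base):
            assert np.allclose(bh_adjust(list(perm)), self._hand_bh(list(perm)))

    def test_matches_statsmodels_and_is_monotone(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPrior:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(123)
        d0, s0, d = 4.0, 0.05, 8
        sigma2 = d0 * s0 / rng.chisquare(d0, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        prior = estimate_prior(s2, d)
        assert abs(prior.d0 - d0) / d0 < 0.20
        assert abs(prior.s0_sq - s0) / s0 < 0.10

    def test_identical_variances_hit_infinite_prior(self):
        prior = estimate_prior(np.full(100, 2.0), df=8)
        assert np.isinf(prior.d0)
        # infinite prior => normal reference distribution (df = inf)
        rpm = pd.DataFrame(np.ones((3, 10)), columns=[f"s{i}" for i in range(10)])
        res = moderated_t(rpm, *_groups(5, 5), prior=prior)
        assert np.isinf(res.df).all()

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior([1.0], df=4)


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self, rng):
        rpm = pd.DataFrame(rng.lognormal(3, 1, size=(80, 12)),
                           columns=[f"s{i}" for i in range(12)])
        a, b = _groups(6, 6)
        res = moderated_t(rpm, a, b, prior=ModerationPrior(0.0, 1.0))
        y = np.log2(rpm + 0.5)
        t_ref, p_ref = stats.ttest_ind(y[a], y[b], axis=1)
        assert np.abs(res.t_stat.to_numpy() - t_ref).max() < 1e-10
        assert np.abs(res.p.to_numpy() - p_ref).max() < 1e-10

    def test_infinite_prior_uses_common_variance(self, rng):
        rpm = pd.DataFrame(rng.lognormal(3, 1, size=(40, 8)),
                           columns=[f"s{i}" for i in range(8)])
        a, b = _groups(4, 4)
        res = moderated_t(rpm, a, b, prior=ModerationPrior(np.inf, 0.7))
        y = np.log2(rpm + 0.5)
        diff = y[a].mean(axis=1) - y[b].mean(axis=1)
        expected = diff / np.sqrt(0.7 * (1 / 4 + 1 / 4))
        assert np.allclose(res.t_stat, expected)

    def test_true_effect_gets_smallest_p(self, rng):
        n_feat = 100
        y = rng.normal(0, 1, size=(n_feat, 10))
        y[0, :5] += 4.0  # one planted shift among nulls
        rpm = pd.DataFrame(2.0 ** y, columns=[f"s{i}" for i in range(10)])
        res = moderated_t(rpm, *_groups(5, 5))
        assert res.p.idxmin() == 0

    def test_zero_variance_equal_means(self):
        rpm = pd.DataFrame(np.ones((3, 8)), columns=[f"s{i}" for i in range(8)])
        res = moderated_t(rpm, *_groups(4, 4), prior=ModerationPrior(0.0, 1.0))
        assert (res.t_stat == 0).all() and (res.p == 1).all()

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: Bioconductor limma on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        y = rng.normal(5, 1, size=(150, 8)) * rng.lognormal(0, 0.4, size=(150, 1))
        ycsv = tmp_path / "y.csv"
        pd.DataFrame(y).to_csv(ycsv, index=False)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.csv('{ycsv}'))
            design <- cbind(Intercept=1, AvsB=c(rep(1,4), rep(0,4)))
            fit <- eBayes(lmFit(y, design))
            write.csv(data.frame(t=fit$t[,'AvsB'], p=fit$p.value[,'AvsB']),
                      '{tmp_path}/out.csv', row.names=FALSE)
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.csv")
        rpm = pd.DataFrame(2.0 ** y - 0.5, columns=[f"s{i}" for i in range(8)])
        res = moderated_t(rpm, *_groups(4, 4))
        assert np.abs(res.t_stat.to_numpy() - ref.t.to_numpy()).max() < 1e-8
        assert np.abs(res.p.to_numpy() - ref.p.to_numpy()).max() < 1e-8


class TestWelch:
    def test_hand_computed_example(self):
        rpm = pd.DataFrame(
            2.0 ** np.array([[1, 2, 3, 4, 5, 6]], dtype=float) - 0.5,
            columns=[f"s{i}" for i in range(6)],
        )
        res = welch_t(rpm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # groups (1,2,3) vs (4,5,6): equal variances 1, t = -3/sqrt(2/3)
        assert res.t_stat.iloc[0] == pytest.approx(-3 / np.sqrt(2 / 3))
        assert res.df.iloc[0] == pytest.approx(4.0)
        assert res.p.iloc[0] == pytest.approx(
            2 * stats.t.sf(3 / np.sqrt(2 / 3), 4)
        )

    def test_equal_variance_equal_n_recovers_pooled_df(self, rng):
        y = rng.normal(0, 1, size=(50, 10))
        rpm = pd.DataFrame(2.0 ** y, columns=[f"s{i}" for i in range(10)])
        res = welch_t(rpm, *_groups(5, 5))
        assert np.all(res.df <= 8 + 1e-9)
        tw, pw = stats.ttest_ind(np.log2(rpm + 0.5).iloc[:, :5],
                                 np.log2(rpm + 0.5).iloc[:, 5:], axis=1, equal_var=False)
        assert np.allclose(res.t_stat, tw) and np.allclose(res.p, pw)

    def test_identical_groups(self):
        rpm = pd.DataFrame(np.tile([[4.0], [9.0]], (1, 8)),
                           columns=[f"s{i}" for i in range(8)])
        res = welch_t(rpm, *_groups(4, 4))
        assert (res.t_stat == 0).all() and (res.p == 1).all()


class TestDeFilter:
    def _records(self):
        return pd.DataFrame(
            {
                "log_fc": [2.5, -1.5, 0.5, -2.0],
                "t_stat": [5, -4, 1, -4.5],
                "df": [10.0] * 4,
                "p": [0.001, 0.002, 0.5, 0.004],
                "p_adj": [0.004, 0.05, 0.6, 0.008],
                "regulation": ["up", "down", "up", "down"],
            },
            index=["a", "b", "c", "d"],
        )

    def test_strict_gates(self):
        kept = de_filter(self._records(), ContrastConfig(fc_threshold=2.0, alpha=0.05))
        # "b" dropped: p_adj == alpha exactly; "c" dropped: |fc| too small
        assert list(kept.index) == ["a", "d"]

    def test_empty_input(self):
        empty = self._records().iloc[:0]
        assert len(de_filter(empty, ContrastConfig())) == 0

    def test_regulation_sign_consistency(self, rng):
        rpm = pd.DataFrame(rng.lognormal(3, 1, size=(60, 8)),
                           columns=[f"s{i}" for i in range(8)])
        res = moderated_t(rpm, *_groups(4, 4))
        assert ((res.regulation == "up") == (res.log_fc > 0)).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ContrastConfig(fc_threshold=0.5)
        with pytest.raises(ValueError):
            ContrastConfig(alpha=1.5)
        with pytest.raises(ValueError):
            ContrastConfig(test="anova")


class TestCalibration:
    def test_null_familywise_discovery_fraction(self):
        """All-null log-normal data: few replicates yield any BH discovery."""
        rng = np.random.default_rng(2024)
        n_feat, n, reps = 1000, 10, 200
        cols = [f"s{i}" for i in range(2 * n)]
        a, b = cols[:n], cols[n:]
        hits = 0
        for _ in range(reps):
            y = rng.normal(3.0, 1.0, size=(n_feat, 2 * n))
            rpm = pd.DataFrame(2.0 ** y, columns=cols)
            res = moderated_t(rpm, a, b)
            hits += int((res.p_adj < 0.05).any())
        assert hits / reps <= 0.10

    def test_moderation_dominates_student_at_small_n(self):
        """With n=3+3 and heteroscedastic features, moderation finds at least
        as many true effects at matched empirical FDR."""
        rng = np.random.default_rng(31)
        n_feat, n_true = 500, 50
        sd = rng.lognormal(-0.5, 0.5, size=n_feat)
        y = rng.normal(0, 1, size=(n_feat, 6)) * sd[:, None]
        y[:n_true, :3] += 1.5
        rpm = pd.DataFrame(2.0 ** y, columns=[f"s{i}" for i in range(6)])
        a, b = _groups(3, 3)
        truth = np.zeros(n_feat, bool)
        truth[:n_true] = True

        def tp_at_fdr(res, level=0.05):
            order = np.argsort(res.p.to_numpy())
            best = 0
            tp = 0
            for k, i in enumerate(order, start=1):
                tp += truth[i]
                if (k - tp) / k <= level:
                    best = tp
            return best

        res_mod = moderated_t(rpm, a, b)
        res_stu = student_t(rpm, a, b)
        assert tp_at_fdr(res_mod) >= tp_at_fdr(res_stu)
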