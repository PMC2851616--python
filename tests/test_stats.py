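"""Integration statistics: gene-level CN extraction, G/N group assignment,
the empirical-Bayes moderated t (checked against an OLS oracle and against
the reference Bioconductor implementation), BH adjustment and the
correlation/Welch helpers."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cni.stats import (GroupAssignment, ModerationPrior, assign_groups,
                       bh_adjust, cn_expr_correlation,
                       estimate_moderation_prior, fit_group_lm,
                       gene_copy_number, interval_copy_number, moderate_fit,
                       moderated_t_test, welch_t_test)

from conftest import seg_frame


def one_sample_segments(rows):
    return seg_frame([("s", *r) for r in rows])[["chrom", "start", "end",
                                                 "n_markers", "mean_cn"]]


class TestGeneCopyNumber:
    def test_gene_inside_one_segment(self):
        segs = one_sample_segments([("chr1", 0, 1_000_000, 3.2)])
        assert gene_copy_number(segs, ("chr1", 100_000, 200_000)) == pytest.approx(3.2)

    def test_weighted_mean_across_two_segments(self):
        # flanked gene covers equal bp in a CN-2 and a CN-4 segment
        segs = one_sample_segments([("chr1", 0, 150_000, 2.0),
                                    ("chr1", 150_000, 400_000, 4.0)])
        cn = gene_copy_number(segs, ("chr1", 110_000, 190_000), flank=10_000)
        assert cn == pytest.approx(3.0)

    def test_uncovered_chromosome_is_missing(self):
        segs = one_sample_segments([("chr2", 0, 1000, 2.0)])
        assert np.isnan(gene_copy_number(segs, ("chr1", 100, 200)))

    def test_weighted_mean_matches_per_base_oracle(self, rng):
        bounds = np.sort(rng.choice(np.arange(1, 10_000), 6, replace=False))
        cns = rng.uniform(1, 5, 7)
        edges = [0, *bounds.tolist(), 10_000]
        segs = one_sample_segments([("chr1", a, b, c) for a, b, c in
                                    zip(edges[:-1], edges[1:], cns)])
        base = np.zeros(10_000)
        for (a, b), c in zip(zip(edges[:-1], edges[1:]), cns):
            base[a:b] = c
        got = interval_copy_number(segs, "chr1", 2345, 7890)
        assert got == pytest.approx(base[2345:7890].mean())


class TestAssignGroups:
    def test_partition_follows_cutoffs(self):
        cn = pd.Series({"a": 3.4, "b": 2.0, "c": 2.7, "d": 1.2, "e": np.nan,
                        "f": 3.0})
        grp = assign_groups("r", cn)
        assert grp.G == ("a",)
        assert grp.N == ("b",)
        assert grp.excluded == {"c": "intermediate", "d": "loss", "e": "missing",
                                "f": "intermediate"}

    def test_untestable_region_flagged(self):
        grp = assign_groups("r", pd.Series({"a": 3.5, "b": 2.0}))
        assert not grp.testable


def simulate_null(n_genes=200, n_g=8, n_n=9, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_g + n_n)]
    expr = pd.DataFrame(rng.normal(5, sd, (n_genes, len(samples))),
                        index=[f"g{i}" for i in range(n_genes)], columns=samples)
    hist = pd.Series(rng.choice(["serous", "mucinous", "clearcell"],
                                size=len(samples)), index=samples)
    groups = GroupAssignment("r", tuple(samples[:n_g]), tuple(samples[n_g:]), {})
    return expr, hist, groups


class TestModeratedT:
    def test_constant_gene_gets_p_one(self):
        expr, hist, groups = simulate_null(20)
        expr.iloc[0] = 3.0
        res, _ = moderated_t_test(expr, groups, hist)
        assert res.iloc[0]["logFC"] == pytest.approx(0.0, abs=1e-12)
        assert res.iloc[0]["p_raw"] == 1.0
        assert res.iloc[0]["t_moderated"] == 0.0

    def test_zero_prior_df_equals_ordinary_ols_t(self):
        """With d0 forced to 0 the statistic must equal the covariate-adjusted
        per-gene t computed independently via lstsq."""
        expr, hist, groups = simulate_null(100, seed=3)
        res, _ = moderated_t_test(expr, groups, hist, d0_override=0)
        samples = list(groups.G) + list(groups.N)
        g = np.array([1.0] * len(groups.G) + [0.0] * len(groups.N))
        H = pd.get_dummies(hist.reindex(samples), drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones(len(samples)), g, H])
        xtx_inv = np.linalg.inv(X.T @ X)
        for gene in expr.index[:25]:
            y = expr.loc[gene, samples].to_numpy()
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = len(samples) - X.shape[1]
            s2 = rss[0] / dof
            t = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
            assert res.loc[gene, "t_moderated"] == pytest.approx(t, abs=1e-10)
            assert res.loc[gene, "p_raw"] == pytest.approx(
                2 * sps.t.sf(abs(t), dof), abs=1e-10)

    def test_infinite_prior_df_shrinks_all_variances_to_s0(self):
        expr, hist, groups = simulate_null(100, seed=4)
        fit = fit_group_lm(expr, groups, hist)
        prior = estimate_moderation_prior(fit["s2"].to_numpy(),
                                          fit["df_residual"].to_numpy())
        res = moderate_fit(fit, np.inf, prior.s0_sq, len(groups.G), len(groups.N))
        expected = fit["logFC"] / np.sqrt(prior.s0_sq * fit["v_group"])
        assert np.allclose(res["t_moderated"], expected)

    def test_planted_logfc_recovered_without_bias(self):
        rng = np.random.default_rng(9)
        n_g = n_n = 15
        samples = [f"s{i}" for i in range(n_g + n_n)]
        groups = GroupAssignment("r", tuple(samples[:n_g]), tuple(samples[n_g:]), {})
        expr = pd.DataFrame(rng.normal(0, 0.5, (500, n_g + n_n)),
                            index=[f"g{i}" for i in range(500)], columns=samples)
        expr.iloc[:, :n_g] += 1.0
        res, _ = moderated_t_test(expr, groups)
        assert res["logFC"].mean() == pytest.approx(1.0, abs=0.1)

    def test_too_small_groups_rejected(self):
        expr, hist, _ = simulate_null(10)
        groups = GroupAssignment("r", ("s0",), ("s1", "s2"), {})
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t_test(expr, groups, hist)

    def test_matches_reference_bioconductor_implementation(self, tmp_path):
        """The re-implemented moderated t must agree with limma (the method's
        reference implementation) on hyperparameters and statistics."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        expr, hist, groups = simulate_null(60, n_g=10, n_n=12, seed=42)
        expr.iloc[:10, :10] += 1.0
        res, prior = moderated_t_test(expr, groups, hist)

        samples = list(groups.G) + list(groups.N)
        expr[samples].to_csv(tmp_path / "expr.tsv", sep="\t")
        pd.DataFrame({"sample": samples,
                      "group": [1] * len(groups.G) + [0] * len(groups.N),
                      "hist": hist.reindex(samples).values}
                     ).to_csv(tmp_path / "design.tsv", sep="\t", index=False)
        rcode = f"""
suppressMessages(library(limma))
expr <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))
des <- read.delim("{tmp_path}/design.tsv")
design <- model.matrix(~ group + hist, data=des)
fit <- eBayes(lmFit(expr, design))
out <- data.frame(logFC=fit$coefficients[,"group"], t=fit$t[,"group"],
                  p=fit$p.value[,"group"], d0=fit$df.prior, s0sq=fit$s2.prior)
write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
"""
        proc = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-6)
        assert np.allclose(res["logFC"], ref["logFC"], atol=1e-10)
        assert np.allclose(res["t_moderated"], ref["t"], atol=1e-8)
        assert np.allclose(res["p_raw"], ref["p"], atol=1e-10)


class TestBhAdjust:
    def test_step_up_closed_form(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_ones_stay_one(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_nan_propagates_and_reduces_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m = 2: 0.01*2/1 = 0.02, 0.04*2/2 = 0.04
        assert out[0] == pytest.approx(0.02)
        assert out[2] == pytest.approx(0.04)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(5):
            p = rng.uniform(0, 1, 50)
            _, ref, *_ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), ref)

    def test_permutation_invariance_and_monotonicity(self, rng):
        p = rng.uniform(0, 1, 40)
        out = bh_adjust(p)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p[perm]), out[perm])
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-15)
        assert np.all(out >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCorrelation:
    def test_exact_linear_relation_is_one(self):
        cn = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
        r, p, n = cn_expr_correlation(1 + 0.5 * cn, cn)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_exact_negative_relation(self):
        cn = np.array([2.0, 3.0, 4.0, 5.0])
        r, _, _ = cn_expr_correlation(-cn, cn)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        r, p, n = cn_expr_correlation(np.array([1.0, 2.0, 3.0]),
                                      np.array([2.0, 2.0, 2.0]))
        assert np.isnan(r) and np.isnan(p)

    def test_missing_pairs_dropped(self):
        expr = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        cn = np.array([2.0, 3.0, np.nan, 3.5, 4.0])
        r, _, n = cn_expr_correlation(expr, cn)
        assert n == 3
        ref, _ = sps.pearsonr([1.0, 4.0, 5.0], [2.0, 3.5, 4.0])
        assert r == pytest.approx(ref)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(1000):
            x, y = rng.normal(size=68), rng.normal(size=68)
            r, _, _ = cn_expr_correlation(x, y)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.02


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p = welch_t_test(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 5
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 4)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), df_ref))

    def test_large_effect_is_significant(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(3, 0.1, 10)
        _, p = welch_t_test(a, b)
        assert p < 1e-6


class TestModerationPrior:
    def test_prior_validation(self):
        with pytest.raises(ValueError):
            ModerationPrior(d0=-1, s0_sq=1.0)
        with pytest.raises(ValueError):
            ModerationPrior(d0=4.0, s0_sq=0.0)

    def test_recovers_known_hyperparameters(self):
        """Variances drawn from the scaled inverse-chi-square model: the
        moment estimator should land near the generating (d0, s0^2)."""
        rng = np.random.default_rng(5)
        d0_true, s0_true, dg = 8.0, 0.25, 20
        n = 5000
        s2_prior = d0_true * s0_true / rng.chisquare(d0_true, n)
        s2 = s2_prior * rng.chisquare(dg, n) / dg
        prior = estimate_moderation_prior(s2, np.full(n, dg))
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.05)
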