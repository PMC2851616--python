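"""Synthetic cohort generator: determinism, planted-event recovery, dosage
and histotype structure of the expression model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cni.synthetic import (CohortConfig, PlantedAmplicon, PlantedCNP,
                           make_cytobands, make_gene_grid, simulate_cohort,
                           simulate_expression, true_gene_cn)


def tiny_config(seed=0, **kw):
    defaults = dict(
        n_tumours=12, n_normals=6,
        histotypes={"serous": 0.6, "mucinous": 0.4},
        chrom_lengths={"chr1": 5_000_000},
        marker_spacing=100_000,
        passenger_rate=0.0,
        noise_sd_cn=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestSimulateCohort:
    def test_same_seed_is_bit_identical(self):
        cfg = tiny_config(seed=5, noise_sd_cn=0.2, passenger_rate=2.0,
                          driver_amplicons=(PlantedAmplicon("chr1", 1_000_000,
                                                            2_000_000, 0.5),))
        t1, n1, tr1 = simulate_cohort(cfg)
        t2, n2, tr2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(n1, n2)
        assert tr1.events == tr2.events

    def test_no_events_no_noise_is_flat_diploid(self):
        tum, nrm, _ = simulate_cohort(tiny_config())
        assert (tum["cn"] == 2.0).all()
        assert (nrm["cn"] == 2.0).all()

    def test_carrier_count_within_binomial_ci(self):
        n, freq = 60, 0.5
        cfg = tiny_config(n_tumours=n, n_normals=0,
                          driver_amplicons=(PlantedAmplicon("chr1", 1_000_000,
                                                            2_000_000, freq),),
                          seed=17)
        _, _, truth = simulate_cohort(cfg)
        carriers = len(truth.amplicon_carriers[0])
        lo = sps.binom.ppf(0.005, n, freq)
        hi = sps.binom.ppf(0.995, n, freq)
        assert lo <= carriers <= hi

    def test_carrier_frequency_converges_at_large_n(self):
        # law of large numbers at n = 500 tumours
        cfg = tiny_config(n_tumours=500, n_normals=0,
                          chrom_lengths={"chr1": 1_000_000},
                          driver_amplicons=(PlantedAmplicon("chr1", 100_000,
                                                            900_000, 0.3),),
                          seed=23)
        _, _, truth = simulate_cohort(cfg)
        fhat = len(truth.amplicon_carriers[0]) / 500
        assert abs(fhat - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 500)

    def test_cnp_carrier_shows_event_in_tumour_and_matched_normal(self):
        cfg = tiny_config(n_tumours=12, n_normals=12,
                          cnp_spec=(PlantedCNP("chr1", 1_000_000, 2_000_000,
                                               population_frequency=0.5),),
                          seed=3)
        tum, nrm, truth = simulate_cohort(cfg)
        carriers = truth.cnp_carriers[0]
        assert carriers, "expected at least one CNP carrier at 50% frequency"
        for k in carriers:
            t_cn = tum[(tum["sample"] == f"T{k + 1:03d}")
                       & (tum["pos"].between(1_000_000, 2_000_000 - 1))]["cn"]
            n_cn = nrm[(nrm["sample"] == f"N{k + 1:03d}")
                       & (nrm["pos"].between(1_000_000, 2_000_000 - 1))]["cn"]
            assert (t_cn != 2.0).all() and (n_cn != 2.0).all()
            assert np.allclose(t_cn.to_numpy(), n_cn.to_numpy())

    def test_overlapping_gains_resolve_to_max(self):
        cfg = tiny_config(
            driver_amplicons=(PlantedAmplicon("chr1", 1_000_000, 3_000_000, 1.0,
                                              cn_low=3.0, cn_high=3.0),
                              PlantedAmplicon("chr1", 2_000_000, 4_000_000, 1.0,
                                              cn_low=5.0, cn_high=5.0)))
        tum, _, _ = simulate_cohort(cfg)
        one = tum[tum["sample"] == "T001"].set_index("pos")["cn"]
        assert one.loc[1_050_000] == 3.0
        assert one.loc[2_050_000] == 5.0  # max rule in the overlap
        assert one.loc[3_050_000] == 5.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_config(histotypes={"a": 0.5, "b": 0.2})
        with pytest.raises(ValueError, match="exceeds"):
            tiny_config(driver_amplicons=(PlantedAmplicon("chr1", 0,
                                                          9_000_000, 0.5),))
        with pytest.raises(ValueError, match="at least 4"):
            tiny_config(n_tumours=2)
        with pytest.raises(ValueError, match="frequency"):
            PlantedAmplicon("chr1", 0, 10, frequency=0.0)


class TestSimulateExpression:
    def setup_cohort(self, beta=0.5, freq=0.6, seed=1, n_tumours=60):
        genes = make_gene_grid({"chr1": 5_000_000}, 10, gene_length=20_000)
        target = genes.iloc[3]
        amp = PlantedAmplicon("chr1", int(target["start"]) - 50_000,
                              int(target["end"]) + 50_000, freq,
                              dosage_genes={target["gene"]: beta})
        cfg = tiny_config(n_tumours=n_tumours, n_normals=0,
                          driver_amplicons=(amp,), seed=seed)
        _, _, truth = simulate_cohort(cfg)
        return cfg, truth, genes, target["gene"]

    def test_noiseless_dosage_gene_has_perfect_correlation(self):
        cfg, truth, genes, gene = self.setup_cohort()
        expr = simulate_expression(cfg, truth, genes, sigma_e=0.0, seed=2,
                                   histotype_offsets={})
        cn = pd.Series({t: true_gene_cn(cfg, truth, genes, t)[gene]
                        for t in expr.columns})
        r = np.corrcoef(expr.loc[gene], cn)[0, 1]
        assert abs(r - 1.0) < 1e-12

    def test_null_genes_have_null_correlation_distribution(self):
        """beta = 0 genes inside the amplicon: r should follow the null
        Pearson distribution; compare against its exact 99.5% quantile."""
        cfg, truth, genes, gene = self.setup_cohort(seed=8)
        # make every gene a passenger
        expr = simulate_expression(cfg, truth, genes, sigma_e=1.0, seed=9,
                                   beta={gene: 0.0}, histotype_offsets={})
        n = expr.shape[1]
        # exact null quantile of |r|: r*sqrt(n-2)/sqrt(1-r^2) ~ t(n-2)
        tq = sps.t.ppf(0.9975, n - 2)
        r_crit = tq / np.sqrt(n - 2 + tq ** 2)
        rs = []
        cn = pd.DataFrame({t: true_gene_cn(cfg, truth, genes, t)
                           for t in expr.columns})
        for g in genes["gene"]:
            c = cn.loc[g].to_numpy()
            if np.std(c) == 0:
                continue
            rs.append(abs(np.corrcoef(expr.loc[g], c)[0, 1]))
        assert rs, "need at least one CN-variable null gene"
        # each |r| exceeds r_crit with prob 0.5%; none of ~10 should, usually
        assert np.mean(np.array(rs) < r_crit) >= 0.9

    def test_planted_histotype_offset_recovered_in_group_means(self):
        cfg, truth, genes, gene = self.setup_cohort(seed=5, n_tumours=200)
        expr = simulate_expression(cfg, truth, genes, sigma_e=0.05, seed=6,
                                   beta={gene: 0.0},
                                   histotype_offsets={gene: {"serous": 1.0,
                                                             "mucinous": 0.0}})
        by_hist = {h: [] for h in cfg.histotypes}
        for t in expr.columns:
            by_hist[truth.histotype[t]].append(expr.loc[gene, t])
        diff = np.mean(by_hist["serous"]) - np.mean(by_hist["mucinous"])
        assert diff == pytest.approx(1.0, abs=0.05)

    def test_negative_noise_rejected(self):
        cfg, truth, genes, _ = self.setup_cohort()
        with pytest.raises(ValueError, match="sigma_e"):
            simulate_expression(cfg, truth, genes, sigma_e=-0.1, seed=1)

    def test_deterministic_given_seed(self):
        cfg, truth, genes, _ = self.setup_cohort()
        e1 = simulate_expression(cfg, truth, genes, sigma_e=0.3, seed=4)
        e2 = simulate_expression(cfg, truth, genes, sigma_e=0.3, seed=4)
        pd.testing.assert_frame_equal(e1, e2)


class TestAnnotationHelpers:
    def test_gene_grid_within_bounds(self):
        genes = make_gene_grid({"chr1": 1_000_000, "chr2": 2_000_000}, 20)
        assert len(genes) == 40
        for chrom, length in (("chr1", 1_000_000), ("chr2", 2_000_000)):
            sub = genes[genes["chrom"] == chrom]
            assert (sub["start"] < sub["end"]).all()
            assert sub["end"].max() <= length

    def test_cytobands_tile_each_chromosome(self):
        bands = make_cytobands({"chr1": 10_000_000}, bands_per_arm=4)
        assert len(bands) == 8
        assert bands["start"].iloc[0] == 0
        assert bands["end"].iloc[-1] == 10_000_000
        assert (bands["end"].to_numpy()[:-1] == bands["start"].to_numpy()[1:]).all()
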