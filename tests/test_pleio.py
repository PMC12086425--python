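"""Cross-trait pleiotropy statistic, genome scan and novelty rules."""

import numpy as np
import pytest
from scipy import stats

import crosstrait as ct
from crosstrait.pleio import (NullCorr, mixture_p, null_stat_draws,
                              pleio_stat_array)


def _nc(c=0.0, h2_1=0.1, h2_2=0.27, gencov=0.0):
    C = np.array([[1.0, c], [c, 1.0]])
    omega = np.array([[h2_1, gencov], [gencov, h2_2]])
    return NullCorr(C=C, omega=omega)


class TestNullCorr:
    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            NullCorr(C=np.array([[1.0, 1.5], [1.5, 1.0]]),
                     omega=np.eye(2))

    def test_estimate_modes_agree(self):
        # the intercept estimate is noisy per replicate; the two modes are
        # compared on replicate averages
        diffs = []
        for s in range(10):
            cfg = ct.ArchitectureConfig(
                n_blocks=100, block_size=50, n1=20_000, n2=20_000,
                n_overlap=20_000, rho_e=0.3, rg=0.0, prop_shared=0.0,
                prop_causal_1=1.0, prop_causal_2=1.0, seed=51 + s)
            panel = ct.make_ld_panel(cfg)
            ss1, ss2, _ = ct.simulate_sumstats(cfg, panel)
            fit = ct.ldsc_rg(ss1, ss2, ct.ld_scores(panel))
            nci = ct.estimate_null_corr(ss1, ss2, fit, mode="intercepts")
            nce = ct.estimate_null_corr(ss1, ss2, fit, mode="empirical")
            diffs.append(nci.C[0, 1] - nce.C[0, 1])
        assert abs(np.mean(diffs)) < 0.05

    def test_full_overlap_recovered_empirically(self):
        cfg = ct.ArchitectureConfig(
            n_blocks=100, block_size=50, n1=20_000, n2=20_000,
            n_overlap=20_000, rho_e=0.3, h2_1=0.0, h2_2=0.0,
            prop_shared=0.0, seed=52)
        panel = ct.make_ld_panel(cfg)
        ss1, ss2, _ = ct.simulate_sumstats(cfg, panel)
        fit = ct.ldsc_rg(ss1, ss2, ct.ld_scores(panel))
        nce = ct.estimate_null_corr(ss1, ss2, fit, mode="empirical")
        assert nce.C[0, 1] == pytest.approx(0.3, abs=0.05)

    def test_no_overlap_near_zero(self):
        vals = []
        for s in range(5):
            cfg = ct.ArchitectureConfig(
                n_blocks=100, block_size=50, n1=20_000, n2=20_000,
                n_overlap=0, rho_e=0.0, prop_shared=0.0, prop_causal_1=1.0,
                prop_causal_2=1.0, ld_decay=0.0, seed=53 + s)
            panel = ct.make_ld_panel(cfg)
            ss1, ss2, _ = ct.simulate_sumstats(cfg, panel)
            # a flat-LD panel cannot identify the LDSC intercept, and the
            # empirical mode does not need it; supply the omega directly
            fit = ct.LdscFit(h2=0.1, h2_se=0.01, intercept=1.0,
                             intercept_se=0.01, h2_2=0.27, gencov=0.0,
                             cross_intercept=0.0)
            nce = ct.estimate_null_corr(ss1, ss2, fit, mode="empirical")
            vals.append(nce.C[0, 1])
        assert abs(np.mean(vals)) < 0.03


class TestPleioStat:
    def test_zero_z_gives_zero_stat_p_one(self):
        stat, p = ct.pleio_stat(0.0, 0.0, _nc(), mc_draws=np.array([]))
        assert stat == 0.0
        assert p == 1.0

    def test_matches_brute_force_grid_profile(self):
        # isotropic case: the profile maximum has a closed form, and a fine
        # grid search is an independent oracle
        nc = NullCorr(C=np.eye(2), omega=np.eye(2))
        stat, _ = ct.pleio_stat(5.0, 5.0, nc, mc_draws=np.array([]))
        taus = np.linspace(0.0, 500.0, 4_000_001)
        grid = -(2 * np.log1p(taus / 2) + 50.0 / (1 + taus / 2) - 50.0)
        assert stat == pytest.approx(grid.max(), abs=1e-6)
        assert stat == pytest.approx(48.0 - 2 * np.log(25.0), abs=1e-9)

    def test_array_path_matches_scalar(self):
        nc = _nc(c=0.2, gencov=0.05)
        rng = np.random.default_rng(0)
        z1 = rng.normal(0, 2, 50)
        z2 = rng.normal(0, 2, 50)
        stats_vec, _ = pleio_stat_array(z1, z2, nc)
        for j in (0, 17, 49):
            s, _ = ct.pleio_stat(z1[j], z2[j], nc, mc_draws=np.array([]))
            assert stats_vec[j] == pytest.approx(s, abs=1e-4)

    def test_trait_swap_invariance(self):
        nc = _nc(c=0.3, h2_1=0.1, h2_2=0.27, gencov=0.02)
        nc_swapped = NullCorr(C=nc.C[::-1, ::-1].copy(),
                              omega=nc.omega[::-1, ::-1].copy())
        s1, _ = ct.pleio_stat(3.0, -2.0, nc, mc_draws=np.array([]))
        s2, _ = ct.pleio_stat(-2.0, 3.0, nc_swapped, mc_draws=np.array([]))
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_null_calibration_with_overlap(self):
        # overlap-aware null: p-values from the shared MC null draws are
        # uniform (randomized PIT over the boundary atom at stat == 0);
        # the misspecified C=I analysis is anticonservative
        rng = np.random.default_rng(7)
        c = 0.4
        n = 4_000
        L = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
        Z = L @ rng.standard_normal((2, n))
        nc = _nc(c=c, gencov=0.15)
        draws = null_stat_draws(nc, n_draws=200_000, seed=17)
        stat, p = pleio_stat_array(Z[0], Z[1], nc, mc_draws=draws)
        # tail calibration
        assert 0.03 <= np.mean(p <= 0.05) <= 0.07
        # randomized PIT against the null CDF (handles the atom exactly)
        lo = np.searchsorted(draws, stat, side="left") / draws.size
        hi = np.searchsorted(draws, stat, side="right") / draws.size
        pit = lo + rng.uniform(size=n) * (hi - lo)
        assert stats.kstest(pit, "uniform").pvalue > 0.01
        # negative control: ignoring the overlap inflates the test
        nc_bad = _nc(c=0.0, gencov=0.15)
        draws_bad = null_stat_draws(nc_bad, n_draws=200_000, seed=18)
        _, p_bad = pleio_stat_array(Z[0], Z[1], nc_bad, mc_draws=draws_bad)
        assert np.mean(p_bad <= 0.05) > 0.07

    def test_mc_refinement_deterministic_and_consistent(self):
        nc = _nc(c=0.1, gencov=0.03)
        draws = null_stat_draws(nc, n_draws=200_000, seed=3)
        draws2 = null_stat_draws(nc, n_draws=200_000, seed=3)
        assert np.array_equal(draws, draws2)
        s, p = ct.pleio_stat(4.0, 4.0, nc, mc_draws=draws)
        # moderate tail: MC and mixture agree within MC error
        p_mix = float(mixture_p(np.array([s]))[0])
        if p >= 10 / draws.size:
            assert p == pytest.approx(p_mix, rel=0.5)

    def test_extreme_tail_keeps_analytic_p(self):
        nc = _nc()
        draws = null_stat_draws(nc, n_draws=10_000, seed=4)
        s, p = ct.pleio_stat(12.0, 12.0, nc, mc_draws=draws)
        assert p == pytest.approx(float(mixture_p(np.array([s]))[0]))
        assert p < 1e-10

    def test_gls_omnibus_null_uniform(self):
        rng = np.random.default_rng(9)
        c = 0.3
        L = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
        Z = L @ rng.standard_normal((2, 3_000))
        _, p = ct.gls_omnibus(Z[0], Z[1], _nc(c=c))
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestPleioScan:
    @pytest.fixture(scope="class")
    @staticmethod
    def shared_loci_scan():
        cfg = ct.ArchitectureConfig(
            n_blocks=100, block_size=50, n1=100_000, n2=100_000,
            n_overlap=50_000, rho_e=0.2, rg=0.1, prop_shared=0.005,
            shared_blocks=[5, 25, 45, 65, 85], effect_dist="fixed",
            prop_causal_1=0.05, prop_causal_2=0.05, seed=55)
        panel = ct.make_ld_panel(cfg)
        ss1, ss2, truth = ct.simulate_sumstats(cfg, panel)
        fit = ct.ldsc_rg(ss1, ss2, ct.ld_scores(panel))
        nc = ct.estimate_null_corr(ss1, ss2, fit, mode="empirical")
        draws = null_stat_draws(nc, n_draws=100_000, seed=1)
        hits = ct.pleio_scan(ss1, ss2, panel, nc, mc_draws=draws)
        return cfg, panel, ss1, ss2, truth, hits

    def test_planted_shared_loci_recovered(self, shared_loci_scan):
        cfg, panel, ss1, ss2, truth, hits = shared_loci_scan
        sig = [h for h in hits if h.significant]
        hit_blocks = {panel.block_of(h.snp) for h in sig}
        shared_blocks = {panel.block_of(s) for s in truth.shared}
        assert len(hit_blocks & shared_blocks) >= 4

    def test_single_trait_locus_filtered(self, shared_loci_scan):
        *_, hits = shared_loci_scan
        for h in hits:
            if h.significant:
                assert h.p_trait1 < 1e-5 and h.p_trait2 < 1e-5
                assert h.p_pleio < 5e-8

    def test_window_is_one_megabase(self, shared_loci_scan):
        *_, hits = shared_loci_scan
        for h in hits:
            assert h.window_end - h.window_start <= 1_000_000


class TestClassifyNovel:
    def _make_hit(self, snp, chrom, pos, p1, p2, significant=True):
        return ct.PleioHit(snp=snp, chr=chrom, pos=pos, z1=5.0, z2=5.0,
                           p_pleio=1e-10, p_trait1=p1, p_trait2=p2,
                           window_start=max(1, pos - 500_000),
                           window_end=pos + 500_000,
                           significant=significant)

    @pytest.fixture(scope="class")
    @staticmethod
    def panel():
        cfg = ct.ArchitectureConfig(n_blocks=4, block_size=10, ld_decay=0.9,
                                    seed=0)
        return ct.make_ld_panel(cfg)

    def test_single_trait_driven_fails_clause_one(self, panel):
        sid = str(panel.snv_ids[0][0])
        hit = self._make_hit(sid, 1, int(panel.pos[0][0]), 1e-9, 5e-6)
        out = ct.classify_novel([hit], [], [], panel)
        assert out[0].novel is False
        assert "single_trait_driven" in out[0].novelty_failures

    def test_ld_with_known_fails_clause_two(self, panel):
        sid = str(panel.snv_ids[0][0])
        neighbor = str(panel.snv_ids[0][1])  # r^2 = 0.81 with the hit
        hit = self._make_hit(sid, 1, int(panel.pos[0][0]), 5e-6, 5e-6)
        out = ct.classify_novel([hit], [neighbor], [], panel)
        assert out[0].novel is False
        assert "ld_with_known" in out[0].novelty_failures

    def test_clean_hit_is_novel_and_matches_hand_rules(self, panel):
        import pandas as pd
        sid = str(panel.snv_ids[0][0])
        pos = int(panel.pos[0][0])
        hit = self._make_hit(sid, 1, pos, 5e-6, 5e-6)
        # neighbor table without genome-wide-significant entries
        rows = []
        for b in range(panel.n_blocks):
            for j, s in enumerate(panel.snv_ids[b]):
                rows.append((str(s), int(panel.chrom[b][j]),
                             int(panel.pos[b][j]), "A", "G", 0.3, 0.01,
                             0.01, 0.5 if str(s) != sid else 5e-6, 1000))
        df = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA",
                                         "EAF", "BETA", "SE", "P", "N"])
        ss = ct.SumStats(trait="t", df=df)
        far_known = str(panel.snv_ids[3][0])  # different block: r^2 = 0
        out = ct.classify_novel([hit], [far_known], [], panel, x=ss, y=ss)
        # hand-evaluated: clause 1 holds (5e-8 < 5e-6 < 1e-5 both traits),
        # clause 2 holds (only known SNV is LD-free), clause 3 holds (no
        # neighbor below 5e-8)
        assert out[0].novel is True
        assert out[0].novelty_failures == []

    def test_gw_significant_neighbor_fails_clause_three(self, panel):
        import pandas as pd
        sid = str(panel.snv_ids[0][0])
        pos = int(panel.pos[0][0])
        hit = self._make_hit(sid, 1, pos, 5e-6, 5e-6)
        neighbor = str(panel.snv_ids[0][5])
        rows = [(str(s), int(panel.chrom[0][j]), int(panel.pos[0][j]), "A",
                 "G", 0.3, 0.01, 0.01,
                 1e-9 if str(s) == neighbor else 0.5, 1000)
                for j, s in enumerate(panel.snv_ids[0])]
        df = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA",
                                         "EAF", "BETA", "SE", "P", "N"])
        ss = ct.SumStats(trait="t", df=df)
        out = ct.classify_novel([hit], [], [], panel, x=ss, y=ss)
        assert out[0].novel is False
        assert "gw_significant_neighbor" in out[0].novelty_failures
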