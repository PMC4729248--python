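"""Contig bootstrap, score machinery and the Godambe-corrected LRT."""

import numpy as np
import pandas as pd
import pytest

import demosfs as d
from demosfs.spectra import build_joint_sfs
from demosfs.uncertainty import (bootstrap_by_contig, godambe_adjusted_lrt,
                                 lrt_pvalue, param_ci, score_vector)

from conftest import make_table, POPMAP6

POP_ORDER = ("MOJ", "SIN", "SON")


class TestBootstrapByContig:
    def test_fixed_seed_is_bit_reproducible(self, toy_table):
        a = bootstrap_by_contig(toy_table, B=2, seed=7, pop_order=POP_ORDER)
        b = bootstrap_by_contig(toy_table, B=2, seed=7, pop_order=POP_ORDER)
        for ra, rb in zip(a.replicates, b.replicates):
            assert np.array_equal(ra.counts, rb.counts)
        for ma, mb in zip(a.contig_multisets, b.contig_multisets):
            assert np.array_equal(ma, mb)

    def test_replicate_is_sum_of_chosen_contig_spectra(self, popmap6):
        # contigs occupying disjoint spectrum cells make the additivity exact
        rows = [
            ("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0)),
            ("c2", 1, 30.0, "synonymous", (0, 0, 1, 1, 0, 0)),
            ("c3", 1, 30.0, "synonymous", (0, 0, 0, 0, 1, 0)),
        ]
        vt = make_table(rows, popmap6)
        boots = bootstrap_by_contig(vt, B=5, seed=1, pop_order=POP_ORDER)
        per_contig = {
            c: build_joint_sfs(vt.subset((vt.df["contig"] == c).to_numpy()),
                               POP_ORDER, fold=True)
            for c in ("c1", "c2", "c3")}
        for rep, chosen in zip(boots.replicates, boots.contig_multisets):
            manual = sum(per_contig[c].counts for c in chosen)
            assert np.array_equal(rep.counts, manual)

    def test_mean_total_matches_original(self, toy_table):
        boots = bootstrap_by_contig(toy_table, B=200, seed=3, pop_order=POP_ORDER)
        totals = np.array([r.sum() for r in boots.replicates])
        original = build_joint_sfs(toy_table, POP_ORDER, fold=True).sum()
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - original) <= 3 * se

    def test_single_contig_warns(self, popmap6, caplog):
        rows = [("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0))]
        import logging
        with caplog.at_level(logging.WARNING):
            bootstrap_by_contig(make_table(rows, popmap6), B=2, seed=0,
                                pop_order=POP_ORDER)
        assert any("degenerate" in r.message for r in caplog.records)


class TestParamCI:
    def test_printed_formula_on_hand_values(self):
        ci = param_ci(np.array([[9.0], [10.0], [11.0]]), names=["x"])
        assert ci.loc["x", "mean"] == pytest.approx(10.0)
        assert ci.loc["x", "sd"] == pytest.approx(1.0)
        assert ci.loc["x", "low"] == pytest.approx(10 - 1.96)
        assert ci.loc["x", "high"] == pytest.approx(10 + 1.96)

    def test_constant_replicates_zero_width(self):
        ci = param_ci(np.full((10, 2), 3.5))
        assert (ci["low"] == ci["high"]).all()

    def test_nonfinite_rows_dropped(self):
        arr = np.array([[1.0], [np.nan], [3.0]])
        ci = param_ci(arr)
        assert ci.loc["p0", "mean"] == pytest.approx(2.0)


class TestScoreVector:
    def test_zero_gradient_at_noiseless_maximum(self):
        truth = np.array([0.5, 2.0, 0.4])
        data = d.expected_sfs("split2_noMig", truth, (4, 4), fold=True).scaled(50.0)
        grad = score_vector("split2_noMig", truth, data, step=1e-3)
        assert np.abs(grad).max() <= 1e-3

    def test_matches_analytic_gradient_of_quadratic(self, monkeypatch):
        # replace the likelihood with a known quadratic to isolate the
        # finite-difference machinery
        import demosfs.uncertainty as unc

        def quad_ll(model, params, data):
            p = np.asarray(params)
            return -np.sum((p - 0.7) ** 2), 1.0

        monkeypatch.setattr(unc, "profile_ll", quad_ll)
        grad = unc.score_vector("split2_noMig", np.array([1.0, 2.0, 0.4]),
                                data=None, step=1e-3)
        analytic = -2 * (np.array([1.0, 2.0, 0.4]) - 0.7)
        assert np.allclose(grad, analytic, atol=1e-4)

    def test_step_halving_stability(self):
        truth = np.array([0.5, 2.0, 0.45])
        data = d.expected_sfs("split2_noMig", [0.55, 1.9, 0.4], (4, 4),
                              fold=True).scaled(80.0)
        g1 = score_vector("split2_noMig", truth, data, step=1e-2)
        g2 = score_vector("split2_noMig", truth, data, step=5e-3)
        assert np.all(np.abs(g1 - g2) <= 0.01 * np.abs(g1) + 1e-6)


class TestLRTPValues:
    def test_known_chi_squared_quantile(self):
        assert lrt_pvalue(3.841, df=1) == pytest.approx(0.05, abs=1e-3)

    def test_boundary_mixture_halves(self):
        assert lrt_pvalue(3.841, df=1, boundary_mixture=True) == pytest.approx(
            0.025, abs=1e-3)


def _simulate_trio5(n_contigs, snps_per_contig, seed):
    truth5 = {"nu_sinson": 0.45, "nu_son": 1.8, "T1": 0.1, "T2": 0.34}
    cfg = d.SimConfig(model="trio_5param", params=truth5, n_contigs=n_contigs,
                      mean_syn_snps_per_contig=snps_per_contig,
                      frac_nonsynonymous=0.0, frac_ambiguous=0.0,
                      prob_low_quality=0.0, missing_rate=0.0, seed=seed)
    return d.simulate_variants(cfg), truth5


class TestGodambeLRT:
    def _fits(self, afs, truth5, seed):
        t5 = np.array([truth5[k] for k in d.get_model("trio_5param").param_names])
        full = d.fit_model(afs, "trio_6param", n_starts=1, seed=seed,
                           start=np.concatenate([[1.0], t5]))
        nested = d.fit_model(afs, "trio_5param", n_starts=1, seed=seed, start=t5)
        return full, nested

    def test_adjustment_near_one_on_unlinked_data(self):
        # one SNP per contig: the composite likelihood's independence
        # assumption holds and the sandwich correction should be ~neutral
        vt, truth5 = _simulate_trio5(n_contigs=4000, snps_per_contig=0.5, seed=91)
        vt.df["contig"] = [f"s{i}" for i in range(vt.n_sites)]
        afs = d.build_joint_sfs(vt, POP_ORDER, fold=True)
        full, nested = self._fits(afs, truth5, seed=1)
        boots = bootstrap_by_contig(vt, B=100, seed=2, pop_order=POP_ORDER)
        res = godambe_adjusted_lrt(full, nested, afs, boots)
        assert res.adjustment == pytest.approx(1.0, abs=0.2)

    def test_null_simulation_is_typically_not_rejected(self):
        vt, truth5 = _simulate_trio5(n_contigs=400, snps_per_contig=3.0, seed=17)
        afs = d.build_joint_sfs(vt, POP_ORDER, fold=True)
        full, nested = self._fits(afs, truth5, seed=3)
        boots = bootstrap_by_contig(vt, B=50, seed=4, pop_order=POP_ORDER)
        res = godambe_adjusted_lrt(full, nested, afs, boots)
        assert res.D >= 0
        assert res.p_value > 0.05

    def test_adjusted_type_one_error_closer_to_nominal_than_raw(self):
        """Under a linked null, the corrected test's rejection rate at the
        5% level must beat the uncorrected test's (which inflates because
        sites within a contig share a genealogy)."""
        n_rej_raw = n_rej_adj = 0
        n_rep = 200
        for rep in range(n_rep):
            vt, truth5 = _simulate_trio5(n_contigs=150, snps_per_contig=5.0,
                                         seed=5000 + rep)
            afs = d.build_joint_sfs(vt, POP_ORDER, fold=True)
            full, nested = self._fits(afs, truth5, seed=rep)
            boots = bootstrap_by_contig(vt, B=30, seed=rep, pop_order=POP_ORDER)
            res = godambe_adjusted_lrt(full, nested, afs, boots)
            n_rej_raw += res.p_value_raw < 0.05
            n_rej_adj += res.p_value < 0.05
        raw_rate = n_rej_raw / n_rep
        adj_rate = n_rej_adj / n_rep
        assert abs(adj_rate - 0.05) <= abs(raw_rate - 0.05)
        assert raw_rate > 0.05  # linkage must actually inflate the raw test
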