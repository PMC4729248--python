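"""Spectrum construction, filtering, folding, marginals and residuals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demosfs.spectra import (JointSFS, anscombe_residuals, build_joint_sfs,
                             filter_variants, fold_sfs, marginalize_pair,
                             read_popmap, read_vcf)
from demosfs.synthetic_data import write_annotation, write_popmap, write_vcf

from conftest import POPMAP6, make_table


class TestFilterVariants:
    def test_quality_threshold_boundary(self, popmap6):
        rows = [("c1", i + 1, q, "synonymous", (1, 0, 0, 0, 0, 0))
                for i, q in enumerate([19.5, 20.0, 25.0, 30.0, 55.0])]
        vt = make_table(rows, popmap6)
        out = filter_variants(vt, min_quality=20.0, synonymous_only=False)
        assert out.n_sites == 4
        assert out.df["qual"].min() == 20.0  # >= is inclusive

    def test_completeness_rule(self, popmap6):
        rows = [
            ("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0)),
            ("c1", 2, 30.0, "synonymous", (1, -1, 0, 0, 0, 0)),
            ("c1", 3, 30.0, "synonymous", (0, 0, 2, 0, 0, 0)),
        ]
        out = filter_variants(make_table(rows, popmap6), require_complete=True,
                              synonymous_only=False)
        assert out.n_sites == 2
        assert list(out.df["pos"]) == [1, 3]

    def test_synonymous_only(self, popmap6):
        rows = [
            ("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0)),
            ("c1", 2, 30.0, "synonymous", (0, 1, 0, 0, 0, 0)),
            ("c1", 3, 30.0, "nonsynonymous", (0, 0, 1, 0, 0, 0)),
            ("c1", 4, 30.0, "ambiguous", (0, 0, 0, 1, 0, 0)),
        ]
        out = filter_variants(make_table(rows, popmap6), synonymous_only=True)
        assert out.n_sites == 2
        assert set(out.df["annotation"]) == {"synonymous"}

    def test_malformed_dosage_rejected(self, popmap6):
        rows = [
            ("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0)),
            ("c1", 2, 30.0, "synonymous", (3, 0, 0, 0, 0, 0)),
        ]
        out = filter_variants(make_table(rows, popmap6))
        assert out.n_sites == 1

    def test_order_preserved_and_pure(self, toy_table):
        out1 = filter_variants(toy_table, min_quality=28.0)
        out2 = filter_variants(toy_table, min_quality=28.0)
        kept = toy_table.df[toy_table.df["qual"] >= 28.0]
        assert list(zip(out1.df["contig"], out1.df["pos"])) == list(
            zip(kept["contig"], kept["pos"]))  # original order preserved
        assert out1.df.equals(out2.df)

    def test_empty_output_is_not_error(self, toy_table):
        out = filter_variants(toy_table, min_quality=1e6)
        assert out.n_sites == 0


class TestBuildJointSFS:
    def test_single_site_placement(self, popmap6):
        vt = make_table([("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0))], popmap6)
        sfs = build_joint_sfs(vt, ("MOJ", "SIN", "SON"), fold=False)
        assert sfs.shape == (5, 5, 5)
        assert sfs.counts[1, 0, 0] == 1.0
        assert sfs.sum() == 1.0

    def test_hand_tallied_spectrum(self, popmap6):
        rows = [
            ("c1", 1, 30.0, "synonymous", (1, 1, 0, 0, 0, 0)),  # (2,0,0)
            ("c1", 2, 30.0, "synonymous", (0, 0, 1, 2, 0, 1)),  # (0,3,1)
            ("c1", 3, 30.0, "synonymous", (1, 1, 0, 0, 0, 0)),  # (2,0,0)
        ]
        sfs = build_joint_sfs(make_table(rows, popmap6), ("MOJ", "SIN", "SON"),
                              fold=False)
        assert sfs.counts[2, 0, 0] == 2.0
        assert sfs.counts[0, 3, 1] == 1.0
        assert sfs.sum() == 3.0

    def test_monomorphic_routed_to_masked_corners(self, popmap6):
        rows = [
            ("c1", 1, 30.0, "synonymous", (0, 0, 0, 0, 0, 0)),
            ("c1", 2, 30.0, "synonymous", (2, 2, 2, 2, 2, 2)),
            ("c1", 3, 30.0, "synonymous", (1, 0, 0, 0, 0, 0)),
        ]
        sfs = build_joint_sfs(make_table(rows, popmap6), ("MOJ", "SIN", "SON"),
                              fold=False)
        assert sfs.sum() == 1.0  # only the polymorphic site counts
        assert sfs.mask[0, 0, 0] and sfs.mask[4, 4, 4]
        assert sfs.counts[0, 0, 0] == 1.0 and sfs.counts[4, 4, 4] == 1.0

    def test_expected_shape_for_study_design(self, popmap6):
        # two diploids per population gives the 5x5x5 folded spectrum used
        # throughout the analysis
        vt = make_table([("c1", 1, 30.0, "synonymous", (1, 0, 0, 0, 0, 0))], popmap6)
        sfs = build_joint_sfs(vt, ("MOJ", "SIN", "SON"), fold=True)
        assert sfs.shape == (5, 5, 5)
        assert sfs.folded


class TestFolding:
    def test_one_pop_fold_by_complements(self):
        # unfolded interior (3, 2, 1) over n=4 folds to (4, 2, masked)
        counts = np.array([0.0, 3, 2, 1, 0])
        sfs = JointSFS(counts, JointSFS.corner_mask((5,)), False, ("P",))
        f = fold_sfs(sfs)
        assert f.counts[1] == 4 and f.counts[2] == 2
        assert f.mask[3] and f.mask[4]

    def test_symmetric_spectrum(self):
        counts = np.array([0.0, 7, 5, 7, 0])
        f = fold_sfs(JointSFS(counts, JointSFS.corner_mask((5,)), False, ("P",)))
        assert f.counts[1] == 14 and f.counts[2] == 5

    def test_two_pop_fold_cell_and_complement(self):
        counts = np.zeros((5, 5))
        counts[1, 0] = 2
        counts[3, 4] = 5
        f = fold_sfs(JointSFS(counts, JointSFS.corner_mask((5, 5)), False, ("A", "B")))
        assert f.counts[1, 0] == 7
        assert f.mask[3, 4]

    def test_refolding_warns_and_is_noop(self, caplog):
        sfs = fold_sfs(JointSFS(np.arange(25.0).reshape(5, 5),
                                JointSFS.corner_mask((5, 5)), False, ("A", "B")))
        again = fold_sfs(sfs)
        assert np.array_equal(again.counts, sfs.counts)
        assert again.folded

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_fold_conserves_unmasked_mass(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(5, 5, 5)).astype(float)
        sfs = JointSFS(counts, JointSFS.corner_mask((5, 5, 5)), False,
                       ("A", "B", "C"))
        assert fold_sfs(sfs).sum() == pytest.approx(sfs.sum())


class TestMarginalize:
    def test_single_count_marginal(self):
        counts = np.zeros((5, 5, 5))
        counts[1, 2, 0] = 1
        sfs = JointSFS(counts, JointSFS.corner_mask((5, 5, 5)), False,
                       ("MOJ", "SIN", "SON"))
        marg = marginalize_pair(sfs, "MOJ", "SIN")
        assert marg.counts[1, 2] == 1
        assert marg.pop_ids == ("MOJ", "SIN")

    def test_uniform_array_scales_by_axis_length(self):
        sfs = JointSFS(np.ones((5, 5, 5)), np.zeros((5, 5, 5), dtype=bool),
                       False, ("A", "B", "C"))
        marg = marginalize_pair(sfs, "A", "B")
        assert np.allclose(marg.counts, 5.0)

    def test_against_brute_force_axis_sum(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(4.0, size=(5, 5, 5)).astype(float)
        sfs = JointSFS(counts, JointSFS.corner_mask((5, 5, 5)), False,
                       ("MOJ", "SIN", "SON"))
        # brute force: explicit loop over the summed-out axis, skipping mask
        expected = np.zeros((5, 5))
        for i in range(5):
            for k in range(5):
                for j in range(5):
                    if not sfs.mask[i, j, k]:
                        expected[i, k] += counts[i, j, k]
        marg = marginalize_pair(sfs, "MOJ", "SON")
        assert np.allclose(marg.counts, expected)
        assert marg.sum() == pytest.approx(sfs.sum())

    def test_axis_order_follows_request(self):
        counts = np.zeros((5, 5, 5))
        counts[1, 2, 3] = 1
        sfs = JointSFS(counts, JointSFS.corner_mask((5, 5, 5)), False,
                       ("MOJ", "SIN", "SON"))
        assert marginalize_pair(sfs, "SON", "MOJ").counts[3, 1] == 1

    def test_unknown_label_errors(self):
        sfs = JointSFS(np.zeros((5, 5)), np.zeros((5, 5), bool), False, ("A", "B"))
        with pytest.raises(ValueError, match="unknown population"):
            marginalize_pair(sfs, "A", "Z")


class TestAnscombeResiduals:
    def _sfs(self, values):
        arr = np.array(values, dtype=float)
        return JointSFS(arr, np.zeros_like(arr, dtype=bool), False,
                        tuple("P" * arr.ndim))

    def test_identity_gives_zero(self):
        m = self._sfs([[4.0, 2.0], [1.0, 3.0]])
        r = anscombe_residuals(m, m)
        assert np.allclose(r, 0.0)

    def test_hand_evaluated_value(self):
        # 1.5 * (8^(2/3) - 4^(2/3)) / 4^(1/6) evaluated by hand, negated for
        # the model-minus-data sign convention
        m, d = self._sfs([4.0]), self._sfs([8.0])
        assert anscombe_residuals(m, d)[0] == pytest.approx(-1.7622031559045979)
        assert anscombe_residuals(m, d, sign="data_minus_model")[0] == pytest.approx(
            1.7622031559045979)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            anscombe_residuals(self._sfs([1.0, 2.0]), self._sfs([1.0]))


class TestIO:
    def test_flat_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        sfs = JointSFS(rng.poisson(2.0, (5, 5, 5)).astype(float),
                       JointSFS.corner_mask((5, 5, 5)), True, ("MOJ", "SIN", "SON"))
        path = tmp_path / "spec.fs"
        sfs.to_file(path)
        back = JointSFS.from_file(path)
        assert np.array_equal(back.counts, sfs.counts)
        assert np.array_equal(back.mask, sfs.mask)
        assert back.folded and back.pop_ids == sfs.pop_ids

    def test_vcf_round_trip(self, tmp_path, toy_table):
        write_vcf(toy_table, tmp_path / "x.vcf")
        write_annotation(toy_table, tmp_path / "x.tsv")
        write_popmap(toy_table, tmp_path / "pm.tsv")
        popmap = read_popmap(tmp_path / "pm.tsv")
        assert popmap == toy_table.popmap
        back = read_vcf(tmp_path / "x.vcf", popmap, tmp_path / "x.tsv")
        assert back.n_sites == toy_table.n_sites
        assert np.array_equal(back.dosage_matrix(), toy_table.dosage_matrix())
        assert list(back.df["annotation"]) == list(toy_table.df["annotation"])
        assert np.allclose(back.df["qual"], toy_table.df["qual"])
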