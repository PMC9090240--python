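"""Empirical-Bayes moderated differential methylation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from uameth import (
    DesignSpec,
    MethylationMatrix,
    call_dmps,
    estimate_sample_weights,
    group_dmrs,
    m_to_beta,
    moderated_t_test,
    top_k_dmps,
)
from uameth.dmp import build_design, fit_variance_prior


def _two_group_sheet(n_a, n_b, group_field="group"):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return pd.DataFrame({
        "sample_id": ids,
        "subject_id": ids,
        group_field: ["HD"] * n_a + ["GP"] * n_b,
        "compartment": "blood",
        "visit": 1,
        "das28": [np.nan] * n_a + [4.0] * n_b,
        "treated_dmard": False,
    })


def _matrix_from_m(m_values, sample_ids):
    beta = m_to_beta(np.asarray(m_values, dtype=float))
    return MethylationMatrix(pd.DataFrame(
        beta, index=[f"cg{i}" for i in range(beta.shape[0])],
        columns=sample_ids))


class TestVariancePrior:
    def test_recovers_simulated_hyperparameters(self):
        rng = np.random.default_rng(0)
        d0_true, s0_true, d = 8.0, 2.0, 10
        sigma_sq = s0_true * d0_true / rng.chisquare(d0_true, size=20000)
        s_sq = sigma_sq * rng.chisquare(d, size=20000) / d
        d0, s0_sq = fit_variance_prior(s_sq, d)
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0_sq == pytest.approx(s0_true, rel=0.1)

    def test_equal_variances_give_infinite_prior_df(self):
        # no spread beyond sampling noise -> homogeneous-variance limit
        s_sq = np.full(5000, 1.3)
        d0, s0_sq = fit_variance_prior(s_sq, 10)
        assert np.isinf(d0)
        assert s0_sq == pytest.approx(1.3)


class TestModeratedT:
    def test_hand_evaluated_shrinkage(self):
        # one probe, {0,0,0} vs {1,1,1} on the M scale: coef = 1, s^2 = 0,
        # residual df 4; with d0 = 4, s0^2 = 0.5 fixed the posterior
        # variance is (4*0.5)/(4+4) = 0.25 and v = 2/3, so t = sqrt(6)
        sheet = _two_group_sheet(3, 3)
        mat = _matrix_from_m([[0, 0, 0, 1, 1, 1]], sheet["sample_id"])
        spec = DesignSpec(contrast=("HD", "GP"))
        table, params = moderated_t_test(mat, sheet, spec,
                                         d0_fixed=4.0, s0_sq_fixed=0.5)
        assert table["t"].iloc[0] == pytest.approx(np.sqrt(6.0))
        expected_p = 2 * sps.t.sf(np.sqrt(6.0), 8)
        assert table["p"].iloc[0] == pytest.approx(expected_p)

    def test_infinite_prior_df_reduces_to_pooled_t(self):
        rng = np.random.default_rng(2)
        sheet = _two_group_sheet(5, 5)
        m = rng.normal(size=(40, 10))
        mat = _matrix_from_m(m, sheet["sample_id"])
        spec = DesignSpec(contrast=("HD", "GP"))
        s_pool = 1.3
        table, _ = moderated_t_test(mat, sheet, spec, d0_fixed=np.inf,
                                    s0_sq_fixed=s_pool ** 2)
        x, y = m[:, :5], m[:, 5:]
        coef = y.mean(axis=1) - x.mean(axis=1)
        expected_t = coef / (s_pool * np.sqrt(1 / 5 + 1 / 5))
        np.testing.assert_allclose(table["t"].to_numpy(), expected_t,
                                   atol=1e-10)

    def test_pvalues_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        sheet = _two_group_sheet(6, 7)
        mat = _matrix_from_m(rng.normal(size=(30, 13)), sheet["sample_id"])
        spec = DesignSpec(contrast=("HD", "GP"))
        t1, _ = moderated_t_test(mat, sheet, spec)
        perm = rng.permutation(13)
        mat2 = MethylationMatrix(mat.beta.iloc[:, perm])
        sheet2 = sheet.iloc[perm].reset_index(drop=True)
        t2, _ = moderated_t_test(mat2, sheet2, spec)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-12)

    def test_direction_follows_delta_beta_sign(self):
        sheet = _two_group_sheet(3, 3)
        mat = _matrix_from_m([[0, 0, 0, 1, 1, 1], [1, 1, 1, 0, 0, 0]],
                             sheet["sample_id"])
        table, _ = moderated_t_test(mat, sheet,
                                    DesignSpec(contrast=("HD", "GP")),
                                    d0_fixed=4.0, s0_sq_fixed=0.5)
        assert list(table["direction"]) == ["hyper", "hypo"]
        assert table["delta_beta"].iloc[0] > 0 > table["delta_beta"].iloc[1]

    def test_three_group_f_detects_any_difference(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(18)]
        sheet = pd.DataFrame({
            "sample_id": ids, "subject_id": ids,
            "group": ["HD"] * 6 + ["GP"] * 6 + ["PP"] * 6,
            "compartment": "blood", "visit": 1,
            "das28": [np.nan] * 6 + [4.0] * 12, "treated_dmard": False,
        })
        m = rng.normal(scale=0.3, size=(200, 18))
        m[0, 6:12] += 1.0   # GP shifted
        m[0, 12:] += 2.0    # PP shifted further (cumulative layout)
        mat = _matrix_from_m(m, ids)
        table, _ = moderated_t_test(mat, sheet,
                                    DesignSpec(contrast=("HD", "GP", "PP")))
        assert table["fdr"].iloc[0] < 0.05
        assert table["p"].iloc[1:].min() > table["p"].iloc[0]

    def test_paired_design_beats_unpaired_on_subject_noise(self):
        rng = np.random.default_rng(5)
        n_subj = 8
        ids = [f"p{i}_v{v}" for i in range(n_subj) for v in (1, 2)]
        sheet = pd.DataFrame({
            "sample_id": ids,
            "subject_id": [f"p{i}" for i in range(n_subj) for _ in (1, 2)],
            "group": "GP", "compartment": "blood",
            "visit": [v for _ in range(n_subj) for v in (1, 2)],
            "das28": 4.0, "treated_dmard": False,
        })
        subj_eff = rng.normal(scale=3.0, size=n_subj)
        m = rng.normal(scale=0.3, size=(300, 2 * n_subj))
        m += np.repeat(subj_eff, 2)[None, :]
        visit2 = np.array([v == 2 for _ in range(n_subj) for v in (1, 2)])
        m[:50, visit2] += 0.8  # visit effect small next to subject spread
        mat = _matrix_from_m(m, ids)
        paired_spec = DesignSpec(contrast=(1, 2), contrast_field="visit",
                                 pairing="subject_id")
        unpaired_spec = DesignSpec(contrast=(1, 2), contrast_field="visit")
        t_p, _ = moderated_t_test(mat, sheet, paired_spec)
        t_u, _ = moderated_t_test(mat, sheet, unpaired_spec)
        hits_paired = (t_p["fdr"].iloc[:50] < 0.05).sum()
        hits_unpaired = (t_u["fdr"].iloc[:50] < 0.05).sum()
        assert hits_paired > hits_unpaired
        assert hits_paired >= 40

    def test_missing_contrast_level_rejected(self):
        sheet = _two_group_sheet(3, 3)
        mat = _matrix_from_m(np.zeros((2, 6)), sheet["sample_id"])
        with pytest.raises(ValueError, match="absent"):
            moderated_t_test(mat, sheet, DesignSpec(contrast=("HD", "PP")))


class TestSampleWeights:
    def _design(self, sheet):
        X, _, _ = build_design(sheet, DesignSpec(contrast=("HD", "GP")))
        return X

    def test_homoscedastic_weights_near_one(self):
        rng = np.random.default_rng(6)
        sheet = _two_group_sheet(5, 5)
        m = pd.DataFrame(rng.normal(size=(2000, 10)),
                         columns=sheet["sample_id"])
        w = estimate_sample_weights(m, self._design(sheet))
        assert w.min() > 0.8 and w.max() < 1.25

    def test_planted_noisy_sample_downweighted(self):
        rng = np.random.default_rng(7)
        sheet = _two_group_sheet(5, 5)
        m = rng.normal(size=(2000, 10))
        m[:, 3] = rng.normal(scale=2.0, size=2000)  # 4x variance
        m = pd.DataFrame(m, columns=sheet["sample_id"])
        w = estimate_sample_weights(m, self._design(sheet))
        assert w.idxmin() == sheet["sample_id"][3]
        assert w.iloc[3] < 0.5

    def test_identical_columns_equal_weights(self):
        rng = np.random.default_rng(8)
        sheet = _two_group_sheet(4, 4)
        m = rng.normal(size=(500, 8))
        m[:, 1] = m[:, 0]
        m = pd.DataFrame(m, columns=sheet["sample_id"])
        w = estimate_sample_weights(m, self._design(sheet))
        assert w.iloc[0] == pytest.approx(w.iloc[1], rel=1e-6)


class TestCallAndRank:
    def _table(self, fdr, delta=None, p=None, t=None):
        n = len(fdr)
        return pd.DataFrame({
            "coef": np.zeros(n),
            "delta_beta": delta if delta is not None else np.full(n, 0.2),
            "t": t if t is not None else np.arange(n, dtype=float) + 1,
            "p": p if p is not None else np.asarray(fdr) / 2,
            "fdr": fdr,
            "direction": "hyper",
        }, index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"))

    def test_fdr_threshold_count(self):
        table = self._table([0.01, 0.04, 0.06, 0.001, 0.2, 0.049])
        assert len(call_dmps(table)) == 4

    def test_delta_beta_cutoff_excludes_small_effects(self):
        table = self._table([0.001], delta=[0.10])
        assert call_dmps(table, min_abs_delta_beta=0.15).empty
        assert len(call_dmps(self._table([0.001], delta=[-0.2]),
                             min_abs_delta_beta=0.15)) == 1

    def test_empty_table(self):
        assert call_dmps(self._table([])).empty

    def test_top_k_smallest_p(self):
        table = self._table([0.5] * 5, p=[0.5, 0.01, 0.3, 0.02, 0.04])
        assert top_k_dmps(table, 3) == ["cg1", "cg3", "cg4"]

    def test_top_k_tie_rule_stable_under_permutation(self):
        table = self._table([0.5] * 6, p=[0.01, 0.01, 0.01, 0.01, 0.5, 0.9],
                            t=[1.0, 3.0, 3.0, 2.0, 9.0, 9.0])
        expected = top_k_dmps(table, 3)
        rng = np.random.default_rng(9)
        for _ in range(5):
            perm = table.iloc[rng.permutation(len(table))]
            assert top_k_dmps(perm, 3) == expected
        assert expected == ["cg1", "cg2", "cg3"]  # |t| desc then id

    def test_k_exceeding_size_warns(self):
        table = self._table([0.1, 0.2])
        with pytest.warns(UserWarning):
            assert len(top_k_dmps(table, 5)) == 2


class TestGroupDmrs:
    def _ann(self, positions, chrom="chr1"):
        return pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(len(positions))],
            "chrom": chrom, "pos": positions,
            "snp_overlap": False,
        })

    def _dmps(self, n, direction="hyper"):
        dirs = [direction] * n if isinstance(direction, str) else direction
        return pd.DataFrame(
            {"delta_beta": [0.2 if d == "hyper" else -0.2 for d in dirs],
             "direction": dirs},
            index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"))

    def test_four_probe_region(self):
        regions = group_dmrs(self._dmps(4), self._ann([100, 400, 900, 1500]),
                             max_gap_bp=1000, min_probes=4)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["n_probes"], r["start"], r["end"]) == (4, 100, 1500)

    def test_distant_probes_not_chained(self):
        regions = group_dmrs(self._dmps(2), self._ann([100, 10100]),
                             max_gap_bp=1000, min_probes=2)
        assert regions.empty

    def test_opposite_directions_never_chained(self):
        regions = group_dmrs(self._dmps(2, ["hyper", "hypo"]),
                             self._ann([100, 200]),
                             max_gap_bp=1000, min_probes=2)
        assert regions.empty
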