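"""NB differential-expression engine: filtering, normalisation, dispersion,
exact test, BH, and RUV — each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import neoblastsig as nb
from neoblastsig.de import DEError, DispersionEstimate

from conftest import nb_counts


def frame(arr, samples=None):
    arr = np.asarray(arr)
    cols = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols)


class TestCpmFilter:
    def test_hand_computed_cases(self):
        # library sizes ~1e6 so CPM == count: (2,0,0,0) passes in 1 < 3 samples
        filler = np.full((1, 4), 999_998)
        m = frame(np.vstack([[2, 0, 0, 0], filler + np.array([[0, 2, 2, 2]])]))
        kept = nb.cpm_filter(m, min_cpm=1, min_samples=3)
        assert "g0" not in kept.index
        m2 = frame(np.vstack([[1, 1, 1, 0], filler + np.array([[-1, -1, -1, 0]])]))
        kept2 = nb.cpm_filter(m2, min_cpm=1, min_samples=3)
        assert "g0" in kept2.index

    def test_all_zero_cluster_removed_and_idempotent(self, null_counts_6):
        m = null_counts_6.copy()
        m.loc["gzero"] = 0
        once = nb.cpm_filter(m)
        assert "gzero" not in once.index
        pd.testing.assert_frame_equal(nb.cpm_filter(once), once)

    def test_empty_result_warns(self):
        m = frame([[1, 0], [0, 1]])
        with pytest.warns(UserWarning):
            out = nb.cpm_filter(m, min_cpm=2e6, min_samples=2)
        assert out.empty


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = frame(np.tile([[10], [20], [5]], (1, 4)))
        assert np.allclose(nb.estimate_size_factors(m), 1.0)

    def test_doubled_column_ratio(self):
        base = np.array([[10, 10, 20], [50, 50, 100], [7, 7, 14]])
        sf = nb.estimate_size_factors(frame(base))
        assert sf.iloc[2] / sf.iloc[0] == pytest.approx(2.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_single_sample_unit_factor(self):
        assert nb.estimate_size_factors(frame([[5], [9]])).iloc[0] == 1.0

    def test_invariant_to_cluster_order(self, null_counts_6):
        sf1 = nb.estimate_size_factors(null_counts_6)
        shuffled = null_counts_6.sample(frac=1, random_state=1)
        sf2 = nb.estimate_size_factors(shuffled)
        pd.testing.assert_series_equal(sf1, sf2)


class TestDispersion:
    def test_zero_variance_cluster_hits_floor(self):
        m = frame([[5, 5, 5, 5], [1, 9, 3, 7]])
        disp = nb.estimate_dispersion(m, pd.Series(1.0, index=m.columns))
        assert disp.phi_raw.loc["g0"] == pytest.approx(1e-8)

    def test_poisson_truth_gives_small_dispersion(self):
        rng = np.random.default_rng(3)
        mu = np.exp(rng.normal(np.log(100), 0.5, 5000))
        m = frame(nb_counts(rng, mu[:, None], 0.0, (5000, 6)))
        disp = nb.estimate_dispersion(m, nb.estimate_size_factors(m))
        assert disp.phi_shrunk.median() <= 0.02

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.normal(np.log(100), 0.5, 2000))
        m = frame(nb_counts(rng, mu[:, None], 0.2, (2000, 20)))
        disp = nb.estimate_dispersion(m, nb.estimate_size_factors(m))
        assert 0.15 <= disp.phi_shrunk.mean() <= 0.25

    def test_single_sample_rejected(self):
        m = frame([[5], [9]])
        with pytest.raises(DEError):
            nb.estimate_dispersion(m, pd.Series([1.0], index=m.columns))


class TestExactTest:
    def _fixed_disp(self, index, phi):
        s = pd.Series(phi, index=index)
        return DispersionEstimate(s, s, phi, 10)

    def test_balanced_split_gives_p_one(self):
        m = frame([[3, 3, 3, 3, 3, 3]])
        sf = pd.Series(1.0, index=m.columns)
        res = nb.nb_exact_test(m, sf, self._fixed_disp(m.index, 0.1), list(m.columns[:3]), list(m.columns[3:]))
        assert res.table["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_oracle(self):
        """phi -> 0, counts (10,10) vs (0,0): p = 2 * 0.5**20 from the binomial split."""
        m = frame([[10, 10, 0, 0]])
        sf = pd.Series(1.0, index=m.columns)
        res = nb.nb_exact_test(
            m, sf, self._fixed_disp(m.index, 1e-8), list(m.columns[:2]), list(m.columns[2:])
        )
        assert res.table["pvalue"].iloc[0] == pytest.approx(2 * 0.5**20, rel=1e-6)

    def test_label_swap_flips_sign_keeps_p(self, null_counts_6):
        m = null_counts_6.iloc[:100]
        sf = nb.estimate_size_factors(m)
        ga, gb = list(m.columns[:3]), list(m.columns[3:])
        disp = nb.estimate_dispersion(m, sf, groups=[ga, gb])
        ab = nb.nb_exact_test(m, sf, disp, ga, gb)
        ba = nb.nb_exact_test(m, sf, disp, gb, ga)
        np.testing.assert_allclose(ab.table["log2fc"], -ba.table["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab.table["pvalue"], ba.table["pvalue"], atol=1e-12)

    def test_agrees_with_label_permutation_ranking(self, null_counts_6):
        """Rank agreement with a label-permutation p at the resolution 20 splits allow."""
        rng = np.random.default_rng(55)
        m = null_counts_6.iloc[:200]
        sf = nb.estimate_size_factors(m)
        ga, gb = list(m.columns[:3]), list(m.columns[3:])
        disp = nb.estimate_dispersion(m, sf, groups=[ga, gb])
        res = nb.nb_exact_test(m, sf, disp, ga, gb)
        norm = (m / sf).to_numpy()
        obs = np.abs(norm[:, :3].mean(1) - norm[:, 3:].mean(1))
        perms = np.array([rng.permutation(6) for _ in range(2000)])
        stat = np.abs(norm[:, perms[:, :3]].mean(2) - norm[:, perms[:, 3:]].mean(2))
        pperm = (stat >= obs[:, None] - 1e-12).mean(axis=1)
        rho = stats.spearmanr(res.table["pvalue"], pperm).statistic
        assert rho >= 0.8

    def test_group_validation(self, null_counts_6):
        m = null_counts_6.iloc[:5]
        sf = nb.estimate_size_factors(m)
        disp = self._fixed_disp(m.index, 0.1)
        with pytest.raises(DEError):
            nb.nb_exact_test(m, sf, disp, [], list(m.columns))
        with pytest.raises(DEError):
            nb.nb_exact_test(m, sf, disp, list(m.columns[:3]), list(m.columns[2:]))
        with pytest.raises(DEError):
            nb.nb_exact_test(m, sf, self._fixed_disp(m.index[:2], 0.1), list(m.columns[:3]), list(m.columns[3:]))


class TestBH:
    def test_hand_computed_example(self):
        fdr = nb.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(fdr, [0.04, 0.04, 0.04, 0.04])

    def test_constant_and_singleton(self):
        np.testing.assert_allclose(nb.bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert nb.bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_invalid_p_rejected(self):
        with pytest.raises(DEError):
            nb.bh_adjust([0.5, 1.2])
        with pytest.raises(DEError):
            nb.bh_adjust([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_step_up_definition(self, pvals):
        """BH output equals the textbook step-up formula with cumulative minima."""
        got = nb.bh_adjust(pvals)
        p = np.asarray(pvals)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * n / np.arange(1, n + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.clip(stepped, 0, 1)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestRUV:
    def test_k_zero_is_identity(self, null_counts_6):
        adj, w = nb.ruv_adjust(null_counts_6, list(null_counts_6.index[:5]), 0)
        pd.testing.assert_frame_equal(adj, null_counts_6)
        assert w.shape == (6, 0)

    def test_near_identity_without_batch(self):
        cfg = nb.SimulationConfig(
            n_clusters=2000, designs=("irradiation",), batch_factor_sd=0.0, seed=30
        )
        counts, _, truth = nb.simulate_counts(cfg)
        prog = pd.Series(truth.cluster_program)
        filt = nb.cpm_filter(counts)
        controls = [c for c in prog[prog == "housekeeping"].index if c in filt.index]
        adj, _ = nb.ruv_adjust(filt, controls, 1)
        # drift measured on the null (control) clusters: genuinely DE clusters
        # shift whenever the estimated factor chance-aligns with condition
        mask = filt.index.isin(controls)
        ratio = np.abs(np.log((adj.to_numpy() + 1.0) / (filt.to_numpy() + 1.0)))
        assert ratio[mask].mean() <= 0.1

    def test_recovers_planted_factor(self):
        cfg = nb.SimulationConfig(
            n_clusters=2000, designs=("irradiation",), batch_factor_sd=0.5, seed=31
        )
        counts, _, truth = nb.simulate_counts(cfg)
        prog = pd.Series(truth.cluster_program)
        filt = nb.cpm_filter(counts)
        controls = [c for c in prog[prog == "housekeeping"].index if c in filt.index]
        _, w = nb.ruv_adjust(filt, controls, 1)
        corr = np.corrcoef(w[:, 0], truth.batch_factor.to_numpy())[0, 1]
        assert abs(corr) >= 0.9

    def test_missing_controls_rejected(self, null_counts_6):
        with pytest.raises(DEError):
            nb.ruv_adjust(null_counts_6, ["nope"], 1)
        with pytest.raises(DEError):
            nb.ruv_adjust(null_counts_6, list(null_counts_6.index[:1]), 2)
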