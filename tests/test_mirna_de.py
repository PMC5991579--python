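"""Count filtering, upper-quartile normalization, and the NB QL strain test."""

import numpy as np
import pytest

from mirmeta.mirna_de import (
    CountMatrix,
    cpm,
    de_frame,
    filter_expressed,
    normalize_uq_log,
    ql_strain_test,
)


def _cm(counts, strains=None, study="s1", feature_ids=None):
    counts = np.atleast_2d(np.asarray(counts))
    n_feat, n_samp = counts.shape
    strains = strains or (["ILS"] * (n_samp // 2) + ["ISS"] * (n_samp - n_samp // 2))
    return CountMatrix(
        feature_ids=feature_ids or [f"f{i}" for i in range(n_feat)],
        sample_ids=[f"{s}_{study}_{j}" for j, s in enumerate(strains)],
        strain=strains,
        study=study,
        counts=counts,
    )


class TestCountMatrix:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            _cm([[-1, 2]], strains=["ILS", "ISS"])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            _cm([[1, 2], [3, 4]], strains=["ILS", "ISS"], feature_ids=["a", "a"])


class TestCpm:
    def test_hand_values(self):
        # count 5 in a library of 1e6 -> 5.0; and the two-library example
        m = _cm(np.array([[5]]), strains=["ILS"])
        m.counts = np.array([[5], [10**6 - 5]])
        m.feature_ids = ["a", "b"]
        assert cpm(m)[0, 0] == pytest.approx(5.0)

        two = _cm(np.array([[2, 0], [10**6 - 2, 2 * 10**6]]), strains=["ILS", "ISS"])
        np.testing.assert_allclose(cpm(two)[0], [2.0, 0.0])

    def test_all_zero_feature_stays_zero(self):
        m = _cm(np.array([[0, 0], [5, 7]]), strains=["ILS", "ISS"])
        assert np.all(cpm(m)[0] == 0)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        m = _cm(rng.integers(0, 500, size=(30, 6)))
        np.testing.assert_allclose(cpm(m).sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_sample_named(self):
        m = _cm(np.array([[0, 3], [0, 4]]), strains=["ILS", "ISS"])
        with pytest.raises(ValueError, match=m.sample_ids[0]):
            cpm(m)


class TestFilterExpressed:
    def _study(self, row, study):
        # one feature of interest on top of a constant background library
        bg = np.full((9, len(row)), 1000)
        counts = np.vstack([np.asarray(row), bg])
        return _cm(counts, study=study)

    def test_passing_both_studies_retained(self):
        # CPM (2,2,2,0,0,0)-like pattern in both studies
        lib = 9 * 1000
        c = int(np.ceil(2e-6 * (lib + 20)))  # cpm comfortably > 1
        row = [c * 10, c * 10, c * 10, 0, 0, 0]
        kept = filter_expressed([self._study(row, "a"), self._study(row, "b")])
        assert "f0" in kept

    def test_passing_one_study_only_dropped(self):
        good = [100, 100, 100, 0, 0, 0]
        bad = [0, 0, 0, 0, 0, 0]
        kept = filter_expressed([self._study(good, "a"), self._study(bad, "b")])
        assert "f0" not in kept
        # background features pass everywhere
        assert "f1" in kept

    def test_cpm_exactly_at_threshold_dropped(self):
        # engineer CPM == 1.0 exactly in three samples: count 1, library 1e6
        bg = np.full((9, 6), (10**6 - 1) // 9)
        row = np.array([1, 1, 1, 0, 0, 0])
        counts = np.vstack([row, bg])
        m = _cm(counts)
        assert np.allclose(cpm(m)[0, :3], 1.0)
        kept = filter_expressed([m], min_cpm=1.0, min_samples=3)
        assert "f0" not in kept

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        m1 = _cm(rng.integers(0, 50, size=(40, 6)), study="a")
        m2 = _cm(rng.integers(0, 50, size=(40, 6)), study="b")
        base = filter_expressed([m1, m2], min_cpm=1, min_samples=3)
        assert filter_expressed([m1, m2], min_cpm=5, min_samples=3) <= base
        assert filter_expressed([m1, m2], min_cpm=1, min_samples=5) <= base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed([])


class TestNormalizeUqLog:
    def test_percentile_oracle_values(self):
        # counts (1,2,3,4): linear-interpolation Q75 = 3.25
        m = _cm(np.array([[1], [2], [3], [4]]), strains=["ILS"])
        got = normalize_uq_log(m, pseudocount=0.0)
        expected = np.log(np.array([1, 2, 3, 4]) / 3.25)
        np.testing.assert_allclose(got[:, 0], expected, rtol=1e-12)

    def test_top_feature_dominated_sample(self):
        # counts (0,...,0,k): Q75 of (0,0,0,k) with linear interpolation
        m = _cm(np.array([[0], [0], [0], [8]]), strains=["ILS"])
        q75 = np.percentile([0, 0, 0, 8], 75)
        got = normalize_uq_log(m)
        assert got[3, 0] == pytest.approx(np.log(8 / q75 + 1.0))
        assert got[0, 0] == pytest.approx(np.log(1.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, size=(20, 4))
        m = _cm(counts)
        doubled = _cm(counts * 2)
        np.testing.assert_allclose(
            normalize_uq_log(m), normalize_uq_log(doubled), rtol=1e-12
        )

    def test_zero_q75_named(self):
        counts = np.zeros((4, 2), dtype=int)
        counts[0, :] = [5, 5]  # Q75 of (5,0,0,0) is 1.25 > 0; make col 1 all zero
        counts[:, 1] = 0
        m = _cm(counts, strains=["ILS", "ISS"])
        with pytest.raises(ValueError, match=m.sample_ids[1]):
            normalize_uq_log(m)


class TestQlStrainTest:
    def test_identical_counts_give_p_one(self):
        counts = np.vstack([np.full(6, 50), np.full(6, 200), np.full(6, 10)])
        res = ql_strain_test(_cm(counts))
        assert res[0].p == pytest.approx(1.0)
        assert res[0].log_fc == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_feature_degenerate(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 100)])
        res = ql_strain_test(_cm(counts))
        assert res[0].degenerate and res[0].p == 1.0

    def test_sign_convention_and_ref_swap(self):
        rng = np.random.default_rng(3)
        counts = np.vstack(
            [
                np.concatenate([rng.poisson(20, 3), rng.poisson(200, 3)]),
                rng.poisson(100, 6),
            ]
        )
        m = _cm(counts)
        res = ql_strain_test(m)
        assert res[0].log_fc > 0  # higher in ISS => positive ISS-over-ILS effect
        swapped = ql_strain_test(m, ref_strain="ISS")
        assert swapped[0].log_fc == pytest.approx(-res[0].log_fc, rel=1e-6)
        assert swapped[0].p == pytest.approx(res[0].p, rel=1e-6)

    def test_column_permutation_invariant(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(80, size=(5, 6))
        m = _cm(counts)
        perm = [3, 0, 5, 1, 4, 2]
        m2 = CountMatrix(
            feature_ids=m.feature_ids,
            sample_ids=[m.sample_ids[j] for j in perm],
            strain=[m.strain[j] for j in perm],
            study=m.study,
            counts=counts[:, perm],
        )
        for a, b in zip(ql_strain_test(m), ql_strain_test(m2)):
            assert a.p == pytest.approx(b.p, rel=1e-9)
            assert a.log_fc == pytest.approx(b.log_fc, rel=1e-9)

    def test_matches_statsmodels_nb_glm(self):
        """Group-mean root-finding fits agree with IRLS on the same NB family."""
        import statsmodels.api as sm
        from mirmeta.mirna_de import _moment_dispersion, _nb_group_mean, _nb_deviance, uq_factors

        rng = np.random.default_rng(5)
        counts = rng.poisson([40, 40, 40, 160, 160, 160], size=(8, 6))
        m = _cm(counts)
        s = uq_factors(m)
        is_ref = np.asarray(m.strain) == "ILS"
        X = np.column_stack([np.ones(6), (~is_ref).astype(float)])
        for row in counts:
            y = row.astype(float)
            phi = _moment_dispersion(y, s, is_ref)
            mine = np.where(
                is_ref,
                s * _nb_group_mean(y[is_ref], s[is_ref], phi),
                s * _nb_group_mean(y[~is_ref], s[~is_ref], phi),
            )
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=phi),
                offset=np.log(s),
            ).fit()
            np.testing.assert_allclose(mine, glm.mu, rtol=1e-5)
            assert _nb_deviance(y, mine, phi) == pytest.approx(glm.deviance, rel=1e-5)

    def test_null_type_one_error_under_permuted_labels(self):
        """Small-scale permutation calibration (the full-size check runs in the
        acceptance suite)."""
        rng = np.random.default_rng(6)
        n_feat = 300
        mu = rng.uniform(20, 500, n_feat)
        counts = rng.poisson(rng.gamma(1 / 0.05, mu[:, None] * 0.05, (n_feat, 6)))
        labels = ["ILS", "ISS", "ILS", "ISS", "ILS", "ISS"]  # permuted arbitrarily
        res = ql_strain_test(_cm(counts, strains=labels))
        frac = np.mean([r.p < 0.05 for r in res])
        # generous 3-sigma band around 0.05 at n = 300
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_feat)

    def test_de_frame_percentage_column(self):
        rng = np.random.default_rng(7)
        res = ql_strain_test(_cm(rng.poisson(100, size=(3, 6))))
        df = de_frame(res)
        np.testing.assert_allclose(df["pct_of_ILS"], 100 * np.exp(df["log_fc"]))
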