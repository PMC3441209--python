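import numpy as np
import pytest
from sklearn.svm import SVC

from tmpore import PoreLiningModel, SyntheticConfig, generate
from tmpore.align import pairwise_identity
from tmpore.features import apply_standardization, fit_standardization, training_matrix
from tmpore.labeling import expand_labels
from tmpore.residue_svm import default_cost_factor


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == pytest.approx(100.0)

    def test_disjoint_sequences(self):
        assert pairwise_identity("AAAA", "CCCC") == pytest.approx(0.0)

    def test_three_quarters(self):
        # brute force over gapless/gapped alignments at this length gives 3/4
        assert pairwise_identity("ACDE", "ACDD") == pytest.approx(75.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")


class TestCostFactor:
    def test_default_equalises_classes(self):
        y = np.array([1] * 3224 + [0] * 3464)
        assert default_cost_factor(y) == pytest.approx(3464 / 3224)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            default_cost_factor(np.ones(10))

    def test_fitted_results_record_the_ratio(self, strong_dataset):
        records, profiles, _ = strong_dataset
        results = PoreLiningModel(records, profiles, gamma=1 / 300,
                                  seed=1).fit()
        assert results.cost_factor == pytest.approx(
            results.n_negative / results.n_positive
        )

    def test_duplicating_positives_with_rescaled_cost_is_invariant(self):
        """Doubling every positive at half the cost factor leaves the
        decision function unchanged (the SVM-Light cost-factor semantics)."""
        records, profiles, _ = generate(SyntheticConfig(n_chains=4, seed=3))
        X, y, _, _ = training_matrix(records, profiles)
        Z = apply_standardization(X, fit_standardization(X))
        j = default_cost_factor(y)
        a = SVC(kernel="rbf", gamma=0.001, C=1.0, class_weight={0: 1.0, 1: j},
                tol=1e-6).fit(Z, y)
        Zdup = np.vstack([Z, Z[y == 1]])
        ydup = np.concatenate([y, y[y == 1]])
        b = SVC(kernel="rbf", gamma=0.001, C=1.0,
                class_weight={0: 1.0, 1: j / 2}, tol=1e-6).fit(Zdup, ydup)
        np.testing.assert_allclose(a.decision_function(Z[:40]),
                                   b.decision_function(Z[:40]), atol=1e-4)


@pytest.fixture(scope="module")
def separable():
    # near-noiseless planted signal: the classes are separable
    records, profiles, _ = generate(
        SyntheticConfig(n_chains=4, noise_sd=0.2, seed=5)
    )
    model = PoreLiningModel(records, profiles, gamma=1 / 300,
                            trade_off=10.0, seed=5)
    return records, profiles, model.fit()


@pytest.fixture(scope="module")
def with_duplicate():
    import dataclasses

    records, profiles, _ = generate(SyntheticConfig(n_chains=4, seed=13))
    twin = dataclasses.replace(records[0], chain_id="TWIN_A")
    profiles = dict(profiles)
    profiles["TWIN_A"] = dataclasses.replace(
        profiles[records[0].chain_id], chain_id="TWIN_A"
    )
    return records + [twin], profiles


class TestTrainingAndPrediction:
    def test_training_accuracy_is_perfect_on_separable_data(self, separable):
        records, profiles, results = separable
        for rec in records:
            track = results.predict_residues(rec, profiles[rec.chain_id])
            truth = expand_labels(rec)
            predicted = {int(i) for i, c in zip(track.indices, track.calls) if c}
            assert predicted == truth

    def test_support_vector_ratio_low_on_separable_data(self, strong_dataset):
        # at the grid-search optimum for this data the planted signal is
        # cleanly separable, so far fewer examples sit on the margin than
        # the ~5:7 seen on real chains
        records, profiles, _ = strong_dataset
        results = PoreLiningModel(records, profiles, gamma=0.001,
                                  trade_off=10.0, seed=1).fit()
        assert results.support_vector_ratio < 0.5

    def test_track_restricted_to_helix_residues(self, separable):
        records, profiles, results = separable
        rec = records[0]
        track = results.predict_residues(rec, profiles[rec.chain_id])
        tm = set(rec.tm_residues())
        assert set(track.indices.tolist()) == tm
        outside = next(i for i in range(1, len(rec) + 1) if i not in tm)
        assert outside not in track

    def test_margin_matches_kernel_expansion(self, separable):
        """Decision scores agree with a direct RBF kernel-expansion oracle."""
        records, profiles, results = separable
        rec = records[0]
        track = results.predict_residues(rec, profiles[rec.chain_id])
        svc = results.svc
        X, _, _, _ = training_matrix([rec], profiles)
        Z = apply_standardization(X, results.standardization)
        sv = svc.support_vectors_
        d2 = ((Z[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        manual = np.exp(-results.gamma * d2) @ svc.dual_coef_.ravel() \
            + svc.intercept_[0]
        np.testing.assert_allclose(manual, track.scores, atol=1e-8)

    def test_missing_profile_rejected(self, strong_dataset):
        records, profiles, _ = strong_dataset
        with pytest.raises(ValueError, match="without a PSSM"):
            PoreLiningModel(records[:3], {records[0].chain_id:
                                          profiles[records[0].chain_id]})


class TestGridSearch:
    def test_singleton_grid_returned_verbatim(self):
        records, profiles, _ = generate(SyntheticConfig(n_chains=4, seed=7))
        model = PoreLiningModel(records, profiles, seed=7)
        best = model.grid_search(gammas=[0.005], trade_offs=[2.0], n_folds=3)
        assert (best.gamma, best.trade_off) == (0.005, 2.0)

    def test_selects_matching_bandwidth(self):
        """A kernel width in the data's regime beats a degenerate one."""
        records, profiles, _ = generate(SyntheticConfig(n_chains=6, seed=2))
        model = PoreLiningModel(records, profiles, seed=2)
        best = model.grid_search(gammas=[0.001, 1.0], trade_offs=[10.0],
                                 n_folds=3)
        assert best.gamma == 0.001

    def test_result_is_argmax_of_cv_table(self):
        records, profiles, _ = generate(SyntheticConfig(n_chains=4, seed=9))
        model = PoreLiningModel(records, profiles, seed=9)
        best = model.grid_search(gammas=[0.001, 0.01], trade_offs=[1.0, 10.0],
                                 n_folds=2)
        table = best.cv_table
        assert best.mcc == table["mcc"].max()
        top = table[table["mcc"] == best.mcc]
        assert best.gamma == top["gamma"].min()


class TestJackknife:
    def test_dissimilar_chains_exclude_only_target(self):
        records, profiles, _ = generate(SyntheticConfig(n_chains=3, seed=11))
        model = PoreLiningModel(records, profiles, gamma=1 / 300, seed=11)
        jk = model.jackknife()
        assert all(excl == [] for excl in jk.exclusions.values())
        assert len(jk.tracks) == 3

    def test_identical_chain_excluded_from_fold(self, with_duplicate):
        records, profiles = with_duplicate
        jk = PoreLiningModel(records, profiles, gamma=1 / 300,
                             seed=13).jackknife()
        assert jk.exclusions[records[0].chain_id] == ["TWIN_A"]
        assert jk.exclusions["TWIN_A"] == [records[0].chain_id]

    def test_no_leakage_from_excluded_homolog(self, with_duplicate):
        """Corrupting the labels of an excluded homolog must not move the
        target fold's predictions at all."""
        import dataclasses
        records, profiles = with_duplicate
        target_id = records[0].chain_id
        jk1 = PoreLiningModel(records, profiles, gamma=1 / 300,
                              seed=13).jackknife()
        twin = records[-1]
        corrupted = dataclasses.replace(
            twin,
            pore_residues=frozenset(set(twin.tm_residues())
                                    - set(twin.pore_residues)),
        )
        jk2 = PoreLiningModel(records[:-1] + [corrupted], profiles,
                              gamma=1 / 300, seed=13).jackknife()
        np.testing.assert_array_equal(jk1.tracks[target_id].indices,
                                      jk2.tracks[target_id].indices)
        np.testing.assert_allclose(jk1.tracks[target_id].scores,
                                   jk2.tracks[target_id].scores, atol=1e-9)

    def test_determinism(self):
        records, profiles, _ = generate(SyntheticConfig(n_chains=3, seed=17))
        jk1 = PoreLiningModel(records, profiles, gamma=1 / 300, seed=17).jackknife()
        jk2 = PoreLiningModel(records, profiles, gamma=1 / 300, seed=17).jackknife()
        for cid in jk1.tracks:
            np.testing.assert_allclose(jk1.tracks[cid].scores,
                                       jk2.tracks[cid].scores, atol=1e-9)

    def test_recovers_planted_signal(self, strong_jackknife):
        assert strong_jackknife.mcc > 0.5


class TestBundleRoundtrip:
    def test_save_load_preserves_scores(self, tmp_path, strong_dataset):
        from tmpore import PoreLiningResults
        records, profiles, _ = strong_dataset
        results = PoreLiningModel(records[:4],
                                  profiles, gamma=1 / 300, seed=1).fit()
        path = tmp_path / "model.bundle"
        results.save(path)
        loaded = PoreLiningResults.load(path)
        rec = records[0]
        np.testing.assert_allclose(
            loaded.predict_residues(rec, profiles[rec.chain_id]).scores,
            results.predict_residues(rec, profiles[rec.chain_id]).scores,
        )
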