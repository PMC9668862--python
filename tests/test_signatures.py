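import numpy as np
import pandas as pd
import pytest

from crossmark.profiles import pool_profiles
from crossmark.signatures import (
    SignatureClassifier,
    confusion_metrics,
    delong_ci,
    evaluate,
    fit_signature,
    lodo_validation,
    rank_auc,
    specificity_screen,
    transfer_validation,
    tune_rf,
)
from crossmark.pipeline import _null_disease_profiles


def brute_force_auc(pos, neg):
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.integers(0, 5, size=6).astype(float)  # ties likely
            neg = rng.integers(0, 5, size=4).astype(float)
            assert rank_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    def test_null_scores_auc_half(self):
        aucs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.random(200)
            labels = rng.random(200) < 0.5
            aucs.append(rank_auc(scores[labels], scores[~labels]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.random(20), rng.random(15)
        a1 = rank_auc(pos, neg)
        a2 = rank_auc(np.exp(5 * pos), np.exp(5 * neg))
        assert a1 == pytest.approx(a2)

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(1, 1, size=40)
        neg = rng.normal(0, 1, size=40)
        auc, lo, hi = delong_ci(pos, neg)
        assert lo <= auc <= hi
        assert auc == pytest.approx(rank_auc(pos, neg))
        assert 0 <= lo and hi <= 1


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "sens,spec,n_pos,n_neg,f,acc",
        [
            (0.61, 0.90, 46, 61, 0.70, 0.78),
            (0.57, 0.87, 46, 47, 0.67, 0.72),
            (0.66, 0.71, 91, 42, 0.74, 0.68),
            (0.59, 0.81, 29, 27, 0.67, 0.70),
        ],
    )
    def test_reported_quadruples(self, sens, spec, n_pos, n_neg, f, acc):
        out = confusion_metrics(sens, spec, n_pos, n_neg)
        assert out["f_score"] == pytest.approx(f, abs=0.005)
        assert out["accuracy"] == pytest.approx(acc, abs=0.005)

    def test_perfect_classifier(self):
        out = confusion_metrics(1.0, 1.0, 10, 10)
        assert out["accuracy"] == 1.0 and out["f_score"] == 1.0

    def test_no_predicted_positives_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0.0, 1.0, 5, 5)


class TestSignatureClassifier:
    def test_sklearn_contract(self):
        from sklearn.utils.validation import check_is_fitted

        clf = SignatureClassifier(["a", "b"], mtry=1, ntree=50, random_state=0)
        params = clf.get_params()
        assert params["mtry"] == 1 and params["ntree"] == 50
        clf.set_params(ntree=60)
        X = pd.DataFrame(np.random.default_rng(0).random((20, 2)), columns=["a", "b"])
        y = np.array(["HC"] * 10 + ["CRC"] * 10)
        clf.fit(X, y)
        check_is_fitted(clf, "forest_")
        assert clf.genera_ == ["a", "b"]
        assert clf.predict_proba(X).shape == (20, 2)

    def test_memorization_sanity(self, default_run):
        _, profiles, truth = default_run
        m = fit_signature(profiles[0], truth.sharp_markers,
                          {"mtry": 1, "ntree": 200}, seed=0)
        rep = evaluate(m, profiles[0], "CRC_vs_HC")
        assert rep.auc >= 0.99

    def test_missing_genus_named(self, default_run):
        _, profiles, _ = default_run
        with pytest.raises(KeyError, match="NotAGenus"):
            fit_signature(profiles[0], ["NotAGenus"], {"mtry": 1, "ntree": 10})

    def test_fit_evaluate_reproducible(self, default_run):
        _, profiles, truth = default_run
        reps = [
            evaluate(
                fit_signature(profiles[0], truth.sharp_markers,
                              {"mtry": 1, "ntree": 100}, seed=5),
                profiles[1], "CRC_vs_HC",
            ).auc
            for _ in range(2)
        ]
        assert reps[0] == reps[1]

    def test_single_class_test_set_rejected(self, default_run):
        _, profiles, truth = default_run
        m = fit_signature(profiles[0], truth.sharp_markers, {"mtry": 1, "ntree": 50})
        hc_only = profiles[1].subset_groups(["HC", "CA"])
        with pytest.raises(ValueError):
            evaluate(m, hc_only, "CRC_vs_HC")


class TestTuning:
    def test_single_point_grid(self, default_run):
        _, profiles, truth = default_run
        params, grid = tune_rf(profiles[0], truth.sharp_markers, "CRC_vs_HC",
                               mtry_grid=[1], ntree_grid=[100], seed=0)
        assert params == {"mtry": 1, "ntree": 100}
        assert list(grid) == [(1, 100)]

    def test_separable_data_low_oob(self):
        from crossmark.simulate import MarkerSpec, default_config, generate_cohorts

        cfg = default_config(
            seed=4, n_cohorts=1, noise_sigma=0.4,
            markers=[MarkerSpec(j, (0.0, 0.0, 4.0), sharp=True) for j in range(3)],
            ko_links=[],
        )
        profiles, truth = generate_cohorts(cfg)
        params, grid = tune_rf(profiles[0], truth.sharp_markers, "CRC_vs_HC",
                               mtry_grid=[1, 2], ntree_grid=[200], seed=0)
        assert min(grid.values()) <= 0.1

    def test_deterministic_selection(self, default_run):
        _, profiles, truth = default_run
        a = tune_rf(profiles[0], truth.sharp_markers, "CRC_vs_HC", [1, 2], [100, 200], seed=3)
        b = tune_rf(profiles[0], truth.sharp_markers, "CRC_vs_HC", [1, 2], [100, 200], seed=3)
        assert a == b

    def test_oversized_mtry_skipped_with_warning(self, default_run):
        _, profiles, truth = default_run
        with pytest.warns(UserWarning, match="mtry"):
            params, grid = tune_rf(profiles[0], truth.sharp_markers, "CRC_vs_HC",
                                   mtry_grid=[1, 99], ntree_grid=[100], seed=0)
        assert (99, 100) not in grid


class TestTransferAndLodo:
    def test_matrix_shape_and_exchangeability(self, default_run):
        _, profiles, truth = default_run
        copies = []
        for i in range(3):
            p = profiles[0]
            q = p.abundance.copy()
            q.index = [f"c{i}_{s}" for s in q.index]
            md = p.metadata.copy()
            md.index = q.index
            from crossmark.profiles import CohortProfile

            copies.append(CohortProfile(f"copy{i}", q, md))
        tm = transfer_validation(copies, truth.sharp_markers, "CRC_vs_HC",
                                 {"mtry": 1, "ntree": 100}, seed=0)
        assert tm.auc.shape == (3, 3)
        off = tm.auc.to_numpy()[~np.eye(3, dtype=bool)]
        diag = np.diag(tm.auc.to_numpy())
        assert abs(off.mean() - diag.mean()) < 0.15

    def test_transfer_auc_high_on_planted_markers(self, default_run):
        _, profiles, truth = default_run
        tm = transfer_validation(profiles[:4], truth.sharp_markers, "CRC_vs_HC",
                                 {"mtry": 1, "ntree": 200}, seed=0)
        off = tm.auc.to_numpy()[~np.eye(4, dtype=bool)]
        assert off.mean() >= 0.80

    def test_lodo_runs_and_scores(self, default_run):
        _, profiles, truth = default_run
        lodo = lodo_validation(profiles[:3], truth.sharp_markers, "CRC_vs_HC",
                               {"mtry": 1, "ntree": 200}, seed=0)
        assert len(lodo) == 3
        assert (lodo > 0.7).all()

    def test_missing_class_cohort_marked(self, default_run):
        _, profiles, truth = default_run
        broken = profiles[2].subset_groups(["HC", "CA"])
        with pytest.warns(UserWarning, match="lacks"):
            lodo = lodo_validation([profiles[0], profiles[1], broken],
                                   truth.sharp_markers, "CRC_vs_HC",
                                   {"mtry": 1, "ntree": 50}, seed=0)
        assert np.isnan(lodo[broken.cohort_id])


class TestSpecificityScreen:
    def test_null_disease_auc_near_half(self, default_run):
        _, profiles, truth = default_run
        model = fit_signature(profiles[0], truth.sharp_markers,
                              {"mtry": 1, "ntree": 200}, seed=0)
        aucs = []
        for seed in range(10):
            disease = _null_disease_profiles(seed)
            aucs += specificity_screen(model, disease).tolist()
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_planted_confound_detected(self, default_run):
        """Negative control: a disease sharing the CRC marker shifts scores
        far above 0.5."""
        from crossmark.profiles import CohortProfile
        from crossmark.simulate import default_config, generate_cohorts

        _, profiles, truth = default_run
        model = fit_signature(profiles[0], truth.sharp_markers,
                              {"mtry": 1, "ntree": 200}, seed=0)
        cfg = default_config(seed=77, n_cohorts=1,
                             samples_per_group={"HC": 30, "CRC": 30})
        sims, _ = generate_cohorts(cfg)
        md = sims[0].metadata.copy()
        md["group"] = md["group"].map({"HC": "control", "CRC": "disease"})
        confounded = CohortProfile("confounded", sims[0].abundance, md)
        auc = specificity_screen(model, [confounded])["confounded"]
        assert auc > 0.8

    def test_empty_disease_list(self, default_run):
        _, profiles, truth = default_run
        model = fit_signature(profiles[0], truth.sharp_markers,
                              {"mtry": 1, "ntree": 50}, seed=0)
        assert specificity_screen(model, []).empty


def test_model_save_load_round_trip(tmp_path, default_run):
    from crossmark.signatures import SignatureModel

    _, profiles, truth = default_run
    m = fit_signature(profiles[0], truth.sharp_markers, {"mtry": 1, "ntree": 50},
                      seed=0, name="sig")
    m.save(tmp_path / "m.pkl")
    back = SignatureModel.load(tmp_path / "m.pkl")
    assert back.genera == m.genera
    a = evaluate(m, profiles[1], "CRC_vs_HC").auc
    b = evaluate(back, profiles[1], "CRC_vs_HC").auc
    assert a == b


def test_roc_points_monotone(default_run):
    from crossmark.signatures import roc_points

    _, profiles, truth = default_run
    m = fit_signature(profiles[0], truth.sharp_markers, {"mtry": 1, "ntree": 100}, seed=0)
    pts = roc_points(m, profiles[1], "CRC_vs_HC")
    assert (pts["fpr"].diff().dropna() >= 0).all()
    assert (pts["tpr"].diff().dropna() >= 0).all()
    assert pts["tpr"].iloc[-1] == 1.0
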