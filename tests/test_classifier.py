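import json

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from tolrad._importance import oob_masks
from tolrad.annotations_io import build_frequency_table
from tolrad.classifier import (
    load_model,
    permutation_importance,
    predict,
    save_model,
    train,
)
from tolrad.labels import RADIOSENSITIVE, TOLERANT
from tolrad.synthetic import PlantedCohortSpec, generate_cohort

from conftest import PLANTED


class TestOOBReconstruction:
    def test_reconstructed_masks_reproduce_sklearn_oob_votes(self):
        """Dual-route check: our bootstrap-mask reconstruction must agree
        with sklearn's own OOB aggregation on data the forest cannot fit
        perfectly."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 0] + rng.normal(scale=1.5, size=80) > 0, "a", "b")
        forest = RandomForestClassifier(n_estimators=100, random_state=2, oob_score=True)
        forest.fit(X, y)
        assert forest.oob_score_ < 1.0  # the check must be non-trivial
        masks = oob_masks(forest, 80)
        proba = np.zeros((80, 2))
        n_oob = np.zeros(80)
        for t, est in enumerate(forest.estimators_):
            oob = masks[t]
            proba[oob] += est.predict_proba(X[oob].astype(np.float32))
            n_oob[oob] += 1
        proba /= n_oob[:, None]
        assert np.allclose(proba, forest.oob_decision_function_)


class TestTrain:
    def test_separated_cohort_reaches_high_cv_accuracy(self, trained_model):
        assert trained_model.cv_accuracy >= 0.95

    def test_same_seed_reproduces_cv_accuracy_and_predictions(
        self, planted_table, small_labels_vector
    ):
        m1 = train(planted_table, small_labels_vector, cv_folds=5, n_trees=100, seed=3)
        m2 = train(planted_table, small_labels_vector, cv_folds=5, n_trees=100, seed=3)
        assert m1.cv_accuracy == m2.cv_accuracy
        assert m1.mtry == m2.mtry
        r1 = predict(m1, planted_table).frame
        r2 = predict(m2, planted_table).frame
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_class_rejected(self, planted_table):
        y = np.full(len(planted_table.genome_ids), TOLERANT)
        with pytest.raises(ValueError, match="both classes"):
            train(planted_table, y, cv_folds=5)

    def test_too_many_folds_rejected(self, planted_table, small_labels_vector):
        with pytest.raises(ValueError, match="cv_folds"):
            train(planted_table, small_labels_vector, cv_folds=11)


class TestPredict:
    def test_training_exemplars_recovered(self, trained_model, planted_table, small_cohort):
        _, labels, _ = small_cohort
        frame = predict(trained_model, planted_table).frame
        for _, row in frame.iterrows():
            if labels[row["genome_id"]] == RADIOSENSITIVE:
                assert row["vote_fraction_radiosensitive"] > 0.5
                assert row["predicted_class"] == RADIOSENSITIVE

    def test_all_zero_predictors_excluded(self, trained_model):
        df = pd.DataFrame(0.0, index=["mag1"], columns=PLANTED)
        frame = predict(trained_model, df).frame
        row = frame.iloc[0]
        assert row["excluded"]
        assert row["n_zero_predictors"] == len(PLANTED)
        assert row["predicted_class"] is None

    def test_one_missing_predictor_still_classified(self, trained_model, planted_table):
        df = planted_table.frequencies.head(1).copy()
        df.iloc[0, 0] = 0.0
        row = predict(trained_model, df).frame.iloc[0]
        assert not row["excluded"]
        assert row["n_zero_predictors"] == 1
        assert row["predicted_class"] in (RADIOSENSITIVE, TOLERANT)

    def test_vote_fractions_are_complementary(self, trained_model, planted_table):
        frame = predict(trained_model, planted_table).frame
        vf = frame["vote_fraction_radiosensitive"]
        assert ((vf >= 0) & (vf <= 1)).all()
        # tolerant fraction is 1 - radiosensitive fraction by construction
        n_trees = len(trained_model.forest.estimators_)
        assert np.allclose((vf * n_trees) % 1, 0, atol=1e-9)

    def test_row_order_invariance(self, trained_model, planted_table):
        a = predict(trained_model, planted_table).frame.set_index("genome_id")
        shuffled = planted_table.frequencies.sample(frac=1, random_state=0)
        b = predict(trained_model, shuffled).frame.set_index("genome_id")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_exclusions_monotone_in_threshold(self, trained_model, planted_table):
        df = planted_table.frequencies.copy()
        df.iloc[0, :2] = 0.0
        df.iloc[1, :3] = 0.0
        n_excluded = [
            int(predict(trained_model, df, exclusion_threshold=k).frame["excluded"].sum())
            for k in (1, 2, 3, 4)
        ]
        assert all(a >= b for a, b in zip(n_excluded, n_excluded[1:]))

    def test_empty_table_rejected(self, trained_model):
        with pytest.raises(ValueError, match="empty"):
            predict(trained_model, pd.DataFrame(columns=PLANTED))


class TestPermutationImportance:
    def test_constant_column_has_zero_importance(
        self, planted_table, small_labels_vector
    ):
        df = planted_table.frequencies.copy()
        df["PF00042"] = 0.01
        model = train(df, small_labels_vector, cv_folds=5, n_trees=200, seed=0)
        mda = permutation_importance(model, df, small_labels_vector, n_repeats=5, seed=0)
        assert abs(mda["PF00042"]) <= 0.5

    def test_sole_informative_feature_dominates(self):
        spec = PlantedCohortSpec(
            n_per_class=15,
            n_noise_domains=30,
            total_instances_range=(2000, 3000),
            seed=19,
        )
        sets, labels, _ = generate_cohort(spec)
        y = np.array([labels[s.genome_id] for s in sets])
        feats = ["PF77001"] + [f"PF{10001 + i:05d}" for i in range(4)]
        table = build_frequency_table(sets, domains=feats)
        model = train(table, y, cv_folds=5, n_trees=200, seed=19)
        mda = permutation_importance(model, table, y, n_repeats=10, seed=19)
        assert max(mda, key=mda.get) == "PF77001"

    def test_values_bounded_on_percent_scale(
        self, trained_model, planted_table, small_labels_vector
    ):
        mda = permutation_importance(
            trained_model, planted_table, small_labels_vector, n_repeats=3, seed=1
        )
        assert all(np.isfinite(v) and -100 <= v <= 100 for v in mda.values())

    def test_zero_repeats_rejected(self, trained_model, planted_table, small_labels_vector):
        with pytest.raises(ValueError):
            permutation_importance(
                trained_model, planted_table, small_labels_vector, n_repeats=0
            )


class TestPersistence:
    def test_roundtrip_preserves_predictions(self, trained_model, planted_table, tmp_path):
        save_model(trained_model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        a = predict(trained_model, planted_table).frame
        b = predict(back, planted_table).frame
        pd.testing.assert_frame_equal(a, b)
        assert back.predictor_domains == trained_model.predictor_domains
        assert back.cv_accuracy == trained_model.cv_accuracy

    def test_corrupt_sidecar_fails_cleanly(self, trained_model, tmp_path):
        save_model(trained_model, tmp_path / "bundle")
        (tmp_path / "bundle" / "model.json").write_text("{not json")
        with pytest.raises(ValueError, match="sidecar"):
            load_model(tmp_path / "bundle")

    def test_version_mismatch_names_both_versions(self, trained_model, tmp_path):
        save_model(trained_model, tmp_path / "bundle")
        sidecar = json.loads((tmp_path / "bundle" / "model.json").read_text())
        sidecar["format_version"] = 99
        (tmp_path / "bundle" / "model.json").write_text(json.dumps(sidecar))
        with pytest.raises(ValueError, match="99"):
            load_model(tmp_path / "bundle")

    def test_sidecar_predictor_order_does_not_change_predictions(
        self, trained_model, planted_table, tmp_path
    ):
        save_model(trained_model, tmp_path / "bundle")
        sidecar_path = tmp_path / "bundle" / "model.json"
        sidecar = json.loads(sidecar_path.read_text())
        sidecar["predictor_domains"] = sidecar["predictor_domains"][::-1]
        sidecar_path.write_text(json.dumps(sidecar))
        back = load_model(tmp_path / "bundle")
        a = predict(trained_model, planted_table).frame
        b = predict(back, planted_table).frame
        pd.testing.assert_frame_equal(a, b)
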