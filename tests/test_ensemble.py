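"""Tests for the multi-class ISS ensemble and the comparison baselines."""

import numpy as np
import pytest

from isspu import (
    ClassEnsemble,
    ISSModel,
    SampleSet,
    SimulatorConfig,
    draw_unlabeled,
    fit_aio_baseline,
    fit_iss,
    fit_one_vs_rest_baseline,
    sample_training_sets,
)
from isspu.ensemble import derive_seed
from isspu.pu import InsufficientPositivesError, PURoutine
from isspu.synthetic import ImbalanceDesign


class _FixedScorer:
    def __init__(self, value):
        self.value = float(value)

    def predict_proba(self, X):
        s = np.full(len(X), self.value)
        return np.column_stack([1 - s, s])


def _routine(value, c=1.0, valid=True):
    return PURoutine(simulator=_FixedScorer(value), c=c, seed=0, valid=valid)


def _toy_model(values_per_class, classes=None):
    classes = classes or list(range(len(values_per_class)))
    ensembles = [ClassEnsemble(target_class=cls,
                               routines=[_routine(v) for v in vals])
                 for cls, vals in zip(classes, values_per_class)]
    return ISSModel(ensembles=ensembles, classes=classes,
                    J=len(values_per_class[0]), seed=0, n_features=1)


@pytest.fixture(scope="module")
def fitted(small_scene, fast_config):
    """A small fitted ISS model plus its train/test sets."""
    design = ImbalanceDesign(a=10, b=90, per_majority=80, test_size=600,
                             seed=5, minority_class=0)
    train, test = sample_training_sets(small_scene, design)
    pool, _ = small_scene.pixel_table()
    model = fit_iss(train, pool, J=3, config=fast_config, seed=5)
    return model, train, test


class TestSampleSet:
    def test_label_outside_catalogue_rejected(self):
        with pytest.raises(ValueError):
            SampleSet(X=np.zeros((2, 1)), y=np.array([0, 5]), classes=[0, 1])

    def test_csv_roundtrip(self, tmp_path, rng):
        ss = SampleSet(X=rng.normal(size=(6, 2)),
                       y=np.array([0, 0, 1, 1, 2, 2]), classes=[0, 1, 2])
        ss.to_csv(tmp_path / "s.csv")
        back = SampleSet.from_csv(tmp_path / "s.csv")
        np.testing.assert_allclose(back.X, ss.X)
        np.testing.assert_array_equal(back.y, ss.y)


class TestDrawUnlabeled:
    def test_draw_contract(self, rng):
        pool = rng.normal(size=(10_000, 2))
        out = draw_unlabeled(pool, 100, exclude=None, seed=0)
        assert out.shape == (100, 2)
        # rows are distinct pool rows (no replacement)
        assert len(np.unique(out, axis=0)) == 100

    def test_exclusion_respected(self, rng):
        pool = np.arange(50, dtype=float).reshape(-1, 1)
        out = draw_unlabeled(pool, 20, exclude=range(30), seed=1)
        assert out.min() >= 30

    def test_same_seed_same_draw(self, rng):
        pool = rng.normal(size=(500, 2))
        a = draw_unlabeled(pool, 50, None, seed=7)
        b = draw_unlabeled(pool, 50, None, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_distinct_seeds_distinct_draws(self, rng):
        pool = rng.normal(size=(100_000, 1))
        draws = [draw_unlabeled(pool, 50, None, seed=s).ravel()
                 for s in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.array_equal(np.sort(draws[i]),
                                          np.sort(draws[j]))

    def test_pool_too_small(self):
        with pytest.raises(ValueError, match="need 30"):
            draw_unlabeled(np.zeros((40, 1)), 30, exclude=range(20), seed=0)


class TestFitIss:
    def test_routine_count(self, fitted):
        model, train, _ = fitted
        assert len(model.ensembles) == len(train.classes)
        assert all(e.J == 3 for e in model.ensembles)

    def test_single_routine_boundary(self, small_scene, fast_config):
        design = ImbalanceDesign(a=50, b=50, per_majority=30, test_size=300,
                                 seed=2)
        train, _ = sample_training_sets(small_scene, design)
        pool, _ = small_scene.pixel_table()
        model = fit_iss(train, pool, J=1, config=fast_config, seed=2)
        assert all(e.J == 1 for e in model.ensembles)

    def test_too_few_positives_named(self, fast_config, rng):
        train = SampleSet(X=rng.normal(size=(43, 2)),
                          y=np.r_[np.zeros(3), np.ones(40)].astype(int),
                          classes=[0, 1])
        with pytest.raises(InsufficientPositivesError, match="0"):
            fit_iss(train, rng.normal(size=(200, 2)), J=2,
                    config=fast_config)

    def test_own_positives_excluded_from_pool(self, fast_config, rng):
        # a pool of exactly the positives plus enough other rows: every
        # unlabeled draw must avoid the class's own labeled rows
        pool = np.vstack([np.full((10, 1), 1000.0), rng.normal(size=(50, 1))])
        train = SampleSet(X=np.vstack([pool[:10], pool[10:20]]),
                          y=np.r_[np.zeros(10), np.ones(10)].astype(int),
                          classes=[0, 1],
                          pool_indices=np.arange(20))
        model = fit_iss(train, pool, J=2, config=fast_config, seed=0)
        assert model is not None  # draws succeeded with exclusions applied


class TestPrediction:
    def test_posterior_is_routine_mean(self):
        model = _toy_model([[0.2, 0.8]])
        proba = model.predict_proba(np.zeros((3, 1)))
        np.testing.assert_allclose(proba[:, 0], 0.5)

    def test_invalid_routines_dropped_from_mean(self):
        ens = ClassEnsemble(target_class=0,
                            routines=[_routine(0.4),
                                      _routine(0.9, valid=False)])
        model = ISSModel(ensembles=[ens], classes=[0], J=2, seed=0,
                         n_features=1)
        np.testing.assert_allclose(
            model.predict_proba(np.zeros((2, 1)))[:, 0], 0.4)

    def test_argmax_rule(self):
        model = _toy_model([[0.1], [0.9], [0.3]],
                           classes=["house", "tree", "road"])
        assert model.predict(np.zeros((1, 1)))[0] == "tree"

    def test_tie_goes_to_first_catalogue_class(self):
        model = _toy_model([[0.5], [0.5]], classes=["a", "b"])
        assert model.predict(np.zeros((1, 1)))[0] == "a"

    def test_all_zero_posteriors_still_predict(self):
        model = _toy_model([[0.0], [0.0]], classes=["x", "y"])
        proba = model.predict_proba(np.zeros((2, 1)))
        assert np.all(proba == 0)
        assert model.predict(np.zeros((2, 1)))[0] == "x"

    def test_single_class_reduces_to_pu_posterior(self):
        model = _toy_model([[0.3, 0.5]], classes=["only"])
        np.testing.assert_allclose(
            model.predict_proba(np.zeros((2, 1)))[:, 0], 0.4)

    def test_dimension_mismatch(self, fitted):
        model, _, _ = fitted
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros((3, 99)))

    def test_probabilities_in_unit_interval(self, fitted):
        model, _, test = fitted
        proba = model.predict_proba(test.X[:100])
        assert proba.min() >= 0.0 and proba.max() <= 1.0

    def test_catalogue_permutation_only_reorders(self, small_scene,
                                                 fast_config):
        design = ImbalanceDesign(a=50, b=50, per_majority=30, test_size=200,
                                 seed=3)
        train, test = sample_training_sets(small_scene, design)
        pool, _ = small_scene.pixel_table()
        m1 = fit_iss(train, pool, J=2, config=fast_config, seed=3)
        perm = [2, 0, 1]
        train2 = SampleSet(X=train.X, y=train.y,
                           classes=[train.classes[i] for i in perm],
                           pool_indices=train.pool_indices)
        m2 = fit_iss(train2, pool, J=2, config=fast_config, seed=3)
        p1 = m1.predict_proba(test.X[:50])
        p2 = m2.predict_proba(test.X[:50])
        np.testing.assert_allclose(p1[:, perm], p2, atol=1e-12)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, _, test = fitted
        model.save(tmp_path / "model.joblib")
        back = ISSModel.load(tmp_path / "model.joblib")
        np.testing.assert_allclose(back.predict_proba(test.X[:20]),
                                   model.predict_proba(test.X[:20]))


class TestBaselines:
    def test_single_class_rejected(self, rng):
        train = SampleSet(X=rng.normal(size=(10, 2)),
                          y=np.zeros(10, dtype=int), classes=[0, 1])
        with pytest.raises(ValueError, match="2 classes"):
            fit_aio_baseline(train)

    @pytest.mark.parametrize("fitter,kw", [
        (fit_aio_baseline, {"backend": "gbt"}),
        (fit_aio_baseline, {"backend": "rf"}),
        (fit_one_vs_rest_baseline, {"backend": "gbt"}),
    ])
    def test_contract_and_sanity(self, small_scene, fast_config, fitter, kw):
        design = ImbalanceDesign(a=50, b=50, per_majority=60, test_size=400,
                                 seed=4)
        train, test = sample_training_sets(small_scene, design)
        clf = fitter(train, config=fast_config, seed=4, **kw)
        proba = clf.predict_proba(test.X)
        assert proba.shape == (len(test.y), len(train.classes))
        pred = clf.predict(test.X)
        # balanced, separable training: clearly better than chance
        assert np.mean(pred == test.y) > 0.6


class TestEnsembleAveraging:
    def test_j10_no_noisier_than_j1(self, small_scene):
        """Averaging 10 routines must not increase minority-F1 spread."""
        from isspu.metrics import confusion_matrix, f1_per_class

        cfg = SimulatorConfig(hyperparameters={"n_estimators": 20,
                                               "max_depth": 3})
        pool, _ = small_scene.pixel_table()
        f1 = {1: [], 10: []}
        for seed in range(10):
            design = ImbalanceDesign(a=7, b=93, per_majority=60,
                                     test_size=400, seed=seed)
            train, test = sample_training_sets(small_scene, design)
            for J in (1, 10):
                model = fit_iss(train, pool, J=J, config=cfg,
                                seed=derive_seed(seed, J))
                cm = confusion_matrix(test.y, model.predict(test.X),
                                      train.classes)
                f1[J].append(f1_per_class(cm)[0])
        assert np.std(f1[10]) <= np.std(f1[1]) + 1e-12


def test_derived_seeds_below_2_31():
    for args in [(0,), (1, 2, 3), (2**30, 5, 9)]:
        s = derive_seed(*args)
        assert 0 <= s < 2**31
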