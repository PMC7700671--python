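"""Multi-class impartial semi-supervised (ISS) PU ensembles.

The n-class problem is decomposed one-by-one: for each class an ensemble of
``J`` PU routines is fitted, each on *all* labeled positives of that class
plus a fresh random unlabeled draw of exactly the same size (the equal-size
draw is what removes the within-routine imbalance).  Per class the posterior
is the mean over valid routines of the calibrated ``min(g_j/c_j, 1)``; the
final label is the class of maximum posterior, ties resolved by catalogue
order.  Class posteriors are independent one-class estimates and are not
required to sum to 1 across columns.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .pu import (
    InsufficientPositivesError,
    PURoutine,
    SimulatorConfig,
    fit_pu_routine,
    pu_posterior,
)

logger = logging.getLogger("isspu")


def derive_seed(seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 from a model seed and indices."""
    ss = np.random.SeedSequence([int(seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SampleSet:
    """Feature matrix with class labels and an ordered class catalogue."""

    X: np.ndarray
    y: np.ndarray
    classes: list
    minority_class: Any = None
    #: optional row indices into the source pool/scene the rows were drawn
    #: from (used to exclude a class's own positives from unlabeled draws)
    pool_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        unknown = set(np.unique(self.y)) - set(self.classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in the catalogue")

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.y == c)) for c in self.classes}

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{i}" for i in range(self.X.shape[1])]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, classes: Sequence | None = None,
                 minority_class=None) -> "SampleSet":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("sample-set file must have a 'label' column")
        y = df["label"].to_numpy()
        X = df.drop(columns=["label"]).to_numpy(dtype=float)
        if classes is None:
            classes = sorted(pd.unique(y).tolist())
        return cls(X=X, y=y, classes=list(classes),
                   minority_class=minority_class)


@dataclass
class ClassEnsemble:
    """All routines fitted for one target class."""

    target_class: Any
    routines: list[PURoutine]

    @property
    def J(self) -> int:
        return len(self.routines)

    @property
    def valid_routines(self) -> list[PURoutine]:
        return [r for r in self.routines if r.valid]

    def posterior(self, X: np.ndarray) -> np.ndarray:
        valid = self.valid_routines
        if not valid:
            raise RuntimeError(
                f"no valid routine left for class {self.target_class!r}"
            )
        return np.mean([pu_posterior(r, X) for r in valid], axis=0)


@dataclass
class ISSModel:
    """One ClassEnsemble per catalogue class plus the fusion rule."""

    ensembles: list[ClassEnsemble]
    classes: list
    J: int
    seed: int
    config: SimulatorConfig = field(default_factory=SimulatorConfig)
    n_features: int | None = None

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if self.n_features is not None and X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model expects "
                f"{self.n_features}, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class mean calibrated posteriors, shape (n, n_classes)."""
        X = self._check(X)
        return np.column_stack([e.posterior(X) for e in self.ensembles])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Maximum-posterior labels; ties go to the earliest catalogue class."""
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)  # argmax keeps the first maximum
        return np.asarray(self.classes, dtype=object)[idx]

    def labeling_constants(self) -> dict:
        return {e.target_class: [r.c for r in e.routines]
                for e in self.ensembles}

    def save(self, path) -> None:
        """Serialize the whole model (simulators, c values, catalogue)."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ISSModel":
        import joblib

        return joblib.load(path)


def draw_unlabeled(
    pool: np.ndarray,
    size: int,
    exclude: Sequence[int] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Uniform draw without replacement from the pool minus excluded rows.

    Unlabeled rows may in truth belong to any class; the PU framework only
    requires that they are drawn at random from the image.
    """
    pool = np.asarray(pool, dtype=float)
    mask = np.ones(pool.shape[0], dtype=bool)
    if exclude is not None and len(exclude):
        mask[np.asarray(list(exclude), dtype=int)] = False
    avail = np.flatnonzero(mask)
    if avail.size < size:
        raise ValueError(
            f"unlabeled pool too small: need {size}, "
            f"only {avail.size} rows available after exclusions"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(avail, size=size, replace=False)
    return pool[chosen]


def fit_iss(
    train: SampleSet,
    pool: np.ndarray,
    J: int = 10,
    config: SimulatorConfig | None = None,
    seed: int = 0,
    exclude: dict | None = None,
) -> ISSModel:
    """Fit the full ISS model: ``J`` PU routines per catalogue class.

    For class *i* every routine uses all labeled positives of *i* plus a
    fresh unlabeled draw of identical size from ``pool``; only the class's
    own labeled positives are excluded from its pool (other classes' labels
    stay eligible as unlabeled).  Per-routine seeds derive deterministically
    from ``seed`` and the (class, routine) indices.

    Parameters
    ----------
    exclude:
        Optional map ``class -> pool row indices`` to remove from that
        class's unlabeled pool.  When ``train.pool_indices`` is set it is
        used automatically.
    """
    config = config or SimulatorConfig()
    if J < 1:
        raise ValueError("J must be >= 1")
    pool = np.asarray(pool, dtype=float)

    ensembles: list[ClassEnsemble] = []
    for cls in train.classes:
        pos_mask = train.y == cls
        positives = train.X[pos_mask]
        if positives.shape[0] < 4:
            raise InsufficientPositivesError(
                f"class {cls!r} has {positives.shape[0]} training positives; "
                "at least 4 are required"
            )
        if exclude is not None and cls in exclude:
            own = np.asarray(exclude[cls], dtype=int)
        elif train.pool_indices is not None:
            own = np.asarray(train.pool_indices)[pos_mask].astype(int)
        else:
            own = np.empty(0, dtype=int)

        # the per-class key is the class identity, not its catalogue slot,
        # so permuting the catalogue permutes nothing but tie resolution
        class_key = zlib.crc32(repr(cls).encode())
        routines = []
        for j in range(J):
            rseed = derive_seed(seed, class_key, j)
            U = draw_unlabeled(pool, positives.shape[0], own, rseed)
            assert U.shape[0] == positives.shape[0], \
                "routine must train on equal positive/unlabeled counts"
            routines.append(
                fit_pu_routine(positives, U, config, rseed, target_class=cls)
            )
        n_valid = sum(r.valid for r in routines)
        if n_valid == 0:
            raise RuntimeError(
                f"all {J} routines invalid for class {cls!r}; "
                "c could not be estimated from any unlabeled draw"
            )
        if n_valid < J:
            logger.warning("class %r: %d of %d routines invalid, dropped "
                           "from the posterior mean", cls, J - n_valid, J)
        ensembles.append(ClassEnsemble(target_class=cls, routines=routines))

    return ISSModel(ensembles=ensembles, classes=list(train.classes),
                    J=J, seed=int(seed), config=config,
                    n_features=train.X.shape[1])


# ---------------------------------------------------------------------------
# Baselines for the comparison harness (existing library backends)
# ---------------------------------------------------------------------------

class _WrappedClassifier:
    """Adapter giving library classifiers the ISSModel predict contract.

    When ``encode`` is true the targets are integer-coded in catalogue
    order before fitting (xgboost requires contiguous integer classes).
    """

    def __init__(self, estimator, classes: list, encode: bool = False):
        self.estimator = estimator
        self.classes = list(classes)
        self.encode = encode

    def fit(self, X, y):
        if self.encode:
            codes = {c: i for i, c in enumerate(self.classes)}
            y = np.array([codes[v] for v in y])
        self.estimator.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        lib = list(getattr(self.estimator, "classes_", []))
        key = list(range(len(self.classes))) if self.encode else self.classes
        out = np.zeros((proba.shape[0], len(self.classes)))
        for k, cls in enumerate(key):
            if cls in lib:
                out[:, k] = proba[:, lib.index(cls)]
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def _make_backend(backend: str, config: SimulatorConfig | None, seed: int,
                  n_classes: int):
    config = config or SimulatorConfig()
    seed = int(seed) % (2**31)
    if backend == "gbt":
        from xgboost import XGBClassifier

        return XGBClassifier(**config.resolved(), tree_method="hist",
                             n_jobs=1, random_state=seed)
    if backend == "rf":
        from sklearn.ensemble import RandomForestClassifier

        n = config.resolved().get("n_estimators", 200)
        return RandomForestClassifier(n_estimators=n, max_features="sqrt",
                                      n_jobs=1, random_state=seed)
    if backend == "mlp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(random_state=seed, max_iter=300)
    if backend == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", probability=True, random_state=seed)
    raise ValueError(f"unknown baseline backend {backend!r}")


def _check_multiclass(train: SampleSet) -> None:
    present = [c for c in train.classes if np.any(train.y == c)]
    if len(present) < 2:
        raise ValueError(
            "baseline training needs at least 2 classes with samples; "
            f"got {len(present)}"
        )


def fit_aio_baseline(train: SampleSet, backend: str = "gbt",
                     config: SimulatorConfig | None = None,
                     seed: int = 0) -> _WrappedClassifier:
    """All-in-one baseline: one multi-class model on all labeled samples."""
    _check_multiclass(train)
    est = _make_backend(backend, config, seed, len(train.classes))
    encode = backend == "gbt"
    return _WrappedClassifier(est, train.classes, encode).fit(train.X, train.y)


def fit_one_vs_rest_baseline(train: SampleSet, backend: str = "svm",
                             config: SimulatorConfig | None = None,
                             seed: int = 0) -> _WrappedClassifier:
    """One-vs-rest baseline around a library binary backend."""
    from sklearn.multiclass import OneVsRestClassifier

    _check_multiclass(train)
    base = _make_backend(backend, config, seed, 2)
    est = OneVsRestClassifier(base, n_jobs=1)
    return _WrappedClassifier(est, train.classes).fit(train.X, train.y)
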