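"""Single-class positive–unlabeled (PU) estimation.

Under the selected-completely-at-random assumption, a binary scorer
``g(x) = p(s=1 | x)`` trained to separate labeled positives (``s = 1``)
from unlabeled instances (``s = 0``) relates to the true class posterior
``f(x) = p(y=1 | x)`` through a single labeling constant
``c = p(s=1 | y=1)``:

    f(x) = g(x) / c

``c`` is estimated as the mean score of ``g`` over held-out positives that
the simulator never saw during training.  One fitted ``(g, c)`` pair is a
*routine*; the multi-class ensemble in :mod:`isspu.ensemble` averages many
of them per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

logger = logging.getLogger("isspu")

#: Floor on the labeling constant; a raw mean score at or below this marks
#: the routine invalid instead of producing exploding posteriors.
EPS_C = 1e-6

#: Default 75/25 train/validation split of each routine's data.
DEFAULT_TRAIN_FRACTION = 0.75

#: Search bounds for the gradient-boosted-tree backend's hyperparameters.
GBT_BOUNDS = {
    "n_estimators": (1, 1000),
    "learning_rate": (0.1, 1.0),
    "max_depth": (2, 23),
    "min_child_weight": (1, 29),
    "subsample": (0.1, 1.0),
}

GBT_DEFAULTS = {
    "n_estimators": 200,
    "learning_rate": 0.3,
    "max_depth": 6,
    "min_child_weight": 1,
    "subsample": 1.0,
}


class InsufficientPositivesError(ValueError):
    """Raised when a class has too few labeled positives for a PU split."""


class InvalidRoutineError(RuntimeError):
    """Raised when a posterior is requested from an invalid routine."""


@dataclass
class SimulatorConfig:
    """Configuration of the binary PU simulator ``g(x)``.

    Parameters
    ----------
    backend:
        ``"gbt"`` (gradient-boosted trees, the default), ``"neural-net"``
        (MLP), ``"margin"`` (RBF support-vector machine with probability
        output) or ``"user"`` with a ``factory`` returning an unfitted
        scikit-learn style classifier.
    hyperparameters:
        Backend keyword overrides.  For the default backend these must lie
        inside the documented search bounds (estimators 1–1000, learning
        rate 0.1–1, depth 2–23, min leaf instances 1–29, subsample 0.1–1).
    factory:
        Only for ``backend="user"``: ``factory(seed) -> estimator`` with
        ``fit`` and ``predict_proba``.
    """

    backend: str = "gbt"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    factory: Callable[[int], Any] | None = None

    def __post_init__(self) -> None:
        if self.backend == "gbt":
            params = {**GBT_DEFAULTS, **self.hyperparameters}
            for name, (lo, hi) in GBT_BOUNDS.items():
                v = params[name]
                if not lo <= v <= hi:
                    raise ValueError(
                        f"{name}={v} outside the allowed range [{lo}, {hi}]"
                    )
        elif self.backend == "user" and self.factory is None:
            raise ValueError("backend='user' requires a factory")

    def resolved(self) -> dict[str, Any]:
        if self.backend == "gbt":
            return {**GBT_DEFAULTS, **self.hyperparameters}
        return dict(self.hyperparameters)

    def build(self, seed: int):
        """Instantiate an unfitted simulator for this configuration."""
        if self.backend == "gbt":
            from xgboost import XGBClassifier

            return XGBClassifier(
                **self.resolved(),
                objective="binary:logistic",
                tree_method="hist",
                n_jobs=1,
                random_state=int(seed) % (2**31),
            )
        if self.backend == "neural-net":
            from sklearn.neural_network import MLPClassifier

            return MLPClassifier(random_state=int(seed) % (2**31),
                                 **self.hyperparameters)
        if self.backend == "margin":
            from sklearn.svm import SVC

            return SVC(kernel="rbf", probability=True,
                       random_state=int(seed) % (2**31),
                       **self.hyperparameters)
        if self.backend == "user":
            return self.factory(int(seed) % (2**31))
        raise ValueError(f"unknown simulator backend {self.backend!r}")


@dataclass
class PURoutine:
    """One fitted PU routine: a scorer ``g`` with its labeling constant."""

    simulator: Any
    c: float
    seed: int
    valid: bool = True
    target_class: Any = None

    def score(self, X: np.ndarray) -> np.ndarray:
        """Raw simulator scores ``g(x)`` in [0, 1]."""
        proba = self.simulator.predict_proba(np.asarray(X, dtype=float))
        return np.clip(proba[:, 1], 0.0, 1.0)


def split_pu(
    positives: np.ndarray,
    unlabeled: np.ndarray,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    target_class: Any = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition positives and unlabeled rows for one routine.

    Both sets are partitioned independently at ``train_fraction`` (seeded
    shuffles).  The held-out positives — count ``max(1,
    round((1 - train_fraction)·|P|))`` — are reserved for estimating the
    labeling constant and are never shown to the simulator.  The held-out
    unlabeled rows are discarded: only positives enter the ``c`` estimate.

    Returns ``(train_positives, train_unlabeled, heldout_positives)``.
    """
    positives = np.asarray(positives, dtype=float)
    unlabeled = np.asarray(unlabeled, dtype=float)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_pos = positives.shape[0]
    if n_pos < 4:
        name = "" if target_class is None else f" for class {target_class!r}"
        raise InsufficientPositivesError(
            f"insufficient positives{name}: need at least 4, got {n_pos}"
        )
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round((1.0 - train_fraction) * n_pos)))
    n_hold = min(n_hold, n_pos - 1)  # simulator always sees >=1 positive
    perm = rng.permutation(n_pos)
    heldout_p = positives[perm[:n_hold]]
    train_p = positives[perm[n_hold:]]

    n_unl = unlabeled.shape[0]
    n_unl_train = max(1, int(round(train_fraction * n_unl)))
    perm_u = rng.permutation(n_unl)
    train_u = unlabeled[perm_u[:n_unl_train]]
    return train_p, train_u, heldout_p


def estimate_c(simulator, heldout_positives: np.ndarray) -> float:
    """Labeling-constant estimate: mean simulator score on held-out positives.

    Returns the raw mean (which may be ``<= EPS_C``; callers treat that as
    an estimation failure).  Raises on an empty held-out set.
    """
    heldout_positives = np.asarray(heldout_positives, dtype=float)
    if heldout_positives.shape[0] == 0:
        raise ValueError("cannot estimate c from an empty held-out set")
    proba = simulator.predict_proba(heldout_positives)
    scores = np.clip(proba[:, 1], 0.0, 1.0)
    return float(np.mean(scores))


def fit_pu_routine(
    positives: np.ndarray,
    unlabeled: np.ndarray,
    config: SimulatorConfig | None = None,
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    target_class: Any = None,
) -> PURoutine:
    """Fit one PU routine: split, train ``g`` on s-labels, estimate ``c``.

    The simulator is trained on the 75% train split with targets ``s``
    (1 for positives, 0 for unlabeled); ``c`` comes from the 25% held-out
    positives.  A raw ``c`` estimate at or below ``EPS_C`` flags the routine
    invalid rather than raising, so ensembles can drop it.
    """
    config = config or SimulatorConfig()
    positives = np.asarray(positives, dtype=float)
    unlabeled = np.asarray(unlabeled, dtype=float)
    for name, arr in (("positive", positives), ("unlabeled", unlabeled)):
        if arr.ndim != 2:
            raise ValueError(f"{name} features must be a 2-D matrix")
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values in {name} features")

    train_p, train_u, heldout_p = split_pu(
        positives, unlabeled, train_fraction, seed, target_class
    )
    X = np.vstack([train_p, train_u])
    s = np.concatenate(
        [np.ones(len(train_p), dtype=int), np.zeros(len(train_u), dtype=int)]
    )
    simulator = config.build(seed)
    simulator.fit(X, s)

    c = estimate_c(simulator, heldout_p)
    valid = c > EPS_C
    if not valid:
        logger.warning(
            "labeling-constant estimate %.3g <= %.1g for class %r "
            "(seed %d); routine marked invalid", c, EPS_C, target_class, seed
        )
    return PURoutine(simulator=simulator, c=max(c, EPS_C), seed=int(seed),
                     valid=valid, target_class=target_class)


def pu_posterior(routine: PURoutine, X: np.ndarray) -> np.ndarray:
    """Calibrated posterior ``f(x) = min(g(x)/c, 1)`` per instance.

    The raw ratio can exceed 1 (the calibration divides by an estimated
    constant), so the output is clipped to [0, 1].
    """
    if not routine.valid:
        raise InvalidRoutineError(
            "routine is invalid (labeling constant could not be estimated); "
            "drop it from the ensemble or refit with a new unlabeled draw"
        )
    g = routine.score(np.asarray(X, dtype=float))
    return np.clip(g / routine.c, 0.0, 1.0)
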