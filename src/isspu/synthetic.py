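"""Synthetic multiband scenes with known ground truth, and the imbalanced
sampling design used by the sweep harness.

The scene generator emulates very-high-resolution land-cover imagery at
fixture scale: class labels come from the argmax of smoothed Gaussian
random fields (bias-calibrated to hit target areal proportions), and each
pixel's spectrum is its class mean plus correlated Gaussian noise, so the
Bayes-optimal classifier of the generating mixture is available in closed
form.  Training sets follow the a:b minority:majority design: every
majority class contributes a fixed count and the minority contributes
``round(count · a / b)``, after an independent test set has been drawn
from the whole scene.

Also provided: the classic SMOTE interpolation used by the oversampling
baselines, and a two-Gaussian positive–unlabeled sampler with a known
labeling frequency for calibration studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import multivariate_normal

from .ensemble import SampleSet, derive_seed

logger = logging.getLogger("isspu")

#: default per-majority-class training count (the 1000 × n design)
DEFAULT_PER_MAJORITY = 1000


@dataclass
class SyntheticScene:
    """A label raster, its rendered multiband image and the generator state."""

    labels: np.ndarray            # (H, W) int class indices
    image: np.ndarray             # (H, W, B) float
    class_means: np.ndarray       # (n_classes, B)
    class_cov: np.ndarray         # (B, B), shared across classes
    target_proportions: np.ndarray
    realized_proportions: np.ndarray
    shdi: float
    spatial_scale: float
    seed: int
    classes: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    def pixel_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (pixels × bands) features and per-pixel labels."""
        H, W, B = self.image.shape
        return self.image.reshape(-1, B), self.labels.reshape(-1)

    def bayes_predict(self, X: np.ndarray) -> np.ndarray:
        """Bayes-optimal labels under the generating Gaussian mixture."""
        X = np.asarray(X, dtype=float)
        priors = np.maximum(self.realized_proportions, 1e-12)
        logp = np.column_stack([
            multivariate_normal.logpdf(X, mean=m, cov=self.class_cov)
            + np.log(priors[k])
            for k, m in enumerate(self.class_means)
        ])
        return np.argmax(logp, axis=1)


@dataclass
class ImbalanceDesign:
    """The a:b minority:majority training design.

    ``a:b`` is the minority:majority *count ratio*; every majority class
    receives ``per_majority`` training samples and the minority receives
    ``round(per_majority · a / b)``.  The balanced design a=b=50 gives
    ``per_majority`` samples for every class (the 1000 × n layout at the
    default count).
    """

    a: int
    b: int
    minority_class: int = 0
    per_majority: int = DEFAULT_PER_MAJORITY
    test_size: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.a <= self.b):
            raise ValueError("need 1 <= a <= b")
        if self.minority_count() < 1:
            raise ValueError(
                f"minority count rounds to 0 at {self.a}:{self.b}; "
                "increase per_majority"
            )

    def minority_count(self) -> int:
        return int(round(self.per_majority * self.a / self.b))


def _ring_means(n_classes: int, n_bands: int, separability: float
                ) -> np.ndarray:
    """Class mean spectra equally spaced on a circle in the first two bands.

    Adjacent classes sit exactly ``separability`` apart (in noise-sd
    units), so every class — minority included — overlaps its spectral
    neighbours by a controlled, identical amount, mimicking the graded
    between-class confusion of real land-cover spectra rather than an
    arbitrary geometry.  With a single band the classes fall on a line at
    ``separability`` spacing instead.
    """
    if n_bands < 1:
        raise ValueError("need at least one band")
    means = np.zeros((n_classes, n_bands))
    if n_classes == 1:
        return means
    if n_bands == 1:
        means[:, 0] = np.arange(n_classes) * separability
        return means
    radius = separability / (2.0 * np.sin(np.pi / n_classes))
    angles = 2.0 * np.pi * np.arange(n_classes) / n_classes
    means[:, 0] = radius * np.cos(angles)
    means[:, 1] = radius * np.sin(angles)
    return means


def generate_scene(
    n_classes: int,
    target_proportions=None,
    spatial_scale: float = 8.0,
    spectral_separability: float = 3.0,
    size: tuple[int, int] = (128, 128),
    n_bands: int = 3,
    band_correlation: float = 0.3,
    seed: int = 0,
    proportion_tolerance: float = 0.02,
) -> SyntheticScene:
    """Generate an n-class scene with controllable mixing and patch size.

    Labels are the per-pixel argmax of ``n_classes`` smoothed, standardised
    Gaussian random fields plus per-class biases; the biases are calibrated
    iteratively until every realized class proportion is within
    ``proportion_tolerance`` of its target (error if unattainable).  The
    image adds correlated Gaussian noise (unit variance per band) to class
    mean spectra whose pairwise spacing scales with
    ``spectral_separability`` (in noise-standard-deviation units).
    """
    H, W = size
    if H < 32 or W < 32:
        raise ValueError("scene must be at least 32x32 pixels")
    if target_proportions is None:
        target_proportions = np.full(n_classes, 1.0 / n_classes)
    target = np.asarray(target_proportions, dtype=float)
    if target.shape != (n_classes,) or (target < 0).any() \
            or abs(target.sum() - 1.0) > 1e-6:
        raise ValueError("target proportions must be n_classes non-negative "
                         "values summing to 1")
    if np.any((target > 0) & (target * H * W < 1)):
        raise ValueError("a positive target proportion is below one pixel "
                         "at this size; enlarge the scene")

    rng = np.random.default_rng(seed)
    fields = np.empty((n_classes, H, W))
    for k in range(n_classes):
        f = gaussian_filter(rng.standard_normal((H, W)), spatial_scale,
                            mode="wrap")
        sd = f.std()
        fields[k] = (f - f.mean()) / (sd if sd > 0 else 1.0)

    # calibrate per-class biases so the argmax hits the target proportions
    bias = np.zeros(n_classes)
    realized = None
    for it in range(400):
        labels = np.argmax(fields + bias[:, None, None], axis=0)
        realized = np.bincount(labels.ravel(), minlength=n_classes) / (H * W)
        err = realized - target
        if np.all(np.abs(err) <= proportion_tolerance) and it >= 1:
            break
        bias = bias - 1.2 * err
        bias -= bias.mean()
    else:
        raise RuntimeError(
            "could not reach the target proportions within tolerance "
            f"{proportion_tolerance}; realized {np.round(realized, 3)}"
        )
    missing = [k for k in range(n_classes)
               if target[k] > 0 and realized[k] == 0]
    if missing:
        raise RuntimeError(f"classes {missing} received no pixels")

    means = _ring_means(n_classes, n_bands, spectral_separability)
    cov = (np.full((n_bands, n_bands), band_correlation)
           + (1.0 - band_correlation) * np.eye(n_bands))
    noise = rng.multivariate_normal(np.zeros(n_bands), cov, size=H * W)
    image = (means[labels.reshape(-1)] + noise).reshape(H, W, n_bands)

    p = realized[realized > 0]
    return SyntheticScene(
        labels=labels, image=image.astype(np.float64), class_means=means,
        class_cov=cov, target_proportions=target,
        realized_proportions=realized, shdi=float(-np.sum(p * np.log(p))),
        spatial_scale=float(spatial_scale), seed=int(seed),
        classes=list(range(n_classes)),
    )


def sample_training_sets(
    scene: SyntheticScene,
    design: ImbalanceDesign,
    features: np.ndarray | None = None,
) -> tuple[SampleSet, SampleSet]:
    """Draw the a:b training set and a disjoint test set from a scene.

    The test set is drawn first, uniformly over the whole scene; training
    samples are then drawn per class from the remaining pixels, without
    replacement.  ``features`` may supply a per-pixel feature table (e.g.
    spectral + texture planes); by default the raw spectral bands are used.
    The returned training set carries its pixel indices so ensembles can
    exclude a class's own positives from the unlabeled pool.
    """
    X_all, y_all = scene.pixel_table()
    if features is not None:
        features = np.asarray(features, dtype=float)
        if features.shape[0] != X_all.shape[0]:
            raise ValueError("feature table must have one row per pixel")
        X_all = features
    n_pix = X_all.shape[0]
    rng = np.random.default_rng(design.seed)

    if design.test_size >= n_pix:
        raise ValueError("test_size must be smaller than the scene")
    test_idx = rng.choice(n_pix, size=design.test_size, replace=False)
    in_test = np.zeros(n_pix, dtype=bool)
    in_test[test_idx] = True

    classes = list(range(scene.n_classes))
    counts = {c: (design.minority_count() if c == design.minority_class
                  else design.per_majority) for c in classes}
    train_idx = []
    for c in classes:
        avail = np.flatnonzero((y_all == c) & ~in_test)
        if avail.size < counts[c]:
            raise ValueError(
                f"class {c} has {avail.size} pixels outside the test set; "
                f"{counts[c]} training samples requested"
            )
        train_idx.append(rng.choice(avail, size=counts[c], replace=False))
    train_idx = np.concatenate(train_idx)
    logger.info("a:b=%d:%d design: minority %d gets %d samples, majorities "
                "%d each", design.a, design.b, design.minority_class,
                design.minority_count(), design.per_majority)

    train = SampleSet(X=X_all[train_idx], y=y_all[train_idx],
                      classes=classes, minority_class=design.minority_class,
                      pool_indices=train_idx)
    test = SampleSet(X=X_all[test_idx], y=y_all[test_idx], classes=classes,
                     minority_class=design.minority_class,
                     pool_indices=np.asarray(test_idx))
    return train, test


def smote(minority_X: np.ndarray, k: int = 5, amount_percent: int = 100,
          seed: int = 0) -> np.ndarray:
    """SMOTE interpolation: new minority points on segments to k-NN.

    For each seed point one of its ``k`` nearest minority neighbours is
    chosen and a synthetic point ``x + u·(neighbour − x)`` with
    ``u ~ U(0, 1)`` is emitted.  ``amount_percent`` controls the output
    size (``round(amount/100 · n)`` points; seeds cycle when > 100%).
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(minority_X, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(
            f"SMOTE needs at least k+1 = {k + 1} minority points, got {n}"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)           # first neighbour is the point itself
    neighbours = idx[:, 1:]

    n_new = int(round(amount_percent / 100.0 * n))
    seeds = np.tile(np.arange(n), n_new // n + 1)[:n_new]
    if amount_percent < 100:
        seeds = rng.permutation(n)[:n_new]
    picks = neighbours[seeds, rng.integers(0, k, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=(n_new, 1))
    return X[seeds] + u * (X[picks] - X[seeds])


def smote_balance(train: SampleSet, k: int = 5, seed: int = 0) -> SampleSet:
    """Equalisation synthesis: oversample the minority up to the majority
    count with SMOTE and return the augmented sample set."""
    counts = train.class_counts()
    target = max(counts.values())
    X_parts, y_parts = [train.X], [train.y]
    for c, cnt in counts.items():
        deficit = target - cnt
        if deficit <= 0:
            continue
        amount = 100.0 * deficit / cnt
        synth = smote(train.X[train.y == c], k=k,
                      amount_percent=int(round(amount)),
                      seed=derive_seed(seed, int(c)))
        X_parts.append(synth)
        y_parts.append(np.full(len(synth), c, dtype=train.y.dtype))
    return SampleSet(X=np.vstack(X_parts), y=np.concatenate(y_parts),
                     classes=train.classes,
                     minority_class=train.minority_class)


def pu_gaussian_sample(
    n: int,
    c_true: float,
    separation: float = 4.0,
    positive_fraction: float = 0.5,
    n_features: int = 2,
    seed: int = 0,
):
    """Two-Gaussian positive–unlabeled draw with a known labeling frequency.

    Instances come from a ``positive_fraction``-weight mixture of two
    unit-variance Gaussians
    whose means are ``separation`` apart along the first axis.  Each true
    positive is labeled independently with probability ``c_true``
    (selected completely at random), so the label indicator satisfies
    ``p(s=1 | y=1) = c_true`` by construction.

    Returns ``(X, s, y, posterior)`` where ``posterior(X)`` is the exact
    ``p(y=1 | x)`` of the generating mixture.
    """
    if not 0.0 < c_true <= 1.0:
        raise ValueError("c_true must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) < positive_fraction).astype(int)
    mu = np.zeros(n_features)
    mu_pos = mu.copy()
    mu_pos[0] = separation
    X = rng.standard_normal((n, n_features))
    X[y == 1] += mu_pos
    s = np.where(y == 1, rng.uniform(size=n) < c_true, False).astype(int)

    w = positive_fraction

    def posterior(Xq: np.ndarray) -> np.ndarray:
        Xq = np.asarray(Xq, dtype=float)
        lp = multivariate_normal.logpdf(Xq, mean=mu_pos,
                                        cov=np.eye(n_features))
        ln = multivariate_normal.logpdf(Xq, mean=mu,
                                        cov=np.eye(n_features))
        a = np.exp(lp + np.log(w))
        b = np.exp(ln + np.log(1 - w))
        return a / (a + b)

    return X, s, y, posterior
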