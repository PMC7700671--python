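"""Accuracy assessment for imbalanced multi-class maps.

Implements the error-matrix toolkit used throughout the package: overall
accuracy and per-class F1 from the sample confusion matrix; the
stratified *population matrix* (sample counts re-weighted by map-class
proportions, stratified by predicted class); Pontius-style quantity
disagreement (QD) and allocation disagreement (AD) on that population
matrix; minority-class QD'/AD' normalised by the minority's reference
amount; a large-sample kappa z-comparison between two matrices; and the
Shannon diversity index (SHDI) of class proportions.

Orientation convention: rows are reference classes, columns are predicted
classes.  Because the population stratification is by predicted class, the
weights ``W`` index columns.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("isspu")


@dataclass
class ConfusionMatrix:
    """Sample counts, reference classes on rows, predictions on columns."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match the catalogue")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        """Read a matrix with a header row and index column of class names."""
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(
                "row and column class names differ; expected a square "
                "reference-by-prediction matrix"
            )
        return cls(counts=df.to_numpy(dtype=np.int64),
                   classes=list(df.columns))


@dataclass
class PopulationMatrix:
    """Estimated whole-map error proportions (stratified by predicted class)."""

    proportions: np.ndarray
    weights: np.ndarray
    valid: bool
    classes: list


@dataclass
class DisagreementReport:
    """The full accuracy summary for one classified map."""

    oa: float                      # percent, from the sample matrix
    qd: float                      # percent, population matrix (NaN if invalid)
    ad: float                      # percent, population matrix (NaN if invalid)
    f1: dict                       # per-class F1
    kappa: float
    minority_class: object = None
    minority_qd: float = float("nan")   # QD' percent
    minority_ad: float = float("nan")   # AD' percent

    def to_dict(self) -> dict:
        return {
            "oa_percent": self.oa,
            "qd_percent": self.qd,
            "ad_percent": self.ad,
            "kappa": self.kappa,
            "f1": {str(k): v for k, v in self.f1.items()},
            "minority_class": None if self.minority_class is None
            else str(self.minority_class),
            "minority_qd_percent": self.minority_qd,
            "minority_ad_percent": self.minority_ad,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [f"OA     {self.oa:10.2f} %",
                 f"QD     {self.qd:10.2f} %",
                 f"AD     {self.ad:10.2f} %",
                 f"kappa  {self.kappa:10.4f}"]
        for cls, v in self.f1.items():
            lines.append(f"F1[{cls}] {v:8.4f}")
        if self.minority_class is not None:
            lines.append(f"minority ({self.minority_class}): "
                         f"QD' {self.minority_qd:.2f} %  "
                         f"AD' {self.minority_ad:.2f} %")
        return "\n".join(lines)


def confusion_matrix(reference: Sequence, predicted: Sequence,
                     classes: Sequence) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #(ref = class_i and pred = class_j)``."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted lengths differ")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    for v in np.unique(np.concatenate([reference, predicted])):
        if v not in index:
            raise ValueError(f"label {v!r} not in the class catalogue")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(reference, predicted):
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of samples on the diagonal: ``100 · trace / total``."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def f1_per_class(cm: ConfusionMatrix) -> dict:
    """Harmonic mean of user (precision) and producer (recall) accuracy."""
    out = {}
    rows = cm.row_totals()
    cols = cm.col_totals()
    for i, cls in enumerate(cm.classes):
        tp = float(cm.counts[i, i])
        precision = tp / cols[i] if cols[i] > 0 else 0.0
        recall = tp / rows[i] if rows[i] > 0 else 0.0
        out[cls] = (0.0 if precision + recall == 0
                    else 2 * precision * recall / (precision + recall))
    return out


def population_matrix(cm: ConfusionMatrix,
                      weights: Mapping | Sequence | None = None
                      ) -> PopulationMatrix:
    """Re-weight sample counts into estimated whole-map proportions.

    ``proportions[i, j] = W_j · counts[i, j] / column_total_j`` where the
    stratum weights ``W`` are the map proportions of each *predicted*
    class.  When no weights are supplied the sample column proportions are
    used (and a notice is logged) — then the population matrix equals the
    sample proportions.  A zero predicted column makes the conversion
    invalid (unless explicit weights assign that class zero map share):
    QD/AD are then reported as NaN while OA (a sample quantity) stays
    defined.
    """
    n = len(cm.classes)
    cols = cm.col_totals().astype(float)
    default_weights = weights is None
    if default_weights:
        logger.info("no map weights supplied; using sample column "
                    "proportions as stratum weights")
        W = cols / cm.total
    elif isinstance(weights, Mapping):
        W = np.array([float(weights[c]) for c in cm.classes])
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != (n,):
            raise ValueError("weights must give one proportion per class")
    if (W < 0).any() or not math.isclose(W.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("weights must be non-negative and sum to 1")

    # a stratum with no samples invalidates the conversion; under default
    # weights an empty predicted column cannot be assumed absent from the
    # map, so it invalidates too
    if default_weights:
        valid = not np.any(cols == 0)
    else:
        valid = not np.any((cols == 0) & (W > 0))
    props = np.full((n, n), np.nan)
    if valid:
        with np.errstate(invalid="ignore", divide="ignore"):
            props = W[None, :] * cm.counts / np.where(cols == 0, 1.0, cols)
        props = np.where(np.isfinite(props), props, 0.0)
    return PopulationMatrix(proportions=props, weights=W, valid=valid,
                            classes=list(cm.classes))


def quantity_allocation_disagreement(pm: PopulationMatrix
                                     ) -> tuple[float, float]:
    """Overall quantity and allocation disagreement, in percent.

    QD is the half-sum of marginal-proportion mismatches; AD is the
    half-sum of ``2·min(omission, commission)`` per class.  On a valid
    population matrix ``OA_pop + QD + AD = 100``.  An invalid matrix
    yields ``(nan, nan)``.
    """
    if not pm.valid:
        return (float("nan"), float("nan"))
    p = pm.proportions
    ref = p.sum(axis=1)
    pred = p.sum(axis=0)
    diag = np.diag(p)
    qd = 100.0 * 0.5 * float(np.sum(np.abs(ref - pred)))
    ad = 100.0 * 0.5 * float(np.sum(2.0 * np.minimum(ref - diag,
                                                     pred - diag)))
    return qd, ad


def minority_qd_ad(cm: ConfusionMatrix, minority) -> tuple[float, float]:
    """Minority-class QD'/AD': disagreement counts over its reference amount.

    With ``FP = column − TP`` and ``FN = row − TP``:
    ``QD' = 100·|FP − FN| / row`` and ``AD' = 100·2·min(FP, FN) / row``.
    Complete omission (TP = FP = 0) gives (100, 0); a perfect class (0, 0).
    """
    i = cm.classes.index(minority)
    row = float(cm.row_totals()[i])
    if row <= 0:
        raise ValueError(
            f"minority class {minority!r} has no reference samples"
        )
    tp = float(cm.counts[i, i])
    fp = float(cm.col_totals()[i]) - tp
    fn = row - tp
    return 100.0 * abs(fp - fn) / row, 100.0 * 2.0 * min(fp, fn) / row


def cohens_kappa(cm: ConfusionMatrix) -> float:
    p = cm.counts / cm.total
    po = float(np.trace(p))
    pe = float(np.sum(p.sum(axis=1) * p.sum(axis=0)))
    if pe >= 1.0:
        raise ValueError("degenerate matrix: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def kappa_variance(cm: ConfusionMatrix) -> float:
    """Large-sample (delta-method) variance of Cohen's kappa."""
    p = cm.counts / cm.total
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    if np.count_nonzero(rows) < 2 or np.count_nonzero(cols) < 2:
        raise ValueError("degenerate matrix: a single marginal class")
    t1 = float(np.trace(p))
    t2 = float(np.sum(rows * cols))
    if t2 >= 1.0:
        raise ValueError("degenerate matrix: chance agreement is 1")
    t3 = float(np.sum(np.diag(p) * (rows + cols)))
    t4 = float(np.sum(p * (rows[None, :] + cols[:, None]) ** 2))
    n = cm.total
    var = (t1 * (1 - t1) / (1 - t2) ** 2
           + 2 * (1 - t1) * (2 * t1 * t2 - t3) / (1 - t2) ** 3
           + (1 - t1) ** 2 * (t4 - 4 * t2 ** 2) / (1 - t2) ** 4) / n
    return max(var, 0.0)


def kappa_z_compare(cm1: ConfusionMatrix, cm2: ConfusionMatrix) -> float:
    """|Z| statistic for the difference of two independent kappas.

    ``|Z| > 1.96`` flags a difference at the 95% confidence level.
    """
    k1, k2 = cohens_kappa(cm1), cohens_kappa(cm2)
    v1, v2 = kappa_variance(cm1), kappa_variance(cm2)
    denom = math.sqrt(v1 + v2)
    if denom == 0:
        return 0.0 if k1 == k2 else float("inf")
    return abs(k1 - k2) / denom


def shdi(proportions: Sequence[float]) -> float:
    """Shannon diversity index ``−Σ p ln p`` (zero entries contribute 0)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("proportions must be non-negative and sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def evaluate_confusion(cm: ConfusionMatrix,
                       weights: Mapping | Sequence | None = None,
                       minority=None) -> DisagreementReport:
    """One-call accuracy summary: OA, QD/AD, per-class F1, kappa, QD'/AD'."""
    pm = population_matrix(cm, weights)
    qd, ad = quantity_allocation_disagreement(pm)
    report = DisagreementReport(
        oa=overall_accuracy(cm), qd=qd, ad=ad, f1=f1_per_class(cm),
        kappa=cohens_kappa(cm), minority_class=minority,
    )
    if minority is not None:
        report.minority_qd, report.minority_ad = minority_qd_ad(cm, minority)
    return report


def load_example_matrices() -> dict[str, ConfusionMatrix]:
    """Bundled worked-example confusion matrices.

    Ten 6-class matrices (house, tree, road, soil, grass, others) from a
    suburban land-cover scene classified by five methods (MLP, SVM, RF,
    XGB, ISS-XGB) with training imbalance 2:98 and 50:50; keys like
    ``"iss-xgb_2v98"``.  Used by the documentation and regression tests.
    """
    data_dir = Path(__file__).parent / "data"
    out = {}
    for path in sorted(data_dir.glob("*.csv")):
        out[path.stem] = ConfusionMatrix.from_csv(path)
    return out
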