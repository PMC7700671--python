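"""Self-contained verification studies for the package's core claims.

Each function runs one end-to-end study at desk scale — re-deriving the
published worked-example accuracies, checking the disagreement identity on
random matrices, measuring labeling-constant recovery, contrasting the
ISS ensemble with an all-in-one baseline across imbalance, and validating
the texture and SMOTE primitives against brute-force references — and
returns plain numbers.  Both the test suite and ``scripts/acceptance.py``
call these, so reported figures are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .ensemble import derive_seed
from .metrics import (
    evaluate_confusion,
    load_example_matrices,
    population_matrix,
    quantity_allocation_disagreement,
)
from .pu import fit_pu_routine, pu_posterior
from .sweep import SweepConfig, run_sweep, summarize
from .synthetic import pu_gaussian_sample, smote
from .texture import glcm, glcm_metrics

# problem sizes of the heavier studies, chosen for a single desktop CPU
CALIBRATION_N = 2000
CALIBRATION_REPLICATES = 50
SWEEP_TRIALS = 10
SWEEP_PER_MAJORITY = 500
SWEEP_TEST_SIZE = 3000
SWEEP_SCENE = {"n_classes": 6, "size": (96, 96), "spatial_scale": 6.0,
               "spectral_separability": 3.0, "n_bands": 3}


def published_matrix_report() -> dict[str, dict]:
    """Overall accuracy (and QD/AD validity) of every bundled matrix."""
    out = {}
    for key, cm in load_example_matrices().items():
        rep = evaluate_confusion(cm, minority="house")
        out[key] = {"oa": rep.oa, "qd": rep.qd, "ad": rep.ad,
                    "n": cm.total}
    return out


def pontius_identity_study(n_matrices: int = 1000, seed: int = 0) -> dict:
    """OA + QD + AD closure on random valid population matrices.

    Returns the worst absolute deviation from 100, the most negative AD
    and the worst excess of QD over the total disagreement.
    """
    rng = np.random.default_rng(seed)
    worst_identity = 0.0
    min_ad = np.inf
    worst_qd_excess = -np.inf
    for _ in range(n_matrices):
        k = int(rng.integers(2, 8))
        counts = rng.integers(1, 500, size=(k, k))
        W = rng.dirichlet(np.ones(k))
        from .metrics import ConfusionMatrix

        pm = population_matrix(
            ConfusionMatrix(counts=counts, classes=list(range(k))), W)
        qd, ad = quantity_allocation_disagreement(pm)
        oa_pop = 100.0 * float(np.trace(pm.proportions))
        total = 100.0 - oa_pop
        worst_identity = max(worst_identity, abs(oa_pop + qd + ad - 100.0))
        min_ad = min(min_ad, ad)
        worst_qd_excess = max(worst_qd_excess, qd - total)
    return {"max_identity_deviation": worst_identity, "min_ad": min_ad,
            "max_qd_minus_total": worst_qd_excess, "n": n_matrices}


def calibration_study(
    c_values=(0.25, 0.5, 0.75),
    n: int = CALIBRATION_N,
    replicates: int = CALIBRATION_REPLICATES,
    separation: float = 4.0,
    seed: int = 0,
) -> dict:
    """Labeling-constant recovery and calibration gain on two-Gaussian PU.

    For each true labeling frequency: the median |c_hat − c_true| over the
    replicates, and in how many replicates the calibrated posterior
    ``min(g/c, 1)`` has lower mean-squared error against the analytic
    posterior than the raw score ``g``.
    """
    out = {}
    for c_true in c_values:
        errors, wins = [], 0
        for rep in range(replicates):
            rs = derive_seed(seed, int(round(c_true * 100)), rep)
            X, s, y, posterior = pu_gaussian_sample(
                n, c_true, separation=separation, seed=rs)
            routine = fit_pu_routine(X[s == 1], X[s == 0], seed=rs)
            errors.append(abs(routine.c - c_true))
            g = routine.score(X)
            f = pu_posterior(routine, X)
            p = posterior(X)
            wins += float(np.mean((f - p) ** 2)) < float(np.mean((g - p) ** 2))
        out[c_true] = {"median_abs_error": float(np.median(errors)),
                       "wins": int(wins), "replicates": replicates, "n": n}
    return out


def imbalance_contrast_study(seed: int = 1,
                             trials: int = SWEEP_TRIALS) -> dict:
    """ISS vs all-in-one gradient boosting at 2:98 and 50:50.

    One fixed 6-class scene; per trial the a:b training design is redrawn
    and both classifiers are fitted and evaluated on a shared held-out
    test set.  Returns the per-condition mean OA and minority F1.
    """
    config = SweepConfig(
        ratios=[(2, 98), (50, 50)], trials=trials,
        methods=("iss", "aio-gbt"), J=10,
        per_majority=SWEEP_PER_MAJORITY, test_size=SWEEP_TEST_SIZE,
        seed=seed, scene=dict(SWEEP_SCENE),
    )
    results = run_sweep(config)
    summary = summarize(results)

    def pick(method, a, col):
        row = summary[(summary.method == method) & (summary.a == a)]
        return float(row[col].iloc[0])

    return {
        "iss_minority_f1_2v98": pick("iss", 2, "minority_f1_mean"),
        "aio_minority_f1_2v98": pick("aio-gbt", 2, "minority_f1_mean"),
        "iss_minority_f1_50v50": pick("iss", 50, "minority_f1_mean"),
        "iss_oa_50v50": pick("iss", 50, "oa_mean"),
        "aio_oa_50v50": pick("aio-gbt", 50, "oa_mean"),
        "n_trials": trials,
        "failed_trials": int((results["error"] != "").sum()),
    }


def _glcm_metrics_double_loop(P: np.ndarray) -> dict[str, float]:
    """Brute-force cell-by-cell reference, independent of glcm_metrics."""
    L = P.shape[0]
    contrast = dissim = homog = asm = entropy = mr = mc = 0.0
    for i in range(L):
        for j in range(L):
            p = float(P[i, j])
            contrast += p * (i - j) ** 2
            dissim += p * abs(i - j)
            homog += p / (1 + (i - j) ** 2)
            asm += p * p
            if p > 0:
                entropy -= p * np.log(p)
            mr += i * p
            mc += j * p
    vr = vc = cov = 0.0
    for i in range(L):
        for j in range(L):
            p = float(P[i, j])
            vr += p * (i - mr) ** 2
            vc += p * (j - mc) ** 2
            cov += p * (i - mr) * (j - mc)
    corr = 0.0 if vr <= 0 or vc <= 0 else cov / np.sqrt(vr * vc)
    return {"mean": mr, "variance": vr, "homogeneity": homog,
            "contrast": contrast, "dissimilarity": dissim,
            "entropy": entropy, "second_moment": asm, "correlation": corr}


def glcm_oracle_study(n_windows: int = 100, levels: int = 8,
                      seed: int = 0) -> dict:
    """Worst metric deviation from the double-loop reference, plus the
    exact flat-window values."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_windows):
        P = glcm(rng.integers(0, levels, (3, 3)), (0, 1), levels)
        got = glcm_metrics(P)
        ref = _glcm_metrics_double_loop(P)
        worst = max(worst, max(abs(got[k] - ref[k]) for k in got))
    flat = glcm_metrics(glcm(np.zeros((3, 3), dtype=int), (0, 1), levels))
    return {"max_abs_deviation": worst, "n": n_windows,
            "flat_contrast": flat["contrast"],
            "flat_homogeneity": flat["homogeneity"],
            "flat_second_moment": flat["second_moment"],
            "flat_entropy": flat["entropy"]}


def smote_segment_study(n_points: int = 1000, k: int = 5,
                        seed: int = 0) -> dict:
    """Exact segment-membership audit of SMOTE output.

    Generates ``n_points`` synthetic points from a Gaussian minority cloud
    and counts how many do NOT lie on the segment between their seed point
    and one of its k nearest minority neighbours.
    """
    from sklearn.neighbors import NearestNeighbors

    rng = np.random.default_rng(seed)
    n_minority = max(n_points, k + 1)
    X = rng.normal(size=(n_minority, 4))
    out = smote(X, k=k, amount_percent=int(round(100 * n_points
                                                 / n_minority)), seed=seed)
    out = out[:n_points]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    violations = 0
    for s, z in enumerate(out):      # seeds cycle in order at 100%
        on_segment = False
        for nb in idx[s % n_minority, 1:]:
            d = X[nb] - X[s % n_minority]
            denom = float(d @ d)
            t = 0.0 if denom == 0 else float((z - X[s % n_minority]) @ d
                                             ) / denom
            if -1e-9 <= t <= 1 + 1e-9 and np.allclose(
                    X[s % n_minority] + t * d, z, atol=1e-9):
                on_segment = True
                break
        violations += not on_segment
    return {"violations": int(violations), "n": n_points}
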