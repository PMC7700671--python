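"""Per-pixel second-order (gray-level co-occurrence) texture metrics.

For every spectral band, each pixel's local window (default 3×3, horizontal
displacement (0, 1)) is summarised by eight Haralick-style metrics: mean,
variance, homogeneity, contrast, dissimilarity, entropy, second moment
(angular second moment) and correlation.  The co-occurrence matrix is
symmetric (each pair counted in both directions) and normalised to sum to
one; bands are linearly quantised to ``levels`` gray levels first, and edge
pixels use replicate padding so the output stays raster-aligned.

Two code paths exist on purpose: :func:`glcm` + :func:`glcm_metrics` compute
one window at a time (the readable reference), while
:func:`extract_features` evaluates all windows of an image at once with a
sliding-slot formulation; a test pins their equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METRIC_NAMES = ("mean", "variance", "homogeneity", "contrast",
                "dissimilarity", "entropy", "second_moment", "correlation")


@dataclass
class TextureConfig:
    """Window geometry, displacement and quantisation of the texture stack."""

    window: int = 3
    offset: tuple[int, int] = (0, 1)
    levels: int = 32
    metrics: tuple[str, ...] = METRIC_NAMES

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        bad = set(self.metrics) - set(METRIC_NAMES)
        if bad:
            raise ValueError(f"unknown texture metrics: {sorted(bad)}")


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Linear min–max quantisation of one band to integers in [0, levels)."""
    band = np.asarray(band, dtype=float)
    if not np.isfinite(band).all():
        raise ValueError("band contains non-finite values")
    lo, hi = float(band.min()), float(band.max())
    if hi == lo:
        return np.zeros(band.shape, dtype=np.int64)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _pair_positions(window: int, offset: tuple[int, int]
                    ) -> list[tuple[int, int]]:
    dr, dc = offset
    out = []
    for r in range(window):
        for c in range(window):
            if 0 <= r + dr < window and 0 <= c + dc < window:
                out.append((r, c))
    if not out:
        raise ValueError(f"offset {offset} does not fit a {window}x{window} "
                         "window")
    return out


def glcm(window_pixels: np.ndarray, offset: tuple[int, int] = (0, 1),
         levels: int = 32) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix of one window.

    ``window_pixels`` holds integer gray levels in ``[0, levels)``.  Every
    co-occurring pair at the given displacement is counted in both
    directions and the matrix is normalised to sum to 1.
    """
    w = np.asarray(window_pixels)
    if w.min() < 0 or w.max() >= levels:
        raise ValueError("window values must lie in [0, levels)")
    dr, dc = offset
    P = np.zeros((levels, levels), dtype=float)
    H, W = w.shape
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                P[w[r, c], w[r2, c2]] += 1.0
                P[w[r2, c2], w[r, c]] += 1.0
    total = P.sum()
    if total == 0:
        raise ValueError("no co-occurring pair fits the window/offset")
    return P / total


def glcm_metrics(P: np.ndarray) -> dict[str, float]:
    """The eight texture metrics of one normalised co-occurrence matrix.

    Mean, variance and correlation are taken from the GLCM marginals (for a
    symmetric matrix the row and column marginals coincide); correlation is
    defined as 0 when the marginal variance vanishes, and ``0·ln 0 = 0`` in
    the entropy.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j

    contrast = float(np.sum(P * diff**2))
    dissimilarity = float(np.sum(P * np.abs(diff)))
    homogeneity = float(np.sum(P / (1.0 + diff**2)))
    second_moment = float(np.sum(P**2))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log(nz)))

    p_row = P.sum(axis=1)
    mean = float(np.sum(np.arange(L) * p_row))
    variance = float(np.sum((np.arange(L) - mean) ** 2 * p_row))
    p_col = P.sum(axis=0)
    mean_c = float(np.sum(np.arange(L) * p_col))
    var_c = float(np.sum((np.arange(L) - mean_c) ** 2 * p_col))
    if variance <= 0 or var_c <= 0:
        correlation = 0.0
    else:
        cov = float(np.sum(P * (i - mean) * (j - mean_c)))
        correlation = cov / np.sqrt(variance * var_c)

    return {"mean": mean, "variance": variance, "homogeneity": homogeneity,
            "contrast": contrast, "dissimilarity": dissimilarity,
            "entropy": entropy, "second_moment": second_moment,
            "correlation": correlation}


def _band_texture(band: np.ndarray, config: TextureConfig) -> np.ndarray:
    """All-window texture metrics of one band, shape (H, W, 8).

    Sliding-slot formulation: the window's co-occurrence distribution puts
    equal mass on ``2·m`` ordered slots (each within-window pair and its
    reverse).  Per-pair functionals (contrast, dissimilarity, homogeneity,
    marginal moments, correlation) are then plain local averages of
    per-slot maps; entropy and the second moment need the slot-code match
    counts, obtained by comparing every slot map against every other.
    """
    H, W = band.shape
    w = config.window
    if w > H or w > W:
        raise ValueError(f"window {w} larger than image {band.shape}")
    q = quantize(band, config.levels)
    pad = w // 2
    qp = np.pad(q, pad, mode="edge")
    positions = _pair_positions(w, config.offset)
    dr, dc = config.offset

    # ordered slots: (i, j) then (j, i) for every pair position
    iv, jv = [], []
    for pr, pc in positions:
        a = qp[pr:pr + H, pc:pc + W]
        b = qp[pr + dr:pr + dr + H, pc + dc:pc + dc + W]
        iv.extend([a, b])
        jv.extend([b, a])
    I = np.stack(iv).astype(float)          # (S, H, W)
    J = np.stack(jv).astype(float)
    S = I.shape[0]

    contrast = np.mean((I - J) ** 2, axis=0)
    dissimilarity = np.mean(np.abs(I - J), axis=0)
    homogeneity = np.mean(1.0 / (1.0 + (I - J) ** 2), axis=0)
    mean = np.mean(I, axis=0)               # symmetric: row marginal mean
    variance = np.mean(I**2, axis=0) - mean**2
    cov = np.mean(I * J, axis=0) - mean**2
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(variance > 1e-12, cov / np.where(
            variance > 1e-12, variance, 1.0), 0.0)

    codes = (I * config.levels + J).astype(np.int64)   # (S, H, W)
    match = np.zeros((S, H, W), dtype=np.int64)
    for k in range(S):
        match[k] = np.sum(codes == codes[k][None, :, :], axis=0)
    second_moment = np.sum(match, axis=0, dtype=float) / (S * S)
    entropy = -np.sum(np.log(match / S), axis=0) / S

    variance = np.maximum(variance, 0.0)
    stack = np.stack([mean, variance, homogeneity, contrast, dissimilarity,
                      entropy, second_moment, correlation], axis=-1)
    keep = [METRIC_NAMES.index(m) for m in config.metrics]
    return stack[..., keep]


def extract_features(raster: np.ndarray,
                     config: TextureConfig | None = None) -> np.ndarray:
    """Original bands plus the texture metrics of each band, channels last.

    A (H, W) or (H, W, B) raster yields (H, W, B·(1 + n_metrics)) planes:
    the spectral bands first, then the metric planes band by band.
    """
    config = config or TextureConfig()
    raster = np.asarray(raster, dtype=float)
    if raster.ndim == 2:
        raster = raster[:, :, None]
    if raster.ndim != 3:
        raise ValueError("raster must be (H, W) or (H, W, bands)")
    if not np.isfinite(raster).all():
        raise ValueError("raster contains non-finite values")
    planes = [raster[:, :, b] for b in range(raster.shape[2])]
    texture = [_band_texture(p, config) for p in planes]
    return np.concatenate([raster] + texture, axis=2)


def features_to_table(features: np.ndarray) -> np.ndarray:
    """Flatten a (H, W, F) feature stack to a (H·W, F) table, row-major."""
    return np.asarray(features).reshape(-1, features.shape[-1])
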