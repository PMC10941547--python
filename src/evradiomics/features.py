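"""The 400-feature radiomic layout: histogram, GLCM and volume-normalized
second-order features, plus voxelwise feature maps.

Per VOI the extractor emits exactly 400 named features:

* ``F001``–``F010`` — 10 first-order intensity-histogram features;
* ``F011``–``F205`` — 195 gray-level co-occurrence matrix (GLCM) features:
  39 rotation-invariant texture statistics at each of 5 gray-level
  quantization settings (default G in {8, 16, 32, 64, 128});
* ``F206``–``F400`` — the same 195 GLCM features divided by the physical
  lesion volume in cm^3 ("volume-dependent second-order features").

The 39 rotation-invariant statistics are 13 classical Haralick texture
statistics, each aggregated over the 13 unique 3D unit-offset directions by
mean, range (max - min) and variance.  Because a 90-degree grid rotation
only permutes the direction set (GLCMs are symmetric, so an offset and its
negation are equivalent), all 39 values are rotation invariant.

Entropies use log base 2 with the convention 0*log(0) = 0.  Degenerate
statistics (correlation with zero marginal variance; skewness/kurtosis of a
constant VOI) are defined as 0 so feature vectors are always total.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCooccurrenceError, ParameterError, ValidationError
from .io import CTVolume, VOISet, muscle_normalize, voi_volume_cc

__all__ = [
    "DEFAULT_GRAY_LEVELS",
    "HARALICK_NAMES",
    "AGGREGATIONS",
    "HISTOGRAM_NAMES",
    "OFFSETS_3D",
    "QuantizedVOI",
    "GLCM",
    "FeatureMap",
    "quantize",
    "glcm",
    "base_texture_stats",
    "rotation_invariant_feature_names",
    "rotation_invariant_features",
    "histogram_features",
    "volume_normalized_features",
    "feature_registry",
    "extract_all",
    "feature_map",
]

DEFAULT_GRAY_LEVELS: tuple[int, ...] = (8, 16, 32, 64, 128)

HARALICK_NAMES: tuple[str, ...] = (
    "Energy",
    "Contrast",
    "Correlation",
    "Variance",
    "Inverse Difference Moment",
    "Sum Average",
    "Sum Variance",
    "Sum Entropy",
    "Entropy",
    "Difference Variance",
    "Difference Entropy",
    "Information Measure of Correlation 1",
    "Information Measure of Correlation 2",
)

AGGREGATIONS: tuple[str, ...] = ("Mean", "Range", "Variance")

HISTOGRAM_NAMES: tuple[str, ...] = (
    "Mean",
    "Median",
    "Standard Deviation",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Minimum",
    "Maximum",
    "10th Percentile",
    "90th Percentile",
)

# The 13 unique unit-offset directions of the 3D 26-neighbourhood (one per
# +/- pair; symmetric GLCMs make the sign irrelevant).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class QuantizedVOI:
    """Integer gray levels in {1..G} over VOI voxels (0 elsewhere)."""

    levels: np.ndarray
    G: int
    binning: str = "equal-width"


@dataclass
class GLCM:
    """Normalized symmetric co-occurrence matrix for one offset."""

    matrix: np.ndarray
    offset: tuple[int, int, int]
    symmetric: bool = True


@dataclass
class FeatureMap:
    """Voxelwise sliding-window map of one rotation-invariant feature."""

    data: np.ndarray
    feature_name: str
    window_radius: int
    G: int


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(volume: CTVolume | np.ndarray, mask: np.ndarray, G: int,
             binning: str = "equal-width", bin_width: float | None = None) -> QuantizedVOI:
    """Quantize VOI intensities to integer gray levels 1..G.

    Default is equal-width binning between the VOI minimum and maximum; a
    constant VOI maps every voxel to level 1.  ``binning="fixed-width"``
    instead uses bins of ``bin_width`` intensity units anchored at the VOI
    minimum (levels above G are clipped).
    """
    if G < 2:
        raise ParameterError(f"gray-level count must be >= 2, got {G}")
    data = volume.data if isinstance(volume, CTVolume) else np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValidationError("mask is empty")
    vals = data[mask]
    levels = np.zeros(data.shape, dtype=np.int32)
    if binning == "equal-width":
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            q = np.ones(vals.shape, dtype=np.int32)
        else:
            q = np.floor((vals - lo) / (hi - lo) * G).astype(np.int32) + 1
            np.clip(q, 1, G, out=q)
    elif binning == "fixed-width":
        if bin_width is None or bin_width <= 0:
            raise ParameterError("fixed-width binning requires a positive bin_width")
        q = np.floor((vals - vals.min()) / bin_width).astype(np.int32) + 1
        np.clip(q, 1, G, out=q)
    else:
        raise ParameterError(f"unknown binning {binning!r}")
    levels[mask] = q
    return QuantizedVOI(levels=levels, G=int(G), binning=binning)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_counts(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int], G: int) -> np.ndarray:
    """Raw symmetric pair counts for one displacement (vectorized slicing)."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        n = levels.shape[ax]
        if abs(d) >= n:
            return np.zeros((G, G), dtype=np.float64)
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    a = levels[tuple(src)]
    b = levels[tuple(dst)]
    valid = mask[tuple(src)] & mask[tuple(dst)]
    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.bincount(i * G + j, minlength=G * G).reshape(G, G).astype(np.float64)
    return counts + counts.T


def glcm(q: QuantizedVOI, mask: np.ndarray, offset: Sequence[int]) -> GLCM:
    """Normalized symmetric GLCM: probability of level pairs (i, j) at the
    given voxel displacement, counting each pair and its reverse."""
    offset = tuple(int(d) for d in offset)
    if len(offset) != 3 or offset == (0, 0, 0):
        raise ParameterError(f"offset must be a nonzero 3-vector, got {offset}")
    mask = np.asarray(mask) > 0
    counts = _glcm_counts(q.levels, mask, offset, q.G)
    total = counts.sum()
    if total == 0:
        raise EmptyCooccurrenceError(f"no valid voxel pair for offset {offset}")
    return GLCM(matrix=counts / total, offset=offset)


# ---------------------------------------------------------------------------
# Haralick statistics
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def base_texture_stats(m: GLCM | np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of one normalized GLCM.

    Entropies are in bits; correlation with a zero-variance marginal and the
    information measures with zero marginal entropy are defined as 0.
    """
    P = m.matrix if isinstance(m, GLCM) else np.asarray(m, dtype=np.float64)
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ i)
    mu_y = float(py @ i)
    var_x = float(px @ (i - mu_x) ** 2)
    var_y = float(py @ (i - mu_y) ** 2)

    # p_{x+y}(k), k = 2..2G and p_{|x-y|}(k), k = 0..G-1
    p_sum = np.zeros(2 * G - 1)
    p_diff = np.zeros(G)
    sums = (I + J).astype(int) - 2
    diffs = np.abs(I - J).astype(int)
    np.add.at(p_sum, sums.ravel(), P.ravel())
    np.add.at(p_diff, diffs.ravel(), P.ravel())
    k_sum = np.arange(2, 2 * G + 1, dtype=np.float64)
    k_diff = np.arange(0, G, dtype=np.float64)

    energy = float((P ** 2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((I * J * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float(((I - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())
    sum_avg = float(p_sum @ k_sum)
    sum_var = float(p_sum @ (k_sum - sum_avg) ** 2)
    sum_ent = float(-_xlog2(p_sum).sum())
    entropy = float(-_xlog2(P).sum())
    diff_avg = float(p_diff @ k_diff)
    diff_var = float(p_diff @ (k_diff - diff_avg) ** 2)
    diff_ent = float(-_xlog2(p_diff).sum())

    hxy = entropy
    pxy = np.outer(px, py)
    mask_nz = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[mask_nz] * np.log2(pxy[mask_nz])).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    hmax = max(hx, hy)
    imc1 = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    vals = (energy, contrast, correlation, variance, idm, sum_avg, sum_var,
            sum_ent, entropy, diff_var, diff_ent, imc1, imc2)
    return dict(zip(HARALICK_NAMES, (float(v) for v in vals)))


# ---------------------------------------------------------------------------
# rotation-invariant aggregation
# ---------------------------------------------------------------------------

def rotation_invariant_feature_names() -> list[str]:
    """The 39 names, statistic-major: Mean/Range/Variance of each statistic."""
    return [f"{agg} of {stat}" for stat in HARALICK_NAMES for agg in AGGREGATIONS]


def rotation_invariant_features(volume: CTVolume | np.ndarray, mask: np.ndarray, G: int,
                                binning: str = "equal-width") -> dict[str, float]:
    """39 rotation-invariant texture features of one VOI at one gray-level
    setting: 13 Haralick statistics x {mean, range, variance} over the 13
    unique unit-offset directions.

    Directions with no valid voxel pair are excluded from the aggregation
    with a warning; if every direction is empty the VOI is too small and an
    :class:`EmptyCooccurrenceError` is raised.
    """
    q = quantize(volume, mask, G, binning=binning)
    mask = np.asarray(mask) > 0
    per_direction: list[list[float]] = []
    for off in OFFSETS_3D:
        counts = _glcm_counts(q.levels, mask, off, q.G)
        total = counts.sum()
        if total == 0:
            warnings.warn(f"offset {off}: no valid voxel pair; direction excluded", stacklevel=2)
            continue
        stats = base_texture_stats(counts / total)
        per_direction.append([stats[name] for name in HARALICK_NAMES])
    if not per_direction:
        raise EmptyCooccurrenceError("no offset direction has a valid voxel pair")
    arr = np.asarray(per_direction)  # (n_dirs, 13)
    out: dict[str, float] = {}
    for s, stat in enumerate(HARALICK_NAMES):
        col = arr[:, s]
        out[f"Mean of {stat}"] = float(col.mean())
        out[f"Range of {stat}"] = float(col.max() - col.min())
        out[f"Variance of {stat}"] = float(col.var())
    # reorder to the canonical registry order
    return {name: out[name] for name in rotation_invariant_feature_names()}


# ---------------------------------------------------------------------------
# histogram features
# ---------------------------------------------------------------------------

def histogram_features(volume: CTVolume | np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """10 first-order intensity features of the VOI.

    SD/variance use the sample convention (ddof=1, 0 for a single voxel);
    skewness and excess kurtosis are defined as 0 for zero variance.
    """
    data = volume.data if isinstance(volume, CTVolume) else np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValidationError("mask is empty")
    x = data[mask]
    n = x.size
    mu = float(x.mean())
    var = float(x.var(ddof=1)) if n > 1 else 0.0
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (x - mu) / x.std(ddof=0)
        skew = float((z ** 3).mean())
        kurt = float((z ** 4).mean() - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    vals = (mu, float(np.median(x)), sd, var, skew, kurt, float(x.min()), float(x.max()),
            float(np.percentile(x, 10)), float(np.percentile(x, 90)))
    return dict(zip(HISTOGRAM_NAMES, vals))


# ---------------------------------------------------------------------------
# volume normalization and the full 400-feature layout
# ---------------------------------------------------------------------------

def volume_normalized_features(glcm_features: Mapping[str, float], lesion_volume_cc: float) -> dict[str, float]:
    """Divide each of the 195 GLCM features by the lesion volume (cm^3)."""
    if lesion_volume_cc <= 0:
        raise ValidationError(f"lesion volume must be positive, got {lesion_volume_cc}")
    return {f"{name} per Volume": v / lesion_volume_cc for name, v in glcm_features.items()}


def feature_registry(gray_levels: Sequence[int] = DEFAULT_GRAY_LEVELS) -> pd.DataFrame:
    """The F001-F400 code -> name mapping table.

    Columns: ``code`` (F001..F400), ``name`` (human-readable), ``family``
    (histogram / glcm / glcm_per_volume).
    """
    if len(gray_levels) != 5:
        raise ParameterError(f"expected 5 gray-level settings, got {len(gray_levels)}")
    rows: list[tuple[str, str, str]] = []
    for name in HISTOGRAM_NAMES:
        rows.append((f"F{len(rows) + 1:03d}", name, "histogram"))
    for g in gray_levels:
        for name in rotation_invariant_feature_names():
            rows.append((f"F{len(rows) + 1:03d}", f"{name} (G={g})", "glcm"))
    for g in gray_levels:
        for name in rotation_invariant_feature_names():
            rows.append((f"F{len(rows) + 1:03d}", f"{name} (G={g}) per Volume", "glcm_per_volume"))
    return pd.DataFrame(rows, columns=["code", "name", "family"])


def extract_all(volume: CTVolume, voi: VOISet,
                gray_levels: Sequence[int] = DEFAULT_GRAY_LEVELS,
                muscle_norm: bool = True,
                volume_mode: str = "physical",
                binning: str = "equal-width") -> dict[str, pd.Series]:
    """Extract the full 400-feature vector for every lesion mask.

    Returns ``{lesion_name: Series}`` where each Series is indexed by the
    registry codes F001..F400.  With ``muscle_norm`` the volume is first
    z-scored against the muscle VOI (within-phase normalization).
    ``volume_mode`` selects physical cm^3 (default) or ``"voxels"`` for the
    second-order volume normalization.
    """
    voi.validate_against(volume)
    if muscle_norm:
        volume = muscle_normalize(volume, voi)
    registry = feature_registry(gray_levels)
    if volume_mode not in ("physical", "voxels"):
        raise ParameterError(f"unknown volume_mode {volume_mode!r}")

    out: dict[str, pd.Series] = {}
    for lesion_name, mask in voi.lesion_masks.items():
        values: list[float] = []
        hist = histogram_features(volume, mask)
        values.extend(hist[n] for n in HISTOGRAM_NAMES)
        glcm_block: list[float] = []
        for g in gray_levels:
            feats = rotation_invariant_features(volume, mask, g, binning=binning)
            glcm_block.extend(feats.values())
        values.extend(glcm_block)
        if volume_mode == "physical":
            vol = voi_volume_cc(mask, volume.spacing_mm)
        else:
            vol = float((np.asarray(mask) > 0).sum())
        values.extend(v / vol for v in glcm_block)
        out[lesion_name] = pd.Series(values, index=registry["code"].to_numpy(), name=lesion_name)
    return out


# ---------------------------------------------------------------------------
# voxelwise feature maps
# ---------------------------------------------------------------------------

def feature_map(volume: CTVolume, mask: np.ndarray, feature_name: str,
                window_radius: int = 2, G: int = 8) -> FeatureMap:
    """Sliding-window map of one of the 39 rotation-invariant features.

    For each lesion voxel the feature is computed on the cubic window of the
    given radius intersected with the lesion mask; voxels whose window
    yields no valid co-occurrence pair are NaN.
    """
    names = rotation_invariant_feature_names()
    if feature_name not in names:
        raise ParameterError(f"unknown feature {feature_name!r}; expected one of the 39 "
                             f"rotation-invariant names, e.g. {names[0]!r}")
    if window_radius < 1:
        raise ParameterError("window_radius must be >= 1")
    mask = np.asarray(mask) > 0
    data = volume.data
    out = np.full(data.shape, np.nan)
    r = window_radius
    idx = np.argwhere(mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny windows routinely drop directions
        for z, y, x in idx:
            sl = (slice(max(z - r, 0), z + r + 1),
                  slice(max(y - r, 0), y + r + 1),
                  slice(max(x - r, 0), x + r + 1))
            sub_mask = mask[sl]
            if sub_mask.sum() < 2:
                continue
            try:
                feats = rotation_invariant_features(data[sl], sub_mask, G)
            except EmptyCooccurrenceError:
                continue
            out[z, y, x] = feats[feature_name]
    return FeatureMap(data=out, feature_name=feature_name, window_radius=window_radius, G=G)
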