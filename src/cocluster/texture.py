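"""Per-cell texture and morphology features.

The canonical battery holds 24 features per cell, computed on the protein
channel only:

* 13 Haralick statistics of a mask-aware gray-level co-occurrence matrix
  (G = 8 levels, distance 1, four orientations, symmetric);
* 4 Gabor filter-bank statistics (mean and s.d. of the magnitude response
  at wavelengths 4 px and 8 px, averaged over orientations 0/45/90/135 deg);
* mean intensity;
* 3 spot / edge / ridge statistics built from Laplacian-of-Gaussian,
  gradient-magnitude and Hessian-eigenvalue responses;
* 2 intensity-weighted radial moments of normalized distance from the cell
  centroid;
* 1 radial-shift Haralick contrast, where each pixel is paired with its
  neighbour along the outward radial direction.

Intensities are quantized per cell by min-max binning, which makes the GLCM
features invariant to affine intensity rescaling of the cell.  Conventions
for degenerate cells (constant intensity, too-small support) return defined
values (0 or the trivial statistic) with a warning flag rather than NaN, so
the downstream PCA stays total.

Haralick statistics use 0-based gray levels and natural logarithms; the
correlation of a constant cell is defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import gabor

from .errors import DegenerateGLCMError, ValidationError

#: canonical feature order (24 entries)
FEATURE_NAMES = tuple(
    [f"haralick_{i:02d}" for i in range(1, 14)]
    + [
        "gabor_f4_mean",
        "gabor_f4_sd",
        "gabor_f8_mean",
        "gabor_f8_sd",
        "mean_intensity",
        "ser_spot",
        "ser_edge",
        "ser_ridge",
        "radial_moment_1",
        "radial_moment_2",
        "radial_haralick_contrast",
    ]
)

DEFAULT_LEVELS = 8
#: distance-1 offsets for the four standard GLCM orientations
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
GABOR_WAVELENGTHS = (4.0, 8.0)
GABOR_ORIENTATIONS = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
SER_SIGMA = 2.0


@dataclass
class GLCM:
    """Normalized symmetric gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    offsets: tuple
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.levels < 2:
            raise ValidationError("GLCM needs at least 2 levels")
        if self.matrix.shape != (self.levels, self.levels):
            raise ValidationError("GLCM matrix shape inconsistent with levels")
        if self.matrix.min() < 0:
            raise ValidationError("GLCM entries must be non-negative")
        if abs(self.matrix.sum() - 1.0) > 1e-8:
            raise ValidationError("GLCM must be normalized to sum 1")


@dataclass
class FeatureVector:
    """The 24 named texture features of one cell."""

    cell_id: int
    values: dict
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValidationError("feature vector must hold the 24 canonical features in order")
        arr = np.array(list(self.values.values()), dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            bad = [n for n, v in self.values.items() if not np.isfinite(v)]
            raise ValidationError(f"non-finite features for cell {self.cell_id}: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=np.float64)


def quantize(pixels: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Min-max bin intensities into integer levels 0..levels-1 within the cell.

    ``q = floor(levels * (I - min) / (max - min + eps))`` clipped to
    ``levels - 1``; a constant cell maps entirely to level 0.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValidationError("cannot quantize an empty pixel set")
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.int64)
    q = np.floor(levels * (pixels - lo) / (hi - lo + 1e-12))
    return np.clip(q, 0, levels - 1).astype(np.int64)


def compute_glcm(quantized: np.ndarray, mask: np.ndarray | None = None,
                 offsets=DEFAULT_OFFSETS, levels: int = DEFAULT_LEVELS,
                 symmetric: bool = True) -> GLCM:
    """Accumulate co-occurrence counts over the given offsets.

    Pairs are counted only when both pixels lie inside the mask; counts are
    symmetrized by adding the transpose and normalized to sum 1.
    """
    quantized = np.asarray(quantized)
    if quantized.ndim != 2:
        raise ValidationError("quantized raster must be 2D")
    if not len(offsets):
        raise ValidationError("at least one offset is required")
    if quantized.min(initial=0) < 0 or quantized.max(initial=0) >= levels:
        raise ValidationError("quantized values must lie in [0, levels)")
    if mask is None:
        mask = np.ones(quantized.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != quantized.shape:
        raise ValidationError("mask shape differs from raster shape")

    H, W = quantized.shape
    counts = np.zeros((levels, levels), dtype=np.float64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = quantized[r0:r1, c0:c1]
        b = quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateGLCMError("no valid pixel pairs for GLCM")
    return GLCM(matrix=counts / total, levels=levels, offsets=tuple(offsets),
                symmetric=symmetric)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def haralick_features(glcm: GLCM) -> dict:
    """The 13 classical Haralick statistics of a normalized GLCM.

    Returns an ordered dict ``haralick_01`` .. ``haralick_13``:
    angular second moment, contrast, correlation, sum of squares variance,
    inverse difference moment, sum average, sum variance, sum entropy,
    entropy, difference variance, difference entropy, and the two
    information measures of correlation.
    """
    P = glcm.matrix
    G = glcm.levels
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(G) * px).sum())
    mu_y = float((np.arange(G) * py).sum())
    var_x = float(((np.arange(G) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(G) - mu_y) ** 2 * py).sum())

    asm = float((P**2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    if var_x > 1e-15 and var_y > 1e-15:
        correlation = float(((i * j * P).sum() - mu_x * mu_y)
                            / math.sqrt(var_x * var_y))
    else:
        correlation = 0.0  # constant-cell convention
    sum_of_squares = float(((i - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    k_sum = np.arange(2 * G - 1)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (i + j).ravel(), P.ravel())
    k_diff = np.arange(G)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(i - j).ravel(), P.ravel())

    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(P.ravel())
    diff_mean = float((k_diff * p_diff).sum())
    diff_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    diff_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = entropy
    outer = px[:, None] * py[None, :]
    pos = (P > 0) & (outer > 0)
    hxy1 = float(-(P[pos] * np.log(outer[pos])).sum())
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log(outer[pos2])).sum())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 1e-15 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    vals = [asm, contrast, correlation, sum_of_squares, idm, sum_average,
            sum_variance, sum_entropy, entropy, diff_variance, diff_entropy,
            imc1, imc2]
    return {f"haralick_{k:02d}": float(v) for k, v in zip(range(1, 14), vals)}


def _masked_stats(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(values.std())


def gabor_features(raster: np.ndarray, mask: np.ndarray,
                   wavelengths=GABOR_WAVELENGTHS,
                   orientations=GABOR_ORIENTATIONS) -> tuple[dict, list]:
    """Mean/s.d. of Gabor magnitude per wavelength, averaged over orientations.

    The cell region is mean-subtracted (masked mean) before filtering, so the
    features are invariant to adding a constant.  Cells whose bounding box is
    smaller than the filter support get zeros plus a warning flag.
    """
    raster = np.asarray(raster, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    out = {}
    warn = []
    x = raster - raster[mask].mean()
    x[~mask] = 0.0
    for lam in wavelengths:
        key = f"gabor_f{int(lam)}"
        sigma = 0.5 * lam
        support = 2 * int(math.ceil(3.0 * sigma)) + 1
        if min(raster.shape) < support:
            out[f"{key}_mean"] = 0.0
            out[f"{key}_sd"] = 0.0
            warn.append(f"{key}: bounding box smaller than filter support")
            continue
        means, sds = [], []
        for theta in orientations:
            real, imag = gabor(x, frequency=1.0 / lam, theta=theta,
                               sigma_x=sigma, sigma_y=sigma)
            mag = np.hypot(real, imag)[mask]
            m, s = _masked_stats(mag)
            means.append(m)
            sds.append(s)
        out[f"{key}_mean"] = float(np.mean(means))
        out[f"{key}_sd"] = float(np.mean(sds))
    return out, warn


def ser_features(raster: np.ndarray, mask: np.ndarray,
                 sigma: float = SER_SIGMA) -> tuple[dict, list]:
    """Spot, edge and ridge statistics of the cell region.

    spot  = masked mean of max(0, -LoG(sigma));
    edge  = masked mean gradient magnitude (central differences);
    ridge = masked mean of max(0, -lambda_min) with lambda_min the smaller
            Hessian eigenvalue at the same scale.
    Pixels outside the mask are replaced by the masked mean so the cell
    boundary does not masquerade as structure.
    """
    raster = np.asarray(raster, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if raster.shape[0] * raster.shape[1] < 9:
        return ({"ser_spot": 0.0, "ser_edge": 0.0, "ser_ridge": 0.0},
                ["ser: cell bounding box smaller than 3x3"])
    img = raster.copy()
    img[~mask] = raster[mask].mean()
    # subtract the mean so truncated filter kernels cannot leak a DC term
    img -= raster[mask].mean()
    log = ndi.gaussian_laplace(img, sigma=sigma)
    spot = float(np.maximum(0.0, -log)[mask].mean())
    gr, gc = np.gradient(img)
    edge = float(np.hypot(gr, gc)[mask].mean())
    helems = hessian_matrix(img, sigma=sigma, order="rc", mode="nearest",
                            use_gaussian_derivatives=True)
    eigs = hessian_matrix_eigvals(helems)  # sorted descending
    ridge = float(np.maximum(0.0, -eigs[-1])[mask].mean())
    return {"ser_spot": spot, "ser_edge": edge, "ser_ridge": ridge}, []


def radial_moments(pixel_values: np.ndarray, coords: np.ndarray,
                   centroid: tuple) -> dict:
    """Intensity-weighted moments of normalized radial distance.

    ``r_i`` is each member pixel's distance to the centroid divided by the
    maximum member distance; RM1 is the intensity-weighted mean of r and RM2
    the intensity-weighted variance.  RM1 lies in [0, 1]; RM2 in [0, 0.25].
    """
    values = np.asarray(pixel_values, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64)
    total = values.sum()
    if total <= 0:
        raise ValidationError("radial moments undefined for all-zero cell")
    d = np.hypot(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
    dmax = d.max()
    r = d / dmax if dmax > 0 else np.zeros_like(d)
    rm1 = float((values * r).sum() / total)
    rm2 = float((values * (r - rm1) ** 2).sum() / total)
    return {"radial_moment_1": rm1, "radial_moment_2": rm2}


_OCTANT_STEPS = ((0, 1), (-1, 1), (-1, 0), (-1, -1),
                 (0, -1), (1, -1), (1, 0), (1, 1))


def radial_shift_haralick(quantized: np.ndarray, mask: np.ndarray,
                          centroid: tuple) -> tuple[float, list]:
    """GLCM-style contrast along the outward radial direction.

    Each mask pixel is paired with its neighbour in the direction away from
    the centroid, rounded to the nearest of the 8 neighbours; the feature is
    the mean squared quantized-level difference over valid pairs.
    """
    quantized = np.asarray(quantized)
    mask = np.asarray(mask, dtype=bool)
    H, W = quantized.shape
    rows, cols = np.nonzero(mask)
    vr = rows - centroid[0]
    vc = cols - centroid[1]
    nonzero = (vr != 0) | (vc != 0)
    # angle measured in (row, col) frame; 0 deg points along +col
    ang = np.arctan2(-vr[nonzero], vc[nonzero])
    octant = np.round(ang / (math.pi / 4)).astype(int) % 8
    steps = np.array(_OCTANT_STEPS)[octant]
    pr = rows[nonzero] + steps[:, 0]
    pc = cols[nonzero] + steps[:, 1]
    inside = (pr >= 0) & (pr < H) & (pc >= 0) & (pc < W)
    pr, pc = pr[inside], pc[inside]
    r0, c0 = rows[nonzero][inside], cols[nonzero][inside]
    valid = mask[pr, pc]
    if not valid.any():
        return 0.0, ["radial_shift: no valid radial pairs"]
    dq = quantized[r0[valid], c0[valid]].astype(np.float64) - quantized[
        pr[valid], pc[valid]]
    return float((dq**2).mean()), []


def mean_intensity(pixel_values: np.ndarray) -> float:
    values = np.asarray(pixel_values, dtype=np.float64)
    if values.size == 0:
        raise ValidationError("mean intensity of an empty pixel set")
    return float(values.mean())


def extract_features(cell_view, channel: str = "protein",
                     levels: int = DEFAULT_LEVELS) -> FeatureVector:
    """Compute the canonical 24-feature vector for one cell view."""
    if channel not in cell_view.pixels:
        raise ValidationError(
            f"cell {cell_view.cell_id}: channel {channel!r} not present"
        )
    pixels = cell_view.pixels[channel]
    raster = cell_view.rasters[channel]
    mask = cell_view.mask
    warnings: list[str] = []
    try:
        q_raster = np.zeros(raster.shape, dtype=np.int64)
        q_raster[mask] = quantize(pixels, levels)
        glcm = compute_glcm(q_raster, mask=mask, levels=levels)
        har = haralick_features(glcm)
    except DegenerateGLCMError as exc:
        raise ValidationError(
            f"cell {cell_view.cell_id}: degenerate GLCM ({exc})"
        ) from exc
    gab, w = gabor_features(raster, mask)
    warnings += w
    ser, w = ser_features(raster, mask)
    warnings += w
    # centroid in cropped-raster coordinates
    rmin, _, cmin, _ = cell_view.bbox
    local_centroid = (cell_view.centroid[0] - rmin, cell_view.centroid[1] - cmin)
    rad = radial_moments(pixels, cell_view.coords, cell_view.centroid)
    rsh, w = radial_shift_haralick(q_raster, mask, local_centroid)
    warnings += w

    values = {}
    values.update(har)
    values.update(gab)
    values["mean_intensity"] = mean_intensity(pixels)
    values.update(ser)
    values.update(rad)
    values["radial_haralick_contrast"] = rsh
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(cell_id=cell_view.cell_id, values=ordered,
                         warnings=warnings)


def feature_table_from_cells(cell_views, class_labels=None,
                             channel: str = "protein"):
    """Extract features for many cells and assemble a FeatureTable."""
    from .io import FeatureTable

    vectors = [extract_features(cv, channel=channel) for cv in cell_views]
    return FeatureTable(
        cell_ids=[v.cell_id for v in vectors],
        feature_names=list(FEATURE_NAMES),
        values=np.array([v.as_array() for v in vectors]),
        class_labels=list(class_labels) if class_labels is not None else None,
    )
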