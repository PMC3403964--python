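"""Rank-weighted co-localization (RWC) between protein and marker channels.

The RWC coefficient measures both *co-occurrence* (pixels above an automatic
intensity threshold in both channels) and *intensity correlation* (agreement
of the intensity ranks of the two channels at those pixels).  For a cell
with channel intensities ``I1`` (protein) and ``I2`` (marker):

1. thresholds ``T1``, ``T2`` are found independently per channel (Otsu);
2. the co-localized set ``C`` holds the pixels above threshold in *both*
   channels; ``Rmax = |C|``;
3. within ``C`` each channel's intensities are ranked (ties averaged) giving
   ``R1_i``, ``R2_i``; the rank disagreement is ``D_i = |R1_i - R2_i|`` and
   each pixel's weight is ``W_i = (Rmax - D_i) / Rmax``;
4. ``RWC1 = sum_{i in C} W_i I1_i / sum_{I1 > T1} I1`` and symmetrically
   ``RWC2`` with channel roles swapped.

Pixels that co-occur with well-correlated intensities therefore contribute
their full intensity, while co-occurring pixels with discordant ranks are
down-weighted; the Manders-style denominator bounds the coefficient in
[0, 1].  The procedure needs no manual threshold, which is what makes it
usable at screening scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateChannelError, ValidationError


@dataclass
class RWCResult:
    """RWC coefficients for one cell, in both channel directions."""

    rwc_1: float
    rwc_2: float
    threshold_1: float
    threshold_2: float
    n_coloc_pixels: int
    n_above_1: int
    n_above_2: int
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("rwc_1", "rwc_2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.n_coloc_pixels > min(self.n_above_1, self.n_above_2):
            raise ValidationError(
                "n_coloc_pixels cannot exceed either above-threshold count"
            )


def auto_threshold(pixels: np.ndarray, method: str = "otsu",
                   nbins: int = 256) -> float:
    """Automatic intensity threshold for the member pixels of one channel.

    Exhaustive Otsu scan over a 256-bin histogram.  When several cut points
    attain the maximal between-class variance (a flat plateau occurs
    whenever the histogram has an empty valley between modes), the plateau
    is averaged, which places the threshold mid-valley instead of at an
    arbitrary edge.  The result lies strictly between the minimum and
    maximum member intensity.  A constant channel has no meaningful
    threshold and raises :class:`DegenerateChannelError`.
    """
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise ValidationError("cannot threshold an empty pixel set")
    if method != "otsu":
        raise ValidationError(f"unknown threshold method {method!r}")
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        raise DegenerateChannelError("constant channel: threshold undefined")
    hist, edges = np.histogram(pixels, bins=nbins)
    hist = hist.astype(np.float64)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    csum = np.cumsum(hist * centers)[:-1]
    total = (hist * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    m0 = np.where(valid, csum / np.where(w0 > 0, w0, 1.0), 0.0)
    m1 = np.where(valid, (total - csum) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (m0 - m1) ** 2, -np.inf)
    peak = sigma_b.max()
    ties = sigma_b >= peak * (1.0 - 1e-12)
    # cut after bin i puts the boundary at edges[i + 1]
    thr = float(edges[1:-1][ties].mean())
    eps = (hi - lo) * 1e-12
    return float(min(max(thr, lo + eps), hi - eps))


def rank_with_ties(values: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..n with ties replaced by the average spanned rank."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValidationError("cannot rank an empty value set")
    return rankdata(values, method="average")


def rwc(protein: np.ndarray, marker: np.ndarray,
        threshold_1: float | None = None,
        threshold_2: float | None = None) -> RWCResult:
    """Rank-weighted co-localization of two matched pixel sets.

    ``protein`` and ``marker`` are the member intensities of one cell (same
    pixels, same order).  Thresholds default to per-channel Otsu; supplying
    them explicitly skips the automatic step.  A constant channel yields
    RWC = 0 with a warning rather than an error.
    """
    I1 = np.asarray(protein, dtype=np.float64).ravel()
    I2 = np.asarray(marker, dtype=np.float64).ravel()
    if I1.shape != I2.shape:
        raise ValidationError(
            f"channel pixel counts differ: {I1.size} vs {I2.size}"
        )
    if I1.size == 0:
        raise ValidationError("empty pixel sets")

    warn: list[str] = []
    try:
        t1 = auto_threshold(I1) if threshold_1 is None else float(threshold_1)
        t2 = auto_threshold(I2) if threshold_2 is None else float(threshold_2)
    except DegenerateChannelError as exc:
        warnings.warn(f"degenerate channel, RWC set to 0: {exc}", stacklevel=2)
        return RWCResult(0.0, 0.0, float("nan"), float("nan"), 0, 0, 0,
                         warnings=[str(exc)])

    above1 = I1 > t1
    above2 = I2 > t2
    in_c = above1 & above2
    n_c = int(in_c.sum())
    n1 = int(above1.sum())
    n2 = int(above2.sum())
    if n_c == 0:
        return RWCResult(0.0, 0.0, t1, t2, 0, n1, n2,
                         warnings=warn + ["empty co-localized set"])

    r1 = rank_with_ties(I1[in_c])
    r2 = rank_with_ties(I2[in_c])
    d = np.abs(r1 - r2)
    w = (n_c - d) / n_c

    denom1 = I1[above1].sum()
    denom2 = I2[above2].sum()
    rwc_1 = float((w * I1[in_c]).sum() / denom1) if denom1 > 0 else 0.0
    rwc_2 = float((w * I2[in_c]).sum() / denom2) if denom2 > 0 else 0.0
    return RWCResult(rwc_1, rwc_2, t1, t2, n_c, n1, n2, warnings=warn)


def rwc_per_cell(image_set, mask, protein: str = "protein",
                 marker: str = "marker"):
    """RWC for every labelled cell; degenerate cells are flagged, not dropped.

    Returns a list of ``(cell_id, RWCResult)`` in label order.
    """
    from .segmentation import extract_cell

    if marker not in image_set.channels:
        raise ValidationError(f"image set lacks the {marker!r} channel")
    if protein not in image_set.channels:
        raise ValidationError(f"image set lacks the {protein!r} channel")
    out = []
    for cid in range(1, mask.n_cells + 1):
        view = extract_cell(image_set, mask, cid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rwc(view.pixels[protein], view.pixels[marker])
        out.append((cid, res))
    return out
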