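"""Per-cell segmentation of the protein channel.

The procedure is deliberately simple and fully deterministic: Gaussian
smoothing, global thresholding (Otsu by default), hole filling, optional
nucleus-seeded watershed splitting of touching objects, then an area filter
and optional border exclusion.  Labels are assigned in raster order of
object centroids so the numbering is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .errors import ValidationError


@dataclass
class LabelMask:
    """Integer-labelled cell mask: 0 = background, 1..n_cells = cells."""

    labels: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label mask must be 2D")
        if self.labels.min(initial=0) < 0:
            raise ValidationError("label mask must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and present.max() > self.n_cells:
            raise ValidationError("labels exceed declared n_cells")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMask":
        labels = np.asarray(labels)
        return cls(labels=labels, n_cells=int(labels.max(initial=0)))


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma_px: float = 2.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 50
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px <= 0:
            raise ValidationError("smoothing_sigma_px must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError(
                f"threshold_method must be 'otsu' or 'fixed', got {self.threshold_method!r}"
            )
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed_threshold required for method='fixed'")
        if self.threshold_method == "otsu" and self.fixed_threshold is not None:
            raise ValidationError("fixed_threshold only valid with method='fixed'")
        if self.min_area_px <= 0:
            raise ValidationError("min_area_px must be positive")


def _relabel_raster_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n in raster order of object centroids."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return np.zeros_like(labels, dtype=np.int32), 0
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    order = sorted(range(len(ids)), key=lambda i: (centroids[i][0], centroids[i][1]))
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for new, i in enumerate(order, start=1):
        lut[ids[i]] = new
    return lut[labels], len(ids)


def segment_cells(protein: np.ndarray, nucleus: np.ndarray | None = None,
                  params: SegmentationParams | None = None) -> LabelMask:
    """Segment cells from the protein channel.

    When a nuclear channel is supplied, touching objects are split by a
    watershed on the distance transform seeded from nuclei; otherwise
    connected components are used directly (sufficient for well-separated
    cells).  An all-zero image yields an empty mask, not an error.
    """
    params = params or SegmentationParams()
    protein = np.asarray(protein, dtype=np.float64)
    if not np.all(np.isfinite(protein)):
        raise ValidationError("protein channel contains non-finite pixels")
    if protein.min(initial=0.0) < 0:
        raise ValidationError("protein channel must be non-negative")
    if nucleus is not None and np.asarray(nucleus).shape != protein.shape:
        raise ValidationError("nucleus channel shape differs from protein channel")

    if protein.max(initial=0.0) == protein.min(initial=0.0):
        return LabelMask(labels=np.zeros(protein.shape, dtype=np.int32), n_cells=0)

    smoothed = gaussian(protein, sigma=params.smoothing_sigma_px,
                        preserve_range=True)
    if params.threshold_method == "otsu":
        # Otsu in the log domain: fluorescence intensities span a
        # multiplicative range (dim cytoplasm vs bright puncta), and a
        # linear-domain Otsu is dragged into the puncta tail, eroding the
        # cell body.  Log transform first, then map the cut back.
        thr = float(np.expm1(threshold_otsu(np.log1p(smoothed))))
    else:
        thr = params.fixed_threshold
    fg = ndi.binary_fill_holes(smoothed > thr)

    if nucleus is not None:
        nuc = gaussian(np.asarray(nucleus, dtype=np.float64),
                       sigma=params.smoothing_sigma_px, preserve_range=True)
        try:
            nthr = threshold_otsu(nuc)
        except ValueError:
            nthr = np.inf
        markers, _ = ndi.label(nuc > nthr)
        if markers.max() > 0:
            dist = ndi.distance_transform_edt(fg)
            labels = watershed(-dist, markers=markers, mask=fg)
        else:
            labels, _ = ndi.label(fg)
    else:
        labels, _ = ndi.label(fg)

    mask = LabelMask.from_labels(labels)
    return filter_cells(mask, min_area_px=params.min_area_px,
                        exclude_border=params.exclude_border)


def filter_cells(mask: LabelMask, min_area_px: int = 1,
                 exclude_border: bool = False) -> LabelMask:
    """Drop small or border-touching objects and relabel compactly.

    Idempotent: applying it twice with the same arguments is a no-op.
    """
    labels = np.asarray(mask.labels).copy()
    ids, counts = np.unique(labels, return_counts=True)
    keep = set()
    border = set()
    if exclude_border and labels.size:
        edges = np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
        ])
        border = set(int(v) for v in np.unique(edges) if v > 0)
    for i, c in zip(ids, counts):
        if i == 0:
            continue
        if c < min_area_px or int(i) in border:
            labels[labels == i] = 0
        else:
            keep.add(int(i))
    relabelled, n = _relabel_raster_order(labels)
    return LabelMask(labels=relabelled, n_cells=n)


@dataclass
class CellView:
    """Pixels of one cell across channels, with geometry.

    ``pixels[role]`` is the 1D array of member intensities; ``rasters[role]``
    is the bounding-box crop with ``mask`` marking membership.  Bounding box
    is half-open ``(rmin, rmax, cmin, cmax)`` in 0-based row/col coordinates.
    """

    cell_id: int
    coords: np.ndarray           # (n_pixels, 2) row/col
    pixels: dict                 # role -> (n_pixels,) intensities
    rasters: dict                # role -> cropped 2D array
    mask: np.ndarray             # cropped boolean membership
    bbox: tuple                  # (rmin, rmax, cmin, cmax), half-open
    centroid: tuple              # (row, col), unweighted mean of coords


def extract_cell(image_set, mask: LabelMask, cell_id: int) -> CellView:
    """Restrict every channel to the pixels of one labelled cell."""
    if cell_id < 1 or cell_id > mask.n_cells:
        raise KeyError(f"cell_id {cell_id} not in mask (n_cells={mask.n_cells})")
    member = mask.labels == cell_id
    if not member.any():
        raise KeyError(f"cell_id {cell_id} has no pixels")
    rows, cols = np.nonzero(member)
    rmin, rmax = rows.min(), rows.max() + 1
    cmin, cmax = cols.min(), cols.max() + 1
    sub = member[rmin:rmax, cmin:cmax]
    pixels = {}
    rasters = {}
    for role, img in image_set.channels.items():
        arr = np.asarray(img, dtype=np.float64)
        if arr.shape != member.shape:
            raise ValidationError(
                f"channel {role!r} shape {arr.shape} differs from mask {member.shape}"
            )
        pixels[role] = arr[member]
        rasters[role] = arr[rmin:rmax, cmin:cmax].copy()
    return CellView(
        cell_id=cell_id,
        coords=np.column_stack([rows, cols]),
        pixels=pixels,
        rasters=rasters,
        mask=sub,
        bbox=(int(rmin), int(rmax), int(cmin), int(cmax)),
        centroid=(float(rows.mean()), float(cols.mean())),
    )


def iter_cells(image_set, mask: LabelMask):
    for cid in range(1, mask.n_cells + 1):
        yield extract_cell(image_set, mask, cid)
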