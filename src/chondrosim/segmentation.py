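"""Classical automated 3D cell segmentation.

Pipeline: isotropic resampling -> denoise/flatten/stretch -> global
auto-threshold -> physical-unit artifact filters (per-slice area, 3D
volume) -> hole filling and distance-transform watershed -> moment-based
3D ellipsoid fitting.  All size thresholds are in physical units (µm²,
µm³) so the filters behave identically across resolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure, morphology, segmentation as skseg

from .types import EllipsoidCell, EllipsoidSet, ImageStack, LabeledVolume

THRESHOLD_METHODS = {
    "otsu": skfilters.threshold_otsu,
    "li": skfilters.threshold_li,
    "yen": skfilters.threshold_yen,
    "triangle": skfilters.threshold_triangle,
    "isodata": skfilters.threshold_isodata,
    "mean": skfilters.threshold_mean,
}


@dataclass
class SegmentationConfig:
    """Parameters of the classical chain.

    slice_area_max: per-slice 2D components larger than this (µm²) are
        removed as gigantic artifacts.
    volume_min: 3D components smaller than this (µm³) are removed as noise.
    threshold_method: key into THRESHOLD_METHODS (default Otsu).
    watershed_h: h-maxima suppression depth for seeding, in µm of
        distance-transform height.
    smoothing_sigma: Gaussian denoising width, µm.
    background_order: polynomial order of the illumination-surface fit
        (2 captures linear and bilinear shading exactly).
    background_percentile: voxels at or below this intensity percentile are
        treated as background when fitting the illumination surface.
    stretch_percentiles: contrast stretch limits.
    """

    slice_area_max: float = 300.0
    volume_min: float = 200.0
    threshold_method: str = "otsu"
    watershed_h: float = 1.0
    smoothing_sigma: float = 0.5
    background_order: int = 2
    background_percentile: float = 60.0
    stretch_percentiles: tuple[float, float] = (1.0, 99.8)
    denoise: bool = True
    flatten_background: bool = True
    stretch_contrast: bool = True

    def __post_init__(self) -> None:
        if self.slice_area_max <= 0 or self.volume_min <= 0:
            raise ValueError("filter thresholds must be positive")


def resample_isotropic(stack: ImageStack, order: int = 1) -> ImageStack:
    """Resample to isotropic voxels equal to min(voxel_size).

    Physical extent is preserved within one voxel per axis.  Returns the
    input unchanged when it is already isotropic.
    """
    vox = stack.voxel_size
    if stack.data.shape[0] < 2:
        raise ValueError("cannot resample a single-slice stack along z")
    target = float(np.min(vox))
    if np.allclose(vox, target):
        return stack
    zoom = vox / target
    data = ndimage.zoom(stack.data.astype(float), zoom, order=order, grid_mode=True,
                        mode="nearest")
    data = np.clip(data, 0, 2**stack.bit_depth - 1)
    return ImageStack(data.astype(stack.data.dtype), np.full(3, target), stack.bit_depth)


def _poly_features(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix in normalized coordinates up to total degree
    ``order`` (3 variables)."""
    z, y, x = coords.T
    cols = [np.ones_like(z)]
    if order >= 1:
        cols += [z, y, x]
    if order >= 2:
        cols += [z * y, z * x, y * x, z**2, y**2, x**2]
    return np.stack(cols, axis=1)


def _illumination_surface(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Least-squares polynomial fit to the low-intensity voxels, evaluated
    everywhere (subsampled for speed; deterministic)."""
    shape = np.array(img.shape)
    step = max(1, int(np.ceil((img.size / 200_000) ** (1 / 3))))
    sub = img[::step, ::step, ::step]
    grids = np.meshgrid(
        *[(np.arange(0, shape[a], step)) / max(shape[a] - 1, 1) for a in range(3)],
        indexing="ij",
    )
    coords = np.stack([gr.ravel() for gr in grids], axis=1)
    values = sub.ravel()
    mask = values <= np.percentile(values, cfg.background_percentile)
    phi = _poly_features(coords[mask], cfg.background_order)
    coeff, *_ = np.linalg.lstsq(phi, values[mask], rcond=None)
    full = np.meshgrid(
        *[np.arange(shape[a]) / max(shape[a] - 1, 1) for a in range(3)], indexing="ij"
    )
    full_coords = np.stack([gr.ravel() for gr in full], axis=1)
    return (_poly_features(full_coords, cfg.background_order) @ coeff).reshape(img.shape)


def preprocess(stack: ImageStack, cfg: SegmentationConfig | None = None) -> ImageStack:
    """Denoise, remove uneven illumination, and stretch contrast.

    Background flattening fits a low-order polynomial illumination surface
    to the low-intensity (background) voxels and subtracts it — exact for
    linear and bilinear shading and free of the boundary artifacts that
    large-kernel filters suffer on small stacks.  Each stage can be
    toggled in the config.
    """
    cfg = cfg or SegmentationConfig()
    img = stack.data.astype(float)
    vox = stack.voxel_size
    if cfg.denoise and cfg.smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.smoothing_sigma / vox)
    if cfg.flatten_background:
        img = img - _illumination_surface(img, cfg)
    if cfg.stretch_contrast:
        lo, hi = np.percentile(img, cfg.stretch_percentiles)
        if hi > lo:
            vmax = 2**stack.bit_depth - 1
            img = (img - lo) / (hi - lo) * vmax
    img = np.clip(img, 0, 2**stack.bit_depth - 1)
    return ImageStack(img, vox, stack.bit_depth)


def auto_threshold(
    stack: ImageStack, method: str = "otsu", invert: bool = False
) -> LabeledVolume:
    """Global automatic threshold into a 0/1 foreground mask."""
    data = np.asarray(stack.data, dtype=float)
    if np.all(data == data.flat[0]):
        raise ValueError("constant image: no threshold found")
    try:
        thresh_fn = THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}") from None
    t = thresh_fn(data)
    mask = data <= t if invert else data > t
    return LabeledVolume(mask.astype(np.int32), stack.voxel_size)


def filter_artifacts(mask: LabeledVolume, cfg: SegmentationConfig | None = None) -> LabeledVolume:
    """Remove gigantic per-slice artifacts and tiny 3D noise.

    First pass: 2D connected components (8-connectivity) with area above
    ``slice_area_max`` µm² are removed slice by slice.  Second pass: 3D
    components (26-connectivity) with volume below ``volume_min`` µm³ are
    removed.  Idempotent.
    """
    cfg = cfg or SegmentationConfig()
    vox = mask.voxel_size
    out = mask.labels > 0
    slice_area = float(vox[1] * vox[2])
    max_px = cfg.slice_area_max / slice_area
    for z in range(out.shape[0]):
        sl = out[z]
        if not sl.any():
            continue
        lab = measure.label(sl, connectivity=2)
        counts = np.bincount(lab.ravel())
        big = np.flatnonzero(counts > max_px)
        big = big[big > 0]
        if big.size:
            sl[np.isin(lab, big)] = False
    voxvol = float(np.prod(vox))
    min_vox = cfg.volume_min / voxvol
    lab3 = measure.label(out, connectivity=3)
    counts = np.bincount(lab3.ravel())
    small = np.flatnonzero(counts < min_vox)
    small = small[small > 0]
    if small.size:
        out[np.isin(lab3, small)] = False
    return LabeledVolume(out.astype(np.int32), vox)


def split_cells(mask: LabeledVolume, watershed_h: float = 1.0) -> LabeledVolume:
    """Fill holes and separate touching cells by distance-transform watershed.

    Seeds are the h-maxima of the Euclidean distance transform (physical
    sampling), which suppresses shallow maxima of depth < ``watershed_h`` µm;
    the watershed floods the inverted distance map within the filled mask.
    """
    binary = mask.labels > 0
    if not binary.any():
        return LabeledVolume(np.zeros_like(mask.labels, dtype=np.int32), mask.voxel_size)
    filled = ndimage.binary_fill_holes(binary)
    edt = ndimage.distance_transform_edt(filled, sampling=mask.voxel_size)
    # h-maxima suppression: regional maxima of the h-reconstruction form one
    # connected plateau across saddles shallower than h, so near-equal twin
    # peaks inside a single cell yield a single seed.
    hrec = morphology.reconstruction(edt - watershed_h, edt, method="dilation")
    peaks = morphology.local_maxima(hrec, connectivity=3) & filled
    markers, _ = ndimage.label(peaks, structure=np.ones((3, 3, 3), dtype=int))
    labels = skseg.watershed(-edt, markers, mask=filled)
    return LabeledVolume(labels.astype(np.int32), mask.voxel_size)


def fit_ellipsoids(labels: LabeledVolume, min_voxels: int = 4) -> EllipsoidSet:
    """Fit a solid ellipsoid to each labeled instance by second moments.

    Center = voxel centroid; axes from the eigen-decomposition of the voxel
    covariance (with the per-voxel uniform-cube term h²/12 added back), using
    semi_axis_i = sqrt(5·λ_i) for a uniform solid, then rescaled so the
    ellipsoid volume equals the labeled voxel volume exactly.
    """
    vox = labels.voxel_size
    voxvol = labels.voxel_volume
    cells: list[EllipsoidCell] = []
    lab = labels.labels
    objects = ndimage.find_objects(lab)
    for idx, sl in enumerate(objects):
        label = idx + 1
        if sl is None:
            continue
        where = np.nonzero(lab[sl] == label)
        n = where[0].size
        if n < min_voxels:
            warnings.warn(f"label {label}: only {n} voxels, skipped")
            continue
        coords = np.stack(
            [(where[a] + sl[a].start + 0.5) * vox[a] for a in range(3)], axis=1
        )
        center = coords.mean(axis=0)
        d = coords - center
        cov = d.T @ d / n + np.diag(vox**2) / 12.0
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] <= 0:
            warnings.warn(f"label {label}: degenerate voxel support, skipped")
            continue
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if np.linalg.det(evecs) < 0:
            evecs[:, -1] *= -1
        semi = np.sqrt(5.0 * evals)
        target_volume = n * voxvol
        scale = (target_volume / (4.0 / 3.0 * np.pi * np.prod(semi))) ** (1.0 / 3.0)
        cells.append(EllipsoidCell(center, semi * scale, evecs, label=label))
    box = vox * np.array(lab.shape)
    return EllipsoidSet(cells, box)


def segment_stack(
    stack: ImageStack, cfg: SegmentationConfig | None = None
) -> tuple[LabeledVolume, EllipsoidSet]:
    """Full classical chain: resample → preprocess → threshold → filters →
    watershed → ellipsoid fit."""
    cfg = cfg or SegmentationConfig()
    iso = resample_isotropic(stack) if stack.data.shape[0] >= 2 else stack
    pre = preprocess(iso, cfg)
    mask = auto_threshold(pre, cfg.threshold_method)
    mask = filter_artifacts(mask, cfg)
    labels = split_cells(mask, cfg.watershed_h)
    return labels, fit_ellipsoids(labels)
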