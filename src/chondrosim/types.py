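"""Core domain containers shared across the pipeline stages.

Axis convention: every 3-vector that refers to image or physical space is
ordered (z, y, x), matching numpy array axes of the image stacks.  Voxel
coordinates are 0-based and the physical center of voxel (i, j, k) is at
((i + 0.5) * dz, (j + 0.5) * dy, (k + 0.5) * dx) in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EllipsoidCell:
    """A single cell modelled as a solid ellipsoid.

    Parameters
    ----------
    center : (3,) array, µm, (z, y, x) order.
    semi_axes : (3,) array, µm, sorted a >= b >= c > 0.
    rotation : (3, 3) proper rotation matrix mapping body axes to lab axes;
        column i is the lab-frame direction of semi-axis i.
    label : positive integer instance id.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.center.shape != (3,) or self.semi_axes.shape != (3,):
            raise ValueError("center and semi_axes must be 3-vectors")
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.label <= 0:
            raise ValueError("label must be positive")

    @property
    def volume(self) -> float:
        """Analytic volume (4/3)·π·a·b·c in µm³."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    def contains(self, points: np.ndarray, inflate: float = 0.0) -> np.ndarray:
        """Membership test for an array of points, shape (..., 3), µm.

        ``inflate`` grows every semi-axis by that many µm (used as a
        touching tolerance).
        """
        pts = np.asarray(points, dtype=float)
        local = (pts - self.center) @ self.rotation  # rows: lab->body
        q = np.sum((local / (self.semi_axes + inflate)) ** 2, axis=-1)
        return q <= 1.0

    def surface_points(self, n: int = 1000) -> np.ndarray:
        """Deterministic quasi-uniform points on the ellipsoid surface.

        A Fibonacci sphere is mapped through the semi-axes and rotation;
        the mapping is not exactly area-uniform, which is acceptable for
        intersection probing.
        """
        i = np.arange(n, dtype=float)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        zc = 1.0 - 2.0 * (i + 0.5) / n
        r = np.sqrt(np.maximum(0.0, 1.0 - zc**2))
        unit = np.stack([zc, r * np.sin(phi), r * np.cos(phi)], axis=1)
        return self.center + (unit * self.semi_axes) @ self.rotation.T


@dataclass
class EllipsoidSet:
    """An ordered collection of ellipsoid cells in a rectangular box."""

    cells: list[EllipsoidCell] = field(default_factory=list)
    box: np.ndarray | None = None  # (3,) µm, (z, y, x)

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([c.volume for c in self.cells])

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cells], dtype=int)


@dataclass
class ImageStack:
    """3D intensity grid with anisotropic physical voxel size."""

    data: np.ndarray  # (nz, ny, nx), non-negative
    voxel_size: np.ndarray  # (3,) µm, (z, y, x)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3-dimensional")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the stack in µm, (z, y, x)."""
        return self.voxel_size * np.array(self.data.shape)


@dataclass
class LabeledVolume:
    """3D instance labels: 0 = background, k > 0 = cell instance k."""

    labels: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-dimensional")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def instance_labels(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    def volume_of(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume
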