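"""Spherical-surface <-> 2-D image reformatting.

Vertex-wise cortical maps live on a unit sphere per hemisphere.  To feed them
to convolutional layers they are resampled onto an H x W grid uniform in
azimuth ``a`` and in ``sin(elevation)`` — an equal-area-ish layout in which
each pixel covers roughly the same solid angle.  Resampling is
nearest-neighbour in both directions so the vertex->pixel->vertex roundtrip
is exactly invertible whenever every vertex owns the pixel nearest to it
(guaranteed in practice once H*W is a few times the vertex count).

Conventions: rows index sin(elevation) ascending (row 0 = south pole side),
columns index azimuth ascending (column 0 = the -pi side); azimuth wraps
circularly.  Pixels whose nearest mesh vertex lies on the medial wall are
invalid and always hold exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic import SurfaceMesh

__all__ = [
    "SphericalCoords",
    "ResamplingMap",
    "GridImage",
    "spherical_coords",
    "build_resampling_map",
    "to_grid",
    "from_grid",
    "profiles_to_images",
    "images_to_profiles",
]


@dataclass(frozen=True)
class SphericalCoords:
    """Per-vertex azimuth in [-pi, pi] and elevation in [-pi/2, pi/2]."""

    azimuth: np.ndarray
    elevation: np.ndarray


@dataclass(frozen=True)
class ResamplingMap:
    """Mutually consistent pixel<->vertex nearest-neighbour maps.

    ``pix2vert_*`` hold the global index of the nearest cortical vertex per
    pixel, or -1 where the nearest vertex is medial wall (invalid pixel).
    ``vert2pix`` holds, for every cortical vertex (in ``cortex_indices``
    order), the flat pixel index ``row * W + col`` within its hemisphere.
    """

    shape: tuple[int, int]
    pix2vert_left: np.ndarray    # (H, W) int, global vertex index
    pix2vert_right: np.ndarray   # (H, W) int
    pix2cortex_left: np.ndarray  # (H, W) int, position in the cortex-ordered vector
    pix2cortex_right: np.ndarray
    vert2pix: np.ndarray         # (n_cortex,) int, flat index within hemisphere
    vert_hemi: np.ndarray        # (n_cortex,) "L"/"R"
    mask_left: np.ndarray        # (H, W) bool, True = valid
    mask_right: np.ndarray

    @property
    def n_cortex(self) -> int:
        return self.vert2pix.shape[0]


@dataclass(frozen=True)
class GridImage:
    """A left/right pair of H x W images with valid-pixel masks.

    Invalid pixels hold exactly 0; values elsewhere are finite.
    """

    left: np.ndarray
    right: np.ndarray
    mask_left: np.ndarray
    mask_right: np.ndarray

    def __post_init__(self) -> None:
        for img, mask in ((self.left, self.mask_left), (self.right, self.mask_right)):
            if img.shape != mask.shape:
                raise ValueError("image and mask shapes disagree")
            if not np.isfinite(img[mask]).all():
                raise ValueError("non-finite values on valid pixels")
            if img[~mask].size and np.any(img[~mask] != 0):
                raise ValueError("invalid pixels must hold exactly 0")

    def stack(self) -> np.ndarray:
        """(2, H, W) array, left hemisphere first."""
        return np.stack([self.left, self.right])


def spherical_coords(mesh: SurfaceMesh, atol: float = 1e-6) -> SphericalCoords:
    """Cartesian -> (azimuth, elevation); atan2(0, 0) at a pole is fixed to 0."""
    norms = np.linalg.norm(mesh.coords, axis=1)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError("mesh coordinates must be unit vectors")
    x, y, z = mesh.coords.T
    a = np.arctan2(y, x)
    e = np.arcsin(np.clip(z, -1.0, 1.0))
    return SphericalCoords(azimuth=a, elevation=e)


def _pixel_centers(H: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    a = -np.pi + (np.arange(W) + 0.5) * (2 * np.pi / W)
    s = -1.0 + (np.arange(H) + 0.5) * (2.0 / H)
    return a, s


def build_resampling_map(
    coords: SphericalCoords, mesh: SurfaceMesh, H: int, W: int
) -> ResamplingMap:
    """Nearest-neighbour maps between grid pixels and mesh vertices.

    pixel->vertex: nearest vertex (chordal == great-circle) among ALL of that
    hemisphere's vertices; if it is medial wall the pixel is invalid.
    vertex->pixel: nearest pixel center in (azimuth, sin e) with circular
    azimuth wraparound.
    """
    if H < 2 or W < 2:
        raise ValueError("grid must be at least 2 x 2")
    a_centers, s_centers = _pixel_centers(H, W)
    e_centers = np.arcsin(s_centers)
    # pixel centers as 3-D unit vectors, shape (H, W, 3)
    ca, sa = np.cos(a_centers), np.sin(a_centers)
    ce, se = np.cos(e_centers), np.sin(e_centers)
    px = ce[:, None] * ca[None, :]
    py = ce[:, None] * sa[None, :]
    pz = np.broadcast_to(se[:, None], (H, W))
    pix_xyz = np.stack([px, py, pz], axis=-1).reshape(-1, 3)

    cortex = mesh.cortex_indices
    lookup = np.full(mesh.n_vertices + 1, -1, dtype=int)
    lookup[cortex] = np.arange(cortex.size)
    pix2vert, pix2cortex, masks = {}, {}, {}
    for hemi in ("L", "R"):
        verts = mesh.hemi_indices(hemi)
        tree = cKDTree(mesh.coords[verts])
        _, nn = tree.query(pix_xyz)
        nearest = verts[nn]
        valid = ~mesh.medial_mask[nearest]
        pix2vert[hemi] = np.where(valid, nearest, -1).reshape(H, W)
        pix2cortex[hemi] = lookup[pix2vert[hemi]]
        masks[hemi] = valid.reshape(H, W)
    a = coords.azimuth[cortex]
    s = np.sin(coords.elevation[cortex])
    da, ds = 2 * np.pi / W, 2.0 / H
    col = np.floor((a + np.pi) / da).astype(int) % W
    row = np.clip(np.floor((s + 1.0) / ds).astype(int), 0, H - 1)
    vert2pix = row * W + col
    return ResamplingMap(
        shape=(H, W),
        pix2vert_left=pix2vert["L"],
        pix2vert_right=pix2vert["R"],
        pix2cortex_left=pix2cortex["L"],
        pix2cortex_right=pix2cortex["R"],
        vert2pix=vert2pix,
        vert_hemi=mesh.hemisphere[cortex].copy(),
        mask_left=masks["L"],
        mask_right=masks["R"],
    )


def to_grid(values: np.ndarray, rmap: ResamplingMap) -> GridImage:
    """Paint a cortex-ordered per-vertex map onto the hemisphere image pair."""
    values = np.asarray(values, dtype=float)
    if values.shape != (rmap.n_cortex,):
        raise ValueError("value vector length does not match cortex size")
    out = {}
    for hemi, p2c, mask in (
        ("L", rmap.pix2cortex_left, rmap.mask_left),
        ("R", rmap.pix2cortex_right, rmap.mask_right),
    ):
        img = np.zeros(rmap.shape)
        img[mask] = values[p2c[mask]]
        out[hemi] = img
    return GridImage(left=out["L"], right=out["R"],
                     mask_left=rmap.mask_left, mask_right=rmap.mask_right)


def from_grid(image: GridImage, rmap: ResamplingMap) -> np.ndarray:
    """Read a per-vertex map back: each vertex takes its nearest pixel's value."""
    H, W = rmap.shape
    if image.left.shape != (H, W) or image.right.shape != (H, W):
        raise ValueError("image shape does not match resampling map")
    flat = {"L": image.left.ravel(), "R": image.right.ravel()}
    values = np.empty(rmap.n_cortex)
    for hemi in ("L", "R"):
        sel = rmap.vert_hemi == hemi
        values[sel] = flat[hemi][rmap.vert2pix[sel]]
    return values


def profiles_to_images(profiles: np.ndarray, rmap: ResamplingMap) -> np.ndarray:
    """Vectorized to_grid for a (n_samples, n_cortex) stack.

    Returns (n_samples, 2, H, W) with hemisphere channel order (L, R); the
    model consumes this array directly.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[1] != rmap.n_cortex:
        raise ValueError("profile length does not match cortex size")
    n = profiles.shape[0]
    H, W = rmap.shape
    out = np.zeros((n, 2, H, W))
    for c, (p2c, mask) in enumerate(
        ((rmap.pix2cortex_left, rmap.mask_left), (rmap.pix2cortex_right, rmap.mask_right))
    ):
        out[:, c][:, mask] = profiles[:, p2c[mask]]
    return out


def images_to_profiles(images: np.ndarray, rmap: ResamplingMap) -> np.ndarray:
    """Vectorized from_grid for a (n, 2, H, W) stack -> (n, n_cortex)."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    n, _, H, W = images.shape
    if (H, W) != rmap.shape:
        raise ValueError("image shape does not match resampling map")
    values = np.empty((n, rmap.n_cortex))
    for c, hemi in enumerate(("L", "R")):
        sel = rmap.vert_hemi == hemi
        flat = images[:, c].reshape(n, H * W)
        values[:, sel] = flat[:, rmap.vert2pix[sel]]
    return values
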