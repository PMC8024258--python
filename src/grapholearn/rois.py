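"""Region-of-interest geometry: spheres in mm space and hippocampus thirds.

Coordinates are millimetres in an MNI-like frame; voxel indices are 0-based.
A spherical ROI snaps its centre to the nearest voxel and keeps every voxel
whose centre lies within the radius of that snapped centre, so translating
the centre by an exact voxel step translates the mask rigidly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ROISpec:
    name: str
    kind: str = "sphere"  # sphere | mask | hippocampus_segment
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 5.0
    segment: str | None = None  # anterior | middle | posterior

    def __post_init__(self) -> None:
        if self.kind == "sphere":
            if self.center_mm is None or not np.all(np.isfinite(self.center_mm)):
                raise ValueError("sphere ROI needs a finite centre")
            if self.radius_mm <= 0:
                raise ValueError("sphere radius must be positive")


def mm_to_voxel(affine: np.ndarray, xyz_mm: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    hom = np.column_stack([xyz, np.ones(len(xyz))])
    return (hom @ inv.T)[:, :3]


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    hom = np.column_stack([ijk, np.ones(len(ijk))])
    return (hom @ np.asarray(affine, dtype=float).T)[:, :3]


def sphere_mask(spec: ROISpec, shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """Binary mask of voxels within ``radius_mm`` of the snapped sphere centre."""
    if spec.kind != "sphere":
        raise ValueError("sphere_mask needs a sphere ROISpec")
    center_vox = np.round(mm_to_voxel(affine, np.array(spec.center_mm))[0]).astype(int)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = voxel_to_mm(affine, coords)
    center_mm = voxel_to_mm(affine, center_vox[None, :])[0]
    dist = np.linalg.norm(mm - center_mm, axis=1)
    mask = (dist <= spec.radius_mm + 1e-9).reshape(shape)
    if not mask.any():
        raise ValueError(f"sphere ROI {spec.name!r} does not intersect the grid")
    return mask


def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """Integer offsets with squared Euclidean norm <= radius^2 (voxel units)."""
    r = int(np.floor(radius_voxels))
    grid = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(grid, grid, grid, indexing="ij")
    offs = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    keep = np.sum(offs**2, axis=1) <= radius_voxels**2 + 1e-9
    return offs[keep]


def split_hippocampus(mask: np.ndarray, affine: np.ndarray) -> dict[str, np.ndarray]:
    """Partition a hippocampus mask into thirds along the anterior–posterior axis.

    Slices (distinct y coordinates in mm, anterior = larger y) are grouped into
    three contiguous bins with voxel counts as equal as possible; when several
    splits tie, the extra slices go to the more anterior bins.  The three masks
    partition the input exactly.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty hippocampus mask")
    idx = np.argwhere(mask)
    y_mm = voxel_to_mm(affine, idx)[:, 1]
    # anterior first: descending y
    slices, inverse = np.unique(np.round(y_mm, 6), return_inverse=True)
    order = np.argsort(slices)[::-1]
    rank_of_slice = np.empty_like(order)
    rank_of_slice[order] = np.arange(len(order))
    slice_rank = rank_of_slice[inverse]  # 0 = most anterior slice
    n_slices = len(slices)
    if n_slices < 3:
        raise ValueError("hippocampus mask needs at least 3 distinct y slices")
    counts = np.bincount(slice_rank, minlength=n_slices).astype(float)
    total = counts.sum()
    cum = np.cumsum(counts)
    best = None
    for i in range(1, n_slices - 1):
        for j in range(i + 1, n_slices):
            sizes = (cum[i - 1], cum[j - 1] - cum[i - 1], total - cum[j - 1])
            imbalance = sum(abs(s - total / 3.0) for s in sizes)
            # ties resolved toward larger anterior bins
            key = (imbalance, -sizes[0], -sizes[1])
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    seg_of_rank = np.zeros(n_slices, dtype=int)
    seg_of_rank[i:j] = 1
    seg_of_rank[j:] = 2
    seg = seg_of_rank[slice_rank]
    out = {}
    for s, name in enumerate(["anterior", "middle", "posterior"]):
        m = np.zeros_like(mask)
        sel = idx[seg == s]
        m[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        out[name] = m
    return out
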