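"""Ordinal morphometry volumes and deterministic voxel-grid transforms.

A morphometry volume encodes each voxel of a brain on a common lattice as one
of five ordinal tissue codes: 0 background, 1 cerebrospinal fluid (CSF),
2 gray matter (GM), 3 white matter (WM), 4 lesion.  The lesion code supersedes
tissue wherever a lesion mask is set.  For model input the codes are mapped
affinely to [-1, 1].

The transforms here (merge, enantiomorphic fill, modal downsampling, common
cropping, min-max scaling) are the final preprocessing steps applied to
already-registered tissue + lesion grids; registration and segmentation of raw
scans are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np

#: allowed ordinal codes, in tie-break priority order (higher wins ties)
CODES = (0, 1, 2, 3, 4)
CODE_BACKGROUND, CODE_CSF, CODE_GM, CODE_WM, CODE_LESION = CODES
N_CODES = len(CODES)


class ShapeMismatchError(ValueError):
    pass


@dataclass
class MorphometryVolume:
    """3D ordinal tissue grid on a voxel lattice.

    Parameters
    ----------
    grid : ndarray of int
        Ordinal codes in {0..4}.
    voxel_size_mm : float
        Isotropic voxel edge length.
    scaled : ndarray of float32, optional
        Affine image of the codes with 0 -> -1 and 4 -> +1.
    orientation : str
        Axis descriptor; ``"LR"`` means axis 0 runs left to right, with the
        first half of the axis being the left hemisphere.
    """

    grid: np.ndarray
    voxel_size_mm: float = 8.0
    scaled: np.ndarray | None = None
    orientation: str = "LR"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.grid.ndim}")
        bad = ~np.isin(self.grid, CODES)
        if bad.any():
            raise ValueError(f"grid contains {bad.sum()} voxels outside codes {CODES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.grid != CODE_BACKGROUND

    def left_mask(self) -> np.ndarray:
        """Boolean mask of the left hemisphere (first half of axis 0)."""
        m = np.zeros(self.shape, dtype=bool)
        m[: self.shape[0] // 2] = True
        return m

    def copy(self) -> "MorphometryVolume":
        return MorphometryVolume(
            self.grid.copy(),
            self.voxel_size_mm,
            None if self.scaled is None else self.scaled.copy(),
            self.orientation,
        )


def mirror_index(i: int | np.ndarray, n: int) -> int | np.ndarray:
    """Index of the midsagittal mirror position along an axis of length n."""
    return n - 1 - i


def mirror_grid(grid: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.flip(grid, axis=axis)


def merge_tissue_and_lesion(
    tissue_grid: np.ndarray, lesion_mask: np.ndarray, voxel_size_mm: float = 8.0
) -> MorphometryVolume:
    """Combine a tissue grid (codes 0-3) with a binary lesion mask.

    Lesioned voxels receive code 4, superseding any tissue value.
    """
    tissue_grid = np.asarray(tissue_grid)
    lesion_mask = np.asarray(lesion_mask)
    if tissue_grid.shape != lesion_mask.shape:
        raise ShapeMismatchError(
            f"tissue {tissue_grid.shape} vs lesion {lesion_mask.shape}"
        )
    if not np.isin(lesion_mask, (0, 1)).all():
        raise ValueError("lesion_mask must be binary")
    merged = np.where(lesion_mask.astype(bool), CODE_LESION, tissue_grid)
    return MorphometryVolume(merged.astype(np.int16), voxel_size_mm)


def enantiomorphic_fill(
    volume: MorphometryVolume, lesion_mask: np.ndarray, smooth_radius: int = 0
) -> MorphometryVolume:
    """Replace tissue inside the (dilated) lesion mask with its mirror value.

    The lesion mask is dilated by ``smooth_radius`` voxels; inside the smoothed
    mask each voxel takes the value found at its midsagittal mirror position
    (reflection along axis 0).  A simplified, voxel-grid version of
    enantiomorphic lesion healing.
    """
    from scipy import ndimage

    lesion_mask = np.asarray(lesion_mask).astype(bool)
    if lesion_mask.shape != volume.shape:
        raise ShapeMismatchError("lesion mask shape differs from volume")
    region = lesion_mask
    if smooth_radius > 0:
        region = ndimage.binary_dilation(lesion_mask, iterations=smooth_radius)
    healed = volume.grid.copy()
    mirrored = mirror_grid(volume.grid, axis=0)
    healed[region] = mirrored[region]
    return MorphometryVolume(healed, volume.voxel_size_mm, None, volume.orientation)


def downsample_mode(volume: MorphometryVolume, factor: int) -> MorphometryVolume:
    """Reduce resolution by taking the modal code of each factor^3 block.

    Ties are broken by the larger code (lesion > WM > GM > CSF > background).
    Partial edge blocks use whatever voxels are available.  Voxel size is
    multiplied by the factor.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return volume.copy()
    g = volume.grid
    out_shape = tuple(-(-s // factor) for s in g.shape)
    # pad with a sentinel that never wins the vote
    pad = [(0, o * factor - s) for s, o in zip(g.shape, out_shape)]
    gp = np.pad(g, pad, constant_values=-1)
    blocks = gp.reshape(
        out_shape[0], factor, out_shape[1], factor, out_shape[2], factor
    ).transpose(0, 2, 4, 1, 3, 5).reshape(*out_shape, factor**3)
    counts = np.stack([(blocks == c).sum(axis=-1) for c in CODES], axis=-1)
    # argmax over reversed code order -> ties go to the larger code
    rev = counts[..., ::-1]
    mode = (N_CODES - 1) - np.argmax(rev, axis=-1)
    return MorphometryVolume(
        mode.astype(g.dtype), volume.voxel_size_mm * factor, None, volume.orientation
    )


def crop_common(
    volumes: Sequence[MorphometryVolume],
) -> tuple[list[MorphometryVolume], tuple[slice, slice, slice]]:
    """Crop planes that are background in *every* subject, identically for all.

    Returns the cropped volumes and the slice triple that was applied.
    """
    if len(volumes) == 0:
        raise ValueError("empty cohort")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape:
            raise ShapeMismatchError("volumes differ in shape")
    occupied = np.zeros(shape, dtype=bool)
    for v in volumes:
        occupied |= v.grid != CODE_BACKGROUND
    slices = []
    for ax in range(3):
        axes = tuple(a for a in range(3) if a != ax)
        line = occupied.any(axis=axes)
        nz = np.nonzero(line)[0]
        if len(nz) == 0:
            raise ValueError("cohort is entirely background")
        slices.append(slice(int(nz[0]), int(nz[-1]) + 1))
    sl = tuple(slices)
    out = [
        MorphometryVolume(v.grid[sl].copy(), v.voxel_size_mm, None, v.orientation)
        for v in volumes
    ]
    return out, sl  # type: ignore[return-value]


def scale_minmax(volume: MorphometryVolume) -> MorphometryVolume:
    """Attach the [-1, 1] affine image of the codes (0 -> -1, 4 -> +1)."""
    scaled = (volume.grid.astype(np.float32) / 2.0) - 1.0
    return replace(volume, grid=volume.grid, scaled=scaled)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_nifti(volume: MorphometryVolume, path: str) -> None:
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.int16), affine)
    nib.save(img, path)


def load_nifti(path: str, orientation: str = "LR") -> MorphometryVolume:
    img = nib.load(path)
    grid = np.asarray(img.dataobj).astype(np.int16)
    voxel = float(abs(img.affine[0, 0])) or 8.0
    return MorphometryVolume(grid, voxel, None, orientation)


def save_map_nifti(grid: np.ndarray, voxel_size_mm: float, path: str) -> None:
    """Write a float-valued map (e.g. saliency) as float32 NIfTI."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), path)
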