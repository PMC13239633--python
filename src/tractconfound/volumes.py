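"""Volumes, masks and the skeleton-projection / CSF-normalization stages.

Raw quantitative anisotropy (QA) maps carry an arbitrary acquisition-dependent
gain, and after standard-space registration white-matter bundles are only
approximately aligned to the template.  Two operations remove both nuisances:

* :func:`normalize_qa` divides every voxel by the participant's mean QA inside
  ventricular CSF, giving normalized QA (nQA) that is invariant to any global
  multiplicative scanner gain.
* :func:`project_to_skeleton` assigns to each voxel of the white-matter
  skeleton the highest nQA found nearby (a local-maximum search restricted to
  white matter), so that the bundle core is sampled even when the participant
  volume is slightly misaligned with the skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "Volume",
    "MaskSet",
    "normalize_qa",
    "project_to_skeleton",
    "load_volume",
    "save_volume",
    "load_mask",
]


@dataclass(frozen=True)
class GridSpec:
    """Isotropic sampling grid in standard space.

    The z-coordinate (mm) of voxel ``(i, j, k)`` is
    ``z_origin_mm + k * voxel_size_mm``; x/y origins are fixed at 0 because
    only the z axis carries anatomical meaning here (the internal-capsule
    slab is a z interval).
    """

    dims: tuple[int, int, int]
    voxel_size_mm: float
    z_origin_mm: float

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 16 for d in self.dims):
            raise ValueError(f"grid dims must be >= (16, 16, 16), got {self.dims}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    def z_coords(self) -> np.ndarray:
        """z-coordinates (mm) of voxel centers along the third axis."""
        return self.z_origin_mm + np.arange(self.dims[2]) * self.voxel_size_mm

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[2, 3] = self.z_origin_mm
        return aff


#: sentinel carried by skeletonized volumes outside the skeleton; NaN (never
#: 0) so that off-skeleton voxels can never leak into downstream means.
NO_DATA = np.nan


@dataclass
class Volume:
    """A 3-D scalar field (QA, nQA or streamline counts) on a :class:`GridSpec`.

    ``values`` may contain NaN only for skeletonized volumes, where NaN is the
    explicit off-skeleton no-data sentinel (see :data:`NO_DATA`).
    """

    values: np.ndarray
    grid: GridSpec
    skeletonized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not self.skeletonized and not np.all(np.isfinite(self.values)):
            raise ValueError("non-skeletonized volume must be finite everywhere")

    def copy_with(self, values: np.ndarray, *, skeletonized: bool | None = None) -> "Volume":
        return Volume(
            values=values,
            grid=self.grid,
            skeletonized=self.skeletonized if skeletonized is None else skeletonized,
        )


@dataclass
class MaskSet:
    """Boolean masks sharing one grid: CSF, skeleton, white matter, lesion."""

    csf: np.ndarray
    skeleton: np.ndarray
    white_matter: np.ndarray
    grid: GridSpec
    lesion: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("csf", "skeleton", "white_matter"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != self.grid.dims:
                raise ValueError(f"{name} mask shape {m.shape} != grid {self.grid.dims}")
            setattr(self, name, m)
        if self.lesion is not None:
            self.lesion = np.asarray(self.lesion, dtype=bool)
            if self.lesion.shape != self.grid.dims:
                raise ValueError("lesion mask shape mismatch")
        if np.any(self.csf & self.white_matter):
            raise ValueError("CSF and white-matter masks overlap")
        if np.any(self.skeleton & ~self.white_matter):
            raise ValueError("skeleton mask extends outside white matter")


def normalize_qa(qa: Volume, csf: np.ndarray) -> Volume:
    """Divide voxel-wise QA by the mean QA within ventricular CSF.

    The CSF signal reflects acquisition gain rather than pathology, so the
    ratio (nQA) is comparable across scans: scaling the input by any k > 0
    leaves the output unchanged.
    """
    csf = np.asarray(csf, dtype=bool)
    if csf.shape != qa.grid.dims:
        raise ValueError("CSF mask shape does not match the QA grid")
    if not csf.any():
        raise ValueError("CSF mask is empty; cannot normalize QA")
    csf_mean = float(qa.values[csf].mean())
    if csf_mean <= 0:
        raise ValueError(f"mean QA within the CSF mask is non-positive ({csf_mean:g})")
    return qa.copy_with(qa.values / csf_mean)


def project_to_skeleton(
    nqa: Volume, masks: MaskSet, search_radius_vox: int = 2
) -> Volume:
    """Project the highest nearby nQA value onto each skeleton voxel.

    Every skeleton voxel receives the maximum nQA over admissible voxels
    within a Chebyshev (cube) radius of ``search_radius_vox``.  Admissible
    donors are white-matter voxels off the skeleton, plus the skeleton voxel
    itself: excluding the *other* skeleton voxels keeps neighbouring search
    windows from chaining along a bundle core, which makes the projection
    idempotent.  Voxels inside a lesion mask are excluded so that necrotic
    near-zero tissue is never "rescued" by the projection.  Off-skeleton
    voxels carry the NaN no-data sentinel; so does a skeleton voxel with no
    admissible donor in reach (or no data of its own on a skeletonized
    input).
    """
    if search_radius_vox < 0:
        raise ValueError("search_radius_vox must be >= 0")
    if not masks.skeleton.any():
        raise ValueError("skeleton mask is empty; nothing to project onto")
    admissible = masks.white_matter.copy()
    if masks.lesion is not None:
        admissible &= ~masks.lesion
    values = np.where(np.isfinite(nqa.values), nqa.values, -np.inf)
    work = np.where(admissible & ~masks.skeleton, values, -np.inf)
    if search_radius_vox > 0:
        size = 2 * search_radius_vox + 1
        work = ndimage.maximum_filter(work, size=size, mode="constant", cval=-np.inf)
    self_vals = np.where(admissible, values, -np.inf)
    work = np.maximum(work, self_vals)
    out = np.full(nqa.grid.dims, NO_DATA)
    on_skel = work[masks.skeleton]
    out[masks.skeleton] = np.where(np.isfinite(on_skel), on_skel, NO_DATA)
    return nqa.copy_with(out, skeletonized=True)


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with voxel size and z-origin in the affine."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine())
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, *, skeletonized: bool = False) -> Volume:
    img = nib.load(str(path))
    aff = img.affine
    vs = float(aff[0, 0])
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = GridSpec(dims=data.shape, voxel_size_mm=vs, z_origin_mm=float(aff[2, 3]))
    return Volume(values=data, grid=grid, skeletonized=skeletonized)


def save_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine())
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    vol = load_volume(path)
    return vol.values > 0.5, vol.grid
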