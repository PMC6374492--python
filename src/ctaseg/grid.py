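"""Volumetric containers and NIfTI I/O.

All volumes live on axis-aligned grids with array axis order (x, y, z) where
axis 0 is the left-right (sagittal-flip) axis, axis 1 anterior-posterior and
axis 2 superior-inferior.  Physical coordinates of voxel (i, j, k) are
``origin + (i, j, k) * spacing`` in millimetres.  Oblique direction matrices
are out of scope for the phantom-based pipeline; volumes loaded from NIfTI are
reoriented to this canonical axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

LR_AXIS = 0
CANONICAL_AXES = ("L-R", "A-P", "S-I")


class ParameterError(ValueError):
    """An operation was called with parameters violating a stated precondition."""


class EmptyMaskError(ValueError):
    """A mask required to be non-empty contained no positive voxels."""


class DegenerateVarianceError(ValueError):
    """In-mask intensities are constant; zero-mean/unit-variance scaling undefined."""


class GridMismatchError(ValueError):
    """Two volumes expected on congruent grids differ in shape/spacing/origin."""


class ConfigurationError(ValueError):
    """A network or pipeline configuration is internally inconsistent."""


class RegistrationConvergenceWarning(UserWarning):
    """Rigid registration hit its iteration cap before meeting tolerance."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities; finite.
    spacing_mm : tuple of 3 floats
        Voxel edge lengths, all positive.
    origin_mm : tuple of 3 floats
        Physical position of voxel (0, 0, 0).
    axes : tuple of 3 str
        Anatomical label of each array axis; axis 0 must be the L-R axis.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ParameterError(f"expected a 3D array, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError(f"spacing must be positive, got {self.spacing_mm}")
        if sorted(self.axes) != sorted(CANONICAL_AXES):
            raise ParameterError(f"axes must be a permutation of {CANONICAL_AXES}")
        if self.axes[LR_AXIS] != "L-R":
            raise ParameterError("axis 0 must be the L-R axis in canonical order")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel data."""
        return replace(self, values=values)

    def grid_congruent(self, other: "ImageVolume | BinaryMask", atol: float = 1e-6) -> bool:
        o = other if isinstance(other, ImageVolume) else other.volume
        return (
            self.shape == o.shape
            and np.allclose(self.spacing_mm, o.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, o.origin_mm, atol=atol)
        )

    def require_congruent(self, other, name: str = "volume") -> None:
        if not self.grid_congruent(other):
            raise GridMismatchError(
                f"{name} grid mismatch: {self.shape}/{self.spacing_mm}/{self.origin_mm} "
                f"vs {other.shape}/{other.spacing_mm}/{other.origin_mm}"
            )


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} labelling on an :class:`ImageVolume` grid."""

    volume: ImageVolume

    def __post_init__(self):
        vals = np.unique(self.volume.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise ParameterError(f"mask values must be in {{0,1}}, found {vals[:5]}")

    @classmethod
    def from_array(cls, arr: np.ndarray, like: ImageVolume) -> "BinaryMask":
        return cls(like.with_values(np.asarray(arr).astype(np.uint8)))

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    @property
    def shape(self):
        return self.volume.shape

    @property
    def spacing_mm(self):
        return self.volume.spacing_mm

    @property
    def origin_mm(self):
        return self.volume.origin_mm

    def as_bool(self) -> np.ndarray:
        return self.volume.values.astype(bool)

    @property
    def n_positive(self) -> int:
        return int(self.volume.values.sum())


# ASPECTS-analogue region names; atlas labels are 1..10 (left) and 11..20 (right).
ASPECTS_REGIONS = ("M1", "M2", "M3", "M4", "M5", "M6", "I", "L", "C", "IC")


def aspects_label_table() -> dict[str, int]:
    """Map 'L_M1' ... 'R_IC' to integer atlas labels 1..20."""
    table = {}
    for side_idx, side in enumerate(("L", "R")):
        for r_idx, name in enumerate(ASPECTS_REGIONS):
            table[f"{side}_{name}"] = side_idx * 10 + r_idx + 1
    return table


@dataclass(frozen=True)
class RegionAtlas:
    """Integer label volume of the 10 ASPECTS regions per hemisphere.

    Label 0 is background; labels 1-10 are the left-hemisphere regions
    (M1..M6, I, L, C, IC) and 11-20 their right-hemisphere homologues.
    """

    volume: ImageVolume
    label_table: dict[str, int] = field(default_factory=aspects_label_table)

    def __post_init__(self):
        labels = np.unique(self.volume.values)
        known = set(self.label_table.values()) | {0}
        unknown = [int(l) for l in labels if int(l) not in known]
        if unknown:
            raise ParameterError(f"atlas contains labels absent from table: {unknown}")

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    @property
    def n_regions(self) -> int:
        return len(self.label_table)

    def region_names(self) -> list[str]:
        return sorted(self.label_table, key=self.label_table.get)


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel lesion confidence in [0,1], zero outside the intracranial mask."""

    volume: ImageVolume
    mask: BinaryMask

    def __post_init__(self):
        v = self.volume.values
        if v.min() < 0 or v.max() > 1:
            raise ParameterError("probabilities must lie in [0,1]")
        self.volume.require_congruent(self.mask.volume, "probability-map mask")
        outside = v[~self.mask.as_bool()]
        if outside.size and np.abs(outside).max() > 0:
            raise ParameterError("probabilities outside the mask must be exactly 0")

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti(vol: ImageVolume, path) -> None:
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine), str(path))


def load_nifti(path) -> ImageVolume:
    """Load a NIfTI volume, reoriented to the canonical (L-R, A-P, S-I) axes."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return ImageVolume(data, tuple(float(z) for z in zooms), tuple(float(o) for o in origin))


def save_mask_nifti(mask: BinaryMask, path) -> None:
    save_nifti(mask.volume, path)


def load_mask_nifti(path) -> BinaryMask:
    vol = load_nifti(path)
    return BinaryMask.from_array(vol.values > 0.5, vol)
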