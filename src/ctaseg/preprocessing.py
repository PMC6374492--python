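"""Input conditioning for CTA-based lesion segmentation.

The chain reproduces the standard conditioning a patch-based 3D network
needs: intracranial (brain) mask estimation from the skull shell, cropping to
the brain bounding box, zero-mean/unit-variance scaling inside the mask,
isotropic resampling (linear for intensities, nearest-neighbour for masks and
atlases), and construction of the *hemispheric comparison volume* — the CTA
flipped left-right and rigidly registered back onto the original grid so that
every voxel sees its approximate contralateral homologue as an extra channel.

Rigid registration minimizes the mean-squared intensity difference over a
3-level multi-resolution pyramid (same-modality problem), via SimpleITK.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import (
    BinaryMask,
    EmptyMaskError,
    DegenerateVarianceError,
    ImageVolume,
    LR_AXIS,
    ParameterError,
    RegionAtlas,
    RegistrationConvergenceWarning,
)

logger = logging.getLogger(__name__)

# single-threaded ITK filters keep registration bit-reproducible
sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    ``target_spacing_mm`` defaults to 1.0 mm for desk-scale phantoms; clinical
    CTA-SI pipelines use 0.5 mm isotropic, reachable here by configuration.
    """

    target_spacing_mm: float = 1.0
    crop_margin_voxels: int = 4
    registration_pyramid: tuple[int, ...] = (4, 2, 1)
    registration_smoothing: tuple[float, ...] = (2.0, 1.0, 0.0)
    registration_max_iterations: int = 200
    registration_tolerance: float = 1e-5
    normalize_before_comparison: bool = True

    def __post_init__(self):
        if self.target_spacing_mm <= 0:
            raise ParameterError("target_spacing_mm must be positive")
        if len(self.registration_pyramid) != len(self.registration_smoothing):
            raise ParameterError("pyramid and smoothing schedules must have equal length")


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF transform (Euler angles + translation about a centre).

    Follows the resampling convention of ITK: the transform maps points of
    the *fixed* image domain into the *moving* image domain, so resampling a
    moving image with this transform pulls it onto the fixed grid.
    """

    rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    final_metric: float | None = None
    converged: bool = True

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center_mm)
        t.SetRotation(*self.rotation_rad)
        t.SetTranslation(self.translation_mm)
        return t

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler3DTransform(self.to_sitk().GetInverse())
        return RigidTransform(
            rotation_rad=(inv.GetAngleX(), inv.GetAngleY(), inv.GetAngleZ()),
            translation_mm=tuple(inv.GetTranslation()),
            center_mm=tuple(inv.GetCenter()),
        )

    def rotation_matrix(self) -> np.ndarray:
        return np.asarray(self.to_sitk().GetMatrix()).reshape(3, 3)

    def magnitude(self) -> tuple[float, float]:
        """(rotation angle in degrees, translation norm in mm) of the transform."""
        R = self.rotation_matrix()
        cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        angle_deg = float(np.degrees(np.arccos(cos_theta)))
        # displacement of the rotation centre measures pure translation
        t = self.to_sitk()
        c = np.asarray(self.center_mm)
        disp = np.asarray(t.TransformPoint(tuple(c))) - c
        return angle_deg, float(np.linalg.norm(disp))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform applying ``other`` first, then ``self``."""
        a, b = self.to_sitk(), other.to_sitk()
        R = self.rotation_matrix() @ other.rotation_matrix()
        offset = np.asarray(a.TransformPoint(b.TransformPoint((0.0, 0.0, 0.0))))
        e = sitk.Euler3DTransform()
        e.SetCenter((0.0, 0.0, 0.0))
        e.SetMatrix(tuple(R.ravel()))
        e.SetTranslation(tuple(offset))
        return RigidTransform(
            rotation_rad=(e.GetAngleX(), e.GetAngleY(), e.GetAngleZ()),
            translation_mm=tuple(e.GetTranslation()),
            center_mm=(0.0, 0.0, 0.0),
        )


# ---------------------------------------------------------------------------
# SimpleITK bridging (array axis order here is (x,y,z); sitk arrays are z,y,x)
# ---------------------------------------------------------------------------

def to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing_mm)
    img.SetOrigin(vol.origin_mm)
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def estimate_brain_mask(vol: ImageVolume) -> BinaryMask:
    """Approximate the intracranial space from a head volume.

    The bright skull shell is thresholded, its interior is taken by hole
    filling, and the largest connected low-to-mid-intensity component inside
    the shell becomes the mask (itself hole-filled, so ventricles and sulci
    stay included).
    """
    v = vol.values
    vmax = np.percentile(v, 99.9)
    if vmax <= 0:
        raise EmptyMaskError("volume has no bright skull shell; cannot estimate brain mask")
    # midway between parenchymal and skull intensity; robust to the shell
    # being smoothed by resampling or pose interpolation
    skull = v > 0.5 * vmax
    filled = ndimage.binary_fill_holes(skull)
    interior = filled & ~skull
    if not interior.any():
        # thin or interpolation-blurred shells can rasterize with pinholes;
        # seal them morphologically before filling
        skull = ndimage.binary_closing(skull, structure=np.ones((3, 3, 3)))
        filled = ndimage.binary_fill_holes(skull)
        interior = filled & ~skull
    labels, n = ndimage.label(interior)
    if n == 0:
        raise EmptyMaskError("no enclosed intracranial component found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = ndimage.binary_fill_holes(labels == np.argmax(counts))
    return BinaryMask.from_array(mask, vol)


def normalize_in_mask(vol: ImageVolume, mask: BinaryMask) -> ImageVolume:
    """Scale so the in-mask voxels have zero mean and unit variance.

    The same affine intensity map x -> (x - mean)/sd is applied to every
    voxel, in and out of the mask.
    """
    vol.require_congruent(mask.volume, "normalization mask")
    m = mask.as_bool()
    if not m.any():
        raise EmptyMaskError("cannot normalize within an empty mask")
    inside = vol.values[m]
    mu, sd = float(inside.mean()), float(inside.std())
    if sd == 0:
        raise DegenerateVarianceError("in-mask intensities are constant")
    return vol.with_values((vol.values - mu) / sd)


def resample(
    vol: ImageVolume,
    config: PreprocessConfig,
    interpolation: str = "linear",
    target_spacing_mm: float | None = None,
) -> ImageVolume:
    """Resample to isotropic target spacing (linear or nearest)."""
    target = config.target_spacing_mm if target_spacing_mm is None else target_spacing_mm
    if target <= 0:
        raise ParameterError("target spacing must be positive")
    img = to_sitk(vol)
    new_size = [
        max(1, int(np.ceil(n * s / target)))
        for n, s in zip(vol.shape, vol.spacing_mm)
    ]
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target,) * 3,
        img.GetDirection(),
        float(np.min(vol.values)),
        sitk.sitkFloat64,
    )
    return from_sitk(out)


def resample_to_reference(
    vol: ImageVolume,
    reference: ImageVolume,
    interpolation: str = "linear",
    transform: RigidTransform | None = None,
) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``reference`` (optionally transformed)."""
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    t = transform.to_sitk() if transform is not None else sitk.Transform()
    out = sitk.Resample(
        to_sitk(vol), to_sitk(reference), t, interp, float(np.min(vol.values)), sitk.sitkFloat64
    )
    return from_sitk(out)


def sagittal_flip(vol: ImageVolume) -> ImageVolume:
    """Mirror the volume along its left-right axis (array reversal; exact involution)."""
    return vol.with_values(vol.values[::-1, :, :].copy())


def rigid_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    config: PreprocessConfig = PreprocessConfig(),
    fixed_mask: BinaryMask | None = None,
) -> RigidTransform:
    """6-DOF registration of ``moving`` onto ``fixed``.

    Mean-squared-difference metric (same modality), multi-resolution pyramid,
    regular-step gradient descent.  Emits a
    :class:`RegistrationConvergenceWarning` when the iteration cap is reached.
    """
    f = sitk.Cast(to_sitk(fixed), sitk.sitkFloat64)
    m = sitk.Cast(to_sitk(moving), sitk.sitkFloat64)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    if fixed_mask is not None:
        reg.SetMetricFixedMask(sitk.Cast(to_sitk(fixed_mask.volume), sitk.sitkUInt8))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=config.registration_tolerance,
        numberOfIterations=config.registration_max_iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.registration_pyramid))
    reg.SetSmoothingSigmasPerLevel(list(config.registration_smoothing))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()

    init = sitk.Euler3DTransform(
        sitk.CenteredTransformInitializer(
            f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
        )
    )
    reg.SetInitialTransform(init, inPlace=True)
    reg.Execute(f, m)
    final = init
    iters = reg.GetOptimizerIteration()
    metric = float(reg.GetMetricValue())
    converged = iters < config.registration_max_iterations
    if not converged:
        warnings.warn(
            f"rigid registration hit the iteration cap ({iters}); final metric {metric:.4g}",
            RegistrationConvergenceWarning,
        )
    logger.info("rigid_register: iterations=%d metric=%.6g converged=%s", iters, metric, converged)
    return RigidTransform(
        rotation_rad=(final.GetAngleX(), final.GetAngleY(), final.GetAngleZ()),
        translation_mm=tuple(final.GetTranslation()),
        center_mm=tuple(final.GetCenter()),
        final_metric=metric,
        converged=converged,
    )


def apply_transform(
    vol: ImageVolume,
    t: RigidTransform,
    interpolation: str = "linear",
    reference: ImageVolume | None = None,
) -> ImageVolume:
    """Resample a volume through a rigid transform onto a reference grid."""
    return resample_to_reference(vol, reference if reference is not None else vol, interpolation, t)


def registration_metric(moving: ImageVolume, fixed: ImageVolume, t: RigidTransform | None = None) -> float:
    """Mean-squared intensity difference after (optionally) transforming moving."""
    resampled = apply_transform(moving, t, "linear", fixed) if t is not None else resample_to_reference(moving, fixed)
    return float(np.mean((resampled.values - fixed.values) ** 2))


def make_hemispheric_comparison(
    cta: ImageVolume,
    mask: BinaryMask,
    config: PreprocessConfig = PreprocessConfig(),
) -> ImageVolume:
    """Build the hemispheric comparison channel.

    The CTA is flipped left-right, then rigidly registered back onto the
    original so each voxel carries its approximate contralateral homologue.
    For a perfectly symmetric head the result equals the input up to noise.
    """
    if not mask.as_bool().any():
        raise EmptyMaskError("hemispheric comparison needs a non-empty brain mask")
    flipped = sagittal_flip(cta)
    t = rigid_register(flipped, cta, config, fixed_mask=mask)
    return apply_transform(flipped, t, "linear", cta)


def crop_to_brain(vol: ImageVolume, mask: BinaryMask, margin_voxels: int = 0) -> ImageVolume:
    """Crop to the mask bounding box dilated by a voxel margin.

    The origin is shifted so physical coordinates of retained voxels are
    unchanged.
    """
    vol.require_congruent(mask.volume, "crop mask")
    m = mask.as_bool()
    if not m.any():
        raise EmptyMaskError("cannot crop to an empty mask")
    slices = []
    offset = []
    for ax in range(3):
        proj = np.any(m, axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        lo = max(0, idx[0] - margin_voxels)
        hi = min(vol.shape[ax], idx[-1] + 1 + margin_voxels)
        slices.append(slice(lo, hi))
        offset.append(lo)
    new_origin = tuple(
        o + lo * s for o, lo, s in zip(vol.origin_mm, offset, vol.spacing_mm)
    )
    return ImageVolume(vol.values[tuple(slices)].copy(), vol.spacing_mm, new_origin, vol.axes)


# ---------------------------------------------------------------------------
# whole-case conditioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessedCase:
    """Grid-congruent conditioned channels and resampled truth for one case."""

    case_id: str
    group: str
    channels: dict  # name -> ImageVolume ("cta", "hemi", "ncct")
    brain_mask: BinaryMask
    lesion_mask: BinaryMask
    atlas: RegionAtlas
    registration_log: dict = field(default_factory=dict)


def preprocess_case(case, config: PreprocessConfig = PreprocessConfig(), channels=("cta", "hemi", "ncct")) -> PreprocessedCase:
    """Run the full conditioning chain on one phantom case.

    Steps: estimate the brain mask from the raw CTA, crop everything to the
    brain bounding box, resample to isotropic target spacing (linear for
    images, nearest for masks/atlas), standardize intensities in the mask,
    rigidly register the NCCT onto the CTA, and derive the hemispheric
    comparison channel from the normalized CTA.
    """
    est_mask = estimate_brain_mask(case.cta)

    cta_c = crop_to_brain(case.cta, est_mask, config.crop_margin_voxels)
    ref = resample(cta_c, config, "linear")

    def on_ref(vol, interp):
        return resample_to_reference(crop_to_brain(vol, est_mask, config.crop_margin_voxels), ref, interp)

    mask_r = BinaryMask.from_array(on_ref(est_mask.volume, "nearest").values > 0.5, ref)
    lesion_r = BinaryMask.from_array(on_ref(case.lesion_mask.volume, "nearest").values > 0.5, ref)
    atlas_r = RegionAtlas(ref.with_values(on_ref(case.atlas.volume, "nearest").values.astype(np.int16)))

    cta_n = normalize_in_mask(ref, mask_r)
    out = {"cta": cta_n}
    reg_log = {}

    if "hemi" in channels:
        src = cta_n if config.normalize_before_comparison else ref
        flipped = sagittal_flip(src)
        t = rigid_register(flipped, src, config, fixed_mask=mask_r)
        hemi = apply_transform(flipped, t, "linear", src)
        if not config.normalize_before_comparison:
            hemi = normalize_in_mask(hemi, mask_r)
        out["hemi"] = hemi
        reg_log["hemi"] = {"metric": t.final_metric, "converged": t.converged}

    if "ncct" in channels:
        ncct_c = crop_to_brain(case.ncct, est_mask, config.crop_margin_voxels)
        ncct_r = resample_to_reference(ncct_c, ref, "linear")
        t = rigid_register(ncct_r, ref, config, fixed_mask=mask_r)
        ncct_reg = apply_transform(ncct_r, t, "linear", ref)
        out["ncct"] = normalize_in_mask(ncct_reg, mask_r)
        reg_log["ncct"] = {"metric": t.final_metric, "converged": t.converged}

    for name, vol in out.items():
        logger.info(
            "preprocess %s channel %s: shape=%s spacing=%s", case.case_id, name, vol.shape, vol.spacing_mm
        )
    return PreprocessedCase(
        case_id=case.case_id,
        group=case.group,
        channels=out,
        brain_mask=mask_r,
        lesion_mask=lesion_r,
        atlas=atlas_r,
        registration_log=reg_log,
    )
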