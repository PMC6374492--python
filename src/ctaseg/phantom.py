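"""Synthetic head phantoms for stroke-lesion segmentation experiments.

The generator produces bilaterally near-symmetric "brains" — nested ellipsoids
with a bright skull shell, CSF-filled ventricles and sulcal grooves — carrying
a unilateral hypoattenuated lesion (group A) or only symmetric aging
confounders (group B): periventricular white-matter hypoattenuation and
widened cortical sulci, the two structures known to drive false positives in
CTA-based lesion detection.  Each case comes with ground-truth lesion and
brain masks and a 20-region ASPECTS-analogue atlas, so the full pipeline is
testable without clinical data.

Intensities are pseudo-HU arbitrary units (parenchyma 35, CSF 5, skull 100);
downstream normalization makes only relative contrast matter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import (
    ASPECTS_REGIONS,
    BinaryMask,
    ImageVolume,
    ParameterError,
    RegionAtlas,
    save_mask_nifti,
    save_nifti,
)

PARENCHYMA = 35.0
CSF = 5.0
SKULL = 100.0
BACKGROUND = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head.

    ``lesion_contrast`` is the fractional intensity drop inside the lesion
    (0.3 means lesion tissue at 70% of parenchymal intensity).  Confounder
    severities are in [0, 1].  ``pose_perturbation`` is (max rotation deg,
    max translation mm) of a random rigid head-pose offset applied jointly to
    image and masks.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_present: bool = True
    lesion_side: str = "left"
    lesion_radius_mm: float = 12.0
    lesion_contrast: float = 0.35
    confounder_periventricular: float = 0.5
    confounder_sulcal: float = 0.5
    noise_sd: float = 2.0
    pose_perturbation: tuple[float, float] = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if any(n < 32 for n in self.grid_shape):
            raise ParameterError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError(f"spacing must be positive, got {self.spacing_mm}")
        if self.lesion_side not in ("left", "right"):
            raise ParameterError(f"lesion_side must be left|right, got {self.lesion_side!r}")
        if not (0.0 < self.lesion_contrast < 1.0):
            raise ParameterError("lesion_contrast must lie in (0,1)")
        for name in ("confounder_periventricular", "confounder_sulcal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0,1], got {v}")


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic subject: image channels, ground truth and atlas."""

    case_id: str
    group: str  # "A" (lesioned) or "B" (confounders only)
    cta: ImageVolume
    ncct: ImageVolume
    lesion_mask: BinaryMask
    brain_mask: BinaryMask
    atlas: RegionAtlas
    spec: PhantomSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grids_mm(shape, spacing):
    """Physical coordinates relative to the grid centre, one array per axis."""
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*coords, indexing="ij")


def _head_semiaxes(shape, spacing):
    extent = np.asarray(shape) * np.asarray(spacing)
    outer = 0.46 * extent
    # skull shell 2-5 mm, but never thinner than ~2 voxels or it rasterizes open
    t_min = max(2.0, 1.8 * float(np.max(spacing)))
    inner = outer - np.clip(0.08 * outer, t_min, max(5.0, t_min))
    return outer, inner


def _ellipsoid_rho(x, y, z, center, semiaxes):
    return np.sqrt(
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    )


def _lesion_semiaxes(radius_mm: float) -> np.ndarray:
    # Slightly anisotropic (MCA-territory-like) ellipsoid with the same
    # volume as a sphere of the requested radius: product of factors ~ 1.
    return radius_mm * np.array([0.78, 1.25, 1.03])


def _lesion_center(side: str, inner: np.ndarray) -> np.ndarray:
    sx = -1.0 if side == "left" else 1.0
    return np.array([sx * 0.45 * inner[0], 0.0, 0.0])


def max_lesion_radius_mm(spec: PhantomSpec) -> float:
    """Largest lesion radius that fits inside one hemisphere of this phantom."""
    _, inner = _head_semiaxes(spec.grid_shape, spec.spacing_mm)
    semi = _lesion_semiaxes(1.0)  # per-mm extent factors
    # stay off the midline ...
    r_mid = (0.5 * inner[0] - 1.0) / semi[0]
    # ... and inside the brain ellipsoid (conservative axis-wise bound)
    center_rho = 0.45  # lesion centred at 0.45 of the x semi-axis
    r_fit = (0.97 - center_rho) * float(np.min(inner / semi))
    return max(0.0, min(r_mid, r_fit))


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _rigid_resample(arr, angles_rad, shift_mm, spacing, order):
    """Rotate about the grid centre then translate, resampling in-place grid."""
    if not np.any(angles_rad) and not np.any(shift_mm):
        return arr
    cx, cy, cz = angles_rad
    rx = np.array([[1, 0, 0], [0, np.cos(cx), -np.sin(cx)], [0, np.sin(cx), np.cos(cx)]])
    ry = np.array([[np.cos(cy), 0, np.sin(cy)], [0, 1, 0], [-np.sin(cy), 0, np.cos(cy)]])
    rz = np.array([[np.cos(cz), -np.sin(cz), 0], [np.sin(cz), np.cos(cz), 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    sp = np.asarray(spacing, dtype=float)
    # affine_transform works in index space: map output index -> input index
    mat = np.diag(1.0 / sp) @ rot @ np.diag(sp)
    center = (np.asarray(arr.shape) - 1) / 2.0
    offset = center - mat @ center - (np.asarray(shift_mm) / sp)
    return ndimage.affine_transform(arr, mat, offset=offset, order=order, mode="constant", cval=arr.flat[0] * 0)


def generate_phantom(spec: PhantomSpec, case_id: str = "case", group: str | None = None) -> PhantomCase:
    """Render one phantom head from its spec.

    Deterministic: the same spec (including seed) yields bit-identical
    volumes.  Raises :class:`ParameterError` when the requested lesion cannot
    fit inside the requested hemisphere.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    x, y, z = _grids_mm(shape, spacing)
    outer, inner = _head_semiaxes(shape, spacing)

    rho_out = _ellipsoid_rho(x, y, z, (0, 0, 0), outer)
    rho_in = _ellipsoid_rho(x, y, z, (0, 0, 0), inner)
    brain = rho_in < 1.0
    skull = (rho_out < 1.0) & ~brain

    img = np.full(shape, BACKGROUND)
    img[skull] = SKULL
    img[brain] = PARENCHYMA

    # --- ventricles: mirrored CSF ellipsoids around the midline -----------
    v_semi = np.array([0.10 * inner[0], 0.32 * inner[1], 0.14 * inner[2]])
    rho_v = np.minimum(
        _ellipsoid_rho(x, y, z, (-0.16 * inner[0], 0.05 * inner[1], 0.0), v_semi),
        _ellipsoid_rho(x, y, z, (+0.16 * inner[0], 0.05 * inner[1], 0.0), v_semi),
    )
    ventricles = brain & (rho_v < 1.0)
    img[ventricles] = CSF

    # --- periventricular white-matter hypoattenuation (symmetric) ---------
    sev_pv = spec.confounder_periventricular
    if sev_pv > 0:
        rim = brain & (rho_v >= 1.0) & (rho_v < 1.6)
        ramp = np.clip((1.6 - rho_v) / 0.6, 0.0, 1.0)
        drop = 0.5 * sev_pv * (PARENCHYMA - CSF)
        img[rim] -= (drop * ramp)[rim]

    # --- widened cortical sulci (symmetric radial grooves) -----------------
    sev_su = spec.confounder_sulcal
    if sev_su > 0:
        u = np.arctan2(z, y)  # angle in the coronal-ish plane; even in x
        groove_angle = np.cos(9.0 * u) > 0.955
        depth = 0.10 + 0.12 * sev_su  # fraction of brain radius invaded
        sulci = brain & ~ventricles & groove_angle & (rho_in > 1.0 - depth)
        img[sulci] = CSF + (1.0 - sev_su) * 0.4 * (PARENCHYMA - CSF)

    # --- unilateral hypoattenuated lesion ----------------------------------
    lesion = np.zeros(shape, dtype=bool)
    if spec.lesion_present:
        r_max = max_lesion_radius_mm(spec)
        if spec.lesion_radius_mm > r_max:
            raise ParameterError(
                f"lesion_radius_mm={spec.lesion_radius_mm:.1f} cannot fit inside the "
                f"{spec.lesion_side} hemisphere of this phantom (max {r_max:.1f} mm): "
                "lesion must not cross the midsagittal plane nor the brain surface"
            )
        center = _lesion_center(spec.lesion_side, inner)
        semi = _lesion_semiaxes(spec.lesion_radius_mm)
        rho_l = _ellipsoid_rho(x, y, z, center, semi)
        hemisphere = x < 0 if spec.lesion_side == "left" else x > 0
        lesion = (rho_l < 1.0) & brain & hemisphere
        img[lesion] *= (1.0 - spec.lesion_contrast)

    # --- ASPECTS-analogue atlas: 4 deep blobs + 6 cortical wedges per side --
    atlas_arr = np.zeros(shape, dtype=np.int16)
    deep = rho_in < 0.45
    wedge = (np.floor((np.arctan2(z, y) + np.pi) / (2 * np.pi / 6))).astype(int) % 6
    deep_idx = 2 * (y > 0).astype(int) + (z > 0).astype(int)
    # deep quadrants -> I, L, C, IC (indices 6..9 of ASPECTS_REGIONS)
    deep_label = 6 + deep_idx
    region_idx = np.where(deep, deep_label, wedge)
    side_offset = np.where(x < 0, 0, 10)  # left labels 1-10, right 11-20
    atlas_arr[brain] = (region_idx + side_offset + 1)[brain]

    # --- pose perturbation (joint), noise, NCCT rendering -------------------
    max_deg, max_mm = spec.pose_perturbation
    angles = np.deg2rad(rng.uniform(-max_deg, max_deg, size=3))
    shifts = rng.uniform(-max_mm, max_mm, size=3)
    img_p = _rigid_resample(img, angles, shifts, spacing, order=1)
    brain_p = _rigid_resample(brain.astype(np.uint8), angles, shifts, spacing, order=0)
    lesion_p = _rigid_resample(lesion.astype(np.uint8), angles, shifts, spacing, order=0)
    atlas_p = _rigid_resample(atlas_arr, angles, shifts, spacing, order=0)

    cta_arr = img_p + rng.normal(0.0, spec.noise_sd, size=shape)

    # NCCT: thicker-slice, lower-contrast rendering with its own small pose
    # offset (independent acquisition), later corrected by rigid registration.
    sigma_vox = np.array([1.0, 1.0, 2.5]) / np.asarray(spacing)
    ncct_base = ndimage.gaussian_filter(img, sigma=sigma_vox)
    ncct_base = PARENCHYMA + 0.6 * (ncct_base - PARENCHYMA)
    n_angles = np.deg2rad(rng.uniform(-0.5 * max_deg, 0.5 * max_deg, size=3))
    n_shifts = rng.uniform(-0.5 * max_mm, 0.5 * max_mm, size=3)
    ncct_arr = _rigid_resample(ncct_base, angles + n_angles, shifts + n_shifts, spacing, order=1)
    ncct_arr = ncct_arr + rng.normal(0.0, 0.8 * spec.noise_sd, size=shape)

    ref = ImageVolume(cta_arr, spacing)
    grp = group if group is not None else ("A" if spec.lesion_present else "B")
    return PhantomCase(
        case_id=case_id,
        group=grp,
        cta=ref,
        ncct=ImageVolume(ncct_arr, spacing),
        lesion_mask=BinaryMask.from_array(lesion_p, ref),
        brain_mask=BinaryMask.from_array(brain_p, ref),
        atlas=RegionAtlas(ref.with_values(atlas_p)),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def case_seed(cohort_seed: int, case_index: int) -> int:
    """Deterministic per-case seed derived by hashing (cohort_seed, index)."""
    digest = hashlib.sha256(f"{cohort_seed}:{case_index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def generate_cohort(
    n_positive: int,
    n_negative: int,
    base_spec: PhantomSpec,
    seed: int,
) -> list[PhantomCase]:
    """A study cohort: lesioned group-A cases then confounder-only group-B.

    Lesion side is randomized with probability 0.5, lesion size and contrast
    and confounder severities vary per case; per-case seeds are derived
    deterministically from the cohort seed.
    """
    if n_positive < 0 or n_negative < 0:
        raise ParameterError("cohort counts must be >= 0")
    r_max = max_lesion_radius_mm(base_spec)
    cases = []
    for i in range(n_positive + n_negative):
        s = case_seed(seed, i)
        rng = np.random.default_rng(s)
        positive = i < n_positive
        kwargs = dict(
            seed=s,
            lesion_present=positive,
            confounder_periventricular=float(rng.uniform(0.3, 0.9)),
            confounder_sulcal=float(rng.uniform(0.3, 0.9)),
        )
        if positive:
            kwargs.update(
                lesion_side="left" if rng.random() < 0.5 else "right",
                lesion_radius_mm=float(rng.uniform(0.40, 0.95) * r_max),
                lesion_contrast=float(rng.uniform(0.25, 0.45)),
            )
        spec = replace(base_spec, **kwargs)
        group = "A" if positive else "B"
        idx = i if positive else i - n_positive
        cases.append(generate_phantom(spec, case_id=f"{group}{idx:02d}", group=group))
    return cases


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_case(case: PhantomCase, directory) -> None:
    """Write one case as NIfTI files into ``directory``."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_nifti(case.cta, d / "cta.nii.gz")
    save_nifti(case.ncct, d / "ncct.nii.gz")
    save_mask_nifti(case.lesion_mask, d / "lesion.nii.gz")
    save_mask_nifti(case.brain_mask, d / "brain.nii.gz")
    save_nifti(case.atlas.volume, d / "atlas.nii.gz")


def write_cohort(cases: list[PhantomCase], directory) -> None:
    """Write all cases plus a tab-separated cohort manifest."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lines = ["case_id\tgroup\tlesion_present\tlesion_side\tlesion_radius_mm\tlesion_contrast\tseed"]
    for case in cases:
        write_case(case, d / case.case_id)
        sp = case.spec
        lines.append(
            f"{case.case_id}\t{case.group}\t{int(sp.lesion_present)}\t"
            f"{sp.lesion_side if sp.lesion_present else '-'}\t"
            f"{sp.lesion_radius_mm if sp.lesion_present else 0:.2f}\t"
            f"{sp.lesion_contrast if sp.lesion_present else 0:.3f}\t{sp.seed}"
        )
    (d / "manifest.tsv").write_text("\n".join(lines) + "\n")
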