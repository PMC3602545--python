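"""Slice-stack reconstruction and volume preprocessing.

The imaging unit of the whole analysis is a 3D optical-density (OD) volume
per animal, reconstructed from serial coronal autoradiograph sections.  The
voxel grid is anisotropic: fine in-plane sampling (x, z axes) and coarse
spacing along the sectioning axis (y).  Preprocessing follows the classical
small-animal SPM adaptation: sequential rigid slice-to-slice registration,
affine normalization into a reference space, voxel-wise template averaging,
in-plane Gaussian smoothing, and a relative-intensity brain mask.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize, minimize_scalar
from skimage.registration import phase_cross_correlation

from .errors import ConvergenceError, DegenerateImageError

#: paper-scale voxel size, µm, axes (in-plane x, section axis y, in-plane z)
DEFAULT_VOXEL_SIZE_UM = (40.0, 300.0, 40.0)

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.3548


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BrainVolume:
    """One animal's 3D OD volume plus the subgroup labels of the 2×2 design.

    Axes are (x, y, z) with y the section axis; ``voxel_size_um`` gives the
    physical edge length per axis in micrometres.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    animal_id: str = ""
    treatment: str = ""          # "WAS" | "sham" | ""
    distension_mmhg: int | None = None   # 0 | 60 | None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def subgroup(self) -> tuple[str, int | None]:
        return (self.treatment, self.distension_mmhg)

    def with_data(self, data: np.ndarray, **kw) -> "BrainVolume":
        return replace(self, data=np.asarray(data, dtype=float), **kw)


@dataclass
class SliceStack:
    """Ordered coronal OD sections prior to 3D reconstruction."""

    slices: list[np.ndarray]
    slice_spacing_um: float = 300.0
    pixel_size_um: float = 40.0
    bregma_start_mm: float = 4.5

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        if not self.slices:
            raise ValueError("empty slice stack")
        shp = self.slices[0].shape
        if any(s.shape != shp for s in self.slices):
            raise ValueError("all slices must share the same in-plane shape")
        if self.slice_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("spacing and pixel size must be positive")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid pose: rotation about the image centre, then translation.

    ``shift`` is in (row, col) pixels.  Applying the transform moves a
    feature at centred coordinates p to ``R(rotation) @ p + shift`` where R
    is the standard rotation matrix in (row, col) axes.
    """

    rotation_deg: float
    shift: tuple[float, float]

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), -math.sin(th)],
                         [math.sin(th), math.cos(th)]])

    def inverse(self) -> "RigidTransform2D":
        rinv = self.matrix().T
        t = rinv @ np.asarray(self.shift)
        return RigidTransform2D(-self.rotation_deg, (-t[0], -t[1]))

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``first`` then ``self``."""
        t = self.matrix() @ np.asarray(first.shift) + np.asarray(self.shift)
        return RigidTransform2D(self.rotation_deg + first.rotation_deg,
                                (t[0], t[1]))

    @property
    def is_identity(self) -> bool:
        return (abs(self.rotation_deg) < 1e-9
                and abs(self.shift[0]) < 1e-9 and abs(self.shift[1]) < 1e-9)


def _background_level(img: np.ndarray) -> float:
    """Fill value for resampling: the median intensity of the frame border
    (film background), robust to signed or offset intensity scales."""
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    return float(np.median(border))


def apply_rigid(image: np.ndarray, transform: RigidTransform2D,
                order: int = 0, cval: float | None = None) -> np.ndarray:
    """Resample ``image`` under a rigid pose.

    Nearest-neighbour resampling (``order=0``) is the default, matching the
    convention for autoradiograph section alignment.  Sub-0.05 components
    are snapped to zero so that a numerically-identity transform is exactly
    the identity.
    """
    img = np.asarray(image, dtype=float)
    if cval is None:
        cval = _background_level(img)
    rot = transform.rotation_deg if abs(transform.rotation_deg) >= 0.05 else 0.0
    sh = np.array([s if abs(s) >= 0.05 else 0.0 for s in transform.shift])
    if rot == 0.0 and not sh.any():
        return img.copy()
    # single resampling: output(o) = input(R⁻¹ (o − c − t) + c)
    snapped = RigidTransform2D(rot, (sh[0], sh[1]))
    rinv = snapped.matrix().T
    c = (np.asarray(img.shape) - 1) / 2.0
    offset = c - rinv @ (c + sh)
    return ndi.affine_transform(img, rinv, offset=offset, order=order,
                                mode="constant", cval=cval)


# ---------------------------------------------------------------------------
# rigid slice-to-slice registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    d = a.std() * b.std()
    if d == 0:
        return 0.0
    return float((a * b).mean() / d)


def register_rigid(moving: np.ndarray, fixed: np.ndarray, *,
                   angle_range_deg: float = 10.0,
                   angle_step_deg: float = 1.0,
                   min_confidence: float = 0.3) -> RigidTransform2D:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    The objective is normalized cross-correlation.  The rotation is searched
    over a coarse grid and refined by bounded 1D minimization; at each
    candidate angle the translation is read off a sub-pixel phase
    correlation.  Returns T such that ``apply_rigid(moving, T) ≈ fixed``.

    A warning is emitted when even the best pose correlates below
    ``min_confidence`` — the images share too little structure (e.g. pure
    noise) for the estimate to mean anything.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share a shape")
    for name, img in (("moving", moving), ("fixed", fixed)):
        if img.std() == 0:
            raise DegenerateImageError(f"{name} image is constant")
    fill = _background_level(moving)   # as apply_rigid uses

    def shift_and_score(angle: float) -> tuple[np.ndarray, float]:
        rot = (moving if angle == 0.0 else
               ndi.rotate(moving, angle, reshape=False, order=3,
                          mode="constant", cval=fill))
        shift = phase_cross_correlation(fixed, rot, upsample_factor=20)[0]
        cand = apply_rigid(moving, RigidTransform2D(angle, tuple(shift)),
                           order=3, cval=fill)
        return shift, _ncc(cand, fixed)

    best_angle, best_shift, best_score = 0.0, np.zeros(2), -np.inf
    for angle in np.arange(-angle_range_deg, angle_range_deg + 1e-9,
                           angle_step_deg):
        shift, score = shift_and_score(float(angle))
        if score > best_score:
            best_angle, best_shift, best_score = float(angle), shift, score

    res = minimize_scalar(lambda a: -shift_and_score(a)[1],
                          bounds=(best_angle - angle_step_deg,
                                  best_angle + angle_step_deg),
                          method="bounded",
                          options={"xatol": 0.02})
    if -res.fun >= best_score:
        best_angle, best_score = float(res.x), float(-res.fun)
        best_shift = shift_and_score(best_angle)[0]

    if best_score < min_confidence:
        warnings.warn(
            f"rigid registration is low-confidence (best correlation "
            f"{best_score:.2f} < {min_confidence}); images may share no "
            "structure", stacklevel=2)
    return RigidTransform2D(best_angle, (float(best_shift[0]),
                                         float(best_shift[1])))


def reconstruct(stack: SliceStack) -> BrainVolume:
    """Align each section to its (already aligned) predecessor and stack.

    Registration is sequential, so the per-slice poses compose cumulatively
    along the stack; resampling is nearest-neighbour.  The output axes are
    (in-plane row → x, section index → y, in-plane col → z) and carry the
    stack's physical voxel sizes.
    """
    if len(stack) < 2:
        raise ValueError("reconstruction needs at least 2 slices")
    aligned = [stack.slices[0]]
    for i, sl in enumerate(stack.slices[1:], start=1):
        try:
            t = register_rigid(sl, aligned[-1])
        except DegenerateImageError as exc:
            raise DegenerateImageError(f"slice {i}: {exc}") from exc
        aligned.append(sl if t.is_identity else apply_rigid(sl, t, order=0))
    vol = np.stack(aligned, axis=1)
    vs = (stack.pixel_size_um, stack.slice_spacing_um, stack.pixel_size_um)
    return BrainVolume(vol, voxel_size_um=vs)


# ---------------------------------------------------------------------------
# affine spatial normalization
# ---------------------------------------------------------------------------

def _affine_matrix(params: np.ndarray) -> np.ndarray:
    """12-parameter affine: 3 translations, 3 rotations (deg), 3 log-scales,
    3 shears, composed as T @ Rz @ Ry @ Rx @ Shear @ Scale."""
    tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz = params
    cx, sx_ = math.cos(math.radians(rx)), math.sin(math.radians(rx))
    cy, sy_ = math.cos(math.radians(ry)), math.sin(math.radians(ry))
    cz, sz_ = math.cos(math.radians(rz)), math.sin(math.radians(rz))
    Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    Sh = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
    Sc = np.diag(np.exp([sx, sy, sz]))
    A = Rz @ Ry @ Rx @ Sh @ Sc
    return A, np.array([tx, ty, tz])


def _resample_affine(data: np.ndarray, params: np.ndarray,
                     out_shape: tuple[int, ...]) -> np.ndarray:
    """Pull-back resampling of ``data`` onto ``out_shape`` under the affine
    (centre-anchored): output voxel o maps to input A⁻¹ (o − c_out − t) + c_in."""
    A, t = _affine_matrix(params)
    Ainv = np.linalg.inv(A)
    c_out = (np.asarray(out_shape) - 1) / 2.0
    c_in = (np.asarray(data.shape) - 1) / 2.0
    offset = c_in - Ainv @ (c_out + t)
    return ndi.affine_transform(data, Ainv, offset=offset,
                                output_shape=out_shape, order=1,
                                mode="constant", cval=float(data.min()))


def affine_normalize(volume: BrainVolume, reference: BrainVolume, *,
                     max_iter: int = 4000,
                     min_score: float = 0.1) -> BrainVolume:
    """Resample ``volume`` into the reference space by a best-fit
    12-parameter affine (translations, rotations, scales, shears).

    Optimization is staged — rigid+scale first, then all 12 parameters —
    with a Powell search on negative normalized cross-correlation.  Raises
    :class:`ConvergenceError` when the iteration cap is hit or the final
    overlap is indistinguishable from no overlap (disjoint fields of view).
    """
    if volume.data.ndim != reference.data.ndim:
        raise ValueError("dimensionality mismatch")
    ref = reference.data

    def objective(p12: np.ndarray) -> float:
        return -_ncc(_resample_affine(volume.data, p12, ref.shape), ref)

    x = np.zeros(12)
    active_sets = [np.arange(9), np.arange(12)]   # rigid+scale, then full
    nit = 0
    for active in active_sets:
        def sub(p_active, x=x, active=active):
            q = x.copy()
            q[active] = p_active
            return objective(q)
        res = minimize(sub, x[active], method="Powell",
                       options={"maxiter": max_iter, "xtol": 1e-4,
                                "ftol": 1e-7})
        x[active] = res.x
        nit += res.nit
    final = -objective(x)
    if nit >= 2 * max_iter:
        raise ConvergenceError(
            f"affine normalization hit the iteration cap ({nit} iterations)",
            objective=final)
    if final < min_score:
        raise ConvergenceError(
            "affine normalization found no usable overlap "
            f"(final correlation {final:.3f}); fields of view may be disjoint",
            objective=final)
    out = _resample_affine(volume.data, x, ref.shape)
    return volume.with_data(out, voxel_size_um=reference.voxel_size_um,
                            normalized=True)


def build_template(volumes: list[BrainVolume]) -> BrainVolume:
    """Voxel-wise mean of spatially normalized volumes."""
    if not volumes:
        raise ValueError("no volumes to average")
    shp = volumes[0].shape
    if any(v.shape != shp for v in volumes):
        raise ValueError("volumes must share a shape to be averaged")
    mean = np.mean([v.data for v in volumes], axis=0)
    return BrainVolume(mean, voxel_size_um=volumes[0].voxel_size_um,
                       animal_id="template", normalized=True)


# ---------------------------------------------------------------------------
# smoothing and masking
# ---------------------------------------------------------------------------

def smooth(volume: BrainVolume, fwhm_factor: float = 3.0,
           slice_axis_sigma_vox: float = 1.0) -> BrainVolume:
    """Gaussian smoothing: FWHM = ``fwhm_factor`` × the in-plane voxel
    dimension within each coronal plane, plus a configurable one-voxel-σ
    kernel along the section axis (the coarse 300-µm spacing makes a
    physically isotropic kernel degenerate).  Reflective boundaries.
    """
    if fwhm_factor <= 0:
        raise ValueError("fwhm_factor must be positive")
    sigma_inplane = fwhm_factor / FWHM_PER_SIGMA   # voxel units
    sigma = (sigma_inplane, slice_axis_sigma_vox, sigma_inplane)
    out = ndi.gaussian_filter(volume.data, sigma=sigma, mode="reflect")
    return volume.with_data(out)


def smoothing_sigma_vox(fwhm_factor: float = 3.0,
                        slice_axis_sigma_vox: float = 1.0
                        ) -> tuple[float, float, float]:
    """Per-axis smoothing σ in voxel units, as applied by :func:`smooth`."""
    s = fwhm_factor / FWHM_PER_SIGMA
    return (s, slice_axis_sigma_vox, s)


def mask_low_intensity(volume: BrainVolume, fraction: float = 0.70
                       ) -> np.ndarray:
    """Boolean mask of voxels at or above ``fraction`` × the grand mean OD.

    The mean is taken over the full grid (single-pass convention); an
    all-nonpositive volume yields an empty mask with a warning.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    mean = float(volume.data.mean())
    if mean <= 0:
        warnings.warn("volume has non-positive mean OD; mask is empty",
                      stacklevel=2)
        return np.zeros(volume.shape, dtype=bool)
    return volume.data >= fraction * mean


# ---------------------------------------------------------------------------
# I/O — NIfTI volumes with a JSON sidecar for subgroup labels
# ---------------------------------------------------------------------------

def save_volume(volume: BrainVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii) with voxel size in the affine (mm) and
    the subgroup labels in a ``.json`` sidecar."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    vs_mm = [s / 1000.0 for s in volume.voxel_size_um]
    affine = np.diag(vs_mm + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), path)
    sidecar = {
        "voxel_size_um": list(volume.voxel_size_um),
        "animal_id": volume.animal_id,
        "treatment": volume.treatment,
        "distension_mmhg": volume.distension_mmhg,
        "normalized": volume.normalized,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path: str | Path) -> BrainVolume:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    vs = tuple(meta.get("voxel_size_um") or
               (np.abs(np.diag(img.affine)[:3]) * 1000.0))
    return BrainVolume(data, voxel_size_um=vs,
                       animal_id=meta.get("animal_id", ""),
                       treatment=meta.get("treatment", ""),
                       distension_mmhg=meta.get("distension_mmhg"),
                       normalized=bool(meta.get("normalized", False)))
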