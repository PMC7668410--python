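"""Digital cardiac phantoms for exercising PET uptake quantification.

The phantom is a voxelised activity map in SUV-like units (dimensionless
g/mL-equivalent) with a matching integer label map.  Geometry is a stylised
heart: spherical atria, ellipsoidal ventricles with a myocardial shell,
cylindrical great veins (superior vena cava, brachiocephalic vein), and
spherical coronary lesions.  Blood pool activity defaults to SUV 1.14 and
myocardium to 0.80, the contrast that makes chamber contours visible on
fluoride PET; the scanner point-spread function is modelled as an isotropic
Gaussian with 6 mm full width at half maximum, which produces realistic
partial-volume spill-in/spill-out around small structures.

Coordinates are world millimetres with the grid origin at the corner of
voxel (0,0,0) and voxel centres at ``(index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import nibabel as nib
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "LABELS", "LESION_LABEL_BASE", "FWHM_TO_SIGMA",
    "LesionTruth", "PhantomConfig", "Phantom",
    "PlacementError", "make_phantom", "save_phantom", "load_phantom",
]

#: label codes for the anatomical regions
LABELS = {
    "background": 0,
    "left_atrium": 1,
    "right_atrium": 2,
    "left_ventricle": 3,
    "right_ventricle": 4,
    "myocardium": 5,
    "svc": 6,
    "brachiocephalic": 7,
}
#: lesion k is painted with label LESION_LABEL_BASE + lesion_id
LESION_LABEL_BASE = 100

#: FWHM = sigma * 2*sqrt(2*ln 2); fixed conversion constant
FWHM_TO_SIGMA = 1.0 / 2.3548


class PlacementError(ValueError):
    """A lesion centre falls outside the phantom grid."""


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth for one simulated coronary lesion.

    ``true_amplitude`` is the peak activity painted before the point-spread
    blur; ``extent_mm`` the along-vessel extent used by the visual
    positivity rule (defaults to the diameter); ``true_positive`` whether
    the lesion is a genuine uptake focus rather than a referent plaque.
    """

    lesion_id: int
    segment: int
    center: tuple[float, float, float]
    diameter_mm: float
    true_amplitude: float
    true_positive: bool = True
    extent_mm: float | None = None

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError(f"lesion {self.lesion_id}: diameter must be > 0")
        if not 1 <= self.segment <= 18:
            raise ValueError(
                f"lesion {self.lesion_id}: segment {self.segment} outside the 18-segment model")
        if self.extent_mm is None:
            object.__setattr__(self, "extent_mm", float(self.diameter_mm))

    @property
    def label(self) -> int:
        return LESION_LABEL_BASE + self.lesion_id


def _default_lesions() -> list[LesionTruth]:
    # one clearly avid plaque, one at blood-pool level near the LV surface
    return [
        LesionTruth(1, segment=2, center=(120.0, 52.0, 95.0), diameter_mm=8.0,
                    true_amplitude=1.8, true_positive=True),
        LesionTruth(2, segment=6, center=(106.0, 56.0, 95.0), diameter_mm=6.0,
                    true_amplitude=1.1, true_positive=False),
    ]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the stylised cardiac phantom.

    Activities are in SUV-like units; the defaults put all blood pool
    (chambers and great veins) at 1.14 and the myocardium at 0.80.
    ``fwhm_mm`` is the Gaussian point-spread full width at half maximum
    (6 mm by default); ``noise_sd`` adds white Gaussian noise after the
    blur (0 by default — measurement noise is usually injected by the
    reproducibility simulation instead).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fwhm_mm: float = 6.0
    noise_sd: float = 0.0
    blood_pool_activity: float = 1.14
    myocardium_activity: float = 0.80
    background_activity: float = 0.0
    lesions: tuple[LesionTruth, ...] = field(default_factory=lambda: tuple(_default_lesions()))

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")
        if any(n < 32 for n in self.shape):
            raise ValueError("phantom grid must be at least 32 voxels per axis")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        for a in (self.blood_pool_activity, self.myocardium_activity, self.background_activity):
            if a < 0:
                raise ValueError("activities must be >= 0")


@dataclass
class Phantom:
    """A voxelised activity volume with its label map and lesion registry."""

    activity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    lesions: list[LesionTruth]

    def __post_init__(self):
        if self.activity.shape != self.labels.shape:
            raise ValueError("activity and label grids must have identical shapes")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.activity.shape


def _voxel_centers(shape, spacing):
    axes = [(np.arange(n) + 0.5) * d for n, d in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _paint_ellipsoid(labels, centers, center, radii, code, where_zero_only=False):
    gx, gy, gz = centers
    u = ((gx - center[0]) / radii[0]) ** 2 \
        + ((gy - center[1]) / radii[1]) ** 2 \
        + ((gz - center[2]) / radii[2]) ** 2
    mask = u <= 1.0
    if where_zero_only:
        mask &= labels == 0
    labels[mask] = code


def _paint_cylinder(labels, centers, axis, center, radius, extent, code):
    """Finite circular cylinder along ``axis`` from extent[0] to extent[1] mm."""
    gx, gy, gz = centers
    coords = [gx, gy, gz]
    perp = [coords[k] - center[k] for k in range(3) if k != axis]
    r2 = perp[0] ** 2 + perp[1] ** 2
    along = coords[axis]
    mask = (r2 <= radius ** 2) & (along >= extent[0]) & (along <= extent[1])
    labels[mask] = code


def build_label_map(config: PhantomConfig) -> np.ndarray:
    """Paint the stylised heart geometry onto an integer grid."""
    labels = np.zeros(config.shape, dtype=np.int16)
    centers = _voxel_centers(config.shape, config.spacing)
    extent_mm = np.asarray(config.shape) * np.asarray(config.spacing)

    # ventricles with a myocardial shell; shell painted first, cavities overwrite
    _paint_ellipsoid(labels, centers, (120, 85, 95), (30, 36, 30), LABELS["myocardium"])
    _paint_ellipsoid(labels, centers, (120, 85, 95), (22, 28, 22), LABELS["left_ventricle"])
    _paint_ellipsoid(labels, centers, (72, 80, 95), (18, 24, 18), LABELS["right_ventricle"])
    # atria
    _paint_ellipsoid(labels, centers, (120, 132, 95), (18, 18, 18), LABELS["left_atrium"])
    _paint_ellipsoid(labels, centers, (72, 132, 95), (18, 18, 18), LABELS["right_atrium"])
    # great veins: SVC running cranially from the right atrium, brachiocephalic
    # vein crossing above it; narrow tubes, hence strong partial-volume effects
    _paint_cylinder(labels, centers, axis=1, center=(72, 0, 95), radius=6.0,
                    extent=(148, 168), code=LABELS["svc"])
    _paint_cylinder(labels, centers, axis=0, center=(0, 170, 112), radius=5.0,
                    extent=(48, 120), code=LABELS["brachiocephalic"])

    for lesion in config.lesions:
        c = np.asarray(lesion.center, dtype=float)
        if np.any(c < 0) or np.any(c > extent_mm):
            raise PlacementError(
                f"lesion {lesion.lesion_id} centre {tuple(c)} lies outside the grid")
        r = lesion.diameter_mm / 2.0
        _paint_ellipsoid(labels, centers, c, (r, r, r), lesion.label)
    return labels


def make_phantom(config: PhantomConfig, seed: int = 0) -> Phantom:
    """Build a phantom: paint activities per label, blur, optionally add noise.

    Each labelled region carries its configured activity exactly before the
    blur.  The point-spread function is applied as a Gaussian filter with
    ``sigma = fwhm / 2.3548`` per axis (in voxel units), with nearest-
    neighbour boundary extension; total activity away from the grid edge is
    conserved.  White Gaussian noise of SD ``noise_sd`` is added after the
    blur.  Identical (config, seed) pairs give bit-identical output.
    """
    labels = build_label_map(config)
    activity = np.full(config.shape, config.background_activity, dtype=np.float64)
    activity[labels == LABELS["myocardium"]] = config.myocardium_activity
    for name in ("left_atrium", "right_atrium", "left_ventricle", "right_ventricle",
                 "svc", "brachiocephalic"):
        activity[labels == LABELS[name]] = config.blood_pool_activity
    for lesion in config.lesions:
        activity[labels == lesion.label] = lesion.true_amplitude

    if config.fwhm_mm > 0:
        sigma_vox = [config.fwhm_mm * FWHM_TO_SIGMA / d for d in config.spacing]
        activity = gaussian_filter(activity, sigma=sigma_vox, mode="nearest")
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = activity + rng.normal(0.0, config.noise_sd, size=config.shape)
    return Phantom(activity, labels, config.spacing, list(config.lesions))


# ---------------------------------------------------------------------------
# NIfTI / YAML persistence

def _affine(spacing):
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = np.asarray(spacing) / 2.0  # voxel centres at (i+0.5)*spacing
    return aff


def save_phantom(phantom: Phantom, activity_path, labels_path, registry_path=None) -> None:
    """Write the activity and label volumes as NIfTI-1, the lesion registry as YAML."""
    aff = _affine(phantom.spacing)
    nib.save(nib.Nifti1Image(phantom.activity.astype(np.float32), aff), str(activity_path))
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff), str(labels_path))
    if registry_path is not None:
        payload = [asdict(l) | {"center": [float(c) for c in l.center]}
                   for l in phantom.lesions]
        with open(registry_path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_phantom(activity_path, labels_path, registry_path=None) -> Phantom:
    act_img = nib.load(str(activity_path))
    lab_img = nib.load(str(labels_path))
    spacing = tuple(float(z) for z in act_img.header.get_zooms()[:3])
    lesions = []
    if registry_path is not None:
        with open(registry_path) as fh:
            for d in yaml.safe_load(fh) or []:
                lesions.append(LesionTruth(
                    d["lesion_id"], d["segment"], tuple(d["center"]),
                    d["diameter_mm"], d["true_amplitude"], d["true_positive"],
                    d.get("extent_mm")))
    return Phantom(np.asarray(act_img.dataobj, dtype=np.float64),
                   np.asarray(lab_img.dataobj, dtype=np.int16),
                   spacing, lesions)
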