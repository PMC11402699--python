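"""Image processing: bone segmentation, rigid NMI registration, osteotomy
cropping and density/modulus mapping.

The processing chain mirrors a clinical QCT-to-FE workflow: the pre-operative
scan carries artifact-free bone geometry and mineral density; it is
co-registered onto the post-operative scan with a normalized mutual
information (NMI) metric and then cropped to the osteotomy pattern so the
fragments inherit pre-op image quality in the post-op pose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.morphology import ball

from .images import Mask, VoxelImage
from .transforms import RigidTransform


@dataclass
class DensityCalibration:
    """HU -> mineral density (mg HA/cm^3) -> elastic modulus mapping.

    The density-modulus power law ``E = coeff * (rho / rho_ref) ** exponent``
    and the HU calibration line are scanner- and study-specific, so every
    constant is configuration. The defaults treat HU values directly as
    mg HA/cm^3 (identity calibration) with a generic power law; override them
    with the constants of whichever published law applies to your scanner.
    """

    hu_slope: float = 1.0
    hu_intercept: float = 0.0
    modulus_coefficient: float = 10_000.0  # MPa at the reference density
    modulus_exponent: float = 1.5
    density_reference: float = 1000.0  # mg HA/cm^3
    min_modulus: float = 0.01  # MPa floor; keeps the stiffness matrix regular

    def __post_init__(self) -> None:
        if self.modulus_coefficient <= 0 or self.modulus_exponent <= 0:
            raise ValueError("modulus law constants must be positive")


def segment_bone(
    image: VoxelImage,
    lo: float = 400.0,
    hi: float = 4000.0,
    close_radius: int = 2,
    fill_holes: bool = False,
    largest_component: bool = False,
) -> Mask:
    """Threshold bone in ``[lo, hi]`` HU (inclusive), then smooth.

    Smoothing is a morphological closing with a ball of ``close_radius``
    voxels. ``fill_holes`` additionally fills enclosed background per
    transverse slice — on real scans this absorbs the trabecular/marrow
    space into the mask, so it is off by default where a cortex-only mask
    is wanted.
    """
    if lo >= hi:
        raise ValueError("lower bound must be below upper bound")
    raw = (image.values >= lo) & (image.values <= hi)
    if not raw.any():
        raise ValueError(f"segmentation empty: no voxels in [{lo}, {hi}] HU")
    out = raw
    if close_radius > 0:
        selem = ball(close_radius)
        # closing with an out-of-image border treated as foreground for the
        # erosion step, so a mask reaching the image edge is not eaten away
        out = ndimage.binary_erosion(
            ndimage.binary_dilation(out, structure=selem), structure=selem,
            border_value=1,
        )
    if fill_holes:
        filled = np.empty_like(out)
        for i in range(out.shape[0]):
            filled[i] = ndimage.binary_fill_holes(out[i])
        out = filled
    if largest_component:
        labels, n = ndimage.label(out)
        if n > 1:
            sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
            out = labels == (1 + int(np.argmax(sizes)))
    if not out.any():
        raise ValueError("segmentation empty after smoothing")
    return Mask.like(image, out)


# ---------------------------------------------------------------------------
# rigid registration with a normalized mutual information metric
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    transform: RigidTransform
    nmi: float
    initial_nmi: float
    overlap_fraction: float
    low_overlap: bool
    n_evaluations: int


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """NMI(A,B) = (H(A) + H(B)) / H(A,B) from the joint histogram of paired samples."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hab = entropy(p.ravel())
    if hab == 0.0:
        return 2.0  # both images constant over the overlap
    return (entropy(pa) + entropy(pb)) / hab


def _resample(moving: VoxelImage, fixed: VoxelImage, transform: RigidTransform):
    """Sample the moving image at ``T^-1(x)`` for fixed-grid centres x.

    Returns (values, validity mask); linear interpolation, out-of-field
    samples flagged invalid.
    """
    gx, gy, gz = np.meshgrid(*fixed.center_grid(), indexing="ij", sparse=False)
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    src = transform.inverse().apply(pts)
    idx = moving.world_to_index(src).T
    shape = np.asarray(moving.shape)
    valid = np.all((idx >= 0) & (idx <= (shape[:, None] - 1)), axis=0)
    vals = ndimage.map_coordinates(
        moving.values.astype(float), idx, order=1, mode="nearest"
    )
    return vals.reshape(fixed.shape), valid.reshape(fixed.shape)


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> RigidTransform:
    """(rx, ry, rz) in degrees and (tx, ty, tz) in mm, rotating about ``center``."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", p[:3], degrees=True).as_matrix()
    base = RigidTransform(R, np.zeros(3)).about_point(center)
    return RigidTransform(base.rotation, base.translation + p[3:6])


def _smooth(img: VoxelImage, sigma_voxels: float) -> VoxelImage:
    if sigma_voxels <= 0:
        return img
    return VoxelImage(
        ndimage.gaussian_filter(img.values.astype(float), sigma_voxels),
        img.spacing, img.origin,
    )


def _downsample(img: VoxelImage, factor: int) -> VoxelImage:
    if factor <= 1:
        return img
    sm = ndimage.gaussian_filter(img.values.astype(float), sigma=0.5 * factor)
    vals = sm[::factor, ::factor, ::factor]
    spacing = img.spacing * factor
    # coarse voxel (0,0,0) keeps the world centre of fine voxel (0,0,0)
    origin = img.origin + 0.5 * img.spacing - 0.5 * spacing
    return VoxelImage(vals, spacing, origin)


def register_rigid_nmi(
    moving: VoxelImage,
    fixed: VoxelImage,
    bins: int = 32,
    initial: RigidTransform | None = None,
    levels: tuple = (4, 2, 1),
    finest_spacing: float | None = None,
    max_iter: int = 120,
    rot_step_deg: float = 2.0,
    trans_step: float | None = None,
    metric_smoothing: float = 1.0,
) -> RegistrationResult:
    """6-DOF registration maximizing NMI with multi-resolution Nelder-Mead.

    Returns the transform that maps moving-image world coordinates onto the
    fixed image: resampling ``moving`` through it aligns it with ``fixed``.
    The search is local, started from ``initial`` (identity by default), so
    a roughly correct initial pose is assumed. ``finest_spacing`` caps the
    finest pyramid level (coarser levels than the native grid keep large
    volumes tractable). ``metric_smoothing`` (voxels) Gaussian-blurs both
    images before the metric: on piecewise-constant images the raw NMI
    optimum is biased by interpolation artifacts, and a one-voxel blur
    restores a smooth, unbiased peak. Each level runs the simplex search
    twice, the second pass restarted with a quarter-size simplex.
    """
    if bins < 8:
        raise ValueError("need at least 8 histogram bins")
    initial = initial or RigidTransform.identity()
    center = fixed.origin + 0.5 * np.asarray(fixed.shape) * fixed.spacing
    if trans_step is None:
        trans_step = 2.0 * float(fixed.spacing.max())

    lv = []
    for f in sorted(set(int(x) for x in levels), reverse=True):
        if finest_spacing is not None and float(fixed.spacing.min()) * f < finest_spacing - 1e-12:
            continue
        lv.append(f)
    if not lv:
        lv = [max(1, int(np.ceil(finest_spacing / float(fixed.spacing.min()))))]

    # parameter offset relative to the initial transform
    p = np.zeros(6)
    n_eval = 0
    init_nmi = -_final_metric(moving, fixed, initial, bins)

    for li, f in enumerate(lv):
        mv = _smooth(_downsample(moving, f), metric_smoothing)
        fx = _smooth(_downsample(fixed, f), metric_smoothing)
        _, valid0 = _resample(mv, fx, _params_to_transform(np.zeros(6), center).compose(initial))
        frac0 = float(valid0.mean())

        def neg_nmi(q):
            nonlocal n_eval
            n_eval += 1
            T = _params_to_transform(q, center).compose(initial)
            vals, valid = _resample(mv, fx, T)
            frac = float(valid.mean())
            # guard against the sliding-off degeneracy: NMI of a mostly
            # background overlap is spuriously high, so poses that lose more
            # than half of the starting overlap are rejected outright
            if frac < max(0.01, 0.5 * frac0):
                return 1.0
            return -normalized_mutual_information(
                vals[valid], fx.values[valid].astype(float), bins
            )

        # the simplex scale tracks the expected residual misalignment, not
        # the pyramid level: over-long steps can hop into aliasing optima
        # (e.g. opposite cortical walls of a ring aligning with each other)
        for shrink in (1.0, 0.25):
            scale = np.array([rot_step_deg] * 3 + [trans_step] * 3) * shrink
            simplex = np.vstack([p, p + np.diag(scale)])
            res = optimize.minimize(
                neg_nmi,
                p,
                method="Nelder-Mead",
                options={
                    "initial_simplex": simplex,
                    "maxiter": max_iter * (1 if li else 2),
                    "xatol": 0.005 * f,
                    "fatol": 1e-9,
                },
            )
            # keep the better of start and optimum (monotonicity contract)
            p = res.x if res.fun <= neg_nmi(p) else p

    final_nmi = -_final_metric(moving, fixed, _params_to_transform(p, center).compose(initial), bins)
    T = _params_to_transform(p, center).compose(initial)
    _, valid = _resample(_downsample(moving, lv[-1]), _downsample(fixed, lv[-1]), T)
    overlap = float(valid.mean())
    low = overlap < 0.10
    if low:
        warnings.warn("registration optimum has <10% field-of-view overlap")
    if final_nmi < init_nmi:  # never return worse than the starting point
        T, final_nmi = initial, init_nmi
    return RegistrationResult(T, float(final_nmi), float(init_nmi), overlap, low, n_eval)


def _final_metric(moving, fixed, T, bins):
    f = max(1, int(round(max(fixed.shape) / 96)))
    mv, fx = _smooth(_downsample(moving, f), 1.0), _smooth(_downsample(fixed, f), 1.0)
    vals, valid = _resample(mv, fx, T)
    if not valid.any():
        return 0.0
    return -normalized_mutual_information(vals[valid], fx.values[valid].astype(float), bins)


def resample_to(moving: VoxelImage, fixed: VoxelImage, transform: RigidTransform,
                fill_value: float = 0.0) -> VoxelImage:
    """Resample ``moving`` into the fixed grid under ``transform`` (linear interp)."""
    vals, valid = _resample(moving, fixed, transform)
    vals[~valid] = fill_value
    return VoxelImage(vals, fixed.spacing.copy(), fixed.origin.copy())


# ---------------------------------------------------------------------------
# osteotomy cropping and density mapping
# ---------------------------------------------------------------------------

def crop_to_osteotomy(
    preop_mask: Mask, gap_center, gap_normal, gap_size: float
) -> tuple[Mask, Mask]:
    """Remove the gap slab and split the mask into (proximal, distal) fragments.

    The slab is ``|(c - gap_center) . n| < gap_size/2`` over voxel centres c;
    the negative-projection side is labelled proximal.
    """
    c = np.asarray(gap_center, dtype=float)
    n = np.asarray(gap_normal, dtype=float)
    n = n / np.linalg.norm(n)
    ax = [g - c[i] for i, g in enumerate(preop_mask.center_grid())]
    proj = (
        ax[0][:, None, None] * n[0]
        + ax[1][None, :, None] * n[1]
        + ax[2][None, None, :] * n[2]
    )
    keep = np.abs(proj) >= gap_size / 2.0
    prox = preop_mask.values & keep & (proj < 0)
    dist = preop_mask.values & keep & (proj >= 0)
    if not prox.any() or not dist.any():
        raise ValueError("osteotomy crop left an empty fragment")
    return (
        Mask(prox, preop_mask.spacing.copy(), preop_mask.origin.copy()),
        Mask(dist, preop_mask.spacing.copy(), preop_mask.origin.copy()),
    )


def map_density(image: VoxelImage, mask: Mask, cal: DensityCalibration) -> VoxelImage:
    """Per-voxel mineral density inside the mask, clamped at zero."""
    rho = cal.hu_slope * image.values.astype(float) + cal.hu_intercept
    rho = np.clip(rho, 0.0, None)
    rho[~mask.values] = 0.0
    return VoxelImage(rho, image.spacing.copy(), image.origin.copy())


def density_to_modulus(rho, cal: DensityCalibration):
    """Power-law density->modulus map with a configurable floor (MPa)."""
    rho = np.asarray(rho, dtype=float)
    E = cal.modulus_coefficient * (rho / cal.density_reference) ** cal.modulus_exponent
    return np.maximum(E, cal.min_modulus)
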