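"""Reference end-to-end computations on the synthetic phantom.

These routines run the whole pipeline at fixed, documented problem sizes and
return the headline quantities (mid-plate bending moment, mesh-refinement
sensitivity, calibration recovery). They are used by the test suite and by
``scripts/acceptance.py``; parameters live here so both run the identical
computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import material, section, synthdata
from .imaging import DensityCalibration, crop_to_osteotomy, map_density, segment_bone
from .kinematics import DivotFrame, make_displacement_steps
from .pipeline import MotionConfig, RunConfig, build_system
from .synthdata import PhantomSpec, PlateSpec
from .transforms import RigidTransform


@dataclass
class MomentBenchmark:
    max_bending_moment: float  # N mm
    n_elements: int
    n_nodes: int
    target_edge: float
    bending_per_step: np.ndarray | None = None  # N mm over the load steps


def reference_motion(frame: DivotFrame, motion: MotionConfig | None = None) -> RigidTransform:
    """The nominal rehabilitation-scale relative transform (no jitter/noise)."""
    motion = motion or MotionConfig()
    about = RigidTransform.from_axis_angle(
        motion.rotation_axis, motion.flexion_angle_deg
    ).about_point(frame.distal_divot)
    return RigidTransform(
        about.rotation, about.translation + np.asarray(motion.translation_mm, dtype=float)
    )


def phantom_moment(
    target_edge: float,
    phantom: PhantomSpec | None = None,
    plate: PlateSpec | None = None,
    motion: MotionConfig | None = None,
    seed: int = 0,
    scale: float = 1.0,
    n_steps: int = 10,
) -> MomentBenchmark:
    """Max mid-plate bending moment of the noiseless reference phantom model.

    Builds the model through the actual pipeline stages (segmentation of the
    intact phantom, osteotomy crop, density mapping, meshing, ties) and
    imposes the nominal relative transform scaled by ``scale`` in ``n_steps``
    evenly spaced steps (linear solver mode).
    """
    phantom = dataclasses.replace(
        phantom or PhantomSpec(), noise_sd=0.0, seed=int(seed) % (2**31 - 1)
    )
    cfg = RunConfig(
        phantom=phantom,
        plate=plate or PlateSpec(),
        seed=int(seed) % (2**31 - 1),
    )
    cfg.registration.enabled = False
    cfg.solver.target_edge = target_edge
    cfg.solver.n_steps = n_steps

    intact = synthdata.make_phalanx_phantom(
        dataclasses.replace(phantom, gap_size=0.0)
    )
    post = synthdata.make_phalanx_phantom(phantom)
    mask = segment_bone(intact.image)
    prox, dist = crop_to_osteotomy(mask, post.gap_center, post.gap_normal, phantom.gap_size)
    density = map_density(intact.image, mask, cfg.calibration)

    curve = synthdata.make_dogbone_curve()
    mat = material.calibrate(curve)
    system, _, frame = build_system(cfg, prox, dist, density, mat, phantom)

    m = motion or MotionConfig()
    if scale != 1.0:
        m = MotionConfig(
            flexion_angle_deg=m.flexion_angle_deg * scale,
            rotation_axis=m.rotation_axis,
            translation_mm=tuple(scale * np.asarray(m.translation_mm)),
        )
    T_rel = reference_motion(frame, m)

    steps = make_displacement_steps(T_rel, n=n_steps, pivot=frame.distal_divot)
    results = system.solve_steps(steps, mode="linear")
    curve_m = section.compute_moment_curve(
        system, results, station=cfg.solver.station, linearize=True
    )
    return MomentBenchmark(
        section.max_bending_moment(curve_m),
        system.mesh.n_elements,
        system.mesh.n_nodes,
        target_edge,
        curve_m.bending_magnitudes(),
    )


def convergence_study(seed: int = 0, coarse: float = 1.0, fine: float = 0.5) -> dict:
    """Mesh-refinement sensitivity of the max bending moment (percent)."""
    mc = phantom_moment(coarse, seed=seed)
    mf = phantom_moment(fine, seed=seed)
    rel = abs(mc.max_bending_moment - mf.max_bending_moment) / mf.max_bending_moment * 100.0
    return {
        "coarse": mc,
        "fine": mf,
        "rel_diff_pct": float(rel),
    }


def calibration_recovery() -> dict:
    """Fit the elastic constants back from a noiseless synthetic tension curve."""
    curve = synthdata.make_dogbone_curve()
    E = material.fit_elastic_modulus(curve)
    nu = material.fit_poisson(curve)
    return {"E_MPa": float(E), "poisson": float(nu), "n_samples": int(curve.axial_strain.size)}
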