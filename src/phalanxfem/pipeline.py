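"""End-to-end orchestration: phantom -> images -> kinematics -> FE -> moments.

One *run* of the pipeline emulates one tested digit: a phantom bone with a
mid-diaphyseal gap osteotomy is imaged, segmented, (optionally) registered
from an intact pre-op pose, meshed with the plated construct, driven through
evenly spaced displacement steps derived from marker data, and reduced to
the maximum mid-plate bending moment. Specimens x digits x repeats build a
summary table with per-group statistics and one-way ANOVAs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import imaging, kinematics, material, section, synthdata
from .fem import apply_ties, combine_meshes, voxels_to_tet10
from .imaging import DensityCalibration
from .synthdata import PhantomSpec, PlateSpec
from .transforms import RigidTransform
from .vtkio import write_vtu

log = logging.getLogger("phalanxfem")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str, last_artifact: str | None = None):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.last_artifact = last_artifact


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MotionConfig:
    """Imposed relative fragment motion (rehabilitation-scale flexion)."""

    flexion_angle_deg: float = 2.0
    rotation_axis: tuple = (0.0, 1.0, 0.0)  # bending about the plate width
    translation_mm: tuple = (0.0, 0.0, 0.1)  # of the distal divot
    n_marker_frames: int = 11
    marker_noise_sd: float = 0.05  # mm, camera-class precision


@dataclass
class RegistrationConfig:
    enabled: bool = True
    finest_spacing: float = 0.45  # mm cap on the finest pyramid level
    bins: int = 32
    max_iter: int = 100
    # synthetic pre-op pose offset recovered by the registration stage
    misalignment_deg: float = 1.0
    misalignment_axis: tuple = (0.3, 1.0, 0.2)
    misalignment_mm: tuple = (0.4, -0.3, 0.2)


@dataclass
class SolverConfig:
    target_edge: float = 1.0  # mm, bone mesh resolution
    plate_edge: float = 0.5  # mm, plate mesh resolution (resolves the holes)
    mode: str = "linear"  # or "incremental"
    n_steps: int = 10
    tie_search_radius: float = 1.0  # mm
    bone_poisson: float = 0.3
    fill_threshold: float = 0.5
    station: float = 0.5  # cut plane at the plate mid-length
    end_cap_depth_factor: float = 0.51  # x block size: nodes forming each end cap
    contact: str = "off"  # "off" | "penalty" (bone-bone gap closure springs)


@dataclass
class JitterConfig:
    """Seeded specimen/digit variation (fractions of the nominal values)."""

    outer_radius: float = 0.05
    cortical_hu: float = 0.05
    flexion_angle: float = 0.15
    translation: float = 0.2


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    plate: PlateSpec = field(default_factory=PlateSpec)
    calibration: DensityCalibration = field(default_factory=DensityCalibration)
    motion: MotionConfig = field(default_factory=MotionConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    jitter: JitterConfig = field(default_factory=JitterConfig)
    specimens: int = 2
    digits: tuple = ("2nd", "3rd")
    repeats: int = 3
    seed: int = 0
    out_dir: str = "phalanxfem_runs"
    write_vtk: bool = False
    dogbone_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.specimens < 1 or not self.digits:
            raise ConfigError("need at least one specimen, digit and repeat")
        if self.solver.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.solver.mode not in ("linear", "incremental"):
            raise ConfigError("solver mode must be 'linear' or 'incremental'")
        if self.solver.contact not in ("off", "penalty"):
            raise ConfigError("contact must be 'off' or 'penalty'")
        noisy = (
            self.phantom.noise_sd > 0
            or self.motion.marker_noise_sd > 0
            or self.dogbone_noise_sd > 0
        )
        if noisy and self.seed is None:
            raise ConfigError("a seed is required when any noise source is enabled")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, np.ndarray):
                return [enc(v) for v in obj.tolist()]
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "phantom": PhantomSpec,
            "plate": PlateSpec,
            "calibration": DensityCalibration,
            "motion": MotionConfig,
            "registration": RegistrationConfig,
            "solver": SolverConfig,
            "jitter": JitterConfig,
        }
        kwargs = {}
        for key, cls in sub.items():
            if key in d:
                v = d.pop(key)
                if not isinstance(v, dict):
                    raise ConfigError(f"'{key}' must be a mapping")
                names = {f.name for f in dataclasses.fields(cls)}
                unknown = set(v) - names
                if unknown:
                    raise ConfigError(f"unknown keys in '{key}': {sorted(unknown)}")
                try:
                    kwargs[key] = cls(**v)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid '{key}' config: {exc}") from exc
        names = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "digits" in d:
            d["digits"] = tuple(d["digits"])
        try:
            return RunConfig(**kwargs, **d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SummaryTable:
    """Repeat-level maximum bending moments with grouped aggregates."""

    table: pd.DataFrame  # columns: specimen_id, digit, repeat, max_bending_moment

    def grand(self) -> tuple:
        v = self.table["max_bending_moment"]
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def by(self, column: str) -> pd.DataFrame:
        g = self.table.groupby(column)["max_bending_moment"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9g")

    def grouped_frame(self) -> pd.DataFrame:
        """Specimen x digit layout of 'mean +/- sd' over repeats, with
        per-specimen, per-digit and grand aggregates."""

        def fmt(v):
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            return f"{v.mean():.2f} +/- {sd:.2f}"

        wide = self.table.pivot_table(
            index="specimen_id", columns="digit", values="max_bending_moment",
            aggfunc=fmt,
        )
        wide["by_specimen"] = self.table.groupby("specimen_id")["max_bending_moment"].agg(fmt)
        by_digit = self.table.groupby("digit")["max_bending_moment"].agg(fmt)
        gm, gsd = self.grand()
        footer = {c: by_digit.get(c, "") for c in wide.columns}
        footer["by_specimen"] = f"{gm:.2f} +/- {gsd:.2f}"
        wide.loc["by_digit"] = pd.Series(footer)
        return wide


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - map any stage failure
        raise StageError(name, str(exc)) from exc
    log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _jittered(cfg: RunConfig, s: int, d: int):
    """Per-(specimen, digit) phantom spec and motion, deterministically varied."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101, s, d]))
    j = cfg.jitter
    ph = dataclasses.replace(
        cfg.phantom,
        outer_radius=cfg.phantom.outer_radius * (1 + j.outer_radius * rng.uniform(-1, 1)),
        cortical_hu=float(
            np.clip(cfg.phantom.cortical_hu * (1 + j.cortical_hu * rng.uniform(-1, 1)), 400, 4000)
        ),
        seed=int(rng.integers(2**31 - 1)),
    )
    angle = cfg.motion.flexion_angle_deg * (1 + j.flexion_angle * rng.uniform(-1, 1))
    trans = np.asarray(cfg.motion.translation_mm) * (1 + j.translation * rng.uniform(-1, 1))
    return ph, angle, trans


def calibrate_plate_material(cfg: RunConfig, seed) -> material.MaterialModel:
    curve = synthdata.make_dogbone_curve(noise_sd=cfg.dogbone_noise_sd, seed=seed)
    return material.calibrate(curve)


def build_fragment_masks(cfg: RunConfig, phantom_spec: PhantomSpec):
    """Imaging stages: post-op scan, optional pre-op registration, crop, density.

    Returns (proximal mask, distal mask, density volume).
    """
    post = synthdata.make_phalanx_phantom(phantom_spec)
    reg = cfg.registration
    if reg.enabled:
        intact = synthdata.make_phalanx_phantom(
            dataclasses.replace(phantom_spec, gap_size=0.0, seed=phantom_spec.seed + 1)
        )
        G = RigidTransform.from_axis_angle(
            reg.misalignment_axis, reg.misalignment_deg, reg.misalignment_mm
        )
        preop = imaging.resample_to(
            intact.image, intact.image, G, fill_value=phantom_spec.background_hu
        )
        result = imaging.register_rigid_nmi(
            preop,
            post.image,
            bins=reg.bins,
            finest_spacing=reg.finest_spacing,
            max_iter=reg.max_iter,
        )
        aligned = imaging.resample_to(
            preop, post.image, result.transform, fill_value=phantom_spec.background_hu
        )
    else:
        aligned = synthdata.make_phalanx_phantom(
            dataclasses.replace(phantom_spec, gap_size=0.0, seed=phantom_spec.seed + 1)
        ).image

    mask = imaging.segment_bone(aligned)
    prox, dist = imaging.crop_to_osteotomy(
        mask, post.gap_center, post.gap_normal, phantom_spec.gap_size
    )
    density = imaging.map_density(aligned, mask, cfg.calibration)
    return prox, dist, density


def build_system(cfg: RunConfig, prox, dist, density, mat: material.MaterialModel,
                 phantom_spec: PhantomSpec):
    """Mesh fragments and plate, position the plate dorsally, tie and assemble."""
    sv = cfg.solver
    prox_mesh = voxels_to_tet10(
        prox, density, sv.target_edge, cfg.calibration,
        poisson=sv.bone_poisson, fill_threshold=sv.fill_threshold,
    )
    dist_mesh = voxels_to_tet10(
        dist, density, sv.target_edge, cfg.calibration,
        poisson=sv.bone_poisson, fill_threshold=sv.fill_threshold,
    )
    for mesh in (prox_mesh, dist_mesh):
        block = sv.target_edge * sv.end_cap_depth_factor
        x = mesh.nodes[:, 0]
        mesh.node_sets["end_cap"] = np.nonzero(
            (x <= x.min() + block) if mesh is prox_mesh else (x >= x.max() - block)
        )[0].astype(np.int64)
    bone = combine_meshes(prox_mesh, dist_mesh, "prox", "dist")

    plate = synthdata.make_plate(
        cfg.plate, edge=sv.plate_edge,
        modulus=mat.youngs_modulus, poisson=mat.poisson_ratio,
    )
    lift = phantom_spec.outer_radius
    plate.mesh.nodes = plate.mesh.nodes + np.array([0.0, 0.0, lift])
    divot_prox = plate.divot_proximal + np.array([0.0, 0.0, lift])
    divot_dist = plate.divot_distal + np.array([0.0, 0.0, lift])

    system, tie_report = apply_ties(
        plate.mesh, bone, search_radius=sv.tie_search_radius,
        yield_stress=mat.yield_stress,
    )
    system.set_constraints(
        fixed_nodes=system.mesh.node_sets["bone_prox_end_cap"],
        driven_nodes=system.mesh.node_sets["bone_dist_end_cap"],
    )
    if sv.contact == "penalty":
        # non-penetration of the osteotomy faces at the gap midplane
        from .fem.system import ContactPlane

        g2 = phantom_spec.gap_size / 2.0
        depth = sv.target_edge * sv.end_cap_depth_factor
        x = system.mesh.nodes[:, 0]
        prox_face = np.intersect1d(
            system.mesh.node_sets["bone_prox_nodes"], np.nonzero(x >= -g2 - depth)[0]
        )
        dist_face = np.intersect1d(
            system.mesh.node_sets["bone_dist_nodes"], np.nonzero(x <= g2 + depth)[0]
        )
        system.contact_planes = [
            ContactPlane(prox_face, (0.0, 0.0, 0.0), (-1.0, 0.0, 0.0)),
            ContactPlane(dist_face, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ]
    else:
        system.contact_planes = None
    frame = kinematics.DivotFrame(divot_prox, divot_dist, (1.0, 0.0, 0.0))
    return system, tie_report, frame


def measure_motion(cfg: RunConfig, frame: kinematics.DivotFrame, angle_deg, translation,
                   seed) -> list:
    """Marker simulation + rigid fits + evenly spaced displacement steps."""
    # rotate about the distal divot, then displace the divot by `translation`
    about = RigidTransform.from_axis_angle(
        cfg.motion.rotation_axis, angle_deg
    ).about_point(frame.distal_divot)
    T_true = RigidTransform(about.rotation, about.translation + np.asarray(translation, dtype=float))
    frames = synthdata.make_marker_trajectory(
        T_true,
        cfg.motion.n_marker_frames,
        noise_sd=cfg.motion.marker_noise_sd,
        seed=seed,
        pivot=frame.distal_divot,
    )
    ref = frames[0]
    fin = frames[-1]
    T_prox, _ = kinematics.fit_rigid_transform(ref.proximal, fin.proximal)
    T_dist, _ = kinematics.fit_rigid_transform(ref.distal, fin.distal)
    T_rel = kinematics.relative_transform_at_divot(T_prox, T_dist, frame)
    return kinematics.make_displacement_steps(
        T_rel, n=cfg.solver.n_steps, pivot=frame.distal_divot
    )


def run_single(cfg: RunConfig, specimen: int, digit_index: int, repeat: int,
               out_dir: Path | None = None) -> dict:
    """One digit test: returns the moment curve, its maximum and metadata."""
    ph, angle, trans = _jittered(cfg, specimen, digit_index)
    mat = _stage("calibrate", calibrate_plate_material, cfg,
                 np.random.SeedSequence([int(cfg.seed), 202, specimen, digit_index]))
    prox, dist, density = _stage("imaging", build_fragment_masks, cfg, ph)
    system, tie_report, frame = _stage("mesh", build_system, cfg, prox, dist, density, mat, ph)
    marker_seed = np.random.SeedSequence(
        [int(cfg.seed), 303, specimen, digit_index, repeat]
    )
    steps = _stage("kinematics", measure_motion, cfg, frame, angle, trans, marker_seed)
    results = _stage(
        "solve", system.solve_steps, steps, cfg.solver.mode,
        contact=getattr(system, "contact_planes", None),
    )
    curve = _stage(
        "moment", section.compute_moment_curve, system, results, cfg.solver.station,
        linearize=cfg.solver.mode == "linear",
    )
    m_max = section.max_bending_moment(curve)

    artifacts = {}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        ccsv = out_dir / "moment_curve.csv"
        curve.to_csv(ccsv)
        artifacts["moment_curve"] = str(ccsv)
        if cfg.write_vtk:
            for res in results:
                p = out_dir / f"step_{res.step_index:02d}.vtu"
                write_vtu(
                    system.mesh, p,
                    point_data={"displacement": res.nodal_displacements},
                    cell_data={
                        "modulus": system.mesh.element_modulus,
                        "von_mises": _vm(res.element_stress),
                    },
                )
                artifacts[f"step_{res.step_index}"] = str(p)
    return {
        "max_bending_moment": m_max,
        "curve": curve,
        "n_nodes": system.mesh.n_nodes,
        "n_elements": system.mesh.n_elements,
        "n_ties": tie_report.n_ties,
        "artifacts": artifacts,
    }


def _vm(stress):
    from .fem.tet10 import von_mises

    return von_mises(stress)


def run_pipeline(cfg: RunConfig) -> SummaryTable:
    """Full study: specimens x digits x repeats; writes summary + provenance."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    artifacts = {}
    models = {}
    for s in range(cfg.specimens):
        for d, digit in enumerate(cfg.digits):
            for r in range(cfg.repeats):
                run_dir = out / f"specimen{s + 1}_{digit}_rep{r + 1}"
                res = run_single(cfg, s, d, r, run_dir)
                rows.append(
                    (f"specimen{s + 1}", digit, r + 1, res["max_bending_moment"])
                )
                artifacts.update(res["artifacts"])
                models[run_dir.name] = {
                    k: res[k] for k in ("n_nodes", "n_elements", "n_ties")
                }
                log.info(
                    "run specimen=%d digit=%s repeat=%d M_max=%.4f Nmm",
                    s + 1, digit, r + 1, res["max_bending_moment"],
                )
    table = SummaryTable(
        pd.DataFrame(rows, columns=["specimen_id", "digit", "repeat", "max_bending_moment"])
    )
    summary_csv = out / "summary.csv"
    table.to_csv(summary_csv)
    table.grouped_frame().to_csv(out / "summary_grouped.csv")
    prov = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "versions": _versions(),
        "solver_mode": cfg.solver.mode,
        "models": models,
        "artifacts": {k: _sha256(Path(v)) for k, v in artifacts.items()},
        "summary_checksum": _sha256(summary_csv),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    return table


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"phalanxfem": __version__, "numpy": np.__version__, "scipy": scipy.__version__}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def summarize(table: SummaryTable) -> dict:
    """Grouped means +/- SD and one-way ANOVAs by specimen and by digit."""
    out = {}
    gm, gsd = table.grand()
    out["grand_mean"] = gm
    out["grand_sd"] = gsd
    for col, key in (("specimen_id", "specimen"), ("digit", "digit")):
        agg = table.by(col)
        out[f"by_{key}"] = {
            str(i): {"mean": float(row["mean"]), "sd": float(row["sd"])}
            for i, row in agg.iterrows()
        }
        out[f"anova_{key}"] = one_way_anova(table.table, col)
    return out


def one_way_anova(df: pd.DataFrame, group_col: str,
                  value_col: str = "max_bending_moment") -> dict:
    groups = [g[value_col].to_numpy() for _, g in df.groupby(group_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(df[value_col].to_numpy()) == 0:
        return {"F": 0.0, "p": 1.0, "degenerate": True}
    if all(np.ptp(g) == 0 for g in groups):
        return {"F": float("inf"), "p": 0.0, "degenerate": True}
    F, p = stats.f_oneway(*groups)
    return {"F": float(F), "p": float(p), "degenerate": False}
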