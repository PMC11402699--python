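"""PEEK constitutive calibration from uniaxial dog-bone tension curves.

Engineering stress/strain throughout (consistent with the small-displacement
FE formulation). The elastic constants come from least-squares fits over a
low-strain window; yield uses the 0.2%-offset construction; the post-yield
behaviour is tabulated as (plastic strain, stress) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class MaterialModel:
    """Isotropic elastic-plastic material summary."""

    youngs_modulus: float  # MPa
    poisson_ratio: float
    yield_stress: float  # MPa
    plastic_table: list = field(default_factory=list)  # (plastic_strain, stress MPa)

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")
        if self.yield_stress <= 0:
            raise ValueError("yield stress must be positive")
        stresses = [s for _, s in self.plastic_table]
        if any(b < a - 1e-12 for a, b in zip(stresses, stresses[1:])):
            raise ValueError("plastic table stress must be non-decreasing")

    def to_json(self, path) -> None:
        d = {
            "youngs_modulus_MPa": self.youngs_modulus,
            "poisson_ratio": self.poisson_ratio,
            "yield_stress_MPa": self.yield_stress,
            "plastic_table": [[float(a), float(b)] for a, b in self.plastic_table],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @staticmethod
    def from_json(path) -> "MaterialModel":
        with open(path) as fh:
            d = json.load(fh)
        return MaterialModel(
            d["youngs_modulus_MPa"],
            d["poisson_ratio"],
            d["yield_stress_MPa"],
            [tuple(p) for p in d["plastic_table"]],
        )


DEFAULT_ELASTIC_WINDOW = (0.0005, 0.0025)


def _window_slice(strain: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    sel = (strain >= lo) & (strain <= hi)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 samples in strain window [{lo}, {hi}]")
    return sel


def fit_elastic_modulus(curve, window=DEFAULT_ELASTIC_WINDOW) -> float:
    """OLS slope (free intercept) of stress vs strain inside the window, MPa."""
    sel = _window_slice(curve.axial_strain, window)
    slope, _ = np.polyfit(curve.axial_strain[sel], curve.axial_stress[sel], 1)
    return float(slope)


def fit_poisson(curve, window=DEFAULT_ELASTIC_WINDOW) -> float:
    """Minus the OLS slope of lateral vs axial strain inside the window."""
    if curve.lateral_strain is None:
        raise ValueError("curve has no lateral strain channel")
    sel = _window_slice(curve.axial_strain, window)
    slope, _ = np.polyfit(curve.axial_strain[sel], curve.lateral_strain[sel], 1)
    return float(-slope)


def offset_yield(curve, E: float, offset: float = 0.002) -> float:
    """Stress at the first crossing of the curve with the line s = E (e - offset).

    Linear interpolation between samples; raises when the curve never meets
    the offset line (purely elastic data).
    """
    eps = curve.axial_strain
    sig = curve.axial_stress
    g = sig - E * (eps - offset)  # non-negative in the elastic region
    tol = 1e-9 * max(1.0, float(np.abs(sig).max()))
    both_zero = (np.abs(g[:-1]) <= tol) & (np.abs(g[1:]) <= tol)
    down = (g[:-1] >= -tol) & (g[1:] <= tol) & ~both_zero
    cross = np.nonzero(down)[0]
    if cross.size == 0:
        raise ValueError("no intersection with the offset line: curve looks purely elastic")
    i = int(cross[0])
    w = 0.0 if g[i] == g[i + 1] else g[i] / (g[i] - g[i + 1])
    return float(sig[i] + w * (sig[i + 1] - sig[i]))


def extract_plastic_table(
    curve, E: float, offset: float = 0.002, policy: str = "reject"
):
    """Convert post-yield samples to (plastic strain, stress) pairs.

    Plastic strain is ``e - s/E``; the table starts at (0, yield_stress).
    ``policy`` controls softening samples: "reject" raises, "clip" enforces a
    non-decreasing stress by running-maximum.
    """
    sy = offset_yield(curve, E, offset)
    eps_star = offset + sy / E  # total strain at the offset intersection
    eps = curve.axial_strain
    sig = curve.axial_stress
    post = eps > eps_star
    table = [(0.0, float(sy))]
    if post.any():
        ep = eps[post] - sig[post] / E
        sp = sig[post].astype(float)
        keep = ep > 1e-12
        ep, sp = ep[keep], sp[keep]
        if np.any(np.diff(np.concatenate([[sy], sp])) < -1e-9):
            if policy == "reject":
                raise ValueError("softening detected in post-yield data")
            sp = np.maximum.accumulate(np.concatenate([[sy], sp]))[1:]
        table += [(float(a), float(b)) for a, b in zip(ep, sp)]
    return table


def calibrate(curve, window=DEFAULT_ELASTIC_WINDOW, offset: float = 0.002,
              policy: str = "clip") -> MaterialModel:
    """Full calibration: E, nu, offset yield and plastic table from one curve."""
    E = fit_elastic_modulus(curve, window)
    nu = fit_poisson(curve, window)
    table = extract_plastic_table(curve, E, offset, policy)
    return MaterialModel(E, nu, table[0][1], table)
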