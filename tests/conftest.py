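import numpy as np
import pytest

from phalanxfem.fem import FESystem, blocks_to_tet10
from phalanxfem.synthdata import PhantomSpec, make_phalanx_phantom
from phalanxfem.transforms import RigidTransform

CANTILEVER = dict(L=20.0, b=1.0, h=1.0, edge=0.5, E=1740.5, nu=0.3779, delta=0.1)


def box_mesh(L, b, h, edge, E, nu):
    nx, ny, nz = round(L / edge), max(1, round(b / edge)), max(1, round(h / edge))
    bidx = np.array([[i, j, k] for i in range(nx) for j in range(ny) for k in range(nz)])
    return blocks_to_tet10(bidx, (L / nx, b / ny, h / nz), (0.0, 0.0, 0.0), E, nu)


@pytest.fixture(scope="session")
def cantilever():
    """Slender square-section cantilever with an imposed transverse tip
    deflection (rotation left free): the classic Euler-Bernoulli oracle."""
    p = CANTILEVER
    mesh = box_mesh(p["L"], p["b"], p["h"], p["edge"], p["E"], p["nu"])
    system = FESystem(mesh)
    x = mesh.nodes[:, 0]
    fixed = np.nonzero(x < 1e-9)[0]
    tip = np.nonzero(x > p["L"] - 1e-9)[0]
    system.set_constraints(fixed, tip, driven_components=(False, False, True))
    result = system.solve_step(RigidTransform(np.eye(3), [0.0, 0.0, p["delta"]]))
    return {"mesh": mesh, "system": system, "result": result,
            "fixed": fixed, "tip": tip, **p}


@pytest.fixture(scope="session")
def coarse_phantom():
    """Noiseless phantom at a coarse test voxel size (fast to generate)."""
    spec = PhantomSpec(voxel_size=0.25, noise_sd=0.0)
    return make_phalanx_phantom(spec)
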