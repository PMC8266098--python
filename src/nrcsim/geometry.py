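"""Construct geometry, axisymmetric (r, z) finite-volume mesh and seeding
profiles.

The construct is a collagen cylinder (core, radius R1, length L) wrapped
in an annular sheath of thickness T. The sheath may be impermeable
(Lp = 0 or porosity 0), fully porous (2 Lp = L) or porous only over a
length Lp at each end. All boundary and initial conditions are
independent of the azimuthal angle, so the 3D problem reduces exactly to
an axisymmetric (r, z) one; fields are stored at cell centres with
axisymmetric volume weights pi (r_o^2 - r_i^2) dz.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .parameters import STRUCTURES, tortuosity

__all__ = ["ConstructGeometry", "SeedingSpec", "seeding_profile",
           "Mesh", "build_mesh"]


@dataclass(frozen=True)
class ConstructGeometry:
    """Cylinder-core / annular-sheath geometry (SI units).

    ``Lp`` is the porous end-zone length: the sheath is porous over
    z in [0, Lp] and [L - Lp, L] (2 Lp in total). Lp = 0 means fully
    impermeable, 2 Lp = L fully porous.
    """

    L: float = 1.50e-2
    R1: float = 2.50e-4
    T: float = 2.50e-4
    Lp: float = 0.0
    epsilon: float = 0.8
    structure: str = "spheres"

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.R1 > 0 and self.T > 0):
            raise ValueError("L, R1 and T must be strictly positive")
        if not 0.0 <= self.Lp <= self.L / 2 + 1e-15:
            raise ValueError("porous zone length must satisfy 0 <= Lp <= L/2")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("porosity must lie in [0, 1]")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")

    @property
    def R2(self) -> float:
        return self.R1 + self.T

    @property
    def is_impermeable(self) -> bool:
        return self.Lp == 0.0 or self.epsilon == 0.0

    @property
    def fully_porous(self) -> bool:
        return not self.is_impermeable and 2 * self.Lp >= self.L - 1e-15

    def tau(self) -> float:
        """Sheath tortuosity for the configured structure and porosity."""
        return tortuosity(self.structure, self.epsilon)

    @property
    def core_volume(self) -> float:
        return math.pi * self.R1 ** 2 * self.L

    def replace(self, **changes) -> "ConstructGeometry":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SeedingSpec:
    """Initial axial cell-density profile.

    ``uniform`` mode seeds a constant density ``n0`` (cell m^-3).
    ``three_zone`` mode splits a total cell number ``n0_tot`` between the
    two stump-adjacent thirds and the central third of the core; the
    repartition factor ``zeta`` scales the central zone (zeta = 1 is
    uniform, zeta > 1 concentrates cells centrally). The volume integral
    of the profile equals ``n0_tot`` for every zeta by construction.
    """

    mode: str = "uniform"
    n0: float = 0.0
    n0_tot: float = 0.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "three_zone"):
            raise ValueError(f"unknown seeding mode {self.mode!r}")
        if self.mode == "uniform" and self.n0 < 0:
            raise ValueError("uniform seeding density must be non-negative")
        if self.mode == "three_zone":
            if self.n0_tot < 0:
                raise ValueError("total cell number must be non-negative")
            if self.zeta < 0:
                raise ValueError("repartition factor zeta must be >= 0")

    @classmethod
    def uniform(cls, n0: float) -> "SeedingSpec":
        return cls(mode="uniform", n0=n0)

    @classmethod
    def three_zone(cls, n0_tot: float, zeta: float) -> "SeedingSpec":
        return cls(mode="three_zone", n0_tot=n0_tot, zeta=zeta)

    def replace(self, **changes) -> "SeedingSpec":
        return dataclasses.replace(self, **changes)


def seeding_profile(spec: SeedingSpec, geometry: ConstructGeometry, z):
    """Initial cell density n0(z) in cell m^-3 at axial positions z."""
    z = np.asarray(z, dtype=float)
    if spec.mode == "uniform":
        return np.full_like(z, spec.n0)
    base = 3.0 * spec.n0_tot / (
        (2.0 + spec.zeta) * math.pi * geometry.R1 ** 2 * geometry.L)
    out = np.full_like(z, base)
    central = (z >= geometry.L / 3.0) & (z < 2.0 * geometry.L / 3.0)
    out[central] = spec.zeta * base
    return out


@dataclass
class Mesh:
    """Structured axisymmetric cell-centred mesh.

    Core cells are indexed (iz, jr) with jr = 0 on the axis; the sheath
    block exists only over the porous z-columns. ``sheath_active`` marks
    those columns; over impermeable columns the gel sees a zero-flux wall
    at r = R1 and the sheath is not discretised at all.
    """

    geometry: ConstructGeometry
    nz: int
    nr_core: int
    nr_sheath: int
    z_faces: np.ndarray
    r_faces_core: np.ndarray
    r_faces_sheath: np.ndarray
    sheath_active: np.ndarray  # (nz,) bool

    # derived
    z_centers: np.ndarray = None
    r_centers_core: np.ndarray = None
    r_centers_sheath: np.ndarray = None
    core_volumes: np.ndarray = None  # (nz, nr_core)
    sheath_volumes: np.ndarray = None  # (nr_sheath,) per column

    def __post_init__(self) -> None:
        self.z_centers = 0.5 * (self.z_faces[1:] + self.z_faces[:-1])
        self.r_centers_core = 0.5 * (self.r_faces_core[1:]
                                     + self.r_faces_core[:-1])
        dz = np.diff(self.z_faces)
        ring_core = math.pi * (self.r_faces_core[1:] ** 2
                               - self.r_faces_core[:-1] ** 2)
        self.core_volumes = dz[:, None] * ring_core[None, :]
        if self.nr_sheath > 0:
            self.r_centers_sheath = 0.5 * (self.r_faces_sheath[1:]
                                           + self.r_faces_sheath[:-1])
            ring_sheath = math.pi * (self.r_faces_sheath[1:] ** 2
                                     - self.r_faces_sheath[:-1] ** 2)
            # uniform dz; per-column ring volumes
            self.sheath_volumes = dz[0] * ring_sheath
        else:
            self.r_centers_sheath = np.empty(0)
            self.sheath_volumes = np.empty(0)

    @property
    def dz(self) -> float:
        return float(self.z_faces[1] - self.z_faces[0])

    @property
    def dr_core(self) -> float:
        return float(self.r_faces_core[1] - self.r_faces_core[0])

    @property
    def dr_sheath(self) -> float:
        if self.nr_sheath == 0:
            return 0.0
        return float(self.r_faces_sheath[1] - self.r_faces_sheath[0])

    @property
    def n_core(self) -> int:
        return self.nz * self.nr_core

    @property
    def active_iz(self) -> np.ndarray:
        return np.flatnonzero(self.sheath_active)

    @property
    def n_sheath(self) -> int:
        return int(self.sheath_active.sum()) * self.nr_sheath

    @property
    def n_total(self) -> int:
        """Number of solute nodes (core + active sheath cells)."""
        return self.n_core + self.n_sheath

    def core_index(self, iz, jr):
        return iz * self.nr_core + jr

    def sheath_index(self, a, jr):
        """Index of sheath cell in active column slot ``a`` (0-based among
        active columns), radial layer jr."""
        return self.n_core + a * self.nr_sheath + jr

    def core_field(self, flat):
        """Reshape a flat core vector to (nz, nr_core)."""
        return np.asarray(flat)[: self.n_core].reshape(self.nz, self.nr_core)


def build_mesh(geometry: ConstructGeometry, nz: int = 99,
               nr_core: int = 12, nr_sheath: int = 8) -> Mesh:
    """Build the structured axisymmetric mesh.

    The porous-zone boundary Lp is snapped to the nearest z-face. With an
    impermeable sheath the sheath block is omitted entirely. Use
    ``nr_core = 1`` for the exact 1D axial reduction (valid when the
    sheath is impermeable and the initial conditions are r-uniform).
    """
    if nz < 8:
        raise ValueError("nz must be at least 8")
    if nr_core < 1:
        raise ValueError("nr_core must be at least 1")
    z_faces = np.linspace(0.0, geometry.L, nz + 1)
    r_faces_core = np.linspace(0.0, geometry.R1, nr_core + 1)

    if geometry.is_impermeable:
        sheath_active = np.zeros(nz, dtype=bool)
        nr_sheath = 0
        r_faces_sheath = np.empty(0)
    else:
        if nr_sheath < 1:
            raise ValueError("nr_sheath must be >= 1 for a porous sheath")
        r_faces_sheath = np.linspace(geometry.R1, geometry.R2, nr_sheath + 1)
        z_centers = 0.5 * (z_faces[1:] + z_faces[:-1])
        # snap Lp to the nearest face
        lp_snapped = z_faces[int(np.argmin(np.abs(z_faces - geometry.Lp)))]
        if geometry.fully_porous:
            sheath_active = np.ones(nz, dtype=bool)
        else:
            sheath_active = (z_centers < lp_snapped) | (
                z_centers > geometry.L - lp_snapped)
    return Mesh(geometry=geometry, nz=nz, nr_core=nr_core,
                nr_sheath=nr_sheath, z_faces=z_faces,
                r_faces_core=r_faces_core, r_faces_sheath=r_faces_sheath,
                sheath_active=sheath_active)
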