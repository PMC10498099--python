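"""Synthetic voxel phantoms and benchmark beam/phantom presets.

Grids are Cartesian with the beam axis along +z.  World coordinates are
in mm with the origin at the corner of the first voxel; the beam axis
passes through the transverse centre of the grid and the phantom surface
lies at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import default_conversion_table, hu_to_material

__all__ = ["VoxelPhantom", "PhantomSpec", "make_phantom", "standard_benchmarks"]


@dataclass
class VoxelPhantom:
    """Cartesian grid of mass / electron / core densities."""

    spacing_mm: tuple[float, float, float]
    rho: np.ndarray  # g/cm^3, shape (I, J, K); z is the last axis
    rho_e: np.ndarray  # relative to water
    rho_c: np.ndarray  # relative to water
    name: str = "phantom"

    def __post_init__(self) -> None:
        if min(self.spacing_mm) <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.rho.min() < 0:
            raise ValueError("densities must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.rho.shape

    @property
    def size_mm(self) -> tuple[float, float, float]:
        return tuple(d * s for d, s in zip(self.dims, self.spacing_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along an axis, mm."""
        n = self.dims[axis]
        h = self.spacing_mm[axis]
        return (np.arange(n) + 0.5) * h

    def central_index(self, axis: int) -> int:
        return self.dims[axis] // 2


@dataclass
class PhantomSpec:
    name: str
    size_mm: tuple[float, float, float] = (300.0, 300.0, 300.0)
    voxel_mm: float = 2.5
    base_density: float = 1.0  # g/cm^3
    base_hu: float = 0.0
    block_size_mm: tuple[float, float, float] | None = None
    block_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    block_density: float | None = None
    extra: dict = field(default_factory=dict)


_PRESET_DENSITIES = {"water": 1.0, "lung": 0.25, "bone": 1.3}
INHOMOGENEITY_DENSITIES = (0.0, 0.23, 1.51, 4.50)


def make_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Build a phantom from a spec or a named preset.

    Presets ``water``/``lung``/``bone`` are homogeneous slabs of the
    stated mass density; densities scale the water electron and core
    densities (water-equivalent composition throughout, so rho_e = rho_c
    = rho relative to water).
    """
    h = spec.voxel_mm
    dims = tuple(int(round(s / h)) for s in spec.size_mm)
    if min(dims) < 1:
        raise ValueError(f"invalid phantom dims {dims}")
    base = _PRESET_DENSITIES.get(spec.name, spec.base_density)
    rho = np.full(dims, base, dtype=float)
    if spec.block_size_mm is not None:
        if spec.block_density is None:
            raise ValueError("block_density required with block_size_mm")
        centre = np.array(spec.size_mm) / 2.0 + np.array(spec.block_offset_mm)
        half = np.array(spec.block_size_mm) / 2.0
        lo = np.maximum(np.round((centre - half) / h).astype(int), 0)
        hi = np.minimum(np.round((centre + half) / h).astype(int), dims)
        if np.any(lo < 0) or np.any(hi > dims):
            raise ValueError("inhomogeneity block outside phantom")
        rho[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = spec.block_density
    return VoxelPhantom(
        spacing_mm=(h, h, h), rho=rho, rho_e=rho.copy(), rho_c=rho.copy(),
        name=spec.name,
    )


def phantom_from_hu(hu_grid: np.ndarray, voxel_mm: float, name: str = "ct") -> VoxelPhantom:
    """Phantom from an HU grid via the stoichiometric conversion table."""
    table = default_conversion_table()
    rho = np.zeros_like(hu_grid, dtype=float)
    rho_e = np.zeros_like(rho)
    rho_c = np.zeros_like(rho)
    for hu in np.unique(hu_grid):
        m = hu_to_material(float(hu), table)
        mask = hu_grid == hu
        rho[mask] = m.rho
        rho_e[mask] = m.rho_e
        rho_c[mask] = m.rho_c
    return VoxelPhantom((voxel_mm,) * 3, rho, rho_e, rho_c, name=name)


def standard_benchmarks(voxel_mm: float = 2.5) -> dict:
    """Named beam+phantom validation configurations.

    ``photon``: 100 x 100 mm field, SAD 1000 mm, SSD 850 mm on a 300 mm
    water cube.  ``proton``: 100 x 100 mm passively scattered beam, SAD
    2300 mm, SSD 2150 mm, energy layers spanning 115-174 MeV (SOBP from
    100 to 200 mm).  ``*_small`` variants use a 5 mm grid and a reduced
    transverse extent for desk-scale runs.
    """
    from .sources import PhotonHeadModel, ProtonBeamModel  # cycle guard

    def photon(vx, size):
        return {
            "particle": "photon",
            "phantom": PhantomSpec("water", size_mm=size, voxel_mm=vx),
            "beam": PhotonHeadModel(field_mm=(100.0, 100.0), ssd_mm=850.0),
        }

    def proton(vx, size):
        # layer ranges span the 115-174 MeV energy window (SOBP roughly
        # from 100 to 200 mm depth under the range-energy relation)
        from .materials import csda_range

        return {
            "particle": "proton",
            "phantom": PhantomSpec("water", size_mm=size, voxel_mm=vx),
            "beam": ProtonBeamModel(
                field_mm=(100.0, 100.0), ssd_mm=2150.0,
                sobp_span_mm=(csda_range(115.0), csda_range(174.0)),
                n_layers=100,  # beams are implicitly split into 100 layers
            ),
        }

    return {
        "photon": photon(voxel_mm, (300.0, 300.0, 300.0)),
        "proton": proton(voxel_mm, (300.0, 300.0, 300.0)),
        "photon_small": photon(5.0, (200.0, 200.0, 300.0)),
        "proton_small": proton(5.0, (200.0, 200.0, 300.0)),
    }
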