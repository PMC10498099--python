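"""Fluence -> absorbed dose conversion, normalisation and curve extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelPhantom
from .quadrature import EnergyGrid

log = logging.getLogger(__name__)

__all__ = [
    "DoseGrid",
    "dose_from_fluence",
    "normalize_pair",
    "extract_curves",
    "toy_dvh",
]


@dataclass
class DoseGrid:
    values: np.ndarray  # (I, J, K), relative units (or % after normalisation)
    spacing_mm: tuple[float, float, float]
    normalisation: float = 1.0
    vacuum_mask: np.ndarray | None = None  # True where rho = 0 (dose forced 0)

    @property
    def dims(self):
        return self.values.shape

    def max(self) -> float:
        return float(self.values.max())


def dose_from_fluence(
    fluence: np.ndarray,
    stopping_power,
    grid: EnergyGrid,
    phantom: VoxelPhantom,
) -> DoseGrid:
    """D = (1/rho) sum_g S(E_g) sum_n Phi[n, g].

    ``stopping_power`` maps energy in MeV to mass collision stopping
    power (MeV cm^2/g).  Vacuum voxels (rho = 0) are reported as zero
    dose and flagged.
    """
    s = np.asarray(stopping_power(grid.group_energy), dtype=float)
    angular_sum = fluence.sum(axis=0)  # (G, I, J, K)
    energy_sum = np.tensordot(s, angular_sum, axes=(0, 0))
    vacuum = phantom.rho <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(vacuum, 0.0, energy_sum / np.where(vacuum, 1.0, phantom.rho))
    if vacuum.any():
        log.info("dose forced to zero in %d vacuum voxels", int(vacuum.sum()))
    return DoseGrid(d, phantom.spacing_mm, vacuum_mask=vacuum)


def normalize_pair(lbte: DoseGrid, comparator: np.ndarray):
    """Scale so the 3-D LBTE maximum is 100%; same factor for the comparator."""
    m = lbte.max()
    if m <= 0.0:
        raise ValueError("cannot normalise an all-zero dose grid")
    factor = 100.0 / m
    out = DoseGrid(
        lbte.values * factor, lbte.spacing_mm, normalisation=factor,
        vacuum_mask=lbte.vacuum_mask,
    )
    return out, np.asarray(comparator) * factor


def extract_curves(
    dose: DoseGrid,
    profile_depth_mm: float = 150.0,
    comparator: DoseGrid | np.ndarray | None = None,
    low_dose_cut: float = 0.05,
):
    """Central-axis depth dose and a lateral profile at the stated depth.

    Returns a dict with ``depth_mm``/``depth_dose``, ``lateral_mm``/
    ``profile`` and, when a comparator grid is given, percent-of-local-
    dose difference curves (points below ``low_dose_cut`` of the maximum
    are reported as NaN and excluded from difference statistics).
    """
    hx, hy, hz = dose.spacing_mm
    ic = dose.dims[0] // 2
    jc = dose.dims[1] // 2
    kz = min(int(profile_depth_mm / hz), dose.dims[2] - 1)
    depth = (np.arange(dose.dims[2]) + 0.5) * hz
    lateral = (np.arange(dose.dims[0]) + 0.5) * hx - dose.dims[0] * hx / 2.0
    out = {
        "depth_mm": depth,
        "depth_dose": dose.values[ic, jc, :].copy(),
        "lateral_mm": lateral,
        "profile": dose.values[:, jc, kz].copy(),
        "profile_depth_mm": (kz + 0.5) * hz,
    }
    if comparator is not None:
        comp = comparator.values if isinstance(comparator, DoseGrid) else comparator
        for key, sl in (("depth", (ic, jc, slice(None))), ("profile", (slice(None), jc, kz))):
            a = dose.values[sl]
            b = comp[sl]
            local = np.where(np.abs(b) > 0, b, np.nan)
            diff = 100.0 * (a - b) / local
            cut = max(a.max(), b.max()) * low_dose_cut
            diff = np.where(np.maximum(a, b) >= cut, diff, np.nan)
            out[f"{key}_diff_pct"] = diff
    return out


def toy_dvh(dose: DoseGrid, mask: np.ndarray, bins: int = 100):
    """Cumulative dose-volume histogram over a boolean voxel mask.

    Smoke-test helper only (no clinical structure handling).  Returns
    (dose_axis, volume_fraction) where volume_fraction[i] is the
    fraction of masked voxels receiving at least dose_axis[i].
    """
    vals = dose.values[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    axis = np.linspace(0.0, float(vals.max()), bins)
    frac = (vals[None, :] >= axis[:, None]).mean(axis=1)
    return axis, frac
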