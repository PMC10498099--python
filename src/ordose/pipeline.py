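"""End-to-end calculation drivers joining sources, transport and dose."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import analytic, materials, sources, transport, xsections
from .dose import DoseGrid, dose_from_fluence, normalize_pair
from .phantoms import VoxelPhantom
from .quadrature import (
    AngularQuadrature,
    EnergyGrid,
    build_energy_grid,
    build_fine_angular_quadrature,
    build_standard_angular_quadrature,
)

log = logging.getLogger(__name__)

__all__ = ["CalcResult", "run_photon", "run_proton", "analytic_comparator"]


@dataclass
class CalcResult:
    dose: DoseGrid
    total_fluence: np.ndarray
    unscattered: np.ndarray
    trace: transport.ConvergenceTrace | None = None
    electron_trace: transport.ConvergenceTrace | None = None
    timings: dict = field(default_factory=dict)
    checkpoints: dict = field(default_factory=dict)  # iteration -> DoseGrid


def _quadrature(kind: str) -> AngularQuadrature:
    if kind == "standard":
        return build_standard_angular_quadrature()
    if kind == "fine":
        return build_fine_angular_quadrature()
    raise ValueError(f"unknown quadrature kind {kind!r}")


def _centre_probe(phantom: VoxelPhantom, depth_mm: float = 150.0):
    ic, jc = phantom.dims[0] // 2, phantom.dims[1] // 2
    kc = min(int(depth_mm / phantom.spacing_mm[2]), phantom.dims[2] - 1)

    def probe(fluence):
        return float(fluence[:, :, ic, jc, kc].sum())

    return probe


def run_photon(
    phantom: VoxelPhantom,
    beam: sources.PhotonHeadModel,
    quadrature: str | AngularQuadrature = "standard",
    n_iterations: int = 5,
    adaptive: bool = False,
    kernel: sources.UncertaintyKernel | None = None,
    probe_depth_mm: float = 150.0,
) -> CalcResult:
    """Photon LBTE dose: photon solve, Compton fixed source, electron solve."""
    t0 = time.perf_counter()
    quad = _quadrature(quadrature) if isinstance(quadrature, str) else quadrature
    pgrid = build_energy_grid("photon")
    egrid = build_energy_grid("electron")
    ctables = xsections.build_compton_tables(quad, pgrid, egrid)
    etables = xsections.build_electron_tables(egrid, quad)
    phi0 = sources.photon_unscattered_fluence(beam, phantom, pgrid)
    unscat = sources.distribute_unscattered(
        phi0, beam.couch_deg, beam.gantry_deg, quad, kernel, phantom.spacing_mm
    ).astype(np.float32)
    del phi0
    mask = transport.build_adaptive_mask(unscat, "photon") if adaptive else None
    t1 = time.perf_counter()
    probe = _centre_probe(phantom, probe_depth_mm)
    total, _scat, trace = transport.solve_photon_transport(
        unscat, ctables, phantom, n_iterations, mask, probe
    )
    t2 = time.perf_counter()
    q_fix = transport.electron_fixed_source(total, ctables, phantom.rho_e)
    phi_e, etrace = transport.solve_electron_transport(
        q_fix, etables, phantom, n_iterations, mask, probe
    )
    t3 = time.perf_counter()
    dose = dose_from_fluence(
        phi_e, materials.electron_stopping_power, egrid, phantom
    )
    return CalcResult(
        dose=dose,
        total_fluence=total,
        unscattered=unscat,
        trace=trace,
        electron_trace=etrace,
        timings={
            "sources_s": t1 - t0,
            "photon_solve_s": t2 - t1,
            "electron_solve_s": t3 - t2,
        },
    )


def run_proton(
    phantom: VoxelPhantom,
    beam: sources.ProtonBeamModel,
    quadrature: str | AngularQuadrature = "standard",
    n_iterations: int = 5,
    adaptive: bool = False,
    kernel: sources.UncertaintyKernel | None = None,
    probe_depth_mm: float = 150.0,
    stopping_power=None,
    checkpoint_iterations: tuple = (),
) -> CalcResult:
    """Proton LBTE dose: CSDA fixed fluence plus elastic Mott transport.

    ``checkpoint_iterations`` requests additional dose grids captured
    after the stated iteration counts (the solve is warm-started between
    checkpoints, so the result is identical to independent longer runs).
    """
    t0 = time.perf_counter()
    quad = _quadrature(quadrature) if isinstance(quadrature, str) else quadrature
    grid = build_energy_grid("proton")
    ptables = xsections.build_proton_tables(grid, quad)
    phi0 = sources.proton_unscattered_fluence(beam, phantom, grid, ptables.mott_tot)
    unscat = sources.distribute_unscattered(
        phi0, beam.couch_deg, beam.gantry_deg, quad, kernel, phantom.spacing_mm
    ).astype(np.float32)  # large tensors: single precision is ample
    del phi0
    mask = transport.build_adaptive_mask(unscat, "proton") if adaptive else None
    t1 = time.perf_counter()
    probe = _centre_probe(phantom, probe_depth_mm)
    # group-averaged stopping keeps the staircase deposition energy-true
    stopping = stopping_power or materials.multigroup_stopping_power(grid)
    stages = sorted(set(checkpoint_iterations) | {n_iterations})
    done = 0
    phi_scat = None
    trace = transport.ConvergenceTrace()
    checkpoints = {}
    for stage in stages:
        total, phi_scat, tr = transport.solve_proton_transport(
            unscat, ptables, phantom, stage - done, mask, probe,
            tau=beam.tau, initial_scattered=phi_scat,
        )
        trace.probes.extend((it + done, v) for it, v in tr.probes)
        done = stage
        if stage in checkpoint_iterations:
            checkpoints[stage] = dose_from_fluence(total, stopping, grid, phantom)
    t2 = time.perf_counter()
    dose = dose_from_fluence(total, stopping, grid, phantom)
    return CalcResult(
        dose=dose,
        total_fluence=total,
        unscattered=unscat,
        trace=trace,
        timings={"sources_s": t1 - t0, "proton_solve_s": t2 - t1},
        checkpoints=checkpoints,
    )


def analytic_comparator(
    beam: sources.ProtonBeamModel,
    phantom: VoxelPhantom,
    delta_mm: float = analytic.STRAGGLE_DELTA_MM,
    loss_model: str = "linear",
) -> np.ndarray:
    """Central-axis analytic SOBP on the phantom's depth axis.

    Shares the beam's energy layers, nuclear-loss constant and geometry
    (inverse square) so the comparison isolates the transport treatment.
    """
    config = analytic.AnalyticBeamConfig(
        layers=beam.energy_layers(),
        delta_mm=delta_mm,
        loss_model=loss_model,
        lam=beam.lam,
        ssd_mm=beam.ssd_mm,
    )
    depth = phantom.axis_coords(2)
    ic, jc = phantom.dims[0] // 2, phantom.dims[1] // 2
    density = float(phantom.rho[ic, jc, 0])
    return analytic.analytic_sobp(
        config, depth, density=density, bin_mm=phantom.spacing_mm[2]
    )
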