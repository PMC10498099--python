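"""Iterative discrete-ordinates transport: sources, sweeps and solvers.

The spatial closure is the published hybrid: the cell-centre equation
uses diamond-difference coefficients (2*|mu|/dx etc.) while the outflow
faces take the centre value (step closure), so the inflow of the next
cell along the sweep equals the centre value of the current cell.
Boundary inflow is vacuum (zero).

Per iteration the scatter sources are rebuilt and one sweep is carried
out per ordinate and group; groups are processed in descending energy so
that down-scatter reads already-updated fluence within the iteration.
Ordinate sweeps are mutually independent (results do not depend on
their ordering).

Cell solves use a numba-compiled kernel when numba is importable and
fall back to a pure-python implementation otherwise (adequate for the
small grids used in unit tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .materials import WATER_ELECTRONS_PER_GRAM
from .phantoms import VoxelPhantom
from .quadrature import AngularQuadrature, EnergyGrid
from .xsections import ComptonTables, ElectronXSTables, ProtonXSTables

log = logging.getLogger(__name__)

__all__ = [
    "AdaptiveMask",
    "sweep_cell",
    "transport_sweep",
    "photon_scatter_source",
    "electron_fixed_source",
    "solve_photon_transport",
    "solve_electron_transport",
    "solve_proton_transport",
    "build_adaptive_mask",
    "ADAPTIVE_THRESHOLDS",
]

# electrons per mm^3 of unit-density water (pairs relative rho_e with
# physical photon/Moller cross sections in mm^2)
WATER_ELECTRONS_PER_MM3 = WATER_ELECTRONS_PER_GRAM / 1000.0

ADAPTIVE_THRESHOLDS = {"photon": 0.20, "proton": 0.05}


def sweep_cell(inflow_x, inflow_y, inflow_z, q, sigma, spacings, cosines):
    """Solve one voxel of the hybrid diamond/step sweep.

    Returns (centre, (out_x, out_y, out_z)); the outflow faces replicate
    the centre value.  ``cosines`` are the magnitudes of the direction
    cosines on the upwind axes; ``sigma`` is the macroscopic removal
    cross section (1/mm).
    """
    mu, eta, xi = (abs(c) for c in cosines)
    dx, dy, dz = spacings
    if mu == 0.0 and eta == 0.0 and xi == 0.0:
        raise ValueError("all three direction cosines are zero")
    cx, cy, cz = 2.0 * mu / dx, 2.0 * eta / dy, 2.0 * xi / dz
    centre = (cx * inflow_x + cy * inflow_y + cz * inflow_z + q) / (
        cx + cy + cz + sigma
    )
    return centre, (centre, centre, centre)


def _sweep_grid_python(phi, q, sigma, mu, eta, xi, dx, dy, dz, merged):
    ni, nj, nk = phi.shape
    sx = 1 if mu >= 0.0 else -1
    sy = 1 if eta >= 0.0 else -1
    sz = 1 if xi >= 0.0 else -1
    am, ae, ax = abs(mu), abs(eta), abs(xi)
    ri = range(ni) if sx > 0 else range(ni - 1, -1, -1)
    rj = range(nj) if sy > 0 else range(nj - 1, -1, -1)
    rk = range(nk) if sz > 0 else range(nk - 1, -1, -1)
    for i in ri:
        for j in rj:
            for k in rk:
                if merged is not None and merged[i, j, k]:
                    bi, bj, bk = 4 * (i // 4), 4 * (j // 4), 4 * (k // 4)
                    ci = bi if sx > 0 else bi + 3
                    cj = bj if sy > 0 else bj + 3
                    ck = bk if sz > 0 else bk + 3
                    if i != ci or j != cj or k != ck:
                        continue
                    iu, ju, ku = ci - sx, cj - sy, ck - sz
                    fx = fy = fz = 0.0
                    qs = ss = 0.0
                    for a in range(4):
                        for b in range(4):
                            if 0 <= iu < ni:
                                fx += phi[iu, bj + a, bk + b]
                            if 0 <= ju < nj:
                                fy += phi[bi + a, ju, bk + b]
                            if 0 <= ku < nk:
                                fz += phi[bi + a, bj + b, ku]
                    fx /= 16.0
                    fy /= 16.0
                    fz /= 16.0
                    for a in range(4):
                        for b in range(4):
                            for c in range(4):
                                qs += q[bi + a, bj + b, bk + c]
                                ss += sigma[bi + a, bj + b, bk + c]
                    qs /= 64.0
                    ss /= 64.0
                    cx = 2.0 * am / (4.0 * dx)
                    cy = 2.0 * ae / (4.0 * dy)
                    cz = 2.0 * ax / (4.0 * dz)
                    val = (cx * fx + cy * fy + cz * fz + qs) / (cx + cy + cz + ss)
                    for a in range(4):
                        for b in range(4):
                            for c in range(4):
                                phi[bi + a, bj + b, bk + c] = val
                    continue
                fx = phi[i - sx, j, k] if 0 <= i - sx < ni else 0.0
                fy = phi[i, j - sy, k] if 0 <= j - sy < nj else 0.0
                fz = phi[i, j, k - sz] if 0 <= k - sz < nk else 0.0
                cx = 2.0 * am / dx
                cy = 2.0 * ae / dy
                cz = 2.0 * ax / dz
                phi[i, j, k] = (cx * fx + cy * fy + cz * fz + q[i, j, k]) / (
                    cx + cy + cz + sigma[i, j, k]
                )


try:  # pragma: no cover - exercised when numba is installed
    import numba

    _sweep_grid_merged = numba.njit(cache=True)(_sweep_grid_python)

    @numba.njit(cache=True)
    def _sweep_grid_plain(phi, q, sigma, mu, eta, xi, dx, dy, dz):
        ni, nj, nk = phi.shape
        sx = 1 if mu >= 0.0 else -1
        sy = 1 if eta >= 0.0 else -1
        sz = 1 if xi >= 0.0 else -1
        am = abs(mu)
        ae = abs(eta)
        ax = abs(xi)
        cx0 = 2.0 * am / dx
        cy0 = 2.0 * ae / dy
        cz0 = 2.0 * ax / dz
        i0 = 0 if sx > 0 else ni - 1
        j0 = 0 if sy > 0 else nj - 1
        k0 = 0 if sz > 0 else nk - 1
        for ii in range(ni):
            i = i0 + sx * ii
            for jj in range(nj):
                j = j0 + sy * jj
                for kk in range(nk):
                    k = k0 + sz * kk
                    fx = phi[i - sx, j, k] if 0 <= i - sx < ni else 0.0
                    fy = phi[i, j - sy, k] if 0 <= j - sy < nj else 0.0
                    fz = phi[i, j, k - sz] if 0 <= k - sz < nk else 0.0
                    phi[i, j, k] = (
                        cx0 * fx + cy0 * fy + cz0 * fz + q[i, j, k]
                    ) / (cx0 + cy0 + cz0 + sigma[i, j, k])

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False
    _sweep_grid_merged = _sweep_grid_python
    _sweep_grid_plain = None


def _sweep_grid(phi, q, sigma, mu, eta, xi, spacing, merged=None):
    dx, dy, dz = spacing
    if merged is None and _HAVE_NUMBA:
        _sweep_grid_plain(phi, q, sigma, mu, eta, xi, dx, dy, dz)
    elif merged is None:
        _sweep_grid_python(phi, q, sigma, mu, eta, xi, dx, dy, dz, None)
    else:
        _sweep_grid_merged(phi, q, sigma, mu, eta, xi, dx, dy, dz, merged)


def transport_sweep(
    phi_scat: np.ndarray,
    sources: np.ndarray,
    sigma: np.ndarray,
    quadrature: AngularQuadrature,
    spacing: tuple[float, float, float],
    group_order=None,
    merged: np.ndarray | None = None,
) -> np.ndarray:
    """One full sweep: every active ordinate, groups in ``group_order``.

    ``phi_scat``/``sources`` have shape (N, G, I, J, K); ``sigma`` has
    shape (G, I, J, K).  Updates ``phi_scat`` in place and returns it.
    """
    dirs = quadrature.directions(active_only=True)
    n, g = phi_scat.shape[:2]
    if group_order is None:
        group_order = range(g - 1, -1, -1)  # descending energy
    for gi in group_order:
        for ni in range(n):
            mu, eta, xi = dirs[ni]
            _sweep_grid(
                phi_scat[ni, gi], sources[ni, gi], sigma[gi],
                mu, eta, xi, spacing, merged,
            )
    return phi_scat


@dataclass
class AdaptiveMask:
    """Per-voxel flag marking 4x4x4 clusters merged into 10 mm cells."""

    merged: np.ndarray  # bool (I, J, K)
    threshold: float
    n_clusters_merged: int = 0

    def as_uint8(self) -> np.ndarray:
        return self.merged.astype(np.uint8)


def build_adaptive_mask(unscattered: np.ndarray, particle: str) -> AdaptiveMask:
    """Merge 4x4x4 voxel clusters whose unscattered fluence is low.

    A cluster merges when its maximum unscattered fluence (summed over
    ordinates and groups) is below the particle threshold times the
    global maximum.  Partial clusters at grid edges never merge.
    """
    threshold = ADAPTIVE_THRESHOLDS[particle]
    amp = unscattered.sum(axis=(0, 1)) if unscattered.ndim == 5 else unscattered
    gmax = amp.max()
    dims = amp.shape
    merged = np.zeros(dims, dtype=bool)
    count = 0
    if gmax <= 0:
        return AdaptiveMask(merged, threshold, 0)
    for bi in range(0, dims[0] - 3, 4):
        for bj in range(0, dims[1] - 3, 4):
            for bk in range(0, dims[2] - 3, 4):
                block = amp[bi:bi + 4, bj:bj + 4, bk:bk + 4]
                if block.max() < threshold * gmax:
                    merged[bi:bi + 4, bj:bj + 4, bk:bk + 4] = True
                    count += 1
    return AdaptiveMask(merged, threshold, count)


def _grouped_coefficients(diff: np.ndarray, gmap: np.ndarray):
    """Split (N, N, G)-indexed tables into per-(out-group, src-group) blocks.

    Returns {g_out: [(g_src, C), ...]} with C the (N_in, N_out)
    coefficient matrix restricted to transitions g_src -> g_out.
    """
    blocks: dict[int, list] = {}
    g = diff.shape[2]
    for gi in range(g):
        m = gmap[:, :, gi]
        for gs in np.unique(m[m >= 0]):
            coeff = np.where(m == gs, diff[:, :, gi], 0.0)
            if coeff.any():
                blocks.setdefault(int(gi), []).append((int(gs), coeff))
    return blocks


def _contract(coeff: np.ndarray, fluence_flat: np.ndarray) -> np.ndarray:
    """Q_flat[m, v] = sum_n coeff[n, m] * fluence_flat[n, v] via BLAS."""
    return coeff.T @ fluence_flat


def photon_scatter_source(
    fluence: np.ndarray, tables: ComptonTables, rho_e_rel: np.ndarray
) -> np.ndarray:
    """Compton in-scatter source Q[n, g, i, j, k] from total photon fluence.

    Collapses the double integral to a single ordinate sum using the
    kinematic initial-group mapping; invalid transitions contribute
    nothing.
    """
    n, g = fluence.shape[:2]
    dims = fluence.shape[2:]
    rho_abs = (rho_e_rel * WATER_ELECTRONS_PER_MM3).reshape(-1)
    flat = fluence.reshape(n, g, -1)
    q = np.zeros_like(flat)
    blocks = _grouped_coefficients(tables.diff_gamma, tables.init_group)
    for gf, items in blocks.items():
        for gs, coeff in items:
            q[:, gf] += _contract(coeff, flat[:, gs])
        q[:, gf] *= rho_abs
    return q.reshape(fluence.shape)


def electron_fixed_source(
    photon_total: np.ndarray, tables: ComptonTables, rho_e_rel: np.ndarray
) -> np.ndarray:
    """Fixed electron source from Compton interactions of the photon field.

    Transposed-map contraction: ``e_group`` is indexed by the *initial*
    photon group and names the recoil-electron group.
    """
    n = photon_total.shape[0]
    ge = tables.electron_grid.n_groups
    dims = photon_total.shape[2:]
    rho_abs = (rho_e_rel * WATER_ELECTRONS_PER_MM3).reshape(-1)
    flat = photon_total.reshape(n, tables.photon_grid.n_groups, -1)
    q = np.zeros((n, ge, flat.shape[2]), dtype=flat.dtype)
    gp = tables.photon_grid.n_groups
    for gs in range(gp):  # initial photon group
        emap = tables.e_group[:, :, gs]
        for gout in np.unique(emap[emap >= 0]):
            coeff = np.where(emap == gout, tables.diff_e[:, :, gs], 0.0)
            if coeff.any():
                q[:, gout] += _contract(coeff.astype(flat.dtype), flat[:, gs])
    q *= rho_abs
    return q.reshape((n, ge) + dims)


def _moller_source(fluence, tables: ElectronXSTables, rho_e_rel):
    """Moller in-scatter (group-changing) source from electron fluence."""
    n, g = fluence.shape[:2]
    rho_abs = (rho_e_rel * WATER_ELECTRONS_PER_MM3).reshape(-1)
    flat = fluence.reshape(n, g, -1)
    q = np.zeros_like(flat)
    for gs in range(g):
        fmap = tables.moller_group[:, :, gs]
        for gout in np.unique(fmap[fmap >= 0]):
            coeff = np.where(fmap == gout, tables.moller_diff[:, :, gs], 0.0)
            if coeff.any():
                q[:, gout] += _contract(coeff.astype(flat.dtype), flat[:, gs])
    q *= rho_abs
    return q.reshape(fluence.shape)


def _elastic_source(fluence, diff, rho_rel):
    """Within-group elastic source: Q[n,g] = rho * sum_n' diff[n',n,g] phi."""
    n, g = fluence.shape[:2]
    flat = fluence.reshape(n, g, -1)
    q = np.empty_like(flat)
    dd = diff.astype(flat.dtype, copy=False)
    for gi in range(g):
        q[:, gi] = _contract(dd[:, :, gi], flat[:, gi])
    q *= rho_rel.reshape(-1)
    return q.reshape(fluence.shape)


@dataclass
class ConvergenceTrace:
    """Per-iteration probe record (relative to the final iteration)."""

    probes: list = field(default_factory=list)  # (iteration, value)

    def record(self, iteration: int, value: float) -> None:
        self.probes.append((iteration, float(value)))

    def relative(self) -> np.ndarray:
        vals = np.array([v for _, v in self.probes])
        ref = vals[-1] if vals[-1] != 0 else 1.0
        return vals / ref


def solve_photon_transport(
    unscattered: np.ndarray,
    tables: ComptonTables,
    phantom: VoxelPhantom,
    n_iterations: int = 5,
    mask: AdaptiveMask | None = None,
    probe=None,
):
    """Iterate scatter-source build + sweep for the photon field.

    Returns (total, scattered, trace); total = scattered + unscattered
    after each iteration.
    """
    if unscattered.shape[0] != len(tables.quadrature.active):
        raise ValueError("fluence tensor does not match the quadrature")
    g = tables.photon_grid.n_groups
    sigma = (
        tables.tot_gamma[:, None, None, None]
        * (phantom.rho_e * WATER_ELECTRONS_PER_MM3)[None]
    )
    phi_scat = np.zeros_like(unscattered)
    total = unscattered.copy()
    trace = ConvergenceTrace()
    merged = mask.as_uint8() if mask is not None else None
    for it in range(n_iterations):
        q = photon_scatter_source(total, tables, phantom.rho_e)
        transport_sweep(
            phi_scat, q, sigma, tables.quadrature, phantom.spacing_mm,
            merged=merged,
        )
        total = phi_scat + unscattered
        if probe is not None:
            trace.record(it + 1, probe(total))
    return total, phi_scat, trace


def solve_electron_transport(
    q_fix: np.ndarray,
    tables: ElectronXSTables,
    phantom: VoxelPhantom,
    n_iterations: int = 5,
    mask: AdaptiveMask | None = None,
    probe=None,
):
    """Electron transport with the Compton fixed source in the RHS."""
    sigma = (
        tables.moller_tot[:, None, None, None]
        * (phantom.rho_e * WATER_ELECTRONS_PER_MM3)[None]
        + tables.mott_tot()[:, None, None, None] * phantom.rho_c[None]
    )
    phi = np.zeros_like(q_fix)
    trace = ConvergenceTrace()
    merged = mask.as_uint8() if mask is not None else None
    for it in range(n_iterations):
        q = (
            q_fix
            + _moller_source(phi, tables, phantom.rho_e)
            + _elastic_source(phi, tables.mott_diff, phantom.rho_c)
        )
        transport_sweep(
            phi, q, sigma, tables.quadrature, phantom.spacing_mm, merged=merged
        )
        if probe is not None:
            trace.record(it + 1, probe(phi))
    return phi, trace


def solve_proton_transport(
    unscattered: np.ndarray,
    tables: ProtonXSTables,
    phantom: VoxelPhantom,
    n_iterations: int = 5,
    mask: AdaptiveMask | None = None,
    probe=None,
    tau: float = 1.0e-3,
    initial_scattered: np.ndarray | None = None,
):
    """Proton elastic (Mott) transport around the CSDA fixed fluence.

    The scattered field is born from the elastic-loss fraction of the
    fixed (CSDA) fluence - the tau-term deficit of the fixed source -
    and thereafter re-scatters itself, so the in-scatter source reads
    phi_scat + tau * phi_unscat.  ``initial_scattered`` warm-starts the
    iteration (continuing a previous solve is exactly equivalent to one
    longer solve).
    """
    sigma = tables.mott_tot[:, None, None, None] * phantom.rho_c[None]
    if initial_scattered is not None:
        phi_scat = initial_scattered
    else:
        phi_scat = np.zeros_like(unscattered)
    trace = ConvergenceTrace()
    merged = mask.as_uint8() if mask is not None else None
    # birth term from the fixed fluence is constant across iterations
    q_feed = _elastic_source(unscattered, tables.mott_diff, phantom.rho_c)
    q_feed *= tau
    total = unscattered  # alias until the first iteration completes
    for it in range(n_iterations):
        q = _elastic_source(phi_scat, tables.mott_diff, phantom.rho_c)
        q += q_feed
        transport_sweep(
            phi_scat, q, sigma, tables.quadrature, phantom.spacing_mm,
            merged=merged,
        )
        del q
        total = phi_scat + unscattered
        if probe is not None:
            trace.record(it + 1, probe(total))
    return total, phi_scat, trace
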