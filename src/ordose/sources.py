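"""Unscattered (fixed) fluence models and the spatial-uncertainty kernel.

The beam axis is +z; the source sits on the axis at z = -SSD (phantom
surface at z = 0) and the isocentre plane at z = SAD - SSD.  Divergent
geometry is handled by projecting voxel positions onto the isocentre
plane and by an obliquity factor on the depth coordinate; this is a
fast equivalent of per-voxel Siddon tracing that is exact on the axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from . import materials
from .phantoms import VoxelPhantom
from .quadrature import AngularQuadrature, EnergyGrid, assign_beam_to_ordinates

log = logging.getLogger(__name__)

__all__ = [
    "PhotonHeadModel",
    "ProtonBeamModel",
    "UncertaintyKernel",
    "photon_unscattered_fluence",
    "proton_unscattered_fluence",
    "distribute_unscattered",
    "sobp_layer_weights",
    "csda_energy_map",
    "build_uncertainty_kernel",
    "identity_kernel",
    "radiological_depth",
]

# plausible 6 MV flattened spectrum on the photon group energies (relative
# weights; not vendor data)
_DEFAULT_6MV_SPECTRUM = {
    0.5: 0.12, 1.0: 0.18, 1.5: 0.17, 2.0: 0.14, 2.5: 0.11, 3.0: 0.09,
    3.5: 0.07, 4.0: 0.05, 5.0: 0.04, 6.0: 0.03, 7.0: 0.0, 8.0: 0.0,
    9.0: 0.0, 10.0: 0.0,
}


@dataclass
class PhotonHeadModel:
    """Dual-source photon head model (primary + head-scatter source)."""

    field_mm: tuple[float, float] = (100.0, 100.0)
    sad_mm: float = 1000.0
    ssd_mm: float = 850.0
    primary_sigma_mm: tuple[float, float] = (0.8, 1.0)  # width, length (std dev)
    secondary_sigma_mm: tuple[float, float] = (18.0, 18.0)
    secondary_distance_mm: float = 150.0  # below the primary source
    secondary_weight: float = 0.10
    collimator_mm: float = 500.0  # effective collimation plane from source
    spectrum: dict = field(default_factory=lambda: dict(_DEFAULT_6MV_SPECTRUM))
    mu_prime: float = 0.0  # off-axis softening, 1/mm^2
    couch_deg: float = 0.0
    gantry_deg: float = 0.0

    def spectrum_weights(self, grid: EnergyGrid) -> np.ndarray:
        w = np.array([self.spectrum.get(float(e), 0.0) for e in grid.group_energy])
        if w.sum() <= 0:
            raise ValueError("beam spectrum has no weight on the energy grid")
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        return w / w.sum()

    def _sigma_iso(self, sigma_src: float, src_to_coll: float) -> float:
        # geometric penumbra of a Gaussian source collimated at src_to_coll
        return sigma_src * (self.sad_mm - src_to_coll) / src_to_coll

    def aperture_convolved(self, x_iso: np.ndarray, y_iso: np.ndarray) -> np.ndarray:
        """(omega (x) s) * psi at the isocentre plane.

        The aperture step convolved with each Gaussian source, weighted
        by the source intensities; psi (the in-air profile) defaults to a
        flat unit profile.
        """
        out = np.zeros(np.broadcast(x_iso, y_iso).shape)
        sources = [
            (1.0 - self.secondary_weight, self.primary_sigma_mm, 0.0),
            (self.secondary_weight, self.secondary_sigma_mm, self.secondary_distance_mm),
        ]
        for wgt, (sx, sy), dist in sources:
            if wgt <= 0.0:
                continue
            s2c = max(self.collimator_mm - dist, 1.0)
            ex = _edge_profile(x_iso, self.field_mm[0], self._sigma_iso(sx, s2c))
            ey = _edge_profile(y_iso, self.field_mm[1], self._sigma_iso(sy, s2c))
            out = out + wgt * ex * ey
        return out


def _edge_profile(u: np.ndarray, field: float, sigma: float) -> np.ndarray:
    """1-D step aperture of width ``field`` convolved with a Gaussian."""
    if sigma <= 1e-9:
        return ((np.abs(u) <= field / 2.0)).astype(float)
    a = (field / 2.0 - u) / (np.sqrt(2.0) * sigma)
    b = (field / 2.0 + u) / (np.sqrt(2.0) * sigma)
    return 0.5 * (erf(a) + erf(b))


@dataclass
class ProtonBeamModel:
    """Passively scattered proton beam model."""

    field_mm: tuple[float, float] = (100.0, 100.0)
    sad_mm: float = 2300.0
    ssd_mm: float = 2150.0
    source_sigma_mm: tuple[float, float] = (30.0, 30.0)
    pencil_sigma_mm: float = 5.0  # arcs: 10 mm = two standard deviations
    collimator_mm: float = 2000.0
    sobp_span_mm: tuple[float, float] | None = (100.0, 200.0)
    n_layers: int = 12
    layers: tuple | None = None  # ((energy_mev, weight), ...) overrides span
    lam: float = 5.0e-4  # nuclear fluence loss per mm radiological path
    tau: float = 1.0e-3  # elastic fluence loss coefficient
    apply_aperture: bool = True  # passive scattering collimates the field
    couch_deg: float = 0.0
    gantry_deg: float = 0.0

    def energy_layers(self) -> tuple:
        if self.layers is not None:
            return tuple(self.layers)
        r_lo, r_hi = self.sobp_span_mm
        energies, weights = sobp_layer_weights(r_lo, r_hi, self.n_layers)
        return tuple(zip(energies.tolist(), weights.tolist()))

    def _sigma_iso(self, sigma_src: float) -> float:
        s2c = max(self.collimator_mm, 1.0)
        return sigma_src * (self.sad_mm - s2c) / s2c

    def lateral_profile(self, x_iso: np.ndarray, y_iso: np.ndarray) -> np.ndarray:
        """(psi (x) s), optionally collimated by the aperture step."""
        if self.apply_aperture:
            ex = _edge_profile(x_iso, self.field_mm[0], self._sigma_iso(self.source_sigma_mm[0]))
            ey = _edge_profile(y_iso, self.field_mm[1], self._sigma_iso(self.source_sigma_mm[1]))
            return ex * ey
        return np.ones(np.broadcast(x_iso, y_iso).shape)


def beam_to_json(beam) -> str:
    """Serialise a beam model (photon or proton) to JSON."""
    from dataclasses import asdict

    kind = "photon" if isinstance(beam, PhotonHeadModel) else "proton"
    payload = {"kind": kind, **asdict(beam)}
    return json.dumps(payload, indent=2)


def beam_from_json(text: str):
    """Rebuild a beam model from :func:`beam_to_json` output."""
    payload = json.loads(text)
    kind = payload.pop("kind")
    cls = PhotonHeadModel if kind == "photon" else ProtonBeamModel
    for key in ("field_mm", "primary_sigma_mm", "secondary_sigma_mm",
                "source_sigma_mm", "sobp_span_mm"):
        if payload.get(key) is not None:
            payload[key] = tuple(payload[key])
    if payload.get("layers") is not None:
        payload["layers"] = tuple(tuple(l) for l in payload["layers"])
    if payload.get("spectrum") is not None:
        payload["spectrum"] = {float(k): v for k, v in payload["spectrum"].items()}
    return cls(**payload)


def sobp_layer_weights(r_min_mm: float, r_max_mm: float, n_layers: int):
    """Energy layers and weights for a flat spread-out Bragg peak.

    Layer ranges are evenly spaced over [r_min, r_max]; weights follow
    the discrete power-law superposition rule (deepest layer heaviest),
    then each layer is corrected by (d/R)^0.7 with d the layer's own
    range and R the deepest range.  Weights are normalised to unit sum.
    """
    if n_layers < 1:
        raise ValueError("need at least one energy layer")
    if r_min_mm >= r_max_mm and n_layers > 1:
        raise ValueError("degenerate range span")
    p = materials.P_EXPONENT
    q = 1.0 - 1.0 / p
    if n_layers == 1:
        return np.array([materials.energy_from_range(r_max_mm)]), np.array([1.0])
    ranges = np.linspace(r_min_mm, r_max_mm, n_layers)
    step = ranges[1] - ranges[0]
    w = np.empty(n_layers)
    for k, r in enumerate(ranges):
        hi = r_max_mm - r + step / 2.0
        lo = max(r_max_mm - r - step / 2.0, 0.0)
        w[k] = hi**q - lo**q
    w *= (ranges / r_max_mm) ** 0.7
    w = np.maximum(w, 0.0)
    energies = materials.energy_from_range(ranges)
    return energies, w / w.sum()


def _beam_geometry(phantom: VoxelPhantom, sad_mm: float, ssd_mm: float):
    """Isocentre-plane coordinates, source distances and obliquity.

    Returns (x_iso[i], y_iso[j], z_src[k], sec[i,j,k]) with z_src the
    axial source distance of each depth plane and sec the path-obliquity
    factor of the ray through each voxel.
    """
    x = phantom.axis_coords(0) - phantom.size_mm[0] / 2.0
    y = phantom.axis_coords(1) - phantom.size_mm[1] / 2.0
    z = phantom.axis_coords(2)
    z_src = ssd_mm + z  # axial distance from source
    scale = sad_mm / z_src  # voxel -> isocentre-plane magnification
    x_iso = x[:, None, None] * scale[None, None, :]
    y_iso = y[None, :, None] * scale[None, None, :]
    r2 = x[:, None, None] ** 2 + y[None, :, None] ** 2
    sec = np.sqrt(1.0 + r2 / z_src[None, None, :] ** 2)
    return x_iso, y_iso, z_src, sec


def radiological_depth(phantom: VoxelPhantom, density: np.ndarray, sec: np.ndarray) -> np.ndarray:
    """Equivalent path length from the surface to each voxel centre, mm.

    Accumulates density along z columns and applies the ray-obliquity
    factor (axis-exact divergent-ray approximation).
    """
    h = phantom.spacing_mm[2]
    cum = np.cumsum(density, axis=2) * h
    centre = cum - 0.5 * density * h
    return centre * sec


def photon_unscattered_fluence(
    beam: PhotonHeadModel,
    phantom: VoxelPhantom,
    grid: EnergyGrid,
    attenuation: materials.AttenuationTable | None = None,
) -> np.ndarray:
    """Per-group, per-voxel unscattered photon fluence, shape (G, I, J, K)."""
    attenuation = attenuation or materials.water_attenuation_table(beam.mu_prime)
    x_iso, y_iso, z_src, sec = _beam_geometry(phantom, beam.sad_mm, beam.ssd_mm)
    aperture = beam.aperture_convolved(x_iso, y_iso)
    if aperture.max() <= 0.0:
        log.warning("beam aperture does not intersect the phantom")
    z_rad = radiological_depth(phantom, phantom.rho_e, sec)
    inv_sq = 1.0 / z_src**2
    eta = beam.spectrum_weights(grid)
    r_off = np.sqrt(x_iso**2 + y_iso**2)
    out = np.zeros((grid.n_groups,) + phantom.dims)
    for g in range(grid.n_groups):
        if eta[g] <= 0.0:
            continue
        mu0 = attenuation.mu0(grid.group_energy[g])
        att = np.exp(-mu0 * z_rad - attenuation.mu_prime * r_off * z_rad)
        out[g] = inv_sq[None, None, :] * aperture * eta[g] * att
    return out


def csda_energy_map(
    rho_line: np.ndarray,
    step_mm: float,
    e0_mev: float,
    stopping=None,
    substeps: int = 8,
) -> np.ndarray:
    """Residual proton energy at successive sample points along a ray.

    Recursion e(r+dr) = e(r) - dr * rho * S(e), refined with ``substeps``
    sub-intervals per sample and clamped at zero.  ``rho_line`` holds the
    mass density at each sample; the first returned value corresponds to
    half a step inside the medium.
    """
    if stopping is None:
        stopping = materials.bragg_kleeman_stopping_power
    arr = np.atleast_2d(np.asarray(rho_line, dtype=float))
    squeeze = np.asarray(rho_line).ndim == 1
    n_ray, n_pt = arr.shape
    e = np.full(n_ray, float(e0_mev))
    out = np.zeros((n_ray, n_pt))
    ds_cm = step_mm / substeps / 10.0
    record_at = substeps // 2  # sample point sits mid-interval
    for i in range(n_pt):
        rho_i = arr[:, i]
        for sub in range(substeps):
            if sub == record_at:
                out[:, i] = e
            alive = e > 0.0
            if not alive.any():
                continue
            s = np.where(alive, stopping(np.maximum(e, 1e-3)), 0.0)
            e = np.maximum(e - rho_i * s * ds_cm, 0.0)
    return out[0] if squeeze else out


def proton_unscattered_fluence(
    beam: ProtonBeamModel,
    phantom: VoxelPhantom,
    grid: EnergyGrid,
    mott_tot: np.ndarray | None = None,
    substeps: int = 8,
) -> np.ndarray:
    """Per-group, per-voxel fixed proton fluence, shape (G, I, J, K).

    Each energy layer is slowed down along rays (CSDA); fluence lands in
    the group containing the local residual energy, resolved at
    sub-voxel steps so a voxel traversed by several groups (or in which
    the proton stops) receives the path-fraction of each.  The published
    linear nuclear-loss (lambda * radiological depth) and elastic-loss
    (tau * sigma_Mott_tot) deficits are applied and floored at zero;
    residual energies below the grid deposit in the lowest group while
    positive.
    """
    x_iso, y_iso, z_src, sec = _beam_geometry(phantom, beam.sad_mm, beam.ssd_mm)
    lateral = beam.lateral_profile(x_iso, y_iso)
    inv_sq = 1.0 / z_src**2
    h = phantom.spacing_mm[2]
    dims = phantom.dims
    n_col = dims[0] * dims[1]
    n_vox = dims[2]
    n_grp = grid.n_groups
    if mott_tot is None:
        mott_tot = np.zeros(n_grp)
    clamped = False
    rho_cols = phantom.rho.reshape(n_col, n_vox)
    rho_sub = np.repeat(rho_cols, substeps, axis=1)
    sec_sub = np.repeat(sec.reshape(n_col, n_vox), substeps, axis=1)
    h_sub = h / substeps
    # radiological depth at sub-sample midpoints
    z_rad_sub = (np.cumsum(rho_sub, axis=1) - 0.5 * rho_sub) * h_sub * sec_sub
    base = (inv_sq[None, None, :] * lateral).reshape(n_col, n_vox)
    base_sub = np.repeat(base, substeps, axis=1) / substeps
    vox_idx = np.repeat(np.arange(n_vox), substeps)[None, :]
    col_idx = np.arange(n_col)[:, None]
    out = np.zeros(n_grp * n_col * n_vox)
    for e0, eta in beam.energy_layers():
        if eta <= 0.0:
            continue
        # the range-consistent stopping model integrates exactly: the
        # residual range falls linearly with radiological path, so the
        # slowing-down recursion has the closed form below
        r_res = materials.csda_range(e0) - z_rad_sub
        valid = r_res > 0.0
        e_sub = np.where(
            valid, materials.energy_from_range(np.maximum(r_res, 1e-12)), 0.0
        )
        g_sub = grid.group_of(np.maximum(e_sub, grid.lower_bound[0] + 1e-9))
        g_sub = np.maximum(g_sub, 0)
        loss = 1.0 - beam.lam * z_rad_sub - beam.tau * mott_tot[g_sub]
        if np.any((loss < 0.0) & valid):
            clamped = True
        loss = np.maximum(loss, 0.0)
        contrib = eta * base_sub * loss
        flat = (g_sub * n_col + col_idx) * n_vox + vox_idx
        out += np.bincount(
            flat[valid].ravel(), weights=contrib[valid].ravel(),
            minlength=out.size,
        )
    if clamped:
        log.info("proton loss factor clamped at zero at extreme depth")
    return out.reshape((n_grp,) + dims)


@dataclass(frozen=True)
class UncertaintyKernel:
    """Discrete positional-uncertainty kernel (offsets in mm)."""

    offsets_mm: np.ndarray  # (M, 3)
    probabilities: np.ndarray  # (M,)
    raw_points: int = 1

    def __post_init__(self) -> None:
        if np.any(self.probabilities < 0):
            raise ValueError("kernel probabilities must be non-negative")

    def __len__(self) -> int:
        return len(self.probabilities)


def identity_kernel() -> UncertaintyKernel:
    return UncertaintyKernel(np.zeros((1, 3)), np.ones(1), raw_points=1)


def build_uncertainty_kernel(p_x, p_y, p_z, max_points: int = 64) -> UncertaintyKernel:
    """Outer-product kernel on the +-16 mm / 2 mm offset grid, resampled.

    The three axis distributions (17 values each) form a 17^3 = 4913
    point kernel; the points are cast onto the regular 2 mm grid (on
    which they already lie) and the ``max_points`` highest-probability
    points are retained, probabilities rescaled to sum to one.  Ties are
    broken by lexicographic offset order, so construction is
    deterministic.
    """
    axes = []
    for p in (p_x, p_y, p_z):
        a = np.asarray(p, dtype=float)
        if a.ndim != 1 or len(a) != 17:
            raise ValueError("each axis distribution needs 17 values (-16..16 mm)")
        if np.any(a < 0):
            raise ValueError("axis probabilities must be non-negative")
        if a.sum() <= 0:
            raise ValueError("axis distribution is all zero")
        axes.append(a / a.sum())
    offsets_1d = np.arange(-16.0, 16.0 + 1e-9, 2.0)
    prob = np.einsum("i,j,k->ijk", *axes)
    pts = np.stack(np.meshgrid(offsets_1d, offsets_1d, offsets_1d, indexing="ij"), axis=-1)
    flat_p = prob.reshape(-1)
    flat_o = pts.reshape(-1, 3)
    raw_points = flat_p.size
    # stable selection: sort by (-p, x, y, z)
    order = np.lexsort((flat_o[:, 2], flat_o[:, 1], flat_o[:, 0], -flat_p))
    keep = order[: min(max_points, raw_points)]
    keep = keep[flat_p[keep] > 0.0]
    probs = flat_p[keep]
    return UncertaintyKernel(flat_o[keep], probs / probs.sum(), raw_points=raw_points)


def distribute_unscattered(
    fluence: np.ndarray,
    beam_couch: float,
    beam_gantry: float,
    quadrature: AngularQuadrature,
    kernel: UncertaintyKernel | None = None,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Spread (G, I, J, K) fluence over ordinates and kernel offsets.

    Returns the unscattered fluence tensor (N_active, G, I, J, K).  The
    angular split follows the four-ordinate bilinear rule; the spatial
    split shifts the fluence by each kernel offset (rounded to whole
    voxels), losing only the mass shifted outside the grid.
    """
    kernel = kernel or identity_kernel()
    pairs = assign_beam_to_ordinates(beam_couch, beam_gantry, quadrature)
    active_index = {id(o): i for i, o in enumerate(quadrature.active)}
    # map full-ordinate index -> active index (pole duplicates excluded)
    full_to_active = {}
    for i, o in enumerate(quadrature.ordinates):
        if o.weight > 0.0:
            full_to_active[i] = active_index[id(o)]
    n_active = len(quadrature.active)
    shifted = np.zeros_like(fluence)
    for off, p in zip(kernel.offsets_mm, kernel.probabilities):
        vox = tuple(int(round(off[a] / spacing_mm[a])) for a in range(3))
        shifted += p * _shift3(fluence, vox)
    out = np.zeros((n_active,) + fluence.shape)
    for idx, frac in pairs:
        if idx not in full_to_active:
            raise KeyError("beam assigned to a zero-weight ordinate")
        out[full_to_active[idx]] += frac * shifted
    return out


def _shift3(arr: np.ndarray, vox: tuple[int, int, int]) -> np.ndarray:
    """Shift the last three axes by whole voxels, zero-filling."""
    out = arr
    for axis, s in enumerate(vox):
        if s == 0:
            continue
        ax = arr.ndim - 3 + axis
        out = np.roll(out, s, axis=ax)
        sl = [slice(None)] * out.ndim
        sl[ax] = slice(0, s) if s > 0 else slice(s, None)
        out[tuple(sl)] = 0.0
    return out
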