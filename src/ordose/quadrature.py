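"""Angular quadratures on the gantry/couch sphere and multigroup energy grids.

Directions are labelled by IEC61217-style couch and gantry angles.  The
mapping to Cartesian direction cosines uses the convention

    mu  = sin(g) * cos(c)
    eta = sin(g) * sin(c)
    xi  = cos(g)

i.e. the gantry angle is the polar angle measured from the +z axis (the
nominal beam axis at gantry 0) and the couch angle is the azimuth in the
transaxial (x, y) plane.  Only self-consistency of this mapping is
guaranteed, not absolute room orientation.

Two quadratures are provided:

* the *standard* quadrature: 4 couch x 8 gantry angles with the ordinates
  at gantry 0 and 180 degrees collapsed onto couch 0 (26 distinct
  directions carry non-zero weight, each 4*pi/32 sr).  Note that the
  weights as defined sum to 26*4*pi/32 = 3.25*pi, not 4*pi; this is the
  published definition and the empirical cross-section factors absorb the
  normalisation.
* the *fine* quadrature: 18 couch x 36 gantry angles at 10 degree spacing
  with sin(g) solid-angle weighting, w0 = 2*pi^2/(C*G).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DirectionOrdinate",
    "AngularQuadrature",
    "EnergyGrid",
    "direction_from_angles",
    "angles_from_direction",
    "build_standard_angular_quadrature",
    "build_fine_angular_quadrature",
    "build_energy_grid",
    "assign_beam_to_ordinates",
]

STANDARD_GANTRY_DEG = (0.0, 47.5, 90.0, 132.5, 180.0, 227.5, 270.0, 312.5)
STANDARD_COUCH_DEG = (270.0, 315.0, 0.0, 45.0)


def direction_from_angles(couch_deg: float, gantry_deg: float) -> np.ndarray:
    """Unit direction vector (mu, eta, xi) for a couch/gantry angle pair."""
    c = math.radians(couch_deg)
    g = math.radians(gantry_deg)
    return np.array(
        [math.sin(g) * math.cos(c), math.sin(g) * math.sin(c), math.cos(g)]
    )


def angles_from_direction(direction: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`direction_from_angles`; couch is 0 at the poles."""
    mu, eta, xi = (float(v) for v in direction)
    g = math.degrees(math.acos(max(-1.0, min(1.0, xi))))
    c = math.degrees(math.atan2(eta, mu)) % 360.0
    if g in (0.0, 180.0):
        c = 0.0
    return c, g


@dataclass(frozen=True)
class DirectionOrdinate:
    couch_deg: float
    gantry_deg: float
    mu: float
    eta: float
    xi: float
    weight: float

    def __post_init__(self) -> None:
        norm = self.mu**2 + self.eta**2 + self.xi**2
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"direction cosines not unit length: {norm}")
        if self.weight < 0.0:
            raise ValueError("ordinate weight must be non-negative")

    @property
    def direction(self) -> np.ndarray:
        return np.array([self.mu, self.eta, self.xi])


@dataclass(frozen=True)
class AngularQuadrature:
    ordinates: tuple[DirectionOrdinate, ...]
    kind: str
    n_couch: int
    n_gantry: int
    couch_angles: tuple[float, ...] = field(default=())
    gantry_angles: tuple[float, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.ordinates)

    @property
    def active(self) -> tuple[DirectionOrdinate, ...]:
        """Ordinates carrying non-zero weight (the transport set)."""
        return tuple(o for o in self.ordinates if o.weight > 0.0)

    def directions(self, active_only: bool = True) -> np.ndarray:
        ords = self.active if active_only else self.ordinates
        return np.array([[o.mu, o.eta, o.xi] for o in ords])

    def weights(self, active_only: bool = True) -> np.ndarray:
        ords = self.active if active_only else self.ordinates
        return np.array([o.weight for o in ords])

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "n_couch": self.n_couch,
            "n_gantry": self.n_gantry,
            "ordinates": [
                {
                    "couch_deg": o.couch_deg,
                    "gantry_deg": o.gantry_deg,
                    "mu": o.mu,
                    "eta": o.eta,
                    "xi": o.xi,
                    "weight_sr": o.weight,
                }
                for o in self.ordinates
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AngularQuadrature":
        payload = json.loads(text)
        ords = tuple(
            DirectionOrdinate(
                couch_deg=o["couch_deg"],
                gantry_deg=o["gantry_deg"],
                mu=o["mu"],
                eta=o["eta"],
                xi=o["xi"],
                weight=o["weight_sr"],
            )
            for o in payload["ordinates"]
        )
        couch = tuple(sorted({o.couch_deg for o in ords}))
        gantry = tuple(sorted({o.gantry_deg for o in ords}))
        return cls(
            ordinates=ords,
            kind=payload["kind"],
            n_couch=payload["n_couch"],
            n_gantry=payload["n_gantry"],
            couch_angles=couch,
            gantry_angles=gantry,
        )


def build_standard_angular_quadrature() -> AngularQuadrature:
    """The 4 couch x 8 gantry quadrature with pole collapse.

    Ordinates at gantry 0/180 with couch != 0 duplicate the polar
    directions and receive weight 0; all other ordinates receive the
    uniform weight 4*pi/(C*G).
    """
    n_couch = len(STANDARD_COUCH_DEG)
    n_gantry = len(STANDARD_GANTRY_DEG)
    w_uniform = 4.0 * math.pi / (n_couch * n_gantry)
    ordinates = []
    for c in STANDARD_COUCH_DEG:
        for g in STANDARD_GANTRY_DEG:
            pole = g in (0.0, 180.0)
            weight = 0.0 if (pole and c != 0.0) else w_uniform
            # at the poles every couch angle maps to the same direction;
            # the weighted representative is the couch-0 ordinate
            mu, eta, xi = direction_from_angles(0.0 if pole else c, g)
            ordinates.append(
                DirectionOrdinate(c, g, float(mu), float(eta), float(xi), weight)
            )
    return AngularQuadrature(
        ordinates=tuple(ordinates),
        kind="standard",
        n_couch=n_couch,
        n_gantry=n_gantry,
        couch_angles=STANDARD_COUCH_DEG,
        gantry_angles=STANDARD_GANTRY_DEG,
    )


def build_fine_angular_quadrature() -> AngularQuadrature:
    """18 couch x 36 gantry ordinates at 10 degree spacing.

    Weights follow w(c, g) = w0 * sin(g) with w0 = 2*pi^2/(C*G), so the
    ordinates at gantry 90 degrees carry exactly w0 and those at gantry
    0/180 carry zero weight.
    """
    n_couch, n_gantry = 18, 36
    couch_angles = tuple(10.0 * i for i in range(n_couch))  # 0..170
    gantry_angles = tuple(10.0 * i for i in range(n_gantry))  # 0..350
    w0 = 2.0 * math.pi**2 / (n_couch * n_gantry)
    ordinates = []
    for c in couch_angles:
        for g in gantry_angles:
            # |sin|: the gantry angle is the polar angle and runs to 360,
            # so the solid-angle factor is the magnitude of sin(g)
            weight = w0 * abs(math.sin(math.radians(g)))
            if weight < 1e-15:  # sin(pi) rounding at the poles
                weight = 0.0
            mu, eta, xi = direction_from_angles(c, g)
            ordinates.append(
                DirectionOrdinate(c, g, float(mu), float(eta), float(xi), weight)
            )
    return AngularQuadrature(
        ordinates=tuple(ordinates),
        kind="fine",
        n_couch=n_couch,
        n_gantry=n_gantry,
        couch_angles=couch_angles,
        gantry_angles=gantry_angles,
    )


@dataclass(frozen=True)
class EnergyGrid:
    """Multigroup energy grid with mid-way boundaries.

    ``group_energy`` is strictly increasing.  ``f_e`` is the constant
    within-group spectral density 1/(E+ - E-), so the integral of the
    continuous fluence over a group equals the group fluence exactly.
    """

    particle: str
    group_energy: np.ndarray  # MeV, strictly increasing
    upper_bound: np.ndarray
    lower_bound: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.group_energy, dtype=float)
        if not np.all(np.diff(e) > 0):
            raise ValueError("group energies must be strictly increasing")

    @property
    def n_groups(self) -> int:
        return len(self.group_energy)

    @property
    def f_e(self) -> np.ndarray:
        return 1.0 / (self.upper_bound - self.lower_bound)

    def group_of(self, energy_mev):
        """Group index containing ``energy_mev``; -1 outside the grid span.

        Accepts scalars or arrays.
        """
        e = np.asarray(energy_mev, dtype=float)
        idx = np.searchsorted(self.upper_bound, e, side="left")
        idx = np.clip(idx, 0, self.n_groups - 1)
        bad = (e < self.lower_bound[0]) | (e > self.upper_bound[-1])
        out = np.where(bad, -1, idx)
        if np.isscalar(energy_mev):
            return int(out)
        return out.astype(np.int64)

    def to_json(self) -> str:
        return json.dumps(
            {
                "particle": self.particle,
                "group_energy_mev": self.group_energy.tolist(),
                "upper_bound_mev": self.upper_bound.tolist(),
                "lower_bound_mev": self.lower_bound.tolist(),
            },
            indent=2,
        )


def _midway_bounds(energies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mids = 0.5 * (energies[:-1] + energies[1:])
    lower = np.concatenate([[energies[0] - (mids[0] - energies[0])], mids])
    upper = np.concatenate([mids, [energies[-1] + (energies[-1] - mids[-1])]])
    return upper, lower


def build_energy_grid(particle: str) -> EnergyGrid:
    """Energy grid per particle kind.

    * ``photon``: 0.5 MeV steps up to 4.0 MeV then 1.0 MeV steps to
      10.0 MeV (14 groups).
    * ``proton``: 5 MeV steps from 5 to 250 MeV (50 groups).
    * ``electron``: reuses the photon grid (configurable upstream).
    """
    if particle in ("photon", "electron"):
        energies = np.concatenate(
            [np.arange(0.5, 4.0 + 1e-9, 0.5), np.arange(5.0, 10.0 + 1e-9, 1.0)]
        )
    elif particle == "proton":
        energies = np.arange(5.0, 250.0 + 1e-9, 5.0)
    else:
        raise ValueError(f"unknown particle kind: {particle!r}")
    upper, lower = _midway_bounds(energies)
    return EnergyGrid(
        particle=particle, group_energy=energies, upper_bound=upper, lower_bound=lower
    )


def _bracket(angles: np.ndarray, value: float, period: float = 360.0):
    """Indices and angles of the two grid angles bracketing ``value``.

    The angle axis is treated as periodic; the returned pair (a1, a2)
    satisfies a1 <= v <= a2 on the unwrapped axis.
    """
    base = np.sort(np.unique(np.asarray(angles, dtype=float) % period))
    v = value % period
    hi = int(np.searchsorted(base, v, side="right"))
    lo = hi - 1
    if hi == len(base):  # wrap: between last angle and first + period
        a1, a2 = base[-1], base[0] + period
        i1, i2 = len(base) - 1, 0
    elif lo < 0:
        a1, a2 = base[-1] - period, base[0]
        i1, i2 = len(base) - 1, 0
    else:
        a1, a2 = base[lo], base[hi]
        i1, i2 = lo, hi
    return (i1, a1), (i2, a2), base, v


def assign_beam_to_ordinates(
    beam_couch: float, beam_gantry: float, quadrature: AngularQuadrature
) -> list[tuple[int, float]]:
    """Bilinear split of a beam orientation over the four nearest ordinates.

    Returns up to four ``(ordinate_index, fraction)`` pairs indexing the
    quadrature's full ordinate list.  Fractions are non-negative and sum
    to one; degenerate pairs (beam exactly on a grid angle) collapse.
    Pole ordinates (weight 0 duplicates) are redirected to the canonical
    couch-0 ordinate of the same gantry angle.  Only gantry angles whose
    ring carries weight take part in the bracketing (the sin-weighted
    fine quadrature has weightless rings at gantry 0/180).
    """
    weighted_gantry = sorted(
        {o.gantry_deg for o in quadrature.ordinates if o.weight > 0.0}
    )
    (ig1, g1), (ig2, g2), gantry_base, gval = _bracket(
        np.array(weighted_gantry), beam_gantry
    )
    (ic1, c1), (ic2, c2), couch_base, cval = _bracket(
        np.array(quadrature.couch_angles), beam_couch
    )

    if g2 == g1:
        fg1, fg2 = 1.0, 0.0
    else:
        # place value on the unwrapped axis between g1 and g2
        v = gval
        if v < g1:
            v += 360.0
        fg1 = (g2 - v) / (g2 - g1)
        fg2 = (v - g1) / (g2 - g1)
    if c2 == c1:
        fc1, fc2 = 1.0, 0.0
    else:
        v = cval
        if v < c1:
            v += 360.0
        fc1 = (c2 - v) / (c2 - c1)
        fc2 = (v - c1) / (c2 - c1)

    # map (couch angle, gantry angle) back to an index in the ordinate list
    lut: dict[tuple[float, float], int] = {}
    for idx, o in enumerate(quadrature.ordinates):
        lut.setdefault((o.couch_deg % 360.0, o.gantry_deg % 360.0), idx)

    def locate(c_ang: float, g_ang: float) -> int:
        g_ang = g_ang % 360.0
        c_ang = c_ang % 360.0
        if g_ang in (0.0, 180.0):
            c_ang = 0.0  # pole collapse
        if (c_ang, g_ang) in lut:
            return lut[(c_ang, g_ang)]
        raise KeyError(f"no ordinate at couch={c_ang}, gantry={g_ang}")

    raw = [
        (locate(couch_base[ic1], gantry_base[ig1]), fg1 * fc1),
        (locate(couch_base[ic1], gantry_base[ig2]), fg2 * fc1),
        (locate(couch_base[ic2], gantry_base[ig1]), fg1 * fc2),
        (locate(couch_base[ic2], gantry_base[ig2]), fg2 * fc2),
    ]
    merged: dict[int, float] = {}
    for idx, frac in raw:
        if frac > 0.0:
            merged[idx] = merged.get(idx, 0.0) + frac
    return sorted(merged.items())
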